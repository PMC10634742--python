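"""Synthetic light-sheet-like axon cubes with dense ground truth.

Real training data for axon segmentation are annotated sub-volumes of a
cleared whole brain: a 160-voxel labeled cube embedded in a 188-voxel
padded source cube, with manual annotation only on every 20th z-slice
starting at slice 15. No public accession exists for such data, so this
module fabricates geometrically comparable scenes — bright tubular
"axons" wandering through a dim noisy background, plus optional bright
blob artifacts — along with dense voxel-accurate labels that can then be
sparsified to the same slice scheme.

Tubes are piecewise-linear random walks with a bounded turning angle,
dilated with a spherical structuring element; this approximates axonal
textures of differing density without modelling any specific
neurotransmitter system's morphology. No optical PSF is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .labels import ARTIFACT, AXON, BACKGROUND, UNLABELED

_MAX_INTENSITY = 65535


@dataclass(frozen=True)
class PhantomConfig:
    """Scene parameters for one synthetic cube.

    Intensities are on the raw 16-bit camera scale (0–65535). Defaults
    emulate sparsely labeled fluorescent axons: mean foreground ~10x the
    background with shot-noise-scale Gaussian noise.
    """

    cube_edge: int = 160
    pad: int = 14
    n_tubes: int = 8
    tube_radius: tuple[int, int] = (1, 3)
    axon_intensity_mean: float = 12000.0
    background_intensity_mean: float = 1200.0
    artifact_intensity_mean: float = 18000.0
    noise_sd: float = 600.0
    n_artifact_blobs: int = 2
    seed: int = 0
    # random-walk geometry (voxels / radians per step)
    step_length: float = 4.0
    turn_sd: float = 0.35
    max_steps: int = field(default=400, repr=False)

    def __post_init__(self) -> None:
        if self.cube_edge <= 0:
            raise ValueError("cube_edge must be positive")
        if self.pad < 0:
            raise ValueError("pad must be >= 0")
        lo, hi = self.tube_radius
        if lo < 0 or hi < lo:
            raise ValueError("tube_radius must be a nondecreasing (lo, hi) pair")
        if hi >= self.cube_edge / 2:
            raise ValueError("tube radius must be < cube_edge / 2")
        if self.axon_intensity_mean <= self.background_intensity_mean:
            raise ValueError("axon mean intensity must exceed background mean")
        if self.n_tubes < 0 or self.n_artifact_blobs < 0:
            raise ValueError("object counts must be >= 0")

    @property
    def padded_edge(self) -> int:
        return self.cube_edge + 2 * self.pad


def _ball(radius: int) -> np.ndarray:
    if radius <= 0:
        return np.ones((1, 1, 1), dtype=bool)
    r = int(radius)
    zz, yy, xx = np.mgrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return zz * zz + yy * yy + xx * xx <= r * r


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _walk_tube(rng: np.random.Generator, edge: int, cfg: PhantomConfig) -> np.ndarray:
    """Rasterize one random-walk polyline into a boolean centreline mask."""
    mask = np.zeros((edge, edge, edge), dtype=bool)
    pos = rng.uniform(0, edge, size=3)
    direction = _random_unit(rng)
    for _ in range(cfg.max_steps):
        nxt = pos + direction * cfg.step_length
        # dense sampling along the segment so the centreline has no gaps
        n_pts = max(2, int(np.ceil(cfg.step_length / 0.5)))
        pts = pos[None, :] + np.linspace(0.0, 1.0, n_pts)[:, None] * (nxt - pos)
        idx = np.round(pts).astype(int)
        inside = np.all((idx >= 0) & (idx < edge), axis=1)
        if inside.any():
            keep = idx[inside]
            mask[keep[:, 0], keep[:, 1], keep[:, 2]] = True
        pos = nxt
        if np.any(pos < -cfg.step_length) or np.any(pos > edge + cfg.step_length):
            break
        # bounded-angle turn: jitter the direction and renormalize
        direction = direction + rng.normal(scale=cfg.turn_sd, size=3)
        direction /= np.linalg.norm(direction)
    return mask


def generate_phantom(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Generate one padded image cube and its dense central labels.

    Returns
    -------
    image
        ``uint16`` volume of edge ``cube_edge + 2*pad`` in (z, y, x) order.
    labels
        ``uint8`` volume of edge ``cube_edge``, aligned with the centre of
        the image, with codes {1 background, 2 axon, 3 artifact}.

    The same config (including seed) reproduces both arrays bit-for-bit.
    """
    rng = np.random.default_rng(config.seed)
    edge = config.padded_edge

    axon = np.zeros((edge, edge, edge), dtype=bool)
    lo, hi = config.tube_radius
    for _ in range(config.n_tubes):
        centreline = _walk_tube(rng, edge, config)
        radius = int(rng.integers(lo, hi + 1))
        axon |= ndimage.binary_dilation(centreline, structure=_ball(radius))

    artifact = np.zeros((edge, edge, edge), dtype=bool)
    for _ in range(config.n_artifact_blobs):
        centre = rng.uniform(0, edge, size=3)
        semi = rng.uniform(2.0, 5.0, size=3)
        z0 = [max(0, int(np.floor(c - s - 1))) for c, s in zip(centre, semi)]
        z1 = [min(edge, int(np.ceil(c + s + 2))) for c, s in zip(centre, semi)]
        if any(a >= b for a, b in zip(z0, z1)):
            continue
        grid = np.mgrid[z0[0] : z1[0], z0[1] : z1[1], z0[2] : z1[2]].astype(float)
        d2 = sum(((grid[i] - centre[i]) / semi[i]) ** 2 for i in range(3))
        artifact[z0[0] : z1[0], z0[1] : z1[1], z0[2] : z1[2]] |= d2 <= 1.0

    image = np.full((edge, edge, edge), config.background_intensity_mean)
    image[artifact] = config.artifact_intensity_mean
    image[axon] = config.axon_intensity_mean
    image += rng.normal(scale=config.noise_sd, size=image.shape)
    image = np.clip(image, 0, _MAX_INTENSITY).astype(np.uint16)

    p = config.pad
    sl = slice(p, p + config.cube_edge)
    labels = np.full((config.cube_edge,) * 3, BACKGROUND, dtype=np.uint8)
    labels[artifact[sl, sl, sl]] = ARTIFACT
    labels[axon[sl, sl, sl]] = AXON  # axon wins where objects overlap
    return image, labels


def sparsify_labels(dense: np.ndarray, stride: int = 20, start: int = 15) -> np.ndarray:
    """Keep annotation only on every ``stride``-th slice from ``start``.

    Slices at indices start, start+stride, ... retain their codes; all
    other slices become unlabeled (code 0). Indexing is 0-based, so the
    default keeps slices {15, 35, ..., 155} of a 160-slice cube.
    """
    dense = np.asarray(dense)
    if dense.ndim != 3:
        raise ValueError(f"expected a 3D label volume, got ndim={dense.ndim}")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if not 0 <= start < dense.shape[0]:
        raise ValueError(f"start={start} outside [0, {dense.shape[0]})")
    sparse = np.full_like(dense, UNLABELED)
    sparse[start::stride] = dense[start::stride]
    return sparse
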