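"""Training-window extraction by corner sampling with axon oversampling.

A training sample is a 64-voxel input window paired with a concentric
label window that is smaller by a fixed margin per side (the network
predicts only the well-contextualised centre of its input). Windows are
placed by their top-left-back corner, drawn uniformly over all valid
placements — or, a configurable fraction of the time, from the list of
axon-labeled voxels so that foreground-rich windows are over-represented.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .labels import AXON


@dataclass(frozen=True)
class SamplerConfig:
    input_size: int = 64
    margin: int = 14
    oversample_p: float = 0.3
    samples_per_cube: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.input_size - 2 * self.margin <= 0:
            raise ValueError("input_size - 2*margin must be positive")
        if not 0.0 <= self.oversample_p <= 1.0:
            raise ValueError("oversample_p must lie in [0, 1]")
        if self.samples_per_cube < 1:
            raise ValueError("samples_per_cube must be >= 1")

    @property
    def output_size(self) -> int:
        return self.input_size - 2 * self.margin


@dataclass(frozen=True)
class Corner:
    """Top-left-back anchor of a window, 0-based (z, y, x)."""

    z: int
    y: int
    x: int

    def as_array(self) -> np.ndarray:
        return np.array([self.z, self.y, self.x], dtype=int)


@dataclass(frozen=True)
class VolumeSample:
    """Paired input intensity window and concentric target label window."""

    input: np.ndarray
    target: np.ndarray


def valid_corner_bounds(
    cube_shape: Sequence[int], input_size: int
) -> tuple[tuple[int, int], ...]:
    """Inclusive per-axis corner range ``[0, dim - input_size]``.

    Corners are restricted so a full window always fits inside the cube;
    no padding is ever required.
    """
    bounds = []
    for dim in cube_shape:
        if dim < input_size:
            raise ValueError(f"cube dimension {dim} smaller than window {input_size}")
        bounds.append((0, dim - input_size))
    return tuple(bounds)


def axon_corner_list(
    labels: np.ndarray, bounds: Sequence[tuple[int, int]]
) -> np.ndarray:
    """Axon-labeled voxels clamped per-axis into the valid corner range.

    Returns an (n, 3) int array; axon voxels beyond the far bound are
    clamped to the nearest valid corner so every entry is placeable.
    """
    coords = np.argwhere(np.asarray(labels) == AXON)
    if coords.size == 0:
        return coords.reshape(0, 3)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return np.clip(coords, lo, hi)


def draw_corner(
    rng: np.random.Generator,
    bounds: Sequence[tuple[int, int]],
    axon_corners: np.ndarray | Sequence[Sequence[int]] | None,
    oversample_p: float,
) -> Corner:
    """Draw one window corner.

    With probability ``oversample_p`` the corner is picked uniformly from
    ``axon_corners`` (foreground oversampling); otherwise — and always
    when the list is empty — it is drawn uniformly over ``bounds``.
    """
    corners = None if axon_corners is None else np.asarray(axon_corners)
    use_list = corners is not None and len(corners) > 0 and rng.random() < oversample_p
    if use_list:
        z, y, x = corners[rng.integers(len(corners))]
        return Corner(int(z), int(y), int(x))
    z, y, x = (int(rng.integers(lo, hi + 1)) for lo, hi in bounds)
    return Corner(z, y, x)


def extract_sample(
    image: np.ndarray,
    labels: np.ndarray,
    corner: Corner,
    config: SamplerConfig,
) -> VolumeSample:
    """Cut the input window at ``corner`` and its concentric label window.

    The target is anchored at ``corner + margin`` per axis with edge
    ``input_size - 2*margin``; windows are half-open ``[c, c+size)``.
    """
    size = config.input_size
    m = config.margin
    c = corner.as_array()
    for axis, dim in enumerate(image.shape):
        if c[axis] < 0 or c[axis] + size > dim:
            raise ValueError(f"corner {corner} out of bounds for shape {image.shape}")
    inp = image[c[0] : c[0] + size, c[1] : c[1] + size, c[2] : c[2] + size]
    t = c + m
    out = config.output_size
    tgt = labels[t[0] : t[0] + out, t[1] : t[1] + out, t[2] : t[2] + out]
    return VolumeSample(input=np.ascontiguousarray(inp), target=np.ascontiguousarray(tgt))


def sample_generator(
    cubes: Sequence[tuple[np.ndarray, np.ndarray]],
    config: SamplerConfig,
    rng: np.random.Generator | None = None,
) -> Iterator[VolumeSample]:
    """Yield ``samples_per_cube`` windows from each (image, labels) cube.

    One pass over ``cubes`` constitutes one epoch's worth of samples
    (e.g. 7 cubes x 100 samples = 700 training volumes). The label cube
    may be smaller than the image cube by an even pad per axis (the
    188 vs 160 layout); corners index the image and targets are read from
    the label cube at the pad-corrected position.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    for image, labels in cubes:
        bounds = valid_corner_bounds(image.shape, config.input_size)
        pad = np.array(image.shape) - np.array(labels.shape)
        if np.any(pad % 2) or np.any(pad < 0):
            raise ValueError("label cube must be centred in the image cube")
        pad //= 2
        # axon voxel positions in image coordinates
        corners = axon_corner_list(labels, bounds)
        if len(corners):
            lo = np.array([b[0] for b in bounds])
            hi = np.array([b[1] for b in bounds])
            corners = np.clip(corners + pad, lo, hi)
        for _ in range(config.samples_per_cube):
            corner = draw_corner(rng, bounds, corners, config.oversample_p)
            yield _extract_padded(image, labels, pad, corner, config)


def _extract_padded(
    image: np.ndarray,
    labels: np.ndarray,
    pad: np.ndarray,
    corner: Corner,
    config: SamplerConfig,
) -> VolumeSample:
    """Extract when labels cover only the centre ``image_edge - 2*pad`` region.

    Target voxels that fall outside the labeled region are unlabeled (0),
    so they drop out of the loss via the zero class weight.
    """
    size, m, out = config.input_size, config.margin, config.output_size
    c = corner.as_array()
    inp = image[c[0] : c[0] + size, c[1] : c[1] + size, c[2] : c[2] + size]
    tgt = np.zeros((out, out, out), dtype=labels.dtype)
    t = c + m - pad  # target anchor in label coordinates
    src_lo = np.maximum(t, 0)
    src_hi = np.minimum(t + out, labels.shape)
    dst_lo = src_lo - t
    dst_hi = dst_lo + (src_hi - src_lo)
    if np.all(src_hi > src_lo):
        tgt[dst_lo[0] : dst_hi[0], dst_lo[1] : dst_hi[1], dst_lo[2] : dst_hi[2]] = labels[
            src_lo[0] : src_hi[0], src_lo[1] : src_hi[1], src_lo[2] : src_hi[2]
        ]
    return VolumeSample(input=np.ascontiguousarray(inp), target=tgt)
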