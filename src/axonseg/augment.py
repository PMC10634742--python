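"""Co-registered spatial and intensity augmentation of training windows.

All geometric transforms apply one identical mapping to the input window
and its concentric label window, so the two stay registered: the label
window is embedded into a full-resolution canvas, transformed alongside
the image, and re-cropped to the centre. Images are resampled with
trilinear interpolation, labels with nearest-neighbour (which can never
invent a label code).

Intensity augmentation follows the divide-scale-offset scheme: raw
voxel values are divided by the 16-bit maximum, then multiplied by a
random gain and shifted by a random constant. Z-score normalisation is
deliberately not offered — removing raw intensity strips the strongest
cue separating dim background from bright axons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .labels import BACKGROUND
from .sampling import VolumeSample


@dataclass(frozen=True)
class AugmentConfig:
    enable_flips: bool = True
    enable_rotation: bool = True
    enable_elastic: bool = True
    rotation_range: float = 15.0  # degrees, per axis, symmetric
    elastic_alpha: tuple[float, float] = (0.0, 200.0)  # displacement scale
    elastic_sigma: tuple[float, float] = (9.0, 13.0)  # smoothing extent, voxels
    intensity_scale_range: tuple[float, float] = (0.8, 1.2)
    intensity_offset_range: tuple[float, float] = (-0.05, 0.05)
    max_intensity: float = 65535.0
    # probability of applying rotation / elastic per sample when enabled
    apply_p: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_intensity <= 0:
            raise ValueError("max_intensity must be positive")
        for name in ("elastic_alpha", "elastic_sigma", "intensity_scale_range",
                     "intensity_offset_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ValueError(f"{name} range must be nondecreasing")


def random_flip(sample: VolumeSample, rng: np.random.Generator) -> VolumeSample:
    """Flip each of the three axes independently with probability 1/2.

    Input and target are flipped along the same axes, so co-registration
    of the concentric windows is preserved exactly.
    """
    axes = tuple(int(a) for a in range(3) if rng.random() < 0.5)
    if not axes:
        return sample
    return VolumeSample(
        input=np.flip(sample.input, axis=axes).copy(),
        target=np.flip(sample.target, axis=axes).copy(),
    )


def _rotation_matrix(angles_deg: np.ndarray) -> np.ndarray:
    az, ay, ax = np.deg2rad(angles_deg)
    cz, sz = np.cos(az), np.sin(az)
    cy, sy = np.cos(ay), np.sin(ay)
    cx, sx = np.cos(ax), np.sin(ax)
    rz = np.array([[1, 0, 0], [0, cz, -sz], [0, sz, cz]])  # rotate in (y,x) plane
    ry = np.array([[cy, 0, -sy], [0, 1, 0], [sy, 0, cy]])
    rx = np.array([[cx, -sx, 0], [sx, cx, 0], [0, 0, 1]])
    return rz @ ry @ rx


def spatial_transform(
    sample: VolumeSample,
    rng: np.random.Generator,
    config: AugmentConfig,
    fill_intensity: float | None = None,
) -> VolumeSample:
    """Apply one random rotation and/or elastic deformation to a sample.

    When enabled, rotation and elastic deformation are each applied with
    probability ``config.apply_p`` (independent draws). Angles are drawn
    uniformly within ``±rotation_range`` per axis; the elastic field is
    white noise smoothed with a Gaussian of extent ``elastic_sigma`` and
    scaled by ``elastic_alpha``. Voxels mapped from outside the window
    are filled with ``fill_intensity`` (default: the input median, a
    robust background estimate) and label code 1 (background).
    """
    do_rot = config.enable_rotation and rng.random() < config.apply_p
    do_ela = config.enable_elastic and rng.random() < config.apply_p
    if not (do_rot or do_ela):
        return sample

    inp = np.asarray(sample.input, dtype=np.float64)
    shape = np.array(inp.shape)
    tgt_shape = np.array(sample.target.shape)
    margin = (shape - tgt_shape) // 2
    if np.any((shape - tgt_shape) % 2) or np.any(margin < 0):
        raise ValueError("target window must be concentric with the input window")

    # label canvas at input resolution, background-filled outside the target
    canvas = np.full(inp.shape, BACKGROUND, dtype=sample.target.dtype)
    mz, my, mx = margin
    tz, ty, tx = tgt_shape
    canvas[mz : mz + tz, my : my + ty, mx : mx + tx] = sample.target

    centre = (shape - 1) / 2.0
    coords = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]].astype(np.float64)

    if do_rot:
        angles = rng.uniform(-config.rotation_range, config.rotation_range, size=3)
        rot = _rotation_matrix(angles)
        rel = coords.reshape(3, -1) - centre[:, None]
        coords = (rot.T @ rel + centre[:, None]).reshape(coords.shape)

    if do_ela:
        alpha = rng.uniform(*config.elastic_alpha)
        sigma = rng.uniform(*config.elastic_sigma)
        for axis in range(3):
            noise = rng.uniform(-1.0, 1.0, size=tuple(shape))
            coords[axis] += ndimage.gaussian_filter(noise, sigma) * alpha

    fill = float(np.median(inp)) if fill_intensity is None else float(fill_intensity)
    warped = ndimage.map_coordinates(inp, coords, order=1, mode="constant", cval=fill)
    warped_labels = ndimage.map_coordinates(
        canvas, coords, order=0, mode="constant", cval=BACKGROUND
    )
    out_target = warped_labels[mz : mz + tz, my : my + ty, mx : mx + tx]
    return VolumeSample(
        input=warped.astype(sample.input.dtype, copy=False)
        if np.issubdtype(sample.input.dtype, np.floating)
        else np.clip(np.round(warped), 0, np.iinfo(sample.input.dtype).max).astype(
            sample.input.dtype
        ),
        target=out_target.astype(sample.target.dtype, copy=False),
    )


def intensity_augment(
    window: np.ndarray, rng: np.random.Generator, config: AugmentConfig
) -> np.ndarray:
    """Normalise and jitter intensities: ``(x / max_intensity) * s + c``.

    ``s`` is drawn from ``intensity_scale_range`` and ``c`` from
    ``intensity_offset_range``. Labels are never touched by intensity
    augmentation. Returns a float64 window.
    """
    s = rng.uniform(*config.intensity_scale_range)
    c = rng.uniform(*config.intensity_offset_range)
    return np.asarray(window, dtype=np.float64) / config.max_intensity * s + c


def augment_sample(
    sample: VolumeSample, rng: np.random.Generator, config: AugmentConfig
) -> VolumeSample:
    """Full augmentation pipeline: flips, spatial transform, intensity.

    Returns a sample whose input is normalised to roughly [0, 1]
    (float64) and whose target keeps its integer label codes.
    """
    if config.enable_flips:
        sample = random_flip(sample, rng)
    sample = spatial_transform(sample, rng, config)
    return VolumeSample(
        input=intensity_augment(sample.input, rng, config),
        target=sample.target,
    )
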