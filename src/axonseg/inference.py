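"""Sliding-window whole-volume prediction with Gaussian overlap fusion.

The network predicts only the centre of each input window (a 14-voxel
margin is cropped per side), so a whole-volume prediction tiles output
windows across the volume: a 188-voxel padded input cube yields a
160-voxel probability cube. With overlapping windows, each window's
prediction is weighted by a Gaussian importance map — highest at the
window centre, where the network has the most surrounding context — and
every voxel's final value is the weighted mean over the windows covering
it. With unit weights and abutting windows this degenerates to plain
tiling. Mirrored (test-time-flip) prediction is intentionally absent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np


def margin(input_size: int, output_size: int) -> int:
    """Per-side offset between input and output windows: (in - out) / 2."""
    if output_size > input_size:
        raise ValueError("output_size must not exceed input_size")
    diff = input_size - output_size
    if diff % 2:
        raise ValueError(f"input/output size difference {diff} must be even")
    return diff // 2


@dataclass(frozen=True)
class WindowGeometry:
    """Input/output window sizes and the stride between output windows."""

    input_size: int = 64
    output_size: int = 36
    stride: int | None = None  # None -> mode-dependent default

    def __post_init__(self) -> None:
        margin(self.input_size, self.output_size)  # validates parity/order
        if self.stride is not None and not 1 <= self.stride <= self.output_size:
            raise ValueError("stride must lie in [1, output_size]")

    @property
    def margin(self) -> int:
        return margin(self.input_size, self.output_size)

    def effective_stride(self, gaussian: bool) -> int:
        """Abutting windows in plain mode; half-window overlap with Gaussian."""
        if self.stride is not None:
            return self.stride
        return max(1, self.output_size // 2) if gaussian else self.output_size


def gaussian_importance(output_size: int, sigma: float) -> np.ndarray:
    """Gaussian importance map over an output window, centre weight 1.

    ``weight(v) = exp(-||v - centre||² / (2 sigma²))``; strictly positive,
    maximal at the centre, symmetric under axis reflection.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    centre = (output_size - 1) / 2.0
    ax = np.arange(output_size) - centre
    d2 = ax[:, None, None] ** 2 + ax[None, :, None] ** 2 + ax[None, None, :] ** 2
    return np.exp(-d2 / (2.0 * sigma**2))


def _window_starts(extent: int, window: int, stride: int) -> list[int]:
    """Start offsets covering [0, extent); the last window ends flush."""
    if extent < window:
        raise ValueError(f"extent {extent} smaller than window {window}")
    starts = list(range(0, extent - window + 1, stride))
    if starts[-1] != extent - window:
        starts.append(extent - window)
    return starts


def sliding_window_predict(
    predict: Callable[[np.ndarray], np.ndarray],
    image: np.ndarray,
    geometry: WindowGeometry | None = None,
    gaussian: bool = True,
    sigma: float | None = None,
) -> np.ndarray:
    """Predict a whole volume by fusing sliding-window predictions.

    Parameters
    ----------
    predict
        Maps one normalised ``input_size³`` window to an ``output_size³``
        probability window (e.g. ``UNet3D.predict_window`` after
        dividing the image by 65535).
    image
        Volume already padded by ``margin`` per side — a 188³ input cube
        produces a 160³ output; no implicit padding is performed.
    gaussian
        Weight each window by :func:`gaussian_importance` (default
        ``sigma = output_size / 8``) instead of uniform weights.

    Returns
    -------
    Probability volume of shape ``image.shape - 2 * margin`` per axis;
    each voxel is sum(w · pred) / sum(w) over the windows covering it.
    """
    geometry = geometry or WindowGeometry()
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={image.ndim}")
    m = geometry.margin
    out_shape = tuple(s - 2 * m for s in image.shape)
    for s, dim in zip(out_shape, image.shape):
        if dim < geometry.input_size:
            raise ValueError(
                f"image dimension {dim} smaller than input window "
                f"{geometry.input_size}"
            )
    stride = geometry.effective_stride(gaussian)
    if gaussian:
        weight = gaussian_importance(
            geometry.output_size,
            sigma if sigma is not None else geometry.output_size / 8.0,
        )
    else:
        weight = np.ones((geometry.output_size,) * 3)

    num = np.zeros(out_shape)
    den = np.zeros(out_shape)
    o = geometry.output_size
    starts = [_window_starts(s, o, stride) for s in out_shape]
    for z0 in starts[0]:
        for y0 in starts[1]:
            for x0 in starts[2]:
                window = image[
                    z0 : z0 + geometry.input_size,
                    y0 : y0 + geometry.input_size,
                    x0 : x0 + geometry.input_size,
                ]
                pred = np.asarray(predict(window))
                if pred.shape != (o, o, o):
                    raise ValueError(
                        f"predictor returned shape {pred.shape}, expected {(o, o, o)}"
                    )
                sl = (slice(z0, z0 + o), slice(y0, y0 + o), slice(x0, x0 + o))
                num[sl] += weight * pred
                den[sl] += weight
    assert (den > 0).all(), "coverage hole: some output voxel under no window"
    return num / den


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Boolean axon mask: strictly above ``threshold`` counts as positive."""
    prob = np.asarray(prob)
    if prob.size and (prob.min() < 0 or prob.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return prob > threshold
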