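"""TIFF volume I/O.

Volumes travel as multipage TIFFs or directories of per-slice 2D TIFFs
in lexicographic z-order — the native currency of stitched light-sheet
data. Images are 16-bit unsigned, label volumes 8-bit with the 0–4 code
convention; both round-trip losslessly. Writes go to a temporary file in
the destination directory followed by an atomic rename.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import numpy as np
import tifffile


def read_volume(path: str | Path) -> np.ndarray:
    """Read a (z, y, x) volume from a multipage TIFF or a slice directory."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")
        )
        if not files:
            raise ValueError(f"no TIFF slices found in {path}")
        slices = [tifffile.imread(f) for f in files]
        shapes = {s.shape for s in slices}
        if len(shapes) != 1:
            raise ValueError(f"inconsistent slice shapes in {path}: {sorted(shapes)}")
        dtypes = {s.dtype for s in slices}
        if len(dtypes) != 1:
            raise ValueError(f"mixed slice dtypes in {path}: {sorted(map(str, dtypes))}")
        return np.stack(slices)
    volume = tifffile.imread(path)
    if volume.ndim == 2:
        volume = volume[None]
    if volume.ndim != 3:
        raise ValueError(f"{path} holds a {volume.ndim}D array, expected 3D")
    return volume


def write_volume(
    path: str | Path, volume: np.ndarray, per_slice: bool = False
) -> Path:
    """Write a volume as one multipage TIFF or a directory of z-slices."""
    path = Path(path)
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3D volume, got ndim={volume.ndim}")
    if per_slice:
        path.mkdir(parents=True, exist_ok=True)
        width = len(str(volume.shape[0] - 1))
        for z in range(volume.shape[0]):
            _atomic_imwrite(path / f"z{z:0{width}d}.tif", volume[z])
        return path
    path.parent.mkdir(parents=True, exist_ok=True)
    _atomic_imwrite(path, volume)
    return path


def _atomic_imwrite(path: Path, data: np.ndarray) -> None:
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".tif.tmp")
    os.close(fd)
    try:
        tifffile.imwrite(tmp, data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
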