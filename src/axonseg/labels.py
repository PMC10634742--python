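"""Label codes, loss weights, edge-class generation and the sparse-slice mask.

Annotated volumes use a five-code convention on an 8-bit grid:

====  ==========  ======================================================
code  name        meaning
====  ==========  ======================================================
0     unlabeled   slice carries no annotation; excluded from loss/metrics
1     background  annotated non-axon tissue
2     axon        foreground class to segment
3     artifact    bright non-axon structure (bubbles, debris)
4     edge        one-voxel ring around annotated axons
====  ==========  ======================================================

The edge class absorbs annotator boundary uncertainty: it is strongly
down-weighted in the loss and forgiven in the edge-corrected metrics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

UNLABELED = 0
BACKGROUND = 1
AXON = 2
ARTIFACT = 3
EDGE = 4

VALID_CODES = frozenset({UNLABELED, BACKGROUND, AXON, ARTIFACT, EDGE})


@dataclass(frozen=True)
class ClassWeights:
    """Per-class loss multipliers (dimensionless).

    Defaults follow the fine-tuning scheme for axons, backgrounds,
    artifacts and edges; unlabeled voxels always carry weight zero so
    that un-annotated slices are masked out of the loss.
    """

    axon: float = 1.5
    background: float = 0.2
    artifact: float = 0.8
    edge: float = 0.05
    unlabeled: float = 0.0

    def __post_init__(self) -> None:
        for name in ("axon", "background", "artifact", "edge"):
            if getattr(self, name) < 0:
                raise ValueError(f"class weight {name!r} must be >= 0")
        if self.unlabeled != 0.0:
            raise ValueError("unlabeled voxels must have weight 0")

    def as_lookup(self) -> np.ndarray:
        """Weight per code, indexable by label code (length 5)."""
        return np.array(
            [self.unlabeled, self.background, self.axon, self.artifact, self.edge],
            dtype=np.float64,
        )


# in-plane 8-neighbourhood (a single z-slice of a 3x3 square)
_STRUCT_8 = np.ones((3, 3), dtype=bool)


def generate_edges(labels: np.ndarray) -> np.ndarray:
    """Derive the edge class around axon annotations, slice by slice.

    On each labeled z-slice, every *background* voxel 8-adjacent in-plane
    to an axon voxel is recoded as edge. Axon, artifact and unlabeled
    voxels are never overwritten. Edges are strictly 2D because only a
    sparse subset of slices carries annotation, so a boundary across
    unlabeled gaps is undefined.

    Parameters
    ----------
    labels
        (z, y, x) integer volume with codes in {0, 1, 2, 3}.

    Returns
    -------
    A new volume of the same shape with edge voxels set to code 4.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValueError(f"expected a 3D label volume, got ndim={labels.ndim}")
    if (labels == EDGE).any():
        raise ValueError("input already contains edge voxels (code 4)")

    out = labels.copy()
    for z in np.flatnonzero(labeled_mask(labels)):
        plane = labels[z]
        axon = plane == AXON
        if not axon.any():
            continue
        ring = ndimage.binary_dilation(axon, structure=_STRUCT_8) & ~axon
        out[z][ring & (plane == BACKGROUND)] = EDGE
    return out


def labeled_mask(labels: np.ndarray) -> np.ndarray:
    """Boolean mask over z: True where the slice contains any annotation.

    A slice is annotated iff it holds at least one nonzero code; all-zero
    slices are the unlabeled gaps that loss and metrics must skip.
    """
    labels = np.asarray(labels)
    if labels.ndim != 3:
        raise ValueError(f"expected a 3D label volume, got ndim={labels.ndim}")
    return labels.reshape(labels.shape[0], -1).any(axis=1)
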