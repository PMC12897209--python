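"""CT-based lung segmentation by HU thresholding.

Candidate parenchyma voxels are those at or below an upper HU threshold
(default -400) that are *not* connected to the grid boundary — the
boundary rule excludes exterior air without needing a lower HU bound.
The two largest 26-connected interior components become the lungs;
left/right assignment compares component centroids with the body
centroid along the left-right axis.  A manual-override hook replaces
either mask wholesale, mirroring slice-by-slice corrections on a
clinical workstation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume import VolumePair

__all__ = ["LungMasks", "SegmentationError", "segment_lungs", "apply_mask_override"]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


class SegmentationError(RuntimeError):
    """Segmentation could not produce two lateralised lungs."""


@dataclass(frozen=True)
class LungMasks:
    """Binary left/right lung masks with physical volumes (mL)."""

    left: np.ndarray
    right: np.ndarray
    spacing_mm: tuple[float, float, float]
    override_applied: bool = False

    def __post_init__(self) -> None:
        left = np.asarray(self.left, dtype=bool)
        right = np.asarray(self.right, dtype=bool)
        if left.shape != right.shape:
            raise ValueError("left/right mask shapes differ")
        if np.any(left & right):
            raise ValueError("left and right masks must be disjoint")
        if not left.any() or not right.any():
            raise ValueError("empty lung mask is not allowed")
        object.__setattr__(self, "left", left)
        object.__setattr__(self, "right", right)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.spacing_mm)) / 1000.0

    @property
    def volume_ml(self) -> dict[str, float]:
        v = self.voxel_volume_ml
        left = float(self.left.sum()) * v
        right = float(self.right.sum()) * v
        return {"left": left, "right": right, "total": left + right}


def _boundary_labels(labels: np.ndarray) -> set[int]:
    faces = []
    for ax in range(labels.ndim):
        sl = [slice(None)] * labels.ndim
        for end in (0, -1):
            sl[ax] = end
            faces.append(labels[tuple(sl)].ravel())
    return set(np.unique(np.concatenate(faces)).tolist())


def segment_lungs(
    pair: VolumePair,
    hu_upper: float = -400.0,
    min_component_frac: float = 0.01,
    closing_iterations: int = 0,
    lr_axis: int = 0,
) -> LungMasks:
    """Segment left and right lungs from the CT volume.

    Parameters
    ----------
    pair
        Co-registered CT/SPECT pair; only the CT is used here.
    hu_upper
        Upper HU bound defining parenchyma; comparison is inclusive
        (``HU <= hu_upper``).
    min_component_frac
        Interior components smaller than this fraction of the largest
        are discarded as noise before the two-largest rule.
    closing_iterations
        Optional binary closing applied to each lung mask (off by
        default; clinical CT with vessels may benefit, phantoms do not).
    lr_axis
        Array axis corresponding to the patient left-right direction,
        index increasing toward the patient's left.

    Raises
    ------
    SegmentationError
        If fewer than two interior low-HU components exist (e.g. uniform
        or consolidated CT — supply a manual mask), if a single
        component spans the midline (manual split required), or if the
        two candidate components do not straddle the body centroid.
    """
    ct = pair.ct
    cand = ct <= hu_upper
    labels, n = ndimage.label(cand, structure=_STRUCT_26)
    exterior = _boundary_labels(labels) - {0}
    sizes = np.bincount(labels.ravel(), minlength=n + 1)
    interior = [lbl for lbl in range(1, n + 1) if lbl not in exterior and sizes[lbl] > 0]
    if not interior:
        raise SegmentationError(
            "no interior low-HU component found; CT appears uniform or "
            "fully consolidated — supply a manual mask"
        )
    largest = max(sizes[lbl] for lbl in interior)
    interior = [lbl for lbl in interior if sizes[lbl] >= min_component_frac * largest]

    body = ct > hu_upper
    body_centroid = ndimage.center_of_mass(body)

    if len(interior) < 2:
        lbl = interior[0]
        xs = np.nonzero(labels == lbl)[lr_axis]
        if xs.min() < body_centroid[lr_axis] < xs.max():
            raise SegmentationError(
                "single low-HU component spans the midline; split it "
                "manually and use apply_mask_override"
            )
        raise SegmentationError(
            "fewer than two interior lung components; consolidated or "
            "atelectatic input — supply a manual mask"
        )

    interior.sort(key=lambda lbl: -sizes[lbl])
    a, b = interior[:2]
    ca = ndimage.center_of_mass(labels == a)
    cb = ndimage.center_of_mass(labels == b)
    da = ca[lr_axis] - body_centroid[lr_axis]
    db = cb[lr_axis] - body_centroid[lr_axis]
    if da * db >= 0:
        raise SegmentationError(
            "candidate lung centroids do not straddle the body centroid "
            "along the left-right axis; refusing to guess lateralisation"
        )
    left_lbl, right_lbl = (a, b) if da > 0 else (b, a)
    left = labels == left_lbl
    right = labels == right_lbl
    if closing_iterations > 0:
        left = ndimage.binary_closing(left, structure=_STRUCT_26, iterations=closing_iterations)
        right = ndimage.binary_closing(right, structure=_STRUCT_26, iterations=closing_iterations)
        overlap = left & right
        left &= ~overlap  # closing must not create overlap; drop contested voxels
        right &= ~overlap
    return LungMasks(left=left, right=right, spacing_mm=pair.spacing_mm)


def apply_mask_override(
    masks: LungMasks,
    override_left: np.ndarray | None = None,
    override_right: np.ndarray | None = None,
) -> LungMasks:
    """Replace one or both automatic masks with manual ones.

    Volumes are recomputed and the result carries a provenance flag
    (``override_applied=True``).  Empty overrides and shape mismatches
    are rejected.
    """
    left = masks.left if override_left is None else np.asarray(override_left, dtype=bool)
    right = masks.right if override_right is None else np.asarray(override_right, dtype=bool)
    for name, m in (("left", left), ("right", right)):
        if m.shape != masks.left.shape:
            raise ValueError(f"{name} override shape {m.shape} != volume shape {masks.left.shape}")
        if not m.any():
            raise ValueError(f"{name} override mask is empty; an empty lung is not allowed")
    if np.any(left & right):
        raise ValueError("override masks overlap")
    return LungMasks(left=left, right=right, spacing_mm=masks.spacing_mm, override_applied=True)
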