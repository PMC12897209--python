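"""Co-registered CT/SPECT volume container and NIfTI-1 I/O.

The CT grid is in Hounsfield Units, the SPECT grid in reconstructed
perfusion counts.  Both grids share shape and voxel spacing: the analysis
assumes the pair was acquired on a hybrid scanner without repositioning,
so no registration is performed anywhere in this package.

Array axis convention: axis 0 is the patient left-right axis with the
index increasing toward the patient's left; axes 1 and 2 are
anterior-posterior and inferior-superior.  Only the left-right axis
matters to the analysis (lung lateralisation); it can be overridden in
:func:`perfquant.segmentation.segment_lungs`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VolumePair", "read_nifti", "write_nifti"]


@dataclass(frozen=True)
class VolumePair:
    """A co-registered CT (HU) and SPECT (counts) voxel grid pair.

    Parameters
    ----------
    ct
        3-D array of Hounsfield Units.
    spect
        3-D array of non-negative perfusion counts, same shape as ``ct``.
    spacing_mm
        Voxel spacing along each axis, in millimetres.
    """

    ct: np.ndarray
    spect: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        ct = np.asarray(self.ct)
        spect = np.asarray(self.spect)
        if ct.ndim != 3 or spect.ndim != 3:
            raise ValueError("ct and spect must be 3-D arrays")
        if ct.shape != spect.shape:
            raise ValueError(
                f"ct shape {ct.shape} != spect shape {spect.shape}; "
                "volumes must be co-registered on a common grid"
            )
        spacing = tuple(float(s) for s in self.spacing_mm)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing_mm must be 3 positive reals, got {self.spacing_mm}")
        if spect.size and float(spect.min()) < 0:
            raise ValueError("spect counts must be non-negative")
        object.__setattr__(self, "ct", ct)
        object.__setattr__(self, "spect", spect)
        object.__setattr__(self, "spacing_mm", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.ct.shape

    @property
    def voxel_volume_ml(self) -> float:
        """Physical volume of one voxel in millilitres."""
        return float(np.prod(self.spacing_mm)) / 1000.0


def write_nifti(volume: np.ndarray, spacing_mm, path: str | os.PathLike) -> None:
    """Write a 3-D volume to a NIfTI-1 file with the given voxel spacing.

    The affine is diagonal (no rotation); spacing is carried both in the
    affine and in the header zooms so the round trip is exact.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError("expected a 3-D volume")
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains non-finite voxel values")
    spacing = tuple(float(s) for s in spacing_mm)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing_mm must be 3 positive reals, got {spacing_mm}")
    if volume.dtype == np.int64:  # NIfTI-1 has no 64-bit integer type
        volume = volume.astype(np.int32)
    affine = np.diag([*spacing, 1.0])
    img = nib.Nifti1Image(volume, affine)
    img.header.set_zooms(spacing)
    nib.save(img, os.fspath(path))


def read_nifti(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a 3-D NIfTI volume; returns ``(array, spacing_mm)``.

    Voxel values are returned in the stored dtype (no scaling applied by
    this package; NIfTI scl_slope/inter, if present, are honoured by
    nibabel's proxy).
    """
    if not os.path.exists(os.fspath(path)):
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D NIfTI volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing
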