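"""Decile-threshold perfusion quantification.

The quantitative read-out of a perfusion SPECT/CT study:

1. the maximum perfusion count is found *separately for each lung*
   (raw peak voxel value within the mask);
2. each lung's counts are divided into ten equal intervals from zero to
   that lung's maximum, and the volume fraction per interval gives the
   decile histogram;
3. at a threshold of k x 10 % of the per-lung maximum (k = 1..9), voxels
   with counts *strictly below* the threshold are perfusion defects;
   voxels exactly at the threshold count as normally perfused;
4. the perfusion defect fraction pools both lungs: defect volume of both
   lungs divided by total lung volume of both lungs.

Because thresholds are relative to each lung's own maximum, every
quantity here is invariant to rescaling the counts of either lung by a
positive constant — absolute calibration of the scanner cancels out.

Histogram bins are left-closed/right-open, with the last bin closed at
the maximum so the peak voxel is counted exactly once (bins partition
the count range).  The pooled histogram weights each lung's fractions by
its share of the total lung volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import LungMasks
from .volume import VolumePair

__all__ = [
    "QuantificationError",
    "DecileHistogram",
    "DefectProfile",
    "lung_max_counts",
    "decile_histogram",
    "defect_fraction",
    "defect_profile",
]

THRESHOLD_PERCENTS: tuple[int, ...] = tuple(range(10, 100, 10))


class QuantificationError(ValueError):
    """Degenerate input to the quantification step (empty/zero-count lung)."""


@dataclass(frozen=True)
class DecileHistogram:
    """Per-lung and pooled volume-fraction histogram over count deciles.

    ``bin_edges[lung]`` has 11 edges from 0 to that lung's maximum;
    ``volume_fraction`` maps ``"left"``/``"right"``/``"pooled"`` to 10
    fractions summing to one.
    """

    bin_edges: dict[str, np.ndarray]
    volume_fraction: dict[str, np.ndarray]
    lung_max_counts: dict[str, float]

    def __post_init__(self) -> None:
        for key in ("left", "right", "pooled"):
            f = np.asarray(self.volume_fraction[key], dtype=float)
            if f.shape != (10,) or np.any(f < 0) or abs(f.sum() - 1.0) > 1e-9:
                raise ValueError(f"{key} volume fractions must be 10 non-negatives summing to 1")


@dataclass(frozen=True)
class DefectProfile:
    """Defect fraction/volume at every decile threshold.

    ``threshold_counts[lung][t]`` is the absolute count threshold
    t/100 x that lung's maximum.
    """

    defect_fraction: dict[int, float]
    defect_volume_ml: dict[int, float]
    threshold_counts: dict[str, dict[int, float]]

    def __post_init__(self) -> None:
        fr = [self.defect_fraction[t] for t in THRESHOLD_PERCENTS]
        if any(not 0.0 <= f <= 1.0 for f in fr):
            raise ValueError("defect fractions must lie in [0, 1]")
        if any(b < a for a, b in zip(fr, fr[1:])):
            raise ValueError("defect fraction must be non-decreasing in threshold")


def _masked(pair: VolumePair, masks: LungMasks):
    if pair.ct.shape != masks.left.shape:
        raise ValueError("mask shape does not match volume shape")
    return {"left": pair.spect[masks.left], "right": pair.spect[masks.right]}


def lung_max_counts(pair: VolumePair, masks: LungMasks) -> dict[str, float]:
    """Peak voxel count within each lung mask (raw maximum).

    Raises :class:`QuantificationError` for an empty mask or a lung with
    all-zero counts (a degenerate study with no measurable perfusion).
    """
    out: dict[str, float] = {}
    for lung, vals in _masked(pair, masks).items():
        if vals.size == 0:
            raise QuantificationError(f"{lung} lung mask is empty")
        m = float(vals.max())
        if m <= 0:
            raise QuantificationError(f"{lung} lung has no counts; degenerate study")
        out[lung] = m
    return out


def decile_histogram(pair: VolumePair, masks: LungMasks) -> DecileHistogram:
    """Volume-fraction histogram over ten equal count intervals per lung.

    Interval k (k = 1..10) covers [(k-1) x max/10, k x max/10), the last
    interval closed at the maximum.  The pooled histogram is the
    volume-weighted combination of the per-lung histograms.
    """
    maxima = lung_max_counts(pair, masks)
    vals = _masked(pair, masks)
    edges: dict[str, np.ndarray] = {}
    fractions: dict[str, np.ndarray] = {}
    n = {lung: v.size for lung, v in vals.items()}
    for lung in ("left", "right"):
        m = maxima[lung]
        edges[lung] = np.linspace(0.0, m, 11)
        idx = np.minimum((vals[lung] * 10.0 / m).astype(int), 9)
        fractions[lung] = np.bincount(idx, minlength=10) / n[lung]
    total = n["left"] + n["right"]
    fractions["pooled"] = (n["left"] * fractions["left"] + n["right"] * fractions["right"]) / total
    return DecileHistogram(bin_edges=edges, volume_fraction=fractions, lung_max_counts=maxima)


def defect_fraction(
    pair: VolumePair, masks: LungMasks, threshold_percent: int
) -> tuple[float, float, np.ndarray]:
    """Perfusion defect fraction at one decile threshold.

    Per lung the absolute threshold is ``threshold_percent``/100 x that
    lung's maximum count; in-mask voxels strictly below it are defects.
    Returns ``(fraction, defect_volume_ml, defect_mask)`` with the
    fraction pooled over both lungs.
    """
    if threshold_percent not in THRESHOLD_PERCENTS:
        raise ValueError(f"threshold_percent must be one of {THRESHOLD_PERCENTS}")
    maxima = lung_max_counts(pair, masks)
    defect = np.zeros(pair.shape, dtype=bool)
    for lung, mask in (("left", masks.left), ("right", masks.right)):
        thr = threshold_percent / 100.0 * maxima[lung]
        defect[mask] = pair.spect[mask] < thr
    n_lung = int(masks.left.sum() + masks.right.sum())
    n_defect = int(defect.sum())
    fraction = n_defect / n_lung
    return fraction, n_defect * masks.voxel_volume_ml, defect


def defect_profile(pair: VolumePair, masks: LungMasks) -> DefectProfile:
    """Defect fraction at all nine decile thresholds (10 %..90 %)."""
    maxima = lung_max_counts(pair, masks)
    fractions: dict[int, float] = {}
    volumes: dict[int, float] = {}
    for t in THRESHOLD_PERCENTS:
        fr, vol, _ = defect_fraction(pair, masks, t)
        fractions[t] = fr
        volumes[t] = vol
    thresholds = {
        lung: {t: t / 100.0 * maxima[lung] for t in THRESHOLD_PERCENTS}
        for lung in ("left", "right")
    }
    return DefectProfile(
        defect_fraction=fractions, defect_volume_ml=volumes, threshold_counts=thresholds
    )
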