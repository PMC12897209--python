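"""Digital thorax phantom generator for perfusion SPECT/CT.

Produces seedable paired CT/SPECT volumes with ground-truth lung masks,
defect geometry and true defect fractions, emulating the count statistics
seen in clinical Tc-99m MAA perfusion studies:

* a **control** pattern whose noise-free in-lung count histogram is
  unimodal with its mode in the 30-40 %-of-maximum decile, the shape
  reported for non-CTEPH patients;
* a **cteph_segmental** pattern with wedge-shaped (spherical-sector)
  near-zero regions anchored at each lung's hilum, mimicking the
  segmental vascular territories lost in chronic thromboembolic disease;
* a **pah_mottled** pattern with spatially uncorrelated small blobs of
  reduced uptake, the diffuse non-segmental texture of Group 1 pulmonary
  arterial hypertension.

Geometry is deliberately simple — two axis-aligned lung ellipsoids inside
a body ellipsoid — because the downstream analysis depends only on the
count statistics within the lung masks, not on anatomical realism.

``target_defect_fraction`` is defined on the *noise-free* count field at
the 10 %-of-per-lung-maximum threshold; observed (Poisson-noisy)
fractions differ by an amount governed by the count level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .volume import VolumePair, write_nifti

__all__ = [
    "PhantomConfig",
    "GroundTruth",
    "PhantomGenerationError",
    "PhantomSubject",
    "SyntheticCohort",
    "generate_phantom",
    "generate_cohort",
]

Pattern = Literal["control", "cteph_segmental", "pah_mottled"]

#: decile thresholds (percent of per-lung maximum) used throughout the package
THRESHOLD_PERCENTS: tuple[int, ...] = tuple(range(10, 100, 10))

# Base (non-defect) intensity distribution, in units of the per-lung
# maximum: truncated Normal(0.35, 0.12) restricted to [0.12, 1].  The
# lower truncation keeps healthy parenchyma out of the <10 % decile so
# the defect fraction is controlled purely by the inserted defects; the
# mean/sd put the histogram mode in the 30-40 % bin.
_BASE_MU = 0.35
_BASE_SD = 0.12
_BASE_LO = 0.12
_DEFECT_LO, _DEFECT_HI = 0.02, 0.08  # defect intensities, well below 10 % of max


class PhantomGenerationError(ValueError):
    """Raised when a phantom cannot be generated under the given config."""


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of one synthetic CT/SPECT subject.

    ``mean_counts`` is the mean noise-free count per in-lung voxel and
    scales the Poisson intensity; 50 counts/voxel is typical of a
    reconstructed clinical MAA study at this voxel size.
    """

    grid_shape: tuple[int, int, int] = (72, 52, 60)
    spacing_mm: tuple[float, float, float] = (4.0, 4.0, 4.0)
    body_hu: float = 40.0
    lung_hu: float = -800.0
    background_hu: float = -1000.0
    pattern: Pattern = "control"
    target_defect_fraction: float = 0.0
    mean_counts: float = 50.0
    n_wedges: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be 3 positive integers")
        if len(self.spacing_mm) != 3 or any(float(s) <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be 3 positive reals")
        if not 0.0 <= self.target_defect_fraction <= 1.0:
            raise ValueError("target_defect_fraction must be in [0, 1]")
        if self.pattern not in ("control", "cteph_segmental", "pah_mottled"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.mean_counts <= 0:
            raise ValueError("mean_counts must be positive")
        if self.n_wedges < 0:
            raise ValueError("n_wedges must be non-negative")
        object.__setattr__(self, "grid_shape", tuple(int(n) for n in self.grid_shape))
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))


@dataclass(frozen=True)
class GroundTruth:
    """Noise-free truth accompanying a generated phantom.

    ``noise_free`` is the Poisson intensity (expected counts per voxel)
    before noise; the defect mask and true fractions are defined on it.
    """

    left_mask: np.ndarray
    right_mask: np.ndarray
    defect_mask: np.ndarray
    true_defect_fraction_by_threshold: dict[int, float]
    noise_free: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(self.left_mask & self.right_mask):
            raise ValueError("left and right masks overlap")
        lungs = self.left_mask | self.right_mask
        if np.any(self.defect_mask & ~lungs):
            raise ValueError("defect mask extends outside the lungs")
        fr = [self.true_defect_fraction_by_threshold[t] for t in THRESHOLD_PERCENTS]
        if any(b < a - 1e-12 for a, b in zip(fr, fr[1:])):
            raise ValueError("true defect fractions must be non-decreasing in threshold")


# ---------------------------------------------------------------------------
# geometry helpers


def _ellipsoid(shape, center, semi_axes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return r2 <= 1.0


def _lung_geometry(shape):
    """Body/lung ellipsoid centres and semi-axes, in voxel units."""
    nx, ny, nz = shape
    body_c = (nx / 2, ny / 2, nz / 2)
    body_a = (0.47 * nx, 0.46 * ny, 0.48 * nz)
    lung_a = (0.17 * nx, 0.28 * ny, 0.35 * nz)
    right_c = (nx / 2 - 0.22 * nx, ny / 2, nz / 2)  # lower index = patient right
    left_c = (nx / 2 + 0.22 * nx, ny / 2, nz / 2)
    return body_c, body_a, left_c, right_c, lung_a


def _base_quantile(u: np.ndarray, tail_fraction: float) -> np.ndarray:
    """Map volume-uniform u in [0, 1] to intensity (units of per-lung max).

    The map is the quantile function of a mixture: with probability
    ``tail_fraction`` a defect-level intensity uniform on
    [0.02, 0.08), otherwise the truncated-normal base distribution.
    Applied to u = 1 - r^3 (r = normalised ellipsoid radius) it yields a
    smooth, monotone centre-bright radial profile whose *volume*
    histogram equals the mixture exactly in the continuum limit.
    """
    a = (_BASE_LO - _BASE_MU) / _BASE_SD
    b = (1.0 - _BASE_MU) / _BASE_SD
    v = np.empty_like(u, dtype=float)
    f = tail_fraction
    low = u < f
    if f > 0:
        v[low] = _DEFECT_LO + (_DEFECT_HI - _DEFECT_LO) * (u[low] / f)
    q = (u[~low] - f) / (1.0 - f) if f < 1 else np.zeros(0)
    v[~low] = _BASE_MU + _BASE_SD * truncnorm.ppf(np.clip(q, 0.0, 1.0), a, b)
    return v


# ---------------------------------------------------------------------------
# defect insertion


def _carve_wedges(field, mask, hilum, lateral_sign, n_voxels, n_wedges, peak_idx, rng):
    """Set ``n_voxels`` of ``mask`` to defect intensity via hilum-anchored cones.

    Each wedge is the set of voxels whose angle to a random, laterally
    oriented axis through the hilum is below a per-wedge quantile chosen
    so the wedge contributes its share of ``n_voxels`` exactly (up to the
    protected peak voxel).
    """
    coords = np.argwhere(mask)
    flat = np.ravel_multi_index(coords.T, mask.shape)
    rel = coords - np.asarray(hilum)[None, :]
    norms = np.linalg.norm(rel, axis=1)
    norms[norms == 0] = 1.0
    is_defect = np.zeros(len(coords), dtype=bool)
    protected = flat == peak_idx
    remaining = n_voxels
    for w in range(n_wedges):
        if remaining <= 0:
            break
        d = rng.normal(size=3)
        d[0] = lateral_sign * (0.6 + abs(d[0]))  # bias axis away from the midline
        d /= np.linalg.norm(d)
        cosang = rel @ d / norms
        quota = remaining if w == n_wedges - 1 else int(round(n_voxels / n_wedges))
        quota = min(quota, remaining)
        candidates = ~is_defect & ~protected
        order = np.argsort(-cosang[candidates])
        idx = np.flatnonzero(candidates)[order[:quota]]
        is_defect[idx] = True
        remaining -= len(idx)
    if remaining > 0:
        raise PhantomGenerationError(
            f"could not reach target defect fraction: {remaining} voxels short"
        )
    sel = flat[is_defect]
    field.ravel()[sel] = rng.uniform(_DEFECT_LO, _DEFECT_HI, size=len(sel))
    return _unravel(sel, mask.shape)


def _unravel(flat_idx, shape):
    out = np.zeros(shape, dtype=bool)
    out.ravel()[flat_idx] = True
    return out


def _carve_blobs(field, mask, n_voxels, peak_idx, rng):
    """Mottled pattern: random small spheres of reduced uptake until the
    voxel quota is met; the last blob is trimmed to hit the quota exactly."""
    coords = np.argwhere(mask)
    flat = np.ravel_multi_index(coords.T, mask.shape)
    lung_flat = set(flat.tolist())
    is_defect = np.zeros(mask.shape, dtype=bool)
    added = 0
    for _ in range(100_000):
        if added >= n_voxels:
            break
        c = coords[rng.integers(len(coords))]
        radius = rng.uniform(1.2, 2.8)
        r_int = int(np.ceil(radius))
        lo = np.maximum(c - r_int, 0)
        hi = np.minimum(c + r_int + 1, mask.shape)
        sub = tuple(slice(l, h) for l, h in zip(lo, hi))
        grids = np.ogrid[sub]
        dist2 = sum((g - cc) ** 2 for g, cc in zip(grids, c))
        blob = (dist2 <= radius**2) & mask[sub] & ~is_defect[sub]
        blob_coords = np.argwhere(blob) + lo
        blob_flat = np.ravel_multi_index(blob_coords.T, mask.shape)
        blob_flat = blob_flat[blob_flat != peak_idx]
        if len(blob_flat) == 0:
            continue
        need = n_voxels - added
        if len(blob_flat) > need:
            d2 = ((blob_coords - c) ** 2).sum(axis=1)
            keep = np.argsort(d2, kind="stable")[:need]
            blob_flat = np.ravel_multi_index(blob_coords[keep].T, mask.shape)
            blob_flat = blob_flat[blob_flat != peak_idx]
        is_defect.ravel()[blob_flat] = True
        added += len(blob_flat)
    if added < n_voxels:
        raise PhantomGenerationError(
            f"mottled pattern could not reach target defect fraction "
            f"({added}/{n_voxels} voxels placed)"
        )
    sel = np.flatnonzero(is_defect.ravel())
    field.ravel()[sel] = rng.uniform(_DEFECT_LO, _DEFECT_HI, size=len(sel))
    return is_defect


# ---------------------------------------------------------------------------
# main generator


def generate_phantom(config: PhantomConfig) -> tuple[VolumePair, GroundTruth]:
    """Generate one paired CT/SPECT phantom with ground truth.

    Deterministic: identical configs (including ``seed``) produce
    bit-identical volumes.

    Raises
    ------
    PhantomGenerationError
        If the grid cannot hold two disjoint interior lung ellipsoids or
        the requested ``target_defect_fraction`` is unattainable under
        the chosen pattern.
    """
    cfg = config
    shape = cfg.grid_shape
    rng = np.random.default_rng(cfg.seed)

    body_c, body_a, left_c, right_c, lung_a = _lung_geometry(shape)
    body = _ellipsoid(shape, body_c, body_a)
    left = _ellipsoid(shape, left_c, lung_a)
    right = _ellipsoid(shape, right_c, lung_a)
    if np.any(left & right):
        raise PhantomGenerationError("grid too small: lung ellipsoids overlap")
    for m in (left, right):
        if not m.any():
            raise PhantomGenerationError("grid too small: empty lung ellipsoid")
        edge = np.zeros(shape, dtype=bool)
        for ax in range(3):
            sl = [slice(None)] * 3
            for end in (0, -1):
                sl[ax] = end
                edge[tuple(sl)] = True
        if np.any(m & edge) or np.any(m & ~body):
            raise PhantomGenerationError("grid too small: lung touches boundary or exits body")
    # the body shell must isolate the lungs from exterior air even under
    # 26-connectivity, or downstream segmentation cannot recover them
    from scipy import ndimage as _ndi

    air = ~body
    lungs_plus_air = air | left | right
    labels, _ = _ndi.label(lungs_plus_air, structure=np.ones((3, 3, 3), dtype=bool))
    exterior_label = labels[0, 0, 0]
    if np.any(labels[left | right] == exterior_label):
        raise PhantomGenerationError(
            "grid too small: body shell thinner than one voxel, lungs "
            "connect to exterior air"
        )

    if cfg.target_defect_fraction > 0.95:
        raise PhantomGenerationError(
            "target_defect_fraction > 0.95 is unattainable (the per-lung "
            "maximum voxel must remain normally perfused)"
        )
    if cfg.pattern == "cteph_segmental" and cfg.target_defect_fraction > 0 and cfg.n_wedges == 0:
        raise PhantomGenerationError("segmental pattern with defects requires n_wedges >= 1")

    ct = np.full(shape, cfg.background_hu, dtype=np.float32)
    ct[body] = cfg.body_hu
    ct[left | right] = cfg.lung_hu

    # noise-free intensity in units of the (eventual) per-lung maximum
    field = np.zeros(shape, dtype=float)
    defect = np.zeros(shape, dtype=bool)
    for mask, center, lateral_sign in ((right, right_c, -1.0), (left, left_c, +1.0)):
        grids = np.ogrid[tuple(slice(0, n) for n in shape)]
        r2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, lung_a))
        r = np.sqrt(np.where(mask, r2, 1.0))
        u = np.clip(1.0 - r**3, 0.0, 1.0)
        tail = cfg.target_defect_fraction if cfg.pattern == "control" else 0.0
        vals = _base_quantile(u[mask], tail)
        field[mask] = vals
        # the most-central voxel carries the per-lung maximum; protect it
        flat_mask = np.flatnonzero(mask.ravel())
        peak_idx = flat_mask[np.argmax(vals)]
        n_lung = int(mask.sum())
        quota = int(round(cfg.target_defect_fraction * n_lung))
        quota = min(quota, n_lung - 1)
        if cfg.pattern == "cteph_segmental" and quota > 0:
            hilum_x = center[0] - lateral_sign * 0.8 * lung_a[0]
            hilum = (hilum_x, center[1], center[2])
            defect |= _carve_wedges(
                field, mask, hilum, lateral_sign, quota, max(cfg.n_wedges, 1), peak_idx, rng
            )
        elif cfg.pattern == "pah_mottled" and quota > 0:
            defect |= _carve_blobs(field, mask, quota, peak_idx, rng)
        elif cfg.pattern == "control":
            defect |= mask & (u < tail)

    # ground-truth defect fractions on the noise-free field
    fractions: dict[int, float] = {}
    n_total = int(left.sum() + right.sum())
    for t in THRESHOLD_PERCENTS:
        n_def = 0
        for mask in (left, right):
            vals = field[mask]
            n_def += int(np.count_nonzero(vals < (t / 100.0) * vals.max()))
        fractions[t] = n_def / n_total
    defect_10 = np.zeros(shape, dtype=bool)
    for mask in (left, right):
        vals = field[mask]
        defect_10[mask] = vals < 0.1 * vals.max()

    lung = left | right
    scale = cfg.mean_counts / float(field[lung].mean())
    lam = field * scale
    truth = GroundTruth(
        left_mask=left,
        right_mask=right,
        defect_mask=defect_10,
        true_defect_fraction_by_threshold=fractions,
        noise_free=lam,
    )
    spect = np.zeros(shape, dtype=np.int64)
    spect[lung] = rng.poisson(lam[lung])

    pair = VolumePair(ct=ct, spect=spect, spacing_mm=cfg.spacing_mm)
    return pair, truth


# ---------------------------------------------------------------------------
# cohort generation


@dataclass(frozen=True)
class PhantomSubject:
    subject_id: str
    config: PhantomConfig
    pair: VolumePair
    truth: GroundTruth


@dataclass(frozen=True)
class SyntheticCohort:
    subjects: list[PhantomSubject]
    manifest: pd.DataFrame


# group-level defect-fraction distributions (truncated to the attainable
# range) and the synthetic mPAP link mPAP = A + B * defect_fraction + noise
CTEPH_CENTER, CTEPH_SD = 0.34, 0.12
CONTROL_CENTER, CONTROL_SD = 0.06, 0.04
MPAP_INTERCEPT, MPAP_SLOPE, MPAP_SD = 25.0, 40.0, 5.0
_SCANNERS = ("NM/CT 670 Pro", "StarGuide")
_P_SCANNER0 = {"CTEPH": 0.75, "control": 0.57}  # observed cohort proportions


def _trunc_draw(rng, mu, sd, lo, hi):
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return float(truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))


def generate_cohort(
    n_cteph: int,
    n_control: int,
    config_template: PhantomConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> SyntheticCohort:
    """Generate a synthetic study cohort with manifest.

    Per-subject phantom seeds follow the sequence ``seed + index`` so
    subjects are reproducible independently of each other.  The manifest
    carries group, scanner and synthetic hemodynamics; mPAP is linked to
    the true defect fraction (slope 40 mmHg per unit fraction, sd 5 mmHg)
    so that rank-correlation recovery is testable.

    If ``out_dir`` is given, CT/SPECT volumes are written as NIfTI and
    ``ct_path``/``spect_path`` columns are added; a ``manifest.csv`` is
    written alongside.
    """
    if n_cteph < 1 or n_control < 1:
        raise ValueError("need at least one subject per group")
    template = config_template or PhantomConfig()
    rng = np.random.default_rng(seed)
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    subjects: list[PhantomSubject] = []
    rows: list[dict] = []
    groups = ["CTEPH"] * n_cteph + ["control"] * n_control
    for i, group in enumerate(groups):
        if group == "CTEPH":
            target = _trunc_draw(rng, CTEPH_CENTER, CTEPH_SD, 0.02, 0.90)
            pattern = "cteph_segmental"
            n_wedges = int(rng.integers(2, 6))
        else:
            target = _trunc_draw(rng, CONTROL_CENTER, CONTROL_SD, 0.0, 0.90)
            pattern = "pah_mottled"
            n_wedges = 0
        scanner = _SCANNERS[int(rng.random() >= _P_SCANNER0[group])]
        cfg = replace(
            template,
            pattern=pattern,
            target_defect_fraction=target,
            n_wedges=n_wedges,
            seed=int((seed + i) % 2**31),
        )
        pair, truth = generate_phantom(cfg)
        sid = f"S{i + 1:03d}"
        mpap = MPAP_INTERCEPT + MPAP_SLOPE * target + rng.normal(0.0, MPAP_SD)
        row = {
            "subject_id": sid,
            "group": group,
            "scanner": scanner,
            "mPAP": round(mpap, 1),
            "sPAP": round(mpap * 1.55 + rng.normal(0.0, 4.0), 1),
            "dPAP": round(mpap * 0.62 + rng.normal(0.0, 3.0), 1),
            "PVR": round(max(0.5, 1.5 + 0.18 * (mpap - 20.0) + rng.normal(0.0, 1.2)), 1),
            "CI": round(float(np.clip(rng.normal(2.4, 0.35), 1.2, 4.0)), 2),
            "SpO2": round(float(np.clip(97.0 - 12.0 * target + rng.normal(0.0, 1.5), 80, 100)), 1),
            "true_defect_fraction": target,
        }
        if out is not None:
            ct_path = out / f"{sid}_ct.nii.gz"
            spect_path = out / f"{sid}_spect.nii.gz"
            write_nifti(pair.ct, cfg.spacing_mm, ct_path)
            write_nifti(pair.spect, cfg.spacing_mm, spect_path)
            row["ct_path"] = str(ct_path)
            row["spect_path"] = str(spect_path)
        rows.append(row)
        subjects.append(PhantomSubject(subject_id=sid, config=cfg, pair=pair, truth=truth))

    manifest = pd.DataFrame(rows)
    if out is not None:
        manifest.to_csv(out / "manifest.csv", index=False)
    return SyntheticCohort(subjects=subjects, manifest=manifest)
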