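# Methods

## Quantification model

The package quantifies perfusion heterogeneity on a co-registered
CT/SPECT pair as a *perfusion defect fraction*. The per-lung maximum
count is the raw peak voxel value inside the lung mask; all thresholds
and histogram edges are expressed relative to it, which makes every
quantity invariant to multiplying either lung's counts by a positive
constant (absolute scanner calibration cancels). A robust maximum
(e.g. an upper-percentile reference) would be less hotspot-sensitive and
is exposed as a documented alternative consideration, but the raw peak
is the default because it is the convention the metric is defined with.

Conventions, chosen once and applied everywhere:

- **Defect rule** — a voxel is a defect when its count is *strictly
  below* `t/100 × max_L` for its lung; a voxel exactly at the threshold
  is normal. Consequence: with no count exactly on a bin edge, the
  defect fraction at threshold `t` equals the cumulative pooled
  histogram below `t`.
- **Histogram bins** — ten equal intervals per lung, left-closed /
  right-open, final bin closed at the maximum so the peak voxel is
  counted exactly once (the bins partition `[0, max_L]`).
- **Pooling** — the two-lung histogram weights each lung's fractions by
  its share of total lung volume (equivalently, voxel counts under a
  shared spacing). The defect fraction pools as total defect volume
  over total lung volume.
- **Floating point** — scale invariance is exact in real arithmetic; in
  binary floating point a count lying exactly on a threshold can flip
  sides when counts are rescaled by a non-dyadic factor, because
  `0.1·c·max` rounds differently from `c·(0.1·max)`. This affects only
  measure-zero edge voxels of integer-count data and is irrelevant to
  noisy data; the property tests use power-of-two factors to verify the
  mathematical invariant exactly.

## Segmentation

Lung parenchyma is `HU ≤ −400` (inclusive; the bound is an *upper*
threshold). Exterior air is removed by a boundary-connectivity rule
rather than a lower HU bound: any thresholded component touching the
grid boundary is discarded. Components are 26-connected; those smaller
than 1 % of the largest interior component are dropped as noise, and
the two largest survivors become the lungs. Left/right assignment
compares component centroids against the body centroid along the
left-right axis (array axis 0 by convention, index increasing toward
the patient's left; overridable via `lr_axis`). The segmentation
refuses to guess on degenerate input: fewer than two interior
components, a single component spanning the midline, or two components
on the same side all raise with instructions to supply a manual mask
through `apply_mask_override`, which replaces masks wholesale,
recomputes volumes, and records a provenance flag. Morphological
closing is available but off by default — noise-free phantom CT does
not need it; vesselly clinical CT may.

## Phantom generator

The generator emulates the count statistics of clinical Tc-99m MAA
studies, not anatomy: the analysis depends only on count distributions
within masks, so two axis-aligned lung ellipsoids inside a body
ellipsoid suffice. Geometry is specified in fractions of the grid so
all structural properties are resolution-independent; generation
validates that the lungs are disjoint, interior, and separated from
exterior air by a 26-connectivity-proof body shell.

**Default scale.** Grid 72×52×60 voxels at 4 mm isotropic, giving
≈ 1000 mL per lung (≈ 2000 mL total, a realistic adult lung volume).
This resolution keeps a 30-subject cohort under a few seconds while
leaving ≈ 16 000 voxels per lung, ample for stable decile statistics.

**Count field.** In-lung noise-free intensity (in units of the
per-lung maximum) is built by quantile-mapping a target distribution
onto the radial profile `u = 1 − r³` (`r` = normalised ellipsoid
radius), so the *volume* histogram equals the target exactly in the
continuum limit while the field stays smooth, monotone, and
centre-bright. The healthy-parenchyma target is a truncated
Normal(0.35, 0.12) on [0.12, 1]: its mode puts the modal decile in the
30–40 %-of-max bin, the shape reported for non-CTEPH patients, and the
lower truncation keeps healthy tissue out of the < 10 % bin so defect
burden is controlled purely by inserted defects. Only the modal bins of
the clinical distributions are published, so the generator is
calibrated to the modal-bin property and nothing finer.

**Defect patterns.** `target_defect_fraction` is defined on the
noise-free field at the 10 % threshold.

- *control*: a low-intensity tail (uniform on [0.02, 0.08) of max)
  mixed into the quantile map with weight equal to the target, placed
  at the lung periphery by the radial mapping.
- *cteph_segmental*: `n_wedges` cone-shaped sectors anchored at each
  lung's hilum (medial point) with laterally biased random axes,
  mimicking segmental vascular territories. Wedge angular extent is
  set by voxel-count quantiles so the carved volume hits the target
  exactly (to one voxel); the per-lung peak voxel is protected so the
  reference maximum survives.
- *pah_mottled*: spatially uncorrelated spheres (radius 1.2–2.8
  voxels) of reduced uptake added until the voxel quota is met, the
  last blob trimmed to land exactly on target — the diffuse,
  non-segmental texture of Group 1 PAH.

Targets above 0.95, or a segmental pattern with defects but zero
wedges, raise a generation error.

**Noise.** Observed counts are Poisson draws of the noise-free field
scaled so the mean in-lung intensity equals `mean_counts` (default 50
counts/voxel, typical of reconstructed clinical studies at this voxel
size). Noisy defect fractions therefore differ from the noise-free
truth: Poisson fluctuation at the hot voxel inflates the measured
maximum and thus the thresholds, biasing measured fractions slightly
upward. Ground truth (masks, defect mask, defect fraction per
threshold, noise-free intensity) is recorded per phantom.

**Cohorts.** `generate_cohort` draws per-subject targets from truncated
normals — CTEPH-like: centre 0.34, sd 0.12; control-like: centre 0.06,
sd 0.04 (controls use the mottled pattern, as the dominant non-CTEPH
aetiology is PAH). Scanner labels follow the observed two-scanner
proportions (75 %/25 % in the diseased group, 57 %/43 % in controls).
Synthetic mPAP follows `25 + 40·fraction + N(0, 5)` mmHg, a positive
monotone link sized so rank-correlation recovery is testable; the other
hemodynamics (sPAP, dPAP, PVR, CI, SpO2) are plausible correlates of
mPAP and the defect burden. Per-subject phantom seeds are
`seed + index`, so subjects are reproducible independently.

**What the phantom does not emulate** — and therefore what passing
tests do not establish about clinical data: attenuation, scatter and
reconstruction physics; scanner-specific resolution and count-rate
differences; respiratory motion and misregistration; real anatomy
(lobar structure, vessels, airways); atelectasis and parenchymal
disease that complicate HU-threshold segmentation; and inter-observer
variability in manual corrections. Results on phantoms validate the
computational pipeline and its statistical behaviour, not clinical
diagnostic performance.

## Statistics

- **Routing** — Shapiro–Wilk per group at p ≥ 0.05 routes to Student's
  t (equal variances, mean ± SD summaries) or Mann–Whitney U
  (median/IQR summaries). Mann–Whitney is exact (full null
  distribution) when both groups have n ≤ 25 and no ties, else the
  tie- and continuity-corrected normal approximation.
- **Fisher 2×k** — full enumeration over tables with the observed
  margins (Freeman–Halton); the two-sided p sums probabilities no
  larger than the observed table's, with a 1e−9 relative tolerance
  against floating-point ties.
- **ROC/AUC** — candidate cutoffs are midpoints between consecutive
  distinct scores plus sentinels; positivity is `score > cutoff`. The
  AUC is the tie-corrected rank statistic (= trapezoidal area).
  Intervals: Hanley–McNeil (labelled "binomial"), DeLong variance, and
  a class-stratified percentile bootstrap (default 1000 replicates,
  seeded). Published AUC tables rarely state their CI method, so both
  analytic forms are emitted.
- **DeLong** — placement-value covariance estimator for paired AUCs,
  two-sided normal p. Identical scores return (z = 0, p = 1); a
  zero-variance difference with unequal AUCs raises, since there is no
  sampling variability to test against.
- **Cutoffs** — Youden maximises sensitivity + specificity − 1 with
  ties broken toward higher specificity, then higher cutoff (the more
  conservative rule-in choice); the screening cutoff is the largest
  with sensitivity 1.0. Sensitivity/specificity get Clopper–Pearson
  exact intervals (inverse-Beta; closed forms `(α/2)^(1/n)` at the
  boundaries).
- **Spearman CI** — Fisher z with variance `1/(n−3)`. Published
  clinical CIs for Spearman coefficients at n = 16 reproduce with this
  variance and not with Fieller's `1.06/(n−3)` inflation, so the plain
  form is the default and Fieller is an option.
- **Multiplicity** — Bonferroni at 0.05/9 ≈ 0.0056 across the nine
  threshold comparisons.

## Pipeline

`run_study` quantifies every subject (in-memory cohort or NIfTI
manifest), assembles a per-subject table (defect fractions in percent,
pooled histogram, lung volumes, covariates), and runs: baseline
covariate comparisons plus a scanner Fisher test; the nine threshold
comparisons with Bonferroni flags; ROC with all three CIs at 10–50 %;
DeLong tests of each exploratory threshold against the pre-specified
primary 10 %; Youden/screening cutoffs at 10 %; Spearman vs mPAP in
the diseased group only; and scanner-stratified subgroups that re-use
the full-cohort cutoffs (subgroup operating points are evaluations, not
re-optimisations). Subjects whose segmentation or quantification fails
are excluded with a logged reason and an exclusion table — never
silently. The report is JSON-native and byte-identical across reruns
with the same seed. Figures (decile histogram with SD bars, box plots,
ROC curves) are optional artifacts; the JSON numbers are the contract.

## Problem sizes in tests

Unit and property tests run phantoms on a 36×26×30 grid (~2000 voxels
per lung), which preserves every structural property of the default
geometry at a fraction of the cost; oracle-equality tests use random
8×8×8 volumes where brute-force voxel loops are feasible. The cohort
parameter-recovery check uses 20 seeded 16-vs-14 cohorts at the default
grid. DeLong calibration uses 1000 null simulations at n = 30.

## Known limitations

- The phantom's radial base profile is deterministic; real parenchyma
  has spatially correlated texture the generator does not model.
- The raw-peak maximum makes all relative thresholds sensitive to a
  single hot voxel under noise (a limitation shared with the clinical
  convention it follows).
- Left/right assignment assumes the array axes follow the documented
  orientation convention; data with arbitrary affines must be
  reoriented before analysis.
- The Freeman–Halton enumeration is exponential in k and intended for
  the small categorical tables of a baseline-characteristics table.
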