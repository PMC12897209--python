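# perfquant

Quantitative analysis of lung perfusion SPECT/CT for chronic
thromboembolic pulmonary hypertension (CTEPH).

Perfusion-only SPECT/CT with Tc-99m MAA is a pragmatic first-line study
for suspected CTEPH when ventilation imaging is infeasible, but routine
reads are qualitative. `perfquant` implements a standardized volumetric
metric — the **perfusion defect fraction** — together with the full
diagnostic-statistics layer needed to evaluate it in a two-group study,
and a digital thorax phantom generator for validation when clinical
images are unavailable.

## The metric

For a co-registered CT/SPECT pair:

1. lungs are segmented from CT by an upper Hounsfield threshold
   (HU ≤ −400) with boundary-connected air excluded and 26-connected
   component analysis (manual mask override supported);
2. the maximum perfusion count `max_L` is found separately for each
   lung (peak voxel value);
3. counts per lung are divided into ten equal intervals on
   `[0, max_L]`, giving a volume-fraction histogram;
4. at a decile threshold `t = k·10 %` (k = 1..9), in-lung voxels with
   counts strictly below `t·max_L` are perfusion defects, and

   ```
   defect fraction(t) = (defect volume, both lungs) / (total lung volume)
   ```

Because thresholds are relative to each lung's own maximum, the metric
is invariant to count calibration. The 10 % threshold is the primary
read-out; 20–90 % are exploratory.

The statistics layer provides Shapiro–Wilk-routed group comparisons
(Student's t / Mann–Whitney U with exact small-sample enumeration),
Fisher's exact test for 2×k tables (Freeman–Halton enumeration),
tie-corrected rank AUC with Hanley–McNeil, DeLong and stratified
bootstrap confidence intervals, DeLong paired ROC comparison,
Youden-index and sensitivity-maximising cutoffs with Clopper–Pearson
exact intervals, Spearman correlation with a Fisher-z interval, and
Bonferroni correction across the nine thresholds.

## Worked example

```python
import perfquant as pq

# synthetic study cohort: 16 CTEPH-like phantoms (wedge-shaped segmental
# defects), 14 control-like (mottled PAH-like texture), Poisson counts
cohort = pq.generate_cohort(n_cteph=16, n_control=14, seed=1)
result = pq.run_study(cohort, seed=17, n_boot=1000)
r = result.report

cmp10 = r["group_comparisons"]["10"]
roc10 = r["roc"]["10"]
opt = r["cutoffs"]["optimal"]
sp = r["spearman_mpap"]["10"]
```

This prints (see `report` fields used above):

```
defect fraction @10%: CTEPH 32.5% vs control 8.1%  (p = 1.5e-07, t_test)
AUC @10%: 0.951  (bootstrap 95% CI 0.857-1.000)
optimal cutoff: >18.2%  sensitivity 88%, specificity 100%
Spearman r_s (defect fraction @10% vs mPAP, CTEPH only): 0.63 (p = 0.0087)
```

Reading: the diseased phantoms carry a four-fold higher defect burden at
the 10 % threshold; the metric separates the groups almost perfectly
(AUC 0.951); the Youden-optimal rule-in cutoff is a defect fraction of
18.2 % of lung volume; and within the diseased group the defect
fraction rises with mean pulmonary arterial pressure, as the generator's
mPAP link prescribes.

`render_tables(result, out_dir)` writes the four standard result tables
(baseline characteristics, AUC per threshold, confusion matrices at the
screening and optimal cutoffs, defect-fraction/mPAP correlation) as CSV,
plus the full JSON report; `make_figures` adds histogram/box-plot/ROC
SVGs.

## Command line

```sh
perfquant phantom  --n-cteph 16 --n-control 14 --seed 1 --out cohort/
perfquant segment  --ct ct.nii.gz --hu-upper -400 --out-left L.nii.gz --out-right R.nii.gz
perfquant quantify --ct ct.nii.gz --spect spect.nii.gz --out profile.json
perfquant run      --manifest cohort/manifest.csv --seed 17 --out results/ --plots
```

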