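"""End-to-end study orchestration.

Runs the full analysis over a cohort of paired CT/SPECT volumes:
segmentation, decile quantification, a per-subject cohort table, and the
diagnostic-statistics battery (group comparisons with Bonferroni
correction over the nine thresholds, per-threshold ROC with bootstrap
and DeLong inference, cutoff selection at the pre-specified primary
10 % threshold, Spearman correlation with mPAP restricted to the
diseased group, and scanner-stratified subgroups re-using the
full-cohort cutoffs).

Defect fractions are reported in percent throughout the pipeline so
cutoffs read like clinical values (e.g. ">20.6 %").  Subjects whose
segmentation or quantification fails are excluded explicitly and listed
in an exclusion table; the pipeline never drops subjects silently.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as pqstats
from .phantom import SyntheticCohort
from .quantify import (
    THRESHOLD_PERCENTS,
    QuantificationError,
    decile_histogram,
    defect_profile,
)
from .segmentation import SegmentationError, segment_lungs
from .volume import VolumePair, read_nifti

__all__ = ["StudyResult", "run_study", "load_manifest_cohort", "render_tables", "make_figures"]

log = logging.getLogger("perfquant")

ROC_THRESHOLDS: tuple[int, ...] = (10, 20, 30, 40, 50)
PRIMARY_THRESHOLD = 10
FAMILY_ALPHA = 0.05
HEMODYNAMIC_COLS = ("sPAP", "dPAP", "mPAP", "PVR", "CI", "SpO2")


@dataclass(frozen=True)
class StudyResult:
    cohort_table: pd.DataFrame
    report: dict
    exclusions: pd.DataFrame

    def report_json(self) -> str:
        return json.dumps(self.report, sort_keys=True, indent=2)


def _quantify_subject(subject_id: str, pair: VolumePair, hu_upper: float) -> dict:
    masks = segment_lungs(pair, hu_upper=hu_upper)
    profile = defect_profile(pair, masks)
    hist = decile_histogram(pair, masks)
    row: dict = {"subject_id": subject_id}
    vols = masks.volume_ml
    row["lung_volume_ml_left"] = vols["left"]
    row["lung_volume_ml_right"] = vols["right"]
    row["lung_volume_ml_total"] = vols["total"]
    for t in THRESHOLD_PERCENTS:
        row[f"defect_fraction_{t}"] = profile.defect_fraction[t] * 100.0  # percent
        row[f"defect_volume_ml_{t}"] = profile.defect_volume_ml[t]
    for k in range(10):
        row[f"hist_pooled_{k + 1}"] = float(hist.volume_fraction["pooled"][k])
    return row


def load_manifest_cohort(manifest: pd.DataFrame | str | Path) -> list[tuple[str, VolumePair, dict]]:
    """Resolve a manifest (CSV path or DataFrame) into loaded volume pairs."""
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    required = {"subject_id", "group", "ct_path", "spect_path"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    out = []
    for rec in manifest.to_dict("records"):
        ct, spacing = read_nifti(rec["ct_path"])
        spect, spacing2 = read_nifti(rec["spect_path"])
        if not np.allclose(spacing, spacing2):
            raise ValueError(f"{rec['subject_id']}: CT/SPECT spacing mismatch")
        out.append((str(rec["subject_id"]), VolumePair(ct, spect, spacing), rec))
    return out


def run_study(
    cohort: SyntheticCohort | pd.DataFrame | str | Path,
    seed: int = 17,
    n_boot: int = 1000,
    hu_upper: float = -400.0,
    conf: float = 0.95,
) -> StudyResult:
    """Run the full quantitative study on a cohort.

    ``cohort`` is either an in-memory :class:`SyntheticCohort` or a
    manifest (CSV path / DataFrame) whose rows point at NIfTI files.
    ``seed`` drives all resampling (bootstrap CIs); the run is
    deterministic given the seed and inputs.
    """
    if isinstance(cohort, SyntheticCohort):
        loaded = [
            (s.subject_id, s.pair, cohort.manifest.iloc[i].to_dict())
            for i, s in enumerate(cohort.subjects)
        ]
    else:
        loaded = load_manifest_cohort(cohort)

    rows: list[dict] = []
    excluded: list[dict] = []
    for subject_id, pair, meta in loaded:
        try:
            row = _quantify_subject(subject_id, pair, hu_upper)
        except (SegmentationError, QuantificationError) as exc:
            log.warning("excluding %s: %s", subject_id, exc)
            excluded.append({"subject_id": subject_id, "reason": str(exc)})
            continue
        row["group"] = str(meta["group"])
        row["scanner"] = str(meta.get("scanner", "unknown"))
        for col in HEMODYNAMIC_COLS:
            if col in meta:
                row[col] = float(meta[col])
        rows.append(row)

    table = pd.DataFrame(rows)
    exclusions = pd.DataFrame(excluded, columns=["subject_id", "reason"])
    if table.empty or table["subject_id"].duplicated().any():
        raise ValueError("cohort table empty or has duplicate subject ids")
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    disease = "CTEPH" if "CTEPH" in groups else groups[0]
    control = next(g for g in groups if g != disease)
    if min((table["group"] == g).sum() for g in groups) < 2:
        raise ValueError("need at least two subjects per group after exclusions")
    is_case = (table["group"] == disease).to_numpy()

    report: dict = {
        "groups": {"disease": disease, "control": control},
        "n": {disease: int(is_case.sum()), control: int((~is_case).sum())},
        "exclusions": excluded,
        "primary_threshold_percent": PRIMARY_THRESHOLD,
        "bonferroni": {
            "family_alpha": FAMILY_ALPHA,
            "m": len(THRESHOLD_PERCENTS),
            "alpha": pqstats.bonferroni_alpha(FAMILY_ALPHA, len(THRESHOLD_PERCENTS)),
        },
    }

    # --- baseline covariates (routed comparisons + scanner Fisher test)
    baseline: dict = {}
    covars = ["lung_volume_ml_total", *[c for c in HEMODYNAMIC_COLS if c in table.columns]]
    for col in covars:
        try:
            cmpres = pqstats.compare_groups(table[col].to_numpy(), table["group"].to_numpy())
            baseline[col] = _comparison_dict(cmpres)
        except ValueError as exc:
            baseline[col] = {"error": str(exc)}
    scanner_tab = pd.crosstab(table["group"], table["scanner"])
    if scanner_tab.shape[1] >= 2:
        baseline["scanner"] = {
            "table": scanner_tab.to_dict(),
            "p_value": pqstats.fisher_exact_2xk(scanner_tab.to_numpy()),
        }
    report["baseline"] = baseline

    # --- per-threshold group comparisons with Bonferroni flags
    alpha = report["bonferroni"]["alpha"]
    comparisons: dict = {}
    for t in THRESHOLD_PERCENTS:
        cmpres = pqstats.compare_groups(
            table[f"defect_fraction_{t}"].to_numpy(), table["group"].to_numpy()
        )
        d = _comparison_dict(cmpres)
        d["bonferroni_significant"] = bool(cmpres.p_value < alpha)
        comparisons[str(t)] = d
    report["group_comparisons"] = comparisons

    # --- ROC per threshold 10-50 %, bootstrap CI, DeLong vs primary
    roc_block: dict = {}
    rocs: dict[int, pqstats.RocResult] = {}
    for t in ROC_THRESHOLDS:
        scores = table[f"defect_fraction_{t}"].to_numpy()
        roc = pqstats.roc_curve(scores, is_case, conf=conf)
        boot = pqstats.bootstrap_auc_ci(
            scores, is_case, n_boot=n_boot, seed=(seed + t) % 2**31, conf=conf
        )
        rocs[t] = roc
        roc_block[str(t)] = {
            "auc": roc.auc,
            "auc_ci_binomial": list(roc.auc_ci_binomial),
            "auc_ci_delong": list(roc.auc_ci_delong),
            "auc_ci_bootstrap": list(boot),
            "n_boot": n_boot,
        }
    report["roc"] = roc_block
    delong: dict = {}
    primary_scores = table[f"defect_fraction_{PRIMARY_THRESHOLD}"].to_numpy()
    for t in ROC_THRESHOLDS:
        if t == PRIMARY_THRESHOLD:
            continue
        _, _, z, p = pqstats.delong_test(
            primary_scores, table[f"defect_fraction_{t}"].to_numpy(), is_case
        )
        delong[str(t)] = {"z": z, "p_value": p}
    report["delong_vs_primary"] = delong

    # --- cutoffs at the primary threshold
    youden, screening = pqstats.select_cutoffs(rocs[PRIMARY_THRESHOLD], conf=conf)
    report["cutoffs"] = {"optimal": asdict(youden), "screening": asdict(screening)}

    # --- Spearman vs mPAP in the diseased group only
    if "mPAP" in table.columns:
        sp: dict = {}
        sub = table[is_case]
        for t in ROC_THRESHOLDS:
            try:
                r_s, lo, hi, p = pqstats.spearman_ci(
                    sub[f"defect_fraction_{t}"].to_numpy(), sub["mPAP"].to_numpy(), conf=conf
                )
                sp[str(t)] = {"r_s": r_s, "ci": [lo, hi], "p_value": p}
            except ValueError as exc:
                sp[str(t)] = {"error": str(exc)}
        report["spearman_mpap"] = sp

    # --- scanner-stratified subgroups, re-using the full-cohort cutoffs
    subgroups: dict = {}
    for scanner, sub in table.groupby("scanner"):
        sub_case = (sub["group"] == disease).to_numpy()
        block: dict = {
            "n": {disease: int(sub_case.sum()), control: int((~sub_case).sum())}
        }
        if sub_case.sum() >= 2 and (~sub_case).sum() >= 2:
            scores = sub[f"defect_fraction_{PRIMARY_THRESHOLD}"].to_numpy()
            roc = pqstats.roc_curve(scores, sub_case, conf=conf)
            block["auc_10"] = roc.auc
            block["auc_10_ci_binomial"] = list(roc.auc_ci_binomial)
            block["comparisons"] = {}
            for t in (10, 20, 30, 40):
                try:
                    cmpres = pqstats.compare_groups(
                        sub[f"defect_fraction_{t}"].to_numpy(), sub["group"].to_numpy()
                    )
                    block["comparisons"][str(t)] = {"p_value": cmpres.p_value}
                except ValueError as exc:
                    block["comparisons"][str(t)] = {"error": str(exc)}
            block["at_cutoffs"] = {}
            for name in ("optimal", "screening"):
                cut = report["cutoffs"][name]["cutoff_value"]
                pos = scores > cut
                tp = int((pos & sub_case).sum())
                fn = int((~pos & sub_case).sum())
                fp = int((pos & ~sub_case).sum())
                tn = int((~pos & ~sub_case).sum())
                block["at_cutoffs"][name] = {
                    "cutoff_value": cut,
                    "tp": tp,
                    "fn": fn,
                    "fp": fp,
                    "tn": tn,
                    "sensitivity": tp / (tp + fn),
                    "specificity": tn / (tn + fp),
                    "sens_ci": list(pqstats.clopper_pearson(tp, tp + fn, conf)),
                    "spec_ci": list(pqstats.clopper_pearson(tn, tn + fp, conf)),
                }
        subgroups[str(scanner)] = block
    report["scanner_subgroups"] = subgroups

    return StudyResult(cohort_table=table, report=_jsonify(report), exclusions=exclusions)


def _jsonify(obj):
    """Normalise a report tree to JSON-native types (lists, floats, ints)."""
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def _comparison_dict(c: pqstats.GroupComparison) -> dict:
    return {
        "test_name": c.test_name,
        "statistic": c.statistic,
        "p_value": c.p_value,
        "group_summaries": c.group_summaries,
        "normality_p": c.normality_p,
    }


# ---------------------------------------------------------------------------
# rendering


def render_tables(result: StudyResult, out_dir: str | Path | None = None) -> dict[str, pd.DataFrame]:
    """Render the four result tables (baseline, AUC, confusion, correlation).

    Percentages are formatted to one decimal and rank correlations to
    two, matching clinical reporting conventions.  Missing report blocks
    produce a warning and a partial render rather than an error.
    """
    report = result.report
    tables: dict[str, pd.DataFrame] = {}

    rows = []
    for var, block in report.get("baseline", {}).items():
        if var == "scanner" or "error" in block:
            continue
        summ = block["group_summaries"]
        fmt = {}
        for g, s in summ.items():
            if "mean" in s:
                fmt[g] = f"{s['mean']:.1f} ± {s['sd']:.1f}"
            else:
                fmt[g] = f"{s['median']:.1f} ({s['q1']:.1f}–{s['q3']:.1f})"
        rows.append({"variable": var, **fmt, "p_value": round(block["p_value"], 4)})
    if "scanner" in report.get("baseline", {}):
        rows.append(
            {
                "variable": "scanner",
                "p_value": round(report["baseline"]["scanner"]["p_value"], 4),
            }
        )
    tables["table1"] = pd.DataFrame(rows)

    rows = [
        {
            "threshold": f"{t}%",
            "auc": round(b["auc"], 3),
            "ci_low": round(b["auc_ci_binomial"][0], 3),
            "ci_high": round(b["auc_ci_binomial"][1], 3),
        }
        for t, b in sorted(report.get("roc", {}).items(), key=lambda kv: int(kv[0]))
    ]
    tables["table2"] = pd.DataFrame(rows)

    rows = []
    disease = report["groups"]["disease"]
    control = report["groups"]["control"]
    for name in ("screening", "optimal"):
        cut = report.get("cutoffs", {}).get(name)
        if cut is None:
            continue
        rows.append(
            {
                "cutoff": f">{cut['cutoff_value']:.1f}%",
                "group": disease,
                "positive": cut["tp"],
                "negative": cut["fn"],
            }
        )
        rows.append(
            {
                "cutoff": f">{cut['cutoff_value']:.1f}%",
                "group": control,
                "positive": cut["fp"],
                "negative": cut["tn"],
            }
        )
    tables["table3"] = pd.DataFrame(rows)

    sp = report.get("spearman_mpap")
    if sp:
        rows = [
            {
                "threshold": f"{t}%",
                "r_s": round(b["r_s"], 2),
                "ci_low": round(b["ci"][0], 2),
                "ci_high": round(b["ci"][1], 2),
                "p_value": round(b["p_value"], 4),
            }
            for t, b in sorted(sp.items(), key=lambda kv: int(kv[0]))
            if "error" not in b
        ]
        tables["table4"] = pd.DataFrame(rows)
    else:
        warnings.warn("correlation block missing; table4 omitted", stacklevel=2)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in tables.items():
            df.to_csv(out / f"{name}.csv", index=False)
        (out / "report.json").write_text(result.report_json())
    return tables


def make_figures(result: StudyResult, out_dir: str | Path) -> list[Path]:
    """Optional SVG figures: decile histogram, defect-fraction box plots, ROC."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = result.cohort_table
    disease = result.report["groups"]["disease"]
    paths: list[Path] = []

    fig, ax = plt.subplots(figsize=(7, 4))
    centers = np.arange(10) * 10 + 5
    width = 4.0
    for off, (g, sub) in zip((-width / 2, width / 2), table.groupby("group")):
        mean = [sub[f"hist_pooled_{k + 1}"].mean() for k in range(10)]
        sd = [sub[f"hist_pooled_{k + 1}"].std(ddof=1) for k in range(10)]
        ax.bar(centers + off, mean, width=width, yerr=sd, capsize=2, label=str(g))
    ax.set_xlabel("perfusion-count interval (% of per-lung max)")
    ax.set_ylabel("lung volume fraction")
    ax.legend()
    p = out / "histogram.svg"
    fig.savefig(p)
    plt.close(fig)
    paths.append(p)

    fig, axes = plt.subplots(1, 5, figsize=(14, 4), sharey=False)
    for ax, t in zip(axes, ROC_THRESHOLDS):
        data = [sub[f"defect_fraction_{t}"] for _, sub in table.groupby("group")]
        ax.boxplot(data, tick_labels=[str(g) for g, _ in table.groupby("group")])
        ax.set_title(f"{t}% threshold")
        ax.set_ylabel("defect fraction (%)")
    fig.tight_layout()
    p = out / "boxplots.svg"
    fig.savefig(p)
    plt.close(fig)
    paths.append(p)

    fig, ax = plt.subplots(figsize=(5, 5))
    is_case = (table["group"] == disease).to_numpy()
    for t in ROC_THRESHOLDS:
        roc = pqstats.roc_curve(table[f"defect_fraction_{t}"].to_numpy(), is_case)
        ax.plot(1 - roc.specificities, roc.sensitivities, label=f"{t}% (AUC {roc.auc:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=8)
    p = out / "roc.svg"
    fig.savefig(p)
    plt.close(fig)
    paths.append(p)
    return paths
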