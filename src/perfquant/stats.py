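"""Diagnostic statistics layer.

Implements the statistical battery of a small two-group diagnostic
study: Shapiro-Wilk-routed group comparisons (Student's t vs
Mann-Whitney U), Fisher's exact test for 2 x k tables, ROC analysis with
tie-corrected rank AUC, stratified bootstrap and DeLong AUC inference,
Youden-index and sensitivity-maximising cutoff selection with
Clopper-Pearson exact intervals, Spearman correlation with a Fisher-z
interval, and Bonferroni correction.

Orientation convention: a subject is called test-positive when its
metric is strictly *greater than* the cutoff (the defect fraction rises
with disease).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "RocResult",
    "CutoffReport",
    "clopper_pearson",
    "roc_curve",
    "bootstrap_auc_ci",
    "delong_test",
    "select_cutoffs",
    "spearman_ci",
    "bonferroni_alpha",
    "compare_groups",
    "fisher_exact_2xk",
]


# ---------------------------------------------------------------------------
# exact binomial interval


def clopper_pearson(successes: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Clopper-Pearson exact binomial confidence interval (proportions).

    Bounds are the usual inverse-Beta quantiles; the lower bound is 0
    exactly when ``successes == 0`` and the upper bound 1 exactly when
    ``successes == n``.
    """
    if not (isinstance(successes, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValueError("successes and n must be integers")
    if n < 1 or not 0 <= successes <= n:
        raise ValueError(f"invalid counts: successes={successes}, n={n}")
    alpha = 1.0 - conf
    lo = 0.0 if successes == 0 else float(sps.beta.ppf(alpha / 2, successes, n - successes + 1))
    hi = 1.0 if successes == n else float(sps.beta.ppf(1 - alpha / 2, successes + 1, n - successes))
    return lo, hi


# ---------------------------------------------------------------------------
# ROC / AUC


@dataclass(frozen=True)
class RocResult:
    """ROC curve with AUC and confidence intervals.

    ``thresholds`` are candidate cutoffs (midpoints between consecutive
    distinct scores plus sentinels below/at the extremes); positivity is
    ``score > cutoff``.  ``auc`` is the tie-corrected rank (Mann-Whitney)
    AUC, identical to the trapezoidal area of the ROC polygon.
    ``auc_ci_binomial`` is the Hanley-McNeil normal-approximation
    interval; ``auc_ci_delong`` uses the DeLong variance; both are
    emitted because published tables rarely say which was used.
    """

    thresholds: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray
    auc: float
    auc_ci_binomial: tuple[float, float]
    auc_ci_delong: tuple[float, float]
    auc_ci_bootstrap: tuple[float, float] | None = None
    n_boot: int = 0


def _check_scores_labels(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return scores, labels


def _rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected rank AUC = U / (n1 * n0)."""
    n1 = int(labels.sum())
    n0 = labels.size - n1
    ranks = sps.rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values (per-case and per-control)."""
    x = scores[labels][:, None]
    y = scores[~labels][None, :]
    psi = (x > y).astype(float) + 0.5 * (x == y)
    return psi.mean(axis=1), psi.mean(axis=0)


def _delong_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def roc_curve(scores, labels, conf: float = 0.95) -> RocResult:
    """ROC analysis of a continuous score against binary labels.

    ``labels`` is truthy for the diseased class.  Candidate cutoffs are
    all midpoints between consecutive distinct scores, plus one below
    the minimum (everything positive) and one at the maximum (nothing
    positive).
    """
    scores, labels = _check_scores_labels(scores, labels)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    uniq = np.unique(scores)
    cuts = np.concatenate([[uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1]]])
    pos = scores[None, :] > cuts[:, None]
    tp = (pos & labels[None, :]).sum(axis=1)
    fp = (pos & ~labels[None, :]).sum(axis=1)
    fn = n1 - tp
    tn = n0 - fp
    sens = tp / n1
    spec = tn / n0

    auc = _rank_auc(scores, labels)
    z = sps.norm.ppf(1 - (1 - conf) / 2)
    # Hanley & McNeil (1982) standard error
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    se_hm = np.sqrt(
        (auc * (1 - auc) + (n1 - 1) * (q1 - auc**2) + (n0 - 1) * (q2 - auc**2)) / (n1 * n0)
    )
    ci_hm = (max(0.0, auc - z * se_hm), min(1.0, auc + z * se_hm))
    v10, v01 = _placements(scores, labels)
    se_dl = np.sqrt(_delong_variance(v10, v01))
    ci_dl = (max(0.0, auc - z * se_dl), min(1.0, auc + z * se_dl))
    return RocResult(
        thresholds=cuts,
        sensitivities=sens,
        specificities=spec,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        auc=auc,
        auc_ci_binomial=ci_hm,
        auc_ci_delong=ci_dl,
    )


def bootstrap_auc_ci(
    scores, labels, n_boot: int = 1000, seed: int | None = None, conf: float = 0.95
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC, stratified by class.

    Cases and controls are resampled separately so every replicate
    contains both classes.
    """
    scores, labels = _check_scores_labels(scores, labels)
    rng = np.random.default_rng(seed)
    pos = scores[labels]
    neg = scores[~labels]
    n1, n0 = pos.size, neg.size
    aucs = np.empty(n_boot)
    lab = np.concatenate([np.ones(n1, dtype=bool), np.zeros(n0, dtype=bool)])
    for b in range(n_boot):
        sample = np.concatenate(
            [pos[rng.integers(0, n1, n1)], neg[rng.integers(0, n0, n0)]]
        )
        aucs[b] = _rank_auc(sample, lab)
    alpha = 1.0 - conf
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def delong_test(scores_a, scores_b, labels) -> tuple[float, float, float, float]:
    """DeLong comparison of two correlated AUCs measured on the same subjects.

    Returns ``(auc_a, auc_b, z, p)`` with a two-sided normal p-value.
    Identical score vectors give z = 0, p = 1; a zero-variance
    difference with unequal AUCs is an error (no sampling variability to
    test against).
    """
    scores_a, labels = _check_scores_labels(scores_a, labels)
    scores_b, _ = _check_scores_labels(scores_b, labels)
    va10, va01 = _placements(scores_a, labels)
    vb10, vb01 = _placements(scores_b, labels)
    auc_a = float(va10.mean())
    auc_b = float(vb10.mean())
    m, n = va10.size, va01.size
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0:
        if abs(diff) < 1e-12:
            return auc_a, auc_b, 0.0, 1.0
        raise ValueError(
            "DeLong variance of the AUC difference is zero while the AUCs "
            "differ; the paired scores are degenerate (e.g. monotone "
            "transforms of each other with perfect separation)"
        )
    z = diff / np.sqrt(var)
    p = 2 * sps.norm.sf(abs(z))
    return auc_a, auc_b, float(z), float(p)


# ---------------------------------------------------------------------------
# cutoff selection


@dataclass(frozen=True)
class CutoffReport:
    """Operating point on the ROC curve with exact intervals."""

    cutoff_value: float
    orientation: str
    tp: int
    fn: int
    fp: int
    tn: int
    sensitivity: float
    specificity: float
    sens_ci: tuple[float, float]
    spec_ci: tuple[float, float]
    criterion: str

    def __post_init__(self) -> None:
        if abs(self.sensitivity - self.tp / (self.tp + self.fn)) > 1e-12:
            raise ValueError("sensitivity inconsistent with tp/fn")
        if abs(self.specificity - self.tn / (self.tn + self.fp)) > 1e-12:
            raise ValueError("specificity inconsistent with tn/fp")


def _report_at(roc: RocResult, i: int, criterion: str, conf: float) -> CutoffReport:
    tp, fn, fp, tn = int(roc.tp[i]), int(roc.fn[i]), int(roc.fp[i]), int(roc.tn[i])
    return CutoffReport(
        cutoff_value=float(roc.thresholds[i]),
        orientation="positive if metric > cutoff",
        tp=tp,
        fn=fn,
        fp=fp,
        tn=tn,
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        sens_ci=clopper_pearson(tp, tp + fn, conf),
        spec_ci=clopper_pearson(tn, tn + fp, conf),
        criterion=criterion,
    )


def select_cutoffs(roc: RocResult, conf: float = 0.95) -> tuple[CutoffReport, CutoffReport]:
    """Youden-optimal and sensitivity-maximising cutoffs.

    The Youden cutoff maximises sensitivity + specificity - 1, breaking
    ties toward higher specificity and then the higher cutoff value (the
    more conservative rule-in threshold).  The screening cutoff is the
    largest cutoff that still attains sensitivity 1.0.
    """
    j = roc.sensitivities + roc.specificities - 1.0
    order = np.lexsort((roc.thresholds, roc.specificities, j))
    youden = _report_at(roc, int(order[-1]), "youden", conf)
    full_sens = np.flatnonzero(roc.sensitivities >= 1.0)
    i_screen = int(full_sens[np.argmax(roc.thresholds[full_sens])])
    screening = _report_at(roc, i_screen, "max_sensitivity", conf)
    return youden, screening


# ---------------------------------------------------------------------------
# correlation


def spearman_ci(
    x, y, conf: float = 0.95, fieller: bool = False
) -> tuple[float, float, float, float]:
    """Spearman rank correlation with Fisher-z confidence interval.

    Returns ``(r_s, lo, hi, p)``.  Ties receive average ranks; the
    two-sided p-value comes from the t reference distribution.  The
    interval uses ``z = atanh(r_s)`` with variance ``1/(n-3)`` by
    default; ``fieller=True`` switches to Fieller's 1.06/(n-3) inflation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 4:
        raise ValueError("need paired 1-D vectors with n >= 4")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    res = sps.spearmanr(x, y)
    r_s = float(res.statistic)
    p = float(res.pvalue)
    n = x.size
    var = (1.06 if fieller else 1.0) / (n - 3)
    zcrit = sps.norm.ppf(1 - (1 - conf) / 2)
    z = np.arctanh(np.clip(r_s, -1 + 1e-15, 1 - 1e-15))
    lo, hi = np.tanh(z - zcrit * np.sqrt(var)), np.tanh(z + zcrit * np.sqrt(var))
    return r_s, float(lo), float(hi), p


def bonferroni_alpha(family_alpha: float = 0.05, m: int = 9) -> float:
    """Per-comparison significance level for an m-way Bonferroni family."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return family_alpha / m


# ---------------------------------------------------------------------------
# group comparisons


@dataclass(frozen=True)
class GroupComparison:
    """Two-group comparison routed by Shapiro-Wilk normality.

    Both groups normal (p >= 0.05) -> Student's t-test with mean +/- SD
    summaries; otherwise Mann-Whitney U with median (IQR) summaries.
    """

    test_name: str
    statistic: float
    p_value: float
    group_summaries: dict[str, dict[str, float]]
    normality_p: dict[str, float]


def compare_groups(values, group_labels, normality_alpha: float = 0.05) -> GroupComparison:
    """Compare a continuous variable between two groups.

    The Mann-Whitney branch uses exact enumeration when both groups have
    n <= 25 and there are no ties, and the tie/continuity-corrected
    normal approximation otherwise.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    names = list(dict.fromkeys(group_labels.tolist()))
    if len(names) != 2:
        raise ValueError(f"need exactly two groups, got {names}")
    a = values[group_labels == names[0]]
    b = values[group_labels == names[1]]
    if min(a.size, b.size) < 3:
        raise ValueError("need n >= 3 per group")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ValueError("all values identical within groups; cannot route by normality")
    norm_p: dict[str, float] = {}
    for name, g in zip(names, (a, b)):
        if np.ptp(g) == 0:
            norm_p[str(name)] = 0.0  # constant group: treat as non-normal
        else:
            norm_p[str(name)] = float(sps.shapiro(g).pvalue)
    if all(p >= normality_alpha for p in norm_p.values()):
        res = sps.ttest_ind(a, b, equal_var=True)
        summaries = {
            str(name): {"mean": float(g.mean()), "sd": float(g.std(ddof=1))}
            for name, g in zip(names, (a, b))
        }
        return GroupComparison("t_test", float(res.statistic), float(res.pvalue), summaries, norm_p)
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 25 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    summaries = {}
    for name, g in zip(names, (a, b)):
        q1, med, q3 = np.percentile(g, [25, 50, 75])
        summaries[str(name)] = {"median": float(med), "q1": float(q1), "q3": float(q3)}
    return GroupComparison(
        "mann_whitney", float(res.statistic), float(res.pvalue), summaries, norm_p
    )


def fisher_exact_2xk(table) -> float:
    """Fisher's exact test for a 2 x k contingency table (two-sided).

    For k = 2 this is the classical Fisher exact test; for k > 2 the
    Freeman-Halton extension, computed by full enumeration of tables
    with the observed margins under the hypergeometric null.  The
    p-value sums the probabilities of all tables no more probable than
    the observed one (with a small relative tolerance against floating-
    point ties).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] != 2:
        raise ValueError("table must be 2 x k")
    if np.any(t < 0):
        raise ValueError("table entries must be non-negative integers")
    col_sums = t.sum(axis=0)
    row1 = int(t.sum(axis=1)[0])
    n_total = int(t.sum())
    if n_total == 0:
        raise ValueError("empty table")
    denom = comb(n_total, row1)

    def table_prob(top_row) -> float:
        num = 1
        for a, c in zip(top_row, col_sums):
            num *= comb(int(c), int(a))
        return num / denom

    p_obs = table_prob(t[0])
    total = 0.0

    def recurse(col: int, remaining: int, prob_partial: int) -> None:
        nonlocal total
        if col == len(col_sums) - 1:
            c = int(col_sums[col])
            if 0 <= remaining <= c:
                prob = prob_partial * comb(c, remaining) / denom
                if prob <= p_obs * (1 + 1e-9):
                    total += prob
            return
        c = int(col_sums[col])
        lo = max(0, remaining - int(col_sums[col + 1 :].sum()))
        hi = min(c, remaining)
        for a in range(lo, hi + 1):
            recurse(col + 1, remaining - a, prob_partial * comb(c, a))

    recurse(0, row1, 1)
    return float(min(total, 1.0))
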