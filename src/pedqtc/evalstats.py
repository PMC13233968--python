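"""Diagnostic and agreement statistics for paired QTc estimators.

Conventions
-----------
* The estimation error is ``e = true - predicted`` throughout, so an
  estimator that *over*-estimates QTc has a *negative* mean error.
* MAE/ME/SDE are mean absolute error, mean error and the sample standard
  deviation of the error.
* Diagnostic metrics come from a TP/FP/FN/TN contingency table at a given
  long-QT cutoff; when a needed cell is empty the table is recomputed with
  a +0.5 smoothing constant in every cell and flagged.
* Bland-Altman agreement regresses the difference ``true - pred`` on the
  gold-standard value (the x-axis of the agreement plot), with a Wald
  t-test of zero slope for proportional bias and 95% limits of agreement
  ``mean(diff) +- 1.96 sd(diff)``.
* Paired comparisons: McNemar for sensitivity/specificity, the
  Leisenring-Alonzo-Pepe generalized score statistic for PPV/NPV, a
  Gu-Pepe style paired likelihood-ratio contrast for PLR/NLR, Wilcoxon
  signed-rank for ME/MAE, Bartlett for SDE, and paired bootstrap for F1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "MetricWithCI",
    "ErrorSummary",
    "BlandAltmanFit",
    "PairedComparison",
    "contingency_from_labels",
    "error_metrics",
    "bootstrap_ci",
    "bland_altman",
    "diagnostic_metrics",
    "ci_prospective",
    "mcnemar_test",
    "lap_predictive_value_test",
    "gu_pepe_lr_test",
    "compare_error_metrics",
    "fairness_mae_by_group",
    "rater_consensus",
    "error_profile",
]


@dataclass(frozen=True)
class ContingencyTable:
    tp: float
    fp: float
    fn: float
    tn: float
    smoothed: bool = False

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("cell counts must be nonnegative")
        if self.total <= 0:
            raise ValueError("table total must be positive")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.fn + self.tn

    def smooth(self) -> "ContingencyTable":
        """The +0.5-in-every-cell smoothed version of this table."""
        return ContingencyTable(self.tp + 0.5, self.fp + 0.5,
                                self.fn + 0.5, self.tn + 0.5, smoothed=True)


@dataclass(frozen=True)
class MetricWithCI:
    estimate: float
    ci_low: float
    ci_high: float
    method: str  # bootstrap | normal | log_normal | exact_binomial

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.ci_high):
            raise ValueError("ci_low must not exceed ci_high")

    def __repr__(self) -> str:
        return (f"{self.estimate:.4g} ({self.ci_low:.4g}-"
                f"{self.ci_high:.4g}; {self.method})")


@dataclass(frozen=True)
class ErrorSummary:
    mae_ms: MetricWithCI
    me_ms: MetricWithCI
    sde_ms: MetricWithCI
    n: int


@dataclass(frozen=True)
class BlandAltmanFit:
    slope: float
    intercept: float
    slope_se: float
    wald_p: float
    loa_low_ms: float
    loa_high_ms: float
    mean_diff_ms: float


@dataclass(frozen=True)
class PairedComparison:
    metric: str
    estimate_a: float
    estimate_b: float
    statistic: float
    p_value: float
    test: str
    ci_low: float = np.nan
    ci_high: float = np.nan

    def __post_init__(self) -> None:
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def contingency_from_labels(pred_positive, gold_positive) -> ContingencyTable:
    p = np.asarray(pred_positive, dtype=bool)
    g = np.asarray(gold_positive, dtype=bool)
    return ContingencyTable(
        tp=int(np.sum(p & g)), fp=int(np.sum(p & ~g)),
        fn=int(np.sum(~p & g)), tn=int(np.sum(~p & ~g)),
    )


# ---------------------------------------------------------------------------
# error metrics and agreement
# ---------------------------------------------------------------------------

def _point(x):
    return MetricWithCI(float(x), float(x), float(x), "normal")


def error_metrics(truth, preds) -> ErrorSummary:
    """MAE, ME and SDE of the errors ``true - predicted`` (point estimates;
    CIs via :func:`bootstrap_ci` when wanted)."""
    t = np.asarray(truth, dtype=float)
    p = np.asarray(preds, dtype=float)
    if t.size == 0 or t.shape != p.shape:
        raise ValueError("truth and preds must be nonempty and aligned")
    e = t - p
    sde = float(np.std(e, ddof=1)) if e.size > 1 else 0.0
    return ErrorSummary(
        mae_ms=_point(np.mean(np.abs(e))), me_ms=_point(np.mean(e)),
        sde_ms=_point(sde), n=e.size,
    )


def bootstrap_ci(statistic, data, n_boot=2000, seed=0, alpha=0.05):
    """Percentile bootstrap CI of ``statistic(data[idx])`` over seeded
    record resamples.  ``data`` may be a 1-D array or a tuple of aligned
    arrays (resampled jointly)."""
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    arrays = data if isinstance(data, tuple) else (data,)
    arrays = tuple(np.asarray(a) for a in arrays)
    n = arrays[0].shape[0]
    rng = np.random.default_rng(seed)
    est = float(statistic(*arrays))
    reps = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        reps[b] = statistic(*(a[idx] for a in arrays))
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return MetricWithCI(est, float(lo), float(hi), "bootstrap")


def bland_altman(truth, preds) -> BlandAltmanFit:
    """OLS of the difference ``true - pred`` on the gold value, Wald t-test
    of zero slope, and 95% limits of agreement."""
    t = np.asarray(truth, dtype=float)
    p = np.asarray(preds, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(t) == 0:
        raise ValueError("zero variance in the gold standard")
    diff = t - p
    fit = stats.linregress(t, diff)
    sd = float(np.std(diff, ddof=1))
    mean_diff = float(np.mean(diff))
    return BlandAltmanFit(
        slope=float(fit.slope), intercept=float(fit.intercept),
        slope_se=float(fit.stderr), wald_p=float(fit.pvalue),
        loa_low_ms=mean_diff - 1.96 * sd, loa_high_ms=mean_diff + 1.96 * sd,
        mean_diff_ms=mean_diff,
    )


# ---------------------------------------------------------------------------
# diagnostic metrics
# ---------------------------------------------------------------------------

def diagnostic_metrics(table: ContingencyTable) -> dict:
    """Sens/spec/PPV/NPV/PLR/NLR/F1 from a contingency table.

    If any cell is zero the +0.5-smoothed table is used instead and the
    returned dict carries ``smoothed=True``.
    """
    t = table
    if min(t.tp, t.fp, t.fn, t.tn) == 0 and not t.smoothed:
        t = t.smooth()
    sens = t.tp / (t.tp + t.fn)
    spec = t.tn / (t.tn + t.fp)
    ppv = t.tp / (t.tp + t.fp)
    npv = t.tn / (t.tn + t.fn)
    plr = sens / (1.0 - spec) if spec < 1 else np.inf
    nlr = (1.0 - sens) / spec
    f1 = 2 * t.tp / (2 * t.tp + t.fp + t.fn)
    return {"sens": sens, "spec": spec, "ppv": ppv, "npv": npv,
            "plr": plr, "nlr": nlr, "f1": f1, "smoothed": t.smoothed,
            "table": t}


def _proportion_ci(k, n, alpha=0.05):
    p = k / n
    if p in (0.0, 1.0):
        # Clopper-Pearson replaces the degenerate normal interval
        lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
        hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
        return MetricWithCI(float(p), lo, hi, "exact_binomial")
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(p * (1 - p) / n)
    return MetricWithCI(float(p), max(0.0, p - half), min(1.0, p + half),
                        "normal")


def ci_prospective(metric: str, table: ContingencyTable, alpha=0.05):
    """Prospective-cohort CIs: normal approximation for proportions
    (exact binomial substituted at the 0/1 boundary) and log-normal for
    likelihood ratios (with the smoothed table when a cell is empty)."""
    t = table
    if metric in ("sens", "specificity", "spec", "ppv", "npv"):
        pairs = {
            "sens": (t.tp, t.tp + t.fn), "spec": (t.tn, t.tn + t.fp),
            "specificity": (t.tn, t.tn + t.fp),
            "ppv": (t.tp, t.tp + t.fp), "npv": (t.tn, t.tn + t.fn),
        }
        k, n = pairs[metric]
        return _proportion_ci(k, n, alpha)
    if metric in ("plr", "nlr"):
        if min(t.tp, t.fp, t.fn, t.tn) == 0:
            t = t.smooth()
        sens = t.tp / (t.tp + t.fn)
        spec = t.tn / (t.tn + t.fp)
        z = stats.norm.ppf(1 - alpha / 2)
        if metric == "plr":
            est = sens / (1 - spec)
            se_log = np.sqrt(1 / t.tp - 1 / (t.tp + t.fn)
                             + 1 / t.fp - 1 / (t.fp + t.tn))
        else:
            est = (1 - sens) / spec
            se_log = np.sqrt(1 / t.fn - 1 / (t.tp + t.fn)
                             + 1 / t.tn - 1 / (t.fp + t.tn))
        return MetricWithCI(float(est), float(est * np.exp(-z * se_log)),
                            float(est * np.exp(z * se_log)), "log_normal")
    raise ValueError(f"unknown metric {metric!r}")


# ---------------------------------------------------------------------------
# paired tests
# ---------------------------------------------------------------------------

EXACT_MCNEMAR_MAX_DISCORDANT = 25


def mcnemar_test(correct_a, correct_b, metric="accuracy") -> PairedComparison:
    """McNemar test on paired correctness indicators of two classifiers.

    Exact binomial form when the number of discordant pairs is small
    (<= 25), otherwise the asymptotic chi-square form without continuity
    correction (the corrected variant is markedly conservative at moderate
    discordance and undershoots the nominal size).  For a sensitivity
    comparison pass the correctness flags restricted to gold-positive
    records; for specificity, to gold-negatives.
    """
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    n01 = int(np.sum(~a & b))
    n10 = int(np.sum(a & ~b))
    m = n01 + n10
    if m == 0:
        stat, p = 0.0, 1.0
        test = "mcnemar_exact"
    elif m <= EXACT_MCNEMAR_MAX_DISCORDANT:
        k = min(n01, n10)
        p = min(1.0, 2.0 * stats.binom.cdf(k, m, 0.5))
        stat = float(k)
        test = "mcnemar_exact"
    else:
        stat = (n01 - n10) ** 2 / m
        p = float(stats.chi2.sf(stat, df=1))
        test = "mcnemar_chi2"
    return PairedComparison(
        metric=metric, estimate_a=float(np.mean(a)),
        estimate_b=float(np.mean(b)), statistic=float(stat),
        p_value=float(p), test=test,
    )


def lap_predictive_value_test(pred_a_positive, pred_b_positive,
                              gold_positive, target="ppv") -> PairedComparison:
    """Generalized score test for equality of PPV (or NPV) of two paired
    binary tests, after Leisenring, Alonzo & Pepe.

    Observations are the (record, test) pairs where the relevant test is
    positive (PPV) or negative (NPV); the score for the test-identity
    covariate is computed under the pooled null and studentised with a
    subject-clustered empirical variance; chi-square(1) reference.
    """
    a = np.asarray(pred_a_positive, dtype=bool)
    b = np.asarray(pred_b_positive, dtype=bool)
    g = np.asarray(gold_positive, dtype=bool)
    if target == "ppv":
        sel_a, sel_b, outcome = a, b, g
    elif target == "npv":
        sel_a, sel_b, outcome = ~a, ~b, ~g
    else:
        raise ValueError("target must be 'ppv' or 'npv'")
    na, nb = int(sel_a.sum()), int(sel_b.sum())
    if na == 0 or nb == 0:
        raise ValueError(f"no qualifying records for {target} comparison")
    est_a = float(outcome[sel_a].mean())
    est_b = float(outcome[sel_b].mean())
    pooled = (outcome[sel_a].sum() + outcome[sel_b].sum()) / (na + nb)
    zbar = nb / (na + nb)  # mean of the test-b indicator over observations
    # per-subject cluster contributions to the centred score
    resid = outcome.astype(float) - pooled
    contrib = sel_a * (0.0 - zbar) * resid + sel_b * (1.0 - zbar) * resid
    u = float(np.sum(contrib))
    v = float(np.sum(contrib ** 2))
    if v == 0:
        stat, p = 0.0, 1.0
    else:
        stat = u * u / v
        p = float(stats.chi2.sf(stat, df=1))
    return PairedComparison(
        metric=target, estimate_a=est_a, estimate_b=est_b,
        statistic=float(stat), p_value=p, test="lap_score",
    )


def gu_pepe_lr_test(pred_a_positive, pred_b_positive, gold_positive,
                    target="plr") -> PairedComparison:
    """Paired comparison of two tests' likelihood ratios after Gu & Pepe.

    The log ratio ``log(LR_a / LR_b)`` is estimated from the paired
    multinomial rates among diseased and non-diseased subjects, its
    variance by the delta method with the paired covariance terms, and the
    reference is standard normal.  Cells are +0.5 smoothed (and the result
    flagged via the test name) when a required rate is degenerate.
    """
    a = np.asarray(pred_a_positive, dtype=bool)
    b = np.asarray(pred_b_positive, dtype=bool)
    g = np.asarray(gold_positive, dtype=bool)
    if target not in ("plr", "nlr"):
        raise ValueError("target must be 'plr' or 'nlr'")
    if target == "plr":
        xa_d, xb_d = a[g], b[g]          # sensitivity components
        xa_h, xb_h = a[~g], b[~g]        # false-positive rates
    else:
        xa_d, xb_d = ~a[g], ~b[g]        # miss rates
        xa_h, xb_h = ~a[~g], ~b[~g]      # true-negative rates
    smoothed = False

    def rates(x1, x2):
        nonlocal smoothed
        n = x1.size
        k1, k2, k12 = x1.sum(), x2.sum(), np.sum(x1 & x2)
        if min(k1, k2) == 0 or min(n - k1, n - k2) == 0:
            smoothed = True
            p1 = (k1 + 0.5) / (n + 1)
            p2 = (k2 + 0.5) / (n + 1)
            p12 = (k12 + 0.25) / (n + 1)
        else:
            p1, p2, p12 = k1 / n, k2 / n, k12 / n
        v1 = (1 - p1) / (p1 * n)
        v2 = (1 - p2) / (p2 * n)
        c = (p12 - p1 * p2) / (p1 * p2 * n)
        return np.log(p1), np.log(p2), v1, v2, c, p1, p2

    ld1, ld2, vd1, vd2, cd, pd1, pd2 = rates(xa_d, xb_d)
    lh1, lh2, vh1, vh2, ch, ph1, ph2 = rates(xa_h, xb_h)
    log_ratio = (ld1 - ld2) - (lh1 - lh2)
    var = (vd1 + vd2 - 2 * cd) + (vh1 + vh2 - 2 * ch)
    lr_a = pd1 / ph1
    lr_b = pd2 / ph2
    if var <= 0:
        stat, p = 0.0, 1.0
    else:
        stat = log_ratio / np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(stat)))
    return PairedComparison(
        metric=target, estimate_a=float(lr_a), estimate_b=float(lr_b),
        statistic=float(stat), p_value=p,
        test="gu_pepe" + ("_smoothed" if smoothed else ""),
    )


def compare_error_metrics(truth, preds_a, preds_b, n_boot=2000, seed=0,
                          thresholds=None) -> list:
    """Paired comparison of two estimators' error metrics.

    Wilcoxon signed-rank on the signed errors (ME) and the absolute errors
    (MAE), Bartlett on the two error samples (SDE), and — when long-QT
    ``thresholds`` are given — a paired-bootstrap CI of the F1 difference
    at each cutoff.
    """
    t = np.asarray(truth, dtype=float)
    ea = t - np.asarray(preds_a, dtype=float)
    eb = t - np.asarray(preds_b, dtype=float)
    out = []

    def wilcoxon_or_trivial(x, y, name, est_a, est_b):
        d = x - y
        if np.allclose(d, 0):
            return PairedComparison(name, est_a, est_b, 0.0, 1.0, "wilcoxon")
        stat, p = stats.wilcoxon(x, y)
        return PairedComparison(name, est_a, est_b, float(stat), float(p),
                                "wilcoxon")

    out.append(wilcoxon_or_trivial(ea, eb, "me",
                                   float(np.mean(ea)), float(np.mean(eb))))
    out.append(wilcoxon_or_trivial(np.abs(ea), np.abs(eb), "mae",
                                   float(np.mean(np.abs(ea))),
                                   float(np.mean(np.abs(eb)))))
    if np.std(ea) == 0 and np.std(eb) == 0:
        out.append(PairedComparison("sde", 0.0, 0.0, 0.0, 1.0, "bartlett"))
    else:
        stat, p = stats.bartlett(ea, eb)
        out.append(PairedComparison(
            "sde", float(np.std(ea, ddof=1)), float(np.std(eb, ddof=1)),
            float(stat), float(p), "bartlett"))
    for thr in thresholds or ():
        gold = t >= thr
        pa = np.asarray(preds_a, dtype=float) >= thr
        pb = np.asarray(preds_b, dtype=float) >= thr

        def f1_diff(g, x, y):
            fa = diagnostic_metrics(contingency_from_labels(x, g))["f1"]
            fb = diagnostic_metrics(contingency_from_labels(y, g))["f1"]
            return fa - fb

        ci = bootstrap_ci(f1_diff, (gold, pa, pb), n_boot=n_boot, seed=seed)
        out.append(PairedComparison(
            f"f1@{thr:g}",
            estimate_a=diagnostic_metrics(contingency_from_labels(pa, gold))["f1"],
            estimate_b=diagnostic_metrics(contingency_from_labels(pb, gold))["f1"],
            statistic=float(ci.estimate), p_value=np.nan,
            test="bootstrap_diff", ci_low=ci.ci_low, ci_high=ci.ci_high))
    return out


# ---------------------------------------------------------------------------
# fairness, raters, error profile
# ---------------------------------------------------------------------------

LOW_N_GROUP = 30


def fairness_mae_by_group(truth, preds, groups, n_boot=500, seed=0):
    """Per-group MAE (bootstrap CI) plus pairwise Wilcoxon tests on the
    absolute errors.  Groups with fewer than 30 records are flagged and
    excluded from the pairwise tests."""
    t = np.asarray(truth, dtype=float)
    p = np.asarray(preds, dtype=float)
    g = np.asarray(groups)
    abs_err = np.abs(t - p)
    per_group, low_n = {}, []
    for name in pd.unique(g):
        mask = g == name
        if mask.sum() < LOW_N_GROUP:
            low_n.append(name)
            continue
        per_group[name] = bootstrap_ci(
            lambda e: np.mean(e), abs_err[mask], n_boot=n_boot, seed=seed)
    comparisons = []
    names = list(per_group)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            x = abs_err[g == names[i]]
            y = abs_err[g == names[j]]
            stat, pv = stats.mannwhitneyu(x, y, alternative="two-sided")
            comparisons.append(PairedComparison(
                f"mae:{names[i]}-vs-{names[j]}",
                float(np.mean(x)), float(np.mean(y)),
                float(stat), float(pv), "wilcoxon_rank_sum"))
    return {"per_group": per_group, "comparisons": comparisons,
            "low_n_groups": low_n}


def rater_consensus(ratings):
    """Consensus gold standards from a record x rater QTc matrix.

    Returns ``(algorithm_gold, per_rater_gold)``: the algorithm gold is the
    row mean over all raters; rater r's gold is the row mean excluding
    rater r (leave-one-rater-out).  Rows with missing values are dropped.
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a record x rater matrix with >= 2 raters")
    keep = np.all(np.isfinite(m), axis=1)
    m = m[keep]
    n_r = m.shape[1]
    algorithm_gold = m.mean(axis=1)
    row_sum = m.sum(axis=1)
    per_rater = (row_sum[:, None] - m) / (n_r - 1)
    return algorithm_gold, per_rater, keep


def error_profile(truth, preds, bin_width_ms=10.0, n_boot=500, seed=0):
    """MAE by left-closed true-QTc bin and the cumulative share of records
    within increasing MAE buckets (10 ms wide)."""
    t = np.asarray(truth, dtype=float)
    p = np.asarray(preds, dtype=float)
    if t.size == 0:
        raise ValueError("empty input")
    abs_err = np.abs(t - p)
    lo = np.floor(t.min() / bin_width_ms) * bin_width_ms
    bins = np.arange(lo, t.max() + bin_width_ms, bin_width_ms)
    idx = np.digitize(t, bins) - 1
    rows = []
    for k in range(len(bins)):
        mask = idx == k
        if not np.any(mask):
            continue
        if mask.sum() >= 3:
            ci = bootstrap_ci(lambda e: np.mean(e), abs_err[mask],
                              n_boot=n_boot, seed=seed)
        else:
            ci = _point(np.mean(abs_err[mask]))
        rows.append({"bin_low_ms": bins[k], "bin_high_ms": bins[k] + bin_width_ms,
                     "n": int(mask.sum()), "mae_ms": ci.estimate,
                     "ci_low": ci.ci_low, "ci_high": ci.ci_high})
    by_bin = pd.DataFrame(rows)
    edges = np.arange(bin_width_ms, abs_err.max() + 2 * bin_width_ms,
                      bin_width_ms)
    cumulative = pd.DataFrame({
        "mae_below_ms": edges,
        "fraction": [(abs_err < e).mean() for e in edges],
    })
    return by_bin, cumulative
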