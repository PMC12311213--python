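"""Diagnostic evaluation of the per-threshold models.

Point metrics at a probability cutoff (accuracy, sensitivity, specificity,
PPV, NPV) with stratified percentile-bootstrap 95% confidence intervals;
ROC/AUC as the tie-corrected Mann–Whitney statistic; the DeLong test for
paired correlated AUCs; decision-curve analysis (net benefit against
treat-all / treat-none); pairwise Pearson agreement between model outputs;
and repeated-measures ANOVA across models with patients as subjects.

One deliberate deviation from a printed formula: NPV is computed as
TN / (TN + FN), the standard definition consistent with the surrounding
prose; the variant FN / (FN + TN) that appears in some renderings is a
typographical slip and is only available behind ``printed_npv=True`` for
audit purposes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

from ._utils import as_binary_labels

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion_at_cutoff(prob, labels, cutoff: float = 0.5) -> ConfusionCounts:
    """Counts with a positive call iff prob >= cutoff."""
    prob = np.asarray(prob, dtype=float)
    y = as_binary_labels(labels)
    if prob.shape[0] != y.shape[0]:
        raise ValueError("prob and labels differ in length")
    call = prob >= cutoff
    return ConfusionCounts(
        TP=int(np.sum(call & (y == 1))),
        FP=int(np.sum(call & (y == 0))),
        TN=int(np.sum(~call & (y == 0))),
        FN=int(np.sum(~call & (y == 1))),
    )


def diagnostic_metrics(counts: ConfusionCounts, printed_npv: bool = False) -> dict:
    """Accuracy, sensitivity, specificity, PPV, NPV from confusion counts.

    Empty denominators yield NaN rather than raising. ``printed_npv``
    switches NPV to the FN/(FN+TN) audit variant (see module docstring).
    """
    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    tp, fp, tn, fn = counts.TP, counts.FP, counts.TN, counts.FN
    npv = ratio(fn, fn + tn) if printed_npv else ratio(tn, tn + fn)
    return {
        "accuracy": ratio(tp + tn, counts.n),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": npv,
    }


def roc_auc(prob, labels) -> tuple[pd.DataFrame, float]:
    """ROC curve and AUC = P(score+ > score-) + 0.5 P(score+ = score-)."""
    prob = np.asarray(prob, dtype=float)
    y = as_binary_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = roc_curve(y, prob)
    auc = float(roc_auc_score(y, prob))
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}), auc


def bootstrap_ci(
    prob,
    labels,
    metric,
    n_boot: int = 2000,
    seed: int = 0,
    cutoff: float = 0.5,
    level: float = 0.95,
) -> tuple[float, float]:
    """Stratified percentile bootstrap interval for a metric.

    ``metric`` is either one of the named threshold metrics
    ('accuracy' | 'sensitivity' | 'specificity' | 'ppv' | 'npv' | 'auc')
    or a callable (prob, labels) -> float. Cases are resampled within each
    label class (so class sizes are fixed); degenerate resamples where the
    metric is undefined are skipped and counted in the log.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    prob = np.asarray(prob, dtype=float)
    y = as_binary_labels(labels)
    rng = np.random.default_rng(seed)
    pos = np.flatnonzero(y == 1)
    neg = np.flatnonzero(y == 0)

    if callable(metric):
        fn = metric
    elif metric == "auc":
        fn = lambda p, t: roc_auc(p, t)[1]
    else:
        fn = lambda p, t: diagnostic_metrics(confusion_at_cutoff(p, t, cutoff))[metric]

    # resample indices for all replicates at once
    pos_draw = rng.choice(pos, size=(n_boot, pos.size), replace=True) if pos.size else None
    neg_draw = rng.choice(neg, size=(n_boot, neg.size), replace=True) if neg.size else None
    values = np.empty(n_boot)
    skipped = 0
    for b in range(n_boot):
        parts = []
        if pos_draw is not None:
            parts.append(pos_draw[b])
        if neg_draw is not None:
            parts.append(neg_draw[b])
        idx = np.concatenate(parts)
        try:
            v = fn(prob[idx], y[idx])
        except ValueError:
            v = float("nan")
        values[b] = v
        if not np.isfinite(v):
            skipped += 1
    if skipped:
        logger.info("bootstrap_ci: skipped %d degenerate resamples of %d", skipped, n_boot)
    values = values[np.isfinite(values)]
    if values.size == 0:
        return float("nan"), float("nan")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# DeLong test for paired correlated AUCs
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(prob, labels):
    """Per-case structural components: V10 (positives), V01 (negatives)."""
    prob = np.asarray(prob, dtype=float)
    y = as_binary_labels(labels)
    pos = prob[y == 1]
    neg = prob[y == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("DeLong components require both classes present")
    all_ranks = _midrank(np.concatenate([pos, neg]))
    pos_ranks = _midrank(pos)
    neg_ranks = _midrank(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n                 # P(neg < pos_i) with tie credit
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m           # P(pos > neg_j) with tie credit
    auc = v10.mean()
    return auc, v10, v01


def delong_variance(prob, labels) -> float:
    """DeLong variance of a single AUC from its structural components."""
    _, v10, v01 = _delong_components(prob, labels)
    m, n = v10.size, v01.size
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def delong_test(prob_a, prob_b, labels) -> tuple[float, float, float, float]:
    """Two-sided paired DeLong test; returns (auc_a, auc_b, z, p).

    Covariance of the two AUCs is estimated from the covariances of the
    paired structural components. Zero variance of the difference with equal
    AUCs yields p = 1 by convention.
    """
    prob_a = np.asarray(prob_a, dtype=float)
    prob_b = np.asarray(prob_b, dtype=float)
    y = as_binary_labels(labels)
    if prob_a.shape != prob_b.shape or prob_a.shape[0] != y.shape[0]:
        raise ValueError("paired scores must share the case set")

    auc_a, v10_a, v01_a = _delong_components(prob_a, y)
    auc_b, v10_b, v01_b = _delong_components(prob_b, y)
    m, n = v10_a.size, v01_a.size

    s10 = np.cov(np.vstack([v10_a, v10_b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01_a, v01_b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        if abs(diff) < 1e-12:
            return float(auc_a), float(auc_b), 0.0, 1.0
        var_diff = 1e-300  # distinct AUCs with no estimated variance: overwhelming evidence
    z = diff / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(auc_a), float(auc_b), float(z), float(min(p, 1.0))


# ---------------------------------------------------------------------------
# decision-curve analysis
# ---------------------------------------------------------------------------

def decision_curve(
    prob, labels, pt_grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Net benefit over threshold probabilities p_t, with references.

    NB(model) = TP/n - (FP/n) * p_t / (1 - p_t); treat-none is identically 0
    and treat-all is pi - (1 - pi) * p_t / (1 - p_t) at prevalence pi.
    Default grid: 0.01 .. 0.99 step 0.01.
    """
    prob = np.asarray(prob, dtype=float)
    y = as_binary_labels(labels)
    if pt_grid is None:
        pt_grid = np.round(np.arange(0.01, 1.0, 0.01), 10)
    pt_grid = np.asarray(pt_grid, dtype=float)
    if np.any(pt_grid <= 0) or np.any(pt_grid >= 1):
        raise ValueError("pt_grid must lie strictly inside (0, 1)")
    if np.any(np.diff(pt_grid) <= 0):
        raise ValueError("pt_grid must be strictly increasing")
    n = y.size
    pi = y.mean()
    rows = []
    for pt in pt_grid:
        w = pt / (1.0 - pt)
        call = prob >= pt
        tp = np.sum(call & (y == 1)) / n
        fp = np.sum(call & (y == 0)) / n
        rows.append(
            {
                "p_t": pt,
                "net_benefit_model": tp - fp * w,
                "net_benefit_all": pi - (1.0 - pi) * w,
                "net_benefit_none": 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# inter-model agreement
# ---------------------------------------------------------------------------

def agreement_matrix(prob_by_model: dict[str, np.ndarray]) -> pd.DataFrame:
    """Pairwise Pearson r of model outputs; NaN for constant outputs."""
    names = list(prob_by_model)
    if len(names) < 2:
        raise ValueError("need at least 2 models")
    arr = np.vstack([np.asarray(prob_by_model[k], dtype=float) for k in names])
    if arr.shape[1] < 3:
        raise ValueError("need at least 3 cases")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(arr)
    const = arr.std(axis=1) == 0
    r[const, :] = np.nan
    r[:, const] = np.nan
    np.fill_diagonal(r, [np.nan if c else 1.0 for c in const])
    return pd.DataFrame(r, index=names, columns=names)


def rm_anova(prob_by_model: dict[str, np.ndarray]) -> tuple[float, float, float, float]:
    """Repeated-measures ANOVA: patients are subjects, models the
    within-subject factor. Returns (F, df_num, df_den, p) with
    df_num = k - 1 and df_den = (k - 1)(n - 1)."""
    from statsmodels.stats.anova import AnovaRM

    names = list(prob_by_model)
    k = len(names)
    if k < 2:
        raise ValueError("need at least 2 models")
    n = len(np.asarray(prob_by_model[names[0]]))
    if n < 3:
        raise ValueError("need at least 3 cases")
    long = pd.DataFrame(
        {
            "score": np.concatenate([np.asarray(prob_by_model[m], dtype=float) for m in names]),
            "model": np.repeat(names, n),
            "subject": np.tile(np.arange(n), k),
        }
    )
    if np.allclose(long.groupby("subject")["score"].std(ddof=0), 0):
        # all models identical for every subject: no model effect at all
        return 0.0, float(k - 1), float((k - 1) * (n - 1)), 1.0
    res = AnovaRM(long, depvar="score", subject="subject", within=["model"]).fit()
    row = res.anova_table.iloc[0]
    return (
        float(row["F Value"]),
        float(row["Num DF"]),
        float(row["Den DF"]),
        float(row["Pr > F"]),
    )


def oneway_anova(prob_by_model: dict[str, np.ndarray]) -> tuple[float, float]:
    """One-way (between-groups) ANOVA across model outputs, for comparison."""
    groups = [np.asarray(v, dtype=float) for v in prob_by_model.values()]
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


# ---------------------------------------------------------------------------
# Table-style reports
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticReport:
    """ACC/SEN/SPEC/PPV/NPV/AUC with 95% CIs at one cutoff."""

    cutoff: float
    estimates: dict[str, float]
    intervals: dict[str, tuple[float, float]]
    n: int

    def to_dict(self) -> dict:
        out: dict = {"cutoff": self.cutoff, "n": self.n}
        for k, v in self.estimates.items():
            lo, hi = self.intervals[k]
            out[k] = {"estimate": v, "ci_low": lo, "ci_high": hi}
        return out


def diagnostic_report(
    prob,
    labels,
    cutoff: float = 0.5,
    n_boot: int = 2000,
    seed: int = 0,
) -> DiagnosticReport:
    """Full per-cohort report: threshold metrics + AUC, each with a
    stratified percentile-bootstrap 95% CI."""
    prob = np.asarray(prob, dtype=float)
    y = as_binary_labels(labels)
    counts = confusion_at_cutoff(prob, y, cutoff)
    est = diagnostic_metrics(counts)
    est["auc"] = roc_auc(prob, y)[1]
    intervals = {}
    for i, name in enumerate(est):
        intervals[name] = bootstrap_ci(
            prob, y, name, n_boot=n_boot, seed=seed + i, cutoff=cutoff
        )
    return DiagnosticReport(cutoff=cutoff, estimates=est, intervals=intervals, n=y.size)
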