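"""Diagnostic-performance statistics for a candidate biomarker assay.

Empirical ROC curve with trapezoidal AUC, stratified-bootstrap (or DeLong)
confidence interval and the conventional discriminative bins (0.5 not
discriminant, 0.5-0.6 fail, 0.6-0.7 poor, 0.7-0.8 fair, 0.8-0.9 good,
0.9-1 excellent; boundary values go to the upper bin); Youden-index cutoff
with Clopper-Pearson sensitivity/specificity intervals and positive
likelihood ratio; Kruskal-Wallis omnibus with Dunn's pairwise post-hoc
(BH-adjusted) and median/IQR group summaries.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from csfpanel.errors import AnalysisError

logger = logging.getLogger(__name__)

AUC_CLASSES = ("not discriminant", "fail", "poor", "fair", "good", "excellent")


@dataclass
class DiagnosticSummary:
    roc: pd.DataFrame              # fpr, tpr, threshold (monotone, (0,0) -> (1,1))
    auc: float
    auc_ci: tuple[float, float]
    auc_class: str
    cutoff: float | None = None
    sensitivity: float | None = None
    sensitivity_ci: tuple[float, float] | None = None
    specificity: float | None = None
    specificity_ci: tuple[float, float] | None = None
    likelihood_ratio: float | None = None
    group_summaries: pd.DataFrame | None = None


def classify_auc(auc: float) -> str:
    """Map an AUC to its discriminative class; boundaries go to the upper bin
    (0.9 -> excellent), and exactly 0.5 (or below) is not discriminant."""
    if auc <= 0.5:
        return "not discriminant"
    if auc < 0.6:
        return "fail"
    if auc < 0.7:
        return "poor"
    if auc < 0.8:
        return "fair"
    if auc < 0.9:
        return "good"
    return "excellent"


def trapezoid_auc(scores, labels) -> float:
    """AUC by trapezoidal integration of the empirical ROC curve."""
    fpr, tpr, _ = roc_curve(labels, scores)
    return float(np.trapezoid(tpr, fpr))


def rank_auc(scores, labels) -> float:
    """AUC via the Mann-Whitney rank statistic U / (n1 * n2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n1, n0 = labels.sum(), (~labels).sum()
    if n1 == 0 or n0 == 0:
        raise AnalysisError("rank_auc requires both classes")
    ranks = stats.rankdata(scores)
    u = ranks[labels].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def roc_analysis(
    scores,
    labels,
    n_boot: int = 2000,
    seed: int = 0,
    ci_method: str = "bootstrap",
    ci_level: float = 0.95,
) -> DiagnosticSummary:
    """Empirical ROC, trapezoidal AUC, CI and discriminative class.

    The CI is a stratified percentile bootstrap by default; ``ci_method=
    "delong"`` uses the DeLong asymptotic normal interval instead.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise AnalysisError("ROC analysis requires both classes")
    fpr, tpr, thresholds = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos = scores[labels]
        neg = scores[~labels]
        boot = np.empty(n_boot)
        for b in range(n_boot):
            sp = rng.choice(pos, size=pos.size, replace=True)
            sn = rng.choice(neg, size=neg.size, replace=True)
            boot[b] = rank_auc(np.concatenate([sp, sn]),
                               np.concatenate([np.ones(sp.size, bool), np.zeros(sn.size, bool)]))
        lo, hi = np.quantile(boot, [(1 - ci_level) / 2, 1 - (1 - ci_level) / 2])
    elif ci_method == "delong":
        lo, hi = _delong_ci(scores, labels, auc, ci_level)
    else:
        raise ValueError(f"unknown ci_method '{ci_method}'")
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return DiagnosticSummary(
        roc=roc,
        auc=auc,
        auc_ci=(float(max(lo, 0.0)), float(min(hi, 1.0))),
        auc_class=classify_auc(auc),
    )


def _delong_ci(scores, labels, auc, ci_level):
    """DeLong variance of the AUC via placement values."""
    pos = np.sort(scores[labels])
    neg = np.sort(scores[~labels])
    m, n = pos.size, neg.size
    v10 = np.array([(np.searchsorted(neg, x, "left") + np.searchsorted(neg, x, "right")) / (2 * n) for x in pos])
    v01 = np.array([1 - (np.searchsorted(pos, y, "left") + np.searchsorted(pos, y, "right")) / (2 * m) for y in neg])
    var = np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n
    z = stats.norm.ppf(1 - (1 - ci_level) / 2)
    half = z * math.sqrt(var)
    return auc - half, auc + half


def youden_cutoff(
    scores, labels, ci_level: float = 0.95
) -> tuple[float, dict[str, float | tuple[float, float]]]:
    """Cutoff maximizing Youden's J = sensitivity + specificity - 1.

    Candidate cutoffs are all observed score values ("positive" means
    score >= cutoff); ties in J resolve to the lower cutoff.  Sensitivity
    and specificity carry Clopper-Pearson intervals; LR+ = sens/(1 - spec),
    reported as +inf when specificity is 1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise AnalysisError("Youden cutoff requires both classes")
    candidates = np.unique(scores)
    best_j, best_cut = -np.inf, None
    for cut in candidates:  # ascending, so strict improvement keeps the lower tie
        pred = scores >= cut
        sens = np.mean(pred[labels])
        spec = np.mean(~pred[~labels])
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_cut = j, float(cut)
    pred = scores >= best_cut
    tp = int(np.sum(pred & labels))
    fn = int(np.sum(~pred & labels))
    tn = int(np.sum(~pred & ~labels))
    fp = int(np.sum(pred & ~labels))
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    sens_ci = proportion_confint(tp, tp + fn, alpha=1 - ci_level, method="beta")
    spec_ci = proportion_confint(tn, tn + fp, alpha=1 - ci_level, method="beta")
    lr = sens / (1.0 - spec) if spec < 1.0 else float("inf")
    return best_cut, {
        "youden_j": best_j,
        "sensitivity": sens,
        "sensitivity_ci": (float(sens_ci[0]), float(sens_ci[1])),
        "specificity": spec,
        "specificity_ci": (float(spec_ci[0]), float(spec_ci[1])),
        "likelihood_ratio": lr,
    }


def diagnostic_summary(
    scores, labels, n_boot: int = 2000, seed: int = 0, ci_method: str = "bootstrap"
) -> DiagnosticSummary:
    """ROC + AUC CI + Youden cutoff performance in one record."""
    summary = roc_analysis(scores, labels, n_boot=n_boot, seed=seed, ci_method=ci_method)
    cutoff, perf = youden_cutoff(scores, labels)
    summary.cutoff = cutoff
    summary.sensitivity = perf["sensitivity"]
    summary.sensitivity_ci = perf["sensitivity_ci"]
    summary.specificity = perf["specificity"]
    summary.specificity_ci = perf["specificity_ci"]
    summary.likelihood_ratio = perf["likelihood_ratio"]
    return summary


def kruskal_dunn(values_by_group: dict[str, np.ndarray]) -> tuple[float, float, pd.DataFrame, pd.DataFrame]:
    """Kruskal-Wallis omnibus (tie-corrected) with Dunn's pairwise post-hoc.

    Dunn z for groups i, j compares mean ranks with the tie-corrected
    variance (N(N+1)/12 - T/(12(N-1))) * (1/n_i + 1/n_j) where
    T = sum(t^3 - t) over tie groups; pairwise p-values are BH-adjusted.
    Groups with fewer than 2 values are excluded with a warning.  Returns
    (H, omnibus p, pairwise table, median/IQR summaries).
    """
    groups = {}
    for name, vals in values_by_group.items():
        vals = np.asarray(vals, dtype=float)
        if vals.size < 2:
            logger.warning("group '%s' has < 2 values; excluded from Kruskal-Wallis", name)
            continue
        groups[name] = vals
    if len(groups) < 2:
        raise AnalysisError("Kruskal-Wallis requires >= 2 groups with >= 2 values")
    names = list(groups)
    h, p_omnibus = stats.kruskal(*groups.values())

    pooled = np.concatenate([groups[n] for n in names])
    ranks = stats.rankdata(pooled)
    n_total = pooled.size
    offsets = np.cumsum([0] + [groups[n].size for n in names])
    mean_ranks = {n: ranks[offsets[i]:offsets[i + 1]].mean() for i, n in enumerate(names)}
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (n_total - 1))

    rows = []
    for a, b in itertools.combinations(names, 2):
        na, nb = groups[a].size, groups[b].size
        se = math.sqrt((n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        rows.append({"group_a": a, "group_b": b, "z": z, "p": 2.0 * stats.norm.sf(abs(z))})
    pairwise = pd.DataFrame(rows)
    pairwise["q"] = multipletests(pairwise["p"], method="fdr_bh")[1]

    summaries = pd.DataFrame(
        {
            "n": {n: groups[n].size for n in names},
            "median": {n: float(np.median(groups[n])) for n in names},
            "q1": {n: float(np.quantile(groups[n], 0.25)) for n in names},
            "q3": {n: float(np.quantile(groups[n], 0.75)) for n in names},
        }
    )
    summaries["iqr"] = summaries["q3"] - summaries["q1"]
    return float(h), float(p_omnibus), pairwise, summaries
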