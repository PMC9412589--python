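"""Per-fraction control-vs-MB differential expression.

A protein is called significant in one fraction only when it passes all five
criteria simultaneously:

1. Benjamini-Hochberg adjusted Welch-t p-value <= alpha (default 0.05);
2. fold change >= 2, evaluated as |log2 FC| >= 1 on group means;
3. detection ("presence") in >= 70% of the samples of at least one group;
4. per-protein ROC AUC (Mann-Whitney rank statistic) > 0.7;
5. post-hoc power of the two-sample t test at the observed standardized
   effect >= 0.8.

Missing values are excluded from the t/AUC computations (no imputation);
detection information is consumed by the presence filter.  A volcano cutoff
curve y = c / (x - x0) on (|log2 FC|, -log10 adjusted p) is provided for
visualization-style flagging.
"""

from __future__ import annotations

import warnings
from contextlib import contextmanager
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from csfpanel.errors import AnalysisError
from csfpanel.ingest import FRACTIONS, IntensityMatrix


@contextmanager
def _nan_stats():
    """Silence the expected empty-slice warnings from nan-aware reductions
    over proteins absent from one group (their results are masked anyway)."""
    with warnings.catch_warnings(), np.errstate(invalid="ignore", divide="ignore"):
        warnings.simplefilter("ignore", RuntimeWarning)
        yield


@dataclass(frozen=True)
class DECriteria:
    """Thresholds of the compound significance call."""

    alpha: float = 0.05
    fc_min: float = 2.0
    presence_threshold: float = 0.7
    auc_min: float = 0.7
    power_min: float = 0.8
    welch: bool = True


def _group_arrays(matrix: IntensityMatrix, fraction: str) -> tuple[np.ndarray, np.ndarray]:
    ctrl = matrix.samples_in(group="control", fraction=fraction)
    mb = matrix.samples_in(group="MB", fraction=fraction)
    if not ctrl or not mb:
        raise AnalysisError(f"fraction '{fraction}' lacks one of the two groups")
    return (
        matrix.values[ctrl].to_numpy(dtype=float),
        matrix.values[mb].to_numpy(dtype=float),
    )


def protein_t_tests(
    matrix: IntensityMatrix, fraction: str, alpha: float = 0.05, welch: bool = True
) -> pd.DataFrame:
    """Two-sample t tests (Welch by default) per protein on detected log2 values.

    Proteins with fewer than 2 detected values in either group are reported
    untested (NaN statistics).  BH adjustment is applied within the fraction
    over tested proteins.  log2 FC = mean(MB) - mean(control).
    """
    xc, xm = _group_arrays(matrix, fraction)
    n1 = np.sum(~np.isnan(xc), axis=1)
    n2 = np.sum(~np.isnan(xm), axis=1)
    tested = (n1 >= 2) & (n2 >= 2)

    with _nan_stats():
        m1 = np.nanmean(xc, axis=1)
        m2 = np.nanmean(xm, axis=1)
        v1 = np.nanvar(xc, axis=1, ddof=1)
        v2 = np.nanvar(xm, axis=1, ddof=1)
        if welch:
            se2 = v1 / n1 + v2 / n2
            df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        else:
            sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se2 = sp2 * (1.0 / n1 + 1.0 / n2)
            df = n1 + n2 - 2.0
        t = (m2 - m1) / np.sqrt(se2)
    # zero-variance pairs: t=0/p=1 when means equal, +-inf/p=0 otherwise
    zero_se = tested & (se2 == 0)
    t = np.where(zero_se & (m2 == m1), 0.0, t)
    df = np.where(zero_se, n1 + n2 - 2.0, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)

    out = pd.DataFrame(
        {
            "n_control": n1,
            "n_mb": n2,
            "tested": tested,
            "mean_control": np.where(n1 > 0, m1, np.nan),
            "mean_mb": np.where(n2 > 0, m2, np.nan),
            "log2_fc": np.where((n1 > 0) & (n2 > 0), m2 - m1, np.nan),
            "t": np.where(tested, t, np.nan),
            "p": np.where(tested, p, np.nan),
        },
        index=matrix.protein_ids,
    )
    out["q"] = np.nan
    if tested.any():
        out.loc[tested, "q"] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
    return out


def presence_filter(
    matrix: IntensityMatrix, fraction: str, threshold: float = 0.7
) -> pd.DataFrame:
    """Detection fraction per group; pass iff >= threshold in control OR MB."""
    xc, xm = _group_arrays(matrix, fraction)
    pc = np.mean(~np.isnan(xc), axis=1)
    pm = np.mean(~np.isnan(xm), axis=1)
    return pd.DataFrame(
        {
            "presence_control": pc,
            "presence_mb": pm,
            "presence_pass": (pc >= threshold) | (pm >= threshold),
        },
        index=matrix.protein_ids,
    )


def protein_auc(matrix: IntensityMatrix, fraction: str) -> pd.DataFrame:
    """Per-protein ROC AUC via the Mann-Whitney rank statistic U / (n1*n2).

    Reported orientation-free as max(AUC, 1-AUC) with the favored direction;
    missing values are excluded.
    """
    xc, xm = _group_arrays(matrix, fraction)
    x = np.hstack([xc, xm])
    is_mb = np.hstack([np.zeros(xc.shape[1], bool), np.ones(xm.shape[1], bool)])
    with _nan_stats():
        ranks = stats.rankdata(x, axis=1, nan_policy="omit")
        n1 = np.sum(~np.isnan(xc), axis=1).astype(float)
        n2 = np.sum(~np.isnan(xm), axis=1).astype(float)
        r_mb = np.nansum(np.where(is_mb[None, :], ranks, np.nan), axis=1)
        u = r_mb - n2 * (n2 + 1) / 2.0
        auc_mb = u / (n1 * n2)
    valid = (n1 >= 1) & (n2 >= 1)
    auc_mb = np.where(valid, auc_mb, np.nan)
    return pd.DataFrame(
        {
            "auc_mb": auc_mb,
            "auc": np.where(np.isnan(auc_mb), np.nan, np.maximum(auc_mb, 1.0 - auc_mb)),
            "auc_direction": np.where(auc_mb >= 0.5, "MB", "control"),
        },
        index=matrix.protein_ids,
    )


def posthoc_power(effect, n1, n2, alpha: float = 0.05):
    """Power of a two-sided two-sample t test at standardized effect ``effect``.

    Vectorized noncentral-t computation: with nc = |d| * sqrt(n1*n2/(n1+n2))
    and critical value t_c at n1+n2-2 df, power = P(|T'| > t_c).  Infinite
    effect (zero pooled variance, nonzero mean difference) gives power 1;
    effect 0 with zero variance gives 0.
    """
    d = np.abs(np.asarray(effect, dtype=float))
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    if np.any((n1 < 1) | (n2 < 1)):
        raise AnalysisError("posthoc_power: group sizes must be positive")
    df = n1 + n2 - 2.0
    nc = d * np.sqrt(n1 * n2 / (n1 + n2))
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
    with np.errstate(invalid="ignore"):
        upper = stats.nct.sf(tcrit, df, nc)
        lower = stats.nct.cdf(-tcrit, df, nc)
    # scipy's noncentral t loses precision at large nc; the affected terms
    # are the negligible wrong-side mass (-> 0) and a tail probability well
    # approximated by the normal limit
    lower = np.where(np.isnan(lower), 0.0, lower)
    upper = np.where(np.isnan(upper), stats.norm.sf(tcrit - nc), upper)
    power = upper + lower
    power = np.where(np.isposinf(d), 1.0, power)
    power = np.where(np.isnan(d), np.nan, power)
    return power if power.ndim else float(power)


def observed_effect_size(t_table: pd.DataFrame, matrix: IntensityMatrix, fraction: str) -> pd.Series:
    """Observed standardized effect d = (mean_MB - mean_control) / pooled SD.

    Zero pooled SD yields +-inf for a nonzero mean difference and 0 otherwise
    (mapped to power 1 / 0 downstream).
    """
    xc, xm = _group_arrays(matrix, fraction)
    n1 = np.sum(~np.isnan(xc), axis=1)
    n2 = np.sum(~np.isnan(xm), axis=1)
    with _nan_stats():
        v1 = np.nanvar(xc, axis=1, ddof=1)
        v2 = np.nanvar(xm, axis=1, ddof=1)
        sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
        diff = np.nanmean(xm, axis=1) - np.nanmean(xc, axis=1)
        d = diff / sp
    d = np.where((sp == 0) & (diff != 0), np.inf * np.sign(diff), d)
    d = np.where((sp == 0) & (diff == 0), 0.0, d)
    return pd.Series(d, index=matrix.protein_ids, name="effect_size")


def volcano_threshold(
    x: np.ndarray, y: np.ndarray, c: float | None = None, x0: float = 1.0, alpha: float = 0.05
) -> np.ndarray:
    """Flag points above the volcano cutoff curve y = c / (x - x0).

    x = |log2 FC|, y = -log10(adjusted p).  A point is flagged iff x > x0 and
    y > c / (x - x0), strictly (a point exactly on the curve is not flagged).
    By default c is calibrated so the curve passes through
    (2, -log10 alpha): c = (2 - x0) * (-log10 alpha).
    """
    if c is None:
        c = (2.0 - x0) * (-np.log10(alpha))
    if c <= 0:
        raise AnalysisError("volcano_threshold: c must be > 0")
    if x0 < 0:
        raise AnalysisError("volcano_threshold: x0 must be >= 0")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (x > x0) & (y > c / (x - x0))


def fraction_diffexpr(
    matrix: IntensityMatrix, fraction: str, criteria: DECriteria = DECriteria()
) -> pd.DataFrame:
    """Full per-fraction table: statistics, per-criterion pass flags and the
    conjunctive ``significant`` call."""
    t_table = protein_t_tests(matrix, fraction, alpha=criteria.alpha, welch=criteria.welch)
    presence = presence_filter(matrix, fraction, threshold=criteria.presence_threshold)
    auc = protein_auc(matrix, fraction)
    effect = observed_effect_size(t_table, matrix, fraction)
    n1 = t_table["n_control"].to_numpy()
    n2 = t_table["n_mb"].to_numpy()
    ok = (n1 >= 1) & (n2 >= 1)
    power = np.full(len(t_table), np.nan)
    power[ok] = posthoc_power(effect.to_numpy()[ok], n1[ok], n2[ok], alpha=criteria.alpha)

    table = pd.concat([t_table, presence, auc], axis=1)
    table["effect_size"] = effect
    table["power"] = power
    table["pass_q"] = table["q"] <= criteria.alpha
    table["pass_fc"] = table["log2_fc"].abs() >= np.log2(criteria.fc_min)
    table["pass_presence"] = table["presence_pass"]
    table["pass_auc"] = table["auc"] > criteria.auc_min
    table["pass_power"] = table["power"] >= criteria.power_min
    table["significant"] = (
        table["tested"]
        & table["pass_q"].fillna(False)
        & table["pass_fc"].fillna(False)
        & table["pass_presence"]
        & table["pass_auc"].fillna(False)
        & table["pass_power"].fillna(False)
    )
    table["volcano_flag"] = volcano_threshold(
        table["log2_fc"].abs().to_numpy(),
        -np.log10(table["q"].to_numpy()),
        alpha=criteria.alpha,
    )
    table["fraction"] = fraction
    return table


def select_significant(
    matrix: IntensityMatrix,
    fractions: tuple[str, ...] = FRACTIONS,
    criteria: DECriteria = DECriteria(),
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Run the compound criterion in every fraction; return per-fraction
    tables and the pooled unique significant protein list (sorted)."""
    tables = {f: fraction_diffexpr(matrix, f, criteria) for f in fractions}
    pooled: set[str] = set()
    for table in tables.values():
        pooled.update(table.index[table["significant"]])
    return tables, sorted(pooled)
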