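"""Weighted co-expression network analysis: soft threshold, adjacency,
topological overlap, module detection, module eigengenes, module-trait
correlation.

The network follows the standard weighted co-expression construction: an
unsigned adjacency a_ij = |cor(x_i, x_j)|^beta with the soft-threshold power
beta chosen as the smallest candidate achieving a scale-free topology fit
R^2 >= 0.8; adjacency is transformed into the topological overlap matrix
(TOM), and modules are cut from an average-linkage dendrogram of 1 - TOM
with a minimum module size (default 20 proteins).  Module eigengenes (first
principal component of the standardized module expression) are correlated
against 0/1 sample traits with Spearman's rho and Benjamini-Hochberg
adjustment; a module-trait pair is flagged when |rho| > 0.7 and adjusted
p <= 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress, spearmanr
from statsmodels.stats.multitest import multipletests

from csfpanel.errors import AnalysisError
from csfpanel.ingest import FRACTIONS, GROUPS, IntensityMatrix

logger = logging.getLogger(__name__)

BACKGROUND_LABEL = "grey"

# arbitrary color names assigned to modules in decreasing-size order
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)

TRAITS = GROUPS + FRACTIONS


@dataclass
class NetworkModel:
    beta: int
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    scale_free_fit: pd.DataFrame   # per candidate power: R^2, slope, mean connectivity


@dataclass
class ModulePartition:
    labels: pd.Series                  # protein -> module color ("grey" = background)
    eigengenes: pd.DataFrame           # samples x modules, unit-norm columns
    explained_variance: pd.Series      # module -> fraction of variance in PC1
    trait_correlations: pd.DataFrame   # tidy: module, trait, rho, p, q, significant
    min_size: int

    def modules(self) -> list[str]:
        return [m for m in self.labels.unique() if m != BACKGROUND_LABEL]


def _pairwise_pearson(matrix: IntensityMatrix, min_pairs: int = 3) -> pd.DataFrame:
    """Protein x protein Pearson correlation on pairwise-complete log2 values.

    Proteins that cannot be correlated against the rest (fewer than
    ``min_pairs`` shared observations) are dropped with a warning.
    """
    corr = matrix.values.T.corr(min_periods=min_pairs)
    while True:
        nan_counts = corr.isna().sum(axis=1)
        if nan_counts.max() == 0:
            break
        worst = nan_counts.idxmax()
        logger.warning("excluding protein %s: insufficient paired observations", worst)
        corr = corr.drop(index=worst, columns=worst)
    return corr


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """R^2 and slope of the log-log regression of degree frequency on degree.

    Connectivities are binned; empty bins are dropped; at least two usable
    bins are required.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.ptp(k) == 0:
        raise AnalysisError("scale-free fit: fewer than 2 usable connectivity bins")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freqs, centers = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        freqs.append(mask.mean())
        centers.append(k[mask].mean())
    if len(freqs) < 2:
        raise AnalysisError("scale-free fit: fewer than 2 usable connectivity bins")
    fit = linregress(np.log10(centers), np.log10(freqs))
    return float(fit.rvalue ** 2), float(fit.slope)


def adjacency_from_correlation(corr: pd.DataFrame, beta: int, signed: bool = False) -> pd.DataFrame:
    if beta < 1:
        raise AnalysisError("beta must be >= 1")
    if signed:
        a = ((1.0 + corr.to_numpy()) / 2.0) ** beta
    else:
        a = np.abs(corr.to_numpy()) ** beta
    np.fill_diagonal(a, 1.0)
    return pd.DataFrame(a, index=corr.index, columns=corr.columns)


def adjacency(matrix: IntensityMatrix, beta: int, signed: bool = False, min_pairs: int = 3) -> pd.DataFrame:
    """a_ij = |cor(x_i, x_j)|^beta on pairwise-complete log2 values; a_ii = 1."""
    corr = _pairwise_pearson(matrix, min_pairs=min_pairs)
    return adjacency_from_correlation(corr, beta, signed=signed)


def _default_power(n_samples: int) -> int:
    """Conventional unsigned-network default power by sample size, used when
    no candidate reaches the scale-free fit target."""
    if n_samples < 20:
        return 9
    if n_samples < 30:
        return 8
    if n_samples < 40:
        return 7
    return 6


def pick_soft_threshold(
    matrix: IntensityMatrix,
    candidate_powers: tuple[int, ...] = tuple(range(1, 13)),
    fit_target: float = 0.8,
    n_bins: int = 10,
    signed: bool = False,
    slope_band: tuple[float, float] = (-3.0, 0.0),
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power beta.

    beta is the smallest candidate whose scale-free topology fit reaches
    ``fit_target`` with a regression slope inside ``slope_band`` (a slope
    steeper than -3 corresponds to a degree exponent outside the range seen
    in real biological networks and indicates a degenerate, compressed
    degree distribution rather than scale-free structure) and whose fit is
    sustained at the next candidate power (soft thresholding strengthens
    genuine scale-free topology, so an R^2 that collapses one power later is
    binning noise, not structure).  If no candidate qualifies, the
    conventional sample-size default power is used with a logged warning.
    A single-candidate list is returned as-is.
    """
    if matrix.values.shape[0] < 20:
        raise AnalysisError("soft-threshold selection needs >= 20 proteins")
    if matrix.values.shape[1] < 4:
        raise AnalysisError("soft-threshold selection needs >= 4 samples")
    corr = _pairwise_pearson(matrix)
    rows = []
    for power in candidate_powers:
        a = adjacency_from_correlation(corr, power, signed=signed).to_numpy()
        k = a.sum(axis=1) - 1.0  # exclude self
        r2, slope = scale_free_fit(k, n_bins=n_bins)
        rows.append({"power": power, "r_squared": r2, "slope": slope, "mean_connectivity": float(k.mean())})
    fits = pd.DataFrame(rows).set_index("power")
    if len(candidate_powers) == 1:
        beta = int(candidate_powers[0])
        if fits.loc[beta, "r_squared"] < fit_target:
            logger.warning("forced power %d does not reach scale-free fit R^2 >= %.2f", beta, fit_target)
        return beta, fits
    lo, hi = slope_band
    reaching = (fits["r_squared"] >= fit_target) & (fits["slope"] > lo) & (fits["slope"] < hi)
    sustained = reaching & reaching.shift(-1, fill_value=True)
    ok = fits[sustained]
    if len(ok) > 0:
        beta = int(ok.index[0])
    else:
        beta = _default_power(matrix.values.shape[1])
        logger.warning(
            "no candidate power reaches scale-free fit R^2 >= %.2f with slope in (%g, %g); "
            "falling back to the sample-size default power %d",
            fit_target, lo, hi, beta,
        )
    return beta, fits


def topological_overlap(adjacency: pd.DataFrame) -> pd.DataFrame:
    """TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij), TOM_ii = 1,
    where l_ij = sum_u a_iu a_uj over u != i, j and k_i = sum_u!=i a_iu."""
    a = np.asarray(adjacency, dtype=float)
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise AnalysisError("adjacency must be square and symmetric")
    a0 = a.copy()
    np.fill_diagonal(a0, 0.0)
    l = a0 @ a0                      # (A0^2)_ij = sum_u a_iu a_uj, u=i and u=j terms vanish
    k = a0.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a0
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a0) / denom
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    if isinstance(adjacency, pd.DataFrame):
        return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)
    return pd.DataFrame(tom)


def detect_modules(
    tom: pd.DataFrame,
    min_size: int = 20,
    cut_height: float | None = None,
    prune_fraction: float = 0.5,
) -> pd.Series:
    """Average-linkage hierarchical clustering on 1 - TOM with a static cut.

    The cut height defaults to the midpoint of the largest gap in the upper
    half of the dendrogram's merge heights, which separates within-module
    merges from the tight band of background merges regardless of the TOM
    scale set by beta.  After cutting, weakly attached members (mean
    within-module TOM below ``prune_fraction`` times the module median) are
    moved to the background iteratively, and clusters smaller than
    ``min_size`` become background ("grey").  Modules are named by color in
    decreasing-size order.  With an all-equal TOM every merge happens at the
    same height and a single module results (documented tie rule).
    """
    n = tom.shape[0]
    if min_size > n:
        raise AnalysisError(f"min_size={min_size} exceeds protein count {n}")
    tom_arr = np.asarray(tom, dtype=float)
    dissim = 1.0 - tom_arr
    dissim = (dissim + dissim.T) / 2.0
    np.fill_diagonal(dissim, 0.0)
    z = linkage(squareform(dissim, checks=False), method="average")
    heights = z[:, 2]
    if cut_height is None:
        if len(heights) < 2:
            cut_height = float(heights[0])
        else:
            gaps = np.diff(heights)
            start = len(heights) // 2
            i = start + int(np.argmax(gaps[start:]))
            cut_height = float((heights[i] + heights[i + 1]) / 2.0)
    raw = fcluster(z, t=cut_height, criterion="distance").astype(int)

    labels = raw.copy()
    for _ in range(20):  # prune to a fixpoint
        changed = False
        for c in np.unique(labels):
            if c < 0:
                continue
            idx = np.where(labels == c)[0]
            if len(idx) < min_size:
                labels[idx] = -1
                changed = True
                continue
            sub = tom_arr[np.ix_(idx, idx)]
            mean_within = (sub.sum(axis=1) - 1.0) / (len(idx) - 1)
            weak = idx[mean_within < prune_fraction * np.median(mean_within)]
            if len(weak):
                labels[weak] = -1
                changed = True
        if not changed:
            break

    sizes = pd.Series(labels[labels >= 0]).value_counts()
    kept = list(sizes.index)
    # deterministic order: descending size, ties by smallest member index
    first_member = {c: int(np.argmax(labels == c)) for c in kept}
    kept.sort(key=lambda c: (-sizes[c], first_member[c]))
    color_of = {c: MODULE_COLORS[i % len(MODULE_COLORS)] for i, c in enumerate(kept)}
    named = [color_of.get(c, BACKGROUND_LABEL) for c in labels]
    return pd.Series(named, index=tom.index, name="module")


def module_eigengenes(
    matrix: IntensityMatrix, labels: pd.Series
) -> tuple[pd.DataFrame, pd.Series]:
    """First principal component of each module's standardized expression.

    Missing values are mean-imputed per protein inside the standardization
    only.  Each eigengene is unit-normalized and oriented so its mean
    correlation with member proteins is positive.  Returns (eigengenes,
    explained-variance fractions).
    """
    eigengenes = {}
    explained = {}
    for module in [m for m in pd.unique(labels) if m != BACKGROUND_LABEL]:
        members = labels.index[labels == module]
        x = matrix.values.loc[members].to_numpy(dtype=float)
        row_mean = np.nanmean(x, axis=1, keepdims=True)
        x = np.where(np.isnan(x), row_mean, x)
        x = x - x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, ddof=0, keepdims=True)
        keep = sd[:, 0] > 0
        if not keep.any():
            raise AnalysisError(f"module '{module}' has rank-0 data")
        x = x[keep] / sd[keep]
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        me = vt[0]
        corr_sign = np.mean([np.dot(row, me) for row in x])
        if corr_sign < 0:
            me = -me
        eigengenes[module] = me / np.linalg.norm(me)
        explained[module] = float(s[0] ** 2 / np.sum(s ** 2))
    frame = pd.DataFrame(eigengenes, index=matrix.sample_ids)
    return frame, pd.Series(explained, name="explained_variance")


def trait_indicators(annotations: pd.DataFrame) -> pd.DataFrame:
    """0/1 indicator per sample for each of the six traits
    (control, MB, total, CPLL, Mv, Ex)."""
    out = {}
    for g in GROUPS:
        out[g] = (annotations["group"] == g).astype(int)
    for f in FRACTIONS:
        out[f] = (annotations["fraction"] == f).astype(int)
    return pd.DataFrame(out, index=annotations.index)


def module_trait_correlation(
    eigengenes: pd.DataFrame,
    traits: pd.DataFrame,
    rho_threshold: float = 0.7,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman rho of each module eigengene against each 0/1 trait, with
    Benjamini-Hochberg adjustment over all (module, trait) pairs.

    ``significant`` is True iff |rho| > rho_threshold and adjusted p <= alpha.
    """
    rows = []
    for trait in traits.columns:
        t = traits[trait].to_numpy(dtype=float)
        if np.ptp(t) == 0:
            raise AnalysisError(f"trait '{trait}' is constant")
        for module in eigengenes.columns:
            rho, p = spearmanr(eigengenes[module].to_numpy(), t)
            rows.append({"module": module, "trait": trait, "rho": float(rho), "p": float(p)})
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table["significant"] = (table["rho"].abs() > rho_threshold) & (table["q"] <= alpha)
    return table


def build_network(
    matrix: IntensityMatrix,
    candidate_powers: tuple[int, ...] = tuple(range(1, 13)),
    fit_target: float = 0.8,
    min_module_size: int = 20,
    cut_height: float | None = None,
    signed: bool = False,
    rho_threshold: float = 0.7,
    alpha: float = 0.05,
    min_detection_fraction: float = 0.5,
) -> tuple[NetworkModel, ModulePartition]:
    """Full network stage: soft threshold -> adjacency -> TOM -> modules ->
    eigengenes -> module-trait correlations.

    Proteins detected in fewer than ``min_detection_fraction`` of samples are
    excluded up front: their pairwise-complete correlations rest on a handful
    of shared observations and inject spurious network structure (the usual
    good-genes screen of co-expression analysis).
    """
    detection = matrix.values.notna().mean(axis=1)
    sparse = detection.index[detection < min_detection_fraction]
    if len(sparse):
        logger.warning(
            "excluding %d proteins detected in < %.0f%% of samples from the network",
            len(sparse), 100 * min_detection_fraction,
        )
        matrix = matrix.subset_proteins([p for p in matrix.protein_ids if p not in set(sparse)])
    beta, fits = pick_soft_threshold(
        matrix, candidate_powers=candidate_powers, fit_target=fit_target, signed=signed
    )
    adj = adjacency(matrix, beta, signed=signed)
    tom = topological_overlap(adj)
    labels = detect_modules(tom, min_size=min_module_size, cut_height=cut_height)
    eigs, explained = module_eigengenes(matrix.subset_proteins(list(labels.index)), labels)
    traits = trait_indicators(matrix.annotations)
    trait_corr = module_trait_correlation(eigs, traits, rho_threshold=rho_threshold, alpha=alpha)
    model = NetworkModel(beta=beta, adjacency=adj, tom=tom, scale_free_fit=fits)
    partition = ModulePartition(
        labels=labels,
        eigengenes=eigs,
        explained_variance=explained,
        trait_correlations=trait_corr,
        min_size=min_module_size,
    )
    return model, partition
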