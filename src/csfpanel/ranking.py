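"""Dual feature prioritization: PLS-DA with VIP scores and linear-SVM
recursive feature elimination, combined into a consensus ranked panel.

PLS-DA regresses the 0/1 class vector on standardized protein profiles
(NIPALS extraction); each protein's variable importance in projection is

    VIP_j = sqrt( p * sum_a [ SSY_a * (w_ja / ||w_a||)^2 ] / sum_a SSY_a )

with p features, per-component weights w_a and explained class variance
SSY_a, so that sum_j VIP_j^2 = p exactly.  The SVM side stratifies a 65/35
learning/held-out split, estimates fourfold cross-validated accuracy on the
learning part, scores the held-out confusion matrix, and ranks features by
recursive elimination of the smallest squared weight of a linear
soft-margin SVM.  The consensus panel intersects VIP > 1 with the top-k SVM
ranks and reports the Spearman concordance of the two orderings.

Missing values are imputed as half the protein's minimum detected value
(standard low-abundance imputation) before either classifier sees the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.svm import SVC

from csfpanel.errors import AnalysisError
from csfpanel.ingest import IntensityMatrix

logger = logging.getLogger(__name__)


@dataclass
class PLSDAModel:
    weights: np.ndarray      # p x a, sign convention: largest |weight| positive
    scores: np.ndarray       # n x a
    y_loadings: np.ndarray   # a
    feature_names: list[str]
    ssy: np.ndarray          # per-component explained class variance


@dataclass
class ClassifierReport:
    """Held-out confusion matrix and learning-part CV accuracy of the SVM."""

    confusion: pd.DataFrame  # 2x2, rows = truth, cols = prediction
    cv_accuracy_mean: float
    cv_accuracy_sd: float
    heldout_accuracy: float
    seed: int


@dataclass
class RankedPanel:
    table: pd.DataFrame          # per protein: vip, svm_rank, selected flags, consensus
    concordance: float           # Spearman rho between the two orderings on the consensus
    report: ClassifierReport | None = None

    @property
    def panel(self) -> list[str]:
        """Consensus proteins ordered by mean of the two rank positions."""
        sub = self.table[self.table["consensus"]]
        return list(sub.sort_values("panel_order").index)


def impute_half_min(matrix: IntensityMatrix) -> pd.DataFrame:
    """Replace missing values by half the protein's minimum detected log2
    value (i.e. min - 1 on the log2 scale); all-missing proteins get the
    matrix-wide minimum."""
    values = matrix.values.copy()
    row_min = values.min(axis=1)
    global_min = np.nanmin(values.to_numpy()) if np.isfinite(np.nanmin(values.to_numpy())) else 0.0
    fill = (row_min - 1.0).fillna(global_min - 1.0)
    return values.apply(lambda row: row.fillna(fill[row.name]), axis=1)


def _standardize(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, ddof=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mean) / sd


def plsda_fit(
    x: np.ndarray, labels: np.ndarray, n_components: int = 2, feature_names=None
) -> PLSDAModel:
    """Fit PLS-DA of standardized features against the 0/1 class vector.

    ``x`` is samples x features; ``labels`` is any 2-level vector.  Weight
    signs follow the convention that each component's largest-magnitude
    weight is positive.
    """
    classes = np.unique(labels)
    if len(classes) != 2:
        raise AnalysisError(f"PLS-DA requires exactly 2 classes, got {len(classes)}")
    y = (np.asarray(labels) == classes[1]).astype(float)
    xs = _standardize(np.asarray(x, dtype=float))
    # components beyond rank(X) are deflation noise and would break the
    # symmetry of VIP scores for duplicated features
    n_components = min(n_components, xs.shape[1], xs.shape[0] - 1,
                       int(np.linalg.matrix_rank(xs)))
    pls = PLSRegression(n_components=n_components, scale=False)
    with np.errstate(invalid="ignore", divide="ignore"):
        pls.fit(xs, y - y.mean())
    w = pls.x_weights_.copy()
    t = pls.x_scores_.copy()
    q = pls.y_loadings_.ravel().copy()
    for a in range(w.shape[1]):
        if w[np.argmax(np.abs(w[:, a])), a] < 0:
            w[:, a] = -w[:, a]
            t[:, a] = -t[:, a]
            q[a] = -q[a]
    ssy = (q ** 2) * np.sum(t ** 2, axis=0)
    names = list(feature_names) if feature_names is not None else [f"f{j}" for j in range(xs.shape[1])]
    return PLSDAModel(weights=w, scores=t, y_loadings=q, feature_names=names, ssy=ssy)


def vip_scores(model: PLSDAModel) -> pd.Series:
    """Variable importance in projection per feature; mean of VIP^2 is 1."""
    w, ssy = model.weights, model.ssy.copy()
    norms = np.linalg.norm(w, axis=0)
    usable = np.isfinite(ssy) & np.isfinite(norms) & (norms > 1e-12)
    if usable.any():  # components carrying numerically negligible class variance are noise
        usable &= ssy > 1e-9 * np.nanmax(ssy)
    if not usable.all():
        logger.warning("skipping %d degenerate PLS component(s) with zero explained class variance",
                       int((~usable).sum()))
    w = w[:, usable]
    ssy = ssy[usable]
    if w.shape[1] == 0:
        raise AnalysisError("no usable PLS components for VIP")
    p = w.shape[0]
    wn2 = (w / np.linalg.norm(w, axis=0, keepdims=True)) ** 2
    vip = np.sqrt(p * (wn2 @ ssy) / ssy.sum())
    return pd.Series(vip, index=model.feature_names, name="vip")


def svm_rfe_ranks(x: np.ndarray, y: np.ndarray, c: float = 1.0, feature_names=None) -> pd.Series:
    """Recursive feature elimination under a linear soft-margin SVM.

    Repeatedly drops the feature with the smallest squared weight; the
    reversed elimination order gives ranks (1 = most important, eliminated
    last).
    """
    x = _standardize(np.asarray(x, dtype=float))
    y = np.asarray(y)
    names = list(feature_names) if feature_names is not None else [f"f{j}" for j in range(x.shape[1])]
    remaining = list(range(x.shape[1]))
    elimination_order: list[int] = []
    while len(remaining) > 1:
        svm = SVC(kernel="linear", C=c)
        svm.fit(x[:, remaining], y)
        weights2 = svm.coef_.ravel() ** 2
        drop = int(np.argmin(weights2))
        elimination_order.append(remaining.pop(drop))
    elimination_order.append(remaining[0])
    ranks = np.empty(x.shape[1], dtype=int)
    for rank, j in enumerate(reversed(elimination_order), start=1):
        ranks[j] = rank
    return pd.Series(ranks, index=names, name="svm_rank")


def svm_rank(
    matrix_values: pd.DataFrame,
    labels: pd.Series,
    seed: int = 0,
    test_size: float = 0.35,
    folds: int = 4,
    c: float = 1.0,
) -> tuple[pd.Series, ClassifierReport]:
    """65/35 stratified split, fourfold CV accuracy on the learning part,
    held-out confusion matrix, and RFE feature ranks.

    The split and CV estimate prediction accuracy; the feature ranking runs
    the same elimination algorithm on all samples so ranks do not depend on
    which samples the accuracy split held out.  ``matrix_values`` is
    proteins x samples (complete, already imputed); ``labels`` maps sample
    id -> class.
    """
    x = _standardize(matrix_values.T.to_numpy(dtype=float))  # samples x features
    y = labels.loc[matrix_values.columns].to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise AnalysisError("SVM ranking requires exactly 2 classes")
    x_learn, x_test, y_learn, y_test = train_test_split(
        x, y, test_size=test_size, stratify=y, random_state=seed
    )
    if min(np.unique(y_learn, return_counts=True)[1]) < 4:
        logger.warning("fewer than 4 learning samples in a class; CV folds may be unstable")
    folds_eff = min(folds, int(min(np.unique(y_learn, return_counts=True)[1])))
    cv = StratifiedKFold(n_splits=folds_eff, shuffle=True, random_state=seed)
    cv_scores = cross_val_score(SVC(kernel="linear", C=c), x_learn, y_learn, cv=cv, scoring="accuracy")
    model = SVC(kernel="linear", C=c)
    model.fit(x_learn, y_learn)
    y_pred = model.predict(x_test)
    conf = confusion_matrix(y_test, y_pred, labels=classes)
    report = ClassifierReport(
        confusion=pd.DataFrame(conf, index=[f"true_{c_}" for c_ in classes],
                               columns=[f"pred_{c_}" for c_ in classes]),
        cv_accuracy_mean=float(cv_scores.mean()),
        cv_accuracy_sd=float(cv_scores.std()),
        heldout_accuracy=float(np.mean(y_pred == y_test)),
        seed=seed,
    )
    ranks = svm_rfe_ranks(x, y, c=c, feature_names=matrix_values.index)
    return ranks, report


def consensus_panel(
    vip: pd.Series,
    svm_ranks: pd.Series,
    vip_threshold: float = 1.0,
    top_k: int | None = None,
    report: ClassifierReport | None = None,
) -> RankedPanel:
    """Consensus of VIP > threshold and SVM rank <= top_k.

    ``top_k`` defaults to the VIP-selected count so both methods nominate
    comparably sized panels.  Concordance is Spearman rho between the
    VIP-descending ordering and the SVM ranks over the consensus set.
    """
    if set(vip.index) != set(svm_ranks.index):
        raise AnalysisError("VIP and SVM rankings cover different protein sets")
    vip = vip.loc[svm_ranks.index]
    vip_selected = vip > vip_threshold
    if top_k is None:
        top_k = int(vip_selected.sum())
    svm_selected = svm_ranks <= top_k
    consensus = vip_selected & svm_selected
    vip_rank = vip.rank(ascending=False, method="average")
    table = pd.DataFrame(
        {
            "vip": vip,
            "vip_rank": vip_rank,
            "svm_rank": svm_ranks,
            "vip_selected": vip_selected,
            "svm_selected": svm_selected,
            "consensus": consensus,
            "panel_order": (vip_rank + svm_ranks) / 2.0,
        }
    )
    if consensus.sum() >= 2:
        rho = float(spearmanr(vip_rank[consensus], svm_ranks[consensus])[0])
    elif consensus.sum() == 0:
        logger.warning("empty consensus panel")
        rho = float("nan")
    else:
        rho = float("nan")
    return RankedPanel(table=table.sort_values("panel_order"), concordance=rho, report=report)


def rank_proteins(
    matrix: IntensityMatrix,
    protein_ids: list[str],
    seed: int = 0,
    n_components: int = 2,
    test_size: float = 0.35,
    folds: int = 4,
    vip_threshold: float = 1.0,
) -> RankedPanel:
    """Full ranking stage over a candidate protein set (e.g. the pooled
    significant proteins): impute, fit PLS-DA + VIP, SVM split/CV/RFE,
    combine into the consensus panel."""
    if not protein_ids:
        raise AnalysisError("no candidate proteins to rank")
    sub = matrix.subset_proteins(protein_ids)
    complete = impute_half_min(sub)
    labels = sub.annotations["group"]
    model = plsda_fit(complete.T.to_numpy(), labels.to_numpy(), n_components=n_components,
                      feature_names=complete.index)
    vip = vip_scores(model)
    ranks, report = svm_rank(complete, labels, seed=seed, test_size=test_size, folds=folds)
    return consensus_panel(vip, ranks, vip_threshold=vip_threshold, report=report)


def rank_fractions(
    matrix: IntensityMatrix,
    candidates_by_fraction: dict[str, list[str]],
    seed: int = 0,
    n_components: int = 2,
    test_size: float = 0.35,
    folds: int = 4,
    vip_threshold: float = 1.0,
) -> tuple[dict[str, RankedPanel], pd.DataFrame]:
    """Rank each fraction's candidate proteins on that fraction's samples and
    pool the per-fraction panels into one deduplicated ranked table.

    A protein's pooled ``panel_order`` is its best (smallest) order across
    fractions; ``consensus`` is True if it entered any fraction's consensus
    panel.  One membership column per fraction records where it ranked.
    """
    panels: dict[str, RankedPanel] = {}
    for fraction, candidates in candidates_by_fraction.items():
        if len(candidates) < 2:
            logger.warning("fraction '%s' has < 2 candidate proteins; ranking skipped", fraction)
            continue
        sub = matrix.subset_samples(matrix.samples_in(fraction=fraction))
        panels[fraction] = rank_proteins(
            sub, candidates, seed=seed, n_components=n_components,
            test_size=test_size, folds=folds, vip_threshold=vip_threshold,
        )
    rows: dict[str, dict] = {}
    for fraction, panel in panels.items():
        for protein, rec in panel.table.iterrows():
            entry = rows.setdefault(protein, {
                "panel_order": np.inf, "vip": 0.0, "consensus": False,
                **{f"in_{f}": False for f in candidates_by_fraction},
            })
            entry[f"in_{fraction}"] = True
            entry["consensus"] = entry["consensus"] or bool(rec["consensus"])
            if rec["panel_order"] < entry["panel_order"]:
                entry["panel_order"] = rec["panel_order"]
                entry["vip"] = rec["vip"]
                entry["best_fraction"] = fraction
                entry["svm_rank"] = rec["svm_rank"]
    pooled = pd.DataFrame.from_dict(rows, orient="index").sort_values("panel_order")
    pooled.index.name = "protein_id"
    return panels, pooled
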