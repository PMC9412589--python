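"""Two-group gene-set enrichment with a bounded [-1, 1] rank value per term.

Over-representation of each gene set in the significant protein list is
tested with the one-sided hypergeometric tail, BH-adjusted across terms.
Each term then receives a per-group rank value

    s_group = clip( sign(group-oriented mean log2 FC) * sqrt(k / K) * (1 - q), -1, 1 )

combining coverage (k significant members of K in the universe), fold-change
direction, and the FDR-adjusted p-value q — bounded in [-1, 1] with -1/1 =
minimal/maximal enrichment in that group.  The exact functional form is this
package's own instantiation of those qualitative constraints and is isolated
in :func:`rank_value` so alternatives can be swapped.

In the (s_MB, s_control) scatter, terms on the x = y diagonal are equally
enriched; the signed perpendicular distance d = (s_MB - s_control) / sqrt(2)
is positive for MB-enriched and negative for control-enriched terms.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from csfpanel.errors import AnalysisError

logger = logging.getLogger(__name__)


def term_enrichment_p(
    term_members: Iterable[str], significant: Iterable[str], universe: Iterable[str]
) -> float:
    """One-sided hypergeometric over-representation p-value of a term.

    p = P(X >= k) with X ~ Hypergeom(N = |universe|, K = |significant|,
    n = |term members in universe|) and k the observed overlap.
    """
    universe = frozenset(universe)
    if not universe:
        raise AnalysisError("empty universe")
    significant = frozenset(significant) & universe
    members = frozenset(term_members) & universe
    k = len(members & significant)
    return float(hypergeom.sf(k - 1, len(universe), len(significant), len(members)))


def rank_value(k: int, K: int, mean_log2_fc: float, q: float, group: str) -> float:
    """Bounded per-group enrichment rank value (see module docstring).

    ``group`` is "MB" or "control"; orientation is positive when the term's
    mean log2 FC (MB - control) favors the scored group.
    """
    if K == 0:
        raise AnalysisError("rank_value: K = 0 (term absent from universe)")
    if not 0.0 <= q <= 1.0:
        raise AnalysisError("rank_value: q must lie in [0, 1]")
    if not np.isfinite(mean_log2_fc):
        raise AnalysisError("rank_value: mean_log2_fc must be finite")
    oriented = mean_log2_fc if group == "MB" else -mean_log2_fc
    s = float(np.sign(oriented)) * math.sqrt(k / K) * (1.0 - q)
    return float(np.clip(s, -1.0, 1.0))


def scatter_geometry(s_mb, s_control):
    """Signed perpendicular distance of (s_MB, s_control) from the x = y line:
    d = (s_MB - s_control) / sqrt(2); positive = MB-enriched."""
    return (np.asarray(s_mb, dtype=float) - np.asarray(s_control, dtype=float)) / math.sqrt(2.0)


def enrich_terms(
    terms: Mapping[str, tuple[str, tuple[str, ...]]],
    diffexpr_table: pd.DataFrame,
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Score every GMT term against one differential-expression table.

    ``diffexpr_table`` must carry ``log2_fc`` and ``significant`` columns
    indexed by protein id (a per-fraction table or a pooled one).  The
    universe defaults to all tested proteins of the table.
    """
    if universe is None:
        universe = diffexpr_table.index[diffexpr_table.get("tested", pd.Series(True, index=diffexpr_table.index))]
    universe = frozenset(universe)
    if not universe:
        raise AnalysisError("empty universe")
    significant = frozenset(diffexpr_table.index[diffexpr_table["significant"]]) & universe

    rows = []
    for term, (description, members) in terms.items():
        members_in = frozenset(members) & universe
        K = len(members_in)
        if K == 0:
            logger.warning("term '%s' has no members in the universe; skipped", term)
            continue
        hits = members_in & significant
        k = len(hits)
        p = float(hypergeom.sf(k - 1, len(universe), len(significant), K))
        fcs = diffexpr_table.loc[sorted(hits), "log2_fc"].dropna()
        mean_fc = float(fcs.mean()) if len(fcs) else 0.0
        rows.append({"term": term, "description": description, "k": k, "K": K,
                     "mean_log2_fc": mean_fc, "p": p})
    columns = ["term", "description", "k", "K", "mean_log2_fc", "p"]
    table = pd.DataFrame(rows, columns=columns).set_index("term")
    if len(table) == 0:
        for extra in ("q", "s_mb", "s_control", "d"):
            table[extra] = []
        return table
    table["q"] = multipletests(table["p"], method="fdr_bh")[1]
    table["s_mb"] = [
        rank_value(r.k, r.K, r.mean_log2_fc, r.q, "MB") for r in table.itertuples()
    ]
    table["s_control"] = [
        rank_value(r.k, r.K, r.mean_log2_fc, r.q, "control") for r in table.itertuples()
    ]
    table["d"] = scatter_geometry(table["s_mb"], table["s_control"])
    return table.sort_values("d", ascending=False)
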