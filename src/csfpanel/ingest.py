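"""Reading, normalisation and overlap (Venn) accounting for protein intensity tables.

Input dialect follows MaxQuant-style ``proteinGroups.txt`` exports: one row
per protein group, one intensity column per sample, zero meaning "not
detected".  Intensities are log2-transformed on read; the missing-value mask
is carried alongside the values and is never altered by normalisation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_DOWN, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from csfpanel.errors import AnalysisError, FormatError

logger = logging.getLogger(__name__)

GROUPS = ("control", "MB")
FRACTIONS = ("total", "CPLL", "Mv", "Ex")


@dataclass
class IntensityMatrix:
    """Proteins x samples log2 intensities with sample annotations.

    Parameters
    ----------
    values
        DataFrame indexed by protein id, one column per sample; NaN encodes
        "not detected".
    annotations
        DataFrame indexed by sample id with columns ``group`` (control/MB)
        and ``fraction`` (total/CPLL/Mv/Ex), one row per sample column.
    """

    values: pd.DataFrame
    annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate protein ids: {dupes[:5]}")
        missing_ann = [s for s in self.values.columns if s not in self.annotations.index]
        if missing_ann:
            raise FormatError(f"samples without annotation: {missing_ann[:5]}")
        self.annotations = self.annotations.loc[list(self.values.columns)]
        bad_group = set(self.annotations["group"]) - set(GROUPS)
        if bad_group:
            raise FormatError(f"unknown group labels in annotations: {sorted(bad_group)}")
        bad_frac = set(self.annotations["fraction"]) - set(FRACTIONS)
        if bad_frac:
            raise FormatError(f"unknown fraction labels in annotations: {sorted(bad_frac)}")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def detected(self) -> pd.DataFrame:
        """Boolean mask, True where a value was measured."""
        return self.values.notna()

    def samples_in(self, group: str | None = None, fraction: str | None = None) -> list[str]:
        """Sample ids matching the given group and/or fraction."""
        mask = pd.Series(True, index=self.annotations.index)
        if group is not None:
            mask &= self.annotations["group"] == group
        if fraction is not None:
            mask &= self.annotations["fraction"] == fraction
        return list(self.annotations.index[mask])

    def subset_samples(self, sample_ids: Sequence[str]) -> "IntensityMatrix":
        return IntensityMatrix(self.values[list(sample_ids)].copy(), self.annotations.loc[list(sample_ids)].copy())

    def subset_proteins(self, protein_ids: Sequence[str]) -> "IntensityMatrix":
        return IntensityMatrix(self.values.loc[list(protein_ids)].copy(), self.annotations.copy())

    def detected_proteins(self, group: str | None = None, fraction: str | None = None) -> set[str]:
        """Protein ids detected in at least one sample of the requested cell."""
        cols = self.samples_in(group, fraction)
        mask = self.values[cols].notna().any(axis=1)
        return set(self.values.index[mask])


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a sample-annotation TSV with columns sample_id, group, fraction."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group", "fraction"):
        if col not in df.columns:
            raise FormatError(f"annotation file {path} lacks column '{col}'")
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicate sample_id in annotation file")
    return df.set_index("sample_id")[["group", "fraction"]]


def read_protein_table(
    path: str | Path,
    annotations: pd.DataFrame,
    id_column: str = "protein_id",
    intensity_prefix: str = "",
) -> IntensityMatrix:
    """Read a protein-group intensity TSV into an :class:`IntensityMatrix`.

    Intensity columns are resolved as ``intensity_prefix + sample_id`` for
    each annotated sample.  Zeros and empty cells become missing values;
    raw intensities are log2-transformed.
    """
    df = pd.read_csv(path, sep="\t")
    if id_column not in df.columns:
        raise FormatError(f"protein table {path} lacks id column '{id_column}'")
    wanted = {f"{intensity_prefix}{s}": s for s in annotations.index}
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise FormatError(f"protein table lacks intensity columns for samples: {missing[:5]}")
    extra = [
        c for c in df.columns
        if c.startswith(intensity_prefix) and c != id_column and c not in wanted
        and pd.api.types.is_numeric_dtype(df[c])
    ]
    if intensity_prefix and extra:
        logger.warning("ignoring %d unannotated intensity columns: %s", len(extra), extra[:5])
    values = df.set_index(id_column)[list(wanted)].astype(float)
    values.columns = [wanted[c] for c in values.columns]
    values = values.where(values > 0)  # zero/negative = not detected
    values = np.log2(values)
    return IntensityMatrix(values, annotations.copy())


def write_protein_table(
    matrix: IntensityMatrix,
    path: str | Path,
    id_column: str = "protein_id",
    intensity_prefix: str = "",
) -> None:
    """Write the matrix back to the raw-intensity TSV dialect (missing -> 0)."""
    raw = np.power(2.0, matrix.values)
    raw = raw.fillna(0.0)
    raw.columns = [f"{intensity_prefix}{c}" for c in raw.columns]
    raw.index.name = id_column
    raw.to_csv(path, sep="\t", float_format="%.10g")


def write_annotations(annotations: pd.DataFrame, path: str | Path) -> None:
    out = annotations.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def normalize(matrix: IntensityMatrix, per_fraction: bool = False) -> IntensityMatrix:
    """Median-center each sample's detected log2 intensities to the grand median.

    With ``per_fraction=True`` the grand median is computed within each
    fraction separately.  The detection mask and protein ordering are
    untouched.
    """
    empty = matrix.values.notna().sum(axis=0) == 0
    if empty.any():
        raise AnalysisError(f"sample(s) with no detected values: {list(matrix.values.columns[empty])[:5]}")
    values = matrix.values.copy()
    if per_fraction:
        for frac in FRACTIONS:
            cols = matrix.samples_in(fraction=frac)
            if not cols:
                continue
            block = values[cols]
            target = np.nanmedian(block.to_numpy())
            values[cols] = block - block.median(axis=0) + target
    else:
        target = np.nanmedian(values.to_numpy())
        values = values - values.median(axis=0) + target
    return IntensityMatrix(values, matrix.annotations.copy())


def percent(part: int, whole: int, decimals: int = 1, rounding: str = "round") -> float:
    """Percentage of ``part`` in ``whole`` with an explicit decimal policy.

    ``rounding`` is ``"round"`` (half-up) or ``"truncate"`` (toward zero),
    matching the two conventions mixed in published Venn accountings.
    """
    if whole == 0:
        raise AnalysisError("zero denominator in percentage")
    if rounding not in ("round", "truncate"):
        raise ValueError(f"unknown rounding policy '{rounding}'")
    value = Decimal(part) / Decimal(whole) * 100
    quantum = Decimal(1).scaleb(-decimals)
    mode = ROUND_HALF_UP if rounding == "round" else ROUND_DOWN
    return float(value.quantize(quantum, rounding=mode))


@dataclass
class OverlapSummary:
    """Venn accounting over named protein-id sets.

    ``percentages`` are relative to ``denominator`` under the stated decimal
    policy and always recompute exactly from the stored counts.
    """

    set_counts: dict[str, int]
    intersection_all: int
    pairwise: dict[tuple[str, str], int]
    exclusive_counts: dict[str, int]
    denominator: int
    decimals: int
    rounding: str
    percentages: dict[str, float] = field(default_factory=dict)

    def percent_of(self, count: int) -> float:
        return percent(count, self.denominator, self.decimals, self.rounding)


def overlap_summary(
    sets: Mapping[str, Iterable[str]],
    denominator: int | str | Iterable[str] | None = None,
    decimals: int = 1,
    rounding: str = "round",
) -> OverlapSummary:
    """Count shared and exclusive members among named sets, with percentages.

    ``denominator`` may be an integer, the name of one of ``sets``, an
    explicit id collection, or None (union of all sets).
    """
    fsets = {name: frozenset(members) for name, members in sets.items()}
    names = list(fsets)
    union = frozenset().union(*fsets.values()) if fsets else frozenset()
    if denominator is None:
        denom = len(union)
    elif isinstance(denominator, int):
        denom = denominator
    elif isinstance(denominator, str) and denominator in fsets:
        denom = len(fsets[denominator])
    else:
        denom = len(frozenset(denominator))
    if denom == 0:
        raise AnalysisError("overlap_summary: empty/zero denominator")

    set_counts = {n: len(s) for n, s in fsets.items()}
    inter_all = len(frozenset.intersection(*fsets.values())) if fsets else 0
    pairwise = {
        (a, b): len(fsets[a] & fsets[b])
        for i, a in enumerate(names)
        for b in names[i + 1:]
    }
    exclusive = {
        n: len(fsets[n] - frozenset().union(*(fsets[m] for m in names if m != n)))
        if len(names) > 1 else len(fsets[n])
        for n in names
    }
    summary = OverlapSummary(
        set_counts=set_counts,
        intersection_all=inter_all,
        pairwise=pairwise,
        exclusive_counts=exclusive,
        denominator=denom,
        decimals=decimals,
        rounding=rounding,
    )
    summary.percentages = {
        **{f"{n}": summary.percent_of(c) for n, c in set_counts.items()},
        "intersection_all": summary.percent_of(inter_all),
        **{f"exclusive:{n}": summary.percent_of(c) for n, c in exclusive.items()},
    }
    return summary


def read_gmt(path: str | Path) -> dict[str, tuple[str, tuple[str, ...]]]:
    """Parse a GMT gene-set file into ``{term: (description, members)}``.

    Duplicate members within a term are collapsed (first occurrence kept).
    """
    terms: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has {len(parts)} fields, need >= 3")
            term, description, *members = parts
            seen: dict[str, None] = {}
            for m in members:
                if m:
                    seen.setdefault(m)
            terms[term] = (description, tuple(seen))
    return terms


def write_gmt(terms: Mapping[str, tuple[str, tuple[str, ...]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for term, (description, members) in terms.items():
            fh.write("\t".join([term, description, *members]) + "\n")
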