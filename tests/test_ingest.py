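"""Table IO, normalization and Venn/overlap accounting."""

import numpy as np
import pandas as pd
import pytest

from csfpanel.errors import AnalysisError, FormatError
from csfpanel import ingest
from csfpanel.synthetic import default_config, generate_dataset


def write_tsv(path, text):
    path.write_text(text)
    return path


ANNOT = "sample_id\tgroup\tfraction\nS1\tcontrol\ttotal\nS2\tMB\ttotal\n"


class TestReadProteinTable:
    def test_zero_cell_becomes_missing(self, tmp_path):
        proteins = write_tsv(tmp_path / "p.tsv",
                             "protein_id\tS1\tS2\nA\t1024\t2048\nB\t0\t4096\nC\t512\t512\n")
        ann = ingest.read_annotations(write_tsv(tmp_path / "a.tsv", ANNOT))
        matrix = ingest.read_protein_table(proteins, ann)
        assert matrix.values.loc["A", "S1"] == 10.0  # log2(1024)
        assert np.isnan(matrix.values.loc["B", "S1"])
        assert matrix.detected.sum().sum() == 5

    def test_extra_intensity_columns_ignored(self, tmp_path):
        proteins = write_tsv(
            tmp_path / "p.tsv",
            "protein_id\tIntensity S1\tIntensity S2\tIntensity S9\nA\t2\t4\t8\n")
        ann = ingest.read_annotations(write_tsv(tmp_path / "a.tsv", ANNOT))
        matrix = ingest.read_protein_table(proteins, ann, intensity_prefix="Intensity ")
        assert matrix.sample_ids == ["S1", "S2"]

    def test_missing_id_column_raises(self, tmp_path):
        proteins = write_tsv(tmp_path / "p.tsv", "name\tS1\tS2\nA\t2\t4\n")
        ann = ingest.read_annotations(write_tsv(tmp_path / "a.tsv", ANNOT))
        with pytest.raises(FormatError, match="protein_id"):
            ingest.read_protein_table(proteins, ann)

    def test_duplicate_protein_ids_raise(self, tmp_path):
        proteins = write_tsv(tmp_path / "p.tsv", "protein_id\tS1\tS2\nA\t2\t4\nA\t8\t16\n")
        ann = ingest.read_annotations(write_tsv(tmp_path / "a.tsv", ANNOT))
        with pytest.raises(FormatError, match="duplicate"):
            ingest.read_protein_table(proteins, ann)

    def test_round_trip_preserves_matrix(self, tmp_path):
        matrix, _ = generate_dataset(default_config(n_proteins=200, seed=4))
        ingest.write_protein_table(matrix, tmp_path / "m.tsv")
        back = ingest.read_protein_table(tmp_path / "m.tsv", matrix.annotations)
        assert back.detected.equals(matrix.detected)
        np.testing.assert_allclose(back.values.to_numpy(), matrix.values.to_numpy(),
                                   rtol=1e-8, equal_nan=True)


class TestNormalize:
    def test_aligns_all_sample_medians(self):
        matrix, _ = generate_dataset(default_config(n_proteins=200, seed=2))
        normed = ingest.normalize(matrix)
        medians = normed.values.median(axis=0)
        np.testing.assert_allclose(medians, medians.iloc[0], atol=1e-9)
        assert normed.detected.equals(matrix.detected)

    def test_idempotent_and_shift_equivariant(self, matrix_factory):
        values = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        m = matrix_factory(values)
        once = ingest.normalize(m)
        twice = ingest.normalize(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)
        # a +3 log2 shift of one sample is removed exactly (up to the
        # overall location, which moves with the grand median)
        shifted = ingest.normalize(matrix_factory(values + np.array([0.0, 3.0])))
        diff = shifted.values.to_numpy() - once.values.to_numpy()
        assert np.ptp(diff) == pytest.approx(0.0, abs=1e-12)

    def test_all_missing_sample_raises_with_name(self, matrix_factory):
        values = np.array([[1.0, np.nan], [2.0, np.nan]])
        with pytest.raises(AnalysisError, match="S1"):
            ingest.normalize(matrix_factory(values))


class TestOverlapAccounting:
    def test_published_venn_percentages_recompute(self):
        """Percentages printed in the source study's protein accounting,
        recomputed from their numerator/denominator pairs."""
        cases = [
            (2412, 3560, 1, "truncate", 67.7),   # shared between groups
            (346, 3560, 1, "truncate", 9.7),     # control-exclusive
            (805, 3560, 1, "truncate", 22.6),    # MB-exclusive
            (584, 2758, 1, "round", 21.2),       # in all four control fractions
            (701, 3217, 1, "round", 21.8),       # in all four MB fractions
            (2371, 2539, 0, "round", 93.0),      # microvesicle database members
            (1746, 2297, 0, "round", 76.0),      # exosome database members
        ]
        for part, whole, decimals, rounding, expected in cases:
            assert ingest.percent(part, whole, decimals, rounding) == expected

    def test_overlap_summary_counts_and_percentages(self):
        shared = {f"x{i}" for i in range(2412)}
        sets = {
            "control": shared | {f"c{i}" for i in range(346)},
            "MB": shared | {f"m{i}" for i in range(805)},
        }
        summary = ingest.overlap_summary(sets, denominator=3560, decimals=1, rounding="truncate")
        assert summary.pairwise[("control", "MB")] == 2412
        assert summary.exclusive_counts == {"control": 346, "MB": 805}
        assert summary.percentages["exclusive:MB"] == 22.6
        assert summary.percentages["exclusive:control"] == 9.7
        assert summary.percent_of(2412) == 67.7

    def test_set_against_itself(self):
        s = {"a", "b", "c"}
        summary = ingest.overlap_summary({"x": s, "y": s})
        assert summary.intersection_all == 3
        assert summary.percentages["intersection_all"] == 100.0

    def test_percentages_recompute_from_counts(self, rng):
        ids = [f"p{i}" for i in range(200)]
        sets = {k: set(rng.choice(ids, size=rng.integers(10, 150), replace=False))
                for k in "ABC"}
        summary = ingest.overlap_summary(sets, denominator=200, decimals=2, rounding="round")
        for name, count in summary.set_counts.items():
            assert summary.percentages[name] == summary.percent_of(count)

    def test_zero_denominator_raises(self):
        with pytest.raises(AnalysisError):
            ingest.overlap_summary({"a": {"x"}}, denominator=0)


class TestGMT:
    def test_parse_two_terms(self, tmp_path):
        gmt = write_tsv(tmp_path / "t.gmt",
                        "GO:1\timmune response\tA\tB\tC\nGO:2\tadhesion\tB\tD\n")
        terms = ingest.read_gmt(gmt)
        assert terms["GO:1"] == ("immune response", ("A", "B", "C"))
        assert terms["GO:2"][1] == ("B", "D")

    def test_duplicate_member_collapsed(self, tmp_path):
        gmt = write_tsv(tmp_path / "t.gmt", "GO:1\tdesc\tA\tB\tA\n")
        assert ingest.read_gmt(gmt)["GO:1"][1] == ("A", "B")

    def test_malformed_line_reports_number(self, tmp_path):
        gmt = write_tsv(tmp_path / "t.gmt", "GO:1\tdesc\tA\nGO:2\tonlydesc\n")
        with pytest.raises(FormatError, match=":2:"):
            ingest.read_gmt(gmt)

    def test_round_trip(self, tmp_path):
        terms = {"GO:1": ("desc one", ("A", "B")), "GO:2": ("desc two", ("C",))}
        ingest.write_gmt(terms, tmp_path / "t.gmt")
        assert ingest.read_gmt(tmp_path / "t.gmt") == terms
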