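"""Compound differential-expression criterion and its five components."""

import numpy as np
import pytest
from scipy import stats

from csfpanel import diffexpr as de
from csfpanel.synthetic import DESpec, SyntheticConfig, generate_dataset
from csfpanel.validation import trapezoid_auc


def sim_config(n_proteins=400, de_specs=(), seed=0, **kw):
    base = dict(n_proteins=n_proteins, n_samples_per_cell=6, module_specs=(),
                de_specs=de_specs, exclusive_specs={}, dropout_midpoint=None, seed=seed)
    base.update(kw)
    return SyntheticConfig(**base)


class TestTTests:
    def test_identical_groups_give_null_statistics(self, matrix_factory):
        values = np.tile([5.0, 5, 5, 5, 5, 5], (3, 1))
        table = de.protein_t_tests(matrix_factory(values), "total")
        assert (table["log2_fc"] == 0).all()
        assert (table["p"] == 1.0).all()

    def test_null_raw_p_uniform(self):
        matrix, _ = generate_dataset(sim_config(n_proteins=1000, seed=3))
        table = de.protein_t_tests(matrix, "total")
        ks = stats.kstest(table["p"], "uniform")
        assert ks.pvalue > 0.01
        assert (table["q"] <= 0.05).mean() <= 0.005

    def test_planted_fold_change_recovered(self):
        cfg = sim_config(n_proteins=300, de_specs=(DESpec(50, 2.0, ("total",)),), seed=4)
        matrix, truth = generate_dataset(cfg)
        table = de.protein_t_tests(matrix, "total")
        planted = list(truth.de_proteins)
        assert abs(table.loc[planted, "log2_fc"].median() - 2.0) < 0.3

    def test_untested_proteins_flagged(self, matrix_factory):
        values = np.array([[1.0, np.nan, np.nan, 2.0, 3.0, 2.5]])
        table = de.protein_t_tests(matrix_factory(values), "total")
        assert not table["tested"].iloc[0]
        assert np.isnan(table["p"].iloc[0])


class TestPresenceFilter:
    def test_arithmetic(self, matrix_factory):
        row_pass = [np.nan] * 6 + [1.0, 1, 1, 1, 1, np.nan]      # 0/6 vs 5/6
        row_fail = [1.0, 1, 1, 1, np.nan, np.nan] * 2             # 4/6 vs 4/6
        m = matrix_factory(np.array([row_pass, row_fail]))
        table = de.presence_filter(m, "total", threshold=0.7)
        assert table["presence_pass"].tolist() == [True, False]
        assert table["presence_mb"].iloc[0] == pytest.approx(5 / 6)

    def test_zero_threshold_passes_everything(self, matrix_factory, rng):
        m = matrix_factory(rng.normal(size=(5, 6)))
        assert de.presence_filter(m, "total", threshold=0.0)["presence_pass"].all()


class TestProteinAUC:
    def test_perfect_separation(self, matrix_factory):
        values = np.array([[1.0, 2, 3, 10, 11, 12]])
        table = de.protein_auc(matrix_factory(values), "total")
        assert table["auc"].iloc[0] == 1.0
        assert table["auc_direction"].iloc[0] == "MB"

    def test_identical_distributions_near_half(self, matrix_factory, rng):
        m = matrix_factory(rng.normal(size=(200, 40)),
                           groups=["control"] * 20 + ["MB"] * 20,
                           fractions=["total"] * 40)
        aucs = de.protein_auc(m, "total")["auc_mb"]
        assert abs(aucs.mean() - 0.5) < 0.03

    def test_equals_trapezoid_integration(self, matrix_factory, rng):
        for _ in range(20):
            values = rng.integers(0, 6, size=(1, 6)).astype(float)  # ties included
            m = matrix_factory(values)
            rank_based = de.protein_auc(m, "total")["auc_mb"].iloc[0]
            labels = np.array([0, 0, 0, 1, 1, 1])
            assert rank_based == pytest.approx(trapezoid_auc(values[0], labels), abs=1e-12)


class TestPosthocPower:
    def test_zero_effect_gives_alpha_level(self):
        assert de.posthoc_power(0.0, 6, 6, alpha=0.05) == pytest.approx(0.05, abs=1e-9)

    def test_large_effect_saturates(self):
        assert de.posthoc_power(10.0, 6, 6) > 0.999

    def test_matches_statsmodels(self):
        from statsmodels.stats.power import TTestIndPower
        for d, n in [(0.5, 10), (1.0, 6), (2.0, 6), (1.5, 8)]:
            ref = TTestIndPower().power(effect_size=d, nobs1=n, ratio=1.0, alpha=0.05)
            assert de.posthoc_power(d, n, n) == pytest.approx(ref, abs=1e-9)

    def test_matches_monte_carlo(self, rng):
        """Power at d = 2, 6 vs 6, alpha 0.05 against 50k simulated t tests."""
        n_sim, n = 50_000, 6
        x = rng.normal(0, 1, (n_sim, n))
        y = rng.normal(2.0, 1, (n_sim, n))
        t, p = stats.ttest_ind(y, x, axis=1)
        mc = (p <= 0.05).mean()
        assert de.posthoc_power(2.0, n, n) == pytest.approx(mc, abs=0.01)

    def test_zero_variance_conventions(self):
        assert de.posthoc_power(np.inf, 4, 4) == 1.0
        assert de.posthoc_power(0.0, 4, 4) < 0.06


class TestVolcanoThreshold:
    def test_below_x0_never_flagged(self):
        x = np.array([0.0, 0.5, 1.0])
        y = np.array([100.0, 100.0, 100.0])
        assert not de.volcano_threshold(x, y, c=1.0, x0=1.0).any()

    def test_point_on_curve_not_flagged(self):
        # y = c/(x - x0) exactly
        c, x0 = 1.0, 1.0
        x = np.array([2.0])
        y = c / (x - x0)
        assert not de.volcano_threshold(x, y, c=c, x0=x0)[0]

    def test_default_calibration_passes_through_fc2_alpha(self):
        # defaults: curve through (2, -log10 0.05); (2.5, 2.0) lies above
        assert de.volcano_threshold(np.array([2.5]), np.array([2.0]))[0]
        edge = -np.log10(0.05)
        assert not de.volcano_threshold(np.array([2.0]), np.array([edge]))[0]


class TestCompoundCriterion:
    def test_conjunction_requires_all_five(self, matrix_factory, rng):
        # protein 0: full effect (passes everything); protein 1: same but
        # fold change ~0.5 log2 units (fails FC only)
        ctrl = rng.normal(0, 0.1, (2, 6))
        mb = ctrl + np.array([[3.0], [0.5]])
        m = matrix_factory(np.hstack([ctrl, mb]) + 20)
        table = de.fraction_diffexpr(m, "total")
        assert table["significant"].iloc[0]
        row = table.iloc[1]
        assert row[["pass_q", "pass_presence", "pass_auc"]].all()
        assert not row["pass_fc"]
        assert not row["significant"]

    def test_null_yields_no_discoveries(self):
        matrix, _ = generate_dataset(sim_config(n_proteins=500, seed=9))
        _, significant = de.select_significant(matrix, ("total",))
        assert len(significant) <= 2

    def test_planted_effects_recovered_with_low_fdp(self):
        cfg = sim_config(n_proteins=500, de_specs=(DESpec(40, 2.0, ("total",)),), seed=10)
        matrix, truth = generate_dataset(cfg)
        tables, significant = de.select_significant(matrix, ("total",))
        planted = set(truth.de_proteins)
        hits = set(significant)
        assert len(hits & planted) / len(planted) >= 0.8
        assert len(hits - planted) / max(len(hits), 1) <= 0.1

    def test_recall_monotone_in_effect_size(self):
        recalls = []
        for fc in (0.8, 1.6, 3.2):
            cfg = sim_config(n_proteins=200, de_specs=(DESpec(30, fc, ("total",)),), seed=11)
            matrix, truth = generate_dataset(cfg)
            _, significant = de.select_significant(matrix, ("total",))
            planted = set(truth.de_proteins)
            recalls.append(len(set(significant) & planted) / len(planted))
        assert recalls == sorted(recalls)
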