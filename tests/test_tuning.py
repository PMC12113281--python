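"""Monkey-sum index, interaction ANOVA, residuals, reliability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import headbody as hb


class TestMSI:
    @pytest.mark.parametrize(
        "m,b,h,expected",
        [
            (10, 4, 2, 0.25),   # (10 - 6) / (10 + 6)
            (0, 3, 2, -1.0),    # silent monkey, driven parts
            (5, 0, 0, 1.0),     # driven monkey, silent parts
            (6, 4, 2, 0.0),     # exact additivity
        ],
    )
    def test_examples(self, m, b, h, expected):
        assert hb.msi(m, b, h) == pytest.approx(expected)

    def test_zero_denominator_dropped(self):
        assert np.isnan(hb.msi(0.0, 0.0, 0.0))

    @given(m=st.floats(-50, 50), s=st.floats(-50, 50))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_antisymmetry(self, m, s):
        """Swapping the monkey response with the part sum flips the sign."""
        if abs(m) + abs(s) == 0:
            return
        assert hb.msi(m, s, 0.0) == pytest.approx(-hb.msi(s, m, 0.0))
        assert -1 <= hb.msi(m, s, 0.0) <= 1

    def test_case_selection_null_rate(self):
        """Three independent alpha=0.05 tests select ~1-(1-a)^3 of null cases."""
        grid = hb.make_stimulus_grid("E1", "P1", "MC")
        triples = [
            (c, h, b)
            for c, h, b in _triples(grid)
        ]
        params = hb.TuningParams(gain=0.0, baseline=10.0)
        n = hits = 0
        for i in range(60):
            unit = hb.simulate_unit(params, grid, seed=3000 + i)
            for m_cond, h_cond, b_cond in triples:
                hits += hb.msi_case_select(unit, m_cond, h_cond, b_cond)
                n += 1
        rate = hits / n
        # rank-sum at alpha=.05 plus the one-sided excitatory check is
        # conservative; expect well below the 0.14 upper bound and above 0
        assert 0.005 < rate < 0.14

    def test_msi_table_parts_driven_monkey_silent(self):
        """Units driven by parts but not the whole monkey yield MSI near -1."""
        grid = hb.make_stimulus_grid("E1", "P1", "MC")
        params = hb.TuningParams(kappa_head=0.5, kappa_body=0.5, gain=50,
                                 baseline=5, part_weights=(0.0, 1.0, 1.0))
        unit = hb.simulate_unit(params, grid, seed=4)
        table = hb.msi_table([unit], grid)
        assert len(table) > 0
        assert table.msi.median() < -0.5


def _triples(grid):
    from headbody.tuning import _matched_triples

    return _matched_triples("P1", "MC", grid)


class TestVarianceStabilize:
    def test_values(self):
        assert hb.variance_stabilize(0) == pytest.approx(np.sqrt(0.375))
        assert hb.variance_stabilize(1) == pytest.approx(np.sqrt(1.375))
        assert hb.variance_stabilize(13 / 8) == pytest.approx(np.sqrt(2))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            hb.variance_stabilize(-1)


class TestAdditiveResiduals:
    def test_additive_matrix_zero_residuals(self):
        rng = np.random.default_rng(0)
        row = rng.normal(size=8)
        col = rng.normal(size=8)
        mat = row[:, None] + col[None, :]
        assert np.abs(hb.additive_residuals(mat)).max() < 1e-12

    def test_single_cell_bump(self):
        mat = np.zeros((8, 8))
        mat[2, 5] = 8.0
        resid = hb.additive_residuals(mat)
        assert resid[2, 5] == pytest.approx(8 * (1 - 1 / 8 - 1 / 8 + 1 / 64))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, derandomize=True, deadline=None)
    def test_centering_and_idempotence(self, seed):
        mat = np.random.default_rng(seed).normal(size=(8, 8))
        resid = hb.additive_residuals(mat)
        assert np.abs(resid.mean(axis=0)).max() < 1e-10
        assert np.abs(resid.mean(axis=1)).max() < 1e-10
        assert np.allclose(hb.additive_residuals(resid), resid)


class TestTwoWayAnova:
    def test_matches_statsmodels(self):
        """Closed-form balanced ANOVA agrees with the OLS route."""
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(1)
        data = rng.poisson(5.0, size=(4, 3, 6)).astype(float)
        res = hb.two_way_anova(data)
        rows = [
            {"y": data[i, j, t], "a": f"a{i}", "b": f"b{j}"}
            for i in range(4) for j in range(3) for t in range(6)
        ]
        lm = ols("y ~ C(a) * C(b)", data=pd.DataFrame(rows)).fit()
        tab = sm.stats.anova_lm(lm, typ=2)
        assert res["p_a"] == pytest.approx(tab.loc["C(a)", "PR(>F)"], rel=1e-8)
        assert res["p_b"] == pytest.approx(tab.loc["C(b)", "PR(>F)"], rel=1e-8)
        assert res["p_ab"] == pytest.approx(tab.loc["C(a):C(b)", "PR(>F)"], rel=1e-8)

    def test_conjunctive_power(self):
        pop = hb.decoding_population(n_units=30, w_conj=1.0, seed=10,
                                     grid=hb.monkey_conditions("P1", "MC"))
        hits = sum(hb.headbody_anova(u).p_interaction < 0.05 for u in pop)
        assert hits >= 27  # >90% of strongly conjunctive units

    def test_missing_cells_rejected(self, tuned_unit):
        partial = hb.UnitRecording("partial")
        conds = hb.monkey_conditions("P1", "MC", angles=(0,))
        for c in conds:
            partial.counts[c] = tuned_unit.counts[c]
        with pytest.raises(ValueError):
            hb.headbody_anova(partial)

    def test_interaction_fraction_monotone_in_w_conj(self):
        """Recovered interaction prevalence grows with the conjunctive weight."""
        grid = hb.monkey_conditions("P1", "MC")
        fractions = []
        for w in (0.0, 0.5, 1.0):
            pop = hb.decoding_population(n_units=40, w_conj=w, seed=11, grid=grid,
                                         gain=30.0)
            fractions.append(
                np.mean([hb.headbody_anova(u).p_interaction < 0.05 for u in pop]))
        assert fractions[0] <= fractions[1] <= fractions[2]


class TestCorrelations:
    def test_centering_correlation_monotone_in_c_tol(self):
        grid = (hb.monkey_conditions("P1", "MC") + hb.monkey_conditions("P1", "HC"))
        medians = []
        for ct in (0.0, 0.5, 1.0):
            sampler = hb.default_param_sampler(w_conj=0.5, c_tol=ct, gain=40,
                                               baseline=10)
            pop = hb.simulate_population(30, sampler, grid, seed=12)
            medians.append(np.nanmedian([hb.centering_correlation(u) for u in pop]))
        assert medians[0] < medians[1] < medians[2]
        assert abs(medians[0]) < 0.25  # independent patterns decorrelate

    def test_residual_correlation_conjunctive_vs_additive(self):
        grid = (hb.monkey_conditions("P1", "MC") + hb.monkey_conditions("P1", "HC"))
        med = {}
        for w in (0.0, 1.0):
            sampler = hb.default_param_sampler(w_conj=w, c_tol=1.0, gain=60,
                                               baseline=10)
            pop = hb.simulate_population(30, sampler, grid, seed=13)
            med[w] = np.nanmedian([hb.residual_correlation(u) for u in pop])
        assert med[1.0] > 0.3       # position-tolerant interaction structure
        assert abs(med[0.0]) < 0.2  # additive units: residuals are noise


class TestReliability:
    def test_spearman_brown_examples(self):
        assert hb.reliability_normalized_correlation(0.5, 1.0, 1.0) == 0.5
        assert hb.reliability_normalized_correlation(0.45, 0.9, 0.9) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            hb.reliability_normalized_correlation(0.5, 0.0, 1.0)

    def test_noiseless_unit_reliability_one(self, monkey_grid_mc):
        unit = hb.UnitRecording("det")
        for k, c in enumerate(monkey_grid_mc):
            unit.counts[c] = np.tile([1, 2, k], (8, 1))
        assert hb.split_half_reliability(unit, monkey_grid_mc) == pytest.approx(1.0)

    def test_pure_noise_reliability_near_zero(self, flat_unit, monkey_grid_mc):
        r = hb.split_half_reliability(flat_unit, monkey_grid_mc, seed=5)
        assert abs(r) < 0.2

    def test_tuned_unit_reliable(self, tuned_unit, monkey_grid_mc):
        assert hb.split_half_reliability(tuned_unit, monkey_grid_mc, seed=5) > 0.7
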