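from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdm import (
    ContextProbabilities,
    GenomeStats,
    initial_state,
    matrix_D,
    matrix_Dprime,
    matrix_Q,
    mutation_budget,
    predict,
    predict_from_summary,
    trend_table,
)
from mdm.composition import DINUCLEOTIDES, DinucleotideProfile, pool_profile
from mdm.core import TREND_DOWN, TREND_UNCHANGED, TREND_UNDETERMINED, TREND_UP


def random_params(draw_floats):
    """Normalize two quadruples of positive reals into valid parameters."""
    a = np.asarray(draw_floats[:4])
    b = np.asarray(draw_floats[4:])
    a = a / a.sum()
    b = b / b.sum()
    return ContextProbabilities(*a.tolist(), *b.tolist())


params_strategy = st.lists(
    st.floats(min_value=0.01, max_value=1.0, allow_nan=False), min_size=8, max_size=8
).map(random_params)


def profile_with_cpg(cpg: float, gc: float = 41.0) -> DinucleotideProfile:
    rest = (100.0 - cpg) / 15.0
    return DinucleotideProfile(
        proportions={d: (cpg if d == "CG" else rest) for d in DINUCLEOTIDES},
        gc_percent=gc,
    )


class TestMatrices:
    def test_d_uniform(self):
        d = matrix_D(ContextProbabilities.uniform())
        assert d["A", "C"] == pytest.approx(-0.25)
        assert d["C", "G"] == pytest.approx(-1.0)
        assert d["T", "G"] == pytest.approx(1.0)
        assert d.total() == pytest.approx(0.0)

    def test_d_human_flank_entry(self, human_params):
        # the (A, T) entry carries the 5'-flank probability of A
        assert matrix_D(human_params)["A", "T"] == pytest.approx(0.2537)

    def test_dprime_uniform(self):
        dp = matrix_Dprime(ContextProbabilities.uniform())
        assert dp["G", "T"] == pytest.approx(-0.25)
        assert dp["C", "A"] == pytest.approx(1.0)
        assert dp.total() == pytest.approx(0.0)

    def test_dprime_human_flank_entry(self, human_params):
        assert matrix_Dprime(human_params)["A", "G"] == pytest.approx(0.2818)

    @settings(max_examples=100, deadline=None)
    @given(params_strategy)
    def test_conservation(self, params):
        assert matrix_D(params).total() == pytest.approx(0.0, abs=1e-12)
        assert matrix_Dprime(params).total() == pytest.approx(0.0, abs=1e-12)
        assert matrix_Q(params, 7.3).total() == pytest.approx(0.0, abs=1e-11)

    @settings(max_examples=100, deadline=None)
    @given(params_strategy)
    def test_q_matches_closed_form_entrywise(self, params):
        """Assembled Q agrees with its closed form, including the
        reconciled (A,C) = P'_C - P_A and (G,T) = P_G - P'_T entries."""
        H = 2.0
        q = matrix_Q(params, H)
        pA, pC, pG, pT = params.p
        ppA, ppC, ppG, ppT = params.pp
        closed = {
            ("A", "A"): ppA, ("A", "C"): ppC - pA, ("A", "G"): ppG, ("A", "T"): ppT + pA,
            ("C", "A"): 1.0, ("C", "C"): -pC, ("C", "G"): -2.0, ("C", "T"): pC,
            ("G", "A"): -ppA, ("G", "C"): -ppC - pG, ("G", "G"): -ppG, ("G", "T"): pG - ppT,
            ("T", "A"): 0.0, ("T", "C"): -pT, ("T", "G"): 1.0, ("T", "T"): pT,
        }
        for key, value in closed.items():
            assert q[key] == pytest.approx(H / 2 * value, abs=1e-12)

    def test_q_scaling_and_zero(self):
        params = ContextProbabilities.uniform()
        assert np.allclose(matrix_Q(params, 0.0).values, 0.0)
        q = matrix_Q(params, 2.0)
        assert q["C", "G"] == pytest.approx(-2.0)
        assert q["C", "A"] == pytest.approx(1.0)
        assert q["T", "G"] == pytest.approx(1.0)


class TestInitialState:
    def test_gc50_uniform(self):
        state = initial_state(50.0)
        assert all(v == pytest.approx(6.25) for v in state.profile.proportions.values())
        assert state.cpg_percent == pytest.approx(6.25)

    def test_gc40_products(self):
        state = initial_state(40.0)
        assert state.profile["CG"] == pytest.approx(4.0)
        assert state.profile["AA"] == pytest.approx(9.0)

    @given(st.floats(min_value=1.0, max_value=99.0))
    def test_proportions_sum_to_100(self, gc):
        state = initial_state(gc)
        assert sum(state.profile.proportions.values()) == pytest.approx(100.0, abs=1e-9)

    @pytest.mark.parametrize("gc", [0.0, 100.0, -3.0])
    def test_out_of_range_rejected(self, gc):
        with pytest.raises(ValueError):
            initial_state(gc)


class TestMutationBudget:
    def test_direct_arithmetic(self):
        h = mutation_budget(
            initial_state(50.0), profile_with_cpg(0.98), GenomeStats(1000, 999)
        )
        assert h == pytest.approx(52.6473)

    def test_zero_deficit(self):
        h = mutation_budget(
            initial_state(50.0), profile_with_cpg(6.25), GenomeStats(1000, 999)
        )
        assert h == pytest.approx(0.0)

    def test_no_cpg_left(self):
        h = mutation_budget(
            initial_state(50.0), profile_with_cpg(0.0), GenomeStats(1001, 1000)
        )
        assert h == pytest.approx(62.5)

    def test_negative_budget_warns(self):
        with pytest.warns(UserWarning, match="negative"):
            h = mutation_budget(
                initial_state(40.0), profile_with_cpg(6.0), GenomeStats(1000, 999)
            )
        assert h < 0


class TestPredict:
    def test_human_reproduces_published_expectations(self, human_params):
        result = predict_from_summary(50.0, 0.98, human_params, gc_obs_percent=40.99)
        pooled = pool_profile(result.expected)
        assert pooled["CpA/TpG"] == pytest.approx(17.77, abs=0.02)
        assert pooled["ApA/TpT"] == pytest.approx(13.67, abs=0.02)
        assert pooled["GpC"] == pytest.approx(4.97, abs=0.02)
        assert pooled["TpA"] == pytest.approx(6.25, abs=1e-9)

    def test_cattle_expected_gc(self):
        from mdm import datasets

        result = predict_from_summary(
            50.0, 1.05, datasets.context_probabilities_for("cattle")
        )
        assert result.gc_exp == pytest.approx(44.80, abs=0.005)

    def test_zero_budget_identity(self, human_params):
        init = initial_state(50.0)
        result = predict(
            init, profile_with_cpg(6.25), human_params, GenomeStats(1000, 999)
        )
        for d in DINUCLEOTIDES:
            assert result.expected[d] == pytest.approx(init.profile[d], abs=1e-12)
        assert set(result.trends.values()) == {TREND_UNCHANGED}

    @settings(max_examples=50, deadline=None)
    @given(params_strategy, st.floats(min_value=0.0, max_value=6.2))
    def test_conservation_and_cpg_self_consistency(self, params, cpg_obs):
        observed = profile_with_cpg(cpg_obs)
        result = predict(
            initial_state(50.0), observed, params, GenomeStats(10_000, 9_999)
        )
        assert sum(result.expected.proportions.values()) == pytest.approx(100.0, abs=1e-9)
        assert result.expected["CG"] == pytest.approx(cpg_obs, abs=1e-9)

    def test_linearity_in_budget(self, human_params):
        init = initial_state(50.0)
        stats = GenomeStats(100_000, 99_999)
        r1 = predict(init, profile_with_cpg(5.25), human_params, stats)
        r2 = predict(init, profile_with_cpg(4.25), human_params, stats)
        for d in DINUCLEOTIDES:
            off1 = r1.expected[d] - init.profile[d]
            off2 = r2.expected[d] - init.profile[d]
            assert off2 == pytest.approx(2.0 * off1, abs=1e-9)


class TestTrendTable:
    def test_without_params_matches_structural_trends(self):
        trends = trend_table()
        assert trends["ApA/TpT"] == TREND_UP
        assert trends["ApC/GpT"] == TREND_UNDETERMINED
        assert trends["ApG/CpT"] == TREND_UP
        assert trends["ApT"] == TREND_UP
        assert trends["CpA/TpG"] == TREND_UP
        assert trends["CpC/GpG"] == TREND_DOWN
        assert trends["CpG"] == TREND_DOWN
        assert trends["GpA/TpC"] == TREND_DOWN
        assert trends["GpC"] == TREND_DOWN
        assert trends["TpA"] == TREND_UNCHANGED

    def test_human_resolves_apc_gpt_down(self, human_params):
        # P'_C - P_A = -0.0117 and P_G - P'_T = -0.0122: both negative
        assert trend_table(human_params)["ApC/GpT"] == TREND_DOWN

    def test_uniform_params_apc_gpt_unchanged(self):
        assert trend_table(ContextProbabilities.uniform())["ApC/GpT"] == TREND_UNCHANGED
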