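import math

import numpy as np
import pytest

from limbcea import (
    CohortTrace,
    MarkovCEA,
    ModelParameters,
    MortalityAdjustment,
    accumulate,
    assign_state_values,
    compare,
    icer,
)
from limbcea.transitions import NO_TREATMENT_STATES, build_no_treatment_matrix
from limbcea.valuation import discount_factor
from limbcea.engine import run_trace
from tests.conftest import constant_table


class TestStateValues:
    def test_surgery_utilities_multiply_pathway_utility(self, params):
        v = assign_state_values(params, "surgery")
        u = dict(zip(v.states, v.utilities))
        assert u["LLL"] == pytest.approx(0.7 * 0.888)     # 0.6216
        assert u["LLComp"] == pytest.approx(0.8 * 0.888)
        assert u["ULL"] == pytest.approx(0.8 * 0.944)
        assert u["ULComp"] == pytest.approx(0.75 * 0.944)
        assert u["NormalLifeLLLOnly"] == 0.888
        assert u["NormalLifeFull"] == 0.944

    def test_baseline_multiplier_variant(self):
        p = ModelParameters(multiplier_base="baseline")
        u = dict(zip(*[assign_state_values(p, "surgery").states,
                       assign_state_values(p, "surgery").utilities]))
        assert u["LLL"] == pytest.approx(0.7 * 0.711)
        assert u["NormalLifeLLLOnly"] == 0.888  # lifelong states unaffected

    def test_unit_multipliers_remove_disutility(self):
        p = ModelParameters(m_lll=1.0, m_ull=1.0, m_llc=1.0, m_ulc=1.0)
        v = assign_state_values(p, "surgery")
        u = dict(zip(v.states, v.utilities))
        assert u["LLL"] == u["NormalLifeLLLOnly"] == 0.888
        assert u["ULL"] == u["NormalLifeFull"] == 0.944

    def test_death_carries_nothing(self, params):
        for strategy in ("no_treatment", "surgery"):
            v = assign_state_values(params, strategy)
            k = v.states.index("Death")
            assert v.utilities[k] == 0.0 and v.costs[k] == 0.0

    def test_costs_attach_to_surgical_states_only(self, params):
        v = assign_state_values(params, "surgery")
        c = dict(zip(v.states, v.costs))
        assert c == {
            "LLL": 28539.0, "LLComp": 6275.0, "ULL": 10834.0, "ULComp": 6275.0,
            "NormalLifeLLLOnly": 0.0, "NormalLifeFull": 0.0, "Death": 0.0,
        }


class TestDiscounting:
    def test_zero_rate_is_unity(self):
        assert np.all(discount_factor(0.0, np.arange(10)) == 1.0)

    def test_three_percent_first_cycle(self):
        assert discount_factor(0.03, 1) == pytest.approx(0.970874, abs=1e-6)

    def test_exponent_law(self):
        r = 0.03
        assert discount_factor(r, 4) * discount_factor(r, 7) == pytest.approx(
            discount_factor(r, 11)
        )


class TestAccumulate:
    def test_single_cycle_identity(self, params):
        tr = run_trace([1.0, 0.0], np.stack([build_no_treatment_matrix(0.3)]),
                       NO_TREATMENT_STATES)
        p = params.update(r_health=0.0, r_cost=0.0)
        q, c = accumulate(tr, assign_state_values(p, "no_treatment"), p)
        assert q == pytest.approx(0.711)
        assert c == 0.0

    def test_geometric_series_closed_form(self):
        # constant dp = 0.2, u = 1, r = 0: QALYs -> 1/dp = 5 as horizon grows
        p = ModelParameters(u_base=1.0, r_health=0.0, r_cost=0.0, n_cycles=500, start_age=0)
        adj = MortalityAdjustment(age_shift=0)
        table = constant_table(0.2, max_age=600)
        from limbcea._run import run_strategy

        tr, q, _ = run_strategy(p, table, adj, "no_treatment")
        assert q == pytest.approx(1 / 0.2, rel=1e-9)

    def test_mismatched_state_sets_rejected(self, params):
        tr = run_trace([1.0, 0.0], np.stack([build_no_treatment_matrix(0.3)]),
                       NO_TREATMENT_STATES)
        with pytest.raises(ValueError, match="states"):
            accumulate(tr, assign_state_values(params, "surgery"), params)

    def test_qalys_bounded_and_decreasing_in_discount_rate(self, life_table, adjustment):
        from limbcea._run import run_strategy

        qs = []
        for r in (0.0, 0.03, 0.06):
            p = ModelParameters(r_health=r)
            _, q, _ = run_strategy(p, life_table, adjustment, "no_treatment")
            qs.append(q)
            assert q <= p.n_cycles + 1
        assert qs[0] > qs[1] > qs[2]

    def test_cost_utility_separability(self, life_table, adjustment):
        # surgery costs are invariant to utilities, QALYs invariant to costs
        from limbcea._run import run_strategy

        base = ModelParameters()
        _, q0, c0 = run_strategy(base, life_table, adjustment, "surgery")
        _, q1, c1 = run_strategy(base.update(u_lll=0.5, m_lll=0.9), life_table, adjustment,
                                 "surgery")
        assert c1 == c0 and q1 != q0
        _, q2, c2 = run_strategy(base.update(c_lll=1.0, c_comp=2.0), life_table, adjustment,
                                 "surgery")
        assert q2 == q0 and c2 != c0

    def test_null_intervention_equivalence(self, life_table):
        # equal utilities, no disutility, no costs, no surgical mortality:
        # both strategies produce identical QALYs and costs
        p = ModelParameters(
            u_lll=0.711, u_full=0.711, m_lll=1.0, m_ull=1.0, m_llc=1.0, m_ulc=1.0,
            c_lll=0.0, c_ull=0.0, c_comp=0.0, surg_dp=0.0,
        )
        res = MarkovCEA(params=p, life_table=life_table).fit()
        assert res.qalys["surgery"] == pytest.approx(res.qalys["no_treatment"], abs=1e-10)
        assert res.costs["surgery"] == res.costs["no_treatment"] == 0.0


class TestCompare:
    def test_published_increment_arithmetic(self):
        assert round(icer(49480.0, 5.954)) == 8310

    def test_identical_strategies_undefined_icer(self):
        res = compare(
            {"no_treatment": 20.0, "surgery": 20.0},
            {"no_treatment": 0.0, "surgery": 0.0},
            wtp=25000,
        )
        assert math.isnan(res.icer)

    def test_nmb_arithmetic(self):
        res = compare(
            {"no_treatment": 20.0, "surgery": 25.0},
            {"no_treatment": 0.0, "surgery": 40000.0},
            wtp=25000,
        )
        assert res.nmb()["no_treatment"] == 500_000.0
        assert res.nmb()["surgery"] == 25000 * 25 - 40000

    def test_dominance_flags(self):
        dominant = compare(
            {"no_treatment": 20.0, "surgery": 25.0},
            {"no_treatment": 10.0, "surgery": 5.0},
            wtp=25000,
        )
        assert dominant.dominance == "intervention"
        dominated = compare(
            {"no_treatment": 20.0, "surgery": 18.0},
            {"no_treatment": 0.0, "surgery": 5.0},
            wtp=25000,
        )
        assert dominated.dominance == "reference"

    def test_nmb_ranking_matches_icer_threshold_rule(self, base_results):
        e = base_results.econ
        assert e.delta_qaly > 0
        below, above = e.icer * 0.5, e.icer * 1.5
        assert e.nmb(below)["surgery"] < e.nmb(below)["no_treatment"]
        assert e.nmb(above)["surgery"] > e.nmb(above)["no_treatment"]

    def test_summary_mentions_icer(self, base_results):
        text = base_results.summary()
        assert "ICER" in text and "Incremental QALYs" in text
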