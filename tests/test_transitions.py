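import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from limbcea import ModelParameters
from limbcea.transitions import (
    NO_TREATMENT_STATES,
    SURGERY_STATES,
    SURGICAL_WINDOW,
    StructuralError,
    TransitionParams,
    build_no_treatment_matrix,
    build_surgery_matrix,
    matrix_sequence,
    validate_matrix,
)
from tests.conftest import constant_table

IDX = {s: i for i, s in enumerate(SURGERY_STATES)}


class TestNoTreatmentMatrix:
    @pytest.mark.parametrize("dp,row", [(0.0, [1, 0]), (1.0, [0, 1]), (0.01, [0.99, 0.01])])
    def test_alive_row(self, dp, row):
        M = build_no_treatment_matrix(dp)
        assert np.allclose(M[0], row)
        assert np.array_equal(M[1], [0.0, 1.0])

    def test_dp_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            build_no_treatment_matrix(1.1)


class TestSurgeryMatrix:
    def test_lll_row_follows_printed_formula(self):
        # arithmetic from the printed row with the base-case probabilities
        tp = TransitionParams(
            p_ll_comp=0.8, p_ul_comp=0.1, p_withdraw=0.1, dp=0.001, surg_dp=0.00013
        )
        M = build_surgery_matrix(tp)
        stay = 1 - 0.8 - 0.001 - 0.00013
        assert M[IDX["LLL"], IDX["LLComp"]] == pytest.approx(0.8)
        assert M[IDX["LLL"], IDX["ULL"]] == pytest.approx(stay * 0.9)
        assert M[IDX["LLL"], IDX["NormalLifeLLLOnly"]] == pytest.approx(stay * 0.1)
        assert M[IDX["LLL"], IDX["Death"]] == pytest.approx(0.00113)
        assert M[IDX["LLL"]].sum() == pytest.approx(1.0, abs=1e-12)

    def test_ull_row(self):
        tp = TransitionParams(p_ll_comp=0.8, p_ul_comp=0.1, p_withdraw=0.1, dp=0.0, surg_dp=0.0)
        M = build_surgery_matrix(tp)
        assert M[IDX["ULL"], IDX["ULComp"]] == pytest.approx(0.1)
        assert M[IDX["ULL"], IDX["NormalLifeFull"]] == pytest.approx(0.9)

    def test_deterministic_pathway_without_complications(self):
        tp = TransitionParams(p_ll_comp=0.0, p_ul_comp=0.0, p_withdraw=0.0, dp=0.0, surg_dp=0.0)
        M = build_surgery_matrix(tp)
        assert M[IDX["LLL"], IDX["ULL"]] == 1.0
        assert M[IDX["ULL"], IDX["NormalLifeFull"]] == 1.0

    def test_normal_life_rows_split_preserves_printed_column(self):
        # the two bookkeeping normal-life states behave identically
        tp = TransitionParams(p_ll_comp=0.3, p_ul_comp=0.1, p_withdraw=0.2, dp=0.05, surg_dp=0.0)
        M = build_surgery_matrix(tp)
        for s in ("NormalLifeLLLOnly", "NormalLifeFull"):
            assert M[IDX[s], IDX[s]] == pytest.approx(0.95)
            assert M[IDX[s], IDX["Death"]] == pytest.approx(0.05)

    def test_infeasible_outflow_names_row(self):
        tp = TransitionParams(p_ll_comp=0.9, p_ul_comp=0.1, p_withdraw=0.1, dp=0.2, surg_dp=0.0)
        with pytest.raises(StructuralError, match="LLL"):
            build_surgery_matrix(tp)

    def test_inactive_surgical_rows_are_still_stochastic(self):
        tp = TransitionParams(p_ll_comp=0.9, p_ul_comp=0.1, p_withdraw=0.1, dp=0.5, surg_dp=0.0)
        M = build_surgery_matrix(tp, surgical_active=False)
        validate_matrix(M)

    @settings(max_examples=50, deadline=None)
    @given(
        p_ll=st.floats(0, 0.95),
        p_ul=st.floats(0, 0.95),
        p_w=st.floats(0, 1),
        dp=st.floats(0, 0.04),
        sd=st.floats(0, 0.01),
    )
    def test_rows_stochastic_for_feasible_inputs(self, p_ll, p_ul, p_w, dp, sd):
        tp = TransitionParams(p_ll_comp=p_ll, p_ul_comp=p_ul, p_withdraw=p_w, dp=dp, surg_dp=sd)
        validate_matrix(build_surgery_matrix(tp))


class TestMatrixSequence:
    def test_sequence_length_matches_horizon(self, params, life_table, adjustment):
        for strategy, n_states in (("no_treatment", 2), ("surgery", 7)):
            seq = matrix_sequence(strategy, params, life_table, adjustment)
            assert seq.shape == (params.n_cycles, n_states, n_states)

    def test_every_cycle_matrix_valid_both_strategies(self, params, life_table, adjustment):
        for strategy in ("no_treatment", "surgery"):
            for M in matrix_sequence(strategy, params, life_table, adjustment):
                validate_matrix(M, tol=1e-12)

    def test_cycle_t_uses_age_shifted_mortality(self, params, life_table, adjustment):
        seq = matrix_sequence("no_treatment", params, life_table, adjustment)
        for t in (0, 10, 40):
            expected_dp = life_table.qx_at(params.start_age + t + adjustment.age_shift)
            assert seq[t, 0, 1] == pytest.approx(expected_dp)

    def test_constant_table_and_zero_shift_gives_identical_matrices(self, params):
        from limbcea import MortalityAdjustment

        table = constant_table(0.02)
        adj = MortalityAdjustment(age_shift=0, surgical_mortality=params.surg_dp)
        seq = matrix_sequence("surgery", params, table, adj)
        # within the surgical window and after it, matrices within each regime coincide
        assert np.array_equal(seq[0], seq[SURGICAL_WINDOW - 1])
        assert np.array_equal(seq[SURGICAL_WINDOW], seq[-1])

    def test_surg_dp_enters_only_surgical_rows(self, params, life_table, adjustment):
        seq = matrix_sequence("surgery", params, life_table, adjustment)
        dp0 = life_table.qx_at(params.start_age + adjustment.age_shift)
        death = IDX["Death"]
        for s in ("LLL", "LLComp", "ULL", "ULComp"):
            assert seq[0, IDX[s], death] == pytest.approx(dp0 + params.surg_dp)
        for s in ("NormalLifeLLLOnly", "NormalLifeFull"):
            assert seq[0, IDX[s], death] == pytest.approx(dp0)

    def test_short_table_error_carries_context(self, params, adjustment):
        short = constant_table(0.01, max_age=60)
        with pytest.raises(ValueError, match="horizon"):
            matrix_sequence("no_treatment", params, short, adjustment)

    def test_unknown_strategy_rejected(self, params, life_table, adjustment):
        with pytest.raises(ValueError, match="strategy"):
            matrix_sequence("watchful_waiting", params, life_table, adjustment)


class TestReachability:
    def _trace(self, params, life_table, adjustment):
        from limbcea._run import initial_occupancy, run_strategy

        return run_strategy(params, life_table, adjustment, "surgery")[0]

    def test_full_withdrawal_blocks_full_lengthening(self, life_table, adjustment):
        p = ModelParameters(p_withdraw=1.0)
        trace = self._trace(p, life_table, adjustment)
        assert np.all(trace.state_column("NormalLifeFull") == 0)

    def test_zero_withdrawal_blocks_lll_only_state(self, life_table, adjustment):
        p = ModelParameters(p_withdraw=0.0)
        trace = self._trace(p, life_table, adjustment)
        assert np.all(trace.state_column("NormalLifeLLLOnly") == 0)

    def test_trace_invariant_to_inactive_row_placeholder(self, params, life_table, adjustment):
        # the placeholder rows outside the surgical window are unreachable:
        # replacing them with any other valid rows leaves the trace unchanged
        from limbcea._run import initial_occupancy
        from limbcea.engine import run_trace

        seq = matrix_sequence("surgery", params, life_table, adjustment)
        alt = seq.copy()
        for t in range(SURGICAL_WINDOW, params.n_cycles):
            for s in ("LLL", "LLComp", "ULL", "ULComp"):
                alt[t, IDX[s]] = 0.0
                alt[t, IDX[s], IDX[s]] = 1.0  # identity instead of death-absorbing
        init = initial_occupancy("surgery")
        t1 = run_trace(init, seq, SURGERY_STATES)
        t2 = run_trace(init, alt, SURGERY_STATES)
        assert np.array_equal(t1.occupancy, t2.occupancy)
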