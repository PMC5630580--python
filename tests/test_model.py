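"""Unit and property tests of the core ecosystem ODE model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oxanox import (
    EcosystemState,
    IntegrationError,
    RedoxModel,
    default_parameters,
    haldane_inhibition,
    monod_growth,
)
from oxanox.model import STATE_VARS

from _oracle import oracle_derivatives
from conftest import random_params, random_states


class TestMonodGrowth:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(g_max=1.0, X=0.0, K_X=5.0), 0.0),
            (dict(g_max=1.0, X=3.0, K_X=3.0, Y=7.0, K_Y=7.0), 0.25),
            (dict(g_max=0.4, X=3.0, K_X=1.0, Y=2.0, K_Y=2.0), 0.15),
        ],
        ids=["zero-substrate", "both-half-saturated", "direct-evaluation"],
    )
    def test_values(self, kwargs, expected):
        assert monod_growth(**kwargs) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(g_max=1.0, X=-1.0, K_X=5.0),
            dict(g_max=1.0, X=1.0, K_X=0.0),
            dict(g_max=0.0, X=1.0, K_X=5.0),
            dict(g_max=1.0, X=1.0, K_X=5.0, Y=-2.0, K_Y=1.0),
            dict(g_max=1.0, X=1.0, K_X=5.0, Y=2.0, K_Y=0.0),
        ],
    )
    def test_domain_errors(self, kwargs):
        with pytest.raises(ValueError):
            monod_growth(**kwargs)

    @given(
        x1=st.floats(0.0, 1e3),
        dx=st.floats(1e-6, 1e3),
        k=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_increasing_and_bounded(self, x1, dx, k):
        lo = monod_growth(1.0, x1, k)
        hi = monod_growth(1.0, x1 + dx, k)
        assert hi > lo
        assert 0.0 <= hi < 1.0


class TestHaldaneInhibition:
    def test_no_inhibitor(self):
        assert haldane_inhibition(0.0, 123.4) == 1.0

    @pytest.mark.parametrize("H", [0.1, 1.0, 300.0])
    def test_half_inhibition_at_H(self, H):
        # the defining property: growth reduced by exactly 50% at X = H
        assert haldane_inhibition(H, H) == pytest.approx(0.5, abs=0.0)

    def test_three_H(self):
        assert haldane_inhibition(3.0 * 7.0, 7.0) == pytest.approx(0.25)

    def test_invalid_H(self):
        with pytest.raises(ValueError):
            haldane_inhibition(1.0, 0.0)

    @given(
        x1=st.floats(0.0, 1e4),
        dx=st.floats(1e-6, 1e4),
        h=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_strictly_decreasing_in_range(self, x1, dx, h):
        a = haldane_inhibition(x1, h)
        b = haldane_inhibition(x1 + dx, h)
        assert b < a
        assert 0.0 < b <= 1.0


class TestDerivatives:
    def test_abiotic_fixed_point(self):
        """With no biology and no oxidation, backgrounds are a fixed point."""
        p = default_parameters(c=0.0)
        model = RedoxModel(p)
        state = EcosystemState(
            N_CB=0, N_PB=0, N_SB=0, S_O=p.S_O_b, S_R=p.S_R_b, O=p.O_b, P=p.P_b
        )
        d = model.derivatives(state)
        for name in STATE_VARS:
            assert getattr(d, name) == pytest.approx(0.0, abs=1e-14)

    def test_no_biology_no_oxygen(self, params):
        """Dead community and O=0: populations frozen, P relaxes diffusively."""
        model = RedoxModel(params)
        state = EcosystemState(N_CB=0, N_PB=0, N_SB=0, S_O=100, S_R=200, O=0, P=2)
        d = model.derivatives(state)
        assert d.N_CB == d.N_PB == d.N_SB == 0.0
        assert d.P == pytest.approx(params.alpha_P * (params.P_b - 2.0), rel=1e-14)

    def test_against_independent_transcription(self, rng):
        """Double-entry check: 1000 random states and parameter sets against
        a second, independently written transcription of the equations."""
        states = random_states(rng, 1000, with_zeros=True)
        for i, x in enumerate(states):
            p = random_params(rng) if i % 5 else default_parameters()
            got = RedoxModel(p).derivatives(x)
            want = np.array(oracle_derivatives(x, p))
            assert np.all(np.abs(got - want) <= 1e-12 * (1.0 + np.abs(want)))

    def test_sulfur_term_cancellation(self, rng):
        """With alpha_S = 0 the sulfur pool is closed: d(S_O + S_R)/dt = 0
        for any state (the biotic exchange and oxidation terms cancel)."""
        states = random_states(rng, 1000)
        p = default_parameters(alpha_S=0.0)
        model = RedoxModel(p)
        for x in states:
            d = model.derivatives(x)
            scale = 1.0 + abs(d[3]) + abs(d[4])
            assert abs(d[3] + d[4]) <= 1e-12 * scale

    def test_rejects_negative_state(self, model):
        with pytest.raises(ValueError):
            model.derivatives(np.array([-1.0, 0, 0, 0, 0, 0, 0]))


class TestIntegration:
    def test_abiotic_fixed_point_preserved(self):
        p = default_parameters(c=0.0)
        model = RedoxModel(p)
        x0 = EcosystemState(
            N_CB=0, N_PB=0, N_SB=0, S_O=p.S_O_b, S_R=p.S_R_b, O=p.O_b, P=p.P_b
        )
        for method in ("rk4", "adaptive"):
            res = model.simulate(x0, t_end=500.0, method=method)
            assert np.allclose(res.final_state.to_array(), x0.to_array(), atol=1e-9)

    def test_total_sulfur_conserved_along_trajectory(self, anoxic_ic):
        """alpha_S = 0 closes the sulfur pool; relative drift < 1e-6 over a
        long trajectory despite large biological turnover."""
        p = default_parameters(alpha_S=0.0)
        model = RedoxModel(p)
        res = model.simulate(anoxic_ic, t_end=10_000.0, method="adaptive")
        total0 = anoxic_ic.S_O + anoxic_ic.S_R
        totals = res.states[:, 3] + res.states[:, 4]
        assert np.max(np.abs(totals - total0)) / total0 < 1e-6

    def test_rk4_and_adaptive_agree(self, oxic_ic):
        model = RedoxModel(default_parameters())
        a = model.simulate(oxic_ic, t_end=2000.0, method="rk4", dt=0.5)
        b = model.simulate(oxic_ic, t_end=2000.0, method="adaptive")
        xa, xb = a.final_state.to_array(), b.final_state.to_array()
        scale = np.abs(xb) + 1e-9 * np.max(np.abs(xb))
        assert np.all(np.abs(xa - xb) / scale < 1e-4)

    def test_non_negativity_maintained(self, anoxic_ic, oxic_ic):
        model = RedoxModel(default_parameters())
        for ic in (anoxic_ic, oxic_ic):
            for method in ("rk4", "adaptive"):
                res = model.simulate(ic, t_end=3000.0, method=method, n_out=300)
                assert np.all(res.states >= 0.0)
        assert np.all(np.diff(res.times) > 0)

    def test_oversized_step_raises(self, oxic_ic):
        model = RedoxModel(default_parameters())
        with pytest.raises(IntegrationError):
            model.simulate(oxic_ic, t_end=10_000.0, method="rk4", dt=2500.0)

    def test_invalid_t_end(self, model, oxic_ic):
        with pytest.raises(ValueError):
            model.simulate(oxic_ic, t_end=0.0)


class TestSteadyState:
    def test_abiotic_fixed_point_converges_immediately(self):
        p = default_parameters(c=0.0)
        model = RedoxModel(p)
        x0 = EcosystemState(
            N_CB=0, N_PB=0, N_SB=0, S_O=p.S_O_b, S_R=p.S_R_b, O=p.O_b, P=p.P_b
        )
        state, converged = model.find_steady_state(x0)
        assert converged
        assert np.allclose(state.to_array(), x0.to_array(), atol=1e-9)

    def test_bistability_of_published_initial_conditions(self, model, anoxic_ic, oxic_ic):
        """The two demonstration initial-condition sets reach distinct
        attractors: one anoxic (cyanobacteria collapsed, sulfur bacteria
        dense, oxygen low) and one oxic (cyanobacteria dominant)."""
        s_anox, c1 = model.find_steady_state(anoxic_ic)
        s_oxic, c2 = model.find_steady_state(oxic_ic)
        assert c1 and c2
        # anoxic outcome
        assert s_anox.N_CB < 1.0
        assert s_anox.N_PB > 1e6 and s_anox.N_SB > 1e6
        assert s_anox.O < 50.0
        # oxic outcome
        assert s_oxic.N_CB > 1e7
        assert s_oxic.N_PB < 1.0 and s_oxic.N_SB < 1.0
        assert s_oxic.O > s_anox.O * 5

    def test_nonconvergence_reported_not_raised(self, model, oxic_ic):
        state, converged = model.find_steady_state(oxic_ic, tol=1e-8, t_max=10.0)
        assert converged is False
        assert isinstance(state, EcosystemState)

    def test_invalid_tolerance(self, model, oxic_ic):
        with pytest.raises(ValueError):
            model.find_steady_state(oxic_ic, tol=0.0)


class TestStateAndResultContainers:
    def test_state_rejects_negative_or_nonfinite(self):
        with pytest.raises(ValueError):
            EcosystemState(N_CB=-1, N_PB=0, N_SB=0, S_O=0, S_R=0, O=0, P=0)
        with pytest.raises(ValueError):
            EcosystemState(N_CB=np.nan, N_PB=0, N_SB=0, S_O=0, S_R=0, O=0, P=0)

    def test_array_round_trip(self, anoxic_ic):
        assert EcosystemState.from_array(anoxic_ic.to_array()) == anoxic_ic

    def test_result_export_columns(self, model, oxic_ic):
        res = model.simulate(oxic_ic, t_end=10.0, n_out=5)
        df = res.to_frame()
        assert list(df.columns) == ["t", *STATE_VARS]
        assert len(df) >= 2
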