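"""Fuel/antifuel state machine and redistribution kinetics."""

import itertools
import math

import numpy as np
import pytest

from guvpart.dynamics import (
    CUES,
    CargoState,
    apply_cue,
    relax_trace,
    simulate_protocol,
    state_equilibrium_f,
)
from guvpart.errors import ValidationError
from guvpart.thermo import dG_to_fraction

S1, S2, S3 = CargoState.STATE1, CargoState.STATE2, CargoState.STATE3


class TestStateMachine:
    def test_listed_transitions(self):
        assert apply_cue(S1, "Fuel1") is S2
        assert apply_cue(S2, "Antifuel2") is S3
        assert apply_cue(S3, "Fuel2") is S2
        assert apply_cue(S2, "Antifuel1") is S1

    def test_unlisted_pair_is_noop_with_warning(self):
        with pytest.warns(UserWarning):
            assert apply_cue(S1, "Antifuel1") is S1

    def test_unknown_cue_rejected(self):
        with pytest.raises(ValidationError):
            apply_cue(S1, "Fuel9")

    def test_full_cycle_visits_2_3_2_1(self):
        state, visited = S1, []
        for cue in ["Fuel1", "Antifuel2", "Fuel2", "Antifuel1"]:
            state = apply_cue(state, cue)
            visited.append(state)
        assert visited == [S2, S3, S2, S1]

    def test_every_state_reachable_within_two_cues(self):
        for a in CargoState:
            reachable = {a}
            frontier = {a}
            for _ in range(2):
                nxt = set()
                for s in frontier:
                    for cue in CUES:
                        t = {k: v for k, v in
                             __import__("guvpart.dynamics", fromlist=["TRANSITIONS"]
                                        ).TRANSITIONS.items()}.get((s, cue))
                        if t is not None:
                            nxt.add(t)
                reachable |= nxt
                frontier = nxt
            assert reachable == set(CargoState)


class TestEquilibria:
    def test_baselines_from_library(self):
        assert state_equilibrium_f(S1) == pytest.approx(dG_to_fraction(1.9))
        assert state_equilibrium_f(S3) == pytest.approx(dG_to_fraction(-0.8))

    def test_state2_additive_vs_measured(self):
        assert state_equilibrium_f(S2, state2_mode="additive") == pytest.approx(
            dG_to_fraction(1.1)
        )  # 1.9 - 0.8 kBT -> f = 0.250
        assert state_equilibrium_f(S2, state2_mode="measured") == pytest.approx(
            dG_to_fraction(1.0), abs=1e-12
        )  # measured coupled construct, ~0.269

    def test_monotone_state_ordering(self):
        for mode in ("additive", "measured"):
            f1 = state_equilibrium_f(S1, state2_mode=mode)
            f2 = state_equilibrium_f(S2, state2_mode=mode)
            f3 = state_equilibrium_f(S3, state2_mode=mode)
            assert f1 < f2 < f3

    def test_hysteresis_zero_means_identical_paths(self):
        assert state_equilibrium_f(S1, reverse=True, hysteresis=0.0) == \
            state_equilibrium_f(S1)

    def test_missing_library_entry(self):
        with pytest.raises(ValidationError):
            state_equilibrium_f(S1, anchor_library={"dC": -0.8})


class TestRelaxation:
    def test_constant_when_at_equilibrium(self):
        tr = relax_trace(0.3, 0.3, tau=5.0, times=np.linspace(0, 30, 7))
        np.testing.assert_allclose(tr.f_values, 0.3)

    def test_within_one_percent_at_five_tau(self):
        tr = relax_trace(0.14, 0.26, tau=5.0, times=[25.0])
        assert abs(tr.f_values[0] - 0.26) < 0.01 * 1.0
        assert abs(tr.f_values[0] - 0.26) / abs(0.14 - 0.26) < 0.01

    def test_exponential_value(self):
        tr = relax_trace(0.14, 0.26, tau=5.0, times=[5.0])
        assert tr.f_values[0] == pytest.approx(0.26 - 0.12 * math.exp(-1), abs=1e-9)
        assert tr.f_values[0] == pytest.approx(0.2159, abs=5e-4)

    def test_monotone_between_endpoints(self):
        tr = relax_trace(0.7, 0.2, tau=3.0, times=np.linspace(0, 40, 100))
        diffs = np.diff(tr.f_values)
        assert np.all(diffs <= 1e-15)
        assert np.all(tr.f_values <= 0.7) and np.all(tr.f_values >= 0.2)

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            relax_trace(0.1, 0.2, tau=0.0, times=[0.0])
        with pytest.raises(ValidationError):
            relax_trace(0.1, 0.2, tau=5.0, times=[1.0, 0.5])


class TestProtocol:
    FWD_REV = [(10.0, "Fuel1"), (60.0, "Antifuel2"), (110.0, "Fuel2"),
               (160.0, "Antifuel1")]

    def test_no_cues_flat_trace(self):
        tr = simulate_protocol([], tau=5.0, t_end=20.0)
        np.testing.assert_allclose(tr.f, state_equilibrium_f(S1))
        assert set(tr.state) == {"STATE1"}

    def test_continuity_at_cue_times(self):
        tr = simulate_protocol(self.FWD_REV, tau=5.0, dt=0.1)
        f = tr.f.to_numpy()
        assert np.abs(np.diff(f)).max() < 0.02  # no jumps on a 0.1 min grid

    def test_forward_reverse_final_state_and_hysteresis(self):
        tr0 = simulate_protocol(self.FWD_REV, tau=5.0, t_end=400.0)
        assert tr0.state.iloc[-1] == "STATE1"
        assert tr0.f.iloc[-1] == pytest.approx(tr0.f.iloc[0], abs=1e-6)
        trh = simulate_protocol(self.FWD_REV, tau=5.0, t_end=400.0, hysteresis=0.04)
        assert trh.f.iloc[-1] > trh.f.iloc[0] + 0.03

    def test_three_plateaus_forward(self):
        cues = [(10.0, "Fuel1"), (60.0, "Antifuel2")]
        tr = simulate_protocol(cues, tau=5.0, t_end=120.0)
        plateau = [
            float(tr.loc[(tr.time_min > lo) & (tr.time_min <= hi), "f"].iloc[-1])
            for lo, hi in [(0, 10), (50, 60), (100, 120)]
        ]
        assert plateau[0] == pytest.approx(state_equilibrium_f(S1), abs=0.005)
        assert plateau[1] == pytest.approx(state_equilibrium_f(S2), abs=0.005)
        assert plateau[2] == pytest.approx(state_equilibrium_f(S3), abs=0.005)

    def test_grid_refinement_agrees_at_shared_points(self):
        coarse = simulate_protocol(self.FWD_REV, tau=5.0, dt=1.0, t_end=200.0)
        fine = simulate_protocol(self.FWD_REV, tau=5.0, dt=0.25, t_end=200.0)
        merged = coarse.merge(fine, on="time_min", suffixes=("_c", "_f"))
        assert len(merged) == len(coarse)
        np.testing.assert_allclose(merged.f_c, merged.f_f, atol=1e-12)

    def test_transition_substantially_complete_in_minutes(self):
        # with tau = 5 min, the State1 -> State2 shift is ~95% done 15 min
        # after fuel addition and >99% done by 25 min
        tr = simulate_protocol([(0.0, "Fuel1")], tau=5.0, t_end=30.0)
        f1, f2 = state_equilibrium_f(S1), state_equilibrium_f(S2)
        at = lambda t: float(tr.loc[tr.time_min == t, "f"].iloc[0])  # noqa: E731
        assert abs(at(15.0) - f2) / abs(f1 - f2) < 0.05
        assert abs(at(25.0) - f2) / abs(f1 - f2) < 0.01

    def test_non_increasing_cue_times_rejected(self):
        with pytest.raises(ValidationError):
            simulate_protocol([(5.0, "Fuel1"), (5.0, "Antifuel2")], tau=5.0)
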