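"""Fuel/antifuel-driven cargo redistribution between lipid phases.

A fluorescent cargo module can hybridise to a tocopherol-anchored (sT)
module, to a double-cholesterol (dC) module, or bridge both, giving three
anchoring states with increasing Lo preference:

    State 1  cargo on sT          (Ld-localised)
    State 2  cargo bridging sT+dC (intermediate)
    State 3  cargo on dC          (Lo-localised)

Toehold-mediated strand displacement moves the system between states: the
molecular cues act as labelled transitions — Fuel1: 1→2, Antifuel2: 2→3,
Fuel2: 3→2, Antifuel1: 2→1; any other (state, cue) pair is a no-op.  Each
state's equilibrium fractional Lo intensity comes from the anchor library:
States 1 and 3 use the single-module baselines, State 2 either the additive
sT+dC sum or the measured coupled value.  After a cue the per-vesicle f
relaxes exponentially toward the new equilibrium with time constant tau
(default 5 min, limited by fuel diffusion through the sample); an optional
hysteresis offset raises reverse-path equilibria to represent incomplete
reversibility.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .thermo import DEFAULT_ANCHOR_LIBRARY, dG_to_fraction, predict_additive

__all__ = [
    "CargoState",
    "Cue",
    "TRANSITIONS",
    "apply_cue",
    "state_equilibrium_f",
    "RelaxationTrace",
    "relax_trace",
    "simulate_protocol",
]


class CargoState(enum.Enum):
    STATE1 = 1  # cargo on the sT module
    STATE2 = 2  # cargo bridging sT and dC
    STATE3 = 3  # cargo on the dC module


Cue = Literal["Fuel1", "Antifuel1", "Fuel2", "Antifuel2"]
CUES: tuple[str, ...] = ("Fuel1", "Antifuel1", "Fuel2", "Antifuel2")

#: Cues that traverse the reverse path (toward State 1); their target
#: equilibria receive the hysteresis offset.
REVERSE_CUES = frozenset({"Fuel2", "Antifuel1"})

TRANSITIONS: dict[tuple[CargoState, str], CargoState] = {
    (CargoState.STATE1, "Fuel1"): CargoState.STATE2,
    (CargoState.STATE2, "Antifuel2"): CargoState.STATE3,
    (CargoState.STATE3, "Fuel2"): CargoState.STATE2,
    (CargoState.STATE2, "Antifuel1"): CargoState.STATE1,
}


def apply_cue(state: CargoState, cue: str) -> CargoState:
    """Advance the state machine by one molecular cue.

    Unlisted (state, cue) pairs leave the state unchanged with a warning;
    an unknown cue is a validation error.
    """
    if cue not in CUES:
        raise ValidationError(f"unknown cue {cue!r}; expected one of {CUES}")
    nxt = TRANSITIONS.get((state, cue))
    if nxt is None:
        warnings.warn(f"cue {cue} has no effect in {state.name}", stacklevel=2)
        return state
    return nxt


def state_equilibrium_f(
    state: CargoState,
    anchor_library: Mapping[str, float] | None = None,
    state2_mode: Literal["additive", "measured"] = "additive",
    hysteresis: float = 0.0,
    reverse: bool = False,
) -> float:
    """Equilibrium fractional Lo intensity of a cargo state.

    State 1 uses the sT-only baseline, State 3 the dC-only baseline, and
    State 2 either the additive sT+dC free-energy sum or the measured
    coupled-construct entry (``"sT+dC"`` in the library).  With
    ``reverse=True`` the ``hysteresis`` offset is added (equilibria
    revisited on the way back sit slightly higher).
    """
    lib = DEFAULT_ANCHOR_LIBRARY if anchor_library is None else anchor_library
    for tag in ("sT", "dC"):
        if tag not in lib:
            raise ValidationError(f"anchor library is missing {tag!r}")
    if state is CargoState.STATE1:
        dg = lib["sT"]
    elif state is CargoState.STATE3:
        dg = lib["dC"]
    elif state is CargoState.STATE2:
        if state2_mode == "additive":
            dg = predict_additive([lib["sT"], lib["dC"]])
        elif state2_mode == "measured":
            if "sT+dC" not in lib:
                raise ValidationError("anchor library is missing 'sT+dC'")
            dg = lib["sT+dC"]
        else:
            raise ValidationError(f"unknown state2_mode {state2_mode!r}")
    else:  # pragma: no cover - enum is exhaustive
        raise ValidationError(f"unknown state {state!r}")
    f = dG_to_fraction(dg)
    if reverse:
        f = min(max(f + hysteresis, 0.0), 1.0)
    return f


@dataclass(frozen=True)
class RelaxationTrace:
    """A sampled exponential approach of f toward its equilibrium."""

    times: np.ndarray  # minutes
    f_values: np.ndarray
    tau: float  # minutes

    def __post_init__(self) -> None:
        if np.any(self.f_values < 0) or np.any(self.f_values > 1):
            raise ValidationError("f values must lie in [0, 1]")


def relax_trace(
    f0: float, f_eq: float, tau: float, times: Sequence[float] | np.ndarray
) -> RelaxationTrace:
    """Single-exponential relaxation ``f(t) = f_eq + (f0 - f_eq) exp(-t/tau)``.

    ``times`` must be non-decreasing; ``tau`` (minutes) must be positive.
    The trace is monotone between ``f0`` and ``f_eq`` and within 1% of
    equilibrium by ``t = 5 tau``.
    """
    if tau <= 0:
        raise ValidationError(f"tau must be > 0, got {tau}")
    t = np.asarray(times, dtype=float)
    if np.any(np.diff(t) < 0):
        raise ValidationError("times must be non-decreasing")
    f = f_eq + (f0 - f_eq) * np.exp(-t / tau)
    return RelaxationTrace(times=t, f_values=f, tau=tau)


def simulate_protocol(
    cues: Sequence[tuple[float, str]],
    anchor_library: Mapping[str, float] | None = None,
    tau: float = 5.0,
    t_end: float | None = None,
    dt: float = 0.25,
    times: Sequence[float] | None = None,
    initial_state: CargoState = CargoState.STATE1,
    state2_mode: Literal["additive", "measured"] = "additive",
    hysteresis: float = 0.0,
) -> pd.DataFrame:
    """Simulate a fuel/antifuel protocol as a piecewise relaxation trace.

    ``cues`` is a list of (time_min, cue) with strictly increasing times.
    The state switches instantaneously at each cue time; f is continuous,
    relaxing from its current value toward the new state's equilibrium.
    Returns a DataFrame (time_min, state, f); the sampled f at any time
    point is a pure function of t, so grid refinement never changes values
    at shared time points.
    """
    cue_times = [t for t, _ in cues]
    if any(b <= a for a, b in zip(cue_times, cue_times[1:])):
        raise ValidationError("cue times must be strictly increasing")
    if any(t < 0 for t in cue_times):
        raise ValidationError("cue times must be non-negative")

    if times is None:
        if t_end is None:
            t_end = (cue_times[-1] if cue_times else 0.0) + 6.0 * tau
        grid = np.arange(0.0, t_end + dt / 2, dt)
        grid = np.unique(np.concatenate([grid, np.asarray(cue_times, dtype=float)]))
    else:
        grid = np.unique(np.asarray(times, dtype=float))

    state = initial_state
    f_start = state_equilibrium_f(state, anchor_library, state2_mode)
    seg_t0 = 0.0
    f_eq = f_start

    rows = []
    cue_iter = list(cues) + [(float("inf"), "")]
    ci = 0
    for t in grid:
        while t >= cue_iter[ci][0] and ci < len(cues):
            ct, cue = cue_iter[ci]
            # f is continuous across the cue: carry the relaxed value forward
            f_at_cue = f_eq + (f_start - f_eq) * np.exp(-(ct - seg_t0) / tau)
            new_state = apply_cue(state, cue)
            state = new_state
            f_start, seg_t0 = float(f_at_cue), ct
            f_eq = state_equilibrium_f(
                state, anchor_library, state2_mode,
                hysteresis=hysteresis, reverse=cue in REVERSE_CUES,
            )
            ci += 1
        f = f_eq + (f_start - f_eq) * np.exp(-(t - seg_t0) / tau)
        rows.append({"time_min": float(t), "state": state.name, "f": float(f)})
    return pd.DataFrame(rows)
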