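"""Dosing protocols and the event-driven simulation engine.

Dose administrations are instantaneous bolus events: the subcutaneous
depot (route ``"sc"``) or the central compartment (route ``"iv"``) jumps
by ``dose_per_admin`` while every other state is continuous.  The system
is integrated piecewise between events with a stiff-capable adaptive
solver; threshold crossings of the discontinuous right-hand side are
resolved by a bounded maximum internal step rather than event
root-finding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .dynamics import STATE_VARS, make_rhs
from .exceptions import (IntegrationError, InvalidProtocolError,
                         InvalidSettingsError)
from .params import INITIAL_DEFAULTS, ModelParams, PKParams

ROUTES = ("sc", "iv")


@dataclass(frozen=True)
class DoseProtocol:
    """Evenly spaced bolus dosing: ``n_doses`` doses of ``dose_per_admin``
    every ``spacing_days`` days starting at ``start_day``."""

    dose_per_admin: float
    n_doses: int
    spacing_days: float
    start_day: float = 0.0
    route: str = "sc"

    def __post_init__(self):
        if self.dose_per_admin < 0:
            raise InvalidProtocolError("dose_per_admin must be nonnegative")
        if int(self.n_doses) != self.n_doses or self.n_doses < 1:
            raise InvalidProtocolError("n_doses must be a positive integer")
        if self.n_doses > 1 and not self.spacing_days > 0:
            raise InvalidProtocolError("spacing_days must be positive for multi-dose protocols")
        if self.start_day < 0:
            raise InvalidProtocolError("start_day must be nonnegative")
        if self.route not in ROUTES:
            raise InvalidProtocolError(f"route must be one of {ROUTES}")

    @property
    def dose_times(self) -> np.ndarray:
        return self.start_day + self.spacing_days * np.arange(self.n_doses)

    @property
    def last_dose_day(self) -> float:
        return float(self.dose_times[-1])

    @property
    def total_dose(self) -> float:
        return self.dose_per_admin * self.n_doses


def make_protocol(total_dose: float, n_doses: int, spacing_days: float,
                  start_day: float = 0.0, route: str = "sc") -> DoseProtocol:
    """Fractionate a fixed cumulative dose into evenly spaced administrations."""
    if not total_dose > 0:
        raise InvalidProtocolError("total_dose must be positive")
    if int(n_doses) != n_doses or n_doses < 1:
        raise InvalidProtocolError("n_doses must be a positive integer")
    return DoseProtocol(dose_per_admin=total_dose / n_doses, n_doses=int(n_doses),
                        spacing_days=spacing_days, start_day=start_day, route=route)


@dataclass(frozen=True)
class SimulationSettings:
    """Horizon, elimination cutoff and solver controls.

    ``t_end=None`` resolves per protocol to
    ``max(last_dose_day + follow_up_days, min_horizon)``.  The
    elimination cutoff defaults to 1, two orders of magnitude below the
    baseline initial tumor volume.
    """

    t_end: float | None = None
    follow_up_days: float = 200.0
    min_horizon: float = 400.0
    elimination_eps: float = 1.0
    rtol: float = 1e-8
    atol: float = 1e-10
    max_step: float = 0.1
    output_resolution: float = 0.05

    def __post_init__(self):
        if not self.elimination_eps > 0:
            raise InvalidSettingsError("elimination_eps must be positive")
        if not (self.output_resolution > 0 and self.max_step > 0):
            raise InvalidSettingsError("solver step controls must be positive")

    def resolve_t_end(self, protocol: DoseProtocol) -> float:
        required = protocol.last_dose_day + self.follow_up_days
        if self.t_end is None:
            return max(required, self.min_horizon)
        if self.t_end < required:
            raise InvalidSettingsError(
                f"t_end={self.t_end} is shorter than last dose + follow-up ({required})")
        return self.t_end

    def replace(self, **changes) -> "SimulationSettings":
        import dataclasses
        return dataclasses.replace(self, **changes)


@dataclass
class Trajectory:
    """Simulation output: time grid, state matrix and dose-event times."""

    times: np.ndarray
    states: np.ndarray  # shape (len(times), 8), columns per STATE_VARS
    dose_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.states = np.asarray(self.states, float)
        if self.states.shape != (self.times.size, len(STATE_VARS)):
            raise ValueError("states must have shape (len(times), 8)")

    def series(self, name: str) -> np.ndarray:
        return self.states[:, STATE_VARS.index(name)]

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    @property
    def final_tumor(self) -> float:
        return float(self.states[-1, 0])

    @property
    def t_end(self) -> float:
        return float(self.times[-1])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.states, columns=list(STATE_VARS))
        frame.insert(0, "time", self.times)
        return frame


def _segment_grid(t0: float, t1: float, resolution: float) -> np.ndarray:
    n = max(int(np.ceil((t1 - t0) / resolution)), 1)
    return np.linspace(t0, t1, n + 1)


def simulate(params: ModelParams, pk: PKParams, protocol: DoseProtocol,
             settings: SimulationSettings | None = None,
             x0: float = INITIAL_DEFAULTS["x0"],
             y1_0: float = INITIAL_DEFAULTS["y1_0"],
             initial_state=None) -> Trajectory:
    """Integrate the 8-state system over ``[0, t_end]`` with dose events.

    The initial state is ``(x0, y1_0, 0, 0, 0, 0, 0, 0)`` unless a full
    8-vector ``initial_state`` is supplied.  Returns a :class:`Trajectory`
    sampled at ``settings.output_resolution``.
    """
    settings = settings or SimulationSettings()
    t_end = settings.resolve_t_end(protocol)
    rhs = make_rhs(params, pk)

    if initial_state is not None:
        state = np.asarray(initial_state, float).copy()
        if state.shape != (8,):
            raise ValueError("initial_state must be an 8-vector")
    else:
        state = np.zeros(8)
        state[0], state[1] = x0, y1_0

    dose_times = protocol.dose_times
    dose_times = dose_times[dose_times <= t_end]
    boundaries = np.unique(np.concatenate([[0.0], dose_times, [t_end]]))
    dose_idx = 5 if protocol.route == "sc" else 6

    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    for t0, t1 in zip(boundaries[:-1], boundaries[1:]):
        if np.any(np.isclose(dose_times, t0)):
            state[dose_idx] += protocol.dose_per_admin
        grid = _segment_grid(t0, t1, settings.output_resolution)
        sol = solve_ivp(rhs, (t0, t1), state, method="LSODA",
                        t_eval=grid, max_step=settings.max_step,
                        rtol=settings.rtol, atol=settings.atol)
        if not sol.success:
            raise IntegrationError(
                f"solver failed on [{t0}, {t1}]: {sol.message}", t_span=(t0, t1))
        times_out.append(sol.t)
        states_out.append(sol.y.T)
        state = sol.y[:, -1].copy()

    times = np.concatenate(times_out)
    states = np.concatenate(states_out, axis=0)
    # keep duplicated time points at dose events (they encode the jump in
    # D_SC); drop only rows identical to their predecessor in time AND state
    same_t = np.diff(times) == 0
    same_s = np.all(states[1:] == states[:-1], axis=1)
    keep = np.concatenate([[True], ~(same_t & same_s)])
    return Trajectory(times=times[keep], states=states[keep], dose_times=dose_times)


def classify_elimination(traj: Trajectory, settings: SimulationSettings,
                         protocol: DoseProtocol | None = None) -> bool:
    """True iff the terminal tumor volume lies below the elimination cutoff.

    If the protocol is supplied, the trajectory must extend at least
    ``follow_up_days`` past the last dose, otherwise the verdict would be
    read mid-treatment and :class:`InvalidSettingsError` is raised.
    """
    if protocol is not None:
        required = protocol.last_dose_day + settings.follow_up_days
        if traj.t_end + 1e-9 < required:
            raise InvalidSettingsError(
                f"trajectory ends at {traj.t_end}, before required follow-up {required}")
    return traj.final_tumor < settings.elimination_eps
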