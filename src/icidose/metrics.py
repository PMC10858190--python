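"""PK summary metrics and the inflammation-burden statistic.

``pk_metrics`` evaluates the three standard exposure metrics — AUC over
one dosing interval at (approximate) steady state, the trough
concentration and the interval-average concentration — on the final
complete dosing interval.  ``area_above_threshold`` integrates the
excess of the inflammation signal over a threshold, the quantity whose
time-integral above the terminal-exhaustion threshold F2 serves as the
efficacy correlate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import DoseProtocol, Trajectory


@dataclass(frozen=True)
class PKMetrics:
    auc_0_tau: float
    c_min: float
    c_avg: float
    interval: tuple[float, float]
    single_dose_warning: bool = False


def _window(traj: Trajectory, lo: float, hi: float):
    mask = (traj.times >= lo - 1e-9) & (traj.times <= hi + 1e-9)
    return traj.times[mask], traj.series("D_p")[mask]


def pk_metrics(traj: Trajectory, protocol: DoseProtocol,
               concentration_scale: float = 1.0) -> PKMetrics:
    """Exposure metrics on the last complete dosing interval.

    The interval ``[t_last - tau, t_last]`` between the final two doses
    is taken as the steady-state interval.  For a single-dose protocol
    the dosing interval is undefined; metrics are then computed over the
    whole trajectory and flagged.

    ``concentration_scale`` converts the simulated central amount to a
    reporting concentration unit (e.g. ``1000/V1`` for ug/mL from a
    mg/kg dose over V1 mL/kg); the default reports the simulated units
    unchanged.
    """
    if protocol.n_doses >= 2:
        hi = protocol.last_dose_day
        lo = hi - protocol.spacing_days
        warn = False
    else:
        lo, hi = 0.0, traj.t_end
        warn = True
    t, dp = _window(traj, lo, hi)
    if t.size < 2:
        raise ValueError("trajectory does not cover the metric interval")
    dp = dp * concentration_scale
    auc = float(np.trapezoid(dp, t))
    tau = hi - lo
    return PKMetrics(auc_0_tau=auc, c_min=float(dp.min()), c_avg=auc / tau,
                     interval=(lo, hi), single_dose_warning=warn)


def area_above_threshold(traj: Trajectory, threshold: float) -> float:
    """Time-integral of ``max(F(t) - threshold, 0)`` over the trajectory."""
    excess = np.maximum(traj.series("F") - threshold, 0.0)
    return float(np.trapezoid(excess, traj.times))
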