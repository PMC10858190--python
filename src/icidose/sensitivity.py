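"""Flip-point sensitivity analysis.

For one disease-model parameter and one dosing protocol, the flip
fraction is the smallest relative perturbation f in (0, 1] — applied as
``param*(1+f)`` or ``param*(1-f)`` — that reverses the elimination
verdict.  The search walks a coarse fraction ladder to bracket the first
flip in each direction, then bisects to the requested resolution.  If
neither a 100% increase nor decrease flips the verdict the result is
censored at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .params import ModelParams, PKParams
from .simulate import (DoseProtocol, SimulationSettings, classify_elimination,
                       simulate)

log = logging.getLogger(__name__)

#: The 18 disease-model (non-PK) parameters subject to sensitivity analysis.
NON_PK_PARAMS = ("lambda_", "K", "b", "c", "xi1", "xi3", "b1", "c1", "d1",
                 "g1", "F1", "F2", "kd", "g2", "g3", "d3", "b2", "d4")


@dataclass(frozen=True)
class SensitivityResult:
    parameter: str
    n_doses: int
    spacing_days: float
    flip_fraction: float     # in (0, 1]; 1 when censored
    direction: str           # "up", "down" or "none" (censored)
    censored: bool
    non_monotone: bool = False


def _verdict(params: ModelParams, pk, protocol, settings) -> bool:
    traj = simulate(params, pk, protocol, settings)
    return classify_elimination(traj, settings, protocol)


def _perturbed(params: ModelParams, name: str, factor: float) -> ModelParams | None:
    value = getattr(params, name) * factor
    if value <= 0:
        return None
    try:
        return params.replace(**{name: value})
    except Exception:
        # perturbation violates a structural constraint (e.g. F2 <= F1):
        # treat like a nonpositive value and skip this fraction
        return None


def _search_direction(name, sign, baseline, params, pk, protocol, settings,
                      ladder_step, resolution, full_ladder):
    """Smallest flipping fraction in one direction, or (None, False).

    Walks f = ladder_step, 2*ladder_step, ... up to 1.  With
    ``full_ladder`` the whole ladder is evaluated and the minimal
    flipping rung is used even if the response is non-monotone (flagged);
    otherwise the walk stops at the first flip (single-flip assumption).
    """
    flips = []
    previous_ok = 0.0
    n_steps = int(round(1.0 / ladder_step))
    first_flip_at = None
    for k in range(1, n_steps + 1):
        f = k * ladder_step
        candidate = _perturbed(params, name, 1.0 + sign * f)
        if candidate is None:
            continue
        flipped = _verdict(candidate, pk, protocol, settings) != baseline
        if flipped:
            flips.append(f)
            if first_flip_at is None:
                first_flip_at = (previous_ok, f)
                if not full_ladder:
                    break
        else:
            previous_ok = f
    if not flips:
        return None, False
    non_monotone = full_ladder and flips[-1] - flips[0] > ladder_step * (len(flips) - 1) + 1e-12
    lo, hi = first_flip_at if not non_monotone else (flips[0] - ladder_step, flips[0])
    # bisect the bracket [lo, hi] down to the resolution
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        candidate = _perturbed(params, name, 1.0 + sign * mid)
        if candidate is None or _verdict(candidate, pk, protocol, settings) == baseline:
            lo = mid
        else:
            hi = mid
    return hi, non_monotone


def flip_fraction(param_name: str, protocol: DoseProtocol, params: ModelParams,
                  pk: PKParams, settings: SimulationSettings | None = None,
                  resolution: float = 0.01, ladder_step: float = 0.05,
                  baseline: bool | None = None,
                  full_ladder: bool = False) -> SensitivityResult:
    """Minimal fractional perturbation of one parameter that flips the verdict.

    ``baseline`` may be supplied to avoid re-simulating the unperturbed
    protocol when scanning many parameters over one cell.
    """
    if param_name not in NON_PK_PARAMS:
        raise ValueError(f"unknown sensitivity parameter {param_name!r}; "
                         f"expected one of {NON_PK_PARAMS}")
    settings = settings or SimulationSettings()
    if baseline is None:
        baseline = _verdict(params, pk, protocol, settings)

    best, best_dir, non_mono = None, "none", False
    for sign, direction in ((1.0, "up"), (-1.0, "down")):
        f, nm = _search_direction(param_name, sign, baseline, params, pk, protocol,
                                  settings, ladder_step, resolution, full_ladder)
        non_mono = non_mono or nm
        if f is not None and (best is None or f < best):
            best, best_dir = f, direction
    censored = best is None
    result = SensitivityResult(parameter=param_name, n_doses=protocol.n_doses,
                               spacing_days=protocol.spacing_days,
                               flip_fraction=1.0 if censored else best,
                               direction=best_dir, censored=censored,
                               non_monotone=non_mono)
    log.info("flip %s n=%s tau=%s -> %.3f (%s%s)", param_name, protocol.n_doses,
             protocol.spacing_days, result.flip_fraction, result.direction,
             ", censored" if censored else "")
    return result


def sensitivity_heatmaps(protocols, params: ModelParams, pk: PKParams,
                         settings: SimulationSettings | None = None,
                         parameters=NON_PK_PARAMS, resolution: float = 0.01,
                         ladder_step: float = 0.05) -> pd.DataFrame:
    """Flip fractions for every (parameter, protocol) combination.

    Returns a long-format frame with one row per combination; pivot on
    (spacing_days x n_doses) per parameter for heatmap display.  The
    unperturbed verdict is computed once per protocol and shared across
    parameters.
    """
    settings = settings or SimulationSettings()
    protocols = list(protocols)
    rows = []
    for proto in protocols:
        base = _verdict(params, pk, proto, settings)
        for name in parameters:
            res = flip_fraction(name, proto, params, pk, settings,
                                resolution=resolution, ladder_step=ladder_step,
                                baseline=base)
            rows.append(dict(parameter=res.parameter, n_doses=res.n_doses,
                             spacing_days=res.spacing_days,
                             flip_fraction=res.flip_fraction,
                             direction=res.direction, censored=res.censored,
                             non_monotone=res.non_monotone,
                             baseline_eliminated=base))
    return pd.DataFrame(rows)
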