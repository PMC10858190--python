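"""Protocol-space exploration: outcome and metric grids over fractionation
strategies.

Every cell of a sweep shares one simulation horizon (the maximum the grid
requires) so that inflammation-burden areas are comparable across cells.
Per-cell integration failures are recorded in the grid rather than
aborting the sweep.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import IntegrationError
from .metrics import area_above_threshold, pk_metrics
from .params import ModelParams, PKParams
from .simulate import (DoseProtocol, SimulationSettings, classify_elimination,
                       make_protocol, simulate)

log = logging.getLogger(__name__)

#: Default fractionation grid: 2..12 doses, 1..10 day spacings.
DEFAULT_N_DOSES = range(2, 13)
DEFAULT_SPACINGS = range(1, 11)

_COLUMNS = ["total_dose", "n_doses", "spacing_days", "dose_per_admin",
            "eliminated", "final_tumor", "auc_0_tau", "c_min", "c_avg",
            "area_above_F2", "error"]


@dataclass
class SweepGrid:
    """Long-format sweep results with pivot helpers."""

    frame: pd.DataFrame
    t_end: float

    @property
    def ok(self) -> pd.DataFrame:
        """Rows whose simulation completed."""
        return self.frame[self.frame["error"].isna()]

    def pivot(self, value: str) -> pd.DataFrame:
        """2-D table of ``value`` with spacing as rows, dose count as columns."""
        return self.frame.pivot(index="spacing_days", columns="n_doses", values=value)

    def metric_overlap(self, metric: str) -> bool:
        """True when the metric's ranges over eliminated and non-eliminated
        cells overlap in both directions (no single threshold separates
        the outcomes)."""
        ok = self.ok
        won = ok.loc[ok["eliminated"] == True, metric]   # noqa: E712
        lost = ok.loc[ok["eliminated"] == False, metric]  # noqa: E712
        if won.empty or lost.empty:
            return False
        return bool(lost.min() < won.max() and won.min() < lost.max())

    def area_separation(self) -> tuple[float, float]:
        """(max area over eliminated cells, min area over non-eliminated).

        Degenerate outcome classes yield ``nan`` on the empty side.
        """
        ok = self.ok
        won = ok.loc[ok["eliminated"] == True, "area_above_F2"]   # noqa: E712
        lost = ok.loc[ok["eliminated"] == False, "area_above_F2"]  # noqa: E712
        return (float(won.max()) if not won.empty else math.nan,
                float(lost.min()) if not lost.empty else math.nan)


def _shared_t_end(protocols, settings: SimulationSettings) -> float:
    return max(settings.resolve_t_end(p) for p in protocols)


def _run_cells(cells, params, pk, settings) -> SweepGrid:
    """cells: iterable of (protocol, row_prefix dict)."""
    cells = list(cells)
    t_end = _shared_t_end([proto for proto, _ in cells], settings)
    shared = settings.replace(t_end=t_end)
    rows = []
    for proto, prefix in cells:
        row = dict(prefix, total_dose=proto.total_dose, n_doses=proto.n_doses,
                   spacing_days=proto.spacing_days, dose_per_admin=proto.dose_per_admin,
                   eliminated=None, final_tumor=np.nan, auc_0_tau=np.nan,
                   c_min=np.nan, c_avg=np.nan, area_above_F2=np.nan, error=None)
        try:
            traj = simulate(params, pk, proto, shared)
            row["eliminated"] = classify_elimination(traj, shared, proto)
            row["final_tumor"] = traj.final_tumor
            if proto.dose_per_admin > 0:
                met = pk_metrics(traj, proto)
                row.update(auc_0_tau=met.auc_0_tau, c_min=met.c_min, c_avg=met.c_avg)
            else:
                row.update(auc_0_tau=0.0, c_min=0.0, c_avg=0.0)
            row["area_above_F2"] = area_above_threshold(traj, params.F2)
        except IntegrationError as err:
            row["error"] = str(err)
            log.warning("cell (n=%s, tau=%s) failed: %s",
                        proto.n_doses, proto.spacing_days, err)
        log.info("cell n=%s tau=%s eliminated=%s", proto.n_doses,
                 proto.spacing_days, row["eliminated"])
        rows.append(row)
    frame = pd.DataFrame(rows)[_COLUMNS].astype({"error": object})
    return SweepGrid(frame=frame, t_end=t_end)


def fractionation_sweep(total_dose: float, params: ModelParams, pk: PKParams,
                        settings: SimulationSettings | None = None,
                        n_doses_range=DEFAULT_N_DOSES,
                        spacing_range=DEFAULT_SPACINGS) -> SweepGrid:
    """Fix the cumulative dose; sweep dose count x spacing.

    Each cell simulates ``make_protocol(total_dose, n, tau)``, classifies
    elimination and computes the PK metrics and the inflammation burden
    above F2.
    """
    settings = settings or SimulationSettings()
    cells = [(make_protocol(total_dose, n, tau), {})
             for n in n_doses_range for tau in spacing_range]
    if not cells:
        raise ValueError("empty sweep ranges")
    return _run_cells(cells, params, pk, settings)


def variable_dose_sweep(mode: str, fixed_value: float, params: ModelParams,
                        pk: PKParams, settings: SimulationSettings | None = None,
                        n_doses_range=DEFAULT_N_DOSES,
                        spacing_range=DEFAULT_SPACINGS,
                        dose_range=(1, 2, 3, 4, 5, 6, 8, 10)) -> SweepGrid:
    """Sweeps with a free cumulative dose.

    ``mode="fixed_n"``: ``fixed_value`` is the dose count; the grid spans
    per-administration dose x spacing.  ``mode="fixed_dose"``:
    ``fixed_value`` is the per-administration dose; the grid spans dose
    count x spacing.
    """
    settings = settings or SimulationSettings()
    if mode == "fixed_n":
        n = int(fixed_value)
        cells = [(DoseProtocol(dose_per_admin=d, n_doses=n, spacing_days=tau), {})
                 for d in dose_range for tau in spacing_range]
    elif mode == "fixed_dose":
        cells = [(DoseProtocol(dose_per_admin=float(fixed_value), n_doses=int(n),
                               spacing_days=tau), {})
                 for n in n_doses_range for tau in spacing_range]
    else:
        raise ValueError("mode must be 'fixed_n' or 'fixed_dose'")
    if not cells:
        raise ValueError("empty sweep ranges")
    return _run_cells(cells, params, pk, settings)


def half_life_variant(pk: PKParams, target_half_life_days: float) -> PKParams:
    """Rescale the central clearance so ln2*V1/Cl1 equals the target.

    One defensible reading of "drug half-life" for a two-compartment
    model; absorption and distribution terms are left unchanged.
    """
    if not target_half_life_days > 0:
        raise ValueError("target half-life must be positive")
    return pk.replace(Cl1=math.log(2.0) * pk.V1 / target_half_life_days)
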