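"""Virtual-population analysis over a heterogeneous model parameter.

The default population assigns the terminal-exhaustion threshold F2 each
integer value in [15, 35] with equal weight — 21 "simulated patients"
differing only in how much inflammation their T cells tolerate before
transitioning irreversibly.  There is no random sampling; population
runs are fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import IntegrationError
from .params import ModelParams, PKParams
from .simulate import (DoseProtocol, SimulationSettings, classify_elimination,
                       make_protocol, simulate)

log = logging.getLogger(__name__)


def _default_grid():
    return tuple(float(v) for v in range(15, 36))


@dataclass(frozen=True)
class PopulationSpec:
    """A one-parameter virtual population: each value is one patient."""

    parameter: str = "F2"
    values: tuple = field(default_factory=_default_grid)

    def __post_init__(self):
        if len(self.values) == 0:
            raise ValueError("population grid must be nonempty")
        if any(v <= 0 for v in self.values):
            raise ValueError("population parameter values must be positive")

    def patients(self, base: ModelParams):
        """Yield (value, ModelParams) per virtual patient; validation of
        e.g. F2 > F1 happens in the parameter constructor."""
        for value in self.values:
            yield value, base.replace(**{self.parameter: value})


@dataclass
class PopulationResult:
    fraction: float
    n_eliminated: int
    n_total: int
    per_patient: pd.DataFrame
    n_failed: int = 0


def population_success_fraction(protocol: DoseProtocol, pop: PopulationSpec,
                                params: ModelParams, pk: PKParams,
                                settings: SimulationSettings | None = None
                                ) -> PopulationResult:
    """Fraction of virtual patients whose tumor is eliminated under the protocol.

    Patients whose integration fails are flagged, excluded from the
    denominator and reported in ``n_failed``.
    """
    settings = settings or SimulationSettings()
    rows = []
    for value, patient in pop.patients(params):
        record = dict(parameter=pop.parameter, value=value, n_doses=protocol.n_doses,
                      spacing_days=protocol.spacing_days,
                      dose_per_admin=protocol.dose_per_admin,
                      eliminated=None, error=None)
        try:
            traj = simulate(params=patient, pk=pk, protocol=protocol, settings=settings)
            record["eliminated"] = classify_elimination(traj, settings, protocol)
        except IntegrationError as err:
            record["error"] = str(err)
            log.warning("patient %s=%s failed: %s", pop.parameter, value, err)
        rows.append(record)
    per_patient = pd.DataFrame(rows)
    done = per_patient[per_patient["error"].isna()]
    n_total = len(done)
    n_elim = int(done["eliminated"].sum()) if n_total else 0
    fraction = n_elim / n_total if n_total else float("nan")
    return PopulationResult(fraction=fraction, n_eliminated=n_elim, n_total=n_total,
                            per_patient=per_patient,
                            n_failed=len(per_patient) - n_total)


def population_heatmaps(total_doses, params: ModelParams, pk: PKParams,
                        pop: PopulationSpec | None = None,
                        settings: SimulationSettings | None = None,
                        n_doses_range=range(2, 13), spacing_range=range(1, 11)
                        ) -> dict[float, pd.DataFrame]:
    """Per-cumulative-dose grids of population success fractions.

    Returns ``{total_dose: frame}`` with long-format columns
    (n_doses, spacing_days, fraction, n_eliminated, n_total).
    """
    pop = pop or PopulationSpec()
    settings = settings or SimulationSettings()
    out = {}
    for total in total_doses:
        rows = []
        for n in n_doses_range:
            for tau in spacing_range:
                res = population_success_fraction(
                    make_protocol(total, n, tau), pop, params, pk, settings)
                rows.append(dict(total_dose=total, n_doses=n, spacing_days=tau,
                                 fraction=res.fraction, n_eliminated=res.n_eliminated,
                                 n_total=res.n_total))
                log.info("dose %s cell n=%s tau=%s fraction=%.3f",
                         total, n, tau, res.fraction)
        out[total] = pd.DataFrame(rows)
    return out
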