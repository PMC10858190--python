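"""Model and pharmacokinetic parameters.

The disease model couples a logistically growing tumor ``x`` with three
T-cell compartments — cytotoxic ``y1``, reversibly exhausted ``y2`` and
terminally exhausted ``y3`` — and an inflammation signal ``F`` whose
crossings of the thresholds ``F1 < F2`` gate the phenotype transitions.
The drug is described by a standard two-compartment PK model with
first-order subcutaneous absorption (``k01``); setting ``k01 = 0``
selects intravenous administration.

All rates are per day; tumor, immune-cell and inflammation quantities
share a common "volume" unit; PK volumes are mL/kg and clearances
mL/kg/day.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path

import yaml

from .exceptions import InvalidParameterError

DRIVER_MODES = ("inflammation", "antigen")

#: Default disease-model parameter values (the baseline parameterization).
MODEL_DEFAULTS = dict(
    lambda_=0.025,   # tumor growth rate (1/day)
    K=3000.0,        # tumor carrying capacity (vol)
    b=0.09,          # tumor kill rate by y1 (1/day/vol)
    c=0.01,          # tumor kill rate by y3 (1/day/vol)
    xi1=1.0,         # half-maximal constant, kill by y1
    xi3=1.0,         # half-maximal constant, kill by y3
    b1=0.1,          # y1 expansion from kill by y1 (1/day/vol)
    c1=0.001,        # y1 expansion from kill by y3 (1/day/vol)
    d1=0.044,        # y1 natural clearance (1/day)
    g1=0.045,        # y1 -> y2 transition rate when F > F1 (1/day/vol)
    g2=0.01,         # y2 -> y1 reversion rate when F < F1 (1/day/vol)
    g3=0.05,         # y2 -> y3 transition rate when F > F2 (1/day/vol)
    F1=10.0,         # inflammation threshold for y1 -> y2 (vol)
    F2=25.0,         # inflammation threshold for y2 -> y3 (vol)
    kd=0.001,        # drug-mediated y2 -> y1 rate (1/day/vol)
    d3=0.01,         # y3 death rate (1/day)
    b2=0.02,         # inflammation production per unit kill flux
    d4=0.01,         # inflammation clearance (1/day)
    b2bar=2.7027e-4,  # antigen production per unit tumor volume (variant model)
)

#: Default PK parameter values (typical mouse anti-PD-1 profile).
PK_DEFAULTS = dict(V1=70.0, V2=33.0, Cl1=20.0, Cl2=22.0, k01=0.11)

#: Default nonzero initial conditions; all other states start at zero.
INITIAL_DEFAULTS = dict(x0=50.0, y1_0=0.1)


@dataclass(frozen=True)
class ModelParams:
    """Disease-model parameters (tumor, immune compartments, inflammation).

    ``driver_mode`` selects the equation for the signal ``F``:
    ``"inflammation"`` produces F proportionally to the tumor-kill flux
    (coefficient ``b2``); ``"antigen"`` produces it proportionally to
    tumor volume (coefficient ``b2bar``).
    """

    lambda_: float = MODEL_DEFAULTS["lambda_"]
    K: float = MODEL_DEFAULTS["K"]
    b: float = MODEL_DEFAULTS["b"]
    c: float = MODEL_DEFAULTS["c"]
    xi1: float = MODEL_DEFAULTS["xi1"]
    xi3: float = MODEL_DEFAULTS["xi3"]
    b1: float = MODEL_DEFAULTS["b1"]
    c1: float = MODEL_DEFAULTS["c1"]
    d1: float = MODEL_DEFAULTS["d1"]
    g1: float = MODEL_DEFAULTS["g1"]
    g2: float = MODEL_DEFAULTS["g2"]
    g3: float = MODEL_DEFAULTS["g3"]
    F1: float = MODEL_DEFAULTS["F1"]
    F2: float = MODEL_DEFAULTS["F2"]
    kd: float = MODEL_DEFAULTS["kd"]
    d3: float = MODEL_DEFAULTS["d3"]
    b2: float = MODEL_DEFAULTS["b2"]
    d4: float = MODEL_DEFAULTS["d4"]
    b2bar: float = MODEL_DEFAULTS["b2bar"]
    driver_mode: str = "inflammation"

    def __post_init__(self):
        for name in ("lambda_", "K", "b", "c", "xi1", "xi3", "b1", "c1",
                     "d1", "g1", "g2", "g3", "F1", "F2", "kd", "d3", "d4"):
            value = getattr(self, name)
            if not value > 0:
                raise InvalidParameterError(
                    f"parameter {name!r} must be strictly positive, got {value!r}")
        for name in ("b2", "b2bar"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"parameter {name!r} must be nonnegative")
        if not self.F2 > self.F1:
            raise InvalidParameterError(
                f"F2 must exceed F1 (terminal-exhaustion threshold above the "
                f"reversible one); got F1={self.F1}, F2={self.F2}")
        if self.driver_mode not in DRIVER_MODES:
            raise InvalidParameterError(
                f"driver_mode must be one of {DRIVER_MODES}, got {self.driver_mode!r}")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)


@dataclass(frozen=True)
class PKParams:
    """Two-compartment PK parameters with derived micro-rate constants.

    The derived rates satisfy ``k10 = Cl1/V1``, ``k12 = Cl2/V1`` and
    ``k21 = Cl2/V2`` exactly.  Construct via :func:`derive_pk_rates`.
    """

    V1: float
    V2: float
    Cl1: float
    Cl2: float
    k01: float
    k10: float
    k12: float
    k21: float

    def __post_init__(self):
        for name in ("V1", "V2", "Cl1", "Cl2"):
            if not getattr(self, name) > 0:
                raise InvalidParameterError(
                    f"PK parameter {name!r} must be strictly positive")
        if self.k01 < 0:
            raise InvalidParameterError("absorption rate k01 must be nonnegative")

    @property
    def is_intravenous(self) -> bool:
        """True when k01 == 0 (drug enters the central compartment directly)."""
        return self.k01 == 0.0

    @property
    def central_half_life(self) -> float:
        """Central-compartment elimination half-life ln2/k10 in days."""
        return math.log(2.0) / self.k10

    def replace(self, **changes) -> "PKParams":
        """Return a copy with macro-parameters replaced; rates re-derived."""
        macro = dict(V1=self.V1, V2=self.V2, Cl1=self.Cl1, Cl2=self.Cl2, k01=self.k01)
        macro.update(changes)
        return derive_pk_rates(**macro)


def derive_pk_rates(V1: float = PK_DEFAULTS["V1"], V2: float = PK_DEFAULTS["V2"],
                    Cl1: float = PK_DEFAULTS["Cl1"], Cl2: float = PK_DEFAULTS["Cl2"],
                    k01: float = PK_DEFAULTS["k01"]) -> PKParams:
    """Build :class:`PKParams`, deriving k10, k12, k21 from volumes and clearances.

    Raises :class:`InvalidParameterError` for nonpositive volumes/clearances
    or a negative absorption rate.
    """
    if not (V1 > 0 and V2 > 0 and Cl1 > 0 and Cl2 > 0):
        raise InvalidParameterError("volumes and clearances must be strictly positive")
    if k01 < 0:
        raise InvalidParameterError("absorption rate k01 must be nonnegative")
    return PKParams(V1=V1, V2=V2, Cl1=Cl1, Cl2=Cl2, k01=k01,
                    k10=Cl1 / V1, k12=Cl2 / V1, k21=Cl2 / V2)


# keys accepted in configuration files, mapped onto dataclass fields
_CONFIG_MODEL_KEYS = {name: name for name in MODEL_DEFAULTS}
_CONFIG_MODEL_KEYS["lambda"] = "lambda_"
_CONFIG_MODEL_KEYS["driver_mode"] = "driver_mode"
_CONFIG_PK_KEYS = set(PK_DEFAULTS)
_CONFIG_INIT_KEYS = set(INITIAL_DEFAULTS)


def load_config(path) -> tuple[ModelParams, PKParams, dict]:
    """Read a YAML parameter file; unspecified keys take the defaults.

    Returns ``(model_params, pk_params, initial_conditions)`` where the
    last item is a dict with keys ``x0`` and ``y1_0``.  Unknown keys
    raise :class:`InvalidParameterError` (fail fast, listing them).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise InvalidParameterError(f"config {path} must be a mapping")
    model_kwargs, pk_kwargs = {}, {}
    init = dict(INITIAL_DEFAULTS)
    unknown = []
    for key, value in raw.items():
        if key in _CONFIG_MODEL_KEYS:
            model_kwargs[_CONFIG_MODEL_KEYS[key]] = value
        elif key in _CONFIG_PK_KEYS:
            pk_kwargs[key] = value
        elif key in _CONFIG_INIT_KEYS:
            init[key] = float(value)
        else:
            unknown.append(key)
    if unknown:
        raise InvalidParameterError(f"unknown configuration keys: {sorted(unknown)}")
    return ModelParams(**model_kwargs), derive_pk_rates(**{**PK_DEFAULTS, **pk_kwargs}), init


def dump_config(params: ModelParams, pk: PKParams, init: dict | None = None) -> str:
    """Serialize a full parameterization to YAML (inverse of load_config)."""
    out = {key: getattr(params, field) for key, field in _CONFIG_MODEL_KEYS.items()
           if key != "lambda_"}
    out.update({k: getattr(pk, k) for k in PK_DEFAULTS})
    out.update(init or INITIAL_DEFAULTS)
    return yaml.safe_dump(out, sort_keys=True)
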