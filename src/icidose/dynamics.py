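"""Right-hand sides of the coupled tumor-immune-inflammation and PK systems.

State ordering used throughout the package::

    (x, y1, y2, y3, F, D_SC, D_p, D_t)

The phenotype-switching terms are discontinuous: each is gated by a
strict threshold indicator on the signal ``F``.  The ratio-dependent
kill terms ``b*y1/(xi1*x + y1)`` are defined as 0 when the killer and
target populations are both empty (no killers, no kill).
"""

from __future__ import annotations

import numpy as np

from .exceptions import DomainError
from .params import ModelParams, PKParams

STATE_VARS = ("x", "y1", "y2", "y3", "F", "D_SC", "D_p", "D_t")


def threshold_indicator(F: float, threshold: float) -> float:
    """Unit step: 1.0 iff ``F > threshold``, else 0.0.

    Realizes the switching ratios of the form ``(F - Fi)+ / (F - Fi)``,
    taking the 0/0 case at equality as 0 (limit from below).
    """
    return 1.0 if F > threshold else 0.0


def _kill_fractions(x, y1, y3, p: ModelParams):
    """Per-tumor-cell kill rates by y1 and y3, with the 0/0 convention."""
    den1 = p.xi1 * x + y1
    den3 = p.xi3 * x + y3
    k1 = p.b * y1 / den1 if den1 > 0 else 0.0
    k3 = p.c * y3 / den3 if den3 > 0 else 0.0
    return k1, k3


def rhs_tumor_immune(state, params: ModelParams):
    """Time derivatives of (x, y1, y2, y3, F).

    ``state`` is any 8-sequence in the package state ordering; the drug
    effect reads the central-compartment level ``D_p``.  Negative
    disease-state components raise :class:`DomainError`.
    """
    x, y1, y2, y3, F = (float(v) for v in state[:5])
    Dp = float(state[6])
    if min(x, y1, y2, y3, F) < 0:
        raise DomainError("negative state component in (x, y1, y2, y3, F)")
    p = params
    k1, k3 = _kill_fractions(x, y1, y3, p)
    den1 = p.xi1 * x + y1
    den3 = p.xi3 * x + y3
    e1 = p.b1 * y1 / den1 if den1 > 0 else 0.0
    e3 = p.c1 * y3 / den3 if den3 > 0 else 0.0
    above_F1 = threshold_indicator(F, p.F1)
    below_F1 = threshold_indicator(p.F1, F)
    above_F2 = threshold_indicator(F, p.F2)

    dx = p.lambda_ * x * (1 - x / p.K) - (k1 + k3) * x
    dy1 = (x * (e1 + e3) + p.kd * Dp * y2 + p.g2 * y2 * below_F1
           - p.g1 * y1 * above_F1 - p.d1 * y1)
    dy2 = (p.g1 * y1 * above_F1 - p.g2 * y2 * below_F1
           - p.g3 * y2 * above_F2 - p.kd * Dp * y2)
    dy3 = p.g3 * y2 * above_F2 - p.d3 * y3
    if p.driver_mode == "antigen":
        dF = p.b2bar * x - p.d4 * F
    else:
        dF = p.b2 * (k1 + k3) * x - p.d4 * F
    return dx, dy1, dy2, dy3, dF


def rhs_pk(state, pk: PKParams):
    """Time derivatives of the drug states (D_SC, D_p, D_t)."""
    Dsc, Dp, Dt = (float(v) for v in state[5:8])
    dDsc = -pk.k01 * Dsc
    dDp = pk.k01 * Dsc - pk.k10 * Dp - pk.k12 * Dp + pk.k21 * (pk.V2 / pk.V1) * Dt
    dDt = pk.k12 * (pk.V1 / pk.V2) * Dp - pk.k21 * Dt
    return dDsc, dDp, dDt


def make_rhs(params: ModelParams, pk: PKParams):
    """Return a fast ``f(t, y) -> ndarray`` closure for the 8-state system.

    Intended for the ODE solver: tiny negative excursions produced by the
    integrator are clamped to zero instead of raising, so the vector
    field stays defined arbitrarily close to the domain boundary.
    """
    p = params
    lam, K, b, c, xi1, xi3 = p.lambda_, p.K, p.b, p.c, p.xi1, p.xi3
    b1, c1, d1, g1, g2, g3 = p.b1, p.c1, p.d1, p.g1, p.g2, p.g3
    F1, F2, kd, d3, d4 = p.F1, p.F2, p.kd, p.d3, p.d4
    antigen = p.driver_mode == "antigen"
    src = p.b2bar if antigen else p.b2
    k01, k10, k12, k21 = pk.k01, pk.k10, pk.k12, pk.k21
    v21, v12 = pk.V2 / pk.V1, pk.V1 / pk.V2

    def rhs(t, y):
        x = y[0] if y[0] > 0 else 0.0
        y1 = y[1] if y[1] > 0 else 0.0
        y2 = y[2] if y[2] > 0 else 0.0
        y3 = y[3] if y[3] > 0 else 0.0
        F = y[4]
        Dsc = y[5]
        Dp = y[6] if y[6] > 0 else 0.0
        Dt = y[7]
        den1 = xi1 * x + y1
        den3 = xi3 * x + y3
        k1 = b * y1 / den1 if den1 > 0 else 0.0
        k3 = c * y3 / den3 if den3 > 0 else 0.0
        e1 = b1 * y1 / den1 if den1 > 0 else 0.0
        e3 = c1 * y3 / den3 if den3 > 0 else 0.0
        iF1 = 1.0 if F > F1 else 0.0
        iF1b = 1.0 if F < F1 else 0.0
        iF2 = 1.0 if F > F2 else 0.0
        kill = (k1 + k3) * x
        return np.array([
            lam * x * (1 - x / K) - kill,
            x * (e1 + e3) + kd * Dp * y2 + g2 * y2 * iF1b - g1 * y1 * iF1 - d1 * y1,
            g1 * y1 * iF1 - g2 * y2 * iF1b - g3 * y2 * iF2 - kd * Dp * y2,
            g3 * y2 * iF2 - d3 * y3,
            (src * x if antigen else src * kill) - d4 * F,
            -k01 * Dsc,
            k01 * Dsc - (k10 + k12) * Dp + k21 * v21 * Dt,
            k12 * v12 * Dp - k21 * Dt,
        ])

    return rhs
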