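"""Independent fixed-step classical Runge-Kutta integrator.

Written directly from the model equations, without reusing any package
integration code, so that agreement with the adaptive solver is a
genuine dual-route check.
"""

import numpy as np


def rk4_integrate(params, pk, y0, t_end, dt=0.005):
    """Integrate the 8-state system from t=0 with a fixed step; returns the
    final state.  No dosing events (drug states evolve freely from y0)."""
    p, q = params, pk

    def f(s):
        x, y1, y2, y3, F, Dsc, Dp, Dt = np.maximum(s, 0.0)
        F = s[4]  # F may legitimately approach 0 from above; no clamp needed
        den1 = p.xi1 * x + y1
        den3 = p.xi3 * x + y3
        k1 = p.b * y1 / den1 if den1 > 0 else 0.0
        k3 = p.c * y3 / den3 if den3 > 0 else 0.0
        e1 = p.b1 * y1 / den1 if den1 > 0 else 0.0
        e3 = p.c1 * y3 / den3 if den3 > 0 else 0.0
        hi1 = 1.0 if F > p.F1 else 0.0
        lo1 = 1.0 if F < p.F1 else 0.0
        hi2 = 1.0 if F > p.F2 else 0.0
        if p.driver_mode == "antigen":
            dF = p.b2bar * x - p.d4 * F
        else:
            dF = p.b2 * (k1 + k3) * x - p.d4 * F
        return np.array([
            p.lambda_ * x * (1 - x / p.K) - (k1 + k3) * x,
            x * (e1 + e3) + p.kd * Dp * y2 + p.g2 * y2 * lo1 - p.g1 * y1 * hi1 - p.d1 * y1,
            p.g1 * y1 * hi1 - p.g2 * y2 * lo1 - p.g3 * y2 * hi2 - p.kd * Dp * y2,
            p.g3 * y2 * hi2 - p.d3 * y3,
            dF,
            -q.k01 * Dsc,
            q.k01 * Dsc - (q.k10 + q.k12) * Dp + q.k21 * (q.V2 / q.V1) * Dt,
            q.k12 * (q.V1 / q.V2) * Dp - q.k21 * Dt,
        ])

    n = int(round(t_end / dt))
    s = np.asarray(y0, float).copy()
    for _ in range(n):
        k1 = f(s)
        k2 = f(s + 0.5 * dt * k1)
        k3 = f(s + 0.5 * dt * k2)
        k4 = f(s + dt * k3)
        s = s + dt * (k1 + 2 * k2 + 2 * k3 + k4) / 6.0
    return s
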