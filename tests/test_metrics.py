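import numpy as np
import pytest

from icidose import (DoseProtocol, SimulationSettings, Trajectory,
                     area_above_threshold, make_protocol, pk_metrics, simulate)


def _flat_trajectory(dp=2.0, F=30.0, t_end=20.0):
    t = np.linspace(0, t_end, 401)
    states = np.zeros((t.size, 8))
    states[:, 4] = F
    states[:, 6] = dp
    return Trajectory(times=t, states=states)


def test_metrics_on_constant_concentration():
    """Constant D_p = c over an interval of length tau gives AUC = c*tau
    and c_min = c_avg = c."""
    traj = _flat_trajectory(dp=3.0)
    proto = DoseProtocol(dose_per_admin=1, n_doses=3, spacing_days=5)
    met = pk_metrics(traj, proto)
    assert met.interval == (5.0, 10.0)
    assert met.auc_0_tau == pytest.approx(15.0)
    assert met.c_min == pytest.approx(3.0)
    assert met.c_avg == pytest.approx(3.0)
    assert not met.single_dose_warning


def test_single_bolus_full_auc(params, pk):
    """Mass balance: AUC(0, inf) of the central compartment after one
    subcutaneous bolus of 6 units equals dose/k10 = 21."""
    proto = DoseProtocol(dose_per_admin=6.0, n_doses=1, spacing_days=1)
    traj = simulate(params, pk, proto, SimulationSettings(t_end=600))
    met = pk_metrics(traj, proto)
    assert met.single_dose_warning
    assert met.auc_0_tau == pytest.approx(6.0 / pk.k10, rel=1e-3)


def test_periodic_steady_state_auc(params, pk):
    """At periodic steady state the per-interval AUC equals
    dose_per_admin/k10 (linear-systems superposition)."""
    proto = make_protocol(125, 25, 5)      # 25 doses of 5, well into steady state
    traj = simulate(params, pk, proto, SimulationSettings())
    met = pk_metrics(traj, proto)
    assert met.auc_0_tau == pytest.approx(5.0 / pk.k10, rel=0.01)
    assert met.c_min <= met.c_avg


def test_auc_scales_linearly_with_dose(params, pk, settings):
    lo = pk_metrics(simulate(params, pk, make_protocol(20, 5, 4), settings),
                    make_protocol(20, 5, 4))
    hi = pk_metrics(simulate(params, pk, make_protocol(40, 5, 4), settings),
                    make_protocol(40, 5, 4))
    assert hi.auc_0_tau == pytest.approx(2 * lo.auc_0_tau, rel=1e-6)


def test_area_above_threshold_cases():
    traj = _flat_trajectory(F=30.0, t_end=10.0)
    assert area_above_threshold(traj, 25.0) == pytest.approx(50.0)
    assert area_above_threshold(_flat_trajectory(F=20.0, t_end=10.0), 25.0) == 0.0
    # the threshold -> -inf limit recovers the plain integral of F
    assert area_above_threshold(traj, -1e9) == pytest.approx(
        np.trapezoid(traj.series("F"), traj.times) + 1e9 * 10, rel=1e-9)


def test_area_nonincreasing_in_threshold(params, pk, settings):
    proto = DoseProtocol(dose_per_admin=0.0, n_doses=1, spacing_days=1)
    traj = simulate(params, pk, proto, settings)
    areas = [area_above_threshold(traj, thr) for thr in (0, 5, 10, 15, 20, 25)]
    assert all(a >= b for a, b in zip(areas, areas[1:]))


def test_concentration_scale_rescales_all_metrics(params, pk, settings):
    proto = make_protocol(20, 5, 4)
    traj = simulate(params, pk, proto, settings)
    base = pk_metrics(traj, proto)
    scaled = pk_metrics(traj, proto, concentration_scale=1000 / pk.V1)
    factor = 1000 / pk.V1
    assert scaled.auc_0_tau == pytest.approx(factor * base.auc_0_tau)
    assert scaled.c_min == pytest.approx(factor * base.c_min)
    assert scaled.c_avg == pytest.approx(factor * base.c_avg)
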