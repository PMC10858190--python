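import numpy as np
import pytest

from icidose import (DoseProtocol, SimulationSettings, classify_elimination,
                     make_protocol, simulate)
from icidose.exceptions import (InvalidProtocolError, InvalidSettingsError)


@pytest.mark.parametrize("total, n, tau, per_dose", [
    (50, 10, 1, 5.0),
    (50, 11, 5, 50 / 11),
    (40, 9, 1, 40 / 9),
])
def test_make_protocol_fractionation(total, n, tau, per_dose):
    proto = make_protocol(total, n, tau)
    assert proto.dose_per_admin == pytest.approx(per_dose)
    assert proto.n_doses == n and proto.spacing_days == tau
    assert proto.start_day == 0 and proto.route == "sc"
    assert proto.total_dose == pytest.approx(total)
    assert proto.last_dose_day == (n - 1) * tau


@pytest.mark.parametrize("kwargs", [
    dict(total_dose=50, n_doses=0, spacing_days=1),
    dict(total_dose=-1, n_doses=2, spacing_days=1),
    dict(total_dose=50, n_doses=2, spacing_days=0),
])
def test_invalid_protocols_rejected(kwargs):
    with pytest.raises(InvalidProtocolError):
        make_protocol(**kwargs)


def test_horizon_resolution():
    s = SimulationSettings()
    assert s.resolve_t_end(make_protocol(50, 2, 10)) == 400       # min horizon
    assert s.resolve_t_end(make_protocol(50, 25, 10)) == 440      # last dose + follow-up
    with pytest.raises(InvalidSettingsError):
        SimulationSettings(t_end=100).resolve_t_end(make_protocol(50, 25, 10))


def test_dose_events_jump_only_the_depot(params, pk):
    """At each dose the subcutaneous depot jumps by exactly the per-dose
    amount while every other state is continuous."""
    proto = make_protocol(12, 3, 5)
    settings = SimulationSettings(t_end=220)
    traj = simulate(params, pk, proto, settings)
    for td in proto.dose_times[1:]:
        i = np.searchsorted(traj.times, td)
        # grid contains the event time twice: pre-dose and post-dose states
        assert traj.times[i] == traj.times[i + 1] == td
        before, after = traj.states[i], traj.states[i + 1]
        assert after[5] - before[5] == pytest.approx(proto.dose_per_admin, rel=1e-9)
        np.testing.assert_allclose(after[[0, 1, 2, 3, 4, 6, 7]],
                                   before[[0, 1, 2, 3, 4, 6, 7]], rtol=1e-9)


def test_iv_route_deposits_into_central(params, pk):
    proto = DoseProtocol(dose_per_admin=6, n_doses=1, spacing_days=1, route="iv")
    traj = simulate(params, pk, proto, SimulationSettings(t_end=400))
    assert traj.states[0, 6] == pytest.approx(6.0)   # D_p jumps at t=0
    assert traj.states[0, 5] == 0.0                  # depot untouched


def test_untreated_growth_and_classification(params, pk, settings):
    """Without drug the tumor grows away from its initial volume and is
    classified as not eliminated."""
    proto = DoseProtocol(dose_per_admin=0.0, n_doses=1, spacing_days=1)
    traj = simulate(params, pk, proto, settings)
    x = traj.series("x")
    assert traj.times[0] == 0 and x[0] == pytest.approx(50)
    assert np.all(np.diff(x[: len(x) // 4]) >= 0)    # early growth is monotone
    assert traj.final_tumor > 500
    assert not classify_elimination(traj, settings, proto)


def test_classification_requires_followup(params, pk):
    proto = make_protocol(50, 5, 10)
    short = SimulationSettings(follow_up_days=10.0, min_horizon=60.0)
    traj = simulate(params, pk, proto, short)
    longer = SimulationSettings(follow_up_days=300.0)
    with pytest.raises(InvalidSettingsError):
        classify_elimination(traj, longer, proto)


def test_simulation_is_deterministic(params, pk, settings):
    proto = make_protocol(50, 4, 3)
    a = simulate(params, pk, proto, settings)
    b = simulate(params, pk, proto, settings)
    assert np.array_equal(a.times, b.times)
    assert np.array_equal(a.states, b.states)


def test_classification_stable_under_tighter_tolerances(params, pk):
    """Refining solver tolerances tenfold does not change the verdict."""
    base = SimulationSettings()
    tight = SimulationSettings(rtol=1e-9, atol=1e-11)
    for n, tau in [(2, 10), (8, 2), (11, 5)]:
        proto = make_protocol(50, n, tau)
        v1 = classify_elimination(simulate(params, pk, proto, base), base, proto)
        v2 = classify_elimination(simulate(params, pk, proto, tight), tight, proto)
        assert v1 == v2


def test_trajectory_frame_layout(params, pk, settings):
    proto = make_protocol(10, 2, 5)
    frame = simulate(params, pk, proto, settings).to_frame()
    assert list(frame.columns) == ["time", "x", "y1", "y2", "y3", "F",
                                   "D_SC", "D_p", "D_t"]
    assert frame["time"].is_monotonic_increasing
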