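import pytest

from icidose import (DoseProtocol, SimulationSettings, classify_elimination,
                     flip_fraction, make_protocol, sensitivity_heatmaps, simulate)

FAST = SimulationSettings(follow_up_days=100.0, min_horizon=150.0)


def test_unknown_parameter_rejected(params, pk):
    with pytest.raises(ValueError, match="unknown"):
        flip_fraction("V1", make_protocol(50, 2, 5), params, pk, FAST)


def test_censoring_by_construction(params, pk):
    """Under a zero-dose protocol no parameter perturbation is evaluated
    against a drug effect, and halving/doubling the reversion rate g2
    cannot flip the (failed) verdict: the result is censored at 1."""
    proto = DoseProtocol(dose_per_admin=0.0, n_doses=1, spacing_days=1)
    res = flip_fraction("g2", proto, params, pk, FAST, ladder_step=0.25)
    assert res.censored and res.flip_fraction == 1.0 and res.direction == "none"


def _ladder_oracle(name, proto, params, pk, settings, fractions):
    """Exhaustive brute force: evaluate the verdict at every ladder rung in
    both directions; return the smallest flipping fraction (or None)."""
    base_traj = simulate(params, pk, proto, settings)
    base = classify_elimination(base_traj, settings, proto)
    best = None
    for f in fractions:
        for sign in (+1, -1):
            factor = 1 + sign * f
            if getattr(params, name) * factor <= 0:
                continue
            try:
                perturbed = params.replace(**{name: getattr(params, name) * factor})
            except Exception:
                continue
            traj = simulate(perturbed, pk, proto, settings)
            if classify_elimination(traj, settings, proto) != base:
                best = f if best is None else min(best, f)
        if best is not None:
            break  # fractions ascend, so the first flipping rung is minimal
    return best


@pytest.mark.parametrize("name", ["lambda_", "K", "b"])
@pytest.mark.parametrize("cell", [(2, 10), (11, 5)])
def test_bisection_agrees_with_brute_force_ladder(params, pk, name, cell):
    """The bracketing-plus-bisection search lands within one coarse ladder
    step of the exhaustive ladder minimum."""
    step = 0.1
    proto = make_protocol(50, *cell)
    fractions = [round(step * k, 10) for k in range(1, 11)]
    expected = _ladder_oracle(name, proto, params, pk, FAST, fractions)
    res = flip_fraction(name, proto, params, pk, FAST,
                        ladder_step=step, resolution=0.02)
    if expected is None:
        assert res.censored
    else:
        assert not res.censored
        assert abs(res.flip_fraction - expected) <= step + 1e-9


def test_flip_fraction_deterministic_and_bounded(params, pk):
    proto = make_protocol(50, 2, 10)
    a = flip_fraction("lambda_", proto, params, pk, FAST, ladder_step=0.2)
    b = flip_fraction("lambda_", proto, params, pk, FAST, ladder_step=0.2)
    assert a == b
    assert 0 < a.flip_fraction <= 1.0


def test_sensitivity_heatmap_layout(params, pk):
    frame = sensitivity_heatmaps([make_protocol(50, 2, 5), make_protocol(50, 3, 5)],
                                 params, pk, FAST, parameters=("lambda_", "g2"),
                                 ladder_step=0.5, resolution=0.25)
    assert len(frame) == 4
    assert set(frame["parameter"]) == {"lambda_", "g2"}
    assert frame["flip_fraction"].between(0, 1).all()
    assert frame["censored"].dtype == bool
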