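"""Boundary solving, crossing probabilities and design calibration.

The two-look cases are validated against a brute-force bivariate-normal
trapezoid integration (see conftest), which shares no code with the
package's recursive integrator.
"""

import numpy as np
import pytest
from scipy.special import ndtr, ndtri
from scipy.optimize import brentq

from seqab.boundaries import (
    INFINITE_BOUND,
    CalibrationError,
    InterimSchedule,
    SpendingFunction,
    calibrate_design,
    crossing_probabilities,
    design_from_name,
    solve_efficacy_bounds,
    solve_futility_bounds,
)

from conftest import two_look_oracle


def test_single_look_bound_is_fixed_critical_value():
    sf = SpendingFunction("pocock", 0.05)
    (c,) = solve_efficacy_bounds(sf, InterimSchedule.equal(1))
    assert c == pytest.approx(1.959964, abs=1e-6)


def test_obf_two_look_first_bound_analytic():
    sf = SpendingFunction("obf", 0.05)
    c = solve_efficacy_bounds(sf, InterimSchedule.equal(2))
    assert c[0] == pytest.approx(ndtri(1 - sf(0.5) / 2), abs=1e-9)
    assert c[0] == pytest.approx(2.7718, abs=2e-4)


def test_obf_two_look_second_bound_vs_oracle():
    """c_2 must make the cumulative two-sided crossing exactly alpha."""
    sf = SpendingFunction("obf", 0.05)
    c1, c2 = solve_efficacy_bounds(sf, InterimSchedule.equal(2))
    oracle = two_look_oracle(c1, c2, f1=0.0, drift=0.0)
    assert oracle["eff1"] + oracle["eff2"] == pytest.approx(0.05, abs=1e-4)


def test_obf_bounds_strictly_decreasing():
    sf = SpendingFunction("obf", 0.05)
    c = solve_efficacy_bounds(sf, InterimSchedule.equal(4))
    assert all(a > b for a, b in zip(c, c[1:]))


@pytest.mark.parametrize("family", ["pocock", "obf"])
def test_cumulative_spend_matches_curve(family):
    """At every look the cumulative crossing equals the spending curve."""
    sf = SpendingFunction(family, 0.05)
    sched = InterimSchedule.equal(4)
    c = solve_efficacy_bounds(sf, sched)
    probs = crossing_probabilities(c, None, 0.0, sched)
    cum = np.cumsum(probs.efficacy)
    for k, t in enumerate(sched.fractions):
        assert cum[k] == pytest.approx(sf(t), abs=1e-6)


def test_crossing_single_look_null():
    probs = crossing_probabilities([1.959964], None, 0.0, InterimSchedule.equal(1))
    assert probs.total_efficacy == pytest.approx(0.05, abs=1e-6)


def test_crossing_probabilities_sum_to_one():
    sched = InterimSchedule.equal(4)
    c = solve_efficacy_bounds(SpendingFunction("obf", 0.05), sched)
    for drift in (0.0, 1.5, 2.8016):
        f = solve_futility_bounds(SpendingFunction("pocock", 0.2), c, 2.8016, sched)
        probs = crossing_probabilities(c, f, drift, sched)
        total = probs.total_efficacy + probs.total_futility + probs.no_stop
        assert total == pytest.approx(1.0, abs=1e-8)


def test_two_look_table_with_futility_vs_oracle():
    """Spec's worked two-look case: OBF efficacy, f_1=0.5, design drift."""
    sched = InterimSchedule.equal(2)
    c = solve_efficacy_bounds(SpendingFunction("obf", 0.05), sched)
    drift = 2.8016
    probs = crossing_probabilities(c, [0.5], drift, sched)
    oracle = two_look_oracle(c[0], c[1], f1=0.5, drift=drift)
    assert probs.efficacy[0] == pytest.approx(oracle["eff1"], abs=1e-4)
    assert probs.futility[0] == pytest.approx(oracle["fut1"], abs=1e-4)
    assert probs.efficacy[1] == pytest.approx(oracle["eff2"], abs=1e-4)
    assert probs.no_stop == pytest.approx(oracle["no_stop"], abs=1e-4)


def test_futility_band_null_closed_form():
    """Under zero drift a band f stops with probability 2*Phi(f) - 1."""
    sched = InterimSchedule.equal(2)
    probs = crossing_probabilities(
        [INFINITE_BOUND, 1.959964], [0.8], 0.0, sched
    )
    assert probs.futility[0] == pytest.approx(2 * ndtr(0.8) - 1, abs=1e-8)


def test_futility_bound_two_look_direct_arithmetic():
    """f_1 solves P(|Z_1| < f | drift) = beta-spend(0.5), a 1-D root."""
    beta_sf = SpendingFunction("pocock", 0.2)
    drift = 2.8016
    sched = InterimSchedule.equal(2)
    (f1,) = solve_futility_bounds(beta_sf, None, drift, sched)
    m = drift * np.sqrt(0.5)
    expected = brentq(
        lambda f: (ndtr(f - m) - ndtr(-f - m)) - beta_sf(0.5), 0.0, 8.0, xtol=1e-12
    )
    assert f1 == pytest.approx(expected, abs=1e-7)


def test_futility_vanishes_when_no_beta_to_spend():
    beta_sf = SpendingFunction("pocock", 1e-9)
    f = solve_futility_bounds(beta_sf, None, 2.8016, InterimSchedule.equal(4))
    assert all(abs(x) < 0.01 for x in f)


def test_futility_collision_reported():
    """A huge beta at a tight efficacy bound cannot be spent."""
    beta_sf = SpendingFunction("pocock", 0.9)
    with pytest.raises(CalibrationError):
        solve_futility_bounds(beta_sf, [0.6, 1.96], 2.8016, InterimSchedule.equal(2))


def test_calibrate_fixed():
    d = calibrate_design("fixed", 0.05, 0.80)
    assert d.drift == pytest.approx(1.959964 + 0.841621, abs=1e-5)
    assert d.inflation_factor == 1.0
    assert d.total_looks == 1
    assert d.efficacy_bounds[0] == pytest.approx(1.959964, abs=1e-6)


def test_single_look_schedule_reduces_to_fixed():
    d = calibrate_design(
        "both", 0.05, 0.80, InterimSchedule.equal(1),
        alpha_family="obf", beta_family="obf",
    )
    assert d.inflation_factor == 1.0
    assert d.futility_bounds is None


@pytest.mark.parametrize(
    "name,looks",
    [(n, k) for n in ("obf-both", "pocock-futility", "pocock-both", "obf-futility")
     for k in (2, 4)],
)
def test_alpha_and_power_consistency(designs, name, looks):
    """Type I error alpha without futility (non-binding), <= alpha with the
    band honoured; power exact at the calibrated drift."""
    d = designs[(name, looks)]
    null_no_fut = crossing_probabilities(d.efficacy_bounds, None, 0.0, d.schedule)
    assert null_no_fut.total_efficacy == pytest.approx(d.alpha, abs=1e-6)
    null = crossing_probabilities(
        d.efficacy_bounds, d.futility_bounds, 0.0, d.schedule
    )
    assert null.total_efficacy <= d.alpha + 1e-9
    alt = crossing_probabilities(
        d.efficacy_bounds, d.futility_bounds, d.drift, d.schedule
    )
    assert alt.total_efficacy == pytest.approx(d.power, abs=1e-6)
    assert d.inflation_factor > 1.0


def test_futility_only_design_shape(designs):
    d = designs[("pocock-futility", 4)]
    assert all(c >= INFINITE_BOUND for c in d.efficacy_bounds[:-1])
    assert d.efficacy_bounds[-1] == pytest.approx(1.959964, abs=1e-6)
    assert len(d.futility_bounds) == 3
    assert all(0 <= f < d.efficacy_bounds[-1] for f in d.futility_bounds)


def test_futility_bounds_below_efficacy_bounds(designs):
    d = designs[("obf-both", 4)]
    assert all(f < c for f, c in zip(d.futility_bounds, d.efficacy_bounds))


def test_design_from_name_unknown():
    with pytest.raises(ValueError):
        design_from_name("bonferroni", 2)


def test_schedule_validation():
    with pytest.raises(ValueError):
        InterimSchedule((0.5, 0.4, 1.0))
    with pytest.raises(ValueError):
        InterimSchedule((0.3, 0.9))
    assert InterimSchedule.equal(4).fractions == (0.25, 0.5, 0.75, 1.0)
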