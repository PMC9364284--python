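"""Unit and property tests for the analytic design machinery."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, optimize, stats

from mamsim import (
    BinaryEndpointModel,
    DesignSpec,
    design_effect_from_odds_ratio,
    find_critical_constant,
    nu_from_delta,
    obf_boundaries,
    odds_ratio_from_rates,
    rejection_probability,
    required_sample_size,
)


# ---------------------------------------------------------------------------
# effect scales
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "p0, p1, expected",
    [
        (0.5, 0.5, 1.0),
        (0.3, 0.6, 3.5),
        (0.1, 0.15, 0.135 / 0.085),
    ],
)
def test_odds_ratio_examples(p0, p1, expected):
    assert odds_ratio_from_rates(p0, p1) == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("bad", [(0.0, 0.5), (0.5, 1.0), (-0.1, 0.5), (0.5, 1.5)])
def test_odds_ratio_rejects_out_of_range(bad):
    with pytest.raises(ValueError):
        odds_ratio_from_rates(*bad)


@pytest.mark.parametrize(
    "p0, delta, expected",
    [
        (0.3, 0.0, 0.5),
        (0.3, 0.2, stats.norm.cdf(0.2 / math.sqrt(0.42))),
        (0.1, 0.4, stats.norm.cdf(0.4 / math.sqrt(0.18))),
    ],
)
def test_nu_examples(p0, delta, expected):
    assert nu_from_delta(p0, delta) == pytest.approx(expected, abs=1e-12)


def test_nu_infeasible_effect_rejected():
    with pytest.raises(ValueError, match="1 - p0"):
        nu_from_delta(0.7, 0.30)


@given(
    p0=st.floats(0.05, 0.95),
    delta=st.floats(0.0, 0.3),
)
@settings(max_examples=50, derandomize=True, deadline=None)
def test_nu_antisymmetric_and_monotone(p0, delta):
    """nu - 0.5 flips sign with delta, and nu increases with delta."""
    if delta >= 1 - p0 or delta >= p0:
        return
    up = nu_from_delta(p0, delta)
    down = nu_from_delta(p0, -delta)
    assert up - 0.5 == pytest.approx(0.5 - down, abs=1e-12)
    assert up >= 0.5
    if delta > 1e-6:
        assert up > nu_from_delta(p0, delta * 0.5)


@pytest.mark.parametrize(
    "probs, odds_ratio, expected",
    [
        ((0.25, 0.75), 1.0, 0.0),
        ((0.1, 0.9), 0.135 / 0.085, math.log(0.135 / 0.085) * math.sqrt(0.27 / 3)),
        ((0.3, 0.7), 3.5, math.log(3.5) * math.sqrt(0.63 / 3)),
    ],
)
def test_design_effect_examples(probs, odds_ratio, expected):
    assert design_effect_from_odds_ratio(probs, odds_ratio) == pytest.approx(expected, abs=1e-12)


def test_design_effect_rejects_unnormalised_probs():
    with pytest.raises(ValueError):
        design_effect_from_odds_ratio((0.3, 0.6), 2.0)


def test_binary_endpoint_model_derivations():
    m = BinaryEndpointModel(0.3, 0.3)
    assert m.p1 == pytest.approx(0.6)
    assert m.odds_ratio == pytest.approx(3.5)
    assert m.sigma2 == pytest.approx(0.21)
    assert m.nu == pytest.approx(stats.norm.cdf(0.3 / math.sqrt(0.42)))
    assert m.design_effect == pytest.approx(math.log(3.5) * math.sqrt(0.21), rel=1e-9)
    null = BinaryEndpointModel(0.3, 0.0)
    assert null.odds_ratio == pytest.approx(1.0)
    assert null.nu == pytest.approx(0.5)
    assert null.design_effect == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        BinaryEndpointModel(0.7, 0.3)


# ---------------------------------------------------------------------------
# boundaries
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "J, C, expected_upper",
    [
        (1, 2.0, (2.0,)),
        (3, 2.0, (2.0 * math.sqrt(3), 2.0 * math.sqrt(1.5), 2.0)),
        (2, 1.0, (math.sqrt(2), 1.0)),
    ],
)
def test_obf_boundary_shape(J, C, expected_upper):
    b = obf_boundaries(J, C)
    assert b.upper == pytest.approx(expected_upper)
    assert all(u1 >= u2 for u1, u2 in zip(b.upper, b.upper[1:]))
    assert b.upper[-1] == pytest.approx(C)
    assert all(l == 0.0 for l in b.lower[:-1])
    assert b.lower[-1] == pytest.approx(b.upper[-1])


# ---------------------------------------------------------------------------
# rejection probabilities and the critical constant
# ---------------------------------------------------------------------------


def dunnett_fwer_oracle(c: float, K: int) -> float:
    """1-D integral for the single-stage many-to-one FWER at critical value c."""
    integrand = lambda x: stats.norm.pdf(x) * stats.norm.cdf(x + math.sqrt(2) * c) ** K
    val, _ = integrate.quad(integrand, -10, 10)
    return 1.0 - val


def test_single_z_test_rejection_probability():
    spec = DesignSpec(K=1, J=1)
    b = obf_boundaries(1, stats.norm.ppf(0.95))
    p = rejection_probability(spec, b, [0.0], [10.0])
    assert p == pytest.approx(0.05, abs=1e-6)


def test_dunnett_constant_matches_one_dimensional_oracle(spec_rct):
    C = find_critical_constant(spec_rct)
    c_oracle = optimize.brentq(lambda c: dunnett_fwer_oracle(c, 4) - 0.05, 1.5, 3.0)
    assert C == pytest.approx(c_oracle, abs=1e-4)
    assert C == pytest.approx(2.16, abs=0.005)


def test_single_arm_single_stage_constant_is_normal_quantile():
    C = find_critical_constant(DesignSpec(K=1, J=1))
    assert C == pytest.approx(stats.norm.ppf(0.95), abs=1e-4)


def test_fwer_at_critical_constant_and_monotonicity(spec_mams, bounds_mams):
    """FWER equals alpha at C and decreases strictly along a C-grid."""
    cum_n = [25.0, 50.0, 75.0]
    fwer = rejection_probability(spec_mams, bounds_mams, [0.0] * 4, cum_n)
    assert fwer == pytest.approx(0.05, abs=1e-6)
    grid = [1.6, 1.9, 2.2, 2.5, 2.8]
    values = [
        rejection_probability(spec_mams, obf_boundaries(3, c), [0.0] * 4, cum_n)
        for c in grid
    ]
    assert all(a > b for a, b in zip(values, values[1:]))


def test_critical_constant_invariant_to_information_rescaling(spec_mams):
    base = find_critical_constant(spec_mams)
    rescaled = find_critical_constant(spec_mams, cum_n=[40.0, 80.0, 120.0])
    assert rescaled == pytest.approx(base, abs=1e-7)


def test_power_monotone_in_n_and_effect(spec_mams, bounds_mams):
    powers_n = [
        rejection_probability(spec_mams, bounds_mams, [0.4, 0, 0, 0],
                              np.arange(1, 4) * n, event="marginal")
        for n in (10, 20, 40, 80)
    ]
    assert all(a < b for a, b in zip(powers_n, powers_n[1:]))
    powers_theta = [
        rejection_probability(spec_mams, bounds_mams, [theta, 0, 0, 0],
                              np.arange(1, 4) * 30.0, event="marginal")
        for theta in (0.1, 0.2, 0.4, 0.6)
    ]
    assert all(a < b for a, b in zip(powers_theta, powers_theta[1:]))


def test_rejection_probability_validates_inputs(spec_mams, bounds_mams):
    with pytest.raises(ValueError):
        rejection_probability(spec_mams, bounds_mams, [0.0] * 4, [30.0, 20.0, 10.0])
    with pytest.raises(ValueError):
        rejection_probability(spec_mams, bounds_mams, [0.0] * 3, [10.0, 20.0, 30.0])


# ---------------------------------------------------------------------------
# required sample size
# ---------------------------------------------------------------------------


def test_single_stage_reduction_matches_closed_form(spec_rct):
    """At J=1 the machinery reproduces n = 2 ((C + z_beta) / theta)^2, rounded up."""
    C = find_critical_constant(spec_rct)
    for p0, delta in [(0.3, 0.3), (0.1, 0.05), (0.5, 0.2)]:
        model = BinaryEndpointModel(p0, delta)
        res = required_sample_size(spec_rct, model)
        closed = 2.0 * ((C + stats.norm.ppf(0.9)) / model.design_effect) ** 2
        assert res.continuous_n == pytest.approx(closed, rel=1e-6)
        assert res.n_per_group_stage == math.ceil(closed - 1e-9)
        assert res.total == 5 * res.n_per_group_stage


def test_required_sample_size_meets_power_at_n_not_below(spec_mams):
    model = BinaryEndpointModel(0.3, 0.2)
    res = required_sample_size(spec_mams, model)
    at = rejection_probability(
        spec_mams, res.bounds, [model.design_effect, 0, 0, 0],
        np.arange(1, 4) * res.n_per_group_stage, event="marginal",
    )
    below = rejection_probability(
        spec_mams, res.bounds, [model.design_effect, 0, 0, 0],
        np.arange(1, 4) * (res.n_per_group_stage - 1), event="marginal",
    )
    assert at >= 0.9
    assert below < 0.9


def test_required_sample_size_rejects_null_effect(spec_rct):
    with pytest.raises(ValueError):
        required_sample_size(spec_rct, BinaryEndpointModel(0.3, 0.0))


def test_mams_to_rct_required_ratio_band(spec_mams, spec_rct):
    """The multi-stage design plans 4-9% more than the single-stage design.

    The continuous ratio is scenario-free; integer rounding moves single
    cells by at most one stage unit per group, so the band is checked with
    that rounding allowance on the grid's smallest designs.
    """
    ratios = []
    for p0, delta in [(0.1, 0.05), (0.1, 0.4), (0.3, 0.1), (0.3, 0.3), (0.5, 0.2), (0.7, 0.25)]:
        model = BinaryEndpointModel(p0, delta)
        mams = required_sample_size(spec_mams, model)
        rct = required_sample_size(spec_rct, model)
        ratios.append(mams.total / rct.total)
        cont_ratio = (3 * mams.continuous_n * 5) / (rct.continuous_n * 5)
        assert 1.04 <= cont_ratio <= 1.09
    assert all(1.02 <= r <= 1.10 for r in ratios)


# ---------------------------------------------------------------------------
# quadrature vs Monte-Carlo oracle
# ---------------------------------------------------------------------------


def _mc_crossing_estimates(upper, lower, cum_n, thetas, n_reps, seed):
    """Brute-force per-arm path simulation of the crossing events.

    Independent of the quadrature code and of the trial engine: builds the
    correlated (arm, stage) statistics from shared-control increments and
    replays the crossing logic path by path.
    """
    rng = np.random.default_rng(seed)
    K, J = len(thetas), len(cum_n)
    m = np.diff(np.asarray(cum_n, float), prepend=0.0)
    incr = rng.standard_normal((n_reps, K + 1, J)) * np.sqrt(m)
    incr[:, 1:, :] += np.asarray(thetas)[:, None] * m
    scores = np.cumsum(incr, axis=2) / np.sqrt(np.asarray(cum_n, float))
    z = (scores[:, 1:, :] - scores[:, :1, :]) / math.sqrt(2)
    crossed = np.zeros((n_reps, K), dtype=bool)
    out = np.zeros((n_reps, K), dtype=bool)
    for j in range(J):
        zj = z[:, :, j]
        live = ~crossed & ~out
        hit = live & (zj >= upper[j])
        crossed |= hit
        if j < J - 1:
            out |= live & ~hit & (zj <= lower[j])
    return crossed


@pytest.mark.parametrize(
    "K, J, C, thetas, n1",
    [
        (1, 1, 1.7, (0.0,), 12.0),
        (2, 2, 1.9, (0.3, 0.0), 20.0),
        (3, 3, 2.1, (0.0, 0.0, 0.0), 15.0),
        (4, 3, 2.2, (0.45, 0.0, 0.0, 0.0), 18.0),
        (4, 2, 2.0, (0.2, 0.2, 0.0, 0.0), 25.0),
    ],
)
def test_quadrature_matches_monte_carlo(K, J, C, thetas, n1):
    """Analytic crossing probabilities agree with 1e5-replicate simulation."""
    spec = DesignSpec(K=K, J=J)
    bounds = obf_boundaries(J, C)
    cum_n = n1 * np.arange(1, J + 1)
    n_reps = 100_000
    crossed = _mc_crossing_estimates(
        bounds.upper_array(), bounds.lower_array(), cum_n, thetas, n_reps, seed=K * 100 + J
    )
    for event, mc in [
        ("familywise", crossed.any(axis=1).mean()),
        ("marginal", crossed[:, 0].mean()),
    ]:
        analytic = rejection_probability(spec, bounds, thetas, cum_n, event=event, arm=0)
        se = math.sqrt(max(mc * (1 - mc), 1e-12) / n_reps)
        assert abs(analytic - mc) <= 3 * se, (event, analytic, mc, se)
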