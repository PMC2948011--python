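"""Closed-form solution branches and derived profile features.

Frozen expected values were computed with the independent characteristics
solver (and, where marked, by hand along a single characteristic) before
being asserted here; the regime-wide certification lives in
test_characteristics/test_acceptance.
"""

import math

import numpy as np
import pytest

from morphograd import (
    Mode,
    ModelParameters,
    concentration,
    concentration_localized,
    concentration_uniform,
    critical_min_features,
    endpoint_curvature,
    equilibrium_concentration,
    evaluate_field,
    evaluate_profile,
    inflection_features,
    tissue_length,
    total_transcripts,
    velocity,
)
from conftest import dense_argmin, second_diff_sign_change


def make(mode, **kw):
    base = dict(S=1.0, d=1.0, k=0.0, w=1.0, L0=1.0, C0=0.0, mode=mode)
    base.update(kw)
    return ModelParameters(**base)


# ---------------------------------------------------------------------------
# concentration branches


def test_flat_special_case_no_gradient_ever():
    """Localized, k=0, C0=S/d: source exactly balances dilution, c stays C0."""
    params = make("localized", C0=1.0)
    for t in (0.0, 0.7, 3.0):
        x = np.linspace(0, tissue_length(params, t), 57)
        assert concentration_localized(params, x, t) == pytest.approx(1.0, abs=1e-14)


def test_localized_zone_derived_value_single_characteristic():
    # material that left the zone at tau = 0.5 carries c = 1 - e^{-0.5}
    params = make("localized", C0=0.0)
    assert concentration_localized(params, 1.5, 1.0) == pytest.approx(
        1.0 - math.exp(-0.5), rel=1e-12  # = 0.3934693402873666
    )


def test_localized_steady_profile_time_independent_exponential():
    params = make("localized", S=2.0, k=1.0, C0=1.0)  # C0 = C_E = 1
    for delta in (0.25, 0.8):
        for t in (1.0, 2.0):
            assert concentration_localized(params, 1.0 + delta, t) == pytest.approx(
                math.exp(-delta), rel=1e-12
            )


def test_uniform_steady_power_law_values():
    steady = make("uniform", k=1.0, C0=0.5)  # C_E = 0.5
    for t in (0.8, 2.5):
        assert concentration_uniform(steady, 2.0, t) == pytest.approx(0.125, rel=1e-12)
    nodeg = make("uniform", C0=1.0)  # k = 0, C_E = 1, steady c = 1/x
    for t in (math.log(4.0), 3.0):
        assert concentration_uniform(nodeg, 4.0, t) == pytest.approx(0.25, rel=1e-12)


@pytest.mark.parametrize("mode", ["localized", "uniform"])
@pytest.mark.parametrize("k", [0.0, 0.5, 2.0])
def test_continuity_across_interfaces(mode, k):
    """c is continuous at the zone edge and at the moving material fronts."""
    params = make(mode, k=k, C0=1.7, L0=1.4)  # w < L0: both fronts exist
    t = 0.9
    eps = 1e-9
    front = (
        params.w + params.d * params.w * t
        if params.mode is Mode.LOCALIZED
        else params.w * math.exp(params.d * t)
    )
    for x0 in (params.w, front):
        lo = concentration(params, x0 - eps, t)
        hi = concentration(params, x0 + eps, t)
        assert lo == pytest.approx(hi, abs=1e-7)


def test_uniform_zone_edge_matches_in_zone_value():
    params = make("uniform", k=0.7, C0=1.3)
    for t in (0.3, 2.0):
        in_zone = params.equilibrium + (params.C0 - params.equilibrium) * math.exp(
            -(params.d + params.k) * t
        )
        assert concentration_uniform(params, params.w, t) == pytest.approx(
            in_zone, rel=1e-12
        )


def test_domain_bounds_enforced():
    params = make("localized")
    with pytest.raises(ValueError):
        concentration_localized(params, 3.5, 1.0)  # L(1) = 2
    with pytest.raises(ValueError):
        concentration_uniform(make("uniform"), -0.1, 1.0)
    with pytest.raises(ValueError):
        concentration_uniform(params, 0.5, 1.0)  # wrong mode


def test_conservation_law_residual_vanishes(grid):
    """The closed forms satisfy dc/dt + d(vc)/dx = S*1[x<w] - k*c pointwise
    (finite differences, away from the characteristic interfaces)."""
    h = 1e-6
    for params in grid:
        t = 0.8
        front = (
            params.w + params.d * params.w * t
            if params.mode is Mode.LOCALIZED
            else params.w * math.exp(params.d * t)
        )
        L = tissue_length(params, t)
        probes = [0.4 * params.w, params.w + 0.45 * (front - params.w)]
        if front < L:
            probes.append(front + 0.5 * (L - front))
        for x in probes:
            dc_dt = (
                concentration(params, x, t + h) - concentration(params, x, t - h)
            ) / (2 * h)
            flux = lambda xx: velocity(params, xx) * concentration(params, xx, t)
            dflux_dx = (flux(x + h) - flux(x - h)) / (2 * h)
            source = params.S if x < params.w else 0.0
            residual = dc_dt + dflux_dx - source + params.k * concentration(params, x, t)
            scale = max(params.S, params.C0, 1.0)
            assert abs(residual) < 1e-5 * scale, (params, x)


# ---------------------------------------------------------------------------
# time monotonicity / gradient direction


@pytest.mark.parametrize("mode", ["localized", "uniform"])
@pytest.mark.parametrize("C0", [0.2, 1.6])
def test_time_trend_sign_is_C0_vs_CE(mode, C0):
    params = make(mode, k=0.5, C0=C0)  # C_E = 2/3
    x = 1.2
    c1, c2 = concentration(params, x, 0.6), concentration(params, x, 1.2)
    assert math.copysign(1, c2 - c1) == math.copysign(1, params.equilibrium - C0)


def test_gradient_direction_localized():
    """Exterior slope has the sign of d*C0 - S: increasing away from the
    zone only when the initial load exceeds what the source sustains."""
    for C0, sign in ((0.3, -1), (1.8, 1)):
        params = make("localized", k=1.0, C0=C0)  # S/d = 1
        t = 0.2  # early: before any interior minimum forms
        c = concentration_localized(params, np.array([1.05, 1.15]), t)
        assert math.copysign(1, c[1] - c[0]) == sign


def test_partial_zone_flat_beyond_material_front():
    """w < L0: tissue never descended from the zone keeps a flat profile."""
    for mode in ("localized", "uniform"):
        params = make(mode, k=0.5, w=0.5, L0=1.0, C0=0.8)
        t = 0.6
        front = (
            params.w + params.d * params.w * t
            if params.mode is Mode.LOCALIZED
            else params.w * math.exp(params.d * t)
        )
        L = tissue_length(params, t)
        x = np.linspace(front * 1.001, L, 33)
        c = concentration(params, x, t)
        assert np.ptp(c) < 1e-13 * max(params.C0, 1.0)


def test_uniform_exterior_always_concave_up(grid):
    for params in grid:
        if params.mode is not Mode.UNIFORM or params.equilibrium == 0:
            continue
        t = 1.1
        front = params.w * math.exp(params.d * t)
        x = np.linspace(params.w * 1.001, front * 0.999, 400)
        d2 = np.diff(concentration_uniform(params, x, t), 2)
        assert np.all(d2 > -1e-12)


# ---------------------------------------------------------------------------
# critical features


def test_critical_time_and_minimum_position():
    params = make("localized", S=2.0, k=1.0, C0=4.0)  # C_E = 1
    feats = critical_min_features(params, t=1.0)
    assert feats.exists_min
    assert feats.t_c == pytest.approx(0.5 * math.log(3.0), rel=1e-12)  # 0.54931
    assert feats.x_min == pytest.approx(1.0 + (1.0 - 0.5 * math.log(3.0)), rel=1e-12)
    # brute-force argmin agrees to grid resolution
    pos, h = dense_argmin(params, 1.0, n=20001)
    assert abs(pos - feats.x_min) <= h
    # before t_c the exterior is increasing: argmin sits at the zone edge
    pos_early, h_early = dense_argmin(params, 0.3, n=20001)
    assert pos_early <= params.w + h_early
    assert critical_min_features(params, 0.3).x_min is None


def test_minimum_requires_degradation_and_large_C0():
    assert not critical_min_features(make("localized", C0=5.0), 1.0).exists_min  # k=0
    assert not critical_min_features(
        make("localized", S=2.0, k=1.0, C0=0.9), 1.0
    ).exists_min  # C0 < S/d


def test_minimum_advances_at_elongation_speed():
    params = make("localized", S=2.0, k=1.0, C0=4.0)
    f1 = critical_min_features(params, 1.0)
    f2 = critical_min_features(params, 2.5)
    assert (f2.x_min - f1.x_min) / 1.5 == pytest.approx(
        params.d * params.w, rel=1e-12
    )


def test_inflection_time_and_position():
    params = make("localized", S=1.5, k=0.5, C0=0.0)  # C_E = 1
    feats = inflection_features(params, t=2.0)
    assert feats.exists_inflection
    assert feats.t_i == pytest.approx(2.0 / 3.0 * math.log(4.0), rel=1e-12)  # 0.92420
    assert feats.x_i == pytest.approx(3.0 - 2.0 / 3.0 * math.log(4.0), rel=1e-12)
    pos, h = second_diff_sign_change(params, 2.0, n=20001)
    assert pos is not None and abs(pos - feats.x_i) <= 2 * h
    # before t_i: concave down over the whole exterior, no sign change
    pos_early, _ = second_diff_sign_change(params, 0.5, n=20001)
    assert pos_early is None
    assert inflection_features(params, 0.5).x_i is None


def test_inflection_requires_low_C0():
    assert not inflection_features(
        make("localized", S=1.0, k=1.0, C0=0.6), 1.0
    ).exists_inflection  # C0 > C_E
    assert not inflection_features(make("localized", C0=0.0), 1.0).exists_inflection


def test_endpoint_curvature_signs():
    # steady exponential profile: concave up at both ends
    steady = make("localized", S=2.0, k=1.0, C0=1.0)
    ze, te = endpoint_curvature(steady, 0.7)
    assert ze > 0 and te > 0
    # inflection regime past t_i: up at the zone edge, down at the tissue edge
    infl = make("localized", S=1.5, k=0.5, C0=0.0)
    ze, te = endpoint_curvature(infl, 2.0)
    assert ze > 0 and te < 0
    # k = 0, C0 < S/d: concave down everywhere
    nodeg = make("localized", C0=0.2)
    ze, te = endpoint_curvature(nodeg, 1.0)
    assert ze < 0 and te < 0


def test_endpoint_curvature_matches_finite_differences(grid_full_zone):
    for params in grid_full_zone:
        if params.mode is not Mode.LOCALIZED:
            continue
        t = 1.0
        ze, te = endpoint_curvature(params, t)
        h = 1e-4 * params.w
        L = tissue_length(params, t)
        cw = concentration_localized(params, params.w + np.array([0, h, 2 * h]), t)
        cL = concentration_localized(params, L - np.array([2 * h, h, 0]), t)
        fd_zone = (cw[0] - 2 * cw[1] + cw[2]) / h**2
        fd_edge = (cL[0] - 2 * cL[1] + cL[2]) / h**2
        for exact, fd in ((ze, fd_zone), (te, fd_edge)):
            if abs(exact) > 1e-10:
                assert math.copysign(1, fd) == math.copysign(1, exact), params


# ---------------------------------------------------------------------------
# sampling and mass


def test_evaluate_profile_matches_pointwise_calls():
    params = make("localized", k=0.5, C0=0.3)
    prof = evaluate_profile(params, 1.0, 101)
    assert prof.L == pytest.approx(2.0)
    assert prof.x[0] == 0.0 and prof.x[-1] == pytest.approx(prof.L)
    np.testing.assert_allclose(
        prof.c, concentration(params, prof.x, 1.0), rtol=0, atol=0
    )
    with pytest.raises(ValueError):
        evaluate_profile(params, 1.0, 2)


def test_evaluate_field_steady_profiles_identical():
    params = make("uniform", k=1.0, C0=0.5)  # C0 = C_E
    fld = evaluate_field(params, [0.5, 2.0], 101)
    # steady case: the later field evaluated at the earlier grid is unchanged
    early = fld.profiles[0]
    np.testing.assert_allclose(
        concentration(params, early.x, 2.0), early.c, rtol=1e-12
    )


def test_evaluate_field_uniform_zone_edge_value():
    params = make("uniform", C0=0.0)  # k=0, C_E=1
    fld = evaluate_field(params, [1.0], 201)
    assert concentration(params, params.w, 1.0) == pytest.approx(
        1.0 - math.exp(-1.0), rel=1e-12
    )
    # grid value: linear interpolation across the zone-edge kink limits accuracy
    assert fld.profiles[0].interp(params.w) == pytest.approx(
        1.0 - math.exp(-1.0), rel=1e-2
    )


@pytest.mark.parametrize("mode", ["localized", "uniform"])
def test_total_transcripts_closed_form(mode):
    assert total_transcripts(make(mode, C0=0.0), 2.0) == pytest.approx(2.0)  # S*w*t
    assert total_transcripts(make(mode, S=0.0, C0=0.7, L0=2.0), 5.0) == pytest.approx(
        1.4
    )  # conserved without source/sink
    decayed = make(mode, k=2.0, C0=0.0)
    assert total_transcripts(decayed, 50.0) == pytest.approx(0.5, rel=1e-12)  # S*w/k


@pytest.mark.parametrize("mode", ["localized", "uniform"])
@pytest.mark.parametrize("k", [0.0, 0.8])
def test_total_transcripts_matches_quadrature(mode, k):
    params = make(mode, k=k, C0=0.6)
    t = 1.5
    prof = evaluate_profile(params, t, 20001)
    mass = np.trapezoid(prof.c, prof.x)
    assert mass == pytest.approx(total_transcripts(params, t), rel=1e-6)
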