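"""Geometry metrics against independent oracles and closed forms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tanglekit.datatypes import PopulationRates
from tanglekit import geometry as geo

from conftest import circle_rates


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def brute_tangling(xs, mode, eps, dt=1.0):
    """O(T^2) double-loop tangling, scalar arithmetic only."""
    states = [x[:, 1:] for x in xs]
    derivs = [(x[:, 1:] - x[:, :-1]) / dt for x in xs]
    out = []
    for s, (xa, va) in enumerate(zip(states, derivs)):
        q = np.zeros(xa.shape[1])
        for i in range(xa.shape[1]):
            best = 0.0
            for s2, (xb, vb) in enumerate(zip(states, derivs)):
                if mode == "within" and s2 != s:
                    continue
                if mode == "across" and s2 == s:
                    continue
                for j in range(xb.shape[1]):
                    num = np.sum((va[:, i] - vb[:, j]) ** 2)
                    den = np.sum((xa[:, i] - xb[:, j]) ** 2) + eps
                    best = max(best, num / den)
            q[i] = best
        out.append(q)
    return out


def pooled_eps(xs, coef=0.1):
    pooled = np.concatenate(xs, axis=1)
    c = pooled.mean(axis=1, keepdims=True)
    return coef * np.mean(np.sum((pooled - c) ** 2, axis=0))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_tangling_matches_double_loop_oracle(seed):
    """Vectorized tangling equals the brute-force double loop exactly."""
    rng = np.random.default_rng(seed)
    dims = rng.integers(2, 6)
    xs = [rng.standard_normal((dims, rng.integers(5, 15))) for _ in range(3)]
    eps = pooled_eps(xs)
    for mode in ("within", "across", "global"):
        res = geo.tangling(xs, mode=mode)
        expect = brute_tangling(xs, mode, eps)
        for q, e in zip(res.Q, expect):
            np.testing.assert_allclose(q, e, rtol=1e-10, atol=1e-12)


def test_straight_line_tangling_is_zero():
    """A constant-velocity line has identical derivatives everywhere."""
    t = np.arange(50, dtype=float)
    x = np.stack([2 * t, -t + 3])
    res = geo.tangling([x], mode="within")
    np.testing.assert_allclose(res.Q[0], 0, atol=1e-20)


def test_circle_tangling_closed_form():
    """Unit circle at angular frequency w: max Q -> 4 w^2 / (4 + eps).

    With ||x - x'||^2 = 2 - 2 cos(d) and ||xdot - xdot'||^2 = w^2 (2 - 2 cos(d)),
    the ratio is maximized where the denominator's +eps matters least, i.e. at
    the antipode d = pi.
    """
    n = 2000
    theta = 2 * np.pi * np.arange(n) / n
    w = 2 * np.pi / n  # radians per sample, dt = 1
    x = np.stack([np.cos(theta), np.sin(theta)])
    res = geo.tangling([x], mode="within", epsilon_coef=0.1)
    eps = res.epsilon_used
    # variance of a centered unit circle is 1 -> eps = 0.1
    assert eps == pytest.approx(0.1, rel=1e-3)
    expected = 4 * w**2 / (4 + eps)
    assert res.Q[0].max() == pytest.approx(expected, rel=1e-3)


def test_tangling_global_geq_within_pointwise():
    rng = np.random.default_rng(5)
    xs = [rng.standard_normal((4, 40)) for _ in range(3)]
    g = geo.tangling(xs, mode="global")
    w = geo.tangling(xs, mode="within")
    for qg, qw in zip(g.Q, w.Q):
        assert np.all(qg >= qw - 1e-12)


def test_tangling_rotation_invariance():
    rng = np.random.default_rng(6)
    xs = [rng.standard_normal((5, 30)) for _ in range(2)]
    q, _ = np.linalg.qr(rng.standard_normal((5, 5)))
    a = geo.tangling(xs, mode="global")
    b = geo.tangling([q @ x for x in xs], mode="global")
    for qa, qb in zip(a.Q, b.Q):
        np.testing.assert_allclose(qa, qb, rtol=1e-10)


def test_tangling_rejects_single_point():
    with pytest.raises(ValueError):
        geo.tangling([np.zeros((2, 1))])


# ---------------------------------------------------------------------------
# ellipse fitting
# ---------------------------------------------------------------------------

def make_ellipse(a, b, phi, center, n, phase0=0.3, noise=0.0, seed=0):
    psi = phase0 + 2 * np.pi * np.arange(n) / n
    rot = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    pts = rot @ np.stack([a * np.cos(psi), b * np.sin(psi)])
    pts += np.asarray(center)[:, None]
    if noise:
        pts += np.random.default_rng(seed).normal(0, noise, pts.shape)
    return pts


def test_exact_ellipse_r2_is_one():
    traj = make_ellipse(3.0, 1.2, 0.7, (2.0, -1.0), 80)
    fit = geo.fit_ellipse(traj)
    assert not fit.degenerate
    assert fit.r_squared == pytest.approx(1.0, abs=1e-6)
    assert sorted(fit.axes, reverse=True) == pytest.approx([3.0, 1.2], rel=1e-6)


def test_noisy_ellipse_r2_matches_generating_ellipse_oracle():
    """R^2 close to the residual computed against the known generator."""
    a, b, phi, c = 3.0, 1.5, 0.4, (0.5, 0.5)
    traj = make_ellipse(a, b, phi, c, 150, noise=0.05, seed=3)
    fit = geo.fit_ellipse(traj)
    clean = make_ellipse(a, b, phi, c, 150)
    sse = np.sum((traj - clean) ** 2)
    sst = np.sum((traj - traj.mean(axis=1, keepdims=True)) ** 2)
    oracle_r2 = 1 - sse / sst
    assert fit.r_squared == pytest.approx(oracle_r2, abs=0.01)


def test_saddle_projection_is_degenerate():
    t = np.linspace(-1, 1, 60)
    hyper = np.stack([np.cosh(t), np.sinh(t)])
    both = np.concatenate([hyper, -hyper], axis=1)
    fit = geo.fit_ellipse(both)
    assert fit.degenerate
    assert np.isnan(fit.r_squared)


def test_collinear_points_degenerate():
    t = np.linspace(0, 1, 30)
    fit = geo.fit_ellipse(np.stack([t, 2 * t]))
    assert fit.degenerate


# ---------------------------------------------------------------------------
# path similarity (Kabsch)
# ---------------------------------------------------------------------------

def rot2(angle):
    return np.array([[np.cos(angle), -np.sin(angle)],
                     [np.sin(angle), np.cos(angle)]])


def test_rotated_copy_has_r2_one():
    rng = np.random.default_rng(2)
    x = rng.standard_normal((2, 60))
    res = geo.path_similarity([x, rot2(1.1) @ x])
    assert res.r_squared_matrix[0, 1] == pytest.approx(1.0, abs=1e-10)


def test_reflection_flag_controls_determinant():
    rng = np.random.default_rng(3)
    x = rng.standard_normal((2, 60))
    reflected = np.diag([1.0, -1.0]) @ x
    strict = geo.path_similarity([x, reflected], allow_reflection=False)
    loose = geo.path_similarity([x, reflected], allow_reflection=True)
    assert strict.r_squared_matrix[0, 1] < 1.0 - 1e-6
    assert loose.r_squared_matrix[0, 1] == pytest.approx(1.0, abs=1e-10)
    assert np.linalg.det(strict.rotations[(0, 1)]) == pytest.approx(1.0)


def test_kabsch_matches_angle_grid_oracle():
    """Closed-form rotation beats (to grid resolution) a 3600-angle sweep."""
    rng = np.random.default_rng(4)
    ref = rng.standard_normal((2, 40))
    other = rng.standard_normal((2, 40))
    r = geo.kabsch_rotation(ref, other)
    best_sse = min(
        np.sum((ref - rot2(a) @ other) ** 2)
        for a in np.linspace(0, 2 * np.pi, 3600, endpoint=False)
    )
    sse = np.sum((ref - r @ other) ** 2)
    assert sse <= best_sse + 1e-9
    assert sse == pytest.approx(best_sse, rel=1e-4)


def test_pathsim_gap_aggregation_symmetric(stacked_population):
    from tanglekit.preprocess import pca

    xs = [pca(stacked_population, scope=s, n_components=2).projected[0]
          for s in range(4)]
    res = geo.path_similarity(xs)
    # aggregation over ordered pairs makes R^2_k invariant to relabeling order
    rev = geo.path_similarity(xs[::-1])
    for k in res.r_squared_by_gap:
        assert res.r_squared_by_gap[k][0] == pytest.approx(
            rev.r_squared_by_gap[k][0], abs=1e-10
        )


# ---------------------------------------------------------------------------
# speed axis
# ---------------------------------------------------------------------------

def test_norm_constrained_lsq_matches_angle_grid():
    """2-D toy: exact secular-equation solver vs a unit-vector sweep."""
    rng = np.random.default_rng(8)
    m = rng.standard_normal((6, 2))
    v = rng.standard_normal(6)
    w = geo._norm_constrained_lsq(m, v)
    assert np.linalg.norm(w) == pytest.approx(1.0, abs=1e-10)
    angles = np.linspace(0, 2 * np.pi, 36000, endpoint=False)
    cands = np.stack([np.cos(angles), np.sin(angles)])
    errs = np.sum((m @ cands - v[:, None]) ** 2, axis=0)
    assert np.sum((m @ w - v) ** 2) <= errs.min() + 1e-8


def test_planted_speed_axis_recovered(muscle_factors):
    """A population whose mean shifts linearly along a known off-plane axis
    yields a speed axis aligned with it (|cos| >= 0.99)."""
    from tanglekit.preprocess import pca
    from tanglekit.synthetic import StackedEllipseSpec, generate_stacked_population

    spec = StackedEllipseSpec(seed=21, speed_axis_gap=5.0, tilt_per_bin=0.0)
    pop = generate_stacked_population(spec, muscle_factors)
    planted = pop.meta["readout"][:, 2]  # the latent speed-axis direction
    proj = pca(pop, scope="global", n_components=12)
    speeds = np.asarray(pop.speed_bins, dtype=float)
    ax = geo.speed_axis(proj, mean_velocities=2 * np.pi * speeds)
    assert abs(planted @ ax.axis) >= 0.99
    # orthogonal to global PCs 1-2 by construction
    assert np.abs(proj.basis[:, :2].T @ ax.axis).max() < 1e-8


def test_speed_axis_variance_bounded_by_pc3(stacked_population):
    from tanglekit.preprocess import pca

    proj = pca(stacked_population, scope="global", n_components=12)
    speeds = np.asarray(stacked_population.speed_bins, dtype=float)
    ax = geo.speed_axis(proj, mean_velocities=2 * np.pi * speeds)
    assert ax.variance_captured <= proj.variance_explained[2] + 1e-10


def test_speed_axis_degenerate_velocities_rejected(stacked_population):
    from tanglekit.preprocess import pca

    proj = pca(stacked_population, scope="global", n_components=12)
    with pytest.raises(ValueError):
        geo.speed_axis(proj, mean_velocities=np.ones(8))


# ---------------------------------------------------------------------------
# distance, variance capture, controls, modulation
# ---------------------------------------------------------------------------

def test_phase_distance_self_is_zero(stacked_population):
    prof = geo.phase_distance(stacked_population.values, reference_bin=2)
    np.testing.assert_allclose(prof.delta_x[2], 0, atol=1e-12)


def test_concentric_circles_distance_is_radius_difference():
    pop = circle_rates([2.0, 5.0])
    prof = geo.phase_distance(pop.values, reference_bin=0)
    np.testing.assert_allclose(prof.delta_x[1], 3.0, rtol=1e-10)
    assert prof.mean_distance[1] == pytest.approx(0.0, abs=1e-10)  # same center


def test_stacked_mean_distance_scales_with_gap(muscle_factors):
    from tanglekit.synthetic import StackedEllipseSpec, generate_stacked_population

    g = 3.0
    spec = StackedEllipseSpec(seed=13, speed_axis_gap=g, tilt_per_bin=0.0,
                              output_dim_amp=0.0)
    pop = generate_stacked_population(spec, muscle_factors)
    prof = geo.phase_distance(pop.values, reference_bin=0)
    for j in range(pop.n_speeds):
        assert prof.mean_distance[j] == pytest.approx(g * j, rel=1e-9, abs=1e-9)


def test_cross_speed_variance_tilt_follows_cos2(muscle_factors):
    from tanglekit.synthetic import StackedEllipseSpec, generate_stacked_population

    alpha = 0.12
    spec = StackedEllipseSpec(seed=17, tilt_per_bin=alpha, speed_axis_gap=0.0,
                              output_dim_amp=0.0, eccentricity_slope=0.0)
    pop = generate_stacked_population(spec, muscle_factors)
    frac = geo.cross_speed_variance(pop, anchor_bin=0, n_pcs=2)
    # ellipse of bin s has half its variance in the tilted component
    expected = 0.5 + 0.5 * np.cos(alpha * np.arange(pop.n_speeds)) ** 2
    np.testing.assert_allclose(frac, expected, atol=5e-3)
    assert np.all(np.diff(frac) < 0)  # monotone decline away from anchor


def test_coplanar_speeds_fully_captured():
    pop = circle_rates([1.0, 2.0, 3.0])
    frac = geo.cross_speed_variance(pop, anchor_bin=0, n_pcs=2)
    np.testing.assert_allclose(frac, 1.0, atol=1e-10)


def test_rescaled_time_control_shares_path():
    pop = circle_rates([2.0, 2.0], n_points=300)
    pop.values[1] = pop.values[1][:, ::3]  # faster traversal, 100 points
    manip = geo.rescaled_time_control(pop, reference_bin=0, n_trials=None)
    # both speeds follow the reference path; lengths preserved
    assert manip.values[1].shape[1] == 100
    ref = manip.values[0]
    for col in manip.values[1].T:
        d = np.linalg.norm(ref - col[:, None], axis=0).min()
        assert d < 0.05  # on the reference path up to resampling


def test_two_speed_circles_global_exceeds_within():
    """Same circle at w and 2w: overlapping paths with different derivatives
    raise global tangling above each within-speed value."""
    n = 240
    theta = 2 * np.pi * np.arange(n) / n
    slow = np.stack([np.cos(theta), np.sin(theta)])
    fast = slow[:, ::2]  # double angular speed, half the samples
    g = geo.tangling([slow, fast], mode="global")
    w = geo.tangling([slow, fast], mode="within")
    assert np.percentile(g.pooled(), 99) > np.percentile(w.pooled(), 99)


def test_separation_removed_identity_on_identical_speeds():
    pop = circle_rates([2.0, 2.0, 2.0])
    manip = geo.separation_removed_control(pop, reference_bin=0)
    for v in manip.values:
        np.testing.assert_allclose(v, pop.values[0], atol=1e-8)


def test_separation_removed_equalizes_means(stacked_population):
    manip = geo.separation_removed_control(stacked_population, reference_bin=5)
    ref_mean = manip.values[5].mean(axis=1)
    for v in manip.values:
        np.testing.assert_allclose(v.mean(axis=1), ref_mean, atol=1e-8)


def test_speed_modulation_recovers_planted_slope():
    n_units, n_speeds = 4, 6
    values = []
    for s in range(n_speeds):
        rng_amp = 2 + 3 * s  # planted dynamic range, hit exactly by a ramp
        values.append(np.tile(np.linspace(0, rng_amp, 100), (n_units, 1)))
    pop = PopulationRates(values, 1.0, list(range(n_speeds)))
    slopes, ranges = geo.speed_modulation(pop)
    np.testing.assert_allclose(slopes, 3.0, rtol=1e-9)
    np.testing.assert_allclose(ranges[:, 0], 2.0, rtol=1e-9)


def test_speed_modulation_constant_unit_zero_slope():
    values = [np.full((2, 50), 7.0) for _ in range(4)]
    pop = PopulationRates(values, 1.0, list(range(4)))
    slopes, _ = geo.speed_modulation(pop)
    np.testing.assert_allclose(slopes, 0.0, atol=1e-12)
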