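"""Trajectory-geometry metrics for multi-speed population dynamics.

The central statistic is *trajectory tangling*::

    Q(t) = max_{t'}  ||xdot(t) - xdot(t')||^2 / (||x(t) - x(t')||^2 + eps)

which is large when nearby states carry dissimilar derivatives — the
signature of a trajectory that no smooth flow field can generate robustly.
The index set of ``t'`` distinguishes within-speed, across-speed, and global
tangling.  Around it sit the companion analyses: direct least-squares
ellipse fitting, Kabsch-rotation path similarity across speeds, the
norm-constrained speed-axis decoder, phase-dependent trajectory distance,
cross-speed variance capture, dynamic-range-vs-speed slopes, and the two
control manipulations (artificially rescaled time; separation removed) that
destroy inter-speed separation to show it is what keeps global tangling low.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .datatypes import FactorProjection, PopulationRates
from .preprocess import pca, smooth_rates
from .synthetic import simulate_spike_trains

__all__ = [
    "TanglingResult",
    "EllipseFit",
    "PathSimilarityResult",
    "SpeedAxis",
    "DistanceProfile",
    "tangling",
    "tangling_percentile",
    "fit_ellipse",
    "kabsch_rotation",
    "path_similarity",
    "speed_axis",
    "phase_distance",
    "cross_speed_variance",
    "rescaled_time_control",
    "separation_removed_control",
    "speed_modulation",
    "resample_trajectory",
]


# ---------------------------------------------------------------------------
# tangling
# ---------------------------------------------------------------------------

@dataclass
class TanglingResult:
    """Q(t) per time and speed under a stated comparison mode."""

    Q: list[np.ndarray]  # one array per speed (length T_s - 1)
    mode: str
    epsilon_used: float
    n_dims: int

    def pooled(self) -> np.ndarray:
        return np.concatenate(self.Q)


def _as_speed_list(trajectories) -> tuple[list[np.ndarray], float]:
    if isinstance(trajectories, FactorProjection):
        return trajectories.projected, trajectories.time_step
    if isinstance(trajectories, PopulationRates):
        return trajectories.values, trajectories.time_step
    return list(trajectories), 1.0


def tangling(
    trajectories,
    mode: str = "global",
    epsilon_coef: float = 0.1,
    time_step: float | None = None,
) -> TanglingResult:
    """Trajectory tangling per time point and speed.

    ``trajectories`` may be a :class:`FactorProjection`, a
    :class:`PopulationRates` (full-dimensional tangling), or a plain list of
    ``(dims, T_s)`` arrays.  Derivatives are backward differences on the
    sampling grid, so the first sample of each speed carries no Q value.
    ``eps`` is ``epsilon_coef`` times the pooled variance of the state
    (mean squared distance from the pooled mean).
    """
    if mode not in ("within", "across", "global"):
        raise ValueError(f"unknown tangling mode {mode!r}")
    xs, dt = _as_speed_list(trajectories)
    if time_step is not None:
        dt = time_step
    for x in xs:
        if x.shape[1] < 2:
            raise ValueError("tangling needs at least 2 time points per speed")

    pooled = np.concatenate(xs, axis=1)
    center = pooled.mean(axis=1, keepdims=True)
    eps = epsilon_coef * float(np.mean(np.sum((pooled - center) ** 2, axis=0)))

    states = [x[:, 1:] for x in xs]
    derivs = [np.diff(x, axis=1) / dt for x in xs]

    n_speeds = len(xs)
    out: list[np.ndarray] = []
    for s in range(n_speeds):
        xa, va = states[s], derivs[s]
        q = np.zeros(xa.shape[1])
        for s2 in range(n_speeds):
            if mode == "within" and s2 != s:
                continue
            if mode == "across" and s2 == s:
                continue
            xb, vb = states[s2], derivs[s2]
            dx2 = (
                np.sum(xa**2, axis=0)[:, None]
                + np.sum(xb**2, axis=0)[None, :]
                - 2 * xa.T @ xb
            )
            dv2 = (
                np.sum(va**2, axis=0)[:, None]
                + np.sum(vb**2, axis=0)[None, :]
                - 2 * va.T @ vb
            )
            ratio = np.maximum(dv2, 0) / (np.maximum(dx2, 0) + eps)
            q = np.maximum(q, ratio.max(axis=1))
        out.append(q)
    return TanglingResult(Q=out, mode=mode, epsilon_used=eps, n_dims=xs[0].shape[0])


def tangling_percentile(
    result: TanglingResult,
    q: float = 99.0,
    n_boot: int = 0,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Percentile summary of pooled tangling, with optional bootstrap.

    The bootstrap resamples time points with replacement from the pooled Q
    values (``n_boot`` draws, seeded) to convey uncertainty in the summary.
    """
    pooled = result.pooled()
    point = float(np.percentile(pooled, q))
    if n_boot <= 0:
        return point, np.empty(0)
    rng = np.random.default_rng(seed)
    draws = np.array([
        np.percentile(rng.choice(pooled, size=pooled.size, replace=True), q)
        for _ in range(n_boot)
    ])
    return point, draws


# ---------------------------------------------------------------------------
# ellipse fitting
# ---------------------------------------------------------------------------

@dataclass
class EllipseFit:
    """Best-fit ellipse of a 2-D trajectory.

    ``degenerate`` marks trajectories whose unconstrained conic fit is a
    hyperbola (e.g. saddle-shaped paths); these carry no meaningful ellipse
    R^2 and are excluded from comparisons.
    """

    center: np.ndarray
    axes: np.ndarray  # semi-axes, major first
    orientation: float  # radians of the major axis
    r_squared: float
    degenerate: bool


def _conic_design(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.column_stack([x**2, x * y, y**2, x, y, np.ones_like(x)])


def _fit_conic_unconstrained(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    d = _conic_design(x, y)
    _, _, vt = np.linalg.svd(d, full_matrices=False)
    return vt[-1]


def _fit_conic_ellipse(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Direct least-squares ellipse-specific conic fit (4ac - b^2 = 1),
    in the numerically stable partitioned form."""
    d1 = np.column_stack([x**2, x * y, y**2])
    d2 = np.column_stack([x, y, np.ones_like(x)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    t = -np.linalg.solve(s3, s2.T)
    m = s1 + s2 @ t
    m = np.array([m[2] / 2, -m[1], m[0] / 2])
    eigval, eigvec = np.linalg.eig(m)
    cond = 4 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    a1 = eigvec[:, np.flatnonzero(cond > 0)[0]].real
    return np.concatenate([a1, t @ a1])


def _conic_params(coef: np.ndarray):
    """Center, semi-axes, orientation from conic coefficients (ellipse)."""
    a, b, c, d, e, f = coef
    m = np.array([[a, b / 2], [b / 2, c]])
    center = np.linalg.solve(2 * m, [-d, -e])
    # value of the quadratic form at the center
    f0 = (
        a * center[0] ** 2 + b * center[0] * center[1] + c * center[1] ** 2
        + d * center[0] + e * center[1] + f
    )
    eigval, eigvec = np.linalg.eigh(m)
    axes2 = -f0 / eigval  # semi-axis^2 along each eigenvector
    if np.any(axes2 <= 0):
        raise ValueError("conic is not a real ellipse")
    order = np.argsort(axes2)[::-1]
    axes = np.sqrt(axes2[order])
    major = eigvec[:, order[0]]
    return center, axes, float(np.arctan2(major[1], major[0]))


def _ellipse_points(center, axes, orientation, psi) -> np.ndarray:
    rot = np.array(
        [[np.cos(orientation), -np.sin(orientation)],
         [np.sin(orientation), np.cos(orientation)]]
    )
    pts = np.stack([axes[0] * np.cos(psi), axes[1] * np.sin(psi)])
    return rot @ pts + np.asarray(center)[:, None]


def fit_ellipse(traj2d: np.ndarray) -> EllipseFit:
    """Fit an ellipse to a 2-D trajectory and score the fit.

    The conic is fit by direct least squares with the ellipse constraint.
    If the *unconstrained* least-squares conic is a hyperbola the trajectory
    is flagged degenerate.  R^2 compares the trajectory, point by point in
    temporal order, against the fitted ellipse sampled uniformly in
    parametric angle with the same number of points; the sampling phase
    offset and direction are chosen to minimize squared error.
    """
    traj = np.asarray(traj2d, dtype=float)
    if traj.shape[0] != 2:
        traj = traj.T
    if traj.shape[1] < 6:
        raise ValueError("need at least 6 points to fit a conic")
    x, y = traj
    # guard collinear input
    if np.linalg.matrix_rank(traj - traj.mean(axis=1, keepdims=True), tol=1e-10) < 2:
        return EllipseFit(np.full(2, np.nan), np.full(2, np.nan), np.nan,
                          np.nan, degenerate=True)
    scale = max(np.ptp(x), np.ptp(y))
    mu = traj.mean(axis=1)
    xs, ys = (x - mu[0]) / scale, (y - mu[1]) / scale
    free = _fit_conic_unconstrained(xs, ys)
    if free[1] ** 2 - 4 * free[0] * free[2] > 0:  # hyperbola wins
        return EllipseFit(np.full(2, np.nan), np.full(2, np.nan), np.nan,
                          np.nan, degenerate=True)
    coef = _fit_conic_ellipse(xs, ys)
    center_n, axes_n, orient = _conic_params(coef)
    center = center_n * scale + mu
    axes = axes_n * scale

    n = traj.shape[1]
    k = np.arange(n)
    sst = float(np.sum((traj - traj.mean(axis=1, keepdims=True)) ** 2))

    def sse_at(psi0: float, direction: int) -> float:
        psi = psi0 + direction * 2 * np.pi * k / n
        pts = _ellipse_points(center, axes, orient, psi)
        return float(np.sum((traj - pts) ** 2))

    best = (np.inf, 0.0, 1)
    grid = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    for direction in (1, -1):
        sses = np.array([sse_at(p, direction) for p in grid])
        i = int(np.argmin(sses))
        if sses[i] < best[0]:
            best = (sses[i], grid[i], direction)
    # refine the phase offset continuously around the best grid point
    width = 2 * np.pi / 720
    res = minimize_scalar(
        lambda p: sse_at(p, best[2]),
        bounds=(best[1] - width, best[1] + width),
        method="bounded",
        options={"xatol": 1e-10},
    )
    sse = min(best[0], float(res.fun))
    r2 = 1.0 - sse / sst
    return EllipseFit(center=center, axes=axes, orientation=orient,
                      r_squared=r2, degenerate=False)


# ---------------------------------------------------------------------------
# path similarity (Kabsch)
# ---------------------------------------------------------------------------

@dataclass
class PathSimilarityResult:
    r_squared_matrix: np.ndarray  # (ref, comparison); diag = 1
    r_squared_by_gap: dict[int, tuple[float, float]]  # gap -> (mean, sem)
    rotations: dict[tuple[int, int], np.ndarray]


def resample_trajectory(x: np.ndarray, n_out: int) -> np.ndarray:
    """Linear resampling of a (dims, T) trajectory to ``n_out`` samples."""
    t_src = np.linspace(0, 1, x.shape[1])
    t_out = np.linspace(0, 1, n_out)
    return np.stack([np.interp(t_out, t_src, row) for row in x])


def kabsch_rotation(
    ref: np.ndarray, other: np.ndarray, allow_reflection: bool = False
) -> np.ndarray:
    """Rotation R minimizing ||ref - R other||_F over orthogonal R.

    By default the determinant is constrained to +1 (a proper rotation); with
    ``allow_reflection`` the unconstrained orthogonal Procrustes solution is
    returned.
    """
    h = other @ ref.T
    u, _, vt = np.linalg.svd(h)
    r = vt.T @ u.T
    if not allow_reflection and np.linalg.det(r) < 0:
        d = np.ones(h.shape[0])
        d[-1] = -1
        r = vt.T @ np.diag(d) @ u.T
    return r


def path_similarity(
    trajectories,
    reference_bin: int | None = None,
    allow_reflection: bool = False,
) -> PathSimilarityResult:
    """Shape similarity of per-speed trajectories under optimal rigid rotation.

    Each comparison trajectory is resampled in time to the reference length,
    rotated by the Kabsch-optimal rotation (no scaling or offset), and scored
    by R^2 = 1 - SSE / (variance of the comparison trajectory).  ``R^2_k``
    aggregates over all ordered pairs separated by k speed bins.
    """
    xs, _ = _as_speed_list(trajectories)
    n = len(xs)
    for x in xs:
        if x.shape[1] < 2:
            raise ValueError("trajectories must have length >= 2")
    refs = range(n) if reference_bin is None else [reference_bin]
    mat = np.full((n, n), np.nan)
    rotations: dict[tuple[int, int], np.ndarray] = {}
    for i in refs:
        ref = xs[i]
        for j in range(n):
            comp = resample_trajectory(xs[j], ref.shape[1])
            r = kabsch_rotation(ref, comp, allow_reflection)
            rotated = r @ comp
            sse = float(np.sum((ref - rotated) ** 2))
            sst = float(np.sum((rotated - rotated.mean(axis=1, keepdims=True)) ** 2))
            mat[i, j] = 1.0 - sse / sst
            rotations[(i, j)] = r
    by_gap: dict[int, tuple[float, float]] = {}
    if reference_bin is None:
        for k in range(1, n):
            vals = np.array([mat[i, j] for i in range(n) for j in range(n)
                             if abs(i - j) == k])
            sem = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
            by_gap[k] = (float(vals.mean()), float(sem))
    return PathSimilarityResult(mat, by_gap, rotations)


# ---------------------------------------------------------------------------
# speed axis
# ---------------------------------------------------------------------------

@dataclass
class SpeedAxis:
    axis: np.ndarray  # unit vector in unit space
    axis_coords: np.ndarray  # coordinates in the PC-3..12 subspace
    variance_captured: float
    decode_error: float


def _norm_constrained_lsq(m: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Solve min ||M w - v||^2 subject to ||w|| = 1.

    The stationarity condition (M'M - lam I) w = M'v is solved exactly via
    the secular equation ||w(lam)|| = 1 with lam below the smallest
    eigenvalue of M'M, where the constrained minimum is unique.  With fewer
    speeds than candidate dimensions M'M is rank deficient, and when the
    minimum-norm least-squares solution already has norm below 1 the
    unit-norm problem is degenerate (any null-space padding leaves the
    residual unchanged); the normalized minimum-norm solution is returned
    then, which is the only choice that carries no arbitrary component.
    """
    g = m.T @ m
    h = m.T @ v
    eigval, eigvec = np.linalg.eigh(g)
    beta = eigvec.T @ h
    scale = max(eigval[-1], 1.0)
    # directions with negligible data variance are exact nulls for this
    # problem: coefficients there change neither decode nor interpretation
    null_mask = eigval < 1e-6 * eigval[-1]
    eigval = np.where(null_mask, 0.0, eigval)
    beta = np.where(null_mask, 0.0, beta)
    lam_min = eigval[0]
    min_space = eigval - lam_min < 1e-12 * scale
    rest = ~min_space
    beta_min = np.linalg.norm(beta[min_space])

    def norm2(lam: float) -> float:
        total = float(np.sum((beta[rest] / (eigval[rest] - lam)) ** 2))
        if beta_min > 0:
            total += float(np.sum((beta[min_space] / (lam_min - lam)) ** 2))
        return total

    if beta_min <= 1e-10 * max(1.0, np.abs(beta).max()):
        # target has no component on the lam_min eigenspace: check whether
        # the minimum-norm solution already satisfies / undershoots the norm
        coords = np.zeros_like(beta)
        coords[rest] = beta[rest] / (eigval[rest] - lam_min)
        n0 = np.linalg.norm(coords)
        if n0 < 1.0:
            return eigvec @ (coords / n0)  # degenerate: min-norm direction
    # unique boundary solution: bracket lam below lam_min
    hi = lam_min - 1e-12 * scale
    step = scale
    lo = hi - step
    while norm2(lo) > 1:
        step *= 4
        lo = hi - step
    lam = brentq(lambda L: norm2(L) - 1, lo, hi, xtol=1e-14 * scale)
    coords = np.zeros_like(beta)
    coords[rest] = beta[rest] / (eigval[rest] - lam)
    if beta_min > 0:
        coords[min_space] = beta[min_space] / (lam_min - lam)
    w = eigvec @ coords
    return w / np.linalg.norm(w)


def speed_axis(
    global_factors: FactorProjection,
    mean_velocities: np.ndarray,
    components: tuple[int, int] = (2, 12),
) -> SpeedAxis:
    """The direction best decoding mean angular velocity, orthogonal to the
    dominant plane.

    Per-speed mean states are taken in global PC components 3..12 (indices
    ``components[0]:components[1]``); the unit-norm decoder minimizing the
    squared decode error of the mean-centered mean angular velocities is
    found by exact norm-constrained least squares, then lifted back to unit
    space (where it is orthogonal to global PCs 1-2 by construction).
    """
    lo, hi = components
    if global_factors.n_components < hi:
        raise ValueError(f"need at least {hi} global components")
    if len(global_factors.projected) < 3:
        raise ValueError("need at least 3 speeds")
    v = np.asarray(mean_velocities, dtype=float)
    v = v - v.mean()
    if np.allclose(v, 0):
        raise ValueError("all mean velocities equal: no speed information")
    m = np.stack([p[lo:hi].mean(axis=1) for p in global_factors.projected])
    w = _norm_constrained_lsq(m, v)
    axis = global_factors.basis[:, lo:hi] @ w
    # variance captured along the axis, as a fraction of total variance
    pooled_states = np.concatenate(
        [p[lo:hi] for p in global_factors.projected], axis=1
    )
    proj = w @ pooled_states
    full = np.concatenate(global_factors.projected, axis=1)
    total = np.sum((full - full.mean(axis=1, keepdims=True)) ** 2)
    captured = np.sum((proj - proj.mean()) ** 2) / total
    rms = float(np.sqrt(np.mean((m @ w - v) ** 2)))
    return SpeedAxis(axis=axis, axis_coords=w,
                     variance_captured=float(captured), decode_error=rms)


# ---------------------------------------------------------------------------
# distance, variance capture, modulation
# ---------------------------------------------------------------------------

@dataclass
class DistanceProfile:
    delta_x: list[np.ndarray]  # phase-dependent distance per speed
    mean_distance: np.ndarray  # per speed
    reference_bin: int
    mode: str


def phase_distance(
    trajectories, reference_bin: int, mode: str = "matched"
) -> DistanceProfile:
    """Distance from the reference trajectory to every other trajectory.

    ``matched`` (default) compares states at the same cycle phase after
    resampling every trajectory to the reference length; ``nearest`` takes,
    for each reference phase, the distance to the nearest point anywhere on
    the other trajectory.
    """
    if mode not in ("matched", "nearest"):
        raise ValueError(f"unknown mode {mode!r}")
    xs, _ = _as_speed_list(trajectories)
    ref = xs[reference_bin]
    n_ref = ref.shape[1]
    deltas, means = [], []
    ref_mean = ref.mean(axis=1)
    for x in xs:
        res = resample_trajectory(x, n_ref)
        if mode == "matched":
            deltas.append(np.linalg.norm(ref - res, axis=0))
        else:
            d2 = (
                np.sum(ref**2, axis=0)[:, None]
                + np.sum(res**2, axis=0)[None, :]
                - 2 * ref.T @ res
            )
            deltas.append(np.sqrt(np.maximum(d2, 0).min(axis=1)))
        means.append(np.linalg.norm(ref_mean - x.mean(axis=1)))
    return DistanceProfile(deltas, np.array(means), reference_bin, mode)


def cross_speed_variance(
    rates: PopulationRates, anchor_bin: int, n_pcs: int = 2
) -> np.ndarray:
    """Fraction of each speed's variance captured by the anchor bin's PCs.

    PCs are fit on the anchor speed's trajectory alone; every bin's
    (own-mean-centered) variance is then projected onto that fixed basis.
    """
    anchor = pca(rates, scope=anchor_bin, n_components=n_pcs)
    basis = anchor.basis
    out = np.empty(rates.n_speeds)
    for s, v in enumerate(rates.values):
        c = v - v.mean(axis=1, keepdims=True)
        total = np.sum(c**2)
        out[s] = np.sum((basis.T @ c) ** 2) / total
    return out


def rescaled_time_control(
    rates: PopulationRates,
    reference_bin: int = 5,
    n_trials: int | None = 20,
    seed: int = 0,
    smooth_sd: float = 20.0,
) -> PopulationRates:
    """Replace every speed's trajectory with the reference path traversed at
    that speed's duration, then re-measure through spiking noise.

    All speeds share an identical path but different traversal rates, which
    is exactly the configuration that inflates global tangling.  With
    ``n_trials`` set, spike trains are regenerated by thinning (the reference
    path as conditional intensity) and smoothed, so the measured trajectories
    carry realistic sampling error; ``n_trials=None`` is the infinite-trial
    limit (no respiking).
    """
    ref = rates.values[reference_bin]
    values = [resample_trajectory(ref, v.shape[1]) for v in rates.values]
    manipulated = PopulationRates(
        values, rates.time_step, list(rates.speed_bins), rates.kind
    )
    if n_trials is None:
        return manipulated
    clipped = manipulated.copy()
    clipped.values = [np.maximum(v, 0) for v in clipped.values]
    trials = simulate_spike_trains(clipped, n_trials=n_trials, seed=seed)
    smoothed = smooth_rates(trials, kernel_sd=smooth_sd)
    values = []
    for s in range(rates.n_speeds):
        group = smoothed.by_speed(s)
        values.append(np.mean([t.traces for t in group], axis=0))
    return PopulationRates(
        values, rates.time_step, list(rates.speed_bins), rates.kind,
        meta={"control": "rescaled_time", "n_trials": n_trials, "seed": seed},
    )


def separation_removed_control(
    rates: PopulationRates, reference_bin: int = 5
) -> PopulationRates:
    """Remove inter-speed separation while preserving trajectory shape.

    Every speed's trajectory is given the reference mean and rotated
    (Kabsch, det +1) onto the reference so all trajectories unfold in the
    same dimensions.  The rotation is *found* on a copy resampled to the
    reference length (the pointwise pairing needs matched lengths) but
    *applied* on the trajectory's own time base: each speed still traverses
    the now-overlapping path at its own rate, which is exactly why removing
    separation exposes the trajectories to tangling.
    """
    ref = rates.values[reference_bin]
    ref_c = ref - ref.mean(axis=1, keepdims=True)
    ref_mean = ref.mean(axis=1, keepdims=True)
    values = []
    for v in rates.values:
        res = resample_trajectory(v, ref.shape[1])
        c = res - res.mean(axis=1, keepdims=True)
        r = kabsch_rotation(ref_c, c, allow_reflection=False)
        values.append(r @ (v - v.mean(axis=1, keepdims=True)) + ref_mean)
    return PopulationRates(
        values, rates.time_step, list(rates.speed_bins), rates.kind,
        meta={"control": "separation_removed"},
    )


def speed_modulation(rates: PopulationRates) -> tuple[np.ndarray, np.ndarray]:
    """Per-unit slope of dynamic range (max - min over the cycle) vs speed bin.

    Returns ``(slopes, ranges)`` where ``ranges`` is unit × speed.  The sign
    of the slope classifies units as increasing or decreasing their
    modulation with speed.
    """
    if rates.n_speeds < 2:
        raise ValueError("need at least 2 speeds")
    ranges = np.stack(
        [v.max(axis=1) - v.min(axis=1) for v in rates.values], axis=1
    )
    s = np.arange(rates.n_speeds)
    design = np.column_stack([s, np.ones_like(s)])
    coef, *_ = np.linalg.lstsq(design, ranges.T, rcond=None)
    return coef[0], ranges
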