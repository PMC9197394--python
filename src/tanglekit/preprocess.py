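"""Normalization, smoothing, trial alignment/averaging, and PCA.

These are the standard steps applied to every population before geometry
analysis: unit responses are range-normalized (softly for neural data, fully
for muscle data), spike trains are smoothed with a Gaussian kernel, trials
are brought onto a common time base in two stages (uniform rescale to the
median duration, then an adaptive monotone warp that aligns each trial's
position trace to the across-trial mean), and factors are extracted by PCA
either per speed bin or globally across all speeds.
"""

from __future__ import annotations

import numpy as np

from .datatypes import FactorProjection, PopulationRates, Trial, TrialSet

__all__ = ["normalize", "smooth_rates", "align_and_average", "pca"]

SOFT_NORM_CONSTANT = 5.0  # spikes/s


def normalize(
    rates: PopulationRates,
    mode: str = "soft",
    soft_constant: float = SOFT_NORM_CONSTANT,
) -> PopulationRates:
    """Range-normalize each unit across all times and speeds.

    ``soft`` divides by (range + soft_constant) so weak units do not dominate
    subsequent PCA; ``full`` divides by the range exactly (appropriate for
    muscle channels whose scale is arbitrary).
    """
    if soft_constant < 0:
        raise ValueError("soft_constant must be >= 0")
    if mode not in ("soft", "full"):
        raise ValueError(f"unknown mode {mode!r}")
    pooled = rates.pooled()
    rng = pooled.max(axis=1) - pooled.min(axis=1)
    if mode == "full":
        zero = np.flatnonzero(rng == 0)
        if zero.size:
            raise ValueError(f"full normalization undefined for zero-range unit(s) {zero.tolist()}")
        denom = rng
    else:
        denom = rng + soft_constant
        if np.any(denom == 0):
            raise ValueError("soft_constant=0 with zero-range unit")
    out = rates.copy()
    out.values = [v / denom[:, None] for v in out.values]
    out.meta["normalization"] = {"mode": mode, "soft_constant": soft_constant}
    return out


def _gauss_kernel(sd_samples: float) -> np.ndarray:
    half = max(int(np.ceil(4 * sd_samples)), 1)
    x = np.arange(-half, half + 1)
    k = np.exp(-0.5 * (x / sd_samples) ** 2)
    return k / k.sum()


def _smooth_matrix(x: np.ndarray, sd_samples: float) -> np.ndarray:
    """Unit-area Gaussian smoothing with edge renormalization."""
    k = _gauss_kernel(sd_samples)
    out = np.empty_like(x, dtype=float)
    # renormalize by the kernel mass actually inside the signal at each edge
    norm = np.convolve(np.ones(x.shape[1]), k, mode="same")
    for i in range(x.shape[0]):
        out[i] = np.convolve(x[i], k, mode="same") / norm
    return out


def smooth_rates(obj, kernel_sd: float = 20.0):
    """Smooth rates or trials with a Gaussian kernel of ``kernel_sd`` ms.

    Spike-indicator trials are converted to firing rates in spikes/s (each
    spike contributes a unit-area kernel, scaled by 1000 ms/s).
    """
    if kernel_sd <= 0:
        raise ValueError("kernel_sd must be positive")
    if isinstance(obj, PopulationRates):
        sd = kernel_sd / obj.time_step
        out = obj.copy()
        out.values = [_smooth_matrix(v, sd) for v in out.values]
        return out
    if isinstance(obj, TrialSet):
        sd = kernel_sd / obj.time_step
        trials = []
        for tr in obj.trials:
            sm = _smooth_matrix(tr.traces, sd)
            if tr.is_spikes:
                sm = sm * (1000.0 / obj.time_step)  # counts/bin -> spikes/s
            trials.append(
                Trial(
                    traces=sm,
                    duration=tr.duration,
                    position=tr.position,
                    speed_bin=tr.speed_bin,
                    is_spikes=False,
                    spike_times=tr.spike_times,
                )
            )
        return TrialSet(trials, time_step=obj.time_step, meta=dict(obj.meta))
    raise TypeError("expected PopulationRates or TrialSet")


def _hat_basis(t: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Piecewise-linear (hat function) design matrix: t × knots."""
    basis = np.zeros((t.size, knots.size))
    for j, kj in enumerate(knots):
        left = knots[j - 1] if j > 0 else kj
        right = knots[j + 1] if j < knots.size - 1 else kj
        basis[:, j] = np.clip(
            np.where(
                t <= kj,
                1.0 if left == kj else (t - left) / (kj - left),
                1.0 if right == kj else (right - t) / (right - kj),
            ),
            0.0,
            1.0,
        )
    return basis


def _fit_monotone_warp(
    exact_map: np.ndarray, t: np.ndarray, knot_ms: float
) -> np.ndarray:
    """Least-squares monotone piecewise-linear fit of a time map.

    The warp family has knots every ``knot_ms`` ms; monotonicity is enforced
    by a running maximum on the fitted knot values (time never inverts).
    """
    n_seg = max(int(np.ceil(t[-1] / knot_ms)), 1)
    knots = np.linspace(0, t[-1], n_seg + 1)
    basis = _hat_basis(t, knots)
    coef, *_ = np.linalg.lstsq(basis, exact_map, rcond=None)
    coef = np.maximum.accumulate(coef)
    return basis @ coef


def align_and_average(
    trials: TrialSet,
    max_scale: float = 0.15,
    target: str | float = "median",
    warp_knot_ms: float = 100.0,
) -> tuple[PopulationRates, list[np.ndarray], dict]:
    """Two-stage trial alignment, then trial averaging.

    Stage 1 uniformly rescales every trial's time base to the target duration
    (per speed bin: the median duration, or a fixed value), discarding trials
    whose required scale factor departs from 1 by more than ``max_scale``.
    Stage 2 applies an adaptive monotone piecewise-linear warp per trial so
    its position trace best matches the across-trial mean position.  Values
    are only re-timed, never rescaled in magnitude.

    Returns the trial-averaged rates, per-speed SEM arrays, and a report with
    per-speed exclusion counts.
    """
    dt = trials.time_step
    values, sems = [], []
    report: dict = {"excluded": {}, "n_used": {}}
    speed_bins = trials.speed_bins
    for s in speed_bins:
        group = trials.by_speed(s)
        if len(group) < 2:
            raise ValueError(f"need >= 2 trials in speed bin {s}")
        durations = np.array([tr.duration for tr in group])
        tgt = float(np.median(durations)) if target == "median" else float(target)
        scales = tgt / durations
        keep = np.abs(scales - 1) <= max_scale
        report["excluded"][s] = int((~keep).sum())
        kept = [tr for tr, k in zip(group, keep) if k]
        if not kept:
            raise ValueError(f"all trials excluded in speed bin {s}")
        report["n_used"][s] = len(kept)

        n_out = int(round(tgt / dt))
        t_out = np.arange(n_out) * dt
        # stage 1: uniform rescale by resampling on normalized time
        rescaled_traces, rescaled_pos = [], []
        for tr in kept:
            t_src = np.arange(tr.traces.shape[1]) * dt
            frac = t_out / tgt * tr.duration  # matching normalized time
            rescaled_traces.append(
                np.stack([np.interp(frac, t_src, row) for row in tr.traces])
            )
            rescaled_pos.append(np.interp(frac, t_src, tr.position))
        mean_pos = np.mean(rescaled_pos, axis=0)

        # stage 2: adaptive monotone warp aligning position to the mean
        aligned = []
        for traces, pos in zip(rescaled_traces, rescaled_pos):
            pos_mono = np.maximum.accumulate(pos)
            exact = np.interp(mean_pos, pos_mono, t_out)  # desired source time
            warp = _fit_monotone_warp(exact, t_out, warp_knot_ms)
            aligned.append(
                np.stack([np.interp(warp, t_out, row) for row in traces])
            )
        stack = np.stack(aligned)
        values.append(stack.mean(axis=0))
        sems.append(stack.std(axis=0, ddof=1) / np.sqrt(stack.shape[0]))
    rates = PopulationRates(
        values, time_step=dt, speed_bins=speed_bins, kind="neural",
        meta={"alignment": report},
    )
    return rates, sems, report


def pca(
    rates: PopulationRates,
    scope: str | int = "global",
    n_components: int | None = None,
) -> FactorProjection:
    """PCA over the stated scope (one speed bin, or all bins pooled).

    Rows (units) are mean-centered over the scope before decomposition; the
    basis comes from the covariance's leading eigenvectors.  Each basis
    vector's largest-magnitude coefficient is made positive so outputs are
    deterministic.  ``variance_explained`` is the fraction of *total* variance
    per retained component.
    """
    if scope == "global":
        x = rates.pooled()
        per_speed = rates.values
        speed_bins = list(rates.speed_bins)
        scope_label = "global"
    else:
        s = int(scope)
        x = rates.values[s]
        per_speed = [rates.values[s]]
        speed_bins = [rates.speed_bins[s]]
        scope_label = f"per_speed:{s}"
    n_max = min(x.shape[0], x.shape[1])
    k = n_max if n_components is None else int(n_components)
    if k > n_max:
        raise ValueError(f"n_components={k} exceeds min(units, samples)={n_max}")
    mean = x.mean(axis=1)
    xc = x - mean[:, None]
    total_var = np.sum(xc**2)
    if total_var == 0:
        raise ValueError("degenerate input: zero variance over scope")
    u, sv, _ = np.linalg.svd(xc, full_matrices=False)
    basis = u[:, :k]
    # sign convention: largest-magnitude coefficient positive
    flip = np.sign(basis[np.argmax(np.abs(basis), axis=0), np.arange(k)])
    basis = basis * flip
    var_frac = sv[:k] ** 2 / total_var
    projected = [basis.T @ (v - mean[:, None]) for v in per_speed]
    return FactorProjection(
        basis=basis,
        projected=projected,
        mean_vector=mean,
        variance_explained=var_frac,
        scope=scope_label,
        time_step=rates.time_step,
        speed_bins=speed_bins,
    )
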