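"""Synthetic inputs for the pipeline.

Four generators cover everything the analyses consume:

* multi-speed periodic "muscle factor" targets (harmonically rich, hence
  non-elliptical trajectories) that serve as network training targets;
* a ground-truth "neural-like" population built from stacked elliptical limit
  cycles translated along a speed axis and tilted into speed-specific
  dimensions, with low-variance output-encoding dimensions — the motif whose
  recovery the geometry metrics are tested against;
* inhomogeneous-Poisson spike trains simulated from rates by thinning;
* trials with uniform time-base scaling plus smooth monotone warps, for
  exercising trial alignment.

All generators are deterministic given their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datatypes import PopulationRates, Trial, TrialSet

__all__ = [
    "MuscleFactorSpec",
    "StackedEllipseSpec",
    "generate_muscle_factors",
    "evaluate_factors",
    "generate_stacked_population",
    "simulate_spike_trains",
    "generate_jittered_trials",
]


def _default_freqs() -> tuple[float, ...]:
    # eight bins spanning ~0.8-2.1 Hz at ~0.2 Hz spacing
    return tuple(np.round(np.linspace(0.8, 2.1, 8), 4))


@dataclass
class MuscleFactorSpec:
    """Defines multi-speed periodic muscle-factor targets.

    Each factor is a sum of harmonics of the speed bin's base frequency with
    per-factor harmonic amplitudes and random (seeded) phases, so factor pairs
    are generically in quadrature and trajectories are non-elliptical whenever
    a harmonic >= 2 is present.  Two properties of real muscle activity are
    emulated across speeds: amplitude grows linearly with speed bin at
    fractional rate ``amp_slope``, and the temporal *pattern* changes — each
    harmonic's phase drifts with speed bin (seeded per-harmonic drift rates
    of SD ``phase_slope`` rad/bin, deliberately not proportional to harmonic
    order, since a proportional drift would only time-shift the waveform).
    """

    n_factors: int = 6
    n_speeds: int = 8
    base_freqs: tuple[float, ...] = field(default_factory=_default_freqs)
    harmonic_amps: tuple[float, ...] = (1.0, 0.4, 0.15)
    amp_slope: float = 0.05
    phase_slope: float = 0.05
    samples_per_ms: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.base_freqs = tuple(float(f) for f in self.base_freqs)
        if len(self.base_freqs) != self.n_speeds:
            raise ValueError("base_freqs must have one entry per speed bin")
        if np.any(np.diff(self.base_freqs) <= 0):
            raise ValueError("base_freqs must be strictly increasing")
        if self.n_factors < 2:
            raise ValueError("need at least two factors")

    def phases(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-(factor, harmonic) phase offsets and per-bin drift rates,
        drawn once at seed time."""
        rng = np.random.default_rng(self.seed)
        shape = (self.n_factors, len(self.harmonic_amps))
        base = rng.uniform(0, 2 * np.pi, size=shape)
        drift = rng.normal(0, self.phase_slope, size=shape)
        return base, drift

    def period_ms(self, s: int) -> float:
        return 1000.0 / self.base_freqs[s]


def evaluate_factors(spec: MuscleFactorSpec, s: int, times_ms: np.ndarray) -> np.ndarray:
    """Evaluate the speed-``s`` factor signals at arbitrary times (ms).

    This is the tiling helper: because factors are closed-form harmonic sums,
    any number of cycles can be produced exactly by evaluating at the desired
    times rather than by resampling a stored cycle.
    """
    if not 0 <= s < spec.n_speeds:
        raise ValueError(f"speed bin {s} out of range")
    t = np.asarray(times_ms, dtype=float)
    f = spec.base_freqs[s] / 1000.0  # cycles per ms
    amp = 1.0 + spec.amp_slope * s
    base, drift = spec.phases()
    phases = base + drift * s
    out = np.zeros((spec.n_factors, t.size))
    for h, a_h in enumerate(spec.harmonic_amps, start=1):
        if a_h == 0:
            continue
        arg = 2 * np.pi * h * f * t[None, :] + phases[:, h - 1][:, None]
        out += a_h * np.sin(arg)
    return amp * out


def generate_muscle_factors(spec: MuscleFactorSpec) -> PopulationRates:
    """One full cycle of the factor signals per speed bin.

    Returns a :class:`PopulationRates` of kind ``"muscle"`` whose per-speed
    duration is one period (rounded to the sampling grid).  The spec is kept
    in ``meta["spec"]`` so downstream code can tile arbitrarily many cycles
    via :func:`evaluate_factors`.
    """
    dt = 1.0 / spec.samples_per_ms
    values = []
    for s in range(spec.n_speeds):
        n = int(round(spec.period_ms(s) / dt))
        t = np.arange(n) * dt
        values.append(evaluate_factors(spec, s, t))
    return PopulationRates(
        values,
        time_step=dt,
        speed_bins=list(spec.base_freqs),
        kind="muscle",
        meta={"spec": spec},
    )


@dataclass
class StackedEllipseSpec:
    """Ground-truth stacked-elliptical population.

    Latent structure per speed bin ``s`` (0-indexed):

    * a planar ellipse of radius ``ellipse_radius`` whose plane is rotated by
      ``tilt_per_bin * s`` radians into a tilt dimension, and whose minor
      axis shrinks by ``eccentricity_slope`` per bin (eccentricity changes
      modestly across speeds, as it does in recorded populations);
    * a constant offset ``speed_axis_gap * s`` along a speed axis orthogonal
      to every ellipse plane;
    * low-variance copies of supplied output factors, scaled by
      ``output_dim_amp``, in further orthogonal dimensions.

    Unit rates are an orthonormal random readout of these latents plus
    Gaussian noise, shifted per unit to be non-negative (an offset, not a
    clip, so the geometry is preserved).
    """

    n_units: int = 50
    ellipse_radius: float = 20.0
    speed_axis_gap: float = 4.0
    tilt_per_bin: float = 0.06
    eccentricity_slope: float = 0.03
    output_dim_amp: float = 3.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed_axis_gap < 0:
            raise ValueError("speed_axis_gap must be >= 0")
        if not 0 <= self.tilt_per_bin < np.pi / 2:
            raise ValueError("tilt_per_bin must lie in [0, pi/2)")
        if not 0 <= self.eccentricity_slope < 1:
            raise ValueError("eccentricity_slope must lie in [0, 1)")
        if self.n_units < 5:
            raise ValueError("need at least 5 units")


def generate_stacked_population(
    spec: StackedEllipseSpec, factors: PopulationRates
) -> PopulationRates:
    """Embed stacked elliptical latents plus output factors into unit rates."""
    n_factors = factors.n_units
    n_latent = 4 + n_factors
    if n_latent > spec.n_units:
        raise ValueError(
            f"latent dimension {n_latent} exceeds n_units={spec.n_units}"
        )
    rng = np.random.default_rng(spec.seed)
    # orthonormal readout: latent geometry appears isometrically in rate space
    w, _ = np.linalg.qr(rng.standard_normal((spec.n_units, n_latent)))
    w *= np.sign(np.sum(w, axis=0))  # deterministic sign convention

    values = []
    for s in range(factors.n_speeds):
        fac = factors.values[s]
        n = fac.shape[1]
        theta = 2 * np.pi * np.arange(n) / n
        alpha = spec.tilt_per_bin * s
        minor = spec.ellipse_radius * (1.0 - spec.eccentricity_slope * s)
        latent = np.zeros((n_latent, n))
        latent[0] = spec.ellipse_radius * np.cos(theta)
        latent[1] = minor * np.cos(alpha) * np.sin(theta)
        latent[2] = spec.speed_axis_gap * s  # speed-axis translation
        latent[3] = minor * np.sin(alpha) * np.sin(theta)
        latent[4:] = spec.output_dim_amp * fac
        x = w @ latent
        if spec.noise_sd > 0:
            x = x + spec.noise_sd * rng.standard_normal(x.shape)
        values.append(x)

    # per-unit offset to enforce non-negative rates without clipping
    global_min = np.min(np.concatenate(values, axis=1), axis=1)
    offset = np.where(global_min < 0, -global_min, 0.0)
    values = [v + offset[:, None] for v in values]
    return PopulationRates(
        values,
        time_step=factors.time_step,
        speed_bins=list(factors.speed_bins),
        kind="neural",
        meta={"spec": spec, "readout": w, "offset": offset},
    )


def _thin_one_unit(
    rate: np.ndarray, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Thinning: spike times (ms) of an inhomogeneous Poisson process.

    Candidate events are drawn from a homogeneous process at the rate's upper
    bound; each candidate at time ``t`` is kept with probability
    ``rate(t) / bound``.
    """
    lam_max = float(rate.max())
    duration = rate.size * dt
    if lam_max <= 0:
        return np.empty(0)
    # expected count + slack, then trim to duration
    n_cand = rng.poisson(lam_max * duration / 1000.0)
    cand = np.sort(rng.uniform(0, duration, size=n_cand))
    lam = np.interp(cand, np.arange(rate.size) * dt, rate)
    keep = rng.uniform(0, lam_max, size=cand.size) < lam
    return cand[keep]


def simulate_spike_trains(
    rates: PopulationRates, n_trials: int, seed: int
) -> TrialSet:
    """Simulate spike trains from rates by the thinning method.

    Each speed bin yields ``n_trials`` independent trials; the trial's rate
    profile is the (bounded, non-negative) population rate for that speed,
    treated as the conditional intensity in spikes/s.
    """
    for v in rates.values:
        if np.any(v < 0):
            raise ValueError("rates must be non-negative for thinning")
    rng = np.random.default_rng(seed)
    dt = rates.time_step
    trials = []
    for s, v in enumerate(rates.values):
        n_t = v.shape[1]
        duration = n_t * dt
        phase = 2 * np.pi * np.arange(n_t) * dt / duration
        for _ in range(n_trials):
            indicator = np.zeros((rates.n_units, n_t))
            times = []
            for u in range(rates.n_units):
                st = _thin_one_unit(v[u], dt, rng)
                times.append(st)
                idx = np.minimum((st / dt).astype(int), n_t - 1)
                np.add.at(indicator[u], idx, 1.0)
            trials.append(
                Trial(
                    traces=indicator,
                    duration=duration,
                    position=phase,
                    speed_bin=s,
                    is_spikes=True,
                    spike_times=times,
                )
            )
    return TrialSet(trials, time_step=dt, meta={"seed": seed, "n_trials": n_trials})


def _monotone_warp(
    duration: float, warp_sd: float, knot_ms: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """A smooth monotone warp of [0, duration] onto itself.

    Knot increments are drawn lognormally with relative SD ``warp_sd`` and
    renormalized so endpoints are fixed; positivity of increments guarantees
    monotonicity.
    """
    n_seg = max(int(np.ceil(duration / knot_ms)), 2)
    knots = np.linspace(0, duration, n_seg + 1)
    if warp_sd <= 0:
        return knots, knots.copy()
    sigma = np.sqrt(np.log1p(warp_sd**2))
    inc = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n_seg)
    warped = np.concatenate([[0.0], np.cumsum(inc)])
    warped *= duration / warped[-1]
    return knots, warped


def generate_jittered_trials(
    rates: PopulationRates,
    scale_range: float,
    warp_sd: float,
    n_trials: int,
    seed: int,
    knot_ms: float = 100.0,
) -> TrialSet:
    """Trials whose time base is uniformly scaled and smoothly warped.

    Each trial's duration is the source duration times a factor drawn from
    ``U[1 - scale_range, 1 + scale_range]``; on top of that a monotone warp
    with relative knot-increment SD ``warp_sd`` re-times the trace.  The
    per-trial position (phase) trace is warped identically, so alignment code
    can recover the warp from position alone.
    """
    if scale_range < 0:
        raise ValueError("scale_range must be >= 0")
    rng = np.random.default_rng(seed)
    dt = rates.time_step
    trials = []
    for s, v in enumerate(rates.values):
        n_t = v.shape[1]
        src_dur = n_t * dt
        src_t = np.arange(n_t) * dt
        src_phase = 2 * np.pi * src_t / src_dur
        for _ in range(n_trials):
            scale = rng.uniform(1 - scale_range, 1 + scale_range)
            dur = src_dur * scale
            n_out = max(int(round(dur / dt)), 2)
            t_out = np.arange(n_out) * dt
            # map trial time -> source time: uniform descale then warp
            knots, warped = _monotone_warp(src_dur, warp_sd, knot_ms, rng)
            src_times = np.interp(t_out / scale, knots, warped)
            traces = np.empty((rates.n_units, n_out))
            for u in range(rates.n_units):
                traces[u] = np.interp(src_times, src_t, v[u])
            position = np.interp(src_times, src_t, src_phase)
            trials.append(
                Trial(
                    traces=traces,
                    duration=dur,
                    position=position,
                    speed_bin=s,
                    is_spikes=False,
                )
            )
    return TrialSet(trials, time_step=dt, meta={"seed": seed})
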