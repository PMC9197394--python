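"""Reverse-engineering trained networks.

Trained networks are interrogated three ways: perturbation probes verify
that each speed's trajectory is a stable input-dependent limit cycle;
designed perturbations dissociate the rhythm-generating elliptical plane
from the (nearly orthogonal) muscle-readout dimensions; and input sweeps
and ramps show that the solution interpolates continuously between trained
speeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import PopulationRates
from .preprocess import pca
from .rnn import InputProtocol, RNNParams, simulate

__all__ = [
    "fundamental_period",
    "probe_limit_cycle",
    "design_perturbations",
    "phase_of_state",
    "phase_shift_after_perturbation",
    "sweep_inputs",
    "instantaneous_frequency",
]


def fundamental_period(signal: np.ndarray, dt: float = 1.0) -> float:
    """Fundamental period (same units as ``dt``) via the autocorrelation peak.

    ``signal`` may be 1-D or (channels, T); channel autocorrelations are
    summed before peak-picking, and the peak lag is refined by parabolic
    interpolation.
    """
    x = np.atleast_2d(np.asarray(signal, dtype=float))
    x = x - x.mean(axis=1, keepdims=True)
    T = x.shape[1]
    ac = np.zeros(T)
    for row in x:
        ac += np.correlate(row, row, mode="full")[T - 1:]
    # skip the zero-lag peak: start after the first non-positive value
    neg = np.flatnonzero(ac <= 0)
    if neg.size == 0:
        raise ValueError("no periodicity detected (autocorrelation never dips)")
    start = neg[0]
    lag = start + int(np.argmax(ac[start:]))
    if lag <= 0 or lag >= T - 1 or ac[lag] <= 0:
        raise ValueError("no interior autocorrelation peak found")
    # parabolic refinement
    y0, y1, y2 = ac[lag - 1], ac[lag], ac[lag + 1]
    denom = y0 - 2 * y1 + y2
    frac = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    return (lag + frac) * dt


def _settled_rollout(
    params: RNNParams,
    protocol: InputProtocol,
    condition: int,
    amplitude: float | None,
    total_steps: int,
):
    """Rollout with the input held on from step 0 through the full horizon."""
    return simulate(
        params, protocol, condition,
        total_steps=total_steps, off_step=total_steps, amplitude=amplitude,
    )


def _nominal_cycle_states(
    params: RNNParams,
    protocol: InputProtocol,
    condition: int,
    settle_steps: int = 1500,
) -> tuple[np.ndarray, float]:
    """Settled states on the limit cycle (n_units × samples) and the period
    in steps."""
    rec = _settled_rollout(params, protocol, condition, None, settle_steps + 1500)
    tail = rec.states[:, settle_steps:]
    period = fundamental_period(tail, dt=1.0)
    n_keep = int(round(2 * period))
    return tail[:, -n_keep:], period


@dataclass
class ProbeReport:
    terminal_distances: np.ndarray
    cycle_radius: float
    max_relative_distance: float
    condition: int

    @property
    def converged(self) -> bool:
        return self.max_relative_distance < 0.05


def probe_limit_cycle(
    params: RNNParams,
    protocol: InputProtocol,
    condition: int,
    n_probes: int = 20,
    horizon_steps: int = 2000,
    seed: int = 0,
    probe_magnitude: float = 0.1,
) -> ProbeReport:
    """Perturb the state off the limit cycle and verify it returns.

    Each probe displaces the settled state by a random vector in the
    condition's top-2 PC plane with plane coefficients drawn from
    ``U[-probe_magnitude, probe_magnitude]``, rolls out ``horizon_steps``
    with the input held on, and reports the terminal distance to the nominal
    cycle (minimum over all cycle phases, full state space), relative to the
    cycle radius.
    """
    cycle, _ = _nominal_cycle_states(params, protocol, condition)
    center = cycle.mean(axis=1, keepdims=True)
    radius = float(np.sqrt(np.mean(np.sum((cycle - center) ** 2, axis=0))))
    basis = _top2_basis(cycle)
    rng = np.random.default_rng(seed)
    dists = np.empty(n_probes)
    u_amp = protocol.amplitude(condition)
    for i in range(n_probes):
        coef = rng.uniform(-probe_magnitude, probe_magnitude, size=2)
        start = cycle[:, int(rng.integers(cycle.shape[1]))] + basis @ coef
        rec = simulate(
            params, protocol, condition,
            total_steps=horizon_steps, off_step=horizon_steps,
            initial_state=start,
        )
        end = rec.states[:, -1][:, None]
        dists[i] = np.sqrt(np.sum((cycle - end) ** 2, axis=0).min())
    return ProbeReport(
        terminal_distances=dists,
        cycle_radius=radius,
        max_relative_distance=float(dists.max() / radius),
        condition=condition,
    )


def _top2_basis(states: np.ndarray) -> np.ndarray:
    rates = PopulationRates([states], time_step=1.0, speed_bins=[0], kind="network")
    return pca(rates, scope=0, n_components=2).basis


def design_perturbations(
    params: RNNParams,
    protocol: InputProtocol,
    condition: int,
    readout_row: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Unit-norm rhythm- and muscle-generation perturbation vectors.

    The rhythm vector is exactly orthogonal to every readout row of C and,
    within that null space, has maximal projection onto the condition's
    top-2 PC plane (so it strongly impacts the elliptical trajectory while
    leaving the output untouched at the instant of perturbation).  The
    muscle vector is the chosen readout row's component orthogonal to the
    top-2 plane (so it jolts the output while leaving the dominant plane
    initially unchanged).
    """
    cycle, _ = _nominal_cycle_states(params, protocol, condition)
    q = _top2_basis(cycle)  # n × 2
    c = params.C
    # null space of the readout
    _, sv, vt = np.linalg.svd(c)
    rank = int(np.sum(sv > 1e-10 * sv[0]))
    null_basis = vt[rank:].T  # n × (n - rank)
    if null_basis.shape[1] == 0:
        raise ValueError("readout rowspace spans the full state space")
    overlap = q.T @ null_basis  # 2 × (n - rank)
    u, s_ov, vt_ov = np.linalg.svd(overlap, full_matrices=False)
    if s_ov[0] < 1e-8:
        raise ValueError("top-2 plane lies entirely in the readout rowspace")
    rhythm = null_basis @ vt_ov[0]
    rhythm /= np.linalg.norm(rhythm)

    row = c[readout_row]
    muscle = row - q @ (q.T @ row)
    nrm = np.linalg.norm(muscle)
    if nrm < 1e-10 * np.linalg.norm(row):
        raise ValueError("readout row lies entirely in the top-2 plane")
    muscle = muscle / nrm
    return rhythm, muscle


def phase_of_state(
    trajectory: np.ndarray, top2_basis: np.ndarray, center: np.ndarray | None = None
) -> tuple[np.ndarray, bool]:
    """Unwrapped angle of the mean-centered top-2 projection over time.

    Returns ``(phase, defined)``; ``defined`` is False when the planar radius
    is ever negligible relative to its mean (the phase is then unreliable).
    """
    proj = top2_basis.T @ trajectory
    if center is None:
        proj = proj - proj.mean(axis=1, keepdims=True)
    else:
        proj = proj - (top2_basis.T @ center)[:, None]
    radius = np.linalg.norm(proj, axis=0)
    defined = bool(radius.min() > 0.05 * radius.mean())
    phase = np.unwrap(np.arctan2(proj[1], proj[0]))
    return phase, defined


def phase_shift_after_perturbation(
    params: RNNParams,
    protocol: InputProtocol,
    condition: int,
    perturbation: np.ndarray,
    n_cycles_after: int = 3,
    settle_steps: int = 1500,
) -> float:
    """Persistent phase shift (radians) a perturbation leaves after settling.

    Runs matched perturbed and unperturbed rollouts from the same settled
    state and measures the difference in unwrapped planar phase
    ``n_cycles_after`` cycles after the perturbation.
    """
    cycle, period = _nominal_cycle_states(params, protocol, condition, settle_steps)
    basis = _top2_basis(cycle)
    horizon = settle_steps + int(round((n_cycles_after + 1) * period))
    base = simulate(params, protocol, condition,
                    total_steps=horizon, off_step=horizon)
    pert = simulate(params, protocol, condition,
                    total_steps=horizon, off_step=horizon,
                    state_offset=perturbation, offset_step=settle_steps)
    t_meas = settle_steps + int(round(n_cycles_after * period))
    ph_base, ok1 = phase_of_state(base.states[:, settle_steps:], basis)
    ph_pert, ok2 = phase_of_state(pert.states[:, settle_steps:], basis)
    if not (ok1 and ok2):
        raise ValueError("phase undefined: trajectory collapses in the plane")
    i = t_meas - settle_steps
    delta = ph_pert[i] - ph_base[i]
    return float((delta + np.pi) % (2 * np.pi) - np.pi)


def sweep_inputs(
    params: RNNParams,
    protocol: InputProtocol,
    amplitudes: np.ndarray,
    total_steps: int = 3000,
    settle_steps: int = 1500,
    warn_outside: tuple[float, float] | None = None,
) -> np.ndarray:
    """Output fundamental frequency (Hz) for each static input amplitude."""
    import warnings

    freqs = np.empty(len(amplitudes))
    for i, a in enumerate(np.asarray(amplitudes, dtype=float)):
        if warn_outside is not None and not warn_outside[0] <= a <= warn_outside[1]:
            warnings.warn(f"amplitude {a} outside trained range {warn_outside}")
        rec = _settled_rollout(params, protocol, 1, a, total_steps)
        tail = rec.outputs[:, settle_steps:]
        try:
            freqs[i] = 1000.0 / fundamental_period(tail, dt=params.dt)
        except ValueError:
            freqs[i] = np.nan  # no rhythm at this amplitude (e.g. saturated)
    return freqs


def instantaneous_frequency(
    trajectory: np.ndarray,
    top2_basis: np.ndarray,
    dt_ms: float,
    window_steps: int = 100,
) -> np.ndarray:
    """Instantaneous cycling frequency (Hz) from the planar phase slope.

    ``trajectory`` (units × T) should cover only the cycling portion of a
    rollout — transients and silent periods shift the planar center and
    corrupt the phase.  The unwrapped phase of the top-2 projection is
    differentiated with a centered sliding-window linear fit of
    ``window_steps`` samples.
    """
    phase, ok = phase_of_state(trajectory, top2_basis)
    if not ok:
        raise ValueError("phase undefined for this trajectory")
    dt_s = dt_ms / 1000.0
    half = window_steps // 2
    out = np.full(phase.size, np.nan)
    t = np.arange(phase.size) * dt_s
    for i in range(half, phase.size - half):
        sl = slice(i - half, i + half + 1)
        slope = np.polyfit(t[sl], phase[sl], 1)[0]
        out[i] = abs(slope) / (2 * np.pi)
    return out
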