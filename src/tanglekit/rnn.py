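"""Continuous-time recurrent network trained to produce multi-speed targets.

Dynamics (one discrete update per timestep ``dt``)::

    r(t+dt) = r(t) + (1/tau) * (-r(t) + A f(r(t)) + B u(t) + b)
    y(t)    = C f(r(t)) + d_out,       f = tanh

A static input whose amplitude grades linearly with the commanded speed bin
(``a = 0.5 + 0.5 (c-1)/8``) instructs the network which speed's periodic
factor pattern to emit.  Training minimizes the mean squared error between
output and target by backpropagation through time with an Adam optimizer,
over trials whose cycling span varies from trial to trial (the input turns
off at a uniformly drawn step), which discourages non-periodic solutions.
Success is defined as normalized MSE < 0.01 (R^2 > 0.99), normalized by the
pooled variance of the target.

Gradients and the optimizer are implemented directly in NumPy; the network
is small (50 units) so dense full-batch updates over the eight conditions
are fast.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numba import njit

from .datatypes import PopulationRates
from .synthetic import MuscleFactorSpec, evaluate_factors

__all__ = [
    "RNNParams",
    "InputProtocol",
    "TrainConfig",
    "TrajectoryRecord",
    "step",
    "readout",
    "make_input",
    "make_target",
    "train",
    "simulate",
    "extract_steady_cycle",
]

SUCCESS_NMSE = 0.01


@dataclass
class RNNParams:
    """Weights and timing constants of the rate network."""

    A: np.ndarray  # recurrent weights (n, n)
    B: np.ndarray  # input weights (n, k)
    b: np.ndarray  # unit bias (n,)
    C: np.ndarray  # readout weights (p, n)
    d_out: np.ndarray  # readout bias (p,)
    tau: float = 10.0  # in timesteps
    dt: float = 4.0  # ms

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError("tau must be >= 1 timestep")
        for w in (self.A, self.B, self.b, self.C, self.d_out):
            if not np.all(np.isfinite(w)):
                raise ValueError("non-finite weights")

    @property
    def n_units(self) -> int:
        return self.A.shape[0]

    @property
    def n_outputs(self) -> int:
        return self.C.shape[0]

    @staticmethod
    def initialize(
        n_units: int,
        n_inputs: int,
        n_outputs: int,
        seed: int,
        spectral_radius: float = 1.0,
        dt: float = 4.0,
        tau: float = 10.0,
    ) -> "RNNParams":
        """Random initialization with the recurrent matrix scaled to a target
        spectral radius (the regime in which rhythmic tasks are learnable)."""
        rng = np.random.default_rng(seed)
        A = rng.standard_normal((n_units, n_units)) / np.sqrt(n_units)
        radius = np.max(np.abs(np.linalg.eigvals(A)))
        A *= spectral_radius / radius
        B = rng.standard_normal((n_units, n_inputs)) / np.sqrt(n_inputs)
        C = rng.standard_normal((n_outputs, n_units)) * 0.01
        return RNNParams(
            A=A, B=B, b=np.zeros(n_units), C=C, d_out=np.zeros(n_outputs),
            tau=tau, dt=dt,
        )


@dataclass
class InputProtocol:
    """How conditions are communicated to the network.

    ``graded``: a single static channel of amplitude ``0.5 + 0.5 (c-1)/8``.
    ``one_hot``: an ``n_speeds``-dimensional indicator with the same timing.
    ``feedback``: the graded channel concatenated with delayed, gain-scaled
    copies of the output factors.

    Timing follows the trial template: input off for the first 2/5 of the
    trial, on until an off step drawn uniformly from the [3/4, 19/20] span
    (with a 2000-step trial: on at 800, off ~ U[1500, 1900]); all timing
    constants scale proportionally with ``total_steps``.
    """

    mode: str = "graded"
    n_speeds: int = 8
    total_steps: int = 2000
    on_step: int | None = None
    off_range: tuple[int, int] | None = None
    noise_var: float = 0.0
    feedback_delay: float = 60.0  # ms
    feedback_gain: float = 0.1

    def __post_init__(self) -> None:
        if self.mode not in ("graded", "one_hot", "feedback"):
            raise ValueError(f"unknown input mode {self.mode!r}")

    def timing(self, total_steps: int | None = None) -> tuple[int, int, int]:
        """(on_step, off_lo, off_hi) scaled to ``total_steps``."""
        ts = self.total_steps if total_steps is None else total_steps
        scale = ts / 2000.0
        on = int(round(800 * scale)) if self.on_step is None else self.on_step
        if self.off_range is None:
            lo, hi = int(round(1500 * scale)), int(round(1900 * scale))
        else:
            lo, hi = self.off_range
        return on, lo, hi

    @property
    def n_channels(self) -> int:
        if self.mode == "graded":
            return 1
        if self.mode == "one_hot":
            return self.n_speeds
        return 1 + 6  # graded channel + 6 factor-feedback channels

    def amplitude(self, condition: int) -> float:
        """Graded amplitude law a(c) = 0.5 + 0.5 (c-1)/8, c in 1..n_speeds."""
        if not 1 <= condition <= self.n_speeds:
            raise ValueError(f"condition {condition} out of 1..{self.n_speeds}")
        return 0.5 + 0.5 * (condition - 1) / self.n_speeds


@dataclass
class TrajectoryRecord:
    """Full rollout: state, firing rate, output, and input per timestep."""

    states: np.ndarray  # n_units × T (pre-nonlinearity)
    firing: np.ndarray  # n_units × T (tanh of states)
    outputs: np.ndarray  # p × T
    inputs: np.ndarray  # k × T
    condition: int
    dt: float
    on_step: int
    off_step: int


def step(params: RNNParams, state: np.ndarray, input_vec: np.ndarray) -> np.ndarray:
    """One discrete update of the network state."""
    if not np.all(np.isfinite(state)):
        raise ValueError("non-finite state")
    f = np.tanh(state)
    return state + (
        -state + params.A @ f + params.B @ input_vec + params.b.reshape(state.shape[0], *([1] * (state.ndim - 1)))
    ) / params.tau


def readout(params: RNNParams, firing: np.ndarray) -> np.ndarray:
    """Linear readout of firing rates: y = C f(r) + d_out."""
    return params.C @ firing + params.d_out.reshape(params.n_outputs, *([1] * (firing.ndim - 1)))


def make_input(
    protocol: InputProtocol,
    condition: int,
    total_steps: int,
    seed: int | None = None,
    off_step: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, int, int]:
    """Input trace (k × T) for one condition, plus the on/off steps used.

    The off step is drawn uniformly from the protocol's range unless given
    explicitly.  Optional additive Gaussian noise (variance ``noise_var``)
    perturbs every channel at every step.
    """
    on, lo, hi = protocol.timing(total_steps)
    if rng is None:
        rng = np.random.default_rng(seed)
    if off_step is None:
        off_step = int(rng.integers(lo, hi + 1))
    u = np.zeros((protocol.n_channels, total_steps))
    if protocol.mode == "one_hot":
        u[condition - 1, on:off_step] = 1.0
    else:  # graded and feedback share the graded command channel
        u[0, on:off_step] = protocol.amplitude(condition)
    if protocol.noise_var > 0:
        u = u + rng.normal(0, np.sqrt(protocol.noise_var), size=u.shape)
    return u, on, off_step


def make_target(
    spec: MuscleFactorSpec,
    condition: int,
    total_steps: int,
    dt: float,
    on_step: int,
    off_step: int,
) -> np.ndarray:
    """Target output: zero while the input is off, the speed-specific factor
    cycle (tiled for as many cycles as fit) while it is on."""
    y = np.zeros((spec.n_factors, total_steps))
    t_on = (np.arange(on_step, off_step) - on_step) * dt
    y[:, on_step:off_step] = evaluate_factors(spec, condition - 1, t_on)
    return y


def _feedback_inputs(
    u: np.ndarray, y: np.ndarray, protocol: InputProtocol, dt: float
) -> np.ndarray:
    """Append delayed gain-scaled factor feedback channels to the input."""
    delay = max(int(round(protocol.feedback_delay / dt)), 1)
    fb = np.zeros((y.shape[0], u.shape[1]))
    fb[:, delay:] = protocol.feedback_gain * y[:, :-delay]
    return np.vstack([u, fb])


@dataclass
class TrainConfig:
    """Training hyperparameters; the task itself does not fix these."""

    max_iterations: int = 14000
    learning_rate: float = 2e-3
    clip_norm: float = 2.0
    total_steps: int = 2000
    check_every: int = 100
    target_nmse: float = SUCCESS_NMSE
    lr_milestones: tuple[tuple[int, float], ...] = ((3000, 0.3), (5500, 0.3))
    average_from: int | None = 9000
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8


@njit(cache=True)
def _fwd_recursion(A, drive_t, tau):  # pragma: no cover - exercised via _forward
    """Sequential state recursion, time-major layout (T, n, C)."""
    T, n, C = drive_t.shape
    phi_t = np.empty((T, n, C))
    state = np.zeros((n, C))
    inv_tau = 1.0 / tau
    leak = 1.0 - inv_tau
    for t in range(T):
        f = np.tanh(state)
        phi_t[t] = f
        state = leak * state + inv_tau * (np.dot(A, f) + drive_t[t])
    return phi_t


@njit(cache=True)
def _bwd_recursion(At, ce_t, gain_t, tau):  # pragma: no cover
    """Adjoint recursion g_t = leak g_{t+1} + gain_t (ce_t + A^T g_{t+1}/tau)."""
    T, n, C = ce_t.shape
    g_t = np.empty((T, n, C))
    g = np.zeros((n, C))
    inv_tau = 1.0 / tau
    leak = 1.0 - inv_tau
    for t in range(T - 1, -1, -1):
        g = leak * g + gain_t[t] * (ce_t[t] + inv_tau * np.dot(At, g))
        g_t[t] = g
    return g_t


def _forward(params: RNNParams, u: np.ndarray) -> np.ndarray:
    """Batched rollout.  ``u``: (k, T, C).  Returns phi = tanh(r): (n, T, C)."""
    n = params.n_units
    k, T, C = u.shape
    drive = (params.B @ u.reshape(k, -1)).reshape(n, T, C) + params.b[:, None, None]
    drive_t = np.ascontiguousarray(drive.transpose(1, 0, 2))
    phi_t = _fwd_recursion(params.A, drive_t, params.tau)
    return np.ascontiguousarray(phi_t.transpose(1, 0, 2))


def _loss_and_grads(params: RNNParams, u: np.ndarray, y_targ: np.ndarray):
    """MSE loss and gradients for all parameters via BPTT.

    ``u``: (k, T, C) inputs; ``y_targ``: (p, T, C) targets.
    """
    phi = _forward(params, u)
    n, T, C = phi.shape
    p = params.n_outputs
    y = (params.C @ phi.reshape(n, -1)).reshape(p, T, C) + params.d_out[:, None, None]
    err = y - y_targ
    n_terms = err.size
    loss = np.sum(err**2) / n_terms
    e = 2.0 * err / n_terms  # dL/dy

    inv_tau = 1.0 / params.tau
    At = params.A.T
    dC = e.reshape(p, -1) @ phi.reshape(n, -1).T
    dd = e.sum(axis=(1, 2))

    # backward recursion: g_t = dL/dr_t; the only sequential dependency is
    # the A^T g propagation, so everything else is hoisted out of the loop
    ce = (params.C.T @ e.reshape(p, -1)).reshape(n, T, C)  # C^T e, all steps
    ce_t = np.ascontiguousarray(ce.transpose(1, 0, 2))
    gain_t = np.ascontiguousarray((1.0 - phi**2).transpose(1, 0, 2))
    g_t = _bwd_recursion(np.ascontiguousarray(At), ce_t, gain_t, params.tau)
    g_arr = g_t.transpose(1, 0, 2)
    # the update r_{t+1} = leak r_t + (1/tau)(A phi_t + B u_t + b) pairs
    # g_{t+1} with phi_t / u_t
    gs = (inv_tau * g_arr[:, 1:]).reshape(n, -1)
    dA = gs @ phi[:, :-1].reshape(n, -1).T
    dB = gs @ u[:, :-1].reshape(u.shape[0], -1).T
    db = gs.reshape(n, -1).sum(axis=1)
    return loss, y, {"A": dA, "B": dB, "b": db, "C": dC, "d_out": dd}


def _nmse(y: np.ndarray, y_targ: np.ndarray) -> float:
    """MSE normalized by the pooled variance of the target."""
    var = np.var(y_targ)
    if var == 0:
        raise ValueError("target has zero variance")
    return float(np.mean((y - y_targ) ** 2) / var)


def _batch(
    spec: MuscleFactorSpec,
    protocol: InputProtocol,
    params: RNNParams,
    total_steps: int,
    rng: np.random.Generator | None,
    off_steps: list[int] | None = None,
):
    """Inputs and targets for all conditions, stacked condition-last."""
    us, ys = [], []
    n_speeds = protocol.n_speeds
    for c in range(1, n_speeds + 1):
        off = None if off_steps is None else off_steps[c - 1]
        u, on, off = make_input(protocol, c, total_steps, off_step=off, rng=rng)
        y = make_target(spec, c, total_steps, params.dt, on, off)
        if protocol.mode == "feedback":
            u = _feedback_inputs(u, y, protocol, params.dt)
        us.append(u)
        ys.append(y)
    return np.stack(us, axis=-1), np.stack(ys, axis=-1)


class _TrialSampler:
    """Draws training trials by truncating a precomputed max-span template.

    The input and target for off step ``n`` equal the template (input on
    through the latest possible off step) with everything from ``n`` onward
    zeroed, so per-iteration work is a copy plus a masked zeroing instead of
    re-evaluating the harmonic targets.
    """

    def __init__(self, spec, protocol, params, total_steps):
        _, self.lo, self.hi = protocol.timing(total_steps)
        self.protocol = protocol
        self.delay = max(int(round(protocol.feedback_delay / params.dt)), 1)
        quiet = replace(protocol, noise_var=0.0)
        self.u_full, self.y_full = _batch(
            spec, quiet, params, total_steps,
            rng=None, off_steps=[self.hi] * protocol.n_speeds,
        )

    def draw(self, rng: np.random.Generator):
        offs = rng.integers(self.lo, self.hi + 1, size=self.u_full.shape[-1])
        u = self.u_full.copy()
        y = self.y_full.copy()
        for c, off in enumerate(offs):
            y[:, off:, c] = 0.0
            if self.protocol.mode == "feedback":
                u[0, off:, c] = 0.0
                u[1:, off + self.delay:, c] = 0.0
            else:
                u[:, off:, c] = 0.0
        if self.protocol.noise_var > 0:
            u = u + rng.normal(0, np.sqrt(self.protocol.noise_var), size=u.shape)
        return u, y


def train(
    targets: PopulationRates,
    protocol: InputProtocol,
    config: TrainConfig | None = None,
    seed: int = 0,
    n_units: int = 50,
    initial_params: RNNParams | None = None,
) -> tuple[RNNParams, dict]:
    """Train the network on the supplied factor targets.

    ``targets`` must carry its generating :class:`MuscleFactorSpec` in
    ``meta["spec"]`` so the target cycle can be tiled exactly over the
    variable cycling span of each training trial.  Returns the trained
    parameters and a history dict with the loss trace and final NMSE.

    Because the off step is resampled every trial, late-stage gradients are
    noisy; from ``config.average_from`` iterations onward a running Polyak
    average of the parameters is maintained and evaluated alongside the raw
    iterate, and whichever converges first (or ends better) is returned.
    """
    if config is None:
        config = TrainConfig()
    spec: MuscleFactorSpec = targets.meta["spec"]
    rng = np.random.default_rng(seed)
    if initial_params is not None:
        params = replace(initial_params)
        for k in ("A", "B", "b", "C", "d_out"):
            setattr(params, k, getattr(initial_params, k).copy())
    else:
        params = RNNParams.initialize(
            n_units=n_units,
            n_inputs=(protocol.n_channels if protocol.mode != "feedback"
                      else 1 + spec.n_factors),
            n_outputs=spec.n_factors,
            seed=seed,
        )
    names = ["A", "B", "b", "C", "d_out"]
    m = {k: np.zeros_like(getattr(params, k)) for k in names}
    v = {k: np.zeros_like(getattr(params, k)) for k in names}
    lr = config.learning_rate
    b1, b2, eps = config.adam_beta1, config.adam_beta2, config.adam_eps

    # fixed evaluation trial: off at the middle of the off range
    _, lo, hi = protocol.timing(config.total_steps)
    eval_off = [(lo + hi) // 2] * protocol.n_speeds
    u_eval, y_eval = _batch(spec, replace(protocol, noise_var=0.0), params,
                            config.total_steps, None, eval_off)
    sampler = _TrialSampler(spec, protocol, params, config.total_steps)

    def eval_nmse(p: RNNParams) -> float:
        phi = _forward(p, u_eval)
        ne, Te, Ce = phi.shape
        y_out = (p.C @ phi.reshape(ne, -1)).reshape(
            p.n_outputs, Te, Ce) + p.d_out[:, None, None]
        return _nmse(y_out, y_eval)

    loss_trace, nmse_trace = [], []
    final_nmse = np.inf
    t_adam = 0
    avg = None
    n_avg = 0
    milestones = dict(config.lr_milestones)
    for it in range(config.max_iterations):
        if it in milestones:
            lr *= milestones[it]
        u, y_targ = sampler.draw(rng)
        loss, _, grads = _loss_and_grads(params, u, y_targ)
        if not np.isfinite(loss):
            raise FloatingPointError(f"training diverged at iteration {it}")
        loss_trace.append(loss)
        gnorm = np.sqrt(sum(np.sum(g**2) for g in grads.values()))
        if gnorm > config.clip_norm:
            grads = {k: g * (config.clip_norm / gnorm) for k, g in grads.items()}
        t_adam += 1
        for k in names:
            m[k] = b1 * m[k] + (1 - b1) * grads[k]
            v[k] = b2 * v[k] + (1 - b2) * grads[k] ** 2
            mhat = m[k] / (1 - b1**t_adam)
            vhat = v[k] / (1 - b2**t_adam)
            setattr(params, k, getattr(params, k) - lr * mhat / (np.sqrt(vhat) + eps))
        if config.average_from is not None and it >= config.average_from:
            n_avg += 1
            if avg is None:
                avg = {k: getattr(params, k).copy() for k in names}
            else:
                for k in names:
                    avg[k] += (getattr(params, k) - avg[k]) / n_avg
        if (it + 1) % config.check_every == 0 or it == config.max_iterations - 1:
            final_nmse = eval_nmse(params)
            if avg is not None:
                avg_params = replace(params)
                for k in names:
                    setattr(avg_params, k, avg[k].copy())
                avg_nmse = eval_nmse(avg_params)
                if avg_nmse < final_nmse:
                    final_nmse = avg_nmse
                    best_is_avg = True
                else:
                    best_is_avg = False
            else:
                best_is_avg = False
            nmse_trace.append((it + 1, final_nmse))
            if final_nmse < config.target_nmse:
                if best_is_avg:
                    params = avg_params
                break
    else:
        if avg is not None and nmse_trace and best_is_avg:
            params = avg_params
    history = {
        "loss": np.array(loss_trace),
        "nmse": nmse_trace,
        "final_nmse": final_nmse,
        "converged": final_nmse < config.target_nmse,
        "iterations": len(loss_trace),
        "seed": seed,
    }
    return params, history


def simulate(
    params: RNNParams,
    protocol: InputProtocol,
    condition: int,
    total_steps: int = 2000,
    seed: int | None = None,
    off_step: int | None = None,
    initial_state: np.ndarray | None = None,
    state_offset: np.ndarray | None = None,
    offset_step: int | None = None,
    amplitude: float | None = None,
    input_trace: np.ndarray | None = None,
    target_spec: MuscleFactorSpec | None = None,
) -> TrajectoryRecord:
    """Roll out the network for one condition, recording everything.

    ``state_offset``/``offset_step`` add a perturbation vector to the state
    at a given step (for limit-cycle probes); ``amplitude`` overrides the
    graded amplitude (for input interpolation); ``input_trace`` overrides the
    input entirely (for ramps).
    """
    if input_trace is not None:
        u = input_trace
        on, off = 0, total_steps
    else:
        if off_step is None:
            _, lo, hi = protocol.timing(total_steps)
            off_step = (lo + hi) // 2
        u, on, off = make_input(
            protocol, condition, total_steps, seed=seed, off_step=off_step
        )
        if amplitude is not None:
            mask = u[0] != 0
            u[0, mask] = amplitude
        if protocol.mode == "feedback":
            if target_spec is None:
                raise ValueError("feedback simulation needs target_spec")
            y_fb = make_target(target_spec, condition, total_steps, params.dt, on, off)
            u = _feedback_inputs(u, y_fb, protocol, params.dt)

    n = params.n_units
    T = u.shape[1]
    states = np.empty((n, T))
    state = np.zeros(n) if initial_state is None else initial_state.copy()
    for t in range(T):
        if offset_step is not None and t == offset_step:
            state = state + state_offset
        states[:, t] = state
        state = step(params, state, u[:, t])
    firing = np.tanh(states)
    outputs = readout(params, firing)
    return TrajectoryRecord(
        states=states, firing=firing, outputs=outputs, inputs=u,
        condition=condition, dt=params.dt, on_step=on, off_step=off,
    )


def extract_steady_cycle(
    record: TrajectoryRecord, period_ms: float, which: str = "middle"
) -> np.ndarray:
    """One steady cycle of the firing-rate trajectory (units × steps).

    The first cycle after input onset can differ while the state settles onto
    the limit cycle, so a middle cycle of the on-period is returned.
    """
    period_steps = period_ms / record.dt
    span = record.off_step - record.on_step
    n_cycles = int(span // period_steps)
    if n_cycles < 1:
        raise ValueError("on-period shorter than one cycle")
    idx = n_cycles // 2 if which == "middle" else 0
    start = record.on_step + int(round(idx * period_steps))
    stop = start + int(round(period_steps))
    return record.firing[:, start:stop]
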