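# Methods

This note documents the models, algorithms, numerical choices, and known
limitations of `tanglekit`.  It states no empirical numbers beyond what the
test suite and `scripts/acceptance.py` themselves compute.

## Synthetic study conditions

All analyses run on synthetic inputs with planted ground truth.

**Muscle-factor targets.**  Eight speed bins span 0.8–2.1 Hz at equal
spacing (`np.linspace(0.8, 2.1, 8)`, ~0.19 Hz apart).  Each of six factors
is a sum of harmonics of the bin's base frequency,
`x_f(t) = a_s Σ_h A_h sin(2π h f_s t + φ_{f,h})`, with per-factor harmonic
phases drawn uniformly once at seed time so factor pairs are generically in
quadrature (this guarantees 2-D rotational structure without hand-tuning).
Default harmonic amplitudes `(1.0, 0.4, 0.15)` decay roughly geometrically —
strong enough above the fundamental that factor-pair trajectories are
clearly non-elliptical, which is what makes the network-vs-muscle ellipse
and tangling contrasts non-trivial.  Two speed-dependent properties of real
muscle activity are emulated: amplitude grows 5% per bin
(`amp_slope = 0.05`), and the temporal pattern changes — each harmonic's
phase drifts across bins with seeded per-harmonic drift rates of SD
`phase_slope = 0.05` rad/bin.  The drift rates are deliberately *not*
proportional to harmonic order: a proportional drift would be a pure time
shift of the waveform, leaving per-speed shapes identical up to scale, and
identical shapes make several cross-speed analyses (path similarity, the
separation-removed control) degenerate in a way real data never is.  One cycle per speed is materialized on a 1 ms grid; because the
factors are closed-form harmonic sums, arbitrary cycle counts are produced
exactly by evaluation (`evaluate_factors`), never by resampling.

**Stacked-elliptical population.**  The neural-like ground truth embeds,
via a seeded orthonormal readout, these latents per speed bin `s`: a planar
ellipse of radius 20 (rate units) whose plane rotates by `tilt_per_bin × s`
(default 0.06 rad) into a tilt dimension and whose minor axis shrinks by
`eccentricity_slope = 0.03` per bin (eccentricity changes modestly across
speeds, as it does in recorded populations); a constant offset
`speed_axis_gap × s` (default 4) along a speed axis orthogonal to every
ellipse plane; and copies of the muscle factors scaled by `output_dim_amp`
(default 3) in further orthogonal dimensions — the low-variance
output-encoding signals.  Defaults put the dominant variance in the
ellipse, several percent in the speed axis, and a small fraction in the
output dimensions, mirroring the arrangement the network adopts.
Non-negativity is enforced by a per-unit additive offset, never clipping,
so the planted geometry is exactly preserved.  The orthonormal readout
makes every planted quantity (speed axis, tilt angles, mean separations)
recoverable in closed form, which is what the parameter-recovery tests use.

**Spike trains** are inhomogeneous Poisson, simulated by thinning: candidate
events from a homogeneous process at the rate's upper bound, kept with
probability `rate(t)/bound`.  **Jittered trials** scale each trial's time
base uniformly (`U[1−scale_range, 1+scale_range]`) and apply a smooth
monotone warp built from lognormal knot increments (relative SD `warp_sd`,
knots every 100 ms); the position trace is warped identically so the
aligner can be tested against known ground truth.

## Preprocessing

Units are range-normalized across all times and speeds: *soft*
(`/(range + 5)`, in spikes/s) for neural-like data so weak units do not
dominate PCA, *full* (`/range`) for muscle-like channels whose scale is
arbitrary.  Smoothing convolves with a unit-area Gaussian (default SD
20 ms) with edge renormalization by the in-window kernel mass.

Trial alignment is two-stage.  Stage 1 rescales each trial uniformly to the
speed bin's median duration, discarding trials whose scale factor departs
from 1 by more than 15%.  Stage 2 fits, per trial, a monotone
piecewise-linear time warp (knots every 100 ms, least squares on hat
functions, monotonicity by running maximum) that aligns the trial's
position trace to the across-trial mean position.  The warp family is a
design choice: it is the smallest family that removes phase misalignment
without inverting time.  Values are only re-timed by interpolation, never
rescaled in magnitude.  Synthetic data has no recording sessions, so the
within-session/across-session distinction collapses to a single alignment
pass.

PCA mean-centers rows over the stated scope (one speed bin, or all bins
pooled) and takes the covariance's leading eigenvectors via SVD.  Sign
convention: each basis vector's largest-magnitude coefficient is positive,
making outputs platform-deterministic.

## The recurrent network

Dynamics: `r ← r + (1/τ)(−r + A tanh(r) + B u + b)` with Δt = 4 ms,
τ = 10 timesteps, 50 units; readout `y = C tanh(r) + d_out`.  Trials last
2000 steps; the input is zero for the first 800 steps, takes amplitude
`a(c) = 0.5 + 0.5(c−1)/8` (graded protocol) until an off step drawn
uniformly from [1500, 1900], then returns to zero.  The target is zero
while the input is off and the speed's factor cycle, tiled, while it is on.
Resampling the off step every trial varies the cycling span, which
discourages degenerate non-periodic solutions.  All timing constants scale
proportionally if a different trial length is configured.

Training minimizes MSE by backpropagation through time with Adam,
implemented directly in NumPy; the two sequential recursions (forward state
update, backward adjoint) are JIT-compiled with numba.  Hyperparameters the
task itself does not fix: learning rate 2e-3 decayed ×0.3 at iterations
3000 and 5500, with Polyak averaging of late iterates, global gradient-norm clip 2.0, full batch over the eight
conditions, recurrent weights initialized at spectral radius 1.0 (the
standard regime in which rhythmic tasks are learnable), readout initialized
small.  These were chosen by pilot runs and are exposed in `TrainConfig`.
The iteration budget (default 14000, minutes on one CPU) is far below
paper-scale training; the success criterion — normalized MSE < 0.01,
equivalently R² > 0.99 — defines convergence, not the budget.  Normalized
MSE divides by the pooled variance of the target over all times and
conditions (the per-factor vs pooled choice is not dictated by the task;
pooled is used and stated here).  Training defaults to noise-free; additive
Gaussian input noise of variance 0.01 is available.

The feedback protocol appends delayed (60 ms), gain-scaled factor channels
to the input.  During training the fed-back signal is the delayed *target*
(the predictable-feedback regime); during simulation it is the network's
own delayed output.  Closed-loop gradients through the feedback path are
therefore not propagated — a simplification that is exact at convergence,
where output equals target.

## Network interrogation

*Limit-cycle probes* displace the settled state by a random vector in the
condition's top-2 PC plane (coefficients `U[−0.1, 0.1]`), roll out 2000
steps with the input held on, and measure the terminal distance to the
nominal cycle — defined, since no standard definition exists, as the
minimum full-state Euclidean distance over all cycle phases, a phase-free
convergence criterion.  Distances are reported relative to the cycle
radius (RMS distance of cycle states from their mean).

*Designed perturbations.*  The muscle-generation vector is a readout row's
component orthogonal to the top-2 plane (unit norm): it jolts the output
while leaving the dominant-plane trajectory initially unchanged.  The
rhythm-generation vector must impact the plane while leaving the readout
silent; a vector exactly inside a 2-D plane cannot generally be orthogonal
to six readout rows, so the implemented vector is the element of the
readout's null space (where orthogonality holds exactly, asserted to 1e-8)
with maximal projection onto the plane — the precise form of the
maximize-plane-impact / minimize-readout-impact trade-off.  Perturbation
magnitudes default to the probe scale.

*Phase and frequency.*  Cycle phase is the unwrapped angle of the
mean-centered top-2 projection, flagged undefined when the planar radius
becomes negligible relative to its mean.  Fundamental frequency comes from
the summed autocorrelation peak with parabolic lag refinement.
Instantaneous frequency uses a sliding-window linear fit to the unwrapped
phase; a one-period window averages over the within-cycle angular-speed
modulation of an elliptical orbit.

## Geometry metrics

**Tangling** is computed with backward-difference derivatives on the
sampling grid and `ε = 0.1 ×` the pooled state variance; the `t'` index set
is explicit (`within` / `across` / `global`).  The default basis is 12
global PCs; 2-D per-speed and full-dimensional computation are options.
The implementation is vectorized over speed-pair blocks and is verified,
property-style, against an O(T²) scalar double loop.  The first sample of
each speed carries no Q value (no backward difference exists).
99th-percentile summaries use linear-interpolation percentiles;
uncertainty, when requested, comes from a seeded bootstrap over time
points (1000 draws).

**Ellipse fits** use the direct least-squares conic method with the
ellipse-specific constraint, in the numerically stable partitioned form,
after centering and scaling the points.  If the *unconstrained* conic fit
is a hyperbola (saddle-shaped trajectories), the fit is flagged degenerate
and excluded from R² comparisons.  R² compares the trajectory in temporal
order against the fitted ellipse sampled uniformly in parametric angle
with the same point count; the sampling phase offset (720-point grid plus
continuous refinement) and direction are chosen to minimize squared error.
Point correspondence is otherwise unspecified in the problem, and this
optimization is the only correspondence-free reading that is well defined.

**Path similarity** resamples each comparison trajectory to the reference
length, finds the rigid rotation minimizing the Frobenius distance (Kabsch,
via SVD), and scores `R² = 1 − SSE / Var(comparison)` with no scaling or
offset.  The determinant is constrained to +1 by default; a flag allows
reflections.  `R²_k` aggregates over all ordered pairs separated by `k`
bins (symmetric under relabeling by construction).

**Speed axis.**  Per-speed mean states in global PCs 3–12 form the rows of
`M`; the axis solves `min ‖M w − v‖² s.t. ‖w‖ = 1` for mean-centered mean
angular velocities `v`, exactly via the secular equation (eigendecomposition
of `MᵀM` plus Brent root-finding for the Lagrange multiplier below the
smallest eigenvalue).  With 8 speeds and 10 candidate dimensions, `MᵀM` is
always rank-deficient; directions carrying less than 1e-6 of the leading
eigenvalue are treated as exact nulls, and when the minimum-norm
least-squares solution already has norm below 1 the unit-norm problem is
degenerate (null-space padding changes nothing measurable) — the
normalized minimum-norm direction is returned, the only choice free of
arbitrary components.  The lifted axis is orthogonal to global PCs 1–2 by
construction; variance captured along it is reported as a fraction of
total variance, bounded above by PC 3's share.

**Distance and variance capture.**  Phase-dependent distance defaults to
matched-phase comparison after resampling to the reference length; a
nearest-point mode also exists because the two definitions appear in
different descriptive contexts and genuinely differ — the discrepancy is
surfaced as an option rather than resolved.  Cross-speed variance capture
fits PCs on an anchor bin and projects every bin's own-mean-centered
variance onto that fixed basis.

**Controls.**  The rescaled-time control replaces every speed's trajectory
with the reference path (bin 6 by default) traversed at the original
duration, then regenerates spike trains by thinning with the rescaled rate
as intensity, smooths, averages, and re-normalizes — so the manipulated
population carries realistic sampling error rather than artificially clean
identical paths.  The separation-removed control equalizes means and
Kabsch-rotates every trajectory onto the reference, removing both
translation and dimension-tilt separation while preserving shape.  The
rotation is fit on a copy resampled to the reference length (the pointwise
pairing requires matched lengths) but applied on each speed's own time
base: every speed still traverses the now-overlapping path at its own
rate.  This detail is load-bearing — resampling the output as well would
equalize per-sample traversal rates, and overlapped same-shape
trajectories traversed at the same rate shadow one another instead of
tangling.  Both manipulations are expected to
*raise* global tangling, which is the evidence that inter-speed separation
is what keeps it low.

## Factor regression

Each unit is fit by ridge regression (intercept included and unpenalized;
factors are PCA-centered, rates are not) against the top 2 or 3 global PCs
of either the network or the muscle population, resampled per speed onto
the rate population's time base.  Population R² pools residual and total
sums of squares across units — variance-weighted, so a poorly fit
low-variance unit contributes proportionally.  The network-vs-muscle
difference in per-speed population R² is tested with a paired one-tailed
t-test across the 8 speeds (identical factor sets are reported as Δ = 0,
p = 0.5).  The default penalty is chosen by leave-one-speed-out
cross-validation over a log grid; leave-one-speed-out generalization R² is
available to guard against overfitting.

## Problem sizes and scope choices

The default pipeline and acceptance script use the full study conditions
(50 units, 8 speeds, 6 factors, 2000-step trials) with a desk-scale
training budget.  Unit tests use a deliberately small two-speed network
fixture (30 units, sinusoid targets, loose convergence target) that trains
in well under a minute while still exhibiting the stacked-limit-cycle
solution.  The contrast between graded and one-hot input protocols
(one-hot networks adopt unrelated per-speed trajectories, steepening the
`R²_k` decline) is available through the pipeline's protocol switch but is
not asserted in the test suite, since it requires two full-scale trainings.

## Known limitations

* The generator's harmonic recipe and amplitude law are stylized; real
  muscle activity changes temporal pattern across speeds in muscle-specific
  ways.  Passing tests demonstrate correctness of the metrics and the
  reproduction of the structural orderings on ground truth, not claims
  about any recorded dataset.
* Training omits the closed-loop gradient path in the feedback protocol
  (see above).
* No spiking-unit networks, no excitatory/inhibitory cell types, no
  unpredictable-feedback control policy, and no loading of recorded data
  files.
* `PopulationRates` stores one matrix per speed because cycle durations
  differ across speeds; all pooling is explicit concatenation along time.
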