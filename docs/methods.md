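# Methods

## Model and observables

The membrane voltage is the sinusoidally forced Ornstein–Uhlenbeck-type
diffusion

    dX = (alpha - X + gamma sin(Omega s)) ds + beta dW,    X(0) = 0,

with an absorbing threshold at 1 and instantaneous reset to 0.  Time is in
units of the membrane time constant and voltage in units of the
threshold-to-reset distance, so the dimensional model (bias mu, time constant
tau, forcing amplitude A and frequency omega, noise sigma, threshold v_th,
reset v_0) maps to alpha = mu*tau/(v_th-v_0), beta = sigma*sqrt(tau)/(v_th-v_0),
gamma = A*tau/(v_th-v_0), Omega = omega*tau.  The only observable is the
sequence of spike times s_1 < s_2 < ...; the n-th ISI I_n = s_n - s_{n-1}
is the first-passage time of a trajectory started at reset with onset phase
phi_{n-1} = s_{n-1} mod (2*pi/Omega).  The noiseless model spikes iff
alpha + gamma/sqrt(1+Omega^2) > 1; the four named regimes (supra-threshold,
supersinusoidal, critical, subthreshold) partition parameter space by this
index and by whether the bias alone suffices (alpha > 1).  The "critical"
label uses a tolerance band |index - 1| <= tol with tol = 0.05 by default:
the model itself has a sharp boundary, the band is labelling convenience,
and no estimation code branches on regime labels.

tau is treated as known throughout.  Joint estimation of tau from ISIs alone
is an identifiability trap — quite different (alpha, beta, gamma, tau)
combinations reproduce the same ISI statistics — and is deliberately out of
scope, as is any non-sinusoidal periodic forcing.

## Phase binning

ISIs are conditionally independent given their onset phase, so the phase
circle [0, 2*pi/Omega) is split into M equal half-open cells with midpoint
representatives, and all ISIs whose onset falls in cell m are treated as a
renewal sample from the single-phase law at the midpoint phi_m.  The
approximation error (half a cell width in phase) decreases as M grows while
the per-bin sample N_m shrinks; the default follows the rule M = 20 for
N >= 1000 and M = 8 for N <= 100, with M = N/50 (clamped to [8, 20]) in
between — the intermediate rule is this package's own interpolation, since
only the two endpoints are prescribed.  Boundary phases belong to the upper
cell (lower-closed convention, a pure tie-break).  Per-bin empirical
survivor functions use the strict count #{i_n > t}/N_m.

## Simulator

Euler–Maruyama with a global clock: crossings are detected at step
resolution (first grid point with X >= 1) and the state resets to 0 while
time keeps running, so onset phases accumulate exactly.  The default step
dt = 1e-3 is far below both the membrane timescale (1) and the fastest
forcing period considered (2*pi/20).  Step-resolution detection biases each
ISI upward by O(beta*sqrt(dt)); at the default step this is below the
sampling noise of the study's sample sizes, and the weak-convergence test
(halving dt leaves the ISI law statistically indistinguishable at N = 1000)
monitors it.  No Brownian-bridge correction is applied inside the *train*
simulator — that plain scheme is what the estimators are tested against.
The Monte-Carlo survivor oracle (`first_passage_survivor_mc`), by contrast,
does apply the standard bridge correction (absorb within a step with
probability exp(-2(1-x0)(1-x1)/(beta^2 dt))), because there it serves as an
accuracy reference for the PDE solver and must not carry the sqrt(dt) bias
itself.  A step-count safety valve aborts deep-subthreshold simulations
with a clear diagnostic instead of hanging.

## Fokker–Planck solver

The solver works with the sub-threshold distribution function
F(x,t) = P(X_t <= x, no spike yet) rather than the density: the initial
condition is then the Heaviside step instead of a Dirac delta.  F obeys

    F_t = (beta^2/2) F_xx - (alpha - x + gamma sin(Omega(t+phi))) F_x

on [x_lo, 1] with F(x,0) = H(x), F(x_lo,t) = 0 and F_x(1,t) = 0; the
survivor function of the phase-phi ISI is the top trace F(1,t) and the ISI
density is its negative time derivative.  The truncation boundary
x_lo = min(alpha - gamma/sqrt(1+Omega^2) - 2*beta/sqrt(2), -0.25) sits two
stationary standard deviations below the lowest asymptotic mean of the free
process, where the neglected mass is negligible; the derivation of the
F-equation fixes the integration constant to zero, which is exactly the
no-flux (reflecting) condition at x_lo, and a test checks the discrete flux
there stays small.

Discretization: Crank–Nicolson, central differences in space, with the
sinusoidal drift evaluated at the half-time level (keeps the scheme second
order for the time-dependent coefficient).  The first two steps are replaced
by four backward-Euler half-steps (Rannacher startup): the discontinuous
initial condition otherwise excites undamped Crank–Nicolson modes that show
up as spatial oscillations.  Default resolution: the space step targets
1/320 of the threshold-reset distance with at least 400 intervals — tied to
the unit voltage scale rather than the domain width, so accuracy does not
degrade when a large gamma widens the domain; the time step keeps the
diffusion number beta^2 dt/(2 dx^2) <= 2 (CN is unconditionally stable;
this bounds oscillatory error) and resolves the forcing period with at
least 200 steps.  Grid-halving moves the survivor trace by < 1e-3 in every
reference regime, and the trace agrees with a 1e5-path bridge-corrected
Monte-Carlo survivor within Monte-Carlo error.  Inside estimation loops a
coarser grid (80 intervals) is used: replicate-mean estimates are
indistinguishable between 80, 120 and 240 intervals (the per-bin sampling
noise of ~50-ISI bins dwarfs the trace error), and one fit needs hundreds
of solves.
Monotonicity overshoots are clipped to [0,1] only at output, never inside
the march, so instability would be visible rather than masked.  The march
stops early once F(1,t) < 1e-4 *and* t has covered the bin's largest ISI.

## Fortet machinery

Subtracting the deterministic solution
v(t) = alpha(1-e^{-t}) + gamma/sqrt(1+Omega^2) [sin(Omega(t+phi)-psi)
- e^{-t} sin(Omega phi - psi)], psi = arctan(Omega), turns X into the plain
OU process Y = X - v with threshold b(t) = 1 - v(t) and Gaussian transition
law N(y0 e^{-d}, (beta^2/2)(1-e^{-2d})), d = t - t0 (CDF evaluated through
the erfc route for tail stability).  The per-bin residual is

    sup_s |LHS(s) - RHS(s)| / omega,
    LHS(s) = 1 - Phi(b(s), s | 0, 0),
    RHS(s) = (1/N_m) sum_{i_n < s} [1 - Phi(b(s), s | b(i_n), i_n)],
    omega  = sup_s |LHS(s)|,

with the sup sampled at K = 500 uniform points in (0, I_max(1+eps)] —
eps = 0.01 is this package's choice, as is reusing the same grid for the
sup and for omega.  The loss is sum_m N_m * residual_m.  The normalization
keeps the residual in [0,1] near parameters consistent with the data; for
trial parameters whose exceedance probability nearly vanishes, omega -> 0
and the ratio exceeds 1 (bounded by 1/omega), which in practice repels the
optimizer from degenerate regions.  Everything that does not depend on the
parameters (sup grids, pairwise time lags, their exponentials) is
precomputed once per fit, so a loss evaluation is elementwise Gaussian-CDF
arithmetic.

## Initializer

Early on, the absorbed-mass picture is approximately a Gaussian bell of
standard deviation beta*sqrt(t) advected toward the threshold at speed
U ~ (alpha - 0.5) + gamma * (running time-average of the sinusoid), where
the space-dependent -x drift is frozen at the domain midpoint 0.5.  If the
bin's empirical survivor crosses the level Phi(c) at time t_c, the bell
geometry gives the linear equation

    alpha*t_c + beta*c*sqrt(t_c) + gamma*s(t_c) = 1 + 0.5*t_c,
    s(t) = (cos(Omega phi) - cos(Omega(t+phi)))/Omega,

and stacking the c = +1 and c = -1 rows (survivor levels 0.8413 / 0.1587)
over all bins gives an overdetermined system solved by ordinary least
squares.  Crossing times come from linear interpolation of the empirical
step survivor (deterministic and monotone); bins with fewer than two ISIs
contribute no rows; a rank-deficient system falls back to the fixed guess
(1, 0.3, 0.5) with a warning, so the initializer always returns a triple.
beta is floored at 0.05 and gamma at 0 after the solve — the downstream
optimizer corrects both.  The choice of the symmetric 1-sigma level pair
over a 2-sigma/1-sigma pairing is deliberate: only the former reproduces
the initializer's documented behavior on the reference regimes (including
its characteristic upward alpha bias near 0.9 in the supersinusoidal
regime); the alternative remains available as `scheme="two-sigma"`.
The initializer needs no PDE solves and no optimization; it runs in
O(N + M) time.

## Optimization

Both losses are minimized by Nelder–Mead over (alpha, log beta, gamma):
the log parameterization keeps beta positive without penalty
discontinuities, while alpha and gamma are unconstrained (negative alpha
estimates legitimately occur in weakly identified regimes).  A negative
trial gamma is handled exactly, not by penalty: sin is odd, so gamma < 0 is
equivalent to |gamma| with all bin phases shifted by half a forcing period.
Negative *final* gamma estimates are clamped to 0 in the reported
parameters (the raw value is kept in `gamma_raw_`).  Defaults
xatol = fatol = 1e-3, maxiter = 300 balance accuracy against the ~1-10 s
per-train budget.  Two safeguards address Nelder-Mead's best-known failure
mode, premature convergence of a collapsed simplex: the initial simplex
uses absolute coordinate steps (0.15, 0.25, 0.25) instead of scipy's 5%
relative perturbation (which is microscopic for near-zero starts), and the
search restarts from the incumbent with a fresh full-size simplex until the
loss stops improving (up to n_restarts = 2 extra runs).  Without these, the
reported optimum in flat subthreshold landscapes can sit measurably above
the loss at the true parameters; with them the subthreshold replicate means
move from heavily biased (alpha ~ 0.7) to nearly unbiased (alpha ~ 0.38-0.41
against a true 0.40).  Note this makes the survivor-matching estimator
*less* biased in the subthreshold regime than historical implementations
whose published intervals exclude the true parameters there; a
reimplementation that minimizes the loss fully cannot reproduce those
particular rows.  A generous sanity box (|alpha| <= 10, beta <= 1.5,
-50 <= gamma <= 100) turns pathological trial points into smooth penalties
instead of exceptions.  Fits are deterministic given (train, init,
options); non-convergence returns the best point found with
`converged_=False`, never an exception.

## Replication harness and study conditions

A replication run simulates R independent trains (replicate r uses seed
base_seed + r) and feeds the *same* train to every estimator, so paired
method comparisons are meaningful.  Summaries report the mean and the
empirical 2.5/97.5 percentiles (linear interpolation between order
statistics — no specific definition is prescribed, this is numpy's
default).  Per-replicate rows are persisted as they complete and keyed by
(replicate, method), so runs are resumable and output is order-independent.
Individual replicate failures are recorded and excluded, never fatal.

The reference study conditions are trains of N = 1000 ISIs, M = 20 bins,
at the four Omega = 1 regime parameter sets and the critical-regime
frequency sweep (Omega in {1, 5, 10, 20} with gamma = (1-alpha)sqrt(1+Omega^2),
alpha = 0.5); those are the package presets.  Problem sizes used here: the
acceptance script runs R = 30 replicates per configuration; the test suite
runs the same pipeline at R = 12 and checks the replicate means against the
reference intervals.  At high Omega both estimators underestimate gamma
(the survivor-matching method more severely), with a bimodal estimate
distribution — many replicates collapse to gamma ~ 0 with a compensating
overestimate of alpha — matching the documented degradation.

## What the synthetic data does and does not cover

All validation data come from the package's own simulator, i.e. exactly the
model the estimators assume: a hard constant threshold, instantaneous
reset, white noise, perfectly sinusoidal forcing with known frequency.
Passing tests therefore demonstrate internal consistency and correct
recovery *within* the model class; they say nothing about robustness to
threshold variability, colored noise, spike-history effects, frequency
misspecification, or detection jitter in real recordings.  The estimators
also inherit the simulator's small O(sqrt(dt)) ISI discretization bias;
at dt = 1e-3 this is invisible at the study's sample sizes.

## Known limitations

- Subthreshold parameters are weakly identified from ISIs alone: the bias
  and the forcing amplitude trade off, estimate spreads are the widest of
  the four regimes, and no amount of optimizer polish fixes that.
- The Fortet loss costs O(K * N) Gaussian CDF evaluations per bin per
  trial point, so its runtime grows linearly with spikes; the PDE loss is
  dominated by M solves per trial point and grows only weakly with N.
- Nelder–Mead is a local method.  With the bell initializer it reliably
  finds the basin of the truth at Omega = 1; at Omega = 20 the landscape
  is bimodal and a fraction of replicates remain in the gamma ~ 0 basin.
- The MLE objective shares the survivor solver but differentiates the
  trace numerically; it is retained as an option, with the survivor-
  matching loss as the default (marginally more robust, no numerical
  differentiation step).
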