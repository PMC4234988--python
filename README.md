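# sinlif

Parameter estimation for a sinusoidally forced, noisy leaky integrate-and-fire
(LIF) neuron **from spike times alone**.

Extracellular recordings see only when a neuron fires, not the voltage path in
between, so the subthreshold model parameters must be inferred from the
statistics of first-passage times. `sinlif` implements two such estimators for
the nondimensional LIF voltage

```
dX = (alpha - X + gamma sin(Omega s)) ds + beta dW,    X(0) = 0,
```

which spikes and resets to 0 whenever X reaches the threshold 1.  The target
is the triple (alpha: bias, beta: noise strength, gamma: forcing amplitude);
the forcing frequency Omega is assumed known.  Because of the sinusoid the
interspike intervals (ISIs) are neither independent nor identically
distributed — they are conditionally independent given the forcing phase at
each interval's onset.  The central device is therefore **phase binning**:
ISIs are grouped into M equal-width bins of onset phase and each bin is
treated as a renewal sample at its midpoint phase.

Two estimators (plus a fast initializer) operate on the binned data:

- **Fokker–Planck survivor matching** (`FokkerPlanckEstimator`): for each bin
  phase, the model survivor function `G(t) = F(1, t)` is obtained by solving
  the distribution-form forward PDE
  `dF/dt = (beta^2/2) F_xx - (alpha - x + gamma sin(Omega(t+phi))) F_x`
  with Crank–Nicolson, and the count-weighted sup distance
  `sum_m N_m sup_t |Ghat_m(t) - F(1,t)|` is minimized by Nelder–Mead.
  An approximate maximum-likelihood objective built from the
  finite-differenced ISI density is available as `objective="mle"`.
- **Fortet integral equation** (`FortetEstimator`): subtracting the
  deterministic trajectory v(t) makes the process a plain
  Ornstein–Uhlenbeck with a moving threshold `b(t) = 1 - v(t)` and a
  closed-form Gaussian transition CDF `Phi`.  The Fortet identity
  `1 - Phi(b(t),t|0,0) = int_0^t g(u)[1 - Phi(b(t),t|b(u),u)] du`
  is turned into an estimating equation by replacing the integral with an
  empirical average over the bin's ISIs; the normalized sup discrepancy is
  minimized.  No PDE solves are needed.
- **Gaussian-bell initializer** (`BellInitializer`): approximates early
  survivor decay by a Gaussian bell advected past the threshold, reads off
  the times where each bin's empirical survivor crosses the 1-sigma tail
  levels, and solves the stacked linear system for (alpha, beta, gamma) by
  least squares.  Automatic and essentially instantaneous; used as the
  starting point for both optimizers.

All estimators follow scikit-learn conventions (`fit`, `get_params`,
fitted attributes `alpha_`, `beta_`, `gamma_`, `loss_`, `converged_`).

## Worked example

```python
import sinlif as sl

true = sl.get_preset("supra")              # alpha=1.40, beta=0.30, gamma=0.14
train = sl.simulate_train(true, 1000, seed=10)

guess = sl.BellInitializer(Omega=1.0).fit(train)
est = sl.FortetEstimator(Omega=1.0, M=20).fit(train)
print(f"init   : alpha={guess.alpha_:.3f} beta={guess.beta_:.3f} gamma={guess.gamma_:.3f}")
print(f"fortet : alpha={est.alpha_:.3f} beta={est.beta_:.3f} gamma={est.gamma_:.3f}")
```

prints

```
init   : alpha=1.399 beta=0.307 gamma=0.144
fortet : alpha=1.382 beta=0.292 gamma=0.126
```

i.e. the initializer already lands near the truth in this strongly driven
regime, and the Fortet fit refines it; with different seeds the estimates
scatter around the true (1.40, 0.30, 0.14) with a spread that shrinks with
the number of spikes.  The same workflow is available from the shell:

```sh
sinlif simulate --alpha 1.4 --beta 0.3 --gamma 0.14 --n-spikes 1000 --seed 10 --out train.csv
sinlif estimate --in train.csv --omega 1.0 --method fortet
sinlif replicate --regime critical --reps 100 --out results/critical/
```

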