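"""Parameter estimation: survivor-matching, likelihood and Fortet objectives.

Everything here turns an observed spike train into an estimate of the
nondimensional triple (alpha, beta, gamma), with the forcing frequency Omega
assumed known.  Three scikit-learn style estimators are provided:

``FokkerPlanckEstimator``
    minimizes the count-weighted sup distance between per-bin empirical
    survivor curves and the numerically solved model survivor F(1, t)
    (objective="survivor"), or the binned negative log-likelihood assembled
    from the finite-differenced ISI density (objective="mle");
``FortetEstimator``
    minimizes the count-weighted normalized Fortet residual, which needs no
    PDE solves because the homogenized OU transition law is known in closed
    form;
``BellInitializer``
    the regression-based initial guess alone, exposed as an estimator so the
    three methods can be compared on equal footing.

All three share the Nelder-Mead driver (the losses are not differentiable in
any convenient closed form); beta is optimized on a log scale to keep it
positive without penalty discontinuities, while alpha and gamma are free.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .binning import BinnedData, bin_train, default_n_bins
from .fokker_planck import survivor_trace
from .fortet import FortetWorkspace, K_DEFAULT
from .initializer import initialize
from .model import ModelParams
from .simulate import SpikeTrain

__all__ = [
    "EstimateResult",
    "fp_loss",
    "mle_loss",
    "fit",
    "FokkerPlanckEstimator",
    "FortetEstimator",
    "BellInitializer",
]

#: Spatial intervals used by the PDE-based losses during optimization.  This
#: is coarser than the standalone-solver default: estimation needs hundreds
#: of solves per fit and the survivor trace is accurate to well below the
#: sampling noise of N ~ 1000 ISIs already at this resolution.
NX_FIT = 80

#: Density floor for the log-likelihood objective.
DENSITY_FLOOR = 1e-10

# Generous sanity box for the optimizer; points outside are pushed back with
# a smooth penalty rather than an exception, keeping Nelder-Mead's simplex
# well-defined and the PDE grids bounded.
_ALPHA_BOX = (-10.0, 10.0)
_LOGBETA_BOX = (math.log(1e-3), math.log(1.5))
_GAMMA_BOX = (-50.0, 100.0)
_PENALTY = 1e8


@dataclass(frozen=True)
class EstimateResult:
    """Outcome of one estimation run on one spike train."""

    params_hat: ModelParams
    method: str
    loss_value: float
    n_evals: int
    converged: bool
    init_used: ModelParams
    M_used: int
    gamma_raw: float = float("nan")
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "alpha": self.params_hat.alpha,
            "beta": self.params_hat.beta,
            "gamma": self.params_hat.gamma,
            "Omega": self.params_hat.Omega,
            "method": self.method,
            "loss": self.loss_value,
            "n_evals": self.n_evals,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# loss functions
# ---------------------------------------------------------------------------

def _bin_spline(isis: np.ndarray) -> PchipInterpolator:
    """Monotone cubic through the empirical survivor's step corners.

    PCHIP preserves monotonicity so the interpolant never leaves [0, 1].
    """
    isis = np.sort(isis)
    n = isis.size
    vals = 1.0 - np.arange(1, n + 1) / n
    uniq, last_idx = np.unique(isis[::-1], return_index=True)
    vals = vals[::-1][last_idx]
    knots_t = np.concatenate(([0.0], uniq))
    knots_v = np.concatenate(([1.0], vals))
    if knots_t.size < 2:
        # single distinct ISI: a two-point "spline" (0,1)-(i,0)
        knots_t = np.array([0.0, float(uniq[0])])
        knots_v = np.array([1.0, 0.0])
    return PchipInterpolator(knots_t, knots_v, extrapolate=False)


def fp_loss(
    data: BinnedData,
    m: ModelParams,
    nx: int = NX_FIT,
    _splines: list | None = None,
) -> float:
    """Survivor-matching loss  sum_m N_m * sup_t |Ghat_m(t) - F^(phi_m)(1, t)|.

    One PDE solve per nonempty bin; the empirical survivor is
    spline-interpolated and sampled at the PDE time nodes, and the sup is the
    maximum over those samples.  Empty bins carry zero weight.
    """
    centers = data.bins.centers
    total = 0.0
    k = 0
    for mth, isis in enumerate(data.members):
        if isis.size == 0:
            continue
        bmax = float(isis.max())
        t_nodes, trace = survivor_trace(
            m, centers[mth], t_max=bmax + 2.0, nx=nx, t_stop_min=bmax
        )
        spline = _splines[k] if _splines is not None else _bin_spline(isis)
        k += 1
        emp = spline(t_nodes)
        emp = np.where(np.isnan(emp), 0.0, np.clip(emp, 0.0, 1.0))
        model = np.clip(trace, 0.0, 1.0)
        total += isis.size * float(np.abs(emp - model).max())
    return total


def mle_loss(
    data: BinnedData,
    m: ModelParams,
    nx: int = NX_FIT,
    floor: float = DENSITY_FLOOR,
) -> float:
    """Binned negative log-likelihood from the finite-differenced density.

    The per-bin ISI density is g(t) = -dF(1, t)/dt, approximated by centered
    differences on the PDE time grid and floored at ``floor`` before the log
    (flooring events are reported via a warning).  One PDE solve per bin.
    """
    centers = data.bins.centers
    total = 0.0
    n_floored = 0
    for mth, isis in enumerate(data.members):
        if isis.size == 0:
            continue
        bmax = float(isis.max())
        t_nodes, trace = survivor_trace(
            m, centers[mth], t_max=bmax * 1.01 + 0.05, nx=nx,
            t_stop_min=bmax * 1.01 + 0.05,
        )
        dt = t_nodes[1] - t_nodes[0]
        g = -np.gradient(trace, dt)
        g_at = np.interp(isis, t_nodes, g)
        n_floored += int((g_at <= floor).sum())
        total -= float(np.log(np.maximum(g_at, floor)).sum())
    if n_floored:
        warnings.warn(
            f"density floor engaged for {n_floored} ISI(s); their likelihood "
            "contribution is capped",
            stacklevel=2,
        )
    return total


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def _as_train(X, Omega: float) -> SpikeTrain:
    if isinstance(X, SpikeTrain):
        return X
    return SpikeTrain(spike_times=np.asarray(X, dtype=float).ravel(), Omega=Omega)


def _box_penalty(a: float, lb: float, g: float) -> float:
    over = 0.0
    for v, (lo, hi) in ((a, _ALPHA_BOX), (lb, _LOGBETA_BOX), (g, _GAMMA_BOX)):
        if v < lo:
            over += lo - v
        elif v > hi:
            over += v - hi
    return over


class _NelderMeadEstimator(BaseEstimator):
    """Shared Nelder-Mead driver over (alpha, log beta, gamma)."""

    #: Absolute initial-simplex steps in (alpha, log beta, gamma).  The
    #: default scipy simplex perturbs coordinates by 5%, which is far too
    #: small for near-zero starting values and lets the simplex collapse
    #: prematurely in the flat valleys of weakly identified regimes.
    _SIMPLEX_STEPS = (0.15, 0.25, 0.25)

    def __init__(
        self,
        Omega: float = 1.0,
        M: int | None = None,
        init: ModelParams | tuple | str = "auto",
        xtol: float = 1e-3,
        ftol: float = 1e-3,
        maxiter: int = 300,
        n_restarts: int = 2,
    ):
        self.Omega = Omega
        self.M = M
        self.init = init
        self.xtol = xtol
        self.ftol = ftol
        self.maxiter = maxiter
        self.n_restarts = n_restarts

    # subclasses provide: _method_name, _make_objective(data) -> callable(ModelParams)

    def _initial_guess(self, data: BinnedData) -> ModelParams:
        if self.init == "auto" or self.init is None:
            return initialize(data, self.Omega)
        if isinstance(self.init, ModelParams):
            return self.init
        a, b, g = self.init
        return ModelParams(alpha=a, beta=b, gamma=max(g, 0.0), Omega=self.Omega)

    def fit(self, X, y=None):
        """Estimate (alpha, beta, gamma) from a spike train.

        ``X`` is a 1-d array of strictly increasing spike times (or a
        :class:`~sinlif.simulate.SpikeTrain`); ``y`` is ignored.
        """
        train = _as_train(X, self.Omega)
        M = self.M if self.M is not None else default_n_bins(len(train))
        data = bin_train(train, M)
        init = self._initial_guess(data)
        objective = self._make_objective(data)

        n_evals = 0

        def wrapped(u):
            nonlocal n_evals
            n_evals += 1
            a, lb, g = float(u[0]), float(u[1]), float(u[2])
            over = _box_penalty(a, lb, g)
            if over > 0:
                return _PENALTY * (1.0 + over)
            return objective(ModelParams(alpha=a, beta=math.exp(lb), gamma=0.0,
                                         Omega=self.Omega), g)

        x0 = np.array([init.alpha, math.log(max(init.beta, 1e-3)), init.gamma])
        steps = np.asarray(self._SIMPLEX_STEPS)

        def run(start):
            simplex = np.vstack([start, start + np.diag(steps)])
            return minimize(
                wrapped,
                start,
                method="Nelder-Mead",
                options={
                    "xatol": self.xtol,
                    "fatol": self.ftol,
                    "maxiter": self.maxiter,
                    "initial_simplex": simplex,
                    "disp": False,
                },
            )

        # Nelder-Mead can report convergence with a collapsed simplex well
        # above the minimum; restart from the best point with a fresh
        # full-size simplex until the loss stops improving.
        res = run(x0)
        for _ in range(self.n_restarts):
            res2 = run(res.x)
            improved = res.fun - res2.fun > self.ftol * (1.0 + abs(res.fun))
            if res2.fun < res.fun:
                res = res2
            if not improved:
                break
        a_hat, lb_hat, g_hat = res.x
        self.alpha_ = float(a_hat)
        self.beta_ = float(math.exp(lb_hat))
        self.gamma_raw_ = float(g_hat)
        # the loss is defined for gamma < 0 (a phase flip), but the model
        # contract is gamma >= 0; negative point estimates clamp to zero
        self.gamma_ = max(self.gamma_raw_, 0.0)
        self.params_ = ModelParams(
            alpha=self.alpha_, beta=self.beta_, gamma=self.gamma_, Omega=self.Omega
        )
        self.loss_ = float(res.fun)
        self.n_evals_ = int(n_evals)
        self.converged_ = bool(res.success)
        self.init_params_ = init
        self.M_ = M
        return self

    def score(self, X, y=None) -> float:
        """Negative loss of the fitted parameters on a (possibly new) train."""
        train = _as_train(X, self.Omega)
        data = bin_train(train, self.M_)
        objective = self._make_objective(data)
        return -objective(self.params_, self.params_.gamma)

    def result(self, seed: int | None = None) -> EstimateResult:
        return EstimateResult(
            params_hat=self.params_,
            method=self._method_name,
            loss_value=self.loss_,
            n_evals=self.n_evals_,
            converged=self.converged_,
            init_used=self.init_params_,
            M_used=self.M_,
            gamma_raw=self.gamma_raw_,
            seed=seed,
        )


class FokkerPlanckEstimator(_NelderMeadEstimator):
    """Survivor-matching (or approximate-MLE) estimation via the PDE solver.

    Parameters
    ----------
    Omega : known forcing angular frequency.
    M : number of phase bins (default: 20 for N >= 1000, 8 for N <= 100).
    objective : "survivor" for the sup-distance loss, "mle" for the binned
        negative log-likelihood.
    nx : spatial intervals of the Crank-Nicolson grid used inside the loss.
    init : "auto" (bell initializer), a ModelParams, or an (a, b, g) tuple.
    """

    def __init__(
        self,
        Omega: float = 1.0,
        M: int | None = None,
        objective: str = "survivor",
        nx: int = NX_FIT,
        init: ModelParams | tuple | str = "auto",
        xtol: float = 1e-3,
        ftol: float = 1e-3,
        maxiter: int = 300,
        n_restarts: int = 2,
    ):
        super().__init__(Omega=Omega, M=M, init=init, xtol=xtol, ftol=ftol,
                         maxiter=maxiter, n_restarts=n_restarts)
        self.objective = objective
        self.nx = nx

    @property
    def _method_name(self) -> str:
        return "fokker-planck" if self.objective == "survivor" else "mle"

    def _make_objective(self, data: BinnedData):
        if self.objective == "survivor":
            splines = [_bin_spline(i) for i in data.members if i.size > 0]

            def obj(m: ModelParams, gamma: float) -> float:
                mm = ModelParams(alpha=m.alpha, beta=m.beta, gamma=abs(gamma),
                                 Omega=m.Omega)
                # negative gamma is a phase flip: sin is odd, so shift phi by
                # half a period instead of rebuilding the binning
                return fp_loss(_flip_if_needed(data, gamma), mm, nx=self.nx,
                               _splines=splines)

            return obj
        if self.objective == "mle":
            def obj(m: ModelParams, gamma: float) -> float:
                mm = ModelParams(alpha=m.alpha, beta=m.beta, gamma=abs(gamma),
                                 Omega=m.Omega)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    return mle_loss(_flip_if_needed(data, gamma), mm, nx=self.nx)

            return obj
        raise ValueError(f"unknown objective {self.objective!r}")


def _flip_if_needed(data: BinnedData, gamma: float) -> BinnedData:
    """For gamma < 0, sin(x) = -sin(x + pi): shift all bin phases by half a
    forcing period so the loss sees an equivalent nonnegative amplitude."""
    if gamma >= 0:
        return data
    half = math.pi / data.bins.Omega
    shifted = _PhaseShiftedBins(data.bins, half)
    return BinnedData(bins=shifted, members=data.members)


class _PhaseShiftedBins:
    def __init__(self, bins, shift):
        self._bins = bins
        self._shift = shift
        self.M = bins.M
        self.Omega = bins.Omega
        self.delta_phi = bins.delta_phi

    @property
    def centers(self):
        return self._bins.centers + self._shift


class FortetEstimator(_NelderMeadEstimator):
    """Estimation from the normalized Fortet integral-equation residual.

    No PDE solves are required: the homogenized OU transition CDF is known
    in closed form, so each loss evaluation is elementwise Gaussian-CDF
    arithmetic on a precomputed (sup grid x ISIs) lattice per bin.

    Parameters
    ----------
    K : number of sup-grid points per bin in (0, I_max + eps].
    eps_frac : eps as a fraction of the bin's largest ISI.
    """

    _method_name = "fortet"

    def __init__(
        self,
        Omega: float = 1.0,
        M: int | None = None,
        K: int = K_DEFAULT,
        eps_frac: float = 0.01,
        init: ModelParams | tuple | str = "auto",
        xtol: float = 1e-3,
        ftol: float = 1e-3,
        maxiter: int = 300,
        n_restarts: int = 2,
    ):
        super().__init__(Omega=Omega, M=M, init=init, xtol=xtol, ftol=ftol,
                         maxiter=maxiter, n_restarts=n_restarts)
        self.K = K
        self.eps_frac = eps_frac

    def _make_objective(self, data: BinnedData):
        ws = FortetWorkspace(data, K=self.K, eps_frac=self.eps_frac)
        half = math.pi / data.bins.Omega

        def obj(m: ModelParams, gamma: float) -> float:
            if gamma >= 0:
                mm = ModelParams(alpha=m.alpha, beta=m.beta, gamma=gamma,
                                 Omega=m.Omega)
                return ws.loss(mm)
            # phase-flip trick for negative amplitudes (see fp objective)
            mm = ModelParams(alpha=m.alpha, beta=m.beta, gamma=-gamma,
                             Omega=m.Omega)
            return ws_loss_shifted(ws, mm, half)

        return obj


def ws_loss_shifted(ws: FortetWorkspace, m: ModelParams, shift: float) -> float:
    total = 0.0
    for b in ws.bins:
        b2 = dict(b)
        b2["phi"] = b["phi"] + shift
        total += b["n"] * ws._residual(b2, m)
    return total


class BellInitializer(BaseEstimator):
    """The Gaussian-bell least-squares initial guess as a standalone estimator.

    Useful both to seed the optimization-based estimators and as a cheap
    (biased, optimization-free) estimator in its own right.
    """

    _method_name = "initializer-only"

    def __init__(self, Omega: float = 1.0, M: int | None = None,
                 scheme: str = "one-sigma"):
        self.Omega = Omega
        self.M = M
        self.scheme = scheme

    def fit(self, X, y=None):
        train = _as_train(X, self.Omega)
        M = self.M if self.M is not None else default_n_bins(len(train))
        data = bin_train(train, M)
        p = initialize(data, self.Omega, scheme=self.scheme)
        self.alpha_, self.beta_, self.gamma_ = p.alpha, p.beta, p.gamma
        self.gamma_raw_ = p.gamma
        self.params_ = p
        self.loss_ = float("nan")
        self.n_evals_ = 0
        self.converged_ = True
        self.init_params_ = p
        self.M_ = M
        return self

    def result(self, seed: int | None = None) -> EstimateResult:
        return EstimateResult(
            params_hat=self.params_,
            method=self._method_name,
            loss_value=self.loss_,
            n_evals=0,
            converged=True,
            init_used=self.init_params_,
            M_used=self.M_,
            gamma_raw=self.gamma_raw_,
            seed=seed,
        )


_METHODS = {
    "fp": lambda **kw: FokkerPlanckEstimator(objective="survivor", **kw),
    "fokker-planck": lambda **kw: FokkerPlanckEstimator(objective="survivor", **kw),
    "mle": lambda **kw: FokkerPlanckEstimator(objective="mle", **kw),
    "fortet": lambda **kw: FortetEstimator(**kw),
    "initializer": lambda **kw: BellInitializer(**kw),
    "initializer-only": lambda **kw: BellInitializer(**kw),
}


def fit(
    train: SpikeTrain,
    method: str = "fortet",
    M: int | None = None,
    init: ModelParams | tuple | str = "auto",
    seed: int | None = None,
    **options,
) -> EstimateResult:
    """One-call estimation: bins the train, initializes, optimizes.

    ``method`` is one of "fp"/"fokker-planck", "fortet", "mle",
    "initializer".  Deterministic given (train, init, options).
    """
    try:
        factory = _METHODS[method]
    except KeyError:
        raise ValueError(f"unknown method {method!r}; choose from {sorted(_METHODS)}") from None
    kw = dict(Omega=train.Omega, M=M, **options)
    if method not in ("initializer", "initializer-only"):
        kw["init"] = init
    est = factory(**kw)
    est.fit(train)
    return est.result(seed=seed)
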