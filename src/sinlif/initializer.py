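"""Automatic starting values from a travelling-Gaussian-bell approximation.

Early on, before much probability has been absorbed, the sub-threshold
density behaves like the solution of a constant-coefficient advection-
diffusion equation: a Gaussian bell of standard deviation beta*sqrt(t)
drifting toward the threshold with speed U ~ alpha - 0.5 + (time-averaged
sinusoid).  Reading off the times at which the empirical survivor crosses
fixed Gaussian tail levels turns each phase bin into linear equations in
(alpha, beta, gamma), solved across all bins by ordinary least squares.
The result is a fast, fully automatic initial guess -- crude in regimes
where diffusion rather than drift carries the mass over the threshold, but
good enough to start the optimization-based estimators.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.special import ndtr

from .binning import BinnedData, SurvivorCurve
from .model import ModelParams

__all__ = [
    "crossing_time",
    "sine_time_average",
    "initialize",
    "initialize_from_curves",
    "ONE_SIGMA_TAIL",
    "DEFAULT_FALLBACK",
]

#: Mass of a Gaussian more than one standard deviation above its mean (~0.158).
ONE_SIGMA_TAIL = float(1.0 - ndtr(1.0))

#: Fallback guess when the regression is rank deficient.
DEFAULT_FALLBACK = (1.0, 0.3, 0.5)

#: Post-solve floor on beta: least squares can return a small or negative
#: noise amplitude; the downstream optimizer corrects it.
BETA_FLOOR = 0.05

# (survivor level, sigma coefficient) pairs per scheme.  The default pairs
# the 2-sigma tail level with coefficient 2 and the 1-sigma level with
# coefficient 1, matching the bell geometry "the c-sigma right tail has
# crossed when G = Phi(c)":  U t + c beta sqrt(t) = 1.  The "one-sigma"
# variant instead uses the symmetric 1-sigma pair (levels Phi(1), Phi(-1)
# with coefficients +1, -1).
_SCHEMES = {
    "two-sigma": ((float(ndtr(2.0)), 2.0), (float(ndtr(1.0)), 1.0)),
    "one-sigma": ((float(ndtr(1.0)), 1.0), (float(ndtr(-1.0)), -1.0)),
}


def crossing_time(curve: SurvivorCurve, level: float) -> float | None:
    """First time the linearly interpolated survivor curve reaches ``level``.

    Returns ``None`` (missing) when the curve never descends to the level.
    """
    if not 0.0 < level < 1.0:
        raise ValueError(f"level must lie strictly in (0, 1), got {level}")
    t = curve.times
    v = curve.values
    below = np.flatnonzero(v <= level)
    if below.size == 0:
        return None
    j = int(below[0])
    if j == 0:
        return float(t[0])
    v0, v1 = v[j - 1], v[j]
    if v0 == v1:
        return float(t[j])
    return float(t[j - 1] + (v0 - level) / (v0 - v1) * (t[j] - t[j - 1]))


def sine_time_average(Omega: float, phi: float, t) -> np.ndarray | float:
    """Integral of the forcing over an interval of length t:

    s(t) = int_0^t sin(Omega(u + phi)) du = (cos(Omega phi) - cos(Omega(t + phi))) / Omega.
    """
    t = np.asarray(t, dtype=float)
    out = (math.cos(Omega * phi) - np.cos(Omega * (t + phi))) / Omega
    return out if out.ndim else float(out)


def _bin_survivor_knots(isis: np.ndarray) -> SurvivorCurve:
    """Piecewise-linear survivor through the step-function corners."""
    isis = np.sort(np.asarray(isis, dtype=float))
    n = isis.size
    vals = 1.0 - np.arange(1, n + 1) / n
    # collapse duplicate ISIs to their final (lowest) survivor value
    uniq, last_idx = np.unique(isis[::-1], return_index=True)
    vals = vals[::-1][last_idx]
    return SurvivorCurve(
        times=np.concatenate(([0.0], uniq)), values=np.concatenate(([1.0], vals))
    )


def initialize_from_curves(
    curves: list[SurvivorCurve],
    phis: np.ndarray,
    Omega: float,
    scheme: str = "one-sigma",
) -> tuple[float, float, float, bool]:
    """Least-squares bell fit from per-bin survivor curves.

    For each curve, each (level L, coefficient c) pair whose crossing time
    t_c exists contributes the row

        alpha * t_c  +  beta * c * sqrt(t_c)  +  gamma * s(t_c)  =  1 + 0.5 * t_c,

    where s(.) integrates the sinusoid at the bin's representative phase.
    Returns (alpha, beta, gamma, ok); ``ok`` is False when the system was
    rank deficient and the fixed fallback was used.  beta is floored at
    ``BETA_FLOOR`` after the solve.
    """
    pairs = _SCHEMES[scheme]
    rows, rhs = [], []
    for curve, phi in zip(curves, phis):
        for level, coeff in pairs:
            tc = crossing_time(curve, level)
            if tc is None or tc <= 0.0:
                continue
            rows.append([tc, coeff * math.sqrt(tc), float(sine_time_average(Omega, phi, tc))])
            rhs.append(1.0 + 0.5 * tc)
    if len(rows) < 3:
        warnings.warn(
            "too few usable survivor crossings for the bell regression; "
            "falling back to the default initial guess",
            stacklevel=2,
        )
        return (*DEFAULT_FALLBACK, False)
    A = np.asarray(rows)
    b = np.asarray(rhs)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        warnings.warn(
            "bell regression is rank deficient; falling back to the default "
            "initial guess",
            stacklevel=2,
        )
        return (*DEFAULT_FALLBACK, False)
    alpha, beta, gamma = (float(v) for v in sol)
    return alpha, max(beta, BETA_FLOOR), gamma, True


def initialize(
    data: BinnedData, Omega: float | None = None, scheme: str = "one-sigma"
) -> ModelParams:
    """Initial guess (alpha, beta, gamma) from binned ISIs.

    Bins with fewer than two ISIs carry no usable survivor shape and are
    skipped; the fallback guess is returned (with a warning) if the stacked
    system cannot pin down all three parameters.  Never raises on valid,
    nonempty data.
    """
    if Omega is None:
        Omega = data.bins.Omega
    centers = data.bins.centers
    curves, phis = [], []
    for mth, isis in enumerate(data.members):
        if isis.size < 2:
            continue
        curves.append(_bin_survivor_knots(isis))
        phis.append(centers[mth])
    alpha, beta, gamma, _ = initialize_from_curves(
        curves, np.asarray(phis), Omega, scheme=scheme
    )
    return ModelParams(alpha=alpha, beta=beta, gamma=max(gamma, 0.0), Omega=Omega)
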