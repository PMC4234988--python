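"""Fortet integral-equation machinery for the forced OU first-passage law.

Subtracting the deterministic (noise-free) trajectory v(t) from the voltage
X turns the sinusoidally forced process into a plain Ornstein-Uhlenbeck
process Y = X - v with a known Gaussian transition law, at the price of a
moving threshold  b(t) = 1 - v(t).  The Fortet identity then links the ISI
density g to the free transition CDF Phi:

    1 - Phi(b(t), t | 0, 0) = integral_0^t g(u) [1 - Phi(b(t), t | b(u), u)] du.

Replacing the integral by an empirical average over observed ISIs (law of
large numbers within a phase bin) gives an estimating equation: at the true
parameters the two sides agree up to sampling noise, and their normalized
sup-distance is the per-bin residual minimized by the Fortet estimator.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.special import ndtr

from .binning import BinnedData
from .model import ModelParams

__all__ = [
    "deterministic_voltage",
    "moving_threshold",
    "transition_cdf",
    "fortet_residual",
    "fortet_loss",
    "FortetWorkspace",
]

#: Number of evaluation points for the sup over (0, I_max + eps].
K_DEFAULT = 500

#: eps = EPS_FRAC * I_max extends the sup grid slightly past the largest ISI.
EPS_FRAC = 0.01

_OMEGA_TINY = 1e-12


def deterministic_voltage(m: ModelParams, phi: float, t) -> np.ndarray | float:
    """Noise-free voltage v(t) from v(0) = 0 at onset phase ``phi``:

    v(t) = alpha (1 - e^-t)
           + gamma/sqrt(1+Omega^2) [sin(Omega(t+phi) - psi) - e^-t sin(Omega phi - psi)]

    with psi = arctan(Omega).
    """
    t = np.asarray(t, dtype=float)
    psi = math.atan(m.Omega)
    amp = m.gamma / math.sqrt(1.0 + m.Omega**2)
    et = np.exp(-t)
    v = m.alpha * (1.0 - et) + amp * (
        np.sin(m.Omega * (t + phi) - psi) - et * math.sin(m.Omega * phi - psi)
    )
    return v if v.ndim else float(v)


def moving_threshold(m: ModelParams, phi: float, t) -> np.ndarray | float:
    """Threshold seen by the homogenized OU process: b(t) = 1 - v(t)."""
    return 1.0 - deterministic_voltage(m, phi, t)


def transition_cdf(beta: float, y, t, y0, t0) -> np.ndarray | float:
    """Free OU transition CDF  P(Y_t <= y | Y_t0 = y0)  for dY = -Y dt + beta dW.

    Gaussian with mean y0*exp(-(t-t0)) and variance (beta^2/2)(1 - exp(-2(t-t0))).
    Evaluated through the complementary-error-function route (scipy's ndtr)
    for tail stability.
    """
    t = np.asarray(t, dtype=float)
    t0 = np.asarray(t0, dtype=float)
    if np.any(t <= t0):
        raise ValueError("transition_cdf requires t > t0")
    d = t - t0
    mean = np.asarray(y0, dtype=float) * np.exp(-d)
    sd = beta * np.sqrt(0.5 * (1.0 - np.exp(-2.0 * d)))
    out = ndtr((np.asarray(y, dtype=float) - mean) / sd)
    return out if out.ndim else float(out)


class FortetWorkspace:
    """Parameter-independent scaffolding for repeated Fortet-loss evaluations.

    For each nonempty bin the sup grid, the pairwise time lags between grid
    points and observed ISIs, and the derived exponential factors depend only
    on the data -- they are precomputed once so each loss evaluation reduces
    to elementwise Gaussian-CDF arithmetic.
    """

    def __init__(self, data: BinnedData, K: int = K_DEFAULT, eps_frac: float = EPS_FRAC):
        self.Omega = data.bins.Omega
        self.K = int(K)
        self.bins = []
        centers = data.bins.centers
        for mth, isis in enumerate(data.members):
            if isis.size == 0:
                continue
            i_max = isis.max()
            s = np.linspace(0.0, i_max * (1.0 + eps_frac), self.K + 1)[1:]
            delta = s[:, None] - isis[None, :]
            mask = delta > 0.0  # strict i_n < s
            dpos = np.where(mask, delta, 1.0)
            E = np.where(mask, np.exp(-dpos), 0.0)
            S = np.where(mask, np.sqrt(0.5 * (1.0 - np.exp(-2.0 * dpos))), 1.0)
            S0 = np.sqrt(0.5 * (1.0 - np.exp(-2.0 * s)))
            self.bins.append(
                {
                    "phi": centers[mth],
                    "isis": isis,
                    "n": isis.size,
                    "s": s,
                    "mask": mask,
                    "E": E,
                    "S": S,
                    "S0": S0,
                }
            )
        if not self.bins:
            raise ValueError("all phase bins are empty")

    def _residual(self, b: dict, m: ModelParams) -> float:
        bth_s = 1.0 - deterministic_voltage(m, b["phi"], b["s"])
        bth_i = 1.0 - deterministic_voltage(m, b["phi"], b["isis"])
        lhs = 1.0 - ndtr(bth_s / (m.beta * b["S0"]))
        omega = np.abs(lhs).max()
        if omega < _OMEGA_TINY:
            warnings.warn(
                "degenerate bin: threshold-exceedance probability vanishes on "
                "the whole sup grid; residual set to 0",
                stacklevel=3,
            )
            return 0.0
        z = (bth_s[:, None] - bth_i[None, :] * b["E"]) / (m.beta * b["S"])
        terms = (1.0 - ndtr(z)) * b["mask"]
        rhs = terms.sum(axis=1) / b["n"]
        return float(np.abs(lhs - rhs).max() / omega)

    def loss(self, m: ModelParams) -> float:
        """Sum over bins of N_m times the normalized sup residual."""
        return float(sum(b["n"] * self._residual(b, m) for b in self.bins))


def fortet_residual(
    bin_isis: np.ndarray,
    m: ModelParams,
    phi_m: float,
    s_grid: np.ndarray | None = None,
    K: int = K_DEFAULT,
    eps_frac: float = EPS_FRAC,
) -> float:
    """Normalized sup-distance between the two sides of the Fortet identity.

    LHS(s) = 1 - Phi(b(s), s | 0, 0); RHS(s) is the empirical average of
    1 - Phi(b(s), s | b(i_n), i_n) over ISIs with i_n < s; the sup of
    |LHS - RHS| over the grid is divided by omega = sup|LHS| so the residual
    lies in [0, 1] for every parameter value.
    """
    isis = np.sort(np.asarray(bin_isis, dtype=float))
    if isis.size == 0:
        raise ValueError("bin is empty")
    if s_grid is None:
        i_max = isis.max()
        s_grid = np.linspace(0.0, i_max * (1.0 + eps_frac), K + 1)[1:]
    s = np.asarray(s_grid, dtype=float)
    bth_s = 1.0 - deterministic_voltage(m, phi_m, s)
    bth_i = 1.0 - deterministic_voltage(m, phi_m, isis)
    lhs = 1.0 - ndtr(bth_s / (m.beta * np.sqrt(0.5 * (1.0 - np.exp(-2.0 * s)))))
    omega = np.abs(lhs).max()
    if omega < _OMEGA_TINY:
        warnings.warn("degenerate bin: sup|LHS| ~ 0; residual set to 0", stacklevel=2)
        return 0.0
    delta = s[:, None] - isis[None, :]
    mask = delta > 0.0
    dpos = np.where(mask, delta, 1.0)
    mean = bth_i[None, :] * np.exp(-dpos)
    sd = m.beta * np.sqrt(0.5 * (1.0 - np.exp(-2.0 * dpos)))
    terms = (1.0 - ndtr((bth_s[:, None] - mean) / sd)) * mask
    rhs = terms.sum(axis=1) / isis.size
    return float(np.abs(lhs - rhs).max() / omega)


def fortet_loss(data: BinnedData, m: ModelParams, K: int = K_DEFAULT) -> float:
    """Count-weighted Fortet loss  sum_m N_m * residual_m  over nonempty bins."""
    return FortetWorkspace(data, K=K).loss(m)
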