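"""Parameter containers, nondimensionalization and dynamical-regime tools.

The model is a leaky integrate-and-fire neuron driven by a constant bias, a
sinusoidal current and white noise,

    dV = ((mu - V)/tau + A sin(omega t)) dt + sigma dW,

with a spike-and-reset rule at a voltage threshold.  Rescaling time by the
membrane time constant ``tau`` and voltage by the threshold-to-reset distance
``v_th - v_0`` yields the nondimensional form

    dX = (alpha - X + gamma sin(Omega s)) ds + beta dW,   X(0) = 0,

with threshold fixed at 1 and reset at 0.  Estimation throughout the package
targets the triple (alpha, beta, gamma) with Omega assumed known.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

__all__ = [
    "DimensionalParams",
    "ModelParams",
    "nondimensionalize",
    "dimensionalize",
    "deterministic_spiking_index",
    "classify_regime",
    "critical_gamma",
    "REGIME_PRESETS",
    "get_preset",
]


@dataclass(frozen=True)
class DimensionalParams:
    """Biophysical (dimensional) LIF parameters.

    Attributes
    ----------
    mu : bias current expressed in voltage/time units.
    tau : membrane time constant (time), must be positive.
    A : amplitude of the sinusoidal drive (voltage/time).
    omega : angular frequency of the drive (1/time).
    sigma : noise strength (voltage/sqrt(time)), must be positive.
    v_th : spiking threshold voltage.
    v_0 : reset (resting) voltage, strictly below ``v_th``.
    """

    mu: float
    tau: float
    A: float
    omega: float
    sigma: float
    v_th: float
    v_0: float

    def __post_init__(self) -> None:
        if not self.tau > 0:
            raise ValueError(f"membrane time constant must be positive, got tau={self.tau}")
        if not self.sigma > 0:
            raise ValueError(f"noise strength must be positive, got sigma={self.sigma}")
        if not self.v_th > self.v_0:
            raise ValueError(
                f"threshold must exceed reset (v_th={self.v_th}, v_0={self.v_0}); "
                "the voltage scale v_th - v_0 would be degenerate"
            )


@dataclass(frozen=True)
class ModelParams:
    """Nondimensional structural parameters (alpha, beta, gamma) plus known Omega."""

    alpha: float
    beta: float
    gamma: float
    Omega: float

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if not self.Omega > 0:
            raise ValueError(f"Omega must be positive, got {self.Omega}")
        if self.gamma < 0:
            raise ValueError(f"gamma must be nonnegative, got {self.gamma}")

    @property
    def period(self) -> float:
        """Forcing period 2*pi/Omega, the range of onset phases."""
        return 2.0 * math.pi / self.Omega

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(alpha=d["alpha"], beta=d["beta"], gamma=d["gamma"], Omega=d["Omega"])


def nondimensionalize(p: DimensionalParams) -> ModelParams:
    """Map dimensional LIF parameters to the nondimensional triple plus Omega.

    alpha = mu*tau/(v_th - v_0), beta = sigma*sqrt(tau)/(v_th - v_0),
    gamma = A*tau/(v_th - v_0), Omega = omega*tau.
    """
    scale = p.v_th - p.v_0
    return ModelParams(
        alpha=p.mu * p.tau / scale,
        beta=p.sigma * math.sqrt(p.tau) / scale,
        gamma=p.A * p.tau / scale,
        Omega=p.omega * p.tau,
    )


def dimensionalize(m: ModelParams, tau: float, v_th: float, v_0: float) -> DimensionalParams:
    """Inverse of :func:`nondimensionalize` for a chosen (tau, v_th, v_0)."""
    if tau <= 0:
        raise ValueError("tau must be positive")
    if v_th <= v_0:
        raise ValueError("v_th must exceed v_0")
    scale = v_th - v_0
    return DimensionalParams(
        mu=m.alpha * scale / tau,
        tau=tau,
        A=m.gamma * scale / tau,
        omega=m.Omega / tau,
        sigma=m.beta * scale / math.sqrt(tau),
        v_th=v_th,
        v_0=v_0,
    )


def deterministic_spiking_index(m: ModelParams) -> float:
    """Return alpha + gamma/sqrt(1 + Omega^2).

    The noiseless model reaches threshold, and hence spikes periodically, if
    and only if this index exceeds 1: the deterministic voltage saturates at a
    sinusoid of mean ``alpha`` and amplitude ``gamma/sqrt(1+Omega^2)``.
    """
    return m.alpha + m.gamma / math.sqrt(1.0 + m.Omega**2)


def classify_regime(m: ModelParams, tol: float = 0.05) -> str:
    """Classify a parameter set into one of the four dynamical regimes.

    - ``supra-threshold``: the bias alone suffices, alpha > 1;
    - ``supersinusoidal``: spiking requires the sinusoid, alpha <= 1 and
      index > 1 + tol;
    - ``critical``: index within ``tol`` of 1;
    - ``subthreshold``: index < 1 - tol, no deterministic spiking.

    ``tol`` sets the half-width of the band called "critical"; the regime
    boundary itself is sharp, the band is a labelling convenience.  Labels
    are advisory metadata only: no estimation code branches on them.
    """
    if tol < 0:
        raise ValueError("tol must be nonnegative")
    idx = deterministic_spiking_index(m)
    if m.alpha > 1.0:
        return "supra-threshold"
    if abs(idx - 1.0) <= tol:
        return "critical"
    if idx > 1.0 + tol:
        return "supersinusoidal"
    return "subthreshold"


def critical_gamma(alpha: float, Omega: float) -> float:
    """Forcing amplitude placing (alpha, gamma) exactly on the deterministic
    spiking boundary: gamma = (1 - alpha) * sqrt(1 + Omega^2).

    Only meaningful for alpha < 1 (otherwise no positive gamma is needed).
    """
    if alpha >= 1.0:
        raise ValueError("critical_gamma requires alpha < 1")
    return (1.0 - alpha) * math.sqrt(1.0 + Omega**2)


def _critical_preset(Omega: float) -> ModelParams:
    return ModelParams(alpha=0.5, beta=0.3, gamma=critical_gamma(0.5, Omega), Omega=Omega)


#: Named parameter sets for the four reference regimes (Omega = 1) and the
#: critical-regime frequency sweep.  These are the standard test-bed
#: configurations used throughout the replication study.
REGIME_PRESETS: dict[str, ModelParams] = {
    "supra": ModelParams(alpha=1.40, beta=0.30, gamma=0.14, Omega=1.0),
    "supersinusoidal": ModelParams(alpha=0.10, beta=0.30, gamma=1.98, Omega=1.0),
    "critical": ModelParams(alpha=0.50, beta=0.30, gamma=0.71, Omega=1.0),
    "subthreshold": ModelParams(alpha=0.40, beta=0.30, gamma=0.57, Omega=1.0),
    "critical-Omega1": _critical_preset(1.0),
    "critical-Omega5": _critical_preset(5.0),
    "critical-Omega10": _critical_preset(10.0),
    "critical-Omega20": _critical_preset(20.0),
}


def get_preset(name: str) -> ModelParams:
    """Look up a named regime preset (see :data:`REGIME_PRESETS`)."""
    try:
        return REGIME_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(REGIME_PRESETS)}"
        ) from None
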