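"""Phase binning: the renewal-process approximation for forced spike trains.

Under sinusoidal forcing the ISIs are neither independent nor identically
distributed -- each interval's law depends on the forcing phase at its onset.
Partitioning the phase circle [0, 2*pi/Omega) into M equal bins and treating
all ISIs whose onset falls in a bin as a renewal sample at the bin midpoint
phase turns the problem into M approximately homogeneous subproblems, at the
price of a phase-discretization error that shrinks as M grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import SpikeTrain

__all__ = [
    "PhaseBins",
    "BinnedData",
    "SurvivorCurve",
    "make_bins",
    "assign_bin",
    "bin_train",
    "bin_isis",
    "empirical_survivor",
    "default_n_bins",
]


@dataclass(frozen=True)
class PhaseBins:
    """Equal-width partition of the phase interval [0, 2*pi/Omega).

    Bin m (0-based) is the half-open cell [centers[m] - delta_phi/2,
    centers[m] + delta_phi/2), with centers[m] = delta_phi/2 + m*delta_phi.
    """

    M: int
    Omega: float

    @property
    def delta_phi(self) -> float:
        return 2.0 * np.pi / (self.Omega * self.M)

    @property
    def centers(self) -> np.ndarray:
        d = self.delta_phi
        return d / 2.0 + d * np.arange(self.M)


@dataclass(frozen=True)
class BinnedData:
    """ISIs grouped by onset-phase bin."""

    bins: PhaseBins
    members: tuple  # tuple of np.ndarray, one per bin (sorted ISIs)

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(m) for m in self.members])

    @property
    def n_total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class SurvivorCurve:
    """An estimate of P(ISI > t) on a time grid; starts at 1, nonincreasing."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape:
            raise ValueError("times and values must have equal shapes")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


def make_bins(M: int, Omega: float) -> PhaseBins:
    """Build the equal-width phase partition with midpoint representatives."""
    if M < 1:
        raise ValueError("M must be >= 1")
    if Omega <= 0:
        raise ValueError("Omega must be positive")
    return PhaseBins(M=int(M), Omega=float(Omega))


def assign_bin(phi: float, bins: PhaseBins) -> int:
    """Index of the bin whose center is closest to ``phi`` (0-based).

    Equivalent to the half-open cell containing ``phi``; a phase exactly on
    the upper cell boundary belongs to the next bin (lower-closed convention).
    """
    period = 2.0 * np.pi / bins.Omega
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0) or np.any(phi >= period):
        raise ValueError(f"phase out of range [0, {period:.6g})")
    idx = np.floor(phi / bins.delta_phi).astype(int)
    return np.minimum(idx, bins.M - 1) if idx.ndim else min(int(idx), bins.M - 1)


def default_n_bins(n_isis: int) -> int:
    """Default bin count: 20 for N >= 1000, 8 for N <= 100, N/50 between."""
    return int(max(8, min(20, n_isis / 50)))


def bin_isis(isis: np.ndarray, phases: np.ndarray, bins: PhaseBins) -> BinnedData:
    """Group ISIs by the phase at their onset; every ISI lands in one bin."""
    isis = np.asarray(isis, dtype=float)
    phases = np.asarray(phases, dtype=float)
    if isis.shape != phases.shape:
        raise ValueError("isis and phases must align")
    idx = assign_bin(phases, bins)
    members = tuple(
        np.sort(isis[idx == m]) for m in range(bins.M)
    )
    return BinnedData(bins=bins, members=members)


def bin_train(train: SpikeTrain, M: int | None = None) -> BinnedData:
    """Bin a spike train's ISIs by onset phase into M equal-width bins."""
    if len(train) == 0:
        raise ValueError("train is empty")
    if M is None:
        M = default_n_bins(len(train))
    bins = make_bins(M, train.Omega)
    return bin_isis(train.isis, train.onset_phases, bins)


def empirical_survivor(isis: np.ndarray, t_grid: np.ndarray) -> SurvivorCurve:
    """Empirical survivor  #{i_n > t} / N  on ``t_grid`` (strict inequality).

    Right-continuous step convention: at t equal to an observed ISI the count
    excludes it, so the curve reaches 0 at the largest observation.
    """
    isis = np.sort(np.asarray(isis, dtype=float))
    if isis.size == 0:
        raise ValueError("empty bin: no ISIs to build a survivor curve from")
    t_grid = np.asarray(t_grid, dtype=float)
    # #{i > t} = N - #{i <= t}
    n_le = np.searchsorted(isis, t_grid, side="right")
    values = (isis.size - n_le) / isis.size
    return SurvivorCurve(times=t_grid, values=values)
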