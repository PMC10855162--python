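"""Q grids, Monte-Carlo orientation sampling, and reciprocal-space rules of thumb.

Orientational averaging <...>_Omega is done by evaluating scattering vectors
Q_vec = Q * Omega for a fixed set of unit vectors Omega drawn uniformly on
the sphere from a seeded generator. The same orientation set is reused for
every Q magnitude and every frame, so that a corrected and an uncorrected
spectrum computed in the same run differ only by the correction, never by
sampling noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "QGrid",
    "TimeEnergyMap",
    "make_qgrid",
    "sample_orientations",
    "q_to_distance",
    "energy_to_time",
    "TIME_ENERGY_FACTOR",
]

#: hbar in ps*meV: converts energy transfer (meV) to time (ps).
TIME_ENERGY_FACTOR = 0.658


@dataclass(frozen=True)
class QGrid:
    """Scattering-vector magnitudes plus sampled orientations.

    Attributes
    ----------
    q_values : ndarray, shape (n_q,)
        Non-negative, strictly increasing magnitudes, A^-1.
    orientations : ndarray, shape (n_orient, 3)
        Unit vectors Omega.
    seed : int
        Seed of the generator that produced the orientations.
    """

    q_values: np.ndarray
    orientations: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        q = np.asarray(self.q_values, dtype=float)
        om = np.asarray(self.orientations, dtype=float)
        if np.any(q < 0) or np.any(np.diff(q) <= 0):
            raise ValueError("q_values must be non-negative and strictly increasing")
        norms = np.linalg.norm(om, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-12):
            raise ValueError("orientations must be unit vectors")
        object.__setattr__(self, "q_values", q)
        object.__setattr__(self, "orientations", om)

    @property
    def n_q(self) -> int:
        return len(self.q_values)

    @property
    def n_orient(self) -> int:
        return len(self.orientations)

    def qvectors(self) -> np.ndarray:
        """All Q vectors, shape (n_q, n_orient, 3)."""
        return self.q_values[:, None, None] * self.orientations[None, :, :]


def sample_orientations(n_orient: int, seed: int) -> np.ndarray:
    """Uniform unit vectors on the sphere via normalised 3D Gaussian draws."""
    if n_orient < 1:
        raise ValueError("n_orient must be >= 1")
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n_orient, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def make_qgrid(q_min: float, q_max: float, n_q: int, n_orient: int,
               seed: int = 0) -> QGrid:
    """Uniform Q grid (endpoints inclusive) with seeded MC orientations.

    Q = 0 is allowed: the scattering amplitude is evaluated exactly there
    (all phase factors are 1).
    """
    if n_q < 1:
        raise ValueError("n_q must be >= 1")
    if q_min > q_max:
        raise ValueError(f"q_min ({q_min}) > q_max ({q_max})")
    if q_min < 0:
        raise ValueError("q_min must be non-negative")
    q = np.linspace(q_min, q_max, n_q)
    return QGrid(q_values=q, orientations=sample_orientations(n_orient, seed),
                 seed=seed)


def q_to_distance(q: float) -> float:
    """Rule of thumb r ~ 2 pi / Q: distance (A) probed at magnitude Q (A^-1)."""
    if q <= 0:
        raise ValueError("Q must be positive")
    return 2.0 * math.pi / q


def energy_to_time(energy_mev: float) -> float:
    """Rule of thumb tau ~ 0.658 * 2 pi / (hbar omega): time scale (ps) of an
    energy transfer (meV)."""
    if energy_mev <= 0:
        raise ValueError("energy transfer must be positive")
    return TIME_ENERGY_FACTOR * 2.0 * math.pi / energy_mev


@dataclass(frozen=True)
class TimeEnergyMap:
    """A (tau, hbar*omega) pair linked by tau * E = 0.658 * 2 pi."""

    tau: float
    energy_transfer: float
    factor: float = TIME_ENERGY_FACTOR

    @classmethod
    def from_energy(cls, energy_mev: float) -> "TimeEnergyMap":
        return cls(tau=energy_to_time(energy_mev), energy_transfer=energy_mev)

    @classmethod
    def from_time(cls, tau_ps: float) -> "TimeEnergyMap":
        if tau_ps <= 0:
            raise ValueError("tau must be positive")
        return cls(tau=tau_ps,
                   energy_transfer=TIME_ENERGY_FACTOR * 2.0 * math.pi / tau_ps)
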