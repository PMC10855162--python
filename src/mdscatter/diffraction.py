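"""Coherent scattering amplitudes and orientation-averaged diffractograms.

The scattering function of N point scatterers with coherent lengths b_j at
positions R_j is

    S(Q) = < | F(Q_vec) |^2 >_{t, Omega},    F(Q_vec) = sum_j b_j e^{i Q_vec . R_j},

averaged over trajectory frames t and Monte-Carlo orientations Omega of the
scattering vector. Complex amplitudes are kept per (frame, Q, orientation)
until the very last step so that reciprocal-space corrections can subtract
a continuum amplitude *before* the modulus is squared.

Units: b in fm, coordinates in A, S in fm^2.

For validation the exact orientational average of S(Q) for an isotropic
ensemble is available in closed form (the Debye scattering equation); it is
kept as an independent O(N^2) oracle and is never used by the MC path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.spatial.distance import pdist

from .qspace import QGrid
from .trajectory import Trajectory

__all__ = [
    "Diffractogram",
    "scattering_amplitude",
    "diffractogram_naive",
    "debye_oracle",
    "normalize_diffractogram",
    "fit_scale_factor",
    "sinc",
]

NORMALIZATION_MODES = ("per-atom", "per-b2", "none")


def sinc(x: np.ndarray | float) -> np.ndarray:
    """sin(x)/x with sinc(0) = 1 (unnormalised convention)."""
    return np.sinc(np.asarray(x, dtype=float) / np.pi)


@dataclass
class Diffractogram:
    """Orientation/time-averaged diffraction pattern.

    Attributes
    ----------
    q : ndarray, shape (n_q,)
        Scattering-vector magnitudes, A^-1.
    S : ndarray, shape (n_q,)
        Averaged intensity <|F|^2>, fm^2.
    D : ndarray, shape (n_q,)
        Normalised intensity (see :func:`normalize_diffractogram`).
    stderr : ndarray, shape (n_q,)
        Monte-Carlo standard error of S over orientations.
    """

    q: np.ndarray
    S: np.ndarray
    D: np.ndarray
    stderr: np.ndarray
    n_frames: int
    n_orient: int
    method: str = "naive"
    seed: int | None = None
    normalization: str = "per-atom"

    def to_tsv(self, path: str | Path) -> None:
        """Write a TSV table; the header records method and seed."""
        import pandas as pd

        df = pd.DataFrame({"q": self.q, "S": self.S, "D": self.D,
                           "stderr": self.stderr})
        with open(path, "w") as fh:
            fh.write(f"# mdscatter diffractogram method={self.method} "
                     f"seed={self.seed} normalization={self.normalization} "
                     f"n_frames={self.n_frames} n_orient={self.n_orient}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.10g",
                      lineterminator="\n")


# ---------------------------------------------------------------------------
# amplitudes

def scattering_amplitude(coords: np.ndarray, b: np.ndarray,
                         qvecs: np.ndarray) -> np.ndarray:
    """F(Q_vec) = sum_j b_j exp(i Q_vec . R_j) for a batch of Q vectors.

    Parameters
    ----------
    coords : (N, 3) array, A
    b : (N,) array, fm
    qvecs : (..., 3) array, A^-1

    Returns
    -------
    complex ndarray of shape ``qvecs.shape[:-1]``, fm.
    """
    coords = np.asarray(coords, dtype=float)
    b = np.asarray(b, dtype=float)
    if coords.shape[0] != b.shape[0]:
        raise ValueError(f"{coords.shape[0]} coordinates vs {b.shape[0]} "
                         "scattering lengths")
    qflat = np.asarray(qvecs, dtype=float).reshape(-1, 3)
    n_atoms = coords.shape[0]
    out = np.empty(qflat.shape[0], dtype=complex)
    # chunk over Q vectors to bound the (N x block) phase matrix
    block = max(1, int(1.2e7 / max(n_atoms, 1)))
    for i in range(0, qflat.shape[0], block):
        phases = coords @ qflat[i:i + block].T  # (N, block)
        out[i:i + block] = b @ np.exp(1j * phases)
    return out.reshape(np.asarray(qvecs).shape[:-1])


def _averaged_intensity(
    traj: Trajectory,
    grid: QGrid,
    b: np.ndarray,
    subtract: Callable[[np.ndarray], np.ndarray] | None = None,
    stride: int = 1,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Mean intensity over frames and orientations, per Q magnitude.

    ``subtract``, if given, maps Q vectors (..., 3) to a complex continuum
    amplitude (fm) removed from F before squaring (reciprocal-space
    finite-size correction). Returns (S, stderr, n_frames_used); stderr is
    the spread of the frame-averaged per-orientation intensities divided by
    sqrt(n_orient), i.e. the MC error of the orientational average.
    """
    qvecs = grid.qvectors()                      # (n_q, n_orient, 3)
    sub = subtract(qvecs) if subtract is not None else None
    acc = np.zeros((grid.n_q, grid.n_orient))
    frames = traj.frames[::stride]
    for coords in frames:
        F = scattering_amplitude(coords, b, qvecs)
        if sub is not None:
            F = F - sub
        acc += F.real**2 + F.imag**2
    acc /= len(frames)
    S = acc.mean(axis=1)
    if grid.n_orient > 1:
        stderr = acc.std(axis=1, ddof=1) / np.sqrt(grid.n_orient)
    else:
        stderr = np.zeros_like(S)
    return S, stderr, len(frames)


def normalize_diffractogram(S: np.ndarray, mode: str, n_atoms: int,
                            b: np.ndarray | None = None) -> np.ndarray:
    """Map raw S(Q) [fm^2] to a diffractogram D(Q).

    Modes: ``per-atom`` D = S/N; ``per-b2`` D = S/(N <b^2>); ``none`` D = S.
    The exact absolute-scale convention is instrument-dependent, so the mode
    is a configuration choice rather than a hard-coded formula.
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"unknown normalization {mode!r}; "
                         f"choose from {NORMALIZATION_MODES}")
    if mode == "none":
        return np.asarray(S, dtype=float).copy()
    if mode == "per-atom":
        return np.asarray(S, dtype=float) / n_atoms
    if b is None:
        raise ValueError("per-b2 normalization needs the scattering lengths")
    mean_b2 = float(np.mean(np.asarray(b, dtype=float) ** 2))
    return np.asarray(S, dtype=float) / (n_atoms * mean_b2)


def diffractogram_naive(
    traj: Trajectory,
    grid: QGrid,
    b_coh: np.ndarray,
    normalization: str = "per-atom",
    stride: int = 1,
    force: bool = False,
) -> Diffractogram:
    """Orientation/time-averaged S(Q) without finite-size correction.

    Requires a wrapped trajectory (structure mode) unless ``force``.
    """
    traj.require_wrapped(force)
    S, err, nf = _averaged_intensity(traj, grid, b_coh, stride=stride)
    D = normalize_diffractogram(S, normalization, traj.n_atoms, b_coh)
    return Diffractogram(q=grid.q_values.copy(), S=S, D=D, stderr=err,
                         n_frames=nf, n_orient=grid.n_orient,
                         method="naive", seed=grid.seed,
                         normalization=normalization)


# ---------------------------------------------------------------------------
# oracles and fitting helpers

def debye_oracle(coords: np.ndarray, b: np.ndarray,
                 q_values: np.ndarray) -> np.ndarray:
    """Exact orientational average of S(Q) via the Debye scattering equation.

    S(Q) = sum_j sum_k b_j b_k sinc(Q r_jk). O(N^2) pair sum; intended as an
    independent validation oracle for small systems, not as a production path.
    """
    coords = np.asarray(coords, dtype=float)
    b = np.asarray(b, dtype=float)
    q = np.atleast_1d(np.asarray(q_values, dtype=float))
    n = len(b)
    if n > 2000:
        warnings.warn(f"debye_oracle is O(N^2); N={n} will be slow")
    self_term = float(np.sum(b * b))
    if n == 1:
        return np.full(q.shape, self_term)
    r = pdist(coords)                     # (n_pairs,)
    w = b[:, None] * b[None, :]
    iu = np.triu_indices(n, k=1)
    w_pairs = w[iu]
    out = np.empty(len(q))
    for i, qi in enumerate(q):
        out[i] = self_term + 2.0 * float(w_pairs @ sinc(qi * r))
    return out


def fit_scale_factor(q_a: np.ndarray, curve_a: np.ndarray,
                     q_b: np.ndarray, curve_b: np.ndarray,
                     q_window: tuple[float, float]) -> float:
    """Least-squares multiplicative factor s minimising sum (a - s b)^2.

    ``curve_b`` is interpolated onto ``q_a`` inside the window. Replaces
    by-eye intensity matching between curves that differ by a constant
    factor (e.g. solute-only reference vs corrected full-system curve).
    """
    q_a = np.asarray(q_a, dtype=float)
    q_b = np.asarray(q_b, dtype=float)
    lo, hi = q_window
    mask = (q_a >= lo) & (q_a <= hi) & (q_a >= q_b.min()) & (q_a <= q_b.max())
    if not mask.any():
        raise ValueError(f"no overlapping Q support in window {q_window}")
    a = np.asarray(curve_a, dtype=float)[mask]
    bb = np.interp(q_a[mask], q_b, np.asarray(curve_b, dtype=float))
    denom = float(bb @ bb)
    if denom == 0.0:
        raise ValueError("reference curve vanishes on the window")
    return float(a @ bb) / denom
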