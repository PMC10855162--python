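"""Incoherent intermediate scattering function I_inc(Q, tau).

The incoherent (self-correlation) channel weights each atom by the square
of its incoherent scattering length:

    I_inc(Q, tau) = sum_j (b_j^inc)^2
                    < exp(i Q_vec . [R_j(t + tau) - R_j(t)]) >_{t, Omega}.

The reference-time average over t is an autocorrelation of the per-atom
phase signal s_j(t) = exp(i Q_vec . R_j(t)) and is evaluated with the
unbiased all-origins estimator via zero-padded FFTs: every available time
origin contributes at every lag, which keeps the large-tau tail of the
curve quiet. Dynamics input must be unwrapped — a periodic jump would be a
huge fake displacement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .qspace import QGrid
from .trajectory import Trajectory

__all__ = [
    "ISFResult",
    "autocorrelate",
    "isf_incoherent",
    "normalize_isf",
    "fit_diffusion",
]


@dataclass
class ISFResult:
    """Incoherent intermediate scattering function on a (Q, tau) grid.

    ``I`` is in fm^2; ``I_norm`` is I(Q,tau)/I(Q,0), exactly 1 at tau = 0.
    ``stderr`` is the MC spread over orientations of I_norm.
    """

    q: np.ndarray            # (n_q,)
    tau: np.ndarray          # (n_tau,) ps
    I: np.ndarray            # (n_q, n_tau) fm^2
    I_norm: np.ndarray       # (n_q, n_tau)
    stderr: np.ndarray       # (n_q, n_tau)
    n_time_origins: int
    n_orient: int
    seed: int | None = None

    def to_tsv(self, path: str | Path) -> None:
        """Long-format TSV (q, tau, I, I_norm, stderr) with a metadata header."""
        import pandas as pd

        qq, tt = np.meshgrid(self.q, self.tau, indexing="ij")
        df = pd.DataFrame({
            "q": qq.ravel(), "tau": tt.ravel(),
            "I": self.I.ravel(), "I_norm": self.I_norm.ravel(),
            "stderr": self.stderr.ravel(),
        })
        with open(path, "w") as fh:
            fh.write(f"# mdscatter isf seed={self.seed} "
                     f"n_time_origins={self.n_time_origins} "
                     f"n_orient={self.n_orient}\n")
            df.to_csv(fh, sep="\t", index=False, float_format="%.10g",
                      lineterminator="\n")


def _autocorrelate_batch(signals: np.ndarray) -> np.ndarray:
    """Unbiased all-origins autocorrelation along the last axis.

    C(k) = 1/(M-k) * sum_{t=0}^{M-1-k} s(t+k) s*(t), via zero-padded FFT.
    """
    signals = np.asarray(signals, dtype=complex)
    m = signals.shape[-1]
    if m == 0:
        raise ValueError("empty time series")
    nfft = 1 << int(np.ceil(np.log2(2 * m)))
    F = np.fft.fft(signals, n=nfft, axis=-1)
    corr = np.fft.ifft(F * np.conj(F), axis=-1)[..., :m]
    counts = m - np.arange(m)
    return corr / counts


def autocorrelate(signal: np.ndarray) -> np.ndarray:
    """Unbiased time-origin-averaged autocorrelation of one complex series."""
    signal = np.asarray(signal, dtype=complex)
    if signal.ndim != 1:
        raise ValueError("autocorrelate expects a 1-D series")
    return _autocorrelate_batch(signal)


def isf_incoherent(
    traj: Trajectory,
    grid: QGrid,
    b_inc: np.ndarray,
    force: bool = False,
    tau_stride: int = 1,
) -> ISFResult:
    """Incoherent intermediate scattering function from an unwrapped trajectory.

    For each orientation and Q magnitude the per-atom phase series is
    autocorrelated over all time origins, weighted by (b_inc)^2, summed over
    atoms and averaged over orientations. ``tau_stride`` decimates the
    returned lag grid (the correlations themselves always use every frame).
    """
    traj.require_unwrapped(force)
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames for a correlation in time")
    b2 = np.asarray(b_inc, dtype=float) ** 2
    if len(b2) != traj.n_atoms:
        raise ValueError(f"{len(b2)} scattering lengths for {traj.n_atoms} atoms")
    m = traj.n_frames
    nq, no = grid.n_q, grid.n_orient
    acc = np.zeros((nq, no, m))
    # frames as (M, N, 3); for one qvec the phase matrix is (N, M)
    for io, omega in enumerate(grid.orientations):
        proj = traj.frames @ omega          # (M, N)
        for iq, qmag in enumerate(grid.q_values):
            s = np.exp(1j * qmag * proj.T)  # (N, M)
            corr = _autocorrelate_batch(s)  # (N, M)
            acc[iq, io] = b2 @ corr.real
    tau = np.arange(m) * traj.dt
    I_per_orient = acc                       # fm^2
    I = I_per_orient.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        inorm_per_orient = I_per_orient / I_per_orient[:, :, :1]
    I_norm = normalize_isf(I)
    if no > 1:
        stderr = inorm_per_orient.std(axis=1, ddof=1) / np.sqrt(no)
    else:
        stderr = np.zeros_like(I)
    sl = slice(None, None, tau_stride)
    return ISFResult(q=grid.q_values.copy(), tau=tau[sl], I=I[:, sl],
                     I_norm=I_norm[:, sl], stderr=stderr[:, sl],
                     n_time_origins=m, n_orient=no, seed=grid.seed)


def normalize_isf(I: np.ndarray) -> np.ndarray:
    """I_norm(Q, tau) = I(Q, tau) / I(Q, 0), row-wise."""
    I = np.asarray(I, dtype=float)
    I0 = I[..., :1]
    if np.any(I0 <= 0):
        raise ValueError("I(Q, tau=0) must be positive for normalization")
    return I / I0


def fit_diffusion(i_norm: np.ndarray, tau: np.ndarray, q: float,
                  decade: float = 0.1) -> float:
    """Self-diffusion coefficient from the free-diffusion decay
    I_norm = exp(-Q^2 D tau), A^2/ps.

    A log-linear least-squares fit through the origin over the initial
    decade of decay (points with I_norm >= ``decade``). Raises on
    non-decaying input.
    """
    i_norm = np.asarray(i_norm, dtype=float)
    tau = np.asarray(tau, dtype=float)
    if q <= 0:
        raise ValueError("Q must be positive")
    mask = (i_norm >= decade) & (i_norm > 0) & (tau >= 0)
    if mask.sum() < 3:
        raise ValueError("too few points in the initial decay window")
    t = tau[mask]
    y = np.log(i_norm[mask])
    denom = float(t @ t)
    if denom == 0:
        raise ValueError("degenerate tau grid")
    slope = float(t @ y) / denom          # = -Q^2 D
    d = -slope / q**2
    if d <= 0:
        raise ValueError("input does not decay; cannot fit a diffusion "
                         "coefficient")
    return d
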