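"""Trajectory I/O with explicit wrapped/unwrapped semantics.

Structure calculations (diffraction) need coordinates folded into the
periodic cell so the density is right; dynamics calculations (intermediate
scattering functions) need continuous, *unwrapped* coordinates so atoms do
not jump across the box. The two conventions are incompatible, so the
wrapped/unwrapped state is carried as an explicit, user-declared flag that
downstream calculations check and refuse to violate unless forced.

File parsing is delegated to MDAnalysis (PDB, DCD, XYZ); this module owns
the frame model, the element-resolution fallback and the selection rules.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "Trajectory",
    "AtomSelection",
    "WrappedStateError",
    "read_structure",
    "read_trajectory",
    "read_xyz",
    "select_atoms",
]


class WrappedStateError(ValueError):
    """A calculation received a trajectory in the wrong wrapping convention."""


@dataclass
class Trajectory:
    """In-memory trajectory: per-frame coordinates plus box and metadata.

    Attributes
    ----------
    labels : ndarray of str, shape (N,)
        Per-atom species labels.
    frames : ndarray, shape (n_frames, N, 3)
        Cartesian coordinates R_j(t), A.
    box : ndarray, shape (n_frames, 3)
        Cuboid edge lengths (a, b, c) per frame, A.
    dt : float
        Frame spacing, ps.
    wrapped : bool
        Coordinate convention flag (see module docstring).
    origin : ndarray, shape (3,)
        Lower corner of the periodic cell; the cell occupies
        [origin, origin + box) per axis.
    """

    labels: np.ndarray
    frames: np.ndarray
    box: np.ndarray
    dt: float = 1.0
    wrapped: bool = True
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        self.frames = np.asarray(self.frames, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError(f"frames must have shape (n_frames, N, 3), "
                             f"got {self.frames.shape}")
        if self.frames.shape[1] != len(self.labels):
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"{len(self.labels)} labels")
        if self.box.ndim == 1:
            self.box = np.tile(self.box, (self.n_frames, 1))
        if self.wrapped and np.any(self.box <= 0):
            raise ValueError("wrapped trajectories need positive box edges")

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def check_containment(self, tol: float = 1e-6) -> bool:
        """True when every coordinate lies within [origin, origin+box] per axis."""
        lo = self.origin - tol
        hi = self.origin + self.box[:, None, :] + tol
        return bool(np.all(self.frames >= lo) and np.all(self.frames <= hi))

    def require_wrapped(self, force: bool = False) -> None:
        """Guard for structure calculations (diffraction)."""
        if not self.wrapped and not force:
            raise WrappedStateError(
                "structure calculations need a wrapped trajectory (correct "
                "density inside the periodic cell); pass force=True to override")

    def require_unwrapped(self, force: bool = False) -> None:
        """Guard for dynamics calculations (intermediate scattering)."""
        if self.wrapped and not force:
            raise WrappedStateError(
                "dynamics calculations need an unwrapped trajectory (atoms "
                "must not jump across periodic boundaries); pass force=True "
                "to override")


@dataclass(frozen=True)
class AtomSelection:
    """Subset of atom indices (0-based) and the rule that built it."""

    indices: np.ndarray
    rule: str

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if len(np.unique(idx)) != len(idx):
            raise ValueError("selection indices must be unique")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


# ---------------------------------------------------------------------------
# element resolution

# two-letter chemical symbols that occur in biomolecular PDB files
_TWO_LETTER = {"CL", "BR", "NA", "MG", "FE", "ZN", "CA", "MN", "CU", "SE", "SI"}


def _element_from_name(name: str) -> str:
    """Fall back from a PDB atom name ("OW", "HW1", "CA") to an element.

    Strips digits/primes, then prefers a known two-letter symbol, else the
    first alphabetic character. Water-model names like OW/HW map to O/H.
    """
    clean = re.sub(r"[^A-Za-z]", "", name).upper()
    if not clean:
        raise ValueError(f"cannot resolve an element from atom name {name!r}")
    if clean[:2] in _TWO_LETTER:
        return clean[:2].capitalize()
    return clean[0]


def _labels_from_universe(u) -> np.ndarray:
    atoms = u.atoms
    labels = []
    if hasattr(atoms, "elements"):
        elements = atoms.elements
    else:
        elements = [""] * len(atoms)
    names = atoms.names if hasattr(atoms, "names") else [""] * len(atoms)
    for i, (el, nm) in enumerate(zip(elements, names)):
        el = str(el).strip()
        if el:
            labels.append(el if len(el) == 1 else el.capitalize())
        else:
            try:
                labels.append(_element_from_name(str(nm)))
            except ValueError:
                raise ValueError(
                    f"atom {i + 1}: no element column and atom name {nm!r} "
                    f"does not resolve to an element") from None
    return np.asarray(labels, dtype=object)


def _quiet_universe(*args, **kwargs):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(*args, **kwargs)


# ---------------------------------------------------------------------------
# readers

def read_structure(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a PDB structure file.

    Returns per-atom species labels (element column 77-78, with an
    atom-name fallback) and coordinates in file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    u = _quiet_universe(str(path))
    labels = _labels_from_universe(u)
    coords = u.atoms.positions.astype(float).copy()
    return labels, coords


def read_trajectory(
    structure: str | Path,
    trajectory: str | Path,
    dt: float = 1.0,
    wrapped: bool = True,
    box: Sequence[float] | None = None,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> Trajectory:
    """Read a PDB structure plus DCD coordinate trajectory.

    Byte order of the DCD is auto-detected by the reader. ``dt`` is taken
    from the caller (DCD time metadata is unreliable); ``box`` overrides or
    supplies the unit cell when the DCD carries none.
    """
    u = _quiet_universe(str(structure), str(trajectory))
    labels = _labels_from_universe(u)
    frames, boxes = [], []
    for ts in u.trajectory:
        if ts.n_atoms != len(labels):
            raise ValueError(
                f"frame {ts.frame}: atom count {ts.n_atoms} does not match "
                f"structure ({len(labels)})")
        frames.append(ts.positions.astype(float).copy())
        if box is not None:
            boxes.append(np.asarray(box, dtype=float))
        elif ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
            dims = ts.dimensions
            if not np.allclose(dims[3:], 90.0, atol=1e-3):
                raise ValueError(
                    f"frame {ts.frame}: non-cuboid cell (angles {dims[3:]}) "
                    "is not supported")
            boxes.append(dims[:3].astype(float).copy())
        else:
            raise ValueError(
                f"frame {ts.frame}: no unit cell in trajectory; supply box=")
    traj = Trajectory(labels=labels, frames=np.array(frames),
                      box=np.array(boxes), dt=dt, wrapped=wrapped,
                      origin=np.asarray(origin, dtype=float))
    if wrapped and not traj.check_containment(tol=1e-3):
        raise WrappedStateError(
            "trajectory declared wrapped but coordinates fall outside "
            "[origin, origin+box]; check the origin convention or declare "
            "wrapped=False")
    return traj


def read_xyz(
    path: str | Path,
    dt: float = 1.0,
    wrapped: bool = False,
    box: Sequence[float] | None = None,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
) -> Trajectory:
    """Read a (multi-frame) XYZ trajectory.

    XYZ files carry no unit cell; ``box`` must be supplied for wrapped use.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty XYZ file")
    _validate_xyz_blocks(path)
    u = _quiet_universe(str(path))
    labels = np.asarray([str(n) for n in u.atoms.names], dtype=object)
    frames = []
    for ts in u.trajectory:
        if ts.n_atoms != len(labels):
            raise ValueError(
                f"frame {ts.frame + 1}: atom count changed to {ts.n_atoms} "
                f"(expected {len(labels)})")
        frames.append(ts.positions.astype(float).copy())
    if box is None:
        if wrapped:
            raise ValueError("wrapped XYZ input needs an explicit box=")
        box_arr = np.zeros((len(frames), 3))
    else:
        box_arr = np.tile(np.asarray(box, dtype=float), (len(frames), 1))
    traj = Trajectory(labels=labels, frames=np.array(frames), box=box_arr,
                      dt=dt, wrapped=wrapped,
                      origin=np.asarray(origin, dtype=float))
    return traj


def _validate_xyz_blocks(path: Path) -> None:
    """Check that every XYZ frame block declares the same atom count."""
    n_ref = None
    frame = 0
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            frame += 1
            try:
                n = int(header.split()[0])
            except ValueError:
                raise ValueError(
                    f"{path}: frame {frame}: bad atom-count line "
                    f"{header.strip()!r}") from None
            if n_ref is None:
                n_ref = n
            elif n != n_ref:
                raise ValueError(
                    f"{path}: frame {frame}: atom count changed from "
                    f"{n_ref} to {n}")
            fh.readline()                      # comment line
            for _ in range(n):
                if not fh.readline():
                    raise ValueError(f"{path}: frame {frame}: truncated block")


# ---------------------------------------------------------------------------
# selections

_RANGE_RE = re.compile(r"^(\d+)(?:\.\.(\d+))?$")


def select_atoms(traj: Trajectory, rule: str) -> AtomSelection:
    """Build an :class:`AtomSelection` from a textual rule.

    Rules: ``all`` | ``species:<label>`` | ``indices:<list>`` where the list
    is comma-separated 1-based indices or ``lo..hi`` inclusive ranges
    (e.g. ``indices:1..10,15``).
    """
    rule = rule.strip()
    if rule == "all":
        return AtomSelection(np.arange(traj.n_atoms), rule)
    if rule.startswith("species:"):
        label = rule.split(":", 1)[1].strip()
        mask = np.array([str(l).upper() == label.upper() for l in traj.labels])
        if not mask.any():
            known = sorted({str(l) for l in traj.labels})
            raise ValueError(f"unknown species {label!r} in selection "
                             f"(trajectory has {known})")
        return AtomSelection(np.where(mask)[0], rule)
    if rule.startswith("indices:"):
        idx: list[int] = []
        for tok in rule.split(":", 1)[1].split(","):
            m = _RANGE_RE.match(tok.strip())
            if not m:
                raise ValueError(f"bad index token {tok!r} in {rule!r}")
            lo = int(m.group(1))
            hi = int(m.group(2)) if m.group(2) else lo
            if lo < 1 or hi > traj.n_atoms or lo > hi:
                raise ValueError(
                    f"index range {tok.strip()!r} outside 1..{traj.n_atoms}")
            idx.extend(range(lo - 1, hi))
        sel = AtomSelection(np.asarray(idx), rule)
        if len(sel) == 0:
            warnings.warn(f"selection {rule!r} is empty")
        return sel
    raise ValueError(
        f"unknown selection rule {rule!r}; use all | species:<label> | "
        f"indices:<ranges>")
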