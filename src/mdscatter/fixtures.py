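"""Synthetic test systems with exactly known scattering properties.

Three generators cover the validation needs of the scattering pipeline:

* :func:`make_toy_system` — the sphere-in-solvent lattice toy: 8000 sites on
  a simple cubic lattice (cell 1 A) filling a 20 A cube, sites within 5 A of
  the box centre labelled solute. Its small-angle pattern is known from the
  analytic sphere form factor, which makes it the ground-truth system for
  the finite-size corrections.
* :func:`make_homogeneous_lattice` — the same lattice with a single species;
  a naive diffractogram of it is *pure* finite-size artefact, so a
  reciprocal-space correction must annihilate it (null test).
* :func:`make_brownian_box` — independent Brownian particles with a known
  diffusion coefficient; the incoherent intermediate scattering function of
  free diffusion is exactly exp(-Q^2 D tau).

The toy "atoms" are element-agnostic: they are written to PDB with
placeholder labels and their scattering lengths are supplied through a
sidecar species table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .species import AtomSpecies, SpeciesTable
from .trajectory import Trajectory

__all__ = [
    "ToySpec",
    "BrownianSpec",
    "make_toy_system",
    "toy_species_table",
    "make_homogeneous_lattice",
    "make_brownian_box",
    "write_system",
    "write_species_table",
]

# vdW radius giving a vdW volume of exactly 1 A^3 = the toy's cubic cell
# volume, so the lattice "atoms" tile the box without gaps.
_R_UNIT_VOLUME = (3.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class ToySpec:
    """Sphere-in-solvent lattice toy (defaults are the validation system).

    ``b_solute``/``b_solvent`` are coherent scattering lengths in fm;
    lengths in A.
    """

    edge: float = 20.0
    cell: float = 1.0
    sphere_r: float = 5.0
    sphere_center: tuple[float, float, float] = (10.0, 10.0, 10.0)
    b_solute: float = -3.739
    b_solvent: float = 6.646
    solute_label: str = "U"
    solvent_label: str = "V"

    def __post_init__(self) -> None:
        n = self.edge / self.cell
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"edge/cell must be an integer, got {n}")
        c = np.asarray(self.sphere_center)
        if np.any(c - self.sphere_r < 0) or np.any(c + self.sphere_r > self.edge):
            raise ValueError("sphere must lie fully inside the box")

    @property
    def n_per_edge(self) -> int:
        return round(self.edge / self.cell)


@dataclass(frozen=True)
class BrownianSpec:
    """Box of independent Brownian particles.

    ``diffusion`` is D in A^2/ps; per axis and step the displacement is
    Gaussian with variance 2 D dt. Coordinates are unwrapped by construction.
    """

    n_particles: int = 500
    edge: float = 46.0
    diffusion: float = 0.5
    dt: float = 0.1
    n_frames: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_particles, self.n_frames) < 1 or self.edge <= 0 \
                or self.diffusion < 0 or self.dt <= 0:
            raise ValueError("BrownianSpec fields must be positive "
                             "(diffusion may be zero)")


def _lattice_sites(edge: float, cell: float) -> np.ndarray:
    """Simple cubic sites (i+1/2, j+1/2, k+1/2)*cell in the first octant."""
    n = round(edge / cell)
    ax = (np.arange(n) + 0.5) * cell
    gx, gy, gz = np.meshgrid(ax, ax, ax, indexing="ij")
    return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def make_toy_system(spec: ToySpec = ToySpec()) -> Trajectory:
    """Build the sphere-in-solvent toy as a 1-frame wrapped trajectory.

    Sites within ``sphere_r`` of ``sphere_center`` (r <= R; no site of the
    default geometry lies exactly at r = R) get the solute label.
    """
    coords = _lattice_sites(spec.edge, spec.cell)
    r = np.linalg.norm(coords - np.asarray(spec.sphere_center), axis=1)
    inside = r <= spec.sphere_r
    labels = np.where(inside, spec.solute_label, spec.solvent_label)
    return Trajectory(labels=labels.astype(object),
                      frames=coords[None, :, :],
                      box=np.array([[spec.edge] * 3]),
                      dt=1.0, wrapped=True)


def _placeholder_species(label: str, b_coh: float,
                         b_inc: float = 0.0) -> AtomSpecies:
    return AtomSpecies(label=label, b_coh=b_coh, b_inc=b_inc,
                       xray_a=(0.0,) * 4, xray_b=(0.0,) * 4, xray_c=0.0,
                       r_vdw=_R_UNIT_VOLUME)


def toy_species_table(spec: ToySpec = ToySpec()) -> SpeciesTable:
    """Sidecar table defining the toy's placeholder species (synthetic).

    The vdW radii are chosen so each site's vdW volume equals the 1 A^3
    lattice cell, which makes the real-space correction mask a homogeneous
    solvent exactly.
    """
    t = SpeciesTable(provenance="synthetic toy sidecar")
    t.add(_placeholder_species(spec.solute_label, spec.b_solute))
    t.add(_placeholder_species(spec.solvent_label, spec.b_solvent))
    return t


def make_homogeneous_lattice(edge: float = 20.0, cell: float = 1.0,
                             b: float = 1.0, label: str = "V"
                             ) -> tuple[Trajectory, SpeciesTable]:
    """Single-species lattice; implied SLD is b/cell^3 (b in fm -> 1e-5 A^-2)."""
    coords = _lattice_sites(edge, cell)
    labels = np.full(len(coords), label, dtype=object)
    traj = Trajectory(labels=labels, frames=coords[None, :, :],
                      box=np.array([[edge] * 3]), dt=1.0, wrapped=True)
    table = SpeciesTable(provenance="synthetic homogeneous lattice")
    table.add(_placeholder_species(label, b))
    return traj, table


def make_brownian_box(spec: BrownianSpec = BrownianSpec()) -> Trajectory:
    """Unwrapped trajectory of independent Brownian particles (seeded)."""
    rng = np.random.default_rng(spec.seed)
    start = rng.uniform(0.0, spec.edge, size=(spec.n_particles, 3))
    sigma = np.sqrt(2.0 * spec.diffusion * spec.dt)
    steps = rng.normal(0.0, sigma,
                       size=(spec.n_frames - 1, spec.n_particles, 3)) \
        if spec.n_frames > 1 else np.zeros((0, spec.n_particles, 3))
    frames = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    labels = np.full(spec.n_particles, "H", dtype=object)
    return Trajectory(labels=labels, frames=frames,
                      box=np.tile([spec.edge] * 3, (spec.n_frames, 1)),
                      dt=spec.dt, wrapped=False)


# ---------------------------------------------------------------------------
# writers (standard formats, via MDAnalysis)

def write_system(traj: Trajectory, prefix: str | Path,
                 formats: tuple[str, ...] = ("pdb", "dcd")) -> dict[str, Path]:
    """Write a trajectory as <prefix>.pdb / .dcd / .xyz.

    The PDB gets one ATOM record per atom with the species label in the
    element columns; DCD/XYZ carry all frames.
    """
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = traj.n_atoms
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n, trajectory=True)
        u.add_TopologyAttr("names", [str(l) for l in traj.labels])
        u.add_TopologyAttr("elements", [str(l) for l in traj.labels])
        u.add_TopologyAttr("resids", [1])
        u.add_TopologyAttr("resnames", ["SYS"])
        dims = np.column_stack([traj.box, np.full((traj.n_frames, 3), 90.0)])
        u.load_new(traj.frames.astype(np.float32), format=MemoryReader,
                   dimensions=dims)
        out: dict[str, Path] = {}
        for fmt in formats:
            path = prefix.with_suffix(f".{fmt}")
            if fmt == "pdb":
                u.trajectory[0]
                u.atoms.write(str(path))
            else:
                with mda.Writer(str(path), n) as w:
                    for _ in u.trajectory:
                        w.write(u.atoms)
            out[fmt] = path
    return out


def write_species_table(table: SpeciesTable, path: str | Path) -> Path:
    """Write a species table in the shipped TSV schema (sidecar file)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# mdscatter species sidecar: {table.provenance}\n")
        fh.write("# label b_coh b_inc a1 b1 a2 b2 a3 b3 a4 b4 c r_vdw\n")
        for sp in table.entries.values():
            gauss = "\t".join(
                f"{a:g}\t{b:g}" for a, b in zip(sp.xray_a, sp.xray_b))
            fh.write(f"{sp.label}\t{sp.b_coh:g}\t{sp.b_inc:g}\t{gauss}\t"
                     f"{sp.xray_c:g}\t{sp.r_vdw:.12g}\n")
    return path
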