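"""Run orchestration: config validation, dispatch, reproducible outputs.

A run is described by a YAML mapping (or equivalent dict). The background
block mirrors the field names of the original scattering tool's input
script: ``background.factor.selection`` triggers the real-space (r-clean)
correction, ``background.cut.box`` the reciprocal-space (Q-clean) one.

Example::

    mode: diffract
    structure: toy.pdb
    trajectory: toy.dcd
    wrapped: true
    dt: 1.0
    species_db: toy_species.tsv     # optional override/merge
    q: {min: 0.0, max: 1.0, count: 301, orientations: 100, seed: 7}
    method: qclean
    background:
      cut:
        box: {edges: [20, 20, 20], center: [10, 10, 10],
              sld: 6.646, sld_scale: 1.0e-5}
    normalization: per-atom
    output: toy_qclean.tsv
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .correction import (BoxSpec, diffractogram_qclean, diffractogram_rclean)
from .diffraction import Diffractogram, diffractogram_naive
from .qspace import make_qgrid
from .species import SpeciesTable
from .spectroscopy import ISFResult, isf_incoherent
from .trajectory import Trajectory, read_trajectory, read_xyz, select_atoms

__all__ = ["RunConfig", "ConfigError", "run"]

MODES = ("diffract", "isf")
METHODS = ("naive", "rclean", "qclean")


class ConfigError(ValueError):
    """A run configuration failed validation; the message names the field."""


@dataclass
class RunConfig:
    """Validated run description (see module docstring for the YAML form)."""

    mode: str
    structure: str | None = None
    trajectory: str | None = None
    wrapped: bool | None = None
    dt: float = 1.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    box: tuple[float, float, float] | None = None
    species_db: str | None = None
    q: dict = field(default_factory=dict)
    method: str = "naive"
    background: dict = field(default_factory=dict)
    selection: str = "all"
    normalization: str = "per-atom"
    output: str = "mdscatter_out.tsv"
    keep_amplitudes: str | None = None
    force: bool = False
    stride: int = 1

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in raw.items()})
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def validate(self) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"mode: must be one of {MODES}, got {self.mode!r}")
        if self.method not in METHODS:
            raise ConfigError(f"method: must be one of {METHODS}, "
                              f"got {self.method!r}")
        if self.mode == "isf" and self.method != "naive":
            raise ConfigError(
                "method: finite-size corrections apply to coherent structure "
                "only; the intermediate scattering function in time cannot "
                "be combined with rclean/qclean")
        for key in ("min", "max", "count", "orientations"):
            if key not in self.q:
                raise ConfigError(f"q.{key}: required")
        if self.structure is None and self.trajectory is None:
            raise ConfigError("structure/trajectory: an input is required")
        if self.method == "qclean":
            box = self.background.get("cut", {}).get("box")
            if not box:
                raise ConfigError("background.cut.box: required for qclean")
            for key in ("edges", "center", "sld"):
                if key not in box:
                    raise ConfigError(f"background.cut.box.{key}: required")
        if self.method == "rclean":
            if not self.background.get("factor", {}).get("selection"):
                raise ConfigError(
                    "background.factor.selection: required for rclean")
        if self.normalization not in ("per-atom", "per-b2", "none"):
            raise ConfigError(f"normalization: unknown mode "
                              f"{self.normalization!r}")
        if self.wrapped is None:
            self.wrapped = self.mode == "diffract"

    # -- helpers --------------------------------------------------------
    def config_hash(self) -> str:
        blob = json.dumps(
            {k: getattr(self, k) for k in self.__dataclass_fields__},
            sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def load_species(self) -> SpeciesTable:
        table = SpeciesTable.default()
        if self.species_db:
            table = table.merged(SpeciesTable.from_tsv(self.species_db))
        return table

    def load_trajectory(self) -> Trajectory:
        if self.trajectory and str(self.trajectory).endswith(".xyz"):
            return read_xyz(self.trajectory, dt=self.dt, wrapped=self.wrapped,
                            box=self.box, origin=self.origin)
        if self.structure is None or self.trajectory is None:
            raise ConfigError("structure + trajectory: both required for "
                              "PDB/DCD input")
        return read_trajectory(self.structure, self.trajectory, dt=self.dt,
                               wrapped=self.wrapped, box=self.box,
                               origin=self.origin)


def _log(msg: str) -> None:
    print(f"[mdscatter] {msg}", file=sys.stderr)


def run(config: RunConfig) -> Diffractogram | ISFResult:
    """Execute a validated run and write its outputs.

    Deterministic for a fixed config (the orientation seed lives in the
    config's q block); the output header records method and seed.
    """
    config.validate()
    species = config.load_species()
    traj = config.load_trajectory()
    qb = config.q
    grid = make_qgrid(qb["min"], qb["max"], qb["count"], qb["orientations"],
                      seed=int(qb.get("seed", 0)))
    _log(f"mdscatter {__version__} mode={config.mode} method={config.method} "
         f"config={config.config_hash()}")
    _log(f"trajectory: {traj.n_atoms} atoms, {traj.n_frames} frames, "
         f"wrapped={traj.wrapped}")
    _log(f"grid: {grid.n_q} Q values x {grid.n_orient} orientations, "
         f"seed={grid.seed}")

    if config.mode == "isf":
        sel = select_atoms(traj, config.selection)
        b_inc = np.zeros(traj.n_atoms)
        b_inc[sel.indices] = species.b_inc_array(traj.labels[sel.indices])
        result: Diffractogram | ISFResult = isf_incoherent(
            traj, grid, b_inc, force=config.force)
    else:
        b_coh = species.b_coh_array(traj.labels)
        if config.method == "naive":
            result = diffractogram_naive(
                traj, grid, b_coh, normalization=config.normalization,
                stride=config.stride, force=config.force)
        elif config.method == "rclean":
            rule = config.background["factor"]["selection"]
            sel = select_atoms(traj, rule)
            result = diffractogram_rclean(
                traj, grid, species, sel,
                normalization=config.normalization,
                stride=config.stride, force=config.force)
        else:
            bx = config.background["cut"]["box"]
            box = BoxSpec.create(bx["edges"], bx["center"], bx["sld"],
                                 sld_scale=float(bx.get("sld_scale", 1.0)))
            result = diffractogram_qclean(
                traj, grid, b_coh, box,
                normalization=config.normalization,
                stride=config.stride, force=config.force)

    result.to_tsv(config.output)
    _log(f"wrote {config.output}")
    if config.keep_amplitudes and config.mode == "diffract":
        _write_amplitudes(config, traj, grid, species)
    return result


def _write_amplitudes(config: RunConfig, traj: Trajectory, grid,
                      species: SpeciesTable) -> None:
    """HDF5 dump of per-(frame, Q, orientation) complex amplitudes."""
    import h5py

    from .diffraction import scattering_amplitude

    b = species.b_coh_array(traj.labels)
    qvecs = grid.qvectors()
    with h5py.File(config.keep_amplitudes, "w") as h5:
        h5.attrs["method"] = config.method
        h5.attrs["seed"] = grid.seed
        h5.create_dataset("q", data=grid.q_values)
        h5.create_dataset("orientations", data=grid.orientations)
        amps = np.array([scattering_amplitude(c, b, qvecs)
                         for c in traj.frames[::config.stride]])
        h5.create_dataset("amplitudes", data=amps)
    _log(f"wrote amplitudes to {config.keep_amplitudes}")
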