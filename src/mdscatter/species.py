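"""Per-species scattering constants and scattering strength factors.

Neutrons see a nucleus through a Q-independent *scattering length* b, split
into a coherent part ``b_coh`` (pair correlations, diffraction) and an
incoherent part ``b_inc`` (self correlations, spectroscopy); both are
isotope-dependent, which is why H (-3.739 fm) and D (+6.671 fm) can be mixed
to tune the average hydrogen scattering length of water.  X-rays see the
electron cloud; the atomic form factor f(Q) is approximated by the standard
four-Gaussian (Cromer-Mann) parameterisation.

Scattering lengths are stored in femtometres throughout and converted to
Angstrom (1 fm = 1e-5 A) only where scattering length *densities* or
amplitudes of continuum bodies are formed.
"""

from __future__ import annotations

import difflib
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "AtomSpecies",
    "SpeciesTable",
    "UnknownSpeciesError",
    "mixed_hydrogen_b",
    "null_mixture_fraction",
    "xray_form_factor",
    "water_sld",
    "FM_TO_ANGSTROM",
    "WATER_DENSITY_300K",
]

#: 1 fm expressed in Angstrom; the unit boundary between b [fm] and SLD [A^-2].
FM_TO_ANGSTROM = 1.0e-5

#: Density of liquid H2O at 300 K, g/cm^3 (CRC Handbook / IAPWS-95).
WATER_DENSITY_300K = 0.996556

AVOGADRO = 6.02214076e23
WATER_MOLAR_MASS = 18.01528  # g/mol


class UnknownSpeciesError(KeyError):
    """Raised when a species label cannot be resolved in a table."""


@dataclass(frozen=True)
class AtomSpecies:
    """Scattering constants of one element or isotope.

    Parameters
    ----------
    label : str
        Element/isotope symbol ("H", "D", "O", ...).
    b_coh, b_inc : float
        Coherent and incoherent neutron scattering lengths, fm.
    xray_a, xray_b : tuple of float
        Cromer-Mann Gaussian amplitudes a_i (dimensionless) and widths
        b_i (A^2).
    xray_c : float
        Constant term of the Gaussian sum.
    r_vdw : float
        Van der Waals radius, A.
    """

    label: str
    b_coh: float
    b_inc: float
    xray_a: tuple[float, ...]
    xray_b: tuple[float, ...]
    xray_c: float
    r_vdw: float

    def __post_init__(self) -> None:
        if self.r_vdw <= 0:
            raise ValueError(f"r_vdw must be positive, got {self.r_vdw}")
        if len(self.xray_a) != len(self.xray_b):
            raise ValueError("xray_a and xray_b must have equal length")

    @property
    def v_vdw(self) -> float:
        """Van der Waals volume (4/3) pi r_vdw^3, A^3."""
        return 4.0 / 3.0 * math.pi * self.r_vdw**3

    @property
    def f_xray_q0(self) -> float:
        """X-ray form factor at Q=0: sum of Gaussian amplitudes plus constant."""
        return float(sum(self.xray_a) + self.xray_c)


# labels that PDB/config files spell differently
_ALIASES = {"2H": "D", "1H": "H"}


@dataclass
class SpeciesTable:
    """Mapping from species label to :class:`AtomSpecies`.

    Lookup is case-insensitive and accepts the isotope aliases "D"/"2H".
    """

    entries: dict[str, AtomSpecies] = field(default_factory=dict)
    provenance: str = ""

    # -- construction ---------------------------------------------------
    @classmethod
    def default(cls) -> "SpeciesTable":
        """Load the table shipped with the package."""
        with resources.files("mdscatter.data").joinpath("species.tsv").open() as fh:
            return cls._parse(fh, provenance="shipped mdscatter species.tsv "
                              "(Sears 1992; Int. Tables C; Bondi 1964)")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SpeciesTable":
        """Load a table from a plain-text TSV file (same schema as shipped)."""
        with open(path) as fh:
            return cls._parse(fh, provenance=f"user table {path}")

    @classmethod
    def _parse(cls, lines: Iterable[str], provenance: str) -> "SpeciesTable":
        table = cls(provenance=provenance)
        for lineno, raw in enumerate(lines, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 13:
                raise ValueError(
                    f"species table line {lineno}: expected 13 fields "
                    f"(label b_coh b_inc a1 b1 a2 b2 a3 b3 a4 b4 c r_vdw), "
                    f"got {len(fields)}: {line!r}"
                )
            label = fields[0]
            vals = [float(x) for x in fields[1:]]
            sp = AtomSpecies(
                label=label,
                b_coh=vals[0],
                b_inc=vals[1],
                xray_a=tuple(vals[2:10:2]),
                xray_b=tuple(vals[3:10:2]),
                xray_c=vals[10],
                r_vdw=vals[11],
            )
            table.add(sp)
        return table

    # -- mutation -------------------------------------------------------
    def add(self, species: AtomSpecies) -> None:
        key = species.label.upper()
        self.entries[key] = species

    def merged(self, other: "SpeciesTable") -> "SpeciesTable":
        """New table with ``other``'s entries overriding this table's."""
        out = SpeciesTable(dict(self.entries),
                           provenance=f"{self.provenance} + {other.provenance}")
        out.entries.update(other.entries)
        return out

    # -- lookup ---------------------------------------------------------
    def __contains__(self, label: str) -> bool:
        key = label.strip().upper()
        key = _ALIASES.get(key, key)
        return key in self.entries

    def lookup(self, label: str) -> AtomSpecies:
        """Return the species record for ``label`` (case-insensitive).

        Raises
        ------
        UnknownSpeciesError
            If the label is absent; the message lists near-matches.
        """
        key = label.strip().upper()
        key = _ALIASES.get(key, key)
        try:
            return self.entries[key]
        except KeyError:
            near = difflib.get_close_matches(key, self.entries, n=3, cutoff=0.4)
            hint = f"; did you mean {', '.join(near)}?" if near else ""
            raise UnknownSpeciesError(
                f"unknown species label {label!r}{hint} "
                f"(table: {sorted(self.entries)})"
            ) from None

    # -- vectorised per-atom arrays --------------------------------------
    def b_coh_array(self, labels: Iterable[str]) -> np.ndarray:
        """Coherent scattering lengths (fm) for a label sequence."""
        return np.array([self.lookup(l).b_coh for l in labels], dtype=float)

    def b_inc_array(self, labels: Iterable[str]) -> np.ndarray:
        """Incoherent scattering lengths (fm) for a label sequence."""
        return np.array([self.lookup(l).b_inc for l in labels], dtype=float)

    def v_vdw_array(self, labels: Iterable[str]) -> np.ndarray:
        """Van der Waals volumes (A^3) for a label sequence."""
        return np.array([self.lookup(l).v_vdw for l in labels], dtype=float)


def mixed_hydrogen_b(x_h2o: float, b_h: float = -3.7390, b_d: float = 6.6710) -> float:
    """Average coherent hydrogen scattering length of an H2O/D2O mixture.

    For a mole fraction ``x_h2o`` of light water the exchangeable hydrogen
    sites carry ``x*b_H + (1-x)*b_D``; defaults are the standard H and D
    coherent lengths in fm.
    """
    if not 0.0 <= x_h2o <= 1.0:
        raise ValueError(f"mole fraction must be in [0, 1], got {x_h2o}")
    return x_h2o * b_h + (1.0 - x_h2o) * b_d


def null_mixture_fraction(b_h: float = -3.7390, b_d: float = 6.6710) -> float:
    """H2O mole fraction at which the average hydrogen b vanishes (null water)."""
    return b_d / (b_d - b_h)


def xray_form_factor(species: AtomSpecies, q: float | np.ndarray) -> np.ndarray:
    """X-ray atomic form factor f(Q) from the Cromer-Mann Gaussian sum.

    f(Q) = sum_i a_i exp(-b_i (Q/4pi)^2) + c, dimensionless (electron units).
    """
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("Q must be non-negative")
    s2 = (q / (4.0 * math.pi)) ** 2
    a = np.array(species.xray_a)
    b = np.array(species.xray_b)
    return np.sum(a * np.exp(-b * s2[..., None]), axis=-1) + species.xray_c


def water_sld(
    b_h: float = -3.7390,
    b_o: float = 5.8030,
    density: float = WATER_DENSITY_300K,
    molar_mass: float = WATER_MOLAR_MASS,
) -> float:
    """Scattering length density of water, A^-2.

    rho = n_H2O * (b_O + 2 b_H) with the molecular number density n_H2O
    taken from the mass density; the same atomic number density is assumed
    for all isotopologues, so D2O/HDO SLDs follow by swapping ``b_h``.
    """
    n_per_A3 = density * AVOGADRO / molar_mass * 1e-24  # molecules / A^3
    return n_per_A3 * (b_o + 2.0 * b_h) * FM_TO_ANGSTROM
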