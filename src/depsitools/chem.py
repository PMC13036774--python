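"""Exact-mass chemistry for lipopeptide mass spectrometry.

Molecular formulas are element->count mappings with monoisotopic-mass
semantics.  All downstream MS arithmetic (adduct m/z, ppm deviation,
ring-plus-double-bond equivalents) is built on this module, as are the
residue and acyl-chain libraries shared by the fragmentation and
simulation stages.

Conventions
-----------
* Protonated adducts only ([M+H]+, [M+2H]2+ ...): the charge carrier is
  the proton (1.00727646 Da), i.e. the electron mass is accounted for.
* ppm deviation is signed: (observed - theoretical) / theoretical * 1e6.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

__all__ = [
    "PROTON_MASS",
    "WATER_MASS",
    "HNCO_MASS",
    "CH2_MASS",
    "OXYGEN_MASS",
    "MolecularFormula",
    "ResidueSpec",
    "AcylChainSpec",
    "AdductSpec",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "adduct_mz",
    "ppm_deviation",
    "rdbe",
    "atomic_masses",
    "load_residue_table",
    "load_acyl_table",
    "default_residues",
    "default_acyl_chains",
]

#: Mass of the proton, Da (charge carrier for protonated adducts).
PROTON_MASS = 1.00727646


class FormulaError(ValueError):
    """Malformed formula text or unknown element symbol."""


def _load_atomic_masses() -> dict[str, float]:
    table = {}
    path = resources.files("depsitools.data").joinpath("atomic_masses.tsv")
    with path.open() as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            table[row[0]] = float(row[1])
    return table


_ATOMIC_MASSES = _load_atomic_masses()


def atomic_masses() -> Mapping[str, float]:
    """The bundled monoisotopic atomic-mass table (element -> Da)."""
    return dict(_ATOMIC_MASSES)


@dataclass(frozen=True)
class MolecularFormula:
    """An element->count mapping; counts are non-negative integers."""

    counts: Mapping[str, int]

    def __post_init__(self):
        cleaned = {}
        for el, n in self.counts.items():
            if el not in _ATOMIC_MASSES:
                raise FormulaError(f"unknown element symbol: {el!r}")
            if int(n) != n or n < 0:
                raise FormulaError(f"count for {el} must be a non-negative integer, got {n!r}")
            if n > 0:
                cleaned[el] = int(n)
        object.__setattr__(self, "counts", cleaned)

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        out = dict(self.counts)
        for el, n in other.counts.items():
            out[el] = out.get(el, 0) + n
        return MolecularFormula(out)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        out = dict(self.counts)
        for el, n in other.counts.items():
            new = out.get(el, 0) - n
            if new < 0:
                raise FormulaError(
                    f"subtraction yields negative count for {el}: {out.get(el, 0)} - {n}"
                )
            out[el] = new
        return MolecularFormula(out)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def hill(self) -> str:
        """Hill-notation string: C first, H second, then alphabetical."""
        order = []
        if "C" in self.counts:
            order.append("C")
            if "H" in self.counts:
                order.append("H")
            order.extend(sorted(el for el in self.counts if el not in ("C", "H")))
        else:
            order.extend(sorted(self.counts))
        return "".join(f"{el}{self.counts[el] if self.counts[el] != 1 else ''}" for el in order)

    def __str__(self) -> str:
        return self.hill()


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-notation formula string such as ``C81H119N19O19``.

    Raises :class:`FormulaError` on malformed tokens or element symbols
    absent from the bundled mass table.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m or m.start() != pos or not m.group(1):
            raise FormulaError(f"malformed formula token at position {pos} in {text!r}")
        el, digits = m.groups()
        if el not in _ATOMIC_MASSES:
            raise FormulaError(f"unknown element symbol: {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return MolecularFormula(counts)


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Monoisotopic mass in Da: sum of count x atomic monoisotopic mass."""
    return sum(n * _ATOMIC_MASSES[el] for el, n in f.counts.items())


# Frequently used neutral masses.
WATER_MASS = monoisotopic_mass(parse_formula("H2O"))
HNCO_MASS = monoisotopic_mass(parse_formula("HNCO"))  # isocyanic acid
CH2_MASS = monoisotopic_mass(parse_formula("CH2"))
OXYGEN_MASS = _ATOMIC_MASSES["O"]


@dataclass(frozen=True)
class AdductSpec:
    """Protonated adduct: ``proton_count`` protons giving charge ``charge``."""

    proton_count: int = 1
    charge: int = 1

    def __post_init__(self):
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        if self.proton_count != self.charge:
            raise ValueError("only protonated species supported: proton_count must equal charge")

    @property
    def name(self) -> str:
        if self.charge == 1:
            return "[M+H]+"
        return f"[M+{self.charge}H]{self.charge}+"


def adduct_mz(f: MolecularFormula | float, adduct: AdductSpec = AdductSpec()) -> float:
    """m/z of a protonated adduct: (M + n x proton) / z.

    ``f`` may be a formula or a precomputed neutral monoisotopic mass.
    """
    m = f if isinstance(f, (int, float)) else monoisotopic_mass(f)
    return (m + adduct.proton_count * PROTON_MASS) / adduct.charge


def ppm_deviation(observed: float, theoretical: float) -> float:
    """Signed mass deviation in parts per million.

    Positive when the observed m/z is higher than the theoretical one.
    """
    if theoretical <= 0:
        raise ValueError(f"theoretical m/z must be > 0, got {theoretical}")
    return (observed - theoretical) / theoretical * 1e6


def rdbe(f: MolecularFormula) -> float:
    """Ring-plus-double-bond equivalents: C - H/2 + N/2 + 1.

    Halogens are treated like hydrogen; divalent elements (O, S) do not
    contribute. May be half-integer for odd-electron/charged formulas.
    """
    h_like = f["H"] + f["F"] + f["Cl"] + f["Br"] + f["I"]
    return f["C"] + f["Si"] - h_like / 2 + (f["N"] + f["P"]) / 2 + 1


@dataclass(frozen=True)
class ResidueSpec:
    """An in-chain amino-acid residue (monomer minus water)."""

    name: str
    residue_formula: MolecularFormula
    flags: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if monoisotopic_mass(self.residue_formula) <= 0:
            raise ValueError(f"residue {self.name} has non-positive mass")
        object.__setattr__(self, "flags", frozenset(self.flags))

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self.residue_formula)

    @property
    def has_ureido(self) -> bool:
        return "ureido" in self.flags


@dataclass(frozen=True)
class AcylChainSpec:
    """An N-terminal fatty-acyl chain, defined by its free fatty acid.

    The acyl increment (the mass the chain adds to a peptide) is the
    acid minus water; it is always derived from ``acid_formula``.
    """

    name: str
    acid_formula: MolecularFormula

    @property
    def acyl_increment(self) -> MolecularFormula:
        return self.acid_formula - parse_formula("H2O")

    @property
    def increment_mass(self) -> float:
        return monoisotopic_mass(self.acyl_increment)


def load_residue_table(path) -> dict[str, ResidueSpec]:
    """Load a residue TSV (columns: name, formula, optional flags)."""
    out: dict[str, ResidueSpec] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            name, formula = row[0], row[1]
            flags = frozenset(row[2].split(";")) if len(row) > 2 and row[2] else frozenset()
            out[name] = ResidueSpec(name, parse_formula(formula), flags)
    return out


def load_acyl_table(path) -> dict[str, AcylChainSpec]:
    """Load an acyl-chain TSV (columns: name, acid_formula)."""
    out: dict[str, AcylChainSpec] = {}
    with open(path) as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            out[row[0]] = AcylChainSpec(row[0], parse_formula(row[1]))
    return out


def default_residues() -> dict[str, ResidueSpec]:
    """Bundled residue library: 20 proteinogenic residues plus Orn,
    OHPro (4-hydroxyproline), Cit (citrulline, ureido-flagged) and
    OHTrp (5-hydroxytryptophan)."""
    path = resources.files("depsitools.data").joinpath("residues.tsv")
    return load_residue_table(str(path))


def default_acyl_chains() -> dict[str, AcylChainSpec]:
    """Bundled beta-hydroxy fatty-acyl chains (C15-C17)."""
    path = resources.files("depsitools.data").joinpath("acyl_chains.tsv")
    return load_acyl_table(str(path))
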