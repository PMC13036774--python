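"""Fragment-ion prediction and MS/MS annotation for cyclic lipodepsipeptides.

A cyclic lipodepsipeptide is handled in its ring-opened (linearized)
form, with position 1 the N-acylated residue.  Ion series generated:

* b_n  : N-terminal fragments, acyl increment included when acylated
* y_n  : C-terminal fragments (+ H2O)
* b deg (``water`` loss)  : b - H2O
* b* (``isocyanic_acid`` loss): b - HNCO, only for fragments containing
  a ureido-flagged residue (citrulline-diagnostic)
* b# (``acyl`` loss): b - acyl increment, only for acylated peptides
  (every b fragment contains position 1)

Doubly charged variants are (mz_1+ + proton)/2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .chem import (
    CH2_MASS,
    HNCO_MASS,
    OXYGEN_MASS,
    PROTON_MASS,
    WATER_MASS,
    AcylChainSpec,
    MolecularFormula,
    ResidueSpec,
    adduct_mz,
    AdductSpec,
    default_acyl_chains,
    default_residues,
    parse_formula,
    ppm_deviation,
)

__all__ = [
    "LinearLipopeptide",
    "FragmentIon",
    "Spectrum",
    "AnnotationResult",
    "CongenerShift",
    "linearize",
    "parse_peptide",
    "theoretical_fragments",
    "annotate_spectrum",
    "rank_candidates",
    "infer_congener_shift",
]

_LOSS_MASSES = {
    "water": WATER_MASS,
    "isocyanic_acid": HNCO_MASS,
}

_LOSS_LABELS = {
    frozenset(): "",
    frozenset({"water"}): "o",
    frozenset({"isocyanic_acid"}): "*",
    frozenset({"acyl"}): "#",
}


@dataclass(frozen=True)
class LinearLipopeptide:
    """Ordered residue list with an optional N-terminal acyl chain.

    For a ring-opened depsipeptide the cyclic parent's neutral mass is
    the acyl increment plus the residue masses (ring closure removes the
    water that linearization adds); the linear form carries one extra
    water.
    """

    residues: tuple[ResidueSpec, ...]
    acyl: AcylChainSpec | None = None
    cyclic_origin: bool = False

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError("peptide must contain at least one residue")
        object.__setattr__(self, "residues", tuple(self.residues))

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def acyl_increment_mass(self) -> float:
        return self.acyl.increment_mass if self.acyl else 0.0

    @property
    def residue_mass_sum(self) -> float:
        return sum(r.mass for r in self.residues)

    @property
    def cyclic_mass(self) -> float:
        """Neutral monoisotopic mass of the macrolactone parent."""
        return self.acyl_increment_mass + self.residue_mass_sum

    @property
    def linear_mass(self) -> float:
        """Neutral monoisotopic mass of the ring-opened (hydrolyzed) form."""
        return self.cyclic_mass + WATER_MASS

    @property
    def formula(self) -> MolecularFormula:
        """Formula of the cyclic parent."""
        f = MolecularFormula({})
        for r in self.residues:
            f = f + r.residue_formula
        if self.acyl:
            f = f + self.acyl.acyl_increment
        return f

    def sequence_str(self) -> str:
        head = f"{self.acyl.name}|" if self.acyl else ""
        return head + "-".join(r.name for r in self.residues)


def linearize(
    residues: Sequence[ResidueSpec],
    acyl: AcylChainSpec | None = None,
    opening: int = 0,
) -> LinearLipopeptide:
    """Ring-open a cyclic sequence at bond ``opening``.

    ``opening`` = 0 (default) opens the macrolactone ester bond so that
    position 1 is the acylated N-terminal residue and residue order is
    preserved.  Other values rotate the sequence accordingly (only
    meaningful for unacylated homodetic rings).
    """
    n = len(residues)
    if n < 1:
        raise ValueError("cyclic sequence must contain at least one residue")
    if not 0 <= opening < n:
        raise IndexError(f"opening index {opening} out of range for {n}-mer ring")
    if opening != 0 and acyl is not None:
        raise ValueError("an acylated macrolactone can only be opened at the ester bond")
    rotated = tuple(residues[opening:]) + tuple(residues[:opening])
    return LinearLipopeptide(rotated, acyl=acyl, cyclic_origin=True)


def parse_peptide(
    text: str,
    residue_table: dict[str, ResidueSpec] | None = None,
    acyl_table: dict[str, AcylChainSpec] | None = None,
) -> LinearLipopeptide:
    """Parse the one-line grammar ``acylName|res1-res2-...-resN``.

    The acyl part is optional; names resolve against the bundled tables
    unless custom tables are given.
    """
    residue_table = residue_table if residue_table is not None else default_residues()
    acyl_table = acyl_table if acyl_table is not None else default_acyl_chains()
    acyl = None
    if "|" in text:
        acyl_name, text = text.split("|", 1)
        try:
            acyl = acyl_table[acyl_name.strip()]
        except KeyError:
            raise KeyError(f"unknown acyl chain {acyl_name!r}") from None
    residues = []
    for name in text.split("-"):
        name = name.strip()
        try:
            residues.append(residue_table[name])
        except KeyError:
            raise KeyError(f"unknown residue {name!r}") from None
    return LinearLipopeptide(tuple(residues), acyl=acyl)


@dataclass(frozen=True)
class FragmentIon:
    series: str  # 'b' or 'y'
    index: int  # 1..N
    losses: frozenset[str] = field(default_factory=frozenset)
    charge: int = 1
    mz: float = 0.0

    def label(self) -> str:
        loss = _LOSS_LABELS.get(self.losses, "?")
        charge = "" if self.charge == 1 else f"^{self.charge}+"
        return f"{self.series}{self.index}{loss}{charge}"


def theoretical_fragments(
    p: LinearLipopeptide,
    max_charge: int = 2,
    losses: Iterable[str] = ("water", "isocyanic_acid", "acyl"),
) -> list[FragmentIon]:
    """Generate the b/y ladder with configured neutral-loss variants.

    Singly charged b_n = sum(residues 1..n) + acyl increment + proton;
    y_n = sum(last n residues) + H2O + proton.  ``isocyanic_acid`` loss
    is emitted only when the fragment contains a ureido-flagged residue;
    ``acyl`` loss only for b ions of acylated peptides.  Output is
    sorted by m/z and de-duplicated.
    """
    losses = set(losses)
    n = len(p.residues)
    ions: set[FragmentIon] = set()
    prefix = 0.0
    ureido_seen = False
    for i, res in enumerate(p.residues, start=1):
        prefix += res.mass
        ureido_seen = ureido_seen or res.has_ureido
        b_mz = prefix + p.acyl_increment_mass + PROTON_MASS
        variants = [(frozenset(), b_mz)]
        if "water" in losses:
            variants.append((frozenset({"water"}), b_mz - WATER_MASS))
        if "isocyanic_acid" in losses and ureido_seen:
            variants.append((frozenset({"isocyanic_acid"}), b_mz - HNCO_MASS))
        if "acyl" in losses and p.acyl is not None:
            variants.append((frozenset({"acyl"}), b_mz - p.acyl_increment_mass))
        for loss, mz1 in variants:
            ions.add(FragmentIon("b", i, loss, 1, mz1))
            if max_charge >= 2:
                ions.add(FragmentIon("b", i, loss, 2, (mz1 + PROTON_MASS) / 2))
    suffix = 0.0
    for j in range(1, n + 1):
        suffix += p.residues[n - j].mass
        y_mz = suffix + WATER_MASS + PROTON_MASS
        ions.add(FragmentIon("y", j, frozenset(), 1, y_mz))
        if max_charge >= 2:
            ions.add(FragmentIon("y", j, frozenset(), 2, (y_mz + PROTON_MASS) / 2))
    return sorted(ions, key=lambda ion: (ion.mz, ion.series, ion.index, ion.charge))


@dataclass
class Spectrum:
    """A centroided peak list with precursor information."""

    peaks: list[tuple[float, float]]
    precursor_mz: float = 0.0
    precursor_charge: int = 1
    id: str = ""

    def __post_init__(self):
        self.peaks = sorted((float(m), float(i)) for m, i in self.peaks)
        if any(i < 0 for _, i in self.peaks):
            raise ValueError("peak intensities must be non-negative")

    @property
    def mz(self) -> list[float]:
        return [m for m, _ in self.peaks]

    @property
    def intensities(self) -> list[float]:
        return [i for _, i in self.peaks]

    @property
    def precursor_neutral_mass(self) -> float:
        return self.precursor_mz * self.precursor_charge - self.precursor_charge * PROTON_MASS

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass
class AnnotationResult:
    """Matched theoretical ions and backbone-ladder support."""

    matches: list[tuple[FragmentIon, int, float]]  # (ion, peak index, ppm error)
    ladder_coverage: float
    n_residues: int

    @property
    def n_matched(self) -> int:
        return len(self.matches)


def annotate_spectrum(
    s: Spectrum,
    candidates: Sequence[FragmentIon],
    tol_ppm: float = 10.0,
    n_residues: int | None = None,
) -> AnnotationResult:
    """Match theoretical ions to the nearest observed peak within tolerance.

    Each ion matches at most one peak (the nearest in ppm; ties resolve
    to the lower-m/z peak); a single peak may satisfy several ions.
    Ladder coverage is the fraction of the N-1 backbone bonds supported
    by at least one matched b_i or y_{N-i} ion (any loss or charge).
    """
    if not candidates:
        raise ValueError("candidate ion list is empty")
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    if n_residues is None:
        n_residues = max(ion.index for ion in candidates)
    mzs = s.mz
    matches: list[tuple[FragmentIon, int, float]] = []
    import bisect

    for ion in candidates:
        if not mzs:
            break
        k = bisect.bisect_left(mzs, ion.mz)
        best = None
        for j in (k - 1, k):
            if 0 <= j < len(mzs):
                err = ppm_deviation(mzs[j], ion.mz)
                if abs(err) <= tol_ppm:
                    if best is None or abs(err) < abs(best[1]) or (
                        abs(err) == abs(best[1]) and mzs[j] < mzs[best[0]]
                    ):
                        best = (j, err)
        if best is not None:
            matches.append((ion, best[0], best[1]))
    covered = set()
    for ion, _, _ in matches:
        if ion.series == "b" and 1 <= ion.index <= n_residues - 1:
            covered.add(ion.index)
        elif ion.series == "y" and 1 <= ion.index <= n_residues - 1:
            covered.add(n_residues - ion.index)
    coverage = len(covered) / (n_residues - 1) if n_residues > 1 else 1.0 if matches else 0.0
    return AnnotationResult(matches, coverage, n_residues)


def rank_candidates(
    s: Spectrum,
    candidate_sequences: Sequence[LinearLipopeptide],
    tol_ppm: float = 10.0,
    max_charge: int = 2,
) -> list[tuple[LinearLipopeptide, float]]:
    """Score candidate sequences against a spectrum (peptidogenomic ranking).

    Score = number of matched ladder ions, with ladder coverage as a
    sub-integer tiebreak; ties beyond that keep candidate input order.
    """
    if not candidate_sequences:
        raise ValueError("need at least one candidate sequence")
    scored = []
    for cand in candidate_sequences:
        ions = theoretical_fragments(cand, max_charge=max_charge)
        if len(s) == 0:
            scored.append((cand, 0.0))
            continue
        result = annotate_spectrum(s, ions, tol_ppm, n_residues=len(cand))
        scored.append((cand, result.n_matched + 0.999 * result.ladder_coverage))
    order = sorted(range(len(scored)), key=lambda i: -scored[i][1])
    return [scored[i] for i in order]


@dataclass
class CongenerShift:
    """Localized interpretation of a congener precursor mass shift."""

    delta_mass: float
    hypothesis: str | None  # e.g. "+O", "-CH2", "+2O", "+O+CH2"; None = unassigned
    locations: tuple = ()  # residue positions and/or "acyl"
    score: float = 0.0
    n_matched: int = 0


def _event_label(n_o: int, n_ch2: int) -> str:
    parts = []
    if n_o:
        parts.append(f"{'+' if n_o > 0 else '-'}{abs(n_o) if abs(n_o) > 1 else ''}O")
    if n_ch2:
        parts.append(f"{'+' if n_ch2 > 0 else '-'}{abs(n_ch2) if abs(n_ch2) > 1 else ''}CH2")
    return "".join(parts)


def _apply_oxidation(p: LinearLipopeptide, pos: int) -> LinearLipopeptide:
    res = list(p.residues)
    old = res[pos - 1]
    res[pos - 1] = ResidueSpec(
        old.name + "(+O)", old.residue_formula + parse_formula("O"), old.flags
    )
    return replace(p, residues=tuple(res))


def _apply_acyl_ch2(p: LinearLipopeptide, delta: int) -> LinearLipopeptide:
    if p.acyl is None:
        raise ValueError("peptide has no acyl chain")
    ch2 = parse_formula("CH2")
    if delta > 0:
        acid = p.acyl.acid_formula + ch2
        name = p.acyl.name + "(+CH2)"
    else:
        acid = p.acyl.acid_formula - ch2
        name = p.acyl.name + "(-CH2)"
    return replace(p, acyl=AcylChainSpec(name, acid))


def infer_congener_shift(
    reference: tuple[LinearLipopeptide, Spectrum],
    query: Spectrum,
    tol_ppm: float = 10.0,
    delta_tol_da: float = 0.01,
    max_events: int = 2,
) -> CongenerShift:
    """Interpret and localize the mass shift of a congener spectrum.

    The precursor neutral-mass delta between query and reference is
    matched against combinations of up to ``max_events`` elementary
    events: +O (hydroxylation, +15.99491 Da) on a residue and +/-CH2
    (fatty-acyl homology, +/-14.01565 Da) on the acyl chain.  Each
    compatible modified peptide is re-annotated against the query
    spectrum; the best-supported placement wins.  A delta matching no
    hypothesis yields an unassigned report (not an exception).
    """
    ref_pep, ref_spec = reference
    delta = query.precursor_neutral_mass - ref_spec.precursor_neutral_mass
    if abs(delta) <= delta_tol_da:
        return CongenerShift(delta, "", (), 0.0)

    hypotheses = []
    for n_o in range(-max_events, max_events + 1):
        for n_ch2 in range(-max_events, max_events + 1):
            n_events = abs(n_o) + abs(n_ch2)
            if n_events == 0 or n_events > max_events:
                continue
            expected = n_o * OXYGEN_MASS + n_ch2 * CH2_MASS
            if abs(delta - expected) <= delta_tol_da:
                hypotheses.append((n_o, n_ch2))
    if not hypotheses:
        return CongenerShift(delta, None)

    n = len(ref_pep)
    best: CongenerShift | None = None
    for n_o, n_ch2 in hypotheses:
        label = _event_label(n_o, n_ch2)
        # enumerate placements: +O on residue positions, CH2 on the acyl chain
        if n_o < 0:
            continue  # loss of oxygen from the reference scaffold is not localizable
        if n_ch2 != 0 and ref_pep.acyl is None:
            continue
        pos_choices = (
            [()] if n_o == 0 else
            [(k,) for k in range(1, n + 1)] if n_o == 1 else
            list(itertools.combinations_with_replacement(range(1, n + 1), n_o))
        )
        for positions in pos_choices:
            pep = ref_pep
            ok = True
            for k in positions:
                pep = _apply_oxidation(pep, k)
            if n_ch2 != 0:
                try:
                    for _ in range(abs(n_ch2)):
                        pep = _apply_acyl_ch2(pep, 1 if n_ch2 > 0 else -1)
                except Exception:
                    ok = False
            if not ok:
                continue
            ions = theoretical_fragments(pep)
            result = annotate_spectrum(query, ions, tol_ppm, n_residues=n)
            locations = tuple(positions) + (("acyl",) if n_ch2 else ())
            score = result.n_matched + 0.999 * result.ladder_coverage
            cand = CongenerShift(delta, label, locations, score, result.n_matched)
            if best is None or cand.score > best.score:
                best = cand
    if best is None:
        # hypothesis matched the delta but could not be placed on the scaffold
        n_o, n_ch2 = hypotheses[0]
        return CongenerShift(delta, _event_label(n_o, n_ch2), ())
    return best
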