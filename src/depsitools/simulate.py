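"""Ground-truth simulators for every analysis stage.

Two generators live here:

* MS/MS spectrum simulation for defined acyl-peptides — theoretical b/y
  ladders with configurable peak dropout, Gaussian m/z jitter (ppm) and
  uniform-m/z noise peaks with exponentially distributed intensities —
  plus congener series built from elementary modification events
  (+O hydroxylation of a residue, +/-CH2 homology of the acyl chain).

* NRPS BGC family simulation — an ancestral multi-module cluster with
  per-member background divergence (per-site independent substitution,
  uniform over the three alternative bases; indels only through
  explicit events) and planted module duplications, A-domain
  recombinations and module deletions, with a ground-truth event log.

Both are deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .bgc import DomainAnnotation, NrpsBgc, infer_modules
from .chem import AdductSpec, adduct_mz
from .fragments import (
    LinearLipopeptide,
    Spectrum,
    _apply_acyl_ch2,
    _apply_oxidation,
    parse_peptide,
    theoretical_fragments,
)

__all__ = [
    "SpectrumSimConfig",
    "BgcSimConfig",
    "Duplication",
    "Recombination",
    "Deletion",
    "simulate_spectrum",
    "simulate_congener_series",
    "simulate_bgc_family",
    "paenidepsin_scaffold",
    "paenidepsin_congener_events",
    "PAENIDEPSIN_A",
]

#: Ring-opened sequence of the flagship 12-residue lipododecapeptide:
#: a 3-hydroxy-14-methylpalmitoyl chain on Orn1, macrolactonized at Asp12.
PAENIDEPSIN_A = (
    "3-OH-14-Me-palmitoyl|Orn-His-Val-OHPro-Gly-Cit-OHTrp-Gly-Trp-Gly-Val-Asp"
)


def paenidepsin_scaffold() -> LinearLipopeptide:
    """The des-hydroxy scaffold (Trp at position 7) that the congener
    series derives from by +O / +/-CH2 events."""
    return parse_peptide(
        "3-OH-14-Me-palmitoyl|Orn-His-Val-OHPro-Gly-Cit-Trp-Gly-Trp-Gly-Val-Asp"
    )


def paenidepsin_congener_events() -> dict[str, list[tuple]]:
    """Elementary-event recipes for the six-member congener family,
    relative to :func:`paenidepsin_scaffold` (Trp7, C17 acyl chain)."""
    return {
        "A": [("+O", 7)],
        "B": [("+O", 7), ("+O", 9)],
        "C": [("+O", 7), ("-CH2", "acyl")],
        "D": [],
        "E": [("+O", 7), ("-CH2", "acyl"), ("-CH2", "acyl")],
        "F": [("-CH2", "acyl"), ("-CH2", "acyl")],
    }


# ---------------------------------------------------------------------------
# spectra


@dataclass
class SpectrumSimConfig:
    """Configuration for one simulated MS/MS spectrum.

    With ``mz_jitter_ppm`` = 0 and ``peak_drop`` = 0 the output is the
    exact theoretical ladder.
    """

    peptide: LinearLipopeptide
    max_charge: int = 2
    losses: tuple[str, ...] = ("water", "isocyanic_acid", "acyl")
    peak_drop: float = 0.0
    mz_jitter_ppm: float = 0.0
    noise_peaks: int = 0
    noise_intensity_scale: float = 50.0
    #: intensity factors emulating QTOF fragment statistics: doubly charged
    #: fragments and neutral-loss satellites are markedly weaker than the
    #: primary singly charged backbone ions.
    charge2_intensity_factor: float = 0.25
    loss_intensity_factor: float = 0.5
    precursor_charge: int = 2
    precursor_form: str = "cyclic"  # or "linear"
    seed: int = 0
    id: str = ""


def simulate_spectrum(cfg: SpectrumSimConfig) -> Spectrum:
    """Draw a spectrum from the theoretical ladder with configured noise."""
    rng = np.random.default_rng(cfg.seed)
    ions = theoretical_fragments(cfg.peptide, max_charge=cfg.max_charge, losses=cfg.losses)
    peaks = []
    for ion in ions:
        intensity = 200.0 + 800.0 * rng.random()
        if ion.charge == 2:
            intensity *= cfg.charge2_intensity_factor
        if ion.losses:
            intensity *= cfg.loss_intensity_factor
        if cfg.peak_drop > 0 and rng.random() < cfg.peak_drop:
            continue
        mz = ion.mz
        if cfg.mz_jitter_ppm > 0:
            mz *= 1.0 + rng.normal(0.0, cfg.mz_jitter_ppm) * 1e-6
        peaks.append((mz, intensity))
    neutral = (
        cfg.peptide.cyclic_mass if cfg.precursor_form == "cyclic" else cfg.peptide.linear_mass
    )
    precursor = adduct_mz(neutral, AdductSpec(cfg.precursor_charge, cfg.precursor_charge))
    if cfg.noise_peaks > 0:
        lo, hi = 100.0, precursor * cfg.precursor_charge + 100.0
        for _ in range(cfg.noise_peaks):
            peaks.append(
                (float(rng.uniform(lo, hi)), float(rng.exponential(cfg.noise_intensity_scale)))
            )
    return Spectrum(peaks, precursor, cfg.precursor_charge, cfg.id)


def _apply_events(base: LinearLipopeptide, events: Sequence[tuple]) -> LinearLipopeptide:
    pep = base
    for event in events:
        kind, where = event
        if kind == "+O":
            if not isinstance(where, int) or not 1 <= where <= len(pep):
                raise ValueError(f"+O event on nonexistent position {where!r}")
            pep = _apply_oxidation(pep, where)
        elif kind in ("+CH2", "-CH2"):
            if where != "acyl":
                raise ValueError(f"{kind} events apply to the acyl chain, got {where!r}")
            pep = _apply_acyl_ch2(pep, +1 if kind == "+CH2" else -1)
        else:
            raise ValueError(f"unknown congener event {kind!r}")
    return pep


def simulate_congener_series(
    base: LinearLipopeptide,
    events_per_congener: Sequence[Sequence[tuple]],
    seed: int = 0,
    **sim_kwargs,
) -> list[tuple[LinearLipopeptide, Spectrum]]:
    """Simulate a congener family from per-congener event lists.

    Each event is ``("+O", position)`` or ``("+CH2"|"-CH2", "acyl")``.
    Precursor masses differ from the base by the exact event-formula
    deltas and fragment ladders shift from the event position onward.
    """
    out = []
    for k, events in enumerate(events_per_congener):
        pep = _apply_events(base, events)
        cfg = SpectrumSimConfig(
            peptide=pep, seed=seed + k, id=f"congener_{k}", **sim_kwargs
        )
        out.append((pep, simulate_spectrum(cfg)))
    return out


# ---------------------------------------------------------------------------
# BGC families


@dataclass(frozen=True)
class Duplication:
    """Copy modules ``source`` (inclusive 1-based pair) in tandem, at the
    given percent nucleotide identity between copy and source."""

    source: tuple[int, int]
    identity: float = 95.0


@dataclass(frozen=True)
class Recombination:
    """Replace the A domain of ``target_module`` with a diverged version
    (fraction of sites substituted = ``divergence``)."""

    target_module: int
    divergence: float = 0.30


@dataclass(frozen=True)
class Deletion:
    """Delete ``modules`` (inclusive 1-based pair), recombining within the
    A-T linker of the upstream module at ``junction_offset`` nt past the
    end of its A domain (default: mid-linker)."""

    modules: tuple[int, int]
    junction_offset: int | None = None


@dataclass
class BgcSimConfig:
    """Ancestral cluster layout and family-level evolution settings."""

    n_modules: int = 10
    e_modules: tuple[int, ...] = (7,)  # modules carrying an E domain
    len_c: int = 1300
    len_a: int = 1500
    len_t: int = 220
    len_e: int = 1300
    len_linker: int = 60  # inter-domain and inter-module linkers
    len_te: int = 750
    background_divergence: float = 0.05
    member_events: Sequence[Sequence[object]] = field(default_factory=lambda: [[]])
    substrates: Sequence[str] | None = None
    split_after_module: int | None = None  # split core genes after this module
    cstarter_aa_len: int = 450
    seed: int = 0


_BASES = np.array(list("ACGT"))
_AA = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _random_seq(rng, n: int, alphabet=_BASES) -> str:
    return "".join(alphabet[rng.integers(0, len(alphabet), size=n)])


def _mutate_rate(rng, seq: str, rate: float, alphabet=_BASES) -> str:
    """Per-site independent substitution, uniform over the alternatives."""
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    for i in np.flatnonzero(hit):
        choices = [c for c in alphabet if c != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return "".join(arr)


def _mutate_exact(rng, seq: str, n_sites: int, alphabet=_BASES) -> str:
    """Substitute exactly ``n_sites`` distinct positions."""
    arr = np.array(list(seq))
    idx = rng.choice(len(arr), size=min(n_sites, len(arr)), replace=False)
    for i in idx:
        choices = [c for c in alphabet if c != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return "".join(arr)


def _build_ancestor(cfg: BgcSimConfig, rng) -> tuple[str, list[DomainAnnotation], str]:
    """Assemble the ancestral cluster sequence and domain annotations."""
    seq_parts: list[str] = []
    domains: list[DomainAnnotation] = []
    pos = 0
    cstarter_aa = _random_seq(rng, cfg.cstarter_aa_len, _AA)

    def emit(n: int) -> tuple[int, int]:
        nonlocal pos
        seq_parts.append(_random_seq(rng, n))
        span = (pos, pos + n)
        pos += n
        return span

    def gene_for(module_index: int) -> str:
        if cfg.split_after_module and module_index > cfg.split_after_module:
            return "nrps2"
        return "nrps1"

    for m in range(1, cfg.n_modules + 1):
        gene = gene_for(m)
        if m > 1:
            emit(cfg.len_linker)  # inter-module linker
        kind = "C_Starter" if m == 1 else "C"
        span = emit(cfg.len_c)
        domains.append(
            DomainAnnotation(
                kind, gene, *span, aa_sequence=cstarter_aa if kind == "C_Starter" else None
            )
        )
        emit(cfg.len_linker)
        span = emit(cfg.len_a)
        substrate = (
            cfg.substrates[m - 1]
            if cfg.substrates and len(cfg.substrates) >= cfg.n_modules
            else None
        )
        domains.append(DomainAnnotation("A", gene, *span, substrate_prediction=substrate))
        emit(cfg.len_linker)  # the A-T linker
        span = emit(cfg.len_t)
        domains.append(DomainAnnotation("T", gene, *span))
        if m in cfg.e_modules:
            emit(cfg.len_linker)
            span = emit(cfg.len_e)
            domains.append(DomainAnnotation("E", gene, *span))
    emit(cfg.len_linker)
    span = emit(cfg.len_te)
    domains.append(DomainAnnotation("TE", gene_for(cfg.n_modules), *span))
    return "".join(seq_parts), domains, cstarter_aa


def _shift_domains(domains: list[DomainAnnotation], at: int, delta: int) -> list[DomainAnnotation]:
    out = []
    for d in domains:
        if d.start >= at:
            out.append(replace(d, start=d.start + delta, end=d.end + delta))
        else:
            out.append(d)
    return out


def _apply_duplication(
    bgc: NrpsBgc, ev: Duplication, cfg: BgcSimConfig, rng, log: dict
) -> NrpsBgc:
    modules = infer_modules(bgc)
    s1, s2 = ev.source
    if not 1 <= s1 <= s2 <= len(modules):
        raise ValueError(f"duplication source {ev.source} out of range")
    pre = modules[s1 - 1].domains[0].start
    block_start = pre - cfg.len_linker if s1 > 1 else pre
    end2 = modules[s2 - 1].domains[-1].end
    block = bgc.sequence[block_start:end2]
    n_mut = round((1 - ev.identity / 100.0) * len(block))
    copy = _mutate_exact(rng, block, n_mut)
    new_seq = bgc.sequence[:end2] + copy + bgc.sequence[end2:]
    shifted = _shift_domains(bgc.domains, end2, len(block))
    offset = end2 + (pre - block_start) - pre
    new_domains = []
    for d in bgc.domains:
        if pre <= d.start and d.end <= end2:
            new_domains.append(replace(d, start=d.start + offset, end=d.end + offset))
    all_domains = sorted(shifted + new_domains, key=lambda d: d.start)
    log.setdefault("duplications", []).append(
        {
            "source_modules": [s1, s2],
            "source_span": [block_start, end2],
            "copy_span": [end2, end2 + len(block)],
            "identity": ev.identity,
            "n_mutated": n_mut,
        }
    )
    return NrpsBgc(bgc.id, bgc.genes, all_domains, new_seq)


def _apply_recombination(
    bgc: NrpsBgc, ev: Recombination, cfg: BgcSimConfig, rng, log: dict
) -> NrpsBgc:
    modules = infer_modules(bgc)
    if not 1 <= ev.target_module <= len(modules):
        raise ValueError(f"recombination target module {ev.target_module} out of range")
    a_dom = modules[ev.target_module - 1].domain("A")
    if a_dom is None:
        raise ValueError(f"module {ev.target_module} has no A domain")
    n_mut = round(ev.divergence * (a_dom.end - a_dom.start))
    segment = _mutate_exact(rng, bgc.sequence[a_dom.start : a_dom.end], n_mut)
    new_seq = bgc.sequence[: a_dom.start] + segment + bgc.sequence[a_dom.end :]
    log.setdefault("recombinations", []).append(
        {
            "module": ev.target_module,
            "a_span": [a_dom.start, a_dom.end],
            "divergence": ev.divergence,
        }
    )
    return NrpsBgc(bgc.id, bgc.genes, bgc.domains, new_seq)


def _apply_deletion(
    bgc: NrpsBgc, ev: Deletion, cfg: BgcSimConfig, rng, log: dict
) -> NrpsBgc:
    modules = infer_modules(bgc)
    d1, d2 = ev.modules
    if not 2 <= d1 <= d2 <= len(modules):
        raise ValueError(f"deletion of modules {ev.modules} out of range (module 1 cannot go)")
    offset = ev.junction_offset if ev.junction_offset is not None else cfg.len_linker // 2
    if not 0 <= offset <= cfg.len_linker:
        raise ValueError(f"junction offset {offset} outside the A-T linker")
    up_a = modules[d1 - 2].domain("A")
    last_a = modules[d2 - 1].domain("A")
    j = up_a.end + offset
    k = last_a.end + offset
    new_seq = bgc.sequence[:j] + bgc.sequence[k:]
    new_domains = []
    for d in bgc.domains:
        if d.end <= j:
            new_domains.append(d)
        elif d.start >= k:
            new_domains.append(replace(d, start=d.start - (k - j), end=d.end - (k - j)))
        # domains overlapping [j, k) are deleted
    log.setdefault("deletions", []).append(
        {
            "modules": [d1, d2],
            "ref_span": [j, k],
            "junction": j,
            "junction_linker": f"module {d1 - 1} A-T linker",
        }
    )
    return NrpsBgc(bgc.id, bgc.genes, new_domains, new_seq)


def simulate_bgc_family(cfg: BgcSimConfig) -> tuple[list[NrpsBgc], dict]:
    """Generate a family of related NRPS clusters with planted events.

    Each family member starts from a shared ancestor, accumulates
    background substitutions at ``background_divergence`` and then its
    event list (applied in order; module indices refer to the member's
    state when the event applies).  Returns the members plus a
    ground-truth event log keyed by member id.
    """
    rng = np.random.default_rng(cfg.seed)
    anc_seq, anc_domains, anc_cstarter = _build_ancestor(cfg, rng)
    genes = ["nrps1"] + (["nrps2"] if cfg.split_after_module else [])
    members = []
    event_log: dict[str, dict] = {
        "ancestor": {"length": len(anc_seq), "n_modules": cfg.n_modules}
    }
    for idx, events in enumerate(cfg.member_events):
        member_id = f"bgc_{idx}"
        seq = _mutate_rate(rng, anc_seq, cfg.background_divergence)
        domains = [
            replace(d, aa_sequence=_mutate_rate(rng, d.aa_sequence, cfg.background_divergence, _AA))
            if d.aa_sequence
            else d
            for d in anc_domains
        ]
        member = NrpsBgc(member_id, list(genes), domains, seq)
        log: dict = {}
        for ev in events:
            if isinstance(ev, Duplication):
                member = _apply_duplication(member, ev, cfg, rng, log)
            elif isinstance(ev, Recombination):
                member = _apply_recombination(member, ev, cfg, rng, log)
            elif isinstance(ev, Deletion):
                member = _apply_deletion(member, ev, cfg, rng, log)
            else:
                raise ValueError(f"unknown event {ev!r}")
        members.append(member)
        event_log[member_id] = log
    return members, event_log
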