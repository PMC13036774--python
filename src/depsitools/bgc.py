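"""Comparative evolution analysis of NRPS biosynthetic gene clusters.

Operations: harvesting starter-condensation (C_Starter) domains from
lipopeptide-scale clusters, pairwise global alignment and identity,
sliding-window nucleotide diversity (pi) for recombination-breakpoint
localization, dot plots and collinearity-gap analysis for module
deletions, module-duplication detection by nucleotide identity, and
neighbor-joining distance trees.

Coordinates are 0-based half-open internally; file writers emit 1-based
inclusive coordinates.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import Align

try:
    import edlib

    _HAVE_EDLIB = True
except ImportError:  # pragma: no cover
    _HAVE_EDLIB = False

__all__ = [
    "DomainAnnotation",
    "NrpsBgc",
    "NrpsModule",
    "PiProfile",
    "DotPlotMatrix",
    "DistanceTree",
    "AlignmentScoring",
    "DuplicationReport",
    "DeletionReport",
    "DOMAIN_KINDS",
    "infer_modules",
    "harvest_cstarter",
    "align_global",
    "pairwise_identity",
    "sliding_window_pi",
    "dot_plot",
    "nj_tree",
    "detect_duplications",
    "detect_deletion",
]

DOMAIN_KINDS = frozenset({"C_Starter", "C", "A", "T", "E", "TE", "other"})


@dataclass(frozen=True)
class DomainAnnotation:
    """One NRPS domain with its nucleotide span (0-based half-open)."""

    kind: str
    gene_id: str
    start: int
    end: int
    strand: str = "+"
    aa_sequence: str | None = None
    substrate_prediction: str | None = None

    def __post_init__(self):
        if self.kind not in DOMAIN_KINDS:
            raise ValueError(f"unknown domain kind {self.kind!r}")
        if self.end <= self.start:
            raise ValueError(f"domain span must have positive length: {self.start}..{self.end}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class NrpsModule:
    """A C(-Starter)/A/T unit with optional E; spans include linkers."""

    index: int  # 1..N
    domains: list[DomainAnnotation]
    start: int
    end: int

    def domain(self, kind: str) -> DomainAnnotation | None:
        for d in self.domains:
            if d.kind == kind:
                return d
        return None

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class NrpsBgc:
    """Gene-ordered NRPS domain annotations, optionally with sequence."""

    id: str
    genes: list[str]
    domains: list[DomainAnnotation]
    sequence: str | None = None

    def __post_init__(self):
        by_gene: dict[str, list[DomainAnnotation]] = {}
        for d in self.domains:
            by_gene.setdefault(d.gene_id, []).append(d)
        for gene, doms in by_gene.items():
            doms_sorted = sorted(doms, key=lambda d: d.start)
            for d1, d2 in zip(doms_sorted, doms_sorted[1:]):
                if d2.start < d1.end:
                    raise ValueError(
                        f"overlapping domain spans in gene {gene!r}: "
                        f"{d1.span} and {d2.span}"
                    )

    @property
    def a_domain_count(self) -> int:
        return sum(1 for d in self.domains if d.kind == "A")

    @property
    def modules(self) -> list[NrpsModule]:
        return infer_modules(self)


def infer_modules(bgc: NrpsBgc) -> list[NrpsModule]:
    """Partition the domain list into modules along the assembly line.

    A module runs from the start of its C (or C_Starter) domain to the
    end of its T domain, extended through an immediately following E
    domain.  Inter-module linkers are assigned to the downstream
    module's span, so breakpoints falling in a linker are attributed to
    the module containing the linker's downstream domains.  The module
    count equals the number of A domains.
    """
    doms = sorted(bgc.domains, key=lambda d: (bgc.genes.index(d.gene_id), d.start))
    modules: list[NrpsModule] = []
    current: list[DomainAnnotation] = []
    index = 0
    i = 0
    while i < len(doms):
        d = doms[i]
        if d.kind in ("C_Starter", "C") and not current:
            current = [d]
        elif current and d.kind in ("A", "T"):
            current.append(d)
            if d.kind == "T":
                if i + 1 < len(doms) and doms[i + 1].kind == "E":
                    current.append(doms[i + 1])
                    i += 1
                index += 1
                start = modules[-1].end if modules else current[0].start
                if current[0].gene_id != (modules[-1].domains[-1].gene_id if modules else None):
                    start = current[0].start  # new gene: no upstream linker to inherit
                modules.append(NrpsModule(index, current, start, current[-1].end))
                current = []
        i += 1
    n_a = bgc.a_domain_count
    if len(modules) != n_a:
        raise ValueError(
            f"module inference failed for {bgc.id}: {len(modules)} modules "
            f"vs {n_a} A domains"
        )
    return modules


def harvest_cstarter(
    bgcs: Iterable[NrpsBgc], min_a_domains: int = 6
) -> list[tuple[str, str]]:
    """Extract C_Starter amino-acid sequences from lipopeptide-scale BGCs.

    Follows the harvesting rule of keeping a cluster only when it
    encodes more than 5 A domains (``min_a_domains`` = 6).  Returns one
    (bgc id, sequence) record per C_Starter domain with a sequence.
    """
    out = []
    for bgc in bgcs:
        if bgc.a_domain_count < min_a_domains:
            continue
        for d in bgc.domains:
            if d.kind == "C_Starter" and d.aa_sequence:
                out.append((bgc.id, d.aa_sequence))
    return out


@dataclass(frozen=True)
class AlignmentScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -5.0  # score of the first position of a gap
    gap_extend: float = -1.0  # score of each subsequent gap position


def _aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = scoring.match
    al.mismatch_score = scoring.mismatch
    al.open_gap_score = scoring.gap_open
    al.extend_gap_score = scoring.gap_extend
    return al


def align_global(
    a: str, b: str, scoring: AlignmentScoring = AlignmentScoring()
) -> tuple[str, str, float]:
    """Optimal global (Needleman-Wunsch) alignment with affine gaps.

    A gap of length L scores gap_open + (L-1) * gap_extend.  Returns
    the two gapped strings and the optimal score; among co-optimal
    alignments the aligner's first (deterministic) traceback is used.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    al = _aligner(scoring)
    aln = al.align(a, b)[0]
    return str(aln[0]), str(aln[1]), aln.score


def pairwise_identity(
    a_aligned: str, b_aligned: str, include_gap_columns: bool = True
) -> float:
    """Percent identity of two aligned, equal-length strings.

    Identical columns / aligned columns x 100.  With
    ``include_gap_columns`` (default) gap-containing columns count in
    the denominator; otherwise they are excluded.
    """
    if len(a_aligned) != len(b_aligned):
        raise ValueError("aligned strings must have equal length")
    if not a_aligned:
        raise ValueError("empty alignment")
    ident = 0
    denom = 0
    for x, y in zip(a_aligned, b_aligned):
        if x == "-" and y == "-":
            continue
        gap = x == "-" or y == "-"
        if gap and not include_gap_columns:
            continue
        denom += 1
        if x == y and not gap:
            ident += 1
    if denom == 0:
        raise ValueError("alignment has no scoreable columns")
    return 100.0 * ident / denom


@dataclass
class PiProfile:
    """Sliding-window nucleotide diversity along an alignment."""

    midpoints: list[float]  # alignment coordinates (0-based)
    values: list[float]
    width: int
    step: int

    @property
    def max_window(self) -> tuple[float, float]:
        """(midpoint, pi) of the global maximum (first on ties)."""
        k = max(range(len(self.values)), key=lambda i: self.values[i])
        return self.midpoints[k], self.values[k]


def sliding_window_pi(
    alignment: Sequence[str], width: int = 300, step: int = 150
) -> PiProfile:
    """Windowed nucleotide diversity over an aligned sequence set.

    For each window, pi is the mean per-site difference over columns
    free of gaps in every sequence, averaged over all sequence pairs.
    Gap columns are excluded from both numerator and denominator.
    Windows with no gap-free column get pi = 0.
    """
    seqs = [s.upper() for s in alignment]
    if len(seqs) < 2:
        raise ValueError("need at least 2 aligned sequences")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("aligned sequences must have equal length")
    if length < width:
        raise ValueError(f"alignment length {length} shorter than window width {width}")
    arr = np.array([list(s) for s in seqs])
    gap_free = ~np.any(arr == "-", axis=0)
    pairs = list(itertools.combinations(range(len(seqs)), 2))
    diff = np.zeros(length)
    for i, j in pairs:
        diff += (arr[i] != arr[j]) & gap_free
    diff /= len(pairs)
    midpoints, values = [], []
    for start in range(0, length - width + 1, step):
        window = slice(start, start + width)
        n_sites = int(gap_free[window].sum())
        pi = float(diff[window].sum() / n_sites) if n_sites else 0.0
        midpoints.append(start + width / 2)
        values.append(pi)
    return PiProfile(midpoints, values, width, step)


@dataclass
class DotPlotMatrix:
    """Exact word-match matrix between two sequences (sparse)."""

    word: int
    shape: tuple[int, int]  # (positions in a, positions in b)
    matches: list[tuple[int, int]]  # (i, j): a[i:i+word] == b[j:j+word]

    def dense(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        for i, j in self.matches:
            m[i, j] = True
        return m

    def main_diagonal_density(self) -> float:
        n = min(self.shape)
        on_diag = sum(1 for i, j in self.matches if i == j and i < n)
        return on_diag / n if n else 0.0


def dot_plot(a: str, b: str, word: int = 25) -> DotPlotMatrix:
    """Exact-word-match dot plot of two nucleotide sequences.

    Entry (i, j) is set iff the length-``word`` substrings starting at
    a[i] and b[j] are identical.  Stored sparsely; a self-comparison
    has a fully set main diagonal.
    """
    if word < 1:
        raise ValueError("word size must be >= 1")
    if len(a) < word or len(b) < word:
        raise ValueError("sequences must be at least one word long")
    a, b = a.upper(), b.upper()
    index: dict[str, list[int]] = {}
    for j in range(len(b) - word + 1):
        index.setdefault(b[j : j + word], []).append(j)
    matches = []
    for i in range(len(a) - word + 1):
        for j in index.get(a[i : i + word], ()):
            matches.append((i, j))
    return DotPlotMatrix(word, (len(a) - word + 1, len(b) - word + 1), matches)


@dataclass
class DistanceTree:
    """Unrooted distance tree (neighbor joining) with optional support."""

    tree: object  # skbio.TreeNode
    labels: list[str]
    support: dict[frozenset, float] | None = None

    def newick(self) -> str:
        import io

        buf = io.StringIO()
        self.tree.write(buf, format="newick")
        return buf.getvalue().strip()

    def path_length(self, a: str, b: str) -> float:
        ta = self.tree.find(a)
        tb = self.tree.find(b)
        return ta.distance(tb)


def _p_distance_matrix(seqs: Sequence[str], labels: Sequence[str]):
    from skbio import DistanceMatrix

    n = len(seqs)
    dm = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        cols = [
            (x, y)
            for x, y in zip(seqs[i], seqs[j])
            if x != "-" and y != "-"
        ]
        if not cols:
            raise ValueError(f"no comparable columns between {labels[i]} and {labels[j]}")
        d = sum(1 for x, y in cols if x != y) / len(cols)
        dm[i, j] = dm[j, i] = d
    return DistanceMatrix(dm, ids=list(labels))


def _nj_from_dm(dm) -> "object":
    from skbio.tree import nj

    tree = nj(dm, neg_as_zero=True)
    return tree


def _bipartitions(tree, labels: set[str]) -> set[frozenset]:
    parts = set()
    for node in tree.non_tips():
        side = frozenset(t.name for t in node.tips())
        if 1 < len(side) < len(labels) - 1:
            parts.add(min(side, frozenset(labels - side), key=sorted))
    return parts


def nj_tree(
    data,
    labels: Sequence[str] | None = None,
    bootstrap: int = 0,
    seed: int | None = None,
) -> DistanceTree:
    """Neighbor-joining tree from a distance matrix or aligned sequences.

    ``data`` is either a symmetric zero-diagonal distance matrix
    (array-like, with ``labels``) or a list of equal-length aligned
    sequences (p-distances are computed, gap pairs excluded).  Negative
    branch lengths are clamped to zero.  With ``bootstrap`` > 0 and
    sequence input, support values from seeded column resampling are
    attached per bipartition.
    """
    from skbio import DistanceMatrix

    seqs = None
    if isinstance(data, DistanceMatrix):
        dm = data
        labels = list(dm.ids)
    elif isinstance(data, (list, tuple)) and data and isinstance(data[0], str):
        seqs = [s.upper() for s in data]
        if labels is None:
            labels = [f"t{i+1}" for i in range(len(seqs))]
        dm = _p_distance_matrix(seqs, labels)
    else:
        arr = np.asarray(data, dtype=float)
        if labels is None:
            labels = [f"t{i+1}" for i in range(arr.shape[0])]
        dm = DistanceMatrix(arr, ids=list(labels))
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa for a neighbor-joining tree")
    tree = _nj_from_dm(dm)
    support = None
    if bootstrap > 0:
        if seqs is None:
            raise ValueError("bootstrap requires aligned sequence input")
        rng = np.random.default_rng(seed)
        label_set = set(labels)
        ref_parts = _bipartitions(tree, label_set)
        counts = {part: 0 for part in ref_parts}
        length = len(seqs[0])
        for _ in range(bootstrap):
            cols = rng.integers(0, length, size=length)
            resampled = ["".join(s[c] for c in cols) for s in seqs]
            try:
                rep = _nj_from_dm(_p_distance_matrix(resampled, labels))
            except ValueError:
                continue
            rep_parts = _bipartitions(rep, label_set)
            for part in ref_parts & rep_parts:
                counts[part] += 1
        support = {part: counts[part] / bootstrap for part in ref_parts}
    return DistanceTree(tree, list(labels), support)


@dataclass
class DuplicationReport:
    """A pair of module windows exceeding the identity threshold."""

    window_a: tuple[int, ...]  # module indices, e.g. (7, 8)
    window_b: tuple[int, ...]
    span_a: tuple[int, int]
    span_b: tuple[int, int]
    identity: float


def _module_windows(modules: list[NrpsModule], tandem: bool) -> list[tuple[tuple[int, ...], tuple[int, int]]]:
    out = [((m.index,), m.span) for m in modules]
    if tandem:
        for m1, m2 in zip(modules, modules[1:]):
            out.append(((m1.index, m2.index), (m1.start, m2.end)))
    return out


def _edlib_identity(a: str, b: str) -> float:
    """Fast global-alignment identity estimate (unit-cost edit distance)."""
    r = edlib.align(a, b, mode="NW", task="distance")
    length = max(len(a), len(b))
    return 100.0 * (1 - r["editDistance"] / length)


def detect_duplications(
    bgc: NrpsBgc,
    identity_threshold: float = 90.0,
    include_gap_columns: bool = True,
    scoring: AlignmentScoring = AlignmentScoring(),
    tandem: bool = True,
) -> list[DuplicationReport]:
    """Find intra-cluster module duplications by nucleotide identity.

    All non-overlapping pairs of module windows (single modules and
    tandem di-module blocks) are globally aligned; pairs whose percent
    identity reaches ``identity_threshold`` are reported with
    coordinates.  A fast edit-distance screen skips pairs far below
    the threshold before the full affine-gap alignment.
    """
    if bgc.sequence is None:
        raise ValueError(f"BGC {bgc.id} has no nucleotide sequence")
    modules = infer_modules(bgc)
    windows = _module_windows(modules, tandem)
    reports = []
    for (wa, span_a), (wb, span_b) in itertools.combinations(windows, 2):
        if set(wa) & set(wb):
            continue
        if span_a[1] > span_b[0] and span_b[1] > span_a[0]:
            continue  # overlapping nucleotide spans
        sa = bgc.sequence[span_a[0] : span_a[1]]
        sb = bgc.sequence[span_b[0] : span_b[1]]
        if not sa or not sb:
            continue
        if _HAVE_EDLIB and _edlib_identity(sa, sb) < identity_threshold - 10:
            continue
        a_aln, b_aln, _ = align_global(sa, sb, scoring)
        ident = pairwise_identity(a_aln, b_aln, include_gap_columns)
        if ident >= identity_threshold:
            reports.append(DuplicationReport(wa, wb, span_a, span_b, ident))
    reports.sort(key=lambda r: (-r.identity, r.window_a, r.window_b))
    return reports


@dataclass
class DeletionReport:
    """A collinearity gap between two clusters (deletion in the query)."""

    ref_span: tuple[int, int]  # reference nucleotides absent from the query
    query_junction: int  # query coordinate where the flanks join
    deleted_modules: tuple[int, ...] = ()
    junction_linker: str | None = None  # e.g. "module 4 A-T linker"
    truncation: bool = False


def _collinear_chain(matches: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Longest strictly increasing (in both coordinates) anchor chain."""
    if not matches:
        return []
    matches = sorted(matches)
    import bisect

    # patience LIS on query coordinates
    tails: list[int] = []
    tails_idx: list[int] = []
    prev = [-1] * len(matches)
    for k, (_, q) in enumerate(matches):
        pos = bisect.bisect_left(tails, q)
        if pos == len(tails):
            tails.append(q)
            tails_idx.append(k)
        else:
            tails[pos] = q
            tails_idx[pos] = k
        prev[k] = tails_idx[pos - 1] if pos > 0 else -1
    chain = []
    k = tails_idx[-1]
    while k != -1:
        chain.append(matches[k])
        k = prev[k]
    return chain[::-1]


def _linker_name(bgc: NrpsBgc, position: int) -> str | None:
    """Name the inter-domain linker containing a reference coordinate."""
    modules = infer_modules(bgc)
    for m in modules:
        doms = sorted(m.domains, key=lambda d: d.start)
        for d1, d2 in zip(doms, doms[1:]):
            if d1.end <= position < d2.start:
                return f"module {m.index} {d1.kind}-{d2.kind} linker"
        if m.start <= position < doms[0].start:
            return f"module {m.index} upstream linker"
    return None


def detect_deletion(
    reference: NrpsBgc,
    query: NrpsBgc,
    word: int = 25,
    min_gap: int = 200,
) -> DeletionReport | None:
    """Localize a module deletion by dot-plot collinearity analysis.

    Exact word matches between reference and query are chained into the
    main collinear diagonal; the largest gap where the reference
    coordinate jumps much further than the query coordinate is reported
    as the deleted reference span plus the query junction.  When module
    annotations are present, fully deleted modules are listed and the
    junction is assigned to the inter-domain linker containing it.  A
    gap at either sequence end is flagged as a truncation.  Returns
    ``None`` when no gap of at least ``min_gap`` nt exists; raises when
    no collinear diagonal is found at all.
    """
    if reference.sequence is None or query.sequence is None:
        raise ValueError("both BGCs need nucleotide sequences")
    dp = dot_plot(reference.sequence, query.sequence, word)
    chain = _collinear_chain(dp.matches)
    if not chain:
        raise ValueError("no collinear diagonal found between the two clusters")

    gaps = []  # (deletion size, ref span, query junction, terminal?)
    # internal gaps between consecutive anchors
    for (r1, q1), (r2, q2) in zip(chain, chain[1:]):
        ref_jump = r2 - r1
        q_jump = q2 - q1
        size = ref_jump - q_jump
        if size >= min_gap:
            # deleted reference block sits between the projected flanks
            del_start = r2 - size
            gaps.append((size, (del_start, r2), q2, False))
    # terminal gap: reference extends beyond the last anchored region
    r_last, q_last = chain[-1]
    tail_ref = len(reference.sequence) - (r_last + word)
    tail_query = len(query.sequence) - (q_last + word)
    tail_size = tail_ref - tail_query
    if tail_size >= min_gap:
        gaps.append((tail_size, (len(reference.sequence) - tail_size, len(reference.sequence)), len(query.sequence), True))
    r0, q0 = chain[0]
    head_size = r0 - q0
    if head_size >= min_gap:
        gaps.append((head_size, (0, head_size), 0, True))

    if not gaps:
        return None
    size, ref_span, junction, terminal = max(gaps, key=lambda g: g[0])
    deleted_modules: tuple[int, ...] = ()
    linker = None
    if reference.domains:
        try:
            modules = infer_modules(reference)
            # a module is deleted when its A domain (the module-defining
            # domain) lies in the span; with a linker junction the upstream
            # module keeps a T domain inherited from the last deleted module.
            # word-size slop covers chance base matches at the gap edges.
            deleted_modules = tuple(
                m.index
                for m in modules
                if (a := m.domain("A")) is not None
                and ref_span[0] - word <= a.start
                and a.end <= ref_span[1] + word
            )
        except ValueError:
            modules = []
        if not terminal:
            linker = _linker_name(reference, ref_span[0])
    return DeletionReport(ref_span, junction, deleted_modules, linker, terminal)
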