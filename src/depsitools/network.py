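"""Classic molecular networking with modified-cosine spectral similarity.

The pipeline mirrors the classic GNPS workflow: per-spectrum peak
filtering (precursor exclusion window, top-k per m/z window), pairwise
modified cosine with precursor-shift-aware peak pairing, then graph
assembly with cosine/matched-peak thresholds, a mutual top-k rank rule,
and iterative pruning of oversized molecular families.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import networkx as nx

from .fragments import Spectrum

__all__ = [
    "NetworkParams",
    "NetworkEdge",
    "MolecularFamily",
    "filter_peaks",
    "modified_cosine",
    "build_network",
]


@dataclass(frozen=True)
class NetworkParams:
    """Networking parameters; defaults follow the classic workflow."""

    precursor_exclusion_da: float = 17.0
    window_da: float = 50.0
    top_k_in_window: int = 6
    precursor_tol_da: float = 0.02
    fragment_tol_da: float = 0.02
    min_cosine: float = 0.7
    min_matched_peaks: int = 6
    mutual_rank_k: int = 10
    max_family_size: int = 100
    #: matched-peak rule: "at least" keeps edges with matched >= min_matched_peaks
    #: (the platform's minimum-matched-peaks semantics); "strict" requires >.
    matched_peaks_rule: str = "at_least"

    def __post_init__(self):
        for name in (
            "precursor_exclusion_da", "window_da", "top_k_in_window",
            "precursor_tol_da", "fragment_tol_da", "min_matched_peaks",
            "mutual_rank_k", "max_family_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class NetworkEdge:
    node_a: str
    node_b: str
    cosine: float
    matched_peaks: int
    delta_mz: float


@dataclass
class MolecularFamily:
    label: int
    members: list[str]

    def __len__(self) -> int:
        return len(self.members)


def filter_peaks(s: Spectrum, p: NetworkParams = NetworkParams()) -> Spectrum:
    """Precursor-exclusion and top-k window filtering of one spectrum.

    Removes every fragment within +/- ``precursor_exclusion_da`` of the
    precursor m/z, then keeps a peak only if it is among the
    ``top_k_in_window`` most intense peaks within +/- ``window_da`` of
    its own m/z.  The window criterion is evaluated against the
    original peak set, so the result does not depend on removal order.
    """
    peaks = [pk for pk in s.peaks if abs(pk[0] - s.precursor_mz) > p.precursor_exclusion_da]
    kept = []
    for mz, inten in peaks:
        neighbors = [i2 for m2, i2 in peaks if abs(m2 - mz) <= p.window_da]
        neighbors.sort(reverse=True)
        cutoff = neighbors[p.top_k_in_window - 1] if len(neighbors) >= p.top_k_in_window else -1.0
        if inten >= cutoff:
            kept.append((mz, inten))
    return replace(s, peaks=kept)


def _normalized(s: Spectrum) -> list[tuple[float, float]]:
    """Square-root transformed, unit-L2-normalized peak list."""
    root = [(m, math.sqrt(i)) for m, i in s.peaks if i > 0]
    norm = math.sqrt(sum(w * w for _, w in root))
    if norm == 0:
        return []
    return [(m, w / norm) for m, w in root]


def _allowed_pair_matrix(
    a: list[tuple[float, float]],
    b: list[tuple[float, float]],
    shift: float,
    tol: float,
):
    """Weight matrix over peak pairs admitted at delta 0 or the parent-mass shift."""
    import numpy as np

    w = np.zeros((len(a), len(b)))
    any_allowed = False
    for i, (ma, wa) in enumerate(a):
        for j, (mb, wb) in enumerate(b):
            if abs(ma - mb) <= tol or abs(ma - (mb + shift)) <= tol:
                w[i, j] = wa * wb
                any_allowed = True
    return w if any_allowed else None


def modified_cosine(
    a: Spectrum, b: Spectrum, p: NetworkParams = NetworkParams()
) -> tuple[float, int]:
    """Modified cosine similarity and matched-peak count of two spectra.

    Intensities are square-root transformed and unit-normalized.  Peak
    pairs are admitted at fragment-mass delta 0 or at the parent
    (singly-protonated-equivalent) mass difference, within
    ``fragment_tol_da``; the one-to-one pairing maximizing the summed
    intensity products is found exactly (linear-sum assignment).
    Symmetric by construction.
    """
    na, nb = _normalized(a), _normalized(b)
    if not na or not nb:
        return 0.0, 0
    # evaluate in a fixed orientation so that (a,b) and (b,a) agree exactly
    swap = (a.precursor_mz, tuple(a.mz)) > (b.precursor_mz, tuple(b.mz))
    if swap:
        na, nb = nb, na
        shift = b.precursor_neutral_mass - a.precursor_neutral_mass
    else:
        shift = a.precursor_neutral_mass - b.precursor_neutral_mass
    w = _allowed_pair_matrix(na, nb, shift, p.fragment_tol_da)
    if w is None:
        return 0.0, 0
    from scipy.optimize import linear_sum_assignment

    rows, cols = linear_sum_assignment(w, maximize=True)
    selected = sorted(
        (i, j) for i, j in zip(rows.tolist(), cols.tolist()) if w[i, j] > 0
    )
    score = float(sum(w[i, j] for i, j in selected))
    return min(score, 1.0), len(selected)


def build_network(
    spectra: list[Spectrum], p: NetworkParams = NetworkParams()
) -> tuple[list[NetworkEdge], list[MolecularFamily]]:
    """Assemble the molecular network from a list of spectra.

    All spectrum pairs are scored with the modified cosine after peak
    filtering.  An edge is kept iff cosine > ``min_cosine``, the
    matched-peak rule holds, and each node ranks in the other's top
    ``mutual_rank_k`` most similar nodes.  Connected components larger
    than ``max_family_size`` lose their lowest-cosine edges until the
    size bound holds.  Deterministic given input order.
    """
    if len(spectra) < 2:
        raise ValueError("need at least 2 spectra to build a network")
    ids = []
    for k, s in enumerate(spectra):
        ids.append(s.id or f"spectrum_{k}")
    if len(set(ids)) != len(ids):
        raise ValueError("spectrum ids must be unique")
    filtered = [filter_peaks(s, p) for s in spectra]

    scores: dict[tuple[int, int], tuple[float, int]] = {}
    for i, j in itertools.combinations(range(len(filtered)), 2):
        scores[(i, j)] = modified_cosine(filtered[i], filtered[j], p)

    # per-node similarity ranking over all scored pairs (by cosine)
    neighbor_rank: list[list[int]] = [[] for _ in filtered]
    for i in range(len(filtered)):
        others = [(j, scores[tuple(sorted((i, j)))][0]) for j in range(len(filtered)) if j != i]
        others.sort(key=lambda t: (-t[1], t[0]))
        neighbor_rank[i] = [j for j, _ in others]

    def mutual_top_k(i: int, j: int) -> bool:
        return (
            j in neighbor_rank[i][: p.mutual_rank_k]
            and i in neighbor_rank[j][: p.mutual_rank_k]
        )

    min_matched = p.min_matched_peaks if p.matched_peaks_rule == "at_least" else p.min_matched_peaks + 1
    edges = []
    for (i, j), (cos, matched) in sorted(scores.items()):
        if cos > p.min_cosine and matched >= min_matched and mutual_top_k(i, j):
            edges.append(
                NetworkEdge(
                    ids[i], ids[j], cos, matched,
                    spectra[i].precursor_mz - spectra[j].precursor_mz,
                )
            )

    g = nx.Graph()
    g.add_nodes_from(ids)
    for e in edges:
        g.add_edge(e.node_a, e.node_b, cosine=e.cosine)
    # iteratively prune oversized families by removing their weakest edges
    while True:
        oversized = [c for c in nx.connected_components(g) if len(c) > p.max_family_size]
        if not oversized:
            break
        for comp in oversized:
            weakest = min(
                ((u, v, d["cosine"]) for u, v, d in g.edges(comp, data=True)),
                key=lambda t: (t[2], t[0], t[1]),
            )
            g.remove_edge(weakest[0], weakest[1])
    kept = {frozenset((u, v)) for u, v in g.edges}
    edges = [e for e in edges if frozenset((e.node_a, e.node_b)) in kept]

    families = []
    for label, comp in enumerate(
        sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    ):
        members = sorted(comp, key=ids.index)
        families.append(MolecularFamily(label, members))
    return edges, families
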