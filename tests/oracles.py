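"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own algorithms: the cosine
oracle enumerates every one-to-one peak pairing, and the alignment
oracle enumerates every global alignment path.
"""

import math


def brute_force_modified_cosine(a, b, p):
    """Exhaustive maximum over all one-to-one peak pairings."""

    def norm(s):
        w = [(m, math.sqrt(i)) for m, i in s.peaks if i > 0]
        z = math.sqrt(sum(x * x for _, x in w))
        return [(m, x / z) for m, x in w] if z else []

    na, nb = norm(a), norm(b)
    shift = a.precursor_neutral_mass - b.precursor_neutral_mass
    allowed = [
        (i, j, wa * wb)
        for i, (ma, wa) in enumerate(na)
        for j, (mb, wb) in enumerate(nb)
        if abs(ma - mb) <= p.fragment_tol_da or abs(ma - (mb + shift)) <= p.fragment_tol_da
    ]
    best = (0.0, 0)

    def recurse(k, used_a, used_b, score, count):
        nonlocal best
        if (score, count) > best:
            best = (score, count)
        for idx in range(k, len(allowed)):
            i, j, w = allowed[idx]
            if i in used_a or j in used_b:
                continue
            recurse(idx + 1, used_a | {i}, used_b | {j}, score + w, count + 1)

    recurse(0, frozenset(), frozenset(), 0.0, 0)
    return best


def brute_force_global_alignment_score(a, b, match=1.0, mismatch=-1.0,
                                       gap_open=-5.0, gap_extend=-1.0):
    """Optimum global alignment score by full path enumeration.

    A gap of length L scores gap_open + (L-1) * gap_extend.  Exponential;
    only usable for sequences of length <= ~6.
    """
    best = -math.inf

    def recurse(i, j, score, prev):
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            recurse(i + 1, j + 1, score + s, "d")
        if i < len(a):
            s = gap_extend if prev == "u" else gap_open
            recurse(i + 1, j, score + s, "u")
        if j < len(b):
            s = gap_extend if prev == "l" else gap_open
            recurse(i, j + 1, score + s, "l")

    recurse(0, 0, 0.0, "")
    return best
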