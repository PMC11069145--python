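"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's seed-and-extend / DFS code paths:
dispersed repeats are recomputed by exhaustive lag scanning, closed walks by
enumerating every multiset permutation, and binomial tails by exact rational
arithmetic.
"""
from __future__ import annotations

from fractions import Fraction
from itertools import permutations, product
from math import comb

import numpy as np

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def _complement(s: str) -> str:
    return s.translate(_COMP)


def bruteforce_dispersed(seq: str, min_len: int = 30, categories=None):
    """All maximal exact repeated pairs by exhaustive lag scanning.

    Returns a set of (category, pos1_0based, pos2_0based, length) applying
    the same reporting contract as the scanner: overlapping intervals are
    excluded outside the palindromic category, trivial self-matches are
    dropped, and pairs nested inside a longer same-category pair are
    suppressed.
    """
    categories = categories or ("forward", "palindromic", "reverse", "complement")
    n = len(seq)
    a = np.frombuffer(seq.encode(), dtype=np.uint8)
    raw = set()
    for category in categories:
        if category == "forward":
            t = seq
        elif category == "palindromic":
            t = _revcomp(seq)
        elif category == "reverse":
            t = seq[::-1]
        else:
            t = _complement(seq)
        b = np.frombuffer(t.encode(), dtype=np.uint8)
        for d in range(-(n - 1), n):
            i_lo = max(0, d)
            i_hi = min(n, n + d)
            if i_hi - i_lo < min_len:
                continue
            m = (a[i_lo:i_hi] == b[i_lo - d : i_hi - d]).astype(np.int8)
            padded = np.concatenate([[0], m, [0]])
            diff = np.diff(padded)
            starts = np.flatnonzero(diff == 1)
            ends = np.flatnonzero(diff == -1)
            for s, e in zip(starts, ends):
                length = int(e - s)
                if length < min_len:
                    continue
                i0 = i_lo + int(s)
                j0 = i0 - d
                if category in ("forward", "complement"):
                    g0 = j0
                else:
                    g0 = n - (j0 + length)
                (p1, p2) = sorted([i0, g0])
                int1 = (p1, p1 + length)
                int2 = (p2, p2 + length)
                if int1 == int2 and category != "palindromic":
                    continue
                overlap = int1[1] > int2[0]
                if overlap and category != "palindromic":
                    continue
                raw.add((category, p1, p2, length))
    # suppress same-category nesting
    kept = set()
    by_len = sorted(raw, key=lambda r: -r[3])
    for cat, p1, p2, ln in by_len:
        nested = False
        for kcat, k1, k2, kln in kept:
            if kcat != cat or kln <= ln:
                continue
            if p1 >= k1 and p1 + ln <= k1 + kln and p2 >= k2 and p2 + ln <= k2 + kln:
                nested = True
                break
        if not nested:
            kept.add((cat, p1, p2, ln))
    return kept


def bruteforce_best_closed_walk(segments, links, copies, support, min_support=1):
    """Best closed walk by enumerating every multiset permutation.

    ``links`` are oriented 4-tuples; a walk is valid when every consecutive
    oriented pair (including the closing one) is a link (or the
    reverse-complement of one) with support >= min_support.  Returns
    (best_score, canonical_walk) or None.
    """
    def flip(node):
        return node[0], "-" if node[1] == "+" else "+"

    adjacency = set()
    for a, oa, b, ob in links:
        adjacency.add(((a, oa), (b, ob)))
        adjacency.add((flip((b, ob)), flip((a, oa))))

    def canon_junction(a, b):
        return min((a, b), (flip(b), flip(a)))

    def canonical(walk):
        k = len(walk)
        rc = tuple(flip(x) for x in reversed(walk))
        return min(w[i:] + w[:i] for w in (walk, rc) for i in range(k))

    items = [seg for seg, c in sorted(copies.items()) for _ in range(c)]
    best = None
    seen = set()
    for perm in set(permutations(items)):
        for orients in product("+-", repeat=len(items)):
            walk = tuple((seg, o) for seg, o in zip(perm, orients))
            ok = True
            score = 0
            for x, y in zip(walk, walk[1:] + walk[:1]):
                if (x, y) not in adjacency:
                    ok = False
                    break
                s = support.get(canon_junction(x, y), 0)
                if s < min_support:
                    ok = False
                    break
                score += s
            if not ok:
                continue
            c = canonical(walk)
            if c in seen:
                pass
            seen.add(c)
            cand = (score, c)
            if best is None or (-cand[0], cand[1]) < (-best[0], best[1]):
                best = cand
    return best


def exact_binomial_tail(u: int, n: int, p_num: int, p_den: int) -> float:
    """P(X >= u | n, p) with exact rational arithmetic."""
    if u <= 0:
        return 1.0
    p = Fraction(p_num, p_den)
    q = 1 - p
    total = Fraction(0)
    for k in range(u, n + 1):
        total += comb(n, k) * p**k * q ** (n - k)
    return float(total)


def coverage_by_intervals(intervals, length):
    """Per-position depth from (start, end) half-open intervals."""
    depth = np.zeros(length, dtype=int)
    for s, e in intervals:
        depth[s:e] += 1
    return depth
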