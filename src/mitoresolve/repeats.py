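"""Repeat scanners: SSRs, tandem repeats, and dispersed repeat pairs.

Three independent detectors over one genome:

* **SSRs** — maximal perfect runs of a 1–6 bp motif above per-unit-length
  copy thresholds (MISA-style definition).
* **Tandem repeats** — loci where the sequence matches itself at a lag
  (period) of 7–200 bp well enough to pass a percent-match and alignment
  score filter (a simplified, score-seeded wraparound comparison, not a TRF
  re-implementation).
* **Dispersed repeats** — maximal repeated pairs >= 30 bp, classified as
  forward (copy vs copy), palindromic (copy vs reverse complement), reverse
  (copy vs reversal) or complement (copy vs complement), found by exact
  k-mer seeding and maximal extension along the diagonal.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_core import complement, revcomp

#: MISA-convention minimum copy numbers per unit length
DEFAULT_SSR_THRESHOLDS: dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


# ---------------------------------------------------------------------------
# SSRs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SSRRecord:
    motif: str  # canonical: lexicographically smallest rotation
    unit_len: int
    copies: int
    start: int  # 1-based inclusive; end may exceed the sequence length when
    end: int    # the run wraps the circular origin

    def __post_init__(self):
        assert self.end - self.start + 1 == self.unit_len * self.copies


def canonical_rotation(motif: str) -> str:
    return min(motif[i:] + motif[:i] for i in range(len(motif)))


def _is_primitive(unit: str) -> bool:
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def find_ssrs(
    seq: str,
    thresholds: Mapping[int, int] | None = None,
    circular: bool = False,
    wrap_window: int = 600,
) -> list[SSRRecord]:
    """Maximal perfect SSR runs; each run reported once at its smallest unit.

    With ``circular=True`` a window of the sequence start is appended so runs
    spanning the origin are found; their ``end`` coordinate then exceeds the
    sequence length (positions continue past the origin).
    """
    thresholds = dict(thresholds or DEFAULT_SSR_THRESHOLDS)
    n = len(seq)
    scan = seq + seq[: min(max(n - 1, 0), wrap_window)] if circular else seq
    m = len(scan)
    records: list[SSRRecord] = []
    for u, min_copies in sorted(thresholds.items()):
        if u < 1 or m <= u:
            continue
        t = 0
        limit = m - u
        while t < limit:
            if scan[t] != scan[t + u]:
                t += 1
                continue
            # maximal lag-u run starting at t
            run_start = t
            while t < limit and scan[t] == scan[t + u]:
                t += 1
            span_total = (t - run_start) + u
            unit = scan[run_start : run_start + u]
            if not _is_primitive(unit):
                continue
            copies = span_total // u
            if copies < min_copies:
                continue
            records.append(
                SSRRecord(
                    motif=canonical_rotation(unit),
                    unit_len=u,
                    copies=copies,
                    start=run_start + 1,
                    end=run_start + copies * u,
                )
            )
    if circular:
        crossing = [r for r in records if r.start <= n < r.end]
        kept = []
        for r in records:
            if r.start > n:
                continue  # duplicate image inside the appended window
            if r.end <= n and any(
                c.motif == r.motif and r.end <= c.end - n for c in crossing
            ):
                continue  # linear fragment of a wrapping run
            kept.append(r)
        records = kept
    return sorted(records, key=lambda r: (r.start, r.unit_len))


def ssr_base_share(ssrs: Sequence[SSRRecord], unit_len: int = 1) -> dict[str, float]:
    """Percent share of each motif among SSRs of one unit length (2 d.p.)."""
    subset = [r for r in ssrs if r.unit_len == unit_len]
    total = len(subset)
    if total == 0:
        return {}
    counts = Counter(r.motif for r in subset)
    return {motif: round(100.0 * c / total, 2) for motif, c in sorted(counts.items())}


# ---------------------------------------------------------------------------
# tandem repeats
# ---------------------------------------------------------------------------

@dataclass
class TandemRepeat:
    consensus: str
    period: int
    copies: float
    percent_match: float
    start: int  # 1-based inclusive
    end: int


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def find_tandem_repeats(
    seq: str,
    min_period: int = 7,
    max_period: int = 200,
    min_match: float = 75.0,
    min_span: int = 12,
    min_copies: float = 1.8,
    min_score: int = 40,
    match_weight: int = 2,
    mismatch_weight: int = 7,
) -> list[TandemRepeat]:
    """Tandem arrays via self-comparison at each candidate period.

    For each period p the sequence is compared with itself at lag p; maximal
    positive-scoring excursions (match +2 / mismatch -7, minimum score 40 —
    TRF-flavoured weights) whose percent match exceeds ``min_match`` and
    whose span and copy number clear the floors are reported.  Overlapping
    reports of the same locus at different periods are collapsed to the
    highest-percent-match (then smallest) period.
    """
    if min_period < 2:
        raise ValueError("min_period must be >= 2")
    n = len(seq)
    arr = _encode(seq)
    candidates: list[TandemRepeat] = []
    for p in range(min_period, min(max_period, n - 1) + 1):
        m = arr[: n - p] == arr[p:]
        if not m.any():
            continue
        w = np.where(m, match_weight, -mismatch_weight).astype(np.int64)
        P = np.concatenate([[0], np.cumsum(w)])  # prefix sums, len n-p+1
        runmin = np.minimum.accumulate(P)
        excursion = P[1:] - runmin[:-1]  # best score of a segment ending here
        hits = np.flatnonzero(excursion >= min_score)
        if hits.size == 0:
            continue
        mpre = np.concatenate([[0], np.cumsum(m.astype(np.int64))])
        # cluster hit-ends separated by a reset (excursion back to 0)
        used_until = -1
        clusters: list[tuple[int, int]] = []
        zero = np.flatnonzero(excursion == 0)
        for h in hits:
            if h <= used_until:
                continue
            nxt = zero[zero > h]
            cluster_end = int(nxt[0]) if nxt.size else len(excursion)
            seg_hits = hits[(hits >= h) & (hits < cluster_end)]
            e = int(seg_hits[np.argmax(excursion[seg_hits])])
            clusters.append((h, e))
            used_until = cluster_end
        for _, e in clusters:
            # segment start: last prefix index attaining the running minimum
            target = runmin[e]
            js = np.flatnonzero(P[: e + 1] == target)
            j = int(js[-1])
            ts, te = j, e  # w-indices [ts, te]
            width = te - ts + 1
            matches = int(mpre[te + 1] - mpre[ts])
            percent = 100.0 * matches / width
            span = width + p
            copies = span / p
            if percent <= min_match or span < min_span or copies < min_copies:
                continue
            candidates.append(
                TandemRepeat(
                    consensus=_tandem_consensus(seq, ts, span, p),
                    period=p,
                    copies=round(copies, 2),
                    percent_match=round(percent, 1),
                    start=ts + 1,
                    end=ts + span,
                )
            )
    return _collapse_tandems(candidates)


def _tandem_consensus(seq: str, start0: int, span: int, period: int) -> str:
    full = span // period
    chunks = [seq[start0 + i * period : start0 + (i + 1) * period] for i in range(full)]
    if not chunks:
        return seq[start0 : start0 + period]
    consensus = []
    for col in range(period):
        consensus.append(Counter(c[col] for c in chunks).most_common(1)[0][0])
    return "".join(consensus)


def _collapse_tandems(candidates: list[TandemRepeat]) -> list[TandemRepeat]:
    kept: list[TandemRepeat] = []
    for cand in sorted(
        candidates, key=lambda r: (-r.percent_match, r.period, r.start)
    ):
        redundant = False
        for k in kept:
            ov = min(cand.end, k.end) - max(cand.start, k.start) + 1
            shorter = min(cand.end - cand.start, k.end - k.start) + 1
            if ov > 0.5 * shorter:
                redundant = True
                break
        if not redundant:
            kept.append(cand)
    return sorted(kept, key=lambda r: (r.start, r.period))


# ---------------------------------------------------------------------------
# dispersed repeats
# ---------------------------------------------------------------------------

CATEGORIES = ("forward", "palindromic", "reverse", "complement")


@dataclass(frozen=True)
class DispersedRepeatPair:
    category: str
    pos1: int  # 1-based starts; pos1 <= pos2
    pos2: int
    length: int
    identity: float

    @property
    def interval1(self) -> tuple[int, int]:
        return self.pos1 - 1, self.pos1 - 1 + self.length

    @property
    def interval2(self) -> tuple[int, int]:
        return self.pos2 - 1, self.pos2 - 1 + self.length


def _category_target(seq: str, category: str) -> str:
    if category == "forward":
        return seq
    if category == "palindromic":
        return revcomp(seq)
    if category == "reverse":
        return seq[::-1]
    if category == "complement":
        return complement(seq)
    raise ValueError(f"unknown category {category!r}")


def _map_target_interval(category: str, j0: int, j1: int, m: int) -> tuple[int, int]:
    """Map an interval on the category-transformed string back to the genome."""
    if category in ("forward", "complement"):
        return j0, j1
    return m - j1, m - j0  # palindromic / reverse mirror the coordinate


def find_dispersed_repeats(
    seq: str,
    min_len: int = 30,
    max_mismatch: int = 0,
    categories: Sequence[str] = CATEGORIES,
    circular: bool = False,
    wrap_window: int = 5000,
) -> list[DispersedRepeatPair]:
    """Maximal dispersed repeat pairs >= ``min_len``.

    Pairs are maximal along their diagonal: extending either end by one base
    breaks the category relation (or runs off the sequence).  Tandem/SSR
    self-matches — pairs whose two intervals overlap — are excluded except
    for palindromic self-spanning hits.  Pairs nested inside a longer pair of
    the same category are suppressed.  ``max_mismatch > 0`` enables a greedy
    mismatch-tolerant extension (exact matching is the default contract).
    """
    if min_len < 8:
        raise ValueError("min_len must be >= 8")
    n = len(seq)
    scan = seq + seq[: min(n // 2, wrap_window)] if circular else seq
    m = len(scan)
    k = min_len if max_mismatch == 0 else max(8, min_len // (max_mismatch + 1))
    pairs: set[tuple[str, int, int, int, float]] = set()
    for category in categories:
        target = _category_target(scan, category)
        index: dict[str, list[int]] = {}
        for j in range(m - k + 1):
            index.setdefault(target[j : j + k], []).append(j)
        seeds_by_diag: dict[int, list[int]] = {}
        for i in range(m - k + 1):
            for j in index.get(scan[i : i + k], ()):
                seeds_by_diag.setdefault(i - j, []).append(i)
        for diag, seed_is in seeds_by_diag.items():
            covered_until = -1
            for i in sorted(set(seed_is)):
                if i < covered_until:
                    continue
                j = i - diag
                i0, i1, mism = _extend_diagonal(scan, target, i, j, k, max_mismatch)
                covered_until = i1
                length = i1 - i0
                if length < min_len:
                    continue
                j0, j1 = i0 - diag, i1 - diag
                g0, g1 = _map_target_interval(category, j0, j1, m)
                a, b = sorted([(i0, i1), (g0, g1)])
                if a == b and category != "palindromic":
                    continue  # trivial self-match
                overlap = a[1] > b[0] and b[1] > a[0]
                if overlap and category != "palindromic":
                    continue  # SSR/tandem-internal self-match
                identity = 1.0 - mism / length
                pairs.add((category, a[0], b[0], length, round(identity, 4)))
    records = [
        DispersedRepeatPair(cat, p1 + 1, p2 + 1, ln, ident)
        for cat, p1, p2, ln, ident in pairs
    ]
    if circular:
        records = [r for r in records if r.pos2 - 1 < n]
    records = _suppress_nested(records)
    return sorted(records, key=lambda r: (r.pos1, r.pos2, r.category))


def _extend_diagonal(
    a: str, b: str, i: int, j: int, k: int, budget: int
) -> tuple[int, int, int]:
    """Maximal match of a[i0:i1] vs b[i0-d:i1-d] containing the seed.

    Exact when ``budget`` is 0; otherwise a greedy right-then-left extension
    spends the mismatch budget and trims mismatched ends.
    """
    n_a, n_b = len(a), len(b)
    i0, i1 = i, i + k
    j0 = j
    mism = 0
    # right
    bud = budget
    while i1 < n_a and j0 + (i1 - i0) < n_b:
        if a[i1] == b[j0 + (i1 - i0)]:
            i1 += 1
        elif bud > 0:
            bud -= 1
            mism += 1
            i1 += 1
        else:
            break
    # left
    while i0 > 0 and j0 > 0:
        if a[i0 - 1] == b[j0 - 1]:
            i0 -= 1
            j0 -= 1
        elif bud > 0:
            bud -= 1
            mism += 1
            i0 -= 1
            j0 -= 1
        else:
            break
    # trim mismatched ends (maximality with mismatches is interior-only)
    while i1 > i0 and a[i1 - 1] != b[j0 + (i1 - 1 - i0)]:
        i1 -= 1
        mism -= 1
    while i0 < i1 and a[i0] != b[j0]:
        i0 += 1
        j0 += 1
        mism -= 1
    return i0, i1, mism


def _suppress_nested(records: list[DispersedRepeatPair]) -> list[DispersedRepeatPair]:
    kept: list[DispersedRepeatPair] = []
    for rec in sorted(records, key=lambda r: -r.length):
        nested = False
        for k in kept:
            if k.category != rec.category or k.length <= rec.length:
                continue
            (a0, a1), (b0, b1) = rec.interval1, rec.interval2
            (ka0, ka1), (kb0, kb1) = k.interval1, k.interval2
            if a0 >= ka0 and a1 <= ka1 and b0 >= kb0 and b1 <= kb1:
                nested = True
                break
        if not nested:
            kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

def summarize_repeats(
    ssrs: Sequence[SSRRecord],
    tandems: Sequence[TandemRepeat],
    dispersed: Sequence[DispersedRepeatPair],
) -> dict:
    """Counts by category — the machine-readable analogue of a repeat figure."""
    ssr_by_unit = Counter(r.unit_len for r in ssrs)
    disp_by_cat = Counter(r.category for r in dispersed)
    return {
        "ssr_total": len(ssrs),
        "ssr_by_unit_length": {str(u): ssr_by_unit.get(u, 0) for u in range(1, 7)},
        "monomer_base_share_percent": ssr_base_share(ssrs, 1),
        "tandem_total": len(tandems),
        "dispersed_total": len(dispersed),
        "dispersed_by_category": {c: disp_by_cat.get(c, 0) for c in CATEGORIES},
    }
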