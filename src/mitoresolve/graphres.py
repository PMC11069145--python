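"""Junction-support resolution of a unitig graph into circular conformations.

The strategy: align long reads to the graph segments, count reads that run
head-to-tail across each oriented link ("junction support"), then search the
closed walks that satisfy segment copy numbers for the one with maximal total
support.  A direct repeat visited twice by the master circle can recombine
into a pair of subcircles; those are enumerated as candidate conformations.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_core import AssemblyGraph, ReadAlignment, SequenceRecord, revcomp

OrientedSeg = tuple[str, str]
Junction = tuple[OrientedSeg, OrientedSeg]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


class UnresolvableGraphError(RuntimeError):
    """No closed walk satisfies the copy-number constraints with support."""

    def __init__(self, message: str, unsupported: Sequence[Junction] = ()):
        super().__init__(message)
        self.unsupported = list(unsupported)


def _flip(node: OrientedSeg) -> OrientedSeg:
    seg, o = node
    return seg, "-" if o == "+" else "+"


def canonical_junction(a: OrientedSeg, b: OrientedSeg) -> Junction:
    """Pool a junction with its reverse-complement image: keep the smaller."""
    fwd = (a, b)
    rc = (_flip(b), _flip(a))
    return min(fwd, rc)


def junction_label(j: Junction) -> str:
    (a, oa), (b, ob) = j
    return f"{a}{oa}>{b}{ob}"


@dataclass
class JunctionEvidence:
    from_node: OrientedSeg
    to_node: OrientedSeg
    read_ids: list[str] = field(default_factory=list)

    @property
    def support(self) -> int:
        return len(self.read_ids)

    @property
    def junction(self) -> Junction:
        return canonical_junction(self.from_node, self.to_node)


@dataclass
class Conformation:
    """A circular walk of oriented segments (master circle or recombinant)."""

    walk: tuple[OrientedSeg, ...]
    length: int
    kind: str  # master | recombinant

    def canonical(self) -> tuple[OrientedSeg, ...]:
        """Rotation- and strand-invariant signature of the circular walk."""
        n = len(self.walk)
        rc = tuple(_flip(node) for node in reversed(self.walk))
        candidates = [
            w[i:] + w[:i] for w in (self.walk, rc) for i in range(n)
        ]
        return min(candidates)

    def sequence(self, segments: Mapping[str, str]) -> str:
        chunks = []
        for seg, o in self.walk:
            s = segments[seg]
            chunks.append(s if o == "+" else revcomp(s))
        return "".join(chunks)


# ---------------------------------------------------------------------------
# bundled read-to-segment aligner (substitution-aware, k-mer seeded)
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _kmer_index(segments: Mapping[str, str], k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for name, seq in segments.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((name, i))
    return index


def align_reads_to_segments(
    reads: Iterable[SequenceRecord],
    segments: Mapping[str, str],
    min_identity: float = 0.9,
    min_anchor: int = 200,
    k: int = 15,
    seed_step: int = 5,
) -> list[ReadAlignment]:
    """Seed-and-extend local alignment of reads against graph segments.

    Exact k-mer seeds are grouped per (segment, strand, diagonal); each group
    is scored over its maximal ungapped window.  The aligner is
    substitution-aware only (no indel rescue) — appropriate for CCS-grade
    reads; pre-computed PAF is the escape hatch for other data.
    """
    usable = {}
    for name, seq in segments.items():
        if len(seq) < k:
            warnings.warn(f"segment {name!r} shorter than seed size {k}; skipped")
            continue
        usable[name] = seq
    if not usable:
        return []
    index = _kmer_index(usable, k)
    seg_arrays = {name: _encode(seq) for name, seq in usable.items()}
    seg_lens = {name: len(seq) for name, seq in usable.items()}

    alignments: list[ReadAlignment] = []
    for read in reads:
        L = len(read.seq)
        if L < k:
            continue
        for orient, q in (("+", read.seq), ("-", revcomp(read.seq))):
            qarr = _encode(q)
            diagonals: set[tuple[str, int]] = set()
            for qpos in range(0, L - k + 1, seed_step):
                for seg, spos in index.get(q[qpos : qpos + k], ()):
                    diagonals.add((seg, qpos - spos))
            for seg, diag in diagonals:
                q_lo = max(0, diag)
                q_hi = min(L, seg_lens[seg] + diag)
                window = q_hi - q_lo
                if window < min_anchor:
                    continue
                sarr = seg_arrays[seg][q_lo - diag : q_hi - diag]
                matches = int(np.count_nonzero(qarr[q_lo:q_hi] == sarr))
                identity = matches / window
                if identity < min_identity:
                    continue
                if orient == "+":
                    rs, re_ = q_lo, q_hi
                else:
                    rs, re_ = L - q_hi, L - q_lo
                alignments.append(
                    ReadAlignment(
                        read_id=read.id,
                        read_start=rs,
                        read_end=re_,
                        segment_id=seg,
                        segment_start=q_lo - diag,
                        segment_end=q_hi - diag,
                        segment_orient=orient,
                        identity=identity,
                    )
                )
    return alignments


# ---------------------------------------------------------------------------
# junction support
# ---------------------------------------------------------------------------

def count_junction_support(
    alignments: Iterable[ReadAlignment],
    segments: Mapping[str, str],
    gap_tol: int = 100,
    end_tol: int = 50,
    min_flank: int = 200,
    graph: AssemblyGraph | None = None,
) -> list[JunctionEvidence]:
    """Count reads running head-to-tail across each oriented junction.

    A read supports ``(X, ox) -> (Y, oy)`` when consecutive alignments on the
    read exit X at its ``ox``-terminus (within ``end_tol``), enter Y at its
    ``oy``-start likewise, leave a read gap of at most ``gap_tol``, and each
    retains at least ``min_flank`` aligned bases.  A junction and its
    reverse-complement image are pooled into one canonical record.  When a
    graph is given, all its links are seeded with zero support so unsupported
    links are visible downstream.
    """
    seg_lens = {name: len(s) for name, s in segments.items()}
    evidence: dict[Junction, JunctionEvidence] = {}
    if graph is not None:
        for a, oa, b, ob in graph.links:
            j = canonical_junction((a, oa), (b, ob))
            evidence.setdefault(j, JunctionEvidence(*j))

    per_read: dict[str, list[ReadAlignment]] = {}
    for aln in alignments:
        per_read.setdefault(aln.read_id, []).append(aln)

    for read_id in sorted(per_read):
        alns = sorted(per_read[read_id], key=lambda a: (a.read_start, a.read_end))
        for first, second in zip(alns, alns[1:]):
            if first.read_end - first.read_start < min_flank:
                continue
            if second.read_end - second.read_start < min_flank:
                continue
            gap = second.read_start - first.read_end
            if abs(gap) > gap_tol:
                continue
            # first must reach its exit terminus
            if first.segment_orient == "+":
                exit_ok = seg_lens[first.segment_id] - first.segment_end <= end_tol
            else:
                exit_ok = first.segment_start <= end_tol
            # second must start at its entry terminus
            if second.segment_orient == "+":
                entry_ok = second.segment_start <= end_tol
            else:
                entry_ok = seg_lens[second.segment_id] - second.segment_end <= end_tol
            if not (exit_ok and entry_ok):
                continue
            j = canonical_junction(
                (first.segment_id, first.segment_orient),
                (second.segment_id, second.segment_orient),
            )
            evidence.setdefault(j, JunctionEvidence(*j)).read_ids.append(read_id)
    return sorted(evidence.values(), key=lambda ev: ev.junction)


def evidence_map(evidence: Iterable[JunctionEvidence]) -> dict[Junction, int]:
    return {ev.junction: ev.support for ev in evidence}


# ---------------------------------------------------------------------------
# conformation search
# ---------------------------------------------------------------------------

def infer_copy_numbers(graph: AssemblyGraph) -> dict[str, int]:
    """Copy numbers from GFA depth tags: round(depth / median depth), min 1."""
    if not graph.depth:
        return {name: 1 for name in graph.segments}
    med = median(graph.depth.get(name, 0.0) for name in graph.segments)
    if med <= 0:
        return {name: 1 for name in graph.segments}
    return {
        name: max(1, round(graph.depth.get(name, med) / med))
        for name in graph.segments
    }


def _adjacency(graph: AssemblyGraph) -> dict[OrientedSeg, set[OrientedSeg]]:
    adj: dict[OrientedSeg, set[OrientedSeg]] = {}
    for a, oa, b, ob in graph.links:
        adj.setdefault((a, oa), set()).add((b, ob))
        adj.setdefault(_flip((b, ob)), set()).add(_flip((a, oa)))
    return adj


def resolve_conformations(
    graph: AssemblyGraph,
    evidence: Iterable[JunctionEvidence] | Mapping[Junction, int],
    repeat_copy_numbers: Mapping[str, int] | None = None,
    min_support: int = 1,
) -> Conformation:
    """Resolve the graph into the best-supported master circle.

    Starting from the longest single-copy segment, all closed walks using
    each segment exactly its copy number of times and only junctions with
    support >= ``min_support`` are enumerated; the walk maximizing total
    support is returned (ties broken by the lexicographically smallest
    canonical walk signature).
    """
    support = (
        dict(evidence) if isinstance(evidence, Mapping) else evidence_map(evidence)
    )
    copies = dict(infer_copy_numbers(graph))
    if repeat_copy_numbers:
        copies.update(repeat_copy_numbers)
    seg_lens = graph.segment_lengths()
    adj = _adjacency(graph)

    single = [s for s in graph.segments if copies.get(s, 1) == 1]
    pool = single if single else list(graph.segments)
    start = max(pool, key=lambda s: (seg_lens[s], s))
    start_node: OrientedSeg = (start, "+")
    total = sum(copies.get(s, 1) for s in graph.segments)

    def edge_support(a: OrientedSeg, b: OrientedSeg) -> int:
        return support.get(canonical_junction(a, b), 0)

    best: tuple[int, tuple[OrientedSeg, ...]] | None = None
    remaining = dict(copies)
    remaining[start] -= 1
    walk: list[OrientedSeg] = [start_node]

    def dfs(node: OrientedSeg, score: int) -> None:
        nonlocal best
        if len(walk) == total:
            closing = edge_support(node, start_node)
            if start_node in adj.get(node, ()) and closing >= min_support:
                cand_walk = tuple(walk)
                cand = (score + closing, cand_walk)
                if best is None or (
                    -cand[0],
                    Conformation(cand_walk, 0, "master").canonical(),
                ) < (
                    -best[0],
                    Conformation(best[1], 0, "master").canonical(),
                ):
                    best = cand
            return
        for nxt in sorted(adj.get(node, ())):
            seg = nxt[0]
            if remaining.get(seg, 0) <= 0:
                continue
            s = edge_support(node, nxt)
            if s < min_support:
                continue
            remaining[seg] -= 1
            walk.append(nxt)
            dfs(nxt, score + s)
            walk.pop()
            remaining[seg] += 1

    dfs(start_node, 0)
    if best is None:
        weak = [
            canonical_junction((a, oa), (b, ob))
            for a, oa, b, ob in graph.links
            if support.get(canonical_junction((a, oa), (b, ob)), 0) < min_support
        ]
        raise UnresolvableGraphError(
            "no closed walk satisfies copy-number constraints with supported "
            f"junctions; junctions below min_support={min_support}: "
            + ", ".join(junction_label(j) for j in sorted(set(weak))),
            unsupported=sorted(set(weak)),
        )
    score, walk_best = best
    length = sum(seg_lens[s] for s, _ in walk_best)
    return Conformation(walk=walk_best, length=length, kind="master")


def enumerate_recombinants(
    master: Conformation,
    repeat_segments: Iterable[str],
    seg_lengths: Mapping[str, int],
) -> list[tuple[Conformation, Conformation]]:
    """Subcircle pairs from recombination across each direct-repeat pair.

    For every pair of same-orientation occurrences of a named repeat in the
    master walk, the two circles exchanged at those copies are emitted; each
    carries exactly one copy of the repeat and their lengths sum to the
    master length.  These are candidate conformations only — coexistence in
    vivo is not asserted.
    """
    pairs: list[tuple[Conformation, Conformation]] = []
    walk = list(master.walk)
    for rep in repeat_segments:
        occ = [i for i, (seg, _) in enumerate(walk) if seg == rep]
        for ai in range(len(occ)):
            for bi in range(ai + 1, len(occ)):
                i, j = occ[ai], occ[bi]
                if walk[i][1] != walk[j][1]:
                    continue  # inverted pair: recombination flips, out of scope
                sub1 = tuple(walk[i:j])
                sub2 = tuple(walk[j:] + walk[:i])
                c1 = Conformation(
                    sub1, sum(seg_lengths[s] for s, _ in sub1), "recombinant"
                )
                c2 = Conformation(
                    sub2, sum(seg_lengths[s] for s, _ in sub2), "recombinant"
                )
                pairs.append((c1, c2))
    return pairs


# ---------------------------------------------------------------------------
# junction PCR amplicon prediction
# ---------------------------------------------------------------------------

@dataclass
class Amplicon:
    junction: Junction
    position: int  # 0-based genome coordinate of the join
    template: str
    product_length: int | None = None
    specific: bool | None = None


def predict_junction_amplicons(
    conformation: Conformation,
    segments: Mapping[str, str],
    flank: int = 1000,
    primer_pairs: Sequence[tuple[str, str]] | None = None,
) -> list[Amplicon]:
    """Per-junction PCR templates (+-flank across each join, wrapping).

    With primers supplied (one ``(forward, reverse)`` pair per junction, in
    walk order), the exact expected product length — inclusive of both primer
    footprints — is computed; a primer absent from its template or present
    more than once flags the amplicon non-specific.
    """
    genome = conformation.sequence(segments)
    n = len(genome)
    amplicons: list[Amplicon] = []
    pos = 0
    walk = list(conformation.walk)
    for idx, (seg, o) in enumerate(walk):
        pos += len(segments[seg])
        join = pos % n
        nxt = walk[(idx + 1) % len(walk)]
        doubled = genome + genome
        lo = (join - flank) % n
        template = doubled[lo : lo + 2 * flank]
        amp = Amplicon(
            junction=canonical_junction((seg, o), nxt),
            position=join,
            template=template,
        )
        if primer_pairs is not None:
            fwd, rev = primer_pairs[idx]
            rev_rc = revcomp(rev)
            n_f = template.count(fwd)
            n_r = template.count(rev_rc)
            if n_f == 1 and n_r == 1:
                f_start = template.find(fwd)
                r_end = template.find(rev_rc) + len(rev_rc)
                if f_start < r_end:
                    amp.product_length = r_end - f_start
                    amp.specific = True
                else:
                    amp.specific = False
            else:
                amp.specific = False
        amplicons.append(amp)
    return amplicons
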