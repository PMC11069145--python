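"""Mitochondrial plastid DNA (MTPT) detection.

Homologous mt<->cp fragments are found with a BLASTN-style seed-and-extend
local alignment: exact 7-mer seeds on both strands, ungapped X-drop
extension under a reward/penalty score (+2/-3), an optional banded affine
gapped pass (open 5, extend 2), and a Karlin-Altschul e-value computed for
the ungapped score system (lambda solved numerically for the +2/-3 scheme,
K = 0.41 — the ungapped approximation is applied to gapped scores as well,
which is conservative for near-identical organelle transfers).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import edlib
import numpy as np
from scipy.optimize import brentq

from .io_core import GeneAnnotation, revcomp

DEFAULT_REWARD = 2
DEFAULT_PENALTY = -3
DEFAULT_GAP_OPEN = 5
DEFAULT_GAP_EXTEND = 2
KA_K = 0.41  # NCBI tabulated value for the +2/-3 ungapped system


def karlin_altschul_lambda(reward: int = DEFAULT_REWARD, penalty: int = DEFAULT_PENALTY) -> float:
    """Solve 0.25*exp(lambda*reward) + 0.75*exp(lambda*penalty) = 1."""

    def f(lam: float) -> float:
        return 0.25 * math.exp(lam * reward) + 0.75 * math.exp(lam * penalty) - 1.0

    return float(brentq(f, 1e-9, 10.0))


_LAMBDA_CACHE: dict[tuple[int, int], float] = {}


def _lambda(reward: int, penalty: int) -> float:
    key = (reward, penalty)
    if key not in _LAMBDA_CACHE:
        _LAMBDA_CACHE[key] = karlin_altschul_lambda(reward, penalty)
    return _LAMBDA_CACHE[key]


def evalue(score: float, m: int, n: int, reward: int = DEFAULT_REWARD,
           penalty: int = DEFAULT_PENALTY) -> float:
    return KA_K * m * n * math.exp(-_lambda(reward, penalty) * score)


@dataclass
class MTPTFragment:
    """A homologous mt/cp interval pair (1-based inclusive coordinates)."""

    mt_start: int
    mt_end: int
    cp_start: int
    cp_end: int
    strand: str
    length: int
    identity: float
    score: float
    evalue: float

    def __post_init__(self):
        assert self.length == self.mt_end - self.mt_start + 1


@dataclass
class TransferredGeneCall:
    gene: str
    feature_type: str
    status: str  # complete | partial
    fragment_index: int


# ---------------------------------------------------------------------------
# extension machinery
# ---------------------------------------------------------------------------

def _ungapped_extend(
    a: str, b: str, i: int, j: int, k: int, reward: int, penalty: int, xdrop: int
) -> tuple[int, int, int, int]:
    """X-drop ungapped extension around an exact seed a[i:i+k]==b[j:j+k].

    Returns ``(i0, i1, score, matches)`` for the maximal-scoring window
    a[i0:i1] vs b[i0-d:i1-d]; ends are trimmed back to the score argmax.
    """
    na, nb = len(a), len(b)
    d = i - j
    score = k * reward
    matches = k
    # right
    best, best_i1, cur, cur_m = score, i + k, score, matches
    p, q = i + k, j + k
    m_run = matches
    while p < na and q < nb and cur > best - xdrop:
        if a[p] == b[q]:
            cur += reward
            m_run += 1
        else:
            cur += penalty
        p += 1
        q += 1
        if cur > best:
            best, best_i1, matches = cur, p, m_run
    score = best
    i1 = best_i1
    # left
    best, best_i0, cur = score, i, score
    m_run = matches
    p, q = i - 1, j - 1
    while p >= 0 and q >= 0 and cur > best - xdrop:
        if a[p] == b[q]:
            cur += reward
            m_run += 1
        else:
            cur += penalty
        if cur > best:
            best, best_i0, matches = cur, p, m_run
        p -= 1
        q -= 1
    return best_i0, i1, best, matches


def _gapped_extend(
    a: str, b: str, ai: int, bi: int, direction: int,
    reward: int, penalty: int, gap_open: int, gap_extend: int,
    band: int = 12, xdrop: int = 30, max_ext: int = 2000,
) -> tuple[int, int, int]:
    """Banded affine X-drop extension from (ai, bi); returns (dscore, da, db).

    ``direction`` +1 extends toward larger coordinates, -1 toward smaller.
    Only the best positive score increment is kept.
    """
    NEG = -(10 ** 9)
    if direction > 0:
        sa = a[ai : ai + max_ext]
        sb = b[bi : bi + max_ext]
    else:
        sa = a[max(0, ai - max_ext) : ai][::-1]
        sb = b[max(0, bi - max_ext) : bi][::-1]
    la, lb = len(sa), len(sb)
    if la == 0 or lb == 0:
        return 0, 0, 0
    width = 2 * band + 1
    # rows over sa; columns j-index offset within band around the diagonal
    M = [NEG] * width
    Ix = [NEG] * width
    best = 0
    best_pos = (0, 0)
    M[band] = 0
    for r in range(1, la + 1):
        newM = [NEG] * width
        newIx = [NEG] * width
        row_best = NEG
        for w in range(width):
            c = r + (w - band)  # column index in sb
            if c < 0 or c > lb:
                continue
            # Ix: gap in sb (consume a only) -> same column, previous row = w+1
            ix = NEG
            if w + 1 < width:
                ix = max(M[w + 1] - gap_open, Ix[w + 1] - gap_extend)
            # Iy: gap in sa (consume b only) -> same row, previous column = w-1
            iy = NEG
            if w - 1 >= 0:
                iy = max(newM[w - 1] - gap_open, newIx[w - 1] - gap_extend)
            mval = NEG
            if c >= 1:
                diagM = M[w]
                prev = max(diagM, Ix[w], iy)
                if prev > NEG // 2:
                    s = reward if sa[r - 1] == sb[c - 1] else penalty
                    mval = prev + s
            newM[w] = mval
            newIx[w] = max(ix, iy)
            cell = max(mval, newIx[w])
            if cell > row_best:
                row_best = cell
            if mval > best:
                best = mval
                best_pos = (r, c)
        M, Ix = newM, newIx
        if row_best < best - xdrop:
            break
    return best, best_pos[0], best_pos[1]


# ---------------------------------------------------------------------------
# fragment discovery
# ---------------------------------------------------------------------------

def find_homologous_fragments(
    mt_seq: str,
    cp_seq: str,
    word_size: int = 7,
    evalue_cutoff: float = 1e-10,
    reward: int = DEFAULT_REWARD,
    penalty: int = DEFAULT_PENALTY,
    gap_open: int = DEFAULT_GAP_OPEN,
    gap_extend: int = DEFAULT_GAP_EXTEND,
    xdrop: int = 20,
    gapped: bool = True,
    gapped_min_gain: int = 16,
    merge: bool = True,
) -> list[MTPTFragment]:
    """Homologous mt<->cp fragments by seed-and-extend on both strands.

    Hits overlapping by >= 50% on both genomes are merged keeping the best
    score (``merge=False`` returns the raw hit list), duplicates with
    identical mt intervals collapsed, fragments sorted by mt_start, and only
    fragments with e-value <= ``evalue_cutoff`` emitted.
    """
    if not mt_seq or not cp_seq:
        raise ValueError("both sequences must be non-empty")
    m_len, n_len = len(mt_seq), len(cp_seq)
    hits: list[tuple[int, int, int, int, str, float, float, int]] = []
    for strand in "+-":
        target = cp_seq if strand == "+" else revcomp(cp_seq)
        index: dict[str, list[int]] = {}
        for j in range(len(target) - word_size + 1):
            index.setdefault(target[j : j + word_size], []).append(j)
        covered: dict[int, int] = {}  # diagonal -> mt index covered through
        for i in range(m_len - word_size + 1):
            for j in index.get(mt_seq[i : i + word_size], ()):
                d = i - j
                if covered.get(d, -1) >= i:
                    continue
                i0, i1, score, matches = _ungapped_extend(
                    mt_seq, target, i, j, word_size, reward, penalty, xdrop
                )
                covered[d] = i1
                j0, j1 = i0 - d, i1 - d
                # gapped refinement only for hits already near the report
                # threshold; random seed hits stop at the ungapped pass
                if evalue(score, m_len, n_len, reward, penalty) > max(
                    evalue_cutoff, 10.0
                ):
                    continue
                if gapped:
                    # a gapped continuation must clear a minimum gain:
                    # affine gaps let short random flank matches accrete a
                    # few points, which would erode end accuracy
                    ds_r, da_r, db_r = _gapped_extend(
                        mt_seq, target, i1, j1, +1, reward, penalty,
                        gap_open, gap_extend,
                    )
                    if ds_r >= gapped_min_gain:
                        score += ds_r
                        i1, j1 = i1 + da_r, j1 + db_r
                    ds_l, da_l, db_l = _gapped_extend(
                        mt_seq, target, i0, j0, -1, reward, penalty,
                        gap_open, gap_extend,
                    )
                    if ds_l >= gapped_min_gain:
                        score += ds_l
                        i0, j0 = i0 - da_l, j0 - db_l
                length = i1 - i0
                if length < word_size:
                    continue
                ev = evalue(score, m_len, n_len, reward, penalty)
                if ev > max(evalue_cutoff, 10.0):
                    continue  # hopeless even for diagnostic use
                hits.append((i0, i1, j0, j1, strand, float(score), ev, matches))
    fragments = []
    for i0, i1, j0, j1, strand, score, ev, matches in hits:
        if strand == "+":
            c0, c1 = j0, j1
        else:
            c0, c1 = n_len - j1, n_len - j0
        frag_mt = mt_seq[i0:i1]
        frag_cp = cp_seq[c0:c1] if strand == "+" else revcomp(cp_seq[c0:c1])
        dist = edlib.align(frag_mt, frag_cp, task="distance")["editDistance"]
        identity = 1.0 - dist / max(len(frag_mt), len(frag_cp))
        fragments.append(
            MTPTFragment(
                mt_start=i0 + 1, mt_end=i1, cp_start=c0 + 1, cp_end=c1,
                strand=strand, length=i1 - i0, identity=round(identity, 4),
                score=score, evalue=ev,
            )
        )
    if merge:
        fragments = _merge_fragments(fragments)
    fragments = [f for f in fragments if f.evalue <= evalue_cutoff]
    return sorted(fragments, key=lambda f: (f.mt_start, f.mt_end, f.cp_start))


def _overlap_frac(a0: int, a1: int, b0: int, b1: int) -> float:
    ov = min(a1, b1) - max(a0, b0) + 1
    if ov <= 0:
        return 0.0
    return ov / min(a1 - a0 + 1, b1 - b0 + 1)


def _merge_fragments(fragments: list[MTPTFragment]) -> list[MTPTFragment]:
    kept: list[MTPTFragment] = []
    for frag in sorted(fragments, key=lambda f: (-f.score, f.mt_start, f.cp_start)):
        dup = False
        for k in kept:
            if (k.mt_start, k.mt_end) == (frag.mt_start, frag.mt_end):
                dup = True  # IR-duplicated cp copies of the same mt interval
                break
            if (
                _overlap_frac(frag.mt_start, frag.mt_end, k.mt_start, k.mt_end) >= 0.5
                and _overlap_frac(frag.cp_start, frag.cp_end, k.cp_start, k.cp_end) >= 0.5
            ):
                dup = True
                break
        if not dup:
            kept.append(frag)
    return kept


# ---------------------------------------------------------------------------
# summaries and gene classification
# ---------------------------------------------------------------------------

@dataclass
class MTPTSummary:
    count: int
    total_bp: int
    fraction_percent: float


def summarize_mtpt(fragments: Sequence[MTPTFragment], mt_length: int) -> MTPTSummary:
    """Fragment count, merged mt footprint, and % of the mitogenome (2 d.p.)."""
    if mt_length <= 0:
        raise ValueError("mt_length must be positive")
    intervals = sorted((f.mt_start, f.mt_end) for f in fragments)
    total = 0
    cur_s = cur_e = None
    for s, e in intervals:
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                total += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s + 1
    return MTPTSummary(
        count=len(fragments),
        total_bp=total,
        fraction_percent=round(100.0 * total / mt_length, 2),
    )


def classify_transferred_genes(
    fragments: Sequence[MTPTFragment],
    cp_annotations: Sequence[GeneAnnotation],
) -> list[TransferredGeneCall]:
    """Complete if a gene lies entirely inside one fragment's cp interval;
    partial if it overlaps by >= 1 bp; untouched genes are omitted."""
    calls: list[TransferredGeneCall] = []
    for ann in cp_annotations:
        lo0, hi0 = ann.span  # 0-based half-open
        g_s, g_e = lo0 + 1, hi0  # 1-based inclusive
        best_status = None
        best_idx = -1
        best_ov = 0
        for idx, frag in enumerate(fragments):
            if g_s >= frag.cp_start and g_e <= frag.cp_end:
                best_status, best_idx = "complete", idx
                break
            ov = min(g_e, frag.cp_end) - max(g_s, frag.cp_start) + 1
            if ov >= 1 and ov > best_ov:
                best_status, best_idx, best_ov = "partial", idx, ov
        if best_status is not None:
            calls.append(
                TransferredGeneCall(ann.gene, ann.feature_type, best_status, best_idx)
            )
    return calls
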