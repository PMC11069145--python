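"""C-to-U RNA editing site calling on protein-coding genes.

RNA reads are aligned to spliced sense-strand CDS references; per-position
base counts form a pileup, and a column whose genomic base is C is called an
editing site when its T (=U) support passes three cut-offs simultaneously:
coverage >= 5, editing frequency >= 0.1, and a one-sided exact binomial
P <= 0.05 against a sequencing-error null (default 1% — the probability that
the observed T count arose from miscalls alone).  Codon effects, including
ACG->AUG start-codon gain, are annotated from the standard genetic code.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_usage import CODON_TO_AA, to_rna
from .graphres import align_reads_to_segments
from .io_core import SequenceRecord, complement

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class PileupColumn:
    gene: str
    cds_pos: int  # 1-based position within the spliced sense-strand CDS
    ref_base: str
    depth: int
    base_counts: dict[str, int]

    def __post_init__(self):
        assert self.depth == sum(self.base_counts.values())


@dataclass
class EditingSite:
    gene: str
    cds_pos: int
    depth: int
    u_count: int
    frequency: float
    p_value: float
    codon_index: int | None = None
    codon_position: int | None = None
    ref_codon: str | None = None
    edited_codon: str | None = None
    aa_change: str | None = None
    start_gain: bool = False


# ---------------------------------------------------------------------------
# pileup
# ---------------------------------------------------------------------------

def pileup_rna(
    reads: Iterable[SequenceRecord],
    pcg_refs: Mapping[str, str],
    min_identity: float = 0.9,
    min_anchor: int = 50,
    k: int = 13,
    seed_step: int = 3,
) -> list[PileupColumn]:
    """Per-position base counts of RNA reads over spliced CDS references.

    Each read contributes through its best alignment only; reads aligning to
    the antisense strand are complement-normalized so all counts are on the
    CDS sense strand.  Alignments to no known gene are skipped (counted in a
    warning).
    """
    refs = {g: s.upper() for g, s in pcg_refs.items()}
    arrays = {
        g: np.zeros((4, len(s)), dtype=np.int64) for g, s in refs.items()
    }
    reads = list(reads)
    alignments = align_reads_to_segments(
        reads, refs, min_identity=min_identity, min_anchor=min_anchor,
        k=k, seed_step=seed_step,
    )
    read_seqs = {r.id: r.seq for r in reads}
    best: dict[str, object] = {}
    for aln in alignments:
        cur = best.get(aln.read_id)
        if cur is None or (aln.identity, aln.read_end - aln.read_start) > (
            cur.identity, cur.read_end - cur.read_start
        ):
            best[aln.read_id] = aln
    n_skipped = 0
    for aln in best.values():
        if aln.segment_id not in arrays:
            n_skipped += 1
            continue
        seq = read_seqs[aln.read_id]
        if aln.segment_orient == "+":
            chunk = seq[aln.read_start : aln.read_end]
        else:
            # antisense read: its complement, reversed, overlays the sense CDS
            chunk = complement(seq[aln.read_start : aln.read_end])[::-1]
        counts = arrays[aln.segment_id]
        pos = np.arange(aln.segment_start, aln.segment_end)
        codes = np.array([_BASE_IDX.get(b, -1) for b in chunk])
        ok = codes >= 0
        np.add.at(counts, (codes[ok], pos[ok]), 1)
    if n_skipped:
        warnings.warn(f"{n_skipped} alignments to unknown genes skipped")

    columns: list[PileupColumn] = []
    for gene in sorted(refs):
        ref = refs[gene]
        counts = arrays[gene]
        depth = counts.sum(axis=0)
        for p in np.flatnonzero(depth > 0):
            columns.append(
                PileupColumn(
                    gene=gene,
                    cds_pos=int(p) + 1,
                    ref_base=ref[p],
                    depth=int(depth[p]),
                    base_counts={b: int(counts[i, p]) for i, b in enumerate(_BASES)},
                )
            )
    return columns


# ---------------------------------------------------------------------------
# site calling
# ---------------------------------------------------------------------------

def binomial_tail(u: int, depth: int, error_rate: float) -> float:
    """One-sided exact binomial P(X >= u | n=depth, p=error_rate)."""
    if u <= 0:
        return 1.0
    return float(stats.binom.sf(u - 1, depth, error_rate))


def call_editing_sites(
    pileup: Sequence[PileupColumn],
    min_cov: int = 5,
    min_freq: float = 0.1,
    alpha: float = 0.05,
    error_rate: float = 0.01,
    freq_denominator: str = "depth",
) -> list[EditingSite]:
    """C->U editing sites passing all three cut-offs simultaneously.

    Only reference-C columns are considered; the editing frequency uses the
    full column depth as denominator by default (``freq_denominator="ct"``
    restricts it to C+T reads).  No multiple-testing correction is applied
    (the threshold is a raw P cut-off); see
    :func:`benjamini_hochberg_filter` for an FDR variant.
    """
    if not (0 <= min_freq <= 1 and 0 < alpha <= 1 and 0 <= error_rate < 1):
        raise ValueError("thresholds out of range")
    sites: list[EditingSite] = []
    for col in pileup:
        if col.ref_base != "C":
            continue
        u = col.base_counts.get("T", 0)
        denom = (
            col.depth
            if freq_denominator == "depth"
            else col.base_counts.get("C", 0) + u
        )
        if col.depth < min_cov or denom == 0:
            continue
        freq = u / denom
        if freq < min_freq:
            continue
        p = binomial_tail(u, col.depth, error_rate)
        if p > alpha:
            continue
        sites.append(
            EditingSite(
                gene=col.gene, cds_pos=col.cds_pos, depth=col.depth,
                u_count=u, frequency=freq, p_value=p,
            )
        )
    return sorted(sites, key=lambda s: (s.gene, s.cds_pos))


def benjamini_hochberg_filter(
    sites: Sequence[EditingSite], fdr: float = 0.05
) -> list[EditingSite]:
    """Optional BH-FDR screen over already-called sites."""
    if not sites:
        return []
    ps = np.array([s.p_value for s in sites])
    order = np.argsort(ps)
    n = len(ps)
    keep_rank = 0
    for rank, idx in enumerate(order, 1):
        if ps[idx] <= fdr * rank / n:
            keep_rank = rank
    kept_idx = set(order[:keep_rank])
    return [s for i, s in enumerate(sites) if i in kept_idx]


# ---------------------------------------------------------------------------
# codon-effect annotation
# ---------------------------------------------------------------------------

def annotate_site_effects(
    sites: Sequence[EditingSite],
    pcg_refs: Mapping[str, str],
) -> tuple[list[EditingSite], pd.DataFrame]:
    """Fill codon fields on each site and build the per-gene summary table.

    ``start_gain`` marks the ACG->AUG initiation-codon creation at codon 1.
    Returns the annotated sites and a DataFrame indexed by gene with
    ``n_sites``, ``n_synonymous``, ``n_nonsynonymous``, ``n_start_gain``.
    """
    annotated: list[EditingSite] = []
    for s in sites:
        ref = pcg_refs[s.gene].upper()
        if not (1 <= s.cds_pos <= len(ref)):
            raise ValueError(f"{s.gene}: cds_pos {s.cds_pos} outside CDS")
        codon_index = math.ceil(s.cds_pos / 3)
        codon_position = (s.cds_pos - 1) % 3 + 1
        c0 = (codon_index - 1) * 3
        ref_codon = ref[c0 : c0 + 3]
        edited = (
            ref_codon[: codon_position - 1] + "T" + ref_codon[codon_position:]
        )
        aa_ref = CODON_TO_AA.get(ref_codon, "X")
        aa_edit = CODON_TO_AA.get(edited, "X")
        if aa_ref == aa_edit:
            aa_change = f"{aa_ref}->{aa_edit} (synonymous)"
        else:
            aa_change = f"{aa_ref}->{aa_edit}"
        site = EditingSite(
            gene=s.gene, cds_pos=s.cds_pos, depth=s.depth, u_count=s.u_count,
            frequency=s.frequency, p_value=s.p_value,
            codon_index=codon_index, codon_position=codon_position,
            ref_codon=to_rna(ref_codon), edited_codon=to_rna(edited),
            aa_change=aa_change,
            start_gain=(codon_index == 1 and ref_codon == "ACG" and edited == "ATG"),
        )
        annotated.append(site)
    rows = {}
    for s in annotated:
        r = rows.setdefault(
            s.gene,
            {"n_sites": 0, "n_synonymous": 0, "n_nonsynonymous": 0, "n_start_gain": 0},
        )
        r["n_sites"] += 1
        if "synonymous" in (s.aa_change or ""):
            r["n_synonymous"] += 1
        else:
            r["n_nonsynonymous"] += 1
        if s.start_gain:
            r["n_start_gain"] += 1
    summary = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    summary.index.name = "gene"
    return annotated, summary


def sites_to_frame(sites: Sequence[EditingSite]) -> pd.DataFrame:
    return pd.DataFrame([vars(s) for s in sites])
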