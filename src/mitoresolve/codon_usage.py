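"""Codon extraction and relative synonymous codon usage (RSCU).

RSCU of a codon c in a synonymous family F is

    RSCU(c) = count(c) * |F| / sum_{c' in F} count(c')

so a uniformly used family has RSCU 1 for every member, single-codon
families (Met/AUG, Trp/UGG) are 1 whenever observed, and values > 1 mark
preferred codons.  Plant mitochondrial PCGs use the standard genetic code;
the three stop codons are treated as one 3-codon family so stop-codon
preference is reported alongside the amino acids.
"""
from __future__ import annotations

import itertools
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .io_core import GeneAnnotation, SequenceRecord

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: DNA codon -> amino acid letter ('*' for stop), standard code
CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
CODON_TO_AA.update({c: "*" for c in _STANDARD.stop_codons})

#: amino acid -> tuple of synonymous DNA codons
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in ("".join(p) for p in itertools.product("TCAG", repeat=3)):
    FAMILIES.setdefault(CODON_TO_AA[_codon], ())
    FAMILIES[CODON_TO_AA[_codon]] += (_codon,)

ALL_CODONS = tuple(sorted(CODON_TO_AA))


def to_rna(codon: str) -> str:
    return codon.replace("T", "U")


def to_dna(codon: str) -> str:
    return codon.upper().replace("U", "T")


@dataclass
class CodonExtraction:
    """Spliced-CDS codon counts plus bookkeeping for skipped material."""

    counts: Counter = field(default_factory=Counter)
    n_skipped: int = 0  # codons containing N
    warnings: list[str] = field(default_factory=list)


def extract_pcg_codons(
    genome: SequenceRecord,
    annotations: Sequence[GeneAnnotation],
    dedupe: bool = True,
) -> CodonExtraction:
    """Count codons over the protein-coding genes of a genome.

    With ``dedupe`` (default) one representative per gene name is counted —
    the lowest copy_index — matching analyses phrased over the unique PCG
    set; ``dedupe=False`` counts every copy.  A spliced CDS whose length is
    not a multiple of 3 contributes its full codons and drops the remainder
    with a warning; codons containing N are excluded and tallied.
    """
    pcgs = [a for a in annotations if a.feature_type == "PCG"]
    if not pcgs:
        raise ValueError("no PCG annotations supplied")
    if dedupe:
        chosen: dict[str, GeneAnnotation] = {}
        for ann in pcgs:
            if ann.gene not in chosen or ann.copy_index < chosen[ann.gene].copy_index:
                chosen[ann.gene] = ann
        pcgs = list(chosen.values())

    out = CodonExtraction()
    for ann in pcgs:
        cds = ann.spliced(genome.seq)
        rem = len(cds) % 3
        if rem:
            msg = f"{ann.gene} copy {ann.copy_index}: dropping {rem} trailing bases"
            out.warnings.append(msg)
            warnings.warn(msg)
            cds = cds[: len(cds) - rem]
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3]
            if "N" in codon:
                out.n_skipped += 1
            else:
                out.counts[codon] += 1
    return out


def compute_rscu(
    codon_counts: Mapping[str, int] | CodonExtraction,
    stop_as_family: bool = True,
) -> pd.DataFrame:
    """RSCU table over all 64 codons of the standard code.

    Index is the RNA-alphabet codon (DNA accepted on input); columns are
    ``amino_acid``, ``count``, ``family_size``, ``rscu``.  Families with no
    observed codon get RSCU NaN (reported as NA).  With
    ``stop_as_family=False`` stop codons are excluded from the table.
    """
    if isinstance(codon_counts, CodonExtraction):
        codon_counts = codon_counts.counts
    counts: Counter = Counter()
    for codon, n in codon_counts.items():
        dna = to_dna(codon)
        if dna not in CODON_TO_AA:
            raise KeyError(f"unknown codon {codon!r}")
        if n < 0:
            raise ValueError(f"negative count for {codon!r}")
        counts[dna] += int(n)

    rows = []
    for aa, fam in sorted(FAMILIES.items()):
        if aa == "*" and not stop_as_family:
            continue
        fam_total = sum(counts.get(c, 0) for c in fam)
        size = len(fam)
        for c in sorted(fam):
            cnt = counts.get(c, 0)
            rscu = cnt * size / fam_total if fam_total > 0 else np.nan
            rows.append((to_rna(c), aa, cnt, size, rscu))
    df = pd.DataFrame(rows, columns=["codon", "amino_acid", "count", "family_size", "rscu"])
    return df.set_index("codon")


def write_rscu_tsv(table: pd.DataFrame, path) -> None:
    out = table.copy()
    out["rscu"] = out["rscu"].round(2)
    out.to_csv(path, sep="\t", na_rep="NA")


def compute_gc(seq: str | SequenceRecord) -> float:
    """GC fraction over unambiguous bases; NaN if the sequence is all N."""
    if isinstance(seq, SequenceRecord):
        seq = seq.seq
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    atgc = gc + seq.count("A") + seq.count("T")
    if atgc == 0:
        return float("nan")
    return gc / atgc
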