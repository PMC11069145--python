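"""Synthetic mitogenome data with planted ground truth.

The generator emulates the structure the downstream analyses assume: a
circular mitogenome built from two single-copy contigs joined through one
direct repeat (master circle ctg1 + repeat + ctg2 + repeat), an assembly
graph with the four oriented links of that topology, CCS-grade long reads
spanning the junctions, planted SSR/tandem/dispersed repeats, a chloroplast
partner carrying mt-homologous fragments with complete and straddling genes,
and RNA reads carrying C->U edits at known sites and frequencies.

Every planted feature is recorded in a :class:`TruthTables` object that is
re-derivable from the emitted files alone; with the same config and seed all
outputs are byte-identical.
"""
from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .graphres import Conformation, canonical_junction, junction_label
from .io_core import (
    AssemblyGraph,
    GeneAnnotation,
    SequenceRecord,
    revcomp,
    write_annotations_gff3,
    write_annotations_tsv,
    write_fasta,
    write_fastq,
    write_gfa,
)
from .repeats import (
    DispersedRepeatPair,
    SSRRecord,
    TandemRepeat,
    canonical_rotation,
    find_ssrs,
    find_tandem_repeats,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}


class ConfigError(ValueError):
    """Invalid or self-contradictory simulation configuration."""


# ---------------------------------------------------------------------------
# plant specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenePlant:
    name: str
    feature_type: str  # PCG | tRNA | rRNA
    strand: str
    segment: str  # ctg1 | ctg2 | repeat
    offset: int
    exon_lengths: tuple[int, ...]
    intron_lengths: tuple[int, ...] = ()
    start_codon: str = "ATG"

    @property
    def length(self) -> int:
        return sum(self.exon_lengths)

    @property
    def footprint(self) -> int:
        return self.length + sum(self.intron_lengths)


@dataclass(frozen=True)
class SSRPlant:
    motif: str
    copies: int
    segment: str
    offset: int


@dataclass(frozen=True)
class TandemPlant:
    unit: str
    copies: int
    segment: str
    offset: int


@dataclass(frozen=True)
class DispersedPlant:
    length: int
    category: str  # forward | palindromic
    segment1: str
    offset1: int
    segment2: str
    offset2: int


@dataclass(frozen=True)
class CpGenePlant:
    name: str
    feature_type: str
    status: str  # complete | partial
    rel_start: int  # relative to the fragment's cp start
    length: int


@dataclass(frozen=True)
class MTPTPlant:
    length: int
    identity: float
    segment: str
    offset: int
    cp_offset: int
    strand: str = "+"
    genes: tuple[CpGenePlant, ...] = ()


@dataclass(frozen=True)
class EditPlant:
    gene: str
    cds_pos: int  # 1-based on the spliced sense-strand CDS
    frequency: float


@dataclass(frozen=True)
class MTPTTruth:
    mt_start: int  # 1-based inclusive
    mt_end: int
    cp_start: int
    cp_end: int
    strand: str
    identity: float
    n_mutations: int


def _default_genes() -> tuple[GenePlant, ...]:
    return (
        GenePlant("mttB", "PCG", "+", "ctg1", 1000, (1800,)),
        GenePlant("cox1", "PCG", "+", "ctg1", 3200, (1200,), start_codon="ACG"),
        GenePlant("nad7", "PCG", "-", "ctg1", 5000, (402, 501), (300,)),
        GenePlant("rps14", "PCG", "-", "ctg1", 7000, (303,)),
        GenePlant("trnD-GUC", "tRNA", "+", "ctg1", 8000, (74,)),
        GenePlant("ccmB", "PCG", "+", "ctg2", 8000, (621,)),
        GenePlant("rrn5", "rRNA", "-", "ctg2", 10000, (120,)),
        GenePlant("rps19", "PCG", "+", "repeat", 500, (279,)),
        GenePlant("trnH-GUG", "tRNA", "-", "repeat", 1200, (74,)),
    )


def _default_ssrs() -> tuple[SSRPlant, ...]:
    return (
        SSRPlant("T", 12, "ctg1", 9000),
        SSRPlant("AT", 8, "ctg1", 9500),
        SSRPlant("AAG", 6, "ctg1", 9800),
        SSRPlant("ACGT", 6, "ctg2", 2000),
        SSRPlant("AATGC", 5, "ctg2", 2500),
    )


def _default_tandems() -> tuple[TandemPlant, ...]:
    return (
        TandemPlant("GATCCTAGGTCAATG", 3, "ctg1", 11000),
        TandemPlant("TGCAATCGGTAC", 4, "ctg2", 4000),
    )


def _default_dispersed() -> tuple[DispersedPlant, ...]:
    return (
        DispersedPlant(40, "forward", "ctg1", 14000, "ctg2", 6000),
        DispersedPlant(60, "palindromic", "ctg1", 15000, "ctg2", 6500),
    )


def _default_mtpts() -> tuple[MTPTPlant, ...]:
    return (
        MTPTPlant(
            1200, 0.98, "ctg1", 16000, 3000, "+",
            genes=(
                CpGenePlant("psbA", "PCG", "complete", 100, 600),
                CpGenePlant("trnH-GUG", "tRNA", "complete", 750, 74),
                CpGenePlant("ndhF", "PCG", "partial", 1100, 300),
            ),
        ),
        MTPTPlant(
            300, 0.95, "ctg2", 9000, 8000, "-",
            genes=(CpGenePlant("trnW-CCA", "tRNA", "complete", 50, 74),),
        ),
        # the shortest transfers real genomes show are tens of bases long;
        # this one sits below any sensible e-value cutoff and tests that the
        # truth tables are not limited to what the scanner can recover
        MTPTPlant(29, 1.0, "ctg1", 18000, 12000, "+"),
    )


def _default_editing() -> tuple[EditPlant, ...]:
    freqs = (0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    sites = [
        EditPlant("mttB", 30 + 33 * i, freqs[i % len(freqs)]) for i in range(52)
    ]
    sites.append(EditPlant("rps14", 150, 0.5))
    sites.append(EditPlant("cox1", 2, 0.9))  # ACG -> AUG start-codon gain
    return tuple(sites)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset (see docs/methods.md)."""

    seed: int = 0
    seg_lengths: dict[str, int] = field(
        default_factory=lambda: {"ctg1": 24000, "ctg2": 18000, "repeat": 4000}
    )
    gc: float = 0.45
    # long reads
    read_count: int = 85
    read_length_mean: float = 12000.0
    read_length_sd: float = 2000.0
    read_min_length: int = 1000
    read_error_rate: float = 0.002
    min_flank: int = 200
    # planted features
    genes: tuple[GenePlant, ...] = field(default_factory=_default_genes)
    ssrs: tuple[SSRPlant, ...] = field(default_factory=_default_ssrs)
    tandems: tuple[TandemPlant, ...] = field(default_factory=_default_tandems)
    dispersed: tuple[DispersedPlant, ...] = field(default_factory=_default_dispersed)
    # chloroplast partner
    mtpts: tuple[MTPTPlant, ...] = field(default_factory=_default_mtpts)
    cp_length: int = 30000
    cp_gc: float = 0.38
    # RNA editing
    editing: tuple[EditPlant, ...] = field(default_factory=_default_editing)
    rna_depth: int = 50
    rna_read_length: int = 150
    rna_error_rate: float = 0.005
    rna_utr: int = 150  # transcribed genomic flank beyond the CDS

    @property
    def genome_length(self) -> int:
        s = self.seg_lengths
        return s["ctg1"] + s["ctg2"] + 2 * s["repeat"]

    def segment_start(self, segment: str, occurrence: int = 1) -> int:
        L1, Lr, L2 = (
            self.seg_lengths["ctg1"],
            self.seg_lengths["repeat"],
            self.seg_lengths["ctg2"],
        )
        if segment == "ctg1":
            return 0
        if segment == "ctg2":
            return L1 + Lr
        if segment == "repeat":
            return L1 if occurrence == 1 else L1 + Lr + L2
        raise ConfigError(f"unknown segment {segment!r}")


@dataclass
class TruthTables:
    """Planted ground truth, re-derivable from the emitted files."""

    true_master: Conformation
    true_subcircles: tuple[Conformation, Conformation]
    junction_positions: dict[str, int]  # canonical label -> 0-based join pos
    true_junction_support: dict[str, int] = field(default_factory=dict)
    true_ssrs: list[SSRRecord] = field(default_factory=list)
    true_tandems: list[TandemRepeat] = field(default_factory=list)
    true_dispersed: list[DispersedRepeatPair] = field(default_factory=list)
    true_mtpts: list[MTPTTruth] = field(default_factory=list)
    true_editing_sites: list[EditPlant] = field(default_factory=list)

    def to_json(self) -> dict:
        def conf(c: Conformation) -> dict:
            return {"walk": list(map(list, c.walk)), "length": c.length, "kind": c.kind}

        return {
            "true_master": conf(self.true_master),
            "true_subcircles": [conf(c) for c in self.true_subcircles],
            "junction_positions": self.junction_positions,
            "true_junction_support": self.true_junction_support,
            "true_ssrs": [dataclasses.asdict(r) for r in self.true_ssrs],
            "true_tandems": [dataclasses.asdict(r) for r in self.true_tandems],
            "true_dispersed": [dataclasses.asdict(r) for r in self.true_dispersed],
            "true_mtpts": [dataclasses.asdict(r) for r in self.true_mtpts],
            "true_editing_sites": [dataclasses.asdict(r) for r in self.true_editing_sites],
        }


# ---------------------------------------------------------------------------
# random sequence helpers
# ---------------------------------------------------------------------------

def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stream])


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """i.i.d. DNA at the requested GC content."""
    draws = rng.choice(4, size=length, p=_base_probs(gc))
    return _BASES[draws].tobytes().decode()


def _has_local_run(s: str) -> bool:
    """Reject codon tails forming the seed of a mono-/di-nucleotide SSR."""
    tail = s[-16:]
    for i in range(len(tail) - 5):
        if len(set(tail[i : i + 6])) == 1:
            return True
    for i in range(len(tail) - 9):
        w = tail[i : i + 10]
        if w == w[:2] * 5 and len(set(w[:2])) == 2:
            return True
    return False


def _random_cds(
    rng: np.random.Generator, length: int, gc: float, start_codon: str = "ATG"
) -> str:
    if length % 3 != 0:
        raise ConfigError(f"CDS length {length} not a multiple of 3")
    if length < 9:
        raise ConfigError("CDS too short")
    probs = _base_probs(gc)
    chunks = [start_codon]
    built = start_codon
    while len(built) < length - 3:
        codon = _BASES[rng.choice(4, size=3, p=probs)].tobytes().decode()
        if codon in _STOPS:
            continue
        if _has_local_run(built[-16:] + codon):
            continue
        chunks.append(codon)
        built += codon
    stop = ["TAA", "TAG", "TGA"][rng.integers(3)]
    return built + stop


# ---------------------------------------------------------------------------
# mitogenome assembly
# ---------------------------------------------------------------------------

class _GenomeBuilder:
    """Mutable segment store with a genome-coordinate view.

    The repeat segment is stored once; edits through genome coordinates that
    fall in either repeat occurrence modify the shared copy, which keeps the
    two occurrences identical by construction.
    """

    def __init__(self, config: SimulationConfig, rng: np.random.Generator):
        self.config = config
        self.seg: dict[str, list[str]] = {
            name: list(random_dna(rng, length, config.gc))
            for name, length in config.seg_lengths.items()
        }
        self.order = [("ctg1", 1), ("repeat", 1), ("ctg2", 1), ("repeat", 2)]

    def genome(self) -> str:
        return "".join("".join(self.seg[name]) for name, _ in self.order)

    def locate(self, pos: int) -> tuple[str, int]:
        c = self.config
        L1, Lr, L2 = (
            c.seg_lengths["ctg1"], c.seg_lengths["repeat"], c.seg_lengths["ctg2"]
        )
        pos %= c.genome_length
        if pos < L1:
            return "ctg1", pos
        if pos < L1 + Lr:
            return "repeat", pos - L1
        if pos < L1 + Lr + L2:
            return "ctg2", pos - L1 - Lr
        return "repeat", pos - L1 - Lr - L2

    def get(self, pos: int) -> str:
        name, i = self.locate(pos)
        return self.seg[name][i]

    def set(self, pos: int, base: str) -> None:
        name, i = self.locate(pos)
        self.seg[name][i] = base

    def write(self, pos: int, chunk: str) -> None:
        for off, b in enumerate(chunk):
            self.set(pos + off, b)


def _protected_mask(config: SimulationConfig, annotations: Sequence[GeneAnnotation]) -> set[int]:
    protected: set[int] = set()
    for ann in annotations:
        for s, e in ann.parts:
            protected.update(range(s, e))
    for plant, span in _feature_spans(config):
        protected.update(range(span[0], span[1]))
    return protected


def _feature_spans(config: SimulationConfig) -> list[tuple[object, tuple[int, int]]]:
    spans = []
    for s in config.ssrs:
        start = config.segment_start(s.segment) + s.offset
        spans.append((s, (start, start + len(s.motif) * s.copies)))
    for t in config.tandems:
        start = config.segment_start(t.segment) + t.offset
        spans.append((t, (start, start + len(t.unit) * t.copies)))
    for d in config.dispersed:
        for seg, off in ((d.segment1, d.offset1), (d.segment2, d.offset2)):
            start = config.segment_start(seg) + off
            spans.append((d, (start, start + d.length)))
    return spans


def _validate_config(config: SimulationConfig) -> None:
    for key in ("ctg1", "ctg2", "repeat"):
        if config.seg_lengths.get(key, 0) <= 0:
            raise ConfigError(f"segment {key} must have positive length")
    seg_lens = config.seg_lengths
    intervals: dict[str, list[tuple[int, int, str]]] = {k: [] for k in seg_lens}

    def claim(segment: str, start: int, end: int, what: str) -> None:
        if segment not in seg_lens:
            raise ConfigError(f"{what}: unknown segment {segment!r}")
        if start < 1 or end > seg_lens[segment] - 1:
            raise ConfigError(f"{what}: outside segment bounds")
        for s, e, other in intervals[segment]:
            if start < e and s < end:
                raise ConfigError(f"{what} overlaps {other}")
        intervals[segment].append((start, end, what))

    for g in config.genes:
        if len(g.exon_lengths) != len(g.intron_lengths) + 1:
            raise ConfigError(f"gene {g.name}: exon/intron structure inconsistent")
        claim(g.segment, g.offset, g.offset + g.footprint, f"gene {g.name}")
    for s in config.ssrs:
        if s.segment == "repeat":
            raise ConfigError("SSRs may not be planted in the repeat segment")
        claim(s.segment, s.offset, s.offset + len(s.motif) * s.copies, f"SSR {s.motif}")
    for t in config.tandems:
        if t.segment == "repeat":
            raise ConfigError("tandems may not be planted in the repeat segment")
        claim(t.segment, t.offset, t.offset + len(t.unit) * t.copies, f"tandem {t.unit}")
    for d in config.dispersed:
        if "repeat" in (d.segment1, d.segment2):
            raise ConfigError("dispersed repeats may not be planted in the repeat segment")
        if d.category not in ("forward", "palindromic"):
            raise ConfigError(f"unsupported planted category {d.category!r}")
        claim(d.segment1, d.offset1, d.offset1 + d.length, f"dispersed@{d.offset1}")
        claim(d.segment2, d.offset2, d.offset2 + d.length, f"dispersed@{d.offset2}")
    for m in config.mtpts:
        if m.identity < 0.7:
            raise ConfigError("MTPT identity < 0.7 is below the detection design range")
        if m.segment == "repeat":
            raise ConfigError("MTPT source intervals may not lie in the repeat segment")
        if m.length > min(config.genome_length, config.cp_length):
            raise ConfigError("MTPT fragment longer than a genome")
        claim(m.segment, m.offset, m.offset + m.length, f"mtpt@{m.offset}")
        if m.cp_offset < 0 or m.cp_offset + m.length > config.cp_length:
            raise ConfigError("MTPT fragment outside cp bounds")
    genes_by_name = {g.name: g for g in config.genes}
    for e in config.editing:
        g = genes_by_name.get(e.gene)
        if g is None or g.feature_type != "PCG":
            raise ConfigError(f"editing spec names unknown PCG {e.gene!r}")
        if not (1 <= e.cds_pos <= g.length - 3):
            raise ConfigError(f"editing site {e.gene}:{e.cds_pos} outside CDS")
        if e.cds_pos <= 3 and not (g.start_codon == "ACG" and e.cds_pos == 2):
            raise ConfigError(
                f"editing site {e.gene}:{e.cds_pos} inside a non-editable start codon"
            )
        if not (0 < e.frequency <= 1):
            raise ConfigError("editing frequency must be in (0, 1]")


def simulate_mitogenome(
    config: SimulationConfig,
) -> tuple[SequenceRecord, AssemblyGraph, list[GeneAnnotation], TruthTables]:
    """Build the synthetic mitogenome, its graph, annotations, and truth."""
    _validate_config(config)
    rng_bg = _rng(config.seed, 1)
    rng_gene = _rng(config.seed, 2)
    rng_feat = _rng(config.seed, 3)

    builder = _GenomeBuilder(config, rng_bg)
    L1 = config.seg_lengths["ctg1"]
    Lr = config.seg_lengths["repeat"]
    L2 = config.seg_lengths["ctg2"]
    L = config.genome_length

    # distinct flank bases around the two repeat occurrences keep the
    # repeat-pair maximal exactly at the segment boundaries
    if builder.seg["ctg1"][-1] == builder.seg["ctg2"][-1]:
        builder.seg["ctg2"][-1] = {"A": "C", "C": "A", "G": "T", "T": "G"}[
            builder.seg["ctg2"][-1]
        ]
    if builder.seg["ctg2"][0] == builder.seg["ctg1"][0]:
        builder.seg["ctg2"][0] = {"A": "G", "C": "T", "G": "A", "T": "C"}[
            builder.seg["ctg2"][0]
        ]

    _scrub_background(builder, rng_bg, protected=set())

    # --- genes -------------------------------------------------------------
    edits_by_gene: dict[str, list[EditPlant]] = {}
    for e in config.editing:
        edits_by_gene.setdefault(e.gene, []).append(e)
    annotations: list[GeneAnnotation] = []
    for g in config.genes:
        if g.feature_type == "PCG":
            sense = _random_cds(rng_gene, g.length, config.gc, g.start_codon)
            sense_list = list(sense)
            for e in edits_by_gene.get(g.name, ()):
                if e.cds_pos == 2 and g.start_codon == "ACG":
                    pass  # already a C
                else:
                    sense_list[e.cds_pos - 1] = "C"
            sense = "".join(sense_list)
        else:
            sense = random_dna(rng_gene, g.length, config.gc)
        genomic = revcomp(sense) if g.strand == "-" else sense
        occurrences = (1, 2) if g.segment == "repeat" else (1,)
        for occ in occurrences:
            base = config.segment_start(g.segment, occ) + g.offset
            parts = []
            cursor_g = 0
            cursor_pos = base
            for i, ex_len in enumerate(g.exon_lengths):
                builder.write(cursor_pos, genomic[cursor_g : cursor_g + ex_len])
                parts.append((cursor_pos, cursor_pos + ex_len))
                cursor_g += ex_len
                cursor_pos += ex_len
                if i < len(g.intron_lengths):
                    cursor_pos += g.intron_lengths[i]
            annotations.append(
                GeneAnnotation(
                    g.name, g.feature_type, g.strand, tuple(parts), copy_index=occ
                )
            )

    truth = TruthTables(
        true_master=Conformation((), 0, "master"),
        true_subcircles=(Conformation((), 0, "recombinant"),) * 2,
        junction_positions={},
    )

    # --- SSRs --------------------------------------------------------------
    for s in config.ssrs:
        start = config.segment_start(s.segment) + s.offset
        run = s.motif * s.copies
        builder.write(start, run)
        u = len(s.motif)
        if builder.get(start - 1) == s.motif[u - 1]:
            builder.set(start - 1, _other_base(rng_feat, {s.motif[u - 1]}))
        if builder.get(start + len(run)) == s.motif[0]:
            builder.set(start + len(run), _other_base(rng_feat, {s.motif[0]}))
        truth.true_ssrs.append(
            SSRRecord(
                motif=canonical_rotation(s.motif), unit_len=u, copies=s.copies,
                start=start + 1, end=start + len(run),
            )
        )

    # --- tandem repeats ----------------------------------------------------
    for t in config.tandems:
        start = config.segment_start(t.segment) + t.offset
        p = len(t.unit)
        span = p * t.copies
        builder.write(start, t.unit * t.copies)
        if builder.get(start - 1) == builder.get(start - 1 + p):
            builder.set(start - 1, _other_base(rng_feat, {builder.get(start - 1 + p)}))
        if builder.get(start + span) == builder.get(start + span - p):
            builder.set(
                start + span, _other_base(rng_feat, {builder.get(start + span - p)})
            )
        truth.true_tandems.append(
            TandemRepeat(
                consensus=t.unit, period=p, copies=float(t.copies),
                percent_match=100.0, start=start + 1, end=start + span,
            )
        )

    # --- dispersed repeats -------------------------------------------------
    for d in config.dispersed:
        p1 = config.segment_start(d.segment1) + d.offset1
        p2 = config.segment_start(d.segment2) + d.offset2
        block = random_dna(rng_feat, d.length, config.gc)
        builder.write(p1, block)
        copy = block if d.category == "forward" else revcomp(block)
        builder.write(p2, copy)
        if d.category == "forward":
            if builder.get(p1 - 1) == builder.get(p2 - 1):
                builder.set(p2 - 1, _other_base(rng_feat, {builder.get(p1 - 1)}))
            if builder.get(p1 + d.length) == builder.get(p2 + d.length):
                builder.set(
                    p2 + d.length, _other_base(rng_feat, {builder.get(p1 + d.length)})
                )
        else:  # palindromic: extension pairs left1/right2 and right1/left2
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            if builder.get(p1 - 1) == comp[builder.get(p2 + d.length)]:
                builder.set(
                    p2 + d.length,
                    _other_base(rng_feat, {comp[builder.get(p1 - 1)]}),
                )
            if builder.get(p1 + d.length) == comp[builder.get(p2 - 1)]:
                builder.set(
                    p2 - 1, _other_base(rng_feat, {comp[builder.get(p1 + d.length)]})
                )
        truth.true_dispersed.append(
            DispersedRepeatPair(
                category=d.category, pos1=p1 + 1, pos2=p2 + 1,
                length=d.length, identity=1.0,
            )
        )
    # the duplicated repeat segment is itself a dispersed forward pair
    truth.true_dispersed.append(
        DispersedRepeatPair(
            category="forward", pos1=L1 + 1, pos2=L1 + Lr + L2 + 1,
            length=Lr, identity=1.0,
        )
    )
    truth.true_dispersed.sort(key=lambda r: (r.pos1, r.pos2, r.category))

    # --- final scrub against accidental features ---------------------------
    protected = _protected_mask(config, annotations)
    _scrub_background(builder, rng_bg, protected, truth=truth)

    genome = SequenceRecord("mito_synth", builder.genome(), circular=True)

    graph = AssemblyGraph(
        segments={
            "ctg1": "".join(builder.seg["ctg1"]),
            "ctg2": "".join(builder.seg["ctg2"]),
            "repeat": "".join(builder.seg["repeat"]),
        },
        depth={"ctg1": 30.0, "ctg2": 30.0, "repeat": 60.0},
    )
    graph.add_link("ctg1", "+", "repeat", "+")
    graph.add_link("repeat", "+", "ctg2", "+")
    graph.add_link("ctg2", "+", "repeat", "+")
    graph.add_link("repeat", "+", "ctg1", "+")

    master_walk = (("ctg1", "+"), ("repeat", "+"), ("ctg2", "+"), ("repeat", "+"))
    truth.true_master = Conformation(master_walk, L, "master")
    truth.true_subcircles = (
        Conformation((("repeat", "+"), ("ctg2", "+")), Lr + L2, "recombinant"),
        Conformation((("repeat", "+"), ("ctg1", "+")), Lr + L1, "recombinant"),
    )
    joins = {
        (("ctg1", "+"), ("repeat", "+")): L1,
        (("repeat", "+"), ("ctg2", "+")): L1 + Lr,
        (("ctg2", "+"), ("repeat", "+")): L1 + Lr + L2,
        (("repeat", "+"), ("ctg1", "+")): 0,
    }
    truth.junction_positions = {
        junction_label(canonical_junction(a, b)): pos
        for (a, b), pos in joins.items()
    }
    truth.true_editing_sites = list(config.editing)
    return genome, graph, annotations, truth


def _other_base(rng: np.random.Generator, forbidden: set[str]) -> str:
    choices = [b for b in "ACGT" if b not in forbidden]
    return choices[rng.integers(len(choices))]


def _scrub_background(
    builder: _GenomeBuilder,
    rng: np.random.Generator,
    protected: set[int],
    truth: TruthTables | None = None,
    max_rounds: int = 6,
) -> None:
    """Mutate accidental SSR/tandem hits in the background until clean.

    Features matching planted truth are left alone; mutations avoid
    protected positions (gene bodies and planted features) and never create
    a stop codon inside a protected frame because they only touch
    unprotected background.
    """
    truth_ssr = {(r.start, r.end) for r in (truth.true_ssrs if truth else [])}
    truth_tandem = (
        [(r.start, r.end) for r in truth.true_tandems] if truth else []
    )
    n = builder.config.genome_length
    for _ in range(max_rounds):
        genome = builder.genome()
        dirty_spans: list[tuple[int, int]] = []
        for r in find_ssrs(genome, circular=True):
            if (r.start, r.end) in truth_ssr:
                continue
            dirty_spans.append((r.start - 1, r.end))
        for r in find_tandem_repeats(genome):
            if any(
                min(r.end, te) - max(r.start, ts) > 0.5 * (r.end - r.start)
                for ts, te in truth_tandem
            ):
                continue
            dirty_spans.append((r.start - 1, r.end))
        if not dirty_spans:
            return
        for s, e in dirty_spans:
            positions = [p % n for p in range(s, e) if p % n not in protected]
            if not positions:
                continue
            pos = positions[len(positions) // 2]
            builder.set(pos, _other_base(rng, {builder.get(pos)}))
    warnings.warn("background scrub did not fully converge; spurious repeats may remain")


# ---------------------------------------------------------------------------
# long reads
# ---------------------------------------------------------------------------

def _apply_substitutions(
    seq: str, rate: float, rng: np.random.Generator
) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    n_err = rng.binomial(len(arr), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(arr), size=n_err, replace=False)
    for p in pos:
        cur = chr(arr[p])
        arr[p] = ord(_other_base(rng, {cur}))
    return arr.tobytes().decode()


def simulate_hifi_reads(
    genome: SequenceRecord,
    config: SimulationConfig,
    junction_positions: Mapping[str, int] | None = None,
) -> tuple[list[SequenceRecord], dict[str, int]]:
    """Sample CCS-grade reads from the circular genome on both strands.

    Returns the reads and the truth junction support: for each junction, the
    number of reads whose error-free source interval covers the join with at
    least ``config.min_flank`` bases on each side.
    """
    rng = _rng(config.seed, 4)
    L = len(genome.seq)
    doubled = genome.seq + genome.seq
    reads: list[SequenceRecord] = []
    support = {label: 0 for label in (junction_positions or {})}
    for i in range(config.read_count):
        length = int(
            np.clip(
                rng.normal(config.read_length_mean, config.read_length_sd),
                config.read_min_length,
                max(config.read_min_length, L - 1),
            )
        )
        start = int(rng.integers(L))
        source = doubled[start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        seq = source if strand == "+" else revcomp(source)
        seq = _apply_substitutions(seq, config.read_error_rate, rng)
        reads.append(SequenceRecord(f"read_{i:05d}", seq))
        if junction_positions:
            f = config.min_flank
            for label, p in junction_positions.items():
                d = (p - start) % L
                if f <= d <= length - f:
                    support[label] += 1
    return reads, support


# ---------------------------------------------------------------------------
# chloroplast partner with MTPTs
# ---------------------------------------------------------------------------

def simulate_cp_with_mtpt(
    mt_genome: SequenceRecord, config: SimulationConfig
) -> tuple[SequenceRecord, list[GeneAnnotation], list[MTPTTruth]]:
    """Random cp background with mt-derived fragments copied in.

    Mutations are placed uniformly to reach each fragment's target identity;
    planted cp genes either lie fully inside a fragment (complete) or
    straddle its boundary (partial).
    """
    _validate_config(config)
    rng = _rng(config.seed, 5)
    cp = list(random_dna(rng, config.cp_length, config.cp_gc))
    annotations: list[GeneAnnotation] = []
    truths: list[MTPTTruth] = []
    for m in config.mtpts:
        mt_start = config.segment_start(m.segment) + m.offset
        fragment = mt_genome.seq[mt_start : mt_start + m.length]
        n_mut = int(round((1.0 - m.identity) * m.length))
        frag = list(fragment)
        if n_mut:
            pos = rng.choice(m.length, size=n_mut, replace=False)
            for p in pos:
                frag[p] = _other_base(rng, {frag[p]})
        planted = "".join(frag)
        if m.strand == "-":
            planted = revcomp(planted)
        cp[m.cp_offset : m.cp_offset + m.length] = list(planted)
        truths.append(
            MTPTTruth(
                mt_start=mt_start + 1, mt_end=mt_start + m.length,
                cp_start=m.cp_offset + 1, cp_end=m.cp_offset + m.length,
                strand=m.strand, identity=round(1.0 - n_mut / m.length, 4),
                n_mutations=n_mut,
            )
        )
        for g in m.genes:
            g_start = m.cp_offset + g.rel_start
            g_end = g_start + g.length
            inside = g.rel_start >= 0 and g.rel_start + g.length <= m.length
            if g.status == "complete" and not inside:
                raise ConfigError(f"cp gene {g.name} marked complete but straddles")
            if g.status == "partial" and inside:
                raise ConfigError(f"cp gene {g.name} marked partial but contained")
            annotations.append(
                GeneAnnotation(g.name, g.feature_type, "+", ((g_start, g_end),))
            )
    record = SequenceRecord("cp_synth", "".join(cp), circular=True)
    return record, annotations, truths


# ---------------------------------------------------------------------------
# RNA reads with planted C->U edits
# ---------------------------------------------------------------------------

def simulate_rna_reads(
    annotations: Sequence[GeneAnnotation],
    mt_genome: SequenceRecord,
    config: SimulationConfig,
) -> tuple[list[SequenceRecord], list[EditPlant]]:
    """Reads from spliced sense-strand transcripts with planted C->U edits.

    Each read covering a planted site carries T with the site's target
    frequency (independent Bernoulli draws, i.e. binomial sampling across
    the depth); substitution sequencing errors are added afterwards.
    Transcripts carry ``config.rna_utr`` bases of genomic flank beyond the
    CDS on each side, so coverage does not collapse at the start/stop codons
    (a start-codon editing site would otherwise be undetectable).
    """
    rng = _rng(config.seed, 6)
    refs: dict[str, str] = {}
    transcripts: dict[str, tuple[str, int]] = {}  # gene -> (seq, cds offset)
    doubled = mt_genome.seq + mt_genome.seq
    n = len(mt_genome.seq)
    for ann in annotations:
        if ann.feature_type != "PCG" or ann.copy_index != 1:
            continue
        cds = ann.spliced(mt_genome.seq)
        refs[ann.gene] = cds
        lo, hi = ann.span
        utr = config.rna_utr
        up_g = doubled[(lo - utr) % n : (lo - utr) % n + utr]
        down_g = doubled[hi : hi + utr]
        if ann.strand == "+":
            transcripts[ann.gene] = (up_g + cds + down_g, utr)
        else:
            transcripts[ann.gene] = (revcomp(down_g) + cds + revcomp(up_g), utr)
    sites_by_gene: dict[str, list[EditPlant]] = {}
    for e in config.editing:
        cds = refs.get(e.gene)
        if cds is None:
            raise ConfigError(f"editing spec names unannotated gene {e.gene!r}")
        if cds[e.cds_pos - 1] != "C":
            raise ConfigError(
                f"editing site {e.gene}:{e.cds_pos} is not a sense-strand C"
            )
        sites_by_gene.setdefault(e.gene, []).append(e)
    reads: list[SequenceRecord] = []
    idx = 0
    if config.rna_depth <= 0:
        return [], list(config.editing)
    for gene in sorted(refs):
        transcript, cds_off = transcripts[gene]
        rl = min(config.rna_read_length, len(transcript))
        n_reads = int(round(config.rna_depth * len(transcript) / rl))
        sites = sites_by_gene.get(gene, [])
        for _ in range(n_reads):
            start = int(rng.integers(0, len(transcript) - rl + 1))
            seq = list(transcript[start : start + rl])
            for site in sites:
                p = cds_off + site.cds_pos - 1
                if start <= p < start + rl and rng.random() < site.frequency:
                    seq[p - start] = "T"
            read = _apply_substitutions("".join(seq), config.rna_error_rate, rng)
            reads.append(SequenceRecord(f"rna_{idx:06d}", read))
            idx += 1
    return reads, list(config.editing)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def simulate_all(config: SimulationConfig, outdir: str | Path) -> dict:
    """Run every generator stage and write the dataset + truth.json.

    Emits genome.fasta, graph.gfa, annotations.gff3/.tsv, reads.fastq,
    cp.fasta, cp_annotations.tsv, rna.fastq and truth.json; returns a dict
    with the in-memory objects and file paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, graph, annotations, truth = simulate_mitogenome(config)
    reads, support = simulate_hifi_reads(genome, config, truth.junction_positions)
    truth.true_junction_support = support
    cp, cp_annotations, mtpt_truth = simulate_cp_with_mtpt(genome, config)
    truth.true_mtpts = mtpt_truth
    rna_reads, editing_truth = simulate_rna_reads(annotations, genome, config)
    truth.true_editing_sites = editing_truth

    write_fasta([genome], outdir / "genome.fasta")
    write_gfa(graph, outdir / "graph.gfa")
    write_annotations_gff3(annotations, genome.id, outdir / "annotations.gff3")
    write_annotations_tsv(annotations, outdir / "annotations.tsv")
    write_fastq(reads, outdir / "reads.fastq")
    write_fasta([cp], outdir / "cp.fasta")
    write_annotations_tsv(cp_annotations, outdir / "cp_annotations.tsv")
    write_fastq(rna_reads, outdir / "rna.fastq")
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth.to_json(), fh, indent=1, sort_keys=True)
    return {
        "genome": genome,
        "graph": graph,
        "annotations": annotations,
        "reads": reads,
        "cp": cp,
        "cp_annotations": cp_annotations,
        "rna_reads": rna_reads,
        "truth": truth,
        "outdir": outdir,
    }
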