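"""Readers/writers and the shared sequence/annotation data model.

Internal coordinates are 0-based half-open throughout the package; every
external file and report uses 1-based inclusive coordinates (GFF3/GenBank
convention).  Conversion helpers live here so the convention is applied in
exactly one place.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

DNA_ALPHABET = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

FEATURE_TYPES = ("PCG", "tRNA", "rRNA")


class FormatError(ValueError):
    """Malformed external file."""


class GraphError(ValueError):
    """Inconsistent assembly graph."""


class ValidationError(ValueError):
    """Annotation set violates an invariant."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


# ---------------------------------------------------------------------------
# coordinate conventions
# ---------------------------------------------------------------------------

def to_1based_inclusive(interval: tuple[int, int]) -> tuple[int, int]:
    """0-based half-open ``[s, e)`` -> 1-based inclusive ``(s+1, e)``."""
    s, e = interval
    return s + 1, e


def to_0based_halfopen(interval: tuple[int, int]) -> tuple[int, int]:
    """1-based inclusive ``(a, b)`` -> 0-based half-open ``(a-1, b)``."""
    a, b = interval
    return a - 1, b


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """A DNA molecule: uppercase ACGTN, optionally circular."""

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"record {self.id!r}: non-ACGTN characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(self.id, revcomp(self.seq), self.circular)


@dataclass
class GeneAnnotation:
    """A gene feature on a parent sequence.

    ``parts`` are 0-based half-open intervals in annotation (transcription
    splice) order along the forward strand of the parent; for minus-strand
    features the spliced sequence is the reverse complement of the joined
    parts.  Features wrapping the circular origin are stored as two parts
    with ``wraps_origin`` set.
    """

    gene: str
    feature_type: str
    strand: str
    parts: tuple[tuple[int, int], ...]
    copy_index: int = 1
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise ValidationError(
                f"{self.gene}: feature_type must be one of {FEATURE_TYPES}"
            )
        if self.strand not in "+-":
            raise ValidationError(f"{self.gene}: strand must be + or -")
        if not self.parts:
            raise ValidationError(f"{self.gene}: no parts")
        self.parts = tuple((int(s), int(e)) for s, e in self.parts)
        for s, e in self.parts:
            if s >= e and not self.wraps_origin:
                raise ValidationError(
                    f"{self.gene}: empty/inverted part {to_1based_inclusive((s, e))}"
                )
        if self.copy_index < 1:
            raise ValidationError(f"{self.gene}: copy_index must be >= 1")

    @property
    def span(self) -> tuple[int, int]:
        return min(s for s, _ in self.parts), max(e for _, e in self.parts)

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.parts)

    def spliced(self, parent_seq: str) -> str:
        """Sense-strand spliced sequence of the feature."""
        joined = "".join(parent_seq[s:e] for s, e in self.parts)
        return revcomp(joined) if self.strand == "-" else joined


@dataclass
class ReadAlignment:
    """A local alignment of a read interval to a segment interval.

    Read coordinates are on the forward (as-sequenced) read; ``segment_orient``
    '-' means the read traverses the segment backwards.
    """

    read_id: str
    read_start: int
    read_end: int
    segment_id: str
    segment_start: int
    segment_end: int
    segment_orient: str
    identity: float

    def __post_init__(self) -> None:
        if not (self.read_start < self.read_end):
            raise ValueError("read interval empty")
        if not (self.segment_start < self.segment_end):
            raise ValueError("segment interval empty")


@dataclass
class AssemblyGraph:
    """Unitig graph: named segments plus oriented links.

    Links are 4-tuples ``(from_seg, from_orient, to_seg, to_orient)`` meaning
    the end of ``from_seg`` (read in ``from_orient``) abuts the start of
    ``to_seg`` (read in ``to_orient``) with zero overlap.
    """

    segments: dict[str, str] = field(default_factory=dict)
    links: list[tuple[str, str, str, str]] = field(default_factory=list)
    depth: dict[str, float] = field(default_factory=dict)

    def segment_lengths(self) -> dict[str, int]:
        return {name: len(s) for name, s in self.segments.items()}

    def add_link(self, a: str, oa: str, b: str, ob: str) -> None:
        for seg in (a, b):
            if seg not in self.segments:
                raise GraphError(f"link references unknown segment {seg!r}")
        self.links.append((a, oa, b, ob))


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, circular: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into validated :class:`SequenceRecord` objects."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(SequenceRecord(rec.id, str(rec.seq), circular=circular))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTQ file; qualities are discarded (the pipeline is CCS-style)."""
    return [
        SequenceRecord(rec.id, str(rec.seq))
        for rec in SeqIO.parse(str(path), "fastq")
    ]


def write_fastq(records: Iterable[SequenceRecord], path: str | Path, quality: int = 30) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{chr(33 + quality) * len(rec.seq)}\n")


# ---------------------------------------------------------------------------
# GFA 1.0
# ---------------------------------------------------------------------------

def read_gfa(path: str | Path) -> AssemblyGraph:
    """Read a GFA 1.0 graph (S and L lines; overlap must be ``0M`` or ``*``).

    Non-trivial overlaps are rejected rather than trimmed: the unitig graphs
    this package resolves are overlap-free, and silently trimming would
    double-count repeat bases.
    """
    graph = AssemblyGraph()
    pending_links: list[tuple[int, tuple[str, str, str, str]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line[0] in "#H":
                continue
            fields = line.split("\t")
            if fields[0] == "S":
                if len(fields) < 3:
                    raise FormatError(f"{path}:{lineno}: S line needs name and sequence")
                name, seq = fields[1], fields[2]
                if seq == "*" or not seq:
                    raise FormatError(f"{path}:{lineno}: segment {name!r} has no sequence")
                graph.segments[name] = seq.upper()
                for tag in fields[3:]:
                    m = re.match(r"^(dp|DP):f:([-+0-9.eE]+)$", tag)
                    if m:
                        graph.depth[name] = float(m.group(2))
            elif fields[0] == "L":
                if len(fields) < 5:
                    raise FormatError(f"{path}:{lineno}: truncated L line")
                a, oa, b, ob = fields[1], fields[2], fields[3], fields[4]
                overlap = fields[5] if len(fields) > 5 else "*"
                if overlap not in ("*", "0M"):
                    raise GraphError(
                        f"{path}:{lineno}: non-trivial overlap {overlap!r} rejected"
                    )
                if oa not in "+-" or ob not in "+-":
                    raise FormatError(f"{path}:{lineno}: bad orientation")
                pending_links.append((lineno, (a, oa, b, ob)))
    for lineno, (a, oa, b, ob) in pending_links:
        for seg in (a, b):
            if seg not in graph.segments:
                raise GraphError(f"{path}:{lineno}: link references unknown segment {seg!r}")
        graph.links.append((a, oa, b, ob))
    return graph


def write_gfa(graph: AssemblyGraph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for name, seq in graph.segments.items():
            tags = ""
            if name in graph.depth:
                tags = f"\tdp:f:{graph.depth[name]:g}"
            fh.write(f"S\t{name}\t{seq}{tags}\n")
        for a, oa, b, ob in graph.links:
            fh.write(f"L\t{a}\t{oa}\t{b}\t{ob}\t0M\n")


# ---------------------------------------------------------------------------
# annotations: GFF3 and the 5-column TSV dialect
# ---------------------------------------------------------------------------

_TSV_HEADER = ["gene", "feature_type", "strand", "parts", "copy_index"]
_FTYPE_TO_GFF = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}
_GFF_TO_FTYPE = {v: k for k, v in _FTYPE_TO_GFF.items()}


def _check_duplicates(annotations: Sequence[GeneAnnotation]) -> None:
    seen: dict[tuple[str, int], GeneAnnotation] = {}
    for ann in annotations:
        key = (ann.gene, ann.copy_index)
        if key in seen:
            a, b = seen[key].span, ann.span
            if a[0] < b[1] and b[0] < a[1]:
                raise ValidationError(
                    f"overlapping duplicate entries for gene {ann.gene!r} copy {ann.copy_index}"
                )
        else:
            seen[key] = ann


def parse_parts(text: str) -> tuple[tuple[int, int], ...]:
    """Parse ``"100..1200,1300..1500"`` (1-based inclusive) into internal parts."""
    parts = []
    for chunk in text.split(","):
        m = re.match(r"^\s*(\d+)\.\.(\d+)\s*$", chunk)
        if not m:
            raise FormatError(f"bad interval {chunk!r} (expected start..end)")
        parts.append(to_0based_halfopen((int(m.group(1)), int(m.group(2)))))
    return tuple(parts)


def format_parts(parts: Sequence[tuple[int, int]]) -> str:
    return ",".join(
        "{}..{}".format(*to_1based_inclusive(p)) for p in parts
    )


def read_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read gene annotations from GFF3 or the package's 5-column TSV."""
    path = Path(path)
    with open(path) as fh:
        head = fh.read(2048)
    if head.startswith("##gff-version") or path.suffix.lower() in (".gff", ".gff3"):
        return _read_gff3(path)
    return _read_tsv(path)


def _read_tsv(path: Path) -> list[GeneAnnotation]:
    annotations = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fields[: len(_TSV_HEADER)] == _TSV_HEADER:
                continue
            if len(fields) < 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            gene, ftype, strand, parts_text, copy_text = fields[:5]
            parts = parse_parts(parts_text)
            wraps = len(parts) == 2 and parts[0][1] > parts[1][0] and parts[1][0] == 0
            annotations.append(
                GeneAnnotation(gene, ftype, strand, parts, int(copy_text), wraps_origin=wraps)
            )
    _check_duplicates(annotations)
    return annotations


def write_annotations_tsv(annotations: Iterable[GeneAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_TSV_HEADER) + "\n")
        for ann in annotations:
            fh.write(
                f"{ann.gene}\t{ann.feature_type}\t{ann.strand}\t"
                f"{format_parts(ann.parts)}\t{ann.copy_index}\n"
            )


def _read_gff3(path: Path) -> list[GeneAnnotation]:
    # grouped by ID/Parent; CDS parts joined in file (annotation) order
    by_id: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            _, _, ftype, start, end, _, strand, _, attrs_text = fields
            if ftype not in _GFF_TO_FTYPE and ftype != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in attrs_text.split(";") if "=" in kv
            )
            ident = attrs.get("Parent") or attrs.get("ID")
            if ident is None:
                raise FormatError(f"{path}:{lineno}: feature without ID/Parent")
            entry = by_id.setdefault(
                ident,
                {"gene": attrs.get("gene_name"), "ftype": None, "strand": strand,
                 "parts": [], "copy": int(attrs.get("copy_index", 1)),
                 "wraps": attrs.get("wraps_origin") == "true"},
            )
            if ftype == "gene":
                entry["gene"] = attrs.get("gene_name") or attrs.get("Name") or ident
                entry["copy"] = int(attrs.get("copy_index", entry["copy"]))
                entry["wraps"] = attrs.get("wraps_origin") == "true" or entry["wraps"]
                continue
            entry["ftype"] = _GFF_TO_FTYPE[ftype]
            entry["strand"] = strand
            entry["parts"].append(to_0based_halfopen((int(start), int(end))))
    annotations = []
    for ident, entry in by_id.items():
        if not entry["parts"]:
            continue
        name = entry["gene"] or ident.rsplit(".", 1)[0]
        annotations.append(
            GeneAnnotation(
                name, entry["ftype"], entry["strand"], tuple(entry["parts"]),
                entry["copy"], wraps_origin=entry["wraps"],
            )
        )
    _check_duplicates(annotations)
    return annotations


def write_annotations_gff3(
    annotations: Iterable[GeneAnnotation], seqid: str, path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for ann in annotations:
            ident = f"{ann.gene}.{ann.copy_index}"
            s1, e1 = to_1based_inclusive(ann.span)
            wrap = ";wraps_origin=true" if ann.wraps_origin else ""
            fh.write(
                f"{seqid}\tmitoresolve\tgene\t{s1}\t{e1}\t.\t{ann.strand}\t.\t"
                f"ID={ident};gene_name={ann.gene};copy_index={ann.copy_index}{wrap}\n"
            )
            sub = _FTYPE_TO_GFF[ann.feature_type]
            for part in ann.parts:
                ps, pe = to_1based_inclusive(part)
                phase = "0" if ann.feature_type == "PCG" else "."
                fh.write(
                    f"{seqid}\tmitoresolve\t{sub}\t{ps}\t{pe}\t.\t{ann.strand}\t{phase}\t"
                    f"Parent={ident}\n"
                )


def validate_annotations(
    genome: SequenceRecord, annotations: Sequence[GeneAnnotation]
) -> list[str]:
    """Consistency checks; returns human-readable warnings (never raises)."""
    warnings: list[str] = []
    n = len(genome.seq)
    for ann in annotations:
        lo, hi = ann.span
        if lo < 0 or hi > n:
            warnings.append(f"{ann.gene}: outside sequence bounds")
        if ann.feature_type == "PCG" and ann.length % 3 != 0:
            warnings.append(
                f"{ann.gene}: spliced CDS length {ann.length} not a multiple of 3"
            )
    return warnings


# ---------------------------------------------------------------------------
# PAF (optional pre-computed alignments)
# ---------------------------------------------------------------------------

def read_paf(path: str | Path) -> list[ReadAlignment]:
    """Read minimal PAF into :class:`ReadAlignment` records.

    Identity is taken as matches / alignment-block-length (columns 10/11).
    """
    alignments = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 12:
                raise FormatError(f"{path}:{lineno}: PAF needs >= 12 columns")
            matches, block = int(f[9]), int(f[10])
            alignments.append(
                ReadAlignment(
                    read_id=f[0],
                    read_start=int(f[2]),
                    read_end=int(f[3]),
                    segment_id=f[5],
                    segment_start=int(f[7]),
                    segment_end=int(f[8]),
                    segment_orient=f[4],
                    identity=matches / block if block else 0.0,
                )
            )
    return alignments
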