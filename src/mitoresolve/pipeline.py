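"""End-to-end orchestration: run stages, write TSVs, aggregate report.json.

Each analysis stage is a thin wrapper over one library module; the report
aggregates only numbers already written to that stage's TSV, so every value
in report.json is traceable to exactly one stage output.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import sys
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import codon_usage, editing, graphres, mtpt, repeats
from .io_core import (
    GeneAnnotation,
    SequenceRecord,
    read_annotations,
    read_fasta,
    read_fastq,
    read_gfa,
    read_paf,
    write_fasta,
)

log = logging.getLogger("mitoresolve")

STAGES = ("resolve", "rscu", "repeats", "mtpt", "editing")

_STAGE_PARAM_KEYS = {
    "resolve": {
        "min_identity", "min_anchor", "gap_tol", "end_tol", "min_flank",
        "min_support", "amplicon_flank", "repeat_copy_numbers",
    },
    "rscu": {"dedupe", "stop_as_family"},
    "repeats": {
        "ssr_thresholds", "min_period", "max_period", "min_match", "min_span",
        "dispersed_min_len", "max_mismatch", "circular",
    },
    "mtpt": {"word_size", "evalue_cutoff", "reward", "penalty", "gapped"},
    "editing": {
        "min_cov", "min_freq", "alpha", "error_rate", "min_identity",
        "freq_denominator",
    },
}


class PipelineInputError(ValueError):
    """Missing or malformed pipeline inputs (CLI exit code 2)."""


@dataclass
class PipelineConfig:
    """Inputs, per-stage parameters and output location for one run."""

    outdir: str = "mitoresolve_out"
    seed: int = 0
    log_level: str = "INFO"
    force: bool = False
    stages: Sequence[str] = ()
    # input paths
    gfa: str | None = None
    reads: str | None = None
    paf: str | None = None
    genome: str | None = None
    annotations: str | None = None
    cp_genome: str | None = None
    cp_annotations: str | None = None
    rna_reads: str | None = None
    # per-stage parameter blocks
    resolve: dict = field(default_factory=dict)
    rscu: dict = field(default_factory=dict)
    repeats: dict = field(default_factory=dict)
    mtpt: dict = field(default_factory=dict)
    editing: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for stage, params in (
            ("resolve", self.resolve), ("rscu", self.rscu),
            ("repeats", self.repeats), ("mtpt", self.mtpt),
            ("editing", self.editing),
        ):
            unknown = set(params) - _STAGE_PARAM_KEYS[stage]
            if unknown:
                raise PipelineInputError(
                    f"unknown {stage} parameters: {sorted(unknown)}"
                )

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise PipelineInputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def summarize_genome(
    genome: SequenceRecord, annotations: Sequence[GeneAnnotation]
) -> dict:
    """Length, circularity, GC%, and unique gene counts by class."""
    gc = codon_usage.compute_gc(genome.seq)
    by_class: dict[str, set[str]] = {"PCG": set(), "tRNA": set(), "rRNA": set()}
    copies: Counter = Counter()
    for ann in annotations:
        by_class.setdefault(ann.feature_type, set()).add(ann.gene)
        copies[ann.gene] = max(copies[ann.gene], ann.copy_index)
    if not annotations:
        log.warning("no annotations supplied; gene counts are zero")
    return {
        "length_bp": len(genome.seq),
        "circular": genome.circular,
        "gc_percent": round(100.0 * gc, 2),
        "unique_genes": sum(len(v) for v in by_class.values()),
        "genes_by_class": {k: len(v) for k, v in sorted(by_class.items())},
        "gene_copy_numbers": {
            g: c for g, c in sorted(copies.items()) if c > 1
        },
    }


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _load_reads(path: str) -> list[SequenceRecord]:
    head = open(path).read(1)
    return read_fastq(path) if head == "@" else read_fasta(path)


def stage_resolve(config: PipelineConfig, outdir: Path) -> dict:
    if not config.gfa:
        raise PipelineInputError("resolve stage requires a GFA input")
    p = dict(config.resolve)
    graph = read_gfa(config.gfa)
    if config.paf:
        alignments = read_paf(config.paf)
    elif config.reads:
        alignments = graphres.align_reads_to_segments(
            _load_reads(config.reads),
            graph.segments,
            min_identity=p.get("min_identity", 0.9),
            min_anchor=p.get("min_anchor", 200),
        )
    else:
        raise PipelineInputError("resolve stage requires reads or a PAF file")
    evidence = graphres.count_junction_support(
        alignments,
        graph.segments,
        gap_tol=p.get("gap_tol", 100),
        end_tol=p.get("end_tol", 50),
        min_flank=p.get("min_flank", 200),
        graph=graph,
    )
    pd.DataFrame(
        [
            {
                "junction": graphres.junction_label(ev.junction),
                "support": ev.support,
                "read_ids": ",".join(ev.read_ids),
            }
            for ev in evidence
        ]
    ).to_csv(outdir / "junctions.tsv", sep="\t", index=False)

    master = graphres.resolve_conformations(
        graph, evidence,
        repeat_copy_numbers=p.get("repeat_copy_numbers"),
        min_support=p.get("min_support", 1),
    )
    seg_lens = graph.segment_lengths()
    copy_counts = Counter(seg for seg, _ in master.walk)
    repeat_names = [s for s, c in copy_counts.items() if c > 1]
    recombinants = graphres.enumerate_recombinants(master, repeat_names, seg_lens)

    conformations = [("master", master)]
    for i, (c1, c2) in enumerate(recombinants, 1):
        conformations.append((f"recombinant_{i}a", c1))
        conformations.append((f"recombinant_{i}b", c2))
    write_fasta(
        [
            SequenceRecord(name, c.sequence(graph.segments), circular=True)
            for name, c in conformations
        ],
        outdir / "conformations.fasta",
    )
    pd.DataFrame(
        [
            {
                "name": name,
                "kind": c.kind,
                "walk": " ".join(f"{s}{o}" for s, o in c.walk),
                "length_bp": c.length,
            }
            for name, c in conformations
        ]
    ).to_csv(outdir / "conformations.tsv", sep="\t", index=False)

    amplicons = graphres.predict_junction_amplicons(
        master, graph.segments, flank=p.get("amplicon_flank", 1000)
    )
    pd.DataFrame(
        [
            {
                "junction": graphres.junction_label(a.junction),
                "join_position": a.position + 1,
                "template_length": len(a.template),
                "product_length": a.product_length,
                "specific": a.specific,
            }
            for a in amplicons
        ]
    ).to_csv(outdir / "amplicons.tsv", sep="\t", index=False)
    return {
        "junctions": {
            graphres.junction_label(ev.junction): ev.support for ev in evidence
        },
        "master_walk": " ".join(f"{s}{o}" for s, o in master.walk),
        "master_length_bp": master.length,
        "conformation_lengths_bp": {
            name: c.length for name, c in conformations
        },
    }


def stage_rscu(config: PipelineConfig, outdir: Path) -> dict:
    genome, annotations = _require_genome(config)
    p = dict(config.rscu)
    extraction = codon_usage.extract_pcg_codons(
        genome, annotations, dedupe=p.get("dedupe", True)
    )
    table = codon_usage.compute_rscu(
        extraction, stop_as_family=p.get("stop_as_family", True)
    )
    codon_usage.write_rscu_tsv(table, outdir / "rscu.tsv")
    preferred = table[table["rscu"] > 1].index.tolist()
    return {
        "total_codons": int(table["count"].sum()),
        "codons_skipped_with_N": extraction.n_skipped,
        "preferred_codons": preferred,
    }


def stage_repeats(config: PipelineConfig, outdir: Path) -> dict:
    genome, _ = _require_genome(config, need_annotations=False)
    p = dict(config.repeats)
    circular = p.get("circular", genome.circular)
    ssrs = repeats.find_ssrs(
        genome.seq, thresholds=p.get("ssr_thresholds"), circular=circular
    )
    tandems = repeats.find_tandem_repeats(
        genome.seq,
        min_period=p.get("min_period", 7),
        max_period=p.get("max_period", 200),
        min_match=p.get("min_match", 75.0),
        min_span=p.get("min_span", 12),
    )
    dispersed = repeats.find_dispersed_repeats(
        genome.seq,
        min_len=p.get("dispersed_min_len", 30),
        max_mismatch=p.get("max_mismatch", 0),
        circular=circular,
    )
    pd.DataFrame([dataclasses.asdict(r) for r in ssrs]).to_csv(
        outdir / "ssr.tsv", sep="\t", index=False
    )
    pd.DataFrame([dataclasses.asdict(r) for r in tandems]).to_csv(
        outdir / "tandem.tsv", sep="\t", index=False
    )
    pd.DataFrame([dataclasses.asdict(r) for r in dispersed]).to_csv(
        outdir / "dispersed.tsv", sep="\t", index=False
    )
    return repeats.summarize_repeats(ssrs, tandems, dispersed)


def stage_mtpt(config: PipelineConfig, outdir: Path) -> dict:
    genome, _ = _require_genome(config, need_annotations=False)
    if not config.cp_genome:
        raise PipelineInputError("mtpt stage requires a chloroplast genome")
    cp = read_fasta(config.cp_genome, circular=True)[0]
    p = dict(config.mtpt)
    kwargs = dict(
        word_size=p.get("word_size", 7),
        evalue_cutoff=p.get("evalue_cutoff", 1e-10),
        reward=p.get("reward", 2),
        penalty=p.get("penalty", -3),
        gapped=p.get("gapped", True),
    )
    raw = mtpt.find_homologous_fragments(genome.seq, cp.seq, merge=False, **kwargs)
    fragments = mtpt.find_homologous_fragments(genome.seq, cp.seq, **kwargs)
    pd.DataFrame([dataclasses.asdict(f) for f in fragments]).to_csv(
        outdir / "mtpt.tsv", sep="\t", index=False
    )
    summary = mtpt.summarize_mtpt(fragments, len(genome.seq))
    result = {
        "fragment_count": summary.count,
        "fragment_count_unmerged": len(raw),
        "total_bp": summary.total_bp,
        "fraction_of_mitogenome_percent": summary.fraction_percent,
    }
    if config.cp_annotations:
        cp_ann = read_annotations(config.cp_annotations)
        calls = mtpt.classify_transferred_genes(fragments, cp_ann)
        pd.DataFrame([dataclasses.asdict(c) for c in calls]).to_csv(
            outdir / "transferred_genes.tsv", sep="\t", index=False
        )
        result["transferred_genes"] = {
            "complete": sum(1 for c in calls if c.status == "complete"),
            "partial": sum(1 for c in calls if c.status == "partial"),
        }
    return result


def stage_editing(config: PipelineConfig, outdir: Path) -> dict:
    genome, annotations = _require_genome(config)
    if not config.rna_reads:
        raise PipelineInputError("editing stage requires RNA reads")
    p = dict(config.editing)
    refs: dict[str, str] = {}
    for ann in annotations:
        if ann.feature_type == "PCG" and ann.copy_index == 1:
            refs[ann.gene] = ann.spliced(genome.seq)
    reads = _load_reads(config.rna_reads)
    pileup = editing.pileup_rna(
        reads, refs, min_identity=p.get("min_identity", 0.9)
    )
    sites = editing.call_editing_sites(
        pileup,
        min_cov=p.get("min_cov", 5),
        min_freq=p.get("min_freq", 0.1),
        alpha=p.get("alpha", 0.05),
        error_rate=p.get("error_rate", 0.01),
        freq_denominator=p.get("freq_denominator", "depth"),
    )
    annotated, summary = editing.annotate_site_effects(sites, refs)
    editing.sites_to_frame(annotated).to_csv(
        outdir / "editing_sites.tsv", sep="\t", index=False
    )
    summary.to_csv(outdir / "editing_summary.tsv", sep="\t")
    return {
        "site_count": len(annotated),
        "sites_per_gene": {g: int(r["n_sites"]) for g, r in summary.iterrows()},
        "start_gain_sites": int(summary["n_start_gain"].sum()) if len(summary) else 0,
    }


def _require_genome(
    config: PipelineConfig, need_annotations: bool = True
) -> tuple[SequenceRecord, list[GeneAnnotation]]:
    if not config.genome:
        raise PipelineInputError("this stage requires an assembled genome FASTA")
    genome = read_fasta(config.genome, circular=True)[0]
    annotations: list[GeneAnnotation] = []
    if config.annotations:
        annotations = read_annotations(config.annotations)
    elif need_annotations:
        raise PipelineInputError("this stage requires gene annotations")
    return genome, annotations


_STAGE_FUNCS = {
    "resolve": stage_resolve,
    "rscu": stage_rscu,
    "repeats": stage_repeats,
    "mtpt": stage_mtpt,
    "editing": stage_editing,
}

_STAGE_INPUTS = {
    "resolve": lambda c: bool(c.gfa and (c.reads or c.paf)),
    "rscu": lambda c: bool(c.genome and c.annotations),
    "repeats": lambda c: bool(c.genome),
    "mtpt": lambda c: bool(c.genome and c.cp_genome),
    "editing": lambda c: bool(c.genome and c.annotations and c.rna_reads),
}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the requested stages and write report.json.

    Stage selection defaults to every stage whose inputs are configured.  An
    existing report.json in the output directory is only overwritten with
    ``force``.  A failing stage is recorded under ``errors`` and does not
    destroy completed outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report_path = outdir / "report.json"
    if report_path.exists() and not config.force:
        raise RuntimeError(
            f"{report_path} exists; refusing to overwrite without force"
        )
    logging.basicConfig(
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        stream=sys.stderr,
        format="%(levelname)s %(name)s: %(message)s",
    )
    run_log = outdir / "run.log"
    with open(run_log, "w") as fh:
        fh.write("mitoresolve run\n")
        fh.write(json.dumps(dataclasses.asdict(config), indent=1, sort_keys=True, default=str))
        fh.write("\n")

    stages = list(config.stages) or [
        s for s in STAGES if _STAGE_INPUTS[s](config)
    ]
    report: dict = {"seed": config.seed, "stages": stages, "errors": {}}
    if config.genome:
        genome = read_fasta(config.genome, circular=True)[0]
        annotations = (
            read_annotations(config.annotations) if config.annotations else []
        )
        report["genome_summary"] = summarize_genome(genome, annotations)
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise PipelineInputError(f"unknown stage {stage!r}")
        log.info("running stage %s", stage)
        try:
            report[stage] = _STAGE_FUNCS[stage](config, outdir)
        except PipelineInputError:
            raise
        except Exception as exc:  # keep completed outputs, record the failure
            log.error("stage %s failed: %s", stage, exc)
            report["errors"][stage] = str(exc)
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report
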