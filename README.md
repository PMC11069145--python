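# mitoresolve

Structural resolution and characterization of plant mitochondrial genomes.

Plant mitogenomes assemble into graphs, not sequences: a long direct repeat
collapses two genomic copies onto one unitig, leaving the circular order of
the single-copy contigs ambiguous — and the same repeat can mediate
recombination that splits the master circle into two smaller rings.
`mitoresolve` is for researchers finishing and describing such genomes. It
resolves the graph with long-read evidence and then runs the standard
characterization battery on the finished molecule:

* **Junction-support resolution** — a read supports the oriented junction
  (X,ox)→(Y,oy) when it aligns head-to-tail across it with ≥ 200 bp on each
  side; among all closed walks satisfying segment copy numbers, the master
  circle maximizes total junction support. Direct-repeat recombinant
  subcircle pairs (lengths summing to the master length) and per-junction
  PCR amplicon templates are derived from the resolved walk.
* **Codon usage** — RSCU(c) = count(c)·|F| / Σ_{c′∈F} count(c′) over the
  synonymous family F, standard genetic code, stop codons as one family.
* **Repeats** — MISA-style SSRs (perfect 1–6 bp motif runs), period-lag
  tandem arrays (period 7–200 bp, > 75 % match), and maximal dispersed
  repeat pairs ≥ 30 bp in forward/palindromic/reverse/complement categories.
* **MTPTs** — chloroplast-derived fragments by BLASTN-style seed-and-extend
  (word size 7, reward +2 / penalty −3, affine gaps 5/2, Karlin–Altschul
  e-values, cutoff 1e-10), with transferred genes classified complete or
  partial by containment in a fragment.
* **C→U RNA editing** — per-CDS pileup of RNA reads; a reference-C column
  is a site when depth ≥ 5, T-frequency ≥ 0.1 and a one-sided exact
  binomial P ≤ 0.05 against a 1 % error null, with codon effects including
  ACG→AUG start-codon gain.

A first-class synthetic-data module generates all of the above with planted
ground truth (graph + reads, repeats, a chloroplast partner, edited RNA
reads), so the whole pipeline is testable end-to-end without downloads.
See `docs/methods.md` for models, parameters, and limitations.

## Worked example

Generate a synthetic dataset and run every stage:

```bash
mitoresolve simulate --seed 3 --outdir sim
mitoresolve all --outdir out --force \
    --gfa sim/graph.gfa --reads sim/reads.fastq \
    --genome sim/genome.fasta --annotations sim/annotations.gff3 \
    --cp-genome sim/cp.fasta --cp-annotations sim/cp_annotations.tsv \
    --rna-reads sim/rna.fastq
```

`out/report.json` then contains (abridged):

```json
{
 "resolve": {
  "junctions": {"ctg1+>repeat+": 15, "ctg1->repeat-": 20,
                "ctg2+>repeat+": 19, "ctg2->repeat-": 17},
  "master_walk": "ctg1+ repeat+ ctg2+ repeat+",
  "conformation_lengths_bp": {"master": 50000,
                              "recombinant_1a": 22000,
                              "recombinant_1b": 28000}
 },
 "repeats": {"ssr_total": 5, "tandem_total": 2, "dispersed_total": 3,
             "dispersed_by_category": {"forward": 2, "palindromic": 1,
                                       "reverse": 0, "complement": 0}},
 "mtpt": {"fragment_count": 2, "total_bp": 1501,
          "fraction_of_mitogenome_percent": 3.0,
          "transferred_genes": {"complete": 3, "partial": 1}},
 "editing": {"site_count": 54,
             "sites_per_gene": {"cox1": 1, "mttB": 52, "rps14": 1},
             "start_gain_sites": 1}
}
```

Reading it: all four junctions of the two-contigs-plus-one-repeat topology
are supported by 15–20 reads each, so the master circle is
ctg1→repeat→ctg2→repeat (50 kb), and recombination across the repeat copies
would yield 22 kb + 28 kb rings. The repeat scans and MTPT/editing blocks
recover exactly the features the simulator planted — including the heavily
edited gene (52 sites), the single-site gene, and the one site that turns a
genomic ACG into a functional AUG start codon. Per-stage TSVs
(`junctions.tsv`, `rscu.tsv`, `ssr.tsv`, `mtpt.tsv`, `editing_sites.tsv`,
…) sit next to the report.

The same subcommands run on real data: a GFA from your assembler plus HiFi
reads for `resolve`; FASTA + GFF3 (or the 5-column TSV dialect) for the
characterization stages; a chloroplast FASTA for `mtpt`; RNA-seq FASTQ for
`editing`.

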