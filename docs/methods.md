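# Methods

`mitoresolve` implements the analysis chain used to turn a draft plant
mitochondrial assembly graph into a finished, characterized circular
genome: long-read junction validation and conformation resolution, codon
usage, repeat content, chloroplast-derived insertions (MTPTs), and C→U RNA
editing. This note records the models behind each stage, the parameters
that matter, what the synthetic data generator does and does not emulate,
and the numerical choices a maintainer would want to know.

## Conformation resolution from junction support

**Model.** The input is an overlap-free unitig graph in which a repeated
segment collapses several genomic copies onto one node. The true genome is
a closed walk through the graph that uses each segment exactly its copy
number of times. Long reads are the arbiter: a read *supports* the oriented
junction (X,ox)→(Y,oy) when it carries an alignment that exits X at the
terminus implied by ox, an alignment that enters Y at its oy-start, with at
most `gap_tol` unaligned read bases between them and at least `min_flank`
aligned bases on each side. A junction and its reverse-complement image are
one object; support is pooled into the lexicographically smaller form.

**Aligner.** The bundled aligner is exact-k-mer seeded (k = 15, query
k-mers sampled every 5 bases), groups seeds per (segment, strand, diagonal)
and scores the maximal ungapped window on that diagonal. It is
substitution-aware only: CCS-grade reads are indel-poor, and keeping the
diagonal fixed makes every reported coordinate exact, which the junction
end-tests rely on. For other read types a pre-computed PAF is accepted
instead.

**Search.** Starting from the longest single-copy segment, a depth-first
search enumerates every closed walk that satisfies the copy-number
constraints using only junctions with support ≥ `min_support` (default 1);
the walk maximizing summed support wins, with ties broken by the smallest
canonical rotation of the walk signature (rotations and the
reverse-complement direction are identified). Exhaustive enumeration is
affordable because organelle graphs have a handful of segments; the search
is exact, not heuristic. If no walk closes, the error lists the
under-supported junctions rather than guessing.

**Copy numbers** come from GFA `dp` depth tags as
round(depth / median depth), overridable per segment. **Recombinants**: for
each pair of same-orientation occurrences of a repeat in the master walk,
the two circles exchanged at those copies are emitted. Their lengths sum to
the master length by construction; they are reported as candidate
conformations, not asserted to coexist. Inverted (opposite-orientation)
occurrence pairs are skipped: recombination there inverts a region instead
of excising a circle. **Amplicons**: each junction's PCR template is the
±1 kb window across the join (wrapping the origin); with primers supplied
the product length is the distance from forward-primer start to
reverse-primer end, and a primer found zero or multiple times flags the
junction non-specific.

Defaults `gap_tol` = 100 bp, `end_tol` = 50 bp, `min_flank` = 200 bp were
chosen to tolerate CCS end noise while excluding alignments that stop short
of a segment terminus; all are exposed as flags.

## Codon usage (RSCU)

Spliced, strand-corrected CDS sequences are decomposed into codons; RSCU of
codon c in synonymous family F is count(c)·|F| / Σ_{c′∈F} count(c′) under
the standard genetic code. Single-codon families (AUG, UGG) are 1 whenever
observed; the three stop codons are treated as one family so termination
preference is reported too. `dedupe=True` (default) counts one
representative per gene name — multi-copy genes inside repeats would
otherwise be double-counted — and a flag restores per-copy counting.
Families with no observations report NA rather than 0. GC content excludes
N from the denominator.

## Repeat scanners

**SSRs** are maximal perfect runs of a 1–6 bp motif with MISA-convention
copy floors (10/6/5/5/5/5 for unit lengths 1–6, configurable). A run whose
unit is itself periodic (AAAAAA as AA×3) is reported once at the smallest
primitive unit; motifs are canonicalized to their smallest rotation.
Circular sequences are scanned with a 600 bp window appended past the
origin; a wrapping run keeps its natural start and an end beyond the
sequence length.

**Tandem repeats** are found by comparing the sequence with itself at every
lag p in 7–200 bp and extracting maximal positive-scoring excursions under
match +2 / mismatch −7 with minimum score 40, then requiring
percent-match > 75, span ≥ 12 bp and ≥ 1.8 copies. The score floor is
load-bearing: without it, windows of ≥75 % lag-agreement short enough to
pass the span floor occur in random sequence at a rate of tens per 10 kb,
so a percent threshold alone cannot give a clean null. The consensus is the
per-column majority over complete copies. Overlapping reports of one locus
at different periods (harmonics) collapse to the best percent-match, then
the smallest period. This is a deliberately simple period-lag detector, not
a full wraparound-DP repeat finder: arrays with copy-length indels are
outside its reach (limitation noted below).

**Dispersed repeats** are maximal repeated pairs ≥ 30 bp in four
categories: forward (sequence vs itself), palindromic (vs reverse
complement), reverse (vs reversal) and complement (vs complementation).
Exact matching is the default contract — seeds of length `min_len` are
looked up in the transformed sequence and extended maximally along the
diagonal, so every reported pair is provably maximal and a brute-force
all-substring oracle can verify the output. Pairs whose two intervals
overlap are self-matches of tandem/SSR structure and are excluded, except
palindromic self-spanning hits (a genuine inverted repeat folds onto
itself). Pairs nested inside a longer same-category pair are suppressed. A
mismatch budget (`max_mismatch`) enables a greedy tolerant mode; it trades
the maximality guarantee for recall and is off by default.

## MTPT detection

Homologous mt↔cp fragments are found BLASTN-style: exact 7-mer seeds on
both strands, X-drop ungapped extension under reward +2 / penalty −3
(endpoints trimmed to the score argmax), then a banded (±12) affine gapped
extension (open 5, extend 2) from each end. A gapped continuation is only
accepted if it improves the score by ≥ 16: affine gaps let chains of short
random flank matches accrete a few points, which would otherwise erode end
accuracy by ~5–10 bp. E-values use Karlin–Altschul statistics with λ solved
numerically for the +2/−3 system (0.625) and K = 0.41, the tabulated
ungapped value; applying ungapped statistics to gapped scores is a stated
approximation and is conservative for the near-identical alignments
organelle transfers produce. Hits overlapping ≥ 50 % on both genomes merge
to the best-scoring representative (both merged and raw counts are
reported); identical mt intervals arising from IR-duplicated cp regions
collapse. The default cutoff is 1e-10. Fragment identity is computed from
the edit distance of the paired substrings (via edlib).

A transferred gene is **complete** when its annotation lies entirely inside
one fragment's cp interval, **partial** when it overlaps by ≥ 1 bp, and
omitted otherwise. The mitogenome fraction uses the union of mt intervals
so overlapping fragments are not double-counted.

## C→U editing calling

RNA reads are aligned to spliced sense-strand CDS references (each read
contributes through its best alignment; antisense alignments are
complement-normalized). A reference-C column is called an editing site when
three cut-offs hold simultaneously: depth ≥ 5, T-frequency ≥ 0.1 (full
column depth as denominator by default; a C+T denominator is a flag), and a
one-sided exact binomial P ≤ 0.05 for the observed T count against a
sequencing-error null of 1 % — the minimal defensible null for
mismatch-based calling. No multiple-testing correction is applied at the
raw-P cut-off; a Benjamini–Hochberg screen is available separately. Codon
effects come from the standard code; `start_gain` marks the ACG→AUG
initiation-codon creation at codon 1.

Power at these thresholds: at depth 50 a site needs ≥ 5 supporting reads,
so miss probability is P[Bin(50, f) ≤ 4] ≈ 1.9 % at frequency f = 0.2 and
< 0.1 % at f ≥ 0.3; the planted-site frequency ladder (0.2–0.9) in the
recovery studies keeps aggregate sensitivity above 99 % while still probing
the threshold region. The false-positive rate is governed by
P[Bin(depth, e/3) ≥ 5] ≈ 3×10⁻⁸ per C column at a 0.5 % error rate.

## Synthetic data generator

The generator is the package's ground-truth instrument. It emulates:

* a circular genome ctg1 + repeat + ctg2 + repeat (defaults 24/4/18 kb →
  50 kb) over i.i.d. background at GC 0.45, with the three-segment,
  four-link assembly graph and depth tags 30/30/60;
* planted PCG/tRNA/rRNA genes with valid ORFs (random codons, no internal
  stops, one two-exon gene, one ACG-start gene, duplicated genes inside the
  repeat), planted SSR/tandem/dispersed repeats with flanking bases forced
  to break accidental extension so truth coordinates are exact;
* CCS-grade reads: truncated-normal lengths (mean 12 kb, sd 2 kb, min
  1 kb), both strands, substitution-only errors (default 0.2 %) so source
  coordinates stay exact; truth junction support counts reads whose
  error-free source interval covers a join with ≥ 200 bp flanks;
* a chloroplast partner (30 kb, GC 0.38) carrying mt-derived fragments at
  specified identities (uniform substitutions), with annotated genes placed
  fully inside fragments (complete) or straddling a boundary (partial),
  plus one 29 bp fragment that documents that truth is not limited to what
  the scanner can recover;
* RNA reads from spliced transcripts extended by 150 bp of genomic UTR on
  each side — without the UTR, coverage collapses at the start codon and a
  start-gain site is undetectable — with per-read Bernoulli editing at the
  planted frequencies and substitution errors at 0.5 %.

Randomness derives from one root seed through fixed per-stage streams, so
identical configs are byte-identical and stages are individually
reproducible. Background segments are scrubbed of accidental SSR/tandem
hits (a base in each offender is mutated, avoiding gene bodies and planted
features) so planted-feature recovery can be asserted exactly.

It does **not** emulate: indel sequencing errors (a flag exists for none of
the analyses that would need it), chimeric reads, nuclear contamination,
quality-score variation, transcript abundance differences between genes,
IR-duplicated chloroplast architecture, or repeat-mediated isoform
mixtures in the read pool. Passing recovery tests therefore demonstrates
correctness of the algorithms under their stated models, not robustness to
every artifact of real sequencing.

## Numerical and degenerate-input choices

* Internal coordinates are 0-based half-open; every file and report is
  1-based inclusive. One pair of helpers performs the conversion.
* GFA links with non-trivial overlaps are rejected, not trimmed.
* Tie-breaks are lexicographic everywhere (canonical junctions, canonical
  walk rotations, sorted outputs), making every pipeline output
  deterministic for a given input.
* Empty inputs are answers, not errors: zero reads → empty FASTQ and
  all-zero support; no fragments → 0 count/0 bp/0.00 %; depth 0 → empty
  pileup. Genuinely contradictory configurations (overlapping planted
  features, editing sites outside a CDS, MTPT identity < 0.7) raise
  configuration errors.
* RSCU of an unobserved family is NA; an all-N sequence has NA GC.
* Reported percentages round to 2 decimals; RSCU to 2 decimals in TSV
  output while full precision is kept in memory.

## Study sizes

The bundled studies use 50 kb genomes at ~20× read depth (85 reads of mean
12 kb), 30 kb chloroplast partners, RNA depth 50, and 5–20 seeded
replicates per property; these sizes were chosen so each property is
measured at comfortable statistical margins (binomial arguments above)
while the whole suite stays interactive. A published-scale run (433,466 bp
with a 5,596 bp repeat) is exercised by the acceptance script to confirm
the generator and summaries behave identically at real organelle sizes.

## Known limitations

* The aligner has no indel rescue; high-indel long reads must come in as
  PAF from an external mapper.
* Tandem detection reports lag-consistent arrays only; arrays whose copies
  differ by indels are missed or fragmented.
* Gapped MTPT statistics reuse ungapped Karlin–Altschul parameters.
* Recombinant enumeration covers direct-repeat excision; inverted-repeat
  isomerization is recognized but not enumerated.
* The editing caller assumes stranded RNA data (antisense alignments are
  normalized, but strand-ambiguous chemistry is not modelled).
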