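# Methods

This note describes the models and procedures implemented in `triobin`, the
parameter defaults and why they were chosen, what the synthetic trio
generator does and does not emulate, and the numerical/design choices made
where the design was genuinely open.

## Trio binning

### k-mer model

All k-mer work uses canonical k-mers: the lexicographic minimum of a window
and its reverse complement over A<C<G<T, which makes counting
strand-independent. k must be odd (an even k admits reverse-complement
palindromes whose canonical form is ambiguous) and 3 ≤ k ≤ 31 so a k-mer
packs into one 64-bit word at 2 bits per base. Any non-ACGT base invalidates
every window containing it; lowercase bases are accepted. The counting
engine streams reads in a single pass, packs windows with a rolling scan
(each base touched once, independent of k) and accumulates counts in a
native hash map, so memory scales with the number of *distinct* k-mers, not
with input bases. The public `KmerSet` behaves as a canonical-k-mer → count
mapping; internally it is a pair of sorted code/count arrays.

### Hap-mer extraction

A k-mer is *specific to parent A* when

- count_A ≥ `min_count` (default 5), and count_A ≤ `max_count` if set, and
- count_B < `min_count`.

`min_count = 5` treats k-mers seen fewer than five times at ~45x parental
coverage as sequencing error; "absent in the other parent" uses the same
floor so that a stray error occurrence in parent B does not disqualify a
genuine A hap-mer. Both thresholds are flags; `max_count` (off by default)
can exclude high-copy repeat k-mers.

### Binning decision rule

Each long read is scored by the number of its canonical k-mer windows that
hit each hap-mer set (occurrences, not distinct hap-mers). The bin is
argmax(score_A, score_B); any tie, including 0–0, is `unknown`. Reads
shorter than k are `unknown` with zero scores. An optional normalisation
mode divides the scores by the hap-mer set sizes before comparing, which
compensates when one parent's set is much larger (e.g. unequal coverage);
it is off by default because raw occurrence counts are the conventional
evidence measure. The counts always conserve: n_A + n_B + n_unknown equals
the number of input reads, and swapping the two parents swaps bins A and B
while leaving `unknown` untouched.

At 0.1168% heterozygosity a 15 kb read spans ~17 heterozygous positions and
so ~350 hap-mer windows in expectation; with low-error reads misassignment
requires the opposite parent's hap-mers to outnumber the true parent's,
which is why error-free simulations bin essentially every read correctly.
The binning accuracy degrades gracefully with shorter reads and lower
heterozygosity (fewer expected hap-mer hits per read).

## Switch detection

Placements of binned reads (from PAF; one placement per read, the record
with the most residue matches, ties to the earliest record) are intersected
with fixed windows tiling each contig (default width 1 Mb; the final window
is truncated, not discarded). Per window and per bin the default statistic
is **breadth**: 100 × (bases covered by the union of that bin's intervals) /
window width — bounded by 100 regardless of depth, matching
bedtools-coverage fraction semantics. A mean-depth mode is available behind
`--mode depth`.

The signed difference Δ = pct_A − pct_B classifies a window to A
(Δ > `min_abs_diff`), B (Δ < −`min_abs_diff`) or tie. `min_abs_diff`
defaults to 0 — any signed difference classifies — and **ties are excluded
from the concordance denominator**: concordance = 100 × (non-tie windows
matching the expected parent) / (non-tie windows). If every window is a tie
the concordance is undefined and reported as NA. Switch blocks are maximal
runs of consecutive same-contig windows classified to the unexpected
parent; their boundaries have window resolution by construction, which is
why recovery of planted blocks is asserted to within ±1 window. When no
expected parent is given (an unbinned assembly), only alternation
statistics (class counts and transitions) are reported. Reads binned
`unknown` are excluded from this analysis; only the two parent bins are
aligned.

## Homology scaffolding and patching

Contigs are placed **whole** — the scaffolder never breaks a contig on a
conflicting alignment, preserving contig integrity; mis-joins are left to
the evidence of later steps rather than cut.

- *Chromosome*: the target with the largest merged query-interval coverage;
  `location_confidence` = best / total coverage; exact ties go to the
  lexicographically smaller name and are flagged low-confidence.
- *Orientation*: the sign of Σ(strand × matches) over the winning
  chromosome's records; zero net mass defaults to "+" at confidence 0.5
  with a low-confidence flag.
- *Order*: coverage-weighted mean of target starts — deterministic and
  robust to split alignments; ties break by contig name.

Alignments are pre-filtered at block length ≥ 1000 and mapq ≥ 10 (the
scaffolding defaults of the reference-guided tools this emulates); scaffold
gaps are 100 N (AGP `U` rows, gap_type `scaffold`, linkage `yes`, evidence
`align_genus`). Scaffolds adopt reference chromosome names; unplaced
contigs pass through unchanged. AGP uses 1-based inclusive coordinates (the
only departure from the package-wide 0-based half-open convention) and
round-trips: parse(write(plan)) == plan, and plan + component sequences
reconstruct the scaffold FASTA byte-identically.

Gap patching fills an N-run when a single donor contig aligns to both gap
flanks (each anchor within `flank` = 50 kb of the gap) on one strand in
collinear order. Anchor pairs are ranked by proximity to the gap, then by
combined alignment length, and edits are kept non-overlapping
(left-to-right); the gap plus any flank overlap implied by the anchor
coordinates is replaced by the intervening donor sequence
(reverse-complemented for minus-strand anchors). Gaps with qualifying
spans from more than one donor are left untouched and logged as conflicts.
Patching can only remove or shrink gaps, never add them.

The workflow driver executes an ordered list of scaffold/patch steps from a
YAML config (each step names query, reference/donor and a PAF; `previous`
chains a step onto the last output), records scaffold/contig N50, N90 and
size after each step, and accepts any externally produced FASTA as a
reference — which is how an optical-map hybrid assembly enters the chain
without this package implementing optical-map merging. When a step lists no
alignments file the driver will call `minimap2 -x asm5` if it is on PATH;
all shipped tests supply alignments explicitly.

## Assembly QC

- **N-statistics**: N50 is the length of the shortest sequence in the
  minimal set of longest sequences covering ≥ 50% of the total; L50 is that
  set's size; N90/L90 analogous. Contigs are scaffolds split at N-runs ≥
  `contig_split_n` (default 10, the common convention distinguishing
  scaffold gaps from ambiguity bases).
- **Gaps**: maximal N-runs ≥ `min_run` (default 1), BED-style 0-based
  half-open.
- **Telomere exploration**: only terminal regions (default 50 kb per end)
  are scanned; for each unit length in [5, 12] tandem arrays (a unit
  repeated ≥ 2 consecutively) are detected via a lag-L self-match scan.
  Units are canonicalised to the lexicographically smallest rotation over
  both strands — telomere repeats are circular-phase and strand ambiguous —
  and non-primitive units (multiples of a shorter period) are discarded so
  a hexamer array is not double-reported as its dodecamer. Candidates rank
  by total tandem copy count.
- **Telomere search**: overlapping occurrences of a unit and its reverse
  complement are counted per window (default 1 kb), assigned by match
  start. Raw counts deliberately include the incidental background any
  i.i.d. sequence produces (a 6-mer matches about once per 4 kb per
  strand); the validation suite therefore calls a window an *array* at
  ≥ 10 copies (60 bp of tandem repeat), a threshold fixed a priori from the
  motif length, and checks that array windows are exclusively terminal.
- **Heterozygosity**: rate = 100 × (SNP positions + indel positions) /
  denominator, an indel counting as one position regardless of length. The
  default denominator is the summed aligned length of the unique alignment
  blocks; a fixed genome size can be supplied instead (the two modes
  bracket the ambiguity in how such rates are conventionally normalised).
- **Dotplot export**: per alignment record ≥ `min_len`, endpoints, strand
  and identity = matches / block length, ready for external plotting.

## The trio simulator

The generator emulates the study design the toolkit targets: two fully
homozygous (double-haploid) parents and their F1, so each parent *is* one
haplotype of the offspring.

- **Ancestor**: i.i.d. bases with GC bias (default 0.38, an AT-rich plant
  genome); default 2 chromosomes × 2.5 Mb (a 5 Mb desk-scale genome), with
  telomere arrays (default TTAGGG × 150, C-rich strand at the left end)
  appended to both ends of every chromosome.
- **Haplotypes**: `snp_rate` and `indel_rate` are the target per-bp rates
  of *haplotype-differing positions*; each variant is applied to exactly
  one haplotype (chosen 50/50), so snp_rate + indel_rate is the expected
  heterozygosity. Defaults 1.0e-3 + 1.68e-4 = 0.1168%. Indel lengths are
  geometric (mean 3 bp, capped at 50); overlapping indels resolve by
  left-to-right application; variants are planted only outside the
  telomere arrays. An indel counts as one heterozygous position, matching
  the QC estimator.
- **Short reads**: 150 bp pairs, FR orientation, insert ~
  Normal(400, 40) bp, uniform starts, substitution errors at 1e-3; pair
  count = coverage × genome / (2 × 150), default 45x.
- **Long reads**: lognormal lengths (mean 15 kb, σ = 0.25), drawn 50/50
  from the two haplotypes and either strand, substitution errors at
  `long_error` (default 1e-3; the validation runs use 0 as their stated
  condition), default 58x. Read descriptions and a truth PAF record the
  exact error-free template coordinates.
- **Fixtures**: mosaic assemblies (alternating haplotype blocks at given
  switch points, truth blocks recorded), genome shredding (Normal fragment
  sizes, optional dropout and random orientation, truth map recorded) and
  truth-derived PAF for fragments and for the donor-to-scaffold alignment
  used by gap patching.

Every operation draws from `numpy` Generators seeded by (config seed,
operation salt), so a fixed config yields byte-identical outputs and
operations are individually reproducible.

### Truth placements and the haplotype-exclusive idealisation

For switch-detection fixtures the simulator emits placements of reads onto
an assembly only where the assembly block at the read's midpoint carries
the read's own haplotype. This is an idealised *haplotype-exclusive*
mapping: it is what makes a phased assembly score exactly 100% concordance
and a mosaic score ≈ 100(1−f). A real aligner also places the opposite
bin's reads (at ~0.1% divergence they align essentially everywhere), and on
real genomes the window-level coverage difference is carried largely by
haplotype-specific insertions and repeat (e.g. LTR) presence/absence
variation — structural features the SNP/small-indel simulator does not
generate. Passing the switch-detection checks therefore validates the
window/classification/concordance machinery, not an end-to-end aligner
pipeline on structurally divergent haplotypes.

### What the simulator does not emulate

No repeat families by default (real pepper-scale genomes are 75–80%
repetitive; an i.i.d. sequence makes nearly every k-mer informative, so
simulated binning accuracy is an upper bound), no long-read indel errors or
chimeras, no optical maps, no GC-coverage bias. Shredded-genome scaffolding
has no repeat-induced ambiguous placements for the same reason.

## Validation scale and numerics

The shipped validation runs use a 5 Mb genome with the study's rates and
coverages (45x short reads ≈ 450 Mb of parental sequence processed); the
acceptance script completes in a few minutes on one CPU. Windows for the
5 Mb switch fixtures are 100 kb (≈ 50 windows, proportionally matching
1 Mb windows on a multi-Gb genome). The heterozygosity grid uses 20 parent
pairs at rates 0.01%–1% on 1 Mb chromosomes, where binomial sampling noise
keeps the mean relative error of the estimator a few percent.

Degenerate inputs: empty read sets produce an empty k-mer set with a
warning; an empty FASTA is an error for statistics; a placement on a contig
absent from the window set is an error; malformed PAF/FASTQ/AGP records
fail with the offending line or record named.

## Known limitations

- Exact canonical k-mer matching only; no inexact matching, so high error
  rates (CLR-like reads) would need larger-scale scoring margins.
- k ≤ 31 (single-word packing). The defaults used anywhere in the toolkit
  are 21 (binning).
- The scaffolder's whole-contig placement cannot fix mis-assembled chimeric
  contigs; conflicts surface as low-confidence flags, not breaks.
- The concordance denominator excludes ties; with sparse coverage many
  windows are ties and the statistic can rest on few windows (the window
  TSV reports `n_tie` so this is visible).
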