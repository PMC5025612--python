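# Methods

## Scope and model

The package compares two unreplicated small-RNA libraries. With one library
per sample there is no dispersion estimate and hence no formal significance
test; the comparison is descriptive, built from three ingredients:

1. **RPM normalisation.** Each unique read's count is divided by its
   library's total clean reads and multiplied by 10⁶. When the total equals
   the sum of counts, RPMs sum to exactly 10⁶ per library.
2. **Pseudocounted fold change.** For a read with RPM values $r_A, r_B$,
   $\mathrm{log_2FC} = \log_2\!\frac{r_A + 0.1}{r_B + 0.1}$. The 0.1 RPM
   pseudocount is applied in RPM units (never to raw counts) and forces
   log₂FC = 0 when both RPMs are 0. The statistic is antisymmetric under
   sample swap.
3. **Categories.** Specificity is decided on raw counts first: a read with
   count 0 in exactly one sample is that sample's *specific* read and is
   never also "regulated" — the four categories (A-specific, B-specific,
   regulated, non-regulated) partition the union of unique reads. Shared
   reads are *regulated* when |log₂FC| ≥ 1, with the threshold inclusive
   (≥, not >). miRNA-table calls use the same rules at the miRNA level
   (specific when one RPM is 0; up/down at log₂FC ≥ +1 / ≤ −1).

## Preprocessing

The 3' adapter is detected at the first read position (scanning from the
read's 5' end) where at least `min_adapter_overlap` (default 10) adapter
bases lie within the read with at most `max_mismatches` (default 1)
mismatches; the adapter may run off the read end, in which case only the
overlapping prefix is scored and must still reach the minimum overlap. The
insert is everything left of that position. Taking the *first* qualifying
position is a deterministic tie-break (common trimmer behaviour); a
`five_prime` mode handles the mirrored protocol by reversing read and
adapter, in which case a boundary-truncated adapter retains its trailing
bases. There is no quality trimming and no maximum insert length; reporting
covers 15–34 nt. Untrimmed reads, inserts < `min_insert_len` (default 15)
and inserts containing non-ACGT characters are dropped, with an accounting
identity (input = untrimmed + too-short + ambiguous + clean) asserted on
every run. Collapsing orders unique reads by descending count then
lexicographic insert.

## Mapping

Matching is exact only — one matching mode keeps the whole artifact
verifiable against a naive substring-search oracle, which the test suite
does exhaustively on ≤ 100 kb genomes. The index seeds on the first k bases
(default k = 15, the minimum insert length) and verifies the full pattern;
minus-strand hits are found by searching the reverse complement and are
reported at plus-strand coordinates. All occurrences are returned — no
best-hit selection; an optional cap truncates deterministically in
(chromosome, position, strand) order. For distribution statistics a
multi-mapped read's count is divided equally among its hits (`fractional`
mode, default); `all` and `unique-only` modes expose the ambiguity. The
conservation profile reports, per foreign genome and read length, the
fraction of unique reads (and of read count) with at least one exact hit;
empty length classes are NA, not 0.

## Annotation

Coordinates are 0-based half-open throughout; only the GFF3 reader/writer
converts. A read's hits are intersected (≥ 1 bp overlap, not containment —
robust to annotation edge noise) with all features; hits on
chloroplast-tagged chromosomes contribute the pseudo-class `chloroplast`.
The highest class present under the precedence

miRNA > rRNA > tRNA > snRNA > snoRNA > chloroplast > repeat > CDS >
UTR5 > UTR3 > intron > gene_up > gene_down > biological_region

is assigned, falling back to `unassigned`. The order is a configurable
package decision: structural RNAs and miRNA outrank everything because
their annotations are short and specific; chloroplast outranks repeat and
genic context because chloroplast-derived reads are tabulated as their own
category. Strand relation is *sense* if any overlapping feature of the
assigned class lies on the hit's strand, *antisense* if all are opposite,
NA for unstranded classes. The siRNA superclass (everything but miRNA and
structural RNA) is derived at reporting time, not stored. Unknown
annotation types map to `biological_region`.

## Distribution summaries

Per read length and sample, relative chromosome frequencies are the
fractional-count weight per chromosome divided by the length's total
weight (sums to 1). The between-sample summary is the mean of **absolute**
log₂ fold changes of these frequencies across chromosomes, with standard
error sd/√n; a signed mean would cancel opposite deviations, hiding
redistribution (a `signed` option exists). Chromosomes with zero frequency
in either sample are excluded from the mean and counted, not pseudocounted.
Spatial profiles bin hit start positions into half-open windows
(default 1 kb for the synthetic genome; purely presentational), normalise
per (length, sample) across all bins genome-wide, then take log₂; empty
bins are NA rather than −∞. Arm splits divide weight at a user-supplied
per-chromosome boundary (no default — centromere positions are
genome-specific inputs).

## Synthetic experiments

The generator emulates the statistical structure this analysis is designed
to detect; its defaults are the package's reference study conditions:

- **Genome**: 7 nuclear chromosomes × 50 kb plus a 12 kb chloroplast
  contig; per chromosome 4 miRNA loci (21 nt), 14 repeat copies (200 bp,
  exactly 2 substitutions from a master element, so pairwise copy identity
  ≥ 98%), 2 tRNA, 1 rRNA, 1 snRNA, 1 snoRNA and 2 genes
  (up/UTR5/CDS/intron/CDS/UTR3/down). Features are placed without overlap
  by rejection sampling (≤ 10⁴ tries). Chromosome 1 carries 2 extra repeat
  copies in its terminal 10%.
- **Reads**: 100,000 per sample; insert lengths 15–26 nt with peaks at
  20/21 and 24. Each (length, class) pool is a set of distinct genomic
  windows; 24-nt reads come exclusively from repeat windows, stratified per
  chromosome into 30 shared + 70 per-sample-specific distinct 24-mers
  (planted specific unique fraction 70/100 = 0.70). 19–20-nt reads are
  mostly chloroplast- and miRNA-derived with 95% of the sampling weight on
  shared windows. Planted effects: a 2.3× 20-nt oversampling in sample B
  on chromosomes 2 and 5; per-locus miRNA fold changes (4× and 0.25×);
  one A-only and one B-only miRNA locus; 80% of 25–26-nt reads from the
  chromosome-1 terminal region. The 3' adapter
  (TGGAATTCTCGGGTGCCAAGG, 21 nt) is appended and the read truncated at 36
  cycles, so every read carries ≥ 10 adapter bases by construction; 1% of
  reads get one base replaced by N. Sequencing error is off by default
  (exact mapping is the contract); a substitution rate exists to
  demonstrate mapping loss.
- **Determinism**: the whole experiment is a pure function of (spec, seed);
  window pools are built once and shared by both samples so
  shared/specific labels are consistent.

What the generator does **not** emulate: realistic repeat taxonomy or
nested families, hairpin secondary structure, quality-score error profiles,
chloroplast insertions in the nuclear genome, GC/ligation bias, and
replicate-level biological variance. Passing tests therefore demonstrate
that the pipeline recovers planted compositional and distributional
structure from idealised reads — not that any particular biological
dataset has that structure.

## Numerical and testing choices

- Expected values in tests come from independent oracles: a brute-force
  all-positions trimmer, naive sliding-window substring search, closed-form
  frequency arithmetic, and the generator's truth tables; property tests
  (hypothesis, derandomised) cover the algebraic identities (accounting,
  normalisation sums, antisymmetry, swap symmetry, idempotence).
- The flagship recovery run uses 2 × 100,000 reads on the 362 kb synthetic
  genome; unit fixtures use 2 × 20,000. At these depths every pool window
  is observed with overwhelming probability, so recovered fractions sit
  within a binomial 95% CI of the planted values computed at the pool
  size (n = 700 distinct 24-mers per sample).
- The 24-nt pool sizes (30 + 2×70 distinct windows per chromosome) are
  sized against the distinct mutation-bearing repeat windows available
  (≥ ~240 per chromosome across seeds at the defaults); an infeasible
  request fails loudly with the available count.
- TSV reports render floats at 6 significant digits; GFF3 round-trips
  reproduce printed coordinates exactly.

## Known limitations

- Exact matching only: any sequencing error unmaps a read; the published
  workflows this mirrors permit mismatched alignment for the initial
  genome-mapping statistics, so mapped-percentage figures are not
  comparable between modes.
- No statistical testing of differential expression (single library per
  sample); the |log₂FC| ≥ 1 rule is a descriptive threshold.
- The precedence hierarchy resolves multi-class overlaps by fiat; a read
  overlapping both a miRNA and a repeat is miRNA by default, and results
  can shift under a different configured order.
- The in-memory k-mer index targets desk-scale genomes (≤ tens of Mb);
  chromosome-scale crop genomes need an external aligner producing
  equivalent exact hits.
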