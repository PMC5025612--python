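# srnacompare

Comparative profiling of small-RNA (sRNA) sequencing libraries from two
samples — e.g. two cultivars of a crop species — without replicates and
without mismatched alignment. The package implements the complete analysis
chain as a library plus numbered analysis drivers:

1. **Preprocessing** — 3' adapter detection (≥ 10 nt of adapter within the
   read, ≤ 1 mismatch), removal of untrimmed/short (< 15 nt)/ambiguous
   reads, and collapsing into unique reads with counts.
2. **Mapping** — exact (zero-mismatch) placement of every unique read on
   both strands of one or more genomes, reporting *all* occurrences.
3. **Annotation** — hierarchical classification of mapped reads into sRNA
   types (miRNA, rRNA, tRNA, snRNA, snoRNA, chloroplast, repeat, genic
   subregions, …) with a configurable precedence order, and class × length
   composition matrices. Reads matching neither miRNA nor structural RNA
   are reported as the derived siRNA superclass.
4. **Comparison** — reads-per-million normalisation
   (RPM = count / total clean reads × 10⁶), the pseudocounted statistic

   log₂FC = log₂((RPM_A + 0.1) / (RPM_B + 0.1)),

   and a per-read-length partition into *sample-specific* (count 0 in the
   other sample), *regulated* (shared, |log₂FC| ≥ 1) and *non-regulated*
   reads; plus up/down/specific calls for miRNA expression tables.
5. **Distribution** — per-chromosome relative frequencies by read length,
   the between-sample mean |log₂FC| of those frequencies, spatial bin
   profiles, and long/short arm splits.
6. **Conservation** — per-length fractions of reads (unique and
   count-weighted) mapping exactly to foreign genomes.

A first-class synthetic-data module generates complete two-sample
experiments (genome, annotation, adaptered FASTQ, per-read truth table)
with planted structure — a bimodal 20/21 + 24 nt length distribution,
repeat-derived 24-nt reads that are 70% cultivar-specific, chloroplast- and
miRNA-derived 19–20-nt reads that are > 90% shared, planted per-locus fold
changes and a planted chromosomal excess — so every stage is testable
end-to-end against known truth.

## Worked example

```python
from srnacompare.simulate import SyntheticSpec, generate_experiment
from srnacompare.pipeline import run_experiment

exp = generate_experiment(SyntheticSpec(), seed=42)   # 2 x 100,000 reads
res = run_experiment(exp)

ps = res.per_sample
print(ps[(ps.length == 24) & (ps.category == "specific")])
```

prints

```
   sample  length  category  unique_fraction  count_fraction
      A        24  specific              0.7        0.703362
      B        24  specific              0.7        0.703045
```

i.e. 70% of each sample's 24-nt unique reads occur in that sample only —
exactly the planted fraction (24-nt reads derive from repeat loci largely
private to each cultivar). The same run gives a 20-nt cultivar-specific
count fraction of ~0.04–0.05 (shared fraction ≈ 0.95, the planted value:
short reads come from chloroplast and miRNA loci common to both samples),
and the chromosome-frequency fold-change summary

```
print(res.fold_by_length.set_index("length").loc[[20, 24]])
```

```
        mean_abs_log2fc        se  n_excluded
length
20             0.505296  0.113282           0
24             0.034807  0.006243           0
```

— the planted 2.3× 20-nt excess on two chromosomes in sample B produces a
large mean |log₂FC| at 20 nt, while the uniformly repeat-derived 24-nt
reads give a near-zero one (a >10-fold contrast between read lengths).

The numbered drivers under `analysis/` run the same stages as a narrative
(`python analysis/01_simulate.py`, …), writing TSV tables under
`results/`. A `srnacompare` command-line tool exposes each stage
(`simulate`, `preprocess`, `map`, `annotate`, `compare`, `distribute`,
`conserve`, `mirna-calls`, `io-validate`) for file-based use.

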