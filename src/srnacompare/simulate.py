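"""Synthetic two-sample small-RNA experiments with known ground truth.

The generator emulates the statistical structure of a plant sRNA library
pair: a bimodal insert-length distribution peaking at 20/21 and 24 nt;
24-nt reads drawn from dispersed near-identical repeat copies with a high
planted cultivar-specific fraction; 19-20-nt reads dominated by chloroplast
and miRNA loci and almost entirely shared; planted per-locus fold changes;
a planted chromosome-level excess of one read length in one cultivar; and a
terminal hotspot for the longest reads. Every emitted read carries a truth
row, so the full pipeline's recovered quantities can be checked against the
planted ones.

Everything is a pure function of (spec, seed).
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import write_annotation_gff3, write_fasta, write_fastq
from .types import (
    AnnotationFeature,
    FeatureClass,
    GenomeSequence,
    RawRead,
    reverse_complement,
)

BASES = np.array(list("ACGT"))
GENIC_CLASSES = {
    FeatureClass.CDS,
    FeatureClass.UTR5,
    FeatureClass.UTR3,
    FeatureClass.INTRON,
    FeatureClass.GENE_UP,
    FeatureClass.GENE_DOWN,
}

_DEFAULT_LENGTH_DIST = {
    15: 0.005,
    16: 0.005,
    17: 0.010,
    18: 0.020,
    19: 0.080,
    20: 0.220,
    21: 0.200,
    22: 0.050,
    23: 0.040,
    24: 0.300,
    25: 0.035,
    26: 0.035,
}

# class mixture of each read length (chloroplast = windows on the
# chloroplast contig; all other keys are FeatureClass values)
_DEFAULT_CLASS_MIX = {
    15: {"tRNA": 0.4, "rRNA": 0.3, "snRNA": 0.15, "snoRNA": 0.15},
    16: {"tRNA": 0.4, "rRNA": 0.3, "snRNA": 0.15, "snoRNA": 0.15},
    17: {"tRNA": 0.4, "rRNA": 0.4, "CDS": 0.2},
    18: {"tRNA": 0.3, "rRNA": 0.3, "CDS": 0.4},
    19: {"chloroplast": 0.5, "miRNA": 0.3, "tRNA": 0.2},
    20: {"chloroplast": 0.6, "miRNA": 0.3, "CDS": 0.1},
    21: {"miRNA": 0.5, "repeat": 0.1, "CDS": 0.2, "tRNA": 0.1, "rRNA": 0.1},
    22: {"CDS": 0.4, "intron": 0.3, "gene_up": 0.15, "gene_down": 0.15},
    23: {"repeat": 0.5, "CDS": 0.3, "UTR3": 0.1, "UTR5": 0.1},
    24: {"repeat": 1.0},
    25: {"repeat": 1.0},
    26: {"repeat": 1.0},
}


@dataclass
class SyntheticSpec:
    """Design of a synthetic two-cultivar experiment.

    The defaults define the package's reference study conditions; tests and
    the acceptance run use them unchanged apart from total_reads.
    """

    n_chromosomes: int = 7
    chrom_length: int = 50_000
    chloroplast_length: int = 12_000
    n_mirna_per_chrom: int = 4
    mirna_length: int = 21
    n_repeat_copies_per_chrom: int = 14
    repeat_length: int = 200
    repeat_mutations_per_copy: int = 2  # keeps pairwise copy identity >= 98%
    n_trna_per_chrom: int = 2
    n_rrna_per_chrom: int = 1
    n_snrna_per_chrom: int = 1
    n_snorna_per_chrom: int = 1
    n_genes_per_chrom: int = 2

    total_reads: int = 100_000
    length_dist: dict = field(default_factory=lambda: dict(_DEFAULT_LENGTH_DIST))
    class_mix: dict = field(default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_CLASS_MIX.items()})

    # specificity plan
    n24_shared_per_chrom: int = 30
    n24_specific_per_chrom: int = 70  # per cultivar
    shared_weight_short: float = 0.95  # count weight on shared loci at 19-20 nt
    generic_specific_windows: int = 4  # per cultivar in generic 80/10/10-ish pools
    generic_pool_size: int = 40

    # planted effects
    excess_chrom_indices: tuple = (1, 4)  # 0-based; 2.3x 20-nt excess in cultivar B
    excess_factor: float = 2.3
    excess_length: int = 20
    mirna_fold_changes: dict = field(
        default_factory=lambda: {"miRNA_chr1_0": 4.0, "miRNA_chr3_0": 0.25}
    )
    mirna_specific: dict = field(
        default_factory=lambda: {"miRNA_chr4_1": "A", "miRNA_chr6_1": "B"}
    )
    hotspot_lengths: tuple = (25, 26)
    hotspot_chrom_index: int = 0
    hotspot_tail_fraction: float = 0.10
    hotspot_weight: float = 0.80

    # library construction
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    read_length: int = 36
    n_spike_fraction: float = 0.01
    error_rate: float = 0.0  # optional substitutions to demonstrate mapping loss
    antisense_fraction: float = 0.2  # genic windows read from the antisense strand

    def __post_init__(self):
        if abs(sum(self.length_dist.values()) - 1.0) > 1e-9:
            raise ValueError("length_dist must sum to 1")
        for L, mix in self.class_mix.items():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"class_mix for length {L} must sum to 1")
        if any(fc <= 0 for fc in self.mirna_fold_changes.values()):
            raise ValueError("planted fold changes must be > 0")
        missing = [
            L for L, p in self.length_dist.items() if p > 0 and L not in self.class_mix
        ]
        if missing:
            raise ValueError(f"lengths {missing} have no class mixture")

    @property
    def planted_specific_fraction_24(self) -> float:
        """Planted per-cultivar specific unique-read fraction at 24 nt."""
        return self.n24_specific_per_chrom / (
            self.n24_specific_per_chrom + self.n24_shared_per_chrom
        )

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chromosomes)]

    @property
    def chloroplast_name(self) -> str:
        return "pltd"


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, n)]


def _place(
    rng: np.random.Generator,
    occupied: list,
    chrom_len: int,
    flen: int,
    lo: int = 0,
    hi: Optional[int] = None,
    max_tries: int = 10_000,
) -> int:
    hi = (chrom_len - flen) if hi is None else hi
    if hi < lo:
        raise ValueError("feature does not fit in the requested region")
    for _ in range(max_tries):
        start = int(rng.integers(lo, hi + 1))
        if all(start + flen <= s or e <= start for s, e in occupied):
            occupied.append((start, start + flen))
            return start
    raise RuntimeError(
        "could not place feature without overlap after "
        f"{max_tries} tries; use longer chromosomes or fewer features"
    )


def generate_genome(
    spec: SyntheticSpec, seed: int
) -> tuple[list[GenomeSequence], list[AnnotationFeature]]:
    """Random genome with planted, non-overlapping features.

    Repeat copies are the master element with exactly
    ``repeat_mutations_per_copy`` substitutions each, so any two copies are
    >= 98% identical at the defaults. Deterministic under a fixed seed.
    """
    rng = np.random.default_rng([int(seed), 3])
    master = _random_seq(rng, spec.repeat_length)
    genome: list[GenomeSequence] = []
    features: list[AnnotationFeature] = []

    for ci, chrom in enumerate(spec.chrom_names):
        seq = _random_seq(rng, spec.chrom_length)
        occupied: list = []

        def add(fclass: FeatureClass, start: int, flen: int, strand: str, idx: int):
            features.append(
                AnnotationFeature(
                    chrom, start, start + flen, strand, fclass,
                    f"{fclass.value}_{chrom}_{idx}",
                )
            )

        # genes: up - UTR5 - CDS - intron - CDS - UTR3 - down, contiguous
        parts = [
            (FeatureClass.GENE_UP, 100),
            (FeatureClass.UTR5, 50),
            (FeatureClass.CDS, 150),
            (FeatureClass.INTRON, 100),
            (FeatureClass.CDS, 150),
            (FeatureClass.UTR3, 60),
            (FeatureClass.GENE_DOWN, 100),
        ]
        block = sum(p[1] for p in parts)
        for gi in range(spec.n_genes_per_chrom):
            start = _place(rng, occupied, spec.chrom_length, block)
            strand = "+" if rng.random() < 0.5 else "-"
            off = start
            for pi, (fclass, flen) in enumerate(parts):
                add(fclass, off, flen, strand, gi * 10 + pi)
                off += flen

        # dispersed repeat copies; chromosome 1 gets 2 extra copies forced
        # into its terminal region (the planted long-read hotspot)
        n_copies = spec.n_repeat_copies_per_chrom
        tail_lo = int(spec.chrom_length * (1 - spec.hotspot_tail_fraction))
        n_tail = 2 if (ci == spec.hotspot_chrom_index and n_copies > 0) else 0
        for ri in range(n_copies + n_tail):
            if ri >= n_copies:
                start = _place(
                    rng, occupied, spec.chrom_length, spec.repeat_length,
                    lo=tail_lo, hi=spec.chrom_length - spec.repeat_length,
                )
            else:
                start = _place(rng, occupied, spec.chrom_length, spec.repeat_length)
            copy = master.copy()
            for p in rng.choice(spec.repeat_length, spec.repeat_mutations_per_copy, replace=False):
                alt = [b for b in "ACGT" if b != copy[p]]
                copy[p] = alt[int(rng.integers(0, 3))]
            seq[start : start + spec.repeat_length] = copy
            add(FeatureClass.REPEAT, start, spec.repeat_length, "+", ri)

        simple = [
            (FeatureClass.MIRNA, spec.mirna_length, spec.n_mirna_per_chrom),
            (FeatureClass.TRNA, 75, spec.n_trna_per_chrom),
            (FeatureClass.RRNA, 160, spec.n_rrna_per_chrom),
            (FeatureClass.SNRNA, 100, spec.n_snrna_per_chrom),
            (FeatureClass.SNORNA, 80, spec.n_snorna_per_chrom),
        ]
        for fclass, flen, n in simple:
            for i in range(n):
                start = _place(rng, occupied, spec.chrom_length, flen)
                strand = "+" if rng.random() < 0.5 else "-"
                add(fclass, start, flen, strand, i)

        genome.append(GenomeSequence(chrom, "".join(seq), "nuclear"))

    # chloroplast contig: one rRNA feature, otherwise background
    cp = _random_seq(rng, spec.chloroplast_length)
    cp_occupied: list = []
    if spec.n_rrna_per_chrom > 0:
        start = _place(rng, cp_occupied, spec.chloroplast_length, 160)
        features.append(
            AnnotationFeature(
                spec.chloroplast_name, start, start + 160, "+",
                FeatureClass.RRNA, f"rRNA_{spec.chloroplast_name}_0",
            )
        )
    genome.append(GenomeSequence(spec.chloroplast_name, "".join(cp), "chloroplast"))
    return genome, features


@dataclass(frozen=True)
class _Window:
    chrom: str
    pos: int
    strand: str  # strand the read is drawn from
    insert: str
    fclass: str  # class label incl. "chloroplast"
    locus: str
    label: str  # shared / A_specific / B_specific


@dataclass
class _LengthPool:
    windows: list
    p_a: np.ndarray
    p_b: np.ndarray


def _unique_windows(
    seqs: dict, feats: Sequence[AnnotationFeature], L: int
) -> list[tuple[str, int, str, str]]:
    """All length-L windows inside the features whose sequence occurs exactly
    once among the candidates (repeat copies make most windows ambiguous)."""
    cand = []
    for f in feats:
        chrom_seq = seqs[f.chrom_id]
        for pos in range(f.start, f.end - L + 1):
            cand.append((f.chrom_id, pos, chrom_seq[pos : pos + L], f.name))
    counts: dict[str, int] = {}
    for _, _, s, _ in cand:
        counts[s] = counts.get(s, 0) + 1
    return [(c, p, s, n) for c, p, s, n in cand if counts[s] == 1]


def build_pools(
    genome: Sequence[GenomeSequence],
    features: Sequence[AnnotationFeature],
    spec: SyntheticSpec,
    seed: int,
) -> dict[int, _LengthPool]:
    """Per read length: the window pool and per-cultivar draw probabilities.

    Pools are a function of (genome, spec, seed) only — both cultivars draw
    from the same pools, so shared/specific labels are consistent.
    """
    rng = np.random.default_rng([int(seed), 7])
    seqs = {g.chrom_id: g.sequence for g in genome}
    by_class: dict[FeatureClass, list[AnnotationFeature]] = {}
    for f in features:
        if f.chrom_id == spec.chloroplast_name:
            continue
        by_class.setdefault(f.feature_class, []).append(f)

    cp_seq = seqs[spec.chloroplast_name]
    cp_feats = [f for f in features if f.chrom_id == spec.chloroplast_name]

    pools: dict[int, _LengthPool] = {}
    seen_inserts: set[str] = set()

    for L, mix in sorted(spec.class_mix.items()):
        if spec.length_dist.get(L, 0.0) == 0.0:
            continue
        windows: list[_Window] = []
        w_a: list[float] = []
        w_b: list[float] = []

        for cls_name, cls_weight in sorted(mix.items()):
            if cls_name == "chloroplast":
                new = _chloroplast_windows(spec, cp_seq, cp_feats, L, rng, seen_inserts)
                _weight_split_short(spec, L, cls_weight, new, windows, w_a, w_b)
            elif cls_name == "miRNA":
                _mirna_windows(
                    spec, seqs, by_class.get(FeatureClass.MIRNA, []), L, rng,
                    cls_weight, windows, w_a, w_b, seen_inserts,
                )
            elif cls_name == "repeat" and L == 24:
                _repeat24_windows(
                    spec, seqs, by_class.get(FeatureClass.REPEAT, []), rng,
                    cls_weight, windows, w_a, w_b, seen_inserts,
                )
            elif cls_name == "repeat" and L in spec.hotspot_lengths:
                _hotspot_windows(
                    spec, seqs, by_class.get(FeatureClass.REPEAT, []), L, rng,
                    cls_weight, windows, w_a, w_b, seen_inserts,
                )
            else:
                fclass = FeatureClass(cls_name)
                cand = _class_candidates(spec, seqs, by_class.get(fclass, []), fclass, L, rng, seen_inserts)
                _weight_split_short(spec, L, cls_weight, cand, windows, w_a, w_b)

        pa = np.array(w_a, dtype=float)
        pb = np.array(w_b, dtype=float)
        pools[L] = _LengthPool(windows, pa / pa.sum(), pb / pb.sum())

    # planted chromosome excess: cultivar B oversamples nuclear windows of
    # the excess length on the designated chromosomes
    Lx = spec.excess_length
    if Lx in pools and spec.excess_factor != 1.0:
        pool = pools[Lx]
        excess_chroms = {spec.chrom_names[i] for i in spec.excess_chrom_indices}
        pb = pool.p_b.copy()
        for i, w in enumerate(pool.windows):
            if w.chrom in excess_chroms:
                pb[i] *= spec.excess_factor
        pool.p_b = pb / pb.sum()
    return pools


def _take(rng, items: list, n: int, what: str):
    if len(items) < n:
        raise ValueError(
            f"synthetic spec infeasible: need {n} {what} windows, only "
            f"{len(items)} distinct candidates available"
        )
    idx = rng.permutation(len(items))[:n]
    return [items[i] for i in idx]


def _register(seen: set, cands: list) -> list:
    out = []
    for c, p, s, name in cands:
        if s not in seen:
            seen.add(s)
            out.append((c, p, s, name))
    return out


def _class_candidates(spec, seqs, feats, fclass, L, rng, seen) -> list[_Window]:
    if fclass == FeatureClass.REPEAT:
        cand = _unique_windows(seqs, feats, L)
    else:
        cand = []
        for f in feats:
            for pos in range(f.start, f.end - L + 1):
                cand.append((f.chrom_id, pos, seqs[f.chrom_id][pos : pos + L], f.name))
    cand = _register(seen, cand)
    if not cand:
        raise ValueError(
            f"read length {L} is incompatible with class {fclass.value}: "
            "no window fits inside any feature"
        )
    n_specific = spec.generic_specific_windows
    n = min(spec.generic_pool_size, len(cand))
    if n < 2 * n_specific + 1:
        n_specific = 0
    chosen = _take(rng, cand, n, fclass.value)
    out = []
    for i, (chrom, pos, seq, name) in enumerate(chosen):
        if i < n_specific:
            label = "A_specific"
        elif i < 2 * n_specific:
            label = "B_specific"
        else:
            label = "shared"
        antisense = fclass in GENIC_CLASSES and rng.random() < spec.antisense_fraction
        strand = "-" if antisense else "+"
        insert = reverse_complement(seq) if strand == "-" else seq
        out.append(_Window(chrom, pos, strand, insert, fclass.value, name, label))
    return out


def _chloroplast_windows(spec, cp_seq, cp_feats, L, rng, seen) -> list[_Window]:
    blocked = [(f.start, f.end) for f in cp_feats]
    cand = []
    for pos in range(0, len(cp_seq) - L + 1):
        if all(pos + L <= s or e <= pos for s, e in blocked):
            cand.append((spec.chloroplast_name, pos, cp_seq[pos : pos + L], "chloroplast"))
    cand = _register(seen, cand)
    n_shared, n_spec = 300, 10
    chosen = _take(rng, cand, n_shared + 2 * n_spec, "chloroplast")
    out = []
    for i, (chrom, pos, seq, name) in enumerate(chosen):
        label = "A_specific" if i < n_spec else "B_specific" if i < 2 * n_spec else "shared"
        out.append(_Window(chrom, pos, "+", seq, "chloroplast", name, label))
    return out


def _weight_split_short(spec, L, cls_weight, wins: list, windows, w_a, w_b):
    """Attach windows with weights; at 19-20 nt shared loci carry
    shared_weight_short of the class weight, specific loci the remainder."""
    shared = [w for w in wins if w.label == "shared"]
    a_spec = [w for w in wins if w.label == "A_specific"]
    b_spec = [w for w in wins if w.label == "B_specific"]
    short = L in (19, 20) and (a_spec or b_spec)
    sw = spec.shared_weight_short if short else None
    for group, in_a, in_b in ((shared, True, True), (a_spec, True, False), (b_spec, False, True)):
        if not group:
            continue
        if sw is not None:
            mass = cls_weight * (sw if group is shared else (1 - sw))
        else:
            # uniform over the windows visible to each cultivar
            mass = None
        for w in group:
            windows.append(w)
            if mass is not None:
                wa = mass / len(group) if in_a else 0.0
                wb = mass / len(group) if in_b else 0.0
            else:
                n_vis_a = len(shared) + len(a_spec)
                n_vis_b = len(shared) + len(b_spec)
                wa = cls_weight / n_vis_a if in_a else 0.0
                wb = cls_weight / n_vis_b if in_b else 0.0
            w_a.append(wa)
            w_b.append(wb)


def _mirna_windows(spec, seqs, feats, L, rng, cls_weight, windows, w_a, w_b, seen):
    if not feats:
        raise ValueError("class mixture requests miRNA but no miRNA loci exist")
    if L > spec.mirna_length:
        raise ValueError(
            f"read length {L} is incompatible with class miRNA: mature "
            f"sequence is only {spec.mirna_length} nt"
        )
    loci_a = [f for f in feats if spec.mirna_specific.get(f.name) != "B"]
    loci_b = [f for f in feats if spec.mirna_specific.get(f.name) != "A"]
    for f in feats:
        side = spec.mirna_specific.get(f.name)
        label = "shared" if side is None else f"{side}_specific"
        fc = spec.mirna_fold_changes.get(f.name, 1.0)
        offsets = list(range(f.end - f.start - L + 1))
        wins = []
        for off in offsets:
            pos = f.start + off
            seq = seqs[f.chrom_id][pos : pos + L]
            if seq in seen:
                continue
            seen.add(seq)
            insert = seq if f.strand != "-" else reverse_complement(seq)
            strand = "+" if f.strand != "-" else "-"
            wins.append(_Window(f.chrom_id, pos, strand, insert, "miRNA", f.name, label))
        if not wins:
            continue
        for w in wins:
            windows.append(w)
            in_a = side != "B"
            in_b = side != "A"
            w_a.append(cls_weight / len(loci_a) / len(wins) if in_a else 0.0)
            w_b.append(cls_weight / len(loci_b) / len(wins) * fc if in_b else 0.0)


def _repeat24_windows(spec, seqs, feats, rng, cls_weight, windows, w_a, w_b, seen):
    """Stratified 24-nt pools: per chromosome, fixed numbers of shared and
    per-cultivar-specific distinct 24-mers, sampled uniformly, so the
    planted specific unique-read fraction is
    n24_specific / (n24_specific + n24_shared) = 0.70 at the defaults."""
    uniq = _register(seen, _unique_windows(seqs, feats, 24))
    by_chrom: dict[str, list] = {}
    for c, p, s, name in uniq:
        by_chrom.setdefault(c, []).append((c, p, s, name))
    n_sh, n_sp = spec.n24_shared_per_chrom, spec.n24_specific_per_chrom
    all_wins = []
    for chrom in spec.chrom_names:
        chosen = _take(rng, by_chrom.get(chrom, []), n_sh + 2 * n_sp, f"24-nt repeat ({chrom})")
        for i, (c, p, s, name) in enumerate(chosen):
            label = (
                "shared" if i < n_sh
                else "A_specific" if i < n_sh + n_sp
                else "B_specific"
            )
            all_wins.append(_Window(c, p, "+", s, "repeat", name, label))
    n_vis = spec.n_chromosomes * (n_sh + n_sp)
    for w in all_wins:
        windows.append(w)
        w_a.append(cls_weight / n_vis if w.label != "B_specific" else 0.0)
        w_b.append(cls_weight / n_vis if w.label != "A_specific" else 0.0)


def _hotspot_windows(spec, seqs, feats, L, rng, cls_weight, windows, w_a, w_b, seen):
    """25-26 nt: most weight on windows in the terminal region of the
    hotspot chromosome; remainder spread over the other chromosomes."""
    uniq = _register(seen, _unique_windows(seqs, feats, L))
    hot_chrom = spec.chrom_names[spec.hotspot_chrom_index]
    tail_lo = int(spec.chrom_length * (1 - spec.hotspot_tail_fraction))
    tail = [x for x in uniq if x[0] == hot_chrom and x[1] >= tail_lo]
    rest = [x for x in uniq if not (x[0] == hot_chrom and x[1] >= tail_lo)]
    n_tail = min(40, len(tail))
    n_rest = min(spec.generic_pool_size, len(rest))
    if n_tail == 0 or n_rest == 0:
        raise ValueError(f"hotspot pool for length {L} is empty")
    for group, mass, n in ((tail, spec.hotspot_weight, n_tail), (rest, 1 - spec.hotspot_weight, n_rest)):
        for c, p, s, name in _take(rng, group, n, f"{L}-nt hotspot"):
            windows.append(_Window(c, p, "+", s, "repeat", name, "shared"))
            w_a.append(cls_weight * mass / n)
            w_b.append(cls_weight * mass / n)


def generate_reads(
    genome: Sequence[GenomeSequence],
    features: Sequence[AnnotationFeature],
    spec: SyntheticSpec,
    cultivar: str,
    seed: int,
    pools: Optional[dict] = None,
) -> tuple[list[RawRead], pd.DataFrame]:
    """Adaptered FASTQ-ready reads plus one truth row per read.

    The insert is the genome window (reverse-complemented for minus-strand
    windows), the 3' adapter is appended and the result truncated at
    ``read_length``; ~1% of reads get one base replaced by N to exercise
    the ambiguity filter.
    """
    if cultivar not in ("A", "B"):
        raise ValueError("cultivar must be 'A' or 'B'")
    if pools is None:
        pools = build_pools(genome, features, spec, seed)
    cidx = 0 if cultivar == "A" else 1
    rng = np.random.default_rng([int(seed), 11, cidx])

    lengths = sorted(L for L in spec.length_dist if spec.length_dist[L] > 0)
    p_len = np.array([spec.length_dist[L] for L in lengths])
    n_per_len = rng.multinomial(spec.total_reads, p_len / p_len.sum())

    inserts: list[str] = []
    rows = []
    i = 0
    for L, nL in zip(lengths, n_per_len):
        pool = pools[L]
        p = pool.p_a if cultivar == "A" else pool.p_b
        counts = rng.multinomial(nL, p)
        for widx in np.nonzero(counts)[0]:
            w = pool.windows[widx]
            for _ in range(int(counts[widx])):
                insert = w.insert
                if spec.error_rate > 0 and rng.random() < spec.error_rate:
                    pos = int(rng.integers(len(insert)))
                    alt = [b for b in "ACGT" if b != insert[pos]]
                    insert = insert[:pos] + alt[int(rng.integers(0, 3))] + insert[pos + 1 :]
                read_id = f"{cultivar}_{i}"
                rows.append(
                    {
                        "read_id": read_id,
                        "cultivar": cultivar,
                        "insert": insert,
                        "length": L,
                        "chrom": w.chrom,
                        "pos": w.pos,
                        "strand": w.strand,
                        "feature_class": w.fclass,
                        "locus": w.locus,
                        "specificity": w.label,
                        "planted_fc": spec.mirna_fold_changes.get(w.locus, 1.0),
                        "n_spiked": False,
                    }
                )
                inserts.append(insert)
                i += 1

    # N-spike a fixed fraction of reads, then assemble the sequencer output
    n_spike = int(spec.n_spike_fraction * len(inserts))
    spiked = set(rng.choice(len(inserts), n_spike, replace=False)) if n_spike else set()
    out: list[RawRead] = []
    for j, insert in enumerate(inserts):
        emitted = insert
        if j in spiked:
            pos = int(rng.integers(len(emitted)))
            emitted = emitted[:pos] + "N" + emitted[pos + 1 :]
            rows[j]["n_spiked"] = True
        seq = (emitted + spec.adapter)[: spec.read_length]
        out.append(RawRead(seq, "I" * len(seq), rows[j]["read_id"]))
    return out, pd.DataFrame(rows)


@dataclass
class Experiment:
    spec: SyntheticSpec
    seed: int
    genome: list
    features: list
    reads_a: list
    reads_b: list
    truth: pd.DataFrame

    @property
    def nuclear_chroms(self) -> list[str]:
        return self.spec.chrom_names

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.genome, outdir / "genome.fa")
        write_annotation_gff3(self.features, outdir / "annotation.gff3")
        write_fastq(self.reads_a, outdir / "cultivarA.fastq.gz")
        write_fastq(self.reads_b, outdir / "cultivarB.fastq.gz")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def generate_experiment(
    spec: Optional[SyntheticSpec] = None, seed: int = 42
) -> Experiment:
    """Genome + annotation + both cultivars' reads + combined truth table."""
    spec = spec if spec is not None else SyntheticSpec()
    genome, features = generate_genome(spec, seed)
    pools = build_pools(genome, features, spec, seed)
    reads_a, truth_a = generate_reads(genome, features, spec, "A", seed, pools=pools)
    reads_b, truth_b = generate_reads(genome, features, spec, "B", seed, pools=pools)
    truth = pd.concat([truth_a, truth_b], ignore_index=True)
    return Experiment(spec, seed, genome, features, reads_a, reads_b, truth)
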