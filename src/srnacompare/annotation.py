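"""Hierarchical classification of mapped reads into small-RNA types.

Every feature class overlapped (>= 1 bp) by any of a read's hits is
collected; hits on chloroplast-tagged chromosomes contribute the pseudo
class ``chloroplast``; the highest-precedence class present is assigned.
The siRNA superclass of the reporting layer is everything not matching
miRNA or structural RNA (rRNA/tRNA/snRNA/snoRNA) and is derived at report
time, never stored.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .types import (
    ALL_CLASS_LABELS,
    CHLOROPLAST,
    UNASSIGNED,
    AnnotationFeature,
    FeatureClass,
    MappingHit,
    UniqueRead,
)

#: default hierarchy: structural RNAs and miRNA outrank chloroplast, which
#: outranks repeats and genic context; biological_region is last resort
#: before unassigned.
DEFAULT_PRECEDENCE = [
    FeatureClass.MIRNA.value,
    FeatureClass.RRNA.value,
    FeatureClass.TRNA.value,
    FeatureClass.SNRNA.value,
    FeatureClass.SNORNA.value,
    CHLOROPLAST,
    FeatureClass.REPEAT.value,
    FeatureClass.CDS.value,
    FeatureClass.UTR5.value,
    FeatureClass.UTR3.value,
    FeatureClass.INTRON.value,
    FeatureClass.GENE_UP.value,
    FeatureClass.GENE_DOWN.value,
    FeatureClass.BIOLOGICAL_REGION.value,
]

STRUCTURAL_CLASSES = {
    FeatureClass.RRNA.value,
    FeatureClass.TRNA.value,
    FeatureClass.SNRNA.value,
    FeatureClass.SNORNA.value,
}


@dataclass
class ClassPrecedence:
    """Ordered class hierarchy; must contain every class exactly once."""

    order: list[str] = field(default_factory=lambda: list(DEFAULT_PRECEDENCE))

    def __post_init__(self):
        expected = set(DEFAULT_PRECEDENCE)
        if set(self.order) != expected or len(self.order) != len(expected):
            missing = expected - set(self.order)
            extra = set(self.order) - expected
            raise ValueError(
                f"precedence must list every class exactly once; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )

    def rank(self, label: str) -> int:
        return self.order.index(label)


@dataclass(frozen=True)
class ReadClassification:
    insert: str
    assigned_class: str  # one of ALL_CLASS_LABELS
    strand_relation: str  # sense / antisense / na


class FeatureIndex:
    """Per-chromosome interval trees plus the chloroplast chromosome set."""

    def __init__(
        self,
        features: Iterable[AnnotationFeature],
        chloroplast_chroms: Iterable[str] = (),
    ):
        self.trees: dict[str, IntervalTree] = {}
        for f in features:
            self.trees.setdefault(f.chrom_id, IntervalTree()).addi(f.start, f.end, f)
        self.chloroplast_chroms = set(chloroplast_chroms)

    def overlapping(self, hit: MappingHit) -> list[AnnotationFeature]:
        tree = self.trees.get(hit.chrom_id)
        if tree is None:
            return []
        return [iv.data for iv in tree.overlap(hit.pos, hit.end)]


def classify_read(
    hits: Sequence[MappingHit],
    index: FeatureIndex,
    precedence: Optional[ClassPrecedence] = None,
) -> ReadClassification:
    """Assign the highest-precedence class overlapped by any hit.

    strand_relation is sense if any overlapping feature of the assigned
    class lies on the same strand as the hit that overlaps it, antisense if
    all such features are opposite-stranded, and na for unstranded classes
    (chloroplast, unassigned, or features without strand).
    """
    if not hits:
        raise ValueError("classify_read requires at least one hit")
    precedence = precedence or ClassPrecedence()
    insert = hits[0].insert

    # (class label, hit strand, feature strand) for every overlap
    overlaps: list[tuple[str, str, str]] = []
    for hit in sorted(hits, key=lambda h: (h.chrom_id, h.pos, h.strand)):
        if hit.chrom_id in index.chloroplast_chroms:
            overlaps.append((CHLOROPLAST, hit.strand, "."))
        for feat in index.overlapping(hit):
            overlaps.append((feat.feature_class.value, hit.strand, feat.strand))

    if not overlaps:
        return ReadClassification(insert, UNASSIGNED, "na")

    present = {label for label, _, _ in overlaps}
    assigned = min(present, key=precedence.rank)

    stranded = [
        (hs, fs) for label, hs, fs in overlaps if label == assigned and fs in "+-"
    ]
    if not stranded:
        relation = "na"
    elif any(hs == fs for hs, fs in stranded):
        relation = "sense"
    else:
        relation = "antisense"
    return ReadClassification(insert, assigned, relation)


def classify_all(
    hits_by_read: Mapping[str, Sequence[MappingHit]],
    index: FeatureIndex,
    precedence: Optional[ClassPrecedence] = None,
) -> dict[str, ReadClassification]:
    """Classify every mapped read (inserts with empty hit lists skipped)."""
    precedence = precedence or ClassPrecedence()
    return {
        insert: classify_read(hits, index, precedence)
        for insert, hits in hits_by_read.items()
        if hits
    }


def composition_by_length(
    classifications: Mapping[str, ReadClassification],
    reads: Sequence[UniqueRead],
    lengths: Sequence[int] = tuple(range(15, 35)),
) -> dict[str, pd.DataFrame]:
    """Class x length percentage matrices (unique and count weighted).

    Each length column sums to 100 over all class labels (including
    unassigned is not applicable here: only classified = mapped reads enter);
    lengths with no classified reads are NA columns.
    """
    counts = {r.insert: r.count for r in reads}
    out = {}
    for weighting in ("unique", "count"):
        mat = pd.DataFrame(0.0, index=ALL_CLASS_LABELS, columns=list(lengths))
        totals = {L: 0.0 for L in lengths}
        for insert, cls in classifications.items():
            L = len(insert)
            if L not in totals:
                continue
            w = 1.0 if weighting == "unique" else float(counts.get(insert, 0))
            mat.loc[cls.assigned_class, L] += w
            totals[L] += w
        for L in lengths:
            if totals[L] > 0:
                mat[L] = 100.0 * mat[L] / totals[L]
            else:
                mat[L] = float("nan")
        out[weighting] = mat
    return out


def sirna_fraction(composition: pd.DataFrame) -> pd.Series:
    """Derived siRNA superclass per length: everything except miRNA and
    structural RNAs (computed at reporting time)."""
    excluded = STRUCTURAL_CLASSES | {FeatureClass.MIRNA.value}
    keep = [c for c in composition.index if c not in excluded]
    return composition.loc[keep].sum(axis=0, skipna=False)
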