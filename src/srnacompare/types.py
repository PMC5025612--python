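"""Shared domain types for the small-RNA comparison pipeline.

Coordinates are 0-based half-open everywhere inside the package; only the
GFF3 reader/writer converts to and from the 1-based closed convention.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

DNA_ALPHABET = frozenset("ACGTN")
CLEAN_ALPHABET = frozenset("ACGT")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FeatureClass(str, Enum):
    """Closed set of annotation feature classes used for read typing."""

    MIRNA = "miRNA"
    RRNA = "rRNA"
    TRNA = "tRNA"
    SNRNA = "snRNA"
    SNORNA = "snoRNA"
    REPEAT = "repeat"
    CDS = "CDS"
    UTR5 = "UTR5"
    UTR3 = "UTR3"
    INTRON = "intron"
    GENE_UP = "gene_up"
    GENE_DOWN = "gene_down"
    BIOLOGICAL_REGION = "biological_region"


#: classification labels = feature classes plus the two labels that do not
#: correspond to an annotated interval: chloroplast (assigned from the
#: source tag of the chromosome a read maps to) and unassigned (no overlap).
CHLOROPLAST = "chloroplast"
UNASSIGNED = "unassigned"

ALL_CLASS_LABELS = [fc.value for fc in FeatureClass] + [CHLOROPLAST, UNASSIGNED]


@dataclass(frozen=True)
class GenomeSequence:
    """One chromosome/contig: uppercase DNA over {A,C,G,T,N}."""

    chrom_id: str
    sequence: str
    source_tag: str = "nuclear"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"{self.chrom_id}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"{self.chrom_id}: sequence contains characters outside "
                f"ACGTN: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AnnotationFeature:
    """A stranded genomic interval with a class label (0-based half-open)."""

    chrom_id: str
    start: int
    end: int
    strand: str
    feature_class: FeatureClass
    name: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"feature {self.name or '?'} on {self.chrom_id}: require "
                f"0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(frozen=True)
class RawRead:
    """Pre-trimming sequencer output; quality is carried, never used."""

    sequence: str
    quality: Optional[str] = None
    read_id: str = ""

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError(f"read {self.read_id}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: quality length {len(self.quality)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class UniqueRead:
    """A distinct insert sequence with its multiplicity in one library."""

    insert: str
    count: int

    def __post_init__(self):
        if "N" in self.insert:
            raise ValueError("unique read insert may not contain N")
        if self.count < 1:
            raise ValueError("unique read count must be >= 1")

    @property
    def length(self) -> int:
        return len(self.insert)


@dataclass(frozen=True)
class MappingHit:
    """A zero-mismatch placement of an insert on a chromosome.

    ``pos`` is the 0-based start on the + strand of the genome; for a hit on
    the minus strand the genome substring equals the reverse complement of
    the insert.
    """

    insert: str
    chrom_id: str
    pos: int
    strand: str

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid hit strand {self.strand!r}")

    @property
    def end(self) -> int:
        return self.pos + len(self.insert)


@dataclass
class TrimParams:
    """Adapter-trimming parameters.

    The detector demands at least ``min_adapter_overlap`` adapter bases
    within the read with at most ``max_mismatches`` mismatches; inserts
    shorter than ``min_insert_len`` or containing ambiguous bases are
    dropped downstream.
    """

    adapter: str
    min_adapter_overlap: int = 10
    max_mismatches: int = 1
    min_insert_len: int = 15
    adapter_end: str = "three_prime"

    def __post_init__(self):
        if len(self.adapter) < 10:
            raise ValueError("adapter must be at least 10 nt")
        if self.min_adapter_overlap > len(self.adapter):
            raise ValueError("min_adapter_overlap exceeds adapter length")
        if self.max_mismatches < 0:
            raise ValueError("max_mismatches must be >= 0")
        if self.min_insert_len < 1:
            raise ValueError("min_insert_len must be >= 1")
        if self.adapter_end not in ("three_prime", "five_prime"):
            raise ValueError("adapter_end must be three_prime or five_prime")


@dataclass
class PreprocessStats:
    """Read accounting: input = untrimmed + too_short + ambiguous + clean."""

    n_input: int = 0
    n_untrimmed: int = 0
    n_too_short: int = 0
    n_ambiguous: int = 0
    n_clean: int = 0
    n_unique: int = 0

    def check(self) -> None:
        total = self.n_untrimmed + self.n_too_short + self.n_ambiguous + self.n_clean
        if total != self.n_input:
            raise AssertionError(
                f"accounting identity violated: {self.n_input} != {total}"
            )
        if self.n_unique > self.n_clean:
            raise AssertionError("more unique reads than clean reads")


class Category(str, Enum):
    """Between-sample category of a unique read."""

    A_SPECIFIC = "A_specific"
    B_SPECIFIC = "B_specific"
    REGULATED = "regulated"
    NON_REGULATED = "non_regulated"


@dataclass(frozen=True)
class ComparisonRecord:
    insert: str
    length: int
    count_a: int
    count_b: int
    rpm_a: float
    rpm_b: float
    log2fc: float
    category: Category


class MirnaCallClass(str, Enum):
    A_SPECIFIC = "A_specific"
    B_SPECIFIC = "B_specific"
    UP_IN_A = "up_in_A"
    DOWN_IN_A = "down_in_A"
    UNCHANGED = "unchanged"


@dataclass(frozen=True)
class MirnaCall:
    mirna_id: str
    rpm_a: float
    rpm_b: float
    log2fc: float
    call: MirnaCallClass
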