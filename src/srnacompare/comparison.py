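"""Between-sample comparison of collapsed read sets.

Counts are normalised to reads per million (RPM = count / total clean reads
x 1e6); differential expression of a read present in both samples is
log2((RPM_A + 0.1) / (RPM_B + 0.1)), the 0.1 RPM pseudocount guarding the
zero case. Categories partition: a read seen in exactly one sample is
sample-specific and never also "regulated"; shared reads are regulated when
|log2 fc| >= 1 (inclusive threshold).
"""
from __future__ import annotations

import math
from collections import Counter
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .types import (
    Category,
    ComparisonRecord,
    MirnaCall,
    MirnaCallClass,
    UniqueRead,
)

DEFAULT_PSEUDOCOUNT = 0.1
DEFAULT_THRESHOLD = 1.0


def rpm_normalize(
    reads: Iterable[UniqueRead], total_clean: int
) -> dict[str, float]:
    """RPM per insert. Sums to 1e6 when total_clean equals the count sum."""
    if total_clean <= 0:
        raise ValueError("total_clean must be > 0")
    return {r.insert: r.count / total_clean * 1e6 for r in reads}


def log2_de(
    rpm_a: float, rpm_b: float, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """Pseudocounted log2 expression ratio; 0 when both RPMs are 0."""
    if rpm_a < 0 or rpm_b < 0:
        raise ValueError("RPM values must be >= 0")
    return math.log2((rpm_a + pseudocount) / (rpm_b + pseudocount))


def categorize(
    count_a: int,
    count_b: int,
    log2fc: float,
    threshold: float = DEFAULT_THRESHOLD,
) -> Category:
    """Specificity on raw counts first; regulation on |log2fc| among shared."""
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be >= 0")
    if count_a == 0 and count_b == 0:
        raise ValueError("read absent from both samples")
    if count_b == 0:
        return Category.A_SPECIFIC
    if count_a == 0:
        return Category.B_SPECIFIC
    return Category.REGULATED if abs(log2fc) >= threshold else Category.NON_REGULATED


def compare_samples(
    reads_a: Sequence[UniqueRead],
    reads_b: Sequence[UniqueRead],
    total_a: Optional[int] = None,
    total_b: Optional[int] = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    threshold: float = DEFAULT_THRESHOLD,
) -> list[ComparisonRecord]:
    """Build one ComparisonRecord per insert in the union of both samples.

    Totals default to each sample's clean-read count (sum of counts).
    """
    counts_a = {r.insert: r.count for r in reads_a}
    counts_b = {r.insert: r.count for r in reads_b}
    total_a = total_a if total_a is not None else sum(counts_a.values())
    total_b = total_b if total_b is not None else sum(counts_b.values())
    if total_a <= 0 or total_b <= 0:
        raise ValueError("sample totals must be > 0")
    records = []
    for insert in sorted(set(counts_a) | set(counts_b)):
        ca = counts_a.get(insert, 0)
        cb = counts_b.get(insert, 0)
        rpm_a = ca / total_a * 1e6
        rpm_b = cb / total_b * 1e6
        fc = log2_de(rpm_a, rpm_b, pseudocount)
        records.append(
            ComparisonRecord(
                insert=insert,
                length=len(insert),
                count_a=ca,
                count_b=cb,
                rpm_a=rpm_a,
                rpm_b=rpm_b,
                log2fc=fc,
                category=categorize(ca, cb, fc, threshold),
            )
        )
    return records


def specificity_summary(records: Sequence[ComparisonRecord]) -> pd.DataFrame:
    """Per-length category fractions over the union of unique reads.

    For each length the four category fractions sum to 1, once weighting
    each unique read equally and once by combined read count.
    """
    rows = []
    for L in sorted({r.length for r in records}):
        of_len = [r for r in records if r.length == L]
        n_unique = len(of_len)
        n_count = sum(r.count_a + r.count_b for r in of_len)
        for weighting, denom in (("unique", n_unique), ("count", n_count)):
            for cat in Category:
                if weighting == "unique":
                    w = sum(1 for r in of_len if r.category == cat)
                else:
                    w = sum(
                        r.count_a + r.count_b for r in of_len if r.category == cat
                    )
                rows.append(
                    {
                        "length": L,
                        "weighting": weighting,
                        "category": cat.value,
                        "fraction": w / denom if denom else math.nan,
                    }
                )
    return pd.DataFrame(rows)


def per_sample_specificity(records: Sequence[ComparisonRecord]) -> pd.DataFrame:
    """Per-sample view: among reads present in a sample (per length), the
    fractions that are that sample's specific, regulated and non-regulated
    reads, for unique reads and for read counts."""
    rows = []
    for sample in ("A", "B"):
        specific = Category.A_SPECIFIC if sample == "A" else Category.B_SPECIFIC
        count_of = (lambda r: r.count_a) if sample == "A" else (lambda r: r.count_b)
        present = [r for r in records if count_of(r) > 0]
        for L in sorted({r.length for r in present}):
            of_len = [r for r in present if r.length == L]
            denom_u = len(of_len)
            denom_c = sum(count_of(r) for r in of_len)
            for cat in (specific, Category.REGULATED, Category.NON_REGULATED):
                label = "specific" if cat == specific else cat.value
                nu = sum(1 for r in of_len if r.category == cat)
                nc = sum(count_of(r) for r in of_len if r.category == cat)
                rows.append(
                    {
                        "sample": sample,
                        "length": L,
                        "category": label,
                        "unique_fraction": nu / denom_u if denom_u else math.nan,
                        "count_fraction": nc / denom_c if denom_c else math.nan,
                    }
                )
    return pd.DataFrame(rows)


def sharing_totals(records: Sequence[ComparisonRecord]) -> dict[str, float]:
    """Shared/specific totals: unique reads and read counts per sample,
    with the specific-count percentages computed from the counts."""
    shared = [r for r in records if r.category in (Category.REGULATED, Category.NON_REGULATED)]
    a_spec = [r for r in records if r.category == Category.A_SPECIFIC]
    b_spec = [r for r in records if r.category == Category.B_SPECIFIC]
    total_count_a = sum(r.count_a for r in records)
    total_count_b = sum(r.count_b for r in records)
    a_spec_count = sum(r.count_a for r in a_spec)
    b_spec_count = sum(r.count_b for r in b_spec)
    return {
        "n_unique_shared": len(shared),
        "n_unique_A_specific": len(a_spec),
        "n_unique_B_specific": len(b_spec),
        "count_A_specific": a_spec_count,
        "count_B_specific": b_spec_count,
        "count_A_shared": sum(r.count_a for r in shared),
        "count_B_shared": sum(r.count_b for r in shared),
        "pct_count_A_specific": 100.0 * a_spec_count / total_count_a if total_count_a else math.nan,
        "pct_count_B_specific": 100.0 * b_spec_count / total_count_b if total_count_b else math.nan,
    }


def mirna_calls(
    table: pd.DataFrame,
    up_threshold: float = 1.0,
    down_threshold: float = -1.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[list[MirnaCall], Counter]:
    """Classify a miRNA expression table (mirna_id, rpm_A, rpm_B).

    A miRNA with RPM 0 in exactly one sample is sample-specific; otherwise
    the pseudocounted log2 ratio is thresholded (>= +1 up in A, <= -1 down
    in A, else unchanged). Returns the calls plus per-class counts.
    """
    if table["mirna_id"].duplicated().any():
        dups = table.loc[table["mirna_id"].duplicated(), "mirna_id"].tolist()
        raise ValueError(f"duplicate mirna_id values: {dups}")
    calls = []
    for row in table.itertuples(index=False):
        rpm_a, rpm_b = float(row.rpm_A), float(row.rpm_B)
        fc = log2_de(rpm_a, rpm_b, pseudocount)
        if rpm_a == 0 and rpm_b > 0:
            call = MirnaCallClass.B_SPECIFIC
        elif rpm_b == 0 and rpm_a > 0:
            call = MirnaCallClass.A_SPECIFIC
        elif fc >= up_threshold:
            call = MirnaCallClass.UP_IN_A
        elif fc <= down_threshold:
            call = MirnaCallClass.DOWN_IN_A
        else:
            call = MirnaCallClass.UNCHANGED
        calls.append(MirnaCall(row.mirna_id, rpm_a, rpm_b, fc, call))
    summary = Counter(c.call.value for c in calls)
    return calls, summary
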