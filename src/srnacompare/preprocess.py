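"""Adapter trimming, insert filtering, and collapsing into unique reads.

The trimming rule: the adapter is detected anywhere in the read provided at
least ``min_adapter_overlap`` adapter bases lie within the read with at most
``max_mismatches`` mismatches; the adapter may run off the read end, in
which case only the overlapping prefix is scored. Untrimmed reads, inserts
shorter than ``min_insert_len`` and inserts with ambiguous bases are
discarded; survivors are collapsed into unique reads with counts.
"""
from __future__ import annotations

from collections import Counter
from typing import Iterable, Iterator, Optional, Union

from .types import CLEAN_ALPHABET, PreprocessStats, RawRead, TrimParams, UniqueRead

#: sentinel returned when no adapter position qualifies
UNTRIMMED = None

KEEP = "keep"
TOO_SHORT = "too_short"
AMBIGUOUS = "ambiguous"


def _qualifies(seq: str, adapter: str, i: int, min_overlap: int, max_mm: int) -> bool:
    """Does the adapter, laid down at read position i, qualify?"""
    overlap = min(len(adapter), len(seq) - i)
    if overlap < min_overlap:
        return False
    mismatches = 0
    for j in range(overlap):
        if seq[i + j] != adapter[j]:
            mismatches += 1
            if mismatches > max_mm:
                return False
    return True


def trim_adapter(read: Union[RawRead, str], params: TrimParams) -> Optional[str]:
    """Return the insert portion of a read, or UNTRIMMED (None).

    Candidate adapter start positions are scanned from the configured end
    inward; the first qualifying position wins. For the (default)
    three-prime adapter the scan runs from the read's 5' end, so the insert
    is everything left of the first qualifying adapter start.
    """
    seq = read.sequence if isinstance(read, RawRead) else read
    adapter = params.adapter
    min_ov = params.min_adapter_overlap
    max_mm = params.max_mismatches

    if params.adapter_end == "five_prime":
        # mirror the read and the adapter; a 5' adapter run is a 3' run in
        # the mirrored coordinate system
        mirrored = trim_adapter(
            seq[::-1],
            TrimParams(
                adapter=adapter[::-1],
                min_adapter_overlap=min_ov,
                max_mismatches=max_mm,
                min_insert_len=params.min_insert_len,
                adapter_end="three_prime",
            ),
        )
        return None if mirrored is None else mirrored[::-1]

    last_start = len(seq) - min_ov
    for i in range(0, last_start + 1):
        if _qualifies(seq, adapter, i, min_ov, max_mm):
            return seq[:i]
    return UNTRIMMED


def filter_insert(insert: str, params: TrimParams) -> str:
    """KEEP, or the drop reason (too_short / ambiguous)."""
    if len(insert) < params.min_insert_len:
        return TOO_SHORT
    if set(insert) - CLEAN_ALPHABET:
        return AMBIGUOUS
    return KEEP


def collapse(inserts: Iterable[str]) -> tuple[list[UniqueRead], int]:
    """Collapse filtered inserts into unique reads with counts.

    Returns the unique reads ordered by descending count then
    lexicographic insert, and the number of input inserts (= sum of counts).
    """
    counter = Counter(inserts)
    n_clean = sum(counter.values())
    unique = [
        UniqueRead(insert, count)
        for insert, count in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return unique, n_clean


def preprocess_reads(
    reads: Iterable[RawRead], params: TrimParams
) -> tuple[list[UniqueRead], PreprocessStats]:
    """Full preprocessing: trim, filter, collapse, with accounting."""
    stats = PreprocessStats()
    clean: Iterator[str] = _clean_inserts(reads, params, stats)
    unique, n_clean = collapse(clean)
    stats.n_clean = n_clean
    stats.n_unique = len(unique)
    stats.check()
    return unique, stats


def _clean_inserts(reads, params, stats) -> Iterator[str]:
    for read in reads:
        stats.n_input += 1
        insert = trim_adapter(read, params)
        if insert is UNTRIMMED:
            stats.n_untrimmed += 1
            continue
        verdict = filter_insert(insert, params)
        if verdict == TOO_SHORT:
            stats.n_too_short += 1
        elif verdict == AMBIGUOUS:
            stats.n_ambiguous += 1
        else:
            yield insert
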