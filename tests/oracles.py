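"""Independent brute-force oracles the implementation is checked against."""
from __future__ import annotations

from typing import Optional

from srnacompare.types import TrimParams, reverse_complement


def brute_force_trim(seq: str, params: TrimParams) -> Optional[str]:
    """Enumerate every adapter start position, count mismatches directly,
    and take the smallest qualifying position (scan from the 5' end)."""
    adapter = params.adapter
    qualifying = []
    for i in range(len(seq) + 1):
        overlap = min(len(adapter), len(seq) - i)
        if overlap < params.min_adapter_overlap:
            continue
        mismatches = sum(
            1 for j in range(overlap) if seq[i + j] != adapter[j]
        )
        if mismatches <= params.max_mismatches:
            qualifying.append(i)
    if not qualifying:
        return None
    return seq[: min(qualifying)]


def naive_exact_hits(pattern: str, sequences: dict[str, str]) -> set[tuple[str, int, str]]:
    """All exact occurrences on both strands by sliding-window search."""
    hits = set()
    for strand, probe in (("+", pattern), ("-", reverse_complement(pattern))):
        for chrom, seq in sequences.items():
            start = 0
            while True:
                pos = seq.find(probe, start)
                if pos == -1:
                    break
                hits.add((chrom, pos, strand))
                start = pos + 1
    return hits


def make_fuzz_reads(rng, n: int, adapter: str) -> list[str]:
    """Reads exercising every trimming branch: clean insert+adapter,
    mutated adapter, truncated adapter, adapter-free, and tiny reads."""
    bases = "ACGT"
    reads = []
    for _ in range(n):
        kind = rng.integers(0, 5)
        insert_len = int(rng.integers(5, 31))
        insert = "".join(bases[i] for i in rng.integers(0, 4, insert_len))
        if kind == 0:  # no adapter at all
            reads.append(insert)
        elif kind == 1:  # full adapter, exact
            reads.append(insert + adapter)
        elif kind == 2:  # truncated adapter (may fall below min overlap)
            keep = int(rng.integers(1, len(adapter) + 1))
            reads.append(insert + adapter[:keep])
        elif kind == 3:  # adapter with 0-3 mismatches
            mutated = list(adapter)
            for _ in range(int(rng.integers(0, 4))):
                p = int(rng.integers(0, len(mutated)))
                mutated[p] = bases[int(rng.integers(0, 4))]
            keep = int(rng.integers(8, len(adapter) + 1))
            reads.append(insert + "".join(mutated)[:keep])
        else:  # pure noise, occasionally shorter than the overlap rule
            total = int(rng.integers(1, 50))
            reads.append("".join(bases[i] for i in rng.integers(0, 4, total)))
    return reads
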