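"""Zero-mismatch placement of unique reads on genomes.

A k-mer seed index (default k = 15, the minimum insert length) supports
exact-occurrence queries for any pattern of length >= k on both strands;
every exact occurrence is reported, with no best-hit selection. The same
machinery produces per-length cross-genome conservation fractions.
"""
from __future__ import annotations

import math
import warnings
from collections import defaultdict
from typing import Iterable, Optional, Sequence

import pandas as pd

from .types import GenomeSequence, MappingHit, UniqueRead, reverse_complement


class KmerIndex:
    """Exact-substring index over a set of chromosomes.

    Seeds on the first k bases of the query, verifies the full pattern
    against the stored sequence. Minus-strand hits are found by searching
    the reverse complement of the query on the plus strand and are reported
    at plus-strand coordinates.
    """

    def __init__(self, genome: Sequence[GenomeSequence], k: int = 15):
        if k < 8:
            warnings.warn(f"k = {k} < 8: seed table may be very large", stacklevel=2)
        self.k = k
        self.sequences = {g.chrom_id: g.sequence for g in genome}
        self.source_tags = {g.chrom_id: g.source_tag for g in genome}
        if len(self.sequences) != len(genome):
            raise ValueError("duplicate chromosome ids in genome")
        self._seeds: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for g in genome:
            seq = g.sequence
            for pos in range(len(seq) - k + 1):
                kmer = seq[pos : pos + k]
                if "N" not in kmer:
                    self._seeds[kmer].append((g.chrom_id, pos))
        self._seeds = dict(self._seeds)

    def find_plus(self, pattern: str) -> list[tuple[str, int]]:
        """All plus-strand exact occurrences of pattern (len >= k)."""
        if len(pattern) < self.k:
            raise ValueError(
                f"pattern length {len(pattern)} < index k = {self.k}"
            )
        out = []
        for chrom, pos in self._seeds.get(pattern[: self.k], ()):
            if self.sequences[chrom][pos : pos + len(pattern)] == pattern:
                out.append((chrom, pos))
        return out


def build_index(genome: Sequence[GenomeSequence], k: int = 15) -> KmerIndex:
    return KmerIndex(genome, k=k)


def map_read(insert: str, index: KmerIndex) -> list[MappingHit]:
    """All exact occurrences of one insert on both strands, sorted."""
    hits = [MappingHit(insert, c, p, "+") for c, p in index.find_plus(insert)]
    rc = reverse_complement(insert)
    hits += [MappingHit(insert, c, p, "-") for c, p in index.find_plus(rc)]
    hits.sort(key=lambda h: (h.chrom_id, h.pos, h.strand))
    return hits


def map_exact(
    reads: Iterable[UniqueRead],
    index: KmerIndex,
    max_hits: Optional[int] = None,
) -> dict[str, list[MappingHit]]:
    """Map every unique read; reads with >= 1 hit are the mapped set.

    Returns insert -> hit list (empty list = unmapped). With ``max_hits``
    the hit list is truncated deterministically in (chrom, pos, strand)
    order.
    """
    result: dict[str, list[MappingHit]] = {}
    for read in reads:
        hits = map_read(read.insert, index)
        if max_hits is not None and len(hits) > max_hits:
            hits = hits[:max_hits]
        result[read.insert] = hits
    return result


def conservation_profile(
    reads: Sequence[UniqueRead],
    genomes: dict[str, Sequence[GenomeSequence]],
    k: Optional[int] = None,
) -> pd.DataFrame:
    """Per (genome, read length): fraction of reads mapping exactly.

    ``mapped_unique_fraction`` counts each distinct insert once;
    ``mapped_count_fraction`` weights by read count. Lengths with no reads
    are reported as NA, not 0.
    """
    lengths = sorted({r.length for r in reads})
    rows = []
    for genome_name, genome in genomes.items():
        kk = k if k is not None else min(lengths) if lengths else 15
        index = build_index(genome, k=kk)
        for L in lengths:
            of_len = [r for r in reads if r.length == L]
            n_unique = len(of_len)
            n_count = sum(r.count for r in of_len)
            if n_unique == 0:
                uf = cf = math.nan
            else:
                mapped = [r for r in of_len if map_read(r.insert, index)]
                uf = len(mapped) / n_unique
                cf = sum(r.count for r in mapped) / n_count
            rows.append(
                {
                    "genome": genome_name,
                    "length": L,
                    "mapped_unique_fraction": uf,
                    "mapped_count_fraction": cf,
                }
            )
    return pd.DataFrame(rows)
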