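"""Chromosome-level and spatially binned read distributions.

Multi-mapped reads are weighted per the count mode: ``fractional`` divides a
read's weight equally among its hits (default), ``all`` gives each hit the
full weight, ``unique-only`` keeps single-hit reads only. All relative
frequency vectors sum to 1 (pre-log) per (length, sample) stratum.
"""
from __future__ import annotations

import math
from collections import defaultdict
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import MappingHit, UniqueRead

COUNT_MODES = ("fractional", "all", "unique-only")


def hit_weights(
    hits_by_read: Mapping[str, Sequence[MappingHit]],
    reads: Sequence[UniqueRead],
    count_mode: str = "fractional",
    unique_weight: bool = False,
) -> list[tuple[MappingHit, int, float]]:
    """Flatten hits to (hit, read length, weight) tuples.

    With ``unique_weight`` each read contributes total weight 1 instead of
    its count (the non-redundant view).
    """
    if count_mode not in COUNT_MODES:
        raise ValueError(f"count_mode must be one of {COUNT_MODES}")
    counts = {r.insert: r.count for r in reads}
    out = []
    for insert, hits in hits_by_read.items():
        if not hits:
            continue
        if count_mode == "unique-only" and len(hits) > 1:
            continue
        base = 1.0 if unique_weight else float(counts.get(insert, 0))
        w = base / len(hits) if count_mode == "fractional" else base
        for hit in hits:
            out.append((hit, len(insert), w))
    return out


def chrom_relative_freq(
    weighted_hits: Sequence[tuple[MappingHit, int, float]],
    length: int,
    chroms: Sequence[str],
) -> pd.Series:
    """Fraction of length-L mapped weight on each chromosome (sums to 1).

    Returns an all-NA vector when no length-L weight is present.
    """
    acc = {c: 0.0 for c in chroms}
    for hit, L, w in weighted_hits:
        if L == length and hit.chrom_id in acc:
            acc[hit.chrom_id] += w
    total = sum(acc.values())
    if total == 0:
        return pd.Series({c: math.nan for c in chroms})
    return pd.Series({c: v / total for c, v in acc.items()})


def chrom_length_profile(
    weighted_hits: Sequence[tuple[MappingHit, int, float]],
    chroms: Sequence[str],
    lengths: Sequence[int],
) -> pd.DataFrame:
    """Relative frequencies, chromosomes x lengths."""
    return pd.DataFrame(
        {L: chrom_relative_freq(weighted_hits, L, chroms) for L in lengths}
    )


def mean_abs_log2fc(
    freqs_a: pd.Series, freqs_b: pd.Series, signed: bool = False
) -> tuple[float, float, int]:
    """Mean (absolute, by default) log2 fold change of B vs A chromosome
    frequencies, with standard error over chromosomes.

    Chromosomes with zero or undefined frequency in either sample are
    excluded and counted. SE is NA with fewer than 2 included chromosomes.
    """
    common = freqs_a.index.intersection(freqs_b.index)
    vals = []
    n_excluded = 0
    for c in common:
        fa, fb = freqs_a[c], freqs_b[c]
        if not (fa > 0) or not (fb > 0):
            n_excluded += 1
            continue
        fc = math.log2(fb / fa)
        vals.append(abs(fc) if not signed else fc)
    if not vals:
        return math.nan, math.nan, n_excluded
    mean = float(np.mean(vals))
    se = float(np.std(vals, ddof=1) / math.sqrt(len(vals))) if len(vals) >= 2 else math.nan
    return mean, se, n_excluded


def mean_abs_log2fc_by_length(
    profile_a: pd.DataFrame,
    profile_b: pd.DataFrame,
    signed: bool = False,
) -> pd.DataFrame:
    """Per read length: mean |log2 fc| between the two samples' chromosome
    frequency vectors, its standard error, and excluded-chromosome count."""
    rows = []
    for L in profile_a.columns:
        if L not in profile_b.columns:
            continue
        mean, se, n_exc = mean_abs_log2fc(profile_a[L], profile_b[L], signed=signed)
        rows.append(
            {"length": L, "mean_abs_log2fc": mean, "se": se, "n_excluded": n_exc}
        )
    return pd.DataFrame(rows)


def spatial_profile(
    weighted_hits: Sequence[tuple[MappingHit, int, float]],
    chrom_lengths: Mapping[str, int],
    bin_size: int,
    lengths: Optional[Sequence[int]] = None,
) -> pd.DataFrame:
    """Binned genome-wide log2 relative frequencies per read length.

    Bins are half-open [i*bin_size, (i+1)*bin_size); a hit belongs to the
    bin containing its start. Frequencies are normalised per read length
    across ALL bins of all chromosomes before the log2; empty bins are NA.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be > 0")
    if lengths is None:
        lengths = sorted({L for _, L, _ in weighted_hits})
    bins = [
        (c, b)
        for c in chrom_lengths
        for b in range(max(1, math.ceil(chrom_lengths[c] / bin_size)))
    ]
    acc: dict[int, dict[tuple[str, int], float]] = {
        L: defaultdict(float) for L in lengths
    }
    for hit, L, w in weighted_hits:
        if L in acc and hit.chrom_id in chrom_lengths:
            acc[L][(hit.chrom_id, hit.pos // bin_size)] += w
    rows = []
    for L in lengths:
        total = sum(acc[L].values())
        for chrom, b in bins:
            w = acc[L].get((chrom, b), 0.0)
            if total > 0 and w > 0:
                log2f = math.log2(w / total)
            else:
                log2f = math.nan
            rows.append(
                {
                    "chrom": chrom,
                    "bin": b,
                    "bin_start": b * bin_size,
                    "length": L,
                    "log2_freq": log2f,
                }
            )
    return pd.DataFrame(rows)


def arm_split(
    weighted_hits: Sequence[tuple[MappingHit, int, float]],
    arm_table: Mapping[str, int],
) -> pd.DataFrame:
    """Split mapped weight at each chromosome's arm boundary.

    Positions before the boundary belong to the short (S) arm. Chromosomes
    missing from the arm table are excluded. Returns per (chrom, arm,
    length) weights plus a genome-wide long/short ratio per length.
    """
    acc: dict[tuple[str, str, int], float] = defaultdict(float)
    for hit, L, w in weighted_hits:
        boundary = arm_table.get(hit.chrom_id)
        if boundary is None:
            continue
        arm = "S" if hit.pos < boundary else "L"
        acc[(hit.chrom_id, arm, L)] += w
    rows = [
        {"chrom": c, "arm": a, "length": L, "weight": w}
        for (c, a, L), w in sorted(acc.items())
    ]
    return pd.DataFrame(rows)


def long_short_ratio(arm_weights: pd.DataFrame) -> pd.Series:
    """Genome-wide long/short arm weight ratio per read length."""
    if arm_weights.empty:
        return pd.Series(dtype=float)
    pivot = arm_weights.groupby(["length", "arm"])["weight"].sum().unstack(fill_value=0.0)
    long_w = pivot.get("L", pd.Series(0.0, index=pivot.index))
    short_w = pivot.get("S", pd.Series(0.0, index=pivot.index))
    return long_w / short_w.replace(0.0, math.nan)
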