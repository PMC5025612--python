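"""End-to-end convenience layer: run the full analysis on an experiment.

Thin composition of the stage modules, shared by the analysis drivers, the
test suite and the acceptance run so all of them measure the same pipeline.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .annotation import ClassPrecedence, FeatureIndex, classify_all, composition_by_length
from .comparison import compare_samples, per_sample_specificity, sharing_totals
from .distribution import chrom_length_profile, hit_weights, mean_abs_log2fc_by_length
from .mapping import build_index, map_exact
from .preprocess import preprocess_reads
from .simulate import Experiment
from .types import PreprocessStats, TrimParams, UniqueRead


@dataclass
class SampleResult:
    unique_reads: list
    stats: PreprocessStats
    hits_by_read: dict


@dataclass
class PipelineResult:
    sample_a: SampleResult
    sample_b: SampleResult
    records: list
    per_sample: pd.DataFrame
    totals: dict
    chrom_profile_a: pd.DataFrame
    chrom_profile_b: pd.DataFrame
    fold_by_length: pd.DataFrame
    composition_a: dict
    composition_b: dict


def run_sample(reads, params: TrimParams, index) -> SampleResult:
    unique, stats = preprocess_reads(reads, params)
    hits = map_exact(unique, index)
    return SampleResult(unique, stats, hits)


def run_experiment(
    exp: Experiment,
    count_mode: str = "fractional",
    lengths: Optional[Sequence[int]] = None,
) -> PipelineResult:
    """Preprocess, map, classify, compare and summarise both cultivars."""
    spec = exp.spec
    params = TrimParams(adapter=spec.adapter)
    index = build_index(exp.genome, k=min(15, params.min_insert_len))
    a = run_sample(exp.reads_a, params, index)
    b = run_sample(exp.reads_b, params, index)

    records = compare_samples(a.unique_reads, b.unique_reads)
    per_sample = per_sample_specificity(records)
    totals = sharing_totals(records)

    if lengths is None:
        lengths = sorted(spec.length_dist)
    findex = FeatureIndex(exp.features, chloroplast_chroms=[spec.chloroplast_name])
    precedence = ClassPrecedence()
    comp_a = composition_by_length(
        classify_all(a.hits_by_read, findex, precedence), a.unique_reads, lengths
    )
    comp_b = composition_by_length(
        classify_all(b.hits_by_read, findex, precedence), b.unique_reads, lengths
    )

    chroms = exp.nuclear_chroms
    wa = hit_weights(a.hits_by_read, a.unique_reads, count_mode=count_mode)
    wb = hit_weights(b.hits_by_read, b.unique_reads, count_mode=count_mode)
    prof_a = chrom_length_profile(wa, chroms, lengths)
    prof_b = chrom_length_profile(wb, chroms, lengths)
    fold = mean_abs_log2fc_by_length(prof_a, prof_b)

    return PipelineResult(
        sample_a=a,
        sample_b=b,
        records=records,
        per_sample=per_sample,
        totals=totals,
        chrom_profile_a=prof_a,
        chrom_profile_b=prof_b,
        fold_by_length=fold,
        composition_a=comp_a,
        composition_b=comp_b,
    )
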