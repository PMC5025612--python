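import math

import numpy as np
import pandas as pd
import pytest

from srnacompare.distribution import (
    arm_split,
    chrom_length_profile,
    chrom_relative_freq,
    hit_weights,
    long_short_ratio,
    mean_abs_log2fc,
    mean_abs_log2fc_by_length,
    spatial_profile,
)
from srnacompare.types import MappingHit, UniqueRead


def wh(chrom, pos, length, weight, strand="+"):
    return (MappingHit("A" * length, chrom, pos, strand), length, weight)


class TestHitWeights:
    def _fixture(self):
        reads = [UniqueRead("A" * 20, 6), UniqueRead("C" * 20, 4)]
        hits = {
            "A" * 20: [
                MappingHit("A" * 20, "c1", 0, "+"),
                MappingHit("A" * 20, "c2", 0, "+"),
                MappingHit("A" * 20, "c2", 50, "+"),
            ],
            "C" * 20: [MappingHit("C" * 20, "c1", 10, "+")],
        }
        return reads, hits

    def test_fractional_divides_count(self):
        reads, hits = self._fixture()
        w = hit_weights(hits, reads, "fractional")
        assert sum(x[2] for x in w) == pytest.approx(10.0)
        assert {x[2] for x in w} == {2.0, 4.0}

    def test_all_multiplies(self):
        reads, hits = self._fixture()
        assert sum(x[2] for x in hit_weights(hits, reads, "all")) == pytest.approx(22.0)

    def test_unique_only_drops_multimappers(self):
        reads, hits = self._fixture()
        w = hit_weights(hits, reads, "unique-only")
        assert [(x[0].chrom_id, x[2]) for x in w] == [("c1", 4.0)]


class TestChromFreq:
    def test_single_chromosome_gets_all(self):
        w = [wh("c1", 0, 20, 3.0), wh("c1", 9, 20, 1.0)]
        freq = chrom_relative_freq(w, 20, ["c1", "c2"])
        assert freq["c1"] == 1.0 and freq["c2"] == 0.0

    def test_absent_length_is_nan(self):
        freq = chrom_relative_freq([wh("c1", 0, 20, 1.0)], 24, ["c1"])
        assert freq.isna().all()

    def test_sums_to_one(self):
        rng = np.random.default_rng(4)
        chroms = [f"c{i}" for i in range(7)]
        w = [
            wh(chroms[int(rng.integers(0, 7))], int(rng.integers(0, 1000)), 24,
               float(rng.integers(1, 5)))
            for _ in range(500)
        ]
        assert chrom_relative_freq(w, 24, chroms).sum() == pytest.approx(1.0)

    def test_uniform_generator_is_flat(self):
        rng = np.random.default_rng(12)
        chroms = [f"c{i}" for i in range(7)]
        w = [wh(chroms[int(i)], 0, 24, 1.0) for i in rng.integers(0, 7, 70_000)]
        freq = chrom_relative_freq(w, 24, chroms)
        assert np.allclose(freq, 1 / 7, atol=0.01)


class TestFoldChange:
    def test_identical_vectors_zero(self):
        f = pd.Series({"c1": 0.4, "c2": 0.6})
        mean, se, n_exc = mean_abs_log2fc(f, f)
        assert mean == 0.0 and se == 0.0 and n_exc == 0

    def test_two_chromosome_closed_form(self):
        # sample A uniform (1/2, 1/2); in B chromosome 1's weight doubles:
        # freqs (2/3, 1/3); |log2 fc| = (log2(4/3), log2(2/3...)) exactly
        fa = pd.Series({"c1": 0.5, "c2": 0.5})
        fb = pd.Series({"c1": 2 / 3, "c2": 1 / 3})
        expected = (math.log2((2 / 3) / 0.5) + abs(math.log2((1 / 3) / 0.5))) / 2
        mean, se, _ = mean_abs_log2fc(fa, fb)
        assert mean == pytest.approx(expected)
        assert mean == pytest.approx((math.log2(4 / 3) + math.log2(3 / 2)) / 2)

    def test_zero_freq_chromosomes_excluded_and_counted(self):
        fa = pd.Series({"c1": 0.5, "c2": 0.5, "c3": 0.0})
        fb = pd.Series({"c1": 0.5, "c2": 0.5, "c3": 0.0})
        _, _, n_exc = mean_abs_log2fc(fa, fb)
        assert n_exc == 1

    def test_se_undefined_below_two(self):
        fa = pd.Series({"c1": 1.0})
        mean, se, _ = mean_abs_log2fc(fa, fa)
        assert mean == 0.0 and math.isnan(se)

    def test_swap_invariance(self):
        fa = pd.Series({"c1": 0.2, "c2": 0.8})
        fb = pd.Series({"c1": 0.7, "c2": 0.3})
        assert mean_abs_log2fc(fa, fb)[0] == pytest.approx(mean_abs_log2fc(fb, fa)[0])

    def test_planted_excess_dominates_uniform_length(self, pipeline_result, experiment):
        """The planted 2.3x 20-nt excess yields a much larger mean |log2 fc|
        than the uniformly distributed 24-nt reads."""
        fold = pipeline_result.fold_by_length.set_index("length")
        Lx = experiment.spec.excess_length
        assert fold.loc[24, "mean_abs_log2fc"] < 0.1
        assert fold.loc[Lx, "mean_abs_log2fc"] > 0.25
        assert fold.loc[Lx, "mean_abs_log2fc"] > 5 * fold.loc[24, "mean_abs_log2fc"]


class TestSpatial:
    def test_single_bin_carries_everything(self):
        w = [wh("c1", 3, 20, 2.0), wh("c1", 7, 20, 1.0)]
        sp = spatial_profile(w, {"c1": 100}, bin_size=100)
        row = sp[(sp.length == 20) & (sp.bin == 0)].iloc[0]
        assert row.log2_freq == pytest.approx(0.0)  # log2(1.0)

    def test_half_open_bin_boundary(self):
        w = [wh("c1", 100, 20, 1.0)]
        sp = spatial_profile(w, {"c1": 300}, bin_size=100).dropna()
        assert list(sp.bin) == [1]

    def test_empty_bins_are_nan(self):
        w = [wh("c1", 0, 20, 1.0)]
        sp = spatial_profile(w, {"c1": 300}, bin_size=100)
        assert sp.log2_freq.isna().sum() == 2

    def test_degenerates_to_chrom_freq_at_full_bin(self, pipeline_result, experiment):
        from srnacompare.distribution import hit_weights

        res = pipeline_result
        w = hit_weights(res.sample_a.hits_by_read, res.sample_a.unique_reads)
        chrom_lengths = {c: experiment.spec.chrom_length for c in experiment.nuclear_chroms}
        w_nuc = [x for x in w if x[0].chrom_id in chrom_lengths]
        sp = spatial_profile(w_nuc, chrom_lengths, bin_size=experiment.spec.chrom_length,
                             lengths=[24])
        freq = chrom_relative_freq(w_nuc, 24, list(chrom_lengths))
        got = sp.set_index("chrom").log2_freq
        for c in chrom_lengths:
            assert got[c] == pytest.approx(math.log2(freq[c]))

    def test_planted_terminal_hotspot(self, pipeline_result, experiment):
        """25-26-nt reads concentrate in the terminal bins of chromosome 1."""
        spec = experiment.spec
        res = pipeline_result
        w = hit_weights(res.sample_a.hits_by_read, res.sample_a.unique_reads)
        chrom_lengths = {c: spec.chrom_length for c in experiment.nuclear_chroms}
        w_nuc = [x for x in w if x[0].chrom_id in chrom_lengths]
        sp = spatial_profile(w_nuc, chrom_lengths, bin_size=spec.chrom_length // 10,
                             lengths=[25, 26])
        for L in (25, 26):
            top = sp[sp.length == L].dropna().sort_values("log2_freq").iloc[-1]
            assert top.chrom == "chr1"
            assert top.bin == 9  # last 10% of the chromosome

    def test_bad_bin_size_rejected(self):
        with pytest.raises(ValueError):
            spatial_profile([], {"c1": 100}, bin_size=0)


class TestArmSplit:
    def test_uniform_midpoint_ratio_near_one(self):
        rng = np.random.default_rng(2)
        w = [wh("c1", int(p), 24, 1.0) for p in rng.integers(0, 10_000, 20_000)]
        ratio = long_short_ratio(arm_split(w, {"c1": 5_000}))
        assert ratio[24] == pytest.approx(1.0, rel=0.05)

    def test_all_past_boundary(self):
        w = [wh("c1", 900, 24, 2.0), wh("c1", 950, 24, 1.0)]
        arms = arm_split(w, {"c1": 500})
        assert set(arms.arm) == {"L"}

    def test_missing_chromosome_excluded(self):
        w = [wh("c1", 10, 24, 1.0), wh("c2", 10, 24, 1.0)]
        arms = arm_split(w, {"c1": 50})
        assert set(arms.chrom) == {"c1"}

    def test_planted_70_30_split_recovered(self):
        rng = np.random.default_rng(31)
        pos = np.where(rng.random(30_000) < 0.7,
                       rng.integers(5_000, 10_000, 30_000),
                       rng.integers(0, 5_000, 30_000))
        w = [wh("c1", int(p), 24, 1.0) for p in pos]
        ratio = long_short_ratio(arm_split(w, {"c1": 5_000}))
        assert ratio[24] == pytest.approx(7 / 3, rel=0.05)
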