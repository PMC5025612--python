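import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnacompare.comparison import (
    categorize,
    compare_samples,
    log2_de,
    mirna_calls,
    per_sample_specificity,
    rpm_normalize,
    sharing_totals,
    specificity_summary,
)
from srnacompare.types import Category, MirnaCallClass, UniqueRead


class TestRpm:
    @pytest.mark.parametrize(
        "count,total,expected", [(50, 1_000_000, 50.0), (3, 2_000_000, 1.5)]
    )
    def test_values(self, count, total, expected):
        rpm = rpm_normalize([UniqueRead("A" * 20, count)], total)
        assert rpm["A" * 20] == pytest.approx(expected)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            rpm_normalize([UniqueRead("A" * 20, 1)], 0)

    @staticmethod
    def _insert(i: int) -> str:
        # distinct 20-mer per index (base-4 encoding)
        out = []
        for _ in range(20):
            out.append("ACGT"[i % 4])
            i //= 4
        return "".join(out)

    @given(st.lists(st.integers(min_value=1, max_value=10_000), min_size=1, max_size=100))
    @settings(max_examples=100, derandomize=True)
    def test_sums_to_one_million(self, counts):
        reads = [UniqueRead(self._insert(i), c) for i, c in enumerate(counts)]
        rpm = rpm_normalize(reads, sum(counts))
        assert sum(rpm.values()) == pytest.approx(1e6, rel=1e-6)


class TestLog2De:
    def test_equal_rpm_is_zero(self):
        assert log2_de(5.0, 5.0) == 0.0

    def test_double_zero_is_zero(self):
        assert log2_de(0.0, 0.0) == 0.0

    def test_pseudocount_arithmetic(self):
        assert log2_de(1.9, 0.9) == pytest.approx(1.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log2_de(-1.0, 2.0)

    @given(
        st.floats(min_value=0, max_value=1e6, allow_nan=False),
        st.floats(min_value=0, max_value=1e6, allow_nan=False),
    )
    @settings(max_examples=200, derandomize=True)
    def test_antisymmetry(self, a, b):
        assert log2_de(a, b) == pytest.approx(-log2_de(b, a), abs=1e-9)


class TestCategorize:
    def test_specific_on_raw_counts(self):
        assert categorize(7, 0, log2fc=5.0) == Category.A_SPECIFIC
        assert categorize(0, 7, log2fc=-5.0) == Category.B_SPECIFIC

    @pytest.mark.parametrize(
        "fc,expected",
        [(1.5, Category.REGULATED), (1.0, Category.REGULATED),
         (0.3, Category.NON_REGULATED), (-1.2, Category.REGULATED)],
    )
    def test_shared_threshold_inclusive(self, fc, expected):
        assert categorize(5, 5, log2fc=fc) == expected

    def test_absent_read_rejected(self):
        with pytest.raises(ValueError):
            categorize(0, 0, log2fc=0.0)

    def test_threshold_monotonicity(self):
        fcs = np.linspace(-3, 3, 61)
        n_reg = [
            sum(categorize(5, 5, fc, threshold=t) == Category.REGULATED for fc in fcs)
            for t in (0.5, 1.0, 1.5, 2.0)
        ]
        assert n_reg == sorted(n_reg, reverse=True)


def _toy_records():
    a = [UniqueRead("A" * 20, 90), UniqueRead("C" * 20, 10), UniqueRead("G" * 24, 5)]
    b = [UniqueRead("A" * 20, 30), UniqueRead("C" * 20, 40), UniqueRead("T" * 24, 8)]
    return compare_samples(a, b)


class TestCompareSamples:
    def test_swap_symmetry(self):
        a = [UniqueRead("A" * 20, 90), UniqueRead("C" * 20, 10), UniqueRead("G" * 24, 5)]
        b = [UniqueRead("A" * 20, 30), UniqueRead("C" * 20, 40), UniqueRead("T" * 24, 8)]
        fwd = {r.insert: r for r in compare_samples(a, b)}
        rev = {r.insert: r for r in compare_samples(b, a)}
        swap = {
            Category.A_SPECIFIC: Category.B_SPECIFIC,
            Category.B_SPECIFIC: Category.A_SPECIFIC,
            Category.REGULATED: Category.REGULATED,
            Category.NON_REGULATED: Category.NON_REGULATED,
        }
        for insert, r in fwd.items():
            assert rev[insert].log2fc == pytest.approx(-r.log2fc)
            assert rev[insert].category == swap[r.category]

    def test_all_shared_equal_is_non_regulated(self):
        a = [UniqueRead("A" * 20, 10), UniqueRead("C" * 21, 4)]
        records = compare_samples(a, a)
        summary = specificity_summary(records)
        nr = summary[summary.category == "non_regulated"]
        assert (nr.fraction == 1.0).all()

    def test_fractions_sum_to_one(self):
        summary = specificity_summary(_toy_records())
        sums = summary.groupby(["length", "weighting"])["fraction"].sum()
        assert np.allclose(sums, 1.0)

    def test_union_accounting(self):
        records = _toy_records()
        totals = sharing_totals(records)
        assert (
            totals["n_unique_shared"]
            + totals["n_unique_A_specific"]
            + totals["n_unique_B_specific"]
            == len(records)
        )
        # per sample, shared + specific counts = sample total
        assert totals["count_A_shared"] + totals["count_A_specific"] == 105
        assert totals["count_B_shared"] + totals["count_B_specific"] == 78

    def test_per_sample_fractions_sum_to_one(self):
        ps = per_sample_specificity(_toy_records())
        for col in ("unique_fraction", "count_fraction"):
            sums = ps.groupby(["sample", "length"])[col].sum()
            assert np.allclose(sums, 1.0)


class TestMirnaCalls:
    def table(self):
        return pd.DataFrame(
            {
                "mirna_id": ["m1", "m2", "m3", "m4", "m5"],
                "rpm_A": [0.0, 4.0, 5.0, 12.0, 1.0],
                "rpm_B": [12.3, 1.9, 5.0, 0.0, 9.0],
            }
        )

    def test_calls(self):
        calls, summary = mirna_calls(self.table())
        by_id = {c.mirna_id: c for c in calls}
        assert by_id["m1"].call == MirnaCallClass.B_SPECIFIC
        assert by_id["m4"].call == MirnaCallClass.A_SPECIFIC
        # log2(4.1/2.0) = 1.036 -> up in A
        assert by_id["m2"].log2fc == pytest.approx(math.log2(4.1 / 2.0))
        assert by_id["m2"].call == MirnaCallClass.UP_IN_A
        assert by_id["m3"].call == MirnaCallClass.UNCHANGED
        assert by_id["m5"].call == MirnaCallClass.DOWN_IN_A
        assert summary["up_in_A"] == 1 and summary["down_in_A"] == 1

    def test_duplicate_id_rejected(self):
        t = self.table()
        t.loc[1, "mirna_id"] = "m1"
        with pytest.raises(ValueError, match="duplicate"):
            mirna_calls(t)


class TestPlantedSpecificityRecovery:
    def test_24nt_specific_and_20nt_shared(self, experiment, pipeline_result):
        """The planted 70% cultivar-specific 24-nt unique fraction and the
        planted >90% shared 20-nt count fraction are recovered."""
        ps = pipeline_result.per_sample
        spec = experiment.spec
        planted = spec.planted_specific_fraction_24
        n_pool = spec.n_chromosomes * (
            spec.n24_shared_per_chrom + spec.n24_specific_per_chrom
        )
        ci = 1.96 * math.sqrt(planted * (1 - planted) / n_pool)
        got = ps[(ps.length == 24) & (ps.category == "specific")]
        for frac in got.unique_fraction:
            assert abs(frac - planted) < ci + 0.02
        shared20 = ps[(ps.length == 20) & (ps.category == "specific")]
        for frac in shared20.count_fraction:
            assert 1 - frac > 0.90
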