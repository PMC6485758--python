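"""Per-position statistics: depths, coverage, allele/indel frequencies,
cohort aggregation and cumulative binning."""

import statistics
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ampliscreen.errors import ConfigError, ValidationError
from ampliscreen.io_formats import PileupColumn, TargetRegion
from ampliscreen.pileup_stats import (
    SampleLibrary,
    alt_allele_freq,
    bin_frequencies,
    cohort_summary,
    coverage,
    indel_freq,
    major_allele_freq,
    mean_depth,
    minor_ref_freq,
    normalized_depth,
    ref_allele_freq,
    strand_bias,
)


def col(ref="A", fwd=None, rev=None, del_span=0, ins=0, chrom="c", pos=1):
    fwd = dict(fwd or {})
    rev = dict(rev or {})
    depth = sum(fwd.values()) + sum(rev.values()) + del_span
    return PileupColumn(
        chrom=chrom, pos=pos, ref_base=ref, fwd_counts=fwd, rev_counts=rev,
        del_span=del_span, ins_anchor=ins, depth=depth,
        ins_seqs=Counter({"A": ins}) if ins else Counter(),
    )


def lib(columns, sample_id="S", genes=None):
    return SampleLibrary(
        sample_id, {(c.chrom, c.pos): c for c in columns}, genes or {}
    )


REGION = [TargetRegion("c", 0, 2, "G", "G_ex1")]  # positions 1..2


class TestDepth:
    def test_mean_depth(self):
        s = lib([col(fwd={"A": 100}, pos=1), col(fwd={"A": 300}, pos=2)])
        assert mean_depth(s) == 200

    def test_missing_positions_count_as_zero(self):
        s = lib([col(fwd={"A": 100}, pos=1)])
        assert mean_depth(s, REGION) == 50

    def test_no_columns_is_error(self):
        with pytest.raises(ConfigError):
            mean_depth(lib([]))

    def test_normalized_depth(self):
        c = col(fwd={"A": 2000})
        assert normalized_depth(c, 2000.0) == 1.0
        with pytest.raises(ConfigError):
            normalized_depth(c, 0.0)

    def test_normalized_depth_mean_is_one(self, small_cohort):
        sample = small_cohort.samples[0]
        regions = small_cohort.panel.regions
        m = mean_depth(sample, regions)
        norm = [
            sample.depth_at(chrom, pos) / m
            for reg in regions
            for chrom, pos in ((reg.chrom, p) for p in reg.positions())
        ]
        assert np.mean(norm) == pytest.approx(1.0, abs=1e-12)


class TestCoverage:
    def test_all_covered(self):
        s = lib([col(fwd={"A": 10}, pos=1), col(fwd={"A": 10}, pos=2)])
        assert coverage(s, REGION, 5) == 1.0
        assert coverage(s, REGION, 0) == 1.0

    def test_empty_regions_error(self):
        with pytest.raises(ConfigError):
            coverage(lib([col()]), [], 10)

    def test_nonincreasing_in_min_depth(self, small_cohort):
        sample = small_cohort.samples[0]
        regions = small_cohort.panel.regions
        grid = [0, 10, 50, 100, 200, 400, 800]
        covs = [coverage(sample, regions, d) for d in grid]
        assert all(a >= b for a, b in zip(covs, covs[1:]))


class TestStrandBias:
    def test_balanced(self):
        assert strand_bias(col(fwd={"A": 10}, rev={"A": 10})) == 0.5

    def test_extreme_bias_boundary(self):
        assert strand_bias(col(fwd={"A": 19}, rev={"A": 1})) == 0.95

    def test_complement_symmetry(self):
        a = strand_bias(col(fwd={"A": 13}, rev={"A": 7}))
        b = strand_bias(col(fwd={"A": 7}, rev={"A": 13}))
        assert a + b == pytest.approx(1.0)

    def test_no_base_calls_undefined(self):
        assert strand_bias(col(del_span=5)) is None


class TestAlleleFrequencies:
    def test_major_allele(self):
        assert major_allele_freq(col(fwd={"A": 950, "G": 50})) == ("A", 0.95)

    def test_major_allele_tie_break(self):
        assert major_allele_freq(col(fwd={"A": 500, "C": 500})) == ("A", 0.5)

    def test_major_allele_undefined(self):
        assert major_allele_freq(col(del_span=3)) is None

    def test_minor_ref_freq(self):
        assert minor_ref_freq(col(fwd={"G": 520, "A": 480})) == pytest.approx(0.48)

    def test_minor_ref_freq_eliminated_below_cutoff(self):
        assert minor_ref_freq(col(fwd={"G": 900, "A": 100})) is None

    def test_minor_ref_freq_single_base_eliminated(self):
        assert minor_ref_freq(col(fwd={"G": 900})) is None

    def test_alt_freq_simple(self):
        c = col(fwd={"A": 1900, "C": 60, "G": 30, "T": 10})
        assert alt_allele_freq(c) == pytest.approx(0.05)

    def test_alt_freq_heterozygote_recalculated(self):
        c = col(fwd={"A": 1000, "C": 950, "G": 40, "T": 10})
        assert alt_allele_freq(c) == pytest.approx(0.025)

    def test_alt_freq_undefined(self):
        assert alt_allele_freq(col(del_span=2)) is None

    @given(
        counts=st.lists(st.integers(0, 5000), min_size=4, max_size=4)
    )
    @settings(deadline=None)
    def test_recalculated_alt_freq_never_exceeds_raw(self, counts):
        if sum(counts) == 0:
            return
        c = col(fwd=dict(zip("ACGT", counts)))
        total = sum(counts)
        raw = (total - max(counts)) / total
        final = alt_allele_freq(c)
        assert 0.0 <= final <= raw + 1e-12

    def test_hemizygous_fraction_recovered_within_3_binomial_sd(self):
        rng = np.random.default_rng(5)
        depth, e = 2000, 0.02
        for _ in range(20):
            alt_n = rng.binomial(depth, e)
            c = col(fwd={"A": depth - alt_n, "G": alt_n})
            _, f = major_allele_freq(c)
            sd = np.sqrt(e * (1 - e) / depth)
            assert abs(f - (1 - e)) <= 3 * sd

    def test_heterozygous_fraction_recovered_within_3_binomial_sd(self):
        rng = np.random.default_rng(6)
        depth = 2000
        for _ in range(20):
            a = rng.binomial(depth, 0.5)
            c = col(fwd={"G": a, "A": depth - a})
            f = minor_ref_freq(c)
            assert f is not None
            sd = np.sqrt(0.25 / depth)
            assert abs(f - 0.5) <= 3 * sd + 1e-9


class TestIndelFreq:
    def test_simple(self):
        c = col(fwd={"A": 1980}, del_span=20, ins=10)
        assert indel_freq(c) == pytest.approx(0.015)

    def test_no_events(self):
        assert indel_freq(col(fwd={"A": 100})) == 0.0

    def test_zero_depth_undefined(self):
        c = PileupColumn("c", 1, "A", {}, {}, depth=0)
        assert indel_freq(c) is None

    def test_called_indel_excluded_from_residual_noise(self):
        # hemizygous deletion: 1900/2000 reads deleted; residual = insertions
        c = col(fwd={"A": 96}, del_span=1900, ins=4)
        assert indel_freq(c) == pytest.approx(4 / 1996)


class TestCohortSummary:
    def _two_samples(self, f1, f2):
        n = 1000
        s1 = lib([col(fwd={"A": n - int(f1 * n), "G": int(f1 * n)}, pos=1)], "S1")
        s2 = lib([col(fwd={"A": n - int(f2 * n), "G": int(f2 * n)}, pos=1)], "S2")
        return [s1, s2]

    def test_mean_of_two(self):
        reg = [TargetRegion("c", 0, 1, "G")]
        df = cohort_summary(self._two_samples(0.02, 0.04), reg)
        assert df.loc[0, "alt_mean"] == pytest.approx(0.03)

    def test_identical_samples_zero_sd(self):
        reg = [TargetRegion("c", 0, 1, "G")]
        df = cohort_summary(self._two_samples(0.03, 0.03), reg)
        assert df.loc[0, "alt_sd"] == 0.0

    def test_requires_two_samples(self):
        with pytest.raises(ConfigError):
            cohort_summary([lib([col()])], REGION)

    def test_matches_brute_force_recomputation(self, small_cohort):
        regions = small_cohort.panel.regions
        df = cohort_summary(small_cohort.samples, regions).set_index(
            ["chrom", "pos"]
        )
        rng = np.random.default_rng(0)
        keys = df.index.to_list()
        picks = rng.choice(len(keys), size=min(100, len(keys)), replace=False)
        for k in picks:
            chrom, pos = keys[int(k)]
            alts = []
            for s in small_cohort.samples:
                c = s.columns.get((chrom, pos))
                if c is None or c.depth == 0:
                    continue
                f = alt_allele_freq(c)
                alts.append(0.0 if f is None else f)
            row = df.loc[(chrom, pos)]
            assert row["alt_mean"] == pytest.approx(
                statistics.fmean(alts), abs=1e-12
            )
            expected_sd = statistics.stdev(alts) if len(alts) > 1 else 0.0
            assert row["alt_sd"] == pytest.approx(expected_sd, abs=1e-12)


class TestBinFrequencies:
    def test_reference_count_table(self):
        # cumulative counts 533 below 1%, then 20 / 9 / 4 / 2 above
        # 1 / 2 / 5 / 10 percent
        freqs = [0.005] * 533 + [0.015] * 11 + [0.03] * 5 + [0.07] * 2 + [0.12] * 2
        t = bin_frequencies(freqs)
        assert t.count_below == 533
        assert t.counts_above == (20, 9, 4, 2)
        assert t.pct_below == 96.0
        assert t.pct_above == (3.6, 1.6, 0.72, 0.36)

    def test_empty_input(self):
        t = bin_frequencies([])
        assert t.count_below == 0
        assert t.counts_above == (0, 0, 0, 0)
        assert t.pct_below == 0.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bin_frequencies([0.5, 1.2])

    @given(
        st.lists(st.floats(0.0, 1.0, allow_nan=False), max_size=300)
    )
    @settings(deadline=None, max_examples=200)
    def test_equals_brute_force_counting(self, freqs):
        t = bin_frequencies(freqs)
        for threshold, count in zip((1, 2, 5, 10), t.counts_above):
            assert count == sum(1 for f in freqs if 100 * f > threshold)
        assert t.count_below == sum(1 for f in freqs if 100 * f <= 1)
        assert t.count_below + t.counts_above[0] == len(freqs)
        assert all(a >= b for a, b in zip(t.counts_above, t.counts_above[1:]))
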