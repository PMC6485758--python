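"""Variant screening: thresholding, multiallelic splitting, population
filter, annotation and homopolymer/strand-bias flags."""

from collections import Counter

import pytest

from ampliscreen.errors import ConfigError
from ampliscreen.io_formats import (
    MutationDatabase,
    MutationRecord,
    PileupColumn,
    PopulationFrequencies,
    PopulationFrequencyRecord,
)
from ampliscreen.pileup_stats import SampleLibrary
from ampliscreen.variant_screen import (
    HOMOPOLYMER_FLAG,
    POP_FREQ_FAIL,
    STRAND_BIAS_FLAG,
    VariantCall,
    annotate_calls,
    call_variants,
    flag_homopolymer,
    flag_strand_bias,
    population_filter,
    split_multiallelic,
)


def col(pos, ref="A", fwd=None, rev=None, del_span=0, ins=0, ins_seq="T",
        chrom="c"):
    fwd = dict(fwd or {})
    rev = dict(rev or {})
    depth = sum(fwd.values()) + sum(rev.values()) + del_span
    return PileupColumn(
        chrom=chrom, pos=pos, ref_base=ref, fwd_counts=fwd, rev_counts=rev,
        del_span=del_span, ins_anchor=ins, depth=depth,
        ins_seqs=Counter({ins_seq: ins}) if ins else Counter(),
    )


def lib(*columns):
    return SampleLibrary("S", {(c.chrom, c.pos): c for c in columns})


def mkcall(pos=5, alt="G", freq=0.5, sb=0.5, **kw):
    defaults = dict(
        sample_id="S", chrom="c", pos=pos, ref="A", alt=alt, freq=freq,
        depth=1000, strand_bias=sb,
    )
    defaults.update(kw)
    return VariantCall(**defaults)


class TestCallVariants:
    def test_threshold_is_inclusive(self):
        called = call_variants(lib(col(1, fwd={"A": 74, "G": 26})))
        assert [(c.alt, c.freq) for c in called] == [("G", 0.26)]

    def test_below_threshold_not_called(self):
        assert call_variants(lib(col(1, fwd={"A": 76, "G": 24}))) == []

    def test_threshold_validation(self):
        with pytest.raises(ConfigError):
            call_variants(lib(col(1)), threshold=0.0)

    def test_hemizygous_substitution_near_one(self):
        (c,) = call_variants(lib(col(1, fwd={"G": 980, "A": 20})))
        assert c.alt == "G" and c.freq == pytest.approx(0.98)

    def test_insertion_call_uses_consensus_sequence(self):
        (c,) = call_variants(lib(col(1, fwd={"A": 100}, ins=50, ins_seq="TT")))
        assert c.alt == "+TT"
        assert c.freq == pytest.approx(0.5)
        assert c.is_indel

    def test_consecutive_deleted_positions_merge_into_one_call(self):
        cols = [
            col(p, ref=r, fwd={r: 50}, del_span=50)
            for p, r in [(10, "A"), (11, "C"), (12, "G")]
        ]
        cols.append(col(20, ref="T", fwd={"T": 60}, del_span=40))
        calls = call_variants(lib(*cols))
        dels = sorted((c for c in calls if c.alt.startswith("-")),
                      key=lambda c: c.pos)
        assert [(c.pos, c.alt) for c in dels] == [(10, "-ACG"), (20, "-T")]


class TestSplitMultiallelic:
    def test_split_and_idempotence(self):
        calls = [mkcall(alt="A,G")]
        split = split_multiallelic(calls)
        assert sorted(c.alt for c in split) == ["A", "G"]
        assert split_multiallelic(split) == split

    def test_pair_count_conserved(self):
        calls = [mkcall(alt="A,G"), mkcall(pos=9, alt="T")]
        split = split_multiallelic(calls)
        assert len({(c.pos, c.alt) for c in split}) == 3


class TestPopulationFilter:
    def _freqs(self, af):
        return PopulationFrequencies(
            [PopulationFrequencyRecord("c", 5, "A", "G", af)]
        )

    def test_common_variant_flagged_not_dropped(self):
        (c,) = population_filter([mkcall()], self._freqs(0.05))
        assert POP_FREQ_FAIL in c.filters
        assert c.pop_af == pytest.approx(0.05)

    def test_rare_variant_passes(self):
        (c,) = population_filter([mkcall()], self._freqs(0.009))
        assert POP_FREQ_FAIL not in c.filters

    def test_unknown_variant_passes(self):
        (c,) = population_filter([mkcall(pos=99)], self._freqs(0.5))
        assert c.pop_af is None
        assert POP_FREQ_FAIL not in c.filters


class TestAnnotateCalls:
    DB = MutationDatabase(
        [
            MutationRecord("c", 5, "A", "G", "c.1135C>T", "Nonsense",
                           "Mild-Severe", 65),
            MutationRecord("c", 5, "A", "T", "c.1135C>A", "Missense", "", 2),
        ]
    )

    def test_exact_match(self):
        (c,) = annotate_calls([mkcall()], self.DB)
        assert c.annotation_confidence == "exact"
        assert c.annotations[0].n_reports == 65

    def test_position_only_match(self):
        (c,) = annotate_calls([mkcall(alt="C")], self.DB)
        assert c.annotation_confidence == "position-only"
        assert len(c.annotations) == 2

    def test_unlisted_position_unannotated(self):
        (c,) = annotate_calls([mkcall(pos=42)], self.DB)
        assert c.annotations == ()
        assert c.annotation_confidence is None

    def test_annotation_never_changes_quality_fields(self):
        before = mkcall()
        (after,) = annotate_calls([before], self.DB)
        assert (after.freq, after.depth, after.strand_bias) == (
            before.freq, before.depth, before.strand_bias,
        )


class TestFlagHomopolymer:
    REF = {"c": "ACGAC" + "T" * 9 + "GACGA" + "T" * 5 + "CGACG"}

    def test_insertion_inside_long_run_flagged(self):
        (c,) = flag_homopolymer([mkcall(pos=10, alt="+T")], self.REF)
        assert HOMOPOLYMER_FLAG in c.filters

    def test_indel_adjacent_to_run_flagged(self):
        (c,) = flag_homopolymer([mkcall(pos=5, alt="+T")], self.REF)
        assert HOMOPOLYMER_FLAG in c.filters

    def test_substitution_in_run_not_flagged(self):
        (c,) = flag_homopolymer([mkcall(pos=10, alt="G")], self.REF)
        assert HOMOPOLYMER_FLAG not in c.filters

    def test_short_run_not_flagged(self):
        (c,) = flag_homopolymer([mkcall(pos=22, alt="+T")], self.REF)
        assert HOMOPOLYMER_FLAG not in c.filters

    def test_uncovered_reference_is_error(self):
        with pytest.raises(ConfigError):
            flag_homopolymer([mkcall(pos=10_000, alt="+T")], self.REF)


class TestFlagStrandBias:
    @pytest.mark.parametrize(
        "sb,flagged", [(0.96, True), (0.04, True), (0.95, False),
                       (0.5, False), (None, False)]
    )
    def test_limits(self, sb, flagged):
        (c,) = flag_strand_bias([mkcall(sb=sb)])
        assert (STRAND_BIAS_FLAG in c.filters) is flagged


def test_population_filter_and_homopolymer_flag_commute():
    freqs = PopulationFrequencies(
        [PopulationFrequencyRecord("c", 10, "A", "+T", 0.2)]
    )
    ref = TestFlagHomopolymer.REF
    calls = [mkcall(pos=10, alt="+T"), mkcall(pos=3, alt="G")]
    ab = flag_homopolymer(population_filter(calls, freqs), ref)
    ba = population_filter(flag_homopolymer(calls, ref), freqs)
    assert [(c.pos, c.alt, sorted(c.filters), c.pop_af) for c in ab] == [
        (c.pos, c.alt, sorted(c.filters), c.pop_af) for c in ba
    ]
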