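"""Simulator: panel structure, determinism, truth/emission consistency
and the frozen 24-patient scenario."""

import numpy as np
import pytest

from ampliscreen.io_formats import (
    format_pileup_column,
    parse_pileup_column,
    read_bed,
)
from ampliscreen.synthetic_cohort import (
    SimulationConfig,
    paper_scenario,
    simulate_cohort,
    simulate_panel,
    small_config,
    write_cohort,
)


class TestPanel:
    def test_default_panel_has_123_amplicons(self):
        rng = np.random.default_rng(0)
        panel = simulate_panel(SimulationConfig(), rng)
        assert len(panel.amplicons) == 123

    def test_every_targeted_base_covered_by_an_amplicon(self):
        rng = np.random.default_rng(0)
        panel = simulate_panel(small_config(0), rng)
        covered = set()
        for a in panel.amplicons:
            covered.update((a.chrom, p) for p in a.positions())
        targeted = {
            (reg.chrom, p) for reg in panel.regions for p in reg.positions()
        }
        assert targeted <= covered
        assert panel.dropout_amplicons  # the designated low-yield amplicon

    def test_poly_t_stretch_embedded_per_gene(self):
        rng = np.random.default_rng(3)
        panel = simulate_panel(SimulationConfig(), rng)
        for gene in ("F8", "F9", "VWF"):
            chrom, start, length = panel.polyT[gene]
            assert length == 9
            assert panel.reference[chrom][start : start + length] == "T" * 9
            # exact length: neighbours differ
            assert panel.reference[chrom][start - 1] != "T"
            assert panel.reference[chrom][start + length] != "T"

    def test_same_seed_identical_panel(self):
        p1 = simulate_panel(small_config(5), np.random.default_rng(5))
        p2 = simulate_panel(small_config(5), np.random.default_rng(5))
        assert p1.reference == p2.reference
        assert p1.amplicons == p2.amplicons


class TestCohortDeterminism:
    def test_same_seed_byte_identical_pileups_and_truth(self):
        a = simulate_cohort(small_config(11))
        b = simulate_cohort(small_config(11))
        for sa, sb in zip(a.samples, b.samples):
            ka, kb = sorted(sa.columns), sorted(sb.columns)
            assert ka == kb
            for k in ka:
                assert format_pileup_column(sa.columns[k]) == \
                    format_pileup_column(sb.columns[k])
        assert a.truth.variants == b.truth.variants
        assert a.truth.genotypes == b.truth.genotypes

    def test_different_seeds_differ(self):
        a = simulate_cohort(small_config(1))
        b = simulate_cohort(small_config(2))
        assert a.panel.reference != b.panel.reference


class TestEmissionConsistency:
    def test_emitted_pileup_reparses_to_exact_truth_counts(self, small_cohort):
        sample = small_cohort.samples[0]
        for key in sorted(sample.columns):
            col = sample.columns[key]
            back = parse_pileup_column(format_pileup_column(col))
            assert back.fwd_counts == col.fwd_counts
            assert back.rev_counts == col.rev_counts
            assert back.del_span == col.del_span
            assert back.ins_anchor == col.ins_anchor
            assert back.depth == col.depth

    def test_written_cohort_loads_back(self, small_cohort, tmp_path):
        paths = write_cohort(small_cohort, tmp_path / "out")
        regions = read_bed(paths["targets"])
        assert {r.gene for r in regions} == {"F8", "F9", "VWF"}
        pileups = sorted((paths["pileups"]).glob("*.mpileup"))
        assert len(pileups) == len(small_cohort.samples)
        cols = [parse_pileup_column(l) for l in
                pileups[0].read_text().splitlines()]
        assert len(cols) == len(small_cohort.samples[0].columns)


class TestSampleRegimes:
    def test_hemizygous_gene_ref_fraction_near_one(self, small_cohort):
        panel = small_cohort.panel
        sample = small_cohort.samples[0]
        sl = panel.gene_slices["F9"]
        fracs = []
        for i in range(sl.start, sl.stop):
            col = sample.columns.get(
                (panel.chrom_arr[i], int(panel.pos_arr[i]))
            )
            if col is None:
                continue
            counts = col.acgt_counts()
            fracs.append(counts[col.ref_base] / sum(counts.values()))
        assert np.mean(fracs) > 0.97

    def test_injected_heterozygous_substitution_near_half(self):
        from ampliscreen.synthetic_cohort import VariantSpec

        cfg = small_config(
            21,
            target_depth=2000.0,
            variants=(
                VariantSpec("S03", "VWF", "substitution", "heterozygous",
                            0.5),
            ),
        )
        cohort = simulate_cohort(cfg)
        (v,) = cohort.truth.variants
        col = cohort.sample("S03").columns[(v.chrom, v.pos)]
        counts = col.acgt_counts()
        frac = counts[v.alt] / sum(counts.values())
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / sum(counts.values()))

    def test_injected_variant_outside_panel_rejected(self):
        from ampliscreen.errors import ConfigError
        from ampliscreen.synthetic_cohort import VariantSpec

        cfg = small_config(
            0,
            variants=(
                VariantSpec("S01", "NOPE", "substitution", "hemizygous", 0.5),
            ),
        )
        with pytest.raises(ConfigError):
            simulate_cohort(cfg)


class TestPaperScenario:
    def test_scenario_composition(self):
        cfg = paper_scenario(0)
        assert cfg.n_samples == 24
        assert len(cfg.resolve_sample_ids()) == 24
        kinds = [v.kind for v in cfg.variants]
        assert kinds.count("substitution") == 21  # 18 primary + 3 additional
        assert kinds.count("insertion") + kinds.count("deletion") == 3
        assert len(cfg.deletions) == 3
        assert sorted(d.zygosity for d in cfg.deletions) == [
            "hemizygous", "hemizygous", "heterozygous",
        ]

    def test_poly_t_lesion_targets_the_run(self):
        cohort = simulate_cohort(paper_scenario(2))
        (ins,) = [v for v in cohort.truth.variants if v.kind == "insertion"]
        assert ins.sample_id == "HA_208"
        chrom, start, length = cohort.panel.polyT["F8"]
        assert chrom == ins.chrom
        assert start < ins.pos <= start + length
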