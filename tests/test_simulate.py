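import io

import numpy as np
import pytest
from scipy import stats

from nrchip import (
    SimConfig,
    SimulationError,
    build_toy_genome,
    simulate_heritable_series,
    simulate_library,
)
from nrchip.io import write_bed


def region_read_count(library, chrom, start, end):
    """Fractionally weighted count of reads whose 5' start lies in [start, end).

    Each record contributes 1/n_hits, so a multimapper's unit mass is split
    across its repeat copies rather than counted once per copy.
    """
    total = 0.0
    for r in library.records:
        five = r.start if r.strand == "+" else r.start + r.read_length
        if r.chrom == chrom and start <= five < end:
            total += 1.0 / r.n_hits
    return total


class TestBuildToyGenome:
    def test_no_grts_requested_means_no_grts_intervals(self):
        cfg = SimConfig(
            chrom_lengths=[("c", 100_000)], n_genes=5, n_grh=2, n_grts=0,
            n_target_genes=2, repeat_in_target_fraction=0.0, n_reads=100,
        )
        _, _, _, regions, _ = build_toy_genome(cfg)
        assert not (regions["name"] == "GRTS").any()
        assert (regions["name"] == "GRH").sum() == 2

    def test_annotations_byte_identical_across_runs(self, small_config):
        def render(cfg):
            _, genes, repeats, regions, _ = build_toy_genome(cfg)
            bufs = []
            for frame in (genes, repeats, regions):
                buf = io.StringIO()
                write_bed(frame, buf)
                bufs.append(buf.getvalue())
            return bufs

        assert render(small_config) == render(small_config)

    def test_regions_on_arms_and_no_overlap(self, small_config, small_genome):
        layout, genes, repeats, regions, truth = small_genome
        for _, r in regions.iterrows():
            mid = (r["start"] + r["end"]) // 2
            assert layout.compartment(r["chrom"], mid) == "arm"
        # genes and regions are mutually non-overlapping
        placed = list(genes[["chrom", "start", "end"]].itertuples(index=False)) + list(
            regions[["chrom", "start", "end"]].itertuples(index=False)
        )
        for i, a in enumerate(placed):
            for b in placed[i + 1:]:
                if a.chrom == b.chrom:
                    assert a.end <= b.start or b.end <= a.start

    def test_repeat_copies_identical_length_per_family(self, small_config, small_genome):
        _, _, repeats, _, _ = small_genome
        for label, copies, length in small_config.repeat_families:
            fam = repeats[repeats["name"] == label]
            assert len(fam) == copies
            assert ((fam["end"] - fam["start"]) == length).all()

    def test_truth_has_one_row_per_element(self, small_config, small_genome):
        _, genes, repeats, regions, truth = small_genome
        el = truth.elements
        assert (el["kind"] == "gene").sum() == len(genes)
        assert (el["kind"] == "region").sum() == len(regions)
        assert (el["kind"] == "repeat").sum() == len(repeats)
        assert el["id"].is_unique

    def test_impossible_placement_reported(self):
        with pytest.raises(SimulationError):
            build_toy_genome(
                SimConfig(chrom_lengths=[("c", 5_000)], n_genes=10, gene_length=2_000,
                          n_grh=0, n_grts=0, n_target_genes=0,
                          repeat_in_target_fraction=0.0, n_reads=10)
            )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(generation_decay=1.5)
        with pytest.raises(ValueError):
            SimConfig(genotype_effects={"WT": 2.0})
        with pytest.raises(ValueError):
            SimConfig(background_enrichment_arms=0.5)


class TestSimulateLibrary:
    def test_exactly_n_reads_and_unit_weight_per_read(self, small_config, small_genome):
        layout, *_, truth = small_genome
        lib = simulate_library(small_config, truth, "H3K23me3", "WT", "chip")
        assert lib.depth == small_config.n_reads
        assert lib.total_weight() == pytest.approx(small_config.n_reads, abs=1e-6)
        lib.validate(layout)

    def test_same_seed_identical_different_replicates_differ(self, small_config, small_genome):
        *_, truth = small_genome
        a = simulate_library(small_config, truth, "H3K23me3", "WT", "chip", replicate=1)
        b = simulate_library(small_config, truth, "H3K23me3", "WT", "chip", replicate=1)
        c = simulate_library(small_config, truth, "H3K23me3", "WT", "chip", replicate=2)
        assert a.records == b.records
        assert a.records != c.records

    def test_unknown_keys_rejected(self, small_config, small_genome):
        *_, truth = small_genome
        with pytest.raises(KeyError):
            simulate_library(small_config, truth, "H3K9me2", "WT")
        with pytest.raises(KeyError):
            simulate_library(small_config, truth, "H3K23me3", "nrde-2")

    def test_input_library_is_uniform_background(self, small_config, small_genome):
        layout, *_, truth = small_genome
        lib = simulate_library(small_config, truth, "H3K23me3", "WT", "input")
        arm_total = sum(
            layout.arms[c][0] + layout.chrom_lengths[c] - layout.arms[c][1]
            for c in layout.chromosomes
        )
        n_arm = sum(
            region_read_count(lib, c, 0, layout.arms[c][0])
            + region_read_count(lib, c, layout.arms[c][1], layout.chrom_lengths[c])
            for c in layout.chromosomes
        )
        p_arm = arm_total / layout.total_length
        ci = stats.binom.interval(0.9999, small_config.n_reads, p_arm)
        assert ci[0] <= n_arm <= ci[1]

    def test_zero_effect_genotype_collapses_region_enrichment(self, small_config, small_genome):
        layout, *_, regions, truth = small_genome
        lib = simulate_library(small_config, truth, "H3K23me3", "hrde-1", "chip")
        # GRTS regions sit on arms: expect only the arm background fold there
        r = regions[regions["name"] == "GRTS"].iloc[0]
        n = region_read_count(lib, r["chrom"], r["start"], r["end"])
        arm_fold = small_config.background_enrichment_arms
        total_intensity = layout.total_length + (arm_fold - 1) * sum(
            layout.arms[c][0] + layout.chrom_lengths[c] - layout.arms[c][1]
            for c in layout.chromosomes
        )  # target excess is zero in this genotype
        p = arm_fold * (r["end"] - r["start"]) / total_intensity
        ci = stats.binom.interval(0.9999, small_config.n_reads, p)
        assert ci[0] <= n <= ci[1]

    def test_planted_fold_recovered_within_binomial_error(self):
        """An 8-fold 2 kb region on a flat 1 Mb genome, 100k reads."""
        cfg = SimConfig(
            chrom_lengths=[("c", 1_000_000)], arm_fraction=0.0,
            background_enrichment_arms=1.0, n_genes=1, n_target_genes=1,
            gene_length=2_000, n_grh=0, n_grts=0, repeat_families=[],
            repeat_in_target_fraction=0.0, target_enrichment={"mk": 8.0},
            genotype_effects={"WT": 1.0}, n_reads=100_000, seed=5,
        )
        layout, genes, *_, truth = build_toy_genome(cfg)
        g = genes.iloc[0]
        lib = simulate_library(cfg, truth, "mk", "WT", "chip")
        n = region_read_count(lib, g["chrom"], g["start"], g["end"])
        total_intensity = 1_000_000 + 7.0 * 2_000
        p = 8.0 * 2_000 / total_intensity
        expected_background = cfg.n_reads * 2_000 / total_intensity
        ci = stats.binom.interval(0.9999, cfg.n_reads, p)
        assert ci[0] <= n <= ci[1]
        assert n / expected_background == pytest.approx(8.0, rel=0.15)

    def test_multimappers_only_inside_repeat_copies(self, small_config, small_genome):
        *_, truth = small_genome
        reps = truth.elements[truth.elements["kind"] == "repeat"]
        spans = {
            c: [(s, e) for _, c2, s, e in reps[reps["chrom"] == c][
                ["id", "chrom", "start", "end"]].itertuples(index=False)]
            for c in reps["chrom"].unique()
        }
        lib = simulate_library(small_config, truth, "H3K23me3", "WT", "chip")
        for r in lib.records:
            if r.n_hits > 1:
                assert any(
                    s <= r.start and r.start + r.read_length <= e
                    for s, e in spans.get(r.chrom, [])
                )


class TestHeritableSeries:
    def test_fold_formula(self, small_genome):
        *_, truth = small_genome
        truth.generation_decay = 0.5
        assert truth.fold(17.0, "WT", 4) == pytest.approx(2.0)
        truth.generation_decay = 1.0
        for g in range(5):
            assert truth.fold(9.0, "WT", g) == 9.0
        truth.generation_decay = 0.7

    def test_all_effects_one_and_no_decay_reduce_to_wt_f0(self, small_genome):
        *_, truth = small_genome
        truth.genotype_effects["mut"] = 1.0
        d = truth.generation_decay
        truth.generation_decay = 1.0
        assert truth.fold(8.0, "mut", 3) == truth.fold(8.0, "WT", 0)
        truth.generation_decay = d

    def test_observed_decay_monotone_non_increasing(self):
        cfg = SimConfig(
            chrom_lengths=[("c", 200_000)], arm_fraction=0.25,
            background_enrichment_arms=1.0, n_genes=1, n_target_genes=0,
            n_grh=0, n_grts=1, region_length=2_000, repeat_families=[],
            repeat_in_target_fraction=0.0, target_enrichment={"mk": 9.0},
            genotype_effects={"WT": 1.0}, generation_decay=0.7,
            n_reads=100_000, seed=23,
        )
        layout, *_, regions, truth = build_toy_genome(cfg)
        r = regions.iloc[0]
        series = simulate_heritable_series(cfg, truth, "mk", generations=4)
        assert len(series) == 5
        folds = []
        for chip, inp in series:
            n_chip = region_read_count(chip, r["chrom"], r["start"], r["end"])
            n_in = region_read_count(inp, r["chrom"], r["start"], r["end"])
            folds.append(n_chip / max(n_in, 1))
        for a, b in zip(folds, folds[1:]):
            assert b <= a * 1.10  # non-increasing within sampling error
        assert folds[0] == pytest.approx(9.0, rel=0.2)

    def test_no_decay_keeps_folds_equal(self):
        cfg = SimConfig(
            chrom_lengths=[("c", 200_000)], arm_fraction=0.25,
            background_enrichment_arms=1.0, n_genes=1, n_target_genes=0,
            n_grh=0, n_grts=1, region_length=2_000, repeat_families=[],
            repeat_in_target_fraction=0.0, target_enrichment={"mk": 9.0},
            genotype_effects={"WT": 1.0}, generation_decay=1.0,
            n_reads=50_000, seed=29,
        )
        _, *_, regions, truth = build_toy_genome(cfg)
        r = regions.iloc[0]
        series = simulate_heritable_series(cfg, truth, "mk", generations=3)
        counts = [
            region_read_count(chip, r["chrom"], r["start"], r["end"])
            for chip, _ in series
        ]
        assert max(counts) / min(counts) < 1.25

    def test_generations_must_be_positive(self, small_config, small_genome):
        *_, truth = small_genome
        with pytest.raises(ValueError):
            simulate_heritable_series(small_config, truth, "H3K23me3", 0)
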