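"""Windowed introgression detector: density tracks, high-window calling,
the 10-kb border rule, zygosity, donor similarity, het profiles and
genome-state classification."""

import numpy as np
import pandas as pd
import pytest

from introtrace import introgression as intro
from introtrace import sim_cross as sc
from introtrace.introgression import DensityTrack, DetectionParams
from introtrace.variant_io import GT_HET, GT_HOM_ALT, GT_HOM_REF, RegionSet

from conftest import make_table


def uniform_table(positions, gts, sample="S", chrom="chr01"):
    return make_table(
        [(chrom, int(p), "A", "C", [g]) for p, g in zip(positions, gts)], [sample]
    )


class TestDensityTrack:
    def test_reference_identical_sample_has_zero_density(self, small_genome):
        pos = np.linspace(1000, 2_400_000, 50, dtype=int)
        table = uniform_table(pos, [GT_HOM_REF] * 50)
        track = intro.snp_density_track(table, "S", small_genome, 100_000, 5_000)
        for df in track.by_chrom.values():
            assert (df["density"] == 0).all()

    def test_full_window_counts_every_snp(self, small_genome):
        """100 SNPs uniform on a 2.5-Mb chromosome with a 2-Mb window: the
        full windows each hold every SNP inside their span; the window
        anchored at 1 with all 100 inside the first 2 Mb counts 100."""
        pos = np.linspace(1, 2_000_000, 100, dtype=int)
        table = uniform_table(pos, [GT_HOM_ALT] * 100)
        track = intro.snp_density_track(table, "S", small_genome, 2_000_000, 2_000_000)
        first = track.by_chrom["chr01"].iloc[0]
        assert first["snp_count"] == 100 and first["density"] == 100

    def test_truncated_window_density_rescaled(self):
        """37 SNPs inside one 500-kb window scale to 37 * 4 per 2 Mb."""
        genome = sc.GenomeSpec((("chr01", 500_000),))
        pos = np.linspace(1, 500_000, 37, dtype=int)
        table = uniform_table(pos, [GT_HOM_ALT] * 37)
        track = intro.snp_density_track(table, "S", genome, 2_000_000, 500_000)
        first = track.by_chrom["chr01"].iloc[0]
        assert first["snp_count"] == 37
        assert first["density"] == pytest.approx(37 * 4)

    def test_het_only_mode_ignores_homozygous_calls(self, small_genome):
        pos = [10_000, 20_000, 30_000]
        table = uniform_table(pos, [GT_HET, GT_HOM_ALT, GT_HET])
        track = intro.snp_density_track(
            table, "S", small_genome, 100_000, 100_000, include="het_only"
        )
        assert track.by_chrom["chr01"]["snp_count"].iloc[0] == 2

    def test_width_below_step_rejected(self, small_genome):
        table = uniform_table([100], [GT_HET])
        with pytest.raises(ValueError):
            intro.snp_density_track(table, "S", small_genome, 1_000, 5_000)


def manual_track(densities, sample="S", width=100_000, step=100_000, chrom="chr01"):
    n = len(densities)
    starts = np.arange(n) * step + 1
    df = pd.DataFrame(
        {
            "start": starts,
            "end": starts + width - 1,
            "snp_count": np.asarray(densities) * width // 2_000_000,
            "density": np.asarray(densities, dtype=float),
        }
    )
    return DensityTrack(sample, width, step, {chrom: df})


class TestHighDensityCalling:
    def test_sample_equal_to_control_gives_empty(self):
        t = manual_track([5.0] * 30)
        c = manual_track([5.0] * 30, "C")
        assert len(intro.call_high_density_regions(t, [c])) == 0

    def test_single_high_run_called(self):
        dens = np.full(30, 2.0)
        dens[10:21] = 500.0
        t = manual_track(dens)
        c = manual_track(np.full(30, 2.0), "C")
        regions = intro.call_high_density_regions(t, [c], fold=10, min_abs=50)
        assert len(regions) == 1
        row = regions.df.iloc[0]
        assert row["start"] == 10 * 100_000 + 1 and row["end"] == 21 * 100_000

    def test_runs_separated_by_wide_gap_stay_separate(self):
        dens = np.full(60, 2.0)
        dens[5:10] = 500.0
        dens[40:45] = 500.0  # 3 Mb away
        t = manual_track(dens)
        c = manual_track(np.full(60, 2.0), "C")
        regions = intro.call_high_density_regions(t, [c])
        assert len(regions) == 2

    def test_controls_required_and_grids_must_match(self):
        t = manual_track([1.0] * 10)
        with pytest.raises(ValueError, match="control"):
            intro.call_high_density_regions(t, [])
        c = manual_track([1.0] * 9, "C")
        with pytest.raises(ValueError, match="grid"):
            intro.call_high_density_regions(t, [c])

    def test_lowering_fold_never_shrinks_called_set(self, desk_genome):
        """Monotonicity: regions called at a stricter fold are contained in
        the regions called at a looser fold."""
        rng = np.random.default_rng(5)
        panel, recipient, donor, _ = sc.make_founders(desk_genome, 5e-4, 0.0, rng)
        f2 = sc.self_plant(sc.cross(recipient, donor, 1.25, rng, "f1"), 1.25, rng, "F2")
        table = sc.genotype_plants(
            panel, [f2, recipient], sc.SimConfig(), rng, noiseless=True
        )
        strack = intro.snp_density_track(table, "F2", desk_genome, 100_000, 5_000)
        ctrack = intro.snp_density_track(table, "recipient", desk_genome, 100_000, 5_000)
        loose = intro.call_high_density_regions(strack, [ctrack], fold=2)
        strict = intro.call_high_density_regions(strack, [ctrack], fold=50)
        assert strict.intersect_bp(loose) == strict.total_bp()


class TestBorderRefinement:
    def test_borders_pad_outermost_specific_snp_by_10kb(self):
        spos = np.array([100_000, 120_000, 130_000, 140_000, 150_000,
                         101_000, 102_000, 103_000, 104_000, 105_000])
        lo, hi, n = intro.refine_borders(("chr01", 50_000, 400_000), spos, 2_500_000)
        assert (lo, hi) == (90_000, 160_000)
        assert n == 10

    def test_start_clipped_at_chromosome_origin(self):
        spos = np.arange(5_000, 15_000, 1_000)
        lo, hi, _ = intro.refine_borders(
            ("chr01", 1, 50_000), spos, 2_500_000, min_region_snps=5
        )
        assert lo == 1
        assert hi == spos.max() + 10_000

    def test_shared_snps_do_not_extend_border(self, small_genome):
        """Sites shared with controls are not sample-specific and must not
        move the border outward."""
        records = []
        for p in range(100_000, 151_000, 5_000):  # specific sites
            records.append(("chr01", p, "A", "C", [GT_HOM_ALT, GT_HOM_REF]))
        records.append(("chr01", 160_500, "A", "C", [GT_HOM_ALT, GT_HOM_ALT]))  # shared
        table = make_table(records, ["S", "CTRL"])
        mask = intro.sample_specific_mask(table, "S", ["CTRL"])
        spos = table.sites["pos"].to_numpy()[mask]
        lo, hi, _ = intro.refine_borders(("chr01", 1, 300_000), spos, 2_500_000)
        assert hi == 150_000 + 10_000

    def test_too_few_specific_snps_drops_region(self):
        assert intro.refine_borders(("chr01", 1, 1000), np.array([500]), 2_500_000) is None


class TestZygosityAndSimilarity:
    def test_all_het_calls_are_heterozygous(self, small_genome):
        table = uniform_table(range(1000, 21000, 1000), [GT_HET] * 20)
        assert intro.classify_zygosity(("chr01", 1, 30_000), table, "S") == "heterozygous"

    def test_all_hom_alt_calls_are_homozygous(self):
        table = uniform_table(range(1000, 21000, 1000), [GT_HOM_ALT] * 20)
        assert intro.classify_zygosity(("chr01", 1, 30_000), table, "S") == "homozygous"

    def test_even_mixture_is_mixed(self):
        gts = [GT_HET, GT_HOM_ALT] * 10
        table = uniform_table(range(1000, 21000, 1000), gts)
        assert intro.classify_zygosity(("chr01", 1, 30_000), table, "S") == "mixed"

    def test_donor_similarity_counts_shared_alt_sites(self):
        """A donor-copied segment with 2 private culture SNPs among 200
        donor sites scores 200/202."""
        records = []
        for i in range(200):
            records.append(("chr01", 1000 + i * 100, "A", "C", [GT_HOM_ALT, GT_HOM_ALT]))
        for i in range(2):
            records.append(("chr01", 50_000 + i, "G", "A", [GT_HET, GT_HOM_REF]))
        table = make_table(records, ["S", "TCS17"])
        sim = intro.donor_similarity(("chr01", 1, 60_000), table, "S", "TCS17")
        assert sim == pytest.approx(200 / 202)

    def test_donor_identical_segment_scores_one(self):
        records = [("chr01", 1000 + i, "A", "C", [GT_HOM_ALT, GT_HOM_ALT]) for i in range(50)]
        table = make_table(records, ["S", "D"])
        assert intro.donor_similarity(("chr01", 1, 2000), table, "S", "D") == 1.0

    def test_culture_only_sample_scores_zero(self):
        records = [("chr01", 1000 + i, "A", "C", [GT_HET, GT_HOM_REF]) for i in range(50)]
        table = make_table(records, ["S", "D"])
        assert intro.donor_similarity(("chr01", 1, 2000), table, "S", "D") == 0.0


class TestHetProfile:
    def test_homozygous_sample_all_zero(self, small_genome):
        table = uniform_table(range(1000, 51000, 1000), [GT_HOM_ALT] * 50)
        profile = intro.het_profile(table, "S", small_genome)
        assert (profile.counts == 0).all()

    def test_bin_counts_and_edge_convention(self, small_genome):
        """Ten het calls inside bin 1 plus a call exactly at 100,000, which
        belongs to bin 1 (positions 1-100,000)."""
        pos = list(range(5_000, 95_000, 10_000)) + [100_000, 100_001]
        table = uniform_table(pos, [GT_HET] * len(pos))
        profile = intro.het_profile(table, "S", small_genome)
        assert profile.by_chrom["chr01"][0] == 10
        assert profile.by_chrom["chr01"][1] == 1


class TestGenomeState:
    def _simulate(self, genome, builder, seed=0):
        rng = np.random.default_rng(seed)
        panel, recipient, donor, _ = sc.make_founders(genome, 1e-3, 0.0, rng)
        plant = builder(panel, recipient, donor, rng)
        table = sc.genotype_plants(
            panel, [plant, recipient], sc.SimConfig(), rng, noiseless=True
        )
        return table, panel

    def test_f1_outcross_is_genome_wide_heterozygous(self, desk_genome):
        table, _ = self._simulate(
            desk_genome, lambda p, r, d, g: sc.cross(r, d, 1.25, g, "X")
        )
        profile = intro.het_profile(table, "X", desk_genome)
        assert intro.classify_genome_state(profile, RegionSet.empty()) == (
            intro.GENOME_WIDE_HET
        )

    def test_recipient_self_is_clean(self, desk_genome):
        table, _ = self._simulate(
            desk_genome, lambda p, r, d, g: sc.self_plant(r, 1.25, g, "X")
        )
        profile = intro.het_profile(table, "X", desk_genome)
        assert intro.classify_genome_state(profile, RegionSet.empty()) == intro.CLEAN

    def test_f3_with_partial_donor_is_segmental(self, desk_genome):
        def builder(panel, r, d, g):
            f1 = sc.cross(r, d, 1.25, g, "f1")
            return sc.self_plant(sc.self_plant(f1, 1.25, g), 1.25, g, "X")

        table, _ = self._simulate(desk_genome, builder, seed=4)
        profile = intro.het_profile(table, "X", desk_genome)
        regions = intro.detect_introgression(
            table, "X", ["recipient"], desk_genome, params=DetectionParams.desk_scale()
        )
        assert intro.classify_genome_state(profile, regions) == intro.SEGMENTAL


class TestEndToEndDetector:
    def test_recovers_truth_segments_on_noiseless_calls(self, desk_genome):
        rng = np.random.default_rng(8)
        panel, recipient, donor, _ = sc.make_founders(desk_genome, 1e-3, 0.0, rng)
        f1 = sc.cross(recipient, donor, 1.25, rng, "f1")
        f3 = sc.self_plant(sc.self_plant(f1, 1.25, rng), 1.25, rng, "F3")
        table = sc.genotype_plants(
            panel, [f3, recipient, donor], sc.SimConfig(), rng, noiseless=True
        )
        regions = intro.detect_introgression(
            table, "F3", ["recipient"], desk_genome, donor_sample="donor",
            params=DetectionParams.desk_scale(),
        )
        called = intro.regions_to_regionset(regions)
        truth = sc.truth_regions(f3)
        assert called.jaccard(truth) >= 0.90
        assert all(r.donor_similarity > 0.99 for r in regions)

    def test_refined_borders_are_order_independent_and_exact(self):
        spos = np.array([200_000, 150_000, 175_000, 160_000, 190_000,
                         155_000, 165_000, 170_000, 180_000, 185_000])
        a = intro.refine_borders(("chr01", 1, 2_500_000), spos, 2_500_000)
        b = intro.refine_borders(("chr01", 1, 2_500_000), np.sort(spos), 2_500_000)
        assert a == b == (140_000, 210_000, 10)
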