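"""Forward-simulator unit and property tests: marker panels, meiosis,
Mendelian segregation, tissue-culture mutations, T-DNA dosage, phenotype
rules, read sampling and the threshold genotype caller."""

import numpy as np
import pandas as pd
import pytest

from introtrace import sim_cross as sc
from introtrace.variant_io import read_vcf
from introtrace.sim_cross import GT_HET, GT_HOM_ALT, GT_HOM_REF, GT_MISSING


class TestFounders:
    def test_marker_count_tracks_poisson_mean(self, desk_genome, rng):
        density = 2e-3
        panel, *_ = sc.make_founders(desk_genome, density, 0.0, rng)
        mean = density * desk_genome.total_bp
        n_donor = (panel.df["mclass"] == sc.DONOR_DIAGNOSTIC).sum()
        assert abs(n_donor - mean) < 5 * np.sqrt(mean)

    def test_zero_parent2_density_gives_no_parent2_markers(self, founders):
        panel, *_ = founders
        # density 1e-4 > 0 here; build a zero-density panel explicitly
        panel0, *_ = sc.make_founders(panel.genome, 1e-3, 0.0, np.random.default_rng(0))
        assert (panel0.df["mclass"] == sc.PARENT2_DIAGNOSTIC).sum() == 0

    def test_same_seed_reproduces_panel(self, desk_genome):
        p1, *_ = sc.make_founders(desk_genome, 1e-3, 1e-4, 7)
        p2, *_ = sc.make_founders(desk_genome, 1e-3, 1e-4, 7)
        pd.testing.assert_frame_equal(p1.df, p2.df)

    def test_founder_genotypes(self, founders):
        panel, recipient, donor, parent2 = founders
        dos = sc.dosage_matrix(panel, [recipient, donor, parent2])
        donor_rows = (panel.df["mclass"] == sc.DONOR_DIAGNOSTIC).to_numpy()
        p2_rows = (panel.df["mclass"] == sc.PARENT2_DIAGNOSTIC).to_numpy()
        assert (dos[:, 0] == 0).all()
        assert (dos[donor_rows, 1] == 2).all() and (dos[p2_rows, 1] == 0).all()
        assert (dos[p2_rows, 2] == 2).all() and (dos[donor_rows, 2] == 0).all()

    def test_excessive_density_rejected(self, small_genome):
        with pytest.raises(ValueError, match="density"):
            sc.make_founders(small_genome, 1.5, 0.0, 0)


class TestMeiosis:
    def test_lambda_zero_returns_whole_parental_copy(self, founders, rng):
        panel, recipient, donor, _ = founders
        f1 = sc.cross(recipient, donor, 0.0, rng, "f1")
        gamete = sc.meiosis(f1, 0.0, rng)
        for chrom, _ in f1.genome.chromosomes:
            seg = gamete.mosaic.segments[chrom]
            assert len(seg) == 1 and seg[0, 2] in (sc.RECIPIENT, sc.DONOR)

    def test_homozygous_plant_gives_identical_gamete(self, founders, rng):
        panel, recipient, *_ = founders
        gamete = sc.meiosis(recipient, 2.0, rng)
        for chrom, length in recipient.genome.chromosomes:
            seg = gamete.mosaic.segments[chrom]
            assert (seg[:, 2] == sc.RECIPIENT).all()
            assert seg[0, 0] == 1 and seg[-1, 1] == length

    def test_crossover_count_matches_poisson_mean(self, rng):
        lam, n = 1.25, 10_000
        counts = [len(sc.draw_crossovers(2_500_000, lam, rng)) for _ in range(n)]
        se = np.sqrt(lam / n)
        assert abs(np.mean(counts) - lam) < 4 * se


class TestSelfingAndCrossing:
    def test_self_of_pure_recipient_stays_pure(self, founders, rng):
        panel, recipient, *_ = founders
        child = sc.self_plant(recipient, 1.25, rng)
        assert (child.dosage(panel) == 0).all()

    def test_f1_heterozygous_at_every_donor_marker(self, founders, rng):
        panel, recipient, donor, _ = founders
        f1 = sc.cross(recipient, donor, 1.25, rng, "f1")
        donor_rows = (panel.df["mclass"] == sc.DONOR_DIAGNOSTIC).to_numpy()
        assert (f1.dosage(panel)[donor_rows] == 1).all()

    def test_mendelian_segregation_of_selfed_heterozygote(self, small_genome):
        """Genotype frequencies at one marker over many selfings of an F1
        stay within 3 SE of the Mendelian (1/4, 1/2, 1/4)."""
        rng = np.random.default_rng(42)
        panel, recipient, donor, _ = sc.make_founders(small_genome, 1e-4, 0.0, rng)
        f1 = sc.cross(recipient, donor, 1.25, rng, "f1")
        chrom = small_genome.names[0]
        pos = int(panel.positions(chrom)[len(panel) // 2])
        n = 10_000
        draws = np.array(
            [sc.self_plant(f1, 1.25, rng).dosage_at(panel, chrom, pos) for _ in range(n)]
        )
        for dosage, expected in ((0, 0.25), (1, 0.5), (2, 0.25)):
            freq = (draws == dosage).mean()
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs(freq - expected) < 3 * se


class TestCultureMutations:
    def test_zero_rate_adds_nothing(self, founders, rng):
        panel, recipient, *_ = founders
        plant, panel2 = sc.apply_culture_mutations(recipient, 0.0, rng, panel)
        assert len(panel2) == len(panel)

    def test_new_site_count_matches_poisson_mean(self, desk_genome):
        mu = 1.5e-6
        mean = mu * desk_genome.total_bp  # 15 for the 4 x 2.5 Mb genome
        rng = np.random.default_rng(3)
        panel, recipient, *_ = sc.make_founders(desk_genome, 1e-4, 0.0, rng)
        reps = 200
        counts = []
        for _ in range(reps):
            _, p2 = sc.apply_culture_mutations(recipient, mu, rng, panel)
            counts.append(len(p2) - len(panel))
        se = np.sqrt(mean / reps)
        assert abs(np.mean(counts) - mean) < 4 * se

    def test_every_new_site_is_heterozygous_in_regenerant(self, founders, rng):
        panel, recipient, *_ = founders
        plant, panel2 = sc.apply_culture_mutations(recipient, 5e-6, rng, panel)
        new = panel2.df["mclass"] == sc.CULTURE_MUTATION
        assert new.sum() > 0
        assert (plant.dosage(panel2)[new.to_numpy()] == 1).all()


class TestTdna:
    def test_insertion_has_dosage_one(self, founders):
        panel, recipient, *_ = founders
        plant, panel2 = sc.insert_tdna(recipient, "chr01", 1_000_000, panel)
        assert plant.tdna_dosage(panel2) == 1

    def test_dosage_zero_parent_transmits_nothing(self, founders, rng):
        panel, recipient, *_ = founders
        _, panel2 = sc.insert_tdna(recipient, "chr01", 1_000_000, panel)
        child = sc.self_plant(recipient, 1.25, rng)  # parent never carried it
        assert child.tdna_dosage(panel2) == 0

    def test_selfing_segregates_one_two_one(self, small_genome):
        rng = np.random.default_rng(9)
        panel, recipient, *_ = sc.make_founders(small_genome, 1e-4, 0.0, rng)
        plant, panel = sc.insert_tdna(recipient, "chr01", 1_000_000, panel)
        n = 10_000
        draws = np.array(
            [sc.self_plant(plant, 1.25, rng).tdna_dosage(panel) for _ in range(n)]
        )
        for dosage, expected in ((0, 0.25), (1, 0.5), (2, 0.25)):
            se = np.sqrt(expected * (1 - expected) / n)
            assert abs((draws == dosage).mean() - expected) < 3 * se

    def test_out_of_range_position_rejected(self, founders):
        panel, recipient, *_ = founders
        with pytest.raises(ValueError, match="out of range"):
            sc.insert_tdna(recipient, "chr01", 99_999_999, panel)


class TestPhenotype:
    @pytest.fixture
    def causal_setup(self, founders, rng):
        panel, recipient, donor, _ = founders
        grain = sc.CausalLocus("large-grain", "chr01", int(panel.positions("chr01")[5]))
        plant, panel = sc.apply_culture_mutations(donor, 0.0, rng, panel)
        return panel, recipient, donor, grain

    def test_homozygous_donor_at_grain_locus_is_large_grain(self, causal_setup):
        panel, _, donor, grain = causal_setup
        assert sc.phenotype_of(donor, [grain], panel) == ["large-grain"]

    def test_heterozygote_shows_no_recessive_label(self, causal_setup, rng):
        panel, recipient, donor, grain = causal_setup
        f1 = sc.cross(recipient, donor, 1.25, rng, "f1")
        assert sc.phenotype_of(f1, [grain], panel) == []

    def test_double_homozygote_gets_both_labels(self, founders, rng):
        panel, recipient, donor, _ = founders
        grain = sc.CausalLocus("large-grain", "chr01", int(panel.positions("chr01")[5]))
        # plant a homozygous culture-style mutation on both haplotypes
        dwarf_site = ("chr02", 1_234_567)
        panel = panel.with_markers(
            pd.DataFrame([{"chrom": dwarf_site[0], "pos": dwarf_site[1],
                           "ref": "G", "alt": "A", "mclass": sc.CULTURE_MUTATION}])
        )
        haps = tuple(
            sc.Haplotype(h.mosaic, h.private | {dwarf_site}) for h in donor.haplotypes
        )
        plant = sc.SimPlant("double", haps, donor.genome)
        dwarf = sc.CausalLocus("tillering-dwarf", *dwarf_site)
        assert sc.phenotype_of(plant, [grain, dwarf], panel) == [
            "large-grain", "tillering-dwarf"
        ]

    def test_unknown_locus_rejected(self, causal_setup):
        panel, recipient, *_ = causal_setup
        bogus = sc.CausalLocus("x", "chr01", 999_999_999)
        with pytest.raises(KeyError):
            sc.phenotype_of(recipient, [bogus], panel)


class TestReadSampling:
    def test_hom_alt_no_error_gives_pure_alt(self, rng):
        ref, alt = sc.sample_reads(np.full(500, 2.0), 20, 0.0, rng)
        assert (ref == 0).all()

    def test_het_alt_fraction_near_half_at_high_depth(self, rng):
        ref, alt = sc.sample_reads(np.full(2000, 1.0), 200, 0.0, rng)
        frac = alt.sum() / (ref + alt).sum()
        assert abs(frac - 0.5) < 0.01

    def test_pool_of_hom_alt_plants_has_alt_fraction_one(self, founders, rng):
        panel, _, donor, _ = founders
        dos = sc.pool_dosage([donor] * 20, panel)
        donor_rows = (panel.df["mclass"] == sc.DONOR_DIAGNOSTIC).to_numpy()
        ref, alt = sc.sample_reads(dos[donor_rows], 15, 0.0, rng)
        covered = (ref + alt) > 0
        assert (ref[covered] == 0).all()

    def test_empty_pool_rejected(self, founders):
        panel, *_ = founders
        with pytest.raises(ValueError, match="empty pool"):
            sc.pool_dosage([], panel)


class TestGenotypeCaller:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            (10, 0, GT_HOM_REF),
            (5, 5, GT_HET),
            (0, 12, GT_HOM_ALT),
            (1, 2, GT_MISSING),  # depth 3 < 4
            (2, 8, GT_HOM_ALT),  # fraction exactly 0.8
            (8, 2, GT_HOM_REF),  # fraction exactly 0.2
        ],
    )
    def test_threshold_rules(self, ref, alt, expected):
        assert sc.genotype_from_counts(np.array([ref]), np.array([alt]))[0] == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            sc.genotype_from_counts(np.array([-1]), np.array([2]))


class TestVcfRoundTrip:
    def test_write_then_read_is_identity(self, founders, rng, tmp_path):
        panel, recipient, donor, _ = founders
        f1 = sc.cross(recipient, donor, 1.25, rng, "f1")
        cfg = sc.SimConfig(seed=5)
        table = sc.genotype_plants(panel, [recipient, donor, f1], cfg, rng)
        path = tmp_path / "x.vcf"
        from introtrace.variant_io import write_vcf

        write_vcf(table, path, panel.genome)
        back = read_vcf(path)
        assert back.equals(table)

    def test_het_serialized_unphased(self, founders, rng, tmp_path):
        panel, recipient, donor, _ = founders
        f1 = sc.cross(recipient, donor, 1.25, rng, "f1")
        table = sc.genotype_plants(panel, [f1], sc.SimConfig(), rng, noiseless=True)
        path = tmp_path / "x.vcf"
        from introtrace.variant_io import write_vcf

        write_vcf(table, path, panel.genome)
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert any("\t0/1" in line for line in body)
        assert not any("|" in line.split("\t")[-1] for line in body)

    def test_seed_determinism_gives_byte_identical_vcf(self, desk_genome, tmp_path):
        from introtrace.variant_io import write_vcf

        paths = []
        for run in range(2):
            rng = np.random.default_rng(77)
            panel, recipient, donor, _ = sc.make_founders(desk_genome, 5e-4, 0.0, rng)
            f2 = sc.self_plant(sc.cross(recipient, donor, 1.25, rng, "f1"), 1.25, rng)
            table = sc.genotype_plants(panel, [f2], sc.SimConfig(seed=77), rng)
            path = tmp_path / f"run{run}.vcf"
            write_vcf(table, path, desk_genome)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]


class TestPedigreeRunner:
    def test_preset_pedigree_defines_roster_and_pools(self, desk_genome):
        spec = sc.m0028590_pedigree(desk_genome, f2_size=160)
        result = sc.run_pedigree(spec, sc.SimConfig(seed=11), desk_genome)
        for name in ("T1a", "T1b", "T1c", "T2a", "T2b", "T3a", "T3b"):
            assert name in result.plants
        assert len(result.pools["pool_mutant"]) == 20
        assert "tillering-dwarf" in result.phenotypes["T1c"]
        assert "tillering-dwarf" not in result.phenotypes["T2a"]
        # dwarf trait breeds true below the conditioned T2b
        assert "tillering-dwarf" in result.phenotypes["T3a"]

    def test_undefined_parent_rejected(self, desk_genome):
        spec = sc.PedigreeSpec([{"op": "self", "parent": "nobody", "child": "x"}])
        with pytest.raises(ValueError, match="founders|undefined"):
            sc.run_pedigree(spec, sc.SimConfig(), desk_genome)

    def test_truth_mosaic_is_exposed_for_scoring(self, desk_genome):
        spec = sc.m0028590_pedigree(desk_genome, f2_size=40, pool_size=5)
        result = sc.run_pedigree(spec, sc.SimConfig(seed=2), desk_genome)
        truth = sc.truth_regions(result.plants["T1b"])
        assert truth.total_bp() > 0
        assert set(truth.df["label"]) <= {"heterozygous", "homozygous"}
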