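"""Breeding-simulator tests: meiosis, inbreeding decay, RIS/CSS construction,
anomaly injection and intensity emission."""

import numpy as np
import pytest

import mosaicmap as mm
from mosaicmap.genome import Chromosome, GenomeModel
from mosaicmap.mosaic import Mosaic
from mosaicmap.simulate import (FEMALE, MALE, SibLineage, _plain_f1,
                                default_selection_markers)

GOLDEN_DECAY = (1 + np.sqrt(5)) / 4  # per-generation sib-mating het decay


def single_chromosome_genome(length_bp=1_000_000, cM=0.0) -> GenomeModel:
    return GenomeModel([Chromosome("1", length_bp, cM)])


class TestMeiosis:
    def test_zero_map_length_returns_a_parental_haplotype(self):
        chrom = Chromosome("1", 1000, 0.0)
        a, b = Mosaic.constant(1000, 0), Mosaic.constant(1000, 1)
        rng = np.random.default_rng(0)
        for _ in range(20):
            g = mm.simulate_meiosis(a, b, chrom, rng)
            assert g.equal(a) or g.equal(b)

    def test_crossover_count_matches_poisson_mean(self):
        chrom = Chromosome("1", 10_000_000, 100.0)
        a, b = Mosaic.constant(chrom.length_bp, 0), Mosaic.constant(chrom.length_bp, 1)
        rng = np.random.default_rng(1)
        n = 10_000
        counts = [len(mm.simulate_meiosis(a, b, chrom, rng).breakpoints())
                  for _ in range(n)]
        se = np.sqrt(1.0 / n)
        assert np.mean(counts) == pytest.approx(1.0, abs=3 * se)

    def test_homozygous_parent_transmits_identically(self):
        chrom = Chromosome("1", 1_000_000, 100.0)
        hap = Mosaic(np.array([200_000, 600_000, 1_000_000]),
                     np.array([0, 1, 0]))
        rng = np.random.default_rng(2)
        for _ in range(30):
            g = mm.simulate_meiosis(hap, Mosaic(hap.ends.copy(), hap.labels.copy()),
                                    chrom, rng)
            assert g.equal(hap)

    def test_gametes_tile_the_chromosome(self):
        chrom = Chromosome("1", 5_000_000, 150.0)
        a = Mosaic(np.array([1_000_000, 5_000_000]), np.array([0, 1]))
        b = Mosaic(np.array([3_000_000, 5_000_000]), np.array([1, 0]))
        rng = np.random.default_rng(3)
        for _ in range(200):
            g = mm.simulate_meiosis(a, b, chrom, rng)
            assert g.ends[-1] == chrom.length_bp
            assert np.all(np.diff(g.ends) > 0)
            assert set(g.labels.tolist()) <= {0, 1}

    def test_nonrecombining_chromosome_rejected(self):
        chrom = Chromosome("Y", 1000, 0.0, "Y")
        a = Mosaic.constant(1000, 0)
        with pytest.raises(ValueError, match="does not recombine"):
            mm.simulate_meiosis(a, a, chrom, np.random.default_rng(0))


class TestSibMatingDecay:
    def test_single_locus_heterozygosity_decays_at_golden_ratio(self):
        """Fraction of lineages heterozygous at an unlinked locus decays at
        (1+sqrt(5))/4 per generation (checked over generations 10-25)."""
        genome = single_chromosome_genome(cM=0.0)
        rng = np.random.default_rng(101)
        n = 20_000
        last_gen = 25
        het_counts = np.zeros(last_gen + 1)
        for _ in range(n):
            mother, father = _plain_f1(genome)
            lin = SibLineage(mother, father, genome, rng)
            for g in range(1, last_gen + 1):
                if lin.fixed:
                    break
                lin.step()
                if lin.mother.het_fraction(genome) > 0:
                    het_counts[g] += 1
        gens = np.arange(10, last_gen + 1)
        y = np.log(het_counts[gens])
        slope = np.polyfit(gens, y, 1)[0]
        assert np.exp(slope) == pytest.approx(GOLDEN_DECAY, rel=0.03)


class TestMapExpansion:
    def test_ris_switch_probability_approaches_4r(self):
        """Fixed sib-mated RIS genomes switch founder between close markers
        at ~4r (Haldane-Waddington); checked at r = 0.01."""
        r = 0.01
        d_morgans = -0.5 * np.log(1 - 2 * r)
        genome = single_chromosome_genome(length_bp=1_000_000, cM=100 * d_morgans)
        founders = _two_founders(genome)
        cfg = mm.BreedingConfig(panel_type="ris_classical", max_sib_generations=300)
        rng = np.random.default_rng(103)
        n = 6000
        switches = 0
        ends = np.array([0, genome.chromosomes[0].length_bp - 1])
        for _ in range(n):
            strain = mm.breed_ris(founders, cfg, genome, rng)
            lab = strain.haplotypes("1")[0].label_at(ends)
            switches += int(lab[0] != lab[1])
        expected = 4 * r / (1 + 6 * r)
        se = np.sqrt(expected * (1 - expected) / n)
        assert switches / n == pytest.approx(expected, abs=3.5 * se)


def _two_founders(genome, labels=("f1", "f2")) -> mm.FounderSet:
    n_snp = int((genome.markers["probe_class"] == "snp").sum())
    alleles = np.zeros((2, max(n_snp, 1)), dtype=np.int8)
    alleles[1] = 1
    return mm.FounderSet(list(labels), alleles)


class TestBreedRis:
    def test_long_inbreeding_reaches_full_homozygosity(self, toy_genome, toy_founders):
        rng = np.random.default_rng(104)
        cfg = mm.BreedingConfig(max_sib_generations=200)
        strain = mm.breed_ris(toy_founders, cfg, toy_genome, rng)
        assert strain.meta["fixed"]
        for chrom in strain.chromosomes:
            assert strain.het_intervals(chrom) == []
        assert not [r for r in strain.ledger if r.kind == "het_segment"]

    def test_finite_inbreeding_retains_heterozygosity(self):
        """At 20 sib generations on a mouse-scale map, a sizeable fraction
        of strains still carries a heterozygous segment."""
        genome = mm.mouse_default(snp_spacing_bp=20_000_000,
                                  invariant_spacing_bp=None)
        founders = _two_founders(genome)
        cfg = mm.BreedingConfig(max_sib_generations=20)
        rng = np.random.default_rng(105)
        n = 200
        with_het = sum(
            1 for _ in range(n)
            if any(r.kind == "het_segment"
                   for r in mm.breed_ris(founders, cfg, genome, rng,
                                         sample_sex=FEMALE).ledger))
        assert with_het / n > 0.20

    def test_advanced_panel_requires_ris_type(self, toy_genome, toy_founders):
        cfg = mm.BreedingConfig(panel_type="css", donor_chrom="1")
        with pytest.raises(ValueError, match="RIS panel type"):
            mm.breed_ris(toy_founders, cfg, toy_genome, np.random.default_rng(0))

    def test_sisters_share_breakpoints_independent_strains_do_not(
            self, toy_genome, toy_founders):
        rng = np.random.default_rng(106)
        cfg = mm.BreedingConfig(max_sib_generations=80)
        s1, s2 = mm.breed_sisters(toy_founders, cfg, toy_genome, rng,
                                  split_generation=15)
        shared = 0
        for chrom in ("1", "2", "3", "4", "5"):
            shared += len(np.intersect1d(s1.breakpoints(chrom), s2.breakpoints(chrom)))
        assert shared >= 1
        a = mm.breed_ris(toy_founders, cfg, toy_genome, rng, name="a")
        b = mm.breed_ris(toy_founders, cfg, toy_genome, rng, name="b")
        independent_shared = sum(
            len(np.intersect1d(a.breakpoints(c), b.breakpoints(c)))
            for c in ("1", "2", "3", "4", "5"))
        assert independent_shared == 0


class TestBreedCss:
    def test_backcross_background_donor_fraction_single_meiosis(
            self, toy_genome, toy_founders):
        cfg = mm.BreedingConfig(panel_type="css", donor_chrom="2",
                                n_backcross_meioses=1)
        rng = np.random.default_rng(107)
        fracs = [mm.breed_css(toy_founders, cfg, toy_genome, rng)
                 .meta["backcross_background_donor_fraction"] for _ in range(200)]
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.03)

    def test_backcross_background_donor_fraction_n10(self, toy_genome, toy_founders):
        """After 9 backcross meioses (an N10 consomic) the unlinked donor
        fraction averages 0.5**9 ~ 0.2%."""
        cfg = mm.BreedingConfig(panel_type="css", donor_chrom="2",
                                n_backcross_meioses=9)
        rng = np.random.default_rng(108)
        fracs = [mm.breed_css(toy_founders, cfg, toy_genome, rng)
                 .meta["backcross_background_donor_fraction"] for _ in range(500)]
        expected = 0.5 ** 9
        assert expected / 2 < np.mean(fracs) < expected * 2

    def test_short_selection_ladder_leaves_distal_host_blocks(
            self, toy_genome, toy_founders):
        length = toy_genome.chromosome("2").length_bp
        cfg = mm.BreedingConfig(panel_type="css", donor_chrom="2",
                                n_backcross_meioses=9,
                                selection_marker_positions=[5_000_000,
                                                            length - 20_000_000])
        rng = np.random.default_rng(109)
        host = toy_founders.code(toy_founders.panel[0])
        distal_host = 0
        for _ in range(60):
            strain = mm.breed_css(toy_founders, cfg, toy_genome, rng)
            tail = np.array([length - 1])
            labs = strain.labels_at("2", tail)
            if np.any(labs == host):
                distal_host += 1
        assert distal_host >= 5

    def test_donor_chromosome_fixed_at_selection_markers(self, toy_genome, toy_founders):
        cfg = mm.BreedingConfig(panel_type="css", donor_chrom="3",
                                n_backcross_meioses=9)
        rng = np.random.default_rng(110)
        donor = toy_founders.code(toy_founders.panel[1])
        markers = np.array(default_selection_markers(toy_genome, "3"))
        for _ in range(10):
            strain = mm.breed_css(toy_founders, cfg, toy_genome, rng)
            labs = strain.labels_at("3", markers)
            assert np.all(labs == donor)

    def test_missing_selection_markers_rejected(self, toy_founders):
        genome = single_chromosome_genome()
        founders = _two_founders(genome)
        cfg = mm.BreedingConfig(panel_type="css", donor_chrom="1",
                                selection_marker_positions=[])
        with pytest.raises(ValueError, match="selection markers"):
            mm.breed_css(founders, cfg, genome, np.random.default_rng(0))

    def test_requires_css_panel_type(self, toy_genome, toy_founders):
        cfg = mm.BreedingConfig(panel_type="ris_classical")
        with pytest.raises(ValueError, match="css"):
            mm.breed_css(toy_founders, cfg, toy_genome, np.random.default_rng(0))


class TestInjectAnomalies:
    def test_empty_spec_leaves_genome_unchanged(self, ris_panel):
        strain = ris_panel["strains"][0]
        out = mm.inject_anomalies(strain, [])
        for chrom in strain.chromosomes:
            for h0, h1 in zip(strain.chromosomes[chrom], out.chromosomes[chrom]):
                assert h0.equal(h1)
        assert out.ledger == strain.ledger

    def test_conversion_tract_with_one_informative_marker(
            self, toy_genome, toy_founders, ris_panel):
        strain = ris_panel["strains"][1]
        info = toy_founders.informative_mask()
        snp = toy_genome.markers[toy_genome.markers["probe_class"] == "snp"]
        pos = snp.loc[(snp["chrom"] == "1").to_numpy() & info, "pos"].to_numpy()
        p = int(pos[10])
        out = mm.inject_anomalies(strain, [
            mm.GeneConversionSpec("1", p - 300, p + 300, "B6")])
        recs = [r for r in out.ledger if r.kind == "gene_conversion"]
        assert len(recs) == 1
        inside = (pos >= recs[0].start) & (pos < recs[0].end)
        assert inside.sum() == 1  # exactly one convertible informative site
        assert np.all(out.labels_at("1", np.array([p])) ==
                      toy_founders.code("B6"))

    def test_homozygous_deletion_marks_invariant_probes(self, toy_genome, ris_panel):
        strain = ris_panel["strains"][2]
        out = mm.inject_anomalies(strain, [mm.CnvSpec("2", 10_000_000, 10_100_000, 0)])
        inv = toy_genome.markers_for("2", "invariant")["pos"].to_numpy()
        cn = out.copy_number_at("2", inv)
        inside = (inv >= 10_000_000) & (inv < 10_100_000)
        assert np.all(cn[inside] == 0) and np.all(cn[~inside] == 2)

    def test_overlapping_same_kind_rejected(self, ris_panel):
        strain = ris_panel["strains"][0]
        with pytest.raises(ValueError, match="overlapping"):
            mm.inject_anomalies(strain, [
                mm.CnvSpec("1", 1_000_000, 2_000_000, 0),
                mm.CnvSpec("1", 1_500_000, 2_500_000, 3)])

    def test_out_of_bounds_rejected(self, ris_panel):
        strain = ris_panel["strains"][0]
        with pytest.raises(ValueError, match="outside"):
            mm.inject_anomalies(strain, [mm.CnvSpec("1", 0, 10**10, 0)])

    def test_het_ledger_is_recoverable_from_mosaics(self):
        genome = mm.mouse_default(snp_spacing_bp=20_000_000,
                                  invariant_spacing_bp=None)
        founders = _two_founders(genome)
        cfg = mm.BreedingConfig(max_sib_generations=15)
        rng = np.random.default_rng(111)
        for _ in range(10):
            strain = mm.breed_ris(founders, cfg, genome, rng, sample_sex=FEMALE)
            ledger = sorted((r.chrom, r.start, r.end) for r in strain.ledger
                            if r.kind == "het_segment")
            derived = sorted((c, s, e) for c in strain.chromosomes
                             for (s, e) in strain.het_intervals(c))
            assert ledger == derived


class TestEmitIntensities:
    def test_noise_free_founder_hits_cluster_center(self, toy_genome, toy_founders):
        noise = mm.NoiseModel(sd=1e-12, bad_probe_fraction=0.0, probe_seed=5)
        rng = np.random.default_rng(112)
        pure = mm.founder_strain_genomes(toy_founders, toy_genome, ["B6"])
        table = mm.emit_intensities(pure, toy_founders, noise, toy_genome, rng)
        snp = table.select_class("snp")
        sig = snp.signal("B6")
        centers = {0: noise.centers["AA"], 1: noise.centers["BB"]}
        expected = np.array([centers[a] for a in toy_founders.alleles[0]])
        assert np.allclose(sig, expected, atol=1e-9)

    def test_zero_copy_invariant_probe_emits_null_average(
            self, toy_genome, toy_founders, ris_panel):
        strain = mm.inject_anomalies(ris_panel["strains"][3],
                                     [mm.CnvSpec("1", 5_000_000, 5_800_000, 0)])
        noise = mm.NoiseModel(sd=1e-12, bad_probe_fraction=0.0, probe_seed=5)
        rng = np.random.default_rng(113)
        table = mm.emit_intensities([strain], toy_founders, noise, toy_genome, rng)
        inv = table.select_class("invariant")
        mask = ((inv.probes["chrom"] == "1") & (inv.probes["pos"] >= 5_000_000)
                & (inv.probes["pos"] < 5_800_000)).to_numpy()
        assert mask.any()
        sig = inv.signal(strain.name)
        assert np.allclose(sig[mask, 0], noise.centers["null"][0], atol=1e-9)

    def test_replicate_noise_recovers_model_sd(self, toy_genome, toy_founders):
        noise = mm.NoiseModel(bad_probe_fraction=0.0, probe_seed=5)
        rng = np.random.default_rng(114)
        pure = mm.founder_strain_genomes(toy_founders, toy_genome, ["B6"])
        table = mm.emit_intensities(pure, toy_founders, noise, toy_genome, rng,
                                    replicates={"B6": 50})
        sd_hat = table.average.std(axis=0, ddof=1)
        assert sd_hat.mean() == pytest.approx(noise.sd, rel=0.10)

    def test_marker_mismatch_rejected(self, toy_genome, toy_founders):
        bad = mm.StrainGenome("bad", MALE, {"1": (Mosaic.constant(10, 0),) * 2})
        noise = mm.NoiseModel(probe_seed=5)
        with pytest.raises(ValueError, match="does not match"):
            mm.emit_intensities([bad], toy_founders, noise, toy_genome,
                                np.random.default_rng(0))
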