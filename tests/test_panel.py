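"""Panel statistics: recombination summaries, shared events, sister strains,
map comparison, fixation-time study and closed-form quantities."""

import itertools

import numpy as np
import pytest

import mosaicmap as mm
from mosaicmap.genome import Chromosome, GenomeModel
from mosaicmap.hmm import F1, F2, HET, HaplotypeMap
from mosaicmap.panel import (FixationSummary, compare_maps,
                             conversion_rate_estimate, css_panel_size,
                             expected_background_donor_fraction,
                             find_shared_events, fixation_time_study,
                             heterozygosity_summary,
                             recombination_prediction_interval, sister_zscore,
                             summarize_recombination)


def manual_map(name, states, positions=None, chrom="1"):
    states = np.asarray(states, dtype=np.int8)
    pos = (np.asarray(positions, dtype=np.int64) if positions is not None
           else np.arange(len(states), dtype=np.int64) * 1000)
    return HaplotypeMap(name, {chrom: pos}, {chrom: states})


def informative_probes(genome, founders):
    snp = genome.markers[genome.markers["probe_class"] == "snp"]
    return snp[founders.informative_mask()].reset_index(drop=True)


def truth_maps(strains, genome, founders):
    probes = informative_probes(genome, founders)
    return {s.name: mm.truth_map(s, genome, probes, founders) for s in strains}


class TestSummarizeRecombination:
    def test_single_block_strains_have_zero_events(self):
        maps = {f"s{i}": manual_map(f"s{i}", [F1] * 20) for i in range(3)}
        summary = summarize_recombination(maps)
        assert (summary["n_events"] == 0).all()

    def test_error_free_counts_match_ground_truth(self, toy_genome, toy_founders):
        rng = np.random.default_rng(601)
        cfg = mm.BreedingConfig(max_sib_generations=200)
        strains = [mm.breed_ris(toy_founders, cfg, toy_genome, rng, name=f"s{i}")
                   for i in range(5)]
        maps = truth_maps(strains, toy_genome, toy_founders)
        summary = summarize_recombination(maps)
        for s in strains:
            truth_events = len(mm.extract_recombination_intervals(maps[s.name]))
            assert summary.loc[s.name, "n_events"] == truth_events

    def test_advanced_panel_has_more_events_than_classical(
            self, toy_genome, toy_founders):
        rng = np.random.default_rng(602)
        means = {}
        for ptype, outcross in (("ris_classical", 0), ("ris_advanced", 6)):
            cfg = mm.BreedingConfig(panel_type=ptype,
                                    n_outcross_generations=outcross,
                                    outcross_pool_size=8,
                                    max_sib_generations=150)
            strains = [mm.breed_ris(toy_founders, cfg, toy_genome, rng,
                                    name=f"{ptype}{i}") for i in range(20)]
            maps = truth_maps(strains, toy_genome, toy_founders)
            means[ptype] = summarize_recombination(maps)["n_events"].mean()
        assert means["ris_advanced"] > means["ris_classical"]

    def test_invariant_under_strain_reordering(self, ris_panel):
        maps = ris_panel["maps"]
        reordered = dict(reversed(list(maps.items())))
        a = summarize_recombination(maps).sort_index()
        b = summarize_recombination(reordered).sort_index()
        assert (a["n_events"] == b["n_events"]).all()
        ev_a = {(e.chrom, e.start_bp, e.end_bp) for e in find_shared_events(maps)}
        ev_b = {(e.chrom, e.start_bp, e.end_bp)
                for e in find_shared_events(reordered)}
        assert ev_a == ev_b


class TestSharedEvents:
    def test_duplicate_strains_share_every_event_with_same_polarity(self, ris_panel):
        m = ris_panel["maps"]["RIS00"]
        twin = HaplotypeMap("twin", m.positions, m.states)
        shared = find_shared_events({"RIS00": m, "twin": twin})
        n_events = len(mm.extract_recombination_intervals(m))
        full = [s for s in shared if {"RIS00", "twin"} <= set(s.strains)]
        assert len(full) == n_events
        assert all(s.polarity_agreement[1] == 0 for s in full)

    def test_independent_strains_share_few_events(self, ris_panel):
        shared = find_shared_events(ris_panel["maps"])
        total = sum(len(mm.extract_recombination_intervals(m))
                    for m in ris_panel["maps"].values())
        involved = sum(len(set(s.strains)) for s in shared)
        assert involved < 0.5 * total

    def test_touching_intervals_do_not_overlap(self):
        a = manual_map("a", [F1, F1, F2, F2], positions=[0, 100, 200, 300])
        b = manual_map("b", [F1, F1, F2, F2], positions=[200, 300, 400, 500])
        # a's interval is (100, 200), b's is (300, 400): a third map bridges
        c = manual_map("c", [F1, F2], positions=[100, 200])
        shared = find_shared_events({"a": a, "b": b})
        assert shared == []  # (100,200) and (300,400) are disjoint
        shared = find_shared_events({"a": a, "c": c})
        assert len(shared) == 1  # identical interval (100,200) does overlap

    def test_needs_two_strains(self):
        with pytest.raises(ValueError):
            find_shared_events({"a": manual_map("a", [F1])})


class TestSisterZscore:
    def test_duplicated_lineage_flags_as_sister(self, ris_panel):
        maps = dict(ris_panel["maps"])
        src = maps["RIS00"]
        maps["twin"] = HaplotypeMap("twin", src.positions, src.states)
        rng = np.random.default_rng(603)
        report = sister_zscore(("RIS00", "twin"), maps, 1000, rng)
        assert report.z > 5 and report.is_sister

    def test_independent_pairs_rarely_flagged(self, ris_panel):
        maps = ris_panel["maps"]
        rng = np.random.default_rng(604)
        zs = [sister_zscore(pair, maps, 500, rng).z
              for pair in itertools.combinations(list(maps)[:10], 2)]
        frac_low = np.mean([abs(z) < 3 for z in zs])
        assert frac_low >= 0.95
        assert not any(z > 5 for z in zs)

    def test_strain_without_events_gets_zero(self, ris_panel):
        maps = dict(ris_panel["maps"])
        maps["flat"] = manual_map("flat", [F1] * 10)
        report = sister_zscore(("flat", "RIS00"), maps, 100,
                               np.random.default_rng(605))
        assert report.z == 0.0 and not report.is_sister


class TestCompareMaps:
    def test_identical_maps(self, ris_panel):
        m = ris_panel["maps"]["RIS02"]
        cmp = compare_maps(m, m)
        assert cmp.concordance == 1.0 and cmp.reduction == 0.0

    def test_density_increase_shrinks_uncertainty(self, dense_genome):
        """Genotyping the same truth on a regular marker grid at 10x density
        cuts the summed recombination-interval length by ~90% (events are far
        apart relative to the sparse spacing, so none is lost to
        cancellation)."""
        rng = np.random.default_rng(606)
        n_snp = int((dense_genome.markers["probe_class"] == "snp").sum())
        alleles = np.zeros((2, n_snp), dtype=np.int8)
        alleles[1] = 1  # every SNP informative: regular grid
        founders = mm.FounderSet(["f1", "f2"], alleles)
        cfg = mm.BreedingConfig(max_sib_generations=200)
        probes = informative_probes(dense_genome, founders)
        total_new = total_old = 0.0
        for i in range(12):
            strain = mm.breed_ris(founders, cfg, dense_genome, rng, name="d")
            dense = mm.truth_map(strain, dense_genome, probes, founders)
            sparse = HaplotypeMap("d", {c: dense.positions[c][::10]
                                        for c in dense.positions},
                                  {c: dense.states[c][::10]
                                   for c in dense.positions})
            cmp = compare_maps(dense, sparse)
            assert cmp.concordance is None or cmp.concordance > 0.95
            total_new += cmp.uncertainty_new
            total_old += cmp.uncertainty_old
        assert 1 - total_new / total_old == pytest.approx(0.9, abs=0.05)

    def test_disjoint_assignments_give_missing_concordance(self):
        a = manual_map("a", [F1] * 5 + [HET] * 5)
        b = manual_map("b", [HET] * 5 + [F2] * 5)
        cmp = compare_maps(a, b)
        assert cmp.concordance is None

    def test_reduction_antisymmetry(self, ris_panel):
        m1 = ris_panel["maps"]["RIS00"]
        m2 = HaplotypeMap("s", {c: m1.positions[c][::3] for c in m1.positions},
                          {c: m1.states[c][::3] for c in m1.positions})
        r12 = compare_maps(m1, m2).reduction
        r21 = compare_maps(m2, m1).reduction
        assert (1 - r12) * (1 - r21) == pytest.approx(1.0)

    def test_chromosome_mismatch_rejected(self):
        a = manual_map("a", [F1] * 3, chrom="1")
        b = manual_map("b", [F1] * 3, chrom="2")
        with pytest.raises(ValueError):
            compare_maps(a, b)


def sib_mating_chain_expected_fixation() -> float:
    """Expected sib matings to fixation at one locus from Aa x Aa, by
    absorbing-Markov-chain matrix inversion (the independent oracle)."""
    def offspring_dist(g1, g2):
        # genotype = number of 'a' alleles / 2: 0 = AA, 1 = Aa, 2 = aa
        def gamete(g):
            return {0: {0: 1.0}, 1: {0: 0.5, 1: 0.5}, 2: {1: 1.0}}[g]
        dist = {0: 0.0, 1: 0.0, 2: 0.0}
        for a1, p1 in gamete(g1).items():
            for a2, p2 in gamete(g2).items():
                dist[a1 + a2] += p1 * p2
        return dist

    pairs = [(i, j) for i in range(3) for j in range(i, 3)]
    index = {p: k for k, p in enumerate(pairs)}
    T = np.zeros((len(pairs), len(pairs)))
    for (g1, g2), k in index.items():
        if (g1, g2) in ((0, 0), (2, 2)):
            T[k, k] = 1.0
            continue
        d = offspring_dist(g1, g2)
        for i in range(3):
            for j in range(3):
                T[k, index[(min(i, j), max(i, j))]] += d[i] * d[j]
    transient = [k for (g1, g2), k in index.items()
                 if (g1, g2) not in ((0, 0), (2, 2))]
    Q = T[np.ix_(transient, transient)]
    t = np.linalg.solve(np.eye(len(Q)) - Q, np.ones(len(Q)))
    return float(t[transient.index(index[(1, 1)])])


class TestFixationStudy:
    def test_single_locus_matches_markov_chain_oracle(self):
        """Simulated single-locus fixation time equals the exact sib-mating
        chain expectation (filial generation = chain steps + 1)."""
        genome = GenomeModel([Chromosome("1", 1000, 0.0)])
        rng = np.random.default_rng(607)
        n = 20_000
        gens = np.array([mm.simulate_sib_lineage(genome, rng)[1]
                         for _ in range(n)], dtype=float)
        expected = sib_mating_chain_expected_fixation() + 1
        se = gens.std(ddof=1) / np.sqrt(n)
        assert gens.mean() == pytest.approx(expected, abs=3.5 * se)

    def test_landmark_ordering_and_panel_maximum(self):
        genome = GenomeModel([Chromosome("1", 10_000_000, 100.0)])
        rng = np.random.default_rng(608)
        s = fixation_time_study(genome, n_strains=4, n_lineages=40, n_panels=10,
                                rng=rng)
        assert s.mean_generation_het_below_1pct <= s.mean_generation_fixed
        assert s.mean_generation_fixed <= s.mean_generation_panel_fixed

    def test_fixation_time_increases_with_map_length(self):
        rng = np.random.default_rng(609)
        means = []
        for cM in (50.0, 400.0, 1600.0):
            genome = GenomeModel([Chromosome("1", 50_000_000, cM)])
            s = fixation_time_study(genome, n_strains=1, n_lineages=150,
                                    n_panels=0, rng=rng)
            means.append(s.mean_generation_fixed)
        assert means[0] < means[1] < means[2]

    def test_inconsistent_summary_rejected(self):
        with pytest.raises(ValueError):
            FixationSummary(30.0, 20.0, None, 1, 0, 1, 0.01)


class TestPredictionInterval:
    def test_zero_length_map_gives_degenerate_interval(self):
        genome = GenomeModel([Chromosome("1", 1_000_000, 0.0)])
        founders = mm.FounderSet(["a", "b"], np.zeros((2, 1), dtype=np.int8))
        cfg = mm.BreedingConfig(max_sib_generations=100)
        pi = recombination_prediction_interval(founders, cfg, genome, 100,
                                               np.random.default_rng(610))
        assert (pi.mean, pi.lower, pi.upper) == (0.0, 0.0, 0.0)

    def test_classical_interval_covers_map_expansion_mean(
            self, toy_genome, toy_founders):
        cfg = mm.BreedingConfig(max_sib_generations=200)
        pi = recombination_prediction_interval(toy_founders, cfg, toy_genome, 150,
                                               np.random.default_rng(611))
        morgans = toy_genome.total_genetic_length_cM / 100
        assert pi.lower < 4 * morgans < pi.upper
        assert pi.mean == pytest.approx(4 * morgans, rel=0.10)

    def test_advanced_interval_lies_above_classical_mean(
            self, toy_genome, toy_founders):
        rng = np.random.default_rng(612)
        classical = recombination_prediction_interval(
            toy_founders, mm.BreedingConfig(max_sib_generations=200),
            toy_genome, 120, rng)
        advanced = recombination_prediction_interval(
            toy_founders, mm.BreedingConfig(panel_type="ris_advanced",
                                            n_outcross_generations=12,
                                            outcross_pool_size=24,
                                            max_sib_generations=200),
            toy_genome, 100, rng)
        assert advanced.lower > classical.mean
        assert advanced.mean > classical.mean

    def test_too_few_replicates_rejected(self, toy_genome, toy_founders):
        with pytest.raises(ValueError):
            recombination_prediction_interval(
                toy_founders, mm.BreedingConfig(), toy_genome, 10,
                np.random.default_rng(0))


class TestClosedFormQuantities:
    def test_background_donor_fraction(self):
        assert expected_background_donor_fraction(9) == pytest.approx(0.001953125)
        assert f"{100 * expected_background_donor_fraction(9):.1g}" == "0.2"
        assert expected_background_donor_fraction(1) == 0.5
        assert expected_background_donor_fraction(0) == 1.0
        with pytest.raises(ValueError):
            expected_background_donor_fraction(-1)

    def test_conversion_rate_estimate(self):
        rate = conversion_rate_estimate([17, 7, 4], typical_informative=200_000)
        assert rate == pytest.approx(100 * 28 / 3 / 200_000)
        assert f"{rate:.1g}" == "0.005"
        assert conversion_rate_estimate([0, 0], typical_informative=1000) == 0.0
        doubled = conversion_rate_estimate([34, 14, 8], typical_informative=200_000)
        assert doubled == pytest.approx(2 * rate)

    def test_conversion_rate_uses_mean_informative_count(self):
        a = conversion_rate_estimate([10], informative_counts=[100_000, 300_000])
        assert a == pytest.approx(100 * 10 / 200_000)

    def test_complete_css_panel_size_is_22(self):
        assert css_panel_size(mm.mouse_default()) == 22


class TestAlleleFrequencyBalance:
    def test_balanced_panel_shows_no_distortion(self, ris_panel):
        df = mm.allele_frequency_balance(ris_panel["maps"])
        assert not df["imbalanced"].any()
        assert ((df["n_founder1"] + df["n_founder2"])
                <= len(ris_panel["maps"])).all()

    def test_fully_distorted_marker_is_flagged(self):
        maps = {f"s{i}": manual_map(f"s{i}", [F1] * 30) for i in range(40)}
        df = mm.allele_frequency_balance(maps)
        assert df["imbalanced"].all()
        assert (df["n_founder1"] == 40).all()


class TestHeterozygositySummary:
    def test_clean_fixed_panel_is_all_zero(self):
        maps = {f"s{i}": manual_map(f"s{i}", [F1] * 10) for i in range(4)}
        table = heterozygosity_summary({"panel": maps})
        row = table.loc["panel"]
        assert row[["n_het", "pct_het", "n_deletion", "pct_duplication"]].sum() == 0

    def test_recovers_injected_rates_and_rounding(self):
        maps = {}
        for i in range(25):
            states = [F1] * 10 + ([HET] * 3 if i < 9 else [F1] * 3)
            maps[f"s{i}"] = manual_map(f"s{i}", states)
        cnvs = {f"s{i}": ([mm.CnvCall("1", 0, 30_000, "deletion", "homozygous",
                                      12, 9.0)] if i < 5 else [])
                for i in range(25)}
        table = heterozygosity_summary({"p": maps}, {"p": cnvs})
        row = table.loc["p"]
        assert row["n_het"] == 9 and row["pct_het"] == 36
        assert row["n_deletion"] == 5 and row["pct_deletion"] == 20
        assert row["n_duplication"] == 0
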