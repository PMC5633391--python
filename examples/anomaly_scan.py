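"""Inject and recover anomalies in a chromosome substitution strain.

Builds a consomic strain (donor chromosome on a host background), injects a
contamination segment, a heterozygous deletion and a single-marker gene
conversion, and shows that each detector recovers its target — and only
its target.
"""

import numpy as np

import mosaicmap as mm
from mosaicmap.anomalies import CssDesign

spec = {"chromosomes": [{"name": "1", "length_bp": 60_000_000,
                         "genetic_length_cM": 30.0}],
        "snp_spacing_bp": 20_000, "invariant_spacing_bp": 6_000}
genome = mm.build_genome_model(spec, seed=6)
rng = np.random.default_rng(7)
founders = mm.simulate_founders(genome, informative_fraction=0.35,
                                extra_founders=1, rng=rng,
                                labels=["B6", "A", "DBA"])

cfg = mm.BreedingConfig(panel_type="css", donor_chrom="1",
                        n_backcross_meioses=9)
strain = mm.breed_css(founders, cfg, genome, rng, name="B6.A-1")

info = founders.informative_mask()
snp = genome.markers[genome.markers["probe_class"] == "snp"]
site = int(snp.loc[info, "pos"].to_numpy()[900])
strain = mm.inject_anomalies(strain, [
    mm.ContaminationSpec("1", 20_000_000, 28_000_000, "DBA"),
    mm.CnvSpec("1", 40_000_000, 40_150_000, 1),          # heterozygous deletion
    mm.GeneConversionSpec("1", site - 250, site + 250, "B6")])

noise = mm.NoiseModel(probe_seed=8)
pure = mm.founder_strain_genomes(founders, genome)
table = mm.emit_intensities(pure + [strain], founders, noise, genome, rng,
                            replicates={p.name: 8 for p in pure})
ref = mm.build_founder_reference(
    table, {f: [s for s in table.samples if s.startswith(f + "_r")]
            for f in founders.panel})
calls = mm.call_genotypes(table, ref, samples=[strain.name])
hmap, _ = mm.fit_haplotype_map(calls, strain.name)
design = CssDesign("1")

for c in mm.detect_contamination(table, strain.name, ref):
    print(f"contamination {c.start_bp / 1e6:.1f}-{c.end_bp / 1e6:.1f} Mb: "
          f"{c.n_discordant}/{c.n_snps} noninformative SNPs discordant")
for c in mm.detect_cnv(table, strain.name, ref):
    print(f"CNV {c.start_bp / 1e6:.2f}-{c.end_bp / 1e6:.2f} Mb: "
          f"{c.zygosity} {c.direction}, {c.n_probes} probes, t={c.segment_t:.1f}")
for c in mm.detect_gene_conversions(hmap, calls, table, ref, design):
    print(f"gene conversion at {c.positions[0]:,} bp "
          f"(injected at {site:,} bp), flanked by "
          f"{c.flank_donor_left}/{c.flank_donor_right} donor calls")
for b in mm.classify_unexpected_blocks(hmap, design):
    print(f"unexpected block {b.start_bp / 1e6:.1f}-{b.end_bp / 1e6:.1f} Mb: "
          f"{b.blk_class}")
print("\nEach detector recovers its injected anomaly, localised to the")
print("injected interval; the contaminated segment additionally surfaces as")
print("unexpected haplotype blocks, since its calls no longer match the")
print("designed donor state.")
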