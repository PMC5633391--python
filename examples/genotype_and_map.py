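"""Full pipeline: intensities -> A/B/N calls -> founder haplotype map.

Emits array-style (average, contrast) intensities for 3 simulated RIS
strains plus founder replicates, selects informative SNPs, calls genotypes
against the founder clusters, smooths them with the iterative Viterbi HMM
and prints the reconstructed haplotype blocks next to the ground truth.
"""

import numpy as np

import mosaicmap as mm

spec = {"chromosomes": [{"name": str(i + 1), "length_bp": 130_000_000,
                         "genetic_length_cM": 70.0} for i in range(3)],
        "snp_spacing_bp": 325_000, "invariant_spacing_bp": 650_000}
genome = mm.build_genome_model(spec, seed=3)
rng = np.random.default_rng(4)
founders = mm.simulate_founders(genome, informative_fraction=0.35, rng=rng,
                                labels=["B6", "D2"])
cfg = mm.BreedingConfig(max_sib_generations=60)
strains = [mm.breed_ris(founders, cfg, genome, rng, name=f"RIS{i}")
           for i in range(3)]

noise = mm.NoiseModel(probe_seed=5)  # sd 0.08, 1% compromised probes
pure = mm.founder_strain_genomes(founders, genome)
table = mm.emit_intensities(pure + strains, founders, noise, genome, rng,
                            replicates={p.name: 8 for p in pure})
ref = mm.build_founder_reference(
    table, {f: [s for s in table.samples if s.startswith(f + "_r")]
            for f in founders.panel})
print(f"informative SNPs: {ref.n_informative} / {len(ref.informative)}")

calls = mm.call_genotypes(table, ref, samples=[s.name for s in strains])
for strain in strains:
    hmap, params = mm.fit_haplotype_map(calls, strain.name)
    events = mm.extract_recombination_intervals(hmap)
    truth = mm.truth_map(strain, genome, calls.probes, founders)
    agree = np.mean([np.mean(hmap.states[c] == truth.states[c])
                     for c in truth.chromosomes])
    print(f"\n{strain.name}: {len(events)} recombination events, "
          f"fitted tau={params.tau:.2e}, marker agreement {100 * agree:.2f}%")
    for b in hmap.blocks("1"):
        print(f"  chr1 {b.start_bp / 1e6:7.2f}-{b.end_bp / 1e6:7.2f} Mb  "
              f"{b.state_name}")
print("\nBlocks alternate between the two founders; the marker agreement")
print("column shows the fraction of informative markers assigned the true")
print("founder state (typically >99% at this noise level).")
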