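"""Shared fixtures: small genomes, founder sets and a simulated panel.

Everything is generated programmatically with fixed seeds; heavier shared
artefacts are session-scoped so the suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pytest

import mosaicmap as mm


@pytest.fixture(scope="session")
def toy_genome() -> mm.GenomeModel:
    """Five 130 Mb / 70 cM autosomes with ~400 SNP + 200 invariant probes each."""
    spec = {"chromosomes": [{"name": str(i + 1), "length_bp": 130_000_000,
                             "genetic_length_cM": 70.0} for i in range(5)],
            "snp_spacing_bp": 325_000, "invariant_spacing_bp": 650_000}
    return mm.build_genome_model(spec, seed=11)


@pytest.fixture(scope="session")
def dense_genome() -> mm.GenomeModel:
    """One 60 Mb chromosome at array-like density (20 kb SNP / 6 kb invariant)."""
    spec = {"chromosomes": [{"name": "1", "length_bp": 60_000_000,
                             "genetic_length_cM": 30.0}],
            "snp_spacing_bp": 20_000, "invariant_spacing_bp": 6_000}
    return mm.build_genome_model(spec, seed=12)


@pytest.fixture(scope="session")
def toy_founders(toy_genome) -> mm.FounderSet:
    rng = np.random.default_rng(21)
    return mm.simulate_founders(toy_genome, informative_fraction=0.35,
                                extra_founders=1, rng=rng,
                                labels=["B6", "D2", "CAST"])


@pytest.fixture(scope="session")
def dense_founders(dense_genome) -> mm.FounderSet:
    rng = np.random.default_rng(22)
    return mm.simulate_founders(dense_genome, informative_fraction=0.35,
                                extra_founders=1, rng=rng,
                                labels=["B6", "A", "DBA"])


@pytest.fixture(scope="session")
def noise_model() -> mm.NoiseModel:
    return mm.NoiseModel(probe_seed=31)


def make_reference(table: mm.IntensityTable, founders: mm.FounderSet,
                   **kwargs) -> mm.FounderReference:
    reps = {f: [s for s in table.samples if s.startswith(f + "_r")]
            for f in founders.panel}
    return mm.build_founder_reference(table, reps, **kwargs)


def emit_panel(strains, founders, noise, genome, rng, founder_reps=8):
    pure = mm.founder_strain_genomes(founders, genome)
    return mm.emit_intensities(pure + list(strains), founders, noise, genome, rng,
                               replicates={p.name: founder_reps for p in pure})


@pytest.fixture(scope="session")
def ris_panel(toy_genome, toy_founders, noise_model):
    """10 classical RIS strains with intensities, reference, calls and maps."""
    rng = np.random.default_rng(41)
    cfg = mm.BreedingConfig(panel_type="ris_classical", max_sib_generations=60)
    strains = [mm.breed_ris(toy_founders, cfg, toy_genome, rng, name=f"RIS{i:02d}")
               for i in range(10)]
    table = emit_panel(strains, toy_founders, noise_model, toy_genome, rng)
    ref = make_reference(table, toy_founders)
    calls = mm.call_genotypes(table, ref, samples=[s.name for s in strains])
    maps = mm.fit_panel(calls)
    return {"genome": toy_genome, "founders": toy_founders, "strains": strains,
            "table": table, "ref": ref, "calls": calls, "maps": maps}
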