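# mosaicmap

Founder haplotype maps, anomaly screens and breeding simulation for
two-founder mouse strain panels — recombinant inbred strains (RIS) and
chromosome substitution (consomic, CSS) strains.

## The problem

The genome of an RIS is a fixed mosaic of its two founder genomes,
assembled by an intercross followed by generations of brother–sister
mating; a CSS carries one donor-strain chromosome on an otherwise pure
host background, built by marker-assisted backcrossing. Genotyping such a
strain on a two-channel SNP array and comparing each probe's
(average, contrast) signal directly with the two founders' cluster centres
yields a call **A** (near founder 1), **B** (near founder 2) or **N**
(near neither — no-call or heterozygous). Smoothing these calls along each
chromosome with a three-state hidden Markov model (founder 1 / founder 2 /
heterozygous), decoded by the Viterbi algorithm with an iteratively
re-estimated per-marker transition probability τ, produces the strain's
founder haplotype blocks and the *recombination intervals* — the marker
gaps that must contain each crossover.

On top of the maps the package screens for everything that should not be
there: residual heterozygosity, contamination by a non-founder strain
(discordant signal at noninformative SNPs, segmented by a two-state HMM,
reported only with ≥3 discordant SNPs), de novo deletions and duplications
(runs of ≥10 invariant probes spanning >20 kb with segment t-statistic >5),
gene conversions (isolated host-genotype markers inside donor haplotype on
the substituted chromosome), unexpected haplotype blocks in consomics, and
sister strains (excess sharing of same-polarity recombination junctions,
resampling Z-score > 5).

Because real array data for these panels is not bundled, the package
includes a first-class forward-in-time simulator: Poisson crossovers
(Haldane, no interference), sexed pedigrees (X recombines only in females;
Y and the mitochondrial genome are clonal), classical and advanced RIS
breeding, marker-assisted CSS construction, anomaly injection with a
ground-truth ledger, and a two-channel intensity emulator. Every detector
is validated against that ground truth.

## A worked example

`examples/genotype_and_map.py` simulates three RIS strains on a
three-chromosome genome, emits noisy intensities (sd 0.08, 1% compromised
probes), builds the founder reference, calls genotypes and fits the maps:

```
informative SNPs: 408 / 1200

RIS0: 7 recombination events, fitted tau=1.73e-02, marker agreement 99.74%
  chr1    1.77-  48.23 Mb  F1
  chr1   48.52-  65.23 Mb  F2
  chr1   66.82-  92.85 Mb  F1
  chr1   93.22- 122.32 Mb  F2
  chr1  123.55- 128.92 Mb  F1
```

About a third of SNPs separate the founders and become informative; each
strain's chromosomes resolve into alternating founder blocks, and marker
agreement against the simulation's ground truth is >99% (the map-level
analogue of a <1% genotyping error rate). The other scripts in
`examples/` demonstrate panel simulation with residual heterozygosity,
the anomaly scan on a consomic strain, the fixation-time study and
sister-strain detection — each prints a short interpretation of its
numbers.

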