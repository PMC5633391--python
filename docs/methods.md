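# Methods

This note records the models behind `mosaicmap`, the parameters that
matter, and the design choices made where more than one reasonable option
existed. Nothing here states a number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Breeding simulator

**Meiosis.** Crossover counts per chromosome are Poisson with mean equal
to the genetic length in Morgans, placed uniformly in genetic distance
(Haldane model: no interference, no obligate chiasma). Each chromosome
carries a single cM/bp rate, so genetic-uniform placement is bp-uniform.
This is the simplest model consistent with the simulation literature the
map-expansion and fixation results rest on; interference would shorten the
far tail of the per-chromosome crossover count but barely moves the
panel-level means checked here.

**Sex and inheritance classes.** Pedigrees are sexed. Autosomes recombine
in both sexes; the X recombines only in female meiosis and males pass
their single X intact to daughters; Y (father→son) and the mitochondrial
genome (mother→offspring) are clonal. In a two-founder panel Y and mito
are fixed from the F1 onward and are excluded from heterozygosity
denominators.

**Genome model.** The mouse-default genome has 19 autosomes plus X with
mm10-scale physical lengths and genetic lengths assigned proportionally to
physical length so the recombining map totals 1400 cM (~14 Morgans), plus
clonal Y and mito records. Marker panels are quasi-regular grids with
jitter; spacing is configurable (tests use 6 kb–50 Mb depending on what
the test exercises, far sparser than a real array except where anomaly
detection needs array-like density).

**RIS breeding.** Classical lines are F1×F1 followed by sib mating for
`max_sib_generations` (default 25 — colonies genotyped at finite
inbreeding retain residual heterozygosity, which the ledger records as
ground truth) or until complete fixation. Advanced lines insert
`n_outcross_generations` of random intercross in a small breeding pool
(default 16) before inbreeding; the pool size controls how much of the
extra recombination survives drift. `breed_sisters` forks one lineage at a
chosen generation so junctions fixed before the split are shared — the
ground truth for sister-strain detection.

**CSS breeding.** An N-generation consomic takes `n_backcross_meioses`
(default 9, the N10 convention) marker-assisted backcrosses: each
generation one offspring heterozygous donor/host at every selection marker
is kept, followed by an intercross fixing the donor chromosome at the
markers. Y, mito and X substitutions follow their inheritance rules
(carrier sex is forced appropriately). Default selection markers are a
~20 Mb ladder spanning the chromosome, not just the two ends: with
end-only selection, a gamete carrying donor alleles at both ends but a
host segment in between is accepted ~20% of the time per generation
(even-crossover gametes), and most strains would end with large internal
host gaps — contrary to how consomics are actually built and audited.
End-only designs remain available via `selection_marker_positions` and are
what produces distal passenger blocks in the tests. Host residue beyond
the outermost marker, residual background donor segments and unfixed
heterozygosity are all retained as ground truth.

**Fixation-time conventions.** The cited landmark figures do not pin down
their conventions, so the package fixes them once: strain heterozygosity
is the bp fraction of the recombining genome *still segregating in the
breeding pair* (heterozygosity measured on one animal underestimates
segregating variation — a strain is "done" when nothing segregates, not
when one sampled mouse happens to be homozygous); generations are filial
numbers (F1 = founder-cross product; the first sib litter is generation 2,
the numbering used for inbred colonies); complete fixation means all
extant haplotypes identical at every bp. Under these conventions the
acceptance run (4400 lineages, mouse-default map, seed-controlled)
reproduces the expected ~24 / ~36 / ~53-generation landmarks within the
stochastic tolerance.

**Intensity model.** Genotype classes emit from configurable
(average, contrast) centres — AA (1.0, +0.6), BB (1.0, −0.6),
AB (1.0, 0.0), null (0.2, 0.0) — with per-channel Gaussian noise
(sd 0.08), chosen to give cluster separation comparable to real
two-channel arrays (~15 sd between homozygous clusters). A fraction of
probes (1%) are "bad": they receive an extra per-sample offset
(sd 0.4), emulating probes compromised by polymorphisms near the probe
sequence; these drive the realistic sub-1% call error rate. Invariant
probes emit the invariant average scaled by the copy-number law
{0: 0.2, 1: 0.6, 2: 1.0, 3: 1.4, 4: 1.8}; copy-0 regions silence SNP
probes to the null class too. Bad-probe identity derives from a dedicated
`probe_seed` so founders and samples see the same array.

**What the emulator does not model:** spatial array artefacts, batch
effects, probe GC/affinity structure, allele-specific intensity asymmetry,
and sequence-level variation. Passing tests therefore demonstrate that the
algorithms are correct under a well-behaved signal model with realistic
noise, error rates and anomaly footprints — not that thresholds are tuned
for any particular real platform.

## Genotyping

Founder cluster centres are replicate means per probe; dispersion is the
pooled per-probe replicate sd averaged over the two channels, floored at
`min_dispersion` (0.02) so single-replicate references remain usable. A
SNP is informative iff the Euclidean centre separation exceeds
`sep_threshold` (6) dispersions; a sample is called A/B iff it lies within
`call_radius` (3) dispersions of a founder centre *and* strictly closer to
it, with exact ties conservatively N. Distances are Euclidean in
(average, contrast) — a single per-probe dispersion rather than a full
covariance keeps the reference estimable from few replicates. With
noise sd σ and exact centres, the N rate among true homozygotes is the
χ²(2) tail beyond 3σ, exp(−9/2) ≈ 1.1%; the tests verify this closed form.

## Haplotype inference

Three states (founder 1, founder 2, Het) with fixed emissions —
e(F1) = {A: 0.98, B: 0.005, N: 0.015}, e(F2) mirrored,
e(Het) = {A: 0.05, B: 0.05, N: 0.90} — and a single per-step transition
probability τ shared by all chromosomes of a strain (split evenly between
the two target states). Fitting alternates Viterbi decoding with
re-estimating τ as (state changes)/(adjacent-marker steps), floored at
1e-6, until the decoded paths repeat or 20 iterations pass (then flagged
non-converged). Emissions are deliberately not re-estimated. Viterbi ties
break toward staying in the current state, then toward founder 1, making
decoding fully deterministic; the suite checks the decoder against
exhaustive path enumeration on short sequences.

A consequence worth knowing: with ~1% emission error the decoder smooths
away genuine single-marker blocks — exactly why isolated host-genotype
markers on a donor chromosome must be hunted separately as gene
conversions. In the error-free limit, pass `noiseless_emission()` so that
the emission error is far below τ; then the decoded map equals the ground
truth exactly, single-marker blocks included.

Recombination events are changes between adjacent *homozygous* blocks; a
Het block flanked by the two different founders is spanned by one event
whose polarity is taken across it. The event's interval runs from the last
marker of the preceding homozygous block to the first marker of the
following one.

## Anomaly detection

**Contamination.** Noninformative SNPs (founders share a cluster) are
marked discordant when the signal is farther than 4 dispersions from the
shared centre *and* not at the null cluster (a deleted region gives
no-calls, not foreign alleles). The radius is wider than the 3-dispersion
call radius because centre and dispersion estimation error would otherwise
put 1–3% of clean probes outside 3σ; the per-probe dispersion is also
floored at the panel median for the same reason. A two-state HMM
(background/contaminated; discordance rates 0.005 / 0.30, switch 1e-4)
segments the sequence; contaminated segments are reported only with ≥3
discordant SNPs. Note the ≥3 rule is a *reporting* filter: the segmenter
itself needs ~5 clustered discordant SNPs to overcome the switch penalty,
so sparse marginal segments are (intentionally) not called.

**CNVs.** Per invariant probe, z = (x − μ_ref)/sd_ref against founder
replicate statistics. Candidate segments are maximal same-signed runs with
|z| > 2, bridged across ≤2 non-qualifying probes; a segment is called when
it covers ≥10 probes, spans >20 kb and its t-statistic
|mean z|·√n exceeds 5. The t threshold is segment-level: a one-copy change
shifts the mean by ~5 sd, so a per-probe |z| > 5 rule would miss
essentially every heterozygous CNV while the segment statistic detects a
10-probe run at t ≈ 16. The "≤10 probes" phrasing that sometimes
accompanies this filter is read as a minimum-evidence rule (≥10):
rewarding sparse coverage would invert the filter's purpose. Zygosity is
assigned by whether the mean intensity ratio is nearer the 1-copy (or
3-copy) law than the 0-copy (or 4-copy) law.

**Gene conversions.** Within donor-state blocks on the designed donor
chromosome: runs of ≤2 host calls flanked on each side by ≥5 donor calls
among the nearest 7 markers with no host call among them, and with the
run's intensities within the call radius of the host cluster (confident
host, not N). Longer host runs are left to block classification — the run
limit is the operational boundary between a conversion tract (<1 kb,
typically one marker) and a short haplotype block. Injected conversion
tracts are applied to both haplotypes: conversions predate fixation, so
they are carried homozygous, which is also what makes them callable.

**Unexpected blocks.** Every block contradicting the CSS design is
reported with Table-style columns (start, end, length, should-be,
actually-is). Classes: host blocks touching an end of the donor chromosome
are `end_passenger` (residue beyond the outermost selection marker), host
blocks strictly inside are `internal_donor_gap`, donor blocks on
background chromosomes are `off_chromosome_donor`, and Het blocks anywhere
are `het_residual` (one class per block; Het is classified as residual
heterozygosity regardless of location, since its cause — incomplete
fixation — is the same everywhere).

## Panel statistics

**Shared events** cluster recombination intervals per chromosome by
single-linkage bp overlap (half-open: touching intervals do not overlap)
and record polarity agreement. **Sister detection** counts same-polarity
overlapping intervals between two strains and compares with a null in
which each strain's events are replaced by equally sized draws (with
replacement) from the pooled panel events — preserving recombination
hotspots — with B = 1000 seeded resamples; drawing the *identical* pooled
event on both sides is excluded from null overlap counting (it would
overlap by identity, inflating the null by |Ea||Eb|/|pool|), while
near-identical events from different strains still count. Z > 5.0
(strict) flags a pair; zero-event strains and degenerate nulls get Z = 0.
Strains with known shared ancestry can be excluded from the pool.
**Map comparison** reports concordance over bp assigned a homozygous
founder in both maps (missing when no such bp exists) and the reduction in
summed recombination-interval length. The ~90% uncertainty reduction at
10× marker density holds for regular grids; thinned (informative-subset)
grids give less because size-biased gap lengths shrink sublinearly.

## Numerical and degenerate-input choices

Internal coordinates are 0-based half-open; all files are written (and
read back) 1-based inclusive, with the converters centralised in `io.py`.
Viterbi runs in log space; exact score ties are resolved by the documented
preference order. Zero-sd reference probes are excluded from CNV scanning
with a warning. Empty call sequences, missing founders, overlapping
same-kind anomaly injections, out-of-bounds intervals and chromosome-set
mismatches raise `ValueError` rather than guessing. Every stochastic
entry point takes an explicit `numpy.random.Generator` or seed; the CLI
logs all thresholds and seeds.

## Problem sizes

The suite validates on deliberately small genomes: a 5×130 Mb / 70 cM toy
genome for pipeline tests, a single dense 60 Mb chromosome (6–20 kb probe
spacing) for anomaly recovery, and the mouse-default 14-Morgan map with
sparse markers for breeding-theory checks (500+ lineages in-suite; 4400 in
the acceptance script; 20 000 replicates for the single-locus
Markov-chain and decay-rate oracles). These sizes give Monte-Carlo
standard errors comfortably inside the asserted tolerances while keeping
the full suite to a few minutes.

## Known limitations

Transition probability is per adjacent-marker step, not per cM, so very
uneven marker spacing distorts block boundaries slightly (mirroring the
single re-estimated parameter of the original approach). The contamination
scan assumes a single contaminant haplotype state and reports segments,
not sources. The CSS selection model idealises breeders (unlimited
offspring per generation until one passes selection). Allele-frequency
balance beyond a per-marker binomial check, and epistatic selection during
breeding, are out of scope.
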