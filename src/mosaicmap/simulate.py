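"""Forward-in-time breeding simulator and array-intensity emulator.

Produces ground-truthed recombinant inbred (RIS) and chromosome substitution
(CSS) strain genomes as founder-label mosaics, injects anomalies
(contamination, CNVs, gene-conversion tracts) with a recoverable ledger, and
emits two-channel array intensities from them.

Model assumptions
-----------------
* Crossovers per meiosis are Poisson with mean ``genetic_length_cM / 100``
  and are placed uniformly in genetic distance (Haldane model, no
  interference, no obligate chiasma).
* The X recombines only in female meiosis; males transmit their single X
  intact to daughters.  Y and the mitochondrial genome are clonal.
* Sib mating starts from an F1 brother-sister pair; generation ``g`` counts
  sib matings after the F1 cross (generation 1 = F2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import AUTOSOME, MITO, X, Y, Chromosome, GenomeModel
from .intensities import IntensityTable
from .mosaic import Mosaic, all_equal, diff_bp

FEMALE = "F"
MALE = "M"

# genotype class codes used by the intensity emitter
AA, BB, AB, NULL = 0, 1, 2, 3
CLASS_NAMES = {AA: "AA", BB: "BB", AB: "AB", NULL: "null"}


# ---------------------------------------------------------------------------
# founders

@dataclass
class FounderSet:
    """Panel founders (exactly two) plus optional contaminant founders.

    ``alleles`` has one row per founder (in ``labels`` order) and one column
    per SNP probe of the genome model's marker table, giving the true allele
    cluster (0 = A cluster, 1 = B cluster).
    """

    labels: list[str]
    alleles: np.ndarray
    n_panel: int = 2

    def __post_init__(self) -> None:
        if self.n_panel != 2 or len(self.labels) < 2:
            raise ValueError("a panel needs exactly 2 panel founders")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("founder labels must be distinct")
        if self.alleles.shape[0] != len(self.labels):
            raise ValueError("alleles rows must match founder labels")

    @property
    def panel(self) -> tuple[str, str]:
        return self.labels[0], self.labels[1]

    def code(self, label: str) -> int:
        return self.labels.index(label)

    def informative_mask(self) -> np.ndarray:
        """True ground-truth informativeness: panel founders differ."""
        return self.alleles[0] != self.alleles[1]


def simulate_founders(genome: GenomeModel, informative_fraction: float = 0.35,
                      extra_founders: int = 0, extra_divergence: float = 0.30,
                      rng: np.random.Generator | None = None,
                      labels: list[str] | None = None) -> FounderSet:
    """Draw founder allele clusters at every SNP probe.

    ``informative_fraction`` is the probability the two panel founders fall
    in opposite clusters at a probe; contaminant founders differ from
    founder 1 at rate ``extra_divergence`` independently per probe.
    """
    rng = np.random.default_rng() if rng is None else rng
    n_snp = int((genome.markers["probe_class"] == "snp").sum())
    if labels is None:
        labels = ["founder1", "founder2"] + [f"contaminant{i+1}" for i in range(extra_founders)]
    a1 = rng.integers(0, 2, size=n_snp, dtype=np.int8)
    flip = rng.random(n_snp) < informative_fraction
    rows = [a1, np.where(flip, 1 - a1, a1).astype(np.int8)]
    for _ in range(extra_founders):
        d = rng.random(n_snp) < extra_divergence
        rows.append(np.where(d, 1 - a1, a1).astype(np.int8))
    return FounderSet(labels, np.stack(rows))


# ---------------------------------------------------------------------------
# noise / intensity model

@dataclass
class NoiseModel:
    """Cluster geometry and noise of the emulated array.

    ``centers`` give (average, contrast) per genotype class; ``sd`` is the
    per-channel Gaussian noise; ``bad_probe_fraction`` of probes receive an
    additional per-sample offset of scale ``bad_probe_sd`` (emulating probes
    compromised by nearby polymorphisms); ``cnv_law`` maps copy number to a
    multiplicative shift of the average channel.
    """

    centers: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "AA": (1.0, 0.6), "BB": (1.0, -0.6), "AB": (1.0, 0.0), "null": (0.2, 0.0)})
    sd: float = 0.08
    bad_probe_fraction: float = 0.01
    bad_probe_sd: float = 0.4
    cnv_law: dict[int, float] = field(default_factory=lambda: {
        0: 0.2, 1: 0.6, 2: 1.0, 3: 1.4, 4: 1.8})
    invariant_average: float = 1.0
    probe_seed: int = 0

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("noise sd must be positive")
        if not (self.centers["AA"][1] * self.centers["BB"][1] < 0):
            raise ValueError("AA and BB contrast centers must have opposite signs")
        if self.cnv_law.get(2) != 1.0:
            raise ValueError("copy number 2 must map to shift 1.0")

    def center_array(self) -> np.ndarray:
        return np.array([self.centers[CLASS_NAMES[c]] for c in (AA, BB, AB, NULL)])


# ---------------------------------------------------------------------------
# breeding configuration

@dataclass
class BreedingConfig:
    """Design of a single strain's derivation.

    ``n_backcross_meioses`` follows the consomic "N" convention: an N10
    strain has had 9 backcross meioses after the F1.
    """

    panel_type: str = "ris_classical"  # ris_classical | ris_advanced | css
    n_outcross_generations: int = 0
    max_sib_generations: int = 25
    outcross_pool_size: int = 16
    donor_chrom: str | None = None
    n_backcross_meioses: int = 9
    selection_marker_positions: list[int] | None = None
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.panel_type not in ("ris_classical", "ris_advanced", "css"):
            raise ValueError(f"unknown panel type {self.panel_type!r}")
        for name in ("n_outcross_generations", "max_sib_generations", "n_backcross_meioses"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


# ---------------------------------------------------------------------------
# anomaly specs and ledger

@dataclass(frozen=True)
class AnomalyRecord:
    kind: str  # "contamination" | "cnv" | "gene_conversion" | "het_segment"
    chrom: str
    start: int  # 0-based half-open
    end: int
    detail: tuple = ()

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ContaminationSpec:
    chrom: str
    start: int
    end: int
    source: str  # founder label of the contaminating strain
    haplotypes: tuple[int, ...] = (0, 1)


@dataclass(frozen=True)
class CnvSpec:
    chrom: str
    start: int
    end: int
    copy_number: int  # 0..4, 2 = normal

    def __post_init__(self) -> None:
        if self.copy_number not in (0, 1, 2, 3, 4):
            raise ValueError("copy number must be in 0..4")


@dataclass(frozen=True)
class GeneConversionSpec:
    chrom: str
    start: int
    end: int
    to_label: str  # receiving haplotype is overwritten with this founder


@dataclass(frozen=True)
class HetSegmentSpec:
    """Force a residual-heterozygosity segment: haplotype 1 gets ``to_label``."""
    chrom: str
    start: int
    end: int
    to_label: str


CNV_SIZE_RANGE = (21_000, 8_400_000)     # observed size range of de novo CNVs
CONVERSION_LENGTH_RANGE = (50, 1000)     # gene-conversion tracts are short (<1 kb)


def random_cnv_spec(genome: GenomeModel, rng: np.random.Generator,
                    copy_number: int | None = None, chrom: str | None = None) -> CnvSpec:
    """CNV with log-uniform length in the observed 21 kb - 8.4 Mb range."""
    chroms = [c for c in genome.chromosomes if c.inheritance == AUTOSOME]
    c = genome.chromosome(chrom) if chrom else chroms[rng.integers(len(chroms))]
    length = int(math.exp(rng.uniform(math.log(CNV_SIZE_RANGE[0]),
                                      math.log(CNV_SIZE_RANGE[1]))))
    length = min(length, c.length_bp - 2)
    start = int(rng.integers(0, c.length_bp - length))
    if copy_number is None:
        copy_number = int(rng.choice([0, 1, 3, 4]))
    return CnvSpec(c.name, start, start + length, copy_number)


def random_conversion_spec(genome: GenomeModel, chrom: str, to_label: str,
                           rng: np.random.Generator) -> GeneConversionSpec:
    c = genome.chromosome(chrom)
    length = int(rng.integers(CONVERSION_LENGTH_RANGE[0], CONVERSION_LENGTH_RANGE[1] + 1))
    start = int(rng.integers(0, c.length_bp - length))
    return GeneConversionSpec(chrom, start, start + length, to_label)


# ---------------------------------------------------------------------------
# individuals and strain genomes

@dataclass
class Individual:
    """A diploid animal: per chromosome, the extant haplotype mosaics.

    Autosomes carry 2 mosaics; X carries 2 (female) or 1 (male); Y carries
    1 (male only); mito carries 1.
    """

    sex: str
    chromosomes: dict[str, tuple[Mosaic, ...]]

    def het_fraction(self, genome: GenomeModel) -> float:
        """bp fraction heterozygous over this animal's two-copy chromosomes."""
        het = tot = 0
        for c in genome.chromosomes:
            haps = self.chromosomes.get(c.name)
            if haps is None or len(haps) != 2:
                continue
            tot += c.length_bp
            het += diff_bp(haps[0], haps[1])
        return het / tot if tot else 0.0


@dataclass
class StrainGenome:
    """A (possibly incompletely inbred) strain, as sampled from one animal."""

    name: str
    sex: str
    chromosomes: dict[str, tuple[Mosaic, ...]]
    ledger: list[AnomalyRecord] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def haplotypes(self, chrom: str) -> tuple[Mosaic, ...]:
        return self.chromosomes[chrom]

    def labels_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """(n_haplotypes, n_positions) founder codes at marker positions."""
        return np.stack([h.label_at(positions) for h in self.chromosomes[chrom]])

    def het_intervals(self, chrom: str) -> list[tuple[int, int]]:
        haps = self.chromosomes[chrom]
        if len(haps) != 2:
            return []
        from .mosaic import merge_labels
        starts, ends, lab = merge_labels(list(haps))
        out: list[tuple[int, int]] = []
        for s, e, different in zip(starts, ends, lab[0] != lab[1]):
            if different:
                if out and out[-1][1] == s:
                    out[-1] = (out[-1][0], int(e))
                else:
                    out.append((int(s), int(e)))
        return out

    def breakpoints(self, chrom: str) -> np.ndarray:
        """Union of founder junction positions over the haplotypes."""
        bps = np.concatenate([h.breakpoints() for h in self.chromosomes[chrom]])
        return np.unique(bps)

    def n_breakpoints(self) -> int:
        return int(sum(len(self.breakpoints(c)) for c in self.chromosomes))

    def copy_number_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        cn = np.full(len(positions), 2, dtype=np.int8)
        for rec in self.ledger:
            if rec.kind == "cnv" and rec.chrom == chrom:
                inside = (positions >= rec.start) & (positions < rec.end)
                cn[inside] = rec.detail[0]
        return cn


def founder_strain_genomes(founders: FounderSet, genome: GenomeModel,
                           which: list[str] | None = None) -> list[StrainGenome]:
    """Pure (fully homozygous) genomes for founder reference samples."""
    out = []
    for label in which or list(founders.panel):
        code = founders.code(label)
        chroms: dict[str, tuple[Mosaic, ...]] = {}
        for c in genome.chromosomes:
            const = Mosaic.constant(c.length_bp, code)
            n = 1 if c.inheritance in (Y, MITO) else 2
            chroms[c.name] = (const,) * n
        out.append(StrainGenome(label, MALE, chroms,
                                meta={"founder_labels": list(founders.labels)}))
    return out


# ---------------------------------------------------------------------------
# meiosis

def simulate_meiosis(hap_a: Mosaic, hap_b: Mosaic, chrom: Chromosome,
                     rng: np.random.Generator) -> Mosaic:
    """One gamete from a pair of parental haplotypes.

    Crossover count is Poisson(cM/100); positions are uniform in genetic
    distance, which for the constant per-chromosome rate used here is
    uniform in bp.
    """
    if not chrom.recombining:
        raise ValueError(f"chromosome {chrom.name} ({chrom.inheritance}) does not recombine")
    k = rng.poisson(chrom.genetic_length_cM / 100.0)
    cur = int(rng.integers(2))
    haps = (hap_a, hap_b)
    if k == 0 or haps[0] is haps[1]:
        return haps[cur]
    xs = np.unique(rng.integers(1, chrom.length_bp, size=k))
    ends_parts, lab_parts = [], []
    lo = 0
    for hi in np.concatenate((xs, [chrom.length_bp])):
        hi = int(hi)
        e, l = haps[cur].restrict(lo, hi)
        ends_parts.append(e)
        lab_parts.append(l)
        lo = hi
        cur ^= 1
    return Mosaic(np.concatenate(ends_parts), np.concatenate(lab_parts),
                  validate=False).simplify()


def _gamete(parent: Individual, chrom: Chromosome, rng: np.random.Generator) -> Mosaic:
    haps = parent.chromosomes[chrom.name]
    if chrom.inheritance == AUTOSOME:
        return simulate_meiosis(haps[0], haps[1], chrom, rng)
    if chrom.inheritance == X:
        if parent.sex == FEMALE:
            return simulate_meiosis(haps[0], haps[1], chrom, rng)
        return haps[0]  # male X passes intact (to daughters)
    return haps[0]  # Y / mito: clonal


def make_offspring(mother: Individual, father: Individual, genome: GenomeModel,
                   rng: np.random.Generator, sex: str | None = None) -> Individual:
    if sex is None:
        sex = FEMALE if rng.random() < 0.5 else MALE
    chroms: dict[str, tuple[Mosaic, ...]] = {}
    for c in genome.chromosomes:
        if c.inheritance == AUTOSOME:
            chroms[c.name] = (_gamete(mother, c, rng), _gamete(father, c, rng))
        elif c.inheritance == X:
            mx = _gamete(mother, c, rng)
            chroms[c.name] = (mx, father.chromosomes[c.name][0]) if sex == FEMALE else (mx,)
        elif c.inheritance == Y:
            if sex == MALE and c.name in father.chromosomes:
                chroms[c.name] = (father.chromosomes[c.name][0],)
        elif c.inheritance == MITO:
            chroms[c.name] = (mother.chromosomes[c.name][0],)
    return Individual(sex, chroms)


def f1_pair(founders: FounderSet, genome: GenomeModel,
            dam_label: str | None = None) -> tuple[Individual, Individual]:
    """An F1 sister/brother pair from founder dam x founder sire."""
    dam = founders.code(dam_label) if dam_label else 0
    sire = 1 - dam
    def build(sex: str) -> Individual:
        chroms: dict[str, tuple[Mosaic, ...]] = {}
        for c in genome.chromosomes:
            cd = Mosaic.constant(c.length_bp, dam)
            cs = Mosaic.constant(c.length_bp, sire)
            if c.inheritance == AUTOSOME:
                chroms[c.name] = (cd, cs)
            elif c.inheritance == X:
                chroms[c.name] = (cd, cs) if sex == FEMALE else (cd,)
            elif c.inheritance == Y:
                if sex == MALE:
                    chroms[c.name] = (cs,)
            elif c.inheritance == MITO:
                chroms[c.name] = (cd,)
        return Individual(sex, chroms)
    return build(FEMALE), build(MALE)


# ---------------------------------------------------------------------------
# sib-mating lineage (fast path used by breeding and fixation studies)

class SibLineage:
    """A brother-sister mating chain with per-chromosome fixation tracking.

    Chromosomes whose extant haplotypes are all identical are marked fixed
    and skipped thereafter (gametes from a fixed pair are that haplotype
    regardless of crossovers, so the shortcut is exact).
    """

    def __init__(self, mother: Individual, father: Individual, genome: GenomeModel,
                 rng: np.random.Generator):
        self.genome = genome
        self.rng = rng
        self.mother = mother
        self.father = father
        self.generation = 0
        self._fixed: dict[str, bool] = {}
        for c in genome.chromosomes:
            self._fixed[c.name] = not c.recombining or self._chrom_fixed(c)

    def _extant(self, c: Chromosome) -> list[Mosaic]:
        return list(self.mother.chromosomes.get(c.name, ())) + \
            list(self.father.chromosomes.get(c.name, ()))

    def _chrom_fixed(self, c: Chromosome) -> bool:
        return all_equal(self._extant(c))

    def step(self) -> None:
        """One generation of sib mating; the offspring pair becomes the breeders."""
        g, rng = self.genome, self.rng
        daughter: dict[str, tuple[Mosaic, ...]] = {}
        son: dict[str, tuple[Mosaic, ...]] = {}
        for c in g.chromosomes:
            name = c.name
            if self._fixed[name]:
                d = self.mother.chromosomes.get(name)
                s = self.father.chromosomes.get(name)
                if d is not None:
                    daughter[name] = d
                if s is not None:
                    son[name] = s
                continue
            if c.inheritance == AUTOSOME:
                daughter[name] = (_gamete(self.mother, c, rng), _gamete(self.father, c, rng))
                son[name] = (_gamete(self.mother, c, rng), _gamete(self.father, c, rng))
            else:  # X
                fx = self.father.chromosomes[name][0]
                daughter[name] = (_gamete(self.mother, c, rng), fx)
                son[name] = (_gamete(self.mother, c, rng),)
        self.mother = Individual(FEMALE, daughter)
        self.father = Individual(MALE, son)
        self.generation += 1
        for c in g.chromosomes:
            if not self._fixed[c.name] and self._chrom_fixed(c):
                self._fixed[c.name] = True

    @property
    def fixed(self) -> bool:
        return all(self._fixed.values())

    def het_fraction(self) -> float:
        """Mean of the sib pair's individual bp heterozygosity fractions."""
        return 0.5 * (self.mother.het_fraction(self.genome) +
                      self.father.het_fraction(self.genome))

    def segregating_fraction(self) -> float:
        """bp fraction of the recombining genome not yet fixed in the pair.

        This is the strain-level heterozygosity rate: founder variation
        still segregating in the lineage, of which the heterozygosity seen
        in any one animal is an underestimate.
        """
        from .mosaic import merge_labels
        seg = tot = 0
        for c in self.genome.chromosomes:
            if not c.recombining:
                continue
            tot += c.length_bp
            if self._fixed[c.name]:
                continue
            starts, ends, lab = merge_labels(self._extant(c))
            bad = (lab != lab[0]).any(axis=0)
            seg += int(np.sum(ends[bad] - starts[bad]))
        return seg / tot if tot else 0.0


def simulate_sib_lineage(genome: GenomeModel, rng: np.random.Generator,
                         het_threshold: float = 0.01,
                         max_generations: int = 500,
                         founders: FounderSet | None = None) -> tuple[int, int]:
    """Sib-mate an F1 pair; return (first generation with strain
    heterozygosity below ``het_threshold``, first generation completely
    fixed).

    Strain heterozygosity is the bp fraction of the genome still
    segregating in the breeding pair.  Generations are filial numbers
    (F1 = founder-cross product, the first sib-mating litter is generation
    2), the numbering used for inbred mouse colonies.  Returns
    ``max_generations`` for landmarks not reached.
    """
    if founders is None:
        mother, father = _plain_f1(genome)
    else:
        mother, father = f1_pair(founders, genome)
    lineage = SibLineage(mother, father, genome, rng)
    gen_het = gen_fix = max_generations
    for g in range(2, max_generations + 1):
        lineage.step()
        if lineage.fixed:
            gen_fix = g
            if gen_het == max_generations:
                gen_het = g
            break
        if gen_het == max_generations and lineage.segregating_fraction() < het_threshold:
            gen_het = g
    return gen_het, gen_fix


def _plain_f1(genome: GenomeModel) -> tuple[Individual, Individual]:
    class _TwoLabels:
        labels = ["founder1", "founder2"]
        def code(self, label: str) -> int:
            return self.labels.index(label)
        panel = ("founder1", "founder2")
    fs = _TwoLabels()
    return f1_pair(fs, genome)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# RIS breeding

def breed_ris(founders: FounderSet, cfg: BreedingConfig, genome: GenomeModel,
              rng: np.random.Generator, name: str = "strain",
              sample_sex: str = MALE) -> StrainGenome:
    """Breed one RIS: (outcrossing for advanced panels, then) sib mating.

    Sib mating runs for ``cfg.max_sib_generations`` or until complete
    fixation; residual heterozygosity remaining at the cap is retained and
    recorded in the ledger as ``het_segment`` ground truth.
    """
    if cfg.panel_type not in ("ris_classical", "ris_advanced"):
        raise ValueError(f"breed_ris needs an RIS panel type, got {cfg.panel_type!r}")
    if len(founders.labels) < 2:
        raise ValueError("need at least 2 founders")
    mother, father = f1_pair(founders, genome)
    if cfg.panel_type == "ris_advanced" and cfg.n_outcross_generations > 0:
        mother, father = _outcross(mother, father, cfg, genome, rng)
    lineage = SibLineage(mother, father, genome, rng)
    while lineage.generation < cfg.max_sib_generations and not lineage.fixed:
        lineage.step()
    return _sample_strain(lineage, name, sample_sex, genome, founders)


def _outcross(mother: Individual, father: Individual, cfg: BreedingConfig,
              genome: GenomeModel, rng: np.random.Generator) -> tuple[Individual, Individual]:
    """Random intercross generations maintaining a small breeding pool."""
    n = max(4, cfg.outcross_pool_size)
    pool_f = [make_offspring(mother, father, genome, rng, FEMALE) for _ in range(n // 2)]
    pool_m = [make_offspring(mother, father, genome, rng, MALE) for _ in range(n // 2)]
    for _ in range(1, cfg.n_outcross_generations):
        new_f, new_m = [], []
        for _ in range(n // 2):
            dam = pool_f[rng.integers(len(pool_f))]
            sire = pool_m[rng.integers(len(pool_m))]
            new_f.append(make_offspring(dam, sire, genome, rng, FEMALE))
            new_m.append(make_offspring(dam, sire, genome, rng, MALE))
        pool_f, pool_m = new_f, new_m
    dam = pool_f[rng.integers(len(pool_f))]
    sire = pool_m[rng.integers(len(pool_m))]
    # final mating: its offspring are the sibs that found the inbreeding chain
    return (make_offspring(dam, sire, genome, rng, FEMALE),
            make_offspring(dam, sire, genome, rng, MALE))


def _sample_strain(lineage: SibLineage, name: str, sample_sex: str,
                   genome: GenomeModel, founders: FounderSet) -> StrainGenome:
    animal = lineage.mother if sample_sex == FEMALE else lineage.father
    chroms = {c: tuple(h.simplify() for h in haps)
              for c, haps in animal.chromosomes.items()}
    strain = StrainGenome(name, animal.sex, chroms,
                          meta={"generations": lineage.generation,
                                "fixed": lineage.fixed,
                                "founder_labels": list(founders.labels)})
    for cname, haps in chroms.items():
        if len(haps) == 2:
            for s, e in strain.het_intervals(cname):
                strain.ledger.append(AnomalyRecord("het_segment", cname, s, e))
    return strain


def breed_sisters(founders: FounderSet, cfg: BreedingConfig, genome: GenomeModel,
                  rng: np.random.Generator, split_generation: int,
                  names: tuple[str, str] = ("sister1", "sister2"),
                  sample_sex: str = MALE) -> tuple[StrainGenome, StrainGenome]:
    """Two strains branching from the same incompletely inbred ancestor pair.

    The lineage is sib-mated to ``split_generation``; both branches then
    continue independently from the same breeder pair, so recombination
    junctions fixed before the split are shared.
    """
    mother, father = f1_pair(founders, genome)
    shared = SibLineage(mother, father, genome, rng)
    for _ in range(split_generation):
        shared.step()
    out = []
    for name in names:
        branch = SibLineage(shared.mother, shared.father, genome, rng)
        branch.generation = shared.generation
        while branch.generation < cfg.max_sib_generations and not branch.fixed:
            branch.step()
        out.append(_sample_strain(branch, name, sample_sex, genome, founders))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# CSS breeding

SELECTION_MARKER_SPACING_BP = 20_000_000


def default_selection_markers(genome: GenomeModel, donor_chrom: str,
                              spacing_bp: int = SELECTION_MARKER_SPACING_BP,
                              ) -> list[int]:
    """A ladder of selection markers along the donor chromosome.

    Marker-assisted consomic construction genotypes a handful of loci
    spanning the chromosome; without internal markers, donor segments
    between the ends are silently lost during backcrossing.  The ladder
    picks the SNP nearest each multiple of ``spacing_bp`` between the
    first and last SNP of the chromosome.
    """
    snp = genome.markers_for(donor_chrom, "snp")["pos"].to_numpy()
    if len(snp) == 0:
        raise ValueError(f"no selection markers available on {donor_chrom}")
    span = snp[-1] - snp[0]
    n = max(2, int(np.ceil(span / spacing_bp)) + 1)
    targets = np.linspace(snp[0], snp[-1], min(n, len(snp)))
    chosen = sorted({int(snp[np.argmin(np.abs(snp - t))]) for t in targets})
    return chosen


def breed_css(founders: FounderSet, cfg: BreedingConfig, genome: GenomeModel,
              rng: np.random.Generator, name: str = "css",
              max_tries: int = 500) -> StrainGenome:
    """Marker-assisted backcrossing of one donor chromosome onto a host.

    Host is founder 1, donor founder 2.  Each of the
    ``cfg.n_backcross_meioses`` generations selects an offspring carrying
    the donor allele (heterozygous) at every selection marker; a final
    intercross fixes the donor chromosome.  Host residue beyond the
    outermost selection markers and donor residue on background chromosomes
    are retained as ground truth.
    """
    if cfg.panel_type != "css":
        raise ValueError("breed_css needs panel_type 'css'")
    if cfg.donor_chrom is None:
        raise ValueError("css breeding needs a donor chromosome")
    donor_c = genome.chromosome(cfg.donor_chrom)
    host, donor = founders.code(founders.panel[0]), founders.code(founders.panel[1])

    markers = cfg.selection_marker_positions
    if markers is None:
        markers = default_selection_markers(genome, donor_c.name)
    markers = np.asarray(sorted(markers), dtype=np.int64)
    if len(markers) == 0:
        raise ValueError("no selection markers on the donor chromosome")
    if markers[0] < 0 or markers[-1] >= donor_c.length_bp:
        raise ValueError("selection markers outside the donor chromosome")

    def host_animal(sex: str) -> Individual:
        chroms: dict[str, tuple[Mosaic, ...]] = {}
        for c in genome.chromosomes:
            const = Mosaic.constant(c.length_bp, host)
            if c.inheritance == AUTOSOME:
                chroms[c.name] = (const, const)
            elif c.inheritance == X:
                chroms[c.name] = (const, const) if sex == FEMALE else (const,)
            elif c.inheritance == Y:
                if sex == MALE:
                    chroms[c.name] = (const,)
            else:
                chroms[c.name] = (const,)
        return Individual(sex, chroms)

    def carries_donor_het(ind: Individual) -> bool:
        haps = ind.chromosomes.get(donor_c.name, ())
        if donor_c.inheritance in (Y, MITO) or len(haps) == 1:
            return bool(np.all(haps[0].label_at(markers) == donor))
        lab = np.stack([h.label_at(markers) for h in haps])
        return bool(np.all((lab == donor).any(axis=0) & (lab == host).any(axis=0)))

    def homozygous_donor(ind: Individual) -> bool:
        haps = ind.chromosomes.get(donor_c.name, ())
        return all(bool(np.all(h.label_at(markers) == donor)) for h in haps)

    # carrier sex: must be able to transmit (and, for X, recombine) the donor chromosome
    carrier_sex = {AUTOSOME: None, X: FEMALE, Y: MALE, MITO: FEMALE}[donor_c.inheritance]

    # F1: dam/sire direction chosen so the donor copy of Y or mito is present
    if donor_c.inheritance == Y:
        dam_label = founders.panel[0]      # host dam x donor sire -> donor Y in sons
    elif donor_c.inheritance == MITO:
        dam_label = founders.panel[1]      # donor dam -> donor mito
    else:
        dam_label = founders.panel[0]
    f1_f, f1_m = f1_pair(founders, genome, dam_label=dam_label)
    carrier = f1_f if carrier_sex in (FEMALE, None) else f1_m

    def select_offspring(dam: Individual, sire: Individual, sex: str | None,
                         accept) -> Individual:
        for _ in range(max_tries):
            child = make_offspring(dam, sire, genome, rng, sex)
            if accept(child):
                return child
        raise RuntimeError("selection failed: no acceptable offspring "
                           f"in {max_tries} tries")

    for k in range(cfg.n_backcross_meioses):
        want_sex = carrier_sex or (FEMALE if k % 2 == 0 else MALE)
        if carrier.sex == FEMALE:
            dam, sire = carrier, host_animal(MALE)
        else:
            dam, sire = host_animal(FEMALE), carrier
        carrier = select_offspring(dam, sire, want_sex, carries_donor_het)

    bg_fraction = _background_donor_fraction(carrier, genome, donor_c.name, donor)

    if donor_c.inheritance == Y:
        final, sample_sex = carrier, MALE
    elif donor_c.inheritance == MITO:
        final, sample_sex = carrier, FEMALE
    elif donor_c.inheritance == X:
        # brother of the carrier line with a donor X, then intercross
        sire = select_offspring(carrier, host_animal(MALE), MALE,
                                lambda ch: homozygous_donor(ch))
        final = select_offspring(carrier, sire, FEMALE, homozygous_donor)
        sample_sex = FEMALE
    else:
        if carrier.sex == FEMALE:
            dam, sire2 = carrier, host_animal(MALE)
        else:
            dam, sire2 = host_animal(FEMALE), carrier
        mate_f = select_offspring(dam, sire2, FEMALE, carries_donor_het)
        mate_m = select_offspring(dam, sire2, MALE, carries_donor_het)
        final = select_offspring(mate_f, mate_m, MALE, homozygous_donor)
        sample_sex = MALE

    chroms = {c: tuple(h.simplify() for h in haps)
              for c, haps in final.chromosomes.items()}
    strain = StrainGenome(name, sample_sex, chroms,
                          meta={"panel_type": "css", "donor_chrom": donor_c.name,
                                "host": founders.panel[0], "donor": founders.panel[1],
                                "n_backcross_meioses": cfg.n_backcross_meioses,
                                "selection_markers": [int(m) for m in markers],
                                "backcross_background_donor_fraction": bg_fraction,
                                "founder_labels": list(founders.labels)})
    for cname, haps in chroms.items():
        if len(haps) == 2:
            for s, e in strain.het_intervals(cname):
                strain.ledger.append(AnomalyRecord("het_segment", cname, s, e))
    return strain


def _background_donor_fraction(ind: Individual, genome: GenomeModel,
                               donor_chrom: str, donor_code: int) -> float:
    """Fraction of background bp carrying a donor allele on >=1 haplotype."""
    from .mosaic import merge_labels
    carry = tot = 0
    for c in genome.chromosomes:
        if c.name == donor_chrom or not c.recombining:
            continue
        haps = list(ind.chromosomes.get(c.name, ()))
        if not haps:
            continue
        tot += c.length_bp
        starts, ends, lab = merge_labels(haps)
        has = (lab == donor_code).any(axis=0)
        carry += int(np.sum(ends[has] - starts[has]))
    return carry / tot if tot else 0.0


# ---------------------------------------------------------------------------
# anomaly injection

def inject_anomalies(strain: StrainGenome, specs: list, rng=None) -> StrainGenome:
    """Apply anomaly specs to a strain genome, updating the ground-truth ledger.

    Contamination overwrites the stated haplotypes with the contaminant
    founder's label; CNVs are recorded in the ledger (they act at emission
    time); gene conversions overwrite a short tract on *both* haplotypes
    (conversions predate fixation, so they are carried homozygous).
    Overlapping anomalies of the same kind are rejected.
    """
    chroms = {c: list(h) for c, h in strain.chromosomes.items()}
    ledger = list(strain.ledger)
    seen: dict[str, list[tuple[str, int, int]]] = {}
    lengths = {c: haps[0].length for c, haps in strain.chromosomes.items()}

    def check(kind: str, chrom: str, start: int, end: int) -> None:
        if chrom not in chroms:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if not (0 <= start < end <= lengths[chrom]):
            raise ValueError(f"{kind} interval [{start}, {end}) outside {chrom}")
        for c0, s0, e0 in seen.get(kind, []):
            if c0 == chrom and start < e0 and s0 < end:
                raise ValueError(f"overlapping {kind} anomalies on {chrom}")
        seen.setdefault(kind, []).append((chrom, start, end))

    # labels needed for contamination sources / conversion targets
    label_code = {lab: i for i, lab in enumerate(strain.meta.get("founder_labels", []))}

    def code_of(label: str, founders_hint: list[str]) -> int:
        if label in label_code:
            return label_code[label]
        if label in founders_hint:
            return founders_hint.index(label)
        raise ValueError(f"unknown founder label {label!r}")

    hint = strain.meta.get("founder_labels") or ["founder1", "founder2",
                                                 "contaminant1", "contaminant2"]
    for spec in specs:
        if isinstance(spec, ContaminationSpec):
            check("contamination", spec.chrom, spec.start, spec.end)
            code = code_of(spec.source, hint)
            for h in spec.haplotypes:
                if h >= len(chroms[spec.chrom]):
                    raise ValueError(f"haplotype index {h} out of range on {spec.chrom}")
                chroms[spec.chrom][h] = chroms[spec.chrom][h].replace(
                    spec.start, spec.end, code)
            ledger.append(AnomalyRecord("contamination", spec.chrom, spec.start,
                                        spec.end, (spec.source, spec.haplotypes)))
        elif isinstance(spec, CnvSpec):
            check("cnv", spec.chrom, spec.start, spec.end)
            ledger.append(AnomalyRecord("cnv", spec.chrom, spec.start, spec.end,
                                        (spec.copy_number,)))
        elif isinstance(spec, GeneConversionSpec):
            check("gene_conversion", spec.chrom, spec.start, spec.end)
            code = code_of(spec.to_label, hint)
            for h in range(len(chroms[spec.chrom])):
                chroms[spec.chrom][h] = chroms[spec.chrom][h].replace(
                    spec.start, spec.end, code)
            ledger.append(AnomalyRecord("gene_conversion", spec.chrom, spec.start,
                                        spec.end, (spec.to_label,)))
        elif isinstance(spec, HetSegmentSpec):
            check("het_segment", spec.chrom, spec.start, spec.end)
            code = code_of(spec.to_label, hint)
            if len(chroms[spec.chrom]) < 2:
                raise ValueError("het segment needs a two-copy chromosome")
            chroms[spec.chrom][1] = chroms[spec.chrom][1].replace(
                spec.start, spec.end, code)
            ledger.append(AnomalyRecord("het_segment", spec.chrom, spec.start,
                                        spec.end, (spec.to_label,)))
        else:
            raise TypeError(f"unknown anomaly spec {type(spec).__name__}")
    return StrainGenome(strain.name, strain.sex,
                        {c: tuple(h) for c, h in chroms.items()},
                        ledger, dict(strain.meta))


# ---------------------------------------------------------------------------
# intensity emission

def emit_intensities(strains: list[StrainGenome], founders: FounderSet,
                     noise: NoiseModel, genome: GenomeModel,
                     rng: np.random.Generator,
                     replicates: dict[str, int] | None = None) -> IntensityTable:
    """Emit (average, contrast) intensities for every marker and sample.

    SNP probes emit from the genotype-class centre implied by the founder
    labels of the two haplotypes (hemizygous chromosomes behave as
    homozygous); positions with copy number 0 emit the null class.
    Invariant probes emit the invariant average scaled by the copy-number
    law.  ``replicates`` maps strain name -> number of replicate arrays
    (default 1), named ``<strain>`` or ``<strain>_r<k>``.
    """
    markers = genome.markers
    probe_rng = np.random.default_rng(noise.probe_seed)
    n_probes = len(markers)
    bad = probe_rng.random(n_probes) < noise.bad_probe_fraction
    is_snp = (markers["probe_class"] == "snp").to_numpy()
    snp_index = np.cumsum(is_snp) - 1  # global probe idx -> SNP column in founders.alleles
    centers = noise.center_array()

    by_name = {c.name: c for c in genome.chromosomes}
    sample_names: list[str] = []
    rows_avg: list[np.ndarray] = []
    rows_con: list[np.ndarray] = []
    for strain in strains:
        for cname, haps in strain.chromosomes.items():
            if cname not in by_name or haps[0].length != by_name[cname].length_bp:
                raise ValueError(f"strain {strain.name}: chromosome {cname} does not "
                                 "match the genome model")
        n_rep = (replicates or {}).get(strain.name, 1)
        gclass = _genotype_classes(strain, founders, genome, markers, is_snp, snp_index)
        cn = _copy_numbers(strain, markers)
        base_avg = np.empty(n_probes)
        base_con = np.empty(n_probes)
        base_avg[is_snp] = centers[gclass[is_snp], 0]
        base_con[is_snp] = centers[gclass[is_snp], 1]
        law = np.array([noise.cnv_law[c] for c in range(5)])
        inv = ~is_snp
        base_avg[inv] = noise.invariant_average * law[cn[inv]]
        base_con[inv] = 0.0
        for r in range(n_rep):
            name = strain.name if n_rep == 1 else f"{strain.name}_r{r + 1}"
            avg = base_avg + rng.normal(0.0, noise.sd, n_probes)
            con = base_con + rng.normal(0.0, noise.sd, n_probes)
            nbad = int(bad.sum())
            if nbad:
                avg[bad] += rng.normal(0.0, noise.bad_probe_sd, nbad)
                con[bad] += rng.normal(0.0, noise.bad_probe_sd, nbad)
            sample_names.append(name)
            rows_avg.append(avg)
            rows_con.append(con)
    return IntensityTable(markers.reset_index(drop=True), sample_names,
                         np.array(rows_avg), np.array(rows_con))


def _genotype_classes(strain: StrainGenome, founders: FounderSet, genome: GenomeModel,
                      markers: pd.DataFrame, is_snp: np.ndarray,
                      snp_index: np.ndarray) -> np.ndarray:
    """Genotype class code per probe (AB/AA/BB/NULL); NULL where no copy."""
    gclass = np.full(len(markers), NULL, dtype=np.int8)
    chrom_arr = markers["chrom"].to_numpy()
    pos_arr = markers["pos"].to_numpy()
    for chrom in pd.unique(chrom_arr):
        sel = (chrom_arr == chrom) & is_snp
        if not sel.any():
            continue
        if chrom not in strain.chromosomes:
            continue  # e.g. Y probes on a female sample -> null
        pos = pos_arr[sel]
        labels = strain.labels_at(chrom, pos)  # (n_hap, n_pos)
        cols = snp_index[sel]
        alleles = founders.alleles[labels, cols[None, :]]  # (n_hap, n_pos)
        if alleles.shape[0] == 1:
            g = np.where(alleles[0] == 0, AA, BB)
        else:
            s = alleles[0] + alleles[1]
            g = np.where(s == 0, AA, np.where(s == 2, BB, AB))
        gclass[sel] = g
    # copy-number zero silences probes of any class
    for rec in strain.ledger:
        if rec.kind == "cnv" and rec.detail[0] == 0:
            inside = (chrom_arr == rec.chrom) & (pos_arr >= rec.start) & (pos_arr < rec.end)
            gclass[inside & is_snp] = NULL
    return gclass


def _copy_numbers(strain: StrainGenome, markers: pd.DataFrame) -> np.ndarray:
    cn = np.full(len(markers), 2, dtype=np.int8)
    chrom_arr = markers["chrom"].to_numpy()
    pos_arr = markers["pos"].to_numpy()
    for rec in strain.ledger:
        if rec.kind == "cnv":
            inside = (chrom_arr == rec.chrom) & (pos_arr >= rec.start) & (pos_arr < rec.end)
            cn[inside] = rec.detail[0]
    return cn
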