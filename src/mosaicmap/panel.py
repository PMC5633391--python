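"""Panel-level statistics and breeding-theory computations.

Covers recombination summaries and their simulated prediction intervals,
shared recombination events and sister-strain detection, comparison of a
new map against an older one, residual-heterozygosity/CNV tables, and the
sib-mating fixation-time study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anomalies import DELETION, DUPLICATION, CnvCall
from .genome import GenomeModel
from .hmm import HET, HaplotypeMap, RecombinationEvent, extract_recombination_intervals
from .simulate import BreedingConfig, FounderSet, breed_ris, simulate_sib_lineage


# ---------------------------------------------------------------------------
# recombination summaries

def summarize_recombination(maps: dict[str, HaplotypeMap]) -> pd.DataFrame:
    """Per-strain recombination event counts with a per-chromosome breakdown."""
    if not maps:
        raise ValueError("need at least one strain")
    rows = []
    for name, hmap in maps.items():
        events = extract_recombination_intervals(hmap)
        row = {"strain": name, "n_events": len(events)}
        for ev in events:
            key = f"chr_{ev.chrom}"
            row[key] = row.get(key, 0) + 1
        rows.append(row)
    df = pd.DataFrame(rows).fillna(0)
    chr_cols = [c for c in df.columns if c.startswith("chr_")]
    df[chr_cols] = df[chr_cols].astype(int)
    return df.set_index("strain")


def recombination_quartiles(summary: pd.DataFrame) -> dict[str, float]:
    q = summary["n_events"].quantile([0.25, 0.5, 0.75])
    return {"q25": float(q[0.25]), "median": float(q[0.5]), "q75": float(q[0.75]),
            "mean": float(summary["n_events"].mean())}


# ---------------------------------------------------------------------------
# shared events and sister strains

@dataclass
class SharedEvent:
    chrom: str
    start_bp: int  # intersection of the clustered intervals
    end_bp: int
    strains: list[str]
    polarities: list[tuple[int, int]]

    @property
    def n_strains(self) -> int:
        return len(set(self.strains))

    @property
    def polarity_agreement(self) -> tuple[int, int]:
        """(majority-direction count, minority count)."""
        if not self.polarities:
            return (0, 0)
        counts: dict[tuple[int, int], int] = {}
        for p in self.polarities:
            counts[p] = counts.get(p, 0) + 1
        major = max(counts.values())
        return (major, len(self.polarities) - major)


def find_shared_events(maps: dict[str, HaplotypeMap]) -> list[SharedEvent]:
    """Cluster recombination intervals shared by >=2 strains.

    Events are grouped per chromosome by single-linkage interval overlap;
    intervals are half-open internally, so touching intervals (end ==
    start) do not overlap.
    """
    if len(maps) < 2:
        raise ValueError("need at least two strains")
    by_chrom: dict[str, list[tuple[int, int, str, tuple[int, int]]]] = {}
    for name, hmap in maps.items():
        for ev in extract_recombination_intervals(hmap):
            by_chrom.setdefault(ev.chrom, []).append(
                (ev.start_bp, ev.end_bp, name, ev.polarity))
    shared: list[SharedEvent] = []
    for chrom, events in by_chrom.items():
        events.sort()
        cluster: list[tuple[int, int, str, tuple[int, int]]] = []
        max_end = -1

        def flush() -> None:
            if len({e[2] for e in cluster}) >= 2:
                shared.append(SharedEvent(
                    chrom,
                    min(e[0] for e in cluster),
                    max(e[1] for e in cluster),
                    [e[2] for e in cluster],
                    [e[3] for e in cluster]))

        for ev in events:
            if cluster and ev[0] >= max_end:
                flush()
                cluster = []
                max_end = -1
            cluster.append(ev)
            max_end = max(max_end, ev[1])
        if cluster:
            flush()
    return shared


@dataclass
class SisterReport:
    strains: tuple[str, str]
    observed_shared: int
    null_mean: float
    null_sd: float
    z: float
    is_sister: bool  # Z > 5.0 flags excess junction sharing


def _same_polarity_overlap(a: list[RecombinationEvent],
                           b: list[RecombinationEvent]) -> int:
    """Number of events of strain a with a same-polarity overlapping event in b."""
    count = 0
    by_chrom: dict[tuple[str, tuple[int, int]], list[tuple[int, int]]] = {}
    for ev in b:
        by_chrom.setdefault((ev.chrom, ev.polarity), []).append((ev.start_bp, ev.end_bp))
    for ev in a:
        for s, e in by_chrom.get((ev.chrom, ev.polarity), ()):
            if ev.start_bp < e and s < ev.end_bp:
                count += 1
                break
    return count


def _null_overlap(pool: list[RecombinationEvent], ia: np.ndarray,
                  ib: np.ndarray) -> int:
    by_key: dict[tuple[str, tuple[int, int]], list[tuple[int, int, int]]] = {}
    for j in ib:
        ev = pool[j]
        by_key.setdefault((ev.chrom, ev.polarity), []).append(
            (ev.start_bp, ev.end_bp, int(j)))
    count = 0
    for i in ia:
        ev = pool[i]
        for s, e, j in by_key.get((ev.chrom, ev.polarity), ()):
            if j != i and ev.start_bp < e and s < ev.end_bp:
                count += 1
                break
    return count


def sister_zscore(pair: tuple[str, str], maps: dict[str, HaplotypeMap],
                  b_resamples: int = 1000, rng: np.random.Generator | None = None,
                  exclude_from_null: set[str] | None = None,
                  z_threshold: float = 5.0) -> SisterReport:
    """Excess sharing of recombination junctions between two strains.

    The observed statistic is the number of same-polarity overlapping
    recombination intervals.  The null replaces each strain's events with
    an equally sized draw (with replacement) from the pooled panel events
    — respecting the panel's recombination density — and recomputes the
    statistic ``b_resamples`` times.  Strains with known shared ancestry
    can be excluded from the pool.
    """
    rng = np.random.default_rng() if rng is None else rng
    name_a, name_b = pair
    ev_a = extract_recombination_intervals(maps[name_a])
    ev_b = extract_recombination_intervals(maps[name_b])
    if not ev_a or not ev_b:
        return SisterReport(pair, 0, 0.0, 0.0, 0.0, False)
    excluded = exclude_from_null or set()
    pool = [ev for name, hmap in maps.items() if name not in excluded
            for ev in extract_recombination_intervals(hmap)]
    observed = _same_polarity_overlap(ev_a, ev_b)
    nulls = np.empty(b_resamples)
    n_pool = len(pool)
    for i in range(b_resamples):
        ia = rng.integers(n_pool, size=len(ev_a))
        ib = rng.integers(n_pool, size=len(ev_b))
        # drawing the very same pooled event on both sides trivially
        # overlaps; only distinct events may count, so the null reflects the
        # panel's recombination density rather than resampling identity
        nulls[i] = _null_overlap(pool, ia, ib)
    mu, sd = float(nulls.mean()), float(nulls.std(ddof=1))
    z = (observed - mu) / sd if sd > 0 else 0.0
    return SisterReport(pair, observed, mu, sd, float(z), bool(z > z_threshold))


# ---------------------------------------------------------------------------
# map comparison

@dataclass
class MapComparison:
    concordance: float | None  # None when no bp is assigned in both maps
    uncertainty_new: float     # summed recombination-interval bp
    uncertainty_old: float
    reduction: float | None    # 1 - new/old

    def __repr__(self) -> str:
        conc = "NA" if self.concordance is None else f"{self.concordance:.4f}"
        red = "NA" if self.reduction is None else f"{self.reduction:.3f}"
        return (f"MapComparison(concordance={conc}, uncertainty {self.uncertainty_old:.0f}"
                f" -> {self.uncertainty_new:.0f} bp, reduction={red})")


def _assigned_intervals(hmap: HaplotypeMap, chrom: str) -> list[tuple[int, int, int]]:
    """(start, end, state) of homozygous blocks, half-open bp intervals."""
    return [(b.start_bp, b.end_bp + 1, b.state)
            for b in hmap.blocks(chrom) if b.state != HET]


def compare_maps(new: HaplotypeMap, old: HaplotypeMap) -> MapComparison:
    """Concordance and uncertainty reduction of a new map versus an old one.

    Concordance is the bp fraction assigned the same founder among bp
    assigned a founder in both maps; uncertainty is each map's summed
    recombination-interval length.
    """
    if set(new.positions) != set(old.positions):
        raise ValueError("maps cover different chromosome sets")
    agree = total = 0
    for chrom in new.positions:
        ints_new = _assigned_intervals(new, chrom)
        ints_old = _assigned_intervals(old, chrom)
        for s1, e1, st1 in ints_new:
            for s2, e2, st2 in ints_old:
                lo, hi = max(s1, s2), min(e1, e2)
                if lo < hi:
                    total += hi - lo
                    if st1 == st2:
                        agree += hi - lo
    unc_new = float(sum(ev.interval_bp for ev in extract_recombination_intervals(new)))
    unc_old = float(sum(ev.interval_bp for ev in extract_recombination_intervals(old)))
    concordance = agree / total if total else None
    reduction = 1.0 - unc_new / unc_old if unc_old > 0 else None
    return MapComparison(concordance, unc_new, unc_old, reduction)


# ---------------------------------------------------------------------------
# fixation-time study

@dataclass
class FixationSummary:
    mean_generation_het_below_1pct: float
    mean_generation_fixed: float
    mean_generation_panel_fixed: float | None
    n_lineages: int
    n_panels: int
    n_strains_per_panel: int
    het_threshold: float

    def __post_init__(self) -> None:
        if not (self.mean_generation_het_below_1pct <= self.mean_generation_fixed):
            raise ValueError("het landmark cannot exceed fixation landmark")


def fixation_time_study(genome: GenomeModel, n_strains: int = 22,
                        n_lineages: int = 500, n_panels: int = 200,
                        rng: np.random.Generator | None = None,
                        het_threshold: float = 0.01,
                        max_generations: int = 500) -> FixationSummary:
    """Sib-mating landmarks: generations to <1% heterozygosity, to complete
    fixation, and to fixation of every strain in a panel of ``n_strains``.

    Simulates ``max(n_lineages, n_panels * n_strains)`` independent F1-start
    lineages; per-lineage means use all of them, the panel landmark
    averages the max over disjoint groups of ``n_strains``.
    """
    rng = np.random.default_rng() if rng is None else rng
    total = max(n_lineages, n_panels * n_strains)
    het_gen = np.empty(total)
    fix_gen = np.empty(total)
    for i in range(total):
        het_gen[i], fix_gen[i] = simulate_sib_lineage(
            genome, rng, het_threshold=het_threshold, max_generations=max_generations)
    panel_mean: float | None = None
    if n_panels > 0 and n_panels * n_strains <= total:
        panels = fix_gen[:n_panels * n_strains].reshape(n_panels, n_strains)
        panel_mean = float(panels.max(axis=1).mean())
    return FixationSummary(float(het_gen.mean()), float(fix_gen.mean()),
                           panel_mean, total, n_panels, n_strains, het_threshold)


# ---------------------------------------------------------------------------
# simulated prediction interval for recombination counts

@dataclass
class PredictionInterval:
    mean: float
    lower: float   # 2.5 percentile
    upper: float   # 97.5 percentile
    counts: np.ndarray


def recombination_prediction_interval(founders: FounderSet, cfg: BreedingConfig,
                                      genome: GenomeModel, replicates: int,
                                      rng: np.random.Generator | None = None,
                                      ) -> PredictionInterval:
    """Empirical 95% prediction interval of per-strain breakpoint counts.

    Breeds ``replicates`` strains under ``cfg`` and counts founder
    junctions in each resulting genome (union over haplotypes).
    """
    if replicates < 100:
        raise ValueError("need at least 100 replicates for a stable interval")
    rng = np.random.default_rng() if rng is None else rng
    counts = np.empty(replicates)
    for i in range(replicates):
        strain = breed_ris(founders, cfg, genome, rng, name=f"sim{i}")
        counts[i] = strain.n_breakpoints()
    lo, hi = np.percentile(counts, [2.5, 97.5])
    return PredictionInterval(float(counts.mean()), float(lo), float(hi), counts)


# ---------------------------------------------------------------------------
# closed-form panel quantities

def css_panel_size(genome: GenomeModel) -> int:
    """Number of strains in a complete consomic panel: one per substitutable
    chromosome (autosomes, X, Y and the mitochondrial genome)."""
    return len(genome.chromosomes)


def expected_background_donor_fraction(n_backcross_meioses: int) -> float:
    """Expected fraction of background genome still carrying donor alleles
    after ``n`` backcross meioses (0.5 ** n)."""
    if n_backcross_meioses < 0:
        raise ValueError("backcross count must be >= 0")
    return 0.5 ** n_backcross_meioses


def conversion_rate_estimate(conversion_counts: list[int],
                             informative_counts: list[int] | None = None,
                             typical_informative: float | None = None) -> float:
    """Genome fraction affected by gene conversion, as a percentage.

    (mean conversions per panel) / (typical informative-SNP count) * 100.
    ``typical_informative`` defaults to the mean of ``informative_counts``.
    """
    if any(c < 0 for c in conversion_counts):
        raise ValueError("conversion counts must be >= 0")
    if typical_informative is None:
        if not informative_counts:
            raise ValueError("need informative counts or a typical count")
        typical_informative = float(np.mean(informative_counts))
    per_panel = sum(conversion_counts) / len(conversion_counts)
    return 100.0 * per_panel / typical_informative


# ---------------------------------------------------------------------------
# allele-frequency balance

def allele_frequency_balance(maps: dict[str, HaplotypeMap],
                             alpha: float = 0.05) -> pd.DataFrame:
    """Per-marker binomial test of founder-assignment balance across a panel.

    At each informative marker, counts strains assigned founder 1 vs
    founder 2 (Het excluded) and tests against the 1:1 segregation
    expectation.  Returns one row per marker with a two-sided p-value and a
    Bonferroni-corrected imbalance flag — a screen for transmission-ratio
    distortion, nothing more.
    """
    from scipy.stats import binomtest
    first = maps[next(iter(maps))]
    rows = []
    n_markers = sum(len(first.positions[c]) for c in first.positions)
    for chrom in first.positions:
        pos = first.positions[chrom]
        counts = np.zeros((2, len(pos)), dtype=int)
        for hmap in maps.values():
            st = hmap.states[chrom]
            counts[0] += st == 0
            counts[1] += st == 1
        for i, p in enumerate(pos):
            n1, n2 = int(counts[0, i]), int(counts[1, i])
            pv = binomtest(n1, n1 + n2, 0.5).pvalue if n1 + n2 else 1.0
            rows.append((chrom, int(p), n1, n2, pv))
    df = pd.DataFrame(rows, columns=["chrom", "pos", "n_founder1",
                                     "n_founder2", "p_value"])
    df["imbalanced"] = df["p_value"] < alpha / max(n_markers, 1)
    return df


# ---------------------------------------------------------------------------
# heterozygosity / CNV table

def heterozygosity_summary(panel_maps: dict[str, dict[str, HaplotypeMap]],
                           panel_cnvs: dict[str, dict[str, list[CnvCall]]] | None = None,
                           ) -> pd.DataFrame:
    """Per-panel counts of strains with Het blocks, deletions, duplications.

    ``panel_maps`` maps panel name -> {strain -> HaplotypeMap};
    ``panel_cnvs`` optionally maps panel -> {strain -> CNV calls}.
    Percentages are rounded to the nearest integer.
    """
    rows = []
    for panel, maps in panel_maps.items():
        if not maps:
            raise ValueError(f"panel {panel!r} has no strains")
        n = len(maps)
        n_het = sum(1 for hmap in maps.values()
                    if any(b.state == HET for b in hmap.blocks()))
        cnvs = (panel_cnvs or {}).get(panel, {})
        n_del = sum(1 for s in maps if any(c.direction == DELETION
                                           for c in cnvs.get(s, [])))
        n_dup = sum(1 for s in maps if any(c.direction == DUPLICATION
                                           for c in cnvs.get(s, [])))
        rows.append({"panel": panel, "n_strains": n,
                     "n_het": n_het, "pct_het": round(100 * n_het / n),
                     "n_deletion": n_del, "pct_deletion": round(100 * n_del / n),
                     "n_duplication": n_dup, "pct_duplication": round(100 * n_dup / n)})
    return pd.DataFrame(rows).set_index("panel")
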