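"""Genome models for two-founder mouse strain panels.

A :class:`GenomeModel` describes the linkage groups (physical length in bp,
genetic length in cM, inheritance class) and the marker panel (sorted bp
positions of SNP and invariant probes per chromosome).  The default model is
mouse-scale: 19 autosomes plus X, Y and the mitochondrial genome, with the
recombining map totalling ~14 Morgans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AUTOSOME = "autosome"
X = "X"
Y = "Y"
MITO = "mito"

#: inheritance classes for which meiotic recombination is modelled
RECOMBINING = (AUTOSOME, X)

# mm10-scale physical lengths (bp).  Genetic lengths are assigned
# proportionally to physical length so that autosomes + X total 1400 cM
# (~14 Morgans), the scale of the mouse genetic map.
_MOUSE_BP = {
    "1": 195_000_000, "2": 182_000_000, "3": 160_000_000, "4": 156_000_000,
    "5": 152_000_000, "6": 150_000_000, "7": 145_000_000, "8": 129_000_000,
    "9": 125_000_000, "10": 131_000_000, "11": 122_000_000, "12": 120_000_000,
    "13": 120_000_000, "14": 125_000_000, "15": 104_000_000, "16": 98_000_000,
    "17": 95_000_000, "18": 91_000_000, "19": 61_000_000, "X": 171_000_000,
}
_MOUSE_Y_BP = 92_000_000
_MOUSE_MITO_BP = 16_300
MOUSE_TOTAL_CM = 1400.0


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    genetic_length_cM: float
    inheritance: str = AUTOSOME

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"chromosome {self.name}: non-positive length {self.length_bp}")
        if self.genetic_length_cM < 0:
            raise ValueError(f"chromosome {self.name}: negative genetic length")
        if self.inheritance not in (AUTOSOME, X, Y, MITO):
            raise ValueError(f"chromosome {self.name}: unknown inheritance {self.inheritance!r}")
        if self.inheritance in (Y, MITO) and self.genetic_length_cM != 0:
            raise ValueError(f"chromosome {self.name}: {self.inheritance} must not recombine")

    @property
    def recombining(self) -> bool:
        return self.inheritance in RECOMBINING


@dataclass
class GenomeModel:
    """Linkage groups plus a marker panel.

    ``markers`` is a DataFrame with columns ``probe_id, chrom, pos,
    probe_class`` (``probe_class`` in {"snp", "invariant"}), sorted by
    chromosome then position, positions strictly increasing per chromosome
    (internal coordinates are 0-based half-open).
    """

    chromosomes: list[Chromosome]
    markers: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["probe_id", "chrom", "pos", "probe_class"]))

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        by_name = {c.name: c for c in self.chromosomes}
        m = self.markers
        if len(m):
            unknown = set(m["chrom"]) - set(names)
            if unknown:
                raise ValueError(f"markers on unknown chromosomes: {sorted(unknown)}")
            for chrom, grp in m.groupby("chrom", sort=False):
                pos = grp["pos"].to_numpy()
                if np.any(np.diff(pos) <= 0):
                    raise ValueError(f"marker positions not strictly increasing on {chrom}")
                if pos[0] < 0 or pos[-1] >= by_name[chrom].length_bp:
                    raise ValueError(f"marker position out of bounds on {chrom}")
            if m["probe_id"].duplicated().any():
                raise ValueError("duplicate probe ids")
        self._by_name = by_name

    def chromosome(self, name: str) -> Chromosome:
        return self._by_name[name]

    @property
    def chromosome_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def recombining_chromosomes(self) -> list[Chromosome]:
        return [c for c in self.chromosomes if c.recombining]

    @property
    def total_genetic_length_cM(self) -> float:
        return float(sum(c.genetic_length_cM for c in self.chromosomes))

    def markers_for(self, chrom: str, probe_class: str | None = None) -> pd.DataFrame:
        m = self.markers[self.markers["chrom"] == chrom]
        if probe_class is not None:
            m = m[m["probe_class"] == probe_class]
        return m

    def diploid_bp(self, include_x: bool = True) -> int:
        """Total bp of chromosomes carried in two copies in a female."""
        tot = sum(c.length_bp for c in self.chromosomes if c.inheritance == AUTOSOME)
        if include_x:
            tot += sum(c.length_bp for c in self.chromosomes if c.inheritance == X)
        return tot


def _make_markers(chromosomes: list[Chromosome], snp_spacing_bp: float,
                  invariant_spacing_bp: float | None, rng: np.random.Generator,
                  jitter: float = 0.35) -> pd.DataFrame:
    """Quasi-regular marker grid with jitter, one pass per probe class."""
    rows: list[pd.DataFrame] = []
    for chrom in chromosomes:
        if chrom.inheritance in (Y, MITO):
            continue
        parts = []
        for cls, spacing in (("snp", snp_spacing_bp), ("invariant", invariant_spacing_bp)):
            if spacing is None or spacing <= 0:
                continue
            n = max(1, int(round(chrom.length_bp / spacing)))
            base = (np.arange(n) + 0.5) * chrom.length_bp / n
            pos = base + rng.uniform(-jitter, jitter, size=n) * chrom.length_bp / n
            pos = np.unique(np.clip(pos.astype(np.int64), 0, chrom.length_bp - 1))
            parts.append(pd.DataFrame({
                "probe_id": [f"{cls[:3]}_{chrom.name}_{i:06d}" for i in range(len(pos))],
                "chrom": chrom.name, "pos": pos, "probe_class": cls}))
        if parts:
            merged = pd.concat(parts, ignore_index=True).sort_values(
                "pos", kind="stable").drop_duplicates("pos")
            rows.append(merged.reset_index(drop=True))
    if not rows:
        return pd.DataFrame(columns=["probe_id", "chrom", "pos", "probe_class"])
    return pd.concat(rows, ignore_index=True)


def mouse_default(snp_spacing_bp: float = 500_000.0,
                  invariant_spacing_bp: float | None = 1_000_000.0,
                  total_cM: float = MOUSE_TOTAL_CM,
                  seed: int = 0) -> GenomeModel:
    """Mouse-scale genome: 19 autosomes + X (+ Y, mito), ~14 Morgans.

    Marker spacing is configurable; the defaults give a few thousand probes
    genome-wide, far sparser than a real array but dense enough to localise
    recombination to sub-cM intervals.
    """
    scale = total_cM / sum(_MOUSE_BP.values())
    chroms = [Chromosome(n, bp, bp * scale, X if n == "X" else AUTOSOME)
              for n, bp in _MOUSE_BP.items()]
    chroms.append(Chromosome("Y", _MOUSE_Y_BP, 0.0, Y))
    chroms.append(Chromosome("MT", _MOUSE_MITO_BP, 0.0, MITO))
    rng = np.random.default_rng(seed)
    markers = _make_markers(chroms, snp_spacing_bp, invariant_spacing_bp, rng)
    return GenomeModel(chroms, markers)


def build_genome_model(spec: dict | str, seed: int = 0) -> GenomeModel:
    """Build a :class:`GenomeModel` from a config dict or the string
    ``"mouse-default"``.

    Config keys: ``chromosomes``: list of dicts with ``name, length_bp,
    genetic_length_cM`` and optional ``inheritance``; ``snp_spacing_bp``,
    ``invariant_spacing_bp``: mean marker spacing (omit or null for none);
    or explicit ``markers``: list of (probe_id, chrom, pos, probe_class).
    """
    if spec == "mouse-default":
        return mouse_default(seed=seed)
    if isinstance(spec, str):
        raise ValueError(f"unknown genome spec {spec!r}")
    chroms = [Chromosome(str(c["name"]), int(c["length_bp"]),
                         float(c["genetic_length_cM"]),
                         c.get("inheritance", AUTOSOME))
              for c in spec["chromosomes"]]
    if "markers" in spec:
        markers = pd.DataFrame(spec["markers"],
                               columns=["probe_id", "chrom", "pos", "probe_class"])
    else:
        rng = np.random.default_rng(seed)
        markers = _make_markers(chroms, spec.get("snp_spacing_bp", 500_000.0),
                                spec.get("invariant_spacing_bp"), rng)
    return GenomeModel(chroms, markers)
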