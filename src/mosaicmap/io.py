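"""File I/O for the pipeline.

All on-disk interval coordinates are 1-based inclusive (the convention of
the published strain tables); internal coordinates are 0-based half-open.
The converters live here and nowhere else.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .anomalies import (CnvCall, ContaminationCall, GeneConversionCall,
                        UnexpectedBlock)
from .genome import GenomeModel
from .hmm import STATE_NAMES, HaplotypeMap
from .intensities import PROBE_COLUMNS, IntensityTable
from .simulate import StrainGenome

log = logging.getLogger(__name__)

RQTL_CODES = {0: "A", 1: "B", 2: "H"}  # map state -> R/qtl genotype code; N = missing


def interval_to_disk(start: int, end: int) -> tuple[int, int]:
    """0-based half-open [start, end) -> 1-based inclusive (start+1, end)."""
    return start + 1, end


def interval_from_disk(start: int, end: int) -> tuple[int, int]:
    return start - 1, end


def position_to_disk(pos: int) -> int:
    return pos + 1


def position_from_disk(pos: int) -> int:
    return pos - 1


# ---------------------------------------------------------------------------
# marker annotation

def write_marker_annotation(genome: GenomeModel, path: str | Path) -> None:
    out = genome.markers.copy()
    out["pos"] = out["pos"] + 1
    out[["chrom", "pos", "probe_class", "probe_id"]].to_csv(path, sep="\t", index=False)


def read_marker_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"chrom", "pos", "probe_class", "probe_id"} - set(df.columns)
    if missing:
        raise ValueError(f"marker annotation missing columns: {sorted(missing)}")
    if df["probe_id"].duplicated().any():
        dup = df.loc[df["probe_id"].duplicated(), "probe_id"].iloc[0]
        line = int(df.index[df["probe_id"] == dup][-1]) + 2
        raise ValueError(f"duplicate probe id {dup!r} (line {line})")
    df["pos"] = df["pos"].astype(np.int64) - 1
    for chrom, grp in df.groupby("chrom", sort=False):
        d = np.diff(grp["pos"].to_numpy())
        if np.any(d <= 0):
            line = int(grp.index[np.flatnonzero(d <= 0)[0] + 1]) + 2
            raise ValueError(f"unsorted marker positions on {chrom} (line {line})")
    return df[PROBE_COLUMNS]


# ---------------------------------------------------------------------------
# intensities

def write_intensities(table: IntensityTable, path: str | Path) -> None:
    table.to_tall().to_csv(path, index=False, float_format="%.5f")


def read_inputs(marker_path: str | Path,
                intensity_path: str | Path) -> tuple[pd.DataFrame, IntensityTable]:
    """Validated marker annotation plus intensity table, in one call."""
    markers = read_marker_annotation(marker_path)
    table = read_intensities(intensity_path, markers)
    log.info("read %d probes, %d samples", table.n_probes, table.n_samples)
    return markers, table


def read_intensities(path: str | Path, markers: pd.DataFrame) -> IntensityTable:
    tall = pd.read_csv(path, dtype={"sample": str, "probe_id": str})
    missing = {"sample", "probe_id", "average", "contrast"} - set(tall.columns)
    if missing:
        raise ValueError(f"intensity file missing columns: {sorted(missing)}")
    return IntensityTable.from_tall(tall, markers)


# ---------------------------------------------------------------------------
# ground truth (simulation output)

def write_strain_truth(strains: list[StrainGenome], path: str | Path) -> None:
    """Ground-truth mosaics, BED-like: strain, chrom, start, end, haplotype,
    founder code (1-based inclusive coordinates)."""
    rows = []
    for strain in strains:
        for chrom, haps in strain.chromosomes.items():
            for h, mosaic in enumerate(haps):
                m = mosaic.simplify()
                for s, e, lab in zip(m.starts, m.ends, m.labels):
                    ds, de = interval_to_disk(int(s), int(e))
                    rows.append((strain.name, chrom, ds, de, h, int(lab)))
    pd.DataFrame(rows, columns=["strain", "chrom", "start", "end",
                                "haplotype", "founder"]).to_csv(path, sep="\t", index=False)


def write_anomaly_ledger(strains: list[StrainGenome], path: str | Path) -> None:
    rows = []
    for strain in strains:
        for rec in strain.ledger:
            ds, de = interval_to_disk(rec.start, rec.end)
            rows.append((strain.name, rec.kind, rec.chrom, ds, de,
                         ";".join(str(x) for x in rec.detail)))
    pd.DataFrame(rows, columns=["strain", "kind", "chrom", "start", "end",
                                "detail"]).to_csv(path, sep="\t", index=False)


def read_strain_truth(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strain": str})
    df["start"], df["end"] = zip(*(interval_from_disk(s, e)
                                   for s, e in zip(df["start"], df["end"])))
    return df


# ---------------------------------------------------------------------------
# haplotype maps

def write_haplotype_maps(maps: dict[str, HaplotypeMap], path: str | Path) -> None:
    """Interval list: strain, chrom, start, end, length, state (1-based incl.;
    block extent runs from its first to its last informative marker)."""
    rows = []
    for name, hmap in maps.items():
        for b in hmap.blocks():
            ds, de = interval_to_disk(b.start_bp, b.end_bp + 1)
            rows.append((name, b.chrom, ds, de, de - ds + 1, b.state_name))
    pd.DataFrame(rows, columns=["strain", "chrom", "start", "end", "length",
                                "state"]).to_csv(path, sep="\t", index=False)


def read_haplotype_maps(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strain": str})
    need = {"strain", "chrom", "start", "end", "length", "state"}
    missing = need - set(df.columns)
    if missing:
        raise ValueError(f"map file missing columns: {sorted(missing)}")
    if not (df["length"] == df["end"] - df["start"] + 1).all():
        raise ValueError("length column inconsistent with start/end")
    return df


def write_rqtl_csv(maps: dict[str, HaplotypeMap], path: str | Path,
                   chrom_cM_per_bp: float | None = None) -> None:
    """Rotated R/qtl genotype CSV: one row per marker (id, chromosome,
    position), one column per strain with A/B/H codes (N where a strain has
    no state at the marker)."""
    strains = list(maps)
    first = maps[strains[0]]
    rows = []
    for chrom in first.chromosomes:
        pos = first.positions[chrom]
        for i, p in enumerate(pos):
            row = [f"{chrom}_{position_to_disk(int(p))}", chrom,
                   (float(p) * chrom_cM_per_bp if chrom_cM_per_bp
                    else position_to_disk(int(p)))]
            for s in strains:
                hmap = maps[s]
                if chrom in hmap.positions and i < len(hmap.positions[chrom]) \
                        and hmap.positions[chrom][i] == p:
                    row.append(RQTL_CODES[int(hmap.states[chrom][i])])
                else:
                    row.append("N")
            rows.append(row)
    pd.DataFrame(rows, columns=["marker", "chrom", "pos"] + strains).to_csv(
        path, index=False)


def read_rqtl_csv(path: str | Path) -> dict[str, HaplotypeMap]:
    df = pd.read_csv(path, dtype={"chrom": str})
    strains = [c for c in df.columns if c not in ("marker", "chrom", "pos")]
    code_to_state = {"A": 0, "B": 1, "H": 2}
    maps: dict[str, HaplotypeMap] = {}
    for s in strains:
        positions: dict[str, np.ndarray] = {}
        states: dict[str, np.ndarray] = {}
        for chrom, grp in df.groupby("chrom", sort=False):
            known = grp[s] != "N"
            positions[str(chrom)] = (grp.loc[known, "pos"].astype(np.int64) - 1).to_numpy()
            states[str(chrom)] = grp.loc[known, s].map(code_to_state).to_numpy(dtype=np.int8)
        maps[s] = HaplotypeMap(s, positions, states)
    return maps


# ---------------------------------------------------------------------------
# anomaly reports

def write_unexpected_blocks(blocks: list[UnexpectedBlock], path: str | Path) -> None:
    """Consomic audit table: strain, chrom, start, end, length, should-be,
    actually-is, class (columns in the published ordering)."""
    rows = []
    for b in blocks:
        ds, de = interval_to_disk(b.start_bp, b.end_bp)
        rows.append((b.strain, b.chrom, ds, de, de - ds + 1,
                     str(STATE_NAMES[b.expected]), str(STATE_NAMES[b.observed]),
                     b.blk_class))
    pd.DataFrame(rows, columns=["strain", "chrom", "start", "end", "length",
                                "should_be", "actually_is", "class"]).to_csv(
        path, sep="\t", index=False)


def write_anomaly_calls(contamination: dict[str, list[ContaminationCall]],
                        cnvs: dict[str, list[CnvCall]],
                        conversions: dict[str, list[GeneConversionCall]],
                        outdir: str | Path) -> None:
    outdir = Path(outdir)
    rows = [(s, c.chrom, *interval_to_disk(c.start_bp, c.end_bp), c.n_snps,
             c.n_discordant) for s, calls in contamination.items() for c in calls]
    pd.DataFrame(rows, columns=["strain", "chrom", "start", "end", "n_snps",
                                "n_discordant"]).to_csv(
        outdir / "contamination.tsv", sep="\t", index=False)
    rows = [(s, c.chrom, *interval_to_disk(c.start_bp, c.end_bp), c.direction,
             c.zygosity, c.n_probes, round(c.segment_t, 2))
            for s, calls in cnvs.items() for c in calls]
    pd.DataFrame(rows, columns=["strain", "chrom", "start", "end", "direction",
                                "zygosity", "n_probes", "segment_t"]).to_csv(
        outdir / "cnv.tsv", sep="\t", index=False)
    rows = [(s, c.chrom, position_to_disk(c.positions[0]), c.run_length,
             ",".join(c.probe_ids)) for s, calls in conversions.items() for c in calls]
    pd.DataFrame(rows, columns=["strain", "chrom", "pos", "run_length",
                                "probes"]).to_csv(
        outdir / "gene_conversions.tsv", sep="\t", index=False)
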