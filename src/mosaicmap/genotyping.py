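"""Informative-SNP selection and A/B/N genotype calling.

Calls are made by direct comparison of a sample's (average, contrast)
intensity with the two panel founders' cluster centres: ``A`` when the
signal lies near founder 1, ``B`` near founder 2, and ``N`` ("notA/notB")
otherwise — the N class covers both no-calls and heterozygous signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intensities import IntensityTable

log = logging.getLogger(__name__)

# call codes
CALL_A, CALL_B, CALL_N = 0, 1, 2
CALL_CHARS = np.array(["A", "B", "N"])

DEFAULT_SEP_THRESHOLD = 6.0
DEFAULT_CALL_RADIUS = 3.0
DEFAULT_MIN_DISPERSION = 0.02


@dataclass
class FounderReference:
    """Per-SNP-probe founder cluster centres and dispersion.

    ``centers1``/``centers2`` are ``(n_snp, 2)`` arrays of (average,
    contrast); ``dispersion`` is a single per-probe scale; a probe is
    informative iff the Euclidean centre separation exceeds
    ``sep_threshold`` dispersions.  Invariant-probe reference statistics
    (``inv_mean``, ``inv_sd`` over the average channel) support CNV
    scanning.
    """

    founder_names: tuple[str, str]
    snp_probes: pd.DataFrame
    centers1: np.ndarray
    centers2: np.ndarray
    dispersion: np.ndarray
    informative: np.ndarray
    sep_threshold: float
    inv_probes: pd.DataFrame = field(default_factory=pd.DataFrame)
    inv_mean: np.ndarray = field(default_factory=lambda: np.empty(0))
    inv_sd: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_informative(self) -> int:
        return int(self.informative.sum())

    def swap_founders(self) -> "FounderReference":
        """Reference with founder roles exchanged (A and B swap)."""
        return FounderReference((self.founder_names[1], self.founder_names[0]),
                                self.snp_probes, self.centers2, self.centers1,
                                self.dispersion, self.informative,
                                self.sep_threshold, self.inv_probes,
                                self.inv_mean, self.inv_sd)


@dataclass
class GenotypeCallSet:
    """A/B/N calls at informative SNPs: ``calls[sample, probe]`` in {0,1,2}."""

    probes: pd.DataFrame  # informative SNP probes (probe_id, chrom, pos)
    samples: list[str]
    calls: np.ndarray  # int8 (n_samples, n_probes)

    def __post_init__(self) -> None:
        self._sample_index = {s: i for i, s in enumerate(self.samples)}
        self._chrom_cache: dict[str, np.ndarray] = {}

    def sample_calls(self, sample: str) -> np.ndarray:
        return self.calls[self._sample_index[sample]]

    def chrom_mask(self, chrom: str) -> np.ndarray:
        if chrom not in self._chrom_cache:
            self._chrom_cache[chrom] = (self.probes["chrom"] == chrom).to_numpy()
        return self._chrom_cache[chrom]

    def chrom_calls(self, sample: str, chrom: str) -> tuple[np.ndarray, np.ndarray]:
        """(positions, calls) along one chromosome for one sample."""
        m = self.chrom_mask(chrom)
        return self.probes["pos"].to_numpy()[m], self.sample_calls(sample)[m]

    @property
    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.probes["chrom"]))

    def swap_founders(self) -> "GenotypeCallSet":
        swapped = self.calls.copy()
        swapped[self.calls == CALL_A] = CALL_B
        swapped[self.calls == CALL_B] = CALL_A
        return GenotypeCallSet(self.probes, list(self.samples), swapped)


def build_founder_reference(founder_intensities: IntensityTable,
                            founder_samples: dict[str, list[str]],
                            sep_threshold: float = DEFAULT_SEP_THRESHOLD,
                            min_dispersion: float = DEFAULT_MIN_DISPERSION,
                            ) -> FounderReference:
    """Estimate founder cluster centres, dispersion and informative flags.

    ``founder_samples`` maps each of the two founder names to its replicate
    sample names.  Centres are replicate means; dispersion is the pooled
    per-probe replicate standard deviation (mean over the two channels and
    both founders), floored at ``min_dispersion``.
    """
    if len(founder_samples) != 2:
        raise ValueError("exactly two panel founders are required")
    (f1, reps1), (f2, reps2) = founder_samples.items()
    for f, reps in ((f1, reps1), (f2, reps2)):
        if not reps:
            raise ValueError(f"founder {f!r} has no replicate samples")
        missing = [s for s in reps if s not in founder_intensities.samples]
        if missing:
            raise ValueError(f"founder {f!r}: missing samples {missing}")

    snp = founder_intensities.select_class("snp")

    def stats(reps: list[str]) -> tuple[np.ndarray, np.ndarray]:
        idx = [snp.sample_row(s) for s in reps]
        a, c = snp.average[idx], snp.contrast[idx]
        center = np.stack([a.mean(axis=0), c.mean(axis=0)], axis=1)
        if len(idx) > 1:
            var = 0.5 * (a.var(axis=0, ddof=1) + c.var(axis=0, ddof=1))
        else:
            var = np.zeros(snp.n_probes)
        return center, var

    c1, v1 = stats(reps1)
    c2, v2 = stats(reps2)
    n1, n2 = len(reps1), len(reps2)
    w1 = max(n1 - 1, 0)
    w2 = max(n2 - 1, 0)
    pooled = np.sqrt((w1 * v1 + w2 * v2) / max(w1 + w2, 1))
    dispersion = np.maximum(pooled, min_dispersion)
    sep = np.hypot(c1[:, 0] - c2[:, 0], c1[:, 1] - c2[:, 1])
    informative = sep > sep_threshold * dispersion

    inv = founder_intensities.select_class("invariant")
    if inv.n_probes:
        idx = [inv.sample_row(s) for s in reps1 + reps2]
        inv_mean = inv.average[idx].mean(axis=0)
        inv_sd = (inv.average[idx].std(axis=0, ddof=1) if len(idx) > 1
                  else np.zeros(inv.n_probes))
        inv_sd = np.maximum(inv_sd, min_dispersion)
    else:
        inv_mean = inv_sd = np.empty(0)
    log.info("founder reference: %d/%d SNP probes informative, %d invariant probes",
             int(informative.sum()), snp.n_probes, inv.n_probes)
    return FounderReference((f1, f2), snp.probes, c1, c2, dispersion, informative,
                            sep_threshold, inv.probes, inv_mean, inv_sd)


def call_genotypes(sample_intensities: IntensityTable, ref: FounderReference,
                   call_radius: float = DEFAULT_CALL_RADIUS,
                   samples: list[str] | None = None) -> GenotypeCallSet:
    """A/B/N calls at informative SNPs for every requested sample.

    A sample is called ``A`` when its signal is within ``call_radius``
    dispersions of the founder-1 centre and strictly closer to it than to
    founder 2 (symmetrically for ``B``); exact ties and everything else are
    ``N``.
    """
    snp = sample_intensities.select_class("snp")
    ref_ids = ref.snp_probes["probe_id"]
    if not snp.probes["probe_id"].equals(ref_ids):
        shared = snp.probes["probe_id"].isin(set(ref_ids)).to_numpy()
        skipped = int((~shared).sum())
        if skipped:
            log.warning("skipping %d probes absent from the founder reference", skipped)
        snp = snp.select_probes(shared)
        keep_ref = ref_ids.isin(set(snp.probes["probe_id"])).to_numpy()
        ref = FounderReference(ref.founder_names, ref.snp_probes[keep_ref].reset_index(drop=True),
                               ref.centers1[keep_ref], ref.centers2[keep_ref],
                               ref.dispersion[keep_ref], ref.informative[keep_ref],
                               ref.sep_threshold, ref.inv_probes, ref.inv_mean, ref.inv_sd)
        if not snp.probes["probe_id"].equals(ref.snp_probes["probe_id"]):
            raise ValueError("sample and reference probe sets cannot be aligned")
    info = ref.informative
    snp = snp.select_probes(info)
    c1, c2 = ref.centers1[info], ref.centers2[info]
    disp = ref.dispersion[info]
    if samples is None:
        samples = list(snp.samples)
    idx = [snp.sample_row(s) for s in samples]
    avg, con = snp.average[idx], snp.contrast[idx]
    d1 = np.hypot(avg - c1[:, 0], con - c1[:, 1])
    d2 = np.hypot(avg - c2[:, 0], con - c2[:, 1])
    r = call_radius * disp
    calls = np.full(d1.shape, CALL_N, dtype=np.int8)
    calls[(d1 <= r) & (d1 < d2)] = CALL_A
    calls[(d2 <= r) & (d2 < d1)] = CALL_B
    return GenotypeCallSet(snp.probes, list(samples), calls)
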