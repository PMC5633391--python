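"""Two-channel array intensity container.

The assay emits, for every sample and probeset, an ``average`` (overall
hybridisation strength) and a ``contrast`` (allele A vs allele B balance).
SNP probes separate genotype classes in the (average, contrast) plane;
invariant probes respond to copy number through the average channel only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROBE_COLUMNS = ["probe_id", "chrom", "pos", "probe_class"]


@dataclass
class IntensityTable:
    """(average, contrast) per sample x probe.

    ``probes`` is a DataFrame with columns ``probe_id, chrom, pos,
    probe_class``; ``average`` and ``contrast`` are ``(n_samples,
    n_probes)`` float arrays aligned with ``samples`` / ``probes``.
    """

    probes: pd.DataFrame
    samples: list[str]
    average: np.ndarray
    contrast: np.ndarray
    _sample_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n_s, n_p = len(self.samples), len(self.probes)
        if self.average.shape != (n_s, n_p) or self.contrast.shape != (n_s, n_p):
            raise ValueError("intensity arrays do not match samples x probes")
        if len(set(self.samples)) != n_s:
            raise ValueError("duplicate sample names")
        if self.probes["probe_id"].duplicated().any():
            raise ValueError("duplicate probe ids")
        self._sample_index = {s: i for i, s in enumerate(self.samples)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def sample_row(self, sample: str) -> int:
        try:
            return self._sample_index[sample]
        except KeyError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def select_probes(self, mask: np.ndarray) -> "IntensityTable":
        return IntensityTable(self.probes[mask].reset_index(drop=True),
                             list(self.samples),
                             self.average[:, mask], self.contrast[:, mask])

    def select_class(self, probe_class: str) -> "IntensityTable":
        return self.select_probes((self.probes["probe_class"] == probe_class).to_numpy())

    def select_samples(self, samples: list[str]) -> "IntensityTable":
        idx = [self.sample_row(s) for s in samples]
        return IntensityTable(self.probes, list(samples),
                             self.average[idx], self.contrast[idx])

    def signal(self, sample: str) -> np.ndarray:
        """(n_probes, 2) array of (average, contrast) for one sample."""
        i = self.sample_row(sample)
        return np.stack([self.average[i], self.contrast[i]], axis=1)

    def to_tall(self) -> pd.DataFrame:
        """Tall DataFrame: sample, probe_id, average, contrast."""
        n_s, n_p = self.n_samples, self.n_probes
        return pd.DataFrame({
            "sample": np.repeat(self.samples, n_p),
            "probe_id": np.tile(self.probes["probe_id"].to_numpy(), n_s),
            "average": self.average.ravel(),
            "contrast": self.contrast.ravel(),
        })

    @classmethod
    def from_tall(cls, tall: pd.DataFrame, probes: pd.DataFrame) -> "IntensityTable":
        ids = probes["probe_id"].to_numpy()
        col = {p: j for j, p in enumerate(ids)}
        unknown = set(tall["probe_id"]) - set(ids)
        if unknown:
            bad = sorted(unknown)[0]
            line = int(tall.index[tall["probe_id"] == bad][0]) + 2  # +header, 1-based
            raise ValueError(f"intensity row references unknown probe id {bad!r} (line {line})")
        samples = list(dict.fromkeys(tall["sample"]))
        row = {s: i for i, s in enumerate(samples)}
        avg = np.full((len(samples), len(ids)), np.nan, dtype=np.float64)
        con = np.full_like(avg, np.nan)
        ri = tall["sample"].map(row).to_numpy()
        ci = tall["probe_id"].map(col).to_numpy()
        avg[ri, ci] = tall["average"].to_numpy()
        con[ri, ci] = tall["contrast"].to_numpy()
        if np.isnan(avg).any():
            raise ValueError("missing intensity values for some sample x probe pairs")
        return cls(probes.reset_index(drop=True), samples, avg, con)


def concat_samples(tables: list[IntensityTable]) -> IntensityTable:
    first = tables[0]
    for t in tables[1:]:
        if not first.probes["probe_id"].equals(t.probes["probe_id"]):
            raise ValueError("probe sets differ between tables")
    samples: list[str] = []
    for t in tables:
        samples.extend(t.samples)
    return IntensityTable(first.probes, samples,
                         np.vstack([t.average for t in tables]),
                         np.vstack([t.contrast for t in tables]))
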