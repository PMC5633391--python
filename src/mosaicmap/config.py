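"""Run configuration: thresholds, panel design, seeds.

A flat YAML file; unspecified keys take the documented defaults.  Every
threshold is echoed to the log so a run's provenance is recoverable.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

log = logging.getLogger(__name__)

_RANGES = {
    "sep_threshold": (0.0, 100.0),
    "call_radius": (0.0, 100.0),
    "min_dispersion": (0.0, 10.0),
    "tau": (0.0, 0.5),
    "cnv_t_threshold": (0.0, 1e6),
    "cnv_min_probes": (1, 10_000),
    "cnv_min_length_bp": (0, 10**9),
    "contamination_min_discordant": (1, 10_000),
    "sister_z_threshold": (0.0, 1e6),
    "informative_fraction": (0.0, 1.0),
    "noise_sd": (0.0, 10.0),
}


@dataclass
class RunConfig:
    # panel design
    panel_type: str = "ris_classical"
    n_strains: int = 10
    founders: list[str] = field(default_factory=lambda: ["founder1", "founder2"])
    donor_chrom: str | None = None
    n_backcross_meioses: int = 9
    selection_marker_positions: list[int] | None = None
    n_outcross_generations: int = 0
    max_sib_generations: int = 25
    # genome / markers
    genome: str | dict = "mouse-default"
    # synthetic intensities
    informative_fraction: float = 0.35
    noise_sd: float = 0.08
    founder_replicates: int = 8
    # thresholds
    sep_threshold: float = 6.0
    call_radius: float = 3.0
    min_dispersion: float = 0.02
    tau: float = 1e-3
    cnv_t_threshold: float = 5.0
    cnv_min_probes: int = 10
    cnv_min_length_bp: int = 20_000
    contamination_min_discordant: int = 3
    sister_z_threshold: float = 5.0
    # bookkeeping
    seed: int = 1
    outdir: str = "mosaicmap_out"

    def __post_init__(self) -> None:
        for key, (lo, hi) in _RANGES.items():
            v = getattr(self, key)
            if not (lo <= v <= hi):
                raise ValueError(f"{key}={v} outside valid range [{lo}, {hi}]")
        if self.panel_type not in ("ris_classical", "ris_advanced", "css"):
            raise ValueError(f"unknown panel type {self.panel_type!r}")

    def echo(self) -> None:
        for key, value in asdict(self).items():
            log.info("config %s = %r", key, value)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(RunConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data.update(overrides)
    cfg = RunConfig(**data)
    cfg.echo()
    return cfg
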