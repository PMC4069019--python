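"""Run configuration, overridable from a TOML file.

Defaults are the settings of the analysis this pipeline implements:
hotspot threshold 10x and block threshold 5x background, common-haplotype
filter 5%, 1000 block-test permutations, 250 rate-test permutations,
4 MCMC runs x 1000 samples (median of 4000), tag-SNP MAF floor 0.07,
LDsplit-style subsampling 190/160 and 10 replicates.
"""

from __future__ import annotations

import copy
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .pac import McmcConfig, PacConfig
from .ldsplit import SplitScanConfig

DEFAULTS: dict[str, dict[str, Any]] = {
    "general": {"seed": 0, "verbosity": "INFO"},
    "hotspots": {"threshold": 10.0, "strict": True, "block_max_relative": 5.0},
    "cohort": {"min_freq": 0.05, "q": 0.05, "n_perm_block": 1000, "n_perm_rate": 250},
    "mcmc": {
        "n_runs": 4,
        "n_samples_per_run": 1000,
        "n_burnin": 500,
        "proposal_sd": 1.0,
        "prior_sd": 2.0,
    },
    "pac": {"n_orders": 20, "theta_tilde": 0.0},  # 0.0 = Watterson per panel
    "split": {
        "n_replicates": 10,
        "subsample_high_maf": 190,
        "subsample_low_maf_total": 160,
        "maf_split": 0.1,
        "inner_n_perm": 200,
        "bonferroni_alpha": 0.05,
        "maf_min": 0.07,
        "r2_threshold": 0.8,
    },
    "simulate": {
        "n_haplotypes": 200,
        "theta": 50.0,
        "region_length": 100_000.0,
        "background": 4e-4,
        "hotspot_start": 45_000.0,
        "hotspot_end": 47_000.0,
        "hotspot_multiplier": 10.0,
        "maf_ascertainment": 0.05,
        "n_case_ind": 100,
        "n_ctrl_ind": 100,
        "case_multiplier": 10.0,
        "n_snps": 30,
    },
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Resolved configuration: defaults merged with file overrides."""

    values: dict[str, dict[str, Any]] = field(
        default_factory=lambda: copy.deepcopy(DEFAULTS)
    )

    def get(self, section: str, key: str) -> Any:
        return self.values[section][key]

    def mcmc_config(self, seed: int | None = None) -> McmcConfig:
        m = self.values["mcmc"]
        return McmcConfig(
            n_runs=m["n_runs"],
            n_samples_per_run=m["n_samples_per_run"],
            n_burnin=m["n_burnin"],
            proposal_sd=m["proposal_sd"],
            prior_sd=m["prior_sd"],
            seed=self.get("general", "seed") if seed is None else seed,
        )

    def pac_config(self, seed: int | None = None) -> PacConfig:
        p = self.values["pac"]
        theta = p["theta_tilde"] or None
        return PacConfig(
            theta_tilde=theta,
            n_orders=p["n_orders"],
            seed=self.get("general", "seed") if seed is None else seed,
        )

    def split_config(self, seed: int | None = None) -> SplitScanConfig:
        s = self.values["split"]
        return SplitScanConfig(
            n_replicates=s["n_replicates"],
            subsample_high_maf=s["subsample_high_maf"],
            subsample_low_maf_total=s["subsample_low_maf_total"],
            maf_split=s["maf_split"],
            inner_n_perm=s["inner_n_perm"],
            bonferroni_alpha=s["bonferroni_alpha"],
            mcmc=self.mcmc_config(seed),
            pac=self.pac_config(seed),
            seed=self.get("general", "seed") if seed is None else seed,
        )

    def as_lines(self) -> list[str]:
        out = []
        for sec in sorted(self.values):
            for key in sorted(self.values[sec]):
                out.append(f"{sec}.{key}={self.values[sec][key]}")
        return out


def load_config(path: str | Path | None) -> RunConfig:
    """Merge a TOML config file over the defaults; unknown keys are rejected."""
    cfg = RunConfig()
    if path is None:
        return cfg
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    for sec, entries in data.items():
        if sec not in cfg.values:
            raise ConfigError(f"unknown config section {sec!r}")
        if not isinstance(entries, dict):
            raise ConfigError(f"section {sec!r} must be a table")
        for key, val in entries.items():
            if key not in cfg.values[sec]:
                raise ConfigError(f"unknown config key {sec}.{key!r}")
            default = cfg.values[sec][key]
            if isinstance(default, bool):
                ok = isinstance(val, bool)
            elif isinstance(default, float):
                ok = isinstance(val, (int, float)) and not isinstance(val, bool)
            elif isinstance(default, int):
                ok = isinstance(val, int) and not isinstance(val, bool)
            else:
                ok = isinstance(val, type(default))
            if not ok:
                raise ConfigError(
                    f"config key {sec}.{key}: expected {type(default).__name__}, "
                    f"got {type(val).__name__}"
                )
            cfg.values[sec][key] = float(val) if isinstance(default, float) else val
    return cfg
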