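"""Run configuration: YAML in, validated defaults out.

Every analysis threshold defaults to the value the study design fixes —
|logFC| > 2 and FDR < 1e-3 for differential expression, phase-mean TPM > 500
for the highly expressed set, detection in at least 3 samples for the
prevalence filter, BH-adjusted p <= 0.05 for domain enrichment, a 20-fold
dilution — and every field can be overridden from the config file.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from typing import Sequence

import yaml

__all__ = ["RunConfig", "load_config", "save_config", "DEFAULT_STAGES"]

DEFAULT_STAGES = (
    "simulate", "kinetics", "curate", "de", "heg", "aggregate", "enrich", "biogeo",
)


@dataclass(frozen=True)
class RunConfig:
    stages: tuple[str, ...] = DEFAULT_STAGES
    seed: int = 0
    out_dir: str = "grazekit_run"
    # expression classification
    logfc_threshold: float = 2.0
    fdr_threshold: float = 1e-3
    tpm_threshold: float = 500.0
    # curation
    min_samples: int = 3
    detection_threshold: float = 1.0
    # enrichment
    enrichment_cutoff: float = 0.05
    # kinetics
    prey_mean_method: str = "geometric"
    predator_mean_method: str = "integral"
    carbon_a: float = 0.216
    carbon_b: float = 0.939
    r2_threshold: float = 0.99
    # simulation
    dilution_factor: float = 20.0
    count_noise_cv: float = 0.05
    n_genes: int = 2000
    de_fraction: float = 0.1

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(DEFAULT_STAGES)
        if unknown:
            raise ValueError(
                f"unknown stages {sorted(unknown)}; valid stages: {list(DEFAULT_STAGES)}"
            )
        for name in ("logfc_threshold", "fdr_threshold", "tpm_threshold",
                     "enrichment_cutoff", "carbon_a", "carbon_b",
                     "dilution_factor", "r2_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_samples < 0 or self.count_noise_cv < 0:
            raise ValueError("min_samples and count_noise_cv must be nonnegative")
        for name in ("prey_mean_method", "predator_mean_method"):
            if getattr(self, name) not in ("geometric", "integral"):
                raise ValueError(f"{name} must be 'geometric' or 'integral'")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["stages"] = list(self.stages)
        return d


def load_config(path) -> RunConfig:
    """Load a YAML config; unset fields take the documented defaults.

    Unknown keys raise, listing the valid keys, so typos never silently fall
    back to a default.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must contain a mapping")
    valid = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(
            f"unknown config keys {sorted(unknown)}; valid keys: {sorted(valid)}"
        )
    if "stages" in raw:
        raw["stages"] = tuple(raw["stages"])
    return RunConfig(**raw)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.as_dict(), fh, sort_keys=True)
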