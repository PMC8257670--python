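"""Configuration objects for the simulation and the end-to-end pipeline.

All randomness in the package flows from the single ``seed`` field of a
:class:`SimulationConfig`; stages derive independent child streams from it so
that rerunning any stage, or the whole pipeline, with the same configuration
reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence


class ConfigError(ValueError):
    """Raised when a configuration fails validation."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    The in-vitro block mirrors a 384-feature qPCR array-card experiment on a
    small panel of cell lines grown in normoxia (21% O2) and hypoxia
    (0.2% and 1% O2) in biological triplicate.  The cohort block mirrors a
    tumour cohort carrying a latent binary hypoxia state that drives an
    anchor mRNA signature, a signed set of miRNAs and survival.  The trial
    block mirrors a 1:1 two-arm radiotherapy +/- hypoxia-modification trial
    with a planted treatment-by-hypoxia interaction.

    Units: Ct values are qPCR cycles (lower = more abundant); expression is
    log2; hazards are events per month; times are months.
    """

    seed: int = 0

    # --- in-vitro qPCR block ---
    n_cell_lines: int = 4
    n_target_features: int = 384
    n_control_features: int = 3
    n_replicates: int = 3
    o2_conditions: tuple[float, ...] = (21.0, 0.2, 1.0)
    n_planted_induced: int = 30
    induction_shift_ct: float = 1.5
    ct_noise_sd: float = 0.25
    sample_offset_sd: float = 0.5
    low_expression_fraction: float = 0.04

    # --- cohort block ---
    cohort_n: int = 400
    anchor_gene_count: int = 99
    n_background_genes: int = 100
    hypoxia_prevalence: float = 0.5
    n_signature_pos: int = 7
    n_signature_neg: int = 7
    n_unexpressed: int = 3
    mirna_effect_log2: float = 1.0
    anchor_effect_log2: float = 1.0
    expression_noise_sd: float = 1.0

    # --- survival / trial block ---
    baseline_hazard: float = 0.015
    log_hr_hypoxia: float = math.log(2.0)
    trial_n_per_arm: int = 95
    trial_hypoxia_prevalence: float = 0.25
    log_hr_treatment_hypoxic: float = math.log(0.45)
    log_hr_treatment_normoxic: float = 0.0
    admin_censor_months: float = 60.0
    dropout_rate: float = 0.005

    def __post_init__(self) -> None:
        counts = {
            "n_cell_lines": self.n_cell_lines,
            "n_target_features": self.n_target_features,
            "n_control_features": self.n_control_features,
            "n_replicates": self.n_replicates,
            "cohort_n": self.cohort_n,
            "anchor_gene_count": self.anchor_gene_count,
            "trial_n_per_arm": self.trial_n_per_arm,
        }
        for name, value in counts.items():
            if not isinstance(value, int) or value <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {value!r}")
        for name in ("n_planted_induced", "n_background_genes", "n_signature_pos",
                     "n_signature_neg", "n_unexpressed"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        for name in ("hypoxia_prevalence", "trial_hypoxia_prevalence"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ConfigError(f"{name} must lie in (0, 1), got {value!r}")
        if not 0.0 <= self.low_expression_fraction < 1.0:
            raise ConfigError("low_expression_fraction must lie in [0, 1)")
        for name in ("ct_noise_sd", "sample_offset_sd", "expression_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.induction_shift_ct < 0:
            raise ConfigError("induction_shift_ct must be >= 0")
        if self.n_planted_induced > self.n_target_features:
            raise ConfigError("n_planted_induced cannot exceed n_target_features")
        if self.n_signature_pos + self.n_signature_neg + self.n_unexpressed > self.n_planted_induced:
            raise ConfigError(
                "signature and unexpressed plantings cannot exceed n_planted_induced")
        if self.baseline_hazard <= 0:
            raise ConfigError("baseline_hazard must be > 0")
        if self.dropout_rate < 0:
            raise ConfigError("dropout_rate must be >= 0")
        if self.admin_censor_months <= 0:
            raise ConfigError("admin_censor_months must be > 0")
        if len(self.o2_conditions) < 2 or 21.0 not in self.o2_conditions:
            raise ConfigError("o2_conditions must include the 21% normoxia reference")

    def replace(self, **kwargs: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["o2_conditions"] = list(self.o2_conditions)
        return d

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown simulation config fields: {sorted(unknown)}")
        d = dict(data)
        if "o2_conditions" in d:
            d["o2_conditions"] = tuple(float(x) for x in d["o2_conditions"])
        return cls(**d)


@dataclass(frozen=True)
class Thresholds:
    """Statistical thresholds of the derivation pipeline (all spec defaults)."""

    p_value: float = 0.05
    fold_change: float = 1.0
    min_lines: int = 2
    o2_hypoxia: float = 0.2
    ct_exclusion: float = 30.0
    train_fraction: float = 0.7
    unexpressed_zero_fraction: float = 0.5
    q_threshold: float = 0.05
    boruta_n_trees: int = 500
    boruta_max_iter: int = 1000
    boruta_alpha: float = 0.05
    boruta_include_tentative: bool = True
    entry_p: float = 0.1
    censor_months: float = 60.0

    def __post_init__(self) -> None:
        if not 0 < self.p_value < 1:
            raise ConfigError("p_value threshold must lie in (0, 1)")
        if not 0 < self.train_fraction < 1:
            raise ConfigError("train_fraction must lie in (0, 1)")
        if self.min_lines < 1:
            raise ConfigError("min_lines must be >= 1")
        if self.boruta_max_iter < 0:
            raise ConfigError("boruta_max_iter must be >= 0")

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "Thresholds":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown threshold fields: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class RunConfig:
    """Top-level configuration of a full pipeline run."""

    seed: int = 0
    outdir: str = "results/run"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    cohort_cutoff: str = "median"
    trial_cutoff: str = "upper_quartile"
    endpoints: tuple[str, ...] = ("OS", "PFS")
    trial_endpoints: tuple[str, ...] = ("OS", "LRFS")
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        valid = {"median", "lower_quartile", "upper_quartile"}
        for name in ("cohort_cutoff", "trial_cutoff"):
            if getattr(self, name) not in valid:
                raise ConfigError(f"{name} must be one of {sorted(valid)}")

    def to_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "outdir": self.outdir,
            "simulation": self.simulation.to_dict(),
            "thresholds": self.thresholds.to_dict(),
            "cohort_cutoff": self.cohort_cutoff,
            "trial_cutoff": self.trial_cutoff,
            "endpoints": list(self.endpoints),
            "trial_endpoints": list(self.trial_endpoints),
            "log_level": self.log_level,
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "RunConfig":
        known = {"seed", "outdir", "simulation", "thresholds", "cohort_cutoff",
                 "trial_cutoff", "endpoints", "trial_endpoints", "log_level"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown run config fields: {sorted(unknown)}")
        d = dict(data)
        sim = d.get("simulation", {})
        if isinstance(sim, Mapping):
            seed = d.get("seed", 0)
            sim = dict(sim)
            sim.setdefault("seed", seed)
            d["simulation"] = SimulationConfig.from_dict(sim)
        thr = d.get("thresholds", {})
        if isinstance(thr, Mapping):
            d["thresholds"] = Thresholds.from_dict(thr)
        for name in ("endpoints", "trial_endpoints"):
            if name in d:
                d[name] = tuple(d[name])
        return cls(**d)
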