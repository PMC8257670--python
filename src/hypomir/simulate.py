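"""Synthetic study generator.

Emits every input the derivation/validation pipeline consumes — array-card Ct
tables, cohort/trial expression matrices, survival tables — together with the
planted ground truth, so the whole analysis can be exercised and its recovery
properties measured without any external cohort.

Structure emulated:

* qPCR block: ``n_cell_lines`` lines x {21%, 0.2%, 1%} O2 x triplicates over
  384 target miRNAs plus endogenous controls.  A planted subset of targets is
  induced (Ct lowered) under hypoxia in >=2 lines; a small fraction is
  unexpressed (Ct >= 30 everywhere) to exercise the exclusion filter; every
  (line, condition, replicate) sample carries a global Ct offset to exercise
  control normalisation.
* cohort block: latent binary hypoxia H drives an anchor mRNA signature
  (up in hypoxia), a signed miRNA set (positives up, negatives down) and
  exponential survival with administrative censoring and dropout.
* trial block: forced 1:1 randomisation to RT vs RT+CON with the treatment
  benefit confined to the hypoxic stratum (planted interaction), plus
  IHC-like continuous hypoxia markers.

All expression is generated directly on the log2 scale; survival times are
exponential so proportional hazards holds exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .config import ConfigError, SimulationConfig

NORMOXIA_O2 = 21.0

_CT_STREAM = 1
_COHORT_STREAM = 2
_TRIAL_STREAM = 3
_TRUTH_STREAM = 4


def target_feature_ids(n: int) -> list[str]:
    return [f"miR-sim-{i + 1:03d}" for i in range(n)]


def control_feature_ids(n: int) -> list[str]:
    return [f"CTRL-{i + 1:02d}" for i in range(n)]


def anchor_gene_ids(n: int) -> list[str]:
    return [f"HYPX-G{i + 1:03d}" for i in range(n)]


def background_gene_ids(n: int) -> list[str]:
    return [f"BG-G{i + 1:03d}" for i in range(n)]


def cell_line_ids(n: int) -> list[str]:
    return [f"CL{i + 1}" for i in range(n)]


@dataclass
class GroundTruth:
    """Planted truths of one simulated study.

    ``planted_induced`` maps each induced feature id to the set of cell lines
    in which it was planted; ``signature_positive``/``signature_negative`` are
    the signed hypoxia-responsive miRNA sets in the cohort; ``latent_hypoxia``
    is the per-sample binary H (with a noisy continuous companion score);
    ``true_log_hrs`` records the hazard structure per endpoint.
    """

    planted_induced: dict[str, tuple[str, ...]] = field(default_factory=dict)
    signature_positive: tuple[str, ...] = ()
    signature_negative: tuple[str, ...] = ()
    unexpressed_features: tuple[str, ...] = ()
    low_expression_features: tuple[str, ...] = ()
    latent_hypoxia: pd.Series | None = None
    latent_hypoxia_score: pd.Series | None = None
    true_log_hrs: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def signature_features(self) -> tuple[str, ...]:
        return tuple(self.signature_positive) + tuple(self.signature_negative)

    def induced_in_at_least(self, k: int) -> list[str]:
        return sorted(f for f, lines in self.planted_induced.items() if len(lines) >= k)

    def to_dict(self) -> dict[str, Any]:
        return {
            "planted_induced": {f: list(v) for f, v in sorted(self.planted_induced.items())},
            "signature_positive": list(self.signature_positive),
            "signature_negative": list(self.signature_negative),
            "unexpressed_features": list(self.unexpressed_features),
            "low_expression_features": list(self.low_expression_features),
            "latent_hypoxia": (None if self.latent_hypoxia is None
                               else {k: int(v) for k, v in self.latent_hypoxia.items()}),
            "latent_hypoxia_score": (None if self.latent_hypoxia_score is None
                                     else {k: float(v) for k, v in self.latent_hypoxia_score.items()}),
            "true_log_hrs": self.true_log_hrs,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "GroundTruth":
        lh = d.get("latent_hypoxia")
        lhs = d.get("latent_hypoxia_score")
        return cls(
            planted_induced={f: tuple(v) for f, v in d.get("planted_induced", {}).items()},
            signature_positive=tuple(d.get("signature_positive", ())),
            signature_negative=tuple(d.get("signature_negative", ())),
            unexpressed_features=tuple(d.get("unexpressed_features", ())),
            low_expression_features=tuple(d.get("low_expression_features", ())),
            latent_hypoxia=None if lh is None else pd.Series(lh),
            latent_hypoxia_score=None if lhs is None else pd.Series(lhs),
            true_log_hrs={k: dict(v) for k, v in d.get("true_log_hrs", {}).items()},
        )


def _plant_truth(config: SimulationConfig) -> GroundTruth:
    """Draw the planted feature sets shared by the qPCR and cohort blocks."""
    rng = np.random.default_rng([_TRUTH_STREAM, config.seed])
    targets = np.array(target_feature_ids(config.n_target_features))
    lines = cell_line_ids(config.n_cell_lines)

    n_low = int(round(config.low_expression_fraction * config.n_target_features))
    order = rng.permutation(config.n_target_features)
    low_expr = sorted(targets[order[:n_low]])
    candidates = targets[order[n_low:]]
    planted = sorted(candidates[: config.n_planted_induced])

    truth = GroundTruth(low_expression_features=tuple(low_expr))
    # each planted feature is induced in >=2 lines so that every one is a
    # legitimate seed candidate at the default min_lines=2 rule
    weights = np.array([0.5, 0.3, 0.2][: max(config.n_cell_lines - 1, 1)], dtype=float)
    weights /= weights.sum()
    for feat in planted:
        if config.n_cell_lines < 2:
            k = config.n_cell_lines
        else:
            k = int(rng.choice(np.arange(2, 2 + len(weights)), p=weights))
            k = min(k, config.n_cell_lines)
        chosen = sorted(rng.choice(lines, size=k, replace=False).tolist())
        truth.planted_induced[feat] = tuple(chosen)

    pool = list(planted)
    rng.shuffle(pool)
    n_pos, n_neg, n_unexpr = (config.n_signature_pos, config.n_signature_neg,
                              config.n_unexpressed)
    truth.signature_positive = tuple(sorted(pool[:n_pos]))
    truth.signature_negative = tuple(sorted(pool[n_pos:n_pos + n_neg]))
    truth.unexpressed_features = tuple(sorted(pool[n_pos + n_neg:n_pos + n_neg + n_unexpr]))
    return truth


def generate_ct_table(config: SimulationConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate the array-card qPCR experiment.

    Returns a long-format Ct table with columns (cell_line, o2_percent,
    replicate, feature_id, feature_class, ct) and the ground truth.  Lower Ct
    means higher expression, so planted induction subtracts
    ``induction_shift_ct`` from the hypoxic Ct values.
    """
    if config.n_control_features == 0:
        raise ConfigError("at least one endogenous control feature is required")
    truth = _plant_truth(config)
    rng = np.random.default_rng([_CT_STREAM, config.seed])

    targets = target_feature_ids(config.n_target_features)
    controls = control_feature_ids(config.n_control_features)
    lines = cell_line_ids(config.n_cell_lines)
    low_expr = set(truth.low_expression_features)

    base_target = rng.uniform(22.0, 28.0, size=config.n_target_features)
    base_target[[f in low_expr for f in targets]] = rng.uniform(31.0, 34.0, size=len(low_expr))
    base_control = rng.uniform(15.0, 17.0, size=config.n_control_features)
    line_effect = rng.normal(0.0, 0.5, size=(config.n_cell_lines, 1))

    records: list[tuple] = []
    for li, line in enumerate(lines):
        for o2 in config.o2_conditions:
            hypoxic = o2 < NORMOXIA_O2
            for rep in range(1, config.n_replicates + 1):
                offset = rng.normal(0.0, config.sample_offset_sd)
                t_noise = rng.normal(0.0, config.ct_noise_sd, size=config.n_target_features)
                c_noise = rng.normal(0.0, config.ct_noise_sd, size=config.n_control_features)
                for fi, feat in enumerate(targets):
                    ct = base_target[fi] + line_effect[li, 0] + offset + t_noise[fi]
                    if (hypoxic and feat in truth.planted_induced
                            and line in truth.planted_induced[feat]):
                        ct -= config.induction_shift_ct
                    records.append((line, o2, rep, feat, "target", ct))
                for fi, feat in enumerate(controls):
                    ct = base_control[fi] + line_effect[li, 0] + offset + c_noise[fi]
                    records.append((line, o2, rep, feat, "control", ct))
    table = pd.DataFrame.from_records(
        records,
        columns=["cell_line", "o2_percent", "replicate", "feature_id", "feature_class", "ct"],
    )
    return table, truth


def _expression_block(rng: np.random.Generator, samples: list[str], features: list[str],
                      h: np.ndarray, truth: GroundTruth, config: SimulationConfig) -> pd.DataFrame:
    """log2 miRNA matrix: signed signature features shifted by +/- effect * H."""
    n, p = len(samples), len(features)
    baseline = rng.uniform(2.0, 8.0, size=p)
    values = baseline[None, :] + rng.normal(0.0, config.expression_noise_sd, size=(n, p))
    pos = set(truth.signature_positive)
    neg = set(truth.signature_negative)
    unexpr = set(truth.unexpressed_features)
    for j, feat in enumerate(features):
        if feat in pos:
            values[:, j] += config.mirna_effect_log2 * h
        elif feat in neg:
            values[:, j] -= config.mirna_effect_log2 * h
        if feat in unexpr:
            zero_mask = rng.random(n) < 0.8
            values[zero_mask, j] = 0.0
            values[~zero_mask, j] = np.abs(rng.normal(0.1, 0.05, size=int((~zero_mask).sum())))
    df = pd.DataFrame(values, index=pd.Index(samples, name="sample_id"), columns=features)
    df.attrs["platform"] = "mirna_seq_rpm"
    df.attrs["transform"] = "log2(x+1), simulated directly on log2 scale"
    return df


def _survival_block(rng: np.random.Generator, samples: list[str], log_hazard: np.ndarray,
                    endpoint: str, config: SimulationConfig,
                    arm: np.ndarray | None = None) -> pd.DataFrame:
    """Exponential event times with exponential dropout + administrative censoring."""
    n = len(samples)
    rate = np.exp(log_hazard)
    t_event = rng.exponential(1.0 / rate)
    if config.dropout_rate > 0:
        t_drop = rng.exponential(1.0 / config.dropout_rate, size=n)
    else:
        t_drop = np.full(n, np.inf)
    t_cens = np.minimum(t_drop, config.admin_censor_months)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    df = pd.DataFrame({
        "sample_id": samples,
        "endpoint": endpoint,
        "time_months": time,
        "event": event,
    })
    if arm is not None:
        df["arm"] = arm
    return df


def generate_cohort(config: SimulationConfig
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the development cohort.

    Returns ``(mrna, mirna, survival, truth)``: an anchor-driven mRNA matrix,
    a miRNA matrix carrying the signed planted signature, a long survival
    table with OS and PFS endpoints, and the ground truth.  The latent binary
    hypoxia state H raises the anchor genes by ``anchor_effect_log2``,
    shifts the signature miRNAs by +/- ``mirna_effect_log2`` and multiplies
    the hazard by exp(``log_hr_hypoxia``).
    """
    truth = _plant_truth(config)
    rng = np.random.default_rng([_COHORT_STREAM, config.seed])
    n = config.cohort_n
    samples = [f"S{i + 1:04d}" for i in range(n)]

    h = (rng.random(n) < config.hypoxia_prevalence).astype(float)
    truth.latent_hypoxia = pd.Series(h.astype(int), index=samples, name="latent_hypoxia")
    truth.latent_hypoxia_score = pd.Series(h + rng.normal(0.0, 0.3, size=n), index=samples,
                                           name="latent_hypoxia_score")

    anchors = anchor_gene_ids(config.anchor_gene_count)
    background = background_gene_ids(config.n_background_genes)
    genes = anchors + background
    base = rng.uniform(4.0, 9.0, size=len(genes))
    mrna = base[None, :] + rng.normal(0.0, config.expression_noise_sd, size=(n, len(genes)))
    mrna[:, :len(anchors)] += config.anchor_effect_log2 * h[:, None]
    mrna = pd.DataFrame(mrna, index=pd.Index(samples, name="sample_id"), columns=genes)
    mrna.attrs["platform"] = "mrna_rsem"
    mrna.attrs["transform"] = "log2(x+1), simulated directly on log2 scale"

    mirna = _expression_block(rng, samples, target_feature_ids(config.n_target_features),
                              h, truth, config)

    log_h0 = np.log(config.baseline_hazard)
    tables = []
    for endpoint, rate_scale in (("OS", 1.0), ("PFS", 1.3)):
        log_hazard = log_h0 + np.log(rate_scale) + config.log_hr_hypoxia * h
        tables.append(_survival_block(rng, samples, log_hazard, endpoint, config))
    surv = pd.concat(tables, ignore_index=True)
    age = rng.normal(70.0, 8.0, size=n)
    stage = rng.choice(["T2", "T3", "T4"], size=n, p=[0.5, 0.35, 0.15])
    covars = pd.DataFrame({"sample_id": samples, "age": age, "stage": stage})
    surv = surv.merge(covars, on="sample_id")

    truth.true_log_hrs = {
        "OS": {"hypoxia": config.log_hr_hypoxia},
        "PFS": {"hypoxia": config.log_hr_hypoxia},
    }
    return mrna, mirna, surv, truth


def generate_trial(config: SimulationConfig
                   ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate the two-arm trial (RT vs RT+CON) with a planted interaction.

    Treatment multiplies the hazard by exp(``log_hr_treatment_hypoxic``) in
    the hypoxic stratum and exp(``log_hr_treatment_normoxic``) in the
    normoxic stratum; arms are forced exactly 1:1.  Returns
    ``(mirna, survival, truth)``; the survival table carries the arm column,
    OS and LRFS endpoints and continuous IHC-like markers (CAIX, GLUT1,
    HIF1A) shifted upward in hypoxic tumours.
    """
    truth = _plant_truth(config)
    rng = np.random.default_rng([_TRIAL_STREAM, config.seed])
    n = 2 * config.trial_n_per_arm
    samples = [f"T{i + 1:04d}" for i in range(n)]

    arm = np.array(["RT"] * config.trial_n_per_arm + ["RT+CON"] * config.trial_n_per_arm)
    rng.shuffle(arm)
    h = (rng.random(n) < config.trial_hypoxia_prevalence).astype(float)
    truth.latent_hypoxia = pd.Series(h.astype(int), index=samples, name="latent_hypoxia")
    truth.latent_hypoxia_score = pd.Series(h + rng.normal(0.0, 0.3, size=n), index=samples,
                                           name="latent_hypoxia_score")

    mirna = _expression_block(rng, samples, target_feature_ids(config.n_target_features),
                              h, truth, config)
    mirna.attrs["platform"] = "nanostring"

    treated = (arm == "RT+CON").astype(float)
    beta_t = config.log_hr_treatment_hypoxic * h + config.log_hr_treatment_normoxic * (1 - h)
    log_h0 = np.log(config.baseline_hazard)
    tables = []
    for endpoint, rate_scale in (("OS", 1.0), ("LRFS", 1.2)):
        log_hazard = (log_h0 + np.log(rate_scale) + config.log_hr_hypoxia * h
                      + beta_t * treated)
        tables.append(_survival_block(rng, samples, log_hazard, endpoint, config, arm=arm))
    surv = pd.concat(tables, ignore_index=True)

    markers = pd.DataFrame({
        "sample_id": samples,
        "CAIX": rng.normal(5.0, 1.0, size=n) + 1.0 * h,
        "GLUT1": rng.normal(5.0, 1.0, size=n) + 1.0 * h,
        "HIF1A": rng.normal(5.0, 1.0, size=n) + 1.0 * h,
    })
    surv = surv.merge(markers, on="sample_id")

    truth.true_log_hrs = {
        ep: {
            "hypoxia": config.log_hr_hypoxia,
            "treatment_hypoxic": config.log_hr_treatment_hypoxic,
            "treatment_normoxic": config.log_hr_treatment_normoxic,
        }
        for ep in ("OS", "LRFS")
    }
    return mirna, surv, truth
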