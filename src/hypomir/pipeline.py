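"""End-to-end orchestration: simulate → seed discovery → signature derivation
→ cohort scoring → survival validation → report.

Every stage communicates through the serialised interfaces in :mod:`.io`, so
any stage can be re-run from files.  One global seed fans out to per-stage
seeds recorded in the run manifest; identical configs reproduce identical
outputs byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as hio
from .config import ConfigError, RunConfig
from .qpcr import run_dge, select_seeds
from .scoring import (HYPOXIC, GeneSignature, ScoreResult, classify_by_quantile,
                      combine_classifications, score_mean_expression,
                      score_signed_signature)
from .selection import derive_signature, split_train_test
from .simulate import (GroundTruth, anchor_gene_ids, generate_cohort,
                       generate_ct_table, generate_trial)
from .survival import (CoxFit, censor_at, cox_univariable, interaction_test,
                       km_estimate, marker_association, stratum_benefit)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnosis."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"run config {path} must be a mapping")
    return RunConfig.from_dict(data)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed derived from the global seed."""
    stages = ("simulate", "dge", "split", "derive", "score", "validate", "trial")
    if stage not in stages:
        raise ValueError(f"unknown stage {stage!r}")
    return int(np.random.default_rng([global_seed, stages.index(stage)])
               .integers(0, 2 ** 31 - 1))


def anchor_signature(config: RunConfig) -> GeneSignature:
    """The simulated anchor mRNA hypoxia signature (unsigned mean-expression)."""
    return GeneSignature(
        name="anchor_mrna_hypoxia",
        positive=tuple(anchor_gene_ids(config.simulation.anchor_gene_count)),
        provenance="simulated anchor signature",
    )


@dataclass
class DerivationOutput:
    signature: GeneSignature
    seeds: list[str]
    seed_summary: pd.DataFrame
    dge_calls: pd.DataFrame
    train_ids: list[str]
    test_ids: list[str]
    truth: GroundTruth
    mrna: pd.DataFrame
    mirna: pd.DataFrame
    survival: pd.DataFrame
    report: Any = None


def run_derivation(config: RunConfig, outdir: Path | None = None,
                   write_plots: bool = True) -> DerivationOutput:
    """Execute the derivation arm: qPCR seeds → training split → signature."""
    thr = config.thresholds
    sim = config.simulation.replace(seed=config.seed)

    try:
        ct_table, _ct_truth = generate_ct_table(sim)
        mrna, mirna, survival, truth = generate_cohort(sim)
    except ConfigError:
        raise
    except Exception as exc:
        raise StageError("simulate", str(exc)) from exc

    try:
        calls = run_dge(ct_table, normoxia=21.0, hypoxia=thr.o2_hypoxia,
                        ct_threshold=thr.ct_exclusion, p_threshold=thr.p_value,
                        fc_threshold=thr.fold_change)
        seeds, seed_summary = select_seeds(calls, min_lines=thr.min_lines,
                                           o2=thr.o2_hypoxia)
    except Exception as exc:
        raise StageError("dge", str(exc)) from exc
    if not seeds:
        raise StageError("dge", "no seed features were called induced")

    anchor = anchor_signature(config)
    try:
        anchor_scores = score_mean_expression(mrna, anchor)
        anchor_labels = classify_by_quantile(anchor_scores, "median").labels
        train_ids, test_ids = split_train_test(
            list(mrna.index), anchor_labels.loc[mrna.index],
            train_fraction=thr.train_fraction, seed=stage_seed(config.seed, "split"))
    except Exception as exc:
        raise StageError("split", str(exc)) from exc

    try:
        signature, report = derive_signature(
            seeds, mrna.loc[train_ids], mirna.loc[train_ids], anchor,
            n_trees=thr.boruta_n_trees, max_iter=thr.boruta_max_iter,
            alpha=thr.boruta_alpha, q_threshold=thr.q_threshold,
            include_tentative=thr.boruta_include_tentative,
            max_zero_fraction=thr.unexpressed_zero_fraction,
            seed=stage_seed(config.seed, "derive"))
    except Exception as exc:
        raise StageError("derive", str(exc)) from exc

    out = DerivationOutput(signature=signature, seeds=seeds, seed_summary=seed_summary,
                           dge_calls=calls, train_ids=train_ids, test_ids=test_ids,
                           truth=truth, mrna=mrna, mirna=mirna, survival=survival,
                           report=report)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        hio.write_ct_table(ct_table, outdir / "ct_table.csv")
        calls_out = calls.copy()
        hio.write_ct_table(calls_out, outdir / "dge_calls.tsv")
        (outdir / "seed_features.txt").write_text("\n".join(seeds) + "\n")
        hio.write_gmt(GeneSignature("seed_features", tuple(seeds),
                                    provenance="induced >=2 lines"),
                      outdir / "seed_features.gmt")
        hio.write_gmt(signature, outdir / "signature.gmt")
        hio.write_signature_json(signature, outdir / "signature.json")
        report.boruta_result.to_frame().to_csv(outdir / "boruta_decisions.tsv",
                                               sep="\t", index=False,
                                               float_format=hio.FLOAT_FORMAT)
        report.correlation_result.table.to_csv(outdir / "signature_correlations.tsv",
                                               sep="\t", index=False,
                                               float_format=hio.FLOAT_FORMAT)
        truth.to_json(outdir / "ground_truth.json")
        if write_plots:
            from .plots import boruta_decision_plot
            boruta_decision_plot(report.boruta_result, outdir / "boruta_plot.png")
        manifest = {
            "config": config.to_dict(),
            "stage_seeds": {s: stage_seed(config.seed, s)
                            for s in ("simulate", "dge", "split", "derive",
                                      "score", "validate", "trial")},
            "n_seeds": len(seeds),
            "seed_counts_by_min_lines": seed_summary.set_index("min_lines")
                                                    ["n_features"].to_dict(),
            "signature_size": len(signature),
            "signature_positive": list(signature.positive),
            "signature_negative": list(signature.negative),
            "n_train": len(train_ids),
            "n_test": len(test_ids),
        }
        hio.write_json(manifest, outdir / "manifest.json")
    return out


def _fit_row(fit: CoxFit, term: str, endpoint: str, analysis: str,
             extra: dict[str, Any] | None = None) -> dict[str, Any]:
    row = {
        "analysis": analysis, "endpoint": endpoint, "term": term,
        "HR": fit.hr.get(term, float("nan")),
        "CI_low": fit.ci_low.get(term, float("nan")),
        "CI_high": fit.ci_high.get(term, float("nan")),
        "p": fit.p.get(term, float("nan")),
        "test": fit.test.get(term, ""),
        "n": fit.n, "events": fit.n_events, "converged": fit.converged,
    }
    if extra:
        row.update(extra)
    return row


@dataclass
class ValidationOutput:
    cohort_fits: pd.DataFrame
    trial_fits: pd.DataFrame
    interaction_p: dict[str, float]
    marker_tests: pd.DataFrame
    cohort_scores: ScoreResult
    trial_scores: ScoreResult
    combined_labels: pd.Series | None = None
    trial_truth: GroundTruth | None = None


def run_validation(config: RunConfig, signature: GeneSignature,
                   derivation: DerivationOutput | None = None,
                   outdir: Path | None = None, write_plots: bool = True,
                   ) -> ValidationOutput:
    """Execute the validation arm.

    Prognostic analyses on the development cohort's held-out test set
    (signature score dichotomised by the configured cohort cut-off), then a
    fresh two-arm trial: within-stratum treatment benefit, treatment-by-
    hypoxia interaction, marker associations, and the combined
    (miRNA AND anchor mRNA) classification on the cohort.
    """
    thr = config.thresholds
    if derivation is None:
        derivation = run_derivation(config, outdir=None, write_plots=False)

    if not (set(signature.positive) | set(signature.negative)) & set(derivation.mirna.columns):
        missing = sorted(signature.features)
        raise StageError("score", f"signature has zero overlap with the cohort "
                                  f"matrix; features: {missing}")

    # --- cohort prognosis on the test split ---
    test_mirna = derivation.mirna.loc[derivation.test_ids]
    try:
        if signature.signed:
            sc = score_signed_signature(test_mirna, signature)
        else:
            sc = score_mean_expression(test_mirna, signature)
        cohort_scores = classify_by_quantile(sc, config.cohort_cutoff)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("score", str(exc)) from exc

    surv = censor_at(derivation.survival, thr.censor_months)
    rows = []
    km_data = {}
    for endpoint in config.endpoints:
        ep = surv[(surv["endpoint"] == endpoint)
                  & surv["sample_id"].isin(derivation.test_ids)].copy()
        ep["label"] = cohort_scores.labels.reindex(ep["sample_id"]).to_numpy()
        fit = cox_univariable(ep, "label")
        rows.append(_fit_row(fit, "label", endpoint, "cohort_prognosis",
                             {"cutoff": config.cohort_cutoff}))
        curves, p_lr = km_estimate(ep, "label")
        km_data[endpoint] = (curves, p_lr)
    cohort_fits = pd.DataFrame(rows)

    # --- combined classification on the cohort test split ---
    anchor = anchor_signature(config)
    anchor_sc = classify_by_quantile(
        score_mean_expression(derivation.mrna.loc[derivation.test_ids], anchor),
        config.cohort_cutoff)
    combined = combine_classifications(cohort_scores, anchor_sc)

    # --- trial: predictive analyses ---
    # same seed as the cohort: the trial is an independent patient draw
    # (separate stream) but shares the planted hypoxia-miRNA biology
    trial_sim = config.simulation.replace(seed=config.seed)
    try:
        trial_mirna, trial_surv, trial_truth = generate_trial(trial_sim)
    except Exception as exc:
        raise StageError("simulate", str(exc)) from exc
    try:
        if signature.signed:
            tsc = score_signed_signature(trial_mirna, signature)
        else:
            tsc = score_mean_expression(trial_mirna, signature)
        trial_scores = classify_by_quantile(tsc, config.trial_cutoff)
    except Exception as exc:
        raise StageError("score", str(exc)) from exc

    trial_surv = censor_at(trial_surv, thr.censor_months)
    trial_rows = []
    interaction_p: dict[str, float] = {}
    for endpoint in config.trial_endpoints:
        ep = trial_surv[trial_surv["endpoint"] == endpoint].copy()
        ep["label"] = trial_scores.labels.reindex(ep["sample_id"]).to_numpy()
        for stratum in (HYPOXIC, "normoxic"):
            fit = stratum_benefit(ep, stratum)
            trial_rows.append(_fit_row(fit, "arm", endpoint, f"benefit_{stratum}",
                                       {"cutoff": config.trial_cutoff}))
        ifit, p_lrt = interaction_test(ep)
        interaction_p[endpoint] = p_lrt
        trial_rows.append(_fit_row(ifit, "arm_x_hypoxia", endpoint, "interaction",
                                   {"p_lrt": p_lrt}))
    trial_fits = pd.DataFrame(trial_rows)

    # --- marker associations (one label per patient; markers are per-patient) ---
    marker_rows = []
    one_ep = trial_surv[trial_surv["endpoint"] == config.trial_endpoints[0]].copy()
    one_ep["label"] = trial_scores.labels.reindex(one_ep["sample_id"]).to_numpy()
    for marker in ("CAIX", "GLUT1", "HIF1A"):
        if marker in one_ep.columns:
            u, p = marker_association(one_ep[marker], one_ep["label"])
            marker_rows.append({"marker": marker, "U": u, "p": p})
    marker_tests = pd.DataFrame(marker_rows)

    out = ValidationOutput(cohort_fits=cohort_fits, trial_fits=trial_fits,
                           interaction_p=interaction_p, marker_tests=marker_tests,
                           cohort_scores=cohort_scores, trial_scores=trial_scores,
                           combined_labels=combined, trial_truth=trial_truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        hio.write_scores(cohort_scores, outdir / "cohort_test_scores.csv")
        hio.write_scores(trial_scores, outdir / "trial_scores.csv")
        cohort_fits.to_csv(outdir / "cohort_fits.tsv", sep="\t", index=False,
                           float_format=hio.FLOAT_FORMAT)
        trial_fits.to_csv(outdir / "trial_fits.tsv", sep="\t", index=False,
                          float_format=hio.FLOAT_FORMAT)
        marker_tests.to_csv(outdir / "marker_tests.tsv", sep="\t", index=False,
                            float_format=hio.FLOAT_FORMAT)
        combined.rename("label").rename_axis("sample_id").to_csv(
            outdir / "combined_labels.csv")
        for endpoint, (curves, p_lr) in km_data.items():
            for group, curve in curves.items():
                curve.to_csv(outdir / f"km_{endpoint}_{group}.csv", index=False,
                             float_format=hio.FLOAT_FORMAT)
            if write_plots:
                from .plots import km_plot
                km_plot(curves, outdir / f"km_{endpoint}.png",
                        title=f"{endpoint}, test cohort", p_value=p_lr)
    return out


def run_all(config: RunConfig, outdir: Path | None = None,
            write_plots: bool = True) -> tuple[DerivationOutput, ValidationOutput]:
    """Derivation followed by validation; writes a combined summary report."""
    outdir = Path(outdir if outdir is not None else config.outdir)
    derivation = run_derivation(config, outdir=outdir / "derivation",
                                write_plots=write_plots)
    validation = run_validation(config, derivation.signature, derivation,
                                outdir=outdir / "validation",
                                write_plots=write_plots)
    truth = derivation.truth
    planted = set(truth.signature_positive) | set(truth.signature_negative)
    recovered_pos = set(derivation.signature.positive) & set(truth.signature_positive)
    recovered_neg = set(derivation.signature.negative) & set(truth.signature_negative)
    summary = {
        "seed": config.seed,
        "n_seed_features": len(derivation.seeds),
        "signature_size": len(derivation.signature),
        "n_planted_signature": len(planted),
        "n_recovered_correct_sign": len(recovered_pos) + len(recovered_neg),
        "interaction_p": validation.interaction_p,
        "cohort_fits": validation.cohort_fits.to_dict(orient="records"),
        "trial_fits": validation.trial_fits.to_dict(orient="records"),
    }
    hio.write_json(summary, outdir / "summary.json")
    return derivation, validation
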