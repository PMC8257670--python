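"""Feature selection: Boruta shadow-feature algorithm and Spearman/FDR filter.

The Boruta implementation follows the published all-relevant procedure: each
iteration appends one independently shuffled shadow copy of every surviving
real feature, fits a random forest on the combined matrix, and scores a *hit*
for each undecided real feature whose impurity importance exceeds the maximum
shadow importance of that iteration.  Undecided features are then tested
against Binomial(iterations, 1/2) — two one-sided tests, Bonferroni-corrected
over all features entering the run — and moved to *confirmed* (hits
significantly above chance) or *rejected* (significantly below; removed from
the matrix).  At least five shadow features are always present.  Features
still undecided when the iteration budget runs out are *tentative*.
Confirmed/rejected decisions are final.

The Spearman filter correlates candidate features with a continuous anchor
hypoxia score, adjusts the two-sided p-values by Benjamini–Hochberg, and
selects features with q below threshold; the sign of rho assigns each
selected feature to the positive or negative side of the derived signature.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

from .scoring import (HYPOXIC, GeneSignature, ScoreResult, classify_by_quantile,
                      score_mean_expression)

logger = logging.getLogger(__name__)

CONFIRMED = "confirmed"
REJECTED = "rejected"
TENTATIVE = "tentative"

_MIN_SHADOWS = 5  # the published algorithm never tests against fewer shadows


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_train_test(sample_ids: Sequence[str], labels: Sequence[str] | pd.Series,
                     train_fraction: float = 0.7, seed: int = 0,
                     ) -> tuple[list[str], list[str]]:
    """Stratified train/test split balanced for the label proportions.

    The total training size is round(train_fraction * n) (half up) and is
    allocated across label strata by largest remainder, so each stratum's
    training share equals train_fraction as nearly as the integers allow.
    Returns disjoint, exhaustive (train_ids, test_ids).
    """
    ids = list(sample_ids)
    lab = pd.Series(list(labels), index=ids)
    if len(ids) != len(set(ids)):
        raise ValueError("sample ids must be unique")
    n_train_total = _round_half_up(train_fraction * len(ids))
    rng = np.random.default_rng(seed)

    strata = {k: sorted(v.index) for k, v in lab.groupby(lab)}
    base = {k: math.floor(train_fraction * len(v)) for k, v in strata.items()}
    remainders = sorted(
        ((train_fraction * len(v) - base[k], k) for k, v in strata.items()),
        key=lambda t: (-t[0], str(t[1])))
    short = n_train_total - sum(base.values())
    take = dict(base)
    for _, k in remainders[:short]:
        take[k] += 1

    train: list[str] = []
    test: list[str] = []
    for k in sorted(strata, key=str):
        members = list(strata[k])
        rng.shuffle(members)
        train.extend(members[:take[k]])
        test.extend(members[take[k]:])
    return sorted(train), sorted(test)


def filter_unexpressed(matrix: pd.DataFrame, features: Sequence[str] | None = None,
                       max_zero_fraction: float = 0.5,
                       ) -> tuple[list[str], list[str]]:
    """Drop features with log2 value 0 (raw zero) in >= max_zero_fraction of samples.

    Returns (kept, dropped) feature id lists.
    """
    feats = list(features) if features is not None else list(matrix.columns)
    missing = [f for f in feats if f not in matrix.columns]
    if missing:
        raise ValueError(f"features absent from matrix: {missing}")
    zero_frac = (matrix[feats] == 0).mean(axis=0)
    dropped = sorted(zero_frac[zero_frac >= max_zero_fraction].index)
    kept = [f for f in feats if f not in set(dropped)]
    if dropped:
        logger.info("filter_unexpressed dropped %d features: %s", len(dropped), dropped)
    return kept, dropped


@dataclass
class BorutaResult:
    decision: dict[str, str]
    hits: dict[str, int]
    decided_at: dict[str, int]
    importance_history: pd.DataFrame     # iterations x features (NaN once removed)
    shadow_history: pd.DataFrame         # iterations x (min, mean, max, sd)
    iterations_run: int
    params: dict[str, Any] = field(default_factory=dict)

    @property
    def confirmed(self) -> list[str]:
        return sorted(f for f, d in self.decision.items() if d == CONFIRMED)

    @property
    def rejected(self) -> list[str]:
        return sorted(f for f, d in self.decision.items() if d == REJECTED)

    @property
    def tentative(self) -> list[str]:
        return sorted(f for f, d in self.decision.items() if d == TENTATIVE)

    def hit_fraction(self, feature: str) -> float:
        n = self.decided_at.get(feature, self.iterations_run)
        return self.hits[feature] / n if n else float("nan")

    def z_scores(self) -> pd.DataFrame:
        """Per-iteration importances standardised against the shadow mean/sd
        (reporting aid for the decision plot; decisions never use these)."""
        mu = self.shadow_history["mean"].to_numpy()[:, None]
        sd = self.shadow_history["sd"].to_numpy()[:, None]
        sd = np.where(sd > 0, sd, np.nan)
        return (self.importance_history - mu) / sd

    def to_frame(self) -> pd.DataFrame:
        feats = sorted(self.decision)
        return pd.DataFrame({
            "feature_id": feats,
            "decision": [self.decision[f] for f in feats],
            "hits": [self.hits[f] for f in feats],
            "iterations": [self.decided_at.get(f, self.iterations_run) for f in feats],
            "hit_fraction": [self.hit_fraction(f) for f in feats],
        })


def boruta(X: pd.DataFrame, y: Sequence[int] | pd.Series, n_trees: int = 500,
           max_iter: int = 1000, alpha: float = 0.05, seed: int = 0,
           ) -> BorutaResult:
    """All-relevant feature selection against shuffled shadow features.

    ``X`` is samples x features; ``y`` a binary label.  Columns are processed
    in sorted order so the result is invariant to the column order of ``X``.
    """
    y = np.asarray(pd.Series(list(y), index=X.index) if not isinstance(y, pd.Series)
                   else y.reindex(X.index))
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("boruta requires at least two classes in y")
    if X.shape[1] < 1:
        raise ValueError("boruta requires at least one feature")

    features = sorted(map(str, X.columns))
    Xs = X[features].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    undecided = set(features)
    decision = {f: TENTATIVE for f in features}
    hits = {f: 0 for f in features}
    decided_at: dict[str, int] = {}
    imp_rows: list[dict[str, float]] = []
    shadow_rows: list[dict[str, float]] = []

    active = list(features)
    it = 0
    while it < max_iter and undecided:
        it += 1
        cols = [features.index(f) for f in active]
        Xa = Xs[:, cols]
        shadow = Xa.copy()
        # at least 5 shadows: with few survivors the max-shadow reference would
        # otherwise be too easy to beat, inflating late-stage false confirmations
        if shadow.shape[1] < _MIN_SHADOWS:
            extra = [Xa[:, j % Xa.shape[1]].copy()
                     for j in range(_MIN_SHADOWS - shadow.shape[1])]
            shadow = np.column_stack([shadow] + extra)
        for j in range(shadow.shape[1]):
            rng.shuffle(shadow[:, j])
        Xfull = np.hstack([Xa, shadow])
        rf = RandomForestClassifier(
            n_estimators=n_trees, random_state=int(rng.integers(2 ** 31)),
            class_weight="balanced", n_jobs=1)
        rf.fit(Xfull, y)
        imp = rf.feature_importances_
        real = imp[:len(active)]
        sh = imp[len(active):]
        shadow_max = float(sh.max())
        shadow_rows.append({"min": float(sh.min()), "mean": float(sh.mean()),
                            "max": shadow_max, "sd": float(sh.std(ddof=0))})
        imp_rows.append(dict(zip(active, real.tolist())))

        for f, v in zip(active, real):
            if f in undecided and v > shadow_max:
                hits[f] += 1

        # Bonferroni over ALL features entering the run (two one-sided tests).
        # Correcting only over the currently undecided set loosens the boundary
        # exactly when the shadow bar is weakest (few survivors), which lets
        # chance-correlated noise through; the published algorithm keeps the
        # correction constant.
        threshold = alpha / 2.0 / len(features)
        newly_rejected = []
        for f in sorted(undecided):
            k = hits[f]
            p_more = float(stats.binom.sf(k - 1, it, 0.5))
            p_less = float(stats.binom.cdf(k, it, 0.5))
            if p_more < threshold:
                decision[f] = CONFIRMED
                decided_at[f] = it
                undecided.discard(f)
            elif p_less < threshold:
                decision[f] = REJECTED
                decided_at[f] = it
                undecided.discard(f)
                newly_rejected.append(f)
        if newly_rejected:
            active = [f for f in active if f not in set(newly_rejected)]

    imp_hist = pd.DataFrame(imp_rows, columns=features)
    imp_hist.index = pd.RangeIndex(1, len(imp_rows) + 1, name="iteration")
    sh_hist = pd.DataFrame(shadow_rows, columns=["min", "mean", "max", "sd"])
    sh_hist.index = pd.RangeIndex(1, len(shadow_rows) + 1, name="iteration")
    return BorutaResult(
        decision=decision, hits=hits, decided_at=decided_at,
        importance_history=imp_hist, shadow_history=sh_hist, iterations_run=it,
        params={"n_trees": n_trees, "max_iter": max_iter, "alpha": alpha,
                "correction": "bonferroni", "seed": seed},
    )


def rank_gini(X: pd.DataFrame, y: Sequence[int] | pd.Series, n_trees: int = 500,
              seed: int = 0) -> pd.Series:
    """Features ranked by mean impurity-decrease (Gini) importance."""
    features = sorted(map(str, X.columns))
    rf = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                class_weight="balanced", n_jobs=1)
    rf.fit(X[features].to_numpy(dtype=float), np.asarray(y))
    imp = pd.Series(rf.feature_importances_, index=features, name="gini_importance")
    return imp.sort_values(ascending=False, kind="stable")


@dataclass
class CorrelationFilterResult:
    table: pd.DataFrame  # feature_id, rho, p_value, q_value, selected, sign
    q_threshold: float
    excluded_constant: list[str] = field(default_factory=list)

    @property
    def selected(self) -> list[str]:
        return sorted(self.table.loc[self.table["selected"], "feature_id"])

    @property
    def positive(self) -> list[str]:
        t = self.table
        return sorted(t.loc[t["selected"] & (t["sign"] == "+"), "feature_id"])

    @property
    def negative(self) -> list[str]:
        t = self.table
        return sorted(t.loc[t["selected"] & (t["sign"] == "-"), "feature_id"])


def spearman_filter(X: pd.DataFrame, scores: pd.Series, q_threshold: float = 0.05,
                    ) -> CorrelationFilterResult:
    """Spearman correlation of each feature with the anchor scores, BH-FDR.

    Average ranks for ties; two-sided p.  Constant features are excluded
    with a warning (rho undefined).
    """
    scores = scores.reindex(X.index)
    if scores.isna().any():
        raise ValueError("anchor scores missing for some samples in the matrix")
    rows = []
    excluded = []
    for feat in X.columns:
        x = X[feat].to_numpy(dtype=float)
        if np.all(x == x[0]):
            excluded.append(str(feat))
            logger.warning("spearman_filter: feature %s is constant; excluded", feat)
            continue
        rho, p = stats.spearmanr(x, scores.to_numpy(dtype=float))
        rows.append((str(feat), float(rho), float(p)))
    table = pd.DataFrame(rows, columns=["feature_id", "rho", "p_value"])
    if len(table):
        _, q, _, _ = multipletests(table["p_value"], method="fdr_bh")
        table["q_value"] = q
    else:
        table["q_value"] = pd.Series(dtype=float)
    table["selected"] = table["q_value"] < q_threshold
    table["sign"] = np.where(table["rho"] >= 0, "+", "-")
    return CorrelationFilterResult(table=table, q_threshold=q_threshold,
                                   excluded_constant=excluded)


@dataclass
class DerivationReport:
    anchor_scores: ScoreResult
    labels: pd.Series
    kept_seed_features: list[str]
    dropped_unexpressed: list[str]
    boruta_result: BorutaResult
    candidate_features: list[str]
    correlation_result: CorrelationFilterResult


def derive_signature(seed_features: Sequence[str], mrna_train: pd.DataFrame,
                     mirna_train: pd.DataFrame, anchor: GeneSignature,
                     n_trees: int = 500, max_iter: int = 1000, alpha: float = 0.05,
                     q_threshold: float = 0.05, include_tentative: bool = True,
                     max_zero_fraction: float = 0.5, seed: int = 0,
                     name: str = "mirna_hypoxia_derived",
                     ) -> tuple[GeneSignature, DerivationReport]:
    """Derive a signed miRNA signature from seed features on the training cohort.

    Steps: anchor mRNA score + median dichotomisation → drop unexpressed
    seeds → Boruta of seed miRNAs vs the hypoxia labels → Spearman/FDR filter
    of the surviving candidates (confirmed, plus tentative unless
    ``include_tentative`` is off) against the continuous anchor scores →
    signed signature by sign of rho, with every intermediate result attached.
    """
    anchor_scores = score_mean_expression(mrna_train, anchor)
    classified = classify_by_quantile(anchor_scores, "median")
    labels = (classified.labels == HYPOXIC).astype(int)

    seeds_present = [f for f in seed_features if f in mirna_train.columns]
    absent = sorted(set(seed_features) - set(seeds_present))
    if absent:
        logger.warning("%d seed features absent from miRNA matrix: %s", len(absent), absent)
    kept, dropped = filter_unexpressed(mirna_train, seeds_present, max_zero_fraction)
    if not kept:
        raise ValueError("no seed features remain after the unexpressed filter")

    bres = boruta(mirna_train[kept], labels, n_trees=n_trees, max_iter=max_iter,
                  alpha=alpha, seed=seed)
    candidates = bres.confirmed + (bres.tentative if include_tentative else [])
    candidates = sorted(candidates)
    if candidates:
        cres = spearman_filter(mirna_train[candidates], classified.scores, q_threshold)
        positive, negative = cres.positive, cres.negative
    else:
        cres = CorrelationFilterResult(
            table=pd.DataFrame(columns=["feature_id", "rho", "p_value", "q_value",
                                        "selected", "sign"]),
            q_threshold=q_threshold)
        positive, negative = [], []

    sig = GeneSignature(
        name=name, positive=tuple(positive), negative=tuple(negative),
        provenance="derived",
        feature_stats=cres.table[cres.table["selected"]].reset_index(drop=True)
        if len(cres.table) else cres.table,
        metadata={
            "anchor": anchor.name,
            "anchor_cutoff": classified.cutoff_value,
            "n_seed_features": len(seed_features),
            "n_after_unexpressed_filter": len(kept),
            "n_boruta_confirmed": len(bres.confirmed),
            "n_boruta_tentative": len(bres.tentative),
            "include_tentative": include_tentative,
            "boruta_iterations": bres.iterations_run,
        },
    )
    report = DerivationReport(
        anchor_scores=classified, labels=labels, kept_seed_features=kept,
        dropped_unexpressed=dropped, boruta_result=bres,
        candidate_features=candidates, correlation_result=cres,
    )
    return sig, report
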