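"""Signature scoring and quantile stratification.

Two scoring rules are supported.  An *unsigned* signature is summarised as
the mean log2 expression of its member features (the convention for anchor
mRNA hypoxia signatures).  A *signed* signature is scored as

    score = mean(positively associated features) − mean(negatively associated)

which makes the score invariant to per-sample additive shifts (any constant
added to all features of a sample cancels).  Samples are dichotomised at a
quantile cut-off (median, lower or upper quartile, or an externally supplied
threshold); ties at the cut-off are called normoxic (strict >), the
conservative choice for hypoxia calling.  Quantiles use linear interpolation
so cut-offs are reproducible across platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HYPOXIC = "hypoxic"
NORMOXIC = "normoxic"

_QUANTILES = {"median": 0.5, "lower_quartile": 0.25, "upper_quartile": 0.75}


@dataclass
class GeneSignature:
    """A named feature set, optionally signed.

    ``negative`` empty means an unsigned mean-expression signature.
    ``feature_stats`` carries per-feature derivation statistics (Spearman rho,
    FDR q) for derived signatures.
    """

    name: str
    positive: tuple[str, ...]
    negative: tuple[str, ...] = ()
    provenance: str = "derived"
    feature_stats: pd.DataFrame | None = None
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positive = tuple(self.positive)
        self.negative = tuple(self.negative)
        overlap = set(self.positive) & set(self.negative)
        if overlap:
            raise ValueError(f"features in both signs of signature: {sorted(overlap)}")

    @property
    def signed(self) -> bool:
        return len(self.negative) > 0

    @property
    def features(self) -> tuple[str, ...]:
        return self.positive + self.negative

    def __len__(self) -> int:
        return len(self.positive) + len(self.negative)

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "name": self.name,
            "positive": list(self.positive),
            "negative": list(self.negative),
            "provenance": self.provenance,
            "metadata": self.metadata,
        }
        if self.feature_stats is not None:
            d["feature_stats"] = self.feature_stats.to_dict(orient="list")
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "GeneSignature":
        stats = d.get("feature_stats")
        return cls(
            name=d["name"],
            positive=tuple(d.get("positive", ())),
            negative=tuple(d.get("negative", ())),
            provenance=d.get("provenance", "derived"),
            feature_stats=None if stats is None else pd.DataFrame(stats),
            metadata=dict(d.get("metadata", {})),
        )


@dataclass
class ScoreResult:
    """Per-sample continuous scores plus (optionally) a dichotomisation."""

    scores: pd.Series
    coverage: float
    cutoff_type: str | None = None
    cutoff_value: float | None = None
    labels: pd.Series | None = None
    signature_name: str | None = None

    @property
    def n_hypoxic(self) -> int:
        if self.labels is None:
            raise ValueError("scores have not been dichotomised")
        return int((self.labels == HYPOXIC).sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"sample_id": self.scores.index, "score": self.scores.to_numpy()})
        df["cutoff_type"] = self.cutoff_type
        df["cutoff_value"] = self.cutoff_value
        df["label"] = None if self.labels is None else self.labels.to_numpy()
        return df


def _intersect(matrix: pd.DataFrame, wanted: tuple[str, ...], sig_name: str,
               side: str) -> list[str]:
    present = [f for f in wanted if f in matrix.columns]
    if not present:
        raise ValueError(
            f"signature {sig_name!r} has zero {side} overlap with the matrix; "
            f"missing features: {sorted(wanted)}")
    missing = sorted(set(wanted) - set(present))
    if missing:
        logger.warning("signature %s: %d/%d %s features absent from matrix: %s",
                       sig_name, len(missing), len(wanted), side, missing)
    return present


def score_mean_expression(matrix: pd.DataFrame, signature: GeneSignature) -> ScoreResult:
    """Mean log2 expression over the signature features present in the matrix."""
    present = _intersect(matrix, signature.features, signature.name, "member")
    scores = matrix[present].mean(axis=1)
    scores.name = signature.name
    return ScoreResult(scores=scores, coverage=len(present) / len(signature.features),
                       signature_name=signature.name)


def score_signed_signature(matrix: pd.DataFrame, signature: GeneSignature) -> ScoreResult:
    """mean(positive features) − mean(negative features), intersection scoring."""
    if not signature.signed:
        raise ValueError(f"signature {signature.name!r} has no negative features; "
                         "use score_mean_expression")
    pos = _intersect(matrix, signature.positive, signature.name, "positive")
    neg = _intersect(matrix, signature.negative, signature.name, "negative")
    scores = matrix[pos].mean(axis=1) - matrix[neg].mean(axis=1)
    scores.name = signature.name
    coverage = (len(pos) + len(neg)) / len(signature.features)
    return ScoreResult(scores=scores, coverage=coverage, signature_name=signature.name)


def classify_by_quantile(result: ScoreResult | pd.Series, cutoff_type: str = "median",
                         reference_scores: pd.Series | None = None,
                         external_value: float | None = None) -> ScoreResult:
    """Dichotomise scores at a quantile cut-off; hypoxic iff score > cut-off.

    The cut-off is computed from ``reference_scores`` when supplied (so a
    threshold identified in one cohort can be carried to another), otherwise
    from the scores themselves.  ``cutoff_type='external'`` uses
    ``external_value`` directly.
    """
    if isinstance(result, pd.Series):
        result = ScoreResult(scores=result, coverage=1.0)
    scores = result.scores
    if cutoff_type == "external":
        if external_value is None:
            raise ValueError("external cutoff requested but no value supplied")
        cutoff = float(external_value)
    else:
        if cutoff_type not in _QUANTILES:
            raise ValueError(f"unknown cutoff_type {cutoff_type!r}")
        ref = scores if reference_scores is None else reference_scores
        if cutoff_type != "median" and len(ref) < 4:
            raise ValueError("quartile cut-offs need at least 4 reference samples")
        cutoff = float(np.quantile(ref.to_numpy(dtype=float), _QUANTILES[cutoff_type],
                                   method="linear"))
    labels = pd.Series(np.where(scores > cutoff, HYPOXIC, NORMOXIC),
                       index=scores.index, name="label")
    return ScoreResult(scores=scores, coverage=result.coverage, cutoff_type=cutoff_type,
                       cutoff_value=cutoff, labels=labels,
                       signature_name=result.signature_name)


def combine_classifications(a: ScoreResult, b: ScoreResult) -> pd.Series:
    """Hypoxic iff hypoxic under both classifications (conjunction)."""
    if a.labels is None or b.labels is None:
        raise ValueError("both inputs must be dichotomised before combining")
    if set(a.labels.index) != set(b.labels.index):
        raise ValueError("classifications cover different sample sets")
    bl = b.labels.reindex(a.labels.index)
    both = (a.labels == HYPOXIC) & (bl == HYPOXIC)
    return pd.Series(np.where(both, HYPOXIC, NORMOXIC), index=a.labels.index, name="label")


def published_mirna_signature() -> GeneSignature:
    """The published 14-miRNA bladder-cancer hypoxia signature.

    Seven miRNAs positively and seven negatively correlated (Spearman rho,
    BH-FDR attached) with anchor mRNA hypoxia scores in the TCGA BLCA
    training cohort.
    """
    rows = [
        ("miR-27a-3p", 0.53, 0.0),
        ("miR-193b-3p", 0.35, 1.82e-08),
        ("miR-455-5p", 0.33, 6.57e-08),
        ("miR-221-3p", 0.33, 7.39e-08),
        ("miR-210-3p", 0.30, 9.35e-08),
        ("miR-21-5p", 0.24, 1.00e-06),
        ("miR-224-5p", 0.24, 8.84e-05),
        ("miR-491-5p", -0.20, 1.21e-03),
        ("miR-93-5p", -0.20, 6.63e-04),
        ("miR-182-5p", -0.21, 4.50e-04),
        ("miR-30b-5p", -0.26, 1.43e-05),
        ("miR-190a-5p", -0.29, 1.56e-06),
        ("miR-28-5p", -0.29, 1.56e-06),
        ("miR-191-5p", -0.29, 1.56e-06),
    ]
    stats = pd.DataFrame(rows, columns=["feature_id", "rho", "fdr"])
    positive = tuple(r[0] for r in rows if r[1] > 0)
    negative = tuple(r[0] for r in rows if r[1] < 0)
    return GeneSignature(name="mirna_hypoxia_14", positive=positive, negative=negative,
                         provenance="published", feature_stats=stats)
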