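"""ΔΔCt differential expression for qPCR array-card data.

Implements the seed-miRNA discovery step: per cell line, target Ct values are
normalised to the geometric mean of endogenous controls (ΔCt), hypoxia vs
normoxia replicate means are differenced (ΔΔCt), fold change is 2^(−ΔΔCt),
and a Welch unequal-variance t test on the ΔCt replicates supplies the
p-value.  A feature is called induced when p < 0.05 and FC > 1.0 (strict, no
multiple-testing correction — intra-group variation at n=3 makes an FDR
cut-off too stringent for seed discovery).  Seeds are features induced at the
0.2% O2 condition in at least ``min_lines`` cell lines.

Undetermined Ct values are carried as NaN (pandas' missing marker), never as
a numeric sentinel.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import NORMOXIA_O2

logger = logging.getLogger(__name__)

CT_COLUMNS = ["cell_line", "o2_percent", "replicate", "feature_id", "feature_class", "ct"]


def _check_ct_table(table: pd.DataFrame) -> None:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns {missing}")
    key = table[["cell_line", "o2_percent", "replicate", "feature_id"]]
    if key.duplicated().any():
        raise ValueError("duplicate (cell_line, o2_percent, replicate, feature_id) records")


def exclude_low_expression(table: pd.DataFrame, threshold: float = 30.0,
                           normoxia: float = NORMOXIA_O2, hypoxia: float = 0.2,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop target features undetected in every replicate of both conditions.

    A target feature is removed, per cell line, iff its Ct is >= ``threshold``
    or undetermined (NaN) in *all* replicates of both the normoxia and the
    hypoxia condition being compared.  Control features are never removed.
    Returns the filtered table (conditions outside the comparison are kept
    for retained features) and a log of removed (cell_line, feature_id) pairs.
    """
    _check_ct_table(table)
    sub = table[table["o2_percent"].isin([normoxia, hypoxia])
                & (table["feature_class"] == "target")]
    n_reps = sub.groupby(["cell_line", "feature_id"])["ct"].size()
    expected = n_reps.groupby("cell_line").max()
    short = n_reps[n_reps < n_reps.index.get_level_values("cell_line").map(expected)]
    for (line, feat), k in short.items():
        logger.warning("feature %s in %s has only %d replicates across the comparison",
                       feat, line, k)
    undetected = sub.assign(low=lambda d: d["ct"].isna() | (d["ct"] >= threshold)) \
                    .groupby(["cell_line", "feature_id"])["low"].all()
    removed = undetected[undetected].reset_index()[["cell_line", "feature_id"]]
    if len(removed):
        flagged = table.merge(removed.assign(_removed=True),
                              on=["cell_line", "feature_id"], how="left")
        keep = ~(flagged["_removed"].notna() & (flagged["_removed"] == True)).to_numpy()  # noqa: E712
        out = table.loc[keep].reset_index(drop=True)
    else:
        out = table.copy()
    return out, removed


def _sample_control_matrix(table: pd.DataFrame, controls: list[str]) -> pd.DataFrame:
    """Pivot control Ct values to (sample x control) with validation."""
    ctrl = table[table["feature_id"].isin(controls)]
    mat = ctrl.pivot_table(index=["cell_line", "o2_percent", "replicate"],
                           columns="feature_id", values="ct")
    n_samples = len(table[["cell_line", "o2_percent", "replicate"]].drop_duplicates())
    if len(mat) < n_samples or mat.isna().any().any() or set(mat.columns) != set(controls):
        absent = [c for c in controls
                  if c not in mat.columns or mat.get(c, pd.Series(dtype=float)).isna().any()]
        raise ValueError(f"controls not measured in every sample: {absent or controls}")
    return mat[sorted(controls)]


def geometric_mean(values: np.ndarray, axis=None) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if np.any(values <= 0):
        raise ValueError("geometric mean undefined for non-positive Ct values")
    return np.exp(np.mean(np.log(values), axis=axis))


def select_controls(table: pd.DataFrame, candidates: list[str]) -> list[str]:
    """Pick the control subset whose per-sample geometric-mean Ct is most stable.

    Every non-empty subset of ``candidates`` is evaluated; the winner has the
    smallest standard deviation of the per-sample geometric mean across all
    samples of the experiment.  Ties go to the larger subset, then to
    lexicographically smallest feature ids.
    """
    _check_ct_table(table)
    present = set(table.loc[table["feature_class"] == "control", "feature_id"])
    bad = [c for c in candidates if c not in present]
    if bad:
        raise ValueError(f"candidate controls absent from the table: {bad}")
    mat = _sample_control_matrix(table, list(candidates))
    best: tuple | None = None
    for r in range(1, len(candidates) + 1):
        for subset in itertools.combinations(sorted(candidates), r):
            gm = geometric_mean(mat[list(subset)].to_numpy(), axis=1)
            sd = float(np.std(gm, ddof=1)) if len(gm) > 1 else 0.0
            key = (sd, -len(subset), subset)
            if best is None or key < best[0]:
                best = (key, subset)
    assert best is not None
    return list(best[1])


def normalize_delta_ct(table: pd.DataFrame, controls: list[str],
                       method: str = "geometric") -> pd.DataFrame:
    """ΔCt = target Ct − (mean of control Cts) per sample.

    ``method='geometric'`` (default) takes the geometric mean of the control
    Ct values themselves; ``method='arithmetic'`` takes their arithmetic mean,
    which equals geometric-mean normalisation of the linear-scale abundances
    2^−Ct and is exactly invariant to per-sample additive Ct shifts.
    Undetermined target Ct propagates as undetermined ΔCt.
    """
    _check_ct_table(table)
    if method not in ("geometric", "arithmetic"):
        raise ValueError(f"unknown normalisation method {method!r}")
    mat = _sample_control_matrix(table, list(controls))
    if method == "geometric":
        ref = pd.Series(geometric_mean(mat.to_numpy(), axis=1), index=mat.index)
    else:
        ref = mat.mean(axis=1)
    targets = table[table["feature_class"] == "target"].copy()
    idx = pd.MultiIndex.from_frame(targets[["cell_line", "o2_percent", "replicate"]])
    targets["delta_ct"] = targets["ct"].to_numpy() - ref.reindex(idx).to_numpy()
    return targets.reset_index(drop=True)


def delta_delta_ct(norm_reps, hyp_reps) -> tuple[float, float]:
    """ΔΔCt = mean(hypoxia ΔCt) − mean(normoxia ΔCt); FC = 2^(−ΔΔCt).

    Requires at least two valid (non-NaN) replicates per condition;
    otherwise returns (nan, nan) and the feature is flagged not-evaluable
    upstream.
    """
    norm = np.asarray(norm_reps, dtype=float)
    hyp = np.asarray(hyp_reps, dtype=float)
    norm = norm[~np.isnan(norm)]
    hyp = hyp[~np.isnan(hyp)]
    if len(norm) < 2 or len(hyp) < 2:
        return float("nan"), float("nan")
    ddct = float(np.mean(hyp) - np.mean(norm))
    return ddct, float(2.0 ** (-ddct))


def welch_test(norm_reps, hyp_reps) -> float:
    """Two-sided Welch unequal-variance t test on ΔCt replicates.

    Degenerate limits: both groups zero-variance with equal means -> p = 1;
    both zero-variance with unequal means -> p = 0 (logged).
    """
    a = np.asarray(norm_reps, dtype=float)
    b = np.asarray(hyp_reps, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        return float("nan")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0.0 and vb == 0.0:
        if np.mean(a) == np.mean(b):
            return 1.0
        logger.warning("zero-variance groups with unequal means; p set to 0 by limit convention")
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


@dataclass(frozen=True)
class DifferentialThresholds:
    p_value: float = 0.05
    fold_change: float = 1.0


def call_differential(results: pd.DataFrame,
                      p_threshold: float = 0.05,
                      fc_threshold: float = 1.0) -> pd.DataFrame:
    """Set the induced flag: p < p_threshold AND FC > fc_threshold (strict).

    No multiple-testing correction is applied, by design.
    """
    out = results.copy()
    out["induced"] = ((out["p_value"] < p_threshold)
                      & (out["fold_change"] > fc_threshold)
                      & out["p_value"].notna() & out["fold_change"].notna())
    return out


def run_dge(table: pd.DataFrame, controls: list[str] | None = None,
            normoxia: float = NORMOXIA_O2, hypoxia: float = 0.2,
            ct_threshold: float = 30.0, p_threshold: float = 0.05,
            fc_threshold: float = 1.0, method: str = "geometric",
            control_scope: str = "experiment") -> pd.DataFrame:
    """Full per-cell-line ΔΔCt analysis for one hypoxia-vs-normoxia comparison.

    Steps: low-expression exclusion → control selection (if ``controls`` is
    None, chosen by stability either once per ``experiment`` or per
    ``cell_line`` via ``control_scope``) → ΔCt normalisation → ΔΔCt + fold
    change → Welch p → induced call.  Returns one row per evaluable
    (feature_id, cell_line) with columns (feature_id, cell_line, o2_percent,
    ddct, fold_change, p_value, induced, evaluable).
    """
    _check_ct_table(table)
    sub = table[table["o2_percent"].isin([normoxia, hypoxia])].reset_index(drop=True)
    if sub["o2_percent"].nunique() < 2:
        raise ValueError(f"table lacks both conditions {normoxia}% and {hypoxia}% O2")
    filtered, _removed = exclude_low_expression(sub, ct_threshold, normoxia, hypoxia)

    all_controls = sorted(set(filtered.loc[filtered["feature_class"] == "control",
                                           "feature_id"]))
    rows = []
    for line, line_tab in filtered.groupby("cell_line"):
        line_tab = line_tab.reset_index(drop=True)
        if controls is not None:
            use = list(controls)
        elif control_scope == "cell_line":
            use = select_controls(line_tab, all_controls)
        else:
            use = select_controls(filtered, all_controls)
        dct = normalize_delta_ct(line_tab, use, method=method)
        piv = dct.pivot_table(index="feature_id", columns=["o2_percent", "replicate"],
                              values="delta_ct", dropna=False)
        norm_mat = piv[normoxia].to_numpy() if normoxia in piv.columns.get_level_values(0) else None
        hyp_mat = piv[hypoxia].to_numpy() if hypoxia in piv.columns.get_level_values(0) else None
        for i, feat in enumerate(piv.index):
            nr = norm_mat[i] if norm_mat is not None else np.array([])
            hr = hyp_mat[i] if hyp_mat is not None else np.array([])
            ddct, fc = delta_delta_ct(nr, hr)
            p = welch_test(nr, hr)
            rows.append((feat, line, hypoxia, ddct, fc, p, not np.isnan(ddct)))
    res = pd.DataFrame(rows, columns=["feature_id", "cell_line", "o2_percent",
                                      "ddct", "fold_change", "p_value", "evaluable"])
    return call_differential(res, p_threshold, fc_threshold)


def select_seeds(per_line_calls: pd.DataFrame, min_lines: int = 2,
                 o2: float = 0.2) -> tuple[list[str], pd.DataFrame]:
    """Seed features: induced at the given O2 condition in >= min_lines lines.

    Also reports, for min_lines' sake of comparison, the number of features
    induced in at least 2, 3 and 4 cell lines.
    """
    calls = per_line_calls[(per_line_calls["o2_percent"] == o2)
                           & per_line_calls["induced"]]
    counts = calls.groupby("feature_id")["cell_line"].nunique()
    seeds = sorted(counts[counts >= min_lines].index)
    summary = pd.DataFrame({
        "min_lines": [2, 3, 4],
        "n_features": [int((counts >= k).sum()) for k in (2, 3, 4)],
    })
    return seeds, summary
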