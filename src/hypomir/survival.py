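"""Cox / Kaplan–Meier machinery for prognosis and treatment-interaction tests.

Conventions, fixed for the whole package: follow-up is censored
administratively at a horizon (default 60 months); univariable comparisons of
two groups report the log-rank (score) p-value; multivariable models screen
candidate covariates at univariable p < 0.1 and report per-term Wald p;
treatment-by-hypoxia interactions are tested by the likelihood-ratio test of
the product term (Wald also reported), which behaves better than Wald at the
small event counts of a biomarker-defined stratum.  Tied event times use the
Efron approximation (lifelines' default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test, multivariate_logrank_test
from scipy import stats

logger = logging.getLogger(__name__)

TIME_COL = "time_months"
EVENT_COL = "event"


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model (or a flagged failure)."""

    terms: list[str]
    coef: dict[str, float] = field(default_factory=dict)
    hr: dict[str, float] = field(default_factory=dict)
    ci_low: dict[str, float] = field(default_factory=dict)
    ci_high: dict[str, float] = field(default_factory=dict)
    p: dict[str, float] = field(default_factory=dict)
    test: dict[str, str] = field(default_factory=dict)
    n: int = 0
    n_events: int = 0
    converged: bool = True
    log_likelihood: float = float("nan")
    diagnostics: str = ""

    @property
    def empty(self) -> bool:
        return not self.coef

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (t, self.hr.get(t, np.nan), self.ci_low.get(t, np.nan),
             self.ci_high.get(t, np.nan), self.p.get(t, np.nan),
             self.test.get(t, ""), self.n, self.n_events)
            for t in self.terms
        ]
        return pd.DataFrame(rows, columns=["term", "HR", "CI_low", "CI_high",
                                           "p", "test", "n", "events"])


def censor_at(table: pd.DataFrame, horizon: float = 60.0) -> pd.DataFrame:
    """Administrative censoring: times beyond the horizon become censored at it."""
    out = table.copy()
    late = out[TIME_COL] > horizon
    out.loc[late, TIME_COL] = horizon
    out.loc[late, EVENT_COL] = 0
    return out


def _validate(table: pd.DataFrame) -> None:
    for col in (TIME_COL, EVENT_COL):
        if col not in table.columns:
            raise ValueError(f"survival table lacks column {col!r}")
    if (table[TIME_COL] < 0).any():
        raise ValueError("negative follow-up times")
    if not table[EVENT_COL].isin([0, 1]).all():
        raise ValueError("event indicator must be 0/1")


def _encode_term(table: pd.DataFrame, term: str) -> tuple[pd.Series, str | None]:
    """Numeric-encode a model term; for 2-level categoricals return the
    reference level so the HR direction is reported explicitly."""
    col = table[term]
    if pd.api.types.is_numeric_dtype(col):
        return col.astype(float), None
    levels = sorted(col.dropna().unique())
    if len(levels) == 1:
        # constant categorical: encode as all-zero so the fit is flagged, not crashed
        return pd.Series(0.0, index=col.index), str(levels[0])
    if len(levels) != 2:
        raise ValueError(f"term {term!r} must be numeric or two-level, got {levels}")
    # hypoxia labels: hypoxic is always the 1-level so HR reads hypoxic vs normoxic
    if set(levels) == {"hypoxic", "normoxic"}:
        return (col == "hypoxic").astype(float), "normoxic"
    return (col == levels[1]).astype(float), str(levels[0])


def _failed_fit(terms: list[str], table: pd.DataFrame, reason: str) -> CoxFit:
    logger.warning("Cox fit failed: %s", reason)
    return CoxFit(terms=list(terms), n=len(table),
                  n_events=int(table[EVENT_COL].sum()) if EVENT_COL in table else 0,
                  converged=False, diagnostics=reason)


def _fit_cox(df: pd.DataFrame, terms: list[str]) -> CoxPHFitter:
    cph = CoxPHFitter()
    cph.fit(df[[TIME_COL, EVENT_COL] + terms], duration_col=TIME_COL,
            event_col=EVENT_COL)
    return cph


def cox_univariable(table: pd.DataFrame, term: str) -> CoxFit:
    """Single-term Cox PH fit (Efron ties).

    For two-group terms the reported p-value is the log-rank (score) test;
    for continuous terms it is the Wald test.
    """
    _validate(table)
    if table[EVENT_COL].sum() < 1:
        return _failed_fit([term], table, "no events")
    encoded, ref = _encode_term(table, term)
    df = table[[TIME_COL, EVENT_COL]].copy()
    df[term] = encoded.to_numpy()
    if df[term].nunique() < 2:
        return _failed_fit([term], table, f"term {term!r} is constant")
    binary = df[term].dropna().isin([0.0, 1.0]).all()
    try:
        cph = _fit_cox(df, [term])
    except Exception as exc:  # non-convergence / separation
        return _failed_fit([term], table, f"{type(exc).__name__}: {exc}")
    summ = cph.summary.loc[term]
    if binary:
        g1 = df[df[term] == 1.0]
        g0 = df[df[term] == 0.0]
        lr = logrank_test(g1[TIME_COL], g0[TIME_COL], event_observed_A=g1[EVENT_COL],
                          event_observed_B=g0[EVENT_COL])
        p, test = float(lr.p_value), "log-rank"
    else:
        p, test = float(summ["p"]), "Wald"
    fit = CoxFit(
        terms=[term],
        coef={term: float(summ["coef"])},
        hr={term: float(summ["exp(coef)"])},
        ci_low={term: float(summ["exp(coef) lower 95%"])},
        ci_high={term: float(summ["exp(coef) upper 95%"])},
        p={term: p},
        test={term: test},
        n=len(df), n_events=int(df[EVENT_COL].sum()),
        log_likelihood=float(cph.log_likelihood_),
    )
    if ref is not None:
        fit.diagnostics = f"reference level: {ref}"
    return fit


def cox_multivariable(table: pd.DataFrame, candidate_terms: Sequence[str],
                      entry_p: float = 0.1) -> tuple[CoxFit, pd.DataFrame]:
    """Screen candidates at univariable p < entry_p, then fit the joint model.

    Returns (fit, screening table).  With no candidate passing the screen the
    returned fit is an explicit empty-model marker (``fit.empty``) — the same
    behaviour as skipping a multivariable analysis when no clinical variable
    reaches p < 0.1 univariably.
    """
    _validate(table)
    screen_rows = []
    entered = []
    for term in candidate_terms:
        uni = cox_univariable(table, term)
        p = uni.p.get(term, float("nan"))
        passed = uni.converged and not np.isnan(p) and p < entry_p
        screen_rows.append((term, uni.hr.get(term, np.nan), p, passed))
        if passed:
            entered.append(term)
    screening = pd.DataFrame(screen_rows, columns=["term", "HR", "p_univariable",
                                                   "entered"])
    if not entered:
        fit = CoxFit(terms=[], n=len(table), n_events=int(table[EVENT_COL].sum()),
                     diagnostics=f"no candidate reached univariable p < {entry_p}")
        return fit, screening
    df = table[[TIME_COL, EVENT_COL]].copy()
    for term in entered:
        df[term], _ = _encode_term(table, term)
    try:
        cph = _fit_cox(df, entered)
    except Exception as exc:
        return _failed_fit(entered, table, f"{type(exc).__name__}: {exc}"), screening
    summ = cph.summary
    fit = CoxFit(
        terms=entered,
        coef={t: float(summ.loc[t, "coef"]) for t in entered},
        hr={t: float(summ.loc[t, "exp(coef)"]) for t in entered},
        ci_low={t: float(summ.loc[t, "exp(coef) lower 95%"]) for t in entered},
        ci_high={t: float(summ.loc[t, "exp(coef) upper 95%"]) for t in entered},
        p={t: float(summ.loc[t, "p"]) for t in entered},
        test={t: "Wald" for t in entered},
        n=len(df), n_events=int(df[EVENT_COL].sum()),
        log_likelihood=float(cph.log_likelihood_),
    )
    return fit, screening


def km_estimate(table: pd.DataFrame, group_col: str,
                ) -> tuple[dict[str, pd.DataFrame], float | None]:
    """Product-limit estimates per group plus a log-rank p-value.

    Each group's step function is returned as a frame with columns
    (time, survival, at_risk).  The p-value is the two-group log-rank test
    (multivariate log-rank for >2 groups); None for a single group.
    """
    _validate(table)
    curves: dict[str, pd.DataFrame] = {}
    for g, sub in table.groupby(group_col):
        kmf = KaplanMeierFitter()
        kmf.fit(sub[TIME_COL], event_observed=sub[EVENT_COL])
        ev = kmf.event_table
        curves[str(g)] = pd.DataFrame({
            "time": ev.index.to_numpy(dtype=float),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            "at_risk": ev["at_risk"].to_numpy(),
        })
    groups = list(curves)
    if len(groups) < 2:
        return curves, None
    if len(groups) == 2:
        g1 = table[table[group_col] == sorted(table[group_col].unique())[0]]
        g2 = table[table[group_col] == sorted(table[group_col].unique())[1]]
        res = logrank_test(g1[TIME_COL], g2[TIME_COL], event_observed_A=g1[EVENT_COL],
                           event_observed_B=g2[EVENT_COL])
    else:
        res = multivariate_logrank_test(table[TIME_COL], table[group_col],
                                        table[EVENT_COL])
    return curves, float(res.p_value)


def stratum_benefit(table: pd.DataFrame, stratum_label: str,
                    label_col: str = "label", arm_col: str = "arm") -> CoxFit:
    """Univariable Cox of treatment arm within one biomarker stratum.

    HR < 1 means the experimental arm (lexicographically later level, e.g.
    RT+CON vs RT) lowers the hazard for patients in that stratum.
    """
    _validate(table)
    sub = table[table[label_col] == stratum_label]
    if len(sub) == 0:
        return _failed_fit([arm_col], sub, f"empty stratum {stratum_label!r}")
    if sub[EVENT_COL].sum() == 0:
        return _failed_fit([arm_col], sub, f"stratum {stratum_label!r} has zero events")
    return cox_univariable(sub, arm_col)


def interaction_test(table: pd.DataFrame, label_col: str = "label",
                     arm_col: str = "arm") -> tuple[CoxFit, float]:
    """Cox model arm + hypoxia + arm x hypoxia; interaction p by LRT.

    Returns the full-model fit (Wald p per term, including the interaction)
    and the likelihood-ratio p-value of the interaction term.  Degenerate
    designs (constant label or arm, inestimable product) yield a flagged fit
    and p = nan.
    """
    _validate(table)
    arm, _ = _encode_term(table, arm_col)
    hyp, _ = _encode_term(table, label_col)
    df = table[[TIME_COL, EVENT_COL]].copy()
    df["arm"] = arm.to_numpy()
    df["hypoxia"] = hyp.to_numpy()
    df["arm_x_hypoxia"] = df["arm"] * df["hypoxia"]
    for col in ("arm", "hypoxia", "arm_x_hypoxia"):
        if df[col].nunique() < 2:
            return (_failed_fit(["arm", "hypoxia", "arm_x_hypoxia"], table,
                                f"term {col!r} is constant; interaction inestimable"),
                    float("nan"))
    try:
        full = _fit_cox(df, ["arm", "hypoxia", "arm_x_hypoxia"])
        reduced = _fit_cox(df, ["arm", "hypoxia"])
    except Exception as exc:
        return (_failed_fit(["arm", "hypoxia", "arm_x_hypoxia"], table,
                            f"{type(exc).__name__}: {exc}"), float("nan"))
    lrt = 2.0 * (full.log_likelihood_ - reduced.log_likelihood_)
    p_lrt = float(stats.chi2.sf(max(lrt, 0.0), df=1))
    summ = full.summary
    terms = ["arm", "hypoxia", "arm_x_hypoxia"]
    fit = CoxFit(
        terms=terms,
        coef={t: float(summ.loc[t, "coef"]) for t in terms},
        hr={t: float(summ.loc[t, "exp(coef)"]) for t in terms},
        ci_low={t: float(summ.loc[t, "exp(coef) lower 95%"]) for t in terms},
        ci_high={t: float(summ.loc[t, "exp(coef) upper 95%"]) for t in terms},
        p={t: float(summ.loc[t, "p"]) for t in terms},
        test={t: "Wald" for t in terms},
        n=len(df), n_events=int(df[EVENT_COL].sum()),
        log_likelihood=float(full.log_likelihood_),
    )
    fit.test["arm_x_hypoxia (LRT)"] = "LRT"
    return fit, p_lrt


def marker_association(values: Sequence[float] | pd.Series,
                       labels: Sequence[Any] | pd.Series,
                       exact_max_n: int = 10) -> tuple[float, float]:
    """Mann–Whitney U comparison of a continuous marker between two groups.

    Uses exact enumeration when both groups have <= ``exact_max_n``
    observations and there are no ties; otherwise the tie-corrected normal
    approximation with continuity correction.  Returns (U of the first
    group, two-sided p).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = sorted(pd.unique(labels).tolist())
    if len(groups) != 2:
        raise ValueError(f"marker_association needs exactly two groups, got {groups}")
    x = values[labels == groups[0]]
    y = values[labels == groups[1]]
    small = len(x) <= exact_max_n and len(y) <= exact_max_n
    has_ties = len(np.unique(values)) < len(values)
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
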