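"""Survival machinery: censoring, Cox fits, Kaplan-Meier against hand
arithmetic, degenerate designs, and the Mann-Whitney marker test against a
brute-force enumeration oracle."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hypomir import SimulationConfig
from hypomir.simulate import generate_cohort, generate_trial
from hypomir.survival import (censor_at, cox_multivariable, cox_univariable,
                              interaction_test, km_estimate, marker_association,
                              stratum_benefit)


def surv_df(times, events, **cols):
    df = pd.DataFrame({"time_months": times, "event": events})
    for k, v in cols.items():
        df[k] = v
    return df


class TestCensorAt:
    def test_late_event_becomes_censored(self):
        out = censor_at(surv_df([72.0], [1]), 60.0)
        assert out["time_months"].iloc[0] == 60.0
        assert out["event"].iloc[0] == 0

    def test_boundary_time_unchanged(self):
        out = censor_at(surv_df([60.0, 59.9], [1, 1]), 60.0)
        assert out["event"].tolist() == [1, 1]
        assert out["time_months"].tolist() == [60.0, 59.9]

    def test_event_count_never_increases(self, rng):
        times = rng.exponential(40, 200)
        events = rng.integers(0, 2, 200)
        out = censor_at(surv_df(times, events), 60.0)
        assert out["event"].sum() <= events.sum()
        assert (out["time_months"] <= 60.0).all()


class TestKaplanMeier:
    def test_no_events_survival_stays_one(self):
        df = surv_df([5.0, 10.0, 15.0], [0, 0, 0], group="g")
        curves, p = km_estimate(df, "group")
        assert p is None
        assert (curves["g"]["survival"] >= 1.0 - 1e-12).all()

    def test_single_event_closed_form(self):
        df = surv_df([3.0, 8.0, 12.0, 20.0], [0, 1, 0, 0], group="g")
        curves, _ = km_estimate(df, "group")
        c = curves["g"].set_index("time")
        assert c.loc[8.0, "survival"] == pytest.approx(2.0 / 3.0)  # 3 at risk at t=8

    def test_five_patient_hand_example(self):
        # events at t=2 (5 at risk) and t=6 (3 at risk); censored at 4, 8;
        # product-limit: S(2)=4/5, S(6)=4/5 * 2/3 = 8/15
        df = surv_df([2.0, 4.0, 6.0, 8.0, 9.0], [1, 0, 1, 0, 1], group="g")
        curves, _ = km_estimate(df, "group")
        c = curves["g"].set_index("time")
        assert c.loc[2.0, "survival"] == pytest.approx(4.0 / 5.0)
        assert c.loc[6.0, "survival"] == pytest.approx(8.0 / 15.0)

    def test_logrank_p_matches_univariable_cox_group_p(self, rng):
        n = 120
        group = np.where(rng.random(n) < 0.5, "hi", "lo")
        rate = np.where(group == "hi", 0.04, 0.02)
        df = surv_df(rng.exponential(1 / rate), np.ones(n, dtype=int), group=group)
        df = censor_at(df, 60.0)
        _, p_km = km_estimate(df, "group")
        fit = cox_univariable(df, "group")
        assert p_km == pytest.approx(fit.p["group"], abs=1e-9)


class TestCoxFits:
    def _two_group(self, seed, hr=2.0, n=400, dropout=False):
        cfg = SimulationConfig(seed=seed, log_hr_hypoxia=np.log(hr),
                               dropout_rate=0.005 if dropout else 0.0)
        _, _, surv, truth = generate_cohort(cfg)
        ep = surv[surv["endpoint"] == "OS"].copy()
        ep["hypoxic"] = truth.latent_hypoxia.reindex(ep["sample_id"]).to_numpy()
        return ep

    def test_recovers_planted_hazard_ratio(self):
        hrs = [cox_univariable(self._two_group(s), "hypoxic").hr["hypoxic"]
               for s in range(12)]
        assert 1.7 < float(np.mean(hrs)) < 2.3

    def test_time_rescaling_leaves_hr_unchanged(self):
        ep = self._two_group(3)
        fit_m = cox_univariable(ep, "hypoxic")
        days = ep.copy()
        days["time_months"] = days["time_months"] * 30.44
        fit_d = cox_univariable(days, "hypoxic")
        assert fit_m.hr["hypoxic"] == pytest.approx(fit_d.hr["hypoxic"], rel=1e-6)

    def test_no_events_flagged(self):
        df = surv_df([5.0, 6.0], [0, 0], hypoxic=[0, 1])
        fit = cox_univariable(df, "hypoxic")
        assert not fit.converged and fit.empty

    def test_constant_term_flagged(self):
        df = surv_df([5.0, 6.0, 7.0], [1, 1, 0], hypoxic=[1, 1, 1])
        fit = cox_univariable(df, "hypoxic")
        assert not fit.converged

    def test_multivariable_screen_and_fit(self):
        ep = self._two_group(4)
        rng = np.random.default_rng(0)
        ep["pure_noise"] = rng.normal(0, 1, len(ep))
        fit, screening = cox_multivariable(ep, ["hypoxic", "pure_noise"])
        entered = screening.set_index("term")["entered"]
        assert bool(entered["hypoxic"])
        assert "hypoxic" in fit.terms
        assert 1.4 < fit.hr["hypoxic"] < 2.8

    def test_multivariable_empty_model_marker(self, rng):
        df = surv_df(rng.exponential(30, 120), np.ones(120, dtype=int),
                     noise1=rng.normal(0, 1, 120), noise2=rng.normal(0, 1, 120))
        fit, screening = cox_multivariable(df, ["noise1", "noise2"], entry_p=1e-6)
        assert fit.empty
        assert not screening["entered"].any()

    def test_entry_p_one_admits_all(self, rng):
        df = surv_df(rng.exponential(30, 150), np.ones(150, dtype=int),
                     a=rng.normal(0, 1, 150), b=rng.normal(0, 1, 150))
        fit, _ = cox_multivariable(df, ["a", "b"], entry_p=1.0)
        assert fit.terms == ["a", "b"]


class TestTrialAnalyses:
    def _trial(self, seed, b_hyp=np.log(0.45), b_norm=0.0, n_per_arm=95):
        cfg = SimulationConfig(seed=seed, log_hr_treatment_hypoxic=b_hyp,
                               log_hr_treatment_normoxic=b_norm,
                               trial_n_per_arm=n_per_arm, dropout_rate=0.0)
        _, surv, truth = generate_trial(cfg)
        ep = surv[surv["endpoint"] == "OS"].copy()
        h = truth.latent_hypoxia.reindex(ep["sample_id"]).to_numpy()
        ep["label"] = np.where(h == 1, "hypoxic", "normoxic")
        return ep

    def test_arms_exactly_balanced(self):
        ep = self._trial(0)
        counts = ep["arm"].value_counts()
        assert counts["RT"] == counts["RT+CON"] == 95

    def test_benefit_confined_to_hypoxic_stratum(self):
        hyp_hrs, norm_hrs = [], []
        for seed in range(10):
            ep = self._trial(seed, n_per_arm=200)
            hyp_hrs.append(stratum_benefit(ep, "hypoxic").hr["arm"])
            norm_hrs.append(stratum_benefit(ep, "normoxic").hr["arm"])
        assert float(np.mean(hyp_hrs)) < 0.75
        assert 0.8 < float(np.mean(norm_hrs)) < 1.25

    def test_zero_event_stratum_flagged(self):
        df = surv_df([5.0, 6.0, 7.0, 8.0], [0, 0, 1, 1],
                     label=["hypoxic", "hypoxic", "normoxic", "normoxic"],
                     arm=["RT", "RT+CON", "RT", "RT+CON"])
        fit = stratum_benefit(df, "hypoxic")
        assert not fit.converged and "zero events" in fit.diagnostics

    def test_constant_hypoxia_label_inestimable(self):
        df = surv_df([5.0, 6.0, 7.0, 8.0], [1, 1, 1, 0],
                     label=["hypoxic"] * 4, arm=["RT", "RT+CON", "RT", "RT+CON"])
        fit, p = interaction_test(df)
        assert not fit.converged and np.isnan(p)

    def test_interaction_detected_when_planted_strongly(self):
        detected = 0
        for seed in range(5):
            ep = self._trial(seed, b_hyp=np.log(0.2), n_per_arm=300)
            _, p = interaction_test(ep)
            detected += p < 0.05
        assert detected >= 4


class TestMarkerAssociation:
    def test_separated_groups_exact_p(self):
        u, p = marker_association([1, 2, 3, 4, 5, 6],
                                  ["a", "a", "a", "b", "b", "b"])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_group_swap_symmetry(self, rng):
        values = rng.normal(0, 1, 14)
        labels = np.array(["x"] * 7 + ["y"] * 7)
        u1, p1 = marker_association(values, labels)
        u2, p2 = marker_association(values, np.where(labels == "x", "y", "x"))
        assert p1 == pytest.approx(p2)
        assert u1 + u2 == pytest.approx(49.0)

    def test_matches_enumeration_oracle(self, rng):
        values = rng.normal(0, 1, 10)
        labels = np.array(["a"] * 5 + ["b"] * 5)
        _, p = marker_association(values, labels)
        # brute force: U for every C(10,5) assignment of the observed values
        def u_stat(x, y):
            return sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
        observed = u_stat(values[:5], values[5:])
        us = []
        for combo in itertools.combinations(range(10), 5):
            x = values[list(combo)]
            y = values[[i for i in range(10) if i not in combo]]
            us.append(u_stat(x, y))
        us = np.array(us)
        mean_u = 12.5
        p_oracle = np.mean(np.abs(us - mean_u) >= abs(observed - mean_u) - 1e-12)
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_three_groups_rejected(self):
        with pytest.raises(ValueError):
            marker_association([1, 2, 3], ["a", "b", "c"])
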