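"""ΔΔCt pipeline: exclusion rule, control selection, normalisation, Welch
test, induced calls and seed selection, each against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from hypomir.qpcr import (call_differential, delta_delta_ct, exclude_low_expression,
                          geometric_mean, normalize_delta_ct, run_dge,
                          select_controls, select_seeds, welch_test)


def welch_oracle(x, y):
    """Textbook Welch formula, independent of scipy.ttest_ind."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    n1, n2 = len(x), len(y)
    se2 = v1 / n1 + v2 / n2
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return 2.0 * stats.t.sf(abs(t), df)


class TestExcludeLowExpression:
    def _table(self, make_ct_table, norm_cts, hyp_cts):
        rows = [("CL1", 21.0, r, "CTRL-01", "control", 16.0) for r in (1, 2, 3)]
        rows += [("CL1", 0.2, r, "CTRL-01", "control", 16.0) for r in (1, 2, 3)]
        rows += [("CL1", 21.0, r, "miR-X", "target", c)
                 for r, c in zip((1, 2, 3), norm_cts)]
        rows += [("CL1", 0.2, r, "miR-X", "target", c)
                 for r, c in zip((1, 2, 3), hyp_cts)]
        return make_ct_table(rows)

    def test_undetected_everywhere_is_removed(self, make_ct_table):
        table = self._table(make_ct_table, [31, 32, 33], [30, 31, 35])
        out, removed = exclude_low_expression(table)
        assert list(removed.itertuples(index=False)) == [("CL1", "miR-X")]
        assert "miR-X" not in out["feature_id"].values
        # controls survive even though their Ct is below the radar of the rule
        assert (out["feature_class"] == "control").sum() == 6

    def test_single_detected_replicate_retains_feature(self, make_ct_table):
        table = self._table(make_ct_table, [31, 31, 31], [29, 31, 31])
        out, removed = exclude_low_expression(table)
        assert removed.empty
        assert (out["feature_id"] == "miR-X").sum() == 6

    def test_undetermined_counts_as_undetected(self, make_ct_table):
        table = self._table(make_ct_table, [np.nan, 32, 33], [np.nan, np.nan, 31])
        out, removed = exclude_low_expression(table)
        assert len(removed) == 1

    def test_empty_table_passes_through(self, make_ct_table):
        table = make_ct_table([])
        out, removed = exclude_low_expression(table)
        assert out.empty and removed.empty


class TestSelectControls:
    def _experiment(self, make_ct_table, control_values):
        """control_values: {feature: per-sample ct list} over 4 samples."""
        rows = []
        for s, (o2, rep) in enumerate([(21.0, 1), (21.0, 2), (0.2, 1), (0.2, 2)]):
            for feat, values in control_values.items():
                rows.append(("CL1", o2, rep, feat, "control", values[s]))
            rows.append(("CL1", o2, rep, "miR-A", "target", 25.0))
        return make_ct_table(rows)

    def test_constant_control_beats_noisy_ones(self, make_ct_table):
        table = self._experiment(make_ct_table, {
            "C1": [16, 16, 16, 16], "C2": [15, 17, 14, 18], "C3": [15, 18, 13, 16]})
        assert select_controls(table, ["C1", "C2", "C3"]) == ["C1"]

    def test_tie_broken_by_larger_subset(self, make_ct_table):
        table = self._experiment(make_ct_table, {
            "C1": [16, 16, 16, 16], "C2": [15, 15, 15, 15]})
        assert select_controls(table, ["C1", "C2"]) == ["C1", "C2"]

    def test_matches_exhaustive_oracle(self, make_ct_table, rng):
        values = {f"C{i}": (16 + rng.normal(0, 0.6, 4)).tolist() for i in range(1, 4)}
        table = self._experiment(make_ct_table, values)
        # independent brute force over all 7 subsets
        best = None
        for r in range(1, 4):
            for subset in itertools.combinations(sorted(values), r):
                mat = np.array([values[c] for c in subset])
                gm = np.exp(np.log(mat).mean(axis=0))
                key = (gm.std(ddof=1), -len(subset), subset)
                if best is None or key < best:
                    best = key
        assert tuple(select_controls(table, sorted(values))) == best[2]

    def test_missing_control_raises(self, make_ct_table):
        table = self._experiment(make_ct_table, {"C1": [16, 16, 16, 16]})
        with pytest.raises(ValueError, match="absent"):
            select_controls(table, ["C1", "C9"])


class TestNormalizeDeltaCt:
    def test_equal_controls_subtract_exactly(self, single_line_table):
        dct = normalize_delta_ct(single_line_table, ["CTRL-01"])
        a = dct[(dct.feature_id == "miR-A") & (dct.o2_percent == 21.0)]
        assert np.allclose(a["delta_ct"], 9.0)

    def test_geometric_mean_worked_example(self, make_ct_table):
        rows = [("CL1", 21.0, 1, c, "control", ct)
                for c, ct in zip(["C1", "C2", "C3"], [15.0, 16.0, 17.0])]
        rows.append(("CL1", 21.0, 1, "miR-A", "target", 25.0))
        dct = normalize_delta_ct(make_ct_table(rows), ["C1", "C2", "C3"])
        expected = 25.0 - (15.0 * 16.0 * 17.0) ** (1.0 / 3.0)
        assert abs(dct["delta_ct"].iloc[0] - expected) < 1e-12
        assert abs(dct["delta_ct"].iloc[0] - 9.0209) < 1e-4

    def test_arithmetic_mode_is_shift_invariant(self, make_ct_table, rng):
        rows = []
        for rep in (1, 2):
            for c in ("C1", "C2"):
                rows.append(("CL1", 21.0, rep, c, "control", 15 + rng.random() * 2))
            rows.append(("CL1", 21.0, rep, "miR-A", "target", 24 + rng.random()))
        table = make_ct_table(rows)
        shifted = table.copy()
        mask = shifted["replicate"] == 1
        shifted.loc[mask, "ct"] += 2.0
        a = normalize_delta_ct(table, ["C1", "C2"], method="arithmetic")
        b = normalize_delta_ct(shifted, ["C1", "C2"], method="arithmetic")
        assert np.allclose(a["delta_ct"], b["delta_ct"], atol=1e-12)

    def test_undetermined_target_propagates(self, make_ct_table):
        rows = [("CL1", 21.0, 1, "C1", "control", 16.0),
                ("CL1", 21.0, 1, "miR-A", "target", np.nan)]
        dct = normalize_delta_ct(make_ct_table(rows), ["C1"])
        assert np.isnan(dct["delta_ct"].iloc[0])

    def test_nonpositive_ct_rejected(self, make_ct_table):
        rows = [("CL1", 21.0, 1, "C1", "control", -1.0),
                ("CL1", 21.0, 1, "miR-A", "target", 25.0)]
        with pytest.raises(ValueError, match="non-positive"):
            normalize_delta_ct(make_ct_table(rows), ["C1"])


class TestDeltaDeltaCtAndWelch:
    @pytest.mark.parametrize("norm, hyp, ddct, fc", [
        ([9, 9, 9], [9, 9, 9], 0.0, 1.0),
        ([9, 9, 9], [8, 8, 8], -1.0, 2.0),
        ([9.1, 8.9, 9.0], [7.6, 7.4, 7.5], -1.5, 2.0 ** 1.5),
    ])
    def test_worked_examples(self, norm, hyp, ddct, fc):
        d, f = delta_delta_ct(norm, hyp)
        assert abs(d - ddct) < 1e-12
        assert abs(f - fc) < 1e-12

    def test_fold_change_consistency(self):
        d, f = delta_delta_ct([9.3, 8.2, 9.9], [7.1, 8.4, 6.9])
        assert abs(f - 2.0 ** (-d)) < 1e-12

    def test_too_few_replicates_not_evaluable(self):
        d, f = delta_delta_ct([9.0], [8.0, 8.1, 7.9])
        assert np.isnan(d) and np.isnan(f)
        assert np.isnan(welch_test([9.0], [8.0, 8.1]))

    def test_welch_identical_groups(self):
        assert abs(welch_test([1, 2, 3], [1, 2, 3]) - 1.0) < 1e-9

    def test_welch_degenerate_conventions(self):
        assert welch_test([5, 5, 5], [5, 5, 5]) == 1.0
        assert welch_test([5, 5, 5], [6, 6, 6]) == 0.0

    def test_welch_matches_formula_oracle(self, rng):
        for _ in range(300):
            x = rng.normal(0, 1, rng.integers(2, 8))
            y = rng.normal(rng.normal(), rng.uniform(0.5, 2), rng.integers(2, 8))
            assert abs(welch_test(x, y) - welch_oracle(x, y)) < 1e-10

    def test_swapping_conditions_flips_sign_not_p(self, rng):
        x = rng.normal(9, 0.3, 3)
        y = rng.normal(8, 0.3, 3)
        d1, f1 = delta_delta_ct(x, y)
        d2, f2 = delta_delta_ct(y, x)
        assert abs(d1 + d2) < 1e-12
        assert abs(f1 * f2 - 1.0) < 1e-12
        assert abs(welch_test(x, y) - welch_test(y, x)) < 1e-12


class TestCallsAndSeeds:
    def test_induced_thresholds_are_strict(self):
        df = pd.DataFrame({
            "feature_id": list("abcd"), "cell_line": "CL1", "o2_percent": 0.2,
            "ddct": 0.0,
            "fold_change": [1.01, 2.0, 0.9, 2.0],
            "p_value": [0.049, 0.05, 0.01, 0.049],
        })
        out = call_differential(df)
        assert out["induced"].tolist() == [True, False, False, True]

    def test_seed_monotone_in_min_lines(self):
        rows = []
        for feat, lines in [("a", 4), ("b", 2), ("c", 1)]:
            for i in range(lines):
                rows.append((feat, f"CL{i + 1}", 0.2, -1.0, 2.0, 0.01, True))
        calls = pd.DataFrame(rows, columns=["feature_id", "cell_line", "o2_percent",
                                            "ddct", "fold_change", "p_value", "induced"])
        previous = None
        for k in (1, 2, 3, 4):
            seeds, _ = select_seeds(calls, min_lines=k)
            if previous is not None:
                assert set(seeds) <= set(previous)
            previous = seeds
        seeds2, summary = select_seeds(calls, min_lines=2)
        assert seeds2 == ["a", "b"]
        assert summary.set_index("min_lines")["n_features"].tolist() == [2, 1, 1]

    def test_noiseless_unit_shift_gives_fc_2(self, single_line_table):
        calls = run_dge(single_line_table, controls=["CTRL-01"])
        a = calls[calls.feature_id == "miR-A"].iloc[0]
        b = calls[calls.feature_id == "miR-B"].iloc[0]
        assert abs(a["fold_change"] - 2.0 ** 1.5) < 1e-12
        assert abs(b["fold_change"] - 1.0) < 1e-12
        assert bool(b["induced"]) is False


@settings(max_examples=30, deadline=None)
@given(st.integers(0, 2 ** 31 - 1))
def test_geometric_mean_between_min_and_max(seed):
    rng = np.random.default_rng(seed)
    vals = rng.uniform(10, 35, rng.integers(1, 6))
    gm = geometric_mean(vals)
    assert vals.min() - 1e-12 <= gm <= vals.max() + 1e-12
    am = vals.mean()
    assert gm <= am + 1e-12  # AM-GM
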