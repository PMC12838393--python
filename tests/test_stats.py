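"""Contingency statistics, stepwise logistic selection, ROC and comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from helpers import brute_force_concordance
from vancohd.datasets import EARLY_RESPONSE_FACTORS, RESPONSE_COUNTS
from vancohd.stats import (
    ContingencyTable,
    correlation_compare,
    crude_or,
    factor_table,
    group_compare,
    proportion,
    roc_analysis,
    stepwise_logistic,
)


class TestCrudeOr:
    @pytest.mark.parametrize(
        "name,entry",
        EARLY_RESPONSE_FACTORS.items(),
        ids=list(EARLY_RESPONSE_FACTORS),
    )
    def test_reproduces_published_factor_table(self, name, entry):
        """Every computable crude OR in the published early-response factor
        table is recovered from its counts to the printed 2 decimals."""
        res = crude_or(entry["table"])
        assert res.or_point == pytest.approx(entry["printed_or"], abs=0.0051)

    def test_woolf_interval_reproduces_published_bounds(self):
        res = crude_or(ContingencyTable(15, 4, 3, 9))
        assert round(res.ci_low, 2) == 2.03
        assert round(res.ci_high, 2) == 62.20

    def test_unit_table_symmetric_on_log_scale(self):
        res = crude_or(ContingencyTable(1, 1, 1, 1))
        assert res.or_point == 1.0
        assert np.log(res.ci_low) == pytest.approx(-np.log(res.ci_high))

    @given(st.tuples(*[st.integers(1, 30)] * 4))
    @hyp_settings(derandomize=True, max_examples=50)
    def test_transposition_inverts_or(self, counts):
        a, b, c, d = counts
        forward = crude_or(ContingencyTable(a, b, c, d)).or_point
        swapped = crude_or(ContingencyTable(b, a, d, c)).or_point
        assert forward * swapped == pytest.approx(1.0, rel=1e-12)

    def test_zero_cell_flagged_undefined(self):
        res = crude_or(ContingencyTable(5, 0, 3, 4))
        assert not res.defined and np.isinf(res.or_point)

    def test_small_cells_use_fisher_large_use_chi2(self):
        assert crude_or(ContingencyTable(2, 2, 16, 11)).test_used == "fisher"
        assert crude_or(ContingencyTable(30, 25, 20, 35)).test_used == "chi2"

    def test_published_exposure_table_p_value(self):
        # (15,4,3,9): all expected cells >= 5, so Pearson chi-square applies
        # and reproduces the published p = 0.003
        res = crude_or(ContingencyTable(15, 4, 3, 9))
        assert res.test_used == "chi2"
        assert res.p_value == pytest.approx(0.003, abs=0.001)


def test_response_rate_arithmetic():
    assert proportion(*RESPONSE_COUNTS["mrsa_auc_mic_ge_400"]) == 78.9
    assert proportion(*RESPONSE_COUNTS["resistant_gp_auc_mic_ge_400"]) == 84.2
    assert proportion(*RESPONSE_COUNTS["mrsa_auc_mic_lt_400"]) == 25.0


class TestStepwiseLogistic:
    @staticmethod
    def _frame(rng, n, strong=True):
        x = rng.integers(0, 2, n)
        lp = -0.5 + (1.6 * x if strong else 0.0)
        y = rng.random(n) < 1 / (1 + np.exp(-lp))
        return pd.DataFrame({"x": x, "y": y.astype(int)})

    def test_single_strong_factor_matches_crude(self, rng):
        df = self._frame(rng, 2000)
        res = stepwise_logistic(df, "y", ["x"])
        assert res.retained_names == ["x"]
        t = ContingencyTable(
            a=int(((df.x == 1) & (df.y == 1)).sum()),
            b=int(((df.x == 1) & (df.y == 0)).sum()),
            c=int(((df.x == 0) & (df.y == 1)).sum()),
            d=int(((df.x == 0) & (df.y == 0)).sum()),
        )
        assert res.retained[0].adjusted_or == pytest.approx(
            crude_or(t).or_point, rel=0.05
        )

    def test_null_candidates_rarely_retained(self):
        """Calibration: two outcome-independent candidates should survive
        the screen-plus-stepwise pipeline only at the nominal error rate."""
        clean = 0
        reps = 60
        rng = np.random.default_rng(314159)
        for _ in range(reps):
            n = 150
            df = pd.DataFrame({
                "y": rng.integers(0, 2, n),
                "x1": rng.integers(0, 2, n),
                "x2": rng.normal(size=n),
            })
            res = stepwise_logistic(df, "y", ["x1", "x2"])
            clean += not res.retained
        assert clean >= 0.8 * reps

    def test_collinear_duplicate_dropped(self, rng):
        df = self._frame(rng, 600)
        df["x_dup"] = df["x"]
        res = stepwise_logistic(df, "y", ["x", "x_dup"])
        assert len(res.retained) == 1
        assert res.retained[0].name in ("x", "x_dup")

    def test_separation_flagged(self):
        df = pd.DataFrame({"y": [0] * 12 + [1] * 12,
                           "x": [0] * 12 + [1] * 12})
        res = stepwise_logistic(df, "y", ["x"])
        if res.retained:  # fit may fail outright, which is also acceptable
            assert res.retained[0].separation
            assert res.warnings


class TestRoc:
    def test_perfect_separation(self):
        res = roc_analysis([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        assert res.auc_roc == 1.0
        assert 3 < res.cutoff <= 10
        assert res.sensitivity_at_cutoff == 1.0
        assert res.specificity_at_cutoff == 1.0

    def test_all_tied_scores(self):
        res = roc_analysis([5.0] * 8, [0, 1] * 4)
        assert res.auc_roc == 0.5

    def test_uninformative_scores_near_half(self, rng):
        scores = rng.normal(size=2000)
        labels = rng.integers(0, 2, 2000)
        assert abs(roc_analysis(scores, labels).auc_roc - 0.5) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis([1.0, 2.0], [1, 1])

    @given(st.data())
    @hyp_settings(derandomize=True, max_examples=40, deadline=None)
    def test_auc_equals_brute_force_concordance(self, data):
        n = data.draw(st.integers(6, 50))
        scores = data.draw(
            st.lists(st.integers(0, 12), min_size=n, max_size=n)
        )
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda ls: 0 < sum(ls) < len(ls)
            )
        )
        res = roc_analysis(np.array(scores, float), labels)
        assert res.auc_roc == pytest.approx(
            brute_force_concordance(scores, labels), abs=1e-12
        )

    def test_youden_tie_prefers_higher_specificity(self):
        # J is maximal (=0.5) at cutoffs 2 and 3; pick the higher cutoff
        res = roc_analysis([1, 2, 3, 4], [0, 1, 0, 1])
        assert res.cutoff == pytest.approx(4.0)


class TestCorrelationCompare:
    def test_identical_samples_p_one(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        _, _, p = correlation_compare(x, y, x, y)
        assert p == pytest.approx(1.0)

    def test_symmetry(self, rng):
        x1, y1 = rng.normal(size=40), rng.normal(size=40)
        x2 = rng.normal(size=60)
        y2 = x2 + 0.5 * rng.normal(size=60)
        _, _, p12 = correlation_compare(x1, y1, x2, y2)
        _, _, p21 = correlation_compare(x2, y2, x1, y1)
        assert p12 == pytest.approx(p21, rel=1e-12)

    def test_strong_vs_weak_correlation_detected(self, rng):
        """Sample sizes and correlations on the scale of the HD (r~0.96,
        n=119) vs non-HD (r~0.6, n=77) comparison are clearly separated."""
        n1, n2 = 119, 77
        x1 = rng.normal(size=n1)
        y1 = x1 + 0.29 * rng.normal(size=n1)   # r ~ 0.96
        x2 = rng.normal(size=n2)
        y2 = x2 + 1.33 * rng.normal(size=n2)   # r ~ 0.6
        r1, r2, p = correlation_compare(x1, y1, x2, y2)
        assert r1 > r2
        assert p < 0.01

    def test_degenerate_perfect_correlation(self, rng):
        x = rng.normal(size=10)
        with pytest.warns(UserWarning, match="infinite"):
            _, _, p = correlation_compare(x, x, x, -x)
        assert p == 0.0


class TestGroupCompare:
    def test_identical_groups_rank_p_one(self):
        vals = [1.0, 2.0, 3.0, 4.0]
        res = group_compare(vals, vals, paired=True)
        assert res.p_value == 1.0

    def test_identical_constant_groups(self):
        res = group_compare([5.0] * 6, [5.0] * 6)
        assert res.p_value == 1.0 and res.test_used == "mannwhitney"

    def test_shifted_normals_powerful(self):
        r = np.random.default_rng(1)
        a = r.normal(0.0, 1.0, 100)
        b = r.normal(1.5, 1.0, 100)
        res = group_compare(a, b)
        assert res.test_used == "t"
        assert res.p_value < 1e-6

    def test_skewed_data_uses_rank_test(self, rng):
        a = rng.lognormal(0.0, 1.5, 80)
        b = rng.lognormal(0.6, 1.5, 80)
        assert group_compare(a, b).test_used == "mannwhitney"

    def test_paired_term_comparison(self, rng):
        auc1 = rng.normal(454.0, 60.0, 50)
        auc2 = auc1 - rng.normal(10.0, 5.0, 50)  # mild within-patient decline
        res = group_compare(auc1, auc2, paired=True)
        assert res.test_used == "wilcoxon"
        assert res.p_value < 1e-4

    def test_tiny_groups_refused(self):
        with pytest.raises(ValueError):
            group_compare([1.0, 2.0], [1.0, 2.0, 3.0])


def test_factor_table_layout(rng):
    df = pd.DataFrame({
        "y": rng.integers(0, 2, 80),
        "f1": rng.integers(0, 2, 80),
    })
    out = factor_table(df, "y", ["f1"])
    assert list(out["factor"]) == ["f1"]
    assert {"a", "b", "c", "d", "crude_or", "ci_low", "ci_high", "p_value"} <= set(
        out.columns
    )
    assert out.loc[0, ["a", "b", "c", "d"]].sum() == 80
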