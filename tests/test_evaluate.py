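"""Metrics, AUC, weighted prevalence, underreporting, validity checks."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from probdem import (
    auc,
    confusion_metrics,
    expected_cases,
    fairness_stratify,
    underreporting,
    underreporting_summary,
    underreporting_table,
    validity_compare,
    weighted_prevalence,
)


def pairwise_auc(scores, truth):
    """Exhaustive oracle: mean over all case-control pairs of
    [case > control] + 0.5 [tie]."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth)
    cases = scores[truth == 1]
    controls = scores[truth == 0]
    total = 0.0
    for c in cases:
        for d in controls:
            total += 1.0 if c > d else (0.5 if c == d else 0.0)
    return total / (len(cases) * len(controls))


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        m = confusion_metrics([1, 0, 1, 0], [1, 0, 1, 0])
        assert all(m[k] == 1.0 for k in m)

    def test_balanced_accuracy_definition(self):
        # sens 0.8, spec 0.6 -> balanced accuracy 0.7
        truth = [1] * 5 + [0] * 5
        pred = [1, 1, 1, 1, 0] + [0, 0, 0, 1, 1]
        m = confusion_metrics(pred, truth)
        assert m["sensitivity"] == pytest.approx(0.8)
        assert m["specificity"] == pytest.approx(0.6)
        assert m["balanced_accuracy"] == pytest.approx(0.7)

    def test_f1_harmonic_mean(self):
        # precision 0.25, sensitivity 0.5 -> F1 = 1/3
        truth = [1, 1, 0, 0, 0, 0]
        pred = [1, 0, 1, 1, 1, 0]
        m = confusion_metrics(pred, truth)
        assert m["precision"] == pytest.approx(0.25)
        assert m["sensitivity"] == pytest.approx(0.5)
        assert m["f1"] == pytest.approx(1.0 / 3.0)

    def test_undefined_ratios_are_nan_not_zero(self):
        m = confusion_metrics([0, 0, 0], [0, 0, 0])
        assert math.isnan(m["sensitivity"])
        assert math.isnan(m["precision"])
        assert m["specificity"] == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics([1, 0], [1])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        pred=st.lists(st.integers(0, 1), min_size=2, max_size=40),
        truth=st.lists(st.integers(0, 1), min_size=40, max_size=40),
    )
    def test_identities_hold_exactly(self, pred, truth):
        m = confusion_metrics(pred, truth[: len(pred)])
        if not math.isnan(m["balanced_accuracy"]):
            assert m["balanced_accuracy"] == (m["sensitivity"] + m["specificity"]) / 2
        if not math.isnan(m["f1"]):
            p, s = m["precision"], m["sensitivity"]
            assert m["f1"] == 2 * p * s / (p + s)


class TestAuc:
    def test_perfect_separation(self):
        assert auc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auc([3.0] * 6, [1, 0, 1, 0, 1, 0]) == 0.5

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(10):
            scores = rng.integers(0, 5, size=20).astype(float)  # many ties
            truth = rng.integers(0, 2, size=20)
            if truth.sum() in (0, 20):
                continue
            assert auc(scores, truth) == pytest.approx(pairwise_auc(scores, truth))

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=200)
        truth = rng.integers(0, 2, size=200)
        assert auc(scores, truth) == pytest.approx(roc_auc_score(truth, scores))

    def test_single_class_undefined(self):
        assert math.isnan(auc([0.1, 0.9], [1, 1]))


class TestWeightedPrevalence:
    def test_unit_weights(self):
        assert weighted_prevalence([1, 0, 0, 1], [1, 1, 1, 1]) == pytest.approx(0.5)

    def test_scale_invariance(self, rng):
        y = rng.integers(0, 2, size=50)
        w = rng.uniform(0.5, 3.0, size=50)
        assert weighted_prevalence(y, w) == pytest.approx(weighted_prevalence(y, 2 * w))

    def test_single_upweighted_positive(self):
        # weight 3 on the positive among three unit-weight negatives -> 0.5
        assert weighted_prevalence([1, 0, 0, 0], [3, 1, 1, 1]) == pytest.approx(0.5)

    def test_by_group(self):
        out = weighted_prevalence([1, 0, 1, 1], [1, 1, 1, 1], by=["a", "a", "b", "b"])
        assert out["a"] == pytest.approx(0.5)
        assert out["b"] == pytest.approx(1.0)

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError):
            weighted_prevalence([1], [0.0])


class TestUnderreporting:
    def test_worked_values(self):
        assert underreporting(39, 100) == pytest.approx(0.61)
        assert underreporting(100, 100) == 0.0
        assert underreporting(108.7, 100) == pytest.approx(-0.087)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            underreporting(10, 0)
        with pytest.raises(ValueError):
            underreporting(-1, 10)

    def test_expected_cases(self):
        assert expected_cases(0.0, [1, 2, 3]) == 0.0
        assert expected_cases(1.0, [1, 2, 3]) == pytest.approx(6.0)
        assert expected_cases(0.03, np.full(10, 100.0)) == pytest.approx(30.0)

    def test_identity_on_emitted_records(self, rng):
        labels = rng.integers(0, 2, size=300)
        weights = rng.uniform(0.5, 2.0, size=300)
        codes = rng.choice(["AT", "BE", "CH"], size=300)
        table = underreporting_table(labels, weights, codes,
                                     {"AT": 0.05, "BE": 0.03, "CH": 0.08})
        resid = table["underreporting"] - (1 - table["n_alg"] / table["n_ext"])
        assert np.abs(resid.to_numpy()).max() == 0.0


class TestUnderreportingSummary:
    def test_constant_values_zero_width(self):
        rec = pd.DataFrame({"underreporting": [0.4] * 5})
        s = underreporting_summary(rec)
        assert s.mean == pytest.approx(0.4)
        assert s.ci95_low == pytest.approx(0.4)
        assert s.ci95_high == pytest.approx(0.4)

    def test_matches_textbook_t_interval(self, rng):
        from scipy import stats

        vals = rng.normal(0.5, 0.1, size=26)
        s = underreporting_summary(pd.DataFrame({"underreporting": vals}))
        mean = vals.mean()
        half = stats.t.ppf(0.975, 25) * vals.std(ddof=1) / np.sqrt(26)
        assert s.mean == pytest.approx(mean)
        assert s.ci95_low == pytest.approx(mean - half)
        assert s.ci95_high == pytest.approx(mean + half)

    def test_permutation_invariant(self, rng):
        vals = rng.normal(size=10)
        a = underreporting_summary(pd.DataFrame({"underreporting": vals}))
        b = underreporting_summary(
            pd.DataFrame({"underreporting": vals[::-1].copy()})
        )
        assert a.mean == pytest.approx(b.mean)
        assert a.ci95_low == pytest.approx(b.ci95_low)
        assert a.ci95_high == pytest.approx(b.ci95_high)

    def test_single_country_undefined_ci(self):
        s = underreporting_summary(pd.DataFrame({"underreporting": [0.3]}))
        assert s.mean == 0.3
        assert math.isnan(s.ci95_low)


class TestFairnessStratify:
    def test_identical_countries_zero_dispersion(self):
        pred = [1, 0, 1, 0] * 2
        truth = [1, 0, 0, 0] * 2
        codes = ["AT"] * 4 + ["BE"] * 4
        per_country, disp = fairness_stratify(pred, truth, codes)
        spread = disp.set_index("metric")["range"].dropna()
        assert (spread == 0).all()

    def test_country_without_cases_keeps_nan_row(self):
        pred = [0, 1, 0, 0]
        truth = [1, 0, 0, 0]
        codes = ["AT", "AT", "BE", "BE"]
        per_country, _ = fairness_stratify(pred, truth, codes)
        be = per_country.set_index("country_code").loc["BE"]
        assert math.isnan(be["sensitivity"])

    def test_matches_per_country_recomputation(self, rng):
        pred = rng.integers(0, 2, size=120)
        truth = rng.integers(0, 2, size=120)
        codes = rng.choice(["AT", "BE", "CH"], size=120)
        scores = rng.normal(size=120)
        per_country, _ = fairness_stratify(pred, truth, codes, scores)
        for code in ("AT", "BE", "CH"):
            m = codes == code
            expected = confusion_metrics(pred[m], truth[m])
            row = per_country.set_index("country_code").loc[code]
            for k, v in expected.items():
                assert row[k] == pytest.approx(v, nan_ok=True)
            assert row["auc"] == pytest.approx(auc(scores[m], truth[m]), nan_ok=True)


class TestValidityCompare:
    @pytest.fixture()
    def cohort(self, rng):
        n = 200
        df = pd.DataFrame(
            {
                "self_report_dx": rng.integers(0, 2, size=n),
                "dep_symptoms": rng.integers(0, 13, size=n).astype(float),
                "grip_strength": rng.normal(30, 8, size=n),
            }
        )
        return df

    def test_identical_groups_give_p_one(self, cohort):
        labels = {"alg": pd.Series(cohort["self_report_dx"].to_numpy(),
                                   index=cohort.index)}
        out = validity_compare(cohort, labels, domains=("dep_symptoms",))
        row = out.iloc[0]
        assert row["mean_alg"] == pytest.approx(row["mean_self_report"])
        assert row["p_bonferroni"] == 1.0

    def test_bonferroni_is_m_times_p_capped(self, cohort, rng):
        labels = {
            "a": pd.Series(rng.integers(0, 2, size=len(cohort)), index=cohort.index),
            "b": pd.Series(rng.integers(0, 2, size=len(cohort)), index=cohort.index),
        }
        out = validity_compare(cohort, labels,
                               domains=("dep_symptoms", "grip_strength"))
        m = len(out)  # 2 algorithms x 2 domains
        assert m == 4
        for _, row in out.iterrows():
            assert row["p_bonferroni"] == pytest.approx(min(1.0, m * row["p_value"]))

    def test_toy_t_statistic_against_closed_form(self):
        # Student's pooled t on two 3-point groups, computed by hand.
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([4.0, 5.0, 6.0])
        cohort = pd.DataFrame(
            {
                "self_report_dx": [0, 0, 0, 1, 1, 1],
                "dep_symptoms": np.concatenate([a, b]),
            }
        )
        labels = {"alg": pd.Series([1, 1, 1, 0, 0, 0], index=cohort.index)}
        out = validity_compare(cohort, labels, domains=("dep_symptoms",),
                               equal_var=True)
        sp2 = (a.var(ddof=1) + b.var(ddof=1)) / 2
        t_manual = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 3))
        assert out.iloc[0]["t_stat"] == pytest.approx(t_manual)

    def test_small_group_undefined(self, cohort):
        labels = {"alg": pd.Series(0, index=cohort.index)}
        labels["alg"].iloc[:1] = 1  # group of one
        out = validity_compare(cohort, labels, domains=("dep_symptoms",))
        assert math.isnan(out.iloc[0]["p_value"])
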