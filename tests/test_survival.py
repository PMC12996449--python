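import numpy as np
import pandas as pd
import pytest
from scipy import stats, optimize

from circscape import survival as surv
from circscape.errors import AnalysisError

from conftest import counts_frame


class TestStratifyByMedian:
    def test_even_split(self):
        labels = surv.stratify_by_median([1, 2, 3, 4])
        assert list(labels) == ["low", "low", "high", "high"]

    def test_ties_go_low(self):
        labels = surv.stratify_by_median([1, 2, 2, 3])
        assert list(labels) == ["low", "low", "low", "high"]

    def test_constant_vector_rejected(self):
        with pytest.raises(AnalysisError, match="not stratifiable"):
            surv.stratify_by_median([5, 5, 5])


class TestKmCurve:
    def test_hand_product_limit(self):
        km = surv.km_curve([1, 2, 3, 4], [0, 1, 0, 1])
        s = dict(zip(km["time"], km["survival"]))
        assert s[2] == pytest.approx(2 / 3)
        assert s[4] == pytest.approx(0.0)

    def test_no_events_flat_curve(self):
        km = surv.km_curve([1, 2, 3], [0, 0, 0])
        assert km.empty  # no steps: S stays 1 throughout

    def test_all_events_equals_empirical_survival(self):
        times = [5, 1, 3, 2, 4]
        km = surv.km_curve(times, [1] * 5)
        np.testing.assert_allclose(km["survival"], [0.8, 0.6, 0.4, 0.2, 0.0])

    def test_monotone_from_one(self, rng):
        times = rng.exponential(10, 50)
        events = rng.integers(0, 2, 50)
        km = surv.km_curve(times, events)
        vals = np.concatenate([[1.0], km["survival"].to_numpy()])
        assert (np.diff(vals) <= 1e-12).all()
        assert ((vals >= 0) & (vals <= 1)).all()


def logrank_bruteforce(times, events, labels):
    """Term-by-term O-E/V computation at each distinct event time."""
    times, events = np.asarray(times, float), np.asarray(events, int)
    labels = np.asarray(labels)
    g1 = np.unique(labels)[0]
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (labels == g1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (labels == g1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var if var > 0 else 0.0
    return chi2, stats.chi2.sf(chi2, 1)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        times = [1, 2, 3, 1, 2, 3]
        events = [1, 0, 1, 1, 0, 1]
        labels = ["a"] * 3 + ["b"] * 3
        chi2, p = surv.logrank_test(times, events, labels)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_bruteforce_on_small_instances(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 9))
            times = rng.integers(1, 6, n).astype(float)
            events = rng.integers(0, 2, n)
            labels = rng.choice(["a", "b"], n)
            if len(set(labels)) < 2 or events.sum() == 0:
                continue
            got = surv.logrank_test(times, events, labels)
            want = logrank_bruteforce(times, events, labels)
            assert got[0] == pytest.approx(want[0], abs=1e-10)
            assert got[1] == pytest.approx(want[1], abs=1e-10)

    def test_matches_lifelines(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        times = rng.exponential(10, 60)
        events = rng.integers(0, 2, 60)
        labels = np.array(["a"] * 30 + ["b"] * 30)
        chi2, p = surv.logrank_test(times, events, labels)
        ll = ll_logrank(times[labels == "a"], times[labels == "b"],
                        events[labels == "a"], events[labels == "b"])
        assert chi2 == pytest.approx(ll.test_statistic, rel=1e-8)
        assert p == pytest.approx(ll.p_value, rel=1e-8)

    def test_label_swap_invariance(self, rng):
        times = rng.exponential(5, 40)
        events = rng.integers(0, 2, 40)
        labels = rng.choice(["x", "y"], 40)
        swapped = np.where(labels == "x", "y", "x")
        assert surv.logrank_test(times, events, labels)[0] == pytest.approx(
            surv.logrank_test(times, events, swapped)[0], abs=1e-12
        )

    def test_patient_order_invariance(self, rng):
        times = rng.exponential(5, 30)
        events = rng.integers(0, 2, 30)
        labels = rng.choice(["x", "y"], 30)
        perm = rng.permutation(30)
        assert surv.logrank_test(times, events, labels)[0] == pytest.approx(
            surv.logrank_test(times[perm], events[perm], labels[perm])[0], abs=1e-12
        )


def _clin(rng, n, high=None, beta=0.0, h0=0.05, censor=0.25):
    high = np.zeros(n) if high is None else np.asarray(high, float)
    t = rng.exponential(1 / (h0 * np.exp(beta * high)))
    c = rng.exponential(1 / (h0 * censor / (1 - censor)), n)
    return pd.DataFrame(
        {"os_time": np.minimum(t, c), "os_event": (t <= c).astype(int)},
        index=[f"p{i}" for i in range(n)],
    )


class TestSurvivalScreen:
    def test_planted_prognostic_ranks_first(self, rng):
        n, n_circ = 200, 80
        expr = rng.lognormal(1.0, 0.6, size=(n_circ, n))
        high = (expr[0] > np.median(expr[0])).astype(float)
        clinical = _clin(rng, n, high, beta=np.log(3.0))
        fpm = counts_frame(expr, [f"c{i}" for i in range(n_circ)], list(clinical.index))
        res = surv.survival_screen(fpm, clinical)
        assert res["p"].idxmin() == "c0"

    def test_subset_purity(self, rng):
        n = 80
        expr = rng.lognormal(1.0, 0.6, size=(30, n))
        clinical = _clin(rng, n)
        clinical["risk_group"] = ["A"] * 40 + ["B"] * 40
        fpm = counts_frame(expr, [f"c{i}" for i in range(30)], list(clinical.index))
        sub_a = clinical.index[clinical["risk_group"] == "A"]
        r1 = surv.survival_screen(fpm, clinical, subset_filter=list(sub_a), subset_name="A")
        # perturbing patients outside the subset changes nothing
        clinical2 = clinical.copy()
        clinical2.loc[clinical2["risk_group"] == "B", "os_time"] *= 10
        r2 = surv.survival_screen(fpm, clinical2, subset_filter=list(sub_a), subset_name="A")
        pd.testing.assert_frame_equal(r1, r2)

    def test_small_subset_refused(self, rng):
        expr = rng.lognormal(1.0, 0.5, size=(5, 10))
        clinical = _clin(rng, 10)
        fpm = counts_frame(expr, [f"c{i}" for i in range(5)], list(clinical.index))
        with pytest.raises(AnalysisError, match="below the minimum"):
            surv.survival_screen(fpm, clinical, min_subset=20)


def cox_partial_loglik(beta, times, events, x):
    """Breslow partial log-likelihood for a single covariate, no ties."""
    ll = 0.0
    for i in np.where(events == 1)[0]:
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestCox:
    def test_toy_grid_search_oracle(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        clinical = pd.DataFrame(
            {"os_time": times, "os_event": events}, index=[f"p{i}" for i in range(4)]
        )
        fit = surv.cox_ph_fit(clinical, x)
        grid = optimize.minimize_scalar(
            lambda b: -cox_partial_loglik(b, times, events, x), bounds=(-5, 5), method="bounded"
        )
        assert fit.loc["circ_high", "beta"] == pytest.approx(grid.x, abs=1e-4)

    def test_score_test_identity_with_logrank(self, rng):
        # classical identity: log-rank == Cox score test at beta=0 (no ties)
        n = 40
        times = rng.exponential(10, n)
        events = rng.integers(0, 2, n)
        x = rng.integers(0, 2, n).astype(float)
        if len(set(times)) < n or events.sum() == 0 or len(set(x)) < 2:
            pytest.skip("degenerate draw")
        chi2, _ = surv.logrank_test(times, events, np.where(x > 0, "high", "low"))
        eps = 1e-5
        u = (cox_partial_loglik(eps, times, events, x)
             - cox_partial_loglik(-eps, times, events, x)) / (2 * eps)
        info = -(cox_partial_loglik(eps, times, events, x)
                 - 2 * cox_partial_loglik(0.0, times, events, x)
                 + cox_partial_loglik(-eps, times, events, x)) / eps**2
        assert chi2 == pytest.approx(u**2 / info, rel=1e-3)

    def test_constant_covariate_dropped(self, rng):
        clinical = _clin(rng, 60)
        clinical["age"] = 50.0
        labels = rng.integers(0, 2, 60).astype(float)
        with pytest.warns(UserWarning, match="constant"):
            fit = surv.cox_ph_fit(clinical, labels, ["age"])
        assert "age" not in fit.index

    def test_null_covariate_calibrated(self, rng):
        clinical = _clin(rng, 400)
        labels = rng.integers(0, 2, 400).astype(float)
        fit = surv.cox_ph_fit(clinical, labels)
        assert abs(fit.loc["circ_high", "beta"]) < 0.3


class TestClinicalAssociation:
    def test_hand_2x2_chisquare_and_or(self):
        labels = pd.Series(
            ["low"] * 30 + ["high"] * 30, index=[f"p{i}" for i in range(60)]
        )
        feat = ["yes"] * 10 + ["no"] * 20 + ["yes"] * 20 + ["no"] * 10
        clinical = pd.DataFrame({"feature": feat}, index=labels.index)
        res = surv.group_clinical_association(labels, clinical, categorical=["feature"])
        row = res[res["feature"] == "feature"].iloc[0]
        assert row["statistic"] == pytest.approx(60 * (10 * 10 - 20 * 20) ** 2 / (30 * 30 * 30 * 30))
        assert row["statistic"] == pytest.approx(6.667, abs=1e-3)
        assert row["odds_ratio"] in (pytest.approx(0.25), pytest.approx(4.0))

    def test_identical_groups_null(self):
        labels = pd.Series(["low"] * 20 + ["high"] * 20,
                           index=[f"p{i}" for i in range(40)])
        feat = (["a"] * 10 + ["b"] * 10) * 2
        clinical = pd.DataFrame({"f": feat}, index=labels.index)
        res = surv.group_clinical_association(labels, clinical, categorical=["f"])
        row = res.iloc[0]
        assert row["odds_ratio"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(1.0)

    def test_single_level_feature_skipped(self):
        labels = pd.Series(["low", "high"] * 10, index=[f"p{i}" for i in range(20)])
        clinical = pd.DataFrame({"f": ["x"] * 20}, index=labels.index)
        res = surv.group_clinical_association(labels, clinical, categorical=["f"])
        assert res.iloc[0]["note"] == "single level"
        assert np.isnan(res.iloc[0]["p"])

    def test_continuous_feature_ranksum(self, rng):
        labels = pd.Series(["low"] * 50 + ["high"] * 50,
                           index=[f"p{i}" for i in range(100)])
        clinical = pd.DataFrame(
            {"age": np.concatenate([rng.normal(60, 5, 50), rng.normal(70, 5, 50)])},
            index=labels.index,
        )
        res = surv.group_clinical_association(labels, clinical, categorical=[])
        row = res[res["feature"] == "age"].iloc[0]
        assert row["p"] < 0.001
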