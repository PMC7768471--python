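"""Endpoint derivation, Kaplan-Meier, log-rank, maxstat and Cox tests."""

import numpy as np
import pandas as pd
import pytest

from xenostroma import survival as sv
from xenostroma import synthetic as syn


def _raw_row(**kw):
    base = dict(psa_rec_time=100.0, psa_rec_event=0, metastasis_time=100.0,
                metastasis_event=0, local_rec_time=100.0, local_rec_event=0,
                os_time=100.0, os_event=0, last_followup=100.0,
                core_1=1.0, core_2=2.0, stage="3a", gleason=7)
    base.update(kw)
    return base


class TestEndpoints:
    def test_psa_only_recurrence(self):
        raw = pd.DataFrame([_raw_row(psa_rec_time=24.0, psa_rec_event=1)],
                           index=["p1"])
        rec = sv.derive_endpoints(raw)[0]
        assert rec.endpoints["psa_progression"] == (24.0, 1)
        assert rec.endpoints["disease_progression"] == (24.0, 1)
        assert rec.endpoints["clinical_progression"] == (100.0, 0)

    def test_metastasis_is_clinical_progression(self):
        raw = pd.DataFrame([_raw_row(metastasis_time=36.0, metastasis_event=1)],
                           index=["p1"])
        rec = sv.derive_endpoints(raw)[0]
        assert rec.endpoints["clinical_progression"] == (36.0, 1)
        assert rec.endpoints["disease_progression"] == (36.0, 1)

    def test_earliest_clinical_event_wins(self):
        raw = pd.DataFrame([_raw_row(metastasis_time=50.0, metastasis_event=1,
                                     local_rec_time=30.0, local_rec_event=1)],
                           index=["p1"])
        rec = sv.derive_endpoints(raw)[0]
        assert rec.endpoints["clinical_progression"] == (30.0, 1)

    def test_no_events_censored_at_last_followup(self):
        raw = pd.DataFrame([_raw_row(last_followup=84.0)], index=["p1"])
        rec = sv.derive_endpoints(raw)[0]
        for ep in sv.ENDPOINTS:
            assert rec.endpoints[ep] == (84.0, 0)

    def test_negative_time_row_rejected(self, caplog):
        raw = pd.DataFrame([_raw_row(), _raw_row(os_time=-1.0)], index=["p1", "p2"])
        with caplog.at_level("WARNING", logger="xenostroma"):
            recs = sv.derive_endpoints(raw)
        assert [r.patient_id for r in recs] == ["p1"]

    def test_marker_is_core_mean(self):
        raw = pd.DataFrame([_raw_row(core_1=4.0, core_2=8.0)], index=["p1"])
        assert sv.derive_endpoints(raw)[0].marker == 6.0


def km_hand_oracle(times, events):
    """Plain product-limit computation for a tiny worked instance."""
    out = {}
    s = 1.0
    for u in sorted(set(t for t, e in zip(times, events) if e == 1)):
        at_risk = sum(t >= u for t in times)
        deaths = sum(t == u and e == 1 for t, e in zip(times, events))
        s *= 1 - deaths / at_risk
        out[u] = s
    return out


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(40)
        t = rng.exponential(10, 80)
        km = sv.km_fit(t, np.ones(80, dtype=int))
        for u in km.times:
            assert np.isclose(km.at(u), np.mean(t > u))

    def test_all_censored_flat_one(self):
        km = sv.km_fit([1.0, 2.0, 3.0], [0, 0, 0])
        assert km.at(10.0) == 1.0 and len(km.times) == 0

    def test_small_worked_instance(self):
        times = [1, 2, 2, 3, 5, 8]
        events = [1, 1, 0, 1, 0, 1]
        km = sv.km_fit(times, events)
        oracle = km_hand_oracle(times, events)
        for u, s in oracle.items():
            assert np.isclose(km.at(u), s)

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(41)
        t = rng.exponential(10, 60)
        e = rng.integers(0, 2, 60)
        if e.sum() == 0:
            e[0] = 1
        km = sv.km_fit(t, e)
        kmf = KaplanMeierFitter().fit(t, e)
        for u in km.times:
            assert np.isclose(km.at(u), kmf.predict(u), atol=1e-10)

    def test_monotone_nonincreasing_from_one(self):
        rng = np.random.default_rng(42)
        km = sv.km_fit(rng.exponential(5, 50), rng.integers(0, 2, 50))
        surv = np.r_[1.0, km.survival]
        assert (np.diff(surv) <= 1e-15).all()


class TestLogrank:
    def test_duplicated_groups_null_statistic(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [1, 1, 0, 1]
        chi2, df, p = sv.logrank(t + t, e + e, ["a"] * 4 + ["b"] * 4)
        assert chi2 < 1e-12 and p > 0.999

    def test_equals_cox_score_test_two_groups(self):
        """Two-group log-rank chi2 equals the Cox score statistic with a
        binary covariate on tie-free data."""
        rng = np.random.default_rng(43)
        t = rng.exponential(10, 40)  # continuous: ties have measure zero
        e = rng.integers(0, 2, 40)
        e[:5] = 1
        g = np.r_[np.zeros(20), np.ones(20)]
        chi2, _, _ = sv.logrank(t, e, g)
        cox = sv.cox_fit(t, e, g)
        assert np.isclose(chi2, cox.score_chi2, rtol=1e-8)

    def test_null_pvalue_calibration(self):
        rng = np.random.default_rng(44)
        hits = 0
        n_sims = 500
        for _ in range(n_sims):
            t = rng.exponential(10, 40)
            e = rng.random(40) < 0.8
            g = rng.integers(0, 2, 40)
            if e.sum() == 0 or len(np.unique(g)) < 2:
                continue
            _, _, p = sv.logrank(t, e.astype(int), g)
            hits += p < 0.05
        assert 0.03 <= hits / n_sims <= 0.075

    def test_pairwise_bh_adjustment(self):
        rng = np.random.default_rng(45)
        t = rng.exponential(10, 90)
        e = np.ones(90, dtype=int)
        g = np.repeat(["a", "b", "c"], 30)
        out = sv.pairwise_logrank(t, e, g)
        assert len(out) == 3
        assert (out["p_adj"] >= out["p"] - 1e-15).all()

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            sv.logrank([1.0, 2.0], [0, 0], ["a", "b"])


@pytest.fixture(scope="module")
def cohort():
    raw = syn.simulate_cohort(syn.CohortTruth(n_patients=80, censor_rate=0.2,
                                              marker_hazard_ratio=2.5), seed=46)
    return raw["psa_rec_time"].values, raw["psa_rec_event"].values, raw["marker"].values


class TestMaxstat:

    def test_two_valued_marker_midpoint(self):
        t = [1, 2, 3, 4, 5, 6, 7, 8.0]
        e = [1] * 8
        m = [1.0] * 4 + [3.0] * 4
        cut = sv.maxstat_cutpoint(t, e, m, minprop=0.1, pmethod="approx")
        assert cut.cutpoint == 2.0

    def test_selected_statistic_matches_brute_force(self, cohort):
        """The selected split equals an exhaustive scan with the
        independent per-split log-rank statistic."""
        t, e, m = cohort
        cut = sv.maxstat_cutpoint(t, e, m, pmethod="approx")
        brute = [(abs(sv.logrank_z(t, e, m > c)), -c) for c in cut.candidates]
        best_z, neg_c = max(brute)
        # ties resolved toward the smaller cutpoint in both paths
        best_c = min(c for z, c in [(z, -nc) for z, nc in brute] if np.isclose(z, best_z))
        assert np.isclose(cut.statistic, best_z, atol=1e-10)
        assert np.isclose(cut.cutpoint, best_c)

    def test_rank_transform_invariance(self, cohort):
        t, e, m = cohort
        a = sv.maxstat_cutpoint(t, e, m, pmethod="approx")
        ranks = pd.Series(m).rank(method="average").values
        b = sv.maxstat_cutpoint(t, e, ranks, pmethod="approx")
        assert np.isclose(a.statistic, b.statistic)
        assert (m <= a.cutpoint).sum() == (ranks <= b.cutpoint).sum()

    def test_adjusted_p_not_below_naive(self, cohort):
        t, e, m = cohort
        for method in ("permutation", "approx"):
            cut = sv.maxstat_cutpoint(t, e, m, pmethod=method, n_perm=300, seed=0)
            assert cut.p_adjusted >= cut.p_naive - 1e-12

    def test_minprop_respected(self, cohort):
        t, e, m = cohort
        cut = sv.maxstat_cutpoint(t, e, m, minprop=0.25, pmethod="approx")
        n = len(m)
        for c in cut.candidates:
            assert 0.25 * n <= (m > c).sum() <= 0.75 * n

    def test_too_few_candidates_rejected(self):
        with pytest.raises(ValueError):
            sv.maxstat_cutpoint([1, 2, 3.0], [1, 1, 1], [1.0, 1.0, 1.0])


class TestCox:
    def test_covariate_rescaling_identity(self):
        rng = np.random.default_rng(47)
        x = rng.normal(0, 1, 50)
        t = rng.exponential(np.exp(-0.5 * x))
        e = np.ones(50, dtype=int)
        fit1 = sv.cox_fit(t, e, x)
        fit2 = sv.cox_fit(t, e, 2.0 * x)
        assert np.isclose(fit1.beta[0], 2.0 * fit2.beta[0], rtol=1e-6)
        assert np.isclose(fit1.hr[0], fit2.hr[0] ** 2, rtol=1e-5)

    def test_matches_lifelines(self):
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(48)
        x = rng.normal(0, 1, 80)
        t = rng.exponential(np.exp(-0.7 * x))
        e = (rng.random(80) < 0.8).astype(int)
        e[0] = 1
        fit = sv.cox_fit(t, e, x)
        df = pd.DataFrame({"t": t, "e": e, "x": x})
        ll = CoxPHFitter().fit(df, "t", "e")
        assert np.isclose(fit.beta[0], ll.params_["x"], atol=1e-5)
        assert np.isclose(fit.se[0], ll.standard_errors_["x"], atol=1e-5)

    def test_loglik_monotone_over_iterations(self):
        """Step-halved Newton never decreases the partial likelihood."""
        rng = np.random.default_rng(49)
        x = rng.normal(0, 1, 60)
        t = rng.exponential(np.exp(-x))
        e = np.ones(60, dtype=int)
        lls = []
        beta = np.zeros(1)
        ll, grad, hess = sv._cox_loglik(beta, t, e, x[:, None])
        lls.append(ll)
        for _ in range(8):
            step = np.linalg.solve(-hess, grad)
            new = beta + step
            nll, ngrad, nhess = sv._cox_loglik(new, t, e, x[:, None])
            while nll < ll:
                step /= 2
                new = beta + step
                nll, ngrad, nhess = sv._cox_loglik(new, t, e, x[:, None])
            beta, ll, grad, hess = new, nll, ngrad, nhess
            lls.append(ll)
        assert (np.diff(lls) >= -1e-12).all()

    def test_null_ci_coverage(self):
        """Under beta = 0 the 95% CI covers HR = 1 in about 95% of runs."""
        rng = np.random.default_rng(50)
        cover = 0
        n_sims = 500
        for _ in range(n_sims):
            x = rng.normal(0, 1, 60)
            t = rng.exponential(1.0, 60)
            e = (rng.random(60) < 0.8).astype(int)
            if e.sum() < 5:
                continue
            fit = sv.cox_fit(t, e, x)
            cover += fit.ci_lower[0] <= 1.0 <= fit.ci_upper[0]
        assert 0.92 <= cover / n_sims <= 0.98

    def test_planted_hazard_ratio_recovery(self):
        """A planted HR of 2.5 in a cohort-sized design is recovered: the
        CI contains the truth in >= 90% of replicates."""
        rng = np.random.default_rng(51)
        hit = 0
        n_sims = 120
        for rep in range(n_sims):
            raw = syn.simulate_cohort(
                syn.CohortTruth(marker_hazard_ratio=2.5, censor_rate=0.3,
                                n_patients=210), seed=7000 + rep)
            g = (raw["true_group"] == "high").astype(float)
            fit = sv.cox_fit(raw["psa_rec_time"], raw["psa_rec_event"], g)
            hit += fit.ci_lower[0] <= 2.5 <= fit.ci_upper[0]
        assert hit / n_sims >= 0.90

    def test_separation_flagged_and_capped(self, caplog):
        t = np.r_[np.arange(1, 21), np.arange(21, 41)].astype(float)
        e = np.ones(40, dtype=int)
        x = np.r_[np.zeros(20), np.ones(20)]  # early deaths all in group 0
        with caplog.at_level("WARNING", logger="xenostroma"):
            fit = sv.cox_fit(t, e, x)
        assert not fit.converged
        assert np.isfinite(fit.beta[0])

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError):
            sv.cox_fit([1.0, 2.0], [1, 1], [3.0, 3.0])
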