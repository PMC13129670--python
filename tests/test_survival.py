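import math

import numpy as np
import pytest

import mrdflow as m
from mrdflow.survival import SurvivalRecord


def rec(i, t, e, g="A"):
    return SurvivalRecord(f"P{i}", float(t), int(e), g)


def km_by_hand(times, events):
    """Brute-force product-limit estimator."""
    order = np.argsort(times)
    times, events = np.asarray(times)[order], np.asarray(events)[order]
    uniq = np.unique(times[events == 1])
    surv = {}
    s = 1.0
    for t in uniq:
        at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1.0 - d / at_risk
        surv[float(t)] = s
    return surv


class TestKaplanMeier:
    def test_three_events_hand_values(self):
        km = m.km_estimate([rec(1, 1, 1), rec(2, 2, 1), rec(3, 3, 1)])
        assert km.at(2.0) == pytest.approx(1 / 3)
        assert km.median == 2.0

    def test_all_censored(self):
        km = m.km_estimate([rec(i, t, 0) for i, t in enumerate([2, 5, 9])])
        assert km.at(9.0) == 1.0
        assert km.median == m.NOT_REACHED

    def test_single_event(self):
        km = m.km_estimate([rec(1, 4.0, 1)])
        assert km.at(4.0) == 0.0 and km.median == 4.0

    def test_matches_brute_force_on_random_instance(self):
        rng = np.random.default_rng(42)
        times = rng.exponential(10, size=20).round(2) + 0.1
        events = rng.integers(0, 2, size=20)
        km = m.km_estimate([rec(i, t, e) for i, (t, e) in enumerate(zip(times, events))])
        for t, s in km_by_hand(times, events).items():
            assert km.at(t) == pytest.approx(s, abs=1e-12)


def logrank_by_hand(times, events, groups):
    """First-principles two-group log-rank chi-square."""
    times, events = np.asarray(times, float), np.asarray(events, int)
    groups = np.asarray(groups)
    O_E, V = 0.0, 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == groups[0])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == groups[0])).sum()
        O_E += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return O_E**2 / V


class TestLogrank:
    def test_identical_groups_give_null(self):
        base = [(2, 1), (4, 1), (6, 0), (8, 1)]
        records = [rec(i, t, e, "X") for i, (t, e) in enumerate(base)]
        records += [rec(i + 10, t, e, "Y") for i, (t, e) in enumerate(base)]
        stat, p = m.logrank_test(records)
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_disjoint_supports_are_separated(self):
        rng = np.random.default_rng(0)
        early = rng.uniform(1, 5, 10)
        late = rng.uniform(50, 60, 10)
        records = [rec(i, t, 1, "E") for i, t in enumerate(early)]
        records += [rec(i + 10, t, 1, "L") for i, t in enumerate(late)]
        stat, p = m.logrank_test(records)
        assert p < 1e-3
        times = np.concatenate([early, late])
        groups = np.array(["E"] * 10 + ["L"] * 10)
        expected = logrank_by_hand(times, np.ones(20, int), groups)
        assert stat == pytest.approx(expected, rel=1e-6)

    def test_six_subject_toy_matches_hand_computation(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [1, 1, 0, 1, 1, 1]
        groups = ["A", "B", "A", "B", "A", "B"]
        records = [rec(i, t, e, g) for i, (t, e, g) in
                   enumerate(zip(times, events, groups))]
        stat, _ = m.logrank_test(records)
        assert stat == pytest.approx(logrank_by_hand(times, events, groups), rel=1e-6)

    def test_single_group_is_an_error(self):
        with pytest.raises(ValueError):
            m.logrank_test([rec(1, 2, 1, "A"), rec(2, 3, 1, "A")])


def cox_partial_loglik(beta, times, events, x):
    """Breslow partial log-likelihood for one binary covariate."""
    ll = 0.0
    for i in range(len(times)):
        if events[i] != 1:
            continue
        risk = [j for j in range(len(times)) if times[j] >= times[i]]
        ll += beta * x[i] - math.log(sum(math.exp(beta * x[j]) for j in risk))
    return ll


class TestCox:
    def test_duplicated_groups_give_unit_hr(self):
        base = [(2, 1), (4, 1), (6, 0), (8, 1), (10, 0)]
        records = [rec(i, t, e, "REF") for i, (t, e) in enumerate(base)]
        records += [rec(i + 10, t, e, "OTHER") for i, (t, e) in enumerate(base)]
        hr, ci, _ = m.cox_hr(records, reference="REF")
        assert hr == pytest.approx(1.0, abs=1e-6)
        assert ci[0] < 1.0 < ci[1]

    def test_eight_subject_toy_matches_grid_search(self):
        """No tied event times, so Breslow = Efron and a beta grid search
        maximizing the partial likelihood is an exact oracle."""
        times = [1.0, 2.5, 3.0, 4.5, 5.0, 6.5, 7.0, 9.0]
        events = [1, 1, 1, 0, 1, 1, 0, 1]
        x = [1, 0, 1, 0, 1, 0, 1, 0]
        records = [
            rec(i, t, e, "EXP" if xi else "REF")
            for i, (t, e, xi) in enumerate(zip(times, events, x))
        ]
        hr, _, _ = m.cox_hr(records, reference="REF")
        grid = np.arange(-3.0, 3.0, 1e-4)
        lls = [cox_partial_loglik(b, times, events, x) for b in grid]
        beta_star = grid[int(np.argmax(lls))]
        assert math.log(hr) == pytest.approx(beta_star, abs=1e-3)

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            m.cox_hr([rec(1, 2, 1, "A"), rec(2, 3, 1, "A")], reference="A")


class TestConcordance:
    def test_identical_labels(self):
        labels = {f"P{i}": i % 4 for i in range(8)}
        frac, counts = m.concordance_table(labels, labels)
        assert frac == 1.0
        assert counts.to_numpy().sum() == 8

    def test_counting_after_merge(self):
        # clusters 0,1 -> FAVORABLE; 2,3 -> UNFAVORABLE
        bm = {"a": 0, "b": 1, "c": 2, "d": 3}
        pb = {"a": 1, "b": 0, "c": 3, "d": 1}  # d flips group
        frac, counts = m.concordance_table(bm, pb)
        assert frac == 0.75
        assert counts.loc[3, 1] == 1

    def test_no_pairs_is_an_error(self):
        with pytest.raises(ValueError):
            m.concordance_table({"a": 0}, {"b": 1})


class TestLandmark:
    def test_leak_freedom(self, fitted_four_cluster):
        """Perturbing every post-landmark measurement must leave every
        landmark classification unchanged."""
        fit, cohort, _ = fitted_four_cluster
        L = 18.0
        res = m.landmark_analysis(fit.model, cohort, [L], min_timepoints=3)[0]

        # corrupt all data strictly after the landmark
        corrupted = []
        for t in cohort.trajectories:
            vals = t.values.copy()
            vals[t.times > L] = -1.0  # wildly different late values
            corrupted.append(
                m.MrdTrajectory(t.patient_id, t.tissue, t.times, vals)
            )
        chaos = m.Cohort(trajectories=corrupted, clinical=dict(cohort.clinical))
        res2 = m.landmark_analysis(fit.model, chaos, [L], min_timepoints=3)[0]
        assert res.labels == res2.labels

    def test_risk_sets_nested_decreasing(self, fitted_four_cluster):
        """Event-free risk sets shrink as the landmark advances, and every
        classified patient belongs to the landmark's risk set."""
        fit, cohort, _ = fitted_four_cluster
        landmarks = [6.0, 12.0, 18.0, 24.0]
        results = m.landmark_analysis(
            fit.model, cohort, landmarks, min_timepoints=2
        )
        risk_sets = [
            {pid for pid, c in cohort.clinical.items() if c.ttp_months > L}
            for L in landmarks
        ]
        for a, b in zip(risk_sets, risk_sets[1:]):
            assert b <= a
        for res, risk in zip(results, risk_sets):
            assert set(res.labels) <= risk

    def test_survival_measured_from_landmark(self, fitted_four_cluster):
        fit, cohort, _ = fitted_four_cluster
        L = 12.0
        res = m.landmark_analysis(fit.model, cohort, [L], min_timepoints=2)[0]
        for r in res.records:
            clin = cohort.clinical[r.patient_id]
            assert r.time == pytest.approx(clin.ttp_months - L)
            assert clin.ttp_months > L

    def test_landmark_beyond_follow_up_not_evaluable(self, fitted_four_cluster):
        fit, cohort, _ = fitted_four_cluster
        res = m.landmark_analysis(fit.model, cohort, [10000.0])[0]
        assert not res.evaluable and res.logrank_p is None

    def test_unmet_minimum_rule_drops_everyone(self, fitted_four_cluster):
        fit, cohort, _ = fitted_four_cluster
        res = m.landmark_analysis(fit.model, cohort, [1.0], min_timepoints=5)[0]
        assert not res.evaluable and len(res.labels) == 0
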