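"""Survival stack: risk groups, KM, logrank (vs manual/permutation), BH."""

import numpy as np
import pandas as pd
import pytest

from tmagleason.survival import (
    bh_correction,
    kaplan_meier,
    logrank_test,
    risk_group,
    stratification_report,
)


def manual_logrank_statistic(times, events, groups):
    """Textbook observed-minus-expected logrank chi-square (group 0 vs 1)."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups, int)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


class TestRiskGroup:
    @pytest.mark.parametrize("score,group", [
        (0, "low"), (6, "low"), (7, "intermediate"),
        (8, "high"), (9, "high"), (10, "high"),
    ])
    def test_tier_assignment(self, score, group):
        assert risk_group(score) == group


class TestKaplanMeier:
    def test_no_events_flat_at_one(self):
        curve = kaplan_meier([5, 8, 12], [0, 0, 0])
        assert np.allclose(curve.survival, 1.0)

    def test_hand_product_limit_example(self):
        # event at 1 (n=3), censored at 2, event at 3 (n=1)
        curve = kaplan_meier([1, 2, 3], [1, 0, 1])
        assert curve.at(1) == pytest.approx(2 / 3)
        assert curve.at(2.5) == pytest.approx(2 / 3)
        assert curve.at(3) == pytest.approx(0.0)

    def test_duplicating_records_leaves_curve_unchanged(self):
        t = [2, 4, 4, 7, 9]
        e = [1, 0, 1, 1, 0]
        c1 = kaplan_meier(t, e)
        c2 = kaplan_meier(t * 2, e * 2)
        for q in (2, 4, 7, 9):
            assert c1.at(q) == pytest.approx(c2.at(q))

    def test_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(10, size=60)
        curve = kaplan_meier(t, np.ones(60, int))
        for q in np.quantile(t, [0.2, 0.5, 0.8]):
            assert curve.at(q) == pytest.approx((t > q).mean(), abs=1e-9)

    def test_bands_contain_estimate(self):
        rng = np.random.default_rng(1)
        t = rng.exponential(10, size=40)
        e = rng.integers(0, 2, size=40)
        e[0] = 1
        curve = kaplan_meier(t, e)
        assert (curve.ci_lower <= curve.survival + 1e-9).all()
        assert (curve.ci_upper >= curve.survival - 1e-9).all()


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        t = [1, 2, 3, 4]
        e = [1, 1, 0, 1]
        stat, p = logrank_test(t, e, t, e)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_manual_o_minus_e(self):
        ta, ea = [1, 3], [1, 1]
        tb, eb = [2, 4], [1, 0]
        stat, _ = logrank_test(ta, ea, tb, eb)
        manual = manual_logrank_statistic(ta + tb, ea + eb, [0, 0, 1, 1])
        assert stat == pytest.approx(manual, rel=1e-9)

    def test_matches_manual_on_random_data(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            ta = rng.exponential(10, 15)
            tb = rng.exponential(5, 12)
            ea = rng.integers(0, 2, 15)
            eb = rng.integers(0, 2, 12)
            if ea.sum() + eb.sum() == 0:
                continue
            stat, _ = logrank_test(ta, ea, tb, eb)
            manual = manual_logrank_statistic(
                np.concatenate([ta, tb]), np.concatenate([ea, eb]),
                np.r_[np.zeros(15, int), np.ones(12, int)])
            assert stat == pytest.approx(manual, rel=1e-6)

    def test_permutation_reference_agrees(self):
        """Chi-square p is consistent with a label-permutation null."""
        rng = np.random.default_rng(4)
        ta = rng.exponential(12, 20)
        tb = rng.exponential(6, 20)
        ea = np.ones(20, int)
        eb = np.ones(20, int)
        stat, p = logrank_test(ta, ea, tb, eb)
        times = np.concatenate([ta, tb])
        events = np.concatenate([ea, eb])
        groups = np.r_[np.zeros(20, int), np.ones(20, int)]
        count = 0
        n_perm = 1000
        for _ in range(n_perm):
            rng.shuffle(groups)
            if manual_logrank_statistic(times, events, groups) >= stat:
                count += 1
        p_perm = count / n_perm
        assert p_perm == pytest.approx(p, abs=3 * np.sqrt(p * (1 - p) / n_perm)
                                       + 0.01)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            logrank_test([1, 2], [0, 0], [3, 4], [0, 0])

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            logrank_test([], [], [1], [1])


class TestBH:
    def test_hand_example(self):
        adj = bh_correction([0.01, 0.02, 0.03])
        assert np.allclose(adj, [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_correction([0.2])[0] == pytest.approx(0.2)

    def test_adjusted_at_least_raw_and_capped(self):
        rng = np.random.default_rng(5)
        p = rng.random(20)
        adj = bh_correction(p)
        assert (adj >= p - 1e-12).all()
        assert (adj <= 1.0).all()
        # monotone in the ranked order
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_correction([0.5, 1.2])


class TestStratificationReport:
    def _cohort_tables(self, seed, n=120, ratio=3.0):
        from tmagleason.synthetic import HazardParams, generate_cohort

        cohort = generate_cohort(n, rng_seed=seed, spot_size_px=300,
                                 hazard=HazardParams(ratio=ratio))
        clin = cohort.clinical
        assignments = clin[["spot_id", "true_score"]].rename(
            columns={"true_score": "score"})
        return assignments, clin[["spot_id", "time_months", "event"]]

    def test_record_count_equals_joined_rows(self):
        assignments, clinical = self._cohort_tables(seed=0)
        report = stratification_report(assignments, clinical)
        assert report.n_records == len(assignments)
        assert sum(report.group_sizes.values()) == len(assignments)

    def test_strong_hazard_separates_low_and_high(self):
        assignments, clinical = self._cohort_tables(seed=1, n=200, ratio=4.0)
        report = stratification_report(assignments, clinical)
        row = report.pairwise.query(
            "group_a == 'low' and group_b == 'high'").iloc[0]
        assert row["p_adj"] < 0.05

    def test_empty_group_reported_unavailable(self):
        assignments = pd.DataFrame({"spot_id": ["a", "b"], "score": [6, 6]})
        clinical = pd.DataFrame({"spot_id": ["a", "b"],
                                 "time_months": [5.0, 9.0], "event": [1, 0]})
        report = stratification_report(assignments, clinical)
        assert report.group_sizes["high"] == 0
        assert report.pairwise["p"].isna().all()
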