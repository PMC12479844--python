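import itertools

import numpy as np
import pytest

from pombescreen import (
    SurvivalSeries,
    auc_difference,
    compare_lifespans,
    logrank_test,
    survival_auc,
    viability_curve,
)
from pombescreen.simulate import gen_cls_experiment


class TestSurvivalSeries:
    def test_days_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            SurvivalSeries("c", [0, 2, 1], [[10, 5, 2]])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            SurvivalSeries("c", [0, 1], [[10, -1]])

    def test_viability_arithmetic(self):
        s = SurvivalSeries("c", [0, 3], [[400, 100]])
        assert s.viability()[0, 1] == pytest.approx(25.0)

    def test_day_zero_is_always_100(self):
        rng = np.random.default_rng(0)
        cfu = rng.integers(50, 500, (4, 5)).astype(float)
        s = SurvivalSeries("c", np.arange(5), cfu)
        assert np.allclose(s.viability()[:, 0], 100.0)

    def test_zero_day0_replicate_dropped(self):
        s = SurvivalSeries("c", [0, 1], [[0, 0], [100, 50]])
        with pytest.warns(UserWarning, match="CFU_0"):
            v = s.viability()
        assert v.shape == (1, 2)

    def test_flat_counts_give_flat_curve(self):
        s = SurvivalSeries("c", np.arange(4), [[200] * 4, [300] * 4])
        curve = viability_curve(s)
        assert np.allclose(curve["mean_viability"], 100.0)

    def test_roundtrip_from_dataframe(self):
        series, _ = gen_cls_experiment(lambda_by_condition={"x": 3.0}, seed=5)
        s = series["x"]
        import pandas as pd

        rows = []
        for r in range(s.n_replicates):
            bio, tech = divmod(r, s.n_technical)
            for d, c in zip(s.days, s.cfu[r]):
                rows.append(("x", bio + 1, tech + 1, d, c))
        df = pd.DataFrame(rows, columns=["condition", "biological_rep", "technical_rep", "day", "cfu"])
        back = SurvivalSeries.from_dataframe(df)
        assert np.allclose(back.cfu, s.cfu)

    def test_exponential_decay_recovered_in_expectation(self):
        """With Weibull shape k=1 the mean viability tracks 100 exp(-t/lambda)."""
        lam, n0 = 4.0, 2000
        series, _ = gen_cls_experiment(
            n0=n0, lambda_by_condition={"c": lam}, k=1.0, n_technical=3, n_biological=3, seed=8
        )
        curve = viability_curve(series["c"])
        expected = 100 * np.exp(-curve["day"] / lam)
        # Poisson error on the mean of 9 replicate series
        se = 100 * np.sqrt(np.maximum(n0 * np.exp(-curve["day"] / lam), 1)) / n0 / 3
        assert np.all(np.abs(curve["mean_viability"] - expected) < 5 * se + 0.5)


def _grouped_stat_oracle(counts_a, counts_b):
    """Independent longhand grouped log-rank chi-square (loops, no numpy)."""
    ca = [sum(col) for col in zip(*counts_a)]
    cb = [sum(col) for col in zip(*counts_b)]
    O = E = V = 0.0
    for i in range(1, len(ca)):
        n1, n2 = ca[i - 1], cb[i - 1]
        e1 = max(0, ca[i - 1] - ca[i])
        e2 = max(0, cb[i - 1] - cb[i])
        d, n = e1 + e2, n1 + n2
        if d == 0 or n <= 1:
            continue
        O += e1
        E += d * n1 / n
        V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V if V > 0 else 0.0


class TestLogRank:
    A = [[50, 40, 28, 18, 9], [48, 36, 30, 16, 11], [52, 42, 26, 20, 8]]
    B = [[50, 45, 38, 30, 24], [49, 44, 40, 33, 26], [51, 47, 36, 31, 22]]

    def _series(self, counts, name):
        return SurvivalSeries(name, np.arange(len(counts[0])), np.array(counts, float))

    def test_series_vs_itself_is_null(self):
        a = self._series(self.A, "a")
        res = logrank_test(a, a)
        assert res.chi_square == 0.0 and res.p_value == 1.0

    def test_label_swap_symmetry(self):
        a, b = self._series(self.A, "a"), self._series(self.B, "b")
        r1, r2 = logrank_test(a, b), logrank_test(b, a)
        assert r1.chi_square == pytest.approx(r2.chi_square)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_observed_equals_expected_total(self):
        a, b = self._series(self.A, "a"), self._series(self.B, "b")
        res = logrank_test(a, b)
        assert res.observed.sum() == pytest.approx(res.expected.sum())

    def test_permutation_p_matches_exhaustive_oracle(self):
        """Enumerating all replicate-label assignments longhand reproduces p."""
        a, b = self._series(self.A, "a"), self._series(self.B, "b")
        res = logrank_test(a, b)  # C(6,3)=20 -> exact enumeration
        assert res.method == "exact"
        pooled = self.A + self.B
        obs = _grouped_stat_oracle(self.A, self.B)
        assert res.chi_square == pytest.approx(obs)
        stats = []
        for combo in itertools.combinations(range(6), 3):
            ga = [pooled[i] for i in combo]
            gb = [pooled[i] for i in range(6) if i not in combo]
            stats.append(_grouped_stat_oracle(ga, gb))
        p_oracle = sum(s >= obs - 1e-12 for s in stats) / len(stats)
        assert res.p_value == pytest.approx(p_oracle)

    def test_monte_carlo_agrees_with_exact(self):
        a, b = self._series(self.A, "a"), self._series(self.B, "b")
        exact = logrank_test(a, b)
        mc = logrank_test(a, b, method="permutation", n_permutations=4000, seed=3)
        assert abs(mc.p_value - exact.p_value) < 0.05

    def test_asymptotic_matches_lifelines_on_cohort_counts(self):
        """Dual route: expanding monotone counts to individual survival times
        and running an established log-rank gives the same chi-square."""
        lifelines_stats = pytest.importorskip("lifelines.statistics")
        ca = [30, 20, 10, 5]
        cb = [30, 25, 20, 15]
        days = [0, 1, 2, 3]

        def expand(counts):
            durations, events = [], []
            for i in range(1, len(counts)):
                deaths = counts[i - 1] - counts[i]
                durations += [days[i]] * deaths
                events += [1] * deaths
            durations += [days[-1]] * counts[-1]
            events += [0] * counts[-1]
            return durations, events

        da, ea = expand(ca)
        db, eb = expand(cb)
        ll = lifelines_stats.logrank_test(da, db, event_observed_A=ea, event_observed_B=eb)
        ours = logrank_test(
            SurvivalSeries("a", days, [ca]), SurvivalSeries("b", days, [cb]),
            method="asymptotic",
        )
        assert ours.chi_square == pytest.approx(ll.test_statistic)
        assert ours.p_asymptotic == pytest.approx(ll.p_value)

    def test_no_events_flagged(self):
        a = SurvivalSeries("a", [0, 1], [[100, 100]])
        b = SurvivalSeries("b", [0, 1], [[100, 100]])
        res = logrank_test(a, b)
        assert res.chi_square == 0.0 and res.p_value == 1.0 and res.flag == "no_events"


class TestAuc:
    def test_triangle(self):
        s = SurvivalSeries("t", [0, 1], [[400, 0]])
        assert survival_auc(s, n_boot=10, seed=0).auc == pytest.approx(50.0)

    def test_flat_rectangle(self):
        s = SurvivalSeries("t", np.arange(5), [[100] * 5])
        assert survival_auc(s, n_boot=10, seed=0).auc == pytest.approx(400.0)

    def test_single_timepoint_is_error(self):
        with pytest.raises(ValueError, match="two time points"):
            survival_auc(SurvivalSeries("t", [0], [[100]]))

    def test_collinear_day_insertion_invariance(self):
        base = SurvivalSeries("t", [0, 2, 4], [[100, 80, 60]])
        dense = SurvivalSeries("t", [0, 1, 2, 4], [[100, 90, 80, 60]])
        assert survival_auc(base, n_boot=5, seed=0).auc == pytest.approx(
            survival_auc(dense, n_boot=5, seed=0).auc
        )

    def test_longer_lifespan_gives_larger_auc(self):
        """lambda_treated = 2 x lambda_control separates AUCs almost surely."""
        rng = np.random.default_rng(17)
        wins = 0
        n_sims = 200
        for _ in range(n_sims):
            series, _ = gen_cls_experiment(
                n0=500,
                lambda_by_condition={"control": 2.5, "treated": 5.0},
                k=1.0,
                seed=int(rng.integers(2**31)),
            )
            auc_c = survival_auc(series["control"], n_boot=2, seed=0).auc
            auc_t = survival_auc(series["treated"], n_boot=2, seed=0).auc
            wins += auc_t > auc_c
        assert wins / n_sims >= 0.95


class TestCompareLifespans:
    def test_identical_conditions_are_null(self):
        s, _ = gen_cls_experiment(lambda_by_condition={"a": 3.0}, seed=2)
        twin = SurvivalSeries("b", s["a"].days, s["a"].cfu.copy())
        report = compare_lifespans([s["a"], twin], n_boot=300, seed=0)
        row = report.iloc[0]
        assert row.p_value == 1.0
        assert row.delta_auc_ci_low <= 0 <= row.delta_auc_ci_high

    def test_three_conditions_give_two_contrasts(self):
        series, _ = gen_cls_experiment(
            lambda_by_condition={"ref": 3.0, "b": 4.0, "c": 5.0}, seed=3
        )
        report = compare_lifespans(list(series.values()), reference="ref", n_boot=50, seed=0)
        assert len(report) == 2
        assert set(report.condition) == {"b", "c"}

    def test_delta_auc_ordering_matches_injected_lifespans(self):
        series, _ = gen_cls_experiment(
            n0=1000, lambda_by_condition={"ref": 2.0, "mid": 4.0, "long": 6.0}, seed=4
        )
        report = compare_lifespans(list(series.values()), reference="ref", n_boot=50, seed=0)
        by_cond = report.set_index("condition")["delta_auc"]
        assert 0 < by_cond["mid"] < by_cond["long"]
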