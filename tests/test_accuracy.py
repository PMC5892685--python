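import numpy as np
import pandas as pd
import pytest

from methylsurv.accuracy import (
    binary_auc,
    brier_curve,
    harrell_c,
    time_dependent_auc,
)


def brute_force_c(time, event, risk):
    """O(n^2) oracle: pairs comparable when the earlier time is an event."""
    n = len(time)
    num = den = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if time[i] == time[j]:
                continue
            a, b = (i, j) if time[i] < time[j] else (j, i)
            if not event[a]:
                continue
            den += 1
            if risk[a] > risk[b]:
                num += 1
            elif risk[a] == risk[b]:
                num += 0.5
    return num / den if den else np.nan


class TestHarrellC:
    def test_perfect_ranking(self):
        res = harrell_c([1, 2, 3], [1, 1, 1], [3, 2, 1])
        assert res.c == 1.0

    def test_all_tied_risks(self):
        res = harrell_c([1, 2, 3], [1, 1, 1], [1, 1, 1])
        assert res.c == 0.5

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(40):
            n = rng.integers(5, 50)
            time = rng.integers(1, 10, n).astype(float)
            event = rng.integers(0, 2, n)
            risk = rng.integers(0, 5, n).astype(float)
            if not event.any():
                continue
            expect = brute_force_c(time, event, risk)
            if np.isnan(expect):
                continue
            assert harrell_c(time, event, risk).c == pytest.approx(expect, abs=1e-12)

    def test_complement_symmetry_tie_free(self):
        rng = np.random.default_rng(4)
        time = rng.permutation(np.arange(1.0, 31.0))
        event = rng.integers(0, 2, 30)
        event[0] = 1
        risk = rng.normal(size=30)
        a = harrell_c(time, event, risk).c
        b = harrell_c(time, event, -risk).c
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        time = rng.exponential(5, 40)
        event = rng.integers(0, 2, 40)
        event[:5] = 1
        risk = rng.normal(size=40)
        a = harrell_c(time, event, risk)
        b = harrell_c(time, event, np.exp(risk))
        assert a.c == b.c
        assert a.se == pytest.approx(b.se)

    def test_ci_shrinks_with_n(self):
        rng = np.random.default_rng(6)

        def width(n):
            t = rng.exponential(5, n)
            e = np.ones(n, int)
            r = -t + rng.normal(0, 3, n)
            res = harrell_c(t, e, r)
            return res.ci_high - res.ci_low

        assert width(400) < width(50)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError, match="comparable"):
            harrell_c([5.0, 5.0], [1, 1], [1.0, 2.0])

    def test_agrees_with_scikit_survival(self):
        sksurv = pytest.importorskip("sksurv.metrics")
        rng = np.random.default_rng(7)
        t = rng.exponential(5, 200)
        e = rng.integers(0, 2, 200).astype(bool)
        e[:10] = True
        r = -t + rng.normal(0, 4, 200)
        mine = harrell_c(t, e.astype(int), r).c
        ref = sksurv.concordance_index_censored(e, t, r)[0]
        assert mine == pytest.approx(ref, abs=1e-10)


class TestBinaryAUC:
    def test_perfect_separation(self):
        assert binary_auc([0, 0, 1, 1], [1, 2, 3, 4]) == 1.0

    def test_constant_score(self):
        assert binary_auc([0, 1, 0, 1], [2, 2, 2, 2]) == 0.5

    def test_hand_pair_count_with_tie(self):
        # cases (2, 3) vs controls (1, 2): (1 + 0.5 + 1 + 1)/4
        assert binary_auc([1, 1, 0, 0], [2, 3, 1, 2]) == pytest.approx(0.875)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            binary_auc([1, 1], [0.2, 0.4])


class TestBrier:
    def test_censoring_free_equals_plain_brier(self):
        rng = np.random.default_rng(8)
        n = 100
        t = rng.exponential(5, n)
        e = np.ones(n, int)
        grid = np.array([1.0, 3.0, 5.0])
        S = pd.DataFrame(
            rng.uniform(size=(3, n)), index=grid, columns=range(n)
        )
        out = brier_curve(grid, t, e, S)
        for tt in grid:
            plain = np.mean(((t > tt).astype(float) - S.loc[tt].to_numpy()) ** 2)
            assert out.loc[tt] == pytest.approx(plain, abs=1e-12)

    def test_two_subject_worked_example(self):
        t = np.array([1.0, 5.0])
        e = np.array([1, 1])
        S = pd.DataFrame({0: [0.3], 1: [0.8]}, index=[2.0])
        out = brier_curve([2.0], t, e, S)
        assert out.loc[2.0] == pytest.approx(0.065, abs=1e-12)

    def test_oracle_predictor_zero_error(self):
        rng = np.random.default_rng(9)
        n = 50
        t = rng.exponential(5, n)
        e = np.ones(n, int)
        grid = np.array([2.0, 4.0])
        S = pd.DataFrame(
            {i: [(t[i] > g) * 1.0 for g in grid] for i in range(n)}, index=grid
        )
        out = brier_curve(grid, t, e, S)
        assert np.allclose(out, 0.0)

    def test_matches_scikit_survival_under_censoring(self):
        sksurv = pytest.importorskip("sksurv.metrics")
        rng = np.random.default_rng(10)
        n = 300
        t = rng.exponential(8, n)
        c = rng.exponential(12, n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        grid = np.array([2.0, 5.0, 8.0])
        S = pd.DataFrame(rng.uniform(0.2, 0.9, size=(3, n)), index=grid)
        mine = brier_curve(grid, time, event, S)
        y = np.array([(bool(e), tt) for e, tt in zip(event, time)],
                     dtype=[("event", bool), ("time", float)])
        _, ref = sksurv.brier_score(y, y, S.to_numpy().T, grid)
        assert np.allclose(mine.to_numpy(), ref, atol=1e-10)

    def test_grid_beyond_support_truncated(self):
        t = np.array([1.0, 2.0, 3.0])
        e = np.array([1, 0, 0])
        S = pd.DataFrame(np.full((2, 3), 0.5), index=[1.5, 10.0])
        with pytest.warns(UserWarning, match="truncated"):
            out = brier_curve([1.5, 10.0], t, e, S)
        assert 10.0 not in out.index


class TestTimeDependentAUC:
    def test_perfect_separation_gives_one(self):
        t = np.array([1.0, 2.0, 8.0, 9.0])
        e = np.array([1, 1, 0, 0])
        r = np.array([4.0, 3.0, 2.0, 1.0])
        out = time_dependent_auc([5.0], t, e, r)
        assert out.loc[5.0] == 1.0

    def test_censoring_free_limit_is_binary_auc(self):
        rng = np.random.default_rng(11)
        n = 200
        t = rng.exponential(5, n)
        e = np.ones(n, int)
        r = rng.normal(size=n)
        for tt in (2.0, 5.0):
            out = time_dependent_auc([tt], t, e, r)
            assert out.loc[tt] == pytest.approx(binary_auc((t <= tt).astype(int), r))

    def test_null_risk_near_half(self):
        rng = np.random.default_rng(12)
        n = 3000
        t = rng.exponential(8, n)
        c = rng.exponential(20, n)
        time = np.minimum(t, c)
        event = (t <= c).astype(int)
        r = rng.normal(size=n)  # independent of outcome
        out = time_dependent_auc([5.0], time, event, r)
        assert abs(out.loc[5.0] - 0.5) < 0.03

    def test_degenerate_split_rejected(self):
        t = np.array([1.0, 2.0])
        e = np.array([1, 1])
        with pytest.raises(ValueError, match="degenerate"):
            time_dependent_auc([5.0], t, e, np.array([1.0, 2.0]))
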