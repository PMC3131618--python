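"""Statistical battery: exactness, identities, stepwise behavior."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, t as t_dist

from itsmorph.stats import (
    correlation_matrix,
    forward_stepwise,
    group_percent_difference,
    mann_whitney_u,
    partial_correlation,
)


def enumeration_p(a, b):
    """Oracle: exact two-tailed p by enumerating all rank assignments."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = rankdata(pooled)
    obs_u = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    lo = hi = tot = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        tot += 1
        lo += u <= obs_u
        hi += u >= obs_u
    return min(1.0, 2 * min(lo / tot, hi / tot))


class TestMannWhitney:
    def test_separated_samples_exact_example(self):
        U, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert U == 0
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_p_one(self):
        _, p = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_degenerate_pooled_sample_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            mann_whitney_u([2, 2], [2, 2])

    def test_exact_path_matches_enumeration_all_small_sizes(self):
        rng = np.random.default_rng(12345)
        for n1 in range(1, 8):
            for n2 in range(1, 8):
                a = rng.normal(size=n1)
                b = rng.normal(size=n2)
                U, p = mann_whitney_u(a, b)
                assert mann_whitney_u.last_method == "exact"
                assert p == pytest.approx(enumeration_p(a, b), abs=1e-12), (n1, n2)

    def test_shifted_gaussians_detected(self):
        rng = np.random.default_rng(42)
        a = rng.normal(0, 1, 26)
        b = rng.normal(1, 1, 31)
        _, p = mann_whitney_u(a, b)
        assert p < 0.01
        assert mann_whitney_u.last_method == "normal-tie-corrected"


class TestCorrelation:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        tab = pd.DataFrame({"x": x, "y": 2 * x})
        rep = correlation_matrix(tab, targets=["y"])
        assert rep.iloc[0]["r"] == pytest.approx(1.0)
        assert rep.iloc[0]["flag"] == "<.001"

    def test_independent_variables_near_zero(self):
        rng = np.random.default_rng(8)
        tab = pd.DataFrame({"x": rng.normal(size=1000), "y": rng.normal(size=1000)})
        rep = correlation_matrix(tab, targets=["y"])
        assert abs(rep.iloc[0]["r"]) < 3.3 / np.sqrt(1000)

    def test_flag_thresholds_match_t_distribution(self):
        # construct a sample whose p sits between .001 and .01
        n = 50
        for r_target in (0.36, 0.40):
            t_stat = r_target * np.sqrt((n - 2) / (1 - r_target**2))
            p = 2 * t_dist.sf(t_stat, n - 2)
            if 0.001 < p < 0.01:
                break
        rng = np.random.default_rng(0)
        for _ in range(50):
            x = rng.normal(size=n)
            y = r_target * x + np.sqrt(1 - r_target**2) * rng.normal(size=n)
            r_emp = np.corrcoef(x, y)[0, 1]
            t_emp = r_emp * np.sqrt((n - 2) / (1 - r_emp**2))
            p_emp = 2 * t_dist.sf(abs(t_emp), n - 2)
            if 0.002 < p_emp < 0.009:
                tab = pd.DataFrame({"x": x, "y": y})
                rep = correlation_matrix(tab, targets=["y"])
                assert rep.iloc[0]["flag"] == "<.01"
                assert rep.iloc[0]["p"] == pytest.approx(p_emp, rel=1e-9)
                return
        pytest.fail("could not construct a sample in the target p band")

    def test_constant_column_rejected(self):
        tab = pd.DataFrame({"x": [1.0, 1.0, 1.0, 1.0], "y": [1, 2, 3, 4.0]})
        with pytest.raises(ValueError, match="constant"):
            correlation_matrix(tab, targets=["y"])


class TestPartialCorrelation:
    def test_reduces_to_plain_correlation_when_control_orthogonal(self):
        rng = np.random.default_rng(3)
        z = rng.normal(size=200)
        z -= z.mean()
        x = rng.normal(size=200)
        y = 0.5 * x + rng.normal(size=200)
        # center, then project out z, so sample correlations with z vanish
        for v in (x, y):
            v -= v.mean()
            v -= (v @ z) / (z @ z) * z
        r_partial = partial_correlation(x, y, z)
        assert r_partial == pytest.approx(np.corrcoef(x, y)[0, 1], abs=1e-12)

    def test_collinear_control_rejected(self):
        y = np.arange(10.0)
        with pytest.raises(ValueError, match="collinear"):
            partial_correlation(np.random.default_rng(0).normal(size=10), y, y)

    def test_confounded_association_vanishes(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=500)
        x = 2 * z + 0.5 * rng.normal(size=500)
        y = -3 * z + 0.5 * rng.normal(size=500)
        assert abs(np.corrcoef(x, y)[0, 1]) > 0.8
        assert abs(partial_correlation(x, y, z)) < 0.1

    def test_identity_equals_residual_correlation(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            x, y, z = rng.normal(size=(3, 60))
            r_id = partial_correlation(x, y, z)

            def resid(v):
                A = np.vstack([np.ones_like(z), z]).T
                beta = np.linalg.lstsq(A, v, rcond=None)[0]
                return v - A @ beta

            r_res = np.corrcoef(resid(x), resid(y))[0, 1]
            assert r_id == pytest.approx(r_res, abs=1e-12)


class TestStepwise:
    def test_recovers_true_predictors_first(self):
        rng = np.random.default_rng(7)
        X = pd.DataFrame(
            rng.normal(size=(200, 10)), columns=[f"v{i}" for i in range(10)]
        )
        y = 3 * X["v2"] + 2 * X["v7"] + 0.5 * rng.normal(size=200)
        res = forward_stepwise(X, y, alpha_enter=0.05)
        assert set(res.predictors[:2]) == {"v2", "v7"}
        assert res.adjusted_r > 0.95

    def test_alpha_zero_gives_empty_model(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        res = forward_stepwise(X, rng.normal(size=50), alpha_enter=0.0)
        assert res.predictors == []
        assert res.adjusted_r == 0.0

    def test_orthonormal_predictors_enter_by_marginal_correlation(self):
        rng = np.random.default_rng(9)
        raw = rng.normal(size=(64, 4))
        Q, _ = np.linalg.qr(raw - raw.mean(0))
        X = pd.DataFrame(Q, columns=list("abcd"))
        y = 0.9 * Q[:, 2] + 0.5 * Q[:, 0] + 0.2 * Q[:, 3] + 0.05 * rng.normal(size=64)
        res = forward_stepwise(X, y, alpha_enter=1.0)
        marg = [abs(np.corrcoef(Q[:, i], y)[0, 1]) for i in range(4)]
        expected = [list("abcd")[i] for i in np.argsort(marg)[::-1]]
        assert res.predictors == expected

    def test_false_entry_rate_near_alpha(self):
        # pure-noise candidates: the step-one entry is a size-alpha test
        rng = np.random.default_rng(11)
        alpha, entries, reps = 0.05, 0, 400
        for _ in range(reps):
            X = pd.DataFrame(rng.normal(size=(30, 1)), columns=["a"])
            res = forward_stepwise(X, rng.normal(size=30), alpha_enter=alpha)
            entries += bool(res.predictors)
        rate = entries / reps
        assert abs(rate - alpha) < 3 * np.sqrt(alpha * (1 - alpha) / reps)


class TestPercentDifference:
    @pytest.mark.parametrize(
        "ctrl,iop,direction,expected",
        [
            (0.053, 0.031, "lower", 42),
            (1.0, 1.0, "lower", 0),
            (0.689, 0.736, "higher", 7),
            (0.171, 0.132, "lower", 23),
        ],
    )
    def test_examples(self, ctrl, iop, direction, expected):
        assert group_percent_difference(ctrl, iop, direction) == expected

    def test_rounds_half_away_from_zero(self):
        assert group_percent_difference(200.0, 115.0, "lower") == 43  # 42.5 -> 43

    def test_nonpositive_control_rejected(self):
        with pytest.raises(ValueError):
            group_percent_difference(0.0, 1.0, "lower")
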