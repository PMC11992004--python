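import itertools

import numpy as np
import pandas as pd
import pytest

from dendritemp.core import DistanceMatrix, ValidationError
from dendritemp.inference import (
    benjamini_hochberg,
    centroid_distance,
    nmds,
    ols,
    partial_regression,
    permanova,
)


def ols_oracle(y, x):
    """Closed-form normal equations (XᵀX)⁻¹Xᵀy with intercept."""
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return beta[1], beta[0]


def permanova_oracle_F(D, codes):
    """Gower-centered partition: F from the explicit N x N centering."""
    n = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    ss_total = np.trace(G)
    groups = np.unique(codes)
    a = len(groups)
    # hat matrix of the one-way design
    X = np.column_stack([(codes == g).astype(float) for g in groups])
    H = X @ np.linalg.inv(X.T @ X) @ X.T
    ss_among = np.trace(H @ G @ H)
    ss_within = ss_total - ss_among
    return (ss_among / (a - 1)) / (ss_within / (n - a))


class TestOls:
    def test_exact_line(self):
        x = np.array([0.0, 1, 2, 3, 4])
        r = ols(2 * x + 1, x)
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_constant_response(self):
        r = ols(np.full(5, 3.0), np.arange(5.0))
        assert r.slope == 0.0 and r.r_squared == 0.0 and not r.significant

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValidationError):
            ols(np.arange(5.0), np.full(5, 1.0))

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(size=13)
            y = rng.normal(size=13)
            r = ols(y, x)
            slope, intercept = ols_oracle(y, x)
            assert r.slope == pytest.approx(slope, abs=1e-10)
            assert r.intercept == pytest.approx(intercept, abs=1e-10)


class TestPartialRegression:
    def test_y_function_of_covariate_leaves_nothing(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=20)
        y = 3 * z - 1
        x = rng.normal(size=20)
        r = partial_regression(y, x, z)
        # y-residuals are zero to machine epsilon: no slope, nothing significant
        assert abs(r.slope) < 1e-10 and not r.significant

    def test_orthogonal_covariate_matches_simple_ols(self):
        # x and y constructed orthogonal to z: residuals equal the originals
        z = np.array([1.0, -1, 1, -1, 1, -1])
        x = np.array([1.0, 1, -1, -1, 2, 2])  # sum(x*z)=0, mean-balanced vs z
        y = np.array([0.5, 0.5, 2.0, 2.0, -1.0, -1.0])
        rp = partial_regression(y, x, z)
        rs = ols(y, x)
        assert rp.slope == pytest.approx(rs.slope, abs=1e-10)
        assert rp.r_squared == pytest.approx(rs.r_squared, abs=1e-10)


class TestPermanova:
    def _matrix(self, n, rng):
        x = rng.normal(size=(n, 3))
        D = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        return DistanceMatrix(tuple(f"s{i}" for i in range(n)), D)

    def test_hand_partition(self):
        # two groups of 2: within d = 0.1, between d = 1
        vals = np.full((4, 4), 1.0)
        np.fill_diagonal(vals, 0.0)
        vals[0, 1] = vals[1, 0] = 0.1
        vals[2, 3] = vals[3, 2] = 0.1
        D = DistanceMatrix(("a", "b", "c", "d"), vals)
        res = permanova(D, {"a": "g1", "b": "g1", "c": "g2", "d": "g2"},
                        n_perm=99, seed=0)
        # SS_total = (0.01 + 0.01 + 4)/4 = 1.005; SS_within = 0.01; F = 199
        assert res.pseudo_F == pytest.approx(199.0, abs=1e-10)
        assert res.df_among == 1 and res.df_within == 2

    def test_group_of_one_rejected(self):
        rng = np.random.default_rng(2)
        D = self._matrix(4, rng)
        with pytest.raises(ValidationError):
            permanova(D, ["g1", "g2", "g2", "g2"], n_perm=9)

    def test_p_value_grid_and_minimum(self):
        rng = np.random.default_rng(3)
        D = self._matrix(8, rng)
        res = permanova(D, ["a"] * 4 + ["b"] * 4, n_perm=999, seed=0)
        grid = np.arange(1, 1001) / 1000
        assert np.any(np.isclose(res.p_value, grid))
        assert res.p_value >= 1 / 1000

    def test_matches_gower_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            D = self._matrix(12, rng)
            codes = rng.integers(0, 3, 12)
            while np.bincount(codes, minlength=3).min() < 2:
                codes = rng.integers(0, 3, 12)
            res = permanova(D, [f"g{c}" for c in codes], n_perm=9, seed=0)
            assert res.pseudo_F == pytest.approx(
                permanova_oracle_F(D.values, codes), abs=1e-10)

    def test_pseudo_F_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(8)
        D = self._matrix(10, rng)
        groups = ["a"] * 5 + ["b"] * 5
        mine = permanova(D, groups, n_perm=9, seed=0)
        theirs = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(D.values, ids=list(D.labels)),
            grouping=groups, permutations=9)
        assert mine.pseudo_F == pytest.approx(theirs["test statistic"], abs=1e-10)

    def test_exact_enumeration_matches_independent_oracle(self):
        rng = np.random.default_rng(5)
        D = self._matrix(6, rng)
        codes = np.array([0, 0, 0, 1, 1, 1])
        res = permanova(D, [f"g{c}" for c in codes], method="exact")
        # independent enumeration of all distinct labelings
        F_obs = permanova_oracle_F(D.values, codes)
        seen = set()
        hits = total = 0
        for perm in itertools.permutations(codes):
            if perm in seen:
                continue
            seen.add(perm)
            total += 1
            if permanova_oracle_F(D.values, np.array(perm)) >= F_obs - 1e-12:
                hits += 1
        assert res.p_value == pytest.approx(hits / total, abs=1e-12)
        assert res.n_permutations == total == 20


class TestNmds:
    def _line(self, n=8):
        x = np.arange(n, dtype=float)
        D = np.abs(x[:, None] - x[None, :])
        return DistanceMatrix(tuple(f"s{i}" for i in range(n)), D)

    def test_embeddable_input_low_stress(self):
        res = nmds(self._line(), k=2, n_restarts=5, seed=0)
        assert res.stress < 0.01

    def test_seeded_determinism_bit_exact(self):
        a = nmds(self._line(), k=2, n_restarts=5, seed=3)
        b = nmds(self._line(), k=2, n_restarts=5, seed=3)
        assert np.array_equal(a.coordinates.to_numpy(), b.coordinates.to_numpy())
        assert a.stress == b.stress

    def test_stress_history_non_increasing(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(12, 4))
        D = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
        res = nmds(DistanceMatrix(tuple(f"s{i}" for i in range(12)), D),
                   k=2, n_restarts=3, seed=1)
        h = res.stress_history
        assert all(b <= a + 1e-7 for a, b in zip(h, h[1:]))

    def test_reported_stress_is_best_of_restarts(self):
        res = nmds(self._line(), k=2, n_restarts=6, seed=2)
        assert res.stress <= min(res.restart_stresses) + 1e-15

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            nmds(self._line(3), k=2)


class TestCentroids:
    def test_hand_value(self):
        coords = pd.DataFrame({"NMDS1": [0, 0, 3, 5], "NMDS2": [0, 2, 1, 1]},
                              index=["a", "b", "c", "d"])
        out = centroid_distance(coords, {"a": "A", "b": "A", "c": "B", "d": "B"})
        assert out.loc["A", "B"] == pytest.approx(4.0)

    def test_identical_clouds_zero(self):
        coords = pd.DataFrame({"NMDS1": [0, 1, 0, 1], "NMDS2": [0, 1, 0, 1]},
                              index=list("abcd"))
        out = centroid_distance(coords, {"a": "A", "b": "A", "c": "B", "d": "B"})
        assert out.loc["A", "B"] == 0.0

    def test_translation_invariance(self):
        rng = np.random.default_rng(7)
        coords = pd.DataFrame(rng.normal(size=(6, 2)), index=list("abcdef"),
                              columns=["NMDS1", "NMDS2"])
        groups = dict(zip("abcdef", "AABBCC"))
        d1 = centroid_distance(coords, groups)
        d2 = centroid_distance(coords + 5.0, groups)
        assert np.allclose(d1.to_numpy(), d2.to_numpy())

    def test_unknown_group_label_rejected(self):
        coords = pd.DataFrame({"NMDS1": [0.0], "NMDS2": [0.0]}, index=["a"])
        with pytest.raises(ValidationError):
            centroid_distance(coords, {"zzz": "A"})


def test_benjamini_hochberg_orders_and_bounds():
    p = np.array([0.001, 0.02, 0.03, 0.5])
    adj = benjamini_hochberg(p)
    assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
    assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-15)
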