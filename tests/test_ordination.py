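import numpy as np
import pandas as pd
import pytest

from trait_seascape import FuzzyTraitTable, coa, fca, mca, pca, weighted_reanalysis
from trait_seascape.ordination import discretize_quantiles
from .conftest import make_fuzzy


def chi2_over_N(table: np.ndarray) -> float:
    """Independent oracle: chi-square/N of a non-negative table."""
    P = table / table.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    tot = 0.0
    for i in range(P.shape[0]):
        for j in range(P.shape[1]):
            e = r[i] * c[j]
            if e > 0:
                tot += (P[i, j] - e) ** 2 / e
    return tot


def frame(arr, prefix=("r", "c")):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, index=[f"{prefix[0]}{i}" for i in range(arr.shape[0])],
                        columns=[f"{prefix[1]}{j}" for j in range(arr.shape[1])])


class TestCoA:
    def test_independence_gives_zero_inertia(self):
        assert coa(frame([[2, 2], [3, 3]])).total_inertia == pytest.approx(0.0, abs=1e-12)

    def test_diagonal_toy(self):
        res = coa(frame([[1, 0], [0, 1]]))
        assert res.total_inertia == pytest.approx(1.0, abs=1e-12)

    def test_matches_chi_square_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            N = rng.integers(0, 8, size=(5, 4)).astype(float)
            if N.sum() == 0 or (N.sum(1) == 0).any() or (N.sum(0) == 0).any():
                continue
            res = coa(frame(N))
            assert res.total_inertia == pytest.approx(chi2_over_N(N), abs=1e-10)
            assert res.eigenvalues.sum() == pytest.approx(res.total_inertia, abs=1e-10)

    def test_zero_row_dropped(self):
        res = coa(frame([[1, 2], [0, 0], [2, 1]]))
        assert len(res.row_scores) == 2

    def test_row_permutation_equivariance(self):
        rng = np.random.default_rng(4)
        N = frame(rng.integers(1, 9, size=(6, 4)))
        res = coa(N)
        perm = rng.permutation(6)
        res_p = coa(N.iloc[perm])
        assert np.allclose(res_p.row_scores.to_numpy(),
                           res.row_scores.iloc[perm].to_numpy(), atol=1e-9)

    def test_axis_orthogonality_in_weighted_metric(self):
        rng = np.random.default_rng(5)
        res = coa(frame(rng.integers(1, 9, size=(7, 5))))
        S = res.row_scores.to_numpy()
        w = res.row_weights.to_numpy()
        G = S.T @ (S * w[:, None])
        assert np.allclose(G, np.diag(res.eigenvalues), atol=1e-10)


class TestMCA:
    def test_two_level_factor_against_oracle(self):
        df = pd.DataFrame({"f": ["a", "b", "a", "b"]}, index=list("wxyz"))
        res = mca(df)
        G = pd.get_dummies(df["f"]).to_numpy(dtype=float)
        assert res.total_inertia == pytest.approx(chi2_over_N(G), abs=1e-12)
        assert len(res.eigenvalues) == 1
        assert np.allclose(np.abs(res.row_scores.to_numpy()[:, 0]), 1.0)

    def test_identical_patterns_zero_inertia(self):
        df = pd.DataFrame({"f": ["a"] * 4, "g": ["u"] * 4}, index=list("wxyz"))
        with pytest.raises(ValueError):
            mca(df)  # both factors collapse to a single level

    def test_classical_inertia_identity(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame({
            "f": rng.choice(["a", "b", "c"], size=30),
            "g": rng.choice(["u", "v"], size=30),
        }, index=[f"s{i}" for i in range(30)])
        res = mca(df)
        n_levels = df["f"].nunique() + df["g"].nunique()
        assert res.total_inertia == pytest.approx(n_levels / 2 - 1, abs=1e-10)

    def test_quantitative_columns_discretized(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"x": rng.normal(size=12)}, index=[f"s{i}" for i in range(12)])
        res = mca(df, n_classes=3)
        assert res.tab.shape[1] == 3
        classes = discretize_quantiles(df["x"], 3)
        assert classes.nunique() == 3


class TestFCA:
    def test_identical_profiles_zero_inertia_flagged(self):
        Q = make_fuzzy({t: {("SD", "0-5"): 1.0, ("MB", "Slow"): 1.0}
                        for t in ("a", "b", "c")})
        res = fca(Q)
        assert res.total_inertia == pytest.approx(0.0, abs=1e-12)
        assert res.meta["zero_inertia"]

    def test_opposite_profiles_symmetric(self):
        Q = make_fuzzy({"a": {("SD", "0"): 1.0}, "b": {("SD", "> 30"): 1.0}})
        res = fca(Q)
        assert len(res.eigenvalues) == 1
        s = res.row_scores.to_numpy()[:, 0]
        assert s[0] == pytest.approx(-s[1], abs=1e-10)

    def test_matches_chi_square_oracle_on_super_table(self):
        rng = np.random.default_rng(8)
        Q = make_fuzzy({
            f"t{i}": {("SD", m1): 1.0, ("MB", m2): 1.0, ("VP", m3): 1.0}
            for i, (m1, m2, m3) in enumerate(zip(
                rng.choice(["0", "0-5", "5-15"], 10),
                rng.choice(["Immobile", "Slow", "Fast"], 10),
                rng.choice(["Null", "Low", "High"], 10)))
        })
        res = fca(Q)
        X = Q.to_profile().data.to_numpy() / 3.0
        assert res.total_inertia == pytest.approx(chi2_over_N(X), abs=1e-10)

    def test_missing_block_rejected(self):
        Q = make_fuzzy({"a": {("SD", "0"): 1.0, ("MB", "Slow"): 1.0},
                        "b": {("SD", "0-5"): 1.0}})
        with pytest.raises(ValueError, match="missing"):
            fca(Q)


class TestWeightedReanalysis:
    @pytest.fixture
    def df(self):
        rng = np.random.default_rng(9)
        return pd.DataFrame({
            "f": rng.choice(["a", "b", "c"], size=8),
            "x": rng.normal(size=8),
        }, index=[f"s{i}" for i in range(8)])

    def test_uniform_weights_identity(self, df):
        res = mca(df)
        w = pd.Series(np.full(8, 1 / 8), index=df.index)
        res_w = weighted_reanalysis(res, w, df)
        assert np.allclose(res.eigenvalues, res_w.eigenvalues, atol=1e-12)

    def test_zero_weight_row_has_no_influence(self, df):
        df = df[["f"]]  # categorical only: discretization is sample-dependent
        w = pd.Series(np.full(8, 1.0), index=df.index)
        w.iloc[3] = 0.0
        res_w = weighted_reanalysis(mca(df), w, df)
        res_drop = mca(df.drop(index="s3"),
                       row_weights=w.drop(index="s3"))
        assert np.allclose(res_w.eigenvalues, res_drop.eigenvalues, atol=1e-10)

    def test_weighted_pca_matches_direct_decomposition(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(4, 3)), index=list("abcd"),
                         columns=["u", "v", "w"])
        w = pd.Series([0.4, 0.3, 0.2, 0.1], index=X.index)
        res = pca(X, row_weights=w)
        # oracle: eigenvalues of the weighted correlation matrix
        Xm = X.to_numpy()
        mu = w.to_numpy() @ Xm
        Z = (Xm - mu)
        sd = np.sqrt(w.to_numpy() @ Z**2)
        Z = Z / sd
        C = (Z * w.to_numpy()[:, None]).T @ Z
        ev = np.sort(np.linalg.eigvalsh(C))[::-1]
        assert np.allclose(res.eigenvalues, ev[: len(res.eigenvalues)], atol=1e-10)

    def test_misaligned_weights_error(self, df):
        res = mca(df)
        bad = pd.Series(np.full(8, 0.125), index=[f"z{i}" for i in range(8)])
        with pytest.raises(ValueError, match="misaligned"):
            weighted_reanalysis(res, bad, df)
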