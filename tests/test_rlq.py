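import itertools

import numpy as np
import pandas as pd
import pytest

from trait_seascape import (
    AbundanceTable,
    EnvironmentTable,
    coa,
    combine_and_adjust,
    fca,
    fourth_corner,
    pca,
    rlq,
    rlq_global_test,
    rlq_pipeline,
    screen_variables,
)
from trait_seascape.rlq import _correlation_ratio, _weighted_corr, axis_correlation_tests
from .conftest import make_fuzzy


def brute_force_rlq_inertia(R_quant: pd.DataFrame, L: pd.DataFrame,
                            Q_profile: pd.DataFrame, n_traits: int) -> float:
    """Oracle: RLQ total inertia from first principles, by explicit loops.

    Standardize env columns under the CA site weights, center fuzzy
    profiles under the CA species weights, accumulate the weighted
    cross-matrix through the cell distribution of L, and sum its
    metric-weighted squared entries.
    """
    A = L.to_numpy(dtype=float)
    P = A / A.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    X = R_quant.to_numpy(dtype=float)
    zR = np.empty_like(X)
    for j in range(X.shape[1]):
        mu = sum(r[i] * X[i, j] for i in range(len(r)))
        sd = np.sqrt(sum(r[i] * (X[i, j] - mu) ** 2 for i in range(len(r))))
        zR[:, j] = (X[:, j] - mu) / sd
    Xq = Q_profile.to_numpy(dtype=float) / n_traits
    cw = np.array([sum(c[l] * Xq[l, k] for l in range(len(c)))
                   for k in range(Xq.shape[1])])
    keep = cw > 0
    Xq, cw = Xq[:, keep], cw[keep]
    zQ = Xq / cw - 1.0
    total = 0.0
    for j in range(zR.shape[1]):
        for k in range(zQ.shape[1]):
            tab_jk = sum(zR[i, j] * P[i, l] * zQ[l, k]
                         for i in range(P.shape[0]) for l in range(P.shape[1]))
            total += 1.0 * cw[k] * tab_jk ** 2
    return total


@pytest.fixture
def six_by_eight():
    rng = np.random.default_rng(21)
    sites = [f"s{i}" for i in range(6)]
    taxa = [f"t{j}" for j in range(8)]
    L = pd.DataFrame(rng.integers(1, 9, size=(6, 8)).astype(float),
                     index=sites, columns=taxa)
    R = pd.DataFrame({"DOX": rng.normal(200, 50, 6), "Depth": rng.normal(80, 30, 6)},
                     index=sites)
    sd_mods = ["0", "0-5", "5-15"]
    mb_mods = ["Immobile", "Slow", "Fast"]
    Q = make_fuzzy({t: {("SD", sd_mods[rng.integers(3)]): 1.0,
                        ("MB", mb_mods[rng.integers(3)]): 1.0} for t in taxa})
    return R, L, Q


class TestRLQDecomposition:
    def test_toy_inertia_matches_brute_force(self, six_by_eight):
        R, L, Q = six_by_eight
        ord_L = coa(L)
        ord_R = pca(R, row_weights=ord_L.row_weights)
        ord_Q = fca(Q, row_weights=ord_L.col_weights)
        res = rlq(ord_R, ord_L, ord_Q)
        oracle = brute_force_rlq_inertia(R, L, Q.to_profile().data, n_traits=2)
        assert res.total_inertia == pytest.approx(oracle, abs=1e-10)
        assert res.eigenvalues.sum() == pytest.approx(res.total_inertia, abs=1e-10)
        assert res.percent_inertia.sum() == pytest.approx(100.0, abs=1e-6)

    def test_constant_traits_zero_inertia(self, six_by_eight):
        R, L, _ = six_by_eight
        Q = make_fuzzy({t: {("SD", "0-5"): 1.0, ("MB", "Slow"): 1.0}
                        for t in L.columns})
        ord_L = coa(L)
        res = rlq(pca(R, row_weights=ord_L.row_weights), ord_L,
                  fca(Q, row_weights=ord_L.col_weights))
        assert res.total_inertia == pytest.approx(0.0, abs=1e-12)

    def test_planted_link_loads_first_axis(self, linked_dataset):
        sc, env, grid, Q, labels, L = linked_dataset
        Qr = Q.subset_traits(["LS", "AM", "FEC", "OP", "OD"])
        res, *_ = rlq_pipeline(env, L.log10p1(), Qr)
        assert res.percent_inertia[0] > 90.0

    def test_misaligned_weights_rejected(self, six_by_eight):
        R, L, Q = six_by_eight
        ord_L = coa(L)
        with pytest.raises(ValueError, match="misaligned"):
            rlq(pca(R), ord_L, fca(Q, row_weights=ord_L.col_weights))

    def test_inertia_invariant_to_relabeling(self, six_by_eight):
        R, L, Q = six_by_eight
        res1, *_ = rlq_pipeline(EnvironmentTable(R), AbundanceTable(L), Q)
        rng = np.random.default_rng(0)
        sp = list(rng.permutation(L.index))
        tp = list(rng.permutation(L.columns))
        res2, *_ = rlq_pipeline(EnvironmentTable(R.loc[sp]),
                                AbundanceTable(L.loc[sp, tp]), Q.subset_taxa(tp))
        assert res1.total_inertia == pytest.approx(res2.total_inertia, abs=1e-10)
        assert res1.percent_inertia[0] == pytest.approx(res2.percent_inertia[0], abs=1e-6)


class TestPermutationTest:
    def test_strong_link_attains_minimal_p(self, linked_dataset):
        sc, env, grid, Q, labels, L = linked_dataset
        Qr = Q.subset_traits(["LS", "AM", "FEC", "OP", "OD"])
        g = rlq_global_test(env, L.log10p1(), Qr, n_perm=99, seed=0)
        assert g.p_model2 == pytest.approx(1 / 100)
        assert g.p_model4 == pytest.approx(1 / 100)

    def test_constant_trait_gives_p_one(self, six_by_eight):
        R, L, _ = six_by_eight
        Q = make_fuzzy({t: {("SD", "0-5"): 1.0} for t in L.columns})
        fc = fourth_corner(EnvironmentTable(R), AbundanceTable(L), Q,
                           n_perm=49, seed=0)
        assert (fc.p_model2.to_numpy() == 1.0).all()
        assert (fc.p_model4.to_numpy() == 1.0).all()

    def test_monte_carlo_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(23)
        sites = [f"s{i}" for i in range(4)]
        L = pd.DataFrame(rng.integers(1, 7, size=(4, 5)).astype(float),
                         index=sites, columns=[f"t{j}" for j in range(5)])
        R = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]}, index=sites)
        Q = make_fuzzy({f"t{j}": {("SD", m): 1.0}
                        for j, m in enumerate(["0", "0", "0-5", "0-5", "5-15"])})

        # independent oracle: the fourth-corner pseudo-correlation by loops
        def stat(order):
            A = L.to_numpy()
            P = A / A.sum()
            r, c = P.sum(1), P.sum(0)
            x = R["x"].to_numpy()[list(order)]
            x = (x - (r * x).sum()) / np.sqrt((r * (x - (r * x).sum()) ** 2).sum())
            prof = Q.to_profile().data.to_numpy()
            cw = c @ prof
            out = []
            for k in np.flatnonzero(cw > 0):
                y = prof[:, k]
                mu = (c * y).sum()
                sd = np.sqrt((c * (y - mu) ** 2).sum())
                if sd == 0:
                    continue
                y = (y - mu) / sd
                out.append(float(x @ P @ y))
            return np.array(out)

        obs = np.abs(stat(range(4)))
        exact_ge = np.zeros_like(obs)
        for perm in itertools.permutations(range(4)):
            exact_ge += np.abs(stat(perm)) >= obs - 1e-12
        p_exact = exact_ge / 24.0

        fc = fourth_corner(EnvironmentTable(R), AbundanceTable(L), Q,
                           n_perm=4999, seed=1)
        occupied = fc.stat.columns[(fc.stat.loc["x"] != 0) | (fc.p_model2.loc["x"] < 1)]
        p_mc = fc.p_model2.loc["x"].to_numpy()
        for k, pe in enumerate(p_exact):
            se = np.sqrt(pe * (1 - pe) / 4999) + 1e-4
            assert abs(p_mc[k] - pe) < 5 * se


class TestCombineAndAdjust:
    def test_max_rule(self):
        p2 = pd.DataFrame([[0.01]], index=["x"], columns=["m"])
        p4 = pd.DataFrame([[0.20]], index=["x"], columns=["m"])
        comb, fdr = combine_and_adjust(p2, p4)
        assert comb.iloc[0, 0] == 0.20
        assert fdr.iloc[0, 0] >= 0.20

    def test_bh_hand_example(self):
        p2 = pd.DataFrame([[0.01, 0.02, 0.04]], index=["x"], columns=list("abc"))
        comb, fdr = combine_and_adjust(p2, p2)
        assert fdr.iloc[0].tolist() == pytest.approx([0.03, 0.03, 0.04])

    def test_all_ones(self):
        p = pd.DataFrame(np.ones((2, 3)), index=["x", "y"], columns=list("abc"))
        comb, fdr = combine_and_adjust(p, p)
        assert (fdr.to_numpy() == 1.0).all()

    def test_fdr_never_below_combined(self, six_by_eight):
        R, L, Q = six_by_eight
        fc = fourth_corner(EnvironmentTable(R), AbundanceTable(L), Q,
                           n_perm=99, seed=3)
        assert (fc.p_fdr.to_numpy() >= fc.p_combined.to_numpy() - 1e-12).all()
        assert (fc.p_combined.to_numpy() >= 1 / 100 - 1e-12).all()


class TestScreening:
    def make_planted(self, rng):
        n = 24
        sites = [f"s{i}" for i in range(n)]
        x = np.linspace(0, 1, n)
        z = rng.normal(size=n)
        taxa = [f"t{j}" for j in range(12)]
        # species 0-5 carry modality "0" and prefer high x; 6-11 carry "0-5"
        lam = np.empty((n, 12))
        for j in range(12):
            pref = x if j < 6 else 1 - x
            lam[:, j] = 1 + 30 * pref
        L = pd.DataFrame(rng.poisson(lam).astype(float), index=sites, columns=taxa)
        Q = make_fuzzy({t: {("SD", "0" if j < 6 else "0-5"): 1.0,
                            ("MB", ["Immobile", "Slow", "Fast"][rng.integers(3)]): 1.0}
                        for j, t in enumerate(taxa)})
        R = pd.DataFrame({"x": x, "z": z}, index=sites)
        return EnvironmentTable(R), AbundanceTable(L), Q

    def test_planted_association_retained(self):
        rng = np.random.default_rng(31)
        R, L, Q = self.make_planted(rng)
        R2, Q2, report = screen_variables(R, L, Q, alpha_screen=0.01,
                                          n_perm=999, seed=0)
        assert "x" in report.kept_descriptors
        assert "z" not in report.kept_descriptors
        assert "SD" in report.kept_traits

    def test_alpha_one_is_identity(self):
        rng = np.random.default_rng(32)
        R, L, Q = self.make_planted(rng)
        R2, Q2, report = screen_variables(R, L, Q, alpha_screen=1.0,
                                          n_perm=49, seed=0)
        assert report.kept_descriptors == list(R.data.columns)
        assert set(report.kept_traits) == set(Q.traits)

    def test_empty_retention_is_error(self):
        rng = np.random.default_rng(33)
        R, L, Q = self.make_planted(rng)
        with pytest.raises(ValueError, match="alpha_screen"):
            screen_variables(R, L, Q, alpha_screen=1e-4, n_perm=49, seed=0)


class TestAxisCorrelations:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(41)
        s = rng.normal(size=10)
        w = rng.random(10) + 0.1
        assert _weighted_corr(s, s, w) == pytest.approx(1.0)

    def test_single_level_factor_zero_ratio(self):
        rng = np.random.default_rng(42)
        y = rng.normal(size=10)
        assert _correlation_ratio(np.zeros(10, dtype=int), y,
                                  np.ones(10)) == pytest.approx(0.0, abs=1e-15)

    def test_axis_tests_flag_linked_descriptor(self, linked_dataset):
        sc, env, grid, Q, labels, L = linked_dataset
        Qr = Q.subset_traits(["LS", "AM", "FEC", "OP", "OD"])
        res, *_ = rlq_pipeline(env, L.log10p1(), Qr)
        out = axis_correlation_tests(res, env, Qr, n_perm=199, seed=0, n_axes=1)
        dox = out[(out.side == "env") & (out.variable == "DOX")].iloc[0]
        assert dox.p <= 0.01
        assert abs(dox.stat) > 0.5

    def test_null_variable_p_roughly_uniform(self, six_by_eight):
        R, L, Q = six_by_eight
        rng = np.random.default_rng(43)
        ps = []
        for rep in range(40):
            Rn = R.copy()
            Rn["noise"] = rng.normal(size=len(R))
            res, *_ = rlq_pipeline(EnvironmentTable(Rn), AbundanceTable(L), Q)
            out = axis_correlation_tests(res, EnvironmentTable(Rn[["noise"]]), Q,
                                         n_perm=49, seed=rep, n_axes=1)
            ps.append(out[out.variable == "noise"].iloc[0].p)
        assert 0.3 < np.mean(ps) < 0.7
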