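import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import traitstab as ts
from traitstab.constants import TRAIT_GROUPS, DataError
from traitstab.inference import simper_pair


def euclid_dm_from_values(y):
    y = np.asarray(y, dtype=float)
    d = np.abs(y[:, None] - y[None, :])
    return ts.DistanceMatrix(list(range(len(y))), d)


class TestAdonis:
    def test_classical_anova_oracle(self):
        rng = np.random.default_rng(0)
        g = np.repeat([0, 1], 12)
        y = rng.normal(0, 1, 24) + g * 0.8
        D = euclid_dm_from_values(y)
        table = ts.adonis(D, [("group", (g == 1).astype(float)[:, None])],
                          n_perm=99, seed=0)
        F = table.loc[table["term"] == "group", "F"].iloc[0]
        F_classic = sps.f_oneway(y[g == 0], y[g == 1]).statistic
        assert F == pytest.approx(F_classic, abs=1e-10)

    def test_ss_conservation(self, tiny_matrices):
        A, _ = tiny_matrices
        D = ts.bray_curtis(A)
        ponds = [l[0] for l in D.labels]
        years = [l[1] for l in D.labels]
        table = ts.permanova(D, ponds, years, n_perm=99, seed=0)
        total = table.loc[table["term"] == "total", "sum_sq"].iloc[0]
        parts = table.loc[table["term"] != "total", "sum_sq"].sum()
        assert parts == pytest.approx(total, abs=1e-8)
        from traitstab.multivariate import gower_center
        assert total == pytest.approx(np.trace(gower_center(D)), abs=1e-8)

    def test_df_pattern_numeric_year(self, tiny_matrices):
        A, _ = tiny_matrices
        D = ts.bray_curtis(A)
        ponds = [l[0] for l in D.labels]
        years = [l[1] for l in D.labels]
        table = ts.permanova(D, ponds, years, n_perm=99, seed=0)
        by_term = dict(zip(table["term"], table["df"]))
        n_ponds = len(set(ponds))
        assert by_term["pond"] == n_ponds - 1
        assert by_term["year"] == 1
        assert by_term["pond:year"] == n_ponds - 1
        assert by_term["residual"] == D.n - 2 * n_ponds

    def test_determinism(self, tiny_matrices):
        A, _ = tiny_matrices
        D = ts.bray_curtis(A)
        ponds = [l[0] for l in D.labels]
        years = [l[1] for l in D.labels]
        t1 = ts.permanova(D, ponds, years, n_perm=199, seed=5)
        t2 = ts.permanova(D, ponds, years, n_perm=199, seed=5)
        pd.testing.assert_frame_equal(t1, t2)

    def test_p_resolution(self, tiny_matrices):
        A, _ = tiny_matrices
        D = ts.bray_curtis(A)
        ponds = [l[0] for l in D.labels]
        years = [l[1] for l in D.labels]
        table = ts.permanova(D, ponds, years, n_perm=199, seed=1)
        p = table.loc[table["p"].notna(), "p"]
        assert (p >= 1 / 200).all()
        assert (p <= 1).all()

    def test_aliased_term_rejected(self):
        D = euclid_dm_from_values(np.arange(6.0))
        x = np.arange(6.0)[:, None]
        with pytest.raises(DataError, match="aliased"):
            ts.adonis(D, [("a", x), ("b", 2 * x)], n_perm=99)

    def test_categorical_year_option(self, tiny_matrices):
        A, _ = tiny_matrices
        D = ts.bray_curtis(A)
        ponds = [l[0] for l in D.labels]
        years = [l[1] for l in D.labels]
        table = ts.permanova(D, ponds, years, n_perm=99, seed=0,
                             year_numeric=False, interaction=False)
        by_term = dict(zip(table["term"], table["df"]))
        assert by_term["year"] == len(set(years)) - 1


class TestSimperPair:
    def test_direct_formula(self):
        c = simper_pair(np.array([2.0, 2.0]), np.array([1.0, 3.0]))
        np.testing.assert_allclose(c, [0.125, 0.125])
        assert c.sum() == pytest.approx(0.25)

    def test_identical_rows(self):
        c = simper_pair(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        np.testing.assert_allclose(c, 0)

    def test_single_column_equals_bc(self):
        x, y = np.array([3.0]), np.array([1.0])
        c = simper_pair(x, y)
        df = pd.DataFrame([[3.0], [1.0]])
        assert c[0] == pytest.approx(ts.bray_curtis(df).data[0, 1])

    def test_negative_rejected(self):
        with pytest.raises(DataError):
            simper_pair(np.array([-1.0]), np.array([1.0]))


class TestSimperGroupings:
    def test_year_to_centroid_example(self, pond_year_matrix_factory):
        M = pond_year_matrix_factory([[2, 0], [0, 2]], ["p", "p"], [2010, 2011])
        res = ts.simper_year_to_centroid(M)
        comp = res.comparisons
        np.testing.assert_allclose(comp["contribution"], 0.25)
        np.testing.assert_allclose(comp["percent"], 50.0)
        np.testing.assert_allclose(
            res.summary["percent"].groupby(res.summary["pond"]).sum(), 100.0
        )

    def test_identical_years_zero(self, pond_year_matrix_factory):
        M = pond_year_matrix_factory([[1, 2], [1, 2]], ["p", "p"], [2010, 2011])
        with pytest.warns(UserWarning, match="zero total"):
            res = ts.simper_year_to_centroid(M)
        np.testing.assert_allclose(res.comparisons["contribution"], 0)

    def test_contribution_sums_to_bc_of_comparison(self, tiny_matrices):
        A, _ = tiny_matrices
        res = ts.simper_year_to_centroid(A)
        X = A.to_numpy()
        ponds = np.array([i[0] for i in A.index])
        years = np.array([i[1] for i in A.index])
        for (pond, year), grp in res.comparisons.groupby(["pond", "year"]):
            i = int(np.where((ponds == pond) & (years == year))[0][0])
            mean_row = X[ponds == pond].mean(axis=0)
            bc = np.abs(X[i] - mean_row).sum() / (X[i] + mean_row).sum()
            assert grp["contribution"].sum() == pytest.approx(bc, abs=1e-10)
            assert grp["percent"].sum() == pytest.approx(100.0, abs=1e-10)

    def test_year_to_year_hand_computed(self, pond_year_matrix_factory):
        M = pond_year_matrix_factory([[4, 0], [1, 3]], ["p", "p"], [2010, 2011])
        res = ts.simper_year_to_year(M)
        comp = res.comparisons
        np.testing.assert_allclose(comp["contribution"], [3 / 8, 3 / 8])
        np.testing.assert_allclose(comp["percent"], [50.0, 50.0])

    def test_year_to_year_consecutive_only(self, tiny_matrices):
        A, _ = tiny_matrices
        res = ts.simper_year_to_year(A)
        n_ponds = A.index.get_level_values(0).nunique()
        n_years = A.index.get_level_values(1).nunique()
        n_cols = A.shape[1]
        assert len(res.comparisons) == n_ponds * (n_years - 1) * n_cols

    def test_trait_group_partition(self, tiny_matrices):
        _, T = tiny_matrices
        res = ts.simper_year_to_year(T, group_map=dict(TRAIT_GROUPS))
        sums = res.summary.groupby("pond")["percent"].sum()
        np.testing.assert_allclose(sums, 100.0, atol=1e-9)

    def test_constant_community(self, pond_year_matrix_factory):
        M = pond_year_matrix_factory(
            [[1, 2], [1, 2], [1, 2]], ["p"] * 3, [2010, 2011, 2012]
        )
        with pytest.warns(UserWarning, match="zero total"):
            res = ts.simper_year_to_year(M)
        np.testing.assert_allclose(res.comparisons["contribution"], 0)


class TestEnvfit:
    @pytest.fixture()
    def scores(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 2))
        X -= X.mean(axis=0)
        return X

    def test_axis_variable_r2_one(self, scores):
        V = pd.DataFrame({"v": scores[:, 0]})
        out = ts.envfit(scores, V, n_perm=99, seed=0)
        assert out["R2"].iloc[0] == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(
            [out["nMDS1"].iloc[0], out["nMDS2"].iloc[0]], [1.0, 0.0], atol=1e-8
        )

    def test_orthogonal_variable_r2_zero(self, scores):
        rng = np.random.default_rng(1)
        v = rng.normal(size=20)
        v -= v.mean()
        Q, _ = np.linalg.qr(scores - scores.mean(axis=0))
        v_orth = v - Q @ (Q.T @ v)
        out = ts.envfit(scores, pd.DataFrame({"v": v_orth}), n_perm=99, seed=0)
        assert out["R2"].iloc[0] == pytest.approx(0.0, abs=1e-10)

    def test_known_linear_combination(self):
        rng = np.random.default_rng(2)
        raw = rng.normal(size=(30, 2))
        Q, _ = np.linalg.qr(raw - raw.mean(axis=0))
        scores = Q  # orthonormal, centered axes
        v = 0.6 * scores[:, 0] + 0.8 * scores[:, 1]
        out = ts.envfit(scores, pd.DataFrame({"v": v}), n_perm=99, seed=0)
        assert out["R2"].iloc[0] == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(
            [out["nMDS1"].iloc[0], out["nMDS2"].iloc[0]], [0.6, 0.8], atol=1e-8
        )

    def test_rotation_invariance(self, scores):
        rng = np.random.default_rng(3)
        v = 0.3 * scores[:, 0] - 1.2 * scores[:, 1] + rng.normal(0, 0.3, 20)
        Q, _ = np.linalg.qr(rng.normal(size=(2, 2)))
        out0 = ts.envfit(scores, pd.DataFrame({"v": v}), n_perm=99, seed=0)
        out1 = ts.envfit(scores @ Q, pd.DataFrame({"v": v}), n_perm=99, seed=0)
        assert out1["R2"].iloc[0] == pytest.approx(out0["R2"].iloc[0], abs=1e-10)
        d0 = np.array([out0["nMDS1"].iloc[0], out0["nMDS2"].iloc[0]])
        d1 = np.array([out1["nMDS1"].iloc[0], out1["nMDS2"].iloc[0]])
        np.testing.assert_allclose(d1, Q.T @ d0, atol=1e-8)

    def test_constant_variable(self, scores):
        with pytest.warns(UserWarning, match="constant"):
            out = ts.envfit(scores, pd.DataFrame({"v": np.ones(20)}), n_perm=99,
                            seed=0)
        assert out["R2"].iloc[0] == 0.0
        assert out["p"].iloc[0] == 1.0

    def test_direction_unit_norm(self, tiny_matrices):
        A, T = tiny_matrices
        o = ts.nmds(ts.bray_curtis(T), k=2, n_starts=5, seed=0)
        out = ts.envfit(o, A, n_perm=99, seed=0)
        norms = np.sqrt(out["nMDS1"] ** 2 + out["nMDS2"] ** 2)
        np.testing.assert_allclose(norms, 1.0, atol=1e-8)
        assert ((out["R2"] >= 0) & (out["R2"] <= 1)).all()
        assert (out["p"] >= 1 / 100).all()

    def test_p_plus_one_convention(self, scores):
        V = pd.DataFrame({"v": scores[:, 0]})
        out = ts.envfit(scores, V, n_perm=99, seed=0)
        assert out["p"].iloc[0] >= 1 / 100
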