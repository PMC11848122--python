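import numpy as np
import pandas as pd
import pytest

import traitstab as ts
from traitstab.constants import DataError


def labelled_dm(dists, ponds, years):
    labels = list(zip(ponds, years))
    return ts.DistanceMatrix(labels, np.asarray(dists, dtype=float))


class TestYearToCentroid:
    def test_identical_years_zero(self):
        D = labelled_dm(np.zeros((2, 2)), ["p", "p"], [2010, 2011])
        out = ts.year_to_centroid(D)
        np.testing.assert_allclose(out["distance"], 0, atol=1e-12)

    def test_two_year_midpoint(self):
        d12 = 0.6
        D = labelled_dm([[0, d12], [d12, 0]], ["p", "p"], [2010, 2011])
        out = ts.year_to_centroid(D)
        np.testing.assert_allclose(out["distance"], d12 / 2, atol=1e-10)

    def test_raw_to_mean_formula(self, pond_year_matrix_factory):
        M = pond_year_matrix_factory([[2, 0], [0, 2]], ["p", "p"], [2010, 2011])
        D = ts.bray_curtis(M)
        out = ts.year_to_centroid(D, mode="raw_to_mean", M=M)
        np.testing.assert_allclose(out["distance"], 0.5, atol=1e-12)

    def test_pcoa_matches_euclidean_centroid(self, euclid_dm_factory):
        rng = np.random.default_rng(0)
        for _ in range(5):
            pts = rng.normal(size=(9, 2))
            ponds = ["a"] * 4 + ["b"] * 5
            years = list(range(2010, 2014)) + list(range(2010, 2015))
            D = euclid_dm_factory(pts, labels=list(zip(ponds, years)))
            out = ts.year_to_centroid(D)
            expected = []
            for g in ("a", "b"):
                idx = [i for i, p in enumerate(ponds) if p == g]
                c = pts[idx].mean(axis=0)
                expected.extend(np.linalg.norm(pts[idx] - c, axis=1))
            np.testing.assert_allclose(out["distance"], expected, atol=1e-8)

    def test_median_centroid_option(self, euclid_dm_factory):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(6, 2))
        D = euclid_dm_factory(pts, labels=[("p", 2010 + i) for i in range(6)])
        out_mean = ts.year_to_centroid(D, centroid="mean")
        out_med = ts.year_to_centroid(D, centroid="median")
        # the geometric median minimizes the *sum* of distances
        assert out_med["distance"].sum() <= out_mean["distance"].sum() + 1e-6

    def test_single_year_pond_dropped(self):
        D = labelled_dm(
            [[0, 0.1, 0.2], [0.1, 0, 0.3], [0.2, 0.3, 0]],
            ["a", "a", "b"], [2010, 2011, 2010],
        )
        with pytest.warns(UserWarning, match="'b'"):
            out = ts.year_to_centroid(D)
        assert set(out["pond"]) == {"a"}


class TestYearToYear:
    def test_transition_count(self, tiny_matrices):
        A, _ = tiny_matrices
        out = ts.year_to_year(ts.bray_curtis(A))
        n_ponds = A.index.get_level_values(0).nunique()
        n_years = A.index.get_level_values(1).nunique()
        assert len(out) == n_ponds * (n_years - 1)

    def test_constant_community_zero(self):
        D = labelled_dm(np.zeros((3, 3)), ["p"] * 3, [2010, 2011, 2012])
        out = ts.year_to_year(D)
        np.testing.assert_allclose(out["distance"], 0, atol=1e-15)

    def test_mean_transition(self):
        D = labelled_dm(
            [[0, 0.2, 0.5], [0.2, 0, 0.4], [0.5, 0.4, 0]],
            ["p"] * 3, [2010, 2011, 2012],
        )
        out = ts.year_to_year(D)
        np.testing.assert_allclose(out["distance"], [0.2, 0.4])
        assert out["distance"].mean() == pytest.approx(0.3)

    def test_gap_not_bridged(self):
        D = labelled_dm(
            [[0, 0.2, 0.5], [0.2, 0, 0.4], [0.5, 0.4, 0]],
            ["p"] * 3, [2010, 2011, 2013],
        )
        out = ts.year_to_year(D)
        assert len(out) == 1
        assert out["distance"].iloc[0] == pytest.approx(0.2)


class TestRelativeStability:
    def test_division_by_max(self):
        df = pd.DataFrame(
            {"pond": ["p"] * 3, "year": [1, 2, 3], "distance": [0.2, 0.4, 0.5]}
        )
        out = ts.relative_stability(df, "species")
        np.testing.assert_allclose(out["relative_distance"], [0.4, 0.8, 1.0])

    def test_single_distance(self):
        df = pd.DataFrame({"pond": ["p"], "year": [1], "distance": [0.37]})
        out = ts.relative_stability(df, "species")
        assert out["relative_distance"].iloc[0] == pytest.approx(1.0)

    def test_scale_invariance(self):
        df = pd.DataFrame(
            {"pond": ["p"] * 3, "year": [1, 2, 3], "distance": [0.1, 0.2, 0.3]}
        )
        r1 = ts.relative_stability(df, "x")["relative_distance"]
        df7 = df.assign(distance=df["distance"] * 7)
        r2 = ts.relative_stability(df7, "x")["relative_distance"]
        np.testing.assert_allclose(r1, r2)

    def test_all_zero_warns(self):
        df = pd.DataFrame({"pond": ["p"] * 2, "year": [1, 2], "distance": [0.0, 0.0]})
        with pytest.warns(UserWarning, match="zero"):
            out = ts.relative_stability(df, "species")
        np.testing.assert_allclose(out["relative_distance"], 0)

    def test_bounds(self, tiny_matrices):
        A, T = tiny_matrices
        table = ts.stability_table(
            {
                "species": ts.year_to_centroid(ts.bray_curtis(A)),
                "trait": ts.year_to_centroid(ts.bray_curtis(T)),
            }
        )
        assert (table["distance"] >= 0).all()
        assert (table["relative_distance"] >= 0).all()
        assert (table["relative_distance"] <= 1).all()
        # max is normalized within each composition type separately
        assert table.groupby("composition_type")["relative_distance"].max().eq(1).all()


def balanced_table(n_ponds=6, n_types=2, n_reps=6, cell_means=None, noise=0.0,
                   seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_ponds):
        for j in range(n_types):
            mu = cell_means[i][j] if cell_means is not None else 0.5
            for r in range(n_reps):
                rows.append(
                    {
                        "pond": f"p{i}",
                        "composition_type": ["species", "trait"][j],
                        "unit": str(r),
                        "distance": mu,
                        "relative_distance": mu + rng.normal(0, noise),
                    }
                )
    return pd.DataFrame(rows)


class TestStabilityAnova:
    def test_df_pattern_6x2x6(self):
        aov = ts.stability_anova(balanced_table(noise=0.1))
        by_term = dict(zip(aov["term"], aov["df"]))
        assert by_term == {"pond": 5, "composition_type": 1, "interaction": 5,
                          "residual": 60}
        assert aov["df"].sum() == 6 * 2 * 6 - 1

    def test_df_pattern_transitions(self):
        aov = ts.stability_anova(balanced_table(n_reps=5, noise=0.1))
        by_term = dict(zip(aov["term"], aov["df"]))
        assert by_term["residual"] == 48

    def test_constant_response_zero_F(self):
        aov = ts.stability_anova(balanced_table(noise=0.0))
        model_terms = aov[aov["term"] != "residual"]
        np.testing.assert_allclose(model_terms["F"], 0.0)

    def test_textbook_ss_oracle(self):
        # known cell means, zero noise: compare against hand-computed
        # balanced two-way ANOVA sums of squares
        cell_means = [[0.2, 0.4], [0.6, 0.1], [0.3, 0.5]]
        table = balanced_table(n_ponds=3, n_reps=4, cell_means=cell_means)
        aov = ts.stability_anova(table)
        y = table["relative_distance"].to_numpy()
        grand = y.mean()
        m = np.array(cell_means)
        r = 4
        ss_pond = 2 * r * ((m.mean(axis=1) - grand) ** 2).sum()
        ss_type = 3 * r * ((m.mean(axis=0) - grand) ** 2).sum()
        ss_int = r * (
            (m - m.mean(axis=1, keepdims=True) - m.mean(axis=0, keepdims=True)
             + grand) ** 2
        ).sum()
        got = dict(zip(aov["term"], aov["sum_sq"]))
        assert got["pond"] == pytest.approx(ss_pond, abs=1e-10)
        assert got["composition_type"] == pytest.approx(ss_type, abs=1e-10)
        assert got["interaction"] == pytest.approx(ss_int, abs=1e-10)
        assert got["residual"] == pytest.approx(0.0, abs=1e-10)

    def test_composition_F_equals_t_squared_one_pond(self):
        from scipy import stats as sps

        rng = np.random.default_rng(3)
        a = rng.normal(0.4, 0.1, 10)
        b = rng.normal(0.6, 0.1, 10)
        table = pd.DataFrame(
            {
                "pond": ["p"] * 20,
                "composition_type": ["species"] * 10 + ["trait"] * 10,
                "unit": list(map(str, range(20))),
                "distance": np.concatenate([a, b]),
                "relative_distance": np.concatenate([a, b]),
            }
        )
        aov = ts.stability_anova(table)
        F = aov.loc[aov["term"] == "composition_type", "F"].iloc[0]
        t = sps.ttest_ind(a, b).statistic
        assert F == pytest.approx(t**2, rel=1e-10)

    def test_empty_cell_rejected(self):
        table = balanced_table(noise=0.1)
        table = table[~((table["pond"] == "p0") &
                        (table["composition_type"] == "trait"))]
        with pytest.raises(DataError):
            ts.stability_anova(table)

    def test_unbalanced_warns(self):
        table = balanced_table(noise=0.1)
        table = table.drop(table.index[0])
        with pytest.warns(UserWarning, match="unbalanced"):
            ts.stability_anova(table)
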