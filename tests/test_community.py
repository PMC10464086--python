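import numpy as np
import pandas as pd
import pytest

from sedstrat import community as comm
from conftest import make_matrix


class TestRarefy:
    def test_column_sums_hit_depth(self):
        m = make_matrix({"a": [10, 20, 5], "b": [40, 0, 2], "c": [7, 7, 7]})
        out = comm.rarefy(m, depth=12, seed=1)
        assert (out.sample_sums() == 12).all()
        assert (out.counts.to_numpy() <= m.counts.to_numpy()).all()

    def test_min_depth_and_already_at_depth(self):
        m = make_matrix({"a": [3, 2], "b": [4, 1]})
        out = comm.rarefy(m, "min", seed=0)
        assert (out.sample_sums() == 5).all()
        assert out.counts["a"].sum() == 5

    def test_single_taxon_degenerate(self):
        m = make_matrix({"a": [10, 0]})
        out = comm.rarefy(m, depth=5, seed=0)
        assert list(out.counts["a"]) == [5, 0]

    def test_depth_too_large_names_sample(self):
        m = make_matrix({"a": [10, 0], "b": [2, 1]})
        with pytest.raises(ValueError, match="b"):
            comm.rarefy(m, depth=5)

    def test_deterministic_under_seed(self):
        m = make_matrix({"a": [50, 30, 20], "b": [10, 60, 30]})
        r1 = comm.rarefy(m, depth=40, seed=9)
        r2 = comm.rarefy(m, depth=40, seed=9)
        assert r1.counts.equals(r2.counts)


class TestAlphaDiversity:
    def test_even_community_no_singletons(self):
        m = make_matrix({"a": [5] * 10})
        res = comm.alpha_diversity(m)
        assert res.loc["a", "chao1"] == pytest.approx(10)
        assert res.loc["a", "pielou"] == pytest.approx(1.0)
        assert res.loc["a", "observed_richness"] == 10

    def test_chao1_bias_corrected_formula(self):
        # S_obs=10, F1=4, F2=2 -> 10 + 4*3/(2*3) = 12
        counts = [1] * 4 + [2] * 2 + [5] * 4
        res = comm.alpha_diversity(make_matrix({"a": counts}))
        assert res.loc["a", "chao1"] == pytest.approx(12.0)

    def test_pielou_two_taxa(self):
        res = comm.alpha_diversity(make_matrix({"a": [9, 1]}))
        h = -(0.9 * np.log(0.9) + 0.1 * np.log(0.1))
        assert res.loc["a", "pielou"] == pytest.approx(h / np.log(2))

    def test_single_taxon_pielou_missing(self):
        res = comm.alpha_diversity(make_matrix({"a": [7]}))
        assert np.isnan(res.loc["a", "pielou"])

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError):
            comm.alpha_diversity(make_matrix({"a": [1.5, 2.0]}))


class TestDissimilarity:
    def test_identical_samples_zero(self):
        m = make_matrix({"a": [2, 0, 6], "b": [2, 0, 6]})
        for metric in ("bray_curtis", "jaccard_binary"):
            assert comm.dissimilarity(m, metric).loc["a", "b"] == 0.0

    def test_bray_curtis_hand_value(self):
        m = make_matrix({"a": [2, 0, 6], "b": [1, 3, 2]})
        assert comm.dissimilarity(m, "bray_curtis").loc["a", "b"] == pytest.approx(8 / 14)

    def test_jaccard_hand_value(self):
        m = make_matrix({"a": [1, 0, 1], "b": [1, 1, 1]})
        assert comm.dissimilarity(m, "jaccard_binary").loc["a", "b"] == pytest.approx(1 / 3)

    def test_zero_total_sample_rejected(self):
        with pytest.raises(ValueError):
            comm.dissimilarity(make_matrix({"a": [1, 2], "b": [0, 0]}))

    def test_range_and_symmetry(self):
        rng = np.random.default_rng(0)
        m = make_matrix({f"s{i}": rng.integers(0, 50, 20) + 1 for i in range(6)})
        d = comm.dissimilarity(m, "bray_curtis")
        a = d.to_numpy()
        assert ((a >= 0) & (a <= 1)).all()
        assert np.allclose(a, a.T)
        assert np.allclose(np.diag(a), 0)


class TestPCoA:
    def test_equilateral_triangle(self):
        d = pd.DataFrame(1 - np.eye(3), index=list("abc"), columns=list("abc"))
        res = comm.pcoa(d, k=2)
        ev = res.eigenvalues
        assert ev[0] == pytest.approx(ev[1], abs=1e-10)
        assert ev[0] + ev[1] == pytest.approx(1.0, abs=1e-10)
        assert abs(ev[2]) < 1e-10

    def test_duplicated_sample_rows_identical(self):
        raw = np.array([[0, 2, 2, 5], [2, 0, 0, 4], [2, 0, 0, 4], [5, 4, 4, 0]], float)
        raw /= raw.max()
        d = pd.DataFrame(raw, index=list("abcd"), columns=list("abcd"))
        res = comm.pcoa(d, k=2)
        assert np.allclose(res.coordinates.loc["b"], res.coordinates.loc["c"], atol=1e-10)

    def test_euclidean_exactness(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(7, 3))
        from scipy.spatial.distance import pdist, squareform

        d = pd.DataFrame(squareform(pdist(pts)), index=range(7), columns=range(7))
        res = comm.pcoa(d, k=3)
        rec = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(rec, d.to_numpy(), atol=1e-8)

    def test_rejects_asymmetry_and_large_k(self):
        d = pd.DataFrame([[0, 1], [0.5, 0]])
        with pytest.raises(ValueError):
            comm.pcoa(d, k=1)
        sym = pd.DataFrame(1 - np.eye(3))
        with pytest.raises(ValueError):
            comm.pcoa(sym, k=3)


class TestUPGMA:
    def test_hand_agglomeration_heights(self):
        d = pd.DataFrame(
            [[0, 2, 8], [2, 0, 8], [8, 8, 0]], index=list("ABC"), columns=list("ABC"),
            dtype=float,
        )
        res = comm.upgma(d)
        assert np.allclose(res.merge_heights, [1.0, 4.0])
        cut = res.cut(2)
        assert cut["A"] == cut["B"] != cut["C"]

    def test_k_equals_n(self):
        d = pd.DataFrame(1 - np.eye(4), index=list("abcd"), columns=list("abcd"))
        assert comm.upgma(d).cut(4).nunique() == 4


class TestANOSIM:
    @staticmethod
    def _separated():
        # all between-group dissimilarities exceed all within-group
        a = np.full((6, 6), 0.9)
        a[:3, :3] = 0.1
        a[3:, 3:] = 0.1
        np.fill_diagonal(a, 0)
        return pd.DataFrame(a, index=list("abcdef"), columns=list("abcdef"))

    def test_perfect_separation_r_is_one(self):
        r, p = comm.anosim(self._separated(), ["g1"] * 3 + ["g2"] * 3, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p >= 1 / 100  # add-one rule lower bound

    def test_matches_skbio_statistic(self):
        from skbio import DistanceMatrix
        from skbio.stats.distance import anosim as sk_anosim

        rng = np.random.default_rng(5)
        pts = rng.normal(size=(8, 4))
        from scipy.spatial.distance import pdist, squareform

        d = pd.DataFrame(squareform(pdist(pts)), index=[f"s{i}" for i in range(8)],
                         columns=[f"s{i}" for i in range(8)])
        groups = ["x"] * 4 + ["y"] * 4
        r, _ = comm.anosim(d, groups, n_perm=9, seed=0)
        ref = sk_anosim(DistanceMatrix(d.to_numpy(), ids=d.index), groups, permutations=9)
        assert r == pytest.approx(ref["test statistic"], abs=1e-12)

    def test_null_mean_r_near_zero(self):
        rng = np.random.default_rng(11)
        rs = []
        for _ in range(100):
            pts = rng.normal(size=(8, 3))
            from scipy.spatial.distance import pdist, squareform

            d = pd.DataFrame(squareform(pdist(pts)))
            g = rng.permutation(["a"] * 4 + ["b"] * 4)
            r, _ = comm.anosim(d, pd.Series(g, index=d.index), n_perm=1, seed=0)
            rs.append(r)
        assert abs(np.mean(rs)) < 0.05

    def test_rejects_singleton_group(self):
        with pytest.raises(ValueError):
            comm.anosim(self._separated(), ["g1"] * 5 + ["g2"], n_perm=9)


class TestMultiTimepoint:
    def test_identical_timepoints_zero(self):
        m = make_matrix({"t1": [3, 4], "t2": [3, 4], "t3": [3, 4]})
        assert comm.multi_timepoint_dissimilarity(m)["total"] == 0.0

    def test_two_sample_reduction_to_bray_curtis(self):
        rng = np.random.default_rng(21)
        for _ in range(100):
            x = rng.integers(0, 30, 12)
            y = rng.integers(0, 30, 12)
            if x.sum() == 0 or y.sum() == 0:
                continue
            m = make_matrix({"t1": x, "t2": y})
            total = comm.multi_timepoint_dissimilarity(m)["total"]
            bc = comm.dissimilarity(m, "bray_curtis").iloc[0, 1]
            assert total == pytest.approx(bc, abs=1e-12)

    def test_three_site_formula_oracle(self):
        # straight-from-formula independent computation
        x = {"t1": [5, 0], "t2": [0, 5], "t3": [5, 5]}
        m = make_matrix(x)
        res = comm.multi_timepoint_dissimilarity(m)
        cols = np.array(list(x.values()), float)
        s_min = s_max = s_a = 0.0
        for i in range(3):
            for j in range(i + 1, 3):
                b_ij = np.clip(cols[i] - cols[j], 0, None).sum()
                b_ji = np.clip(cols[j] - cols[i], 0, None).sum()
                s_min += min(b_ij, b_ji)
                s_max += max(b_ij, b_ji)
                s_a += np.minimum(cols[i], cols[j]).sum()
        assert res["total"] == pytest.approx((s_min + s_max) / (2 * s_a + s_min + s_max))
        assert res["balanced"] == pytest.approx(s_min / (s_a + s_min))
        assert res["gradient"] == pytest.approx(res["total"] - res["balanced"])

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            comm.multi_timepoint_dissimilarity(make_matrix({"t1": [1, 2]}))


class TestMergeAndDegree:
    def test_merge_single_season_identity(self):
        m = make_matrix({"a": [1, 2], "b": [3, 4]}, layers=[1, 2])
        merged = comm.merge_seasons(m)
        assert np.array_equal(merged.counts.to_numpy(), m.counts.to_numpy())

    def test_merge_additivity_and_conservation(self):
        m = make_matrix({"a": [1, 2], "b": [1, 2], "c": [5, 0]},
                        layers=[1, 1, 2], seasons=["S1", "S2", "S1"])
        merged = comm.merge_seasons(m)
        assert list(merged.counts["L01"]) == [2, 4]
        assert merged.counts.to_numpy().sum() == m.counts.to_numpy().sum()

    def test_connection_degree_threshold(self):
        m = make_matrix({"s1": [10, 9, 0], "s2": [10, 9, 9],
                         "s3": [10, 9, 10], "s4": [10, 9, 1000]})
        deg = comm.connection_degree(m)
        assert deg["t0"] == 4   # boundary inclusive
        assert deg["t1"] == 0   # below threshold everywhere
        assert deg["t2"] == 2   # mixed row (0, 9, 10, 1000)
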