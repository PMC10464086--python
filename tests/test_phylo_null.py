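import itertools
import subprocess

import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st_

from sedstrat import generate_tree
from sedstrat import phylo_null as pn
from sedstrat.containers import CommunityMatrix
from sedstrat.trees import patristic_matrix
from conftest import make_matrix


# ----------------------------------------------------------------------
# independent brute-force oracles
def brute_mntd(abund, dist, weighted):
    present = [t for t in dist.index if abund[t] > 0]
    total = sum(abund[t] for t in present)
    out = 0.0
    for s in present:
        nearest = min(dist.loc[s, t] for t in present if t != s)
        out += (abund[s] / total if weighted else 1 / len(present)) * nearest
    return out


def brute_beta_mntd(c1, c2, dist, weighted):
    p1 = [t for t in dist.index if c1[t] > 0]
    p2 = [t for t in dist.index if c2[t] > 0]
    t1, t2 = sum(c1[t] for t in p1), sum(c2[t] for t in p2)
    term1 = sum(
        (c1[s] / t1 if weighted else 1 / len(p1)) * min(dist.loc[s, t] for t in p2)
        for s in p1
    )
    term2 = sum(
        (c2[s] / t2 if weighted else 1 / len(p2)) * min(dist.loc[s, t] for t in p1)
        for s in p2
    )
    return 0.5 * (term1 + term2)


class TestMNTD:
    def test_hand_values_three_taxa(self, three_taxon_dist):
        equal = pd.Series({"A": 1.0, "B": 1.0, "C": 1.0})
        assert pn.mntd(equal, three_taxon_dist, weighted=False) == pytest.approx(8 / 3)
        skew = pd.Series({"A": 0.5, "B": 0.25, "C": 0.25})
        assert pn.mntd(skew, three_taxon_dist, weighted=True) == pytest.approx(2.5)

    def test_two_taxon_community_equals_patristic(self, three_taxon_dist):
        two = pd.Series({"A": 1.0, "C": 3.0})
        for weighted in (True, False):
            assert pn.mntd(two, three_taxon_dist, weighted) == pytest.approx(4.0)

    def test_requires_two_present_taxa(self, three_taxon_dist):
        with pytest.raises(ValueError):
            pn.mntd(pd.Series({"A": 1.0}), three_taxon_dist)


class TestBetaMNTD:
    def test_identical_communities_zero(self, three_taxon_dist):
        c = pd.Series({"A": 2.0, "C": 1.0})
        assert pn.beta_mntd(c, c, three_taxon_dist) == 0.0

    def test_disjoint_singletons(self, three_taxon_dist):
        a = pd.Series({"A": 1.0})
        c = pd.Series({"C": 1.0})
        assert pn.beta_mntd(a, c, three_taxon_dist) == pytest.approx(4.0)

    def test_symmetry(self, three_taxon_dist):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = pd.Series(rng.integers(0, 5, 3), index=list("ABC")).astype(float)
            y = pd.Series(rng.integers(0, 5, 3), index=list("ABC")).astype(float)
            if (x > 0).sum() == 0 or (y > 0).sum() == 0:
                continue
            assert pn.beta_mntd(x, y, three_taxon_dist) == pytest.approx(
                pn.beta_mntd(y, x, three_taxon_dist)
            )

    def test_brute_force_equivalence_all_five_tip_communities(self):
        """MNTD and betaMNTD match exhaustive enumeration exactly on every
        community over a 5-tip tree."""
        tree = generate_tree(5, seed=3)
        dist = patristic_matrix(tree)
        taxa = list(dist.index)
        rng = np.random.default_rng(1)
        subsets = []
        for r in range(1, 6):
            for combo in itertools.combinations(taxa, r):
                abund = pd.Series(0.0, index=taxa)
                abund[list(combo)] = rng.integers(1, 9, r).astype(float)
                subsets.append(abund)
        for abund in subsets:
            if (abund > 0).sum() >= 2:
                for weighted in (True, False):
                    assert pn.mntd(abund, dist, weighted) == pytest.approx(
                        brute_mntd(abund, dist, weighted), abs=1e-12
                    )
        for c1, c2 in itertools.combinations(subsets, 2):
            for weighted in (True, False):
                assert pn.beta_mntd(c1, c2, dist, weighted) == pytest.approx(
                    brute_beta_mntd(c1, c2, dist, weighted), abs=1e-12
                )

    def test_matches_picante_comdistnt(self, tmp_path):
        """Cross-check against R picante's comdistnt on a small fixture."""
        tree = generate_tree(8, seed=11)
        dist = patristic_matrix(tree)
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 10, size=(3, 8))
        counts[counts.sum(axis=1) == 0, 0] = 1
        taxa = list(dist.index)
        comm_df = pd.DataFrame(counts, columns=taxa, index=["s1", "s2", "s3"])
        tree_path = tmp_path / "t.nwk"
        tree.write(path=str(tree_path), schema="newick", unquoted_underscores=True)
        comm_path = tmp_path / "c.tsv"
        comm_df.to_csv(comm_path, sep="\t")
        script = f"""
        suppressMessages(library(picante))
        tr <- read.tree("{tree_path}")
        cm <- as.matrix(read.table("{comm_path}", sep="\\t", header=TRUE, row.names=1,
                                   check.names=FALSE))
        d <- cophenetic(tr)
        out <- comdistnt(cm, d, abundance.weighted=TRUE)
        write.table(as.matrix(out), "{tmp_path / 'out.tsv'}", sep="\\t")
        """
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        for i, j in itertools.combinations(range(3), 2):
            ours = pn.beta_mntd(comm_df.iloc[i], comm_df.iloc[j], dist, weighted=True)
            assert ours == pytest.approx(ref.iloc[j, i], abs=1e-8)


class TestNTI:
    def test_star_tree_undefined(self):
        tree = dendropy.Tree.get(data="(A:1,B:1,C:1,D:1,E:1);", schema="newick")
        dist = patristic_matrix(tree)
        abund = pd.Series({"A": 1.0, "B": 1.0, "C": 1.0})
        with pytest.warns(UserWarning, match="zero spread"):
            assert np.isnan(pn.nti(abund, dist, n_null=99, seed=0))

    def test_clade_community_is_clustered(self):
        """Taxa drawn from one clade of a two-clade tree give NTI > 0 in
        nearly all seeds."""
        tree = dendropy.Tree.get(
            data="(((A:1,B:1):1,(C:1,D:1):1):10,((E:1,F:1):1,(G:1,H:1):1):10);",
            schema="newick",
        )
        dist = patristic_matrix(tree)
        abund = pd.Series({"A": 1.0, "B": 1.0, "C": 1.0, "D": 1.0})
        hits = sum(pn.nti(abund, dist, n_null=199, seed=s) > 0 for s in range(40))
        assert hits >= 38

    def test_random_subsets_centred_null(self):
        tree = generate_tree(30, seed=5)
        dist = patristic_matrix(tree)
        rng = np.random.default_rng(8)
        vals = []
        for _ in range(200):
            abund = pd.Series(0.0, index=dist.index)
            idx = rng.choice(30, rng.integers(5, 16), replace=False)
            abund.iloc[idx] = rng.random(len(idx)) + 0.1
            vals.append(pn.nti(abund, dist, n_null=99, seed=rng.integers(2 ** 31)))
        assert abs(np.nanmean(vals)) < 0.15


class TestBNTI:
    def test_symmetry_under_shared_seed(self, three_taxon_dist):
        tree = generate_tree(20, seed=1)
        dist = patristic_matrix(tree)
        rng = np.random.default_rng(0)
        c1 = pd.Series(rng.integers(0, 6, 20).astype(float), index=dist.index)
        c2 = pd.Series(rng.integers(0, 6, 20).astype(float), index=dist.index)
        a = pn.bnti(c1, c2, dist, n_null=99, seed=7)
        b = pn.bnti(c2, c1, dist, n_null=99, seed=7)
        assert a == pytest.approx(b, abs=1e-12)

    def test_pair_pool_restriction_runs(self):
        tree = generate_tree(20, seed=2)
        dist = patristic_matrix(tree)
        rng = np.random.default_rng(1)
        c1 = pd.Series(rng.integers(0, 4, 20).astype(float), index=dist.index)
        c2 = pd.Series(rng.integers(0, 4, 20).astype(float), index=dist.index)
        z = pn.bnti(c1, c2, dist, n_null=99, seed=0, pool="pair")
        assert np.isfinite(z) or np.isnan(z)


class TestRaupCrick:
    def test_score_formula(self):
        assert pn.rc_score(5000, 100, 9999) == pytest.approx(2 * (5050 / 9999) - 1)

    def test_upper_bound_when_obs_exceeds_all_nulls(self):
        # two taxa: every null pair holds both taxa with near-even abundance,
        # while the observed pair has opposite extreme splits -> BC_obs beats
        # every simulated BC_null
        meta = make_matrix({"s1": [500, 500], "s2": [500, 500]})
        c1 = pd.Series({"t0": 1000.0, "t1": 1.0})
        c2 = pd.Series({"t0": 1.0, "t1": 1000.0})
        rc = pn.raup_crick_bray(c1, c2, meta, n_null=199, seed=0)
        assert rc == 1.0

    def test_empty_community_rejected(self):
        meta = make_matrix({"s1": [5, 5], "s2": [5, 5]})
        with pytest.raises(ValueError):
            pn.raup_crick_bray(pd.Series({"t0": 0.0}), pd.Series({"t0": 5.0}), meta,
                               n_null=9)


class TestPartition:
    def test_pure_heterogeneous_selection(self):
        fractions, labels = pn.partition_processes([3.0, 3.5, 4.0], [0.0, 0.5, -0.5])
        assert fractions["heterogeneous_selection"] == 1.0
        assert sum(fractions.values()) == pytest.approx(1.0)

    def test_rule_table_mixed(self):
        fractions, labels = pn.partition_processes([1.0, 0.0, -3.0], [0.99, 0.0, 0.0])
        assert labels == ["dispersal_limitation", "drift", "homogeneous_selection"]
        assert fractions["dispersal_limitation"] == pytest.approx(1 / 3)
        assert fractions["drift"] == pytest.approx(1 / 3)
        assert fractions["homogeneous_selection"] == pytest.approx(1 / 3)

    @given(
        b=st_.lists(st_.floats(-5, 5), min_size=1, max_size=30),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_fractions_always_sum_to_one(self, b):
        rc = [0.0] * len(b)
        fractions, _ = pn.partition_processes(b, rc)
        assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-12)

    def test_mismatched_pairs_rejected(self):
        with pytest.raises(ValueError):
            pn.partition_processes([1.0, 2.0], [0.5])


class TestAdjacentProfile:
    def test_merged_boundary_count(self, small_dataset):
        ds = small_dataset
        prof = pn.adjacent_layer_profile(ds.counts, ds.tree, mode="merged",
                                         n_null=19, n_null_rc=19, seed=0)
        assert len(prof) == 10  # 11 layers -> 10 boundaries

    def test_snapshot_boundary_count(self):
        from sedstrat import GeneratorConfig, generate_dataset

        ds = generate_dataset(GeneratorConfig(n_taxa=60, n_layers=6, n_seasons=2,
                                              damming_layer=3, seed=4))
        prof = pn.adjacent_layer_profile(ds.counts, ds.tree, mode="snapshots",
                                         n_null=19, n_null_rc=19, seed=0)
        assert len(prof) == 10  # 5 boundaries x 2 seasons
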