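"""Distance matrices, Ward.D2 oracle equivalence, dendrogram comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from chromopan import phylo
from chromopan.phylo import (
    Dendrogram,
    bakers_gamma,
    bootstrap_support,
    entanglement,
    permutation_test_gamma,
    simple_matching_distance,
    to_newick,
    ward_clustering,
)


def random_binary_matrix(n_rows, n_cols, seed, missing_frac=0.0):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 2, size=(n_rows, n_cols)).astype(float)
    if missing_frac:
        x[rng.random((n_rows, n_cols)) < missing_frac] = np.nan
    return pd.DataFrame(x, columns=[f"a{i}" for i in range(n_cols)])


class TestSimpleMatching:
    def test_identical_columns_zero(self):
        m = pd.DataFrame({"a": [0, 1, 1], "b": [0, 1, 1]})
        assert simple_matching_distance(m).loc["a", "b"] == 0.0

    def test_complementary_columns_one(self):
        m = pd.DataFrame({"a": [0, 1, 0], "b": [1, 0, 1]})
        assert simple_matching_distance(m).loc["a", "b"] == 1.0

    def test_missing_entries_pairwise_complete_oracle(self):
        m = random_binary_matrix(200, 6, seed=5, missing_frac=0.2)
        d = simple_matching_distance(m)
        cols = list(m.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1 :]:
                both = m[a].notna() & m[b].notna()
                expected = (m.loc[both, a] != m.loc[both, b]).mean()
                assert d.loc[a, b] == pytest.approx(expected)

    def test_no_comparable_positions_errors(self):
        m = pd.DataFrame({"a": [0.0, np.nan], "b": [np.nan, 1.0]})
        with pytest.raises(ValueError, match=r"\(a, b\)"):
            simple_matching_distance(m)


class TestWard:
    def test_two_leaves_single_merge(self):
        d = pd.DataFrame([[0, 3.0], [3.0, 0]], index=["a", "b"], columns=["a", "b"])
        dend = ward_clustering(d)
        assert dend.merges.shape == (1, 4)
        assert dend.merges[0, 2] == pytest.approx(3.0)

    def test_closest_pair_merges_first(self):
        labels = ["A", "B", "C"]
        d = pd.DataFrame(
            [[0, 1, 10], [1, 0, 10], [10, 10, 0]], index=labels, columns=labels, dtype=float
        )
        dend = ward_clustering(d)
        assert sorted(dend.merges[0, :2]) == [0, 1]
        # Lance-Williams by hand: S(AB,C) = (2*100 + 2*100 - 1)/3
        assert dend.merges[1, 2] == pytest.approx(np.sqrt(399 / 3))

    def test_heights_non_decreasing(self):
        for seed in range(5):
            m = random_binary_matrix(80, 10, seed)
            dend = ward_clustering(simple_matching_distance(m))
            heights = dend.merges[:, 2]
            assert (np.diff(heights) >= -1e-12).all()

    def test_matches_exhaustive_lance_williams_oracle(self):
        def oracle_heights(dist):
            """Naive O(n^3) Ward.D2 recomputation with explicit cluster sets."""
            n = dist.shape[0]
            S = {
                (i, j): dist[i, j] ** 2
                for i in range(n)
                for j in range(n)
                if i != j
            }
            sizes = {i: 1 for i in range(n)}
            active = list(range(n))
            next_id = n
            heights = []
            while len(active) > 1:
                best = min(
                    (S[(a, b)], a, b) for i, a in enumerate(active) for b in active[i + 1 :]
                )
                v, a, b = best
                heights.append(np.sqrt(v))
                new = next_id
                next_id += 1
                for k in active:
                    if k in (a, b):
                        continue
                    S[(new, k)] = S[(k, new)] = (
                        (sizes[a] + sizes[k]) * S[(a, k)]
                        + (sizes[b] + sizes[k]) * S[(b, k)]
                        - sizes[k] * S[(a, b)]
                    ) / (sizes[a] + sizes[b] + sizes[k])
                sizes[new] = sizes[a] + sizes[b]
                active = [k for k in active if k not in (a, b)] + [new]
            return heights

        for seed in range(6):
            m = random_binary_matrix(60, 8, seed=100 + seed)
            dm = simple_matching_distance(m)
            dend = ward_clustering(dm)
            assert dend.merges[:, 2] == pytest.approx(oracle_heights(dm.to_numpy()))

    def test_agrees_with_scipy_ward_on_tie_free_input(self):
        rng = np.random.default_rng(17)
        pts = rng.normal(size=(9, 4))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        labels = [f"a{i}" for i in range(9)]
        dend = ward_clustering(pd.DataFrame(d, index=labels, columns=labels))
        Z = linkage(squareform(d), method="ward")
        assert dend.merges[:, 2] == pytest.approx(Z[:, 2])


def caterpillar(labels):
    """((l0,l1),l2),l3)... with unit height steps."""
    n = len(labels)
    merges = np.zeros((n - 1, 4))
    cur = 0
    for t in range(n - 1):
        merges[t] = (cur, t + 1, t + 1.0, t + 2)
        cur = n + t
    return Dendrogram(labels=list(labels), merges=merges)


class TestBakersGamma:
    def test_self_comparison_is_exactly_one(self):
        for seed in range(4):
            m = random_binary_matrix(60, 8, seed)
            dend = ward_clustering(simple_matching_distance(m))
            assert bakers_gamma(dend, dend) == 1.0

    def test_caterpillar_reversal_hand_computed(self):
        """Fusion-level vectors of opposite caterpillars are heavily tied;
        the hand-computed Spearman correlation is -29/60, not -1."""
        d1 = caterpillar(["A", "B", "C", "D"])
        d2 = caterpillar(["C", "D", "B", "A"])
        assert bakers_gamma(d1, d2) == pytest.approx(-29 / 60)

    def test_random_label_shuffles_center_near_zero(self):
        m = random_binary_matrix(80, 12, seed=3)
        dend = ward_clustering(simple_matching_distance(m))
        rng = np.random.default_rng(0)
        labels = np.array(dend.labels)
        vals = [
            bakers_gamma(dend.relabel(list(labels[rng.permutation(12)])), dend)
            for _ in range(100)
        ]
        assert abs(np.mean(vals)) < 0.1

    def test_leaf_set_mismatch_errors(self):
        d1 = caterpillar(["A", "B", "C"])
        d2 = caterpillar(["A", "B", "X"])
        with pytest.raises(ValueError):
            bakers_gamma(d1, d2)


class TestEntanglement:
    def test_identical_orders_zero(self):
        d = caterpillar(["A", "B", "C", "D", "E"])
        assert entanglement(d, d) == 0.0

    def test_reversed_order_one(self):
        d1 = caterpillar(["A", "B", "C", "D"])
        d2 = caterpillar(["A", "B", "C", "D"])
        d2.leaf_order = list(reversed(d1.leaf_order))
        assert entanglement(d1, d2) == 1.0

    @settings(max_examples=50, deadline=None)
    @given(st.permutations(list("ABCDEF")))
    def test_matches_bruteforce_norm(self, perm):
        d1 = caterpillar(list("ABCDEF"))
        d2 = caterpillar(list("ABCDEF"))
        d2.leaf_order = list(perm)
        pos2 = {l: i for i, l in enumerate(perm)}
        num = sum(abs(i - pos2[l]) ** 1.5 for i, l in enumerate(d1.leaf_order))
        worst = sum(abs(i - (5 - i)) ** 1.5 for i in range(6))
        assert entanglement(d1, d2) == pytest.approx(num / worst)
        assert 0.0 <= entanglement(d1, d2) <= 1.0


class TestPermutationTest:
    def test_self_comparison_floor_p(self):
        m = random_binary_matrix(50, 10, seed=2)
        dend = ward_clustering(simple_matching_distance(m))
        obs, null_mean, p = permutation_test_gamma(dend, dend, n_iter=49, seed=0)
        assert obs == 1.0
        assert p == pytest.approx(1 / 50)
        assert abs(null_mean) < 0.2

    def test_null_mean_near_zero_at_100_iter(self):
        m1 = random_binary_matrix(60, 12, seed=4)
        m2 = random_binary_matrix(60, 12, seed=5)
        d1 = ward_clustering(simple_matching_distance(m1))
        d2 = ward_clustering(simple_matching_distance(m2))
        _, null_mean, _ = permutation_test_gamma(d1, d2, n_iter=100, seed=1)
        assert abs(null_mean) < 0.1

    def test_deterministic_under_seed(self):
        m = random_binary_matrix(40, 8, seed=6)
        d = ward_clustering(simple_matching_distance(m))
        r1 = permutation_test_gamma(d, d, n_iter=10, seed=3)
        r2 = permutation_test_gamma(d, d, n_iter=10, seed=3)
        assert r1 == r2

    def test_independent_trees_p_not_extreme(self):
        """Unrelated random trees should rarely yield significant gamma."""
        ps = []
        for seed in range(8):
            m1 = random_binary_matrix(60, 10, seed=50 + seed)
            m2 = random_binary_matrix(60, 10, seed=150 + seed)
            d1 = ward_clustering(simple_matching_distance(m1))
            d2 = ward_clustering(simple_matching_distance(m2))
            _, _, p = permutation_test_gamma(d1, d2, n_iter=60, seed=seed)
            ps.append(p)
        assert np.mean(ps) > 0.15  # roughly uniform p-values, not piled at 0


class TestBootstrap:
    def test_perfectly_separated_groups_full_support(self):
        rng = np.random.default_rng(9)
        cols = {}
        for g in range(3):
            signature = rng.integers(0, 2, size=90)
            for i in range(3):
                cols[f"g{g}_{i}"] = signature
        m = pd.DataFrame(cols)
        support = bootstrap_support(m, n_boot=30, seed=0)
        for g in range(3):
            cluster = frozenset(f"g{g}_{i}" for i in range(3))
            assert support.get(cluster) == 1.0

    def test_reproducible_single_replicate(self):
        m = random_binary_matrix(40, 6, seed=8)
        assert bootstrap_support(m, 1, seed=5) == bootstrap_support(m, 1, seed=5)

    def test_weak_signal_gives_partial_support(self):
        rng = np.random.default_rng(21)
        m = random_binary_matrix(30, 8, seed=21)
        support = bootstrap_support(m, n_boot=40, seed=2)
        assert any(0.0 < v < 1.0 for v in support.values())


class TestRecoveryOnPanel:
    def test_planted_groups_in_both_trees_and_high_gamma(self, panel):
        from chromopan import loci, snp

        matrix = snp.call_genotypes_panel(
            {a: s.allele_counts for a, s in panel.summaries.items()}, panel.sites
        )
        cls = snp.classify_sites(matrix)
        snp_mat = matrix.geno.loc[cls.isin([1, 2])]
        d_snp = ward_clustering(simple_matching_distance(snp_mat, missing=-1))
        pres = loci.locus_presence(
            {a: s.locus_depth for a, s in panel.summaries.items()}, panel.loci
        )
        d_pav = ward_clustering(simple_matching_distance(pres.astype(int)))
        groups = panel.groups
        want = {
            frozenset(a for a, g in groups.items() if g == grp) for grp in set(groups.values())
        }
        assert want <= set(d_snp.clusters())
        assert want <= set(d_pav.clusters())
        assert bakers_gamma(d_snp, d_pav) >= 0.9


class TestNewick:
    def test_two_leaf_tree(self):
        d = pd.DataFrame([[0, 2.0], [2.0, 0]], index=["a", "b"], columns=["a", "b"])
        assert to_newick(ward_clustering(d)) == "(a:2,b:2);"

    def test_parses_with_biopython(self, tmp_path):
        from io import StringIO

        from Bio import Phylo

        m = random_binary_matrix(50, 7, seed=9)
        nwk = to_newick(ward_clustering(simple_matching_distance(m)))
        tree = Phylo.read(StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == [f"a{i}" for i in range(7)]
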