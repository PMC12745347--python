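"""PCA, neighbour joining, AMOVA and F_ST clustering against oracles."""

import numpy as np
import pandas as pd
import pytest

from lochgen import structure
from lochgen.io import MISSING
from lochgen.sim import SimConfig, simulate_metapopulation

from conftest import make_matrix, make_popmap, random_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(23)


class TestPca:
    def test_matches_svd_oracle(self, rng):
        G = random_matrix(rng, n_ind=15, n_sites=40, missing_rate=0.0)
        res = structure.pca(G)
        X = G.genotypes.astype(float)
        X -= X.mean(axis=0)
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        assert np.allclose(np.abs(res.scores.to_numpy()), np.abs(U * s), atol=1e-8)
        assert np.allclose(res.eigenvalues, s**2 / (len(X) - 1), atol=1e-10)

    def test_percent_variance_matches_eigenvalue_ratios(self, rng):
        G = random_matrix(rng, n_ind=12, n_sites=30, missing_rate=0.05)
        res = structure.pca(G)
        assert np.allclose(
            res.percent_variance, 100 * res.eigenvalues / res.eigenvalues.sum()
        )
        assert res.percent_variance.sum() <= 100 + 1e-9
        assert (np.diff(res.eigenvalues) <= 1e-12).all()

    def test_duplicated_individual_identical_scores(self, rng):
        G = random_matrix(rng, n_ind=10, n_sites=30, missing_rate=0.0)
        g2 = np.vstack([G.genotypes, G.genotypes[3]])
        G2 = make_matrix(g2)
        res = structure.pca(G2)
        assert np.allclose(res.scores.iloc[3], res.scores.iloc[-1], atol=1e-9)

    def test_two_point_geometry(self):
        g = np.vstack([np.zeros((5, 10)), np.full((5, 10), 2)]).astype(np.int8)
        res = structure.pca(make_matrix(g))
        ev1 = res.scores["EV1"].to_numpy()
        assert res.percent_variance[0] == pytest.approx(100.0)
        assert len(set(np.sign(ev1[:5]))) == 1 and len(set(np.sign(ev1[5:]))) == 1
        assert np.sign(ev1[0]) != np.sign(ev1[5])

    def test_all_missing_snp_rejected(self):
        g = np.zeros((4, 3), dtype=np.int8)
        g[:, 1] = MISSING
        with pytest.raises(ValueError, match="all calls missing"):
            structure.pca(make_matrix(g))


class TestDistance:
    def test_identical_and_opposite(self):
        same = np.tile(np.repeat([0, 2], 5), (2, 1)).astype(np.int8)
        G = make_matrix(np.vstack([same, same]))
        pm = make_popmap(G, [2, 2])
        D = structure.genetic_distance(G, pm)
        assert D.iloc[0, 1] == pytest.approx(0.0)
        opp = np.vstack([np.zeros((3, 8)), np.full((3, 8), 2)]).astype(np.int8)
        G2 = make_matrix(opp)
        pm2 = make_popmap(G2, [3, 3])
        assert structure.genetic_distance(G2, pm2).iloc[0, 1] == pytest.approx(1.0)

    def test_three_pop_hand_toy(self):
        # allele freqs: pop1 (0, .5, 1, .25); pop2 (.5, .5, 0, .75); pop3 (1, 0, 1, .25)
        g1 = np.array([[0, 1, 2, 0], [0, 1, 2, 1]], dtype=np.int8)
        g2 = np.array([[1, 0, 0, 2], [1, 2, 0, 1]], dtype=np.int8)
        g3 = np.array([[2, 0, 2, 1], [2, 0, 2, 0]], dtype=np.int8)
        G = make_matrix(np.vstack([g1, g2, g3]))
        pm = make_popmap(G, [2, 2, 2])
        D = structure.genetic_distance(G, pm)
        assert D.loc["pop1", "pop2"] == pytest.approx((0.5 + 0 + 1 + 0.5) / 4)
        assert D.loc["pop1", "pop3"] == pytest.approx((1 + 0.5 + 0 + 0) / 4)
        assert D.loc["pop2", "pop3"] == pytest.approx((0.5 + 0.5 + 1 + 0.5) / 4)


def random_additive_tree(rng, n_taxa):
    """Random binary topology with branch lengths; returns the taxon list,
    the additive distance matrix, and the set of non-trivial bipartitions."""
    import itertools

    nodes = {i: [f"t{i}"] for i in range(n_taxa)}
    dist = {(i, i): 0.0 for i in range(n_taxa)}
    D = np.zeros((n_taxa, n_taxa))
    # grow a tree by random joins, tracking path lengths
    active = list(range(n_taxa))
    lengths = {}
    parent = {}
    next_id = n_taxa
    edges = []
    while len(active) > 1:
        i, j = rng.choice(len(active), 2, replace=False)
        a, b = active[int(i)], active[int(j)]
        la, lb = rng.uniform(0.1, 1.0, 2)
        parent[a], parent[b] = next_id, next_id
        lengths[a], lengths[b] = la, lb
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    root = active[0]

    def depth_to(leaf):
        path = {}
        node, acc = leaf, 0.0
        while node in parent:
            path[node] = acc
            acc += lengths[node]
            node = parent[node]
        path[node] = acc
        return path

    paths = {k: depth_to(k) for k in range(n_taxa)}
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            shared = set(paths[i]) & set(paths[j])
            mrca_d = min(paths[i][s] + paths[j][s] for s in shared)
            D[i, j] = D[j, i] = mrca_d
    labels = [f"t{i}" for i in range(n_taxa)]
    return pd.DataFrame(D, index=labels, columns=labels)


class TestNeighborJoining:
    def test_three_taxa_closed_form(self):
        D = pd.DataFrame(
            [[0, 5, 9], [5, 0, 10], [9, 10, 0]], index=list("abc"), columns=list("abc")
        )
        tree = structure.neighbor_joining(D)
        lengths = {t.name: t.length for t in tree.tips()}
        assert lengths["a"] == pytest.approx((5 + 9 - 10) / 2)
        assert lengths["b"] == pytest.approx((5 + 10 - 9) / 2)
        assert lengths["c"] == pytest.approx((9 + 10 - 5) / 2)

    def test_four_taxon_additive_recovery(self):
        # classic additive matrix with ((a,b),(c,d)) split
        D = pd.DataFrame(
            [[0, 3, 7, 8], [3, 0, 6, 7], [7, 6, 0, 3], [8, 7, 3, 0]],
            index=list("abcd"),
            columns=list("abcd"),
        )
        tree = structure.neighbor_joining(D)
        parts = structure.tree_bipartitions(tree)
        assert parts == {frozenset({"c", "d"})}
        td = tree.tip_tip_distances()
        for x in "abcd":
            for y in "abcd":
                assert td[x, y] == pytest.approx(D.loc[x, y], abs=1e-9)

    @pytest.mark.parametrize("n_taxa", [5, 8, 12])
    def test_random_additive_trees_recovered_exactly(self, rng, n_taxa):
        for _ in range(5):
            D = random_additive_tree(rng, n_taxa)
            tree = structure.neighbor_joining(D)
            td = tree.tip_tip_distances()
            for i, x in enumerate(D.index):
                for y in D.index[i + 1 :]:
                    assert td[x, y] == pytest.approx(D.loc[x, y], abs=1e-8)

    def test_tip_permutation_invariance(self, rng):
        D = random_additive_tree(rng, 7)
        perm = rng.permutation(len(D))
        D2 = D.iloc[perm, perm]
        t1 = structure.neighbor_joining(D)
        t2 = structure.neighbor_joining(D2)
        assert structure.tree_bipartitions(t1) == structure.tree_bipartitions(t2)

    def test_too_few_taxa(self):
        D = pd.DataFrame([[0, 1], [1, 0]], index=list("ab"), columns=list("ab"))
        with pytest.raises(ValueError, match="at least 3"):
            structure.neighbor_joining(D)


class TestBootstrap:
    def test_separated_clades_full_support(self):
        cfg = SimConfig(
            n_snps=300, seed=13, n_regions=2, n_ha_per_region=1, n_lakes_per_ha=3,
            fst_levels={"region": 0.5, "ha": 0.01, "lake": 0.01, "ecotype": 0.01},
            n_adaptive=0, missing_rate=0.0,
        )
        G, pm, *_ = simulate_metapopulation(cfg)
        tree = structure.bootstrap_support(G, pm, n_boot=50, seed=1)
        # the deep region split must be recovered with near-full support
        region_support = []
        for node in tree.non_tips():
            tips = {t.name for t in node.tips()}
            regions = {t[:2] for t in tips}
            if len(regions) == 1 and len(tips) == 3 and node.name:
                region_support.append(float(node.name))
        assert region_support and max(region_support) > 90

    def test_single_replicate_supports_binary(self, rng):
        G = random_matrix(rng, n_ind=20, n_sites=80, missing_rate=0.0)
        pm = make_popmap(G, [4, 4, 4, 4, 4])
        tree = structure.bootstrap_support(G, pm, n_boot=1, seed=3)
        supports = {float(n.name) for n in tree.non_tips() if n.name}
        assert supports <= {0.0, 100.0}

    def test_seed_determinism(self, rng):
        G = random_matrix(rng, n_ind=20, n_sites=60, missing_rate=0.0)
        pm = make_popmap(G, [5, 5, 5, 5])
        t1 = structure.bootstrap_support(G, pm, n_boot=20, seed=9)
        t2 = structure.bootstrap_support(G, pm, n_boot=20, seed=9)
        assert str(t1) == str(t2)


def oracle_two_level_amova(X, pop_labels):
    """Independently coded one-way (populations / within) AMOVA."""
    pops = sorted(set(pop_labels))
    n = len(X)
    grand = X.mean(axis=0)
    ss_within = ss_among = 0.0
    n_sizes = []
    for p in pops:
        idx = [i for i, q in enumerate(pop_labels) if q == p]
        m = X[idx].mean(axis=0)
        ss_within += ((X[idx] - m) ** 2).sum()
        ss_among += len(idx) * ((m - grand) ** 2).sum()
        n_sizes.append(len(idx))
    df_a, df_w = len(pops) - 1, n - len(pops)
    ms_a, ms_w = ss_among / df_a, ss_within / df_w
    n0 = (n - sum(s**2 for s in n_sizes) / n) / df_a
    sig_w = ms_w
    sig_a = (ms_a - ms_w) / n0
    return sig_a, sig_w


class TestAmova:
    def test_all_identical_zero_components(self):
        g = np.ones((12, 10), dtype=np.int8)
        G = make_matrix(g)
        pm = make_popmap(G, [3, 3, 3, 3])
        res = structure.amova(G, pm, {"ha1": "east", "ha2": "west"})
        assert np.allclose(res.components.to_numpy(), 0.0)

    def test_two_level_case_matches_oracle(self, rng):
        # collapse the hierarchy: each population its own HA, one group
        G = random_matrix(rng, n_ind=24, n_sites=30, missing_rate=0.0)
        pm_df = make_popmap(G, [8, 8, 8]).df.copy()
        pm_df["hydrometric_area"] = pm_df["population"]
        from lochgen.io import PopulationMap

        pm = PopulationMap(pm_df)
        groups = {p: "all" for p in pm_df["hydrometric_area"].unique()}
        res = structure.amova(G, pm, groups)
        sig_a, sig_w = oracle_two_level_amova(
            G.genotypes.astype(float), list(pm_df["population"])
        )
        # with HAs == populations, the among-population variance surfaces at
        # the among-HA level and the population-within-HA stratum is empty
        assert res.components["among_ha_within_groups"] == pytest.approx(sig_a, abs=1e-8)
        assert res.components["within_pops"] == pytest.approx(sig_w, abs=1e-8)
        assert res.components["among_pops_within_ha"] == 0.0
        assert res.percents.sum() == pytest.approx(100.0, abs=1e-6)

    def test_permuted_labels_kill_structure(self, rng):
        cfg = SimConfig(n_snps=200, seed=31, n_regions=2, n_ha_per_region=2,
                        n_lakes_per_ha=2, n_adaptive=0, missing_rate=0.0)
        G, pm, *_ = simulate_metapopulation(cfg)
        df = pm.df.copy()
        # shuffle individuals across populations: only within-pop variance remains
        perm = rng.permutation(len(df))
        df["population"] = df["population"].to_numpy()[perm]
        df["lake"] = df["lake"].to_numpy()[perm]
        df["hydrometric_area"] = df["hydrometric_area"].to_numpy()[perm]
        from lochgen.io import PopulationMap

        pm2 = PopulationMap(df)
        res = structure.amova(G, pm2, {"R1H1": "r1", "R1H2": "r1", "R2H1": "r2", "R2H2": "r2"})
        assert res.percents["within_pops"] > 95
        assert abs(res.percents["among_pops_within_ha"]) < 5

    def test_structured_simulation_percents(self, reference_data):
        _, G, pm, env, _ = reference_data
        groups = {ha: ("east" if ha.startswith("R1") else "west") for ha in set(pm.df["hydrometric_area"])}
        res = structure.amova(G, pm, groups, n_perm=30, seed=2)
        assert res.percents.sum() == pytest.approx(100.0, abs=1e-6)
        # strong per-lake drift: among-populations dominates the hierarchy
        assert res.percents["among_pops_within_ha"] > res.percents["among_groups"]
        assert res.p_values is not None


class TestClustering:
    def _fst(self):
        pops = ["a", "b", "c", "d"]
        m = np.array(
            [
                [0.0, 0.01, 0.3, 0.3],
                [0.01, 0.0, 0.3, 0.3],
                [0.3, 0.3, 0.0, 0.02],
                [0.3, 0.3, 0.02, 0.0],
            ]
        )
        return pd.DataFrame(m, index=pops, columns=pops)

    def test_threshold_extremes(self):
        fst = self._fst()
        assert structure.cluster_populations(fst, 0.0).nunique() == 4
        assert structure.cluster_populations(fst, 1.0).nunique() == 1

    def test_planted_groups_recovered(self):
        labels = structure.cluster_populations(self._fst(), 0.05)
        assert labels["a"] == labels["b"]
        assert labels["c"] == labels["d"]
        assert labels["a"] != labels["c"]

    def test_planted_simulation_clusters(self):
        cfg = SimConfig(
            n_snps=200, seed=17, n_regions=3, n_ha_per_region=1, n_lakes_per_ha=2,
            fst_levels={"region": 0.4, "ha": 0.01, "lake": 0.02, "ecotype": 0.01},
            n_adaptive=0, missing_rate=0.0,
        )
        G, pm, *_ = simulate_metapopulation(cfg)
        fst = __import__("lochgen.popstats", fromlist=["pairwise_fst"]).pairwise_fst(G, pm)
        labels = structure.cluster_populations(fst, 0.15)
        region_of = {p: p[:2] for p in labels.index}
        # same region -> same cluster, different region -> different cluster
        for p in labels.index:
            for q in labels.index:
                same = region_of[p] == region_of[q]
                assert (labels[p] == labels[q]) == same
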