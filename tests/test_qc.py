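"""Filter-cascade correctness: brute-force recounts, idempotence, telescoping,
and the replicate-discordance estimator."""

import math

import numpy as np
import pandas as pd
import pytest

from lochgen import qc
from lochgen.io import MISSING
from lochgen.popstats import global_per_locus_fst

from conftest import make_matrix, make_popmap, random_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(77)


def brute_presence_keep(G, popmap, min_prop):
    keep = []
    rows = popmap.row_indices(G)
    for j in range(G.n_sites):
        ok = True
        total_called = total_n = 0
        for idx in rows.values():
            called = sum(G.genotypes[i, j] != MISSING for i in idx)
            total_called += called
            total_n += len(idx)
            if called / len(idx) < min_prop:
                ok = False
        if total_called / total_n < min_prop:
            ok = False
        keep.append(ok)
    return np.array(keep)


@pytest.mark.parametrize("min_prop", [0.5, 0.66, 0.8])
def test_presence_filter_matches_recount(rng, min_prop):
    G = random_matrix(rng, n_ind=24, n_sites=80, missing_rate=0.3)
    pm = make_popmap(G, [8, 8, 8])
    G2, stage = qc.filter_presence(G, pm, min_prop)
    expected = brute_presence_keep(G, pm, min_prop)
    assert set(G2.site_ids) == set(G.site_ids[expected])
    assert stage.n_out == expected.sum()


def test_presence_removes_pop_specific_gap():
    g = np.ones((8, 2), dtype=np.int8)
    g[0:2, 0] = MISSING  # 50% missing in pop1 at SNP 0
    G = make_matrix(g)
    pm = make_popmap(G, [4, 4])
    G2, _ = qc.filter_presence(G, pm, 0.66)
    assert list(G2.site_ids) == ["snp0001"]
    # complete matrix: nothing removed
    G3, stage = qc.filter_presence(make_matrix(np.ones((8, 2))), pm, 0.66)
    assert stage.n_removed == 0


def test_maf_filter_single_allele_removed():
    # 1 alt allele among 200 -> MAF 0.005 < 0.01
    g = np.zeros((100, 2), dtype=np.int8)
    g[0, 0] = 1
    g[:50, 1] = 1
    G2, _ = qc.filter_maf(make_matrix(g), 0.01)
    assert list(G2.site_ids) == ["snp0001"]


def test_max_het_filter():
    g = np.column_stack([np.ones(20), np.repeat([0, 2], 10)]).astype(np.int8)
    G2, _ = qc.filter_max_het(make_matrix(g), 0.5)
    assert list(G2.site_ids) == ["snp0001"]


def test_first_snp_per_locus_keeps_lowest_position():
    g = np.zeros((4, 5), dtype=np.int8)
    loci = ["locA", "locA", "locA", "locB", "locB"]
    G = make_matrix(g, loci=loci)
    G2, stage = qc.first_snp_per_locus(G)
    assert stage.n_out == 2
    assert list(G2.sites["pos"]) == [100, 400]


class TestHwe:
    def brute_pvalue(self, n_het, n_hom_r, n_hom_a):
        """Enumeration oracle with explicit factorials."""
        n = n_het + n_hom_r + n_hom_a
        rare = 2 * min(n_hom_r, n_hom_a) + n_het
        common = 2 * n - rare

        def prob(h):
            r = (rare - h) // 2
            c = n - h - r
            return (
                2**h
                * math.factorial(n)
                / (math.factorial(h) * math.factorial(r) * math.factorial(c))
                * math.factorial(rare)
                * math.factorial(common)
                / math.factorial(2 * n)
                * 1.0
            )

        hs = range(rare % 2, rare + 1, 2)
        probs = {h: prob(h) for h in hs}
        total = sum(probs.values())
        obs = probs[n_het] / total
        return sum(p / total for p in probs.values() if p / total <= obs * (1 + 1e-12))

    @pytest.mark.parametrize(
        "counts", [(10, 5, 5), (20, 0, 0), (1, 10, 1), (7, 3, 9), (0, 12, 4)]
    )
    def test_exact_test_matches_enumeration(self, counts):
        assert qc.hwe_exact_pvalue(*counts) == pytest.approx(self.brute_pvalue(*counts), abs=1e-10)

    def test_balanced_counts_retained_all_het_removed(self):
        # 1:2:1 at p=0.5 is the HWE archetype
        assert qc.hwe_exact_pvalue(10, 5, 5) > 0.5
        # an all-heterozygote population of 20 is wildly out of HWE
        assert qc.hwe_exact_pvalue(20, 0, 0) < 0.001
        g = np.column_stack([np.ones(20), np.repeat([0, 1, 2], [5, 10, 5])]).astype(np.int8)
        G = make_matrix(g)
        pm = make_popmap(G, [20])
        G2, _ = qc.filter_hwe_per_pop(G, pm, alpha=0.001)
        assert list(G2.site_ids) == ["snp0001"]

    def test_rejection_rate_calibrated(self, rng):
        # data simulated under HWE: rejection rate should not exceed alpha
        n, S = 50, 400
        p = rng.uniform(0.2, 0.8, S)
        g = rng.binomial(1, p, (n, S)) + rng.binomial(1, p, (n, S))
        G = make_matrix(g.astype(np.int8))
        pm = make_popmap(G, [n])
        alpha = 0.05
        _, stage = qc.filter_hwe_per_pop(G, pm, alpha=alpha)
        assert stage.n_removed / S <= alpha * 1.5  # exact test is conservative


def test_depth_filter_inclusive_bounds(rng):
    depths = [9.9, 10.0, 15.0, 30.0, 35.0]
    G = make_matrix(np.zeros((4, 5), dtype=np.int8), depths=depths)
    G2, _ = qc.filter_depth(G)
    assert list(G2.sites["mean_depth"]) == [10.0, 15.0, 30.0]
    # random depths: retained set equals brute recount
    G = random_matrix(rng, n_ind=5, n_sites=50)
    G2, _ = qc.filter_depth(G, 10, 30)
    expected = [d for d in G.sites["mean_depth"] if 10 <= d <= 30]
    assert list(G2.sites["mean_depth"]) == expected


def test_depth_filter_skips_without_depth():
    G = make_matrix(np.zeros((2, 3), dtype=np.int8), depths=[np.nan] * 3)
    with pytest.warns(UserWarning, match="skipped"):
        G2, stage = qc.filter_depth(G)
    assert stage.n_removed == 0


class TestReplicateError:
    def _with_pairs(self, g, n_pairs):
        G = make_matrix(g)
        groups = {}
        for k in range(n_pairs):
            groups[G.individuals[2 * k]] = f"rg{k}"
            groups[G.individuals[2 * k + 1]] = f"rg{k}"
        pm = make_popmap(G, [len(g)], replicate_groups=groups)
        return G, pm

    def test_identical_replicates_zero_rate(self, rng):
        g = np.tile(rng.integers(0, 3, 50, dtype=np.int8), (4, 1))
        G, pm = self._with_pairs(g, 2)
        rep = qc.estimate_replicate_error(G, pm)
        assert rep.overall_rate == 0.0

    def test_three_mismatches_in_hundred(self):
        g = np.zeros((2, 100), dtype=np.int8)
        g[1, :3] = 1
        G, pm = self._with_pairs(g, 1)
        rep = qc.estimate_replicate_error(G, pm)
        assert rep.overall_rate == pytest.approx(0.03)
        assert rep.per_pair["co_called"].iloc[0] == 100

    def test_planted_snp_discordant_in_two_pairs(self):
        g = np.zeros((4, 10), dtype=np.int8)
        g[1, 0] = 2  # pair 1 mismatch at snp0000
        g[3, 0] = 1  # pair 2 mismatch at snp0000
        g[3, 1] = 1  # pair 2 only at snp0001
        G, pm = self._with_pairs(g, 2)
        rep = qc.estimate_replicate_error(G, pm)
        assert rep.per_snp_discordant_pairs["snp0000"] == 2
        assert rep.per_snp_discordant_pairs["snp0001"] == 1
        G2, _ = qc.drop_mismatch_snps(G, rep, max_pairs=1)
        assert "snp0000" not in set(G2.site_ids)
        assert "snp0001" in set(G2.site_ids)

    def test_drop_never_increases_error(self, rng):
        g = rng.integers(0, 3, (6, 200), dtype=np.int8)
        g[1] = g[0].copy()
        g[3] = g[2].copy()
        g[5] = g[4].copy()
        flips = rng.random((3, 200)) < 0.05
        for k, row in enumerate((1, 3, 5)):
            g[row, flips[k]] = (g[row, flips[k]] + 1) % 3
        G, pm = self._with_pairs(g, 3)
        before = qc.estimate_replicate_error(G, pm)
        G2, _ = qc.drop_mismatch_snps(G, before, max_pairs=1)
        after = qc.estimate_replicate_error(G2, pm)
        assert after.overall_rate <= before.overall_rate + 1e-12

    def test_higher_coverage_replicate_kept(self):
        g = np.zeros((2, 10), dtype=np.int8)
        g[0, :4] = MISSING  # original has lower coverage
        G, pm = self._with_pairs(g, 1)
        G2, pm2 = qc.drop_replicates(G, pm)
        assert G2.individuals == ["ind001"]
        assert not pm2.replicate_pairs()


def test_remove_nonneutral_quantile_and_union(rng):
    G = random_matrix(rng, n_ind=20, n_sites=100, missing_rate=0.0)
    pm = make_popmap(G, [10, 10])
    fst = global_per_locus_fst(G, pm)
    # empty candidates: exactly ceil(0.05*S) removed
    G2, stage = qc.remove_nonneutral(G, set(), fst, 0.05)
    assert stage.n_removed == math.ceil(0.05 * 100)
    # candidates inside the top set: removed count unchanged
    top5 = set(fst.sort_values(ascending=False).index[:5])
    G3, stage3 = qc.remove_nonneutral(G, top5, fst, 0.05)
    assert stage3.n_removed == 5
    # random candidate set: brute-force union
    cand = set(rng.choice(G.site_ids, 10, replace=False))
    order = fst.reindex(G.site_ids).sort_values(ascending=False, kind="stable")
    brute = set(order.index[:5]) | cand
    G4, stage4 = qc.remove_nonneutral(G, cand, fst, 0.05)
    assert set(G.site_ids) - set(G4.site_ids) == brute


def test_complete_cases(rng):
    g = np.zeros((5, 4), dtype=np.int8)
    g[2, 1] = MISSING
    G2, _ = qc.complete_cases(make_matrix(g))
    assert list(G2.site_ids) == ["snp0000", "snp0002", "snp0003"]
    G = random_matrix(rng, n_ind=10, n_sites=50, missing_rate=0.2)
    G2, _ = qc.complete_cases(G)
    brute = [sid for j, sid in enumerate(G.site_ids) if (G.genotypes[:, j] != MISSING).all()]
    assert list(G2.site_ids) == brute


def test_every_filter_idempotent(rng):
    G = random_matrix(rng, n_ind=24, n_sites=120, missing_rate=0.15, n_loci=60)
    pm = make_popmap(G, [8, 8, 8])
    filters = [
        lambda g: qc.filter_presence(g, pm, 0.66),
        lambda g: qc.filter_maf(g, 0.05),
        lambda g: qc.filter_max_het(g, 0.5),
        qc.first_snp_per_locus,
        lambda g: qc.filter_hwe_per_pop(g, pm, 0.01),
        lambda g: qc.filter_depth(g, 10, 30),
        qc.complete_cases,
    ]
    for f in filters:
        G1, _ = f(G)
        G2, stage2 = f(G1)
        assert stage2.n_removed == 0


def test_cascade_report_telescopes(rng):
    G = random_matrix(rng, n_ind=24, n_sites=150, missing_rate=0.1, n_loci=80)
    pm = make_popmap(G, [8, 8, 8])
    Gf, pmf, report, err = qc.apply_cascade(G, pm)
    frame = report.to_frame()
    assert (frame["snps_out"] == frame["snps_in"] - frame["snps_removed"]).all()
    assert (frame["snps_in"].iloc[1:].to_numpy() == frame["snps_out"].iloc[:-1].to_numpy()).all()
    assert frame["snps_out"].iloc[-1] == Gf.n_sites
    assert list(frame["stage"][:4]) == ["presence", "maf", "max_het", "first_snp_per_locus"]
    # chaining a stage with the wrong input count is rejected
    with pytest.raises(ValueError, match="starts from"):
        report.add(qc.FilterStage("bogus", Gf.n_sites + 1, 0))
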