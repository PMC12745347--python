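"""Shared fixtures and tiny matrix builders for the test suite."""

import numpy as np
import pandas as pd
import pytest

from lochgen.io import POPMAP_COLUMNS, GenotypeMatrix, PopulationMap
from lochgen.sim import reference_config, simulate_metapopulation


def make_matrix(genotypes, loci=None, depths=None, chrom=None) -> GenotypeMatrix:
    """GenotypeMatrix from a plain (individuals x sites) array."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_ind, n_sites = genotypes.shape
    sites = pd.DataFrame(
        {
            "id": [f"snp{j:04d}" for j in range(n_sites)],
            "chrom": chrom if chrom is not None else ["chr1"] * n_sites,
            "pos": np.arange(1, n_sites + 1) * 100,
            "locus": loci if loci is not None else [f"loc{j:04d}" for j in range(n_sites)],
            "ref": ["A"] * n_sites,
            "alt": ["C"] * n_sites,
            "mean_depth": depths if depths is not None else [15.0] * n_sites,
        }
    )
    inds = [f"ind{i:03d}" for i in range(n_ind)]
    return GenotypeMatrix(genotypes, sites, inds)


def make_popmap(G: GenotypeMatrix, pop_sizes, replicate_groups=None) -> PopulationMap:
    """Assign the first sum(pop_sizes) individuals to populations pop1..popK,
    one lake per population, two HAs split halfway."""
    rows = []
    k = 0
    n_pops = len(pop_sizes)
    for p, size in enumerate(pop_sizes):
        for _ in range(size):
            rows.append(
                {
                    "individual": G.individuals[k],
                    "population": f"pop{p + 1}",
                    "lake": f"lake{p + 1}",
                    "hydrometric_area": f"ha{1 if p < n_pops / 2 else 2}",
                    "ecotype": "unimodal",
                    "replicate_group": (replicate_groups or {}).get(G.individuals[k]),
                }
            )
            k += 1
    return PopulationMap(pd.DataFrame(rows, columns=POPMAP_COLUMNS))


def random_matrix(rng, n_ind=30, n_sites=60, missing_rate=0.1, n_loci=None) -> GenotypeMatrix:
    p = rng.uniform(0.05, 0.95, n_sites)
    g = rng.binomial(2, p, size=(n_ind, n_sites)).astype(np.int8)
    g[rng.random((n_ind, n_sites)) < missing_rate] = -1
    loci = None
    if n_loci:
        loci = [f"loc{rng.integers(0, n_loci):04d}" for _ in range(n_sites)]
        loci = sorted(loci)
    depths = np.round(rng.uniform(5, 40, n_sites), 2)
    return make_matrix(g, loci=loci, depths=depths)


@pytest.fixture(scope="session")
def reference_data():
    """The seeded reference simulation shared by the heavier tests."""
    cfg = reference_config(1)
    G, popmap, env, truth = simulate_metapopulation(cfg)
    return cfg, G, popmap, env, truth
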