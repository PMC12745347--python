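"""Diversity and differentiation statistics.

Per-population observed/expected heterozygosity, nucleotide diversity at
variant sites, private alleles, F_IS, Weir-Cockerham (1984) pairwise and
multi-population per-locus F_ST, and the Weir-Goudet population-specific
F_ST (beta) based on allele-matching proportions.

Pairwise theta is the ratio-of-averages estimator (sum of a over loci divided
by the sum of a + b + c); loci monomorphic across the compared populations are
skipped, and a pair is only scored at loci where both populations have at
least two called genotypes.  Entries may be slightly negative: that is a
property of the estimator, not an error.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, PopulationMap


# ---------------------------------------------------------------------------
# per-population summaries
# ---------------------------------------------------------------------------


def per_pop_stats(G: GenotypeMatrix, popmap: PopulationMap) -> pd.DataFrame:
    """Per-population Ho, He, pi, private alleles, F_IS and sample size.

    For each SNP and population, statistics use non-missing calls only:
    ``Ho`` is the heterozygote fraction; ``He = 2 p (1 - p)``;
    ``pi = n/(n-1) * 2 p (1 - p)`` with ``n`` the number of called alleles
    (the small-sample-corrected expected heterozygosity); per-site
    ``F_IS = 1 - Ho/He`` is averaged over sites where ``He > 0``.  Averages
    are over the sites that are variant in the full dataset.  A private allele
    is an allele segregating in the focal population and absent (frequency
    zero among non-missing calls) in every other population.
    """
    rows_by_pop = popmap.row_indices(G)
    pops = list(rows_by_pop)
    if any(len(r) == 0 for r in rows_by_pop.values()):
        raise ValueError("population with zero individuals")

    # per-pop per-site allele counts
    alt = np.zeros((len(pops), G.n_sites))
    tot = np.zeros((len(pops), G.n_sites))
    ho_site = np.zeros((len(pops), G.n_sites))
    ncalled = np.zeros((len(pops), G.n_sites))
    for k, pop in enumerate(pops):
        g = G.genotypes[rows_by_pop[pop]]
        called = g != MISSING
        alt[k] = np.where(called, g, 0).sum(axis=0)
        ncalled[k] = called.sum(axis=0)
        tot[k] = 2 * ncalled[k]
        ho_site[k] = ((g == 1) & called).sum(axis=0)

    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot > 0, alt / np.maximum(tot, 1), np.nan)
        ho = np.where(ncalled > 0, ho_site / np.maximum(ncalled, 1), np.nan)
    he = 2 * p * (1 - p)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(tot > 1, tot / np.maximum(tot - 1, 1) * he, np.nan)
        fis_site = np.where(he > 0, 1 - ho / he, np.nan)

    def _nanmean(x: np.ndarray) -> float:
        x = x[np.isfinite(x)]
        return float(x.mean()) if x.size else float("nan")

    # private alleles: allele present here, absent among called everywhere else
    present_alt = (alt > 0) & (tot > 0)
    present_ref = (alt < tot) & (tot > 0)
    out = []
    for k, pop in enumerate(pops):
        others = [m for m in range(len(pops)) if m != k]
        others_alt = present_alt[others].any(axis=0)
        others_ref = present_ref[others].any(axis=0)
        pa = int(
            ((present_alt[k] & ~others_alt) | (present_ref[k] & ~others_ref)).sum()
        )
        out.append(
            {
                "population": pop,
                "n": len(rows_by_pop[pop]),
                "ho": _nanmean(ho[k]),
                "he": _nanmean(he[k]),
                "pi": _nanmean(pi[k]),
                "private_alleles": pa,
                "fis": _nanmean(fis_site[k]),
            }
        )
    df = pd.DataFrame(out).set_index("population")
    beta = population_specific_fst(G, popmap)
    df["beta_fst"] = beta
    return df


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------


def _wc_components(G: GenotypeMatrix, rows_list: list[np.ndarray]):
    """Per-locus Weir-Cockerham a, b, c variance components for r populations.

    Returns (a, b, c, usable) arrays over loci; ``usable`` marks loci where at
    least two populations have >= 2 called genotypes and the locus is
    polymorphic across the included populations.
    """
    r_max = len(rows_list)
    S = G.n_sites
    n_i = np.zeros((r_max, S))
    p_i = np.zeros((r_max, S))
    h_i = np.zeros((r_max, S))
    for k, rows in enumerate(rows_list):
        g = G.genotypes[rows]
        called = g != MISSING
        n = called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(n > 0, np.where(called, g, 0).sum(axis=0) / (2 * np.maximum(n, 1)), 0.0)
            h_i[k] = np.where(n > 0, ((g == 1) & called).sum(axis=0) / np.maximum(n, 1), 0.0)
        n_i[k] = n

    include = n_i >= 2  # a population joins a locus only with >= 2 genotypes
    r = include.sum(axis=0).astype(float)
    n_i = np.where(include, n_i, 0.0)
    sum_n = n_i.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = sum_n / np.maximum(r, 1)
        pbar = (n_i * p_i).sum(axis=0) / np.maximum(sum_n, 1)
        hbar = (n_i * h_i).sum(axis=0) / np.maximum(sum_n, 1)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / np.maximum((r - 1) * nbar, 1e-300)
        nc = (sum_n - (n_i**2).sum(axis=0) / np.maximum(sum_n, 1)) / np.maximum(r - 1, 1e-300)

        a = (nbar / np.maximum(nc, 1e-300)) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / np.maximum(r, 1) * s2 - hbar / 4) / np.maximum(nbar - 1, 1e-300)
        )
        b = (nbar / np.maximum(nbar - 1, 1e-300)) * (
            pbar * (1 - pbar) - (r - 1) / np.maximum(r, 1) * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2

    polymorphic = (pbar > 0) & (pbar < 1)
    usable = (r >= 2) & polymorphic & (nbar > 1) & (nc > 0)
    return a, b, c, usable


def pairwise_fst(G: GenotypeMatrix, popmap: PopulationMap) -> pd.DataFrame:
    """Symmetric matrix of pairwise Weir-Cockerham theta (ratio of averages)."""
    rows_by_pop = popmap.row_indices(G)
    pops = list(rows_by_pop)
    if len(pops) < 2:
        raise ValueError("pairwise F_ST needs at least two populations")
    mat = np.zeros((len(pops), len(pops)))
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            a, b, c, use = _wc_components(G, [rows_by_pop[pops[i]], rows_by_pop[pops[j]]])
            denom = (a + b + c)[use].sum()
            if not use.any() or denom == 0:
                mat[i, j] = mat[j, i] = np.nan
            else:
                mat[i, j] = mat[j, i] = a[use].sum() / denom
    return pd.DataFrame(mat, index=pops, columns=pops)


def global_per_locus_fst(G: GenotypeMatrix, popmap: PopulationMap) -> pd.Series:
    """Multi-population Weir-Cockerham theta per locus (NaN where undefined)."""
    rows_by_pop = popmap.row_indices(G)
    a, b, c, use = _wc_components(G, list(rows_by_pop.values()))
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(use & ((a + b + c) != 0), a / (a + b + c), np.nan)
    return pd.Series(theta, index=G.site_ids, name="fst")


def mean_pairwise_fst(fst: pd.DataFrame) -> float:
    vals = fst.to_numpy()[np.triu_indices(len(fst), k=1)]
    return float(np.nanmean(vals))


# ---------------------------------------------------------------------------
# Weir-Goudet population-specific beta
# ---------------------------------------------------------------------------


def population_specific_fst(G: GenotypeMatrix, popmap: PopulationMap) -> pd.Series:
    """Population-specific F_ST via allele-matching proportions.

    ``beta_i = (M_i - M_B) / (1 - M_B)`` where ``M_i`` is the probability
    that two distinct alleles drawn within population ``i`` match and ``M_B``
    the mean matching probability for alleles drawn from two different
    populations; both are averaged over loci before the ratio is taken.
    """
    rows_by_pop = popmap.row_indices(G)
    pops = list(rows_by_pop)
    if len(pops) < 2:
        raise ValueError("population-specific F_ST needs at least two populations")
    S = G.n_sites
    x = np.zeros((len(pops), S))  # alt allele counts
    n = np.zeros((len(pops), S))  # called allele counts
    for k, pop in enumerate(pops):
        alt, tot = G.alt_counts(rows_by_pop[pop])
        x[k], n[k] = alt, tot

    with np.errstate(invalid="ignore", divide="ignore"):
        y = n - x
        m_within = np.where(
            n >= 2, (x * (x - 1) + y * (y - 1)) / np.maximum(n * (n - 1), 1), np.nan
        )
        p = np.where(n > 0, x / np.maximum(n, 1), np.nan)

    m_between = []
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            m_between.append(p[i] * p[j] + (1 - p[i]) * (1 - p[j]))
    mb_loci = np.nanmean(np.array(m_between), axis=0)
    mb = float(np.nanmean(mb_loci))
    if mb >= 1.0 - 1e-12:
        raise ValueError("all populations fixed and identical: beta undefined")
    mi = np.nanmean(m_within, axis=1)
    beta = (mi - mb) / (1.0 - mb)
    return pd.Series(beta, index=pops, name="beta_fst")
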