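"""Synthetic metapopulation generator.

Emulates the statistical structure of a lake-resident salmonid system:
a two-region (east/west) x Hydrometric-Area x lake hierarchy with strong
per-lake drift, sympatric ecotype pairs in a fraction of lakes, loci whose
frequencies track a climatic gradient, technical replicate pairs with a known
genotyping-error rate, missingness and per-site read depth.

Drift is modelled with Balding-Nichols beta draws composed top-down: at each
hierarchy level with intensity ``F`` the child frequency is drawn from
``Beta(p(1-F)/F, (1-p)(1-F)/F)`` around the parent frequency ``p``.
Environment-associated ("adaptive") loci additionally shift the lake frequency
on the logit scale in proportion to the lake's standardised climate value.
No linkage, recombination or coalescent genealogy is simulated.

All randomness derives from a single integer seed; each stage draws from its
own deterministically spawned sub-stream, so seeded runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import (
    CLIMATE_VARS,
    MISSING,
    POPMAP_COLUMNS,
    EnvironmentTable,
    GenotypeMatrix,
    PopulationMap,
)

# frequencies are clipped away from fixation before binomial draws so that the
# minor-allele-frequency filter stays exercisable
FREQ_CLIP = (0.001, 0.999)


@dataclass
class SimConfig:
    """Study conditions for the synthetic metapopulation.

    ``fst_levels`` gives the Balding-Nichols drift intensity applied at each
    hierarchy level (region, Hydrometric Area, lake, ecotype-within-lake),
    each in the open interval (0, 1).  ``gea_effect`` is the logit-scale shift
    per unit of standardised climate applied to adaptive loci.  ``error_rate``
    is the per-genotype replicate discordance probability.
    """

    n_regions: int = 2
    n_ha_per_region: int = 4
    n_lakes_per_ha: int = 2
    ecotype_lake_fraction: float = 0.15
    n_ind_per_pop: int = 10
    n_snps: int = 1000
    fst_levels: dict = field(
        default_factory=lambda: {"region": 0.02, "ha": 0.05, "lake": 0.25, "ecotype": 0.05}
    )
    n_adaptive: int = 20
    gea_effect: float = 2.0
    error_rate: float = 0.026
    n_replicate_pairs: int = 10
    missing_rate: float = 0.10
    depth_mean: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_regions, self.n_ha_per_region, self.n_lakes_per_ha) < 1:
            raise ValueError("hierarchy must contain at least one region, HA and lake")
        if self.n_snps < 1:
            raise ValueError("n_snps must be positive")
        if self.n_ind_per_pop < 1:
            raise ValueError("n_ind_per_pop must be positive")
        for key in ("region", "ha", "lake", "ecotype"):
            f = self.fst_levels.get(key)
            if f is None or not (0.0 < f < 1.0):
                raise ValueError(f"fst_levels[{key!r}] must lie in (0, 1)")
        for name in ("ecotype_lake_fraction", "missing_rate", "error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_adaptive > self.n_snps:
            raise ValueError("n_adaptive cannot exceed n_snps")

    @property
    def n_lakes(self) -> int:
        return self.n_regions * self.n_ha_per_region * self.n_lakes_per_ha


@dataclass
class SimTruth:
    """Ground truth recorded alongside a simulated dataset."""

    adaptive_snp_ids: set
    env_driver: str
    pop_freqs: pd.DataFrame  # populations x SNP ids, true sampling frequencies
    env_z: pd.Series  # standardised driver value per lake
    cluster_labels: dict  # population -> planted cluster (its lake)
    replicate_pairs: list = field(default_factory=list)  # (original, replicate)


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    p = np.clip(p, *FREQ_CLIP)
    shape = (1.0 - f) / f
    return rng.beta(p * shape, (1.0 - p) * shape)


def _environment(rng: np.random.Generator, lake_names: list[str], region_of: dict) -> pd.DataFrame:
    """One row per lake: latitude gradient, 19 bioclim variables and lake
    bathymetry.

    The bioclim set reproduces the strong block structure of real WorldClim
    data: a temperature block (bio1/5/6/10/11 near-duplicates, |rho| > 0.7,
    exercising collinearity pruning), quarter-mean temperatures (bio8, bio9)
    only moderately tied to the annual mean, a tight precipitation block
    (bio12 driving bio13/14/16-19), and a handful of quasi-independent
    seasonality measures.
    """
    n = len(lake_names)
    # latitude: east region sits a little further north, plus lake scatter
    reg_idx = np.array([region_of[lake] for lake in lake_names])
    latitude = 55.0 + 1.5 * reg_idx + rng.uniform(0, 3.0, n)
    rows = {"lake": lake_names, "latitude": np.round(latitude, 4)}
    # temperature block falls with latitude
    bio1 = 12.0 - 0.8 * (latitude - 55.0) + rng.normal(0, 0.6, n)
    rows["bio1"] = bio1
    rows["bio5"] = bio1 + 8.0 + rng.normal(0, 0.5, n)
    rows["bio6"] = bio1 - 8.0 + rng.normal(0, 0.5, n)
    rows["bio10"] = bio1 + 4.0 + rng.normal(0, 0.4, n)
    rows["bio11"] = 0.9 * bio1 - 4.0 + rng.normal(0, 0.25, n)
    # wettest/driest-quarter means only partly track the annual mean
    rows["bio8"] = 0.5 * bio1 + rng.normal(0, 1.5, n) + 2.0
    rows["bio9"] = 0.5 * bio1 + rng.normal(0, 1.5, n) - 2.0
    # ranges and seasonality
    rows["bio2"] = rng.normal(7.0, 1.0, n)
    rows["bio3"] = rng.normal(33.0, 3.0, n)
    rows["bio7"] = rows["bio5"] - rows["bio6"] + rng.normal(0, 0.1, n)
    rows["bio4"] = 30.0 * rows["bio7"] + rng.normal(0, 8.0, n)
    rows["bio15"] = rng.normal(25.0, 5.0, n)
    # precipitation block
    bio12 = rng.normal(1400.0, 300.0, n)
    rows["bio12"] = bio12
    rows["bio13"] = 0.13 * bio12 + rng.normal(0, 8.0, n)
    rows["bio14"] = 0.04 * bio12 + rng.normal(0, 4.0, n)
    rows["bio16"] = 0.35 * bio12 + rng.normal(0, 15.0, n)
    rows["bio17"] = 0.13 * bio12 + rng.normal(0, 10.0, n)
    rows["bio18"] = 0.20 * bio12 + rng.normal(0, 12.0, n)
    rows["bio19"] = 0.30 * bio12 + rng.normal(0, 12.0, n)
    max_depth = np.exp(rng.normal(3.2, 0.9, n))
    rows["max_depth"] = np.round(np.clip(max_depth, 2.0, 310.0), 1)
    rows["mean_depth"] = np.round(0.4 * rows["max_depth"], 1)
    rows["surface_area"] = np.round(np.exp(rng.normal(3.0, 1.2, n)).clip(1.0, 4000.0), 1)
    rows["littoral_pct"] = np.round(rng.uniform(5, 80, n), 1)
    rows["altitude"] = np.round(rng.uniform(5, 500, n), 1)
    rows["distance_to_sea"] = np.round(rng.uniform(1, 120, n), 1)
    df = pd.DataFrame(rows)
    df["scenario"] = "current"
    return df


def simulate_metapopulation(config: SimConfig):
    """Generate a full synthetic dataset.

    Returns
    -------
    (GenotypeMatrix, PopulationMap, EnvironmentTable, SimTruth)
    """
    rngs = _spawn(config.seed, 6)
    rng_freq, rng_env, rng_geno, rng_miss, rng_depth, rng_layout = rngs

    # --- hierarchy layout -------------------------------------------------
    lake_names, region_of, ha_of = [], {}, {}
    for r in range(config.n_regions):
        for h in range(config.n_ha_per_region):
            ha = f"R{r + 1}H{h + 1}"
            for l in range(config.n_lakes_per_ha):
                lake = f"{ha}L{l + 1}"
                lake_names.append(lake)
                region_of[lake] = r
                ha_of[lake] = ha
    n_eco = int(round(config.ecotype_lake_fraction * len(lake_names)))
    eco_lakes = set(
        rng_layout.choice(lake_names, size=n_eco, replace=False) if n_eco else []
    )

    pops, pop_lake, pop_ecotype, pop_sizes = [], {}, {}, {}
    for lake in lake_names:
        if lake in eco_lakes:
            half = max(config.n_ind_per_pop // 2, 1)
            for eco, tag in (("benthivore", "bn"), ("planktivore", "pl")):
                pop = f"{lake}_{tag}"
                pops.append(pop)
                pop_lake[pop], pop_ecotype[pop], pop_sizes[pop] = lake, eco, half
        else:
            pops.append(lake)
            pop_lake[lake] = lake
            pop_ecotype[lake], pop_sizes[lake] = "unimodal", config.n_ind_per_pop

    # --- environment ------------------------------------------------------
    env_df = _environment(rng_env, lake_names, region_of)
    env = EnvironmentTable(env_df)
    driver = "bio1"
    vals = env_df.set_index("lake")[driver]
    env_z = (vals - vals.mean()) / vals.std(ddof=0)

    # --- allele frequencies: Balding-Nichols composed top-down ------------
    S = config.n_snps
    p0 = rng_freq.uniform(0.05, 0.95, S)
    region_freq = {
        r: _balding_nichols(rng_freq, p0, config.fst_levels["region"])
        for r in range(config.n_regions)
    }
    ha_freq = {}
    for lake in lake_names:
        ha = ha_of[lake]
        if ha not in ha_freq:
            ha_freq[ha] = _balding_nichols(
                rng_freq, region_freq[region_of[lake]], config.fst_levels["ha"]
            )
    lake_freq = {
        lake: _balding_nichols(rng_freq, ha_freq[ha_of[lake]], config.fst_levels["lake"])
        for lake in lake_names
    }

    adaptive_idx = (
        np.sort(rng_freq.choice(S, size=config.n_adaptive, replace=False))
        if config.n_adaptive
        else np.array([], dtype=int)
    )
    for lake in lake_names:
        p = lake_freq[lake]
        shifted = expit(
            logit(np.clip(p[adaptive_idx], *FREQ_CLIP))
            + config.gea_effect * env_z[lake]
        )
        p[adaptive_idx] = shifted
        lake_freq[lake] = np.clip(p, *FREQ_CLIP)

    pop_freq = {}
    for pop in pops:
        base = lake_freq[pop_lake[pop]]
        if pop_ecotype[pop] == "unimodal":
            pop_freq[pop] = base
        else:
            p = _balding_nichols(rng_freq, base, config.fst_levels["ecotype"])
            p[adaptive_idx] = base[adaptive_idx]  # adaptation acts at lake level
            pop_freq[pop] = np.clip(p, *FREQ_CLIP)

    # --- site metadata ----------------------------------------------------
    n_chroms = 4
    chrom_of = np.sort(rng_layout.integers(0, n_chroms, S))
    # ~30% of RAD loci carry a second SNP; positions strictly increasing
    site_rows = []
    locus_counter = 0
    j = 0
    pos_cursor = np.zeros(n_chroms, dtype=np.int64)
    while j < S:
        c = int(chrom_of[j])
        locus_counter += 1
        locus = f"loc{locus_counter:06d}"
        pos_cursor[c] += int(rng_layout.integers(500, 5000))
        span = 2 if (rng_layout.random() < 0.3 and j + 1 < S and chrom_of[j + 1] == c) else 1
        for k in range(span):
            pos_cursor[c] += 10 * k + (0 if k == 0 else int(rng_layout.integers(1, 80)))
            ref, alt = rng_layout.choice(list("ACGT"), size=2, replace=False)
            site_rows.append(
                {
                    "id": f"snp{j:06d}",
                    "chrom": f"chr{c + 1}",
                    "pos": int(pos_cursor[c]),
                    "locus": locus,
                    "ref": ref,
                    "alt": alt,
                }
            )
            j += 1
            if j >= S:
                break
    sites = pd.DataFrame(site_rows)
    sites["mean_depth"] = np.round(
        rng_depth.gamma(10.0, config.depth_mean / 10.0, S), 2
    )

    # --- genotypes, missingness -------------------------------------------
    # RADseq missingness is site-structured: a fraction of sites is fully
    # genotyped while the rest lose calls at a beta-distributed per-site rate
    # (so that complete-case subsets stay non-trivial at realistic cohort
    # sizes, as in real reduced-representation data).
    if config.missing_rate > 0:
        complete_sites = rng_miss.random(S) < 0.3
        rate_rest = config.missing_rate / 0.7
        b = 2.0 * (1.0 - rate_rest) / rate_rest
        site_rate = np.where(complete_sites, 0.0, rng_miss.beta(2.0, b, S))
    else:
        site_rate = np.zeros(S)
    individuals, pm_rows, geno_blocks = [], [], []
    for pop in pops:
        n = pop_sizes[pop]
        g = rng_geno.binomial(2, pop_freq[pop], size=(n, S)).astype(np.int8)
        if config.missing_rate > 0:
            mask = rng_miss.random((n, S)) < site_rate[None, :]
            g[mask] = MISSING
        geno_blocks.append(g)
        lake = pop_lake[pop]
        for i in range(n):
            ind = f"{pop}_i{i + 1:02d}"
            individuals.append(ind)
            pm_rows.append(
                {
                    "individual": ind,
                    "population": pop,
                    "lake": lake,
                    "hydrometric_area": ha_of[lake],
                    "ecotype": pop_ecotype[pop],
                    "replicate_group": None,
                }
            )

    G = GenotypeMatrix(np.vstack(geno_blocks), sites, individuals)
    popmap = PopulationMap(
        pd.DataFrame(pm_rows, columns=POPMAP_COLUMNS),
        lake_coords=env_df[["lake", "latitude"]].assign(
            longitude=np.round(rng_layout.uniform(-6.5, -3.0, len(lake_names)), 4)
        ),
    )
    truth = SimTruth(
        adaptive_snp_ids=set(sites["id"].iloc[adaptive_idx]),
        env_driver=driver,
        pop_freqs=pd.DataFrame(
            np.vstack([pop_freq[p] for p in pops]), index=pops, columns=sites["id"]
        ),
        env_z=env_z,
        cluster_labels={p: pop_lake[p] for p in pops},
    )
    return G, popmap, env, truth


def simulate_replicates(G: GenotypeMatrix, popmap: PopulationMap, config: SimConfig):
    """Append technical replicate individuals with planted genotyping error.

    The first individual of each of ``n_replicate_pairs`` distinct populations
    is duplicated; each non-missing genotype of the copy is replaced by one of
    the other two codes with probability ``error_rate``.  Pairings are recorded
    in the population map's ``replicate_group`` column.

    Returns the extended ``(GenotypeMatrix, PopulationMap, pairs)``.
    """
    if not (0.0 <= config.error_rate <= 1.0):
        raise ValueError("error_rate must lie in [0, 1]")
    pops = popmap.populations
    if config.n_replicate_pairs > len(G.individuals):
        raise ValueError("more replicate pairs requested than individuals available")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(8)[7])
    sources = []
    for pop in pops:
        inds = popmap.individuals_of(pop)
        if inds:
            sources.append(inds[0])
        if len(sources) == config.n_replicate_pairs:
            break
    # fall back to additional individuals if there are fewer pops than pairs
    for ind in G.individuals:
        if len(sources) == config.n_replicate_pairs:
            break
        if ind not in sources:
            sources.append(ind)

    lookup = {ind: i for i, ind in enumerate(G.individuals)}
    new_rows, pm_rows, pairs = [], [], []
    pm = popmap.df.copy()
    for k, src in enumerate(sources):
        row = G.genotypes[lookup[src]].copy()
        called = row != MISSING
        flip = called & (rng.random(G.n_sites) < config.error_rate)
        for j in np.flatnonzero(flip):
            others = [g for g in (0, 1, 2) if g != row[j]]
            row[j] = others[int(rng.integers(0, 2))]
        rep = f"{src}_rep"
        group = f"repgrp{k + 1:03d}"
        new_rows.append(row)
        src_row = pm.loc[pm["individual"] == src].iloc[0].to_dict()
        pm.loc[pm["individual"] == src, "replicate_group"] = group
        src_row.update({"individual": rep, "replicate_group": group})
        pm_rows.append(src_row)
        pairs.append((src, rep))

    G2 = GenotypeMatrix(
        np.vstack([G.genotypes] + [r[None, :] for r in new_rows]) if new_rows else G.genotypes,
        G.sites.copy(),
        G.individuals + [f"{s}_rep" for s in sources],
    )
    pm2 = PopulationMap(
        pd.concat([pm, pd.DataFrame(pm_rows)], ignore_index=True)[POPMAP_COLUMNS],
        popmap.lake_coords,
    )
    return G2, pm2, pairs


def simulate_future_climate(env: EnvironmentTable, displacement: dict, scenario: str = "future") -> EnvironmentTable:
    """Produce a future-scenario environment table by shifting climate columns.

    ``displacement`` maps climate variable names to either a scalar shift or a
    per-lake mapping/Series.  Bathymetric variables may not be shifted.
    """
    for var in displacement:
        if var not in CLIMATE_VARS:
            raise ValueError(f"cannot displace non-climatic variable {var!r}")
    cur = env.df[env.df["scenario"] == "current"].copy()
    if cur.empty:
        raise ValueError("environment table has no 'current' scenario")
    for var, shift in displacement.items():
        if np.isscalar(shift):
            cur[var] = cur[var] + shift
        else:
            shift = pd.Series(shift)
            cur[var] = cur[var].to_numpy() + shift.reindex(cur["lake"]).to_numpy()
    cur["scenario"] = scenario
    return EnvironmentTable(pd.concat([env.df, cur], ignore_index=True))


def reference_config(seed: int = 0) -> SimConfig:
    """The seeded reference regime used throughout the test-bed: 20 unimodal
    lake populations (2 regions x 5 HAs x 2 lakes), 2000 SNPs of which 20 are
    planted environment-associated loci at large effect (a logit shift of 4
    per standard deviation of climate, well clear of the configured drift
    noise), replicate pairs at a 2.6% error rate."""
    return SimConfig(
        n_regions=2,
        n_ha_per_region=5,
        n_lakes_per_ha=2,
        ecotype_lake_fraction=0.0,
        n_ind_per_pop=10,
        n_snps=2000,
        fst_levels={"region": 0.02, "ha": 0.05, "lake": 0.15, "ecotype": 0.05},
        n_adaptive=20,
        gea_effect=4.0,
        error_rate=0.026,
        n_replicate_pairs=10,
        missing_rate=0.05,
        depth_mean=15.0,
        seed=seed,
    )


def expected_pairwise_fst(config: SimConfig) -> float:
    """Mean configured pairwise differentiation over all population pairs.

    For two populations whose lineages separate ``levels`` below their common
    ancestor, the composite Balding-Nichols drift is
    ``1 - prod(1 - F_level)`` over the levels on which they drift
    independently; the mean weights each pair type by its frequency among all
    unimodal lake pairs.
    """
    f = config.fst_levels
    lakes_per_ha = config.n_lakes_per_ha
    has = config.n_ha_per_region
    n_lakes = config.n_lakes
    same_ha = n_lakes * (lakes_per_ha - 1) / 2
    same_region = config.n_regions * has * (has - 1) / 2 * lakes_per_ha**2
    total = n_lakes * (n_lakes - 1) / 2
    cross_region = total - same_ha - same_region
    w = np.array([same_ha, same_region, cross_region]) / total
    comp = np.array(
        [
            1 - (1 - f["lake"]),
            1 - (1 - f["ha"]) * (1 - f["lake"]),
            1 - (1 - f["region"]) * (1 - f["ha"]) * (1 - f["lake"]),
        ]
    )
    return float((w * comp).sum())
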