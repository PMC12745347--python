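"""SNP retention cascade and replicate-based genotyping-error filtering.

The cascade mirrors a standard RADseq post-genotyping pipeline: per-population
and overall presence, pooled minor-allele frequency, pooled observed
heterozygosity, one SNP per RAD locus, per-population Hardy-Weinberg exact
tests, mean-depth bounds, and removal of SNPs discordant across technical
replicate pairs.  Every stage returns the filtered matrix together with a
:class:`FilterStage` record; :class:`FilterReport` chains stages and checks
that counts telescope (``out = in - removed`` at every stage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, PopulationMap


@dataclass
class FilterStage:
    name: str
    n_in: int
    n_removed: int

    @property
    def n_out(self) -> int:
        return self.n_in - self.n_removed


@dataclass
class FilterReport:
    stages: list = field(default_factory=list)

    def add(self, stage: FilterStage) -> None:
        if self.stages and stage.n_in != self.stages[-1].n_out:
            raise ValueError(
                f"stage {stage.name!r} starts from {stage.n_in} SNPs but the "
                f"previous stage left {self.stages[-1].n_out}"
            )
        self.stages.append(stage)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"stage": s.name, "snps_in": s.n_in, "snps_removed": s.n_removed, "snps_out": s.n_out}
                for s in self.stages
            ]
        )


def _apply(G: GenotypeMatrix, keep: np.ndarray, name: str) -> tuple[GenotypeMatrix, FilterStage]:
    keep = np.asarray(keep, dtype=bool)
    stage = FilterStage(name, G.n_sites, int((~keep).sum()))
    return G.take_sites(keep), stage


# ---------------------------------------------------------------------------
# cascade stages
# ---------------------------------------------------------------------------


def filter_presence(G: GenotypeMatrix, popmap: PopulationMap, min_prop: float = 0.66):
    """Keep SNPs genotyped in >= ``min_prop`` of individuals within every
    population and across all mapped individuals pooled."""
    called = G.called()
    rows_by_pop = popmap.row_indices(G)
    keep = np.ones(G.n_sites, dtype=bool)
    all_rows = np.concatenate([r for r in rows_by_pop.values()]) if rows_by_pop else np.array([], dtype=int)
    for pop, rows in rows_by_pop.items():
        if len(rows) == 0:
            raise ValueError(f"population {pop!r} has no genotyped individuals")
        keep &= called[rows].mean(axis=0) >= min_prop
    keep &= called[all_rows].mean(axis=0) >= min_prop
    return _apply(G, keep, "presence")


def filter_maf(G: GenotypeMatrix, min_maf: float = 0.01):
    """Keep SNPs whose pooled minor-allele frequency is >= ``min_maf``."""
    alt, n = G.alt_counts()
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, alt / np.maximum(n, 1), 0.0)
    maf = np.minimum(p, 1.0 - p)
    return _apply(G, maf >= min_maf, "maf")


def filter_max_het(G: GenotypeMatrix, max_ho: float = 0.5):
    """Keep SNPs with pooled observed heterozygosity <= ``max_ho``."""
    called = G.called()
    het = (G.genotypes == 1) & called
    n = called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        ho = np.where(n > 0, het.sum(axis=0) / np.maximum(n, 1), 0.0)
    return _apply(G, ho <= max_ho, "max_het")


def first_snp_per_locus(G: GenotypeMatrix):
    """Keep, per RAD locus id, the SNP with the lowest position."""
    sites = G.sites
    order = sites.sort_values(["locus", "chrom", "pos"]).index
    first = sites.loc[order].drop_duplicates("locus").index
    keep = np.zeros(G.n_sites, dtype=bool)
    keep[first] = True
    return _apply(G, keep, "first_snp_per_locus")


def hwe_exact_pvalue(n_het: int, n_hom_ref: int, n_hom_alt: int) -> float:
    """Exact two-sided Hardy-Weinberg test for one biallelic SNP.

    Sums the probabilities of all heterozygote counts (given the observed
    allele counts) no more likely than the observed one -- the standard exact
    SNP-HWE construction.
    """
    n = n_het + n_hom_ref + n_hom_alt
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    # unnormalised probabilities over all feasible heterozygote counts
    het_values = np.arange(rare % 2, rare + 1, 2)
    logs = np.zeros(len(het_values))
    from scipy.special import gammaln

    for k, h in enumerate(het_values):
        r = (rare - h) // 2  # rare homozygotes
        c = n - h - r  # common homozygotes
        logs[k] = (
            h * np.log(2.0)
            - gammaln(h + 1)
            - gammaln(r + 1)
            - gammaln(c + 1)
        )
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    obs = probs[np.searchsorted(het_values, n_het)]
    return float(probs[probs <= obs * (1 + 1e-12)].sum())


def filter_hwe_per_pop(
    G: GenotypeMatrix,
    popmap: PopulationMap,
    alpha: float = 0.001,
    max_reject_frac: float = 0.5,
):
    """Remove SNPs out of Hardy-Weinberg equilibrium within populations.

    A SNP is removed when the exact test rejects at ``alpha`` in more than
    ``max_reject_frac`` of the populations in which it is typed.
    """
    rows_by_pop = popmap.row_indices(G)
    rejected = np.zeros(G.n_sites, dtype=np.int64)
    typed = np.zeros(G.n_sites, dtype=np.int64)
    for rows in rows_by_pop.values():
        g = G.genotypes[rows]
        called = g != MISSING
        n_called = called.sum(axis=0)
        for j in np.flatnonzero(n_called > 0):
            col = g[called[:, j], j]
            typed[j] += 1
            p = hwe_exact_pvalue(
                int((col == 1).sum()), int((col == 0).sum()), int((col == 2).sum())
            )
            if p < alpha:
                rejected[j] += 1
    with np.errstate(invalid="ignore"):
        frac = np.where(typed > 0, rejected / np.maximum(typed, 1), 0.0)
    return _apply(G, frac <= max_reject_frac, "hwe")


def filter_depth(G: GenotypeMatrix, min_dp: float = 10.0, max_dp: float = 30.0):
    """Keep SNPs with mean read depth in the inclusive band [min_dp, max_dp]."""
    depth = G.sites["mean_depth"].to_numpy(float)
    if np.all(~np.isfinite(depth)):
        warnings.warn("mean depth absent; depth filter skipped")
        return _apply(G, np.ones(G.n_sites, dtype=bool), "depth(skipped)")
    keep = (depth >= min_dp) & (depth <= max_dp)
    return _apply(G, keep, "depth")


# ---------------------------------------------------------------------------
# replicate-based genotyping error
# ---------------------------------------------------------------------------


@dataclass
class ReplicateErrorReport:
    per_pair: pd.DataFrame  # pair id, original, replicate, co-called, discordant, rate
    per_snp_discordant_pairs: pd.Series  # SNP id -> number of discordant pairs
    overall_rate: float


def estimate_replicate_error(G: GenotypeMatrix, popmap: PopulationMap) -> ReplicateErrorReport:
    """Per-pair genotype discordance over sites called in both members, the
    mean rate across pairs, and the per-SNP count of discordant pairs."""
    pairs = popmap.replicate_pairs()
    if not pairs:
        raise ValueError("no replicate pairs in population map")
    lookup = {ind: i for i, ind in enumerate(G.individuals)}
    rows = []
    per_snp = np.zeros(G.n_sites, dtype=np.int64)
    for a, b in pairs:
        ga, gb = G.genotypes[lookup[a]], G.genotypes[lookup[b]]
        both = (ga != MISSING) & (gb != MISSING)
        n_both = int(both.sum())
        if n_both == 0:
            warnings.warn(f"replicate pair ({a}, {b}) shares no called sites; excluded")
            continue
        disc = both & (ga != gb)
        per_snp += disc
        rows.append(
            {
                "original": a,
                "replicate": b,
                "co_called": n_both,
                "discordant": int(disc.sum()),
                "rate": disc.sum() / n_both,
            }
        )
    if not rows:
        raise ValueError("no replicate pair shares any called sites")
    per_pair = pd.DataFrame(rows)
    return ReplicateErrorReport(
        per_pair=per_pair,
        per_snp_discordant_pairs=pd.Series(per_snp, index=G.site_ids, name="discordant_pairs"),
        overall_rate=float(per_pair["rate"].mean()),
    )


def drop_mismatch_snps(G: GenotypeMatrix, report: ReplicateErrorReport, max_pairs: int = 1):
    """Remove SNPs discordant in more than ``max_pairs`` replicate pairs."""
    counts = report.per_snp_discordant_pairs.reindex(G.site_ids).to_numpy()
    return _apply(G, counts <= max_pairs, "replicate_mismatch")


def drop_replicates(G: GenotypeMatrix, popmap: PopulationMap):
    """Remove one member of each replicate pair, keeping the one with the
    higher coverage (larger number of non-missing genotypes)."""
    lookup = {ind: i for i, ind in enumerate(G.individuals)}
    drop = set()
    for a, b in popmap.replicate_pairs():
        na = int((G.genotypes[lookup[a]] != MISSING).sum())
        nb = int((G.genotypes[lookup[b]] != MISSING).sum())
        drop.add(b if na >= nb else a)
    keep = [ind for ind in G.individuals if ind not in drop]
    pm = popmap.df[~popmap.df["individual"].isin(drop)].copy()
    pm["replicate_group"] = None
    return G.take_individuals(keep), PopulationMap(pm, popmap.lake_coords)


# ---------------------------------------------------------------------------
# downstream subsetting used by the structure analyses
# ---------------------------------------------------------------------------


def remove_nonneutral(
    G: GenotypeMatrix,
    candidate_ids,
    per_locus_fst: pd.Series,
    top_fst_prop: float = 0.05,
):
    """Remove the union of a candidate-SNP set and the top quantile of global
    per-locus F_ST.

    The cut keeps off exactly ``ceil(top_fst_prop * n_sites)`` SNPs ranked by
    F_ST descending, ties broken by (chrom, pos).
    """
    n_top = int(np.ceil(top_fst_prop * G.n_sites)) if top_fst_prop > 0 else 0
    fst = per_locus_fst.reindex(G.site_ids).to_numpy(float)
    order = pd.DataFrame(
        {
            "fst": fst,
            "chrom": G.sites["chrom"],
            "pos": G.sites["pos"],
        }
    ).sort_values(["fst", "chrom", "pos"], ascending=[False, True, True])
    top_idx = set(order.index[:n_top])
    cand = set(candidate_ids)
    keep = np.array(
        [(j not in top_idx) and (sid not in cand) for j, sid in enumerate(G.site_ids)]
    )
    return _apply(G, keep, "remove_nonneutral")


def complete_cases(G: GenotypeMatrix):
    """Keep SNPs with zero missing genotypes."""
    keep = G.called().all(axis=0)
    return _apply(G, keep, "complete_cases")


# ---------------------------------------------------------------------------
# the full cascade
# ---------------------------------------------------------------------------


def apply_cascade(
    G: GenotypeMatrix,
    popmap: PopulationMap,
    min_prop: float = 0.66,
    min_maf: float = 0.01,
    max_ho: float = 0.5,
    hwe_alpha: float = 0.001,
    min_dp: float = 10.0,
    max_dp: float = 30.0,
    max_mismatch_pairs: int = 1,
):
    """Run the full retention cascade in its canonical order:
    presence -> MAF -> max Ho -> first SNP per locus -> HWE -> depth ->
    replicate mismatch (when replicate pairs exist), then drop replicates.

    Returns ``(G, popmap, FilterReport, ReplicateErrorReport | None)``.
    """
    report = FilterReport()
    G, st = filter_presence(G, popmap, min_prop)
    report.add(st)
    G, st = filter_maf(G, min_maf)
    report.add(st)
    G, st = filter_max_het(G, max_ho)
    report.add(st)
    G, st = first_snp_per_locus(G)
    report.add(st)
    G, st = filter_hwe_per_pop(G, popmap, hwe_alpha)
    report.add(st)
    G, st = filter_depth(G, min_dp, max_dp)
    report.add(st)
    err = None
    if popmap.replicate_pairs():
        err = estimate_replicate_error(G, popmap)
        G, st = drop_mismatch_snps(G, err, max_mismatch_pairs)
        report.add(st)
        G, popmap = drop_replicates(G, popmap)
    return G, popmap, report, err
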