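"""Readers, writers and in-memory containers for the standard formats the
pipeline touches.

Genotypes are stored as alternate-allele dosage (0/1/2) with ``-1`` marking a
missing call; every downstream statistic needs only allele counts, so richer
per-call information is never kept in memory.  Variant positions are 1-based
(VCF convention); genomic intervals are 0-based half-open (BED convention) and
converted at a single boundary (:func:`interval_contains_position`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import pysam

log = logging.getLogger(__name__)

MISSING = -1

#: column order of the tab-delimited population map
POPMAP_COLUMNS = [
    "individual",
    "population",
    "lake",
    "hydrometric_area",
    "ecotype",
    "replicate_group",
]

ECOTYPES = {"benthivore", "planktivore", "piscivore", "unimodal"}

#: the 19 WorldClim bioclimatic variables (shiftable between scenarios)
CLIMATE_VARS = [f"bio{i}" for i in range(1, 20)]

#: lake bathymetry / topography -- identical across climate scenarios
BATHYMETRIC_VARS = [
    "altitude",
    "max_depth",
    "mean_depth",
    "surface_area",
    "littoral_pct",
    "distance_to_sea",
    "latitude",
]

SITE_META_COLUMNS = ["id", "chrom", "pos", "locus", "ref", "alt", "mean_depth"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic SNPs, coded as alt-allele dosage.

    Parameters
    ----------
    genotypes
        ``(n_individuals, n_sites)`` int8 array with entries in
        ``{0, 1, 2, MISSING}``.
    sites
        Per-site metadata with columns ``id, chrom, pos, locus, ref, alt,
        mean_depth`` (``pos`` is 1-based; ``mean_depth`` may be NaN).
    individuals
        Individual identifiers, aligned with the rows of ``genotypes``.
    """

    genotypes: np.ndarray
    sites: pd.DataFrame
    individuals: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a 2-D array")
        self.individuals = list(self.individuals)
        if self.genotypes.shape != (len(self.individuals), len(self.sites)):
            raise ValueError(
                f"genotype array {self.genotypes.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.sites)} sites"
            )
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be 0, 1, 2 or MISSING (-1)")
        self.sites = self.sites.reset_index(drop=True)
        missing_cols = set(SITE_META_COLUMNS) - set(self.sites.columns)
        if missing_cols:
            raise ValueError(f"site metadata lacks columns: {sorted(missing_cols)}")
        for chrom, grp in self.sites.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on {chrom}")

    # -- basic geometry ----------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def site_ids(self) -> np.ndarray:
        return self.sites["id"].to_numpy()

    def called(self) -> np.ndarray:
        """Boolean mask of non-missing calls, same shape as ``genotypes``."""
        return self.genotypes != MISSING

    # -- subsetting --------------------------------------------------------

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            self.genotypes[:, index],
            self.sites.iloc[index].reset_index(drop=True),
            self.individuals,
        )

    def take_individuals(self, which) -> "GenotypeMatrix":
        """Subset by positional index array or list of individual ids."""
        which = list(which)
        if which and isinstance(which[0], str):
            lookup = {ind: i for i, ind in enumerate(self.individuals)}
            idx = [lookup[w] for w in which]
        else:
            idx = which
        return GenotypeMatrix(
            self.genotypes[idx, :],
            self.sites.copy(),
            [self.individuals[i] for i in idx],
        )

    # -- allele arithmetic -------------------------------------------------

    def alt_counts(self, rows: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (alt allele count, called allele count) over ``rows``."""
        g = self.genotypes if rows is None else self.genotypes[rows]
        called = g != MISSING
        alt = np.where(called, g, 0).sum(axis=0)
        return alt.astype(np.int64), 2 * called.sum(axis=0).astype(np.int64)

    def alt_freq(self, rows: np.ndarray | None = None) -> np.ndarray:
        """Per-site alternate-allele frequency (NaN where nothing is called)."""
        alt, n = self.alt_counts(rows)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, alt / np.maximum(n, 1), np.nan)

    def equals(self, other: "GenotypeMatrix", depth_atol: float = 1e-4) -> bool:
        return (
            self.individuals == other.individuals
            and np.array_equal(self.genotypes, other.genotypes)
            and self.sites[["id", "chrom", "pos", "locus", "ref", "alt"]].equals(
                other.sites[["id", "chrom", "pos", "locus", "ref", "alt"]]
            )
            and np.allclose(
                self.sites["mean_depth"].to_numpy(float),
                other.sites["mean_depth"].to_numpy(float),
                atol=depth_atol,
                equal_nan=True,
            )
        )


@dataclass
class PopulationMap:
    """Individual -> population -> lake -> Hydrometric Area hierarchy.

    ``df`` holds one row per individual with :data:`POPMAP_COLUMNS`;
    ``lake_coords`` optionally maps lakes to latitude/longitude (degrees).
    Ecotype populations within a lake share the lake id (and hence lake-level
    environment and coordinates).
    """

    df: pd.DataFrame
    lake_coords: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        missing = set(POPMAP_COLUMNS) - set(self.df.columns)
        if missing:
            raise ValueError(f"population map lacks columns: {sorted(missing)}")
        self.df = self.df.reset_index(drop=True)
        if self.df["individual"].duplicated().any():
            raise ValueError("duplicate individual ids in population map")
        bad_eco = set(self.df["ecotype"].dropna()) - ECOTYPES
        if bad_eco:
            raise ValueError(f"unknown ecotype labels: {sorted(bad_eco)}")
        lakes_per_pop = self.df.groupby("population")["lake"].nunique()
        if (lakes_per_pop > 1).any():
            raise ValueError("a population spans more than one lake")

    @property
    def populations(self) -> list[str]:
        return sorted(self.df["population"].unique())

    @property
    def lakes(self) -> list[str]:
        return sorted(self.df["lake"].unique())

    def individuals_of(self, population: str) -> list[str]:
        return self.df.loc[self.df["population"] == population, "individual"].tolist()

    def population_of(self) -> dict[str, str]:
        return dict(zip(self.df["individual"], self.df["population"]))

    def lake_of_population(self) -> dict[str, str]:
        sub = self.df.drop_duplicates("population")
        return dict(zip(sub["population"], sub["lake"]))

    def ha_of_population(self) -> dict[str, str]:
        sub = self.df.drop_duplicates("population")
        return dict(zip(sub["population"], sub["hydrometric_area"]))

    def replicate_pairs(self) -> list[tuple[str, str]]:
        """(original, replicate) pairs from the replicate_group column."""
        pairs = []
        grouped = self.df.dropna(subset=["replicate_group"]).groupby("replicate_group")
        for group_id, grp in grouped:
            inds = grp["individual"].tolist()
            if len(inds) != 2:
                raise ValueError(
                    f"replicate group {group_id!r} has {len(inds)} members, expected 2"
                )
            pairs.append((inds[0], inds[1]))
        return sorted(pairs)

    def row_indices(self, G: GenotypeMatrix) -> dict[str, np.ndarray]:
        """Population -> row indices into ``G`` (only mapped individuals)."""
        lookup = {ind: i for i, ind in enumerate(G.individuals)}
        out: dict[str, np.ndarray] = {}
        for pop, grp in self.df.groupby("population", sort=True):
            rows = [lookup[i] for i in grp["individual"] if i in lookup]
            out[pop] = np.array(rows, dtype=np.intp)
        return out

    def restrict_to(self, individuals) -> "PopulationMap":
        keep = self.df["individual"].isin(set(individuals))
        dropped = (~keep).sum()
        if dropped:
            warnings.warn(f"dropping {dropped} unmatched individuals from population map")
        return PopulationMap(self.df.loc[keep].reset_index(drop=True), self.lake_coords)


@dataclass
class EnvironmentTable:
    """Per-lake environment, keyed by (lake, scenario).

    Columns are the 19 bioclim variables plus the bathymetric/topographic set
    (:data:`BATHYMETRIC_VARS`).  Bathymetric values must be identical across
    scenarios for a lake; depths and areas must be positive.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"lake", "scenario"}
        if not need <= set(self.df.columns):
            raise ValueError("environment table needs 'lake' and 'scenario' columns")
        self.df = self.df.reset_index(drop=True)
        if self.df.duplicated(["lake", "scenario"]).any():
            raise ValueError("duplicate (lake, scenario) rows")
        for col in ("max_depth", "mean_depth", "surface_area"):
            if col in self.df.columns and (self.df[col] <= 0).any():
                raise ValueError(f"non-positive values in {col}")
        static = [v for v in BATHYMETRIC_VARS if v in self.df.columns]
        if static and self.df["scenario"].nunique() > 1:
            per_lake = self.df.groupby("lake")[static].nunique()
            if (per_lake > 1).any().any():
                raise ValueError("bathymetric variables differ across scenarios")

    @property
    def scenarios(self) -> list[str]:
        return sorted(self.df["scenario"].unique())

    @property
    def lakes(self) -> list[str]:
        return sorted(self.df["lake"].unique())

    @property
    def climate_vars(self) -> list[str]:
        return [v for v in CLIMATE_VARS if v in self.df.columns]

    def scenario(self, name: str) -> pd.DataFrame:
        """One row per lake (lake-indexed) for the given scenario."""
        sub = self.df[self.df["scenario"] == name]
        if sub.empty:
            raise KeyError(f"scenario {name!r} absent from environment table")
        return sub.set_index("lake").drop(columns="scenario").sort_index()

    def require_scenarios(self, names, lakes=None) -> None:
        """Hard error naming the first lake missing a requested scenario."""
        lakes = list(lakes) if lakes is not None else self.lakes
        have = set(zip(self.df["lake"], self.df["scenario"]))
        for name in names:
            for lake in lakes:
                if (lake, name) not in have:
                    raise ValueError(f"lake {lake!r} has no environment row for scenario {name!r}")


@dataclass
class IntervalSet:
    """Genomic features as 0-based half-open records (chrom, start, end, name)."""

    df: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=["chrom", "start", "end", "name"]))

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        if len(self.df) and not (self.df["start"] < self.df["end"]).all():
            raise ValueError("interval start must be < end")

    def __len__(self) -> int:
        return len(self.df)


def interval_contains_position(start: int, end: int, pos: int) -> bool:
    """1-based variant position ``pos`` falls in 0-based half-open [start, end)."""
    return start < pos <= end


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(G: GenotypeMatrix, path: str) -> None:
    """Write an uncompressed VCF v4.2 with GT calls and per-site mean depth.

    The locus id is stored in the ID column and the mean read depth in the
    ``MEANDP`` INFO field so that :func:`read_vcf` round-trips the matrix.
    Output is deterministic given identical inputs.
    """
    header = pysam.VariantHeader()
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"), ("Type", "String"), ("Description", "Genotype")])
    header.add_meta(
        "INFO",
        items=[("ID", "MEANDP"), ("Number", "1"), ("Type", "Float"), ("Description", "Mean read depth across individuals")],
    )
    header.add_meta("INFO", items=[("ID", "LOCUS"), ("Number", "1"), ("Type", "String"), ("Description", "RAD locus id")])
    for chrom, grp in G.sites.groupby("chrom", sort=False):
        header.contigs.add(str(chrom), length=int(grp["pos"].max()) + 1000)
    for ind in G.individuals:
        header.add_sample(ind)
    with pysam.VariantFile(path, "w", header=header) as out:
        for j, site in G.sites.iterrows():
            rec = out.new_record(
                contig=str(site["chrom"]),
                start=int(site["pos"]) - 1,
                alleles=(str(site["ref"]), str(site["alt"])),
                id=str(site["id"]),
            )
            if np.isfinite(site["mean_depth"]):
                rec.info["MEANDP"] = float(site["mean_depth"])
            rec.info["LOCUS"] = str(site["locus"])
            col = G.genotypes[:, j]
            for i, ind in enumerate(G.individuals):
                g = int(col[i])
                if g == MISSING:
                    rec.samples[ind]["GT"] = (None, None)
                else:
                    rec.samples[ind]["GT"] = ((0, 0), (0, 1), (1, 1))[g]
            out.write(rec)


def read_vcf(path: str) -> GenotypeMatrix:
    """Read a diploid VCF into a :class:`GenotypeMatrix`.

    Multi-allelic and non-SNP records are skipped (count logged); missing or
    half-called genotypes become :data:`MISSING`.  Ploidy other than 2 is an
    error.
    """
    with pysam.VariantFile(path) as vf:
        individuals = list(vf.header.samples)
        rows: list[dict] = []
        columns: list[np.ndarray] = []
        skipped = 0
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or alt == "*":
                skipped += 1
                continue
            col = np.empty(len(individuals), dtype=np.int8)
            for i, ind in enumerate(individuals):
                gt = rec.samples[ind].get("GT")
                if gt is None:
                    col[i] = MISSING
                    continue
                if len(gt) != 2:
                    raise ValueError(f"ploidy {len(gt)} != 2 for {ind} at {rec.chrom}:{rec.pos}")
                if None in gt:
                    col[i] = MISSING
                else:
                    col[i] = int(gt[0] > 0) + int(gt[1] > 0)
            try:
                depth = rec.info.get("MEANDP", np.nan)
            except ValueError:  # INFO field not declared in this header
                depth = np.nan
            try:
                locus = rec.info.get("LOCUS", rec.id or f"{rec.chrom}:{rec.pos}")
            except ValueError:
                locus = rec.id or f"{rec.chrom}:{rec.pos}"
            rows.append(
                {
                    "id": rec.id or f"{rec.chrom}:{rec.pos}",
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "locus": locus,
                    "ref": ref,
                    "alt": alt,
                    "mean_depth": float(depth) if depth is not None else np.nan,
                }
            )
            columns.append(col)
    if skipped:
        log.info("read_vcf: skipped %d multi-allelic or non-SNP records", skipped)
    sites = pd.DataFrame(rows, columns=SITE_META_COLUMNS)
    geno = np.column_stack(columns) if columns else np.empty((len(individuals), 0), dtype=np.int8)
    return GenotypeMatrix(geno, sites, individuals)


# ---------------------------------------------------------------------------
# tab-delimited tables and BED
# ---------------------------------------------------------------------------


def read_popmap(path: str, genotyped: list[str] | None = None) -> PopulationMap:
    """Read the tab-delimited population map; optionally drop (with a warning)
    individuals absent from the genotyped set."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(POPMAP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"population map lacks columns: {sorted(missing)}")
    df["replicate_group"] = df["replicate_group"].replace({"": None, "NA": None, ".": None})
    pm = PopulationMap(df)
    if genotyped is not None:
        pm = pm.restrict_to(genotyped)
    return pm


def write_popmap(pm: PopulationMap, path: str) -> None:
    df = pm.df[POPMAP_COLUMNS].copy()
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_env(path: str) -> EnvironmentTable:
    df = pd.read_csv(path, sep="\t")
    return EnvironmentTable(df)


def write_env(env: EnvironmentTable, path: str) -> None:
    env.df.sort_values(["scenario", "lake"]).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def read_bed(path: str) -> IntervalSet:
    """Read a 4+ column BED file (0-based half-open)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        usecols=[0, 1, 2, 3],
        names=["chrom", "start", "end", "name"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "name": str},
    )
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].iloc[0]
        raise ValueError(f"BED interval with start >= end: {bad['chrom']}:{bad['start']}-{bad['end']}")
    return IntervalSet(df)


def write_bed(intervals: IntervalSet, path: str) -> None:
    intervals.df.to_csv(path, sep="\t", index=False, header=False)
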