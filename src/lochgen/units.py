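"""Lake sensitivity scores, the multi-metric vulnerability table, and
rule-based delineation of conservation units (MUs and ESUs).

Populations are merged into one unit when they are geographically close
(great-circle lake distance below 20 km) AND weakly differentiated (pairwise
F_ST below a gene-flow threshold), or when linked by a known conservation
translocation or a shared-close-genetic-history group.  A unit is elevated
from Management Unit (MU) to Evolutionarily Significant Unit (ESU) when any
member is an ecotype population (sympatric or parapatric divergence) or is
the only extant population of its Hydrometric Area.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io import EnvironmentTable, PopulationMap

EARTH_RADIUS_KM = 6371.0088


# ---------------------------------------------------------------------------
# lake sensitivity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SensitivityScore:
    depth_score: int  # 1 (deep) .. 4 (shallow)
    area_score: int  # 1 (large) .. 3 (small)
    altitude_score: int  # 1 (high) .. 4 (low)

    @property
    def composite(self) -> int:
        return self.depth_score + self.area_score + self.altitude_score


def _bin_score(value: float, bounds: list[float], scores: list[int]) -> int:
    # bounds lower-inclusive: value in [bounds[i-1], bounds[i]) -> scores[i]
    for b, s in zip(bounds, scores):
        if value < b:
            return s
    return scores[-1]


def sensitivity_score(max_depth_m: float, surface_area_ha: float, altitude_m: float) -> SensitivityScore:
    """Composite lake-sensitivity score (3 = least concern .. 11 = highest).

    Maximum depth: < 10 m -> 4, [10, 30) -> 3, [30, 100) -> 2, >= 100 -> 1.
    Surface area: < 10 ha -> 3, [10, 30) -> 2, >= 30 -> 1.
    Altitude: < 10 m -> 4, [10, 50) -> 3, [50, 200) -> 2, >= 200 -> 1.
    Bin edges are lower-inclusive.
    """
    if max_depth_m <= 0 or surface_area_ha <= 0:
        raise ValueError("depth and surface area must be positive")
    if altitude_m < 0:
        raise ValueError("altitude must be non-negative")
    return SensitivityScore(
        depth_score=_bin_score(max_depth_m, [10, 30, 100], [4, 3, 2, 1]),
        area_score=_bin_score(surface_area_ha, [10, 30], [3, 2, 1]),
        altitude_score=_bin_score(altitude_m, [10, 50, 200], [4, 3, 2, 1]),
    )


# ---------------------------------------------------------------------------
# vulnerability table
# ---------------------------------------------------------------------------

#: orientation of each metric: +1 means higher value = higher vulnerability
VULNERABILITY_ORIENTATION = {"offset": +1, "sensitivity": +1, "ho": -1}


def assemble_vulnerability(
    stats: pd.DataFrame,
    offsets: pd.Series,
    env: EnvironmentTable,
    popmap: PopulationMap,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join genetic offset, observed heterozygosity and lake sensitivity per
    population (lake-level metrics repeat across ecotypes in a lake).

    Populations whose lake lacks an offset (for instance when too few
    individuals were genotyped) keep a NaN and are excluded from the
    correlation matrix.  Returns ``(table, metric_correlations)``.
    """
    lake_of = popmap.lake_of_population()
    cur = env.scenario("current")
    rows = []
    for pop in popmap.populations:
        lake = lake_of[pop]
        e = cur.loc[lake]
        sens = sensitivity_score(e["max_depth"], e["surface_area"], e["altitude"]).composite
        rows.append(
            {
                "population": pop,
                "lake": lake,
                "offset": float(offsets.get(lake, np.nan)),
                "ho": float(stats.loc[pop, "ho"]) if pop in stats.index else np.nan,
                "sensitivity": sens,
            }
        )
    table = pd.DataFrame(rows).set_index("population")
    metrics = table[["offset", "ho", "sensitivity"]].dropna()
    constant = [c for c in metrics.columns if metrics[c].nunique() <= 1]
    corr = metrics.drop(columns=constant).corr(method="pearson")
    for c in constant:
        corr[c] = np.nan
        corr.loc[c] = np.nan
    return table, corr


def offset_regressions(offsets: pd.Series, env: EnvironmentTable, covariates=("latitude", "distance_to_sea")) -> pd.DataFrame:
    """Simple OLS of per-lake offset on each covariate separately; returns
    slope, R-squared and the two-sided slope p-value per covariate."""
    cur = env.scenario("current")
    joined = pd.DataFrame({"offset": offsets}).join(cur[list(covariates)]).dropna()
    out = []
    for cov in covariates:
        if joined["offset"].nunique() <= 1:
            out.append({"covariate": cov, "slope": 0.0, "r2": 0.0, "p_value": 1.0})
            continue
        model = sm.OLS(joined["offset"], sm.add_constant(joined[cov])).fit()
        out.append(
            {
                "covariate": cov,
                "slope": float(model.params.iloc[1]),
                "r2": float(model.rsquared),
                "p_value": float(model.pvalues.iloc[1]),
            }
        )
    return pd.DataFrame(out).set_index("covariate")


# ---------------------------------------------------------------------------
# conservation units
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConservationUnit:
    members: tuple  # population ids, sorted
    unit_type: str  # "MU" or "ESU"
    criteria: frozenset  # tags from CRITERION_TAGS


CRITERION_TAGS = {
    "diverged_ecotype",
    "sole_HA_population",
    "merged_proximity",
    "merged_gene_flow",
    "merged_translocation",
    "merged_shared_history",
}


@dataclass
class ConservationUnitSet:
    units: list

    def __post_init__(self) -> None:
        seen: set = set()
        for u in self.units:
            overlap = seen & set(u.members)
            if overlap:
                raise ValueError(f"units overlap on {sorted(overlap)}")
            seen |= set(u.members)

    @property
    def populations(self) -> set:
        return {m for u in self.units for m in u.members}

    def of_type(self, unit_type: str) -> list:
        return [u for u in self.units if u.unit_type == unit_type]

    def summarize(self) -> dict:
        esu = self.of_type("ESU")
        mu = self.of_type("MU")
        return {
            "esu_units": len(esu),
            "mu_units": len(mu),
            "esu_populations": sum(len(u.members) for u in esu),
            "mu_populations": sum(len(u.members) for u in mu),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "populations": ", ".join(u.members),
                "unit_type": u.unit_type,
                "criteria": ";".join(sorted(u.criteria)),
            }
            for u in sorted(self.units, key=lambda u: u.members)
        ]
        return pd.DataFrame(rows)


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance between two (degree) coordinates in km."""
    la1, lo1, la2, lo2 = map(np.radians, (lat1, lon1, lat2, lon2))
    h = np.sin((la2 - la1) / 2) ** 2 + np.cos(la1) * np.cos(la2) * np.sin((lo2 - lo1) / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def delineate_units(
    pops: pd.DataFrame,
    fst: pd.DataFrame | None = None,
    proximity_km: float = 20.0,
    gene_flow_fst: float = 0.05,
) -> ConservationUnitSet:
    """Delineate MUs and ESUs from population metadata.

    ``pops`` has one row per population with columns ``population``,
    ``ecotype_flag`` (bool), ``sole_ha`` (bool) and optionally ``latitude``,
    ``longitude``, ``translocation_group`` and ``shared_history_group``.

    Merge edges: great-circle lake distance < ``proximity_km`` AND pairwise
    F_ST < ``gene_flow_fst`` (both conditions; proximity alone never merges,
    and the rule is skipped when ``fst`` is None); shared non-null
    ``translocation_group``; shared non-null ``shared_history_group``.
    Connected components become units; a unit is an ESU iff any member is
    ecotype-flagged or the sole extant population of its Hydrometric Area.
    The result is independent of the row order of ``pops``.
    """
    df = pops.set_index("population", drop=False).sort_index()
    names = list(df.index)
    g = nx.Graph()
    g.add_nodes_from(names)
    edge_tags: dict = {}

    for col, tag in (
        ("translocation_group", "merged_translocation"),
        ("shared_history_group", "merged_shared_history"),
    ):
        if col in df.columns:
            for _, grp in df.dropna(subset=[col]).groupby(col):
                members = sorted(grp.index)
                for a, b in zip(members, members[1:]):
                    g.add_edge(a, b)
                    edge_tags.setdefault((a, b), set()).add(tag)

    if fst is not None:
        if not {"latitude", "longitude"} <= set(df.columns) or df[["latitude", "longitude"]].isna().any().any():
            raise ValueError("proximity rule requires lake coordinates for every population")
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                if a not in fst.index or b not in fst.index:
                    continue
                dist = haversine_km(
                    df.loc[a, "latitude"], df.loc[a, "longitude"], df.loc[b, "latitude"], df.loc[b, "longitude"]
                )
                if dist < proximity_km and fst.loc[a, b] < gene_flow_fst:
                    g.add_edge(a, b)
                    edge_tags.setdefault(tuple(sorted((a, b))), set()).update(
                        {"merged_proximity", "merged_gene_flow"}
                    )

    units = []
    for comp in sorted(nx.connected_components(g), key=min):
        members = tuple(sorted(comp))
        criteria: set = set()
        for a, b, in g.subgraph(comp).edges:
            criteria |= edge_tags.get(tuple(sorted((a, b))), set())
        if df.loc[list(members), "ecotype_flag"].any():
            criteria.add("diverged_ecotype")
        if df.loc[list(members), "sole_ha"].any():
            criteria.add("sole_HA_population")
        unit_type = "ESU" if criteria & {"diverged_ecotype", "sole_HA_population"} else "MU"
        units.append(ConservationUnit(members, unit_type, frozenset(criteria)))
    return ConservationUnitSet(units)


def summarize_units(units: ConservationUnitSet) -> dict:
    return units.summarize()
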