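"""Gradient-forest-style turnover model and per-lake genetic offset.

For every climate-associated SNP, an ensemble of regression trees is fitted on
bootstrap samples of lakes (response: the SNP's minor-allele frequency;
predictors: the climate variables, with random predictor subsetting at each
split).  Every split contributes its impurity reduction at its threshold
location to that predictor's importance profile, weighted by the SNP's
out-of-bag R-squared; SNPs that predict no better than the mean out-of-bag
contribute nothing.  Profiles are accumulated over SNPs on a fixed grid of 50
equal-width bins per predictor and integrated into non-decreasing cumulative
importance functions.  Climate vectors are mapped through these functions and
the Euclidean distance between the transformed current and future vectors of a
lake is its genetic offset.

This is a reimplementation of the gradient-forest idea, not a port of the R
package; hyperparameters are declared in :func:`fit_turnover`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .io import EnvironmentTable, GenotypeMatrix, PopulationMap

#: distinct-MAF counting precision for the low-variation filter
MAF_ROUND = 6


def population_maf_matrix(G: GenotypeMatrix, popmap: PopulationMap, by_lake: bool = True) -> pd.DataFrame:
    """Population (or lake) x SNP minor-allele-frequency matrix."""
    rows_by_pop = popmap.row_indices(G)
    if by_lake:
        lake_of = popmap.lake_of_population()
        merged: dict[str, list] = {}
        for pop, rows in rows_by_pop.items():
            merged.setdefault(lake_of[pop], []).append(rows)
        rows_by_pop = {lake: np.concatenate(r) for lake, r in merged.items()}
    freqs = {}
    for key, rows in sorted(rows_by_pop.items()):
        p = G.alt_freq(rows)
        freqs[key] = np.minimum(p, 1 - p)
    return pd.DataFrame(freqs, index=G.site_ids).T


def low_variation_filter(pop_freqs: pd.DataFrame, min_distinct: int = 6) -> list:
    """Retain SNPs whose minor-allele frequency takes at least ``min_distinct``
    distinct values across populations (distinctness after rounding to
    ``MAF_ROUND`` decimals).  The default drops SNPs with 5 or fewer values."""
    rounded = pop_freqs.round(MAF_ROUND)
    counts = rounded.nunique(axis=0, dropna=True)
    return list(counts.index[counts >= min_distinct])


@dataclass
class TurnoverModel:
    predictors: list
    bin_edges: dict  # predictor -> (n_bins + 1,) grid over the observed range
    cumulative: dict  # predictor -> (n_bins + 1,) non-decreasing, starts at 0
    total_importance: pd.Series
    n_trees: int
    seed: int
    snp_ids: list
    snp_r2: pd.Series

    def transform_value(self, predictor: str, value: float) -> float:
        """Step-function evaluation with clamping outside the fitted range."""
        edges = self.bin_edges[predictor]
        cum = self.cumulative[predictor]
        if value <= edges[0]:
            return float(cum[0])
        if value >= edges[-1]:
            return float(cum[-1])
        k = int(np.searchsorted(edges, value, side="right")) - 1
        return float(cum[k + 1])  # importance accrued up to the bin containing value

    def transform_env(self, env_row: pd.Series) -> np.ndarray:
        return np.array([self.transform_value(p, float(env_row[p])) for p in self.predictors])


def fit_turnover(
    pop_freqs: pd.DataFrame,
    env_current: pd.DataFrame,
    n_trees: int = 250,
    seed: int = 0,
    n_bins: int = 50,
    min_samples_leaf: int = 2,
) -> TurnoverModel:
    """Fit the turnover model on lake-level MAFs and current climate.

    ``pop_freqs``: lakes x SNPs; ``env_current``: lakes x climate variables
    (aligned by index).  Trees are unlimited in depth, use
    ``ceil(n_predictors / 3)`` predictors per split and at least
    ``min_samples_leaf`` lakes per leaf.
    """
    lakes = list(pop_freqs.index)
    env_current = env_current.loc[lakes]
    predictors = list(env_current.columns)
    n = len(lakes)
    if n < 5:
        raise ValueError("turnover model needs at least 5 lakes")
    if pop_freqs.shape[1] < 2:
        raise ValueError("turnover model needs at least 2 SNPs")
    if n < 2 * min_samples_leaf:
        raise ValueError("fewer lakes than the minimum node size allows")

    Xenv = env_current.to_numpy(float)
    v = len(predictors)
    max_features = max(1, int(np.ceil(v / 3)))

    edges = {
        p: np.linspace(Xenv[:, k].min(), Xenv[:, k].max(), n_bins + 1)
        for k, p in enumerate(predictors)
    }
    # guard degenerate (constant) predictors: give them a token range
    for k, p in enumerate(predictors):
        if edges[p][0] == edges[p][-1]:
            edges[p] = edges[p] + np.linspace(0, 1e-9, n_bins + 1)

    binned = {p: np.zeros(n_bins) for p in predictors}
    r2s = {}
    used = []
    seeds = np.random.SeedSequence(seed).spawn(pop_freqs.shape[1])
    for s_idx, snp in enumerate(pop_freqs.columns):
        y = pop_freqs[snp].to_numpy(float)
        var_y = y.var()
        if var_y == 0:
            r2s[snp] = 0.0
            continue
        rng = np.random.default_rng(seeds[s_idx])
        oob_sum = np.zeros(n)
        oob_cnt = np.zeros(n)
        split_imp = {p: np.zeros(n_bins) for p in predictors}
        for _ in range(n_trees):
            boot = rng.integers(0, n, n)
            oob = np.setdiff1d(np.arange(n), boot)
            tree = DecisionTreeRegressor(
                max_features=max_features,
                min_samples_leaf=min_samples_leaf,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(Xenv[boot], y[boot])
            if oob.size:
                oob_sum[oob] += tree.predict(Xenv[oob])
                oob_cnt[oob] += 1
            t = tree.tree_
            internal = t.children_left != -1
            if not internal.any():
                continue
            w = t.weighted_n_node_samples
            left, right = t.children_left[internal], t.children_right[internal]
            dec = (
                w[internal] * t.impurity[internal]
                - w[left] * t.impurity[left]
                - w[right] * t.impurity[right]
            ) / n
            feats = t.feature[internal]
            thrs = t.threshold[internal]
            pos = dec > 0
            for f in np.unique(feats[pos]):
                p = predictors[f]
                sel = pos & (feats == f)
                k = np.clip(
                    np.searchsorted(edges[p], thrs[sel], side="right") - 1, 0, n_bins - 1
                )
                np.add.at(split_imp[p], k, dec[sel])
        seen = oob_cnt > 0
        if not seen.any():
            r2s[snp] = 0.0
            continue
        resid = y[seen] - oob_sum[seen] / oob_cnt[seen]
        r2 = 1.0 - (resid**2).mean() / var_y
        r2s[snp] = float(r2)
        if r2 <= 0:
            continue
        total = sum(split_imp[p].sum() for p in predictors)
        if total <= 0:
            continue
        for p in predictors:
            binned[p] += r2 * split_imp[p] / total
        used.append(snp)

    n_used = max(len(used), 1)
    cumulative = {
        p: np.concatenate([[0.0], np.cumsum(binned[p]) / n_used]) for p in predictors
    }
    totals = pd.Series({p: cumulative[p][-1] for p in predictors}, name="importance")
    return TurnoverModel(
        predictors=predictors,
        bin_edges=edges,
        cumulative=cumulative,
        total_importance=totals,
        n_trees=n_trees,
        seed=seed,
        snp_ids=used,
        snp_r2=pd.Series(r2s, name="oob_r2"),
    )


def transform_env(model: TurnoverModel, env: pd.DataFrame) -> pd.DataFrame:
    """Map each lake's climate vector through the cumulative-importance
    functions.  Values beyond the fitted range are clamped to the boundary."""
    out = np.vstack([model.transform_env(row) for _, row in env.iterrows()])
    return pd.DataFrame(out, index=env.index, columns=model.predictors)


def genetic_offset(
    model: TurnoverModel,
    env: EnvironmentTable,
    future_scenario: str,
    current_scenario: str = "current",
) -> pd.Series:
    """Per-lake genetic offset: the Euclidean distance between transformed
    current and future climate vectors.  One score per lake; ecotype
    populations in a lake share it by construction."""
    env.require_scenarios([current_scenario, future_scenario])
    cur = env.scenario(current_scenario)[model.predictors]
    fut = env.scenario(future_scenario)[model.predictors]
    t_cur = transform_env(model, cur)
    t_fut = transform_env(model, fut.loc[t_cur.index])
    d = np.sqrt(((t_cur.to_numpy() - t_fut.to_numpy()) ** 2).sum(axis=1))
    return pd.Series(d, index=t_cur.index, name="offset")
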