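"""Population structure: PCA, neighbour-joining with bootstrap support,
hierarchical AMOVA and an F_ST-threshold population clustering.

The clustering is a deliberately simple surrogate for model-based admixture
assignment: populations whose pairwise F_ST falls below a threshold are merged
by single linkage (equivalently, connected components of the sub-threshold
graph).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from skbio.tree import TreeNode

from .io import MISSING, GenotypeMatrix, PopulationMap


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    scores: pd.DataFrame  # individuals x axes
    eigenvalues: np.ndarray  # non-increasing
    percent_variance: np.ndarray
    loadings: np.ndarray  # sites x axes


def _mean_impute(G: GenotypeMatrix) -> np.ndarray:
    """Dosage matrix with missing calls replaced by the per-SNP mean dosage
    across all individuals (twice the mean allele frequency)."""
    X = G.genotypes.astype(float)
    miss = X == MISSING
    if miss.all(axis=0).any():
        raise ValueError("SNP with all calls missing cannot be mean-imputed")
    X[miss] = np.nan
    col_mean = np.nanmean(X, axis=0)
    idx = np.where(miss)
    X[idx] = col_mean[idx[1]]
    return X


def pca(G: GenotypeMatrix, n_axes: int | None = None) -> PcaResult:
    """PCA of the column-centred, mean-imputed dosage matrix.

    Eigenvalues are those of the individual covariance matrix; percent
    variance is each eigenvalue over the trace.  Axis signs are fixed by
    making the largest-magnitude SNP loading positive on every axis.
    """
    if G.n_individuals < 2:
        raise ValueError("PCA needs at least two individuals")
    X = _mean_impute(G)
    X -= X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    eig = s**2 / (G.n_individuals - 1)
    total = eig.sum()
    if n_axes is None:
        n_axes = len(eig)
    U, s, Vt, eig = U[:, :n_axes], s[:n_axes], Vt[:n_axes], eig[:n_axes]
    # deterministic axis orientation
    for k in range(len(s)):
        jmax = np.argmax(np.abs(Vt[k]))
        if Vt[k, jmax] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = pd.DataFrame(
        U * s,
        index=G.individuals,
        columns=[f"EV{k + 1}" for k in range(len(s))],
    )
    pct = 100.0 * eig / total if total > 0 else np.zeros_like(eig)
    return PcaResult(scores, eig, pct, Vt.T)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def _pop_freqs(G: GenotypeMatrix, popmap: PopulationMap, complete_only: bool = True):
    if complete_only:
        keep = G.called().all(axis=0)
        G = G.take_sites(keep)
    rows_by_pop = popmap.row_indices(G)
    freqs = {pop: G.alt_freq(rows) for pop, rows in rows_by_pop.items()}
    return pd.DataFrame(freqs).T  # pops x loci


def genetic_distance(
    G: GenotypeMatrix,
    popmap: PopulationMap,
    metric: str = "prevosti",
    complete_only: bool = True,
) -> pd.DataFrame:
    """Population x population genetic distance from allele frequencies.

    ``prevosti`` (default): mean absolute allele-frequency difference over
    loci (for biallelic loci this equals the mean |delta p|).  ``nei``:
    Nei's (1972) standard distance.  Complete-case SNPs only by default.
    """
    F = _pop_freqs(G, popmap, complete_only)
    P = F.to_numpy()
    pops = list(F.index)
    n = len(pops)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pi, pj = P[i], P[j]
            ok = np.isfinite(pi) & np.isfinite(pj)
            if metric == "prevosti":
                d = np.abs(pi[ok] - pj[ok]).mean()
            elif metric == "nei":
                num = (pi[ok] * pj[ok] + (1 - pi[ok]) * (1 - pj[ok])).sum()
                di = (pi[ok] ** 2 + (1 - pi[ok]) ** 2).sum()
                dj = (pj[ok] ** 2 + (1 - pj[ok]) ** 2).sum()
                d = -np.log(num / np.sqrt(di * dj))
            else:
                raise ValueError(f"unknown metric {metric!r}")
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=pops, columns=pops)


# ---------------------------------------------------------------------------
# neighbour joining
# ---------------------------------------------------------------------------


def neighbor_joining(D: pd.DataFrame) -> TreeNode:
    """Saitou-Nei neighbour joining; returns an unrooted tree (trifurcating
    root) over the row labels of ``D``.

    A negative branch length is clamped to zero and its deficit moved to the
    adjacent branch of the joined pair, the standard fix preserving the path
    length between the two joined taxa.
    """
    labels = list(D.index)
    if len(labels) < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    if not np.allclose(D.to_numpy(), D.to_numpy().T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    d = D.to_numpy(float).copy()
    nodes = [TreeNode(name=str(l)) for l in labels]

    while len(nodes) > 3:
        n = len(nodes)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        i, j = np.unravel_index(np.argmin(q), q.shape)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        nodes[i].length = float(li)
        nodes[j].length = float(lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        dnew = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], dnew[keep][None, :]])
        d = np.hstack([d, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # final three taxa join at the unrooted centre with closed-form lengths
    (a, b, c) = nodes
    la = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
    lb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
    lc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
    a.length, b.length, c.length = (max(float(x), 0.0) for x in (la, lb, lc))
    return TreeNode(children=[a, b, c])


def tree_bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of tip names (the side not
    containing the lexicographically smallest tip)."""
    tips = {t.name for t in tree.tips()}
    anchor = min(tips)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if 1 < len(side) < len(tips) - 1:
            if anchor in side:
                side = tips - side
            parts.add(frozenset(side))
    return parts


def bootstrap_support(
    G: GenotypeMatrix,
    popmap: PopulationMap,
    n_boot: int = 1000,
    seed: int = 0,
    metric: str = "prevosti",
) -> TreeNode:
    """Neighbour-joining tree with bootstrap support on internal nodes.

    Loci (complete-case columns) are resampled with replacement ``n_boot``
    times; each internal node of the full-data tree is labelled with the
    percentage of replicates containing the same bipartition.
    """
    F = _pop_freqs(G, popmap, complete_only=True)
    P = F.to_numpy()
    pops = list(F.index)
    full = neighbor_joining(_freq_distance(P, pops, metric))
    target = {
        node: frozenset(t.name for t in node.tips()) for node in full.non_tips(include_self=False)
    }
    tips = set(pops)
    anchor = min(tips)
    canon = {
        node: frozenset(tips - side) if anchor in side else side for node, side in target.items()
    }
    counts = {node: 0 for node in canon}
    rng = np.random.default_rng(seed)
    L = P.shape[1]
    for _ in range(n_boot):
        cols = rng.integers(0, L, L)
        boot = neighbor_joining(_freq_distance(P[:, cols], pops, metric))
        parts = tree_bipartitions(boot)
        for node, side in canon.items():
            if len(side) > 1 and len(side) < len(tips) - 1:
                if side in parts:
                    counts[node] += 1
    for node, cnt in counts.items():
        side = canon[node]
        if 1 < len(side) < len(tips) - 1:
            node.name = f"{100.0 * cnt / n_boot:g}"
    return full


def _freq_distance(P: np.ndarray, pops: list, metric: str) -> pd.DataFrame:
    n = len(pops)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "prevosti":
                d = np.abs(P[i] - P[j]).mean()
            else:
                num = (P[i] * P[j] + (1 - P[i]) * (1 - P[j])).sum()
                d = -np.log(num / np.sqrt(((P[i] ** 2 + (1 - P[i]) ** 2).sum()) * ((P[j] ** 2 + (1 - P[j]) ** 2).sum())))
            D[i, j] = D[j, i] = d
    return pd.DataFrame(D, index=pops, columns=pops)


# ---------------------------------------------------------------------------
# hierarchical AMOVA
# ---------------------------------------------------------------------------


@dataclass
class AmovaResult:
    components: pd.Series  # variance components per level
    percents: pd.Series  # percent of total (sums to 100)
    df: pd.Series
    p_values: pd.Series | None = None


def amova(
    G: GenotypeMatrix,
    popmap: PopulationMap,
    group_of_ha: dict,
    n_perm: int = 0,
    seed: int = 0,
) -> AmovaResult:
    """Hierarchical AMOVA: among groups / among HAs within groups / among
    populations within HAs / within populations.

    Individuals are points in SNP dosage space (mean-imputed); variance
    components come from the nested analysis of the squared Euclidean
    distances, i.e. an unbalanced three-fold nested ANOVA summed over SNP
    coordinates.  Components can be negative (reported as-is); percents are
    components over their sum.  With ``n_perm > 0``, one-sided permutation
    p-values are computed by permuting labels at the matching level.
    """
    X = _mean_impute(G)
    pop_of = popmap.population_of()
    ha_of_pop = popmap.ha_of_population()
    pop_labels = np.array([pop_of[i] for i in G.individuals])
    ha_labels = np.array([ha_of_pop[p] for p in pop_labels])
    grp_labels = np.array([group_of_ha[h] for h in ha_labels])
    res = _amova_components(X, grp_labels, ha_labels, pop_labels)

    p_values = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        comp = res.components
        hits = pd.Series(0.0, index=comp.index[:-1])
        for _ in range(n_perm):
            perm_pop = _permute_within(rng, pop_labels, ha_labels)
            perm_ha = _permute_level(rng, ha_labels, grp_labels, pop_labels)
            perm_grp = _permute_groups(rng, grp_labels, ha_labels)
            r_pop = _amova_components(X, grp_labels, ha_labels, perm_pop)
            r_ha = _amova_components(X, perm_ha[0], perm_ha[1], pop_labels)
            r_grp = _amova_components(X, perm_grp, ha_labels, pop_labels)
            if r_grp.components.iloc[0] >= comp.iloc[0]:
                hits.iloc[0] += 1
            if r_ha.components.iloc[1] >= comp.iloc[1]:
                hits.iloc[1] += 1
            if r_pop.components.iloc[2] >= comp.iloc[2]:
                hits.iloc[2] += 1
        p_values = (hits + 1) / (n_perm + 1)
    return AmovaResult(res.components, res.percents, res.df, p_values)


def _amova_components(X, grp_labels, ha_labels, pop_labels) -> AmovaResult:
    n_tot = len(X)
    grand = X.mean(axis=0)

    pops = pd.unique(pop_labels)
    has = pd.unique(ha_labels)
    grps = pd.unique(grp_labels)
    g, h, p = len(grps), len(has), len(pops)

    pop_ha = {}
    ha_grp = {}
    for pop, ha in zip(pop_labels, ha_labels):
        pop_ha[pop] = ha
    for ha, gr in zip(ha_labels, grp_labels):
        ha_grp[ha] = gr

    pop_idx = {q: np.flatnonzero(pop_labels == q) for q in pops}
    ha_idx = {q: np.flatnonzero(ha_labels == q) for q in has}
    grp_idx = {q: np.flatnonzero(grp_labels == q) for q in grps}
    pop_mean = {q: X[i].mean(axis=0) for q, i in pop_idx.items()}
    ha_mean = {q: X[i].mean(axis=0) for q, i in ha_idx.items()}
    grp_mean = {q: X[i].mean(axis=0) for q, i in grp_idx.items()}

    ss_within = sum(((X[i] - pop_mean[q]) ** 2).sum() for q, i in pop_idx.items())
    ss_pop = sum(len(pop_idx[q]) * ((pop_mean[q] - ha_mean[pop_ha[q]]) ** 2).sum() for q in pops)
    ss_ha = sum(len(ha_idx[q]) * ((ha_mean[q] - grp_mean[ha_grp[q]]) ** 2).sum() for q in has)
    ss_grp = sum(len(grp_idx[q]) * ((grp_mean[q] - grand) ** 2).sum() for q in grps)

    df = pd.Series(
        {
            "among_groups": g - 1,
            "among_ha_within_groups": h - g,
            "among_pops_within_ha": p - h,
            "within_pops": n_tot - p,
        }
    )

    n_pop = {q: len(i) for q, i in pop_idx.items()}
    n_ha = {q: len(i) for q, i in ha_idx.items()}
    n_grp = {q: len(i) for q, i in grp_idx.items()}

    # Expected-mean-square coefficients for the unbalanced three-fold nested
    # design (Searle's variance-components formulas).
    sum_npop2_by_ha = {q: sum(n_pop[r] ** 2 for r in pops if pop_ha[r] == q) for q in has}
    sum_npop2_by_grp = {q: sum(n_pop[r] ** 2 for r in pops if ha_grp[pop_ha[r]] == q) for q in grps}
    sum_nha2_by_grp = {q: sum(n_ha[r] ** 2 for r in has if ha_grp[r] == q) for q in grps}

    c1 = (n_tot - sum(sum_npop2_by_ha[q] / n_ha[q] for q in has)) / max(p - h, 1)
    c2 = (
        sum(sum_npop2_by_ha[q] / n_ha[q] for q in has)
        - sum(sum_npop2_by_grp[q] / n_grp[q] for q in grps)
    ) / max(h - g, 1)
    c3 = (n_tot - sum(sum_nha2_by_grp[q] / n_grp[q] for q in grps)) / max(h - g, 1)
    c4 = (
        sum(sum_npop2_by_grp[q] / n_grp[q] for q in grps)
        - sum(n_pop[q] ** 2 for q in pops) / n_tot
    ) / max(g - 1, 1)
    c5 = (
        sum(sum_nha2_by_grp[q] / n_grp[q] for q in grps)
        - sum(n_ha[q] ** 2 for q in has) / n_tot
    ) / max(g - 1, 1)
    c6 = (n_tot - sum(n_grp[q] ** 2 for q in grps) / n_tot) / max(g - 1, 1)

    ms_within = ss_within / df["within_pops"] if df["within_pops"] > 0 else 0.0
    ms_pop = ss_pop / df["among_pops_within_ha"] if df["among_pops_within_ha"] > 0 else 0.0
    ms_ha = ss_ha / df["among_ha_within_groups"] if df["among_ha_within_groups"] > 0 else 0.0
    ms_grp = ss_grp / df["among_groups"] if df["among_groups"] > 0 else 0.0

    sig_w = ms_within
    sig_p = (ms_pop - sig_w) / c1 if df["among_pops_within_ha"] > 0 else 0.0
    sig_h = (ms_ha - sig_w - c2 * sig_p) / c3 if df["among_ha_within_groups"] > 0 else 0.0
    sig_g = (ms_grp - sig_w - c4 * sig_p - c5 * sig_h) / c6 if df["among_groups"] > 0 else 0.0

    comps = pd.Series(
        {
            "among_groups": sig_g,
            "among_ha_within_groups": sig_h,
            "among_pops_within_ha": sig_p,
            "within_pops": sig_w,
        }
    )
    total = comps.sum()
    percents = 100.0 * comps / total if total != 0 else comps * 0.0
    return AmovaResult(comps, percents, df)


def _permute_within(rng, pop_labels, ha_labels):
    """Permute individuals' population labels within each HA."""
    out = pop_labels.copy()
    for ha in pd.unique(ha_labels):
        idx = np.flatnonzero(ha_labels == ha)
        out[idx] = out[rng.permutation(idx)]
    return out


def _permute_level(rng, ha_labels, grp_labels, pop_labels):
    """Permute whole populations among HAs within groups."""
    pops = pd.unique(pop_labels)
    pop_ha = {q: ha_labels[pop_labels == q][0] for q in pops}
    pop_grp = {q: grp_labels[pop_labels == q][0] for q in pops}
    new_ha = dict(pop_ha)
    for gr in pd.unique(grp_labels):
        members = [q for q in pops if pop_grp[q] == gr]
        has = [pop_ha[q] for q in members]
        shuffled = [has[i] for i in rng.permutation(len(has))]
        for q, haq in zip(members, shuffled):
            new_ha[q] = haq
    ha_new = np.array([new_ha[q] for q in pop_labels])
    return grp_labels, ha_new


def _permute_groups(rng, grp_labels, ha_labels):
    """Permute whole HAs among groups."""
    has = pd.unique(ha_labels)
    ha_grp = {q: grp_labels[ha_labels == q][0] for q in has}
    vals = [ha_grp[q] for q in has]
    shuffled = [vals[i] for i in rng.permutation(len(vals))]
    new = dict(zip(has, shuffled))
    return np.array([new[q] for q in ha_labels])


# ---------------------------------------------------------------------------
# F_ST-threshold clustering (admixture surrogate)
# ---------------------------------------------------------------------------


def cluster_populations(fst: pd.DataFrame, threshold: float) -> pd.Series:
    """Single-linkage merge of populations with pairwise F_ST below the
    threshold; negative estimates are treated as zero.  Returns integer
    cluster labels (by sorted population name of each component's smallest
    member)."""
    pops = list(fst.index)
    g = nx.Graph()
    g.add_nodes_from(pops)
    vals = fst.to_numpy().clip(min=0.0)
    for i in range(len(pops)):
        for j in range(i + 1, len(pops)):
            if vals[i, j] < threshold:
                g.add_edge(pops[i], pops[j])
    comps = sorted(nx.connected_components(g), key=min)
    labels = {}
    for k, comp in enumerate(comps, start=1):
        for pop in comp:
            labels[pop] = k
    return pd.Series([labels[p] for p in pops], index=pops, name="cluster")
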