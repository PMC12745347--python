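"""Genotype-environment association via redundancy analysis (RDA).

The workflow: prune collinear environment variables, impute missing genotypes
with the per-SNP modal genotype, fit a (partial) RDA of centred dosages on
standardised predictors, assess per-axis significance by permutation, flag
candidate SNPs with extreme loadings on the significant axes, and annotate
candidates against gene and QTL intervals with field-standard windows
(1 kbp for genes, 100 kbp for QTLs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import MISSING, GenotypeMatrix, IntervalSet


# ---------------------------------------------------------------------------
# predictors
# ---------------------------------------------------------------------------


def prune_collinear(env: pd.DataFrame, rho_max: float = 0.7, priority: list | None = None):
    """Greedy collinearity pruning.

    Variables are scanned in ``priority`` order (default: column order); a
    variable is dropped when its absolute Pearson correlation with any
    already-retained variable reaches ``rho_max``.  Constant columns are
    dropped with a warning entry.  Returns ``(retained, dropped_because_of)``.
    """
    priority = list(priority) if priority is not None else list(env.columns)
    retained: list = []
    dropped: dict = {}
    for var in priority:
        x = env[var].to_numpy(float)
        if np.std(x) == 0:
            dropped[var] = "constant"
            continue
        clash = None
        for kept in retained:
            rho = np.corrcoef(x, env[kept].to_numpy(float))[0, 1]
            if abs(rho) >= rho_max:
                clash = kept
                break
        if clash is None:
            retained.append(var)
        else:
            dropped[var] = clash
    return retained, dropped


def impute_most_common(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls with the modal genotype of each SNP (ties broken
    toward the lower dosage)."""
    g = G.genotypes.copy()
    miss = g == MISSING
    for j in np.flatnonzero(miss.any(axis=0)):
        col = g[:, j]
        counts = np.array([(col == code).sum() for code in (0, 1, 2)])
        mode = int(np.argmax(counts))  # argmax takes the first (lowest) on ties
        col[col == MISSING] = mode
    return GenotypeMatrix(g, G.sites.copy(), G.individuals)


# ---------------------------------------------------------------------------
# the RDA itself
# ---------------------------------------------------------------------------


@dataclass
class RdaModel:
    site_scores: pd.DataFrame  # rows x axes (weighted by singular values)
    snp_loadings: pd.DataFrame  # SNPs x axes
    eigenvalues: np.ndarray
    total_variance: float
    constrained_proportion: float
    conditioned_proportion: float
    predictors: list
    dropped_predictors: list
    X_std: np.ndarray = field(repr=False)  # standardized predictors, post-conditioning
    Y_res: np.ndarray = field(repr=False)  # centred (and conditioned) response
    axis_p_values: pd.Series | None = None

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)


def _drop_rank_deficient(X: np.ndarray, names: list):
    """Greedy left-to-right scan dropping columns that do not raise the rank."""
    keep, dropped = [], []
    cur = np.empty((X.shape[0], 0))
    for k, name in enumerate(names):
        trial = np.hstack([cur, X[:, [k]]])
        if np.linalg.matrix_rank(trial, tol=1e-9) > cur.shape[1]:
            cur = trial
            keep.append(k)
        else:
            dropped.append(name)
    return keep, dropped


def rda_fit(Y: np.ndarray, X: pd.DataFrame, Z: np.ndarray | None = None) -> RdaModel:
    """Redundancy analysis of response ``Y`` on predictors ``X``.

    ``Y`` is centred column-wise; ``X`` is standardised to zero mean and unit
    variance.  With conditioning covariates ``Z`` both are first replaced by
    their residuals from a least-squares projection on ``[1, Z]`` (partial
    RDA).  Constrained axes come from the SVD of the fitted values; the
    eigenvalue of axis ``k`` is its variance contribution, and the constrained
    proportion is relative to the total variance of the centred response.
    """
    Y = np.asarray(Y, float)
    names = list(X.columns)
    Xm = X.to_numpy(float)
    if Y.shape[0] != Xm.shape[0]:
        raise ValueError("Y and X must have aligned rows")
    n = Y.shape[0]

    Yc = Y - Y.mean(axis=0)
    total_var = (Yc**2).sum() / (n - 1)

    sd = Xm.std(axis=0, ddof=0)
    if np.any(sd == 0):
        const = [names[k] for k in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant predictor(s): {const}")
    Xs = (Xm - Xm.mean(axis=0)) / sd

    conditioned_prop = 0.0
    if Z is not None:
        Z = np.asarray(Z, float)
        if Z.ndim == 1:
            Z = Z[:, None]
        Zc = np.hstack([np.ones((n, 1)), Z])
        bz, *_ = np.linalg.lstsq(Zc, Yc, rcond=None)
        Y_fit_z = Zc @ bz
        conditioned_prop = float((Y_fit_z**2).sum() / (n - 1) / total_var) if total_var > 0 else 0.0
        Yc = Yc - Y_fit_z
        bx, *_ = np.linalg.lstsq(Zc, Xs, rcond=None)
        Xs = Xs - Zc @ bx

    keep, dropped = _drop_rank_deficient(Xs, names)
    Xs = Xs[:, keep]
    names = [names[k] for k in keep]

    b, *_ = np.linalg.lstsq(Xs, Yc, rcond=None)
    Yhat = Xs @ b
    U, s, Vt = np.linalg.svd(Yhat, full_matrices=False)
    rank = min(len(names), int((s > s[0] * 1e-9).sum()) if len(s) and s[0] > 0 else 0)
    U, s, Vt = U[:, :rank], s[:rank], Vt[:rank]
    eig = s**2 / (n - 1)
    constrained = float(eig.sum() / total_var) if total_var > 0 else 0.0

    axes = [f"RDA{k + 1}" for k in range(rank)]
    return RdaModel(
        site_scores=pd.DataFrame(U * s, columns=axes),
        snp_loadings=pd.DataFrame(Vt.T, columns=axes),
        eigenvalues=eig,
        total_variance=float(total_var),
        constrained_proportion=constrained,
        conditioned_proportion=conditioned_prop,
        predictors=names,
        dropped_predictors=dropped,
        X_std=Xs,
        Y_res=Yc,
    )


def axis_significance(model: RdaModel, n_perm: int = 999, seed: int = 0) -> pd.Series:
    """Marginal per-axis permutation p-values.

    Rows of the (conditioned) predictor matrix are freely permuted, the RDA
    refitted, and each observed eigenvalue compared with its permuted
    distribution: ``p_k = (1 + #{perm lambda_k >= lambda_k}) / (n_perm + 1)``.
    """
    rng = np.random.default_rng(seed)
    n = model.Y_res.shape[0]
    obs = model.eigenvalues
    hits = np.zeros(len(obs))
    # fitted values under a permuted X are P Q Q' P' Y for Q an orthonormal
    # basis of X, so their singular values are those of (Q[perm])' Y
    Q, _ = np.linalg.qr(model.X_std)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        s = np.linalg.svd(Q[perm].T @ model.Y_res, compute_uv=False)
        lam = s[: len(obs)] ** 2 / (n - 1)
        lam = np.pad(lam, (0, len(obs) - len(lam)))
        hits += lam >= obs
    p = (1 + hits) / (n_perm + 1)
    model.axis_p_values = pd.Series(p, index=[f"RDA{k + 1}" for k in range(len(obs))])
    return model.axis_p_values


# ---------------------------------------------------------------------------
# candidates
# ---------------------------------------------------------------------------


@dataclass
class CandidateSet:
    table: pd.DataFrame  # snp id, strongest predictor, max |loading| in SD units

    @property
    def snp_ids(self) -> set:
        return set(self.table["id"])

    def __len__(self) -> int:
        return len(self.table)


def candidate_snps(
    model: RdaModel,
    G: GenotypeMatrix,
    X: pd.DataFrame,
    axes: list | None = None,
    sd_cut: float = 3.0,
    rule: str = "union",
) -> CandidateSet:
    """Flag SNPs with extreme loadings on the chosen constrained axes.

    Per axis, loadings are standardised (z-scores of that axis's loading
    distribution) and SNPs with ``|z| > sd_cut`` are flagged; flags combine
    across axes by ``union`` (default) or ``intersection``.  Each candidate's
    strongest predictor is the environment variable maximising the absolute
    correlation with the (imputed) SNP dosage column.
    """
    if axes is None:
        if model.axis_p_values is not None:
            axes = list(model.axis_p_values.index[model.axis_p_values < 0.05])
        else:
            axes = list(model.snp_loadings.columns)
    if not axes:
        return CandidateSet(pd.DataFrame(columns=["id", "strongest_predictor", "max_abs_sd"]))
    flags = []
    zmax = np.zeros(len(model.snp_loadings))
    for ax in axes:
        v = model.snp_loadings[ax].to_numpy()
        z = (v - v.mean()) / v.std(ddof=0)
        flags.append(np.abs(z) > sd_cut)
        zmax = np.maximum(zmax, np.abs(z))
    combined = np.logical_or.reduce(flags) if rule == "union" else np.logical_and.reduce(flags)
    idx = np.flatnonzero(combined)
    if len(idx) == 0:
        return CandidateSet(pd.DataFrame(columns=["id", "strongest_predictor", "max_abs_sd"]))

    Xm = X.to_numpy(float)
    Xc = (Xm - Xm.mean(axis=0)) / Xm.std(axis=0, ddof=0)
    rows = []
    for j in idx:
        y = model.Y_res[:, j]
        sy = y.std(ddof=0)
        if sy == 0:
            best = X.columns[0]
        else:
            cors = (Xc * ((y - y.mean()) / sy)[:, None]).mean(axis=0)
            best = X.columns[int(np.argmax(np.abs(cors)))]
        rows.append(
            {
                "id": G.site_ids[j],
                "chrom": G.sites["chrom"].iloc[j],
                "pos": int(G.sites["pos"].iloc[j]),
                "strongest_predictor": best,
                "max_abs_sd": float(zmax[j]),
            }
        )
    return CandidateSet(pd.DataFrame(rows))


def annotate_candidates(
    candidates: CandidateSet,
    features: IntervalSet,
    window: int,
) -> pd.DataFrame:
    """SNP-feature overlap table with a symmetric window around features.

    A SNP at 1-based position ``p`` is reported for a 0-based half-open
    feature ``[s, e)`` when ``s - window < p <= e + window`` (window edges
    inclusive).  ``relative_position`` is 0 inside the unexpanded feature,
    otherwise the signed distance to the nearer feature edge.
    """
    trees: dict[str, IntervalTree] = {}
    for _, f in features.df.iterrows():
        trees.setdefault(str(f["chrom"]), IntervalTree()).addi(
            f["start"] - window, f["end"] + window, (f["start"], f["end"], f["name"])
        )
    rows = []
    cand_chroms = set(candidates.table["chrom"].astype(str)) if len(candidates) else set()
    if cand_chroms and not (cand_chroms & set(trees)):
        import warnings

        warnings.warn("no shared chromosome names between candidates and features")
    for _, snp in candidates.table.iterrows():
        tree = trees.get(str(snp["chrom"]))
        if tree is None:
            continue
        pos = int(snp["pos"])
        for hit in tree[pos - 1]:  # 1-based pos p lies in [s,e) iff s <= p-1 < e
            s, e, name = hit.data
            if s < pos <= e:
                rel = 0
            elif pos <= s:
                rel = pos - (s + 1)
            else:
                rel = pos - e
            rows.append(
                {
                    "id": snp["id"],
                    "chrom": snp["chrom"],
                    "pos": pos,
                    "feature": name,
                    "feature_start": s,
                    "feature_end": e,
                    "relative_position": rel,
                }
            )
    return pd.DataFrame(rows, columns=["id", "chrom", "pos", "feature", "feature_start", "feature_end", "relative_position"])


def dosage_response(G: GenotypeMatrix) -> np.ndarray:
    """Imputed, float dosage response matrix for the RDA (individual level)."""
    return impute_most_common(G).genotypes.astype(float)
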