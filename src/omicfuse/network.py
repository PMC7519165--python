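"""Consensus signed co-methylation/co-expression networks and enrichment.

Feature-feature similarity uses the biweight midcorrelation (robust to
single gross outliers), mapped to a signed adjacency
a_ij = ((1 + cor_ij)/2)^beta and then to the topological overlap measure
(TOM).  A consensus TOM is the edge-wise median over bootstrap resamples
of the samples.  Modules come from average-linkage clustering of 1 - TOM
with a static height cut chosen by modularity, small clusters sent to the
unassigned ("grey") pool, and near-identical modules merged by eigengene
correlation.  Module summaries (eigengenes) are tested against diagnosis
with the same random-intercept mixed model used for per-feature analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .differential import DesignSpec, bh_fdr
from .lmm import RandomInterceptModel

__all__ = [
    "NetworkParams",
    "ModuleSet",
    "bicor_matrix",
    "signed_adjacency",
    "topological_overlap",
    "consensus_tom",
    "detect_modules",
    "module_eigengene",
    "module_trait_association",
    "hub_selection",
    "geneset_enrichment_logistic",
    "fisher_exact_2x2",
]

GREY = "grey"


@dataclass
class NetworkParams:
    beta: float = 9.0              # soft-threshold power (9 promoters, 8 bodies)
    n_bootstraps: int = 100
    min_module_size: int = 100
    merge_threshold: float = 0.1   # merge modules with eigengene cor > 1-thr
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not (0 < self.merge_threshold < 1):
            raise ValueError("merge_threshold must lie in (0, 1)")


@dataclass
class ModuleSet:
    labels: pd.Series                 # feature -> module ("grey" = unassigned)
    eigengenes: pd.DataFrame          # sample x module
    kme: pd.DataFrame                 # feature x module correlations
    extras: dict = field(default_factory=dict)

    @property
    def modules(self) -> list[str]:
        return [m for m in self.eigengenes.columns]


# ---------------------------------------------------------------------------
# Correlation / adjacency / TOM


def _bicor_transform(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows -> biweight-weighted deviations; returns (transformed, mad_zero)."""
    med = np.median(X, axis=1, keepdims=True)
    dev = X - med
    mad = np.median(np.abs(dev), axis=1, keepdims=True)
    mad_zero = mad[:, 0] == 0
    safe_mad = np.where(mad == 0, 1.0, mad)
    u = dev / (9.0 * safe_mad)
    w = (1 - u**2) ** 2 * (np.abs(u) < 1)
    t = dev * w
    # MAD-zero rows fall back to Pearson: plain centered values
    t[mad_zero] = X[mad_zero] - X[mad_zero].mean(axis=1, keepdims=True)
    return t, mad_zero


def bicor_matrix(X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Biweight midcorrelation between features (rows), tuning constant 9.

    Features with zero median absolute deviation fall back to Pearson for
    their rows (flagged by warning); all-constant features yield NaN rows
    and raise.
    """
    A = X.to_numpy(float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if A.shape[1] < 4:
        raise ValueError("need >= 4 samples")
    const = A.std(axis=1) == 0
    if const.any():
        raise ValueError(
            f"{int(const.sum())} constant features have undefined correlation; "
            "exclude them first")
    t, mad_zero = _bicor_transform(A)
    if mad_zero.any():
        warnings.warn(
            f"{int(mad_zero.sum())} features with MAD=0 fell back to Pearson",
            stacklevel=2)
    norm = np.sqrt((t**2).sum(axis=1))
    C = (t @ t.T) / np.outer(norm, norm)
    C = np.clip(C, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    return C


def signed_adjacency(cor: np.ndarray, beta: float) -> np.ndarray:
    """Signed soft-threshold adjacency ((1+cor)/2)^beta with zero diagonal."""
    a = ((1.0 + np.asarray(cor, float)) / 2.0) ** beta
    np.fill_diagonal(a, 0.0)
    return a


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij); diag 1."""
    a = np.asarray(adjacency, float)
    if not np.allclose(a, a.T):
        raise ValueError("adjacency must be symmetric")
    k = a.sum(axis=1)
    num = a @ a + a
    den = np.minimum.outer(k, k) + 1.0 - a
    tom = num / den
    np.fill_diagonal(tom, 1.0)
    return tom


def consensus_tom(X: pd.DataFrame, params: NetworkParams,
                  resample: bool = True) -> np.ndarray:
    """Edge-wise median TOM over bootstrap resamples of the samples.

    With ``resample=False`` and n_bootstraps=1 this equals the plain TOM of
    the full data.  Bootstraps in which a feature becomes constant have
    that feature's edges excluded from the median for that bootstrap
    (flagged).
    """
    A = X.to_numpy(float)
    p, n = A.shape
    rng = np.random.default_rng(params.seed)
    toms = np.empty((params.n_bootstraps, p, p))
    n_flagged = 0
    for b in range(params.n_bootstraps):
        idx = rng.integers(0, n, size=n) if resample else np.arange(n)
        sub = A[:, idx]
        const = sub.std(axis=1) == 0
        if const.any():
            n_flagged += 1
            keep = ~const
            tom_b = np.full((p, p), np.nan)
            cor = bicor_matrix(sub[keep])
            tom_b[np.ix_(keep, keep)] = topological_overlap(
                signed_adjacency(cor, params.beta))
        else:
            cor = bicor_matrix(sub)
            tom_b = topological_overlap(signed_adjacency(cor, params.beta))
        toms[b] = tom_b
    if n_flagged:
        warnings.warn(
            f"{n_flagged} bootstraps had constant features; their edges were "
            "excluded from the median", stacklevel=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cons = np.nanmedian(toms, axis=0)
    cons = np.nan_to_num(cons, nan=0.0)
    np.fill_diagonal(cons, 1.0)
    return cons


# ---------------------------------------------------------------------------
# Modules


def module_eigengene(X: pd.DataFrame, members: list) -> pd.Series:
    """First principal direction score of a module's standardized features.

    Returns unit-norm per-sample scores oriented to correlate positively
    with the module's mean standardized profile.
    """
    sub = X.loc[members].to_numpy(float)
    if sub.shape[0] < 2:
        raise ValueError("module must have >= 2 features")
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (sub - mu) / sd
    if not np.any(Z):
        raise ValueError("rank-0 module submatrix")
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eig = Vt[0]
    mean_profile = Z.mean(axis=0)
    if np.dot(eig, mean_profile) < 0:
        eig = -eig
    return pd.Series(eig, index=X.columns)


def _modularity(W: np.ndarray, labels: np.ndarray) -> float:
    """Newman modularity of a partition on a weighted graph (zero diagonal)."""
    A = W.copy()
    np.fill_diagonal(A, 0.0)
    two_m = A.sum()
    if two_m == 0:
        return 0.0
    deg = A.sum(axis=1)
    q = 0.0
    for c in np.unique(labels):
        idx = labels == c
        q += A[np.ix_(idx, idx)].sum() / two_m - (deg[idx].sum() / two_m) ** 2
    return q


def detect_modules(tom: np.ndarray, X: pd.DataFrame,
                   params: NetworkParams) -> ModuleSet:
    """Cut the average-linkage tree of 1 - TOM into modules.

    A static height cut is chosen among candidate heights (quantiles of the
    merge heights) to maximize the modularity of the induced partition on
    the TOM graph; clusters below ``min_module_size`` become grey; modules
    whose eigengenes correlate above 1 - merge_threshold are merged
    iteratively.  Module names are M1, M2, ... by decreasing size.
    """
    p = tom.shape[0]
    if p != len(X.index):
        raise ValueError("TOM and matrix disagree on feature count")
    dist = 1.0 - tom
    np.fill_diagonal(dist, 0.0)
    dist = 0.5 * (dist + dist.T)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    heights = link[:, 2]
    cands = np.unique(np.quantile(heights, np.linspace(0.1, 0.98, 30)))
    best_labels, best_q = None, -np.inf
    for h in cands:
        lab = hierarchy.fcluster(link, t=h, criterion="distance")
        if len(np.unique(lab)) < 2:
            continue
        q = _modularity(tom, lab)
        if q > best_q:
            best_q, best_labels = q, lab
    if best_labels is None:
        warnings.warn("no height produced >1 cluster; all features grey",
                      stacklevel=2)
        labels = pd.Series(GREY, index=X.index)
        return ModuleSet(labels=labels,
                         eigengenes=pd.DataFrame(index=X.columns),
                         kme=pd.DataFrame(index=X.index))
    # enforce minimum size
    lab = best_labels.copy()
    sizes = pd.Series(lab).value_counts()
    small = sizes.index[sizes < params.min_module_size]
    grey_mask = np.isin(lab, small)
    lab = lab.astype(object)
    lab[grey_mask] = GREY
    groups: dict[object, list] = {}
    for f, l in zip(X.index, lab):
        groups.setdefault(l, []).append(f)
    groups.pop(GREY, None)
    if not groups:
        warnings.warn("all clusters below min_module_size; all features grey",
                      stacklevel=2)
        labels = pd.Series(GREY, index=X.index)
        return ModuleSet(labels=labels,
                         eigengenes=pd.DataFrame(index=X.columns),
                         kme=pd.DataFrame(index=X.index))
    # iterative merge by eigengene correlation
    merged = True
    while merged and len(groups) > 1:
        merged = False
        keys = list(groups)
        eigs = {k: module_eigengene(X, groups[k]) for k in keys}
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                r = np.corrcoef(eigs[keys[i]], eigs[keys[j]])[0, 1]
                if r > 1.0 - params.merge_threshold:
                    groups[keys[i]] = groups[keys[i]] + groups[keys[j]]
                    del groups[keys[j]]
                    merged = True
                    break
            if merged:
                break
    # name by decreasing size
    ordered = sorted(groups.values(), key=len, reverse=True)
    labels = pd.Series(GREY, index=X.index, dtype=object)
    eig_cols = {}
    for rank, members in enumerate(ordered, start=1):
        name = f"M{rank}"
        labels.loc[members] = name
        eig_cols[name] = module_eigengene(X, members)
    eigengenes = pd.DataFrame(eig_cols)
    # kME: correlation of each (standardized) feature with each eigengene
    Z = X.to_numpy(float)
    Zc = Z - Z.mean(axis=1, keepdims=True)
    sd = Zc.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Zc = Zc / sd
    kme_cols = {}
    for m in eigengenes.columns:
        e = eigengenes[m].to_numpy()
        ec = (e - e.mean()) / (e.std() + 1e-300)
        kme_cols[m] = (Zc @ ec) / Z.shape[1]
    kme = pd.DataFrame(kme_cols, index=X.index).clip(-1.0, 1.0)
    return ModuleSet(labels=labels, eigengenes=eigengenes, kme=kme,
                     extras={"cut_modularity": best_q})


def module_trait_association(
    eigengene: pd.Series,
    metadata: pd.DataFrame,
    design: DesignSpec,
    contrast: tuple[str, str] | None = None,
    diagnosis_col: str = "diagnosis",
) -> dict:
    """Diagnosis effect on a module eigengene via the random-intercept LMM.

    Returns dict(estimate, se, p).  BH across modules is applied by the
    caller over the collected p-values.
    """
    from .differential import differential_lmm

    if eigengene.std() == 0:
        raise ValueError("constant eigengene: degenerate fit")
    mat = pd.DataFrame([eigengene.to_numpy()], index=["eigengene"],
                       columns=eigengene.index)
    tab = differential_lmm(mat, metadata, design, contrast=contrast,
                           diagnosis_col=diagnosis_col)
    row = tab.iloc[0]
    return {"estimate": float(row["estimate"]), "se": float(row["se"]),
            "p": float(row["p"])}


def hub_selection(kme: pd.DataFrame, labels: pd.Series, module: str,
                  quantile: float = 0.25) -> list:
    """Top-``quantile`` members of a module by kME (ties included)."""
    members = labels.index[labels == module]
    if len(members) == 0:
        raise ValueError(f"module {module!r} is empty")
    vals = kme.loc[members, module]
    thr = np.quantile(vals.to_numpy(float), 1.0 - quantile)
    return vals.index[vals >= thr].tolist()


# ---------------------------------------------------------------------------
# Enrichment statistics


def geneset_enrichment_logistic(set1, set2, background) -> dict:
    """Logistic enrichment of gene set 1 on gene set 2 over a background.

    Per background gene, indicator(set1) ~ indicator(set2); OR is the
    exponentiated slope.  On separation the fit falls back to the
    Haldane-corrected odds ratio from the 2x2 table with a Fisher p
    (flagged in the result).
    """
    bg = list(background)
    if len(bg) < 10:
        raise ValueError("background must have >= 10 genes")
    s1, s2 = set(set1), set(set2)
    if not s1 or not s2:
        raise ValueError("gene sets must be nonempty")
    if not (s1 <= set(bg) and s2 <= set(bg)):
        raise ValueError("gene sets must be subsets of the background")
    y = np.array([g in s1 for g in bg], float)
    x = np.array([g in s2 for g in bg], float)

    import statsmodels.api as sm

    a = int(((y == 1) & (x == 1)).sum())
    b = int(((y == 1) & (x == 0)).sum())
    c = int(((y == 0) & (x == 1)).sum())
    d = int(((y == 0) & (x == 0)).sum())
    separated = min(a, b, c, d) == 0
    if not separated:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, np.column_stack([np.ones(len(y)), x])).fit(
                disp=0, maxiter=200)
        if res.mle_retvals.get("converged", False) and abs(res.params[1]) < 20:
            return {"odds_ratio": float(np.exp(res.params[1])),
                    "p": float(res.pvalues[1]), "fallback": False}
        separated = True
    orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    p = fisher_exact_2x2(np.array([[a, b], [c, d]]))
    return {"odds_ratio": float(orr), "p": float(p), "fallback": True}


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table (probability-mass rule).

    Sums hypergeometric probabilities of all tables with the observed
    margins whose probability does not exceed the observed table's.  A
    zero margin gives p = 1.
    """
    t = np.asarray(table, int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 integer table")
    if t.sum(axis=0).min() == 0 or t.sum(axis=1).min() == 0:
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])
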