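"""Similarity network fusion and spectral bipartition of sample graphs.

Each omics layer is reduced to its differential features, standardized,
converted to a sample-sample affinity via a locally scaled exponential
kernel, and the per-layer affinity graphs are fused by iterated
cross-diffusion.  The fused graph is split into two groups (the convergent
candidate group vs the rest) by normalized-cut spectral clustering.

Kernel: W(i,j) = exp(-rho^2(i,j) / (mu * eps_ij)) with rho the Euclidean
distance and eps_ij = (mean rho to i's K nearest neighbours
+ mean rho to j's K nearest neighbours + rho(i,j)) / 3.  Self is excluded
from the neighbour sets; neighbour-rank ties break by sample index.

Fusion: per layer v the full-kernel transition matrix P_v carries mass 1/2
on the diagonal and 1/2 spread over the off-diagonal proportional to W;
the sparse kernel S_v row-normalizes the K-nearest-neighbour entries.
Each of T iterations performs P_v <- S_v . mean_{k!=v}(P_k) . S_v', then
re-symmetrizes and re-applies the half-diagonal normalization so every row
keeps unit mass.  The fused network is the layer average, symmetrized.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.cluster import KMeans

__all__ = [
    "SNFParams",
    "AffinityMatrix",
    "select_differential_features",
    "standard_normalize",
    "squared_euclidean_distances",
    "affinity_matrix",
    "snf_fuse",
    "spectral_cluster",
    "leave_one_dataset_out",
]

EPS_FLOOR = 1e-12


@dataclass
class SNFParams:
    K: int = 20            # neighbourhood size
    alpha: float = 0.5     # kernel scale mu
    T: int = 15            # fusion iterations
    k_clusters: int = 2

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.T < 1:
            raise ValueError("T must be >= 1")

    def effective_k(self, n: int) -> int:
        k = min(self.K, n - 1)
        if k < self.K:
            warnings.warn(f"K reduced to {k} for n={n} samples", stacklevel=3)
        return k


@dataclass
class AffinityMatrix:
    """Affinity W with its full (P) and K-NN local (S) transition kernels."""

    W: np.ndarray
    P: np.ndarray
    S: np.ndarray
    eps: np.ndarray
    samples: list[str] = field(default_factory=list)


def select_differential_features(diff: pd.DataFrame, q_threshold: float) -> list:
    """Features differential at the layer's FDR threshold, order-stable."""
    if not (0 < q_threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    sel = diff.index[diff["q"] < q_threshold].tolist() if q_threshold < 1 \
        else diff.index.tolist()
    if not sel:
        raise ValueError(
            f"no features pass q < {q_threshold}; fusion undefined on 0 features")
    return sel


def standard_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center and scale each feature (row) to mean 0, sd 1 (n-1 denominator).

    Zero-variance features are dropped with a warning.
    """
    X = matrix.to_numpy(float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance features dropped", stacklevel=2)
        X, mu, sd = X[~flat], mu[~flat], sd[~flat]
        matrix = matrix.loc[~flat]
    return pd.DataFrame((X - mu) / sd, index=matrix.index, columns=matrix.columns)


def squared_euclidean_distances(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Sample-sample squared Euclidean distances (features x samples input)."""
    X = matrix.to_numpy(float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    G = X.T @ X
    sq = np.diag(G)
    D = sq[:, None] + sq[None, :] - 2 * G
    np.fill_diagonal(D, 0.0)
    return np.clip(D, 0.0, None)


def affinity_matrix(D: np.ndarray, params: SNFParams,
                    samples: list[str] | None = None) -> AffinityMatrix:
    """Locally scaled exponential kernel affinity from squared distances."""
    D = np.asarray(D, float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("D must be square")
    k = params.effective_k(n)
    rho = np.sqrt(np.clip(D, 0.0, None))
    # K nearest neighbours excluding self; stable sort -> index tie-break
    order = np.argsort(rho + np.where(np.eye(n, dtype=bool), np.inf, 0.0),
                       axis=1, kind="stable")
    nbr = order[:, :k]
    mean_knn = np.take_along_axis(rho, nbr, axis=1).mean(axis=1)
    eps = (mean_knn[:, None] + mean_knn[None, :] + rho) / 3.0
    eps = np.maximum(eps, EPS_FLOOR)
    W = np.exp(-np.clip(D, 0.0, None) / (params.alpha * eps))
    W = 0.5 * (W + W.T)
    P = _full_transition(W)
    S = _local_transition(W, nbr)
    return AffinityMatrix(W=W, P=P, S=S, eps=eps,
                          samples=list(samples) if samples is not None else [])


def _full_transition(W: np.ndarray) -> np.ndarray:
    """P with diagonal 1/2 and off-diagonal mass 1/2 proportional to W."""
    n = W.shape[0]
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    rs = off.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    P = off / (2.0 * rs)
    np.fill_diagonal(P, 0.5)
    return P


def _local_transition(W: np.ndarray, nbr: np.ndarray) -> np.ndarray:
    """Row-normalized kernel restricted to each row's K neighbours."""
    n = W.shape[0]
    S = np.zeros_like(W)
    rows = np.repeat(np.arange(n), nbr.shape[1])
    S[rows, nbr.ravel()] = W[rows, nbr.ravel()]
    rs = S.sum(axis=1, keepdims=True)
    rs[rs == 0] = 1.0
    return S / rs


def snf_fuse(affinities: list[AffinityMatrix], params: SNFParams) -> np.ndarray:
    """Fuse >=2 per-layer affinity graphs by iterated cross-diffusion."""
    if len(affinities) < 2:
        raise ValueError("need at least 2 layers to fuse")
    sample_sets = [tuple(a.samples) for a in affinities if a.samples]
    if sample_sets and len(set(sample_sets)) > 1:
        all_sets = [set(s) for s in sample_sets]
        sym = set.union(*all_sets) - set.intersection(*all_sets)
        raise ValueError(f"layers disagree on samples: {sorted(sym)}")
    Ps = [a.P.copy() for a in affinities]
    Ss = [a.S for a in affinities]
    m = len(Ps)
    for _ in range(params.T):
        new = []
        for v in range(m):
            mean_others = sum(Ps[k] for k in range(m) if k != v) / (m - 1)
            Pv = Ss[v] @ mean_others @ Ss[v].T
            Pv = 0.5 * (Pv + Pv.T)
            new.append(_full_transition(Pv))
        Ps = new
    fused = sum(Ps) / m
    return 0.5 * (fused + fused.T)


def spectral_cluster(W: np.ndarray, k: int = 2, seed: int = 0,
                     orient_scores: np.ndarray | None = None,
                     n_restarts: int = 50) -> np.ndarray:
    """Normalized-cut spectral clustering of a fused affinity graph.

    Embeds samples in the top-k eigenvectors of D^{-1/2} W D^{-1/2},
    row-normalizes, and runs k-means with ``n_restarts`` seeded restarts.
    Labels are 1..k.  With ``orient_scores`` given (per-sample differential
    signature loading) and k=2, label 2 is assigned to the cluster with the
    higher mean score (the convergent candidate); otherwise labels follow
    first-occurrence order.
    """
    W = np.asarray(W, float)
    n = W.shape[0]
    import scipy.sparse.csgraph as csgraph
    ncomp, _ = csgraph.connected_components((W > 0).astype(int), directed=False)
    if ncomp > k:
        raise ValueError(f"affinity graph has {ncomp} components > k={k}")
    d = W.sum(axis=1)
    d_isqrt = 1.0 / np.sqrt(np.maximum(d, 1e-300))
    M = W * d_isqrt[:, None] * d_isqrt[None, :]
    M = 0.5 * (M + M.T)
    vals, vecs = eigh(M, subset_by_index=[n - k, n - 1])
    U = vecs[:, ::-1]
    norms = np.linalg.norm(U, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    U = U / norms
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(U)
    if orient_scores is not None and k == 2:
        scores = np.asarray(orient_scores, float)
        means = [scores[raw == c].mean() for c in range(2)]
        hi = int(np.argmax(means))
        labels = np.where(raw == hi, 2, 1)
    else:
        # deterministic relabel by first occurrence
        remap: dict[int, int] = {}
        labels = np.empty(n, int)
        for i, c in enumerate(raw):
            if c not in remap:
                remap[c] = len(remap) + 1
            labels[i] = remap[c]
    return labels


def fuse_layers(layers: dict[str, pd.DataFrame], params: SNFParams) -> tuple[np.ndarray, list[str]]:
    """Normalize each layer, build affinities, and fuse; returns (W, samples).

    Layers are feature x sample frames restricted to differential features;
    all layers must share an identical sample set and order.
    """
    names = list(layers)
    cols = [tuple(layers[n].columns) for n in names]
    if len(set(cols)) > 1:
        sets = [set(c) for c in cols]
        sym = set.union(*sets) - set.intersection(*sets)
        raise ValueError(f"layers disagree on samples: {sorted(sym)}")
    affs = []
    for nm in names:
        Xn = standard_normalize(layers[nm])
        D = squared_euclidean_distances(Xn)
        affs.append(affinity_matrix(D, params, samples=list(layers[nm].columns)))
    return snf_fuse(affs, params), list(cols[0])


def assignment_agreement(a: np.ndarray, b: np.ndarray) -> float:
    """Fraction of samples identically assigned after optimal 2-label matching."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    direct = float(np.mean(a == b))
    la, lb = np.unique(a), np.unique(b)
    if len(la) == 2 and len(lb) == 2:
        swapped = float(np.mean(np.where(b == lb[0], lb[1], lb[0]) == a))
        return max(direct, swapped)
    return direct


def leave_one_dataset_out(layers: dict[str, pd.DataFrame], params: SNFParams,
                          seed: int = 0,
                          orient_scores: np.ndarray | None = None) -> pd.DataFrame:
    """Re-cluster leaving out each layer; concordance with full-data labels.

    Returns a DataFrame indexed by the left-out layer with the agreement
    fraction (after optimal 2-label matching) against the 4-layer labels.
    """
    if len(layers) < 3:
        raise ValueError("need >=3 layers so each leave-out still fuses >=2")
    W_full, _ = fuse_layers(layers, params)
    full = spectral_cluster(W_full, params.k_clusters, seed, orient_scores)
    rows = {}
    for left_out in layers:
        sub = {k: v for k, v in layers.items() if k != left_out}
        W, _ = fuse_layers(sub, params)
        lab = spectral_cluster(W, params.k_clusters, seed, orient_scores)
        rows[left_out] = assignment_agreement(full, lab)
    return pd.DataFrame({"concordance": rows})
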