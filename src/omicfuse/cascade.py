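"""Logistic classifier cascade for samples missing from some omics layers.

Samples present in all four layers get subtype labels directly from the
fused-network clustering; every other sample is assigned by a logistic
regression trained on the layer-wise differential-signature scores it does
have.  One model per observed availability pattern of layers is trained on
the fully observed reference cohort; its decision cutoff is tuned by
exhaustive leave-one-out cross-validation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "LAYERS",
    "DEFAULT_PATTERNS",
    "pc1_zscores",
    "fit_logistic",
    "train_cascade",
    "classify_samples",
    "assignment_concordance",
    "CascadeModel",
]

LAYERS = ("mrna", "mirna", "meth", "acetyl")

# The two availability patterns never observed in the reference cohort
# (miRNA+methylation+acetylation triple and miRNA alone) are excluded,
# leaving twelve models: 3 triples, 6 pairs, 3 singles.
_EXCLUDED = {("mirna", "meth", "acetyl"), ("mirna",)}
DEFAULT_PATTERNS: tuple[tuple[str, ...], ...] = tuple(
    pat
    for size in (3, 2, 1)
    for pat in itertools.combinations(LAYERS, size)
    if pat not in _EXCLUDED
)


def pc1_zscores(
    diff_matrix: pd.DataFrame,
    reference_group2: list[str] | None = None,
) -> pd.Series:
    """Per-sample Z-scored loadings on PC1 of a differential-feature matrix.

    The matrix is feature x sample; features are centered and the first
    right singular vector gives the sample loadings.  The sign is oriented
    so the mean score of the ``reference_group2`` (convergent) samples is
    positive; without a reference the sign makes the loading positively
    correlated with the mean feature profile.  Scores are standardized to
    mean 0, sd 1 over all scored samples.
    """
    X = diff_matrix.to_numpy(float)
    if X.shape[0] < 1 or X.shape[1] < 2:
        raise ValueError("need >=1 feature and >=2 samples")
    Xc = X - X.mean(axis=1, keepdims=True)
    if not np.any(Xc):
        raise ValueError("matrix is rank 0 after centering")
    _, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = Vt[0] * s[0]
    if reference_group2 is not None:
        idx = diff_matrix.columns.get_indexer(reference_group2)
        idx = idx[idx >= 0]
        if len(idx) and scores[idx].mean() < 0:
            scores = -scores
    else:
        if np.corrcoef(scores, Xc.mean(axis=0))[0, 1] < 0:
            scores = -scores
    z = (scores - scores.mean()) / scores.std(ddof=0)
    return pd.Series(z, index=diff_matrix.columns, name="pc1_z")


# ---------------------------------------------------------------------------
# Logistic fitting with Firth fallback under separation


def _firth_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 200,
                    tol: float = 1e-8) -> np.ndarray:
    """Firth-penalized logistic regression (Jeffreys prior) by Newton steps."""
    n, q = X.shape
    beta = np.zeros(q)
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        XW = X * w[:, None]
        info = X.T @ XW
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        # hat diagonal of the weighted design
        H = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        score = X.T @ (y - p + H * (0.5 - p))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def fit_logistic(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, bool]:
    """Maximum-likelihood logistic fit; Firth-penalized under separation.

    Returns (coefficients incl. intercept in column 0, firth_used).
    """
    import statsmodels.api as sm

    Xd = np.column_stack([np.ones(len(y)), X])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, Xd).fit(disp=0, maxiter=200)
            beta = np.asarray(res.params, float)
            separated = (not res.mle_retvals.get("converged", False)
                         or np.max(np.abs(beta)) > 20)
        except Exception:
            separated = True
    if separated:
        return _firth_logistic(Xd, y), True
    return beta, False


def _predict_proba(beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    eta = np.clip(np.column_stack([np.ones(len(X)), X]) @ beta, -30, 30)
    return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class CascadeModel:
    pattern: tuple[str, ...]
    coef: np.ndarray          # intercept + one slope per layer in pattern
    cutoff: float
    loo_accuracy: float
    firth: bool


def train_cascade(
    scores: pd.DataFrame,
    snf_labels: pd.Series,
    patterns: tuple[tuple[str, ...], ...] = DEFAULT_PATTERNS,
) -> dict[tuple[str, ...], CascadeModel]:
    """Train one logistic model per layer-availability pattern.

    scores: training-sample x layer frame of PC1 Z-scores (all four layers
        observed for the reference cohort).
    snf_labels: 1 (Group 1) / 2 (Group 2, convergent candidate) per sample.

    For each pattern, the model regresses (label == 2) on that pattern's
    Z-scores; leave-one-out refits give per-sample held-out probabilities,
    and the decision cutoff is the accuracy-maximizing midpoint between
    sorted LOO probabilities (ties resolved toward 0.5).
    """
    common = scores.index.intersection(snf_labels.index)
    scores = scores.loc[common]
    y = (snf_labels.loc[common].to_numpy() == 2).astype(float)
    if scores.isna().any().any():
        raise ValueError("training samples must have scores for all layers")
    models: dict[tuple[str, ...], CascadeModel] = {}
    n = len(y)
    for pat in patterns:
        X = scores[list(pat)].to_numpy(float)
        beta, firth = fit_logistic(X, y)
        loo = np.empty(n)
        mask = np.ones(n, bool)
        for i in range(n):
            mask[i] = False
            # once the full fit needed the Firth penalty the LOO refits
            # will separate too; skip the doomed ML attempts
            if firth:
                b_i = _firth_logistic(
                    np.column_stack([np.ones(n - 1), X[mask]]), y[mask])
            else:
                b_i, _ = fit_logistic(X[mask], y[mask])
            loo[i] = _predict_proba(b_i, X[i:i + 1])[0]
            mask[i] = True
        cutoff, acc = _best_cutoff(loo, y)
        models[pat] = CascadeModel(pattern=pat, coef=beta, cutoff=cutoff,
                                   loo_accuracy=acc, firth=firth)
    return models


def _best_cutoff(probs: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Accuracy-maximizing cutoff over midpoints of sorted LOO probabilities."""
    ps = np.unique(probs)
    cands = [0.5 * (a + b) for a, b in zip(ps[:-1], ps[1:])]
    cands = np.array([0.0] + cands + [1.0])
    accs = np.array([np.mean((probs >= c) == (y == 1)) for c in cands])
    best = accs.max()
    ties = cands[accs == best]
    cutoff = float(ties[np.argmin(np.abs(ties - 0.5))])
    return cutoff, float(best)


def classify_samples(
    test_scores: pd.DataFrame,
    models: dict[tuple[str, ...], CascadeModel],
    diagnosis: pd.Series | None = None,
) -> pd.DataFrame:
    """Assign partially observed samples to SNF Group 1/2.

    test_scores: sample x layer frame with NaN where a layer is missing.
    Each sample's availability pattern must match a trained model; the
    model probability is thresholded at its cutoff (>= cutoff -> Group 2).
    With a diagnosis Series, ASD Group-2 samples are called "convergent",
    ASD Group-1 "disparate", controls "control".
    """
    rows = []
    for sid, row in test_scores.iterrows():
        avail = tuple(l for l in LAYERS if l in row.index and not pd.isna(row[l]))
        if avail not in models:
            raise KeyError(f"no trained model for availability pattern {avail}")
        m = models[avail]
        p = float(_predict_proba(m.coef, row[list(avail)].to_numpy(float)[None, :])[0])
        group = 2 if p >= m.cutoff else 1
        rows.append((sid, "+".join(avail), p, group))
    out = pd.DataFrame(rows, columns=["sample_id", "pattern", "prob_group2",
                                      "snf_group"]).set_index("sample_id")
    if diagnosis is not None:
        diag = diagnosis.loc[out.index]
        call = np.where(diag == "control", "control",
                        np.where(out["snf_group"] == 2, "convergent", "disparate"))
        out["subtype_call"] = call
    return out


def assignment_concordance(labels_a: pd.Series, labels_b: pd.Series) -> float:
    """Fraction identically assigned after optimal 2-label matching."""
    common = labels_a.index.intersection(labels_b.index)
    if len(common) == 0:
        raise ValueError("label sets share no samples")
    if len(common) != len(labels_a) or len(common) != len(labels_b):
        missing = set(labels_a.index).symmetric_difference(labels_b.index)
        raise ValueError(f"label sets differ on samples: {sorted(missing)[:5]}")
    a = labels_a.loc[common].to_numpy()
    b = labels_b.loc[common].to_numpy()
    direct = float(np.mean(a == b))
    ub = np.unique(b)
    if len(np.unique(a)) <= 2 and len(ub) == 2:
        swapped = float(np.mean(np.where(b == ub[0], ub[1], ub[0]) == a))
        return max(direct, swapped)
    return direct
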