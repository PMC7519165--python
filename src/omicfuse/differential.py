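"""Per-feature differential statistics with subject-level random effects.

Implements the differential-analysis surface of the pipeline: sample QC
(correlation outliers, ChIP-seq metric thresholds), covariate adjustment
that preserves the diagnosis signal, random-intercept mixed models per
feature with Benjamini-Hochberg correction, and one-vs-rest cluster-marker
detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lmm import RandomInterceptModel

__all__ = [
    "DesignSpec",
    "remove_outlier_samples",
    "build_design_matrix",
    "regress_out_covariates",
    "differential_lmm",
    "bh_fdr",
    "chipseq_qc_filter",
    "detect_cluster_markers",
    "CHIPSEQ_QC_THRESHOLDS",
]


@dataclass
class DesignSpec:
    """Model formula for one omics layer.

    covariates: metadata columns entering the fixed-effect design (the
        diagnosis/term of interest included).
    keep_effects: effects NOT regressed out during covariate adjustment
        (typically ["diagnosis"]).
    group: metadata column giving the random-intercept grouping (brain ID).
    categorical: columns treatment-coded with the first sorted level as
        reference; inferred from dtype when None.
    """

    covariates: list[str]
    keep_effects: list[str] = field(default_factory=lambda: ["diagnosis"])
    group: str = "brain_id"
    categorical: list[str] | None = None

    def __post_init__(self) -> None:
        extra = set(self.keep_effects) - set(self.covariates)
        if extra:
            raise ValueError(f"keep_effects not among covariates: {sorted(extra)}")


def _is_categorical(s: pd.Series) -> bool:
    return s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool


def build_design_matrix(metadata: pd.DataFrame, spec: DesignSpec) -> pd.DataFrame:
    """Treatment-coded fixed-effect design with intercept.

    Categorical covariates are dummy-coded dropping the first sorted level
    (the reference); numeric covariates enter as-is.  Column names are
    ``cov`` or ``cov[level]``.
    """
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(len(metadata))}
    cat = set(spec.categorical) if spec.categorical is not None else None
    for cov in spec.covariates:
        s = metadata[cov]
        treat_cat = cov in cat if cat is not None else _is_categorical(s)
        if treat_cat:
            levels = sorted(pd.unique(s.astype(str)))
            for lev in levels[1:]:
                cols[f"{cov}[{lev}]"] = (s.astype(str) == lev).to_numpy(float)
        else:
            cols[cov] = s.to_numpy(float)
    X = pd.DataFrame(cols, index=metadata.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        aliased = _find_aliased(X.to_numpy(), list(X.columns))
        raise ValueError(
            f"rank-deficient design (rank {rank} < {X.shape[1]}); "
            f"aliased columns: {aliased}"
        )
    return X


def _find_aliased(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns not reachable by greedy QR-style forward selection."""
    kept: list[int] = []
    aliased = []
    for j in range(X.shape[1]):
        trial = kept + [j]
        if np.linalg.matrix_rank(X[:, trial]) == len(trial):
            kept.append(j)
        else:
            aliased.append(names[j])
    return aliased


def remove_outlier_samples(matrix: pd.DataFrame, z_thresh: float = 3.0) -> list[str]:
    """Drop samples with anomalously low mean inter-sample correlation.

    Each sample's mean Pearson correlation to all other samples is
    standardised across samples; samples on the low-connectivity side
    (Z < -z_thresh) are removed, and the screen is repeated once on the
    survivors.  Returns the kept sample ids (column order preserved).
    Constant (zero-variance) samples are removed with a warning.
    """
    if matrix.shape[1] < 4:
        raise ValueError("need at least 4 samples for outlier screening")
    kept = list(matrix.columns)
    for _ in range(2):  # one removal pass + one re-check
        sub = matrix[kept].to_numpy(float)
        sd = sub.std(axis=0)
        const = sd == 0
        if const.any():
            bad = [kept[i] for i in np.flatnonzero(const)]
            warnings.warn(f"constant samples removed: {bad}", stacklevel=2)
            kept = [s for s in kept if s not in set(bad)]
            sub = matrix[kept].to_numpy(float)
        C = np.corrcoef(sub, rowvar=False)
        n = C.shape[0]
        mean_cor = (C.sum(axis=1) - 1.0) / (n - 1)
        sdm = mean_cor.std(ddof=0)
        if sdm == 0:
            break
        z = (mean_cor - mean_cor.mean()) / sdm
        drop = z < -z_thresh
        if not drop.any():
            break
        kept = [s for s, d in zip(kept, drop) if not d]
    return kept


def regress_out_covariates(
    matrix: pd.DataFrame, metadata: pd.DataFrame, design: DesignSpec
) -> pd.DataFrame:
    """Remove fixed covariate effects while preserving the kept effects.

    For each feature the full fixed-effect linear model is fitted by least
    squares; the returned value is residual + intercept + fitted
    contribution of the ``keep_effects`` columns, so diagnosis-associated
    variance survives adjustment.
    """
    meta = metadata.loc[matrix.columns]
    X = build_design_matrix(meta, design)
    keep_cols = ["Intercept"] + [
        c for c in X.columns
        if any(c == k or c.startswith(f"{k}[") for k in design.keep_effects)
    ]
    Xv = X.to_numpy()
    Y = matrix.to_numpy(float).T          # samples x features
    B, *_ = np.linalg.lstsq(Xv, Y, rcond=None)
    resid = Y - Xv @ B
    keep_idx = [X.columns.get_loc(c) for c in keep_cols]
    kept_part = Xv[:, keep_idx] @ B[keep_idx]
    return pd.DataFrame((resid + kept_part).T, index=matrix.index,
                        columns=matrix.columns)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    NaN p-values propagate as NaN and do not count toward the number of
    tests.
    """
    p = np.asarray(pvalues, float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    qv = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(qv, 1.0)
    q[ok] = out
    return q


def differential_lmm(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    design: DesignSpec,
    contrast: tuple[str, str] | None = None,
    diagnosis_col: str = "diagnosis",
) -> pd.DataFrame:
    """Per-feature random-intercept LMM for the diagnosis effect.

    contrast: (case_level, control_level) restricting the samples before
        fitting (e.g. ``("convergent", "control")`` for a subtype-specific
        analysis); None uses all samples.

    Returns a DiffTable DataFrame indexed by feature with columns
    estimate, se, p, q, direction (+1/-1) and lmm_ok (False where the
    variance-ratio estimate pinned to zero and the fit is plain OLS).
    """
    meta = metadata.loc[matrix.columns].copy()
    if contrast is not None:
        case, ctrl = contrast
        keep = meta[diagnosis_col].isin([case, ctrl])
        meta = meta.loc[keep]
        matrix = matrix.loc[:, keep.to_numpy()]
        counts = meta[diagnosis_col].value_counts()
        if counts.get(case, 0) < 2 or counts.get(ctrl, 0) < 2:
            raise ValueError(f"need >=2 samples per group, got {dict(counts)}")
    else:
        levels = sorted(pd.unique(meta[diagnosis_col].astype(str)))
        if len(levels) != 2:
            raise ValueError(
                f"diagnosis must be binary without an explicit contrast, got {levels}")
        ctrl, case = levels[0], levels[1]
    # explicit 0/1 indicator: coefficient = case minus control
    diag_col = f"{diagnosis_col}[{case}]"
    meta[diag_col] = (meta[diagnosis_col].astype(str) == str(case)).astype(float)
    covs = [diag_col if c == diagnosis_col else c for c in design.covariates]
    cat = None
    if design.categorical is not None:
        cat = [c for c in design.categorical if c != diagnosis_col]
    spec = DesignSpec(covariates=covs, keep_effects=[diag_col],
                      group=design.group, categorical=cat)
    X = build_design_matrix(meta, spec)
    model = RandomInterceptModel(X.to_numpy(), meta[design.group].to_numpy())
    res = model.fit(matrix.to_numpy(float))
    j = X.columns.get_loc(diag_col)
    est = res.coef[:, j]
    table = pd.DataFrame(
        {
            "estimate": est,
            "se": res.se[:, j],
            "p": res.pvalues[:, j],
            "q": bh_fdr(res.pvalues[:, j]),
            "direction": np.where(est >= 0, 1, -1),
            "lmm_ok": ~res.ols_fallback,
        },
        index=matrix.index,
    )
    return table


CHIPSEQ_QC_THRESHOLDS = {
    "total_reads": ("lt", 10_000_000),
    "align_frac": ("lt", 0.75),
    "dup_frac": ("gt", 0.30),
    "nsc": ("lt", 1.03),
    "rsc": ("lt", 0.5),
    "frip": ("lt", 0.11),
}


def chipseq_qc_filter(metrics: pd.DataFrame) -> list[str]:
    """Keep ChIP-seq samples passing all six cross-correlation QC cuts.

    A sample fails if total_reads < 1e7, align_frac < 0.75,
    dup_frac > 0.30, NSC < 1.03, RSC < 0.5 or FRiP < 0.11 (all strict).
    Samples with a missing metric are removed with a warning.  Returns the
    kept sample ids in input order.
    """
    missing_cols = set(CHIPSEQ_QC_THRESHOLDS) - set(metrics.columns)
    if missing_cols:
        raise ValueError(f"metrics table lacks columns: {sorted(missing_cols)}")
    kept: list[str] = []
    flagged = []
    for sid, row in metrics.iterrows():
        vals = row[list(CHIPSEQ_QC_THRESHOLDS)]
        if vals.isna().any():
            flagged.append(sid)
            continue
        fail = False
        for col, (op, thr) in CHIPSEQ_QC_THRESHOLDS.items():
            v = float(row[col])
            if (op == "lt" and v < thr) or (op == "gt" and v > thr):
                fail = True
                break
        if not fail:
            kept.append(sid)
    if flagged:
        warnings.warn(f"samples with missing QC metrics removed: {flagged}",
                      stacklevel=2)
    return kept


def detect_cluster_markers(
    expr: pd.DataFrame,
    cluster_labels: pd.Series,
    restrict_set=None,
    q_thresh: float = 0.05,
    log2fc_thresh: float = 0.75,
) -> pd.DataFrame:
    """One-vs-rest marker genes per cluster.

    For each cluster, each gene is modelled as expression ~ cluster
    indicator by least squares within the (optionally restricted) sample
    set; markers need FDR-corrected p < ``q_thresh`` and a positive
    log2 fold change exceeding ``log2fc_thresh`` (expression assumed on a
    log2 scale, so the indicator coefficient is the log2FC).
    Size-1 clusters are skipped with a warning.
    """
    labels = cluster_labels.loc[expr.columns]
    if restrict_set is not None:
        keep = labels.isin(restrict_set)
        expr = expr.loc[:, keep.to_numpy()]
        labels = labels[keep]
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least 2 clusters")
    Y = expr.to_numpy(float).T
    n = Y.shape[0]
    frames = []
    for cl in uniq:
        ind = (labels == cl).to_numpy(float)
        if ind.sum() < 2:
            warnings.warn(f"cluster {cl!r} has <2 samples; skipped", stacklevel=2)
            continue
        X = np.column_stack([np.ones(n), ind])
        B, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ B
        dof = n - 2
        s2 = (resid**2).sum(axis=0) / dof
        xtx_inv = np.linalg.inv(X.T @ X)
        se = np.sqrt(s2 * xtx_inv[1, 1])
        from scipy import stats as _st
        with np.errstate(divide="ignore", invalid="ignore"):
            t = B[1] / se
        p = 2 * _st.t.sf(np.abs(t), dof)
        q = bh_fdr(p)
        frames.append(pd.DataFrame({
            "cluster": cl, "gene": expr.index, "log2fc": B[1],
            "p": p, "q": q,
            "marker": (q < q_thresh) & (B[1] > log2fc_thresh),
        }))
    out = pd.concat(frames, ignore_index=True)
    return out
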