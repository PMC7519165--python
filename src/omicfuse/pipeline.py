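"""End-to-end subtype discovery: differential screen -> SNF -> cascade.

Mirrors the analysis order of the study design this package emulates:

1. per-layer all-case-vs-control differential screen (random-intercept
   LMM) and restriction of each layer to its differential features at the
   layer's FDR threshold;
2. covariate adjustment preserving the diagnosis signal;
3. similarity network fusion over the samples observed in all four layers
   and spectral bipartition into SNF Groups 1/2 (Group 2 = convergent
   candidate, oriented by differential-signature loading);
4. per-layer PC1 Z-scores and the logistic classifier cascade assigning
   every partially observed sample to a group;
5. subtype-specific differential reanalysis (convergent vs control,
   disparate vs control).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cascade import (CascadeModel, classify_samples, pc1_zscores,
                      train_cascade)
from .differential import DesignSpec, differential_lmm, regress_out_covariates
from .snf import (SNFParams, fuse_layers, select_differential_features,
                  spectral_cluster)
from .synthetic import LAYERS, CohortBundle

__all__ = ["DEFAULT_DESIGNS", "FDR_THRESHOLDS", "SubtypeResult",
           "run_subtype_discovery", "subtype_differential"]

DEFAULT_DESIGNS: dict[str, DesignSpec] = {
    "mrna": DesignSpec(["diagnosis", "age", "sex", "region", "rin", "bank",
                        "batch", "seq_pc1"]),
    "mirna": DesignSpec(["diagnosis", "age", "sex", "region", "rin", "bank",
                         "pmi"]),
    "meth": DesignSpec(["diagnosis", "age", "sex", "region", "bank", "batch",
                        "cet"]),
    "acetyl": DesignSpec(["diagnosis", "age", "sex", "region", "bank", "cet"]),
}

# per-layer FDR thresholds for the feature restriction feeding the fusion
FDR_THRESHOLDS = {"mrna": 0.10, "mirna": 0.10, "meth": 0.10, "acetyl": 0.20}


@dataclass
class SubtypeResult:
    fused: np.ndarray
    snf_samples: list[str]
    snf_groups: pd.Series           # SNF-set samples -> 1|2
    subtype: pd.Series              # all classified samples -> call
    groups_all: pd.Series           # all classified samples -> 1|2
    scores: pd.DataFrame            # sample x layer PC1 Z-scores (NaN = missing)
    models: dict[tuple, CascadeModel]
    initial_diff: dict[str, pd.DataFrame]
    selected: dict[str, list]
    adjusted: dict[str, pd.DataFrame]
    extras: dict = field(default_factory=dict)


def run_subtype_discovery(
    bundle: CohortBundle,
    params: SNFParams | None = None,
    designs: dict[str, DesignSpec] | None = None,
    thresholds: dict[str, float] | None = None,
    seed: int = 0,
) -> SubtypeResult:
    params = params or SNFParams()
    designs = designs or DEFAULT_DESIGNS
    thresholds = thresholds or FDR_THRESHOLDS
    meta = bundle.metadata

    initial_diff: dict[str, pd.DataFrame] = {}
    selected: dict[str, list] = {}
    adjusted: dict[str, pd.DataFrame] = {}
    for layer in LAYERS:
        mat = bundle.layers[layer]
        initial_diff[layer] = differential_lmm(mat, meta, designs[layer],
                                               contrast=("ASD", "control"))
        selected[layer] = select_differential_features(initial_diff[layer],
                                                       thresholds[layer])
        adjusted[layer] = regress_out_covariates(mat, meta, designs[layer])

    snf_samples = bundle.complete_samples()
    sel_adj = {l: adjusted[l].loc[selected[l], snf_samples] for l in LAYERS}

    # orientation score: per-layer PC1 loading oriented so the mean over
    # ASD samples is positive (the convergent cluster loads high)
    asd_snf = [s for s in snf_samples if meta.loc[s, "diagnosis"] == "ASD"]
    orient = np.zeros(len(snf_samples))
    for layer in LAYERS:
        z = pc1_zscores(sel_adj[layer], reference_group2=asd_snf)
        orient += z.to_numpy()
    orient /= len(LAYERS)

    W, _ = fuse_layers(sel_adj, params)
    labels = spectral_cluster(W, params.k_clusters, seed=seed,
                              orient_scores=orient)
    snf_groups = pd.Series(labels, index=snf_samples, name="snf_group")

    # layer scores over every observed sample (union-cohort moments),
    # oriented by the SNF Group 2 reference
    group2 = snf_groups.index[snf_groups == 2].tolist()
    scores = pd.DataFrame(np.nan, index=meta.index, columns=list(LAYERS))
    for layer in LAYERS:
        obs = bundle.observed[layer]
        z = pc1_zscores(adjusted[layer].loc[selected[layer], obs],
                        reference_group2=group2)
        scores.loc[obs, layer] = z

    models = train_cascade(scores.loc[snf_samples], snf_groups)
    test_samples = [s for s in meta.index if s not in set(snf_samples)]
    groups_all = snf_groups.copy()
    if test_samples:
        calls = classify_samples(scores.loc[test_samples], models,
                                 diagnosis=meta["diagnosis"])
        groups_all = pd.concat([groups_all,
                                calls["snf_group"].rename("snf_group")])
    groups_all = groups_all.loc[[s for s in meta.index if s in groups_all.index]]
    diag = meta.loc[groups_all.index, "diagnosis"]
    subtype = pd.Series(
        np.where(diag == "control", "control",
                 np.where(groups_all == 2, "convergent", "disparate")),
        index=groups_all.index, name="subtype")
    return SubtypeResult(fused=W, snf_samples=snf_samples,
                         snf_groups=snf_groups, subtype=subtype,
                         groups_all=groups_all, scores=scores, models=models,
                         initial_diff=initial_diff, selected=selected,
                         adjusted=adjusted)


def subtype_differential(
    bundle: CohortBundle,
    result: SubtypeResult,
    subtype: str,
    designs: dict[str, DesignSpec] | None = None,
    layers: tuple[str, ...] = LAYERS,
) -> dict[str, pd.DataFrame]:
    """Differential reanalysis of one subtype against controls, per layer."""
    designs = designs or DEFAULT_DESIGNS
    meta = bundle.metadata.copy()
    meta["subtype"] = result.subtype.reindex(meta.index)
    out = {}
    for layer in layers:
        mat = bundle.layers[layer]
        keep = [s for s in mat.columns if pd.notna(meta.loc[s, "subtype"])]
        spec = designs[layer]
        spec2 = DesignSpec(
            covariates=["subtype" if c == "diagnosis" else c
                        for c in spec.covariates],
            keep_effects=["subtype"], group=spec.group,
            categorical=spec.categorical)
        out[layer] = differential_lmm(mat[keep], meta, spec2,
                                      contrast=(subtype, "control"),
                                      diagnosis_col="subtype")
    return out
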