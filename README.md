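# omicfuse

Multi-omic molecular subtyping of brain cohorts: similarity network
fusion (SNF) over differential features of four omics layers, spectral
bipartition into a *convergent* and a *disparate* case subtype, a
logistic classifier cascade for samples missing from some layers,
per-feature random-intercept differential models, regulatory peak-to-gene
linkage, and consensus signed-bicor network modules.

## The problem

Post-mortem molecular studies of autism spectrum disorder measure mRNA
expression, miRNA expression, DNA methylation and histone acetylation
(H3K27ac) on overlapping but not identical sets of cortical samples.
Roughly two thirds of case samples share a coherent differential
signature across all of these layers; the rest look molecularly like
controls. Pooling both groups dilutes every downstream analysis, so the
first task is to *subtype*: find the convergent cases, assign the
partially observed samples, and only then ask which genes, promoters and
regulatory elements are dysregulated — and how the epigenomic changes
relate to the transcriptomic ones.

`omicfuse` implements that analysis as a tested Python library. Because
the motivating datasets are controlled-access, a first-class synthetic
cohort generator (`omicfuse.synthetic`) emulates the study design — two
latent case subtypes, paired frontal/temporal samples per subject,
realistic nuisance covariates, per-layer missingness, and a toy genome
with genes, CpG probes, peaks, eSNPs and chromatin contacts — so every
stage of the pipeline is exercisable at desk scale with known truth.

## The method

For each layer `v`, samples are compared on standardized differential
features via the locally scaled kernel

    W_v(i,j) = exp( −ρ²(i,j) / (μ · ε_ij) ),
    ε_ij = ( mean ρ(i, N_i) + mean ρ(j, N_j) + ρ(i,j) ) / 3,

with ρ the Euclidean distance, `N_i` the K nearest neighbours (K = 20,
μ = 0.5). Each affinity graph yields a full transition kernel `P_v`
(diagonal mass ½) and a sparse K-NN kernel `S_v`; T = 15 rounds of
cross-diffusion

    P_v ← S_v · mean_{k≠v}(P_k) · S_vᵀ

(with re-symmetrization and renormalization each round) fuse the layers,
and normalized-cut spectral clustering splits the fused graph into two
groups. Group 2 — the cluster loading high on the differential
signatures — is the convergent-subtype candidate.

Samples absent from ≥1 layer are assigned by one of twelve logistic
models (one per observed layer-availability pattern) on per-layer PC1
Z-scores, each with a leave-one-out-tuned probability cutoff.
Differential analysis fits, per feature,

    value ~ diagnosis + covariates + (1 | brain ID)

by exact REML (one eigendecomposition of the grouping structure plus a
1-D profile optimization per feature), with Benjamini–Hochberg FDR.
Peak-to-gene linkage assigns promoter-overlapping H3K27ac peaks to their
gene and distal peaks through eSNPs-in-peak or Hi-C contacts at FDR < 1%
within 1 Mb. Network modules come from a consensus topological-overlap
matrix (edge-wise median over sample bootstraps of signed
biweight-midcorrelation adjacencies, soft power 9/8).

## Worked example

```python
from sklearn.metrics import adjusted_rand_score
from omicfuse import CohortConfig, generate_cohort, run_subtype_discovery

bundle = generate_cohort(CohortConfig(seed=1))   # 30 ASD / 17 control subjects
result = run_subtype_discovery(bundle, seed=1)

truth = (bundle.truth.sample_subtype.loc[result.snf_samples] == "convergent")
print(len(result.snf_samples),
      int((result.snf_groups == 2).sum()),
      adjusted_rand_score(truth.astype(int), result.snf_groups))
```

prints

```
49 19 1.0
```

49 samples were observed in all four layers; fusion + spectral clustering
put 19 of them in SNF Group 2, and the adjusted Rand index of 1.0 says
the partition matches the planted convergent/disparate+control truth
exactly. The `examples/` directory has one narrative script per
capability (cohort generation, subtyping, the classifier cascade,
subtype-specific differential analysis, peak-to-gene linkage, network
modules); each prints the numbers it computes and a line on what they
mean.

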