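"""Discover molecular subtypes by similarity network fusion.

Runs the full discovery pipeline on a synthetic cohort: per-layer
differential screen, restriction to differential features, covariate
adjustment, fusion of the four sample-similarity graphs, and spectral
bipartition into SNF Group 1 (disparate candidates + controls) and
Group 2 (convergent candidates).
"""

from sklearn.metrics import adjusted_rand_score

from omicfuse import CohortConfig, generate_cohort, run_subtype_discovery

bundle = generate_cohort(CohortConfig(seed=1))
result = run_subtype_discovery(bundle, seed=1)

print("differential features selected per layer (input to fusion):")
for layer, feats in result.selected.items():
    print(f"  {layer:7s} {len(feats)}")

truth = (bundle.truth.sample_subtype.loc[result.snf_samples]
         == "convergent").astype(int)
ari = adjusted_rand_score(truth, result.snf_groups)
print(f"\nSNF set: {len(result.snf_samples)} samples -> "
      f"{int((result.snf_groups == 2).sum())} in Group 2 (convergent candidates)")
print(f"adjusted Rand index vs planted truth: {ari:.3f}")
print("\nARI 1.0 means the fused network separates the convergent subtype "
      "perfectly from disparate + control samples.")
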