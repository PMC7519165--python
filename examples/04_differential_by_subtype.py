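"""Subtype-specific differential analysis with subject random effects.

After subtyping, each layer is re-analysed per subtype against controls
with a per-feature random-intercept linear mixed model (brain ID as the
grouping variable) and Benjamini-Hochberg correction. The convergent
contrast should light up; the disparate contrast is expected to be null.
"""

from omicfuse import (CohortConfig, generate_cohort, run_subtype_discovery,
                      subtype_differential)

bundle = generate_cohort(CohortConfig(seed=1))
result = run_subtype_discovery(bundle, seed=1)

for subtype in ("convergent", "disparate"):
    tables = subtype_differential(bundle, result, subtype,
                                  layers=("mrna", "acetyl"))
    print(f"{subtype} vs control:")
    for layer, tab in tables.items():
        n_sig = int((tab["q"] < 0.05).sum())
        truth = bundle.truth.diff_features[layer].index
        recall = float((tab.loc[truth, "q"] < 0.05).mean())
        print(f"  {layer:7s} {n_sig:4d} features at FDR<5% "
              f"(recall of planted signal: {recall:.2f})")
    print()

print("A near-zero disparate count reproduces the expected pattern: only "
      "the convergent subtype carries the shared molecular signature.")
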