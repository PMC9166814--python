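"""Simulate a functional-assay dataset and classify its VUS.

Builds a small synthetic dataset (60 labeled variants incl. two controls,
150 VUS, 30 batches), fits the function-only hierarchical model and prints
the call table plus a few per-variant posteriors.
"""

import numpy as np

import varcallxt as vx

assay, evidence, truth = vx.simulate_dataset(vx.PRESETS["small"])
batch_means = vx.average_within_batch(assay)
print(f"simulated {len(assay)} replicate rows -> {len(batch_means)} "
      f"batch means over {truth.variants.shape[0]} variants")

config = vx.ModelConfig(evidence_set=("function",), n_iter=2000, n_burn=1000,
                        thin=1, n_chains=2, seed=1)
result = vx.fit(batch_means, evidence, config)

vus = result.df[result.df["label"] == "unlabeled"]
print("\ncall table for the 150 VUS (benign < 0.05 <= no-call < 0.99 <= pathogenic):")
print(vus["call"].value_counts().to_string())

merged = vus.merge(truth.variants, on="variant_id")
mae = float(np.abs(merged["prob_pathogenic"] - merged["true_D"]).mean())
print(f"\nmean absolute error of Pr(pathogenic) against the true indicator: "
      f"{mae:.4f}")
print("(small values mean the posterior probabilities track the simulated "
      "truth almost perfectly — the mixture components are well separated)")

print("\nfirst five VUS posteriors:")
print(merged[["variant_id", "prob_pathogenic", "log_odds", "call",
              "true_D"]].head().to_string(index=False))
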