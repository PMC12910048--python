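"""Train an elastic-net HR-status classifier on a synthetic cohort.

Runs the full training recipe — coding-gene and expression filters, TMM
normalization, moderated differential expression, z-scaling with stored
statistics, 5-fold cross-validation over the elastic-net mixing
parameter with the one-standard-error rule — and saves the resulting
model bundle to disk.

A coarse alpha grid (step 0.1) keeps this example quick; the default
grid steps by 0.01.
"""

import numpy as np

from hrclassify import TrainingConfig, train_pipeline, write_model_bundle
from hrclassify.synthetic import default_train_test

counts_train, truth_train, _, _ = default_train_test(seed=1, n_train=160, n_test=40, n_genes=800)

config = TrainingConfig(alpha_grid=tuple(np.round(np.linspace(0, 1, 11), 2)), fold_seed=0)
result = train_pipeline(counts_train, truth_train.labels, truth_train.annotation(), config)

print(f"genes after filters: {result.filter_report['retained']} coding, "
      f"{result.filter_report['low_expression_removed']} low-expression removed")
print(f"signature: {len(result.signature)} differentially expressed genes "
      f"(BH-adjusted p < 0.05)")
print(f"one-SE selection: alpha = {result.alpha:.2f}, lambda = {result.lambda_:.4g}")
print(f"final model: {result.bundle.n_nonzero} genes with non-zero weights")

write_model_bundle(result.bundle, "model_bundle.json")
print("bundle saved to model_bundle.json (signature, stored means/SDs, coefficients)")
# The bundle is self-contained: scoring a new cohort needs only raw
# counts and this JSON file.
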