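"""Compare the trained model against simpler transcriptomic HR classifiers.

Three comparison rules are run on the same held-out z-scores: two-means
clustering of a signature subset (low marker expression called HRD), a
centroid-correlation rule, and thresholding a noisy surrogate score at
the clinical cutoff of 42.  Agreement between partitions is summarized
by the adjusted Rand index.
"""

import numpy as np

from hrclassify import TrainingConfig, predict_samples, train_pipeline
from hrclassify.benchmark import (
    SignatureCentroids,
    adjusted_rand_index,
    centroid_correlation_classify,
    confusion_metrics,
    kmeans_signature_classify,
    score_threshold_classify,
)
from hrclassify.predict import preprocess_for_prediction
from hrclassify.synthetic import default_train_test

counts_tr, truth_tr, counts_te, truth_te = default_train_test(
    seed=1, n_train=160, n_test=40, n_genes=800
)
config = TrainingConfig(alpha_grid=tuple(np.round(np.linspace(0, 1, 11), 2)))
result = train_pipeline(counts_tr, truth_tr.labels, truth_tr.annotation(), config)
truth = truth_te.labels

pred = predict_samples(counts_te, result.bundle)
z, _ = preprocess_for_prediction(counts_te, result.bundle)

# 2-means on a random 40-gene signature subset; markers = down-in-HRD genes
rng = np.random.default_rng(0)
subset = list(rng.choice(result.signature, size=min(40, len(result.signature)), replace=False))
down = set(
    result.de_table.loc[result.de_table["direction"] == "down", "gene_id"]
)
markers = [g for g in subset if g in down][:10] or subset[:5]
km = kmeans_signature_classify(z, subset, markers, seed=0)

# centroid correlation against the class-mean z-profile of the training set
z_tr, _ = preprocess_for_prediction(counts_tr, result.bundle)
hrd_centroid = z_tr.loc[:, truth_tr.labels == 1].mean(axis=1).to_numpy()
cc = centroid_correlation_classify(z, SignatureCentroids(list(z.index), hrd_centroid))

# clinical-style score threshold on a noisy surrogate of the latent score
noisy_score = truth_te.hrd_scores + rng.normal(0, 15, size=len(truth))
st = score_threshold_classify(noisy_score, cutoff=42)

print(f"{'method':<24}{'accuracy':>9}{'ARI vs truth':>14}")
for name, called in [
    ("elastic net", pred.status),
    ("2-means signature", km),
    ("centroid correlation", cc),
    ("score threshold @42", st),
]:
    rep = confusion_metrics(called, truth)
    ari = adjusted_rand_index(called, truth)
    print(f"{name:<24}{rep.accuracy:>9.3f}{ari:>14.3f}")
# The weighted, trained model should dominate the unsupervised and
# single-score rules on the same expression data.
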