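"""Align trials to a DTW template and classify them with the linear SVM.

One subject's 60 trials are split into two halves; a representative
template is selected from the training half by pairing trial i with trial
i + n/2 and maximizing the score s = rho * (1 - d); every trial is then
warp-resampled to the template length and classified one-vs-rest with the
SVM-light default box constraint.
"""

import numpy as np

import gripdec as gd
from gripdec import dtw, svm

cfg = gd.SyntheticConfig(n_subjects_per_group=1, runs=1, noise_sd=0.02, seed=7)
vel = gd.preprocess_dataset(gd.generate_dataset(cfg))
trials = [t for t in vel.trials if t.subject_id == "S01"]
labels = np.array([t.task for t in trials])

# interleave so both halves contain every class
train_idx = [i for i in range(60) if i % 2 == 0]
test_idx = [i for i in range(60) if i % 2 == 1]

template, aligned_train, aligned_test = dtw.align_dataset(
    [trials[i] for i in train_idx], [trials[i] for i in test_idx])
print(f"template: {template.n_samples} samples, picked from "
      f"{template.provenance}")

X_train = dtw.to_feature_matrix(aligned_train)
X_test = dtw.to_feature_matrix(aligned_test)
print(f"feature space: {X_train.shape[1]} dims "
      f"({template.n_samples} samples x 15 channels)")

C = svm.default_C(X_train)
print(f"default box constraint C = {C:.4f} (reciprocal mean squared norm)")

model = svm.train(X_train, labels[train_idx])
pred, _ = svm.predict(model, X_test)
acc = 100.0 * np.mean(pred == labels[test_idx])
print(f"held-out accuracy: {acc:.1f}% on {len(test_idx)} trials")
# The template defines a fixed-length feature space, so ragged trials become
# comparable vectors; near-100% accuracy reflects the distinct per-class
# channel co-activation patterns in the simulator.
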