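"""Layer-wise DeepSVM on Gaussian blob features, versus the flat SVM.

Depth 1 of the ensemble IS the flat one-vs-rest RBF-SVM; deeper layers
feed each layer's decision scores (plus a pass-through copy of its input)
to the next.  Depths are scored on a validation set and the best one is
returned, so the ensemble can only match or beat the flat model there.
"""

import numpy as np

import histotile as ht
from histotile.backbone import FeatureMatrix


K, D = 4, 8
CENTERS = np.random.default_rng(42).standard_normal((K, D)) * 1.4


def blobs(seed, n_per=40):
    rng = np.random.default_rng(seed)
    values = np.vstack([CENTERS[c] + rng.standard_normal((n_per, D))
                        for c in range(K)])
    labels = np.repeat([f"class{c}" for c in range(K)], n_per)
    return FeatureMatrix(values=values, labels=labels)


train, val, test = blobs(0), blobs(1), blobs(2)
model = ht.train_deepsvm(train, val, max_layers=4,
                         config=ht.EnsembleConfig(max_layers=4, patience=2,
                                                  seed=0))
accs = model.val_accuracy_per_depth
print("validation accuracy per depth:", [round(a, 3) for a in accs])
print("chosen depth:", model.depth, "(1 = flat one-vs-rest SVM)")
test_acc = float(np.mean(ht.predict(model, test.values) == test.labels))
print("held-out accuracy at the chosen depth: %.3f" % test_acc)
# The depth the stopping rule returns attains the max of the per-depth
# validation accuracies; with well-separated blobs that is usually depth 1.
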