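"""Wrapper feature selection and fusion-weight tuning on a planted dataset.

40 features, of which 5 carry a 3-SD class shift; the optimizer-selected
mask should contain most of the 5 planted indices, and the tuned fusion
weights (tau, rho, eps) always lie on the probability simplex.
"""

import numpy as np
from sklearn.model_selection import train_test_split

import hybridseek as hs

X, y, informative = hs.generate_feature_dataset(
    hs.SynthFeatureConfig(n_samples=400, n_features=40, n_informative=5,
                          effect_size=3.0, seed=5)
)
print("planted informative indices:", sorted(informative))

config = hs.PipelineConfig(seed=5)
mask = hs.select_features(X, y, config)
hit = sorted(set(mask.indices.tolist()) & informative)
print(f"selected {len(mask.indices)} features; recovered {len(hit)}/5 "
      f"planted indices: {hit}")

Xm = mask.apply(X)
X_fit, X_val, y_fit, y_val = train_test_split(
    Xm, y, test_size=0.25, stratify=y, random_state=0
)
ab = hs.adaboost_train(X_fit, y_fit, rounds=30)
rf = hs.rf_train(X_fit, y_fit, n_trees=50, seed=0)
dt = hs.dt_train(X_fit, y_fit)
tau, rho, eps = hs.tune_fusion_weights((ab, rf, dt), X_val, y_val, config)
print(f"fusion weights tau={tau:.4f} rho={rho:.4f} eps={eps:.4f} "
      f"(sum {tau + rho + eps:.12f})")

model = hs.EnsembleModel(ab, rf, dt, (tau, rho, eps))
fused, labels = hs.fuse_predict(model, X_val)
metrics = hs.evaluate_metrics(labels, y_val)
print(f"validation accuracy {metrics.accuracy:.3f}, "
      f"sensitivity {metrics.sensitivity:.3f}, "
      f"specificity {metrics.specificity:.3f}")
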