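"""Staging metrics: one-vs-rest confusion arithmetic, ROC/AUC, k-fold CV.

Builds a toy prediction set, walks through the per-stage metrics, and
shows the patient-grouped cross-validation splitter.
"""

import numpy as np

from logstage.evaluate import kfold_split, roc_curve, stage_metrics
from logstage.imaging_io import DatasetManifest, ManifestRecord

rng = np.random.default_rng(0)
truth = rng.integers(1, 5, 200)
# a decent but imperfect classifier: correct stage gets the biggest score
probs = rng.dirichlet(np.ones(4) * 0.6, size=200)
boost = np.zeros_like(probs)
boost[np.arange(200), truth - 1] = 0.35
probs = (probs + boost) / (probs + boost).sum(axis=1, keepdims=True)

report = stage_metrics(truth, probs)
print("per-stage one-vs-rest metrics:")
print("stage |  acc  | sens  | spec  |  bac  |  AUC")
for s, m in report.per_stage.items():
    print(f"  T{s}  | {m['accuracy']:.3f} | {m['sensitivity']:.3f} | "
          f"{m['specificity']:.3f} | {m['balanced_accuracy']:.3f} | {m['auc']:.3f}")
print(f"macro balanced accuracy: {report.macro['balanced_accuracy']:.3f}")

scores = probs[:, 2]
pts, auc = roc_curve((truth == 3).astype(int), scores)
print(f"\nT3 ROC: {len(pts)} threshold points, AUC = {auc:.3f} "
      "(trapezoid = tie-averaged Mann-Whitney)")

manifest = DatasetManifest([
    ManifestRecord(f"slice_{p}_{i}.png", None, f"patient{p:02d}")
    for p in range(25) for i in range(3)
])
folds = kfold_split(manifest, k=5, seed=0, group_by_patient=True)
print(f"\n5-fold patient-grouped CV over 25 patients x 3 slices:")
for i, (train, test) in enumerate(folds):
    patients = {p.split("_")[1] for p in test}
    print(f"  fold {i}: {len(test)} test slices from {len(patients)} patients "
          "(never split across train/test)")
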