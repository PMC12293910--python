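"""Train the CNN pattern classifier under 5-fold cross-validation.

A desk-scale run (12 sessions per class, reduced epochs) to keep this
example under ~2 minutes; the acceptance script runs the full 50-per-class
experiment. Minority classes {2, 3, 5} are oversampled with replacement in
each training fold; test folds are never touched.
"""

from vibrouroflow import CohortSpec, CvConfig, generate_cohort
from vibrouroflow.classifier import prepare_features, run_cv

cohort = generate_cohort(
    CohortSpec(class_counts={k: 12 for k in range(6)}, seed=11))
X, y = prepare_features(cohort)
print(f"MFCC input: {X.shape} (sessions x pooled frames x coefficients)")

cfg = CvConfig(shuffle_seed=11, model_seed=11, epochs=25)
report = run_cv((X, y), cfg)

agg = report.aggregate
print(f"\n5-fold aggregate (weighted): precision {agg.precision:.3f}  "
      f"recall {agg.recall:.3f}  F1 {agg.f1:.3f}")
print("per-fold F1:", [round(m.f1, 3) for m in report.per_fold])
print("summed confusion matrix (rows = truth, cols = prediction):")
print(agg.confusion)
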