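"""Project MFCC features of a labeled cohort onto a 2-D UMAP manifold.

Well-separated pattern classes form distinct clusters; the embedding (with
labels) is the standard visual check that the spectrogram features carry
class structure before any classifier is trained.
"""

import numpy as np

from vibrouroflow import CohortSpec, generate_cohort, umap_embed
from vibrouroflow.classifier import prepare_features

cohort = generate_cohort(
    CohortSpec(class_counts={k: 8 for k in range(6)}, seed=19))
X, y = prepare_features(cohort)

emb = umap_embed(X.reshape(X.shape[0], -1), seed=19, labels=y)
print(f"embedded {emb.coords.shape[0]} sessions into 2-D")
for lab in range(6):
    pts = emb.coords[emb.labels == lab]
    print(f"  class {lab}: centroid ({pts[:, 0].mean():+6.2f}, "
          f"{pts[:, 1].mean():+6.2f}), spread {pts.std(axis=0).mean():.2f}")

from sklearn.metrics import silhouette_score
print(f"\nmean silhouette over labels: "
      f"{silhouette_score(emb.coords, emb.labels):.2f} (> 0 means classes "
      f"separate in the embedding)")
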