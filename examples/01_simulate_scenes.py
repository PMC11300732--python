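"""Generate an imbalanced synthetic nuclei dataset and inspect its census.

The generator emulates the structure the augmentation pipeline expects:
non-overlapping elliptical nuclei of similar sizes, per-class sampling
probabilities (the imbalance control), and the 3-channel mask encoding
(red = class intensity, blue = instance id).
"""

import numpy as np

from histocp import class_counts
from histocp.augment import imbalance_ratio
from histocp.synthetic import SceneSpec, generate_dataset

p = np.array([50.0, 10.0, 5.0, 2.0, 1.0])
spec = SceneSpec(
    class_labels=("tumor", "lymphocyte", "fibroblast", "macrophage", "eosinophil"),
    class_probabilities=tuple(p / p.sum()),
)
records, triplets, coco = generate_dataset(spec, n_images=12, seed=11)

counts: dict[str, int] = {}
for record in records:
    for label, n in class_counts(record.instances).items():
        counts[label] = counts.get(label, 0) + n

print(f"{len(records)} images, {sum(counts.values())} nuclei")
for label in spec.class_labels:
    print(f"  {label:22s} {counts.get(label, 0):4d}")
print(f"imbalance ratio (max/min class count): {imbalance_ratio(counts):.1f}")
print(f"COCO document: {len(coco.annotations)} annotations, "
      f"{len(coco.categories)} categories")
# The ratio shows the majority class outnumbering the rarest by an order of
# magnitude or more — the regime the copy-paste rebalancer is built for.
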