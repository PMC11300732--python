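"""Inverse-frequency class weights and what they do to the loss.

w_c = N / (M * alpha_c): a class with few instances gets a weight above 1,
a majority class below 1, and sum_c alpha_c * w_c = N always. Applied to
the published training census under the minority-merged grouping.
"""

import numpy as np

from histocp import nucls
from histocp.formats import group_classes
from histocp.losses import compute_class_weights, focal_loss, weighted_cross_entropy

grouped = group_classes(nucls.CSRD_COUNTS, nucls.CONFIG2_GROUPING)
labels = list(grouped)
cw = compute_class_weights([grouped[l] for l in labels])

print(f"{'class':22s} {'count':>7s} {'weight':>9s}")
for label, count, weight in zip(labels, cw.counts, cw.weights):
    print(f"{label:22s} {int(count):7d} {weight:9.3f}")
print(f"identity sum_c alpha_c*w_c = {np.dot(cw.weights, cw.counts):.1f} "
      f"(N = {int(cw.total)})")

# a mediocre prediction on the rarest grouped class vs the majority class
m = len(labels)
for target in ("tumor", "other_nuclei"):
    onehot = np.eye(m)[labels.index(target)]
    probs = np.full(m, 0.5 / (m - 1))
    probs[labels.index(target)] = 0.5
    print(f"p=0.5 on {target:13s}: weighted CE = "
          f"{weighted_cross_entropy(probs, onehot, cw):7.3f}, "
          f"focal = {focal_loss(probs, onehot):5.3f}")
# The same predictive quality costs ~50x more on the rare class than on the
# majority class — that asymmetry is what pushes a detector to attend to
# minority nuclei.
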