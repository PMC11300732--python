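# Methods

## The augmentation model

The engine treats an annotated image as a set of non-overlapping instance
footprints on a pixel grid. One augmentation pass over an image is:

1. **Occupancy map.** `LT` is the pixelwise union of all instance masks
   (white = occupied). It is the single source of truth for free space and
   is updated after every accepted paste, so within one pass occupancy is
   monotone — a pixel never reverts to free.
2. **Missing classes.** The set difference between the dataset's class
   universe and the classes present in the image. Only missing classes are
   pasted: an image that already contains a class never receives more of
   it, which caps the growth of majority classes at zero and concentrates
   new instances where they change the census.
3. **Candidate sampling.** `n` missing classes uniformly without
   replacement, then `k` instances per class uniformly without replacement
   from the pooled training instances (the *ChIns* array). A drawn class
   with an empty pool is skipped with a warning — copy-paste cannot
   create a class of which no specimen exists.
4. **Placement.** A candidate centre is drawn uniformly on the open
   interval that keeps the full instance inside the image. The occupancy
   test reads nine pixels: the centre and the eight offsets by half the
   instance width/height. All nine must be free.
5. **Paste.** Hard masked copy of the instance's RGB crop (no blending);
   ground truth gains a translated copy of the instance under a fresh id
   (continuing from the image's largest id, so a re-rendered 3-channel
   mask stays valid); `LT` gains the footprint.

The nine-point test is an O(1) proxy for footprint overlap that is accurate
when instances have similar sizes. It can miss a thin occupied sliver
strictly between probe points, so the package also offers
`strict_occupancy`, which tests the entire footprint against `LT` and makes
the zero-overlap guarantee unconditional. The default remains the
nine-point rule; for same-size convex instances it already prevents complete
occlusion of any existing nucleus.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `n_missing_classes` (n) | 3 | missing classes drawn per image |
| `k_samples_per_class` (k) | 5 | candidate instances per drawn class |
| `placement_attempts` | 1 | centre draws per candidate before giving up |
| `strict_occupancy` | off | full-footprint occupancy check |
| `seed` | 0 | root of all per-image random streams |

`n = 3, k = 5` were fixed once as a realistic rebalancing intensity for
dense scenes: with ~15–20 nuclei per 128² image, up to 15 candidates per
image keeps the accepted pastes well below the free-space budget while
still moving minority counts substantially. One placement attempt per
candidate matches the acceptance rule "if the drawn location is occupied,
the instance is not pasted"; raising `placement_attempts` increases the
fill rate without changing that rule. Each image gets a random stream keyed
by `(seed, crc32(image_id))`, so results are independent of processing
order and safe under parallelism.

### Imbalance ratio

Dataset imbalance is summarized as the max/min per-class instance count,
computed over classes with at least one instance. Classes with zero
instances are excluded: they are outside the reach of copy-paste (there is
nothing to copy), and including them would pin the ratio at infinity
regardless of what the augmentation achieves. With fewer than two populated
classes the ratio is undefined (NaN).

## Color normalization

Reinhard color transfer in the log-LMS opponent space: RGB (kept on its
native 0–255 scale) is mapped through the Ruderman LMS matrix, `log10(LMS +
1)` (the +1 makes black pixels well defined), and the orthogonal lαβ
rotation. Each channel is then shifted/scaled to the target mean/std and
mapped back, clipped to 0–255. The default target is the dataset-pooled
statistics (mean of per-image means and stds) — deterministic and free of
an arbitrary reference-image choice; an explicit reference image or
precomputed statistics can be supplied instead. CIELAB is available as an
alternative space. A source channel with zero spread cannot be rescaled;
it is pinned to the target mean with a logged warning. Instance crops used
for pasting are taken from the normalized images, so pasted pixels match
the destination slide's tone.

## Loss weighting

`w_c = N/(M·α_c)` is read elementwise over the class-count vector α; the
identities `Σ_c α_c w_c = N` and *balanced counts ⇒ unit weights* hold
exactly and are tested. A zero-count class has an undefined weight; the
default assigns 0 (the class cannot appear in ground truth, so it is
excluded from the loss) with a warning, configurable to an error. The
weighted cross-entropy and focal losses are pure numeric references —
probabilities clamped at 1e-12 — intended for exporting weight tables and
for testing, not as training machinery.

## Metrics

Matching is greedy in descending score (ties broken by input order), each
ground truth claimed at most once, IoU threshold 0.5; duplicates on a
claimed ground truth are false positives. AP uses all-point interpolation
(the monotone precision envelope integrated over recall). For the confusion
matrix, localization matching is deliberately class-agnostic so that class
swaps appear as off-diagonal cells; the background row collects spurious
detections and the background column undetected nuclei. Balanced accuracy
is one-vs-rest (sensitivity + specificity)/2 per class, averaged unweighted;
excluding the background row/column restricts the question from "detected
and classified" to "classified once detected". IoU is computed on boxes by
default and on masks when both sides carry them.

## Synthetic data

Scenes are rejection-sampled rotated ellipses (semi-axes uniform on 4–8 px,
a ≤ 2:1 spread — the similar-size regime the nine-point probe assumes) on
an eosin-pink background with Gaussian noise; nuclei colors are
hematoxylin-like per-class tints with per-pixel noise. Placement rejects
any overlap, so generated ground truth is exactly non-overlapping and the
parser roundtrip is exact. What the generator does *not* emulate: tissue
texture, nucleus chromatin structure, touching/overlapping real nuclei,
stain gradients within a slide, annotation noise. Passing tests therefore
demonstrate the correctness of the algorithms on inputs satisfying their
stated assumptions, not detector-level performance on real tissue.

The detector simulator drops ground truth with a set miss rate, swaps
classes with a set confusion rate and jitters boxes, returning the exact
tally of what it did; metric implementations are tested against those known
rates (e.g. sensitivity within three binomial standard errors of 1 − miss
rate).

## Numerical choices

* Polygon segmentation is traced along pixel edges (vertices at integer
  corner coordinates, holes filled first), and rasterized by testing pixel
  centres against the polygon — the mask → polygon → mask roundtrip is
  exact, comfortably inside the ≤ 2 % disagreement budget the converters
  promise.
* Half-size rounding: probe offsets use `floor(w/2)`; the exclusion margins
  of the centre draw use `ceil(w/2)`, so all nine probes and the full paste
  stay in bounds for odd sizes.
* The centre draw is on the *open* interval (strict inequalities), matching
  the placement conditions exactly.
* Problem sizes in the test and acceptance runs (128²–256² scenes, 10–70
  nuclei, 10–20 images, ~10³ ground truths for rate-recovery checks) were
  chosen so every statistical check has at least three-standard-error
  resolution while the whole suite stays interactive.

## Known limitations

* The nine-point rule can overlap a pasted instance with a thin existing
  structure between probe points; use `strict_occupancy` when a hard
  guarantee matters (the paste-acceptance rate drops slightly).
* Pasting cannot help a class absent from the entire training pool, and
  extremely rare classes rebalance slowly because the same few specimens
  are recycled.
* COCO polygons cannot encode holes; instances are assumed simply
  connected (true for nuclei masks), and any hole is filled on conversion.
* No scale/rotation jitter of pasted instances, no blending, no
  photorealistic H&E simulation — all deliberate non-goals.
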