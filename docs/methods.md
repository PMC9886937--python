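# Methods

## Problem setting and coordinate conventions

The pipeline detects metastatic pelvic lymph nodes on axial slices of a
contrast-enhanced CT volume, searching only inside the pelvic nodal
clinical target volume (CTV). All arrays are indexed `(z, y, x)`
(slice, row, column); in-plane boxes are `(x0, y0, x1, y1)`, 0-based
and half-open, so box area is `(x1−x0)·(y1−y0)` in pixels. Default
voxel spacing is 3.0 mm between slices and 0.648 mm in-plane, at which
the 10-pixel CTV expansion equals 6.48 mm.

DICOM series are converted to Hounsfield units with the standard
rescale transform `HU = slope·stored + intercept`; series with
non-uniform slice gaps (a missing slice) or mixed orientations are
rejected rather than resampled. NIfTI inputs are taken to be in HU
already. Masks must be pre-rasterized to NIfTI on the CT grid;
RTSTRUCT conversion is out of scope.

## 2.5D inputs and the two preprocessing paths

A detector sample is a 3-channel stack of slices `(z−1, z, z+1)`. At
volume ends the missing neighbour is a copy of the edge slice — this
keeps every ground-truth slice usable and is the only boundary policy
that never fabricates intensity values.

Two paths prepare samples:

* **whole-slice**: crop the all-air border (threshold ≤ −1000 HU,
  maximal margin shared by all three channels), then the soft-tissue
  window;
* **regional**: zero everything outside the CTV expanded in-plane by
  `k_px` (default 10) pixels, crop to the expanded mask's bounding box,
  then a quantile window. The crop origin is carried on the sample so
  detections map back to volume coordinates exactly.

CTV expansion is 2D per slice with a Euclidean disc
`{(dy,dx): dy²+dx² ≤ k²}`: the quoted physical expansion length is an
in-plane distance, and through-plane spacing (3 mm/slice) makes a 3D
ball at pixel radius meaningless. Dilation by the disc is equivalent to
thresholding the Euclidean distance transform at `k`, which is how the
tests verify it.

Training-time augmentation (resize of the longest side to 640–800 px,
horizontal flip at p = 0.5, rotation 0–180°, correlated Gaussian noise
smoothed with a 5-wide σ = 1 kernel, multiplicative brightness) applies
geometric transforms identically to image and boxes and is fully
seeded. Magnitudes the protocol leaves open were fixed once:
brightness factor uniform in [0.9, 1.1] and noise amplitude 0.02 on the
normalized image — mild perturbations on a [0, 1] scale, both
configurable. Rotation resamples bilinearly with a constant fill (0
after windowing, −1024 HU before); a rotated box is the axis-aligned
hull of its rotated corners. Inference never augments.

## Quantile windows

A window `(low, high)` clips HU and maps linearly to [0, 1]; a
degenerate window maps everything to 0.5. Windows are derived from the
pooled HU values of all ground-truth node pixels by taking the
nearest-rank quantiles (the `⌈q·n⌉`-th order statistic) at a symmetric
pair such as (1%, 99%). Nearest-rank is used because it returns actual
sample values — integer-HU pools give integer window edges, matching
the integer-valued preset windows — and because it has an exact sort-based
oracle. The pool is assumed to aggregate node pixels across all
training volumes equally. Normalization is per-image min-max over the
window range; no other formula is implied by "uniform normalization",
and this reading makes windowed outputs comparable across slices.

## Detector contract and the oracle

Anything with `detect(samples) -> [DetectionBox]` (boxes in volume
coordinates, scores in [0, 1]) plugs into the pipeline via a registry.
The scripted oracle detector emits each ground-truth slice box with
probability `hit_prob` (edges jittered by ≤ `jitter_px` integer pixels,
score ~ U(0.6, 1)) and planted false positives with score ~ U(0.05, 0.7);
the overlapping score ranges make score-rank logic (greedy matching,
AUC) non-trivial. Per-slice random substreams keep output independent
of sample order. Score calibration is deliberately not modelled.

The trainable backbone (two-stage detection head, mask branch disabled)
is an optional extra whose configuration defaults encode the two-stage
SGD protocol: whole-slice pretraining 3000 iterations at LR 0.01 (×0.1 at
2000), regional fine-tuning 6000 iterations at LR 0.005 (×0.1 at 4000
and 5000), batch 64, momentum 0.9, weight decay 1e−4. Without the
extra, training raises an explicit unavailability error and the rest of
the package is unaffected. The default inference score floor before
post-processing is 0.05.

## Rule-based false-positive filters

* **Expansion-zone filter (τ₄).** A box is kept iff it overlaps, by at
  least one pixel, the un-expanded CTV dilated by τ₄ pixels on its
  slice. Overlap (rather than box-center containment) is the
  permissive reading of "box in the expansion zone" and is what makes
  the filter monotone in τ₄; the choice of measuring from the CTV
  outward is an interpretation and is flagged as such.
* **HU-quantile filter (τ₅, τ₆).** For each box, the nearest-rank τ₆
  quantile of the HUs of all pixels inside the box (on its slice) is
  compared to τ₅; the box is removed on strict excess (`q > τ₅`),
  equality keeps it. Contrast-enhanced vessels and bowel sit well
  above nodal soft tissue, so a high in-box quantile is a vessel
  signature. The estimator matches the windowing module's for
  consistency.

Both filters are contractions and idempotent; they compose spatial
filter first (the cheaper test), and on detections whose FP causes are
disjoint the order provably does not matter — the tests check both
orders.

## Window bagging

Voters are detectors trained on differently windowed copies of the same
slices; no data bootstrap is performed (the constructor feeds every
voter the same slice set, so this holds by construction). Per slice,
boxes from all voters are clustered by greedy single-linkage: the
highest-score unassigned box seeds a cluster (score ties broken by
(z, x0, y0), making the result order-independent) and absorbs all
unassigned boxes with IoU ≥ τ₁ to the seed. Clusters with ≥ τ₂
distinct voters survive; duplicate boxes from one voter count once.
The merged box is the score-weighted mean of member coordinates with
mean member score; a union-box merge is available behind a switch. The
greedy rule itself is a design choice — only the IoU threshold and the
vote count are externally fixed — and it is verified against a naive
re-derivation on random instances.

## Evaluation

Matching is greedy one-to-one: predictions in descending score order
claim the unmatched same-slice ground-truth box of maximal IoU when
that IoU ≥ τ₃. Sensitivity is node-level (a 3D connected component of
the node mask — 26-connectivity, so diagonally touching lesion voxels
are one node — counts as found if any of its slices is matched);
precision is slice-level; F-1 is the harmonic mean of the two
percentages despite the level mismatch, because that is the quantity
the thresholds are tuned on. With zero predictions precision is
defined as 0 and flagged, keeping grid search total.

Image-based AUC treats each axial slice of the evaluated region (the
CTV slices — slices the detector never saw are excluded) as one
observation: label = slice contains node voxels, score = maximum box
score on the slice, 0 when none. AUC is the normalized Mann–Whitney
statistic with ties at ½, cross-checked against an all-pairs count.

Grid search enumerates the full cross-product of the default tuning
ranges (τ₁, τ₃, τ₆ ∈ {0.1,…,1.0}; τ₂ ∈ {1,…,5}; τ₄ ∈ {1,…,10};
τ₅ ∈ {80, 100, 120, 140, 160}), caching the post-processing stage per
(τ₄, τ₅, τ₆); ties resolve to the lexicographically smallest threshold
vector.

## The phantom: what it emulates and what it does not

The generator produces, from a single seed: Gaussian soft-tissue
background (20 ± 15 HU); non-overlapping ellipsoidal nodes (in-plane
semi-axes 3–6 px, 1–2 slices through-plane) with voxel HU ~ N(45, 35),
placed with a 2-pixel guard band so distinct lesions stay distinct
under 26-connectivity; drifting tubular vessels at 250 ± 40 HU — above
the strictest τ₅ cutoff by construction, and kept ≥ 2 px clear of
nodes so the two FP causes never mix; a CTV built as the dilated
convex envelope of the node footprint (nodes are inside it by
construction); and a −1024 HU air frame. Default 20×160×160 voxels at
(3.0, 0.648, 0.648) mm.

Planted false positives give each filter a dedicated target: ring FPs
are 6×6 boxes centered 7–9 px outside the CTV (inside the 10-px search
expansion, provably clear of any τ₄ ≤ 2 dilation), vessel FPs cover a
vessel cross-section inside the CTV with ≥ 30% bright pixels (so the
0.8 nearest-rank quantile lands in vessel HU), and soft-tissue FPs
survive both rules and can only be removed by voting.

What passing on phantoms shows: the geometry, bookkeeping and
thresholds behave exactly as specified — coordinates survive cropping,
filters remove precisely their FP family, voting removes unshared
detections, metrics count what they claim. What it does not show:
performance on real CT. Real nodes are not ellipsoids with i.i.d.
Gaussian texture, real vessels are not always bright or tubular, real
detectors produce correlated, calibrated-ish scores — none of which
the oracle models. The clinical headline numbers therefore cannot be
(and are not) reproduced here; they require the confidential patient
data and GPU-trained weights.

## Orchestration, seeds and problem sizes

A single global seed fans out to stage seeds by a CRC-32 hash of the
stage name, so each stage is independently re-runnable and chaining the
CLI subcommands reproduces the orchestrated `run` byte for byte (volumes
are stored as float64 NIfTI and box JSONs carry full-precision floats
precisely so disk round-trips are lossless). All randomness flows
through `numpy.random.default_rng`.

The validation suite sizes its simulations for tight feedback loops on
one CPU: the reference phantom (12 nodes, 8 vessels, 20 slices)
for end-to-end recovery; a 30-node, 26-slice phantom (> 5000 node
voxels) for distributional checks — empirical node-HU quantiles within
±10 HU of the analytic N(45, 35) values, oracle hit rates inside the
99% binomial interval; and randomized oracle-equivalence sweeps
(1000 IoU pairs, 200 quantile pools, 500 clustering instances, 300 AUC
sets, 100 connected-component masks).

## Known limitations

* RTSTRUCT contours, PET handling and inter-modality registration are
  out of scope by design; masks must arrive rasterized on the CT grid.
* The τ₄ filter's dilated-overlap convention is one defensible reading
  of the expansion-zone rule; a center-based or inward-measured variant
  would need only a local change but is not implemented.
* Precision and F-1 mix node-level and slice-level counts; comparisons
  against detectors evaluated purely at one level are not meaningful.
* The grid search optimizes on the same detections it evaluates; on
  real data the search belongs on a validation split, as the pipeline's
  staging (tune on validation, report on test) assumes.
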