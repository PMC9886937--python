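# pelvidet

**CT-only detection of metastatic pelvic lymph nodes, restricted to the
radiotherapy clinical target volume.**

Metastatic pelvic lymph nodes in recurrent prostate cancer are confirmed
on PSMA PET/CT, but PET is expensive and not always available.
`pelvidet` implements a detection pipeline that works from the
contrast-enhanced CT alone: it searches only inside the pelvic
lymph-node clinical target volume (CTV, the RTOG consensus contour,
expanded in-plane by 10 pixels ≈ 6.5 mm so boundary nodes are covered),
feeds a 2D detector 2.5D inputs (each axial slice stacked with its
superior/inferior neighbours as channels), and wraps the detector with
three ideas that carry the performance:

1. **Quantile HU windowing.** Instead of a fixed soft-tissue window,
   windows are derived from the pooled Hounsfield units of ground-truth
   node pixels by symmetrically trimming the distribution tails at a
   quantile pair (q, 1−q). Windows ship as presets
   (−97, 310), (−90, 169), (−84, 151), (−79, 141) and the standard
   soft-tissue (−125, 225); pixels are clipped and mapped linearly to
   [0, 1]. Quantiles use the nearest-rank estimator
   `x_(⌈q·n⌉)`, so window edges are actual sample values.
2. **Rule-based false-positive filtering.** Two dominant FP families
   have closed-form fixes: boxes in the outer CTV expansion ring are
   dropped unless they overlap the CTV dilated by τ₄ pixels
   (τ₄ ∈ 1..10); bright vessel/bowel boxes are dropped when the τ₆
   nearest-rank quantile of the HUs inside the box exceeds τ₅ HU
   (τ₅ ∈ {80,…,160}, τ₆ ∈ {0.1,…,1.0}).
3. **Window bagging.** One detector per window is an ensemble voter
   (the windows, not data bootstraps, provide diversity). Per slice,
   cross-voter boxes are clustered greedily by IoU ≥ τ₁ to the
   highest-score seed; clusters supported by ≥ τ₂ distinct voters
   survive, merged as the score-weighted mean box.

Evaluation follows clinical reading: **sensitivity is node-level** (any
detected slice of a 3D metastasis counts the whole node as found,
matching by IoU ≥ τ₃), **precision is slice-level** (fraction of
predicted slice boxes matching a ground-truth node slice), F-1 is their
harmonic mean, and **AUC is image-based** (each slice scored by its
maximum box score, 0 when empty; Mann–Whitney with ties at ½). An
exhaustive grid search tunes τ₁…τ₆ over their full default ranges.

Clinical CT with PSMA-confirmed annotations cannot be redistributed, so
the package includes a seeded **phantom generator** that emulates the
relevant geometry and contrast — soft-tissue background, Gaussian-HU
node lesions inside a CTV envelope, bright tubular vessel confounders,
an air border — plus a scripted **oracle detector** that emits
ground-truth boxes with configurable hit probability, jitter and
planted, cause-labelled false positives. Every stage and the end-to-end
run are exercised against these synthetic volumes; a real trained
detector (Mask R-CNN family with the mask branch disabled, whole-slice
pretraining then regional fine-tuning) plugs in behind the same
`detect(samples) -> boxes` contract as an optional deep-learning extra.

## Worked example

```bash
python examples/02_end_to_end_phantom.py
```

```
end-to-end phantom run (seed 1):
  node sensitivity : 100.000 %   (12/12 metastases found on >=1 slice)
  slice precision  :  84.211 %   (16 TP / 19 predicted slice boxes)
  F-1              :  91.429 %
  image AUC        :  87.500 %   (slice-level ranking by max box score)
```

All 12 planted node lesions are recovered on at least one slice; of the
19 bagged slice predictions, 16 match a ground-truth node slice at
IoU ≥ 0.3. The ten false positives planted per voter in the expansion
ring and on vessels were all removed by the rule filters, and the
per-voter soft-tissue decoys were voted out by the ≥ 3-voter rule; the
3 residual FPs are jittered detections that fell below the matching
IoU. The other examples walk through window derivation
(`01_quantile_windows.py`), the two FP filters
(`03_false_positive_filters.py`) and threshold grid search
(`04_grid_search.py`).

The same pipeline is scriptable from the shell, one stage per
subcommand:

```bash
pelvidet phantom --seed 1 --out ph/
pelvidet detect --phantom-dir ph/ --seed 2 --out det/
pelvidet postprocess det/voter_q1_99.json det/voter_q1_99_f.json \
    --tau4 2 --tau5 160 --tau6 0.8 --ctv ph/ctv.nii.gz --volume ph/ct.nii.gz
pelvidet bag det/*_f.json bagged.json --tau1 0.5 --tau2 3
pelvidet evaluate bagged.json --nodes ph/nodes.nii.gz --volume ph/ct.nii.gz \
    --ctv ph/ctv.nii.gz --tau3 0.3 --report report.json
pelvidet run --seed 1 --out full/        # all of the above in one go
```

Inputs are NIfTI volumes/masks or DICOM series; detection lists travel
between stages as JSON.

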