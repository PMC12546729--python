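# slidemil

Attention-based multiple-instance learning (MIL) for whole-slide-image
(WSI) tumour classification — tiling and quality control, Macenko stain
normalization, a NumPy attention-MIL classifier with pluggable instance
encoders, the full training/evaluation protocol, attention heatmaps for
weakly supervised tumour localization, and artifact-bias statistics — plus
a synthetic cohort generator so the whole pipeline is testable without
clinical data.

## The problem

Digitised H&E slides are gigapixel images with one label per slide
("tumour" / "normal") and no annotation of *where* the tumour is. MIL
handles this: a slide is a bag X = {x_1, ..., x_N} of 256x256 tiles with

    Y = 0  iff  sum_i y_i = 0,    Y = 1  otherwise,

i.e. a slide is positive iff at least one tile is. Each tile is encoded to
a feature vector f_i; a single-headed attention module scores each tile
(D -> 32, tanh -> 1), the scores pass through a softmax into weights
w_i (sum w_i = 1), and the bag representation z = sum_i w_i f_i — whose
dimension is independent of N and invariant to tile order — is classified
by a small dense head (D -> 128 -> 2, cross-entropy). The learned
attention weights double as a tumour-localization signal: scanning a slide
with overlapping tiles, min-max normalizing the raw scores to p_att in
[0, 1], averaging overlaps and Gaussian-smoothing gives a heatmap, and
tiles with p_att > 0.6 / p_att < 0.4 form tumour-suspect / normal
galleries.

Around the model sit the pieces a practitioner needs: resolution levels
R in {0..3} (2 * 2^R um/px from a 0.25 um/px native scan), tessellation,
background (> 75% bright pixels) and Canny-informativeness tile filters,
the 80/2^R valid-tile slide gate, Macenko stain normalization against a
reference profile, +/-5% colour-jitter and flip/rotation augmentation,
channel standardization, stratified 90/10 splits, 5-fold cross-validation,
repeated training with 95% CIs, randomized hyperparameter search,
per-resolution sweeps, pooling and normalization ablations, and a
two-proportion-Z-test artifact-bias audit with Bonferroni correction.

Evaluation uses imbalance-robust metrics, in particular the Matthews
correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

macro F1 and AUROC. See `docs/methods.md` for the complete model and
design notes.

## Worked example

Train attention-MIL on synthetic feature bags whose witness structure is
known (200 bags of 32 instances at dimension 32; witness rate 0.3, 3-sigma
witness/background separation), then inspect what attention learned:

```python
from slidemil.benchmarks import feature_bag_study

r = feature_bag_study(seed=1)
print(f"held-out AUROC : {r['auroc']:.3f}")
print(f"held-out MCC   : {r['mcc']:.3f}")
print(f"attention on witnesses  : {r['mean_witness_weight']:.4f}")
print(f"attention on background : {r['mean_background_weight']:.4f}")
```

```
held-out AUROC : 0.998
held-out MCC   : 0.886
attention on witnesses  : 0.0804
attention on background : 0.0101
```

The model separates positive from negative bags almost perfectly, and the
attention weights concentrate on the witness instances (0.080 vs 0.010
mean weight; uniform attention over 32 instances would give 0.031
everywhere) — the mechanism that makes the tumour heatmaps work.

The same workflow runs from the shell on rendered slide images:

```bash
slidemil synth --n-slides 40 --prevalence 0.82 --seed 1 --out cohort/
slidemil qa --manifest cohort/manifest.csv --out qa/
slidemil train --manifest cohort/manifest.csv --level 2 --seed 1 --out run/
slidemil heatmap --slide cohort/slides/synthetic_0000.png \
    --model run/model --reference run/stain_profile.json --out heat/
```

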