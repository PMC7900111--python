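# Methods

## Problem and model

Contrast-enhanced brain metastases are detected and segmented from
multisequence MRI, but the set of acquired sequences varies between
sites: a model trained on four sequences is useless at a site that
acquires three unless it can tolerate the missing input. `ildseg`
implements **sequence-level input dropout**: during training, entire
input sequences are stochastically replaced by zeros and the surviving
channels are rescaled, so a single network learns to segment from the
full set *and from every admissible subset* of its inputs.

The network is 2.5D: the input for one prediction is k = 5 contiguous
axial slices of each of S = 4 sequences, stacked channel-wise into an
S·k = 20-channel image; the output is a per-pixel sigmoid probability
map for the center slice, and whole volumes are segmented slice by
slice. Let `p = d/S` be the fraction of dropped sequences in one
sample. Input dropout zeroes all k channels of each dropped sequence
(never a partial slab — the slab of one sequence is atomic) and
multiplies every surviving channel by `1/(1 − p)`, which preserves the
expected total input activation. The identical zero-fill + reweighting
is applied at inference to declare the sequences a site is missing;
the all-dropped pattern (`p = 1`) is inadmissible everywhere, since it
would feed the network an all-zero tensor.

The training-time distribution over patterns is configurable through
`DropoutPolicy`: by default the number dropped `d` is uniform over
{0, …, S−1} and the dropped subset is uniform given `d`, so every
subset size receives equal training exposure. The no-dropout baseline
is the degenerate policy that always keeps everything.

## Network and training

The segmentation backbone is a compact fully-convolutional 2D network
written directly on numpy (im2col/col2im + GEMM forward and backward,
Adam optimizer): a 3×3 stem, `n_stages` 3×3 convolutions, a dilated-
convolution pyramid head (parallel 3×3 branches at atrous rates 1, 2, 4,
concatenated) for a large receptive field without downsampling, and a
1×1 sigmoid logit head. All spatial shapes are preserved, outputs are
clipped to the open interval (0, 1), and initialization, batch order
and pattern sampling derive from explicit seeds, so two runs with the
same configuration are bit-identical.

The default loss is weighted cross-entropy (foreground weight 4) plus
soft Dice; pure cross-entropy is near-degenerate for lesions occupying
well under 1% of the volume. Learning rate 3e-3 with Adam, batch size 8.
Intensities are z-scored per sequence over brain-mask voxels before
slab extraction; dropout is applied after normalization so a dropped
sequence's zeros coincide with the masked-mean background level, and an
unavailable (all-zero) sequence is left untouched by normalization.

## Synthetic phantoms

No public cohort accompanies the problem, so the package generates its
own study material. Each phantom is a 48×48×16 voxel grid at 1 mm
isotropic spacing (defaults; all configurable) containing:

* an ellipsoidal brain mask and a smooth two-tissue background
  (low-pass-filtered noise thresholded at its median into gray/white
  levels 0.45/0.65) — not an anatomical atlas;
* 1–3 axis-aligned ellipsoidal lesions with semi-axes drawn from
  2.5–6 mm, placed wholly inside the brain mask (bounded retries, then
  an explicit placement error); their union is the ground truth;
* curvilinear vessel-like tubes (persistent random walks stamped with a
  ~1.5 mm ball) that never contribute to the ground truth;
* per-sequence contrast offsets plus Gaussian noise (sd 0.15).

The four sequences emulate the contrast behaviour that matters for the
missing-sequence scenario. Lesion / vessel contrasts: sequence 0
(post-Gd fast spin echo) 1.2 / 0.0 — the strongest enhancement with
suppressed vessels; sequence 1 (post-Gd gradient echo) 0.9 / 1.0 —
strong enhancement but bright vessels; sequence 2 (FLAIR) 0.5 / 0.0;
sequence 3 (pre-Gd) 0.1 / 0.8 — essentially non-enhancing with bright
vessels. The evaluation scenario drops sequence 0, so the model loses
its cleanest source of lesion signal while vessel confounders remain on
two of the surviving sequences: a conventionally trained model has a
learnable reason to fail, and a dropout-trained model a learnable route
to succeed (lean on the vessel-free FLAIR and cross-check the GRE).

What the phantoms deliberately do not model: anatomy, MR physics
(TR/TE), bias fields, motion, irregular lesion shapes, partial-volume
effects. Passing tests therefore demonstrate that the dropout
mechanism, pipeline and evaluation protocol behave as specified — not
clinical-grade performance on real data.

## Evaluation protocol

Per test case, against the binary ground truth and within the brain
mask only (counting true negatives over padded air would deflate the
false-positive rate arbitrarily):

* **ROC/AUC** voxel-wise, trapezoidal rule on the empirical curve; each
  case's curve is also resampled onto a fixed 101-point FPR grid so the
  cohort mean ROC and its normal-approximation 95% band
  (mean ± 1.96·sd/√n per grid point) can be computed vertically.
* **Operating threshold** by the Youden index (max sensitivity +
  specificity − 1) on validation voxels pooled across cases; candidate
  thresholds are the observed probabilities plus {0, 1}; ties break
  toward the larger threshold; a voxel is positive iff probability ≥
  threshold (closed lower bound).
* **Voxel metrics** Dice, IoU, precision, recall, FPR from TP/FP/FN/TN.
  Degenerate conventions: precision = 1 with no predictions and no
  truth, 0 with no predictions against a nonempty truth; recall = 1 for
  an empty truth; Dice = IoU = 1 when both masks are empty, 0 when
  exactly one is; FPR = 0 without negatives. Per case,
  Dice = 2·IoU/(1 + IoU) holds to 1e-12 by construction (the identity
  does not survive cohort averaging, so it is asserted per case only).
* **Lesion-wise false positives** on 26-connected components (voxels
  touching by face, edge or corner are one lesion): a predicted
  component with zero ground-truth overlap is a false positive;
  components below a minimum volume (10 mm³ by default, i.e. ~2 mm
  linear size) are excluded before counting, and the limit 0 gives the
  unfiltered count.
* **Between-model comparison** with the two-sided Wilcoxon rank-sum
  test on per-case values (exact for small tie-free samples), α = 0.05;
  if every value in both groups is identical the comparison is vacuous
  and p = 1 by convention.

## The missing-sequence experiment

`ildseg.experiment.run_missing_sequence_experiment(seed)` is the
package's end-to-end check and the computation behind
`scripts/acceptance.py`. It generates 24 training, 4 validation and 8
test phantoms, trains the dropout model and the no-dropout baseline on
identical data (15 epochs, base width 12 — sizes chosen so one model
trains in about a minute on a single CPU core), selects each model's
Youden threshold on the validation set under the availability pattern
being evaluated, and evaluates every test case twice: with all four
sequences and with sequence 0 declared missing.

The headline quantities are the mean test Dice of each model under
each condition, each model's Dice *drop* (all-available minus missing),
and the **excess baseline degradation** — baseline drop minus dropout-
model drop — which is positive when dropout training buys robustness.
Representative values at seed 1: dropout model 0.96 → 0.93 Dice when
the sequence disappears, baseline 0.98 → 0.66, excess degradation 0.29.

## Numerical and design notes

* Boundary slabs are edge-replicated (zero padding would mimic dropout).
* Slices are predicted independently; no test-time augmentation or
  overlap blending.
* Probability maps are clipped to [1e-7, 1 − 1e-7] so outputs are
  strictly inside the unit interval even when float32 sigmoids saturate.
* Component labeling uses a full 3×3×3 structuring element
  (26-connectivity); volumes are voxel counts × voxel volume in mm³.
* Lesion/vessel indicators are generated before contrast is applied, so
  changing a contrast never changes geometry for a fixed seed, and with
  zero noise lesion intensities are monotone in the contrast.
* Known limitations: 2D slice-wise prediction has no through-plane
  smoothness beyond the slab; the numpy backbone is desk-scale (it is
  not meant to replicate GPU-scale clinical training); phantom realism
  is deliberately minimal (above).
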