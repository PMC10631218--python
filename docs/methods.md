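# Methods

## The hybrid model

`convboost` implements a two-stage classifier for low-volume,
high-dimensional supervised problems. A block-structured convolutional
network is first trained end-to-end on the labeled data. The network is then
frozen and used only as a feature map: the post-activation output of one
internal layer re-expresses every example as a feature vector, and a
gradient-boosted decision-tree ensemble (XGBoost at default hyperparameters)
is fit on that representation to make the final predictions. The premise is
that a convolutional network trained on few examples learns useful local
feature detectors long before its dense head learns a good decision rule, so
handing an intermediate representation to a tree ensemble — which has a much
stronger inductive bias at small *n* — outperforms both the network's own
predictions and trees fit on the raw encoding. A common rule of thumb says
overfitting looms once the feature count reaches √n (`overfit_diagnostic`
reports this); the datasets this method targets violate it badly in their
raw encoding.

### Network architecture

Each convolutional block is: convolution (no padding) → batch-norm → ReLU,
convolution ('same' padding, conserving length) → batch-norm → ReLU,
max-pool, dropout 0.4. Block 1 has `base_filters` (default 64) filters;
every added block doubles the filter count and keeps the kernel size. After
the blocks come a flattening layer and a dense head, then the classifier
activation (softmax for multiclass, sigmoid for binary). Per-modality
variants, bundled as recipes:

| modality   | kernel | pool | dense head | output  | optimizer |
|------------|--------|------|-----------|---------|-----------|
| timeseries | 3      | 2    | 256, 128  | softmax | Adam      |
| sequence   | 3      | 2    | 64, 1     | sigmoid | Adam      |
| text       | 5      | 3    | 64, 1     | sigmoid | RMSprop   |

Text inputs pass through a trainable embedding (default dimension 64; the
embedding dimension is not pinned by the protocol we follow, so it is
configurable). The binary heads use a single sigmoid unit trained with
binary cross-entropy; a one-node softmax layer is degenerate, and for binary
labels the sigmoid unit is the mathematically equivalent form. For
multiclass tasks the loss is categorical cross-entropy — the k-class
generalization of the binary formula — over integer labels.

The network engine is implemented directly on NumPy with exact analytic
gradients (verified against central finite differences in the test suite).
Layer choices that the protocol leaves open and that we fixed: batch-norm
sits between the convolution and the ReLU (conv → BN → ReLU); batch-norm
uses momentum 0.9 and eps 1e-3 for its running statistics — with only a
handful of mini-batches per epoch at desk scale, slower statistics fall out
of sync with the weights and corrupt every inference-mode evaluation,
including the early-stopping signal; convolution
weights use Glorot-uniform initialization; Adam/RMSprop run at their
conventional defaults (lr 1e-3). One integer seed drives weight
initialization, epoch shuffling and dropout masks.

### Training and early stopping

Mini-batch training (default batch 32, max 100 epochs — both configurable;
only the patience is fixed by the protocol) monitors validation loss. If no
new strict minimum is reached for 10 consecutive epochs, training stops and
the weights from the best epoch are restored. A constant validation loss
therefore stops training at epoch 11. Non-finite losses abort with a
diagnostic rather than silently corrupting the run.

### Layer catalog and extraction

Every extraction-eligible layer is listed in a 1-based catalog: per block
`conv1`, `conv2` (both post-ReLU) and `pool`, then `flatten`, each hidden
dense layer (post-ReLU) and the classifier output (post-activation), so
`|catalog| = 3·n_blocks + 1 + n_dense`. Extraction runs in inference mode
(dropout off, batch-norm on its learned population statistics) and flattens
multi-axis outputs row-major as (position, channel), making tree feature
indices traceable back to layer coordinates for the importance report.
Handcrafted features (e.g. FFT magnitudes for signal windows) can be
concatenated after the extracted columns.

### Search protocol

`run_block_sweep` grows the network one block at a time, retraining from
scratch, and fits trees on every catalog layer of every trained network.
Growth stops when the best-over-layers accuracy fails to exceed the previous
block count's best (a strict ≤ comparison), at `max_blocks`, or when the
spatial dimension becomes too small for another block. Ties for the overall
best break toward fewer blocks, then the shallower layer. By default the
best (blocks, layer) cell is selected on the *validation* split and its
held-out test accuracy reported separately (`selection="val"`);
`selection="test"` reproduces the report-the-best protocol in which the
maximum test accuracy over all configurations is itself the reported number.
The grid always stores the selection-split accuracies, so the invariant
best = max(grid) holds under either protocol. Learning curves
(`run_learning_curve`) subsample the training pool stratified by class,
retrain at each size, and report the network's own accuracy alongside the
best-over-layers hybrid accuracy per size.

## Preprocessing

* **Windowing** — sensor streams are cut into windows of `time_period`
  steps every `time_step` steps (equal values ⇒ no overlap), never across
  subjects; a window of 80 steps × 4 channels yields 320 values. Windows are
  labeled by majority vote over their timesteps, ties broken by the
  earliest-occurring class in the window (the protocol does not specify
  window labeling; majority vote is the simplest deterministic rule).
* **One-hot DNA** — fixed channel order (a, c, g, t); unknown characters are
  an error rather than silently imputed, because downstream feature indices
  must be stable.
* **Tokenization** — frequency-ranked word indices (0 = pad, 1 = OOV),
  fitted on the training split only, sequences truncated/padded to
  `max_len` (default 100) with a 10,000-word cap.
* **Rating binarization** — label 1 iff rating strictly exceeds the
  per-dataset threshold.
* **Normalization** — per-feature min-max to [0, 1] fitted on the training
  split (constant features map to 0); chosen as the simplest reproducible
  reading of "normalized floating-point features".
* **Splitting** — plain random (not stratified) 80/20 with 20 % of the
  training portion held out for validation; sizes follow
  `round(n·0.8·0.8) / round(n·0.8·0.2) / remainder` and the partition is
  exact and seed-deterministic.

## Synthetic data

The generators produce data with *known recoverable structure* so every
stage is testable without downloads; they make no attempt to match real
datasets beyond size, balance and file format.

* **Planted motif** (sequence): balanced two-class 57-base sequences over a
  uniform background; positives carry one copy of an 8-base motif whose
  bases mutate independently with probability 0.15 (each mutation is to a
  *different* base). Placement is **random** by default — the regime where
  position-invariant convolutional features matter and trees on the raw
  one-hot encoding sit near chance — while `placement="fixed"` gives the
  complementary regime where raw trees succeed directly. Defaults (n = 106,
  53/53 balance, length 57) mirror the promoter-task scale.
* **Activity signals**: per-subject multichannel sinusoids with a
  class-specific frequency/amplitude signature (classes spread 0.5–2.75 Hz
  at 20 Hz sampling), phase-varied channels and Gaussian noise (sd 0.3).
  Trees on FFT-magnitude features reach ≥ 0.9 at the defaults, calibrating
  the windows as clearly learnable.
* **Biased tokens** (text): Zipf-distributed token draws where class 1
  over-samples a marked 5 % of the vocabulary by a bias factor; bias 1 makes
  the classes indistinguishable, large bias drives them toward disjoint
  support.

Because the sequences are i.i.d. draws with a single planted signal, passing
benchmarks here demonstrates the pipeline's mechanics and its low-volume
behaviour — not performance on real promoters, whose signal is a
constellation of positionally-anchored elements.

## Benchmark problem sizes

The self-contained benchmarks run at desk scale, chosen to exercise the
low-volume regime the method targets on a single CPU:

* *Hybrid vs baselines*: planted-motif data, n = 300 (192/48/60 split),
  random placement, mutation 0.15, genomic recipe (64 filters), block budget
  2, max 30 epochs, 10 seeded replicates. Reported as the mean
  best-configuration test accuracy under the report-the-best protocol
  (`selection="test"`) against the mean network-alone and trees-on-raw
  accuracies.
* *Learning curve*: training sizes 50–1000 drawn stratified from a pool of
  1024 (generator n = 1600), a 1-block 16-filter sequence network, 30
  epochs, 5 replicates per size.

## Numerical choices and edge cases

* Softmax uses max-subtraction; BCE clips probabilities to [1e-7, 1-1e-7];
  the training losses are computed from logits in their numerically stable
  forms.
* Max-pooling drops remainder timesteps (floor semantics); building a
  network whose spatial length would fall below the kernel size raises an
  error advising fewer blocks.
* Constant features min-max-normalize to 0; re-applying a fitted transform
  is exactly idempotent.
* Tree-ensemble defaults are snapshotted into the run log at fit time so a
  library upgrade that silently changes defaults is detectable.
* Tie-breaks: window labels → earliest class in the window; sweep best →
  fewer blocks, then shallower layer; importance ranking → gain descending,
  then feature index.

## Known limitations

* The network engine is CPU-only and float64; it is sized for the
  desk-scale experiments above, not for ImageNet-scale training.
* Class imbalance is not handled (balanced generators, plain accuracy); the
  tree ensemble's imbalance-handling options are deliberately not exposed.
* The flat-file readers cover the three supported dialects only; ambiguous
  DNA bases are rejected rather than imputed.
* `selection="test"` reproduces a protocol with selection bias — the
  reported best-over-grid accuracy is an optimistic estimate; use the
  default validation selection when an unbiased single-configuration
  estimate matters.
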