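# Methods

## Model

The classifier maps a preprocessed record `x ∈ R^{leads × T}` to two
per-class score vectors. The trunk is a stack of 1-D SE-ResNet blocks;
each block applies two convolution–batch-norm–ReLU stages (kernel 7,
dropout 0.2 after each stage), then a squeeze-and-excitation gate —
per-channel global mean ("squeeze"), a two-layer bottleneck (reduction
ratio `se_reduction`, ReLU then logistic) producing one multiplicative
gate per channel — and adds a shortcut (a pointwise strided convolution
whenever shape changes). The default trunk is 4 blocks of widths
(64, 128, 128, 256) with stride-2 downsampling per block, chosen so a
60 s × 250 Hz input reaches a sequence length a recurrent layer handles;
depth and widths are configurable and the desk-scale experiments use a
2-block (8, 16) trunk.

The CoT block treats the trunk output `E` as query and key (`Q = E`,
`K = E`) and embeds values pointwise (`V = W(E)`). A kernel-3 convolution
of `K` yields the static local context `K1`; the attention map is
`A = W_θ(ReLU(W_σ([K1, Q])))` with `W_σ`, `W_θ` pointwise convolutions;
the dynamic context is the element-wise product `K2 = V ∗ A`; the output
projects the channel concatenation `[K1, K2]` back to `E`'s width, so the
block is drop-in shape-preserving. Two readings of the attention
composition exist (with or without a local softmax aggregation); this
implementation takes the literal element-wise product, which the oracle
tests pin down exactly. The attention map is *not* normalized; `A` can
take any real values and acts as a learned per-position, per-channel gain.

The Bi-GRU (standard reset/update/candidate gate equations, hidden width
`gru_hidden`, default 128) reads the CoT output forwards and backwards;
the record representation is the concatenation of the two final hidden
states (2 × hidden). Without the Bi-GRU (ablation), global average
pooling over time replaces it. Two independent linear heads score the
main and auxiliary label spaces. By default CoT and Bi-GRU are shared by
both tasks and only the heads are task-specific (hard parameter sharing);
`per_task_branch=True` instead duplicates CoT + Bi-GRU per task, exposing
the alternative architectural reading without committing to it.

Both tasks are multi-label: scores pass through per-class logistics and
the per-task loss is the mean binary cross-entropy. The joint loss is
`λ·L_main + (1−λ)·L_aux`. λ is a free parameter with no canonical value;
the default is the symmetric 0.5 and it is recorded in every run config.

## Auxiliary-task construction

A two-level hierarchy assigns each fine class exactly one coarse parent.
Merge direction: auxiliary labels are the deduplicated parent images of
the main labels (a record with LBBB+RBBB gets the single auxiliary label
of their shared conduction-block group). Split direction: the auxiliary
task reuses the finer level under the main (coarse) labels. The control
condition regroups fine classes randomly — seeded shuffle of the fine
class list, groups refilled in the original size order — preserving the
group-size multiset while destroying clinical meaning.

## Training protocol

Adam; initial learning rate 5e-4, divided by 10 every 10 epochs; batch
size 32; early stop when the best validation total loss is 10 or more
epochs in the past (ties are not improvements), with best-epoch weights
restored. The early-stop monitor is validation loss; monitoring training
loss is the other defensible reading and would only change when runs end.
Splits: `ptbxl_recommended` uses a per-record fold tag (folds 1–8 train,
9 validation, 10 test); `stratified_10fold` deals each stratum (first
main label) round-robin into ten folds after a seeded shuffle — unlike a
plain stratified k-fold this tolerates classes rarer than the fold count.
All randomness (init, batch order, splits, data) flows from explicit
seeds; runs are bit-reproducible.

## Synthetic data

Records are sums of Gaussian bumps (P, Q, R, S, T) tiled at jittered RR
intervals, projected to `leads` channels by a fixed gain vector with
per-record jitter, plus white Gaussian noise of standard deviation
`noise_sd` (mV). The coarse group of a class sets a shared morphology
trait, cycling through a five-entry menu by group position: none
(normal), RR irregularity with suppressed P waves, widened QRS complexes,
periodic premature beats, and a signed ST-segment plateau between S and
T. The fine class perturbs its group trait (magnitude and sign of the
distinguishing feature, a small heart-rate bias, P-onset and T-amplitude
tweaks), so siblings resemble each other more than non-siblings — the
property that makes a hierarchy-derived auxiliary task informative, and
the property the random-grouping control removes. Trait strengths were
set so that a nearest-centroid baseline on averaged beats exceeds 0.9
macro F1 on noise-free data and degrades monotonically with noise.

Label planning assigns each fine class exactly its configured number of
label assignments; a fraction `multilabel_rate` of records carries two
labels from different coarse groups. Fold tags spread every class evenly
over folds 1–10 with a per-class phase, so even rare classes reach the
validation and test folds. Defaults emulate the CPSC2018 setting (its
taxonomy, one-tenth of its class frequencies, 12 leads, 500 Hz, 10 s).
What the generator does **not** emulate: real inter-patient morphology
variation, vectorcardiographically consistent lead geometry, baseline
wander or electrode artifacts, and pathology-accurate waveforms. Passing
tests therefore demonstrate the mechanics and the relative value of a
meaningful hierarchy on data engineered to have one — not clinical-grade
performance.

## Desk-scale experiment sizes

The multi-task benefit experiment uses ~690 records (tenth-scale class
frequencies), 12 leads at 100 Hz for 4 s, noise 0.1 mV, the 2-block
trunk, GRU width 12, 10 epochs at initial learning rate 1e-2 (the small
model tolerates — and at ten epochs needs — a hotter schedule than the
full-scale default), λ = 0.5, five seeds with a fresh dataset and
initialization each. The reported comparison is the mean held-out macro
F1 with the true hierarchy versus a random regrouping as auxiliary task.
At these sizes runs sit mid-learning: per-class AUCs are high while
0.5-thresholded F1 is far below published full-scale values, which is the
regime where auxiliary regularization is visible. The ablation smoke run
(four variants: full, −CoT, −BiGRU, random-aux) uses ~230 records and 10
epochs and asserts completion and comparable report schemas, not
ordering — variant ordering at full scale is a dataset-scale result.

## Numerical choices and conventions

- Zero-denominator convention: precision, recall and F1 are 0 when their
  denominators vanish (affects rare classes); AUC is undefined without
  both a positive and a negative and is excluded from the macro AUC with
  a warning.
- Multi-label binarization at 0.5 for count-based metrics; AUC uses raw
  scores via the tie-aware rank statistic.
- Per-class accuracy is (TP+TN)/N per class, not subset accuracy.
- Resampling is anti-aliased polyphase decimation; upsampling is
  rejected rather than silently interpolated. Length-fixing keeps the
  first `target_seconds` (deterministic prefix) and zero-pads at the end.
- Batch norm uses batch statistics in training and running averages
  (momentum 0.1) in eval; dropout masks are rescaled by 1/keep.
- Weights are Glorot-uniform from a per-model seeded generator; Adam uses
  the standard bias-corrected moments (β₁ 0.9, β₂ 0.999, ε 1e-8).
- The multi-label cross-entropy is computed in the numerically stable
  log-sum-exp form; its gradient is exact (`σ(s) − y`)/n.
- The CoT embedding `W` is pointwise (stride 1); a strided reading would
  break the block's shape-preservation contract.

## Known limitations

The NumPy implementation is single-threaded CPU code: full-scale inputs
(12 × 15000 after preprocessing) forward fine, but training at published
dataset sizes is out of reach here, so published per-class benchmark
values are validated only through their internal arithmetic, which the
shipped tables reproduce. The generator's traits are stylized; transfer
of the multi-task benefit to real recordings is not established by these
experiments. Hierarchies deeper than two levels are out of scope.
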