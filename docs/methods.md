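# Methods

## The problem and the model

Sleep staging assigns one of five AASM stages — W, N1, N2, N3, REM — to
every 30-second epoch of an overnight EEG recording. `somnoseq` scores a
whole *sequence* of epochs jointly with an encoder-decoder network, because
stages evolve through 90–120-minute NREM/REM cycles and neighboring epochs
carry most of the information needed to disambiguate a single one.

The network, per input sequence of `maxtime` epochs (3000 samples each at
100 Hz, standardized to zero mean and unit variance):

1. **Dual-resolution CNN.** Two branches of four 1-D convolutions with
   ReLU, a max-pool after the first layer and dropout after the last. The
   small-filter branch (filter 50, stride 6) resolves fine temporal
   structure; the large-filter branch (filter 400, stride 50) resolves
   coarse spectral content. Branch outputs are concatenated per epoch and
   passed through a final dropout. Convolutions use SAME (zero) padding,
   matching the dual-resolution design this CNN follows; without padding
   the large branch's feature maps would collapse below one sample by the
   third layer.
2. **Bidirectional recurrent encoder.** A forward pass in time order and a
   backward pass in reverse order over the per-epoch feature vectors;
   position t's two hidden states are combined linearly,
   `y_t = U·[h→_t ; h←_t] + b_y`, into encoder states `e_0 … e_{T−1}`.
   LSTM cells by default; `cell="simple"` selects the plain tanh
   recurrence `h_t = tanh(W x_t + V h_{t−1} + b)` for a literal,
   hand-checkable form of the same contract.
3. **Attention decoder.** One decoding step per epoch. Encoder position i
   is scored against the decoder state through a tanh layer,
   `score_i = v·tanh(W_h h + W_e e_i)`, softmax-normalized into attention
   weights α (one attention-map row per decoded epoch); the context
   `c_t = Σ_i α_i e_i` is consumed three ways, following the legacy
   TensorFlow `attention_decoder` design this family of models was built
   on: the previous step's context is fed into the cell with the embedded
   previous label (input feeding), the *updated* hidden state queries the
   attention, and the fresh context joins the output through an
   attentional layer `h̃ = tanh(W_c [h ; c])` before the class projection.
   The score width `attention_dim` defaults to 16; width 1 degenerates to
   a purely scalar tanh score.

Decoding starts from a special SOD (start-of-decoding) token. During
training the decoder is teacher-forced — it receives the true previous
label — and one extra step predicts the EOD (end-of-decoding) class after
the last epoch. At test time it feeds back its own greedy argmax over the
five stage logits, so exactly one stage is emitted per input epoch; the
EOD logit exists in the output projection (6 logits) but never competes
with stages when labels are reported. A `use_attention=False` ablation
gives the basic decoder: no context, decoder state initialized from the
last encoder state.

## Losses

Plain MSE averages squared error over samples, so the majority stages (W,
N2) dominate the gradient. The mean-false-error family averages *within*
each class first:

    l(c)   = (1/C_c) Σ_{j∈c} ‖y_j − ŷ_j‖²
    L_MFE  = Σ_c l(c)            L_MSFE = Σ_c l(c)²

with `‖·‖²` the squared Euclidean distance between the one-hot target and
the predicted probability vector (summed over dimensions; a per-dimension
mean is available via `inner_error="mean"`). Each class present in a batch
contributes one term regardless of frequency; classes absent from a
mini-batch contribute zero. EOD steps are excluded from the class set and
trained with a plain per-token squared-error term, so imbalance weighting
concerns only real stages. An L2 penalty β·Σ‖W‖² (β = 0.001, biases
excluded) is added to whichever loss is selected. MFE is the training
default; MSFE and MSE are selectable.

Training uses RMSProp (decay 0.9, ε = 1e−10 — the accumulator defaults of
the framework this recipe originated in), learning rate 0.001,
mini-batches of 20 sequences, at most 120 passes, teacher forcing on, and
optional early stopping on a loss plateau.

## Balancing

SMOTE oversamples minority stages among the raw training epochs: a
synthetic epoch is `x + u·(x′ − x)` for a real minority epoch x, one of
its k = 5 nearest same-class neighbors x′ (Euclidean distance on the
normalized 3000-sample vectors), and u uniform on [0, 1]. Synthetic epochs
have no temporal context of their own, so they are assembled into
homogeneous all-one-stage sequences appended to the real training
sequences — real sequences keep their genuine stage dynamics while the
loss sees balanced class exposure. Oversampling happens strictly inside
training folds; every epoch carries a provenance flag and the
cross-validation harness asserts test folds contain none.

## Evaluation

Cross-validation is subject-wise (all recordings of a subject share a
fold; subjects are shuffled by seed and dealt round-robin), so every
evaluation is inter-patient. Per-fold test predictions are pooled into one
5×5 confusion matrix (reference rows × predicted columns, W/N1/N2/N3/REM
order) and the metric stack is computed on the pooled counts: per-class
precision, recall, specificity and F1 from the TP/TN/FP/FN tallies,
overall accuracy = trace/total, macro-F1 as the unweighted mean of
per-class F1, and Cohen's κ = (p_o − p_e)/(1 − p_e). Percentages are
rounded to two decimals. Zero-denominator metrics report 0 with a
degeneracy flag instead of NaN. The stack reproduces the published
benchmark tables it is validated against to their printed precision
(two cells differ by 0.01, the tables' own rounding).

## The synthetic generator

Real overnight PSG is not redistributable with the package, so every
component is exercised on a surrogate that keeps what the model exploits:

* **Stage-dependent spectra** — per stage, a sum of sinusoids with
  randomized phases and ±20% amplitude jitter plus white Gaussian noise
  (SD 0.5): alpha-dominant W (10/11.5 Hz), theta N1 (5.5/7 Hz),
  spindle-band N2 (13 Hz over 5 Hz), high-amplitude slow N3 (1/1.8 Hz),
  and low-amplitude mixed REM (4.5/6/9 Hz).
* **Cyclic dynamics** — a first-order Markov chain at 30-s resolution
  whose self-loops set dwell times and whose off-diagonal structure
  follows the W → N1 → N2 → N3 → N2 → REM cycle; cycle length is induced
  by the transition probabilities rather than an explicit clock.
* **Class imbalance** — the default chain's stationary distribution is
  ≈ 8 : 2.8 : 18.3 : 5.5 : 8.3 (W:N1:N2:N3:REM), approximating the skew of
  scored Sleep-EDF nights: N2 dominant, N1 rare.

The generator is deterministic under a fixed seed (byte-identical
bundles). What it does **not** emulate: K-complex/spindle morphology,
artifacts and electrode pops, non-stationarity within a night, and
inter-subject variability. Its stages are separable by bandpower alone (a
nearest-centroid bandpower classifier exceeds 80% by construction — the
suite checks this learnability floor), so passing functional tests shows
the pipeline trains and evaluates correctly, not that it would reach any
particular accuracy on real EEG.

## Scaled-down benchmark runs

The functional benchmarks are sized for minutes on one CPU, as the
package's standard test conditions:

* **Cross-validation run**: the standard bundle (4 recordings × 240
  epochs), subject-wise 4-fold CV, maxtime 5, SMOTE balancing, MFE loss,
  30 training epochs, and a reduced preset (8-channel CNN branches, hidden
  32 per encoder direction, decoder hidden 64, embedding 16, dropout
  0.25 — a network this small underfits a 30-epoch budget at the
  full-scale 0.5 dropout, so the preset regularizes more lightly).
* **Imbalance contrast**: a 95:5 two-class task built from two
  deliberately overlapping single-sinusoid classes (10 vs 8.5 Hz,
  amplitude 0.7, noise SD 1.5), 500 training / 400 test epochs, 10
  training epochs, five replicates; identical models trained with MFE vs
  MSE, compared on median minority-class recall. The overlap matters: on a
  cleanly separable task both losses reach full recall and the contrast is
  invisible.

## Numerical choices and known limitations

* All computation is float64 on a small in-repo reverse-mode autodiff
  engine (vectorized numpy kernels); analytic gradients of every operation
  and of the full training objective are tested against central
  differences at 1e−4 relative tolerance.
* Weights initialize uniform ±1/√fan_in from a seeded generator; biases
  zero, except LSTM forget-gate biases at 1. Initial recurrent states are
  zero. Softmax subtracts the row maximum before exponentiation.
* Zero-variance epochs raise rather than emit NaNs; a non-finite training
  loss aborts with a diagnostic.
* Trailing partial epochs, trailing partial sequences, and
  movement/unscored spans are dropped, not padded; epoch windows are
  half-open and 0-based, so exclusions leave index gaps that mark real
  discontinuities.
* Inputs must be 100 Hz; resampling is deliberately out of scope.
* **Attention diagonality at toy scale.** On the synthetic benchmark the
  trained attention maps are close to uniform rather than diagonal: the
  bidirectional encoder shuttles the entire (trivially separable,
  maxtime-5) label sequence into every encoder state, so uniform
  attention already supports >90% accuracy and the objective exerts no
  pressure to focus positionally. Diagonal attention is a property
  reported for full-scale training on real EEG with longer sequences; the
  package computes and reports the diagonality fraction honestly rather
  than reproducing that qualitative figure at desk scale.
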