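# somnoseq

Sequence-to-sequence sleep-stage scoring from single-channel EEG.

Scoring sleep means labeling every 30-second epoch of an overnight EEG
recording with one of the five AASM stages (W, N1, N2, N3, REM) — a slow,
expert-driven task that automated scorers aim to replace. `somnoseq` is a
tested reimplementation of an end-to-end attention encoder-decoder scorer
for researchers who want to study its ingredients in isolation: a
dual-resolution CNN over raw epochs (small filters for temporal detail,
large filters for spectral content), a bidirectional LSTM encoder, an
attention decoder that emits one stage per epoch via the SOD/EOD
teacher-forcing protocol, SMOTE oversampling, and the imbalance-aware
mean-false-error losses

    l(c) = (1/C_c) Σ_{j∈c} ‖y_j − ŷ_j‖² ,   L_MFE = Σ_c l(c) ,   L_MSFE = Σ_c l(c)²

which average squared error within each class before summing across
classes, so rare stages (above all N1) are not drowned out by W and N2.
Evaluation is subject-wise k-fold cross-validation pooled into a single
confusion matrix, with per-class precision/recall/specificity/F1, overall
accuracy, macro-F1 and Cohen's κ.

Everything runs on a built-in synthetic-EEG generator (stage-dependent
spectra, Markov stage cycling, realistic class imbalance), so the whole
pipeline is testable on one CPU without downloading polysomnography data.
Real Sleep-EDF recordings (EDF + EDF+ hypnograms, 100 Hz, Fpz-Cz or Pz-Oz)
are supported through the `prepare` command. The model itself — network,
losses, and gradients — runs on a small in-repo autodiff engine verified
against central differences, so there is no deep-learning framework
dependency.

## Worked example

The evaluation stack, applied to the published pooled confusion matrix of
a 20-fold cross-validation on Sleep-EDF-13 (Fpz-Cz channel):

```python
from somnoseq.reference_tables import FPZ_CZ_CONFUSION
from somnoseq.metrics import report

rep = report(FPZ_CZ_CONFUSION)
print(rep.accuracy, rep.macro_f1, rep.kappa)
print(rep.per_class["N1"].f1, rep.per_class["W"].precision)
```

prints

```
84.26 79.66 0.79
52.19 87.84
```

— overall accuracy 84.26%, macro-F1 79.66% and κ = 0.79 for the full
benchmark, an F1 of 52.19% for the hard minority stage N1, and a precision
of 87.84% for wake, all matching the published values at printed
precision.

A complete synthetic experiment from the shell:

```bash
somnoseq synth --recordings 4 --epochs 240 --seed 1 --out bundle/
somnoseq train --bundle bundle/ --folds 4 --maxtime 5 --max-epochs 30 \
               --reduced --balance smote --loss mfe --seed 1 --out runs/demo
somnoseq plot --run runs/demo --out runs/demo/figs
```

generates 960 labeled epochs, trains the reduced model subject-wise with
SMOTE balancing and the MFE loss, and writes `metrics.json`,
`confusion.csv`, per-fold checkpoints and training-curve figures. The same
configuration run through the library
(`somnoseq.experiments.synthetic_cv_benchmark(seed=1)`) yields a pooled
accuracy of 91.56%, macro-F1 87.93% and κ = 0.88 on the held-out folds —
the synthetic stages are separable by design, so this demonstrates that
training and evaluation work, not that real EEG is this easy.

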