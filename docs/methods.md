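# Methods

This note records the model, the numerical conventions, the synthetic data
design, and the open design choices made while building `mdfpnet`.  It
states no result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Signal standardisation

All clips are resampled to a common analysis rate (default 10 kHz,
`preprocess.target_rate`) by polyphase band-limited resampling
(`scipy.signal.resample_poly` on the exact rational rate ratio), then
brought to a fixed length (default 30,000 samples = 3 s,
`preprocess.target_len`).  Long clips keep one contiguous window; short
clips are zero-padded with the deficit split between the two ends.
Training-time draws are uniform and seeded per clip key (CRC of the clip
path mixed into the global seed), so re-draws are possible but
reproducible; evaluation uses center-crop/symmetric-pad so metrics are
deterministic.  Resampling precedes length-fixing so the target length
always means 3 s regardless of the source rate.  Padding conserves signal
energy exactly; cropping can only remove energy.

## Features

The STFT uses frame 1024, hop 512, and a periodic Hann window on centered
frames with reflection padding.  Centering is forced by the frame-count
contract: `L = 1 + floor(30000/512) = 59` frames; an uncentered analysis
would give 57.  K = 513 one-sided bins.  Power is `|STFT|²`; the band
projection sums over the one-sided bins (the triangular filters are zero
above Nyquist, so the two-sided sum adds nothing).

Filter banks place `M + 2` breakpoints equally on the mel axis
(`mel = 2595·log10(1 + f/700)`, the HTK convention; no mel formula is
canonical, this is the most common) or on the Hz axis, spanning 0 Hz to
Nyquist, then snap them to FFT-bin indices.  Snapping makes each triangle
attain exactly 1.0 at its center bin and lets every element be checked
against a scalar piecewise-linear oracle; a filter narrower than one bin is
a validation error naming the filter.  With the defaults (K = 513, M = 128
at 10 kHz) the tightest mel filters near 0 Hz are two bins wide, so the
default bank is always valid.

Band powers are converted to dB (`10·log10`, floor ε = 1e−10; the floor
maps exact zeros from padded silence to −100 dB instead of −inf).  The
cepstrum is the literal unnormalised DCT-II sum over the dB matrix
(`cepstra` with `orthonormal=False`); the orthonormal option exists only
for cross-checks against standard toolkits (ours equals `scipy.fft.dct`
type-II divided by 2).  Using the dB matrix as the log-spectrum input is a
deliberate reading: the stepwise definition (convert to dB, then DCT) is
followed rather than a natural-log variant, which would differ only by the
constant 10/ln 10.

The mean-MFCC branch input is defined as the full 128-coefficient mel
cepstrum averaged over the 59 frames.  The published branch takes a
128-long vector while the cepstral matrix has only 32 coefficients and the
derivation of the 128 is not stated; computing a 128-coefficient cepstrum
from the 128-band mel matrix and averaging over time is this package's
bridge, recorded as an open question.

Branch inputs: 2-D features are transposed to frequency × time, min-max
scaled per clip to [0, 1], optionally resized bilinearly (corner-aligned,
exact identity at the native size) and replicated to 3 identical channels
for image-style backbones.  The published 128 × 345 × 3 input shape is
inconsistent with the 59-frame feature matrices; extraction follows the
feature sizes and the resize bridges to any configured branch shape.  Tests
and the default experiment use the native sizes (mel 128 × 59, cepstra
32 × 59).  The 1-D branch input is the mean-MFCC vector min-max scaled per
clip.

## Augmentation

Time reversal (`samples[::-1]`) is an exact involution and mirrors the
spectrogram along the time axis (bit-level symmetric for a symmetric taper
and hop-aligned length; the property test uses that configuration).  The
selection rule `below_mean` doubles every class whose count is under the
mean class count — on the published six-species counts (604, 1213, 1034,
1422, 681, 560; mean 919) it doubles exactly the three minority classes and
reproduces the published totals (5514 → 7359).  Flipped copies are
materialised as files with a `__flip` suffix so the splitter can group them
with their sources; re-running augmentation is idempotent.

## Model and training

Branch nets end in a softmax over the classes (computed max-shifted).  The
bespoke 1-D CNN is four blocks of 16 size-3 kernels (stride 1, ReLU,
dropout, max-pool 2); the published pooling line prints stride 1, which
cannot reduce 128 → 8 over four blocks, so the conventional stride-2
pooling is used — it reproduces the printed 8 × 16 → 128 flatten.  `tiny2d`
is a small 4-conv-block 2-D CNN (channels 8, 8, 16, 16, dense 64) for
desk-scale training.  The deep pretrained backbones are plug-ins via
`register_backbone`; nothing in the package downloads weights.

The layers, backpropagation and SGD-with-momentum optimizer are implemented
in numpy (`mdfpnet.nn`), with convolutions as batched im2col matrix
products; the backward pass of a stride-1 same-padded convolution is itself
a convolution with the channel-transposed, spatially flipped kernel.
Gradients are verified against central finite differences in the test
suite.  All randomness (init, dropout, batch order, crops) derives from
explicit seeds; identical seeds give bit-identical runs.

Training is two-stage: each branch trains independently, is frozen, and the
fusion head (dense 24 → 6 + softmax) trains on the concatenated branch
outputs.  Whether fusion training should back-propagate into the branches
is not specified anywhere; the two-stage protocol matches the depiction of
the branch outputs as finished predictions, and keeps the branches'
individual accuracies measurable.  The head is initialised at the exact
block-averaging weights (with identity activation, averaging branch
probabilities is itself a valid prediction and is exposed as
`FusionHead.averaging()` — the stated special case the trainable layer
generalises), then trained with softmax activation.

Hyperparameter defaults, none of which are published: lr 0.01, momentum
0.9, batch 32, dropout 0.25, 12 branch epochs and 100 fusion epochs in the
default experiment.  These converge on the synthetic corpus; all are
config keys.

## Evaluation

20% of clips are held out, and the remaining 80% is cycled through 5-fold
cross-validation.  Splits are stratified by species (keeps folds
class-balanced) and grouped by source clip, so a flip and its source never
straddle a partition boundary — stricter than any published protocol
states, and the conservative choice against leakage.  Implemented with
scikit-learn's `StratifiedGroupKFold` (outer 1-of-5 split for the holdout,
inner 5-fold on the rest).

The headline accuracy is the mean over classes of the one-vs-rest binary
accuracy; for N classes this equals `(N−2)/N + (2/N)·plain accuracy`, so it
is never below plain multiclass accuracy.  Because the defining formula and
its prose gloss ("ratio of correctly classified samples") disagree, both
are computed and reported.  Cross-fold dispersion uses the sample (n−1)
standard deviation — the estimator behind the published dispersion value is
not stated; the choice is recorded here.  Per-class precision/recall/F1 are
one-vs-rest; zero-denominator classes report NaN with a warning rather than
a fill value.  Display rounding is 2 decimals.

## Synthetic data

The generator emulates a heterogeneous PAM call archive: six classes drawn
from three parametric families — FM whistles (sinusoidal frequency
contour), click trains (periodic exponentially decaying resonant
impulses), harmonic moans (1/h-weighted harmonic stack with slow AM) — at
mixed sample rates (16/22.05/44.1 kHz), durations 1–6 s, additive white
Gaussian noise at an exactly realised SNR (default 20 dB), and deliberately
imbalanced counts (60/120/100/140/70/55 = 545 clips) so augmentation has
work to do.  Each class owns a disjoint frequency band (moans 120–480 Hz
fundamentals, whistles sweeping 500–1500 and 2450–3850 Hz, click resonances
2000–2400 and 4100–4600 Hz): a decaying resonant click is spectrally a
narrow line, so without disjoint bands a fast click train is
indistinguishable from a tonal whistle in time-averaged cepstral space.
All content stays below 4.8 kHz to survive resampling to 10 kHz.

What the generator does *not* emulate: propagation and multipath, ambient
noise colour, overlapping calls, label noise, or real call morphology.
Passing end-to-end tests therefore demonstrates that the pipeline learns
and fuses separable spectral classes under its published protocol — not
field-recording performance.

A fixed property of the corpus: at SNR ≥ 20 dB a nearest-centroid rule on
the *direction* of mean-MFCC coefficients 1..127 separates the six classes
at ≥ 95% held-out accuracy.  The direction is the right invariant because
zero-padding short clips scales the informative coefficients by the
non-silent frame fraction, and coefficient 0 tracks overall level; both are
nuisance dimensions.

## Scale of the default experiment

The default experiment (545 clips + 185 flips, four branches × five folds,
12 epochs per branch) runs in about six minutes on one CPU with the numpy
trainer; the fused model reaches ≥ 90% mean one-vs-rest validation accuracy
and is never below its best single branch on the cross-fold mean.  These
problem sizes are the package's test defaults; larger corpora and deep
backbones scale through the same interfaces.

## Known limitations

* No GPU path; the numpy trainer is for desk-scale corpora and tests.
* No VAD/denoising/segmentation: one clean label per clip is assumed.
* FLAC/MP3 and streaming input are out of scope (WAV only).
* Delta/delta-delta cepstral features are deliberately not computed.
* The published branch input shape (128 × 345 × 3) and the mean-MFCC
  dimensionality are bridged by documented conventions (resize; 128-band
  cepstrum averaged over time) because their derivations are unstated.
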