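# Methods

This note documents the models implemented in `collarml`, the synthetic
data they are exercised on, the defaults that matter, and the numerical
and design choices behind them.

## The problem

A smart collar on a dog undergoing a scripted evaluation session records
six sensor modalities at two rates: a 3-axis IMU, an audio
decibel-level channel and an ambient-light channel at 100 Hz, and
temperature, humidity and barometric pressure at 1 Hz.  A trainer app
logs the start and end of each of 50 scripted protocol states (exam
handling steps, noise distractions, free exploration, ...).  The
analysis asks whether the state can be recovered from the sensors
alone, which sensor fusions help, and whether common motion patterns
can be extracted without labels.

## Synthetic sessions

Real recordings of this kind are not freely distributable, so the
package generates sessions with the statistical structure the analysis
assumes.  Each of the 50 states has a *motif*: per-axis IMU base level,
a dominant oscillation (amplitude, frequency in 0.4–8 Hz), a jerkiness
multiplier that injects a 7x-frequency harmonic, Gaussian sensor noise,
and a per-second probability of a loud audio burst (a +30 dB spike with
0.2 s exponential decay over a 45 dB baseline).  Environmental channels
drift slowly (~millidegrees per second) with tiny measurement noise,
emulating an indoor test room where they carry almost no state
information.  Events follow the catalogue's protocol order; durations
are drawn uniformly from 8–16 s, so a 50-event session lasts about ten
minutes.  Per-dog seeds are split from the master seed with
`numpy.random.SeedSequence(master_seed, spawn_key=(dog_index,))`, making
generation a pure function of (config, dog id, seed).

Two state pairs ("Noise can shake"/"Noise can seen" and "Vacuum on-On
leash"/"Vacuum off-On leash") share identical IMU motifs and differ only
in audio-burst probability.  This makes the audio channel genuinely
informative: no IMU-only model can separate those pairs.

What the generator does **not** emulate: inter-dog temperament
variability, motion artifacts from a loosely fitting collar, trainer
timing errors, overlapping or skipped protocol states, and sensor
dropouts.  Passing tests on this cohort therefore demonstrate that the
pipeline's machinery is correct and can exploit the structure it was
designed for — not that real collar data are this separable.  Real
recordings are noisier in precisely the ways the motif model is clean,
and accuracies on them are expected to be far lower.

## Preprocessing

Each labeled event is resampled onto a common 500-point grid spanning
the event by piecewise-linear interpolation of every selected channel
("interpolate" sampling); the grid is per event, so events of different
durations are time-warped to a fixed length.  Optionally each 500-row
sequence is split into twenty contiguous 25-row windows ("subsample"
sampling; 20x the samples, each covering ~1/20 of the event).
Z-normalization uses the per-modality mean and population SD over the
entire session and is applied to the raw streams *before* gridding:
session statistics are a property of the stream, not of any particular
grid, and since interpolation is linear the order affects values only at
rounding level.  A modality with zero SD is set to zero with a logged
warning.  Channel order is fixed: IMU x, y, z; audio; light;
temperature; humidity; pressure.  Fusions select 3 (IMU), 4 (+audio) or
8 (+light/temperature/humidity/pressure) channels; light is sampled at
100 Hz but belongs to the environmental fusion group.

Train/test splits are stratified by state at a 70/30 ratio.  The default
split level is *event*: all 20 windows of one event land on the same
side, preventing leakage of nearly identical windows across the split.
A window-level mode is provided for completeness but is not the default.

The 10-state subset is chosen the way a practitioner would: a quick
preliminary run (KPCA+ridge on the interpolated 50-state IMU variant)
and selection of the ten states with the highest per-class recall, ties
broken lexicographically.

## Conv-LSTM classifier

Defaults: four 1-D convolutions (width 64, kernel 5, ReLU, valid
padding) → two LSTM layers (hidden 128) → dense softmax over the 10 or
50 states; a high-capacity variant widens the convolutions to 1024.  The
exact layer list of the lineage architecture is not fully specified
anywhere, so these defaults follow the common deep-conv-LSTM recipe for
wearable-sensor activity recognition and every piece is overridable via
`ConvLSTMConfig`.  Training is mini-batch Adam (batch 64) on softmax
cross-entropy with a stratified 10% validation split and optional early
stopping on validation loss (patience 25).  Learning rate (default
1e-3) and hidden size are the hyperparameters that matter most for this
family and are the ones the provided grid helper varies.

The network runs on a compact numpy engine written for this package
(1-D conv via im2col, full backpropagation-through-time LSTM, Adam);
every layer's backward pass is verified against central finite
differences in the test suite.  Given a seed, training is exactly
reproducible on the same machine.

## KPCA + ridge classifier

Sequences are flattened to vectors; the RBF kernel
K_ij = exp(−γ‖x_i − x_j‖²) is computed on the training set,
double-centered, and eigendecomposed.  Components with eigenvalue below
1e-10 are dropped; at most min(n−1, 256) are kept.  Out-of-sample
points are centered with the stored training-kernel means.  γ is the
single main hyperparameter; the kernel family itself is not dictated by
anything beyond that, and a single width parameter implies RBF.  γ is
selected on a validation split over a log grid (1e-5 … 1e-1 by default).
The classifier is a one-vs-rest ridge regression on ±1 targets over the
components (closed form, unpenalized intercept, α = 1 by default); the
L2 penalty is what suppresses uninformative components.  Component signs
are fixed by making each component's largest-magnitude dual coefficient
positive.  The O(n³) eigendecomposition limits training-set size;
`reduce_training_set` provides stratified 1/4 and 1/16 subsampling
(largest-remainder allocation so the total is exactly round(n·factor)).

## Autoencoder lexicon

A 1-D convolutional autoencoder (conv 16 → pool 5 → conv 8 → dense)
maps windows of M_in rows × C channels to a latent space of N = 4
(interpolated) or N = 8 (subsampled) dimensions and back (dense →
conv → upsample → conv).  Loss is mean squared reconstruction error.
Windowing for AE training uses heavy overlap, default 75% of the window
length.

Lexicon construction: the latent cloud is embedded in 2-D by t-SNE
(fixed random state); a Gaussian KDE (Scott's rule) scores each embedded
point; points are visited in decreasing density and accepted as peaks
while at least 10% of the embedding bounding-box diagonal away from
every accepted peak; each peak's members are the points within its basin
radius (half the minimum inter-peak distance; everything, for a single
peak).  The representative latent ϕ* is the member centroid **in the
original latent space**, not in the embedding — an embedding coordinate
cannot be decoded, a latent centroid can.  The pre-image x* is simply
decode(ϕ*): the trained decoder is the functional inverse from the
latent space back to sequence space, so no gradient-based pre-image
optimization is needed; the residual ‖encode(x*) − ϕ*‖ is reported with
every entry as a self-consistency diagnostic.  KDE bandwidth, minimum
peak separation and basin rule are declared defaults, all configurable.

For interpretation, `double_integrate` converts an acceleration channel
to position (cumulative trapezoids twice, zero initial conditions) and
`axis_plane_trajectory` slices time-ordered axis-pair trajectories for
manifold-style plots.

## Evaluation

Macro precision/recall are unweighted class means of diag/column-sum and
diag/row-sum (0 for an empty column/row); macro-F1 is the mean of
per-class F1 values — the standard aggregation, stated explicitly
because published tables of this kind sometimes use variants that can
exceed both macro-precision and accuracy.  The state-flow ("Sankey")
map sends each true state to its modal predicted state when that mode
holds at least θ of the state's predictions and to the null state
otherwise; θ defaults to 0.30, chosen so that a state spread evenly
over four or more predictions is null while any clear mode survives;
ties break toward the diagonal, then lexicographically.  States sharing
a target are recommended for aggregation into one superstate;
stand-alone null states are recommended for removal.

The experiment grid enumerates both samplings × {10, 50} states × three
fusions for both models.  The two 50-state environmental-fusion cells
are emitted as explicit NaN rows: 1 Hz channels provide too few
independent low-rate samples per state to populate them meaningfully.

## Study conditions and problem sizes

The canned experiments in `collarml.experiments` (also driven by
`scripts/acceptance.py`) use a 20-dog cohort — large enough for ~14
training events per state in the 10-state variants while keeping every
experiment in the seconds-to-minutes range on one CPU core.  The
Conv-LSTM runs 20 epochs there, which is past the point where its
validation accuracy plateaus on this cohort.  The audio-fusion contrast
is averaged over five independent 70/30 splits: a single split leaves
only ~60 test events, too few to resolve a few-point accuracy
difference.  The contrast uses the interpolated variant because the
kernel method is consistently the stronger model on interpolated data,
and the noise-rich subset (the two audio-only-separable pairs plus
eight ordinary states) because that is where audio carries information.
The lexicon experiment plants k = 3 motifs (150 noisy copies each) and
asks whether the three decoded pre-images map one-to-one onto the
planted motifs by nearest MSE.

## Known limitations

- Motif parameters are invented, not calibrated to real dogs; absolute
  accuracies on this cohort say nothing about accuracies on real data.
- The numpy engine is CPU-only and single-threaded by design; it is
  suitable for desk-scale experiments, not for 460-dog training runs.
- t-SNE is reproducible only for a fixed seed and library version;
  lexicon identities (x1, x2, ...) are stable per run, not across
  environments.
- The KPCA implementation stores the full training set and kernel; its
  memory and time grow quadratically/cubically, which is inherent to
  the method rather than to this implementation.
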