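# Methods

`hapticode` re-implements, as a tested pipeline on synthetic data, an
unsupervised efficient-coding analysis of haptic material perception:
vibratory texture signals are compressed through a convolutional
autoencoder, and the learned latent space is interrogated for material
category structure, agreement with perceptual (rating-based) distances, and
temporal-frequency tuning comparable to tactile afferents.

## The model

An 80 ms acceleration segment (256 samples at 3200 Hz), normalized to
[0, 1], passes through four 1-D convolutional layers (kernel size 5, same
padding, ReLU), each followed by max pooling with window and stride 4, so
the temporal axis contracts 256 → 64 → 16 → 4 → 1. Feature counts are
64, 32, 16, then `latent_dim`; the final pooling leaves one time step of
`latent_dim` features — the *code*. The decoder mirrors this with
step-repetition upsampling (1 → 4 → 16 → 64 → 256) through layers of
`latent_dim`, 16, 32, 64 features and a final sigmoid layer with a single
feature, so reconstructions live in (0, 1) and can be compared with the
input under the mean-absolute-error loss

    MAE = (1/N) Σᵢ |yᵢ − ŷᵢ|.

For a bottleneck of d features the *compression rate* is d/256 × 100%; the
reference model (d = 16) runs at 6.25%. In the compression sweep every
intermediate layer's feature count is clamped to at least d so no layer is
narrower than the code. The sweep takes an explicit list of bottleneck
sizes; `{16, 64, 128, 192, 256}` realizes the rate ladder
6.25 / 25 / 50 / 75 / 100% (a textual source for this analysis lists
feature counts 16, 32, 64, 192, 256 against those same rates, which is
arithmetically inconsistent — 32/256 is 12.5% — so the explicit-list form
is authoritative here).

Training uses Adam (default learning rate 1e-3, batch 128, 50 epochs) and
a single seeded generator for weights and batch order, which makes
training bit-reproducible on one CPU. The network engine is a small numpy
implementation (im2col-free GEMM convolutions with hand-derived gradients,
verified against finite differences in the test suite); no deep-learning
framework is required.

Three optimization choices keep every bottleneck width trainable at CPU
step counts, and all were forced by observed failure modes rather than
taste: ReLU convolutions use He-normal weights with a small positive bias
(Glorot/zero-bias stacks frequently die into constant codes at these
widths); the initial weights are rescaled LSUV-style so each layer's
activations start at unit RMS (otherwise the no-compression variant begins
with a saturated output sigmoid and never recovers); and Adam applies a
per-layer learning-rate multiplier min(1, 160/fan_in), because a unit's
drift per Adam step grows with its fan-in and the widest layers otherwise
saturate within a few batches. The sigmoid output layer keeps
Glorot-uniform/zero-bias initialization.

## Downstream analyses

- **Latent PCs space.** PCA is fit on the codes of the full dataset; the
  retained dimensionality k is the smallest number of components whose
  cumulative explained variance reaches 95%. All subsequent analyses work
  in this k-dimensional projection.
- **Embeddings and distances.** Each material is the mean projection of its
  segments; categories get centroids; pairwise Euclidean centroid distances
  form the latent distance matrix. Two distance matrices are compared by
  Pearson correlation over their 21 unique category pairs.
- **Perceptual distances.** Descriptor ratings are z-scored per
  (participant, descriptor) with the population SD, averaged across
  participants into one 7-vector per material, correlated per material
  pair, averaged per category pair (distinct pairs on the diagonal), and
  mapped through δ = 2(1 − ρ). The conventional correlation distance is
  √(2(1 − ρ)); both are monotone in ρ and a `sqrt_variant` switch selects
  the square-root form. The as-printed linear form is the default.
- **Perceived categories.** Per participant, the highest-rated category of
  each material; across participants, the majority vote. Ties break to the
  lowest category index and are logged. Between-participant agreement is
  leave-one-participant-out majority prediction accuracy.
- **Classification.** Linear discriminant analysis on the material
  embeddings with a deterministic leave-one-material-per-category-out
  scheme: with S the largest category size, fold i tests each category's
  (i mod size)-th material by sorted id, so every material is tested at
  least once and every fold tests one material per category. How unequal
  category sizes cycle through folds is this package's documented choice;
  LDA is the minimal-assumption reading of "linear classifier" and is
  swappable for any sklearn classifier. The chance level is the mean
  accuracy over label permutations (default 5000), with a [2.5th, 97.5th]
  percentile confidence interval.
- **Tuning probe.** 830 sinusoids on a uniform grid up to 800 Hz (the 0 Hz
  endpoint is replaced by the first positive grid frequency — a DC probe is
  the baseline itself), 8 phases each, peak-to-peak 0.5 around mid-range.
  A dimension's response at a frequency is the phase-averaged |projection −
  baseline-projection|; curves are min-max normalized per dimension. The
  response definition is operational in this package because the source
  analysis never defines "model response" formally. Each dimension is
  summarized by its sensitivity-weighted mean frequency, summaries are
  split into low/high groups by 1-D k-means (10 restarts), and group peak
  frequencies are compared with RA (40–60 Hz) and PC (250–300 Hz) afferent
  bands. The bundled afferent reference table is synthetic — constructed
  log-Gaussian curves with peaks inside the physiological bands — because
  the measured threshold data belongs to the cited physiology literature;
  users can supply their own CSV.

## The synthetic study

The generator emulates a tool-mediated texture exploration study: 7
material categories over 81 samples (default split 12,12,12,12,11,11,11 —
the per-category breakdown of the original study is not public, so this is
a stand-in), 11 participants, 10 s recordings at 3200 Hz.

Each category owns a spectral envelope of 2–4 Gaussian bumps (centers
25–450 Hz) under a 1/f-like roll-off (corner 150 Hz), redrawn until all
pairs correlate below 0.8. Bump widths default to 6–25 Hz: textures with
periodic surface structure produce quasi-periodic, narrowband vibrations,
and narrow peaks are what makes an 80 ms window genuinely low-dimensional
and therefore compressible. Materials multiply their category envelope by a
smooth log-normal jitter field (SD 0.5), giving the large within-category
heterogeneity everyday materials show — calibrated so that ground-truth
classification is hard but above chance, the regime the original analysis
operates in. Participants carry a log-uniform exploration-speed factor in
[0.8, 1.25] that rescales the frequency axis, plus rating noise. Recordings
are envelope-shaped Gaussian noise with (i) a soft tanh saturation at 2.5×
the texture RMS, standing in for sensor range and contact-mechanics
compression of rare extreme excursions — without it the global min/max
normalization is dominated by Gaussian tails and typical amplitudes shrink
to a tenth of the unit interval; (ii) sub-10 Hz hand-movement drift; and
(iii) broadband noise above 800 Hz. The latter two exist so the band-pass
stage has real work to do.

Ratings derive from the same spectral structure the autoencoder sees:
descriptor ratings are a fixed linear map of five coarse envelope
attributes (log power, centroid, spread, low- and mid-band fractions) plus
participant noise; category-similarity ratings follow the correlation
between 30 Hz-smoothed envelopes (perceived similarity tracks coarse
spectral proximity, not line-by-line overlap of narrow peaks) plus a bonus
on the true category, so noiseless ratings always recover the ground truth
while noisy confusions land on spectrally similar categories. A confusion
probability replaces a participant's similarity vector with uniform noise.

What the generator does **not** model: biomechanical contact dynamics,
accelerometer noise spectra, discrete rating scales, or any dependence of
exploration behavior on the material. Passing tests on this data show the
pipeline computes the intended quantities and preserves the intended
orderings; they do not show that real vibratory textures are this
compressible or this cleanly category-structured.

## Preprocessing choices

A 4th-order Butterworth band-pass (10–800 Hz) applied forward–backward
(zero phase, ~48 dB/octave effective roll-off) filters whole recordings
*before* segmentation — per-window filtering would be dominated by edge
transients. Segmentation tiles recordings into non-overlapping 80 ms
windows. Normalization uses one global min/max from the training set (not
per segment, which would erase amplitude differences between materials);
later data is mapped with the same constants and clipped. The train/test
split is random at the segment level with floor(0.95·N) training segments.

## Problem sizes in the test suite

The original training regime (~105k segments × 50 epochs ≈ 41k Adam steps)
is far beyond what a single CPU can do inside a test run, so the suite
works at deliberately small scales. The compression-comparison test uses a
study of 7×5 materials, one participant, 0.8 s recordings (~350 segments)
trained for 60 epochs at batch 8 — a capacity-limited regime in which
reconstruction quality is bounded by the bottleneck rather than by
optimization time, which is precisely the axis the efficient-coding
comparison probes. Directional assertions there average two training seeds
and carry sampling tolerances fixed in the test (0.02 on R², 0.05 on
distance-matrix correlations, 5 percentage points on accuracies). The
bootstrap-null check runs 1000 permutations in the suite and 5000 in
`scripts/acceptance.py`.

## Numerical notes and edge cases

- Constant rating slices (zero SD) and constant training segment sets are
  errors; constant *input* segments are excluded from reconstruction R²
  with a warning, while a constant reconstruction of a varying segment
  scores r = 0.
- Argmax/majority ties break deterministically to the lowest category
  index and are logged.
- k-means on tuning summaries flags an all-equal input as degenerate
  instead of clustering it; degenerate (zero-response) latent dimensions
  are excluded from clustering.
- Codes are float32 end to end; two identical segments encoded in one
  batch can differ by ~1 ulp through BLAS column blocking, so exactness
  assertions use tolerances of 1e-6.
- t-SNE is a visualization aid only; no analysis consumes its coordinates
  (its fidelity is reported as the correlation between 2-D and k-D
  centroid distances).

## Known limitations

- The numpy trainer is faithful but slow; paper-scale training runs are
  hours, not minutes, on one CPU. The pipeline's defaults mirror the
  canonical study dimensions regardless — scale down via the configuration
  for exploratory runs.
- In heavily undertrained regimes the latent PCA can collapse to one or
  two effective components; downstream classification is then unstable.
  The test-suite configurations avoid that regime; user configurations
  with large bottlenecks and few gradient steps may not.
- The perceptual distance matrix is only defined for materials with
  non-constant descriptor profiles; degenerate materials are dropped with
  a warning.
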