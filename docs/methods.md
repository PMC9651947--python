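# Methods

`glomcode` re-creates, on synthetic ground-truth data, the analysis chain of
a population-imaging study of *Drosophila* visual projection neurons (VPNs):
how a heterogeneously tuned set of optic glomeruli encodes local visual
features, how a shared trial-to-trial gain shapes that code, and how
locomotor and visual self-motion signals modulate it. Every quantitative
stage has a generator whose injected structure the analysis must recover, so
the whole pipeline is testable without imaging data. This note documents the
models, the parameters that matter, the numerical choices, and what passing
tests do and do not establish.

## Ideal-observer spot discriminability

A dark spot (diameter 15°, intensity 0, speed 100°/s) sweeps through a hard
circular receptive field (RF, default 30°, exceeding the spot as is typical
of small-object-detecting lobula columnar cells) over a panoramic background
that rotates azimuthally at a constant speed, emulating body rotation. Per
frame we record **local luminance** (mean pixel intensity in the RF) and
**local spatial contrast** (variance of RF pixel intensities divided by
their mean). Discriminability between spot-present and spot-absent
conditions is

    d' = (mean_present − mean_absent) / sqrt((var_present + var_absent) / 2)

with moments taken over the frames whose spot centre lies inside the RF
disc; luminance d' is sign-inverted because the dark spot lowers luminance.
Variances use the population (1/N) normalisation. When the pooled variance
is zero with a nonzero mean difference, d' is ±inf and flagged *capped*
(perfect discriminability); capped values are excluded from across-image
summaries only when every requested speed is nonzero, so a static-background
condition reports its capped/maximal value.

Geometry is equirectangular (azimuth × elevation pixel grid, no perspective
correction) because the analysis operates on image pixels, not a rendered
screen. Background rotation uses nearest-integer pixel shifts with
cylindrical wrap. Repetitions sample random initial background phases so a
sweep probes different regions of each panorama.

## Naturalistic background surrogates

Natural images are dominated by low spatial frequencies (power ∝ 1/f²). The
generator synthesises surrogates spectrally: white Gaussian noise is shaped
in the frequency domain with amplitude |f|^(slope/2) (default slope −2),
inverse-transformed with random phases, rescaled to mean 0.5 and standard
deviation 0.3, and clipped to [0, 1]. Two deliberate choices:

- **std 0.3 with clipping.** The clipped tails create saturated patches, so
  local contrast becomes spatially heterogeneous, as in photographs. A purely
  Gaussian field has statistically uniform local contrast, which would make
  the contrast channel of the discriminability task insensitive to
  background speed.
- **Low-frequency amplitude floor at 0.02 cycles/degree.** Without it, a
  handful of the lowest-frequency modes carries most of the pixel variance,
  and surrogates from different seeds are substantially correlated by
  chance. The floor spreads variance over enough modes that 20 surrogate
  images behave as an independent collection. It flattens the spectrum below
  the default fit band's useful range and biases the fitted slope by less
  than 0.1, well inside the ±0.3 recovery tolerance.

Spectra are estimated by radially binning the 2D periodogram (geometric
bins, DC excluded, so the estimate is invariant to additive constants) and
fitting a log–log line over a band (default 0.01–0.2 cyc/deg), weighting
bins by the square root of their Fourier-mode count because sparse
low-frequency bins are noisy.

Filtering uses radially symmetric transfer functions: the lowpass filter is
Gaussian with half-power at the cutoff (default 0.1 cyc/deg); the highpass
filter is its amplitude complement (1 − H_lp), so highpass + lowpass
reconstruct the input exactly before rescaling (the highpass half-power
frequency therefore sits slightly off the nominal cutoff). Filtered images
are rescaled to the input's mean and standard deviation; whitened images
flatten the amplitude spectrum (epsilon floor 1e-8, DC preserved) and are
scaled to the input's peak pixel intensity.

## Stimulus generators

- **Dot kinematograms.** `round(coherence · n_dots)` dots (half-away-from-
  zero) move along the signal direction; the rest take iid uniform
  directions. All dots share diameter (15°), speed, and intensity; initial
  positions are drawn before directions, so fields sharing a seed have
  identical frame-0 geometry at every coherence. `frame_stats` reports the
  per-frame dot count and the stimulus's intensity budget with each dot
  contributing its full disc area (overlap counted with multiplicity): this
  bookkeeping is exactly identical across coherence levels, which is the
  stimulus's defining design property. Rasterised frames composite
  overlapping dots to the darker value and can deviate slightly in mean when
  dots happen to overlap.
- **Saccade playback.** Background displacement is 0 before onset, a linear
  ramp to 70° over 200 ms (350°/s, a ballistic constant-velocity turn), and
  70° after.
- **Grating + probe.** A sinusoidal grating drifting at `speed` with spatial
  period `period` (temporal frequency = speed/period, checked against the
  frame-rate Nyquist limit) with an optional dark probe sweeping the screen
  centre.
- **Trial order** is a seeded permutation of the spec multiset (randomly
  interleaved trials).

## Population-response generator

Peak amplitude of glomerulus *g* on trial *t*:

    a[g, t] = g_t · T[g, s(t)] · exp(β_g · b_t) + ε,   ε ~ N(0, σ²)

with `g_t ~ LogNormal(0, 0.4)` (median 1, shared across glomeruli — gain is
log-normal to stay positive), `b_t` the standardised per-trial walking
amplitude, `β_g = −1` for the modulated subset (first 40% of glomeruli,
emulating the small-object-tuned subset) and 0 otherwise (exponential-
multiplicative coupling keeps gains positive), and private noise σ = 0.1
(10% of the mean tuning amplitude — chosen because the observed single-trial
covariance is dominated by the shared gain, so glomerulus-private noise must
be comparatively small). The tuning matrix T has four functional groups,
each owning a block of preferred stimuli (strong responses 0.8–1.2, weak
0.05–0.25, per-glomerulus scale 0.7–1.3 and jitter), so complete-linkage
clustering recovers the groups. Defaults: 13 glomeruli, 14 stimuli (chance
≈ 7% for the decoder), 30 trials per stimulus. Trials are rendered as
monophasic dF/F time courses via a difference-of-exponentials kernel (rise
0.1 s, decay 0.5 s — a calcium-indicator-like response spanning several
hundred ms), sampled at the 7.22 Hz imaging rate with 1.5 s pre, 3 s
stimulus, 1.5 s tail epochs. Trial behavior is a walking/stationary mixture
(gamma-distributed amplitudes, 50% walking trials).

## Walking generator

Saccade onsets follow a renewal process: inter-onset interval = 0.5 s hard
refractory + Gamma(shape 2) with scale set so the mean interval is
1/rate (default rate 0.8 Hz). The shape-2 choice puts the inter-turn-
interval mode near 1 s with a long tail, the signature of saccadic walking.
Each saccade is a 200 ms angular-velocity pulse with a fast rise (peak at
30 ms — ballistic acceleration; this also pins the 160°/s threshold crossing
within 50 ms of the true onset at the 50 Hz sampling rate) and peak speed
~N(350, 80) truncated below at 220°/s. Forward velocity consists of bouts
gated by smoothed noise on a ~2 s timescale, *independent* of saccade
timing. The ball trace carries the turning signal on rot-z attenuated by
0.3 relative to the free-walking trajectory (head-fixed turning attempts
move the ball less than free saccades turn the body) plus in-bout rotational
jitter (sd 15°/s); rot-x/rot-y scale with forward velocity, so forward and
rotational components are correlated, as on a real ball. With these scales
the Li threshold on the walking amplitude lands near 10–15°/s, between the
rest and walking modes.

## Analysis stack

- **dF/F**: (F − F0)/F0 per glomerulus per trial, F0 the mean over a
  pre-stimulus baseline window; non-positive baselines raise an error naming
  the offending glomerulus and trial.
- **Peak amplitudes**: max dF/F in a response window (stimulus + tail by
  default). Peak, not mean, is the canonical response statistic throughout.
- **Noise correlations**: Pearson correlations of peak amplitudes across
  trials within each stimulus, averaged across stimuli; zero-variance
  glomeruli are excluded from the average and logged.
- **Clustering**: complete-linkage agglomerative clustering (Euclidean) of
  tuning rows, cut at 4 groups.
- **Shared gain**: PC1 (SVD) of the trials × glomeruli matrix after
  per-glomerulus, *per-stimulus* mean removal (so the component reflects
  trial-to-trial variation, not tuning), sign-oriented so loadings have
  positive mean. With a single repeated probe stimulus and ≤25% private
  noise, the score recovers the injected gain at r > 0.9; with many stimuli
  and heterogeneous tuning, mean removal alone leaves stimulus-dependent
  loading directions and recovery degrades — the probe paradigm is the
  intended use for gain tracking.
- **Behavior correlation**: per-glomerulus Spearman ρ between within-
  stimulus mean-normalised amplitudes and walking amplitude; across flies, a
  one-sample, one-sided t-test (ρ < 0) per glomerulus, Holm step-down
  Bonferroni corrected at α = 0.05 (delegated to statsmodels; the hand-
  stepped procedure is the test oracle).
- **Decoding**: multinomial logistic regression (L2, C = 1, lbfgs) on peak
  amplitudes; per iteration a stratified 90/10 split, z-scoring fit on the
  training fold only (avoiding leakage; the split is stratified per class so
  every class appears in the test fold), 100 iterations averaged.
- **Trial shuffle control**: independent within-stimulus permutation per
  glomerulus — per-stimulus marginals exactly preserved, cross-glomerulus
  correlations destroyed in expectation.
- **Gain curves**: gain is the ratio of condition means of peak amplitudes
  (ratio-of-means is stabler than mean-of-ratios when single-trial
  amplitudes are small). Surround speed tuning normalises to the static-
  background condition; walking curves bin per-stimulus-normalised trial
  gains by walking amplitude (bins under 5 trials dropped and logged);
  saccade-timing curves normalise to trials with |offset| ≥ 2 s (gain has
  recovered by such lags).
- **Independence test**: predicted joint gain = product of the two marginal
  gains; deviation = observed − predicted, with a seeded trial bootstrap
  (1000 replicates, resampling within each condition cell, percentile 95%
  CI). Deviation CIs covering zero indicate multiplicative (independent)
  combination.
- **Li threshold**: direct minimisation of Li's cross-entropy criterion
  (−Σ_below x·log μ_below − Σ_above x·log μ_above) over midpoints of
  consecutive sorted unique values — the exhaustive search over all distinct
  partitions, chosen over the classic fixed-point iteration because the
  iteration can stall in local minima on multimodal amplitude histograms.
  The criterion is scale-equivariant, so thresholds scale with the data.
- **Saccade detection**: contiguous |angular velocity| ≥ 160°/s excursions,
  gaps under 0.1 s merged, onset at the first supra-threshold sample.
- **Saccade-cycle KS test**: peri- vs intersaccade forward velocities are
  compared after decimating each set to one sample per 2 s, because
  locomotor velocity is autocorrelated on the bout timescale and the KS test
  assumes independent samples.

## Pipeline and provenance

A single global seed expands into per-stage child seeds through
`numpy.random.SeedSequence(seed).spawn`, so stages rerun in isolation.
Every written artifact gets a `.provenance.json` sidecar with the config
hash and seeds. Trial tensors round-trip through a versioned HDF5 layout
(`/responses`, `/labels`, optional `/behavior` and `/truth` groups; absent
optional groups stay absent).

## Problem sizes

The shipped tests and the reproduction script use: 20 surrogate images at
96×512 px with 6 background speeds and 2 phase repetitions; 13 glomeruli ×
14 stimuli × 30 trials for decoding (100 train/test iterations); 100-trial
probe sessions for gain extraction; cohorts of 8 simulated flies for the
behavior-correlation test; 300 s walking sessions (~240 saccades); 50
trials per condition cell with 1000 bootstrap replicates for the
independence test. These sizes put every Monte-Carlo check comfortably past
its decision threshold while keeping a full run in minutes on one core.

## What the generator does and does not emulate

The generator reproduces the *statistical structure* the analyses assume:
group-structured tuning, a dominant shared multiplicative gain, selective
negative behavior coupling, saccadic walking with a refractory period, and
1/f² image statistics. It does not emulate calcium-indicator nonlinearity
or kinetics beyond a fixed kernel, imaging noise with temporal structure,
motion artifacts, cross-fly variability in tuning (each simulated fly draws
a new tuning matrix), translation-induced optic flow, or the real geometry
of a projector screen. Passing tests therefore demonstrate that the
implementations are correct and that the recovery logic works under the
assumed model — not that the model captures every property of in-vivo
recordings. Two quantities reported for real data in this literature (the
ρ ≈ −0.23 gain-behavior rank correlation and the r = 0.80 correlation
between visual and behavioral gain across glomeruli) depend on the real
per-glomerulus coupling profile; the synthetic pipeline reproduces their
signs and mechanisms but not their specific magnitudes.

## Known limitations

- Background rotation uses integer-pixel shifts; speeds that move the scene
  a non-integer number of pixels per frame are quantised (at the default
  0.7°/px this is at most half a pixel per frame).
- The decoder's regularisation strength is fixed (C = 1) rather than
  cross-validated; accuracy comparisons (intact vs shuffled) share the same
  setting, so the control is internally consistent.
- `behavior_correlation` assumes the behavior vector varies; constant
  behavior raises rather than returning NaN.
- The dot-field elevation wraps (torus topology) rather than reflecting at
  the screen edge; this keeps dot count exactly constant at the cost of a
  physically odd reappearance for vertically moving dots.
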