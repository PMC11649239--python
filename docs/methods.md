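# Methods

This note documents the models, numerical choices, and limitations of
the package. Symbols follow the README.

## Segmentation

Sound events are detected on an amplitude trace: the short-time Fourier
transform (Hann window, `nperseg=512`, `noverlap=256` at 125 kHz,
natural-log modulus clamped to `[-8, -7.25]`, rows restricted to
500–62,500 Hz) is summed per column, normalized, and Gaussian-smoothed
with σ = 0.007 s × frame-rate frames (≈3.4 frames at 488 frames/s).

**Trace units.** The integer thresholds (th₁=2, th₂=5, th₃=2) are
meaningful only relative to a reference level, which recordings do not
share. The trace is therefore centered by its median and scaled by its
median absolute deviation over each processing chunk, making the
thresholds robust z-scores; `normalize_trace=False` restores raw
column sums.

**State machine.** Onset where the trace first exceeds th₃; offset at
the first subsequent strict local minimum (3-frame neighborhood,
plateaus resolve to their last frame) below th₂, or the first frame
below th₁, whichever comes first. After an offset, a new onset requires
crossing th₂ while the trace has stayed at or above th₃, or crossing
th₃ after dipping below it. Events shorter than 0.03 s or longer than
0.3 s are discarded (not truncated): the duration bounds act as
validity filters. An event still open at the end of a trace is dropped.

**Chunking.** Recordings are processed in 300 s chunks overlapping by
2×max_dur plus a smoothing margin; each chunk owns events whose onset
falls in its non-overlapped core, so boundary-straddling events are
detected intact exactly once.

**Known bias.** Detected boundaries are broadened by roughly one
analysis window plus twice the smoothing timescale (≈12 ms total at the
default parameters): onsets are recovered within ~7 ms of ground truth
on rendered fixtures, while durations carry a near-constant positive
offset whose spread is ~±3 ms. Tests therefore check onsets raw and
durations after removing the constant broadening. A second realistic
effect: syllables whose trace plateau sits below th₂ (weak, strongly
amplitude-modulated, or high-frequency syllables whose harmonics fall
outside the band) can fragment at interior local minima — the
interactive threshold tuning in field deployments exists precisely to
avoid this regime.

**Non-monotonicity caveat.** Raising th₃ does not *strictly* reduce
onset counts: an offset landing between two th₃ levels switches the
re-onset requirement between th₂ and th₃ and can occasionally create an
extra event. On smoothed random traces the violation rate is below 1%;
the property test bounds it rather than asserting strict monotonicity.

## Vocal screening

Spectral flatness is the per-frame geometric mean over arithmetic mean
of the power spectrum (Hann window, `n_fft=256`, `hop=128`, no
centering, power 2.0), averaged across frames; zero-energy frames are
excluded and an all-zero segment is defined as flatness 1 with a flag.
Events with flatness strictly below 0.3 are classified vocal. Note that
ungated white noise converges to per-frame flatness exp(−γ) ≈ 0.56 (the
periodogram ordinates are exponential), not 1 — still far above the
threshold, so the screen separates cleanly. Threshold calibration
estimates the false-positive vocalization rate by repeatedly sampling
100 events below each candidate threshold
(grid 0.1–0.4, 10 repetitions) and scoring them against labels; the
study's manual grid inspection becomes label-driven scoring on
synthetic truth.

## Embedding

Vocal segments become 128×128 images: log-spectrogram clamped to
`[-8, -5]`, band 500–62,500 Hz interpolated to 128 linear rows, time
axis stretched to 128 frames (`time_stretch=True`), rescaled to [0, 1].

The VAE uses fully-connected mirrored encoder/decoder stacks
(default hidden sizes 256→128) written directly in numpy with manual
backpropagation and Adam. The observation model is spherical Gaussian
with precision 40, so the per-sample loss is
`0.5·40·‖x−x̂‖² + KL(q(z|x)‖N(0,I))`; 32 latent dimensions; training
for 50 epochs by default (desk-scale runs use fewer). The downstream
statistics consume posterior-mean latents, not a specific architecture;
a convolutional encoder would sharpen reconstructions but does not
change the statistical contracts, which is why the dependency-free
dense network was chosen. Reconstruction error is tracked
deterministically (posterior-mean decode) per epoch.

Latent selection sorts dimensions by variance of the posterior means
and keeps the smallest prefix reaching 99.5% cumulative variance. The
study's manual removal of residual false positives via an interactive
embedding viewer is replaced by a flatness re-screen plus a Mahalanobis
outlier flag (diagonal covariance, distance > 6); flagged items are
excluded from statistics, never deleted.

## Cohort mixture

The hierarchical mixture (README) is fit two ways sharing one E-step:

- `em_map`: MAP expectation-maximization. All M-step updates are
  closed-form; the half-normal scale prior gives the per-dimension
  stationarity condition σ⁴/s² + Nσ² − S = 0, a quadratic in σ²
  (s = 3 is the prior scale, N the responsibility mass, S the weighted
  squared deviation). The MAP objective is monitored and is
  non-decreasing.
- `variational`: structured variational EM — q(z) categorical and
  q(θᵢ) Dirichlet in closed form (responsibilities use E[log θ] via
  digamma), with (β, σ) point-estimated at their MAP. Reported usages
  are Dirichlet posterior means. A fully factorized q over (β, σ) as
  well would add conjugacy workarounds for the half-normal prior
  without changing what downstream consumers read (point parameters
  and usage expectations), so the structured family was preferred.

Initialization is k-means (best of `restarts=5` seeds); scales are
floored at 10⁻³ to prevent collapse. Cluster identifiability is up to
permutation; evaluation matches components by the Hungarian algorithm
on mean distances.

K selection holds out 25% of points, fits each K on the remainder, and
takes the knee of the held-out log-likelihood curve — the interior grid
point with the most negative discrete second difference (maximum
curvature of an increasing, saturating curve). Grids shorter than 3
fall back to the argmax. The full curve is always returned so a user
can override; with overlapping components the likelihood knee merges
clusters and under-reports K, which is visible (and expected) in the
desk-scale analysis.

## Repertoire comparison

MMD² uses the biased V-statistic with an RBF kernel so that identical
multisets give exactly 0 and the estimate is nonnegative; permutation
calibration is unaffected by the bias. The bandwidth is the median
pairwise distance of the pooled sample (subsampled to ≤2,000 points for
tractability), recomputed per comparison and overridable. The
permutation test's observed statistic is the mean MMD² over
`⌊min(|X|,|Y|)/batch⌋` (≥1) batches of `batch=1000` points drawn
without replacement per side; the null permutes pooled labels and
recomputes the same batched statistic; the add-one p-value
`(1+#{null≥obs})/(1+n_perm)` never returns 0. When the pooled sample
fits (≤12,000 points), the kernel matrix is computed once (float32) and
every batched statistic is a submatrix mean, which makes the
5,000-per-family, 1,000-permutation configuration a minutes-long run.
Per-batch MMD² values are also returned as the histogram analog.

MDS is classical Torgerson double-centering (exact for
Euclidean-realizable inputs); daily-usage PCA centers rows and reports
explained-variance fractions.

## Temporal and transition structure

Intervals are onset-to-onset; bouts are maximal runs with consecutive
onset-to-onset gaps strictly below 2 s and at least 5 members (a gap of
exactly 2 s breaks a run). Diurnal histograms bin onsets by clock hour
with a configurable recording-start anchor (default hour 0).

Transition analysis concatenates each cohort's cluster labels
chronologically into one sequence (optionally broken at gaps > 2 s for
sensitivity analysis) and tallies bigrams; rows with no outgoing counts
are excluded from testing. The null shuffles the full sequence
uniformly 1,000 times — preserving 1-gram usage exactly — and each
transition is tested either by a two-sided one-sample t-test of the
null sample against the observed value (flagging only observed > null
mean, "above chance") or by the add-one empirical upper-tail p
(the recommended default: distribution-free and one-sided by
construction). Benjamini–Hochberg runs across all K² tested cells at
α=0.05. The bigram graph keeps pair probabilities strictly above 0.001
as edge weights; node weight is total incident pair probability.

## Acoustic features

Features are frame-wise on a Hann/512/256 power spectrum (65–62,500 Hz
band), collapsed by the median across frames — except flatness, which
uses its own 256/128 transform and the mean across frames so the screen
and the feature table share one definition. Pitch per frame: the
linear autocorrelation (via zero-padded power spectrum,
sinc-interpolated 4× for sub-sample lag resolution) is scanned for
local maxima in the pitch band; the shortest lag within 90% of the best
peak is taken (octave-error guard) and the frequency is refined by the
parabolically interpolated spectral peak near that estimate. Goodness
of pitch is the normalized autocorrelation peak height. Amplitude is
10·log₁₀ of frame power; entropy is Wiener entropy on the log scale
(≤0); frequency modulation is the median absolute frame-to-frame
spectral-centroid slope in Hz/s. Start/stop frequencies are the median
of the first and last ⌊n/3⌋ frames of the pitch track (degenerate
tracks <3 frames return the overall median, flagged). These are
independent implementations following the conventions of the standard
song-analysis feature suites; parity with any particular binary is not
a goal — invariants (polarity, scaling, fundamental-vs-harmonic,
chirp direction) are.

## Synthetic generator

What it emulates: a shared repertoire of K linear-FM harmonic-stack
syllables (tapered-cosine envelopes with 25% raised-cosine edges, so
analytic start/end frequencies and durations hold); per-family usage
simplexes and first-order Markov label sequences with dominant
self-transitions; bout-structured emission — hourly counts
Poisson-distributed on a 24-bin diurnal profile, grouped into bouts of
shifted-Poisson size (min 5) with truncated-lognormal gaps on (0, 2) s —
and band-limited white-noise distractors as a separate Poisson stream.
Latents can bypass audio entirely, drawn from the mixture's own
generative model.

Default study conditions (3 families, bimodal diurnal profile peaking
at 400 vocalizations/hour morning and afternoon, Dirichlet(2) usage
draws, self-transition 0.6, bouts of mean size 8 with 0.5 s gaps,
60 noise bursts/hour) are one fixed choice of plausible values: the
source study estimates, but does not publish, per-family ground-truth
usages, so synthetic specs are free parameters rather than calibration
targets.

What it does not emulate: overlapping vocalizers and their attribution,
reverberation and microphone-array geometry, acoustic realism of real
gerbil calls, or non-stationary repertoire drift. Passing tests
demonstrate the statistical machinery is correct on data matching the
model's assumptions; they do not certify segmentation accuracy on field
recordings, where threshold tuning remains empirical.

## Validation scale

The test suite and the acceptance script run on one CPU in minutes:
recovery designs use 2,000 points per cohort, calibration uses 200
permutation-test repetitions at n=60 per side with 79 permutations, and
the family-discrimination study uses 5,000 latents per family with
1,000 permutations (300 in the test suite). These sizes were chosen so
Monte-Carlo error is comfortably inside every asserted tolerance.

## Interfaces

The library is the interface: `analysis/` scripts (argparse, `--seed`,
`--out`) are thin drivers over `vocalscape.*` and double as the
command-line entry points; no console script is installed. All
randomness flows through explicit integer seeds; identical seeds give
identical outputs (bitwise, up to BLAS summation order in the VAE).
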