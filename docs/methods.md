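# Methods

`gazetex` implements an eye-movement biometric pipeline: raw gaze
scanpaths are rendered as grayscale trajectory images, a Gabor-wavelet
filter bank turns each image into a 176-dimensional texture descriptor,
and subjects are verified/identified with an LDA + one-vs-one SVM
matcher evaluated by EER and rank-k identification rates.  Because no
public gaze corpus with the required task and session structure exists,
the package ships a first-class synthetic scanpath simulator; all tests
and the acceptance script run on simulated cohorts.

## The task and its simulation

The stimulus is a number-search question: a 7-digit target, four
comparison numbers of lengths 2-5 shown right-aligned, and a row of five
answer options.  The correct answer is the length of the longest
comparison matching the target's suffix (`longest_suffix_match`), so a
random clicker scores 1/5.  Generated layouts place matching suffixes at
every length up to the answer and break longer comparisons in their
leading digit, guaranteeing the answer rule by construction.  Four
answer kinds (lengths 2-5) are balanced across a session; the option row
still carries five rectangles (the four lengths plus a distractor) so
chance accuracy stays at 20%.

Each synthetic subject is an `OculomotorProfile`:

| parameter | default | role |
|---|---|---|
| fixation duration Gamma(shape, scale) | (6, 0.04 s) | ~240 ms mean fixations |
| saccade main sequence (intercept, slope) | 21 ms, 2.2 ms/deg | amplitude-duration law |
| drift SD | 0.10 deg | within-fixation Ornstein-Uhlenbeck drift (100 ms time constant) |
| tremor SD | 0.05 deg | white sample-level noise |
| saccade curvature | 0 ± 0.2 | signed lateral bulge of the saccade path, as a fraction of amplitude |
| landing bias (x, y) | 0 ± 0.7 deg | systematic fixation-landing offset from region centres |
| scan bias | log-normal weights, log-SD 1.5 | habitual region-visit order |
| revisit probability | logit-normal around 0.3, logit-SD 2.5 | stable target re-checking habit |

Population values are typical adult visual-search phenomenology;
between-subject idiosyncrasy is log-normal spread around the scale
parameters (and zero-mean Gaussian spread for the signed geometric
ones) whose SD scales with a single `separation` knob (0 = clones,
1 = the default cohort used in all benchmarks).  Saccades follow
minimum-jerk paths (peak velocity = 1.875 A/D, strictly increasing in
amplitude under the linear main sequence) with the profile's
idiosyncratic curvature — saccade trajectories curve subject-
specifically, and because line-rendered images are blind to *when* a
pixel was traversed, it is geometric signatures like curvature and
landing bias, not speed, that carry identity into the texture features.
Fixations land at region centres plus the subject's systematic bias and
drift-scaled scatter, samples drop out independently at 3.5% (matching
the ~96.5% validity typical of remote 300 Hz trackers), and a second
session is emulated by multiplicative log-normal jitter of the profile
(`aging_sd`, "template aging").

Scanning habits are deliberately stereotyped: at separation 1 a subject
has a stable habitual comparison-visit order (occasionally swapped via
Gumbel noise) and a re-checking probability pushed toward near-always
or near-never.  Human scanning strategies are idiosyncratic and stable
across sessions, and this stability is precisely what lets a
*per-trajectory* image carry identity; with order re-randomized per
question, within-subject image variance swamps every other cue.  The
separation knob is calibrated so that "1" means a cohort the default
texture pipeline can separate well — the scale on which the knob's
contract (identical subjects at 0, clearly separable subjects at 1) is
defined.

What the simulator does *not* emulate: cognitive search strategy beyond
biased region orders, blinks and tracker-loss bursts (dropout is i.i.d.),
pupil dynamics, calibration drift, and head movement.  Passing tests
therefore demonstrate that the pipeline recovers identity signal of the
kind the oculomotor literature describes, not that it reaches any
particular accuracy on human data.

## Rendering

The full 1920x1080 screen is mapped anisotropically onto the square
N x N canvas (N = 64/128/256; the package default is 64, the smallest
size the original design considers, which keeps desk-scale experiments
fast).  Consecutive valid samples are joined by 1-px Bresenham lines;
gaps across invalid samples are not bridged.  Intensity accumulates by
0.25 per traversal and clips at 1, giving multi-level gray without
anti-aliasing — integer rasterization keeps rendering exactly
reproducible and oracle-testable.  Off-screen samples (possible after
noise injection, which deliberately does not clamp) are clipped out at
render time.

## Texture features

The bank holds 88 kernels: 11 scales, f_i = 0.5/sqrt(2)^(i-1)
cycles/pixel, and 8 orientations theta_j = pi(j-1)/8.  The half-octave
ladder is chosen so the lowest frequency is exactly 1/64 = 4/256 — the
classical lower design bound f >= 4/N for the largest 256-px images.
Each kernel is G(x,y) = (f^2/(pi*gamma*eta)) exp(-(x'^2 +
gamma^2 y'^2)/(2 sigma^2)) exp(i 2 pi f x') with sigma = 1/f, gamma = 1,
eta = 2, phi = 0.  This parameterization places eta only in the
prefactor; the conventional form with envelope widths gamma/f and eta/f
is available as `exponent_variant="standard"`, but the default is kept
as above for fidelity to the published variant.

Kernels are truncated at 3 sigma (up to 385 px wide at f = 1/64) and
applied by zero-padded FFT convolution — linear, not circular, because
the largest kernels exceed the image.  The feature vector interleaves
the mean and the *population* standard deviation of each magnitude
response, scale-major: 176 values.  Features are homogeneous of degree
1 in image intensity and deterministic bit-for-bit.

## Recognition

A probe is the mean of NoET per-trajectory feature vectors of one
subject (within-probe sampling without replacement; probes may overlap
when n_probes x NoET exceeds the pool, mirroring the ambiguity of
"non-replacement sampling" at scale — strict global non-replacement
would make the standard 20-training-probe protocol infeasible for
NoET = 16).  Averaging shrinks within-subject variance as sigma^2/n,
which is why performance improves with NoET.

Training probes are z-scored; the intrinsic dimension is estimated with
the Levina-Bickel maximum-likelihood estimator averaged over
neighbourhood sizes 6-12, and LDA projects to min(round(d_hat), k-1)
dimensions.  The estimate is recomputed per dataset rather than fixed,
since it is a property of the data at hand.  Singular within-class
scatter (common when probes outnumber dimensions only slightly) falls
back to shrinkage LDA with a warning.

Matching uses one-vs-one linear SVMs (C = 1) in the LDA space — after
LDA the classes are near-linearly separable and an unstated kernel
choice defaults most defensibly to linear; RBF is available via config.
Identification counts votes over all k(k-1)/2 classifiers (ties broken
by summed margins, then subject id).  Verification scores a claim by
the mean signed margin of the k-1 classifiers involving the claimed
subject — a continuous generalization of vote counting that gives DET
curves fine-grained thresholds; the discrete vote fraction is also
reported.

## Evaluation, normalization, fusion

EER is read off the threshold sweep over the pooled score set with
linear interpolation at the FPR/FNR sign change; the implementation is
tested against exhaustive enumeration on every score set up to 10^3
scores.  CMC ranks use the optimistic tie policy (rank = 1 + number of
strictly greater scores); the pessimistic variant is available.  Score
fusion tanh-normalizes each matcher, s' = tanh(0.01 (s - mu)/sigma) + 1,
and sums.  mu and sigma are estimated from each matcher's
*training-phase* score pool to avoid test-set leakage (the estimation
pool is not prescribed by the published method; genuine-only estimation
is a selectable alternative).  Being strictly monotone, the
normalization provably leaves single-matcher EER and CMC unchanged —
asserted numerically in the tests.

## Baselines

Three comparison matchers are deliberately simplified re-implementations:

* **LVD** — 27-bin local-velocity-direction histograms over sliding
  windows, 16-Gaussian diagonal-covariance UBM, mean-only MAP adaptation
  with relevance factor 16, log-likelihood-ratio scoring.  The original
  method's full training schedule is out of scope.
* **FDM** — duration-weighted fixation density maps (default 64x64 grid,
  ~1 deg Gaussian smoothing; both unstated in the source and exposed as
  config) compared by histogram intersection, Pearson correlation, or
  symmetrised KL with a 1e-12 floor, all oriented so larger = more
  similar.
* **CEM** — 11 fixation/saccade statistics, classified through the same
  LDA + SVM pipeline as the texture features rather than the original
  weighted-comparison scheme; a uniform classifier isolates feature
  quality.  Flagged "simplified" wherever reported.

Events come from I-VT segmentation: central-difference angular
velocities, 30 deg/s threshold, 60 ms minimum fixation (community
defaults; no detector is prescribed by the published method).  Fixation
runs shorter than the minimum are relabelled as saccade samples so
events always partition the recording.

## Numerical and protocol choices

* Visual angle to pixels: 2 d tan(deg/2) in mm times the horizontal
  pixel density; within 0.5% of the small-angle form below 3 deg.
* Temporal degradation is pure decimation (every k-th sample, no
  anti-alias filter) — the conservative reading of "down-sampling";
  spatial degradation adds unclamped i.i.d. Gaussian pixel noise of the
  stated angular SD to valid samples only.
* The ST protocol splits trial-1 recordings 70/30 per subject; LT trains
  on trial 1 and tests on trial 2; headline numbers average 10 random
  partitions.
* All randomness flows through integer seeds (numpy `SeedSequence`
  namespacing); identical configs reproduce outputs bit for bit.
* Gaze CSVs are written at repr precision and parsed with round-trip
  float parsing, so I/O is lossless.

## Benchmark scale

The separability benchmark behind the acceptance checks uses 10
subjects at separation 1, one 56-question session each, 64-px images,
20 training / 6 test probes per subject and NoET in {2, 4, 8, 16} over
10 random partitions.  56 questions is the smallest session for which
the 30% test pool still supports NoET = 16 probes with a margin; 10
subjects keeps a single-core run in the minutes range while leaving the
chance Rank-1 level at 10%, far below the >= 80% the texture pipeline is
required to reach.

## Known limitations

* The published 58-subject human results (e.g. 0.89% EER, 96.44% Rank-1
  short-term) are not reproducible here: that dataset is private, and
  the synthetic cohort is both smaller and cleaner.  Only structural,
  analytic and qualitative properties are asserted.
* Published relative-loss percentages were evidently computed before
  table rounding; recomputation from printed cells differs by up to one
  unit in the last digit (42.49 vs 42.50), and the package reports the
  recomputed value.
* The gray-image (GI) control — plain mean/SD of the trajectory image —
  is near chance on the synthetic cohort as it is on human data, but the
  margin depends on how strongly trace density varies between simulated
  subjects.
* LDA + linear SVM assumes probe classes are unimodal in feature space;
  heavily multimodal subjects (e.g. mixed strategies) would need the RBF
  configuration.
* On desk-scale simulated cohorts the LVD matcher sits at chance: its
  velocity-direction histograms need far more material per subject than
  a small session provides, and with a shared stimulus template the
  simulated subjects' direction statistics differ only subtly.  FDM, by
  contrast, separates simulated subjects well (their landing biases and
  habitual scan orders shift the density maps directly).
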