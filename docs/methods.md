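# Methods

`neurogaze` implements a resting-state EEG analysis that relates three
spontaneous oscillatory features — relative band power, the individual alpha
frequency (IAF), and long-range temporal correlations (LRTCs) of the
alpha-band amplitude envelope — to visual-exploration phenotypes: "static"
viewers (long fixations, PC1 > 1) versus "dynamic" viewers (short fixations,
PC1 < −1), with PC1 scores treated as given per subject. Because no raw data
ship with the package, a synthetic-cohort generator with full ground truth is
a first-class component: every estimator in the pipeline can be validated
against the parameters that generated its input.

## The analysis chain

**Preprocessing** (`neurogaze.preprocess`). Zero-phase Kaiser-windowed sinc
FIR band-pass (0.5–47 Hz; high-pass transition bandwidth 1 Hz, order 1812 at
500 Hz; low-pass transition bandwidth 2 Hz, order 908 — orders are rescaled
to the recording rate so the transition bandwidths in Hz are preserved),
polyphase resampling to 250 Hz, automated bad-channel detection, spherical-
spline interpolation of flagged channels (Perrin-type, stiffness m=4, 50
Legendre terms, Tikhonov regularization 1e−5), and average re-referencing.
A channel is bad when (i) its end-of-session impedance exceeds 100 kΩ, OR
(ii) its maximum Pearson correlation with montage neighbours within a 25°
angular radius falls below 0.75, OR at least two of: (iii) z > 4 for the RMS
deviation of its log-spectrum from the channel-mean log-spectrum, (iv) z > 4
for its negative mean Gaussian log-likelihood under a fit to all channels'
pooled amplitudes, (v) z > 7 for its sample kurtosis. The "surrounding
channels" neighbourhood and the exact forms of tests (iii)–(v) are
implementation choices in the spirit of common EEG practice; the thresholds
are the conventional printed values and are configurable. Component-based
artifact removal (ICA classification, subspace reconstruction) is
intentionally out of scope; `artifact_hook` is a no-op insertion point.

**Spectra** (`neurogaze.spectral`). Welch PSD with Hamming taper, 50%
overlap and segment length fs/resolution (0.5 Hz grid at 250 Hz), density
scaling in µV²/Hz. Relative band power is the trapezoidal band integral
divided by the trapezoidal integral over 1–45 Hz (the outermost analysed
band edges; "whole spectrum" would otherwise be ambiguous under the 0.5–47 Hz
filter). Bands: delta 1–3, theta 3.5–7, alpha 7.5–12, beta 12.5–32, gamma
32.5–45 Hz. The IAF is the argmax of the occipital-average eyes-closed PSD
on 7–13 Hz, accepted only if it is a strict local maximum away from the
search boundaries; flagged subjects are excluded rather than guessed
(replacing manual spectrum vetting with an algorithmic rule).

**Temporal dynamics** (`neurogaze.dynamics`). The alpha envelope is the
analytic-signal magnitude of the order-66 zero-phase FIR band-passed signal
(7.5–12 Hz); half the filter order is trimmed per edge before DFA. DFA uses
the cumulative-sum profile, 15 log-spaced window lengths from 1 s to 20 s,
50% window overlap, per-window order-1 least-squares detrending, F(s) = RMS
residual pooled over windows, and an OLS fit of log F(s) on log s. These
DFA parameters follow common practice for EEG envelope LRTC and are
config-exposed; the envelope is block-averaged to 25 Hz before DFA (it is
band-limited far below the 1-s minimum fit scale, so the exponent is
unchanged while whole-cohort runs get ~50× cheaper). Fixations are extracted
from gaze velocity by a 30 deg/s threshold with 50 ms minimum fixation and
10 ms minimum saccade duration (short runs merged into the surrounding
state); the behavioural exponent is the DFA exponent of the binary
fixation(0)/saccade(1) series at the gaze rate.

**Group statistics** (`neurogaze.stats`). Per-band global (non-face channel
mean) relative power is compared between groups with a one-way ANOVA whose
p-value comes from 1000 label permutations, Benjamini–Hochberg-corrected
across the five-band family within each condition. Scalp maps are tested
with cluster-based permutation tests: per-channel two-sample pooled-variance
t (or Spearman r against a covariate), two-tailed forming threshold at
cluster alpha 0.01, clusters = sign-consistent connected components in the
montage neighbour graph with face channels excluded, observed statistic =
cluster size (channel count), null = maximum cluster size over 1000 label
(or covariate) permutations, significant at p < 0.05. All permutation
p-values use the add-one estimator (1 + #{T_perm ≥ T_obs})/(n_perm + 1) and
are deterministic given the seed. Spearman correlations report the
t-approximation p and a Fisher-transform 95% CI.

**Orchestration** (`neurogaze.pipeline`). `run_study` chains
simulate → preprocess → spectra/IAF/DFA → statistics and emits a
machine-readable report in which every p-value records its seed, permutation
count and family. One deliberate deviation from the gated workflow that
inspired it: scalp cluster tests are run for **all** five bands in both
conditions rather than only for bands whose global ANOVA survives FDR —
conditioning a spatial test on a channel-mean gate can hide focal effects;
the band-level ANOVA results are reported alongside. `check_directions`
evaluates the headline sign pattern (PC1 vs occipital alpha cluster power
positive; vs frontal beta, occipital gamma and IAF negative; eyes-open
brain-vs-behaviour DFA correlation positive). Because relative-power
normalization necessarily produces compensatory opposite-sign clusters in
other regions (e.g. a frontal gamma cluster induced by the beta
denominator), each direction is judged on the significant cluster covering
most of its home region. A wrong-sign association counts as a failure only
when it is itself nominally significant; a wrong-sign noise estimate, or a
missing cluster (null cohort), is "inconclusive".

## The synthetic cohort

No generative model for resting EEG or fixation sequences is established in
this literature; the constructions below are explicit stand-ins chosen so
that the LRTC ground truth is analytic — the DFA exponent of fractional
Gaussian noise (fGn) equals its Hurst exponent H — and so that every
reported group effect is planted with a known direction and size.

**Phenotypes.** 19 static and 21 dynamic viewers. Each subject draws a
latent trait that generates both the PC1 score (|PC1| > 1 by construction)
and, with coupling 0.5, the generative parameters, so PC1 correlates
positively with eyes-open alpha gain and both Hurst exponents and negatively
with IAF, beta and gamma gains across the cohort. Group medians/means:
IAF 9.5 vs 10.5 Hz (sd 0.6, clipped to 8.6–11.0 Hz — wider tails would let
the fixed 7.5–12 Hz band truncate the ±1 Hz alpha carrier asymmetrically by
group, a band-edge artifact that masquerades as an eyes-closed alpha
difference); eyes-open alpha gain 1.21 vs 1.02; beta gain 0.18 vs 0.28;
gamma gain 0.28 vs 0.42; envelope and fixation Hurst exponents 0.82 vs 0.63
(sd 0.05, clipped to 0.62–0.88, and sharing 80% of their subject-level
noise — one LRTC trait expressed in both brain and behaviour, which is the
premise the pipeline is meant to detect). Eyes-closed alpha gain is drawn
from one distribution for both groups (mean 1.1, sd 0.7, floor 0.5) and
scales the whole eyes-closed alpha field, focal and diffuse alike:
eyes-closed alpha is strong but highly variable across subjects, which is
what makes the arousal controls uninformative about group, as they should
be.

**EEG.** Each channel is a spatially coherent 1/f background (32 global 1/f
sources mixed with Gaussian-in-angle weights, kernel 50°, plus 10% local
noise — a surrogate for volume-conduction smoothness, without which the
neighbour-correlation bad-channel criterion would flag every channel) plus
three narrowband oscillations. The alpha component is one shared
constant-envelope carrier per recording — the cosine of the analytic phase
of Gaussian-shaped narrowband noise (spectral sd 0.4 Hz, peaked exactly at
the subject's IAF and contained well inside IAF ± 1 Hz) — multiplied by
1 + 0.5·fGn(H = hurst_alpha):
a plain noise carrier's own Rayleigh envelope fluctuations — or interference
between several independent carriers — would ride on top of the imposed
modulation and cap the envelope-exponent recovery far below the package's
own recovery requirement at these durations. Beta (15–25 Hz) and gamma
(35–45 Hz) are plain narrowband noise mixtures of a shared and a
channel-local component (channel-noise fraction 0.2). The group-specific components have focal, **zero-sum
(dipolar)** topographies: weight 1 in the home region (alpha/gamma:
occipital, the lowest 20% of posterior electrodes; beta: frontal), near-zero
elsewhere, and the compensating return lobe on the face channels — which are
excluded from all scalp statistics. Zero-sum topographies are invariant
under average referencing, so the occipital alpha group effect does not leak
into distant channels through the reference (with a non-zero-sum topography
that leakage makes the global alpha reactivity ratio group-informative, and
the study's own control analyses fail). Group-independent diffuse alpha and
beta rhythms (alpha sharing the subject's fGn envelope, with a smooth
height-gradient topography and lognormal subject-level amplitude) put
realistic alpha everywhere and carry the envelope LRTC to all channels. In
eyes-closed, alpha uses the group-independent gain and gamma is suppressed
(×0.2). Impedances are drawn in 5–40 kΩ.

**Gaze.** Alternating fixations and saccades: fixation duration of event k
is exp(μ + 0.8·g_k) with g an fGn of exponent hurst_fix over event index —
long memory in durations is what puts the binary series' DFA exponent in
(0.5, 1). The log-scale σ = 0.8 matters: with materially smaller duration
variability the alternation is quasi-periodic and the binary series becomes
anti-persistent (exponents below 0.5, outside the published range). σ is
held fixed across subjects because it influences the exponent as strongly
as H does and has no phenotype role; similarly the group gap in mean
fixation duration (0.30 vs 0.26 s log-means, ~0.41 vs ~0.36 s after the
log-normal correction) is kept modest and uncoupled from the latent trait,
because event rate also shifts the exponent, in the opposite direction
to H. Saccades last ~30 ms with a
ballistic half-sine velocity profile peaking near 220 deg/s over low-
velocity fixation jitter, so a 30 deg/s threshold recovers the true
labelling at ≳98% of samples.

**Problem sizes.** Defaults: 64-channel montage (256 supported), 100 s of
EEG per condition at 250 Hz, 10-minute gaze traces at 500 Hz, 1000
permutations. The emulated study recorded 10 minutes of EEG per condition
at 500 Hz on a 256-channel net; the package's defaults are the sizes at
which the full 40-subject pipeline runs in under a minute while every
estimator still has the precision its validation requires (e.g. envelope
DFA exponents need ≥ 4×20 s for the largest fit scale). All sizes are
config fields, not constants.

**Calibration.** The group effect sizes above were calibrated once, on
seeds disjoint from any test seed, to the design targets the package sets
itself: the n = 19/21 cluster pipeline detects the three band effects with
high power; the eyes-closed alpha and reactivity controls are null; IAF is
recovered to the 0.5 Hz bin for ≈99% of subjects; envelope and fixation
exponents track their generative Hurst exponents. They were then frozen.

## What the synthetic data do and do not show

Passing tests demonstrate that the estimators and inference machinery
recover planted effects of realistic size and direction at the study's n,
and that the null controls stay null under the stated conditions. They do
not validate the neuroscience: the generator has no volume-conduction head
model, no artifacts (blinks, EMG), no non-stationarity across the session,
no connectivity structure, and its LRTC mechanism (fGn modulation) is one
convenient choice among many. Real-data users should treat the defaults for
bad-channel thresholds and DFA scales as starting points, and insert their
own artifact removal via `artifact_hook`.

## Numerical choices and degenerate inputs

- fGn synthesis is exact (Davies–Harte circulant embedding); eigenvalue
  round-off is clipped at zero. Deterministic per (seed, stream, subject)
  via counter-based seed fan-out, so adding a subject never perturbs
  another's data.
- Zero-phase filtering is centred convolution with an odd-length symmetric
  kernel (even order required), not forward–backward filtering, so the
  stated filter orders apply literally and an impulse maps to a symmetric
  response.
- DFA requires series length ≥ 4× the largest scale; the largest scale is
  clamped to length/4. Constant series are rejected (zero fluctuations).
  Window matrices are built per scale and detrended with a precomputed
  pseudo-inverse; accumulation is in float64 even for float32 inputs.
- Cluster tests: permutation t-values are computed for all permutations by
  matrix algebra; connected components are evaluated only for permutations
  with ≥ 2 suprathreshold same-sign channels (a single channel is its own
  max cluster), which makes 500-replicate FWER studies cheap.
- Relative power returns NaN for channels with non-positive total power
  rather than raising; IAF candidates at the search boundary are reported
  with `is_true_peak=False` for exclusion.
- Interpolating more than 25% of channels logs a warning; interpolating all
  channels is an error.
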