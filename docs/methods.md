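# Methods

This note documents the models, numerical choices and known limitations of
`emgau` — what each stage assumes, which knobs matter, and what the
synthetic sessions do and do not establish about real recordings.

## The synthetic session model

The generator produces paired sEMG/AU sessions in which every quantity the
pipeline later estimates is known exactly.

**Protocol.** The calibration protocol presents six instructed expressions
(big smile, wrinkle the nose, close the eyes, contract the eyebrows, press
the lips, small smile), each for 3 s followed by a 3 s neutral gap,
repeated 3 times consecutively (default), i.e. a 108 s session. A
spontaneous-smile protocol (8 smile windows of 2 s separated by 4 s rest)
drives the segmentation analyses.

**Muscle sources.** Each expression activates one muscle(-segment) source:
unit-RMS Gaussian noise band-limited to 25–300 Hz (4th-order Butterworth,
applied forward–backward) and gated by the protocol with 100 ms
raised-cosine ramps. The ramps avoid the spectral splatter that hard
on/off edges would inject, which would otherwise contaminate the
band-power triage criterion. The gating is also what makes the sources
non-Gaussian — bursty, heavy-tailed amplitude distributions are precisely
the property FastICA exploits; stationary Gaussian band-limited noise
would be unidentifiable in principle.

**Spatial mixing.** Source *k* at face-frame position `c_k` reaches
electrode *c* at position `p_c` with gain
`A[c,k] = exp(−‖p_c − c_k‖² / 2σ_s²)`. The default spread is
`σ_s = 0.15` face-frame units, comparable to the inter-electrode spacing
of the 16-channel layout. This value matters: it sets the conditioning of
the mixing matrix. At `σ_s = 0.25` the six source columns become nearly
collinear (condition number ≈ 40) and *no* unmixing method can separate
them cleanly — which would contradict the premise that high-density sEMG
resolves distinct muscle segments. At 0.15 the condition number is ≈ 7
and the sources have spatially distinct signatures, the regime the
method is designed for.

**Interference.** Three classes, matching what the component triage must
reject:

| term | default | rationale |
| --- | --- | --- |
| powerline comb | 50 Hz, harmonic amplitudes (0.20, 0.08, 0.03, 0.01); one shared waveform, per-channel gains U(0.8, 1.2) | mains pickup is common-mode across a small array (rank-1), with decaying harmonics |
| 1/f drift | 2 independent sources, exponent α = 1, amplitude 0.15, random dense mixing | motion/electrode-interface drift is low-rank and broadband-low |
| white noise | σ = 0.05 per channel | amplifier/sensor noise well below burst amplitude (unit RMS) |

1/f noise is generated by spectral shaping of white noise
(`|H(f)| ∝ f^{−α/2}`), which gives direct control of the log-log slope the
triage criterion tests.

**AU tracks.** Each of 17 synthetic AU intensity tracks is
`clip₀⁵(G · env(s) + ε)`, `ε ~ N(0, σ_AU²)`, `σ_AU = 0.05`, at
30 frames/s, where `env(·)` is the *same* RMS-envelope + block-mean
operation the analysis pipeline uses. That identity makes the noiseless
session an exact linear model: MLR weight recovery can be checked against
`G` to numerical precision rather than approximately. The default `G`
assigns each AU an anatomically plausible driver and plants 10–30%
crosstalk from the Zygomaticus-like big-smile source into the eye-region
AUs (AU6 "cheek raiser", AU7 "lid tightener"). The **crosstalk preset**
removes every direct readout of the big-smile source so that it reaches
the AU tracks *only* through AU6 — a single path. (An earlier design fed
two eye AUs; the planted envelope was then reachable through two
collinear columns and ordinary least squares split the weight between
them unstably. Identifiability of the planted confound requires the
single path.)

**What the generator does not emulate.** Motor-unit action potentials and
their firing statistics; nonstationary muscle fatigue spectra; EOG/ECG
biopotentials; video-side failure modes (occlusion, head pose, lighting);
nonlinear AU saturation beyond simple clipping; inter-subject anatomical
variability. Passing tests therefore establish that the *pipeline
machinery* is correct (filters meet their specs, ICA recovers separable
sources, the regression recovers planted superposition weights, the
confound is detectable when present) — not that real AU tracks contain a
given amount of crosstalk.

## Conditioning

The comb filter is a cascade of second-order IIR notches at 50 Hz and all
harmonics below Nyquist, quality factor 30 (−3 dB width 1.7 Hz at 50 Hz),
so adjacent sEMG energy survives. The band-pass is a 4th-order Butterworth
(20–400 Hz). Both are applied zero-phase (forward–backward): the envelopes
are later compared against video frame times, and a causal filter's group
delay would bias that comparison by tens of milliseconds. Zero-phase
application squares the magnitude response, so all attenuation oracles in
the tests use `|H(f)|²`. Edge transients of `filtfilt` are real; spectral
assertions exclude the first and last 0.5 s (the data itself is never
trimmed).

## FastICA and its convergence

Decomposition uses scikit-learn's FastICA: log-cosh contrast, symmetric
(parallel) decorrelation, unit-variance whitening, all 16 components
retained. Two numerical choices deserve explanation.

*Decimated fitting.* The unmixing matrix is estimated on a time-decimated
view of at most 40 000 samples and then applied to the full recording
(sources renormalized to unit variance over the full length, `W` and
`A = W⁻¹` rescaled consistently). FastICA treats samples as exchangeable
draws from a static mixture — it uses no temporal structure — so regular
decimation is statistically neutral (aliasing changes temporal order,
not marginal distributions) while cutting the cost of unmixing a
324 000-sample session by roughly an order of magnitude.

*Convergence policy.* With 6 bursty sources, ~2 drift sources and white
noise on 16 channels, about half of the whitened directions are
essentially Gaussian. The symmetric fixed-point iteration locks the
informative components within tens of iterations, but the Gaussian
subspace keeps rotating indefinitely and the worst-component tolerance
criterion is never satisfied — at any tolerance, with any number of
restarts. A fit that stops at `max_iter` (default 200, tol 1e-4) is
therefore returned with a `ConvergenceWarning` rather than discarded;
restarts with incremented seeds are reserved for fits that produce
non-finite output, and `strict=True` turns residual non-convergence into
an error for users who want the guarantee. Component sign is fixed so the
largest-magnitude entry of each inverse-weight column is positive, making
heat-maps deterministic under the ICA sign ambiguity; evaluation against
ground truth uses optimal assignment (Hungarian) on |correlation|, which
handles the permutation ambiguity.

Recovery is scored against the *conditioned* true sources (same comb +
band-pass applied to the clean source signals): the comb removes ~5% of
in-band source power, which no unmixing can recover and which is not an
unmixing error.

## Component triage

Welch PSDs use 1 s Hann segments with 50% overlap (1 Hz bins — enough to
resolve 50 Hz harmonic spacing). A component is accepted as sEMG iff all
three criteria pass. The thresholds are package defaults, exposed in
`TriageThresholds` and the pipeline config:

* **Band confinement** — fraction of total power in 25–300 Hz ≥ **0.92**.
  The threshold is deliberately strict because triage runs *after* the
  20–400 Hz band-pass: filtered white sensor noise already has ≈ 0.85 of
  its power in 25–300 Hz, so a lax threshold (e.g. 0.75) rejects nothing.
  Genuine band-limited sEMG measures ≈ 0.98; filtered broadband noise
  ≤ 0.87.
* **No harmonic comb** — reject when ≥ 3 peaks standing ≥ 6 dB above a
  median-smoothed log-PSD baseline (~15 Hz window) align on integer
  multiples of a common fundamental (± 2 Hz). The baseline reference is
  essential: the comb filter leaves 50 Hz-spaced *notches* in every
  spectrum, and peak prominence measured against neighboring minima would
  misread the plateaus between notches as a harmonic series.
* **No strong 1/f trend** — log-log PSD slope fitted *inside* the
  passband (25–250 Hz) must exceed **−0.6**. The conventional 1–100 Hz
  fit range is meaningless after the band-pass has removed everything
  below 20 Hz; inside the passband, α = 1 drift keeps its −1 slope while
  band-limited sEMG is approximately flat (measured −0.3 to −0.45 for
  the notched synthetic sources), so −0.6 separates the two populations.

## Spatial mapping

Inverse-weight columns are interpolated over the unit face frame with a
thin-plate-spline radial basis (exact at electrode sites, degree-1
polynomial tail, so constant columns reproduce exactly — both properties
are tested). Grids default to 64×64. Matching against the 16
facial-building-block templates uses absolute cosine similarity
(sign-invariant), acceptance threshold 0.5, with conflicts (two components
claiming one FBB) resolved in favor of the higher similarity. The shipped
templates are *synthetic* Gaussian-blob stand-ins on abstract face
coordinates — six of them co-located with the generator's source centers
so that ground-truth assignment is testable — and are a first-class input
so digitized anatomical templates can replace them. The smile analyses
expose the ordering component as a parameter (`order_by`, default the
Zygomaticus-associated FBB XIII) rather than hard-coding one.

## Alignment

The IC-to-video bridge computes the moving RMS **at the native rate**
(800-sample centered window at 3000 samples/s ≈ 267 ms, truncated — not
padded — at the edges) and then block-mean decimates by the integer
factor 100 to 30 frames/s. An 800-sample window applied *after*
decimation would span 26.7 s, far beyond expression dynamics, which is
why window-before-decimation is the default; the other ordering is
available via `rms_after=True` for sensitivity analyses. Block means
(rather than point decimation) keep the operation deterministic and
oracle-checkable. A synchronization `offset` in seconds shifts the IC
tracks in whole frames; frames where any AU track is missing (long
tracking-failure runs) are dropped pairwise. Active-AU selection keeps an
AU if its intensity exceeds 5% of full scale (0.25 on the 0–5 scale)
continuously for at least 1 s.

OpenFace tables are taken at face value except tracking-failure rows
(`success = 0`), which are removed and linearly interpolated when the gap
is ≤ 0.5 s, else left as explicit missing runs. Non-finite values in
signal matrices are a hard error — silent imputation would corrupt the
ICA statistics downstream.

## Cross-reconstruction

`fit_mlr` is ordinary least squares with intercept (statsmodels), with
R², the overall F statistic on (p, n−p−1) degrees of freedom, its
p-value, and residual variance SSR/(n−p−1). A constant dependent has no
variance to explain: R² = 0 and F = 0 by convention. Rank-deficient
designs fall through to the pseudo-inverse with a warning. Weight tables
are row-normalized |slope| matrices (unit row maximum; in the grey-level
rendering convention, white = most influential). The default AU subset
for intra-session reconstruction is {4, 6, 12, 25, 23, 9} (brow lowerer,
cheek raiser, lip corner puller, lips part, lip tightener, nose
wrinkler — the AUs most engaged by the calibration expressions); a
variance-ranked top-k rule is available via `target_aus="top6var"`.

Smile segmentation builds one candidate window per trigger (onset − 0.5 s
to offset + 0.5 s; the fixed margin replaces manual segmentation with a
reproducible rule), computes the ordering component's RMS per window, and
defines SNR against the RMS over all *neutral* frames (outside every
candidate window) of the same session — the natural baseline when none is
otherwise specified. Windows with SNR > 1.25 are kept, sorted from
biggest to smallest activation.

## Problem sizes and determinism

Default analyses run on single 108 s sessions (16 × 324 000 samples,
3 240 video frames); repeated-seed studies use 10 seeds. These sizes keep
a full study under two minutes on one CPU while leaving all recovery
margins wide (source correlations ≈ 0.99 against a 0.95 requirement,
Amari index ≈ 0.004 against 0.1). All randomness flows from explicit
seeds through `numpy.random.SeedSequence`; a pipeline run with the same
config and seed is byte-identical, and the run log records every stage
with input/output digests.

## Known limitations

* PSD-based triage cannot distinguish genuine sEMG from broadband noise
  that happens to be band-confined; it relies on the band-pass leaving
  noise spectrally distinguishable. Temporal criteria (burstiness,
  kurtosis) would be a natural extension.
* The FBB template bank is synthetic; assignments on real data are only
  as good as the supplied templates.
* Regression is unregularized by design; strongly collinear AU sets make
  individual weights unstable (the crosstalk preset exists precisely to
  provide an identifiable case).
* EDF input requires the optional `mne` dependency and maps channels by
  order or an explicit label map; no other vendor formats are supported.
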