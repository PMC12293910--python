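# Methods

This note documents the models, parameter choices and numerical decisions
behind `vibrouroflow`, in the order the pipeline runs them.

## 1. Synthetic cohort generator

### Flow-curve templates

Each of the six uroflow-curve classes is a parametric template on a
normalized time grid, scaled to a drawn Q<sub>max</sub> and duration:

* **normal** — a beta-density bell `u^(a-1)(1-u)^(b-1)` with a, b ~ U(2.2–4,
  2.2–5) and the peak constrained to the central 25–60 % of the void;
* **decreased** — the same family but sharper (a, b ~ U(4, 7)) and lower;
  sharpness keeps the central coefficient of variation above the flattened
  rule's 0.25 threshold, which is what distinguishes a low bell from a
  plateau;
* **flattened** — a smoothstep-edged plateau carrying a monotone drift of
  ±(24–36) % plus a small fast ripple (±3–10 %). The drift makes the
  envelope's rank order track the flow within the plateau (see §2); it has
  no dips, so it cannot trip the sawtooth rule;
* **intermittent** — a bell with 1–3 zero-flow pauses of 1.5–4 s spliced in
  (0.2 s cosine tapers), pause centers in the central 15–85 % of the void;
* **sawtooth** — a bell multiplied by a 3.5–7-cycle oscillation of depth
  0.45–0.65 whose amplitude fades where the bell is low, so the flow never
  reaches zero inside the void;
* **tall-peak** — a gamma-like pulse (peak at 7–13 % of the duration)
  riding on a low sustained tail (10–16 % of peak). The tail is essential:
  without it the void ends so soon after the peak that the time-to-peak
  fraction exceeds the tall-peak rule's own 20 % bound.

Every draw is checked against the rule labeler (§3) and resampled until it
is accepted (budget 200 tries), so generated labels are correct by
construction. Contradictory overrides (e.g. a normal-class curve with
Q<sub>max</sub> 5) exhaust the budget and raise an error.

### Joint parameter distribution

Voided volume VV is drawn uniformly per class and Q<sub>max</sub> follows
`k_class · sqrt(VV) · exp(0.08 N(0,1))`, clipped to a class range; the
voiding time follows from volume conservation, `T = VV / (mean-shape ·
Qmax)`. The square-root coupling reflects the physiological rise of flow
with bladder filling and gives the cohort-level feature correlations their
near-deterministic structure in the noiseless limit. Class ranges were
chosen once so that cohort marginals stay inside Q<sub>max</sub> 4–50 mL/s,
VV 50–690 mL and voiding time 4–62 s, and so that each class is an
archetypal exemplar of its morphology — boundary-ambiguous curves would be
rater-ambiguous for human readers too, and the six classes are treated as
mutually exclusive.

### Vibration model

The waveform is white Gaussian noise amplitude-modulated by
`g · Q(t)^alpha` with α = 1 (amplitude proportional to flow; simplest law
consistent with uniformly positive flow-vibration correlations) and
`g = 1/50` so that 50 mL/s maps to unit amplitude. The modulated carrier
splits into two unit-variance-normalized paths mixed at 15/85 power:

* a second-order resonator at 600 Hz, Q-factor 5 — the container's
  structural resonance coloring the spectrum;
* a 4th-order 150–1800 Hz band-pass path — broadband turbulent impact
  noise.

The broadband path dominates deliberately: a pure 120 Hz-wide resonance
gives a windowed-RMS estimate with ~14 % relative scatter per 100 ms
window, too noisy for the envelope to track the flow curve rank-for-rank;
with the 15/85 mix the scatter is ~4 % and Spearman(Q(t), RMS(t)) stays
above 0.95 on every noiseless session, flattened plateaus included.

Stationary white background noise is added at `noise_snr_db` (default
20 dB) relative to the active-segment signal power; 1 s silence pads
surround the void, so onset detection is non-trivial. Sampling rate
defaults to 4 kHz (no rate is standard for this device class). An optional
slow lognormal coupling-gain drift (`coupling_drift_sigma`, default off)
models the stream's impact point wandering on the container wall; it is
the controlled way to inject peak-timing jitter when studying how timing
correlations degrade (§5).

## 2. Vibration features

The RMS envelope uses 100 ms windows with a 50 ms hop (≥ 80 envelope
points for the shortest clinical voids), stamped at window centers. Scalar
features come from the envelope's *active segment*: all points at or above
`floor + onset_frac · (Mmax − floor)`, with `onset_frac = 0.05` and the
floor estimated as the envelope's 5th percentile. The floor compensation
matters: at 20 dB SNR the background envelope sits near 10 % of the active
RMS, above a bare 5 %-of-maximum threshold, which would otherwise never
release. On noiseless records the floor is zero and the rule reduces to
the plain fractional threshold. Ties at the maximum resolve to the
earliest point.

The headline RMS scalar defaults to the envelope *integral* over the
active segment (amplitude·seconds). With amplitude ∝ flow, the integral is
the vibration-side analogue of voided volume; an envelope-RMS or
envelope-mean scalar instead tracks Q<sub>max</sub> and structurally
decorrelates from volume in cohorts where low-flow voiders still void
normal volumes. Both alternatives remain selectable (`rms_stat`).

MFCCs use the standard pipeline — framing (25 ms / 10 ms), Hann window,
power spectrum, 26 triangular mel filters spanning 20 Hz–f<sub>s</sub>/2,
log with floor 1e−10, orthonormal DCT-II, first 13 coefficients — on a
fixed 64 s canvas (6400 frames) that accommodates the longest clinical
voiding time; the waveform is zero-padded before framing so padding frames
equal genuine digital-silence frames. Classifier inputs are mean-pooled
×40 along time (160 frames at 0.4 s — still ~4 frames per minimum
intra-void pause), and the energy coefficient of digital-silence frames is
clamped up to the quietest physical frame in the cohort: the log-floor c0
(−117) otherwise dominates the feature scale four-fold and, after
standardization, compresses every physiological contrast the classifier
needs.

## 3. Rule-based pattern labeler

An explicit decision cascade stands in for the physician's visual read
(first match wins): intermittent (an interior run below 0.5 mL/s lasting
≥ 1 s) → sawtooth (≥ 2 dips of prominence ≥ 0.25 Q<sub>max</sub>, none
reaching zero) → tall-peak (Q<sub>max</sub> ≥ 25 mL/s reached within 20 %
of the voiding time) → flattened (Q<sub>max</sub> < 15 and central-60 % CV
≤ 0.25) → normal (Q<sub>max</sub> ≥ 15) → decreased. Only the 15 mL/s
normal-bell threshold has a clinical citation; the rest are package
defaults, all exposed in `PatternRuleConfig`. Precedence follows
specificity: a true pause is the most specific visual feature. All
temporal thresholds are relative to voiding time except the 1 s minimum
pause, which is deliberately absolute — the labeler is therefore invariant
to uniform time stretching except for sub-second-compressed pauses.

Uroflow parameters: Q<sub>max</sub> is the curve maximum (first maximum on
ties); voiding time spans first-to-last samples above the cutoff,
*including* intra-void pauses; voided volume is the trapezoidal integral;
time to Q<sub>max</sub> runs from voiding onset. `flow_parameters` uses a
zero cutoff by default (pure geometry); the labeler passes its configured
0.5 mL/s cutoff explicitly.

## 4. Pattern classifier

A compact CNN implemented directly on numpy: three 3×3 conv blocks
(8/16/32 channels, batch-norm, ReLU, 2×2 max-pool), a pooling head that
concatenates global *average* and global *max* pooling, a 64-unit dense
layer with dropout 0.3, and a 6-way softmax. Average pooling summarizes
sustained structure; max pooling keeps localized events (a 2 s silence gap
is ~2 % of the canvas and washes out under averaging alone). The input has
two channels: the pooled MFCC matrix and its central-difference delta
along time, which turns oscillation texture (the sawtooth signature) into
a first-layer feature.

Training: Adam at 5e−3 with cosine decay, 60 epochs, batch 32, seeded
init/shuffling/dropout (fully deterministic); random time-shift
augmentation (content never shifted past the canvas end — label-preserving
because the canvas is mostly silence); per-coefficient standardization
with statistics from the training fold. After training, batch-norm
statistics are recalibrated to population statistics over the training
set (small-batch running averages are visibly biased). A refit guard
retrains (at most twice, derived seeds) any run that cannot reproduce its
own training labels in evaluation mode — a rare batch-norm calibration
pathology that otherwise costs a whole class in one fold; the guard never
sees test data.

Cross-validation is stratified, shuffled, k = 5 (plain shuffled split with
a logged warning when a class has fewer than k members). Naive random
oversampling with replacement brings labels {2, 3, 5} up to the
training-fold majority count; test folds are never oversampled, and the
pipeline asserts that the test folds partition the cohort exactly.
Headline metrics are weighted-average precision/recall/F1 (macro and
per-class always reported alongside); fold metrics are averaged
unweighted, confusion matrices summed. UMAP (seeded) embeds flattened
features or penultimate activations in 2-D for visual checks.

## 5. Correlation analysis

Pearson's r with two-sided p-values from the t-distribution (n − 2 df),
significance at p < 0.05, on four fixed pairs: VV↔RMS,
Q<sub>max</sub>↔M<sub>max</sub>, voiding-time↔signal-time, and
time-to-Q<sub>max</sub>↔time-to-M<sub>max</sub>. Exact p-values are
stored; "p < 0.001"-style formatting is left to rendering. On noiseless
synthetic cohorts all four correlations exceed 0.9 (the features are
near-deterministic functions of the flow curve); at the default 20 dB they
remain positive and highly significant.

Clinically, the timing pair is much weaker than the duration pair. That
ordering is *not* reproduced by the default generator — flow and vibration
share Q(t) exactly, so peak times coincide by construction — and plain
background noise degrades durations faster than peak times. The ordering
emerges exactly when peak-timing jitter is injected while durations stay
intact, which is what the coupling-gain drift of §1 provides; the test
suite asserts the ordering as a trend across ten seeded cohorts with
`coupling_drift_sigma = 0.2`.

## 6. What the synthetic cohort does and does not show

The generator reproduces the *statistical skeleton* of a clinical cohort:
class counts, parameter ranges, rule-consistent morphologies, a monotone
flow-vibration coupling, and a controllable noise floor. It does not
emulate fluid dynamics, container geometry, female-voiding acoustics,
inter-rater disagreement, or clinical borderline curves (archetypes are
drawn away from rule boundaries). Classification scores on it are
therefore a *clean-conditions* upper bound and a correctness check of the
pipeline — evidence that the method separates the six morphologies when
they are present — not a clinical performance claim.

## 7. Problem sizes and runtime

The heavy experiment (300 sessions, 50 per class, full 5-fold CV) runs in
roughly 5–10 CPU-minutes; it is the scale used by the acceptance script
and the headline test. Unit tests use 12–76-session cohorts. The
chance-level control (label-shuffled training on a balanced 72-session
cohort) uses 30 epochs — convergence quality is irrelevant when labels are
random — and disables the refit guard, which presumes learnable labels.

## Known limitations

* The CNN is data-hungry relative to 76-session clinical cohorts; the
  packaged reference-distribution cohort trains noticeably worse than the
  300-session experiment (4 sessions in a test fold for class 2).
* The coupling law is phenomenological (α = 1 with lognormal drift);
  nothing in the package calibrates it to a physical container.
* Single-channel only: triaxial fusion, denoising and transfer across
  sensing media (bucket vs toilet bowl) are out of scope.
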