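# Methods

This note documents the models, defaults and numerical choices behind
`ei_hrv`, and what the synthetic generators do and do not emulate.

## Signal model and R-peak detection

ECG records are single-lead sample streams with a sampling-rate header
(500 Hz in the intended acquisition setting). The detector is the classic
Pan–Tompkins cascade: zero-phase Butterworth band-pass 5–15 Hz, derivative,
squaring, 150 ms moving-window integration, then candidate peaks of the
integrated signal at a 200 ms refractory spacing. The signal/noise levels of
the adaptive threshold (`noise + 0.25·(signal − noise)`, exponential updates
with weight 0.125) are initialised robustly: the signal level from the
median of the strongest candidate heights (sized for at least 40 bpm), the
noise level from the median of the detection function. Two safeguards matter
in practice: the signal-level update is clamped to 4× its current value so a
single filter edge transient cannot freeze the threshold above genuine
beats, and after each detection is re-localised to the raw-signal maximum
(±75 ms), detections whose raw amplitude falls below 0.3× the median peak
amplitude are discarded (they are ringing sidelobes re-localised onto
baseline). A record in which no clear signal level exists (flat or
all-noise) yields an empty beat list with a warning rather than an error.

## RR cleaning and epochs

Intervals outside [300, 2000] ms, or deviating more than 25 % from the
median of their five nearest retained neighbours, are flagged rejected. The
median rule is iterated to a fixed point, which makes cleaning idempotent.
Rejected intervals are excluded from statistics but kept in the container
(no interpolation by default; cubic interpolation is available behind a
flag). An epoch with more than 20 % rejections raises a quality error. All
bounds are configurable; no claim is made that the original acquisition
applied any cleaning — these are explicit, recorded defaults.

Epochs are half-open `[start, end)` and an interval is owned by its later
beat, so segmentation partitions the retained intervals unambiguously. The
session protocol (6 min neutral baseline, 6 min emotional stimulus, 3 min
trailing neutral) is checked by `validate_protocol` (±5 s) rather than baked
into the `Epoch` type, so trimmed or exploratory segments remain usable.

## HRV indices

Time domain: BPM = 60000/mean(RR); SDNN with denominator n−1; RMSSD over
successive retained pairs (pairs spanning a rejected interval are excluded);
pNN50 counts differences strictly greater than 50 ms.

Frequency domain: the tachogram (RR in ms versus time of the later beat) is
cubic-resampled at 4 Hz and a Welch spectrum is taken with Hann-tapered,
linearly detrended 120 s segments at 50 % overlap (shortened to ⅔ of the
window when a sliding window is shorter than a segment). Band powers are
trapezoidal integrals with interpolated band edges, which makes integrals
additive across adjacent bands and lets the spectrum integrate to the
tachogram variance within ~10 % for stationary input. Default bands are the
conventional short-term ones — VLF 0.0033–0.04, LF 0.04–0.15, HF
0.15–0.40 Hz. A variant with LF starting at 0.004 Hz and HF at 0.015 Hz
(`SpectralConfig.printed_bands()`) is retained for comparison even though
those limits overlap and are not recommended. Relative powers are normalised
by the three-band sum, so VLFp+LFp+HFp ≡ 1 by construction. `tPow` and `tHz`
are carried as two fields with identical values (both defined as the
absolute power over the full 0.0033–0.4 Hz band); downstream code should
treat them as duplicates. The dominant peak (dHz) is the highest density in
the full band; its power (dPow) integrates ±0.015 Hz around the peak — a
single-bin definition would make the coherence ratio dPow/(tPow − dPow)
depend on frequency resolution. Logs of non-positive band powers raise
rather than return −inf.

RSA uses a peak–valley definition: band-pass the resampled tachogram to a
fixed respiratory band 0.12–0.40 Hz (no respiration channel is assumed),
split the signal into half-cycles at zero crossings, and average the
peak-to-trough excursions of interior cycles. A tachogram whose band-passed
variance is below 1e-6 ms² returns 0 by convention. RSA is deliberately a
time-domain quantity distinct from lnHF; no standard formula exists for it,
and this choice is a design decision, not a reconstruction of any particular
analysis suite.

Sliding windows default to 180 s advancing by 10 s (the step is a free
choice; 10 s gives 19 windows on a 6 min epoch). Windows that fail (for
example, no spectral power) become NaN rows, not errors.

## Affect dynamics

For each index, the per-window series of the whole session (baseline,
stimulus, trailing neutral in time order) is normalised against the
baseline-epoch mean — difference by default, ratio behind a flag — and three
statistics are computed: sample variance (n−1), MSSD over consecutive
non-missing pairs (gaps break the chain), and lag-1 Pearson autocorrelation
(undefined, hence NaN in feature tables, for constant series). The per-index
HRV feature itself is mean(stimulus windows) − mean(baseline windows).
Features are averaged across the four emotional-domain sessions into one
record per participant; per-domain records are available behind a flag.
Whether dynamics should be computed on raw or normalised windows, and
whether domains should be pooled or averaged, are genuinely open choices;
both decisions are surfaced in the writer metadata.

## Scoring

Likert 1–7 responses map to quadrant halves with the midpoint 4 excluded
(configurable): 5–7 high, 1–3 low. A photo item scores 10 only when arousal
half, valence half and keyword all match the target quadrant; an avatar item
only when the expression was recognised and the chosen domain equals the
target; a discrimination item carries an all-placements-correct flag. The
full design (3 evaluations × 4 domains × 10 stimuli × 10 points) totals
1200. Stimulus filters are inclusive at their thresholds (a photo at exactly
81 % accuracy is kept) and intensity-peak ties break toward the lower
intensity.

## Cut-point selection

`CutpointSweep` sorts participants by score, places candidate cuts only
between distinct score values (tied scores are never split) with both groups
at least `min_group` (default 5), Welch-tests every feature at every cut
(pooled-variance option available; Welch is the default because group
spreads typically differ several-fold), counts features with p < 0.05 and
p < 0.01, and selects the cut with the maximal 0.05-tier count, breaking
ties toward the most balanced split. No multiple-testing correction is
applied by default; Benjamini–Hochberg is available but changes the meaning
of the count. Marker tables star p < 0.05 (*) and p < 0.01 (**) with strict
inequalities.

**Selection effect.** Because the criterion is an argmax over many
correlated splits, the selected count is biased upward relative to any
prespecified split, and on cohorts where several features carry genuine
group effects the significance count *plateaus*: a feature with a d ≈ 1.5
effect at the true boundary remains significant when the cut moves several
participants in either direction, so the argmax is decided by which split
happens to pick up extra chance significance in null features. Two
consequences, both reproduced by the package's own experiments
(`scripts/acceptance.py`): the injected markers are recovered almost always
(≥ 95 % of seeds), but the *exact* generating group sizes are recovered only
rarely (≈ 5–10 % of seeds). A reported cut-point should therefore be read as
a neighbourhood, and the number of significant markers at the selected split
should always be compared against a synthetic null cohort
(`null_mean_significant_count` ≈ 0.05 × n_features per fixed split, higher
for the selected split).

## Synthetic generators

The RR generator modulates the interval sequence additively with sinusoids
(amplitude ms, frequency Hz, phase) plus Gaussian noise, redrawing a
non-positive interval up to 10 times before declaring the spec degenerate.
This is not an integral-pulse-frequency-modulation model: it is analytically
tractable, places spectral power exactly where the test needs it, and
reproduces none of the frequency-pulling or amplitude-rate coupling of real
sinus-node physiology. ECG synthesis places a unit Gaussian spike (default
40 ms nominal width) at each beat time — no P/T waves, ectopy or baseline
wander — so detector results on it bound only the bookkeeping of the
pipeline, not clinical robustness. Cohorts draw each feature from
Normal(μ, σ) with the high group shifted by d·σ, and scores uniformly on a
10-point grid below/above the cut; response tables contain exactly
round(n·accuracy) correct items. Defaults mirror the study conditions: 22
low / 26 high participants, an 820-point cut on the 1200-point scale, and
effect sizes on the d = 0.6–1.5 scale used in the power analysis and
recovery experiments. Passing tests on these generators demonstrate correct
computation and calibrated statistics, not physiological validity.

## Problem sizes

The default test and reproduction runs use 2–6 min synthetic records at
500 Hz, 10 records for the detection round trip, 100 seeded cohorts for the
recovery experiment and 500 for the null calibration — sizes chosen so the
whole suite completes in well under a minute while keeping Monte-Carlo
standard errors an order of magnitude below the asserted margins.

## Known limitations

- The detector is tuned for clean, synthetic-grade ECG; it has no search-back
  stage and no T-wave discrimination.
- RSA assumes respiration inside 0.12–0.40 Hz; paced or slow breathing
  violates this.
- Group summary statistics from a sweep inherit the selection bias described
  above; the package reports them but deliberately provides the null-cohort
  machinery to contextualise them.
- `tHz` duplicates `tPow`; it exists only for column-compatibility with the
  21-index convention.
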