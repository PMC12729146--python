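# Methods

This note documents the models, parameter choices and numerical decisions
behind `hrvscreen`, and states what the synthetic validation does and does
not show about real recordings.

## Beat generation (IPFM)

Beats are generated by integral pulse frequency modulation: the
instantaneous rate

    r(t) = (hr_mean / 60) · (1 + a_lf sin 2π f_lf t + a_hf sin 2π f_resp t)

is integrated on a 10 ms grid (piecewise-linear cumulative integral,
crossings located by interpolation — exact for constant rate, so an
unmodulated series is a perfect metronome) and a beat is emitted at every
unit crossing.  IPFM was chosen over direct interval jittering because the
features under test are partly spectral: the two sinusoidal modulators
place variability at controlled LF (sympathetic/baroreflex) and HF
(respiratory sinus arrhythmia) frequencies, so frequency-domain features
have a ground truth.  White Gaussian jitter with SD `jitter_sd` (ms) is
then added per interval — the broadband vagal channel that dominates RMSSD.
The first beat sits at t = 0.25 s so a rendered waveform can represent its
full QRS.  Parameters, units and defaults:

| parameter  | unit  | default | role |
|------------|-------|---------|------|
| hr_mean    | bpm   | 70      | mean rate; MeanNN ≈ 60000/hr |
| a_lf       | —     | 0.030   | LF modulation amplitude (fraction of mean RR) |
| a_hf       | —     | 0.045   | HF/respiratory amplitude |
| f_lf       | Hz    | 0.10    | LF tone position (0.04 ≤ f < 0.15) |
| f_resp     | Hz    | 0.25    | respiratory frequency, = Resp_rate/60 truth |
| jitter_sd  | ms    | 12      | white per-interval noise |

Between-subject baselines are drawn per participant (SDs: 7 bpm, 0.007,
0.010, 0.012 Hz, 0.030 Hz, 3 ms respectively, clipped to stay inside the
band invariants), from an RNG stream keyed by (cohort seed, group,
within-group index) so growing the cohort never reshuffles existing
participants.

## Study-condition defaults

The default cohort is 66 HC / 30 IWD.  Each session holds seven trials in
the fixed valence order calm, positive, negative, ×3, where the three
negatives cover sadness/fear/anger in per-participant random order and
exemplar durations are drawn from the stimulus-set values (calm 192 s;
happiness 67/60/93 s; sadness 66/166 s; fear 78/62 s; anger 123/101 s).
PHQ-9 totals are drawn uniformly in 0–4 (HC) and 10–20 (IWD); the 5–9
stratum is excluded by design and never generated.

### Effect profiles (version 1, frozen)

Group-by-emotion divergences are additive on heart rate and multiplicative
on the modulation amplitudes and jitter.  Directions: both groups respond to
each emotion the same way; IWD diverges with a much stronger broadband vagal
sadness response (jitter ×1.85 vs ×1.02; drives RMSSD/CVSD), a blunted
frequency-domain sadness response (HC's LF amplitude drops to 0.78× while
IWD's barely moves, so HC's LFn falls further), an attenuated happiness
SDNN response, and small LF-channel differences under anger and fear.
Magnitudes were calibrated once against the screening-power design targets
and frozen: over 20 probe cohorts the realized phase-2 epoch-level Cohen's d
under sadness averages ≈ 0.9 for RMSSD/CVSD and ≈ 0.5 for LFn/LFHF, with
|d| ≲ 0.2 under the other emotions.  The gap between the nominal planted
shift and the realized d is structural: the calm baseline has only three
epochs, so σ_calm is itself noisy (chi with 2 df), standardized values are
heavy-tailed, and a fixed generative shift realizes as a cohort-level d that
fluctuates by a few tenths.  The magnitudes sit high enough in that
distribution that the sadness cells are recovered reliably at this sample
size.

## Preprocessing

*Filtering.* The 0.5–100 Hz band-pass and 50 Hz notch are applied in the
frequency domain (raised-cosine transitions: 0.5 Hz wide at the high-pass
edge, 10 Hz at the low-pass edge, 2 Hz notch half-width).  A spectral
application is exactly zero-phase — R-peak latencies are untouched — and,
unlike filtfilt'd IIR sections, cannot ring at the record edges: a mains or
drift cycle truncated mid-period puts a derivative discontinuity exactly at
the boundary, where reflection padding cannot absorb a recursive filter's
transient (the high-Q notch rings for ~0.2 s and the 0.5 Hz high-pass pole
far longer).

*R detection.* Classic derivative–square–moving-window-integrate energy
(5–15 Hz detection band, 150 ms integration window), candidate peaks at
≥ 200 ms spacing, running signal/noise peak levels with threshold
`npk + 0.25(spk − npk)` (update factor 0.125), then each accepted candidate
is refined to the local maximum of the filtered ECG within ±100 ms, with the
refractory period re-enforced after refinement.  Flat signals and records
yielding fewer than two beats raise a detection error rather than returning
an empty series.

*Epoching.* Segments are cut by stimulus timestamps; each segment of length
L yields ⌊L/60⌋ non-overlapping 1-min windows tiled backward from the
segment end (the final beat always falls in epoch 0).  An NN interval
belongs to the window containing its *terminating* beat (half-open
[start, end)).  Intervals outside 200–3000 ms are removed, never
interpolated, and removal breaks adjacency so successive differences are
only taken between truly consecutive beats.  Epochs with fewer than 20
cleaned intervals are dropped with a warning — frequency features are
meaningless below that.

## Features

Time domain uses the textbook formulas; SDNN and the calm-baseline SD both
use the n−1 denominator.  CVNN = SDNN/MeanNN and CVSD = RMSSD/MeanNN hold
exactly on every emitted vector.

Frequency domain: the tachogram (NN against terminating beat time) is
resampled to a uniform 4 Hz grid by cubic spline, and the PSD estimated by
Welch (Hann, 32 s windows, 50% overlap — fixed in config; nothing shorter
resolves the LF band in a 1-min epoch, and VLF is unresolvable entirely,
which is why "total power" for normalization is LF + HF and LFn + HFn ≡ 1).
HFn is HF/(LF+HF); defining it otherwise would make HFn ≡ LFn, which the
screening contrasts contradict.  The LF/HF ratio errors out when HF power is
exactly zero; an all-equal tachogram yields a zero-power warning and missing
normalized powers rather than NaN arithmetic downstream.

The respiratory rate is 60 × the HF-band PSD peak (respiratory sinus
arrhythmia), with parabolic refinement of the peak bin — at a 1/32 Hz bin
width the raw argmax alone could err by ±0.9 breaths/min.  An out-of-band
peak raises an error rather than reporting a rate.  An ECG-derived
respiration variant was considered and rejected: the HF-peak convention
needs no waveform and is the only one available on RR-only input.

Cross-check: on 50 tone-dominated epochs the Welch band fractions agree
with a Lomb–Scargle periodogram computed directly on the uneven tachogram
(no resampling path shared) within 10% relative / 0.05 absolute in ≥ 90% of
epochs.  The residual spread is a genuine estimator difference: a 32-s Hann
window has a ±1/16 Hz mainlobe, so tone power near the 0.04/0.15 Hz band
edges straddles the boundary for one estimator and not the other.

## Standardization

μ and σ of each feature over a participant's calm epochs (1/n and 1/(n−1));
every epoch of that participant, calm included, is then expressed as
(F − μ)/σ.  At least two calm epochs are required — the n−1 SD is undefined
at one — and the 192 s calm segment yields three, so the design satisfies
this with a margin.  Zero-variance calm features are flagged and propagate
as missing (never ±∞), excluded pairwise downstream with counts recorded.
The transform is strictly within-participant (other participants' data is
irrelevant by construction) and invariant to affine rescaling of any raw
feature.

## Dual-phase screening

Phase 1 (elicitation validity): per group × emotion × feature, emotion
epochs vs calm epochs.  Phase 2 (group divergence): per condition × feature,
IWD vs HC; the calm column doubles as a built-in sanity contrast since calm
standardized values are ≈ N(0,1) for everyone.  Mann–Whitney U is two-sided,
exact (full permutation distribution) when the pooled sample is ≤ 16 and
tie-free, otherwise the tie-corrected normal approximation with continuity
correction.  BH-FDR is applied within each family of nine features (one
family per phase × emotion × contrast — matching the per-column annotation
structure of the screening grid; the family choice is configurable).
Significance requires raw p < 0.05, adjusted p < 0.05 and |d| > 0.2
simultaneously; the absolute value is used because decreases count as
responses too.  Epoch-level observations are the default test unit;
`unit="participant"` averages epochs per participant first (the conservative
variant — epochs within a participant are correlated, so epoch-level p-values
are anti-conservative; both modes ship because the choice is a genuine
design fork).

## Classifiers

One model per condition: emotion models on standardized features, the calm
baseline on raw calm features (calm standardized values are ≈ N(0,1) by
construction and carry no between-group signal).  The split is stratified by
group and grouped by participant — no participant's epochs straddle
train/test; epoch-level splitting would leak within-participant correlation
and inflate the metrics (the leaky variant is reachable by splitting the
table upstream, but the shipped protocol is the conservative one).
Hyperparameters (ERTC: trees 100–800, depth 2–16/none, min-leaf 1–8;
logistic control: C on a log grid) are selected by mean participant-grouped
5-fold CV AUC under a fixed evaluation budget, with a lightweight sequential
model-based search (extra-trees surrogate over evaluated points, argmax over
a sampled pool) or pure random search under a flag; budget 1 evaluates the
default configuration (100 trees) only.  Evaluation: accuracy and precision
at threshold 0.5 (IWD positive), rank-based AUC (equal to the normalized
Mann–Whitney U of the scores — asserted in tests), ROC from score
thresholds, and 95% percentile CIs from 2000 bootstrap resamples over test
*participants* (resampling epochs would understate the CI for the same
leakage reason; the CI method is labeled in the JSON output because several
defensible conventions exist).

## Pipeline and determinism

`run_pipeline` executes simulate → (optional render/filter/detect) →
epoch → features → standardize → screen → battery, writing every
intermediate table with fixed float formatting plus a manifest (config hash,
seed, per-file SHA-256).  Identical config + seed reproduces every byte.
The default run consumes the generator's beat times directly
(`render_ecg: false`): rendering 96 participants × ~13 min at 500 Hz is a
~40 M-sample detour that adds nothing once detector fidelity is verified
separately, and writing those waveforms as CSV would be ~600 MB.  The full
waveform chain runs in the determinism check and the examples at reduced
cohort size.

## Validation scope (what passing tests show)

The replicated experiments run at these problem sizes: 100 one-minute
epochs for respiratory recovery; five 2-min records (clean and 10 dB SNR)
for detector fidelity; 100 null-profile replicate cohorts (30/66) for
calibration (significant-cell rate ≤ 7.5%, mean AUC per condition inside
[0.38, 0.62]); 25 default-profile replicates for planted-effect recovery
(sadness RMSSD/CVSD flag rate, median sadness-vs-calm AUC, sadness-first
rank rate).

The generator emulates stationary within-segment autonomic state, clean
sinus rhythm and Gaussian-shaped QRS complexes.  It does **not** emulate
ectopic beats or arrhythmia, electrode motion artifacts, non-stationary
respiration, circadian structure, medication effects, or any coupling
between PHQ-9 severity and effect size (group membership is binary).
Passing the planted-effect tests therefore shows the *pipeline* recovers
divergences of the planted kind and size at the study's sample size — it is
evidence about the method's power and calibration, not about how real
depressed and control populations differ.

## Known limitations

- Frequency-domain indices from 1-min epochs are at the edge of validity;
  the 32-s Welch window barely resolves the LF band, and VLF is out of
  reach (hence the LF+HF normalization).
- With three calm epochs the baseline SD is noisy, making standardized
  features heavy-tailed; participant-level aggregation or longer calm
  recordings would stabilize them.
- The exact-U path switches to the asymptotic approximation whenever ties
  are present, even below the small-sample cutoff; with continuous features
  ties essentially never occur, but heavily rounded input would silently
  take the approximate path.
- The SMBO search is intentionally minimal (tree surrogate, no acquisition
  uncertainty); for the 4-dimensional spaces here it is indistinguishable
  from random search beyond small budgets.
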