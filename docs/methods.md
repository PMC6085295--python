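# Methods

## Signal model and rationale

Beat averaging exploits the one reliable property of the U wave: it recurs
at a fixed latency after every ventricular beat. Writing the recorded lead
as `x(t) = s(t - R_i) + n(t)` around each R peak `R_i`, where `s` is the
beat-locked waveform (QRS, T, U) and `n` collects the fibrillatory wave,
EMG and powerline components, the per-sample mean over N aligned beats
preserves `s` while the uncorrelated part shrinks as `sigma/sqrt(N)`. The
method only works because the f-wave's phase is unrelated to the
ventricular cycle; anything beat-locked (e.g. the preceding beat's
repolarisation tail at short RR) is preserved by the average, which is both
a feature — it is physiology — and a measurement hazard (see Limitations).

Averaging is restricted to beats with similar preceding RR because U-wave
timing and amplitude depend primarily on the preceding cycle length.
Candidates come from the modal 100 ms bin of the preceding-RR histogram
(maximises N at roughly constant RR), and the following RR must exceed
RR_min so the next QRS cannot run into the averaged U wave.

## Parameters

All amplitudes are µV, times ms, indices 0-based; histogram bins are
half-open `[left, right)` with edges anchored at multiples of the bin width
from zero, so the modal bin is exactly "RR_mode ± 50 ms". Ties between
equally full bins go to the shorter-RR bin, deterministically.

| parameter | default | meaning |
|---|---|---|
| `rr_bin_ms` | 100 | RR histogram bin width |
| `rr_min_af_ms` | 650 | min following RR, AF |
| `rr_min_sr_ms` | 800 | min following RR, SR (keeps the next P wave out) |
| `window_pre_ms` / `window_post_ms` | 250 / 650 | beat window around R |
| `qrs_onset_offset_ms` | 60 | AF baseline window ends at R − 60 ms |
| `p_onset_offset_ms` | 220 | SR baseline window ends at R − 220 ms |
| baseline window | 10 samples | taken literally at native fs (20 ms at 500 Hz, 78 ms at 128 Hz) |
| `u_search_ms` | (450, 590) | post-T apex search window |
| `u_noise_floor_uV` | 10 | presence threshold |
| `morph_corr_min` | 0.9 | QRS-template correlation below which a beat is ectopic |
| `rr_dev_frac` | 0.3 | SR-only preceding-RR deviation rule |

The search window's upper bound is deliberately below
`rr_min − qrs_onset_offset`: with RR_min = 650 ms the following R may sit
at 651 ms and its Q wave onsets near 595 ms, so searching past ~590 ms
would read next-QRS contamination in the average. The window clips to the
beat window if configured wider.

No filtering is applied before averaging by default — the averaging itself
is the noise-reduction step. An optional zero-phase 0.5 Hz high-pass for
baseline wander and a robust (median) average exist but are off, and their
use is recorded in the output provenance.

## R-peak detection and ectopic screening

Detection is a Pan–Tompkins-style chain: order-2 Butterworth band-pass
(5–18 Hz, clipped below Nyquist so the same settings serve 128–1953 Hz),
squared derivative, 150 ms moving integration, candidate peaks at ≥250 ms
spacing, and a two-stage adaptive threshold (first against the tallest
candidate to reject filter-ringing and f-wave bumps, then against the
median retained height so wide, low-slope ectopic complexes survive). The
reported index is the raw-signal maximum within ±50 ms of the fiducial. A
record with one enormous artefact can mask true beats at the first
threshold stage — acceptable for the intended inputs, and visible in the
peak count.

Ectopic beats are flagged when their R ± 60 ms window correlates with the
median beat template below 0.9; in SR an additional rule flags beats whose
preceding RR deviates from the local median by >30%. RR-deviation tests are
meaningless in AF and are disabled there. A flagged beat contributes no RR
interval on either side, so no spurious interval ever spans a removed beat.
"Confirmed by visual inspection" becomes an optional text annotation export
for external review; the core pipeline has no interactive step.

## U-wave measurement

Baseline is the mean of exactly 10 consecutive samples ending at the
estimated onset (QRS onset in AF, P onset in SR), with a flatness check
that warns when the window is electrically active. The U apex is found by
least-squares fitting `b + c·(t − t0) + A·exp(−(t − τ)²/2w²)` over the
search window; the linear part absorbs the T-wave tail and slow residual,
and the reported amplitude is the fitted apex value minus the baseline —
signed, negative for an inverted U. Reading a single extremum sample
instead (available as `apex_method="point"`) carries the full per-sample
residual noise plus a positive max-selection bias; the fit averages noise
over the window while agreeing exactly with the point reading on clean
input. If the fit fails or its apex pins to a window edge, the point
reading is used and flagged in the output.

The `u_present` call — |amplitude| above a 10 µV floor and a genuine
interior extremum — is an automatic surrogate for the visual presence
assessment a human reader would make, and is labelled as such in outputs.

## Synthetic data: what it emulates and what it does not

`synth` builds beats as sums of Gaussian kernels (Q, R, S, T, U, plus P in
SR) placed at beat times from a truncated-lognormal RR model in AF
(mean 780, sd 150, floor 400 ms — chosen so the modal bin plus the
RR > 650 ms rule pass roughly a quarter of the beats, exercising both
selection criteria) or a near-constant RR model in SR (950 ± 25 ms). The
f-wave is a sinusoid whose instantaneous frequency performs an
Ornstein–Uhlenbeck walk around 6 Hz (continuous phase, never locked to beat
times); its amplitude parameter is peak-to-peak, the convention in the
f-wave literature, so the 80 µV default oscillates ±40 µV — comparable to
the U wave itself, which is exactly why the raw trace hides it. EMG is
white noise (20 µV), powerline a 50 Hz sinusoid (5 µV). Ectopics are
inserted as premature wide-QRS beats. Ground truth (R samples, ectopic
flags, planted U amplitude) accompanies every record, and everything is
bit-reproducible from (config, seed).

Deliberately not emulated: amplitude modulation and harmonics of real
f-waves, respiratory baseline wander, electrode artefacts, T-wave
alternans, and the sharper-than-Gaussian offset of real T waves. Passing
tests therefore demonstrate the algorithm's behaviour under idealised but
adversarial-amplitude noise, not robustness to every clinical artefact.

Problem sizes used in the test-bench runs: 420–480 s records at 500 Hz
(enough for 100+ qualifying beats), 10-record cohorts for the
number-of-beats summary, 1000 draw-level cohorts for t-test calibration.

## Numerical choices and degenerate inputs

- Alignment is at the integer R-apex sample; at 500 Hz the quantisation is
  ≤ 1 ms and no sub-sample interpolation is attempted.
- The average of identical beats reproduces them to float precision; the
  reference sub-trial's ΔU amp is exactly zero by construction.
- McNemar with zero discordant pairs, paired t with zero-variance
  differences, and a repeated-measures ANOVA with zero between-record
  variance all return flagged degenerate results (p = 1 by convention)
  instead of raising.
- Flat or empty signals yield empty peak series with warnings; zero
  qualifying beats produce a per-criterion failure count in the
  diagnostics.

## Known limitations

- **Preceding-RR overlap.** When the modal RR bin is fast (below ~700 ms),
  the preceding beat's T/U tails genuinely overlap the pre-QRS baseline
  window. This contamination is beat-locked, so averaging preserves it and
  baseline-to-peak amplitude then measures U relative to an elevated
  baseline. The flatness check warns; no automatic correction is applied.
  The same physiology hides U waves at fast SR rates behind the next P
  wave, which the pipeline flags when the median SR RR is below 700 ms.
- **Measurement noise floor.** With an 80 µV p-p f-wave, the f-residual
  after averaging 100 beats is ~2.8 µV RMS, and the 10-sample baseline
  window (20 ms at 500 Hz, shorter than the f-wave correlation time)
  inherits it in full. Single measurements therefore carry a few µV of
  irreducible uncertainty under these conditions; the 4–9 Hz residual also
  partially overlaps the U-wave band, bounding what any apex estimator can
  remove within one beat window.
- One modal bin only: no multi-bin pooling or heart-rate correction of U
  timing; no T-end delineation; no 12-lead fusion or lead-selection
  heuristics beyond the V4-first preference.
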