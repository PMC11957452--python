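# Methods

This note records the models, numerical choices and open design decisions
behind `belumask`, in the spirit of a statistical software methods appendix.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Calibration

A digital sample d ∈ [−1, 1] maps to pressure p = d · V_peak ·
10^(−(S+G)/20) µPa, with S the end-to-end sensitivity (dB re 1 V/µPa) and G
any added gain. Two deployment presets are built in: SoundTrap HF300
(288 kHz, 16-bit, −172.7 dB) and icListen HF (256 kHz, 24-bit, −170 dB).
The mapping is linear and invertible; synthesized scenes round-trip through
PCM WAV within quantisation (the 16-bit LSB at −172.7 dB sensitivity is
~82 dB re 1 µPa, far below the synthetic ambient bed, so round-trip RMS
error is well under 0.1 dB).

## Spectral estimation

* Welch SSDL: 1-s Hann windows, 50% overlap, density scaling, so bins are
  1 Hz apart and band-limited white noise of variance σ² reads
  σ²/(fs/2) µPa²/Hz. Ten 0.5-s call-free snippets are concatenated into one
  5-s sample (9 snapshots) rather than averaging ten separate 0.5-s spectra:
  0.5-s windows cannot give 1-Hz bins, and the per-bin average over the 5 s
  is the quantity the analysis needs.
* All averaging and band integration happens in linear power; dB only at
  interfaces. A chi-square estimator note: averaging *dB values* of a noisy
  spectrum is biased low by ≈ 4.34/(2·n_eff) dB; tests that check the white
  noise closed form therefore average power, not dB.
* Bins below 100 Hz are discarded after estimation (shallow-waveguide
  cutoff; local flow noise), not filtered in the time domain.
* 1/3-octave bands use the base-10 convention: centers 10^(n/10) Hz, edge
  ratio 10^(1/10), half-open [lower, upper) membership. Only bands fully
  inside the spectral coverage are kept, so there are no under-integrated
  partial bands at the 100-Hz floor or at Nyquist.
* The waveguide cutoff helper uses the quarter-wavelength form
  f₀ = c_w / (4 z √(1 − (c_w/c_b)²)). With z = 20 m and c_w/c_b = 0.95 this
  gives ~58 Hz for c_w = 1450 m/s; the exact constants any user assumes
  should be reported alongside results, since f₀ is sensitive to both.

## Signal excess and masking frequency

ΔSSDL per band is the during level minus the *linear-power* mean of the
before/after levels (averaging in dB would understate the baseline by the
Jensen gap; the linear mean is the physically meaningful expected power).
f↓ is the lowest band center at which ΔSSDL ≤ 0 **and remains ≤ 0 for all
higher bands** — a suffix condition rather than a first-crossing rule, so a
single noisy dip below zero in the middle of a vessel-dominated range does
not produce a spuriously low f↓. The lower bound shifts the threshold up by
the hydrophone measurement uncertainty (default ±3 dB). Events with no
qualifying band are flagged full-band and excluded (never imputed) from the
mean/SD/percentile summary, with their count reported.

## Synthetic soundscapes

The generator's job is to produce data with the statistical structure the
analysis assumes, with every quantity the pipeline estimates known by
construction.

* **Ambient bed**: Gaussian-like noise with deterministic spectral
  magnitudes (−5 dB/decade, 60 dB re 1 µPa²/Hz at 1 kHz by default) and
  random phases. Deterministic magnitudes keep 5-s band levels tight so
  recovery tests measure the estimators, not synthesis noise.
* **Ambient drift**: the bed's level changes linearly in dB across
  before → during → after (default |change| drawn from 2–3.5 dB, random
  sign), emulating tidal-cycle nonstationarity at an estuarine site.
  Because the masking baseline is the linear mean of the before/after
  levels, symmetric drift of ±g dB places the baseline
  10·log₁₀ cosh(g·ln10/10) dB (≈0.4–1.3 dB) above the during ambient.
  This is what lets ΔSSDL fall below zero above the vessel's spectral
  reach — the same below-zero excursions real noise events show — and it is
  a deliberate design choice: with a drift-free bed, ΔSSDL above the
  rolloff would hover at +ε with random sign and the suffix rule would
  almost never latch. Consequently the f↓ estimate lands in the band at or
  just above the vessel–ambient crossing (the crossing band itself still
  carries ~3 dB of excess), a positive bias of at most one band that the
  recovery tests account for.
* **Vessel noise**: power-law density (−15 dB/decade default) times an
  order-10 Butterworth-style magnitude cutoff at `rolloff_hz`
  (~200 dB/decade beyond). When the renderer constructs the vessel for a
  scene it sets the level so the vessel density crosses the ambient bed
  exactly at the rolloff, making `rolloff_hz` the ground-truth masking
  frequency; `rolloff_hz = Nyquist` emulates small fast craft that dominate
  the full recorded bandwidth.
* **Calls**: pulsed classes are trains of 0.3-ms Hann-windowed transients
  amplitude-modulating a band-limited noise carrier, brick-wall filtered to
  the template band (so measured band edges are sharp); whistles are FM
  tones with harmonics; biphonal calls add a low-frequency harmonic stack
  (~0.8 kHz fundamental reaching ~12 kHz) separated from the main band by a
  silent gap. Template defaults follow the measured HFBP population
  statistics (band onset 36.4±6.5 kHz monophonic / 34.5±6.7 kHz biphonal,
  upper limit at Nyquist, duration 0.4±0.3 s) and the contact-call
  description (broadband from 200 Hz, >1 s); apparent level defaults to
  130 dB re 1 µPa RMS, ~20–25 dB of in-band SNR over the default bed.
  Pulse repetition defaults to 300 s⁻¹ (not reported for the real calls;
  chosen as a plausible burst-pulse rate), and buzzes accelerate with a
  fractional IPI trend of −0.8.
* **Counts**: per treatment × class, negative-binomial around a shared
  per-event log-normal intercept (θ = 2, σ_event = 0.8 by default) — the
  same family the rate model assumes.
* **Placement**: uniform random start times, whole-placement retried up to
  100× until ten 0.5-s call-free windows remain per treatment (the noise
  snippets the spectral chain needs); an optional minimum call separation
  supports controlled non-overlapping scenes. Scenes never clip at the
  default levels; clipping would be warned about and recorded in the scene
  log.

What the generator does **not** emulate: propagation and reverberation,
vessel source-level physics, frequency-dependent absorption, animal
movement, overlapping-source mixtures beyond chance call overlap, or
recorder self-noise. Passing tests therefore demonstrate correctness of the
estimators under the assumed statistical structure, not field performance.

## Call measurement and classification

* `measure_call` uses a 1024-point Hann Welch spectrum of the selection:
  peak = argmax; center/Q1/Q3 at 50/25/75% cumulative energy within the
  analysis band (bin resolution, matching a cumulative-sum oracle);
  low/high at the first/last bins within 20 dB of the peak. A call whose
  band reaches Nyquist reports high = fs/2 exactly. Low/high are widened to
  the quantiles in the rare case the threshold crossing would invert the
  ordering, so low ≤ Q1 ≤ center ≤ Q3 ≤ high always holds.
* `spectral_components` automates the analyst's reading of the
  spectrogram: contiguous spectral runs within 20 dB of the ultrasonic peak
  are components; the run holding that peak is the main pulse band; a run
  below 20 kHz is a biphonal LF element if it clears the ambient floor by
  6 dB and the gap to the main band dips 10 dB below the LF peak. When
  adjacent call-free audio is available the background spectrum (per-bin
  minimum of the two flanking 0.5-s windows) gates the analysis —
  spectrogram contrast — which keeps vessel noise from either faking an LF
  element or welding the biphonal components together.
* `detect_pulses`: 4th-order Butterworth band-pass, analytic-signal
  envelope smoothed over 0.15 ms, peaks >10 dB above the median envelope
  with ≥0.2 ms separation. Pulse-train statistics: rate = 1/median IPI,
  IPI coefficient of variation, least-squares IPI slope, and the fractional
  IPI trend (slope × span / mean IPI) used for buzz detection.
* Classifier thresholds (all configurable, none dictated by the recordings):
  IPI CV ≤ 0.35 operationalizes "consistent repetition rate"; fractional
  IPI trend < −0.3 operationalizes buzz acceleration; ±1 s operationalizes
  adjacency to echolocation click trains; contact calls need ≥20 kHz of
  bandwidth and ≥0.5 s. Two printed band thresholds coexist: ≥20 kHz gates
  HFBP, and absence of energy below 30 kHz characterizes the monophonic
  subtype. By default a consistent no-LF train starting between 20 and
  30 kHz still counts as HFBP_M — the pooled HFBP category is what the rate
  analysis consumes, and ultrasonic trains were counted as HFBP regardless
  of subtype; `strict_hfbp_m=True` restores the strict reading (such calls
  fall to OTHER). A biphonal call whose LF element is masked by noise
  degrades to HFBP_M, which the HFBP pooling absorbs.
* Overlapping calls are classified independently per selection; no source
  separation is attempted, so dense scenes can contaminate each other's
  measurements.

## Rate model

Counts (not pre-divided rates) with a log-exposure offset, NB2 response,
treatment × call-type fixed effects and a per-event random intercept. The
reference level is (during, CC), so `before`/`after` main effects are the
contact-call log rate-ratios against the noisy phase and the six reported
contrasts are linear combinations of at most two coefficients.

Estimation maximizes the Laplace-approximated marginal likelihood: the
1-D conditional mode per event is found by safeguarded Newton (the
conditional log-density is strictly concave in the intercept), and the
outer problem over (β, log θ, log σ) runs L-BFGS-B with central-difference
gradients under box bounds log θ ∈ [−8, 8], log σ ∈ [−6, 3]. The θ upper
bound is the Poisson limit; equidispersed data legitimately converge there.
Convergence requires a projected central-difference score below 1e−4 in
max-norm (the inner solve always starts from zero so the objective is a
deterministic smooth function of the parameters); up to five seeded random
restarts follow a failed attempt. Standard errors come from the inverse
numerical Hessian of the negative marginal log-likelihood, with boundary
variance parameters held fixed (conditional information). Wald coverage of
the fixed effects and null z-calibration are verified by simulation in the
test suite.

Holm adjustment is applied jointly to the six within-type treatment
contrasts — back-calculation from the published contrast table confirms the
six contrasts were adjusted as one family. The variance decomposition is the
marginal/conditional pseudo-R² for log-link count models: σ²_f is the
variance of the fixed-effect predictor over the data, σ²_α the random-
intercept variance, and the distribution-specific residual variance uses the
trigamma form ψ₁((1/λ + 1/θ)⁻¹) with λ = exp(mean linear predictor + σ²_α/2);
the lognormal and delta forms differ by at most a few points at these
parameter values, and the trigamma form is the one implied by the published
shares. The three shares sum to 100% by construction.

## Pipeline and reproducibility

All randomness flows from one seed through `numpy.random.SeedSequence`
spawning, so a config plus seed pins every byte of the outputs (reports are
JSON with sorted keys; reruns are byte-identical). Every report embeds the
config hash and seed. Events with zero calls across all treatments are
dropped from the rate analysis and listed in the report. Manifest validation
enforces the experimental-design constraints: treatments ≤ 5 min and ≥10 min
separation between events.

Default problem sizes (test suite and demo configs) are scaled to
desk-top runs: treatment clips of 8–60 s instead of 5 min, 4–12 events,
100 GLMM recovery replicates of 200 events; the estimators are size-agnostic
and the spectral chain always operates on the same 5-s concatenated noise
sample the full-scale design produces.

## Known limitations

* The masking-frequency estimate is positively biased by up to one
  1/3-octave band (the crossing band retains ~3 dB of excess by
  construction of the baseline).
* The classifier's thresholds are calibrated on the synthetic call model;
  field recordings will need threshold review, especially the buzz
  adjacency window and LF-element contrast.
* The Laplace approximation is known to bias variance components slightly
  low with few observations per group; with 9 cells per event and 20+
  events the fixed-effect coverage is nominal in simulation, but σ²_event
  itself is estimated with noticeable downward bias at small event counts.
* The chi-square reconstruction of repertoire proportions is limited by the
  rounding of the published percentages (~0.1% on the statistic).
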