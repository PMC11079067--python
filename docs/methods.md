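# Methods

## Model and procedure

The pipeline treats an intraoperative binaural BAEP session as two parallel
streams of averaged epochs, one per ear, each epoch summarized by ten
indicators: absolute latencies of waves I–V (ms), interpeak latencies I–III,
III–V, I–V (ms), and peak-to-trough amplitudes of waves I and V (µV). The
analysis proceeds in five stages.

1. **Pairing.** Affected- and healthy-side epochs are matched by timestamp
   proximity under the synchronicity criterion |Δt| ≤ 180 s (the "≤ 3 min"
   rule, interpreted inclusively). Matching is greedy on increasing interval
   with each epoch used at most once; with near-alternating streams this is
   equivalent to optimal bipartite matching, and the implementation is
   isolated behind `pair_streams` so it can be swapped. Pairs must share a
   surgical phase; unmatched epochs are dropped, and the per-patient pairing
   yield is logged because pairing loss is the pipeline's main attrition
   point.
2. **Phase summarization.** Epochs between tumor exposure and complete
   resection are excluded. Within the pre-resection and post-resection
   phases, each indicator is collapsed per ear to its median over the epochs
   where it is present (mean available as an option). The median is chosen
   for robustness to the outlier epochs that interference produces. An
   indicator absent in more than half of a phase's pairs is absent from the
   summary — a vanished wave is qualitatively different from a small one and
   is never imputed.
3. **Standardization.** Per indicator, STI = affected/healthy − 1
   (dimensionless; exactly cancels multiplicative common-mode factors),
   D = affected_post − affected_pre, and STD = D − (healthy_post −
   healthy_pre) (exactly cancels additive common drift). Absence propagates;
   a healthy-side zero raises a division-guard error naming the indicator.
   When a constant laboratory normal reference value is configured, the
   reference-scaled diagnostics reference·(a/h) and reference·STI are also
   reported; they are constant multiples of STI and carry no additional
   information. A subtraction of the reference from the raw affected value
   is likewise exposed only as a diagnostic.
4. **Outcome labeling.** Audiometry (PTA, WRS) is graded by the AAO-HNS
   1995 thresholds — A: PTA ≤ 30 and WRS ≥ 70; B: PTA ≤ 50 and WRS ≥ 50;
   C: PTA > 50 and WRS ≥ 50; D: WRS < 50 — and HP = class A–C, which under
   these thresholds is equivalent to WRS ≥ 50 %. Cohort percentages are
   rounded half-up to one decimal; postoperative class percentages use the
   preop-HP subgroup as denominator, with the cohort-wide rate reported
   alongside.
5. **Predictor evaluation.** Univariate binary logistic regression per
   indicator (maximum likelihood, Wald 95 % CI and p — Wald rather than
   profile likelihood to match mainstream clinical statistics software);
   variables with p ≤ 0.05 enter a stepwise multivariate model (backward
   elimination with stay threshold p ≤ 0.05 by default; forward selection
   available). ROC analysis reports the rank-statistic AUC (ties
   half-counted, orientation as given — an inversely oriented predictor
   reports AUC < 0.5), the cutoff maximizing Youden's J over observed score
   values with the decision rule score ≥ cutoff, and sensitivity/specificity
   at that cutoff. Correlated AUCs on the same subjects are compared with
   DeLong's paired test (implemented here; no installed dependency provides
   it). Paired t-tests and one-way ANOVA cover the audiometric group
   contrasts. Missingness is handled complete-case per model with the n
   used reported.

Three analyses are run: pre-resection indicators (raw and STI) against
preoperative HP on the whole cohort; post-resection indicators against
postoperative HP on the whole cohort; and D/STD differences against
postoperative HP within the preop-HP subgroup.

## Synthetic cohort generator

The generator is the package's test bed and defines its study conditions.
Per patient it draws a latent cochlear-function variable f ∈ [0, 1], with a
preoperative value (tumor compression) and a postoperative value f_post ≤
f_pre (surgical injury), interpolated linearly across the resection window.

* **HP structure, label-first.** The preoperative HP label is
  Bernoulli(0.661) and, among preop-HP patients, the postoperative label is
  Bernoulli(0.452); WRS is then drawn from truncated normals inside the
  class band (preop preserved: mean 66, sd 11 on 51–90 %; postop preserved:
  mean 63.6, sd 6.7 on 50–83 %; lost: mean 30, sd 12 on 5–48 %) and inverted
  through the audiometric link to obtain f. This makes the generated HP
  rates match their targets exactly in expectation while giving the latent
  injury severity a realistic audiometric marginal distribution.
* **Audiometric link.** WRS(f) is a logistic in f (slope 8, midpoint 0.45)
  scaled so f = 1 maps exactly to the configured maximum (90 %); PTA(f) is
  affine decreasing from 100 dB at f = 0 to 10 dB at f = 1. Outputs are
  clamped to WRS ∈ [0, 100] %, PTA ∈ [0, 120] dB, with 1 dB/percentage-point
  measurement noise. Monotone forms suffice for the parameter-recovery and
  calibration tests; the link is not calibrated to audiological growth
  functions.
* **Feature streams.** Epochs every 168 s per ear (2000 sweeps at 11.9 Hz),
  healthy side offset by 60 s — the inter-ear offset is a parameter because
  simultaneous vs alternating stimulation is an open acquisition choice —
  with 4 % epoch dropout so the pairing rule is exercised non-trivially.
  Baselines per ear scatter around canonical reference latencies
  (I 1.7, II 2.8, III 3.9, IV 5.1, V 5.7 ms) and amplitudes (I 0.20,
  V 0.30 µV). Injury adds `injury_effect_latency` (default 1.0 ms per unit
  dysfunction 1 − f) to wave V's latency and removes
  `injury_effect_amplitude` (default 0.8 fractional per unit) of wave V's
  amplitude, affected side only. A wave whose amplitude falls below 0.05 µV
  is reported absent ("wave disappearance"); the threshold is configurable.
* **Common-mode interference** is a stationary AR(1) log-drift evaluated on
  a 30 s grid and applied multiplicatively to BOTH ears — one trajectory for
  amplitudes (sd 0.7) and a separate, much smaller one for latencies
  (sd 0.02), since sub-microvolt amplitudes drift far more than conduction
  times; correlation time 60 min. The amplitude scale is set so the session
  drift is large relative to the injury effect (×0.5–2 swings over an
  hours-long case), which is the regime in which raw amplitude indicators
  are unreliable (AUC < 0.7) and healthy-side referencing pays off: this is
  the package's central demonstrated condition, not a fitted quantity.
  Per-epoch measurement noise (log-amplitude sd 0.15, latency fraction
  one-tenth of that) is independent across ears and epochs.
* **Determinism.** Each patient consumes independent child seed streams for
  latent draws, baselines, drift, measurement noise, dropouts, demographics
  and audiometry, so cohorts are byte-reproducible given the seed and any
  single noise source can be switched off without perturbing the others
  (this is what makes the drift-division recovery test exact).

What the generator does *not* emulate: real ABR morphology (waves are
reduced to indicator vectors; the waveform module renders stylized biphasic
peaks, not far-field potentials), electrode or impedance artifacts,
non-common-mode unilateral interference (e.g. drill noise near one ear),
demographic–outcome correlations, surgeon-dependent injury dynamics, or
delayed hearing deterioration after discharge. Passing tests therefore show
that the analysis machinery is correct and that the standardization rescues
a predictor under shared multiplicative drift; they do not validate the
clinical effect size on real patients.

## Waveform layer

The optional waveform round trip renders each present wave as a Gaussian
positive lobe (σ = 0.08 ms) followed 0.3 ms later by a matched negative
lobe, scaled so the component's on-grid peak-to-trough distance equals the
wave's amplitude; residual noise scales as noise_sd/√averages. Extraction
takes, per canonical search window (I 1.2–2.2, II 2.3–3.3, III 3.4–4.5,
IV 4.6–5.4, V 5.4–6.8 ms), the maximal positive sample (earliest on ties,
for determinism), then the minimum between that peak and the start of the
next wave's window — the trough search deliberately stops at the next
window (end of recording for wave V), an interpretation of "positive peak to
next negative peak" that keeps windows independent. Amplitudes below
0.05 µV mark the wave absent. At the default 40 kHz sampling the round-trip
tolerances are one sample (0.025 ms) in latency and the grid-reading error
(≤ 2 % + 1 nV) in amplitude, both verified over randomized feature vectors.
Waveforms are exchanged in a two-column plain-text format
(time_ms, amplitude_uv) with a metadata header line.

## Numerical and interface choices

* Pairing interval boundary inclusive at 180 s; candidate order and
  tie-breaks fully deterministic.
* Youden cutoff chosen among observed score values only (the degenerate
  predict-nothing threshold is excluded); on J ties the higher, more
  specific cutoff is reported.
* Logistic degenerate cases: a constant predictor returns the null result
  (OR 1, p 1) with status `degenerate`; complete separation is detected
  (boundary fitted probabilities, exploding |β| or non-finite SEs) and
  flagged `separated` rather than reported as an astronomically small p —
  separated univariate fits are excluded from the stepwise candidate set.
  Duplicate/collinear stepwise candidates are pruned by incremental rank.
* DeLong variance of zero (rank-identical scores) returns p = 1; fewer than
  two subjects in a class returns p = 1 (no evidence).
* CSVs carry a versioned `# schema=` header, floats are written at 17
  significant digits and parsed in round-trip mode, so re-running any stage
  from persisted artifacts is byte-identical.
* All cohort randomness flows from one integer seed through spawned
  `SeedSequence` children.

## Problem sizes

Default cohort 127 patients (~85 epochs per ear, ~240 min surgery). The
replicate study behind the headline comparison uses 100 seeded replicates in
the test suite and 25 in the acceptance script; type-I calibration uses 1000
pure-noise predictors in the suite and 400 in the script. These sizes give
Monte-Carlo error comfortably below the margins asserted.

## Known limitations

* Under purely multiplicative drift the additive STD correction is
  imperfect by construction (the drift factor multiplies the injury signal
  itself), so STD's advantage over D is smaller here than the standardized
  ratio's advantage over raw values; the two difference indexes' AUCs are
  close, mirroring their statistically indistinguishable performance in
  clinical reports.
* Latency-based indexes are oriented "larger = worse"; their AUCs are
  reported as computed (below 0.5) rather than flipped, so readers must
  interpret orientation from the sign of the association.
* The stepwise procedure inherits the usual instability of stepwise
  selection at n ≈ 127; it is provided because it is the field's standard
  screening practice, not as a recommendation.
* Epochs are reduced to indicators before analysis; no denoising or
  artifact rejection at the waveform level is attempted.
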