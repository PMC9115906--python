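# Methods

This note documents the models implemented in `thermoloop`, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
cohorts can and cannot tell you about real trials.

## Heat-load index and room programs

The temperature-humidity index is computed as
`THI = 0.8·TA + (RH/100)·(TA − 14.3) + 46.3` from instantaneous (TA, RH)
pairs. Two aggregations are exposed and never silently interchanged:
`mean_of_thi` (average the hourly indices) and `thi_of_means` (index of
the average conditions). THI is bilinear in TA and RH, so the two differ
whenever conditions vary; a thermoneutral room logged at TA 20.34 °C /
RH 71.51 % has a set-point THI of 66.9 while the mean of its fluctuating
hourly indices sits slightly higher.

The advisory categories are printed as integer bands with gaps
(…≤74, 75–78, 79–83, ≥84…). For continuous THI values we use the
half-open convention Normal ≤ 74 < Alert ≤ 78 < Danger ≤ 83 < Emergency,
so every real value maps to exactly one category and the mapping is
monotone.

The diurnal program interpolates set-points piecewise-linearly between the
schedule anchors (trough until 0700 h, plateau 0900–1600 h, trough again
at 2000 h), evaluated on the hour. The program generator emits *targets*;
whether a physical room tracks them with lag is outside its scope.

## Preprocessing rules

* Respiration rate is derived from the time for ten flank movements:
  `RR = 600 / seconds`.
* Rumen-temperature readings ≤ 35 °C are discarded (bolus hardware spans
  30.5–44.4 °C; values at the floor reflect drinking artefacts or faults).
  An optional, off-by-default mask additionally removes RT readings within
  60 min after a ≥ 8 L drinking event; the window and threshold are
  configurable because no accepted standard exists. Every removal is
  logged with its reason.
* Bolus retransmissions (each transmission repeats the previous 11
  points) are collapsed to one value per animal–measure–timestamp.
  Conflicting duplicates are resolved *latest transmission wins*, on the
  view that retransmission acts as a correction channel; conflicts are
  logged, never silent. Note that two consecutive transmissions of 12
  points sharing 11 yield 13 unique points — the union, not either
  transmission alone.
* Daily water consumption is the day's closing meter reading minus the
  previous day's close; summed over the trial this telescopes to the
  total meter span, which the tests assert as a conservation law.
* DMI = (offered − refusals, as-fed) × diet DM fraction, plus the fixed
  1.08 kg DM chaff allocation. Refusal DM uses the diet DM fraction
  (refusals are not itemized by component). `chaff_policy` controls
  whether chaff counts fully (`assume_consumed`, default — chaff is
  consistently consumed first in practice) or in proportion to the grain
  consumed (`prorate_refusals`).
* Daily means weight all retained records of a measure equally and store
  the contributing count beside each mean. Bolus RT contributes ~144
  records/day while observer measures contribute 7 (or 12 on
  around-the-clock challenge days); the counts make that coverage
  difference visible rather than hiding it. A day with no retained
  records yields a missing value, never zero.
* Trial calendar: Pre-Challenge days 1–4, Challenge 5–11, Recovery 12–18,
  with days 4 and 12 flagged as transitions.

## Ellipse engine

The conic `a x² + b x y + c y² + d x + e y + f = 0` is fitted by direct
least squares under the constraint `4ac − b² = 1`, solved as a 3×3
generalized eigenproblem on the stabilized block partition of the scatter
matrix. This guarantees an elliptical solution whenever one exists; the
unconstrained algebraic fit (SVD null vector) is attached to the error as
a diagnostic when it does not.

Numerical choices:

* **Conditioning.** Each axis is centered and scaled to unit variance
  before solving, and the coefficients are back-transformed. RT spans
  ~1 °C while DMI spans ~4 kg·d⁻¹; raw-unit design matrices are
  ill-conditioned. Reported coefficients and geometry are in raw data
  units (the canonical form); fitting on standardized data is what the
  conditioning step does internally.
* **Normalization.** Coefficients are scaled to unit Euclidean norm with
  `a + c > 0`, making fits of the same curve comparable; all geometry is
  invariant to coefficient rescaling.
* **Geometry.** The center solves the gradient system; semi-axes and
  rotation come from the eigen-decomposition of `[[a, b/2], [b/2, c]]`
  with the translated constant. Tangency extrema (horizontal/vertical
  tangents) are evaluated in closed form from the parametric
  representation and checked in tests against a 10⁵-point parametric
  oracle. Rotation is reported in (−π/2, π/2].
* **Orientation.** The shoelace signed area over the chronologically
  ordered points, in the plotting frame with RT rightward and DMI upward;
  negative area is clockwise. Magnitudes below 10⁻⁹ of the bounding-box
  area are `undetermined` (degenerate/collinear trajectories).
* **Goodness of fit.** Two definitions, always tagged: the
  *responding-variable* R² predicts y at each observed x on the nearer
  ellipse branch (ties deterministically to the upper branch; x outside
  the ellipse's extent contributes its residual to the nearest
  vertical-tangency y) and forms `1 − SS_res/SS_tot` about the mean
  observed y; the *Sampson* R² normalizes the summed squared Sampson
  (first-order geometric) distances by the total bivariate scatter.
  Zero `SS_tot` flags the responding-variable R² undefined rather than
  raising.

At least 6 points are required; collinear or constant-axis inputs raise a
rank error.

## Linear battery and contrasts

Simple OLS per (x, y, group) on *group-level* daily means (animals
averaged within arm and day, then days regressed), with Pearson r and the
two-sided slope t-test. Days are serially correlated but treated as
independent observations — the convention for this trial design — and
every fit carries an explicit caveat field saying so. Pooled fits
concatenate both arms' daily means without weighting. p < 0.05 is labelled
significant and 0.05–0.08 a tendency. Day-wise group comparisons use
Welch's unequal-variance t-test per day and measure, with no multiplicity
correction by default (Holm available); degenerate days (single animal,
zero variance) report the difference but suppress the test. An optional
flag drops day 1 from water-consumption fits, whose drinking is inflated
by drinker training.

## Synthetic cohort generator

Defaults are the study conditions: 18 pairs, 18 days, Challenge on days
5–11; thermoneutral band THI ≈ 68–71 (TA 21.1–23.1 °C at RH 70 %),
Challenge band THI ≈ 73–84 (TA 26.0–34.5 °C at RH 50 %); FRTN rooms at
TA 20.34 °C / RH 71.51 % throughout. Hourly room noise (SD 0.25 °C TA,
2 % RH) is shared within a room, not per animal.

Dynamics, per animal:

* `RT` relaxes hourly (τ = 6 h) toward
  `baseline + 0.33·max(0, THI − 74) + 0.14·(DMI_prev − 11.2)`.
* Total appetite relaxes daily (τ = 2 d) toward
  `baseline − 7.0·max(0, RT_day − 39.8)`.
* Offers follow the pair rule (previous-day TC intake + 20 %, both arms
  the same day), with the FRTN step-down capped at 2.5 kg/d; intake is
  the lesser of appetite and offer plus small noise.
* RR, PS, the four surface temperatures and WC are linear in the day's
  latent mean RT plus iid observation noise (slopes 46 bpm/°C,
  0.63 PS/°C, 4.3 °C/°C head ST, 10.5 L/°C); PS is clipped to the 0–4.5
  half-step scale. Responses are driven by the *daily-mean* latent RT
  rather than the instantaneous hourly RT: the battery operates on daily
  means, and an instantaneous driver would introduce a daytime-coverage
  covariate mismatch this design never intends to probe.
* Live weight integrates 1.3 kg per kg DMI above a 9.8 kg maintenance
  level, recorded on the ten weigh days.

The heat sensitivity (0.33 °C per THI unit above threshold) and appetite
suppression (7.0 kg per °C above threshold) were set from the
steady-state balance of the two feedback loops so that a sustained
Challenge plateau settles near daily-mean RT 40.4 °C and intake 7.0
kg·d⁻¹, with the transition-day sensitivity ≈ 0.09 °C per daily-mean THI
unit — the operating point this class of moderate-heat-load trial reports.
An adapted-state option (default on) lowers the RT baseline by 0.06 °C
and appetite to 88 % from Recovery onward, so Recovery does not simply
retrace Pre-Challenge (the intake deficit itself contributes a further
≈ 0.19 °C RT reduction through the feeding term). A transient
stress-induced-hyperthermia bump for the FRTN arm (0.2 °C, days 3–6) is
available but off by default. Between-animal variation enters as random
intercepts on the RT baseline (SD 0.1 °C) and appetite baseline
(SD 0.5 kg).

Because the RT lag is fast (hours) and the intake lag slow (days), the
daily (RT, DMI) trajectory over challenge and recovery closes into a
clockwise loop; the configuration validator enforces τ_DMI (days) >
τ_RT (hours)/24.

Within-day RT noise (SD 0.15 °C per 10-min transmission) is chosen for
test power, not measured fidelity — no published within-day variance was
available to calibrate it.

**What the generator does not emulate:** heat-balance energetics, rumen
fermentation, staggered cohort entry dates (all pairs share one date
axis; the analysis is date-shift invariant), bolus dropouts and
transmission conflicts (constructed fixtures cover the dedupe logic),
drinking-event RT artefacts, and weather-station noise structure.
Passing recovery tests therefore demonstrate that the *analysis* is
correct and well calibrated under the assumed structure, not that real
cattle behave this simply.

## Determinism and problem sizes

All randomness flows from one `numpy` generator seeded from the config;
the same config and seed reproduce every table and report byte-for-byte.
Monte-Carlo guarantees are asserted at 200 replicates (ellipse recovery
at 2 % noise; confidence-interval coverage of the generating slopes,
accepted between 85 % and 99 % at nominal 95 %), 50 replicates
(opposing DMI–RT slope signs in ≥ 90 % of runs) and 1000 replicates
(null calibration of the slope test at 5 % ± 2 points); the cohort
simulator's vectorized daily path makes each replicate a few tens of
milliseconds.

## Known limitations

* The serial-correlation caveat on the battery is real: p-values are
  anti-conservative for strongly autocorrelated series. Mixed-effects
  repeated-measures modelling is deliberately out of scope.
* The responding-variable R² depends on branch assignment near the
  vertical tangencies; with very noisy data points may flip branches.
  The Sampson R² is the stabler companion and both are always reported.
* The ellipse model assumes one closed loop; trajectories with multiple
  lobes or drift fit poorly and should be screened with the direction
  statistic (`undetermined`) and R² before interpretation.
* Panting score is treated as numeric on the 0–4.5 half-step scale;
  ordinal-scale analyses are not provided.
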