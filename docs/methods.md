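# Methods

`neolus` implements a quantitative analysis of lung aeration after birth as
measured by lung ultrasound (LUS), together with the synthetic cohort used to
exercise it end to end. This note documents the models, the defaults and the
numerical choices, and what the synthetic data does and does not establish.

## Aeration from pixel statistics

A liquid-filled newborn lung images like solid tissue: homogeneous speckle
with a faint or absent pleural line. As air enters, the pleural interface
becomes strongly reflective and the image below it is dominated by
reverberation artifacts (horizontal A-lines, vertical B-lines) over a dark
field. The pixel-intensity coefficient of variation

    CoV = SD(intensity) / mean(intensity)

inside rectangular regions of interest (ROIs) below the pleural line — placed
between the acoustic shadows of the ribs — therefore rises with aeration. The
estimated proportion of air (EPA) is a linear function of CoV, clamped to
[0, 1]: 0 is a fully liquid-filled lung, 1 a fully air-filled one.

Numerical choices:

* **Population SD (ddof 0), not sample SD.** The ROI's pixels are the whole
  population under study; fixing this makes CoV reproducible to the last bit.
* **Aggregation.** CoV is computed per (frame, ROI) and then averaged over
  frames and ROIs ("the mean CoV in these regions"); pooling all pixels first
  is available as `pool_pixels=True` but is not the default.
* **Gain invariance.** CoV is invariant under multiplicative intensity
  scaling, so EPA does not depend on scanner gain given a fixed calibration.
  Intensities are converted to float64 before any statistic; there is no
  histogram preprocessing.
* **Motion exclusion.** A frame is excluded when its mean absolute
  difference from the previous frame, divided by the clip's global mean
  intensity, exceeds a threshold (default 0.15). The first frame is never
  flagged by this rule, so at least one frame always survives. The threshold
  is a package choice; the underlying protocol states only that movement
  frames were excluded.
* **Calibration.** `fit_calibration` is an ordinary least-squares line from
  CoV to a reference EPA. The original calibration coefficients are not
  published, so the pipeline fits its own on synthetic reference clips with
  known air fraction (R² of this fit is reported and is ≥ 0.99 at defaults).

ROIs are 0-based, half-open pixel rectangles with a 64-px minimum area,
stored in JSON next to the clips; clips travel as 8-bit multi-page TIFF or
multi-frame DICOM secondary capture.

## Ordinal grading and backsliding

The ordinal grade {0, 0.5, 1, 2, 3} describes the qualitative appearance
(hepatisation → speckled pleural line → white-out → B-lines with A-lines →
pure A-lines). Grades are summarised as median (IQR) with
linear-interpolation quantiles; inter-rater agreement is raw percent exact
agreement.

Backsliding between consecutive scans is defined as (i) any strict decrease
of the grade in either lung — 0.5-steps count, since 0.5 is a grade — or
(ii) a decrease of EPA by strictly more than 0.2 in either lung. An event is
severe when the grade after the drop is ≤ 1, or when an EPA-drop event
leaves the mean EPA over the available lungs strictly below 0.6. A
consecutive pair may yield both a grade event and an EPA event (they are
counted in separate columns, matching the occurrence-table layout). When
only one lung was imaged, "either lung" and the "both-lung mean" reduce to
that lung. Pairs with neither grade nor EPA at one end are skipped with a
warning. All inequalities are strict; these conventions are frozen and the
detector is verified against a literal-rule oracle on random timelines.

A rule-based auto-grader is included as a demonstrator: it extracts pleural
brightness, A-line periodicity (autocorrelation of the sub-pleural row
profile), B-line streak count and sub-pleural homogeneity, then walks a
decision list whose thresholds are configuration. The default thresholds are
matched to the synthetic renderer's appearance and achieve ~95% agreement
within half a grade on the synthetic grid; they are not calibrated for real
images.

## Gas exchange

The alveolar-arterial oxygen difference is

    AaDO2 = FiO2 · (Patm − P_H2O(T)) − PaCO2 / RQ − PaO2   [mmHg]

with Patm = 760 mmHg and RQ = 0.8 by default. Saturated water vapour
pressure uses Buck's (1981) formulation over liquid water converted to mmHg
(52.49 mmHg at 39 °C, printing as 52). Per-record body temperature is the
default; a fixed vapour pressure (e.g. 52 mmHg throughout) is available via
`GasExchangeConfig.fixed_svp_mmhg` because either convention is found in
practice. Negative AaDO2 values — possible under measurement noise — are
returned as computed with a warning, never clipped.

## Breathing traces

Inspiration is a negative deflection of intrapleural pressure. Breaths are
segmented by trough detection on that channel (minimum period 0.3 s;
prominence defaults to 25% of the robust 2.5–97.5 percentile swing), with
end-expiratory boundaries at the maxima between troughs. A breath's length
is the trough-to-trough period, which is edge-clean; pauses longer than 10 s
(configurable) are apnoeic gaps and form no breath. Respiratory rate is
60 / mean breath length; breath-length CoV uses the sample SD (ddof 1);
the intrapleural swing is end-expiratory level minus trough pressure.

Windowed summaries around an imaging time pick the 5-s sub-window (within
±1 min) with the least band-limited > 10 Hz energy, which avoids broadband
movement/vocalisation bursts; if the sampling rate cannot support a 10 Hz
cut the criterion falls back to first differences. Five-breath block
analysis takes the last five breaths before a gas-flow change and six
consecutive five-breath blocks over the first 30 breaths after it; the
breath straddling the event belongs to neither side.

## Statistical plan

* **Test selection.** Shapiro-Wilk at α = 0.05 gates parametric (mean ± SEM)
  vs rank (median, IQR) summaries and tests; degenerate samples (n < 3 or
  constant) force the rank branch.
* **Per-timepoint group comparison.** Mann-Whitney U (mid-ranks, SciPy's
  exact/asymptotic switching) per timepoint; Bonferroni over the number of
  timepoints actually tested, p_adj = min(1, m·p).
* **Longitudinal EPA model.** Random-intercept-per-lamb linear model with
  fixed effects time (categorical) and group, fitted by REML. The group
  effect is a between-lamb contrast and is tested on a t reference with
  df = n_lambs − 2 (a between-within approximation, exact for balanced
  designs and honest at n ≈ 19); the time effect uses a Wald χ². Missing
  cells are tolerated, unlike a classical repeated-measures ANOVA. If the
  default optimizer lands on a degenerate boundary the fit is retried with
  Powell.
* **Gas exchange vs aeration.** `AaDO2 ~ predictor + C(lamb)`: fixed lamb
  intercepts with a common slope, reporting the pooled R² and the
  predictor's p-value; per-lamb slopes are an option.
* **Block family.** Each post-event block vs baseline from the
  random-intercept model; the family-wise adjustment evaluates the Dunnett
  max-|t| null by Monte Carlo under the shared-baseline correlation
  structure (each contrast correlates 0.5 with the others through the common
  pre block); Bonferroni is available as a fallback.
* **Minimal detectable difference.** `paired_mdd` inverts the exact
  noncentral-t power of the two-sided paired t-test with Brent's method; the
  returned δ satisfies power(δ) = target within 5 × 10⁻³ and scales linearly
  with the difference SD. For 17 pairs, SD 0.1, 80% power, α = 0.05 the
  exact value is 0.0724.

## The synthetic cohort

The generator's defaults encode the emulated study's conditions: 10 control
and 9 elevated-liquid lambs; one pre-breathing scan (time −1 min) then scans
at 2.5-min spacing to 10 min, 5-min to 30 min, 10-min to 60 min and 20-min
to 240 min.

* **Trajectories.** Per lung, EPA(t) = epa_max·(1 − e^(−t/τ)) + u_lamb +
  noise, clamped to [0, 1]; zero before breathing onset. A saturating
  exponential is the simplest shape matching the observed rise; no
  functional form is established, so τ is purely a config. Defaults:
  epa_max = 0.95, τ_control = 15 min, τ_elevated = 30 min (the
  elevated-liquid group clears liquid half as fast), lamb-level intercept SD
  0.04 and per-observation noise SD 0.04. The noise SDs are free parameters
  — the variance decomposition of real EPA is unreported — chosen so the
  group trajectories separate reliably at study scale.
* **Backsliding injection.** Poisson(2.0) events per lamb per experiment,
  each a one-timepoint drop of depth U(0.2, 0.5) on one randomly chosen
  lung, at timepoints with an established post-onset predecessor. At these
  defaults the cohort produces roughly 2.5–3.8 grade-drop occurrences per
  lamb, the scale reported for real lambs.
* **Grade truth.** Thresholds on true EPA (< 0.1 → 0, < 0.3 → 0.5,
  < 0.5 → 1, < 0.85 → 2, else 3). The mapping from air fraction to grade is
  not established anywhere; these cut points are config, chosen so grade
  trajectories look like the qualitative descriptions.
* **Clips.** The renderer blends a liquid pattern (homogeneous 120-intensity
  field) with an aerated one (dark field, bright pleural line, decaying
  periodic A-line bands), adds B-line streaks most numerous at intermediate
  aeration, darkens two rib-shadow column bands, and applies multiplicative
  gamma speckle (shape 16, so speckle CoV = 0.25) shared across frames plus
  a small per-frame perturbation — consecutive frames are therefore strongly
  correlated, as in a real clip. Because SD/mean of a blended pattern is not
  linear in the blend weight, the renderer computes the expected ROI CoV of
  the pattern analytically on a grid and inverts it, so that the expected
  measured CoV is linear in true EPA by construction. Motion frames
  (independent shift + blur) are appended at the end of the stack so that
  the inter-frame difference rule flags exactly the injected frames.
* **Blood gases.** AaDO2_true = 30 + 400·(1 − meanEPA) mmHg + N(0, 15);
  PaCO2 ~ N(45, 5) mmHg floored at 15; temperature fixed at 39 °C. FiO2
  follows a titration policy (0.30 + 0.70·(1 − EPA), clamped to [0.21, 1],
  raised further if needed to keep PaO2 ≥ 20 mmHg), and PaO2 is then
  back-computed from the alveolar gas equation so that recomputing AaDO2
  from the emitted record reproduces the true gradient exactly.
* **Breathing.** Breath-by-breath synthesis at 100 Hz: rate 60 /min,
  intrapleural baseline −2 cmH2O with 8 cmH2O inspiratory deflections over
  the first 40% of each breath, breath-length jitter CoV 0.08, and a
  tracheal channel at gain 0.5. After a flow-change event the rate drops by
  20.74 breaths/min, breath-length CoV rises by 31% (relative) and the
  swing rises by 13.4 cmH2O — the study's observed effect sizes — fully
  expressed over post-event breaths 1–10 and decaying linearly to baseline
  by breath 30; an apnoea of configurable length can be inserted at the
  event. Overlapping event windows are rejected.

Everything is reproducible bit for bit from the config seed, and pipeline
reruns produce byte-identical CSV output.

### What the synthetic cohort does not establish

The renderer is a statistical texture model, not wave propagation: no
scan conversion, attenuation, anatomy, or probe physics. Its CoV–EPA
linearity is built in, so calibration recovery tests the pipeline's
plumbing, not the physical validity of the CoV technique on real tissue.
The grade ground truth is derived from EPA, so grade/EPA analyses are more
concordant than two independent human/physical measurements would be.
AaDO2 is deterministically coupled to aeration; consequently severe
backsliding visibly raises AaDO2 in the synthetic cohort, whereas real
blood gases are far noisier and the corresponding real-data comparison was
null. Passing tests demonstrate correctness of the computations and the
statistical machinery at study scale — they say nothing about ultrasound
physics or lamb physiology.

## Problem sizes

Power and type-I-error properties are evaluated at the study's own scale
(19 lambs, 21 timepoints): the group effect is detected in ≈100% of default
cohorts, and null cohorts (equal time constants) reject at ≈4–5%. The
acceptance evaluation uses 50 seeds for detection rate, 200–400 for the
null rate, 60 reference clips for calibration, 1,000 random timelines for
the backsliding oracle and 10,000 replicates for the Monte-Carlo power
cross-check.
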