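# Methods

This note documents the models, numerical choices and known limitations of
the package. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Heart-video model and beat detection

The simulator renders two soft-edged ellipses (ventricle and atrium) on a
256×256 px frame at 1.23 µm/px, the acquisition geometry of the screen it
emulates (75.9 fps, 40 s recordings). The ventricle's horizontal (minor)
diameter oscillates between the diastolic and systolic diameters; each beat
is a raised-cosine contraction pulse of width 0.45 of the base period
(configurable), and overlapping pulses combine by maximum so the chamber
never contracts below the systolic diameter. The edge profile is a linear
ramp about 1.4 px wide crossing half-intensity exactly at the geometric
boundary, so any mid-level threshold recovers the true diameter to within a
pixel. Beats are scheduled at multiples of the period, strictly inside the
recording and at least half a contraction width from its end — a pulse that
cannot complete inside the video is not an observable beat, and excluding
it keeps the scheduled count identical to the observable count. An arrest
window (start, length) replaces the beats inside it with one beat exactly
at the window start and one at its end, so the ground-truth longest gap
equals the window length by construction; a beat falling closer to the
window start than a contraction width is shifted onto it rather than
duplicated, keeping adjacent pulses resolvable.

Phenotype models, where the emulated screen names phenotypes but no
generative model: arrhythmia is multiplicative lognormal jitter (unit mean)
on the RR intervals; bigeminy alternates 0.6×/1.4× coupling intervals; an
AV ratio of *r* places *r* atrial beats per ventricular beat, spaced RR/r
apart and led by a 60 ms AV delay. Noise is white Gaussian per pixel
(default SD 4 on a 0–255 scale, ~5 % of the 200-unit foreground contrast —
typical of a cooled CMOS camera at short exposure). As a rendering economy
the noise field is drawn once per 512 frames and reused cyclically with
random spatial rolls; within any smoothing window it is white, and no
downstream statistic spans the 6.7 s reuse period coherently.

Analysis: kymographs are sampled by bilinear interpolation at 1 px steps
(averaged over the line's sampling width), binarised by Otsu's threshold on
the whole kymograph (fixed threshold optional), and the longest contiguous
bright run per frame is the chamber extent. The contraction curve 1/extent
is smoothed by an edge-corrected 5-frame moving average (a plain "same"
convolution dips at the boundaries and can fabricate a peak on a flat
curve). Peaks need a prominence of 10 % of the curve range and a separation
of 0.15 s (caps the detectable rate at 400 beats/min, ample margin over the
300 beats/min upper study condition); peak times are refined by a parabolic
fit through the three samples around each maximum; ties in peak height
break toward the earlier frame. Onset/offset per beat are the
half-prominence crossings, and their mean width is the QT proxy — the
emulated software never specifies how QT is read from video, so this is a
documented reconstruction, as is the whole segmentation/detection chain.

The QTc correction uses RR in seconds. The alternative printed convention
"RR = 6.6 ms/bpm" (dimensionally inconsistent with RR as an interval) is
available behind the `rr_from_bpm` flag but never asserted as the default.
Ejection fraction defaults to the spherical-volume estimate
1 − (Dsys/Ddia)³ with linear fractional shortening as an option, since the
source only says EF is "estimated from" the two diameters.

## Vessel flow

Particles advect along a straight horizontal vessel with
v(t) = mean · (1 + pulsatility · sin(2πf t)); the zero-net-flow phenotype
uses mean 0 with a pure oscillation amplitude. The particle field is
periodic in x, so circular cross-correlation of consecutive kymograph rows
recovers displacement without edge losses; sub-pixel refinement is
parabolic, and featureless rows are masked. Systolic/diastolic velocities
are the 90th/10th percentiles of the signed distribution (the source
sentence orders them ambiguously; this assignment makes systolic the
faster). "No flow" means |net displacement| over the whole video below one
cell diameter — covering both stopped flow and back-and-forth oscillation.
Note the per-frame quantiles of a sinusoid follow the arcsine law: for mean
300 µm/s and pulsatility 0.5 the true p90/p10 are 442.7/157.3 µm/s, not the
450/150 extremes.

## Calcium transients

Transients are triangular with configurable base width and rise fraction;
closed forms give the ground-truth features (area = ½·ampl·base, width at
level ℓ of the peak = (1−ℓ)·base). The extractor takes the 10th percentile
of the trace as baseline, so amplitudes are exact only when the duty cycle
leaves a genuine inter-peak baseline (width < period); at width = period
the 10th percentile sits on the ramp and amplitude reads ~10 % low. That is
a property of any percentile baseline, not an implementation artifact.

## Screen mixed model

The generative and fitted model is y_irpj = μ + β_r + γ_p + α_i + e_irpj
with γ_p ~ N(0, σ_γ²), α_i ~ N(0, σ_α²), e ~ N(0, σ_e²), β_r a row effect
shared across plates, and DMSO on every plate. Variance components are
estimated by REML (log-variance parametrisation, L-BFGS-B, dense Cholesky —
screens here are ≤ a few thousand rows); the implementation agrees with
statsmodels' crossed-variance-component MixedLM to the fourth decimal on
test fixtures, and statsmodels serves only as a cross-check, never the
implementation.

For inference the per-compound levels are re-estimated by GLS with
compound as a fixed level and V = σ̂_γ² Z_pZ_p' + σ̂_e² I. The BLUP
alternative (shrunken random-effect predictions with conditional SDs) was
evaluated and rejected: under the null its DMSO-contrast z collapses
(empirical SD ≈ 0.27) and power at a 3 σ_e effect is below 0.1, because
shrinkage scales both numerator and denominator by the estimated σ_α. The
GLS contrast z_i = (α̂_i − α̂_DMSO)/SE(α̂_i − α̂_DMSO) is standard normal
under the null (Monte-Carlo SD 1.00 ± a few percent); its SE includes the
covariance between the two level estimates — compounds share plate
uncertainty, and dropping that term overstates the SE several-fold.
p-values are 2Φ(−|z|); BH adjustment runs within one feature (and one time
point for the cardiomyocyte assay). Cutoffs: .05 everywhere except
ventricular beat rate at .0013 — that constant was calibrated on the
original screen and is adopted as given, since the calibration data are not
reproducible from a desk. One-sided positivity (z > 0 required) applies to
arrhythmic beats and cardiac arrest, whose decreases are not pathological.

The simulated plate design assigns each compound's 12 replicates
column-wise (rows rotate within the compound), so the row effect is
estimable separately from compound effects. A row-per-compound layout
confounds the two — the fitter raises an explicit degeneracy error rather
than returning arbitrary estimates.

The cardiomyocyte (FLIPR) pipeline averages triplicate wells per compound ×
plate × feature × time point (missing replicates average over what exists),
then applies the same model per feature × time point at the .05 cutoff.

## Compound calls and cross-comparison

A zebrafish compound is positive when any numeric feature is significant or
any flag reaches 30 % incidence ("30 % and above" — the boundary counts,
configurable); a cardiomyocyte compound when any feature is significant at
any time point. Contingency tables use TPR = TP/(TP+FN), TNR = TN/(TN+FP);
reported percentages round half-up to integers. ATC subgroups map the first
code letter: C → Cardio, N → Neuro, else Other (missing codes warn and fall
to Other). The package ships a reference table of per-compound detection
calls for the 18 market-withdrawn cardiotoxic drugs in both models, from
which the subgroup sensitivities are recomputed rather than stated.

## Disproportionality analysis

Curation collapses reports identical in every content field deposited
within 7 days ("a few days" is unquantified; 7 is the package's choice) to
the earliest deposit, and drops rows with out-of-range age/weight or
unparseable dates, logging counts. The MCE is the argmax of report counts
over the 29 cardiotoxicity terms, counting primary-suspect, secondary and
concomitant mentions alike; ties break by the fixed vocabulary order.

Background pools have the drug pool's size, exclude the drug's reports, and
are selected by a genetic algorithm (population 50, 100 generations,
tournament selection of 3, uniform membership crossover repaired to pool
size, 5 % swap mutation, 2 elites) maximising minus the summed
total-variation distance between pool and drug-pool distributions of
indication, concomitant-drug mentions, gender, and octile-binned age and
weight. All distances and hyperparameters are the package's documented
choices — the original procedure is unpublished. Elitism makes best-of-
generation fitness non-decreasing. PRR uses the 2×2 with a = drug reports
carrying the event; the Haldane +0.5 on all cells handles c = 0. The final
drug-event PRR is the mean over the pools; PRR ≥ 2 on the MCE is positive,
with an explicit allowlist for curation overrides of well-established
cardiotoxicants.

In the validation suites the GA runs at population 30 / 20 generations with
10–20 pools: the averaged PRR stabilises long before the matcher fully
converges, and the full 50/100/100 defaults remain the analysis setting.
A single null drug-event pair at 1000 reports carries roughly ten event
reports per pool, so its PRR is binomial-noisy and convexity
(averaging 1/rate) biases it slightly above 1; the null suite therefore
averages eight drug-event pairs per table and reports the across-table
mean.

## Synthetic data: what it does and does not emulate

The generators reproduce the geometry, acquisition parameters, plate
structure and statistical structure of the screen's inputs — not embryo
anatomy, optics or reporting behaviour. Hearts are ellipses without yolk
autofluorescence, drift, or occlusion; vessels are straight with
monodisperse cells; report covariates are a four-niche caricature of
prescription patterns. Passing recovery tests therefore shows the
*algorithms* are correct and calibrated on data satisfying their
assumptions; it does not certify performance on real larvae with motion
artifacts, nor real FAERS with coding noise. Problem sizes in the suites
(50 videos for recovery, 20 seeds for flags and flow, 500 null screens,
20 report tables) were chosen so each summary is stable well within the
tolerance it is compared against.

## Known limitations

- No motion compensation or 2-D segmentation; a drifting embryo breaks the
  fixed-line assumption.
- The QT proxy is a contraction-width surrogate; absolute QTc values are
  only comparable within the pipeline.
- The ventricular-rate cutoff .0013 is adopted, not re-derived.
- Flow velocimetry assumes a dominant axial motion along the selected line.
- The GA matcher optimises marginal distributions only, not joint
  covariate structure.
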