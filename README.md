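# cardioscreen

Kymograph-based cardiovascular phenotyping of zebrafish larvae, plate-aware
mixed-model screening statistics, and pharmacovigilance disproportionality
calls — the full desk side of an *in vivo* cardiotoxicity screen, from raw
time-lapse videos of beating hearts and vessel blood flow to
sensitivity/specificity tables against clinical labels.

## Who this is for

Groups running (or modelling) high-throughput cardiac safety screens in
zebrafish larvae or cardiomyocyte cultures: image analysts extracting
chronotropic/inotropic/hemodynamic features from videos, biostatisticians
calling compound effects on 96-well plate screens, and pharmacovigilance
analysts deriving clinical cardiotoxicity labels from spontaneous
adverse-event reports.

## What it computes

**Video phenotyping.** The user (or a simulation's ground truth) supplies a
line along the heart axis; two perpendicular lines at the ventricle and
atrium yield kymographs, whose bright-segment length per frame is the
chamber extent *L(t)*. Peaks of the contraction curve *1/L(t)* are
individual beats. From the beat series: beat rate 60/median(RR), percentage
of arrhythmic beats (|RR − median| > 20 % of median), cardiac arrest
(longest beat-free gap), and the rate-corrected QT interval using the
zebrafish-adapted Framingham linear correction

    QTc = QT + 0.154 (2.66 − RR)

with the mean half-prominence contraction width as the QT proxy. Ejection
fraction comes from diastolic vs systolic diameters, EF = 1 − (Dsys/Ddia)³
(spherical; linear fractional shortening optional). Vessel kymographs give
signed blood-cell velocities by row-to-row circular cross-correlation with
sub-pixel refinement; the 90th/10th percentiles are systolic/diastolic
velocities, and "no flow" is flagged when net displacement over the video
is below one cell diameter. Calcium-transient traces yield the five
plate-reader features (bpm, ampl, auc, pkw, ppkw).

**Screen statistics.** Per-subject features from a multi-plate screen are
modelled as

    y_irpj = μ + β_r + γ_p + α_i + e_irpj

(row fixed effect shared across plates; plate/day and compound random
effects). Variance components are REML-estimated; each compound is compared
with the DMSO control through a z-score whose two-sided p-values are
Benjamini–Hochberg adjusted per feature. Adjusted p < .05 is significant
(ventricular beat rate uses the stricter calibrated cutoff .0013), and only
positive z counts for arrhythmic beats and cardiac arrest. Binary flags
(AV-coupling defect, bigeminy, no beating, no flow) call a compound
positive at ≥ 30 % incidence among its larvae.

**Disproportionality.** Adverse-event reports are curated (near-duplicate
collapse, field validation); a drug's major cardiotoxicity event (MCE) is
the most-reported of the 29 cardiotoxicity terms counting every drug role;
the proportional reporting ratio PRR = [a/(a+b)] / [c/(c+d)] is averaged
over 100 background pools matched to the drug's covariate distributions by
a genetic algorithm; mean PRR ≥ 2 labels the drug positive.

Every input modality has a seeded synthetic generator with machine-readable
ground truth (`cardioscreen.sim`), so the whole pipeline is testable
without any external data.

## Worked example

```sh
python examples/heart_phenotyping.py
```

```
ventricular rate :   150.1 beats/min (truth 150)
atrial rate      :   150.1 beats/min
QTc              :   0.440 s (contraction-width proxy, rate-corrected)
cardiac arrest   :   0.401 s  (longest beat-free gap)
arrhythmic beats :     0.0 %
ejection fraction:    70.8 %  (spherical; truth 70.4)
max diameter     :   120.5 um (diastolic; truth 120)
flags            : AV defect=False bigeminy=False no_beating=False
```

A 40 s heart video at 75.9 fps is rendered with a 150 beats/min schedule
and diameters 120/80 µm, then analysed blind to the schedule: the recovered
rate is within 0.1 %, the diastolic diameter within one pixel (1.23 µm),
and the ejection fraction within half a point of the generative truth. The
other scripts in `examples/` walk the vessel-flow, calcium-transient,
screen-statistics, disproportionality and withdrawn-drug paths the same
way.

A thin CLI mirrors the pipeline stages
(`cardioscreen simulate|analyze-heart|analyze-flow|analyze-transients|`
`screen-stats|classify|faers-prr`); see `cardioscreen --help`.

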