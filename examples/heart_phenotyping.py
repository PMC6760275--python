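"""Phenotype a simulated beating zebrafish heart.

Renders a 40 s two-chamber heart video at 75.9 fps (150 beats/min,
diastolic/systolic diameters 120/80 um), then runs the full analysis path:
axis line -> perpendicular chamber lines -> kymographs -> contraction
curves -> beat detection -> cardiac features.
"""

from cardioscreen.pipeline import analyze_heart, default_heart_axis
from cardioscreen.sim import HeartSimParams, simulate_heart_video

params = HeartSimParams(ventricular_bpm=150, dia_diameter_um=120,
                        sys_diameter_um=80, seed=7)
stack, truth = simulate_heart_video(params)
feats = analyze_heart(stack, default_heart_axis(stack, truth))

print(f"ventricular rate : {feats.ventricular_bpm:7.1f} beats/min (truth 150)")
print(f"atrial rate      : {feats.atrial_bpm:7.1f} beats/min")
print(f"QTc              : {feats.qtc:7.3f} s (contraction-width proxy, rate-corrected)")
print(f"cardiac arrest   : {feats.cardiac_arrest:7.3f} s  (longest beat-free gap)")
print(f"arrhythmic beats : {feats.arrhythmic_beats:7.1f} %")
print(f"ejection fraction: {feats.ejection_fraction:7.1f} %  (spherical; truth 70.4)")
print(f"max diameter     : {feats.max_diameter:7.1f} um (diastolic; truth 120)")
print(f"flags            : AV defect={feats.av_coupling_defect} "
      f"bigeminy={feats.bigeminy} no_beating={feats.no_beating}")
print("\nRates within ~1 % and diameters within ~1 px of the generative "
      "truth indicate the kymograph pipeline is calibrated.")
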