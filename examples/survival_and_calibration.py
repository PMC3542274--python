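"""Dose-response anchors: seedling survival and breakage calibration.

Interpolates the seedling survival curve at a candidate dose and fits the
breakage-model parameters so the simulator's expected per-marker loss
tracks the observed 1.2-2.4% dose curve.
"""

from dataclasses import replace

from rhpanel import survival_curve, uniform_marker_map
from rhpanel.simulate import MARKER_LOSS_ANCHORS, calibrate_scenario, expected_marker_loss

print("Seedling survival (percent of control) by gamma dose:")
for dose in (0, 150, 200, 350, 450, 550):
    print(f"  {dose:>4} Gy -> {survival_curve(dose):5.1f}%")

marker_map = uniform_marker_map()  # the 35-locus whole-genome SSR screen
scenario = calibrate_scenario(marker_map)
print(
    f"\nCalibrated breakage model: {scenario.break_rate_per_Gb_per_Gy:.4f} "
    f"breaks/Gb/Gy, acentric fragment loss prob "
    f"{scenario.fragment_loss_prob:.4f}"
)
print("Expected vs target per-marker loss by dose:")
for dose, target in sorted(MARKER_LOSS_ANCHORS.items()):
    pred = 100 * expected_marker_loss(replace(scenario, dose_Gy=dose), marker_map)
    print(f"  {dose:>4.0f} Gy -> {pred:4.2f}%  (observed anchor {target}%)")
# The survival percentages say how many irradiated seeds grow into plants;
# the loss percentages say what fraction of marker assays on surviving
# progeny come back deleted -- the two costs a panel design trades off.
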