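"""Simulate a ground-truth litter field and draw a 530-point survey.

The truth has the published spatial structure (nugget + spherical, 84 m
along-shore / 27 m cross-shore) and lognormal marginals calibrated to the
printed summary table; the survey samples 530 of the 7500 one-metre cells.
"""

import numpy as np

from littersim import GridSpec, calibrated_model_and_specs, draw_survey, simulate_truth

model, specs = calibrated_model_and_specs()
grid = GridSpec()  # 50 m x 150 m at 1 m resolution
truth = simulate_truth(model, specs, grid, seed=2024)
survey = draw_survey(truth, n=530, seed=7)

print(f"grid: {grid.nx} x {grid.ny} cells, {grid.area:.0f} m^2")
print(f"survey: {len(survey)} sampled cells\n")
print(f"{'':24s}{'butts/m2':>10s}{'sharp/m2':>10s}   (published)")
for label, fn in [
    ("mean", np.mean),
    ("standard deviation", np.std),
    ("median", np.median),
    ("maximum", np.max),
]:
    b = fn(survey["butts_per_m2"])
    s = fn(survey["sharp_per_m2"])
    print(f"{label:24s}{b:10.2f}{s:10.2f}")
print("(published means 3.57 / 2.39, SDs 4.0 / 2.4, medians 1.94 / 1.55)")
corr = np.corrcoef(survey["butts_per_m2"], survey["sharp_per_m2"])[0, 1]
print(f"\nraw-scale correlation: {corr:.3f}  (target 0.87)")
print(
    "\nAny single survey wanders around the calibration targets because the\n"
    "84 m correlation range barely fits the 150 m domain; averages over\n"
    "generator seeds converge to the targets."
)
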