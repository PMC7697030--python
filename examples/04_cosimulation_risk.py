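"""Conditional cosimulation and risk mapping of a synthetic survey.

Runs the core of the analysis: normal-score the survey, generate conditional
turning-bands realizations of both litter variables on the full grid, and
post-process them into the two beach-condition indices, per-node class maps
and the sharp-item injury-risk (exceedance) map.
"""

import numpy as np

from littersim import (
    GridSpec,
    beach_litter_lmc,
    calibrated_model_and_specs,
    draw_survey,
    run_cosimulation,
    simulate_truth,
    summarize_risk,
)
from littersim.risk import BUTT_LABELS, SHARP_LABELS

grid = GridSpec()
gen_model, specs = calibrated_model_and_specs()
truth = simulate_truth(gen_model, specs, grid, seed=2024)
survey = draw_survey(truth, n=530, seed=7)

stack = run_cosimulation(survey, beach_litter_lmc(), grid, n_real=50, seed=99)
risk = summarize_risk(stack)

print(f"{stack.n_real} conditional realizations on {grid.nx}x{grid.ny} nodes")
print(f"\nHII = {risk.hii.value:.2f} (category {risk.hii.category}; "
      f"+/- {risk.hii_sd:.2f} over realizations)")
print(f"CCI = {risk.cci.value:.1f} ({risk.cci.category}; "
      f"+/- {risk.cci_sd:.1f} over realizations)")
print("(survey-scale references: HII 9.4 category V, CCI 110.8 Extremely Dirty)")

print("\ncigarette-butt contamination classes (E-type map):")
for name, n in risk.butt_class_freq.items():
    print(f"  {name:12s} {n:5d} nodes ({100 * n / grid.n_nodes:.0f}%)")
print("sharp-item injury-risk classes:")
for name, n in risk.sharp_class_freq.items():
    print(f"  {name:14s} {n:5d} nodes ({100 * n / grid.n_nodes:.0f}%)")

p = risk.exceedance
print(f"\nP(sharp items >= {risk.exceedance_threshold:g}/m^2): "
      f"mean {p.mean():.2f}, {np.mean(p >= 0.8) * 100:.0f}% of nodes above 0.8")
print(
    "\nEach realization honors the 530 survey values exactly; the maps say\n"
    "where injury risk and contamination concentrate, the indices grade the\n"
    "beach as a whole."
)
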