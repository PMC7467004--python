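"""Generate synthetic allele-frequency data with a known convergent sweep.

Shows the two generator outputs — unlinked neutral sites and a selected
region — and the footprint the sweep leaves: near the selected site the
selected populations' standardized variance is pushed toward 1 (complete
coalescence), decaying with recombination distance.
"""

import numpy as np

from sweepmodes.coancestry import standardize_matrix
from sweepmodes.simulate import example_scenario, simulate_neutral, simulate_selected_region

scenario = example_scenario(seed=4, n_neutral_sites=5_000, n_selected_sites=400)
neutral = simulate_neutral(scenario)
selected = simulate_selected_region(scenario)

print(f"neutral matrix:  {neutral.n_pops} populations x {neutral.n_sites} sites")
print(f"selected region: {selected.n_pops} populations x {selected.n_sites} sites, "
      f"positions {selected.positions.min():.4f}..{selected.positions.max():.4f}")
print(f"true selected site: {scenario.true_site}, s = {scenario.params.s}, "
      f"selected populations (1-based): {[p + 1 for p in scenario.selected_pops0]}")

Z, _, usable = standardize_matrix(selected.freqs)
near = selected.positions < 0.05
far = selected.positions > 0.5
for label, mask in [("near the sweep (pos < 0.05)", near & usable),
                    ("far from it (pos > 0.5)", far & usable)]:
    var_sel = (Z[[0, 2, 4]][:, mask] ** 2).mean()
    var_neu = (Z[[1, 3, 5]][:, mask] ** 2).mean()
    print(f"{label}: mean standardized variance "
          f"selected pops {var_sel:.2f}, non-selected {var_neu:.2f}")
print(
    "\nSelected populations show strongly inflated variance only near the\n"
    "true site — the hitchhiking signal the composite likelihood exploits —\n"
    "while non-selected populations stay near the neutral drift level."
)
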