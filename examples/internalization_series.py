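"""Receptor internalization shifts the membrane/cytoplasm ratio downward.

Moves a growing fraction of each cell's membrane signal into the cytoplasm
(conserving total fluorescence), re-renders and re-profiles the field, and
prints the measured group ratio at each internalized fraction — the direction
of the agonist-stimulated redistribution the profiler is built to detect.
"""

import numpy as np

import traffickit as tk

spec = tk.FieldSpec(image_shape=(600, 600), n_cells=30, seed=7)
truths = tk.random_truths(spec, membrane_intensity=300.0, cytoplasm_intensity=100.0,
                          membrane_width_px=5)
_, truths = tk.render_field(spec, truths)

print("internalized_fraction -> group mean membrane/cytoplasm ratio")
for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
    field, _ = tk.render_field(spec, tk.simulate_internalization(truths, frac))
    profiles, _ = tk.profile_field(field)
    ratios = [s.mc_ratio for s in tk.summarize_cells(profiles) if s.valid]
    print(f"  {frac:4.2f} -> {np.mean(ratios):.3f}")
print("Fraction 0 is the surface-resident control; fraction 1 fully equalizes the "
      "compartments, driving the background-corrected ratio toward 1.")
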