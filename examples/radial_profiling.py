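"""Radial profiling of a synthetic field: from label masks to membrane/cytoplasm ratios.

Builds a small noisy field of cells with a known 3:1 membrane:cytoplasm
intensity contrast, extracts 60 concentric contour bands per cell (20
dilations, 40 erosions, one pixel per cycle), background-corrects each
profile using the most distant extracellular bands, and prints the per-group
membrane/cytoplasm ratio.
"""

import numpy as np

import traffickit as tk

spec = tk.FieldSpec(image_shape=(512, 512), n_cells=20, seed=42)
truths = tk.random_truths(spec, membrane_intensity=300.0, cytoplasm_intensity=100.0,
                          membrane_width_px=5)
field, truths = tk.render_field(spec, truths, condition="control", genotype="WT")

profiles, qc = tk.profile_field(field)
summaries = tk.summarize_cells(profiles, condition="control", genotype="WT",
                               experiment_id="demo")
ratio_frame, _ = tk.aggregate(summaries)

print(f"cells profiled: {len(profiles)}  (skipped: {len(qc)})")
prof = profiles[0]
print(f"cell 1 background estimate: {prof.background_value:.2f} counts "
      f"(true background {spec.background_level})")
print("cell 1 corrected band means (edge bands 0-5 = membrane, deeper = cytoplasm):")
for i in range(0, 10):
    print(f"  band {i:2d}: {prof.corrected[i]:7.2f}")
row = ratio_frame.iloc[0]
print(f"group membrane/cytoplasm ratio: {row.ratio_mean:.3f} ± {row.ratio_sem_cells:.3f} "
      f"(SEM over {row.n_cells} cells)")
print("The ratio is computed on background-corrected fluorescence, so with membrane "
      "300, cytoplasm 100 and background 50 the expected noise-free value is "
      "((5*250+50)/6)/50 = 4.33: membrane bands 0-4 carry the ring signal and band 5 "
      "already samples cytoplasm.")
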