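# traffickit

Quantitative analysis of GPCR surface localization and trafficking from two
standard readouts:

1. **Per-cell radial fluorescence profiling** of segmented confocal images —
   how much receptor sits at the plasma membrane versus the cytoplasm, cell
   by cell, from any intensity image plus an integer label mask (e.g. from
   cellpose; segmentation itself is out of scope here).
2. **BRET time-course processing** of dual-wavelength plate-reader data —
   ratio formation, baseline and vehicle correction, dose–response fitting
   (logEC50), and derived readouts such as cAMP-reporter inhibition.

A synthetic-data module generates microscopy fields and BRET plates with
known ground truth, so every stage of the pipeline is verifiable end to end
without any external data.

## The core measurements

**Radial contour profile.** Each cell mask is dilated 20× and eroded 40×,
one pixel per cycle (3×3 square structuring element, Chebyshev metric). The
set difference between consecutive masks is a one-pixel-wide concentric band;
the ring removed by the first erosion is band 0 (the cell edge), deeper
erosions give bands 1…39, dilations give extracellular bands −1…−20 — 60
bands in total. Mean fluorescence per band, minus the per-cell background
(mean of bands −10…−20, the most distant contours), is the radial profile.
The **membrane-to-cytoplasm ratio** of a cell is

```
mc_ratio = mean(corrected bands 0–5) / mean(corrected bands 6–39)
```

Profiles can be normalized to the average overall cell fluorescence of each
experiment, and are aggregated per condition × genotype as mean ± SEM (over
cells and, where several experiments are present, over experiments).

**ΔBRET and dose–response.** The BRET ratio is I530/I480 per timepoint. Each
well is baseline-corrected by subtracting its own pre-stimulation mean ratio;
the mean of the vehicle wells is then subtracted timepoint-wise, giving
ΔBRET. Plateau responses per concentration are fit with the four-parameter
logistic

```
y(c) = bottom + span / (1 + 10^((logEC50 − log10 c) · hill))
```

with a multi-start least-squares fit (span ≥ 0, hill ∈ [0.3, 3]) that reports
standard errors, a convergence flag and an identifiability flag.

## Worked example

`examples/radial_profiling.py` builds a 20-cell synthetic field (membrane 300,
cytoplasm 100, background 50 counts, shot + read noise), profiles it, and
prints:

```
cells profiled: 20  (skipped: 0)
cell 1 background estimate: 50.07 counts (true background 50.0)
cell 1 corrected band means (edge bands 0-5 = membrane, deeper = cytoplasm):
  band  0:  248.22
  band  1:  248.23
  ...
  band  7:   51.73
group membrane/cytoplasm ratio: 4.315 ± 0.046 (SEM over 20 cells)
```

The ratio is computed on background-corrected fluorescence: with a 5-px
membrane ring the noise-free expectation is ((5·250 + 50)/6)/50 ≈ 4.33, and
the measured 4.315 ± 0.046 recovers it. `examples/internalization_series.py`
moves membrane signal into the cytoplasm (total fluorescence conserved) and
shows the ratio falling monotonically from 4.34 to 1.00 as the internalized
fraction goes from 0 to 1. `examples/bret_dose_response.py` simulates a plate
with true logEC50 −6.3 and recovers −6.305 ± 0.026;
`examples/trace_readouts.py` shows the 7-minute cAMP-reporter inhibition
readout and per-genotype average ΔBRET differences versus a reference.

## Command line

```bash
traffickit synth field --spec field.yaml --seed 5 --out data/      # synthetic field + truth.csv
traffickit synth bret --seed 3 --out traces.csv                    # synthetic plate
traffickit profile run --image i.tif --labels l.tif --out results/ # profiles, cells, groups, QC
traffickit bret process --traces traces.csv --out results/         # ΔBRET per well
traffickit bret fit --traces traces.csv --out fit.csv              # 4PL dose–response
```

All outputs are plain CSV. Profile tables carry (experiment_id, condition,
genotype, cell_id, band_index, mean_fluor_raw, mean_fluor_corrected,
n_pixels); cell tables add membrane_mean, cytoplasm_mean, mc_ratio,
total_cell_fluor and a validity flag; group tables carry mean, SEM and n per
band and per ratio.

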