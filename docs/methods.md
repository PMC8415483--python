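# Methods

## Radial contour profiling

### Band construction

A cell's binary mask is iteratively eroded (40 cycles) and dilated (20
cycles), one pixel per cycle, with a 3×3 square structuring element. The ring
removed between erosion steps *i* and *i+1* is intracellular band *i* (band 0
is the cell-edge ring); the ring added at dilation step *j* is extracellular
band −*j*. This yields exactly `n_dilate + n_erode` = 60 bands per cell.
Bands become empty once the eroded core vanishes (a cell of Chebyshev
inradius *d* populates bands 0…*d*−1); empty bands carry a missing mean and
are excluded from every downstream average.

Two deliberate choices fix ambiguities in this construction:

- **Structuring element.** A 3×3 square makes "one pixel per cycle"
  isotropic in the Chebyshev (chessboard) metric and gives the decomposition
  a closed-form equivalent: a pixel inside the mask belongs to band
  (Chebyshev distance to the nearest background pixel) − 1, a pixel outside
  to band −(Chebyshev distance to the mask). The test suite checks this
  equivalence pixel-by-pixel against `scipy.ndimage.distance_transform_cdt`,
  an independent code path from the iterative morphology used in the
  implementation.
- **Index convention.** The ring removed by the *first* erosion is band 0
  ("the contour at the cell edge"). The alternative — a separate zero-width
  edge contour — would produce 61 bands instead of 60.

### Background correction and profiles

The per-cell background is the unweighted mean of the non-empty band means at
dilation steps 10–20 (bands −10…−20, the most distant contours) and is
subtracted from every band mean. Consequences, both enforced by tests:
corrected profiles are exactly invariant to adding any constant to the image,
and cells whose background bands are *all* empty (e.g. masks reaching the
image border) raise an explicit error rather than producing silently biased
profiles; the field-level driver records such cells in a QC report and
continues.

Extracellular bands exclude pixels inside any *other* cell's original mask
(configurable via `exclude_neighbors`). Rationale: a background estimate
sampled from neighbor-occupied pixels would be systematically biased upward.
Band pixels falling outside the image are simply absent (bands clip).

### Membrane/cytoplasm ratio

`mc_ratio` = mean of corrected band means over bands 0–5 divided by that over
bands 6–39. Band 5 is included in the membrane range (six edge-proximal
bands, 0–5 px from the edge). The ratio uses **means of band means**, not
pixel sums: band areas grow with dilation depth, and the per-contour profile
this mirrors is a per-band mean; a pixel-weighted variant is available via
`method="sum"`. Cells with non-positive cytoplasm means — or too small to
populate any cytoplasm band — are flagged invalid, excluded from aggregates
and counted.

Normalization divides every profile by the experiment-wide mean of
`total_cell_fluor` (mean intensity over the full original mask), making the
normalized experiment mean exactly 1 and profiles comparable across
experiments with different gains. Aggregation reports mean ± SEM per band and
per ratio, at two levels — across cells and, when several experiment ids are
present, across per-experiment means — because published error bars may be
defined at either level. SEM with n = 1 is reported as 0 with an `n_is_1`
flag.

## Synthetic fields

Cells are star-convex blobs: the boundary radius is
`r(θ) = R·(1 + irregularity · s(θ))` with `s` a normalized sum of random
harmonics 2–5, guaranteeing a single connected component with a well-defined
edge. The membrane compartment is the set of mask pixels within
`membrane_width_px` Chebyshev distance of the boundary — the same metric the
profiler uses, so ground truth and measurement share one geometry. Cells are
placed with ≥ 25 px margins from the border and from each other so that no
band clips or touches a neighbor; adversarial cases (frame-filling masks,
overlaps) are constructed directly in tests.

Noise model: Poisson shot noise applied to signal + background, then additive
Gaussian read noise — the standard detector model. Defaults (background 50
counts, read noise SD 2, membrane 300 / cytoplasm 100, radii 10–16 px,
irregularity 0.25) describe a moderately bright channel; no acquisition gain
figures exist to calibrate against, so these are chosen for testability and
stated here once. The generator does **not** simulate a point-spread
function, 3-D stacks, intensity gradients within compartments, or touching
cells, so passing tests demonstrate correctness of the band bookkeeping and
statistics, not robustness to segmentation errors or optical blur in real
images.

`simulate_internalization` moves membrane signal into the cytoplasm by
relaxing both compartments toward the area-weighted uniform level
`u = (m·A_m + c·A_c)/(A_m + A_c)` linearly in the internalized fraction:
fraction 0 is the identity, fraction 1 equalizes the compartments, and the
integrated fluorescence `m·A_m + c·A_c` is conserved exactly. This requires
the compartment areas measured during rendering, which is why the operation
consumes truths returned by `render_field`.

## BRET processing

The BRET ratio is I530/I480 per timepoint; donor counts must be positive
wherever a ratio is formed (validated at read time, with the offending well
and timepoint named). ΔBRET: each well's own pre-stimulation mean ratio is
subtracted (all samples before the stimulation time — the correction window
is not otherwise specified, so the full baseline is used; subtractive rather
than ratiometric correction is implemented), then the mean of the
baseline-corrected vehicle wells is subtracted timepoint-wise. This makes
ΔBRET exactly invariant to per-well constant offsets and to rescaling both
channels by a common factor, and identically zero for vehicle against
itself — all asserted in tests at 1e-12 on noise-free input.

### Dose–response fitting

Plateau responses (mean of the last 5 post-stimulation samples per well) are
fit with `bottom + span/(1 + 10^((logEC50 − log10 c)·hill))` by multi-start
least squares (7 initial logEC50 values spanning the tested range ± 1
decade), with span bounded ≥ 0 and hill ∈ [0.3, 3]. Vehicle (c = 0) lives at
−∞ on the log axis and is excluded from the fit; it informs the baseline
upstream. Standard errors come from the local covariance; a fit is flagged
non-identifiable when the span is numerically or statistically
indistinguishable from zero (logEC50 is then meaningless), and
non-convergence from all starts is reported as such rather than as numbers.

Simulated plates use logEC50 −6.3, span 0.05 BRET units, hill 1, 8
log-spaced concentrations (1 nM–100 µM) in triplicate, 85 s sampling over 40
timepoints with stimulation after 5 samples, onset time constant 180 s,
per-well baseline scatter SD 0.01, drift 2×10⁻⁶ s⁻¹ and ratio noise SD
0.002 — amplitudes and noise typical of luciferase/fluorophore biosensor
plates. Under these conditions the fitted logEC50 deviates from truth by
≤ 0.05 (median) and ≤ 0.15 (max) over 20 seeds; because the plateau estimate
underestimates the asymptote by a common factor `1 − exp(−Δt/τ)` across
concentrations, the midpoint is not biased by onset kinetics.

Secondary readouts: the cAMP-reporter inhibition is
`1 − L_agonist/L_control` evaluated at the sample nearest 7 min (420 s)
after β-adrenergic stimulation — nearest-sample rather than interpolation,
since at 85 s sampling the timing error is under half a sample and the value
stays exactly reproducible. The per-genotype trace summary is the plain mean
over post-stimulation timepoints of (genotype ΔBRET − reference ΔBRET).

## Numerical and scale choices

Band extraction crops each cell to its bounding box padded by the dilation
reach before iterating morphology, which keeps multi-cell fields fast without
changing any band. Profiles store band means as float64; empty bands as NaN.
The acceptance script exercises a 100-cell 900×900 field, 50 oracle masks and
20 simulated plates — sizes at which every quantity is stable at the reported
tolerances while the full run completes in well under a minute.

## Known limitations

- No sub-pixel, geodesic or 3-D profiling; bands are one pixel wide by
  construction.
- The generator's realism is limited as described above; quantitative ratio
  values depend on membrane width relative to the 0–5 band range (a 5-px ring
  places band 5 in the cytoplasm plateau, which the noise-free oracle
  accounts for).
- Hypothesis testing across groups (ANOVA, post-hoc comparisons) is left to
  standard statistics packages; the aggregate tables are designed to feed
  them.
- Actual published potency or ratio values cannot be reproduced here since
  raw images and plate data are not deposited; all quantitative checks are
  against synthetic ground truth.
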