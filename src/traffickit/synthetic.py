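"""Synthetic microscopy fields and BRET traces with known ground truth.

The field generator emulates confocal acquisitions of adherent cells
expressing a fluorescently tagged receptor: irregular star-convex cells whose
mask-edge pixels carry a membrane-localized ring signal and whose interior
carries a diffuse cytoplasmic signal, over a uniform background, with Poisson
shot noise followed by Gaussian read noise.  The trace generator emulates
plate-reader BRET time courses: per-well baselines with slow drift, a
mono-exponential response onset after ligand addition, and a four-parameter
logistic dependence of the plateau amplitude on ligand concentration.

Every generated object comes with its ground truth (per-cell intensities and
compartment areas; dose–response parameters), so downstream measurements can
be checked against known values.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import MaskOverlapError, MaskPlacementError
from .io import BretTrace, LabeledField

#: Margin (px) kept between any mask pixel and the image border, and between
#: cells, so that 20 dilation bands never clip or touch a neighbor's bands.
BORDER_MARGIN = 25


@dataclass
class CellGroundTruth:
    """Known per-cell truth: geometry seed plus compartment intensities.

    ``membrane_width_px`` is the Chebyshev depth of the membrane compartment
    (pixels within that distance of the mask boundary, inside the mask), the
    same metric the contour profiler uses, so truth and measurement share one
    geometry.  Compartment areas are filled by :func:`render_field`.
    """

    cell_id: int
    center: tuple[int, int]
    membrane_intensity: float
    cytoplasm_intensity: float
    membrane_width_px: int = 5
    radius_px: float | None = None
    membrane_area_px: int | None = None
    cytoplasm_area_px: int | None = None

    def __post_init__(self) -> None:
        if self.cell_id <= 0:
            raise ValueError("cell_id must be a positive integer")
        if self.membrane_width_px < 1:
            raise ValueError("membrane_width_px must be >= 1")
        if self.cytoplasm_intensity <= 0 or self.membrane_intensity <= 0:
            raise ValueError("intensities must be positive")

    @property
    def true_ratio(self) -> float:
        return self.membrane_intensity / self.cytoplasm_intensity


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of a synthetic field.

    Defaults model a moderately bright receptor channel: background 50 counts,
    shot noise on, 2-count read noise, cells of radius 10–16 px with 25%
    boundary irregularity.
    """

    image_shape: tuple[int, int] = (512, 512)
    n_cells: int = 20
    radius_range: tuple[float, float] = (10.0, 16.0)
    irregularity: float = 0.25
    background_level: float = 50.0
    poisson_noise: bool = True
    gaussian_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.radius_range[0] < 3:
            raise ValueError("minimum radius must be >= 3")


@dataclass(frozen=True)
class BretSimSpec:
    """Parameters of a simulated BRET dose–response experiment.

    The asymptotic vehicle-subtracted response at concentration ``c`` is
    ``floor + span * c**hill / (c**hill + ec50**hill)``; the onset after the
    stimulation timepoint follows ``1 − exp(−t/onset_tau)``.  Sampling every
    85 s over 40 timepoints (~57 min) matches a typical kinetic plate read;
    the default amplitude (span 0.05 BRET units) and read noise (0.002) are
    typical of luciferase/YFP biosensor plates.
    """

    logec50: float = -6.3
    span: float = 0.05
    hill: float = 1.0
    floor: float = 0.0
    onset_tau: float = 180.0
    baseline_ratio: float = 0.8
    baseline_drift_per_s: float = 2e-6
    well_offset_sd: float = 0.01
    noise_sd: float = 0.002
    concentrations: tuple[float, ...] = tuple(np.logspace(-9, -4, 8))
    sample_interval_s: float = 85.0
    n_timepoints: int = 40
    stimulation_time_s: float = 425.0
    n_replicates: int = 3
    donor_counts: float = 1e5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.span < 0:
            raise ValueError("span must be >= 0")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be strictly positive")
        if self.sample_interval_s <= 0:
            raise ValueError("sample_interval_s must be > 0")


def _mask_seed(field_seed: int, cell_id: int) -> int:
    return int(np.random.SeedSequence([field_seed, cell_id]).generate_state(1)[0] % (2**31))


def make_cell_mask(
    image_shape: tuple[int, int],
    center: tuple[int, int],
    mean_radius: float,
    irregularity: float,
    seed: int,
) -> np.ndarray:
    """Generate one star-convex cell mask by radial boundary perturbation.

    The boundary radius is ``r(θ) = R·(1 + irregularity·s(θ))`` where ``s`` is
    a smooth zero-mean sum of low-order harmonics normalized to |s| ≤ 1; a
    pixel belongs to the mask iff its distance to ``center`` is ≤ r at its
    angle.  This guarantees a single connected, star-convex component.
    Reproducible for a fixed seed.
    """
    if mean_radius < 3:
        raise MaskPlacementError(f"mean_radius {mean_radius} < 3")
    rng = np.random.default_rng(seed)
    harmonics = np.arange(2, 6)
    amps = rng.normal(size=harmonics.size)
    phases = rng.uniform(0, 2 * np.pi, size=harmonics.size)
    norm = np.sum(np.abs(amps))
    if norm == 0:
        amps[:] = 0
        norm = 1.0

    r_max = mean_radius * (1 + abs(irregularity)) + 2
    cr, cc = center
    nrows, ncols = image_shape
    r0, r1 = int(np.floor(cr - r_max)), int(np.ceil(cr + r_max)) + 1
    c0, c1 = int(np.floor(cc - r_max)), int(np.ceil(cc + r_max)) + 1
    if r0 < 0 or c0 < 0 or r1 > nrows or c1 > ncols:
        raise MaskPlacementError(
            f"mask of radius ~{mean_radius} at {center} would reach the image border"
        )
    rows = np.arange(r0, r1)[:, None]
    cols = np.arange(c0, c1)[None, :]
    dy = rows - cr
    dx = cols - cc
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    s = np.zeros_like(theta)
    for k, a, ph in zip(harmonics, amps, phases):
        s += a * np.cos(k * theta + ph)
    s /= norm
    radius = mean_radius * np.clip(1 + irregularity * s, 0.2, None)
    local = dist <= radius
    mask = np.zeros(image_shape, dtype=bool)
    mask[r0:r1, c0:c1] = local
    if (
        mask[0, :].any()
        or mask[-1, :].any()
        or mask[:, 0].any()
        or mask[:, -1].any()
    ):
        raise MaskPlacementError(f"mask at {center} touches the image border")
    return mask


def random_truths(
    spec: FieldSpec,
    membrane_intensity: float = 300.0,
    cytoplasm_intensity: float = 100.0,
    membrane_width_px: int = 5,
) -> list[CellGroundTruth]:
    """Place ``spec.n_cells`` non-overlapping cells with safe border margins.

    Centers are drawn by rejection sampling so that every mask stays at least
    25 px from the image border and masks cannot touch each other (center
    separation exceeds the sum of maximal perturbed radii plus 3 px).
    """
    rng = np.random.default_rng(spec.seed)
    nrows, ncols = spec.image_shape
    r_lo, r_hi = spec.radius_range
    r_eff = r_hi * (1 + abs(spec.irregularity)) + 2
    margin = BORDER_MARGIN + r_eff
    if 2 * margin >= min(nrows, ncols):
        raise MaskPlacementError("image too small for the requested radii and margins")
    truths: list[CellGroundTruth] = []
    centers: list[tuple[float, float]] = []
    radii: list[float] = []
    attempts = 0
    max_attempts = 2000 * spec.n_cells
    while len(truths) < spec.n_cells:
        attempts += 1
        if attempts > max_attempts:
            raise MaskPlacementError(
                f"could not place {spec.n_cells} cells in {spec.image_shape} "
                f"after {max_attempts} attempts; enlarge the image or shrink the cells"
            )
        cr = rng.uniform(margin, nrows - margin)
        cc = rng.uniform(margin, ncols - margin)
        radius = rng.uniform(r_lo, r_hi)
        r_this = radius * (1 + abs(spec.irregularity)) + 2
        ok = True
        for (pr, pc), prad in zip(centers, radii):
            r_other = prad * (1 + abs(spec.irregularity)) + 2
            if np.hypot(cr - pr, cc - pc) < r_this + r_other + 3:
                ok = False
                break
        if not ok:
            continue
        cell_id = len(truths) + 1
        centers.append((cr, cc))
        radii.append(radius)
        truths.append(
            CellGroundTruth(
                cell_id=cell_id,
                center=(int(round(cr)), int(round(cc))),
                membrane_intensity=membrane_intensity,
                cytoplasm_intensity=cytoplasm_intensity,
                membrane_width_px=membrane_width_px,
                radius_px=float(radius),
            )
        )
    return truths


def render_field(
    spec: FieldSpec,
    truths: list[CellGroundTruth],
    experiment_id: str = "synthetic",
    condition: str = "control",
    genotype: str = "synthetic",
) -> tuple[LabeledField, list[CellGroundTruth]]:
    """Render a field: membrane ring + cytoplasm fill per cell, then noise.

    For each cell, mask pixels within ``membrane_width_px`` (Chebyshev
    distance to the nearest background pixel) of the boundary carry
    ``membrane_intensity``, the remaining mask pixels ``cytoplasm_intensity``,
    and non-cell pixels ``background_level``.  Poisson shot noise is applied
    to the noise-free image, then Gaussian read noise is added.  Returns the
    labeled field and a copy of the truths with measured compartment areas
    filled in.  Mask geometry depends only on ``(spec.seed, cell_id,
    center, radius_px)``, so re-rendering after an intensity change (e.g.
    :func:`simulate_internalization`) reuses identical masks.
    """
    nrows, ncols = spec.image_shape
    image = np.full(spec.image_shape, float(spec.background_level))
    labels = np.zeros(spec.image_shape, dtype=np.int64)
    out_truths: list[CellGroundTruth] = []
    for t in truths:
        radius = t.radius_px
        if radius is None:
            cell_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, t.cell_id, 7]))
            radius = float(cell_rng.uniform(*spec.radius_range))
        mask = make_cell_mask(
            spec.image_shape, t.center, radius, spec.irregularity, _mask_seed(spec.seed, t.cell_id)
        )
        rows, cols = np.nonzero(mask)
        if (
            rows.min() < BORDER_MARGIN
            or cols.min() < BORDER_MARGIN
            or rows.max() >= nrows - BORDER_MARGIN
            or cols.max() >= ncols - BORDER_MARGIN
        ):
            raise MaskPlacementError(
                f"cell {t.cell_id} violates the {BORDER_MARGIN} px border margin"
            )
        if (labels[mask] != 0).any():
            raise MaskOverlapError(f"cell {t.cell_id} overlaps a previously placed cell")
        depth = ndimage.distance_transform_cdt(mask, metric="chessboard")
        membrane = mask & (depth <= t.membrane_width_px)
        cytoplasm = mask & ~membrane
        image[membrane] = t.membrane_intensity
        image[cytoplasm] = t.cytoplasm_intensity
        labels[mask] = t.cell_id
        out_truths.append(
            dataclasses.replace(
                t,
                radius_px=radius,
                membrane_area_px=int(membrane.sum()),
                cytoplasm_area_px=int(cytoplasm.sum()),
            )
        )
    rng = np.random.default_rng(spec.seed)
    if spec.poisson_noise:
        image = rng.poisson(np.clip(image, 0, None)).astype(float)
    if spec.gaussian_noise_sd > 0:
        image = image + rng.normal(0, spec.gaussian_noise_sd, size=image.shape)
    field = LabeledField(image, labels, experiment_id, condition, genotype)
    return field, out_truths


def truth_table(truths: list[CellGroundTruth]) -> pd.DataFrame:
    """Flatten ground truths into the CSV-ready truth table."""
    return pd.DataFrame(
        [
            {
                "cell_id": t.cell_id,
                "center_row": t.center[0],
                "center_col": t.center[1],
                "membrane_intensity": t.membrane_intensity,
                "cytoplasm_intensity": t.cytoplasm_intensity,
                "membrane_width_px": t.membrane_width_px,
                "true_ratio": t.true_ratio,
                "membrane_area_px": t.membrane_area_px,
                "cytoplasm_area_px": t.cytoplasm_area_px,
            }
            for t in truths
        ]
    )


def simulate_internalization(
    truths: list[CellGroundTruth],
    internalized_fraction: float,
) -> list[CellGroundTruth]:
    """Move membrane signal into the cytoplasm, conserving total fluorescence.

    With area-weighted uniform level ``u = (m·A_m + c·A_c)/(A_m + A_c)``, both
    compartments relax toward ``u`` linearly in ``internalized_fraction``:
    fraction 0 leaves the cell unchanged, fraction 1 equalizes the two
    compartments, and the integrated fluorescence ``m·A_m + c·A_c`` is
    conserved exactly at every fraction.  Requires compartment areas, i.e.
    truths returned by :func:`render_field`.
    """
    if not 0 <= internalized_fraction <= 1:
        raise ValueError("internalized_fraction must be in [0, 1]")
    out = []
    for t in truths:
        if t.membrane_area_px is None or t.cytoplasm_area_px is None:
            raise ValueError(
                f"cell {t.cell_id}: compartment areas unknown; render the field first"
            )
        am, ac = t.membrane_area_px, t.cytoplasm_area_px
        if am + ac == 0:
            raise ValueError(f"cell {t.cell_id}: empty mask")
        u = (t.membrane_intensity * am + t.cytoplasm_intensity * ac) / (am + ac)
        f = internalized_fraction
        out.append(
            dataclasses.replace(
                t,
                membrane_intensity=t.membrane_intensity + f * (u - t.membrane_intensity),
                cytoplasm_intensity=t.cytoplasm_intensity + f * (u - t.cytoplasm_intensity),
            )
        )
    return out


def _hill_amplitude(c: float, spec: BretSimSpec) -> float:
    ec50 = 10.0**spec.logec50
    return spec.floor + spec.span * c**spec.hill / (c**spec.hill + ec50**spec.hill)


def simulate_bret_experiment(spec: BretSimSpec) -> list[BretTrace]:
    """Simulate one plate of BRET traces: vehicle wells plus a dose ladder.

    Each well's BRET ratio is ``R0 + well_offset + drift·t`` before the
    stimulation timepoint, after which the response amplitude rises as
    ``A(c)·(1 − exp(−Δt/onset_tau))`` with ``A(c)`` on the four-parameter
    logistic curve (vehicle wells have zero amplitude).  Gaussian noise of SD
    ``noise_sd`` is added to the ratio; the two wavelength channels are then
    reconstructed as ``I480 = donor_counts`` and ``I530 = ratio · I480``.
    Bit-identical output for identical spec (including seed).
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_timepoints) * spec.sample_interval_s
    onset = np.where(
        t >= spec.stimulation_time_s,
        1.0 - np.exp(-np.maximum(t - spec.stimulation_time_s, 0) / spec.onset_tau),
        0.0,
    )
    traces: list[BretTrace] = []

    def one_well(well: str, conc: float, treatment: str) -> BretTrace:
        amp = 0.0 if not np.isfinite(conc) else _hill_amplitude(conc, spec)
        offset = rng.normal(0, spec.well_offset_sd)
        ratio = spec.baseline_ratio + offset + spec.baseline_drift_per_s * t + amp * onset
        if spec.noise_sd > 0:
            ratio = ratio + rng.normal(0, spec.noise_sd, size=t.shape)
        i480 = np.full_like(t, spec.donor_counts)
        return BretTrace(
            well=well,
            time_s=t,
            I530=ratio * i480,
            I480=i480,
            treatment=treatment,
            concentration=conc,
            stimulation_time_s=spec.stimulation_time_s,
        )

    for rep in range(1, spec.n_replicates + 1):
        traces.append(one_well(f"veh-r{rep}", float("nan"), "vehicle"))
    for ci, conc in enumerate(spec.concentrations, start=1):
        for rep in range(1, spec.n_replicates + 1):
            traces.append(one_well(f"c{ci:02d}-r{rep}", float(conc), "agonist"))
    return traces
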