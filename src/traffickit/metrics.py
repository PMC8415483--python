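"""Summary statistics over radial profiles: membrane/cytoplasm ratios,
per-experiment normalization, and per-condition aggregates.

The membrane-to-cytoplasm ratio is the background-corrected mean fluorescence
over the edge-proximal bands (defaults 0–5, i.e. 0–5 px from the cell edge)
divided by that over the deeper bands (6 and beyond).  Ratios are computed
from unweighted means of band means — band areas grow with distance, and the
per-contour profile plots this mirrors are per-band means; a pixel-weighted
("sum") variant is available behind a flag.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contours import RadialProfile
from .errors import NormalizationError

SUMMARY_COLUMNS = [
    "experiment_id",
    "condition",
    "genotype",
    "cell_id",
    "membrane_mean",
    "cytoplasm_mean",
    "mc_ratio",
    "total_cell_fluor",
    "valid",
]


@dataclass
class CellSummary:
    """Per-cell membrane/cytoplasm summary.

    ``valid`` is False when the cytoplasm mean is non-positive, in which case
    ``mc_ratio`` is NaN; invalid cells are excluded from aggregates and
    counted in the QC report.
    """

    cell_id: int
    membrane_mean: float
    cytoplasm_mean: float
    mc_ratio: float
    total_cell_fluor: float
    condition: str = ""
    genotype: str = ""
    experiment_id: str = ""
    valid: bool = True


def mc_ratio(
    profile: RadialProfile,
    membrane_bands: tuple[int, int] = (0, 5),
    cytoplasm_bands: tuple[int, int] = (6, 39),
    method: str = "mean",
    condition: str = "",
    genotype: str = "",
    experiment_id: str = "",
) -> CellSummary:
    """Compute one cell's membrane-to-cytoplasm fluorescence ratio.

    ``method="mean"`` (default) averages corrected band means with equal
    weight per band; ``method="sum"`` weights each band by its pixel count
    (equivalent to pooling pixels).  Bands with missing means (empty after
    full erosion) are excluded.  Raises ValueError when a range contains no
    measurable band.
    """
    if method not in ("mean", "sum"):
        raise ValueError(f"unknown method {method!r}")

    def range_mean(lo: int, hi: int) -> float:
        idx = [i for i in range(lo, hi + 1) if i in profile.corrected and np.isfinite(profile.corrected[i])]
        if not idx:
            raise ValueError(
                f"cell {profile.cell_id}: no non-missing bands in range {lo}..{hi}"
            )
        vals = np.array([profile.corrected[i] for i in idx])
        if method == "sum":
            w = np.array([profile.n_pixels.get(i, 0) for i in idx], dtype=float)
            return float(np.sum(vals * w) / np.sum(w))
        return float(vals.mean())

    membrane = range_mean(*membrane_bands)
    cytoplasm = range_mean(*cytoplasm_bands)
    valid = cytoplasm > 0
    ratio = membrane / cytoplasm if valid else float("nan")
    return CellSummary(
        cell_id=profile.cell_id,
        membrane_mean=membrane,
        cytoplasm_mean=cytoplasm,
        mc_ratio=ratio,
        total_cell_fluor=profile.total_cell_fluor,
        condition=condition,
        genotype=genotype,
        experiment_id=experiment_id,
        valid=bool(valid),
    )


def summarize_cells(
    profiles: list[RadialProfile],
    membrane_bands: tuple[int, int] = (0, 5),
    cytoplasm_bands: tuple[int, int] = (6, 39),
    method: str = "mean",
    condition: str = "",
    genotype: str = "",
    experiment_id: str = "",
) -> list[CellSummary]:
    """Apply :func:`mc_ratio` to every profile of one field/experiment.

    Cells whose membrane or cytoplasm band range is entirely empty (fully
    eroded before reaching the range — very small or pinched cells) are
    flagged invalid instead of aborting the run.
    """
    out = []
    for p in profiles:
        try:
            out.append(
                mc_ratio(p, membrane_bands, cytoplasm_bands, method, condition, genotype, experiment_id)
            )
        except ValueError:
            out.append(
                CellSummary(
                    cell_id=p.cell_id,
                    membrane_mean=float("nan"),
                    cytoplasm_mean=float("nan"),
                    mc_ratio=float("nan"),
                    total_cell_fluor=p.total_cell_fluor,
                    condition=condition,
                    genotype=genotype,
                    experiment_id=experiment_id,
                    valid=False,
                )
            )
    return out


def summaries_to_frame(summaries: list[CellSummary]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(s) for s in summaries], columns=SUMMARY_COLUMNS)


def normalize_by_experiment(profiles: list[RadialProfile]) -> tuple[list[RadialProfile], float]:
    """Normalize one experiment's profiles to its average overall cell fluorescence.

    Every raw and corrected band mean, background value and total is divided
    by the experiment-wide mean of ``total_cell_fluor``; after normalization
    that mean equals 1, making profiles comparable across experiments with
    different gains or expression levels.
    """
    if not profiles:
        raise NormalizationError("no cells in experiment")
    normalizer = float(np.mean([p.total_cell_fluor for p in profiles]))
    if normalizer <= 0:
        raise NormalizationError(f"non-positive experiment normalizer {normalizer}")
    out = []
    for p in profiles:
        out.append(
            RadialProfile(
                cell_id=p.cell_id,
                raw={i: v / normalizer for i, v in p.raw.items()},
                corrected={i: v / normalizer for i, v in p.corrected.items()},
                background_value=p.background_value / normalizer,
                total_cell_fluor=p.total_cell_fluor / normalizer,
                n_pixels=dict(p.n_pixels),
            )
        )
    return out, normalizer


def _sem(values: np.ndarray) -> float:
    n = len(values)
    if n <= 1:
        return 0.0
    return float(np.std(values, ddof=1) / np.sqrt(n))


def aggregate(
    summaries: pd.DataFrame | list[CellSummary],
    profiles_frame: pd.DataFrame | None = None,
    by: tuple[str, ...] = ("condition", "genotype"),
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Aggregate per-cell summaries (and optionally band profiles) by group.

    Returns ``(ratio_frame, group_profile_frame)``.  The ratio frame carries,
    per group, the mean and SEM of ``mc_ratio`` across cells, plus — when an
    ``experiment_id`` column distinguishes several experiments — the SEM of
    per-experiment mean ratios across experiments (the level at which the
    source assay reports its error bars).  SEM with n=1 is reported as 0 and
    flagged.  Invalid cells are excluded and counted.  The profile frame
    (when ``profiles_frame`` with ``band_index``/``mean_fluor_corrected``
    columns is given) carries per-band mean, SEM and n over cells per group.
    """
    if not isinstance(summaries, pd.DataFrame):
        summaries = summaries_to_frame(summaries)
    by = list(by)
    ratio_rows = []
    for keys, grp in summaries.groupby(by, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        valid = grp[grp["valid"] & np.isfinite(grp["mc_ratio"])]
        if valid.empty:
            warnings.warn(f"group {dict(zip(by, keys))} has no valid cells; omitted")
            continue
        ratios = valid["mc_ratio"].to_numpy()
        row = dict(zip(by, keys))
        row.update(
            ratio_mean=float(ratios.mean()),
            ratio_sem_cells=_sem(ratios),
            n_cells=len(ratios),
            n_invalid=int(len(grp) - len(valid)),
            n_is_1=len(ratios) == 1,
        )
        if "experiment_id" in valid.columns and valid["experiment_id"].nunique() > 1:
            per_exp = valid.groupby("experiment_id")["mc_ratio"].mean().to_numpy()
            row["ratio_sem_experiments"] = _sem(per_exp)
            row["n_experiments"] = len(per_exp)
        ratio_rows.append(row)
    ratio_frame = pd.DataFrame(ratio_rows)

    profile_frame = None
    if profiles_frame is not None:
        prof_rows = []
        for keys, grp in profiles_frame.groupby(by, sort=True):
            keys = keys if isinstance(keys, tuple) else (keys,)
            for band, band_grp in grp.groupby("band_index", sort=True):
                vals = band_grp["mean_fluor_corrected"].to_numpy()
                vals = vals[np.isfinite(vals)]
                if vals.size == 0:
                    continue
                row = dict(zip(by, keys))
                row.update(
                    band_index=int(band),
                    mean=float(vals.mean()),
                    sem=_sem(vals),
                    n=int(vals.size),
                )
                prof_rows.append(row)
        profile_frame = pd.DataFrame(prof_rows)
    return ratio_frame, profile_frame
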