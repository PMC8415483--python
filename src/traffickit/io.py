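"""Readers and writers for images, label masks, plate-reader tables and profiles.

Conventions: pixel coordinates are 0-based (row, col); label 0 is background
and label k>0 is cell k, matching the output of common segmentation tools.
Metadata travels as explicit arguments or CSV columns, never encoded in
filenames.  All readers validate and reject rather than coerce.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import (
    MissingColumnsError,
    NoCellsError,
    NonIntegerLabelsError,
    NonMonotoneTimeError,
    NonPositiveLuminescenceError,
    ShapeMismatchError,
)

BRET_COLUMNS = ["well", "time_s", "I530", "I480", "treatment", "concentration_M"]
PROFILE_COLUMNS = [
    "experiment_id",
    "condition",
    "genotype",
    "cell_id",
    "band_index",
    "mean_fluor_raw",
    "mean_fluor_corrected",
    "n_pixels",
]


@dataclass
class LabeledField:
    """An intensity image plus its integer label mask and experiment metadata."""

    intensity: np.ndarray
    labels: np.ndarray
    experiment_id: str = ""
    condition: str = ""
    genotype: str = ""

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity)
        labels = np.asarray(self.labels)
        if self.intensity.shape != labels.shape:
            raise ShapeMismatchError(
                f"intensity shape {self.intensity.shape} != labels shape {labels.shape}"
            )
        if np.issubdtype(labels.dtype, np.floating):
            if not np.all(labels == np.round(labels)):
                raise NonIntegerLabelsError("label mask contains non-integer values")
            labels = labels.astype(np.int64)
        elif not np.issubdtype(labels.dtype, np.integer):
            raise NonIntegerLabelsError(f"label mask has non-numeric dtype {labels.dtype}")
        if labels.min() < 0:
            raise NonIntegerLabelsError("label mask contains negative values")
        if labels.max() == 0:
            raise NoCellsError("label mask contains no cells (all zeros)")
        self.labels = labels.astype(np.int64)

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


@dataclass
class BretTrace:
    """Dual-wavelength luminescence time course for one well.

    ``I530``/``I480`` are acceptor- and donor-channel counts sampled at
    ``time_s`` (strictly increasing).  ``stimulation_time_s`` marks ligand
    addition; ``concentration`` is molar, NaN for vehicle wells.
    """

    well: str
    time_s: np.ndarray
    I530: np.ndarray
    I480: np.ndarray
    treatment: str = ""
    concentration: float = float("nan")
    stimulation_time_s: float = 0.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.I530 = np.asarray(self.I530, dtype=float)
        self.I480 = np.asarray(self.I480, dtype=float)
        if not (len(self.time_s) == len(self.I530) == len(self.I480)):
            raise ShapeMismatchError(f"well {self.well}: time/I530/I480 length mismatch")
        if len(self.time_s) and np.any(np.diff(self.time_s) <= 0):
            raise NonMonotoneTimeError(f"well {self.well}: time not strictly increasing")
        bad = np.nonzero(self.I480 <= 0)[0]
        if bad.size:
            raise NonPositiveLuminescenceError(
                f"well {self.well}: I480 <= 0 at t={self.time_s[bad[0]]:g} s"
            )

    @property
    def is_vehicle(self) -> bool:
        return not np.isfinite(self.concentration) or self.concentration == 0


def read_field(
    intensity_path: str | Path,
    labels_path: str | Path,
    experiment_id: str = "",
    condition: str = "",
    genotype: str = "",
) -> LabeledField:
    """Read an intensity TIFF and a label-mask TIFF/PNG into a validated field."""
    intensity = tifffile.imread(str(intensity_path)) if str(intensity_path).lower().endswith(
        (".tif", ".tiff")
    ) else np.asarray(_read_png(intensity_path))
    labels = tifffile.imread(str(labels_path)) if str(labels_path).lower().endswith(
        (".tif", ".tiff")
    ) else np.asarray(_read_png(labels_path))
    return LabeledField(intensity, labels, experiment_id, condition, genotype)


def _read_png(path: str | Path) -> np.ndarray:
    from imageio.v3 import imread

    return imread(str(path))


def write_field(field: LabeledField, intensity_path: str | Path, labels_path: str | Path) -> None:
    """Write intensity and labels as TIFF (16-bit where the range allows)."""
    intensity = field.intensity
    if np.issubdtype(intensity.dtype, np.integer) and intensity.min() >= 0 and intensity.max() <= 65535:
        intensity = intensity.astype(np.uint16)
    tifffile.imwrite(str(intensity_path), intensity)
    labels = field.labels
    if labels.max() <= 65535:
        labels = labels.astype(np.uint16)
    tifffile.imwrite(str(labels_path), labels)


def read_bret_csv(path: str | Path) -> list[BretTrace]:
    """Read a long-format plate-reader CSV into one validated trace per well.

    Required columns: well, time_s, I530, I480, treatment, concentration_M;
    optional stimulation_time_s.  Rows are sorted by time within well.
    """
    df = pd.read_csv(path)
    missing = [c for c in BRET_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnsError(f"{path}: missing columns {missing}")
    traces = []
    for well, grp in df.groupby("well", sort=True):
        grp = grp.sort_values("time_s")
        stim = float(grp["stimulation_time_s"].iloc[0]) if "stimulation_time_s" in grp else 0.0
        conc = grp["concentration_M"].iloc[0]
        traces.append(
            BretTrace(
                well=str(well),
                time_s=grp["time_s"].to_numpy(),
                I530=grp["I530"].to_numpy(),
                I480=grp["I480"].to_numpy(),
                treatment=str(grp["treatment"].iloc[0]),
                concentration=float(conc) if pd.notna(conc) else float("nan"),
                stimulation_time_s=stim,
            )
        )
    return traces


def write_bret_csv(traces: list[BretTrace], path: str | Path) -> None:
    """Write traces to the long-format CSV read back by :func:`read_bret_csv`."""
    rows = []
    for tr in traces:
        for t, a, d in zip(tr.time_s, tr.I530, tr.I480):
            rows.append(
                {
                    "well": tr.well,
                    "time_s": t,
                    "I530": a,
                    "I480": d,
                    "treatment": tr.treatment,
                    "concentration_M": tr.concentration,
                    "stimulation_time_s": tr.stimulation_time_s,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def profiles_to_frame(
    profiles,
    experiment_id: str = "",
    condition: str = "",
    genotype: str = "",
) -> pd.DataFrame:
    """Flatten RadialProfiles into the long profile table (one row per band)."""
    rows = []
    for p in profiles:
        for idx in p.band_indices:
            rows.append(
                {
                    "experiment_id": experiment_id,
                    "condition": condition,
                    "genotype": genotype,
                    "cell_id": p.cell_id,
                    "band_index": idx,
                    "mean_fluor_raw": p.raw[idx],
                    "mean_fluor_corrected": p.corrected[idx],
                    "n_pixels": p.n_pixels.get(idx, 0),
                }
            )
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def write_profiles(profiles_frame: pd.DataFrame, path: str | Path) -> None:
    """Write the long-format profile table to CSV."""
    missing = [c for c in PROFILE_COLUMNS if c not in profiles_frame.columns]
    if missing:
        raise MissingColumnsError(f"profile frame missing columns {missing}")
    profiles_frame.to_csv(path, index=False)


def read_profiles(path: str | Path) -> pd.DataFrame:
    """Read a profile CSV written by :func:`write_profiles`."""
    df = pd.read_csv(path)
    missing = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing:
        raise MissingColumnsError(f"{path}: missing columns {missing}")
    return df
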