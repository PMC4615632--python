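"""File readers and writers.

Formats handled:

* spectra — two-column CSV with header ``wavelength_nm,value``; reflectance
  given in percent (detected when the maximum exceeds 1.5) is converted to a
  fraction with a log entry;
* images — PNG or TIFF, 8- or 16-bit RGB, scaled to [0, 1] on read;
* masks — single-channel PNG (nonzero = inside) or a run-length JSON sidecar
  ``{"shape": [H, W], "runs": [[row, start_col, length], ...]}``;
* measurement tables — tidy CSV (or XLSX converted via
  :func:`convert_xlsx_to_csv`) carrying the per-female colour features,
  hormone records and weekly colour time courses.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .classify import FEATURE_COLUMNS
from .spectra import Spectrum
from .stats import HORMONE_COLUMNS, TIMEPOINT_ORDER

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_image",
    "read_mask",
    "write_mask",
    "read_measurement_table",
    "convert_xlsx_to_csv",
]

logger = logging.getLogger(__name__)

#: Mandatory columns of the tidy measurement table.
MEASUREMENT_FEATURE_COLUMNS = ("id", "morph") + FEATURE_COLUMNS


def read_spectrum_csv(path, kind: str = "reflectance") -> Spectrum:
    """Read a two-column wavelength/value CSV into a :class:`Spectrum`.

    Values with a maximum above 1.5 are treated as percent reflectance and
    divided by 100 (logged); small negative values (spectrometer noise) are
    clipped to zero with a warning.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns, got {df.shape[1]}")
    wl = pd.to_numeric(df.iloc[:, 0], errors="coerce")
    vals = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    bad = wl.isna() | vals.isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise ValueError(f"{path}: non-numeric entry at line {line}")
    wl = wl.to_numpy(dtype=float)
    vals = vals.to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        line = int(np.argmax(np.diff(wl) <= 0)) + 3
        raise ValueError(
            f"{path}: wavelengths not strictly increasing at line {line}"
        )
    if np.any(vals < 0):
        logger.warning("%s: %d negative values clipped to 0",
                       path, int((vals < 0).sum()))
        vals = np.clip(vals, 0.0, None)
    if kind == "reflectance" and vals.max() > 1.5:
        logger.info("%s: values look like percent (max %.3g); dividing by 100",
                    path, vals.max())
        vals = vals / 100.0
    return Spectrum(wl, vals, kind=kind)


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    """Write a spectrum as ``wavelength_nm,value`` CSV (full precision)."""
    df = pd.DataFrame({"wavelength_nm": spectrum.wavelengths_nm,
                       "value": spectrum.values})
    df.to_csv(path, index=False, float_format="%.12g")


def read_image(path) -> np.ndarray:
    """Read an 8/16-bit RGB PNG or TIFF, scaled to [0, 1] float."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3 and arr.shape[2] == 4:   # drop alpha
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path}: expected an RGB image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    arr = arr.astype(float)
    if arr.max() > 1.5:
        raise ValueError(f"{path}: float image values must lie in [0, 1]")
    return arr


def read_mask(path) -> np.ndarray:
    """Read a region mask: single-channel PNG (nonzero = inside) or a
    run-length JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        spec = json.loads(path.read_text())
        h, w = spec["shape"]
        mask = np.zeros((h, w), dtype=bool)
        for row, start, length in spec["runs"]:
            mask[row, start:start + length] = True
        return mask
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 0


def write_mask(mask: np.ndarray, path) -> None:
    """Write a boolean mask as an 8-bit PNG (255 = inside) or RLE JSON."""
    path = Path(path)
    mask = np.asarray(mask, dtype=bool)
    if path.suffix.lower() == ".json":
        runs = []
        for r in range(mask.shape[0]):
            row = mask[r]
            edges = np.flatnonzero(np.diff(np.r_[0, row.view(np.int8), 0]))
            for start, stop in zip(edges[::2], edges[1::2]):
                runs.append([int(r), int(start), int(stop - start)])
        path.write_text(json.dumps(
            {"shape": list(mask.shape), "runs": runs}))
    else:
        iio.imwrite(path, (mask.astype(np.uint8) * 255))


def convert_xlsx_to_csv(xlsx_path, csv_path, sheet=0) -> Path:
    """Convert one sheet of an XLSX workbook to CSV (the pipeline core
    consumes CSV only)."""
    df = pd.read_excel(Path(xlsx_path), sheet_name=sheet)
    csv_path = Path(csv_path)
    df.to_csv(csv_path, index=False)
    return csv_path


def read_measurement_table(path):
    """Parse the tidy measurement table into the three analysis inputs.

    Expected columns (long format, one row per female per record):

    * ``id``, ``morph`` — always required;
    * the seven colour variables (``prop_red`` ... ``bib_achromatic_jnd``)
      on rows marked ``record_type == 'peak'`` (or on all rows when no
      ``record_type`` column exists) — the per-female peak-expression rows
      entering the discriminant analysis;
    * ``timepoint``, ``testosterone`` — hormone records;
    * ``week``, ``value`` (plus optional ``variable``) — weekly colour
      time-course records.

    Returns ``(feature_table, hormone_panel, timecourse)`` DataFrames; an
    element is ``None`` when its columns are absent. XLSX input is converted
    on the fly.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    for col in ("id", "morph"):
        if col not in df.columns:
            raise ValueError(
                f"{path}: measurement table is missing mandatory column "
                f"{col!r} (schema: id, morph, [features], [timepoint, "
                "testosterone], [week, value])"
            )

    feature_table = None
    have_features = [c for c in FEATURE_COLUMNS if c in df.columns]
    if have_features:
        if len(have_features) != len(FEATURE_COLUMNS):
            missing = sorted(set(FEATURE_COLUMNS) - set(have_features))
            raise ValueError(f"{path}: incomplete feature columns; "
                             f"missing {missing}")
        rows = df
        if "record_type" in df.columns:
            rows = df[df["record_type"] == "peak"]
        feature_table = (rows.dropna(subset=list(FEATURE_COLUMNS))
                         .loc[:, ["id", "morph"] + list(FEATURE_COLUMNS)]
                         .drop_duplicates(subset="id")
                         .reset_index(drop=True))

    hormone_panel = None
    if {"timepoint", "testosterone"}.issubset(df.columns):
        hp = (df.dropna(subset=["timepoint", "testosterone"])
                .loc[:, ["id", "timepoint", "testosterone"]]
                .rename(columns={"id": "female_id"}))
        if hp.duplicated(subset=["female_id", "timepoint"]).any():
            raise ValueError(
                f"{path}: duplicate (female, timepoint) hormone records"
            )
        unknown = set(hp["timepoint"]) - set(TIMEPOINT_ORDER)
        if unknown:
            raise ValueError(f"{path}: unknown timepoints {sorted(unknown)}")
        hormone_panel = hp.reset_index(drop=True)

    timecourse = None
    if {"week", "value"}.issubset(df.columns):
        tc = (df.dropna(subset=["week", "value"])
                .loc[:, ["id", "week", "morph", "value"]
                     + (["variable"] if "variable" in df.columns else [])]
                .rename(columns={"id": "female_id"}))
        timecourse = tc.reset_index(drop=True)

    logger.info(
        "%s: %d rows; features=%s hormones=%s timecourse=%s", path, len(df),
        0 if feature_table is None else len(feature_table),
        0 if hormone_panel is None else len(hormone_panel),
        0 if timecourse is None else len(timecourse),
    )
    return feature_table, hormone_panel, timecourse
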