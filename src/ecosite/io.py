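"""Readers and writers for the pipeline's file formats.

Rasters travel as TIFF (one page per scene for stacks) with two plain
sidecars: a CSV date index (band, ISO date) and a JSON geo sidecar
holding the affine geotransform, CRS tag, nodata value, and provenance
metadata (seed, package version, config hash).  Samples, climate and
error matrices are CSV; reports and model metadata are JSON; run
configuration is YAML.  Missing observations are encoded on disk by the
declared nodata value and re-derived into an explicit mask on read.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .accuracy import ErrorMatrix
from .classify import SampleSet
from .geo import GeoTransform
from .stack import NDVIStack
from .synthetic import ClimateRecord

__all__ = [
    "NODATA",
    "write_stack",
    "read_stack",
    "write_class_raster",
    "read_class_raster",
    "write_climate",
    "read_climate",
    "read_samples",
    "write_error_matrix",
    "read_error_matrix",
    "load_reference_matrices",
    "load_config",
    "provenance",
]

NODATA = -9999.0


def _sidecar_path(tiff_path) -> Path:
    return Path(tiff_path).with_suffix(".geo.json")


def provenance(seed: int | None = None, config: dict | None = None) -> dict:
    """Provenance block embedded in every written artifact."""
    from . import __version__

    block = {"package": "ecosite", "version": __version__}
    if seed is not None:
        block["seed"] = int(seed)
    if config is not None:
        digest = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()
        block["config_sha256"] = digest
    return block


def write_stack(stack: NDVIStack, tiff_path, date_index_csv, seed: int | None = None) -> None:
    """Write a stack as multi-page float32 TIFF + CSV date index + sidecar."""
    values = stack.values.astype(np.float32).copy()
    values[stack.mask] = NODATA
    tifffile.imwrite(tiff_path, values)
    pd.DataFrame(
        {"band": np.arange(1, stack.n_times + 1), "date": stack.dates.strftime("%Y-%m-%d")}
    ).to_csv(date_index_csv, index=False)
    sidecar = {
        "transform": stack.transform.to_dict(),
        "crs": stack.crs,
        "nodata": NODATA,
        "provenance": provenance(seed=seed),
    }
    _sidecar_path(tiff_path).write_text(json.dumps(sidecar, indent=2))


def read_stack(tiff_path, date_index_csv) -> NDVIStack:
    """Read a stack written by :func:`write_stack` (exact round trip)."""
    values = tifffile.imread(tiff_path).astype(float)
    if values.ndim == 2:
        values = values[None]
    index = pd.read_csv(date_index_csv)
    if {"band", "date"} - set(index.columns):
        raise ValueError("date index must have 'band' and 'date' columns")
    if index["date"].isna().any():
        raise ValueError("date index contains missing dates")
    if len(index) != values.shape[0]:
        raise ValueError(
            f"band count ({values.shape[0]}) does not match date index rows ({len(index)})"
        )
    dates = pd.DatetimeIndex(pd.to_datetime(index["date"]))
    if len(dates) > 1 and not dates.is_monotonic_increasing:
        raise ValueError("date index is not ascending")
    nodata = NODATA
    transform = GeoTransform.north_up(0.0, 0.0, 30.0)
    crs = ""
    sidecar = _sidecar_path(tiff_path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        transform = GeoTransform.from_dict(meta["transform"])
        crs = meta.get("crs", "")
        nodata = float(meta.get("nodata", NODATA))
    mask = values == nodata
    values = values.copy()
    values[mask] = np.nan
    return NDVIStack(values=values, mask=mask, dates=dates, transform=transform, crs=crs)


def write_class_raster(
    raster: np.ndarray,
    tiff_path,
    legend_json,
    transform: GeoTransform | None = None,
    crs: str = "",
    seed: int | None = None,
) -> None:
    """Write a class-label raster as int16 TIFF + JSON class-code legend."""
    raster = np.asarray(raster)
    labels = sorted(np.unique(raster).tolist())
    code = {label: i for i, label in enumerate(labels)}
    coded = np.vectorize(code.__getitem__, otypes=[np.int16])(raster)
    tifffile.imwrite(tiff_path, coded)
    legend = {
        "classes": {str(i): label for label, i in code.items()},
        "provenance": provenance(seed=seed),
    }
    Path(legend_json).write_text(json.dumps(legend, indent=2))
    if transform is not None:
        sidecar = {"transform": transform.to_dict(), "crs": crs, "provenance": provenance(seed=seed)}
        _sidecar_path(tiff_path).write_text(json.dumps(sidecar, indent=2))


def read_class_raster(tiff_path, legend_json) -> np.ndarray:
    coded = tifffile.imread(tiff_path)
    legend = json.loads(Path(legend_json).read_text())["classes"]
    out = np.empty(coded.shape, dtype=object)
    for code, label in legend.items():
        out[coded == int(code)] = label
    return out


def write_climate(record: ClimateRecord, csv_path) -> None:
    record.to_frame().to_csv(csv_path, index=False)


def read_climate(csv_path) -> ClimateRecord:
    frame = pd.read_csv(csv_path)
    if {"date", "precip_mm"} - set(frame.columns):
        raise ValueError("climate CSV needs 'date' and 'precip_mm' columns")
    return ClimateRecord(
        dates=pd.DatetimeIndex(pd.to_datetime(frame["date"])),
        precip=frame["precip_mm"].to_numpy(dtype=float),
    )


def read_samples(csv_path, stack: NDVIStack, logger=None) -> SampleSet:
    """Read a field-sample CSV and bind points to stack pixels.

    Required columns: id, x, y, es_class, state_code (optional:
    dataset).  Coordinates are mapped through the stack geotransform to
    0-based (row, col); points outside the raster extent are dropped
    with their ids reported via the logger.
    """
    frame = pd.read_csv(csv_path)
    required = {"id", "x", "y", "es_class", "state_code"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"samples CSV missing columns: {sorted(missing)}")
    rows, cols = stack.transform.rowcol(frame["x"].to_numpy(), frame["y"].to_numpy())
    frame = frame.assign(row=rows, col=cols)
    inside = (
        (frame["row"] >= 0)
        & (frame["row"] < stack.n_rows)
        & (frame["col"] >= 0)
        & (frame["col"] < stack.n_cols)
    )
    if not inside.all():
        rejected = frame.loc[~inside, "id"].tolist()
        if logger is not None:
            logger.warning("rejecting %d out-of-extent samples: %s", len(rejected), rejected)
        frame = frame[inside]
    return SampleSet(frame.reset_index(drop=True))


def write_error_matrix(matrix: ErrorMatrix, csv_path) -> None:
    matrix.counts.rename_axis("class").to_csv(csv_path)


def read_error_matrix(csv_path) -> ErrorMatrix:
    counts = pd.read_csv(csv_path, index_col=0)
    counts.index.name = None
    counts.columns.name = None
    return ErrorMatrix(counts)


def load_reference_matrices() -> dict:
    """Bundled validation error matrices from a published five-class
    ecological-site mapping study (SVM cross-validated, expert-map, and
    gSSURGO-map matrices over the same 176 field points; the SVM matrix
    pools 100 hold-out repeats)."""
    out = {}
    for name in ("svm", "expert", "gssurgo"):
        ref = resources.files("ecosite.data") / f"error_matrix_{name}.csv"
        with resources.as_file(ref) as path:
            out[name] = read_error_matrix(path)
    return out


def load_config(yaml_path) -> dict:
    with open(yaml_path) as fh:
        config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("config must be a YAML mapping")
    return config
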