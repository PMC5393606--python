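"""Ecological-state diagnostics of classifier errors and map summaries.

Ecological state codes (1 grassland ... 7 bare/annuals) are never model
covariates; they stratify classification records after the fact to ask
which states drive misclassification, which wrong classes absorb them,
and what the corresponding spectral signatures look like.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stack import NDVIStack

__all__ = [
    "classification_records",
    "misclassification_by_state",
    "misclassified_as_breakdown",
    "spectral_signature",
    "class_area_summary",
    "SpectralSignature",
]


def classification_records(ids, true_classes, predicted_classes, state_codes) -> pd.DataFrame:
    """Tidy per-sample record table (id, true, predicted, state, correct)."""
    frame = pd.DataFrame(
        {
            "id": list(ids),
            "true_class": list(true_classes),
            "predicted_class": list(predicted_classes),
            "state_code": np.asarray(state_codes, dtype=int),
        }
    )
    bad = set(frame["state_code"]) - set(range(1, 8))
    if bad:
        raise ValueError(f"state codes outside 1..7: {sorted(bad)}")
    frame["correct"] = frame["true_class"] == frame["predicted_class"]
    return frame


def misclassification_by_state(records: pd.DataFrame) -> pd.DataFrame:
    """Per-state totals, misclassification counts and percentages.

    States absent from the records are omitted.  ``pct`` is the raw
    percentage; ``pct_rounded`` its integer report form.
    """
    grouped = records.groupby("state_code")
    out = pd.DataFrame(
        {
            "n_total": grouped.size(),
            "n_misclassified": grouped["correct"].apply(lambda c: int((~c).sum())),
        }
    )
    out["pct"] = 100.0 * out["n_misclassified"] / out["n_total"]
    out["pct_rounded"] = out["pct"].round().astype(int)
    return out


def misclassified_as_breakdown(records: pd.DataFrame, site_class: str) -> dict:
    """How one site class's errors distribute over assigned classes.

    Returns {wrong class: {"n": count, "states": {state code: count}}},
    a disjoint and exhaustive partition of the class's misclassified
    records.
    """
    if site_class not in set(records["true_class"]):
        raise ValueError(f"unknown site class: {site_class!r}")
    wrong = records[(records["true_class"] == site_class) & ~records["correct"]]
    breakdown = {}
    for assigned, grp in wrong.groupby("predicted_class"):
        states = grp["state_code"].value_counts().sort_index()
        breakdown[assigned] = {
            "n": int(len(grp)),
            "states": {int(k): int(v) for k, v in states.items()},
        }
    return breakdown


@dataclass
class SpectralSignature:
    """Per-date mean +/- population SD over a pixel subset."""

    dates: pd.DatetimeIndex
    mean: np.ndarray
    sd: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "date": self.dates.strftime("%Y-%m-%d"),
                "mean": self.mean,
                "sd": self.sd,
                "n": self.n,
            }
        )


def spectral_signature(stack: NDVIStack, pixels) -> SpectralSignature:
    """Mean and population SD series over a set of (row, col) pixels."""
    pixels = list(pixels)
    if not pixels:
        raise ValueError("empty pixel subset")
    rows = np.array([p[0] for p in pixels], dtype=int)
    cols = np.array([p[1] for p in pixels], dtype=int)
    values = stack.values[:, rows, cols]  # (T, n)
    return SpectralSignature(
        dates=stack.dates,
        mean=values.mean(axis=1),
        sd=values.std(axis=1),  # ddof=0
        n=len(pixels),
    )


def class_area_summary(class_raster: np.ndarray, pixel_area: float = 900.0) -> pd.DataFrame:
    """Pixel counts, areas, and percent cover per mapped class.

    ``pixel_area`` defaults to 900 m^2 (a 30 m pixel); percentages sum
    to 100 exactly up to float rounding.
    """
    raster = np.asarray(class_raster)
    if raster.size == 0:
        raise ValueError("empty raster")
    labels, counts = np.unique(raster, return_counts=True)
    out = pd.DataFrame(
        {
            "n_pixels": counts,
            "area": counts * float(pixel_area),
            "percent": 100.0 * counts / raster.size,
        },
        index=pd.Index(labels, name="class"),
    )
    out["percent_rounded"] = out["percent"].round().astype(int)
    return out
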