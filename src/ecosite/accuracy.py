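"""Error matrices and the quantity/allocation accuracy decomposition.

An error matrix here is oriented rows = prediction, columns = reference.
Overall agreement C (trace proportion) decomposes the total disagreement
1 - C into:

* quantity disagreement  QD = 1/2 * sum_i |p_i+ - p_+i|  — error due to
  mismatched class proportions between map and reference, and
* allocation disagreement AD = sum_i min(p_i+, p_+i) - C — error due to
  swapped (mislocated) assignments at fixed proportions,

with p_i+ / p_+i the row / column marginal proportions; QD + AD = 1 - C
holds exactly.  Percent metrics follow the reporting convention of
integer percent for PCC/UA/PA and two decimals for QD/AD, rounding
half away from zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ErrorMatrix",
    "AccuracyReport",
    "error_matrix",
    "pcc",
    "users_producers",
    "quantity_disagreement",
    "allocation_disagreement",
    "confidence_interval",
    "accuracy_report",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (0.5 -> 1, -0.5 -> -1)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass
class ErrorMatrix:
    """c x c contingency counts, rows = prediction, columns = reference."""

    counts: pd.DataFrame  # index = predicted class, columns = reference class

    def __post_init__(self):
        counts = self.counts
        if not counts.index.equals(counts.columns):
            raise ValueError("row and column class orderings differ")
        if (counts.values < 0).any():
            raise ValueError("negative counts")
        self.counts = counts.astype(int)

    @property
    def classes(self) -> list:
        return list(self.counts.index)

    @property
    def total(self) -> int:
        return int(self.counts.values.sum())

    @property
    def proportions(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("empty error matrix")
        return self.counts.values / self.total

    @property
    def row_marginals(self) -> np.ndarray:
        """Prediction marginal proportions p_i+."""
        return self.proportions.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        """Reference marginal proportions p_+i."""
        return self.proportions.sum(axis=0)

    @property
    def overall_agreement(self) -> float:
        """C: the trace proportion."""
        return float(np.trace(self.proportions))


def error_matrix(predictions, references, class_list) -> ErrorMatrix:
    """Cross-tabulate (prediction, reference) label pairs."""
    predictions = list(predictions)
    references = list(references)
    if len(predictions) != len(references):
        raise ValueError("prediction and reference lengths differ")
    classes = list(class_list)
    index = {cl: i for i, cl in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for p, r in zip(predictions, references):
        if p not in index:
            raise ValueError(f"unknown predicted label: {p!r}")
        if r not in index:
            raise ValueError(f"unknown reference label: {r!r}")
        counts[index[p], index[r]] += 1
    return ErrorMatrix(pd.DataFrame(counts, index=classes, columns=classes))


def pcc(matrix: ErrorMatrix) -> float:
    """Percent correctly classified: 100 * trace / total."""
    return 100.0 * matrix.overall_agreement


def users_producers(matrix: ErrorMatrix) -> tuple[pd.Series, pd.Series]:
    """Per-class user's and producer's accuracy in percent.

    UA_i = 100 * n_ii / row-sum_i (map reliability); PA_i = 100 * n_ii /
    col-sum_i (detectability).  A zero marginal yields NaN — undefined,
    deliberately never reported as 0.
    """
    counts = matrix.counts.values.astype(float)
    diag = np.diag(counts)
    rowsum = counts.sum(axis=1)
    colsum = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ua = np.where(rowsum > 0, 100.0 * diag / rowsum, np.nan)
        pa = np.where(colsum > 0, 100.0 * diag / colsum, np.nan)
    return (
        pd.Series(ua, index=matrix.classes, name="users_accuracy"),
        pd.Series(pa, index=matrix.classes, name="producers_accuracy"),
    )


def quantity_disagreement(matrix: ErrorMatrix) -> float:
    """QD: half the L1 distance between the two marginal distributions."""
    return float(0.5 * np.abs(matrix.row_marginals - matrix.col_marginals).sum())


def allocation_disagreement(matrix: ErrorMatrix) -> float:
    """AD: sum of min(row, column) marginals minus overall agreement."""
    return float(
        np.minimum(matrix.row_marginals, matrix.col_marginals).sum() - matrix.overall_agreement
    )


def confidence_interval(per_rep_pcc, level: float = 0.95) -> tuple[float, float]:
    """Percentile interval of per-repeat PCC values."""
    values = np.asarray(list(per_rep_pcc), dtype=float)
    if values.size < 2:
        raise ValueError("need at least two repeats")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


@dataclass
class AccuracyReport:
    """Rounded headline metrics plus exact underlying proportions."""

    pcc: float
    users_accuracy: dict
    producers_accuracy: dict
    qd: float
    ad: float
    overall_agreement: float
    pcc_ci: tuple | None = None
    raw: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def _clean(v):
            return None if (isinstance(v, float) and math.isnan(v)) else v

        return {
            "pcc": self.pcc,
            "users_accuracy": {k: _clean(v) for k, v in self.users_accuracy.items()},
            "producers_accuracy": {k: _clean(v) for k, v in self.producers_accuracy.items()},
            "qd": self.qd,
            "ad": self.ad,
            "overall_agreement": self.overall_agreement,
            "pcc_ci": list(self.pcc_ci) if self.pcc_ci is not None else None,
            "raw": self.raw,
        }


def accuracy_report(matrix: ErrorMatrix, per_rep_pcc=None) -> AccuracyReport:
    """Full accuracy decomposition of one error matrix.

    Headline values are rounded (integer percent; QD/AD to 2 decimals);
    the ``raw`` field keeps full precision.
    """
    ua, pa = users_producers(matrix)
    qd = quantity_disagreement(matrix)
    ad = allocation_disagreement(matrix)
    overall = matrix.overall_agreement
    ci = None
    if per_rep_pcc is not None:
        lo, hi = confidence_interval(per_rep_pcc)
        ci = (round_half_away(lo), round_half_away(hi))
    return AccuracyReport(
        pcc=round_half_away(pcc(matrix)),
        users_accuracy={k: round_half_away(v) if not math.isnan(v) else float("nan") for k, v in ua.items()},
        producers_accuracy={k: round_half_away(v) if not math.isnan(v) else float("nan") for k, v in pa.items()},
        qd=round_half_away(qd, 2),
        ad=round_half_away(ad, 2),
        overall_agreement=overall,
        pcc_ci=ci,
        raw={
            "pcc": pcc(matrix),
            "qd": qd,
            "ad": ad,
            "users_accuracy": {k: v for k, v in ua.items()},
            "producers_accuracy": {k: v for k, v in pa.items()},
            "total": matrix.total,
        },
    )
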