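"""Covariate extraction, RFE, weighted RBF-SVM, and LGOCV validation.

Each field sample contributes one covariate row: the filtered NDVI
series of its pixel, one column per scene date.  Feature selection is
backward recursive elimination in fixed-size steps; the classifier is a
radial-basis-kernel support vector machine (one-vs-one multiclass) with
class weights inversely proportional to class frequency so that rare
site classes are not swamped by the dominant one.  Validation is
leave-group-out cross-validation: repeated random 70/30 splits whose
pooled test predictions form one compiled error matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .accuracy import ErrorMatrix, error_matrix
from .stack import NDVIStack

__all__ = [
    "SampleSet",
    "RFEResult",
    "SVMModel",
    "extract_covariates",
    "inverse_frequency_weights",
    "tune_svm",
    "rfe",
    "fit_svm",
    "lgocv",
    "predict_map",
    "DEFAULT_C_GRID",
    "DEFAULT_GAMMA_GRID",
]

logger = logging.getLogger(__name__)

DEFAULT_C_GRID = [2.0**k for k in range(-2, 9)]
DEFAULT_GAMMA_GRID = [2.0**k for k in range(-8, 3)]

STATE_CODES = set(range(1, 8))


@dataclass
class SampleSet:
    """Labelled field points bound to stack pixels.

    ``frame`` columns: id, x, y, row, col, es_class, state_code and an
    optional ``dataset`` sampling-campaign tag.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        required = {"id", "x", "y", "row", "col", "es_class", "state_code"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"samples table missing columns: {sorted(missing)}")
        if self.frame["id"].duplicated().any():
            dupes = self.frame.loc[self.frame["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        bad = set(self.frame["state_code"].astype(int)) - STATE_CODES
        if bad:
            raise ValueError(f"state codes outside 1..7: {sorted(bad)}")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def labels(self) -> np.ndarray:
        return self.frame["es_class"].to_numpy()

    @property
    def state_codes(self) -> np.ndarray:
        return self.frame["state_code"].to_numpy(dtype=int)

    @property
    def ids(self) -> np.ndarray:
        return self.frame["id"].to_numpy()


def extract_covariates(stack: NDVIStack, samples: SampleSet) -> pd.DataFrame:
    """Covariate table: row per sample, column per scene date.

    The stack must be gap-free (preprocessed); rows are the filtered
    series at each sample's pixel, columns labelled by ISO scene date.
    """
    rows = samples.frame["row"].to_numpy(dtype=int)
    cols = samples.frame["col"].to_numpy(dtype=int)
    oob = (rows < 0) | (rows >= stack.n_rows) | (cols < 0) | (cols >= stack.n_cols)
    if oob.any():
        bad = samples.frame.loc[oob, "id"].tolist()
        raise ValueError(f"sample pixels outside the stack extent: {bad}")
    values = stack.values[:, rows, cols].T  # (n_samples, n_times)
    if np.isnan(values).any():
        raise ValueError("stack contains missing values at sample pixels; preprocess first")
    columns = stack.dates.strftime("%Y-%m-%d")
    return pd.DataFrame(values, index=pd.Index(samples.ids, name="id"), columns=columns)


def inverse_frequency_weights(labels) -> dict:
    """Class weights proportional to 1/frequency, normalized to mean 1."""
    labels = pd.Series(labels)
    freq = labels.value_counts()
    raw = 1.0 / freq
    return (raw / raw.mean()).to_dict()


def _make_svc(C: float, gamma, class_weights: dict | None) -> Pipeline:
    # covariates are standardized inside the model; one-vs-one voting is
    # the SVC default for multiclass RBF machines
    return Pipeline(
        [
            ("scale", StandardScaler()),
            ("svc", SVC(kernel="rbf", C=C, gamma=gamma, class_weight=class_weights)),
        ]
    )


def _lgo_splits(y, reps, test_frac, rng, max_redraws=10):
    """Random train/test index splits with every class in the train set."""
    classes = set(np.unique(y))
    n = len(y)
    n_test = int(round(test_frac * n))
    if n_test < 1 or n_test >= n:
        raise ValueError("test_frac yields an empty train or test set")
    for rep in range(reps):
        for _ in range(max_redraws + 1):
            perm = rng.permutation(n)
            test_idx, train_idx = perm[:n_test], perm[n_test:]
            if set(np.unique(y[train_idx])) == classes:
                break
            logger.warning("rep %d: class missing from training split, redrawing", rep)
        else:
            raise RuntimeError(f"rep {rep}: could not draw a split covering all classes")
        yield train_idx, test_idx


def _cv_accuracy(X, y, C, gamma, class_weights, cv_folds, seed) -> float:
    """Mean hold-out accuracy over repeated random 70/30 splits.

    Tuning and feature elimination are scored with the same
    leave-group-out splitting scheme used for final validation.
    """
    rng = np.random.default_rng(seed)
    correct = total = 0
    for train_idx, test_idx in _lgo_splits(y, cv_folds, 0.30, rng):
        model = _make_svc(C, gamma, class_weights)
        model.fit(X[train_idx], y[train_idx])
        correct += int((model.predict(X[test_idx]) == y[test_idx]).sum())
        total += len(test_idx)
    return correct / total


def tune_svm(
    table,
    labels,
    C_grid=DEFAULT_C_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    class_weights: dict | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> tuple[float, float, pd.DataFrame]:
    """Exhaustive grid search over (C, gamma) by cross-validated PCC.

    Returns the winning pair and the full results table.  Accuracy ties
    break toward smaller C, then smaller gamma.
    """
    X = np.asarray(table, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes to tune")
    records = []
    best = None
    for C in sorted(C_grid):
        for gamma in sorted(gamma_grid):
            acc = _cv_accuracy(X, y, C, gamma, class_weights, cv_folds, seed)
            records.append({"C": C, "gamma": gamma, "cv_pcc": 100.0 * acc})
            if best is None or acc > best[0] + 1e-12:
                best = (acc, C, gamma)
    _, C_best, gamma_best = best
    return C_best, gamma_best, pd.DataFrame(records)


def _importance_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-covariate class-separation score.

    Ratio of between-class variance (of class means, sample-size
    weighted) to pooled within-class variance; zero-variance covariates
    score 0 and therefore rank below any informative covariate.
    """
    classes = np.unique(y)
    grand = X.mean(axis=0)
    between = np.zeros(X.shape[1])
    within = np.zeros(X.shape[1])
    for cl in classes:
        sub = X[y == cl]
        between += sub.shape[0] * (sub.mean(axis=0) - grand) ** 2
        within += ((sub - sub.mean(axis=0)) ** 2).sum(axis=0)
    between /= X.shape[0]
    within /= max(X.shape[0] - len(classes), 1)
    # zero-variance covariates (within ~ 0 up to accumulation error) score 0
    scale = (X**2).mean(axis=0) + 1.0
    degenerate = within <= 1e-12 * scale
    with np.errstate(invalid="ignore", divide="ignore"):
        score = np.where(~degenerate, between / np.where(degenerate, 1.0, within), 0.0)
    return score


@dataclass
class RFEResult:
    """Backward-elimination outcome.

    ranking : 1..n permutation over all covariates (1 = most important)
    selected : column labels of the best iteration's subset
    sizes, cv_accuracies : the per-iteration schedule and CV PCC
    """

    ranking: pd.Series
    selected: list
    sizes: list
    cv_accuracies: list
    best_size: int

    @property
    def importance_series(self) -> pd.Series:
        """Rank per covariate keyed by column label (scene date)."""
        return self.ranking


def rfe(
    table,
    labels,
    step: int = 10,
    C: float = 1.0,
    gamma: str | float = "scale",
    class_weights: dict | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> RFEResult:
    """Recursive feature elimination in fixed steps of ``step``.

    Iteration sizes run n, n-step, n-2*step, ... (>= 1).  At each
    iteration the CV accuracy of an RBF-SVM on the active subset is
    recorded, then the ``step`` lowest-scoring covariates are dropped.
    The selected subset is the iteration with the highest CV accuracy
    (ties toward the smaller subset); the returned ranking is a
    permutation of 1..n with dropped covariates ranked by drop order
    and final survivors by their last importance score.
    """
    frame = pd.DataFrame(table)
    X = frame.to_numpy(dtype=float)
    y = np.asarray(labels)
    n = X.shape[1]
    if step < 1:
        raise ValueError("step must be >= 1")
    if step > n:
        raise ValueError("step exceeds covariate count")

    active = list(range(n))
    sizes, accs, subsets = [], [], []
    rank = np.empty(n, dtype=int)
    while True:
        sizes.append(len(active))
        subsets.append(list(active))
        accs.append(
            100.0
            * _cv_accuracy(X[:, active], y, C, _resolve_gamma(gamma, X[:, active]), class_weights, cv_folds, seed)
        )
        if len(active) <= step:
            break
        scores = _importance_scores(X[:, active], y)
        order = np.argsort(scores, kind="stable")  # ascending: worst first
        drop = [active[i] for i in order[:step]]
        # worst-scoring covariate gets the worst remaining rank
        next_rank = len(active)
        for col in drop:
            rank[col] = next_rank
            next_rank -= 1
        active = [a for a in active if a not in set(drop)]

    final_scores = _importance_scores(X[:, active], y)
    order = np.argsort(-final_scores, kind="stable")  # best first
    for pos, i in enumerate(order, start=1):
        rank[active[i]] = pos

    best_idx = max(range(len(sizes)), key=lambda i: (accs[i], -sizes[i]))
    selected = [frame.columns[j] for j in subsets[best_idx]]
    ranking = pd.Series(rank, index=frame.columns, name="rank")
    return RFEResult(
        ranking=ranking,
        selected=selected,
        sizes=sizes,
        cv_accuracies=accs,
        best_size=sizes[best_idx],
    )


def _resolve_gamma(gamma, X):
    return gamma  # SVC accepts 'scale'/'auto'/float directly


@dataclass
class SVMModel:
    """Fitted RBF-SVM plus the metadata needed to apply it to rasters."""

    estimator: Pipeline
    classes: list
    columns: list  # covariate column labels (ISO scene dates)
    C: float
    gamma: float | str
    class_weights: dict | None = None
    seed: int = 0

    def predict(self, X) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float))

    def metadata(self) -> dict:
        return {
            "classes": list(self.classes),
            "n_covariates": len(self.columns),
            "columns": list(self.columns),
            "C": self.C,
            "gamma": self.gamma,
            "class_weights": self.class_weights,
            "seed": self.seed,
        }


def fit_svm(
    table,
    labels,
    C: float = 1.0,
    gamma: float | str = "scale",
    class_weights: dict | None = None,
    seed: int = 0,
) -> SVMModel:
    """Fit the weighted RBF-SVM on a covariate table."""
    frame = pd.DataFrame(table)
    X = frame.to_numpy(dtype=float)
    y = np.asarray(labels)
    if np.isnan(X).any():
        raise ValueError("covariate table contains NaN")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least two classes")
    est = _make_svc(C, gamma, class_weights)
    est.fit(X, y)
    return SVMModel(
        estimator=est,
        classes=sorted(np.unique(y).tolist()),
        columns=list(frame.columns),
        C=C,
        gamma=gamma,
        class_weights=class_weights,
        seed=seed,
    )


def lgocv(
    table,
    labels,
    reps: int = 100,
    test_frac: float = 0.30,
    C: float = 1.0,
    gamma: float | str = "scale",
    class_weights: dict | None = None,
    seed: int = 0,
    max_redraws: int = 10,
    return_records: bool = False,
):
    """Leave-group-out cross-validation with pooled error matrix.

    Each repeat draws round(test_frac * n) samples as the test group,
    fits on the rest with fixed hyper-parameters, and predicts the test
    group; all (prediction, reference) pairs across repeats are pooled
    into one compiled matrix.  A split leaving any class absent from
    the training set is redrawn (up to ``max_redraws`` times, logged).

    Returns ``(matrix, per_rep_pcc)``, plus a tidy per-prediction record
    frame (rep, sample_index, reference, prediction) when
    ``return_records`` is set.
    """
    frame = pd.DataFrame(table)
    X = frame.to_numpy(dtype=float)
    y = np.asarray(labels)
    classes = sorted(np.unique(y).tolist())
    counts = pd.Series(y).value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"classes with fewer than 2 members: {small}")
    rng = np.random.default_rng(seed)
    all_pred, all_ref, per_rep_pcc, records = [], [], [], []
    for rep, (train_idx, test_idx) in enumerate(_lgo_splits(y, reps, test_frac, rng, max_redraws)):
        model = _make_svc(C, gamma, class_weights)
        model.fit(X[train_idx], y[train_idx])
        pred = model.predict(X[test_idx])
        all_pred.extend(pred.tolist())
        all_ref.extend(y[test_idx].tolist())
        per_rep_pcc.append(100.0 * float(np.mean(pred == y[test_idx])))
        if return_records:
            records.append(
                pd.DataFrame(
                    {"rep": rep, "sample_index": test_idx, "reference": y[test_idx], "prediction": pred}
                )
            )
    matrix = error_matrix(all_pred, all_ref, classes)
    if return_records:
        return matrix, per_rep_pcc, pd.concat(records, ignore_index=True)
    return matrix, per_rep_pcc


def predict_map(model: SVMModel, stack: NDVIStack, chunk_pixels: int = 4096) -> np.ndarray:
    """Predict a class label for every pixel of a filtered stack.

    The stack's date grid must contain every covariate date the model
    was trained on; other dates are ignored.  Returns an (R, C) object
    array of class labels.
    """
    stack_dates = list(stack.dates.strftime("%Y-%m-%d"))
    pos = {d: i for i, d in enumerate(stack_dates)}
    missing = [d for d in model.columns if d not in pos]
    if missing:
        raise ValueError(f"stack lacks {len(missing)} model covariate dates, e.g. {missing[:3]}")
    sel = [pos[d] for d in model.columns]
    T, R, C = stack.shape
    flat = stack.values[sel].reshape(len(sel), R * C).T  # (pixels, covariates)
    if np.isnan(flat).any():
        raise ValueError("stack contains missing values; preprocess first")
    out = np.empty(R * C, dtype=object)
    for start in range(0, R * C, chunk_pixels):
        stop = min(start + chunk_pixels, R * C)
        out[start:stop] = model.predict(flat[start:stop])
    return out.reshape(R, C)
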