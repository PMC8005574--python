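"""Subject-specific linear soft-margin SVM decoding of medication state.

Samples are balanced across classes, standardized, and split into 10
contiguous unshuffled stratified folds.  Per-fold weight vectors, decision
values, a fold-averaged ROC and the median fold accuracy are reported.
Class coding is ON = +1, OFF = -1, so a positive weight means a larger
standardized band power under medication pushes the decision toward ON.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .spectral import BAND_COLUMNS

LABEL_CODES = {"OFF": -1, "ON": +1}

#: fixed false-positive-rate grid for vertical ROC averaging
FPR_GRID = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)


@dataclass(frozen=True)
class SVMModel:
    weights: np.ndarray
    bias: float
    box_constraint: float
    feature_means: np.ndarray
    feature_sds: np.ndarray

    def decision(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.feature_means) / self.feature_sds
        return Z @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.where(self.decision(X) >= 0, 1, -1)


@dataclass
class DecodeResult:
    subject_id: str
    fold_accuracies: np.ndarray
    fold_weight_vectors: np.ndarray  # (k, n_features)
    fold_biases: np.ndarray
    fold_decision_values: list[np.ndarray]
    fold_test_labels: list[np.ndarray]
    box_constraint: float
    n_samples_per_class: int

    @property
    def median_accuracy(self) -> float:
        return float(np.median(self.fold_accuracies))

    @property
    def roc(self) -> tuple[np.ndarray, np.ndarray, float]:
        return averaged_roc(self.fold_decision_values, self.fold_test_labels)

    def to_dict(self) -> dict:
        fpr, tpr, auc = self.roc
        return {
            "subject_id": self.subject_id,
            "fold_accuracies": self.fold_accuracies.tolist(),
            "fold_weight_vectors": self.fold_weight_vectors.tolist(),
            "fold_biases": self.fold_biases.tolist(),
            "median_accuracy": self.median_accuracy,
            "box_constraint": self.box_constraint,
            "n_samples_per_class": self.n_samples_per_class,
            "roc": {"fpr": fpr.tolist(), "tpr": tpr.tolist(), "auc": auc},
        }


def balance_classes(table: pd.DataFrame, mode: str = "tail",
                    seed: int | None = None) -> pd.DataFrame:
    """Equalize OFF/ON sample counts.

    ``tail`` (default) drops the chronologically last surplus samples of the
    larger class; ``random`` drops a seeded random subset instead.
    """
    counts = table["condition"].value_counts()
    for label in ("OFF", "ON"):
        if counts.get(label, 0) == 0:
            raise ValueError(f"class {label} is empty")
    n_keep = int(counts.min())
    parts = []
    for label in ("OFF", "ON"):
        sub = table[table["condition"] == label]
        if len(sub) > n_keep:
            if mode == "tail":
                sub = sub.iloc[:n_keep]
            elif mode == "random":
                rng = np.random.default_rng(seed)
                idx = np.sort(rng.choice(len(sub), size=n_keep, replace=False))
                sub = sub.iloc[idx]
            else:
                raise ValueError(f"unknown balancing mode {mode!r}")
        parts.append(sub)
    return pd.concat(parts).reset_index(drop=True)


def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise z-scoring; returns (Z, means, sds)."""
    X = np.asarray(X, dtype=float)
    means = X.mean(axis=0)
    sds = X.std(axis=0)
    bad = np.flatnonzero(sds == 0)
    if len(bad):
        raise ValueError(f"zero-variance feature column(s): {bad.tolist()}")
    return (X - means) / sds, means, sds


def assign_folds(n_samples_per_class: int, k: int = 10) -> np.ndarray:
    """Contiguous per-class fold labels: the first n mod k blocks get the
    extra sample.  Applied identically to each class (stratified, unshuffled).
    """
    n = int(n_samples_per_class)
    if n < k:
        raise ValueError(f"need at least {k} samples per class, got {n}")
    base, extra = divmod(n, k)
    sizes = [base + 1 if i < extra else base for i in range(k)]
    return np.repeat(np.arange(k), sizes)


def train_linear_svm(X: np.ndarray, y: np.ndarray, C: float,
                     max_iter: int = 50_000) -> tuple[np.ndarray, float]:
    """Fit w, b minimizing 0.5*||w||^2 + C * sum hinge(y_i (w.x_i + b)).

    The iteration cap only binds at extreme C on heavily overlapping
    classes, where the exact optimum is degenerate; on separable or small
    instances the solver converges well before the cap.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if C <= 0:
        raise ValueError("box constraint C must be > 0")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in training data")
    clf = SVC(kernel="linear", C=C, tol=1e-7, max_iter=max_iter)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # libsvm iteration-cap warnings
        clf.fit(X, y)
    w = clf.coef_.ravel().astype(float)
    b = float(clf.intercept_[0])
    # libsvm orients the decision toward classes_[1]; flip if that is OFF
    if clf.classes_[1] == -1:
        w, b = -w, -b
    return w, b


def table_to_xy(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    X = table[list(BAND_COLUMNS)].to_numpy(dtype=float)
    y = table["condition"].map(LABEL_CODES).to_numpy()
    return X, y


def cross_validate(table: pd.DataFrame, C: float, k: int = 10,
                   standardization: str = "global") -> DecodeResult:
    """Unshuffled stratified k-fold cross-validation at a fixed box constraint."""
    balanced = balance_classes(table)
    n_per_class = int((balanced["condition"] == "OFF").sum())
    folds = assign_folds(n_per_class, k)

    X, y = table_to_xy(balanced)
    if standardization == "global":
        Z, _, _ = standardize(X)
    elif standardization == "per_fold":
        Z = X  # standardized inside the loop on training folds only
    else:
        raise ValueError(f"unknown standardization scope {standardization!r}")

    fold_of_sample = np.empty(len(balanced), dtype=int)
    for code in (-1, +1):
        fold_of_sample[y == code] = folds

    accs, weight_vecs, biases, decisions, test_labels = [], [], [], [], []
    for i in range(k):
        train = fold_of_sample != i
        test = ~train
        if standardization == "per_fold":
            Ztr, mu, sd = standardize(X[train])
            Zte = (X[test] - mu) / sd
        else:
            Ztr, Zte = Z[train], Z[test]
        w, b = train_linear_svm(Ztr, y[train], C)
        dec = Zte @ w + b
        pred = np.where(dec >= 0, 1, -1)
        accs.append(float(np.mean(pred == y[test])))
        weight_vecs.append(w)
        biases.append(b)
        decisions.append(dec)
        test_labels.append(y[test])
    subject_id = str(balanced["subject_id"].iloc[0]) if "subject_id" in balanced else ""
    return DecodeResult(
        subject_id=subject_id,
        fold_accuracies=np.array(accs),
        fold_weight_vectors=np.array(weight_vecs),
        fold_biases=np.array(biases),
        fold_decision_values=decisions,
        fold_test_labels=test_labels,
        box_constraint=float(C),
        n_samples_per_class=n_per_class,
    )


def cv_loss(table: pd.DataFrame, C: float, k: int = 10,
            standardization: str = "global") -> float:
    """1 - mean fold accuracy; the objective the hyperparameter search minimizes."""
    result = cross_validate(table, C, k, standardization)
    return 1.0 - float(np.mean(result.fold_accuracies))


def _fold_roc(decision: np.ndarray, labels: np.ndarray,
              ) -> tuple[np.ndarray, np.ndarray]:
    """ROC points from sweeping the decision threshold (step curve)."""
    order = np.argsort(-decision, kind="stable")
    labels = labels[order]
    tps = np.cumsum(labels == 1)
    fps = np.cumsum(labels == -1)
    # collapse threshold ties: keep the last point of each distinct score
    distinct = np.r_[np.flatnonzero(np.diff(decision[order]) != 0), len(labels) - 1]
    tpr = np.r_[0.0, tps[distinct] / tps[-1]]
    fpr = np.r_[0.0, fps[distinct] / fps[-1]]
    return fpr, tpr


def averaged_roc(fold_decisions: list[np.ndarray], fold_labels: list[np.ndarray],
                 ) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-fold ROC curves vertically averaged on a fixed FPR grid.

    Folds whose test data lack a class are skipped with a warning.  Area is
    by trapezoid on the averaged curve.
    """
    curves = []
    for dec, lab in zip(fold_decisions, fold_labels):
        if len(np.unique(lab)) < 2:
            warnings.warn("fold lacks one class in its test data; skipped in ROC")
            continue
        fpr, tpr = _fold_roc(np.asarray(dec, dtype=float), np.asarray(lab))
        # step interpolation: tpr at the largest curve fpr <= grid fpr
        idx = np.searchsorted(fpr, FPR_GRID, side="right") - 1
        curves.append(tpr[np.clip(idx, 0, len(tpr) - 1)])
    if not curves:
        raise ValueError("no fold had both classes in its test data")
    mean_tpr = np.mean(curves, axis=0)
    auc = float(np.trapezoid(mean_tpr, FPR_GRID))
    return FPR_GRID.copy(), mean_tpr, auc


def weight_profile(result: DecodeResult) -> tuple[np.ndarray, np.ndarray]:
    """Mean and across-fold sd of each feature weight."""
    return (result.fold_weight_vectors.mean(axis=0),
            result.fold_weight_vectors.std(axis=0))


def results_to_frame(results: list[DecodeResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        mean_w, _ = weight_profile(r)
        rows.append({
            "subject_id": r.subject_id,
            "median_accuracy": r.median_accuracy,
            "box_constraint": r.box_constraint,
            **{f"w_{c[3:]}": w for c, w in zip(BAND_COLUMNS, mean_w)},
        })
    return pd.DataFrame(rows)
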