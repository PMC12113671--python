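"""Kennard–Stone partitioning, classifiers, and evaluation metrics.

The training/testing split is drawn by the Kennard–Stone (KS) max–min
Euclidean algorithm, run independently *within each class* so per-class
proportions are preserved: the first two picks are the mutually farthest
samples, and each subsequent pick maximizes its minimum distance to the
already-chosen set.  With a 2:1 target and classes of 800/640/480 seeds
this yields training counts 533/427/320.

Three classifiers are supported: KNN, LDA (with a 2-component discriminant
subspace — full rank for 3 classes), and an RBF-kernel SVM.

Metrics, all in percent, computed from a K x K confusion matrix with rows =
actual and columns = predicted:

* accuracy        = 100 * trace / N
* sensitivity_c   = 100 * cm[c, c] / rowsum_c            (per-class recall)
* accuracy_rnd    = 100 * sum_c(rowsum_c * colsum_c) / N**2

``accuracy_rnd`` is the expected accuracy of a chance classifier that
reproduces the predicted-class marginals, so ``accuracy - accuracy_rnd``
measures skill above chance; for three perfectly balanced classes the
chance level is 33.3%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .errors import StratificationError
from .segmentation import SpectraTable
from .selection import SelectionResult

__all__ = [
    "SplitIndex",
    "ConfusionMatrix",
    "EvalReport",
    "ModelSpec",
    "ks_split",
    "kennard_stone",
    "fit_predict",
    "accuracy",
    "sensitivity",
    "accuracy_rnd",
    "report",
    "round1",
]


def round1(x: float) -> float:
    """Round to one decimal, ties to even (matches the reported tables)."""
    return float(np.round(x, 1))


@dataclass
class SplitIndex:
    """Disjoint train/test row indices covering an entire table."""

    train_rows: np.ndarray
    test_rows: np.ndarray
    train_fraction: float = 2 / 3

    def __post_init__(self) -> None:
        tr = np.asarray(self.train_rows, dtype=np.int64)
        te = np.asarray(self.test_rows, dtype=np.int64)
        if np.intersect1d(tr, te).size:
            raise ValueError("train and test rows overlap")
        self.train_rows, self.test_rows = tr, te


@dataclass
class ConfusionMatrix:
    """K x K counts; rows = actual class, columns = predicted class."""

    counts: np.ndarray
    class_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (c < 0).any():
            raise ValueError("confusion matrix counts must be non-negative")
        self.counts = c
        if self.class_ids is None:
            self.class_ids = np.arange(1, c.shape[0] + 1)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        import pandas as pd

        ids = self.class_ids
        pd.DataFrame(
            self.counts,
            index=[f"actual_{c}" for c in ids],
            columns=[f"predicted_{c}" for c in ids],
        ).to_csv(path)


@dataclass
class EvalReport:
    """Display-rounded metrics bundle; raw values kept alongside."""

    accuracy: float
    sensitivity: tuple[float, ...]
    accuracy_rnd: float
    accuracy_minus_rnd: float
    raw: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": list(self.sensitivity),
            "accuracy_rnd": self.accuracy_rnd,
            "accuracy_minus_rnd": self.accuracy_minus_rnd,
        }


@dataclass
class ModelSpec:
    """Classifier kind + hyperparameters.

    ``knn``: *k* neighbors (default 5).  ``lda``: 2-component linear
    discriminant.  ``svm_rbf``: RBF kernel with cost ``svm_c`` (default 10)
    and ``svm_gamma`` either a float or ``"scale"`` (1 / (n_bands * X.var())).
    """

    kind: str = "lda"
    knn_k: int = 5
    lda_components: int = 2
    svm_c: float = 10.0
    svm_gamma: float | str = "scale"
    seed: int = 0

    def build(self):
        if self.kind == "knn":
            return KNeighborsClassifier(n_neighbors=self.knn_k)
        if self.kind == "lda":
            return LinearDiscriminantAnalysis(n_components=self.lda_components)
        if self.kind == "svm_rbf":
            return SVC(
                kernel="rbf", C=self.svm_c, gamma=self.svm_gamma,
                random_state=self.seed,
            )
        raise ValueError(f"unknown model kind {self.kind!r}")


def kennard_stone(X: np.ndarray, n_select: int) -> np.ndarray:
    """Greedy max–min Euclidean KS selection of *n_select* rows of *X*.

    Deterministic: the first pick is the mutually farthest pair; every
    later pick maximizes its minimum distance to the chosen set; all ties
    break toward the lowest row index.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= n_select <= n:
        raise ValueError(f"n_select must be in [1, {n}]")
    D = cdist(X, X)
    # farthest pair, lowest indices on ties
    i, j = np.unravel_index(np.argmax(D), D.shape)
    chosen = [min(i, j), max(i, j)] if n_select >= 2 else [min(i, j)]
    if n_select == 1:
        return np.array(chosen[:1], dtype=np.int64)
    mind = np.minimum(D[chosen[0]], D[chosen[1]])
    mind[chosen] = -1.0
    while len(chosen) < n_select:
        nxt = int(np.argmax(mind))  # argmax takes the first (lowest) index
        chosen.append(nxt)
        mind = np.minimum(mind, D[nxt])
        mind[nxt] = -1.0
    return np.array(sorted(chosen), dtype=np.int64)


def ks_split(table: SpectraTable, train_fraction: float = 2 / 3) -> SplitIndex:
    """Stratified Kennard–Stone 2:1 split (train target = round(n_c * frac)).

    KS runs independently within each class on the spectra; chosen rows go
    to training, the remainder to testing.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    train: list[np.ndarray] = []
    test: list[np.ndarray] = []
    for c in np.unique(table.labels):
        rows = np.nonzero(table.labels == c)[0]
        if rows.size < 3:
            raise ValueError(f"class {c} has {rows.size} samples; need >= 3")
        n_train = int(np.round(rows.size * train_fraction))
        n_train = min(max(n_train, 1), rows.size - 1)
        picked = kennard_stone(table.spectra[rows], n_train)
        train.append(rows[picked])
        test.append(np.setdiff1d(rows, rows[picked]))
    return SplitIndex(
        np.sort(np.concatenate(train)),
        np.sort(np.concatenate(test)),
        train_fraction,
    )


def fit_predict(
    table: SpectraTable,
    split: SplitIndex,
    selection: SelectionResult | None,
    model: ModelSpec,
) -> tuple[ConfusionMatrix, ConfusionMatrix]:
    """Fit on the training rows and evaluate on both partitions.

    Columns are restricted to ``selection``'s bands (or all bands when
    ``selection`` is None).  Returns (training, testing) confusion matrices
    with rows = actual class, columns = predicted class.
    """
    if selection is not None:
        if selection.band_indices is None or len(selection) == 0:
            raise ValueError("selection has no band indices for this table")
        X = table.spectra[:, selection.band_indices]
    else:
        X = table.spectra
    y = table.labels
    classes = np.unique(y)
    if np.setdiff1d(classes, np.unique(y[split.train_rows])).size:
        raise StratificationError("a class is absent from the training partition")
    clf = model.build()
    clf.fit(X[split.train_rows], y[split.train_rows])

    def cm(rows: np.ndarray) -> ConfusionMatrix:
        pred = clf.predict(X[rows])
        counts = np.zeros((classes.size, classes.size), dtype=np.int64)
        pos = {c: k for k, c in enumerate(classes)}
        for actual, predicted in zip(y[rows], pred):
            counts[pos[actual], pos[predicted]] += 1
        return ConfusionMatrix(counts, classes)

    return cm(split.train_rows), cm(split.test_rows)


def accuracy(cm: ConfusionMatrix) -> float:
    """Overall accuracy in percent: 100 * trace / N."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    return 100.0 * np.trace(cm.counts) / cm.n


def sensitivity(cm: ConfusionMatrix) -> np.ndarray:
    """Per-class recall in percent (one-vs-rest TP / (TP + FN))."""
    rowsums = cm.counts.sum(axis=1)
    if (rowsums == 0).any():
        raise ValueError("a class has zero actual samples; sensitivity undefined")
    return 100.0 * np.diag(cm.counts) / rowsums


def accuracy_rnd(cm: ConfusionMatrix) -> float:
    """Chance-agreement accuracy from the matrix marginals, in percent.

    The expected accuracy of a classifier that assigns labels at random
    with the model's own predicted-class frequencies:
    100 * sum_c(rowsum_c * colsum_c) / N**2.
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    rows = cm.counts.sum(axis=1).astype(float)
    cols = cm.counts.sum(axis=0).astype(float)
    return 100.0 * float(rows @ cols) / cm.n**2


def report(cm: ConfusionMatrix) -> EvalReport:
    """Metrics bundle for one partition, display-rounded to 1 d.p.

    The difference is taken between the rounded accuracy and rounded
    chance accuracy, as in the reported tables; raw values are retained in
    ``raw``.
    """
    acc, rnd = accuracy(cm), accuracy_rnd(cm)
    sens = sensitivity(cm)
    return EvalReport(
        accuracy=round1(acc),
        sensitivity=tuple(round1(s) for s in sens),
        accuracy_rnd=round1(rnd),
        accuracy_minus_rnd=round1(round1(acc) - round1(rnd)),
        raw={"accuracy": acc, "accuracy_rnd": rnd, "sensitivity": sens.tolist()},
    )
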