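"""Locally weighted nearest-neighbour classification and model selection.

The classifier is a lazy, kernel-weighted kNN in the spirit of locally
weighted learning (LWL): a query is labelled by its k nearest training
instances (Euclidean distance), each contributing a vote weighted by a
distance kernel.  The linear kernel uses w_i = max(0, 1 - d_i / d_cut),
where d_cut is the distance to the (k+1)-th neighbour — so the nearest
neighbours dominate and the weight fades to zero at the edge of the
neighbourhood; the constant kernel reduces to plain majority-vote kNN.

Model quality is summarised by %CCI (percentage of correctly classified
instances) on both partitions; candidate configurations are ranked by test
CCI with the train-test CCI gap |delta| as tie-break, mirroring the
"top right corner" reading of a CCI-vs-delta scatter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .dataset_sampling import PPIDataset
from .ppi_features import NEGATIVE, POSITIVE

logger = logging.getLogger(__name__)

KERNELS = ("linear", "constant")


@dataclass
class LWLModel:
    """Lazy model: stored training table plus neighbourhood hyperparameters."""

    train_features: np.ndarray
    train_labels: np.ndarray
    k: int
    kernel: str
    _index: NearestNeighbors | None = None

    @property
    def n_train(self) -> int:
        return self.train_features.shape[0]


def fit_lwl(train: PPIDataset, k: int | str = 50, kernel: str = "linear") -> LWLModel:
    """Store the training data; ``k="all"`` uses every training instance.

    A ``k`` larger than the training set is clamped with a warning.
    """
    if kernel not in KERNELS:
        raise ValueError(f"kernel must be one of {KERNELS}, got {kernel!r}")
    n = len(train)
    if n == 0:
        raise ValueError("training set must be non-empty")
    if k == "all":
        k = n
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise ValueError(f"k must be a positive integer or 'all', got {k!r}")
    if k > n:
        logger.warning("k=%d exceeds training size %d; clamping", k, n)
        k = n
    index = NearestNeighbors(n_neighbors=min(int(k) + 1, n)).fit(train.features)
    return LWLModel(
        train_features=np.asarray(train.features, dtype=float),
        train_labels=np.asarray(train.labels, dtype=object),
        k=int(k),
        kernel=kernel,
        _index=index,
    )


def _predict_batch(model: LWLModel, queries: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    queries = np.atleast_2d(np.asarray(queries, dtype=float))
    if queries.shape[1] != model.train_features.shape[1]:
        raise ValueError(
            f"query dimension {queries.shape[1]} does not match "
            f"training dimension {model.train_features.shape[1]}"
        )
    k = model.k
    n_query = min(k + 1, model.n_train)
    dist, idx = model._index.kneighbors(queries, n_neighbors=n_query)
    labels = np.empty(queries.shape[0], dtype=object)
    scores = np.zeros((queries.shape[0], 2))  # columns: negative, positive
    for q in range(queries.shape[0]):
        d = dist[q, :k]
        neigh = idx[q, :k]
        if model.kernel == "constant":
            w = np.ones_like(d)
        else:
            d_cut = dist[q, k] if n_query > k else d.max()
            if d_cut <= 0:
                w = np.ones_like(d)
            else:
                w = np.clip(1.0 - d / d_cut, 0.0, None)
                if not w.any():  # every neighbour at the cut distance
                    w = np.ones_like(d)
        neigh_labels = model.train_labels[neigh]
        s_pos = float(w[neigh_labels == POSITIVE].sum())
        s_neg = float(w[neigh_labels == NEGATIVE].sum())
        scores[q] = (s_neg, s_pos)
        labels[q] = POSITIVE if s_pos > s_neg else NEGATIVE  # ties -> negative
    return labels, scores


def predict(model: LWLModel, query: np.ndarray) -> tuple[str, dict[str, float]]:
    """Classify one feature vector; returns (label, class scores)."""
    labels, scores = _predict_batch(model, np.atleast_2d(query))
    return labels[0], {NEGATIVE: scores[0, 0], POSITIVE: scores[0, 1]}


@dataclass(frozen=True)
class EvalReport:
    cci_train: float
    cci_test: float
    delta: float  # cci_test - cci_train
    tp: int
    tn: int
    fp: int
    fn: int
    configuration: str = ""


def _cci(model: LWLModel, dataset: PPIDataset) -> tuple[float, np.ndarray]:
    pred, _ = _predict_batch(model, dataset.features)
    correct = pred == dataset.labels
    return 100.0 * float(np.mean(correct)), pred


def evaluate(
    model: LWLModel, train: PPIDataset, test: PPIDataset, configuration: str = ""
) -> EvalReport:
    """%CCI on both partitions plus the test confusion matrix."""
    if len(test) == 0:
        raise ValueError("test set must be non-empty")
    cci_train, _ = _cci(model, train)
    cci_test, pred = _cci(model, test)
    actual = test.labels
    tp = int(np.sum((pred == POSITIVE) & (actual == POSITIVE)))
    tn = int(np.sum((pred == NEGATIVE) & (actual == NEGATIVE)))
    fp = int(np.sum((pred == POSITIVE) & (actual == NEGATIVE)))
    fn = int(np.sum((pred == NEGATIVE) & (actual == POSITIVE)))
    return EvalReport(
        cci_train=cci_train,
        cci_test=cci_test,
        delta=cci_test - cci_train,
        tp=tp, tn=tn, fp=fp, fn=fn,
        configuration=configuration,
    )


def model_selection_surface(reports: list[EvalReport]) -> list[EvalReport]:
    """Rank configurations toward the top-right corner of the CCI scatter.

    Order: test CCI descending, |train-test gap| ascending, configuration
    label lexicographic.  Input order never matters.
    """
    if not reports:
        raise ValueError("need at least one report")
    return sorted(
        reports,
        key=lambda r: (-r.cci_test, abs(r.delta), r.configuration),
    )
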