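"""Leave-one-material-per-category-out linear classification with a
label-shuffling bootstrap null.

Materials (one averaged latent embedding each) are classified into the 7
categories with a linear discriminant. Folds cycle deterministically: with
S the largest category size, fold i holds out each category's (i mod
size)-th material (by sorted material id), so every material is tested at
least once and each fold tests exactly one material per category. The
empirical chance level is the mean accuracy over label permutations; its
95% confidence interval is the 2.5th-97.5th percentile of that null
distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = ["ClassificationResult", "loo_classify", "bootstrap_null", "classify_with_null"]


@dataclass
class ClassificationResult:
    accuracy: float  # percent
    predictions: pd.DataFrame  # fold, material_id, true label, predicted label
    label_source: str = "ground_truth"
    null_mean: float | None = None  # percent
    null_ci: tuple | None = None  # (2.5th, 97.5th) percentiles, percent
    n_shuffles: int = 0

    def __post_init__(self):
        if not 0.0 <= self.accuracy <= 100.0:
            raise ValueError("accuracy must be a percentage")
        if self.null_ci is not None and self.null_mean is not None:
            lo, hi = self.null_ci
            if not lo <= self.null_mean <= hi:
                raise ValueError("null mean must lie inside its confidence interval")


def _prepare(embeddings, labels):
    X = np.asarray(getattr(embeddings, "values", embeddings), dtype=np.float64)
    ids = (
        np.asarray(embeddings.index)
        if isinstance(embeddings, pd.DataFrame)
        else np.arange(X.shape[0])
    )
    y = np.asarray(getattr(labels, "values", labels))
    if X.shape[0] != y.shape[0]:
        raise ValueError("embeddings and labels must align")
    return X, y, ids


def _fold_indices(y: np.ndarray, ids: np.ndarray):
    """Deterministic leave-one-material-per-category-out folds."""
    by_cat = {}
    for cat in np.unique(y):
        members = np.flatnonzero(y == cat)
        members = members[np.argsort(ids[members].astype(str))]
        if members.size < 2:
            raise ValueError(f"category {cat!r} has fewer than 2 materials")
        by_cat[cat] = members
    n_folds = max(len(m) for m in by_cat.values())
    folds = []
    for i in range(n_folds):
        folds.append(np.array([m[i % len(m)] for m in by_cat.values()]))
    return folds


def loo_classify(embeddings, labels, classifier=None, label_source: str = "ground_truth") -> ClassificationResult:
    """Run the cyclic leave-one-material-per-category-out scheme.

    Accuracy is correct test predictions over all test predictions, in
    percent. ``classifier`` defaults to linear discriminant analysis and may
    be any sklearn classifier.
    """
    X, y, ids = _prepare(embeddings, labels)
    base = classifier if classifier is not None else LinearDiscriminantAnalysis()
    rows = []
    correct = total = 0
    for fold, test_idx in enumerate(_fold_indices(y, ids)):
        mask = np.ones(len(y), dtype=bool)
        mask[test_idx] = False
        clf = clone(base)
        clf.fit(X[mask], y[mask])
        pred = clf.predict(X[test_idx])
        correct += int((pred == y[test_idx]).sum())
        total += len(test_idx)
        for m, t, p in zip(ids[test_idx], y[test_idx], pred):
            rows.append({"fold": fold, "material_id": m, "true": t, "predicted": p})
    return ClassificationResult(
        accuracy=100.0 * correct / total,
        predictions=pd.DataFrame(rows),
        label_source=label_source,
    )


def bootstrap_null(embeddings, labels, n_shuffles: int = 5000, seed: int | None = None,
                   classifier=None):
    """Accuracy distribution under shuffled category labels.

    Returns ``(null_mean, (ci_low, ci_high), accuracies)`` in percent. The
    mean is the empirical chance level; the CI reads the 2.5th and 97.5th
    percentiles.
    """
    if n_shuffles < 100:
        raise ValueError("n_shuffles must be at least 100")
    X, y, ids = _prepare(embeddings, labels)
    rng = np.random.default_rng(seed)
    emb = pd.DataFrame(X, index=ids)
    accs = np.empty(n_shuffles)
    for s in range(n_shuffles):
        accs[s] = loo_classify(emb, rng.permutation(y), classifier=classifier).accuracy
    lo, hi = np.percentile(accs, [2.5, 97.5])
    return float(accs.mean()), (float(lo), float(hi)), accs


def classify_with_null(embeddings, labels, n_shuffles: int = 5000, seed: int | None = None,
                       classifier=None, label_source: str = "ground_truth") -> ClassificationResult:
    """Observed accuracy plus the shuffled-label null in one result object."""
    res = loo_classify(embeddings, labels, classifier=classifier, label_source=label_source)
    null_mean, ci, _ = bootstrap_null(embeddings, labels, n_shuffles=n_shuffles, seed=seed,
                                      classifier=classifier)
    res.null_mean = null_mean
    res.null_ci = ci
    res.n_shuffles = n_shuffles
    return res
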