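"""Linear SVM training and recursive feature elimination (SVM-RFE).

One-hot sequence encodings produce far more binary variables (56 for a
14-nt DNA window, 231 for an 11-residue protein window) than a two-level
logic minimizer can take as inputs.  SVM-RFE ranks the variables by
training a linear soft-margin SVM and repeatedly discarding the feature
whose removal perturbs the margin least — the standard surrogate being the
squared weight ``w_i**2`` of the separating hyperplane.  The surviving
top-k variables (k ≤ 22 here, matching the input cap of classic
espresso-family minimizers) are what the rule extraction operates on.

The fit is deterministic for fixed inputs: fixed solver tolerance, one
feature eliminated per round, ties broken by lowest feature index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVC

from .encoding import EncodedDataset

__all__ = ["SVMModel", "FeatureRanking", "train_linear_svm", "rfe_rank", "project_dataset"]


@dataclass(frozen=True)
class SVMModel:
    """A fitted linear decision function ``D(x) = w·x + b``."""

    weights: np.ndarray
    bias: float
    C: float

    @property
    def margin(self) -> float:
        """Geometric margin ``2/‖w‖`` (separable-case interpretation)."""
        norm = float(np.linalg.norm(self.weights))
        return np.inf if norm == 0 else 2.0 / norm

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.weights + self.bias

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Labels in {0,1}; the internal −1/+1 signs map back to 0/1."""
        return (self.decision_values(X) > 0).astype(int)


@dataclass(frozen=True)
class FeatureRanking:
    """RFE output: elimination order (worst first) and the survivors.

    ``order`` lists all feature indices, the first eliminated (least
    informative) first; ``selected`` are the final k survivors, kept in
    original column order for projection.
    """

    order: tuple[int, ...]
    selected: tuple[int, ...]

    def __post_init__(self) -> None:
        if sorted(self.order) != list(range(len(self.order))):
            raise ValueError("order must be a permutation of 0..n_features-1")
        if set(self.selected) - set(self.order):
            raise ValueError("selected indices outside feature range")


def train_linear_svm(
    X: np.ndarray, y: np.ndarray, C: float = 1.0, tol: float = 1e-6
) -> SVMModel:
    """Fit a linear soft-margin SVM on {0,1} labels.

    Labels are mapped internally to −1/+1; the returned weight vector is
    oriented so positive decision values correspond to label 1.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    clf = SVC(kernel="linear", C=C, tol=tol)
    clf.fit(X, np.where(y > 0, 1, -1))
    return SVMModel(
        weights=clf.coef_.ravel().copy(), bias=float(clf.intercept_[0]), C=C
    )


def rfe_rank(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    C: float = 1.0,
    tol: float = 1e-6,
    step: int = 1,
) -> FeatureRanking:
    """Rank features by recursive elimination; keep the top ``k``.

    Each round refits the SVM on the surviving features and removes the
    ``step`` features with the smallest ``w_i**2`` (ties: lowest original
    index).  The final ``k`` survivors are never eliminated; their mutual
    order in ``order`` comes from a last ranking pass (most informative
    last).
    """
    X = np.asarray(X, dtype=float)
    n_features = X.shape[1]
    if k <= 0:
        raise ValueError("k must be positive")
    if k > n_features:
        raise ValueError(f"k={k} exceeds n_features={n_features}")
    if step < 1:
        raise ValueError("step must be >= 1")

    surviving = list(range(n_features))
    eliminated: list[int] = []
    while len(surviving) > k:
        model = train_linear_svm(X[:, surviving], y, C=C, tol=tol)
        crit = model.weights**2
        n_drop = min(step, len(surviving) - k)
        # argsort is stable, so ties resolve to the lowest index
        drop_local = np.argsort(crit, kind="stable")[:n_drop]
        for j in sorted(drop_local, reverse=True):
            eliminated.append(surviving.pop(int(j)))
    # rank the survivors themselves by a final fit (least informative first)
    if len(surviving) > 1:
        model = train_linear_svm(X[:, surviving], y, C=C, tol=tol)
        crit = model.weights**2
        survivor_order = [surviving[int(j)] for j in np.argsort(crit, kind="stable")]
    else:
        survivor_order = list(surviving)
    order = tuple(eliminated + survivor_order)
    return FeatureRanking(order=order, selected=tuple(sorted(surviving)))


def project_dataset(ds: EncodedDataset, ranking: FeatureRanking) -> EncodedDataset:
    """Restrict a dataset to the selected columns (original column order).

    Distinct wide patterns often collapse onto the same projected pattern;
    deduplication and contradiction handling are left to
    :func:`sitelogic.encoding.clean_dataset` downstream.
    """
    cols = list(ranking.selected)
    if cols and max(cols) >= ds.width:
        raise ValueError("selected feature index outside dataset width")
    meanings = [ds.meanings[c] for c in cols] if ds.meanings else []
    return EncodedDataset(
        patterns=ds.patterns[:, cols],
        labels=ds.labels.copy(),
        meanings=meanings,
        multiplicity=ds.multiplicity.copy(),
        provenance=list(ds.provenance) if ds.provenance is not None else None,
    )
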