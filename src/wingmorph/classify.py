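"""Group classification of wing shapes and canonical variate analysis.

The classifier is linear discriminant analysis under the Mahalanobis
rule: each group is summarized by its mean in shape space and a pooled
within-group covariance; a specimen is assigned to the group maximizing
``ln(prior) - 0.5 * Mahalanobis^2``.  Because 2k Procrustes coordinates
carry at most 2k - 4 dimensions, shape variables are first projected
onto their principal components of non-negligible variance so the
pooled covariance is invertible.

Leave-one-out cross-validation refits the whole pipeline (rank
reduction and LDA) on the remaining n - 1 specimens for every fold; the
superimposition itself is not recomputed per fold, mirroring a single
up-front GPA (a `strict` mode re-runs GPA per fold for sensitivity
analysis).  Canonical variate analysis rotates shape space to axes
maximizing between- relative to within-group variance and yields the
Mahalanobis distance matrix between group means that seeds the
neighbor-joining tree.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.base import BaseEstimator, ClassifierMixin


def reduce_rank(shapes, tol: float = 1e-10):
    """Principal-component projection to the numerically non-null space.

    Keeps every component whose variance exceeds ``tol`` times the
    largest.  Returns ``(scores, basis, mean)`` with orthonormal rows in
    ``basis``; ``scores @ basis + mean`` reconstructs the input and
    pairwise distances are preserved exactly on the retained subspace.
    """
    X = np.asarray(shapes, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two rows")
    mean = X.mean(axis=0)
    u, s, vt = np.linalg.svd(X - mean, full_matrices=False)
    ev = s ** 2
    if ev[0] <= 0:
        raise ValueError("zero total variance")
    keep = ev > tol * ev[0]
    return (u[:, keep] * s[keep], vt[keep], mean)


class LandmarkLDA(BaseEstimator, ClassifierMixin):
    """Linear discriminant classifier on (rank-reduced) shape variables.

    Parameters
    ----------
    priors : {"proportional", "uniform"}
        Group priors: observed group frequencies (default, the
        convention of the R discriminant-analysis family) or equal.
    rank_tol : float
        Relative eigenvalue cutoff for the internal PCA reduction.
    auto_reduce : bool
        If True, trailing principal components are dropped until the
        pooled within-group covariance is positive definite instead of
        raising.  Useful under bootstrap resampling, where duplicated
        specimens lower the pooled rank below the data rank.

    Attributes
    ----------
    classes_ : ndarray of sorted group labels
    means_ : (g, d) group means in the reduced space
    pooled_cov_ : (d, d) pooled within-group covariance (denominator n - g)
    priors_ : (g,) prior probabilities, summing to 1
    basis_, center_ : the PCA reduction applied to inputs
    """

    def __init__(self, priors: str = "proportional",
                 rank_tol: float = 1e-10, auto_reduce: bool = False):
        self.priors = priors
        self.rank_tol = rank_tol
        self.auto_reduce = auto_reduce

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or len(y) != X.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need at least two groups")
        if counts.min() < 2:
            small = classes[counts.argmin()]
            raise ValueError(f"group {small!r} has a single specimen")
        scores, basis, center = reduce_rank(X, tol=self.rank_tol)
        n, d = scores.shape
        g = len(classes)
        if n <= d + g:
            warnings.warn(
                f"only {n} specimens for {d} dimensions and {g} groups; "
                "the pooled covariance estimate may be unstable")
        while True:
            means = np.stack([scores[y == c].mean(axis=0) for c in classes])
            pooled = np.zeros((d, d))
            for c, mu in zip(classes, means):
                dev = scores[y == c] - mu
                pooled += dev.T @ dev
            pooled /= (n - g)
            try:
                chol = linalg.cholesky(pooled, lower=True)
                break
            except linalg.LinAlgError:
                if not self.auto_reduce or d <= 1:
                    raise ValueError(
                        "pooled within-group covariance is singular after "
                        "rank reduction; increase rank_tol") from None
                d -= 1
                scores, basis = scores[:, :d], basis[:d]
        if self.priors == "proportional":
            priors = counts / n
        elif self.priors == "uniform":
            priors = np.full(g, 1.0 / g)
        else:
            raise ValueError(f"unknown priors {self.priors!r}")
        self.classes_, self.means_, self.pooled_cov_ = classes, means, pooled
        self.priors_ = priors
        self.basis_, self.center_ = basis, center
        self._chol = chol
        return self

    def _reduced(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.basis_.shape[1]:
            raise ValueError(
                f"X must have {self.basis_.shape[1]} columns")
        return (X - self.center_) @ self.basis_.T

    def mahalanobis_sq(self, X) -> np.ndarray:
        """Squared Mahalanobis distance of each row to each group mean."""
        Z = self._reduced(X)
        d2 = np.empty((Z.shape[0], len(self.classes_)))
        for j, mu in enumerate(self.means_):
            w = linalg.solve_triangular(self._chol, (Z - mu).T, lower=True)
            d2[:, j] = (w ** 2).sum(axis=0)
        return d2

    def decision_scores(self, X) -> np.ndarray:
        return np.log(self.priors_) - 0.5 * self.mahalanobis_sq(X)

    def predict(self, X):
        scores = self.decision_scores(X)
        ties = (scores == scores.max(axis=1, keepdims=True)).sum(axis=1) > 1
        if ties.any():
            warnings.warn(f"{int(ties.sum())} exact posterior tie(s); "
                          "assigned to the lexicographically lowest group")
        return self.classes_[np.argmax(scores, axis=1)]

    def predict_proba(self, X) -> np.ndarray:
        scores = self.decision_scores(X)
        scores -= scores.max(axis=1, keepdims=True)
        p = np.exp(scores)
        return p / p.sum(axis=1, keepdims=True)


def fit_lda(shapes, labels, priors: str = "proportional") -> LandmarkLDA:
    """Fit :class:`LandmarkLDA` on a shape matrix."""
    return LandmarkLDA(priors=priors).fit(shapes, labels)


def predict(model: LandmarkLDA, shapes):
    """Predicted labels and normalized posterior matrix."""
    return model.predict(shapes), model.predict_proba(shapes)


@dataclass
class ConfusionMatrix:
    """True x predicted count matrix from a reclassification test."""
    counts: pd.DataFrame
    rank: str = "species"

    @property
    def accuracy(self) -> float:
        c = self.counts.to_numpy()
        return float(np.trace(c) / c.sum())

    def row_percentages(self) -> pd.DataFrame:
        c = self.counts
        return c.div(c.sum(axis=1), axis=0) * 100


def loocv_confusion(shapes, labels, rank: str = "species",
                    priors: str = "proportional") -> ConfusionMatrix:
    """Exact leave-one-out reclassification.

    For every specimen the classifier (PCA reduction plus LDA) is refit
    on the other n - 1 specimens and the held-out specimen classified;
    the confusion matrix rows are true groups, columns predictions.
    Groups of size one cannot be held out and raise an error.
    """
    X = np.asarray(shapes, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        raise ValueError(
            f"group {classes[counts.argmin()]!r} has a single specimen")
    n = len(y)
    predicted = np.empty(n, dtype=y.dtype)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        model = LandmarkLDA(priors=priors).fit(X[mask], y[mask])
        predicted[i] = model.predict(X[i:i + 1])[0]
        mask[i] = True
    counts_df = pd.DataFrame(0, index=classes, columns=classes)
    for t, p in zip(y, predicted):
        counts_df.loc[t, p] += 1
    return ConfusionMatrix(counts_df, rank)


def collapse_to_genus(species_confusion: ConfusionMatrix,
                      genus_map: dict) -> ConfusionMatrix:
    """Sum a species-level confusion matrix into genus blocks.

    Within-genus species confusions become correct at genus rank, so
    collapsing can never decrease accuracy.
    """
    counts = species_confusion.counts
    missing = [s for s in counts.index if s not in genus_map]
    if missing:
        raise ValueError(f"species without genus mapping: {missing}")
    genera = sorted(set(genus_map[s] for s in counts.index))
    out = pd.DataFrame(0, index=genera, columns=genera)
    for t in counts.index:
        for p in counts.columns:
            out.loc[genus_map[t], genus_map[p]] += counts.loc[t, p]
    return ConfusionMatrix(out, "genus")


@dataclass
class CVAResult:
    """Canonical axes, specimen scores and Mahalanobis group distances."""
    axes: np.ndarray                      # (d, n_axes) in reduced space
    scores: np.ndarray                    # (n, n_axes)
    eigenvalues: np.ndarray
    mahalanobis: pd.DataFrame             # distances between group means
    group_means_scores: pd.DataFrame


def cva(shapes, labels, priors: str = "proportional",
        auto_reduce: bool = False) -> CVAResult:
    """Canonical variate analysis of group separation in shape space.

    Canonical axes solve the generalized eigenproblem of between-group
    against pooled within-group covariance on the rank-reduced shape
    variables (at most g - 1 axes).  The Mahalanobis distance between
    group means i and j is ``sqrt((mi - mj)' W^-1 (mi - mj))`` with W
    the pooled within-group covariance.
    """
    model = LandmarkLDA(priors=priors, auto_reduce=auto_reduce).fit(
        shapes, labels)
    Z = model._reduced(np.asarray(shapes, dtype=float))
    y = np.asarray(labels)
    classes, means, W = model.classes_, model.means_, model.pooled_cov_
    grand = Z.mean(axis=0)
    B = np.zeros_like(W)
    for c, mu in zip(classes, means):
        n_c = int((y == c).sum())
        dev = (mu - grand)[:, None]
        B += n_c * (dev @ dev.T)
    B /= (len(classes) - 1)
    evals, evecs = linalg.eigh(B, W)
    order = np.argsort(evals)[::-1]
    n_axes = min(len(classes) - 1, (evals > 1e-10 * max(evals.max(), 1)).sum())
    axes = evecs[:, order[:n_axes]]
    evals = np.clip(evals[order[:n_axes]], 0, None)
    scores = (Z - grand) @ axes

    chol = linalg.cholesky(W, lower=True)
    g = len(classes)
    D = np.zeros((g, g))
    for i in range(g):
        w = linalg.solve_triangular(chol, (means - means[i]).T, lower=True)
        D[i] = np.sqrt((w ** 2).sum(axis=0))
    D = (D + D.T) / 2
    mah = pd.DataFrame(D, index=classes, columns=classes)
    mean_scores = pd.DataFrame((means - grand) @ axes, index=classes)
    return CVAResult(axes, scores, evals, mah, mean_scores)
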