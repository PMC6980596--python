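"""Ordination and discrimination of shape data.

PCA of Procrustes shape coordinates, broken-stick axis retention,
canonical variate analysis with permutation-tested Mahalanobis
distances, and cross-validated linear discriminant classification.
Shape data are rank-deficient after superimposition, so the CVA is
computed in the subspace of principal components carrying non-zero
variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

_RANK_TOL = 1e-10


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaResults:
    eigenvalues: np.ndarray          # descending, >= 0
    percent_variance: np.ndarray     # sums to 100 over positive axes
    scores: np.ndarray               # n x axes
    loadings: np.ndarray             # axes x p, orthonormal rows
    mean: np.ndarray

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)

    def summary(self, max_axes: int = 10) -> str:
        lines = ["Principal component analysis", "  axis  eigenvalue   % variance  cumulative"]
        cum = 0.0
        for i in range(min(max_axes, self.n_axes)):
            cum += self.percent_variance[i]
            lines.append(
                f"  PC{i + 1:<3d} {self.eigenvalues[i]:.6e}  {self.percent_variance[i]:10.3f}  {cum:10.3f}"
            )
        return "\n".join(lines)


class ShapePCA:
    """Principal component analysis of a specimens x variables matrix."""

    def __init__(self, X):
        self.X = np.asarray(X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] < 2:
            raise ValueError("PCA requires a 2D matrix with >= 2 rows")

    def fit(self) -> PcaResults:
        mean = self.X.mean(axis=0)
        Xc = self.X - mean
        cov = Xc.T @ Xc / (self.X.shape[0] - 1)
        evals, evecs = np.linalg.eigh(cov)
        # stable descending order: by value then original axis index
        order = np.argsort(-evals, kind="stable")
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        total = evals.sum()
        percent = 100.0 * evals / total if total > 0 else np.zeros_like(evals)
        return PcaResults(
            eigenvalues=evals,
            percent_variance=percent,
            scores=Xc @ evecs,
            loadings=evecs.T,
            mean=mean,
        )


def pca(X) -> PcaResults:
    return ShapePCA(X).fit()


def broken_stick_retain(eigenvalues) -> int:
    """Number of leading axes exceeding the broken-stick expectation.

    The broken-stick model partitions unit variance at random into p
    pieces; the expected share of the i-th largest piece is
    b_i = (1/p) * sum_{j=i..p} 1/j. The retained count is the length of
    the initial run of axes whose observed variance share exceeds b_i.
    """
    ev = np.asarray(eigenvalues, dtype=float)
    if ev.ndim != 1 or len(ev) == 0:
        raise ValueError("eigenvalues must be a non-empty 1D sequence")
    if np.any(ev < 0) or np.any(np.diff(ev) > 1e-12):
        raise ValueError("eigenvalues must be non-negative and descending")
    total = ev.sum()
    if total <= 0:
        raise ValueError("all eigenvalues are zero")
    p = len(ev)
    shares = ev / total
    inv = 1.0 / np.arange(1, p + 1)
    bstick = np.cumsum(inv[::-1])[::-1] / p
    count = 0
    for s, b in zip(shares, bstick):
        if s > b:
            count += 1
        else:
            break
    return count


# ---------------------------------------------------------------------------
# CVA
# ---------------------------------------------------------------------------


@dataclass
class CvaResults:
    """Canonical variate analysis with permutation-tested distances.

    ``mahalanobis`` holds pairwise distances between group means scaled
    by the pooled within-group covariance; ``perm_pvalues`` the share of
    label permutations with a distance at least as large (observed
    included in numerator and denominator).
    """

    groups: list
    canonical_axes: np.ndarray      # axes x p unit rows (input-variable space)
    canonical_scores: np.ndarray    # n x axes
    eigenvalues: np.ndarray
    mahalanobis: pd.DataFrame
    perm_pvalues: pd.DataFrame
    n_perm: int
    seed: int | None

    def summary(self) -> str:
        lines = ["Canonical variate analysis",
                 f"  groups: {', '.join(map(str, self.groups))}",
                 f"  permutations: {self.n_perm}",
                 "  Mahalanobis distances (upper) / permutation p (lower):"]
        lines.append(self.mahalanobis.round(4).to_string())
        lines.append("  p-values:")
        lines.append(self.perm_pvalues.to_string())
        return "\n".join(lines)


def _nonzero_pc_basis(X: np.ndarray):
    """Rotate to principal axes with non-zero variance (rank guard)."""
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    keep = s > _RANK_TOL * max(1.0, s[0] if len(s) else 1.0)
    basis = Vt[keep]
    return Xc @ basis.T, basis, mean


def _pairwise_mahalanobis(Z: np.ndarray, labels: np.ndarray, groups) -> np.ndarray:
    n, d = Z.shape
    g = len(groups)
    means = np.empty((g, d))
    W = np.zeros((d, d))
    for i, grp in enumerate(groups):
        sub = Z[labels == grp]
        means[i] = sub.mean(axis=0)
        dev = sub - means[i]
        W += dev.T @ dev
    W /= n - g
    try:
        Wi = np.linalg.inv(W)
    except np.linalg.LinAlgError:
        raise ValueError(
            "singular pooled within-group covariance; reduce dimensionality "
            "(e.g. retain fewer PCs) before the CVA"
        ) from None
    D = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            diff = means[i] - means[j]
            D[i, j] = D[j, i] = np.sqrt(max(0.0, diff @ Wi @ diff))
    return D


class CanonicalVariates:
    """CVA maximizing between/within group variance of shape scores.

    Computed in the principal-component subspace of non-zero variance so
    that the pooled within-group covariance is invertible.
    """

    def __init__(self, X, groups):
        self.X = np.asarray(X, dtype=float)
        self.labels = np.asarray(groups)
        uniq, counts = np.unique(self.labels, return_counts=True)
        if len(uniq) < 2 or np.any(counts < 2):
            raise ValueError("CVA needs >= 2 groups with >= 2 specimens each")
        self.groups = list(uniq)

    def fit(self, n_perm: int = 10000, seed: int | None = None) -> CvaResults:
        Z, basis, _ = _nonzero_pc_basis(self.X)
        n, d = Z.shape
        g = len(self.groups)
        labels = self.labels

        grand = Z.mean(axis=0)
        B = np.zeros((d, d))
        W = np.zeros((d, d))
        for grp in self.groups:
            sub = Z[labels == grp]
            m = sub.mean(axis=0)
            B += len(sub) * np.outer(m - grand, m - grand)
            dev = sub - m
            W += dev.T @ dev
        B /= g - 1
        W /= n - g
        try:
            evals, evecs = linalg.eigh(B, W)
        except linalg.LinAlgError:
            raise ValueError(
                "singular pooled within-group covariance; reduce dimensionality"
            ) from None
        order = np.argsort(-evals, kind="stable")[: g - 1]
        evals = np.clip(evals[order], 0.0, None)
        axes_reduced = evecs[:, order].T        # in PC space
        axes_full = axes_reduced @ basis        # back to input-variable space
        norms = np.linalg.norm(axes_full, axis=1, keepdims=True)
        axes_full = axes_full / np.where(norms > 0, norms, 1.0)
        scores = Z @ axes_reduced.T

        D_obs = _pairwise_mahalanobis(Z, labels, self.groups)
        rng = np.random.default_rng(seed)
        exceed = np.ones((g, g))  # observed counts once
        for _ in range(n_perm):
            perm = rng.permutation(n)
            D_null = _pairwise_mahalanobis(Z, labels[perm], self.groups)
            exceed += D_null >= D_obs
        pvals = exceed / (n_perm + 1)
        np.fill_diagonal(pvals, 1.0)

        idx = self.groups
        return CvaResults(
            groups=self.groups,
            canonical_axes=axes_full,
            canonical_scores=scores,
            eigenvalues=evals,
            mahalanobis=pd.DataFrame(D_obs, index=idx, columns=idx),
            perm_pvalues=pd.DataFrame(pvals, index=idx, columns=idx),
            n_perm=n_perm,
            seed=seed,
        )


def cva_mahalanobis(X, groups, n_perm: int = 10000, seed: int | None = None) -> CvaResults:
    return CanonicalVariates(X, groups).fit(n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Cross-validated classification
# ---------------------------------------------------------------------------


@dataclass
class ClassificationResults:
    confusion: pd.DataFrame          # rows: true, columns: predicted
    accuracy: float
    kappa: float
    posteriors: pd.DataFrame         # per-specimen class posterior probabilities
    scheme: str

    def summary(self) -> str:
        return "\n".join(
            [
                f"Cross-validated LDA classification ({self.scheme})",
                self.confusion.to_string(),
                f"  accuracy: {self.accuracy:.4f}",
                f"  kappa:    {self.kappa:.4f}",
            ]
        )


def kappa_from_confusion(confusion: np.ndarray) -> float:
    """Cohen's kappa: (p_o - p_e) / (1 - p_e), p_e from marginals."""
    C = np.asarray(confusion, dtype=float)
    total = C.sum()
    p_o = np.trace(C) / total
    p_e = float((C.sum(axis=1) * C.sum(axis=0)).sum()) / total**2
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else 0.0
    return float((p_o - p_e) / (1 - p_e))


def cross_validated_classification(
    scores,
    groups,
    scheme: str = "loo",
    seed: int | None = None,
    n_folds: int = 5,
) -> ClassificationResults:
    """Leave-one-out or k-fold cross-validated linear discriminant analysis.

    The discriminant is fitted on training folds only; held-out specimens
    receive posterior class probabilities and a predicted label.
    """
    X = np.asarray(scores, dtype=float)
    y = np.asarray(groups)
    classes = np.unique(y)
    if scheme == "loo":
        splitter = LeaveOneOut()
        split_iter = splitter.split(X)
    elif scheme == "kfold":
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, y)
    else:
        raise ValueError("scheme must be 'loo' or 'kfold'")

    pred = np.empty(len(y), dtype=object)
    post = np.zeros((len(y), len(classes)))
    for train, test in split_iter:
        if len(np.unique(y[train])) < len(classes):
            raise ValueError(
                "a training fold lacks a class; use scheme='loo' or fewer folds"
            )
        lda = LinearDiscriminantAnalysis()
        lda.fit(X[train], y[train])
        pred[test] = lda.predict(X[test])
        proba = lda.predict_proba(X[test])
        for ci, cls in enumerate(lda.classes_):
            post[test, np.flatnonzero(classes == cls)[0]] = proba[:, ci]

    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y, pred):
        conf[np.flatnonzero(classes == t)[0], np.flatnonzero(classes == p)[0]] += 1
    accuracy = float(np.trace(conf) / conf.sum())
    return ClassificationResults(
        confusion=pd.DataFrame(conf, index=classes, columns=classes),
        accuracy=accuracy,
        kappa=kappa_from_confusion(conf),
        posteriors=pd.DataFrame(post, columns=classes),
        scheme=scheme,
    )


def confidence_ellipse(scores_2d, labels, level: float = 0.90) -> pd.DataFrame:
    """Numeric group-ellipse summaries (center, axis lengths, orientation)."""
    from scipy.stats import chi2

    rows = []
    r = np.sqrt(chi2.ppf(level, df=2))
    scores_2d = np.asarray(scores_2d, dtype=float)
    labels = np.asarray(labels)
    for grp in np.unique(labels):
        sub = scores_2d[labels == grp]
        centr = sub.mean(axis=0)
        cov = np.cov(sub.T)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(-evals)
        evals, evecs = evals[order], evecs[:, order]
        rows.append(
            {
                "group": grp,
                "center_1": centr[0],
                "center_2": centr[1],
                "semi_axis_major": r * np.sqrt(max(evals[0], 0.0)),
                "semi_axis_minor": r * np.sqrt(max(evals[1], 0.0)),
                "orientation_deg": np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])),
                "level": level,
            }
        )
    return pd.DataFrame(rows)
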