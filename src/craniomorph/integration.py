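"""Two-block partial least squares analysis of morphological integration.

The cross-block covariance matrix of two landmark modules (here
neurocranium vs viscerocranium, both taken from a single Procrustes fit
of the whole configuration) is factorized by singular value
decomposition. Each pair of singular vectors spans the direction of
maximal covariation between the blocks; the correlation of the paired
specimen scores on the first axis (r-PLS) is the standard scalar
measure of integration. Permutation tests shuffle the specimens of one
block relative to the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landmark_io import ModulePartition
from .superimposition import GeneralizedProcrustes, ProcrustesResults

_SV_TOL = 1e-12


@dataclass
class PLSResults:
    """Singular axes of cross-block covariation with permutation p-values."""

    singular_values: np.ndarray
    percent_total_covariance: np.ndarray
    left_vectors: np.ndarray      # axes x p1, unit rows (first block)
    right_vectors: np.ndarray     # axes x p2, unit rows (second block)
    scores_left: np.ndarray       # n x axes
    scores_right: np.ndarray
    axis_correlations: np.ndarray
    block_labels: tuple
    p_singular: np.ndarray | None = None
    p_correlation: np.ndarray | None = None
    n_perm: int = 0
    seed: int | None = None
    component: str = "full"
    group_scope: str = "all"
    degenerate: bool = False      # zero cross-covariance; r_pls undefined

    @property
    def r_pls(self) -> float:
        """First-axis score correlation, the scalar integration measure."""
        if self.degenerate:
            return np.nan
        return float(self.axis_correlations[0])

    @property
    def n_axes(self) -> int:
        return len(self.singular_values)

    def table(self) -> pd.DataFrame:
        """Per-axis table: singular value, p, % covariance, correlation, p."""
        data = {
            "axis": [f"PLS{i + 1}" for i in range(self.n_axes)],
            "singular_value": self.singular_values,
            "p_singular": self.p_singular
            if self.p_singular is not None
            else [np.nan] * self.n_axes,
            "percent_total_covariance": self.percent_total_covariance,
            "correlation": self.axis_correlations,
            "p_correlation": self.p_correlation
            if self.p_correlation is not None
            else [np.nan] * self.n_axes,
        }
        return pd.DataFrame(data)

    def summary(self, max_axes: int = 8) -> str:
        head = [
            "Two-block partial least squares",
            f"  blocks:    {self.block_labels[0]} vs {self.block_labels[1]}",
            f"  component: {self.component}   scope: {self.group_scope}",
            f"  r-PLS (axis 1 score correlation): {self.r_pls:.4f}",
            f"  permutations: {self.n_perm}",
        ]
        return "\n".join(head) + "\n" + self.table().head(max_axes).round(5).to_string(index=False)


class TwoBlockPLS:
    """Two-block PLS model of a flattened shape matrix.

    Parameters
    ----------
    X : (n, 3k) shape matrix from a single Procrustes fit.
    part : ModulePartition
        Defines which flattened columns belong to each block; the block
        order follows ``part.labels``.
    """

    def __init__(self, X, part: ModulePartition):
        self.X = np.asarray(X, dtype=float)
        if self.X.shape[0] < 3:
            raise ValueError("PLS requires >= 3 specimens")
        self.part = part
        labels = part.labels
        if len(labels) != 2:
            raise ValueError("two-block PLS needs exactly two modules")
        self.block_labels = (labels[0], labels[1])
        self._cols1 = part.column_indices(labels[0])
        self._cols2 = part.column_indices(labels[1])

    @classmethod
    def from_blocks(cls, X1, X2, labels=("block1", "block2")) -> "TwoBlockPLS":
        """Build from two explicit score/variable blocks."""
        X1 = np.atleast_2d(np.asarray(X1, dtype=float))
        X2 = np.atleast_2d(np.asarray(X2, dtype=float))
        if X1.shape[0] != X2.shape[0]:
            raise ValueError("blocks must have the same number of specimens")
        # fabricate a column partition over the concatenated matrix; PLS only
        # uses column indices, so non-multiple-of-3 blocks are fine here
        obj = cls.__new__(cls)
        obj.X = np.hstack([X1, X2])
        obj.part = None
        obj.block_labels = tuple(labels)
        obj._cols1 = np.arange(X1.shape[1])
        obj._cols2 = np.arange(X1.shape[1], X1.shape[1] + X2.shape[1])
        return obj

    def _svd(self, X1c, X2c):
        n = X1c.shape[0]
        C = X1c.T @ X2c / (n - 1)
        U, s, Vt = np.linalg.svd(C, full_matrices=False)
        return U, s, Vt

    def fit(self, n_perm: int = 0, seed: int | None = None,
            component: str = "full", group_scope: str = "all") -> PLSResults:
        X1 = self.X[:, self._cols1]
        X2 = self.X[:, self._cols2]
        X1c = X1 - X1.mean(axis=0)
        X2c = X2 - X2.mean(axis=0)
        U, s, Vt = self._svd(X1c, X2c)

        degenerate = bool(s[0] <= _SV_TOL)
        if degenerate:
            warnings.warn("zero cross-block covariance; r-PLS undefined",
                          stacklevel=2)
        keep = max(1, int(np.sum(s > _SV_TOL * max(s[0], 1.0))))
        U, s, Vt = U[:, :keep], s[:keep], Vt[:keep]

        scores_l = X1c @ U
        scores_r = X2c @ Vt.T
        # orient so axis-1 score correlation is non-negative
        if not degenerate:
            c0 = np.corrcoef(scores_l[:, 0], scores_r[:, 0])[0, 1]
            if c0 < 0:
                Vt[0] *= -1
                scores_r[:, 0] *= -1
        corr = np.array(
            [
                _safe_corr(scores_l[:, i], scores_r[:, i])
                for i in range(keep)
            ]
        )
        ssq = (s**2).sum()
        percent = 100.0 * s**2 / ssq if ssq > 0 else np.zeros_like(s)

        p_sing = p_corr = None
        if n_perm > 0:
            if n_perm < 99:
                warnings.warn(
                    f"n_perm={n_perm} gives coarse p-value granularity",
                    stacklevel=2,
                )
            rng = np.random.default_rng(seed)
            n = X1c.shape[0]
            count_s = np.ones(keep)
            count_c = np.ones(keep)
            abs_corr = np.abs(corr)
            for _ in range(n_perm):
                perm = rng.permutation(n)
                Up, sp, Vtp = self._svd(X1c, X2c[perm])
                kp = min(keep, len(sp))
                count_s[:kp] += sp[:kp] >= s[:kp]
                sl = X1c @ Up[:, :kp]
                sr = X2c[perm] @ Vtp[:kp].T
                null_corr = np.abs(
                    [_safe_corr(sl[:, i], sr[:, i]) for i in range(kp)]
                )
                count_c[:kp] += null_corr >= abs_corr[:kp]
            p_sing = count_s / (n_perm + 1)
            p_corr = count_c / (n_perm + 1)

        return PLSResults(
            singular_values=s,
            percent_total_covariance=percent,
            left_vectors=U.T,
            right_vectors=Vt,
            scores_left=scores_l,
            scores_right=scores_r,
            axis_correlations=corr,
            block_labels=self.block_labels,
            p_singular=p_sing,
            p_correlation=p_corr,
            n_perm=n_perm,
            seed=seed,
            component=component,
            group_scope=group_scope,
            degenerate=degenerate,
        )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return np.nan
    return float(np.corrcoef(a, b)[0, 1])


def two_block_pls(X, part: ModulePartition, component: str = "full",
                  group_scope: str = "all") -> PLSResults:
    """Point estimates only (no permutation p-values)."""
    return TwoBlockPLS(X, part).fit(component=component, group_scope=group_scope)


def pls_permutation_test(
    X,
    part: ModulePartition,
    n_perm: int = 10000,
    seed: int | None = None,
    component: str = "full",
    group_scope: str = "all",
) -> PLSResults:
    """Two-block PLS with row-permutation p-values per axis."""
    return TwoBlockPLS(X, part).fit(
        n_perm=n_perm, seed=seed, component=component, group_scope=group_scope
    )


def run_integration_suite(
    fit: ProcrustesResults,
    part: ModulePartition,
    groups,
    component: str = "symmetric",
    refit_per_group: bool = True,
    n_perm: int = 0,
    seed: int | None = None,
    min_group_size: int = 4,
) -> dict:
    """PLS of the pooled data and of each category separately.

    With ``refit_per_group`` each category is re-superimposed (its own
    Procrustes fit, preserving the object-symmetry handling of the
    parent fit) before blocking; otherwise the pooled-fit coordinates
    are simply subset. Categories smaller than ``min_group_size`` are
    skipped with a warning.
    """
    groups = np.asarray(groups)
    rng = np.random.default_rng(seed)
    results: dict[str, PLSResults] = {}
    X_pooled = fit.component_matrix(component)
    results["all"] = TwoBlockPLS(X_pooled, part).fit(
        n_perm=n_perm, seed=int(rng.integers(2**31 - 1)),
        component=component, group_scope="all",
    )
    for grp in np.unique(groups):
        mask = groups == grp
        if mask.sum() < min_group_size:
            warnings.warn(f"skipping category {grp!r}: fewer than "
                          f"{min_group_size} specimens", stacklevel=2)
            continue
        if refit_per_group:
            raw = fit.dataset.coords[mask] if fit.dataset is not None else None
            if raw is None:
                raise ValueError("refit_per_group requires the fit to carry its dataset")
            sub_fit = GeneralizedProcrustes(raw, symmetry=fit.symmetry).fit()
            Xg = sub_fit.component_matrix(component if fit.symmetry else "full")
        else:
            Xg = X_pooled[mask]
        results[str(grp)] = TwoBlockPLS(Xg, part).fit(
            n_perm=n_perm, seed=int(rng.integers(2**31 - 1)),
            component=component, group_scope=str(grp),
        )
    return results
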