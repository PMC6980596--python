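"""Covariance-ratio (CR) test of modularity between landmark modules.

The CR statistic compares the magnitude of between-module covariation
with the within-module covariation:

    CR = ||S12||_F / sqrt(||S11*||_F * ||S22*||_F)

where S is the specimen covariance matrix of the flattened shape
coordinates partitioned by module columns, S12 the between-module block
and S11*, S22* the within-module blocks with their diagonals zeroed.
Values well below 1 indicate modularity. Significance comes from a
permutation null that randomly reassigns whole landmarks (x, y, z moved
together) to modules of the same sizes; the hypothesis of modularity is
supported when the observed CR sits in the lower tail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .landmark_io import ModulePartition


@dataclass
class CRResults:
    """Observed covariance ratio, its permutation null and p-value."""

    cr_observed: float
    null_distribution: np.ndarray = field(default_factory=lambda: np.array([]))
    p_value: float = np.nan
    n_perm: int = 0
    seed: int | None = None
    component: str = "full"
    group_scope: str = "all"

    def summary(self) -> str:
        return "\n".join(
            [
                "Covariance ratio test of modularity",
                f"  component:   {self.component}",
                f"  scope:       {self.group_scope}",
                f"  CR observed: {self.cr_observed:.4f}",
                f"  p (null CR <= observed): {self.p_value:.4g}",
                f"  permutations: {self.n_perm}",
            ]
        )

    def to_dict(self, include_null: bool = False) -> dict:
        out = {
            "cr_observed": self.cr_observed,
            "p_value": self.p_value,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "component": self.component,
            "group_scope": self.group_scope,
        }
        if include_null:
            out["null_distribution"] = self.null_distribution.tolist()
        return out


def _cr_from_cov(S: np.ndarray, cols1: np.ndarray, cols2: np.ndarray) -> float:
    S12 = S[np.ix_(cols1, cols2)]
    S11 = S[np.ix_(cols1, cols1)].copy()
    S22 = S[np.ix_(cols2, cols2)].copy()
    np.fill_diagonal(S11, 0.0)
    np.fill_diagonal(S22, 0.0)
    denom = np.sqrt(np.linalg.norm(S11) * np.linalg.norm(S22))
    if denom == 0:
        return np.nan
    return float(np.linalg.norm(S12) / denom)


def _landmark_columns(landmarks: np.ndarray) -> np.ndarray:
    return (3 * landmarks[:, None] + np.arange(3)[None, :]).ravel()


def covariance_ratio(X, part: ModulePartition) -> float:
    """CR of a (n, 3k) shape matrix under a two-module partition."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("CR requires >= 3 specimens")
    labels = part.labels
    lm1, lm2 = part.indices(labels[0]), part.indices(labels[1])
    if len(lm1) < 2 or len(lm2) < 2:
        raise ValueError("each module needs >= 2 landmarks")
    S = np.cov(X, rowvar=False)  # n-1 denominator
    return _cr_from_cov(S, _landmark_columns(lm1), _landmark_columns(lm2))


class ModularityCR:
    """Covariance-ratio modularity model for a two-module hypothesis.

    Parameters
    ----------
    X : (n, 3k) shape matrix from a single Procrustes fit.
    part : ModulePartition
    adjacency : optional mapping landmark -> iterable of neighbour
        landmarks (0-based). When given to :meth:`fit` via
        ``contiguous_null=True``, null modules are constrained to be
        connected subgraphs, mirroring spatially contiguous alternative
        partitions.
    """

    def __init__(self, X, part: ModulePartition, adjacency: dict | None = None):
        self.X = np.asarray(X, dtype=float)
        self.part = part
        self.adjacency = adjacency
        labels = part.labels
        self._lm1 = part.indices(labels[0])
        self._lm2 = part.indices(labels[1])
        if self.X.shape[0] < 3:
            raise ValueError("CR requires >= 3 specimens")
        if len(self._lm1) < 2 or len(self._lm2) < 2:
            raise ValueError("each module needs >= 2 landmarks")
        self._k = self.X.shape[1] // 3

    def _random_contiguous_module(self, rng, size: int) -> np.ndarray:
        """Grow a random connected landmark set of the given size."""
        if self.adjacency is None:
            raise ValueError("contiguous null requires an adjacency graph")
        for _ in range(1000):
            start = int(rng.integers(self._k))
            chosen = {start}
            frontier = set(self.adjacency.get(start, ()))
            while len(chosen) < size and frontier:
                nxt = int(rng.choice(sorted(frontier)))
                chosen.add(nxt)
                frontier |= set(self.adjacency.get(nxt, ()))
                frontier -= chosen
            if len(chosen) == size:
                return np.array(sorted(chosen))
        raise RuntimeError("could not sample a contiguous module of requested size")

    def fit(
        self,
        n_perm: int = 999,
        seed: int | None = None,
        contiguous_null: bool = False,
        component: str = "full",
        group_scope: str = "all",
    ) -> CRResults:
        if n_perm < 99:
            warnings.warn(
                f"n_perm={n_perm} gives coarse p-value granularity", stacklevel=2
            )
        S = np.cov(self.X, rowvar=False)
        cr_obs = _cr_from_cov(
            S, _landmark_columns(self._lm1), _landmark_columns(self._lm2)
        )
        rng = np.random.default_rng(seed)
        size1 = len(self._lm1)
        all_lm = np.arange(self._k)
        null = np.empty(n_perm)
        for b in range(n_perm):
            if contiguous_null:
                lm1 = self._random_contiguous_module(rng, size1)
            else:
                lm1 = rng.choice(all_lm, size=size1, replace=False)
            lm2 = np.setdiff1d(all_lm, lm1)
            null[b] = _cr_from_cov(
                S, _landmark_columns(lm1), _landmark_columns(lm2)
            )
        p = (1 + int(np.sum(null <= cr_obs))) / (1 + n_perm)
        return CRResults(
            cr_observed=cr_obs,
            null_distribution=null,
            p_value=p,
            n_perm=n_perm,
            seed=seed,
            component=component,
            group_scope=group_scope,
        )


def cr_permutation_test(
    X,
    part: ModulePartition,
    n_perm: int = 999,
    seed: int | None = None,
    adjacency: dict | None = None,
    contiguous_null: bool = False,
    component: str = "full",
    group_scope: str = "all",
) -> CRResults:
    """Covariance-ratio test with a landmark-reassignment null."""
    return ModularityCR(X, part, adjacency=adjacency).fit(
        n_perm=n_perm,
        seed=seed,
        contiguous_null=contiguous_null,
        component=component,
        group_scope=group_scope,
    )
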