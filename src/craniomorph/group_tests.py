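"""Pairwise PERMANOVA on Euclidean distances between shape scores.

One-way permutational ANOVA with a pseudo-F statistic on the pooled
distance matrix of each group pair, with Holm step-down correction
across the family of requested pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from statsmodels.stats.multitest import multipletests


@dataclass
class PermanovaResult:
    group_a: str
    group_b: str
    f_stat: float
    r_squared: float
    p_raw: float
    p_adjusted: float = np.nan
    n_perm: int = 0


def _permanova_ss(D2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Total and within-group sums of squares from squared distances.

    Uses the distance identity SS = (1/n) * sum of squared pairwise
    distances within a set.
    """
    n = len(labels)
    ss_total = D2.sum() / (2 * n)
    ss_within = 0.0
    for grp in np.unique(labels):
        idx = np.flatnonzero(labels == grp)
        ss_within += D2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    return ss_total, ss_within


def permanova_pair(
    X: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 10000,
    seed: int | None = None,
) -> tuple[float, float, float]:
    """One-way two-group PERMANOVA; returns (F, R2, p).

    F = (SS_between/(g-1)) / (SS_within/(n-g)); the permutation null
    shuffles specimen labels within the pooled pair, observed statistic
    included in numerator and denominator of p.
    """
    D2 = squareform(pdist(X)) ** 2
    labels = np.asarray(labels)
    n = len(labels)
    g = len(np.unique(labels))
    ss_total, ss_within = _permanova_ss(D2, labels)
    ss_between = ss_total - ss_within
    f_obs = (ss_between / (g - 1)) / (ss_within / (n - g))
    r2 = ss_between / ss_total if ss_total > 0 else 0.0

    rng = np.random.default_rng(seed)
    exceed = 1
    for _ in range(n_perm):
        perm_labels = labels[rng.permutation(n)]
        sst, ssw = _permanova_ss(D2, perm_labels)
        f_null = ((sst - ssw) / (g - 1)) / (ssw / (n - g))
        if f_null >= f_obs:
            exceed += 1
    return float(f_obs), float(r2), exceed / (n_perm + 1)


def pairwise_permanova(
    X,
    groups,
    n_perm: int = 10000,
    seed: int | None = None,
    pairs: list[tuple] | None = None,
) -> list[PermanovaResult]:
    """PERMANOVA for every unordered group pair with Holm correction.

    Parameters
    ----------
    X : (n, p) array of scores (e.g. all PC scores).
    groups : length-n labels.
    pairs : optional explicit family of pairs; defaults to all pairs.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(groups)
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("pairwise PERMANOVA needs >= 2 groups")
    sizes = dict(zip(uniq, counts))
    if pairs is None:
        pairs = [(uniq[i], uniq[j]) for i in range(len(uniq)) for j in range(i + 1, len(uniq))]

    rng = np.random.default_rng(seed)
    results = []
    for a, b in pairs:
        if sizes.get(a, 0) < 2 or sizes.get(b, 0) < 2:
            warnings.warn(f"skipping pair ({a}, {b}): a group has < 2 members",
                          stacklevel=2)
            continue
        mask = (labels == a) | (labels == b)
        f, r2, p = permanova_pair(
            X[mask], labels[mask], n_perm=n_perm,
            seed=int(rng.integers(2**31 - 1)),
        )
        results.append(PermanovaResult(str(a), str(b), f, r2, p, n_perm=n_perm))

    if results:
        raw = [r.p_raw for r in results]
        _, adjusted, _, _ = multipletests(raw, method="holm")
        for r, padj in zip(results, adjusted):
            r.p_adjusted = float(padj)
    return results


def permanova_table(results: list[PermanovaResult]) -> pd.DataFrame:
    """Result table with one row per comparison (CSV-ready)."""
    return pd.DataFrame(
        [
            {
                "comparison": f"{r.group_a} vs {r.group_b}",
                "F": r.f_stat,
                "R2": r.r_squared,
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "n_perm": r.n_perm,
            }
            for r in results
        ]
    )
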