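"""Comparison of covariation patterns between analyses.

Two tools: (i) angular comparison of PC/PLS axis vectors, with an
analytic null for the angle between independent uniformly distributed
unit vectors (the squared cosine follows a Beta(1/2, (d-1)/2) law) or a
Monte-Carlo null; (ii) element-wise matrix correlation between two
covariance matrices of the same landmark configuration, tested by
permuting the landmark order of one matrix at the 3x3-block level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class AngleTestResult:
    vector_a_id: str
    vector_b_id: str
    angle_degrees: float
    p_value: float
    dimension: int
    method: str


@dataclass
class MatrixCorrResult:
    correlation: float
    p_value: float
    include_diagonal_blocks: bool
    n_perm: int
    seed: int | None


def vector_angle(v1, v2) -> float:
    """Angle between two axis vectors in degrees, folded to [0, 90].

    PC/PLS vector signs are arbitrary, so the absolute cosine is used.
    """
    v1 = np.asarray(v1, dtype=float).ravel()
    v2 = np.asarray(v2, dtype=float).ravel()
    if v1.shape != v2.shape:
        raise ValueError(f"dimension mismatch: {v1.shape} vs {v2.shape}")
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero vector has no direction")
    cos = abs(float(v1 @ v2)) / (n1 * n2)
    return float(np.degrees(np.arccos(min(cos, 1.0))))


def angle_significance(
    angle_degrees: float,
    dimension: int,
    method: str = "analytic_null",
    n_draws: int = 100000,
    seed: int | None = None,
) -> float:
    """P(angle between independent uniform unit vectors <= observed).

    Small angles between high-dimensional vectors are exceedingly
    unlikely by chance, so a small p supports genuinely shared
    direction. The analytic form uses cos^2(theta) ~ Beta(1/2, (d-1)/2);
    the permutation method draws random unit-vector pairs.
    """
    if dimension < 2:
        raise ValueError("dimension must be >= 2")
    if not 0.0 <= angle_degrees <= 90.0:
        raise ValueError("angle must lie in [0, 90] degrees")
    cos2 = np.cos(np.radians(angle_degrees)) ** 2
    if method == "analytic_null":
        # P(angle <= obs) = P(cos^2 >= cos^2_obs)
        return float(stats.beta.sf(cos2, 0.5, (dimension - 1) / 2))
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        u = rng.standard_normal((n_draws, dimension))
        cosines = np.abs(u[:, 0]) / np.linalg.norm(u, axis=1)
        return (1 + int(np.sum(cosines**2 >= cos2))) / (1 + n_draws)
    raise ValueError("method must be 'analytic_null' or 'permutation'")


def angle_test(
    v1,
    v2,
    vector_a_id: str = "a",
    vector_b_id: str = "b",
    method: str = "analytic_null",
    seed: int | None = None,
) -> AngleTestResult:
    """Angle between two axis vectors plus its null-model p-value."""
    v1 = np.asarray(v1, dtype=float).ravel()
    angle = vector_angle(v1, v2)
    p = angle_significance(angle, dimension=len(v1), method=method, seed=seed)
    return AngleTestResult(
        vector_a_id=vector_a_id,
        vector_b_id=vector_b_id,
        angle_degrees=angle,
        p_value=p,
        dimension=len(v1),
        method=method,
    )


# ---------------------------------------------------------------------------
# Matrix correlation
# ---------------------------------------------------------------------------


def _block_entries(S: np.ndarray, include_diagonal_blocks: bool) -> np.ndarray:
    """Flatten a (3k, 3k) matrix blockwise by landmark.

    Takes all 9 entries of each off-diagonal 3x3 landmark block (upper
    block triangle only, by symmetry) and, when included, the 6 upper
    entries of each diagonal block.
    """
    k = S.shape[0] // 3
    vals = []
    triu3 = np.triu_indices(3)
    for i in range(k):
        for j in range(i, k):
            block = S[3 * i:3 * i + 3, 3 * j:3 * j + 3]
            if i == j:
                if include_diagonal_blocks:
                    vals.append(block[triu3])
            else:
                vals.append(block.ravel())
    return np.concatenate(vals)


def _permute_landmarks(S: np.ndarray, perm: np.ndarray) -> np.ndarray:
    cols = (3 * perm[:, None] + np.arange(3)[None, :]).ravel()
    return S[np.ix_(cols, cols)]


def matrix_correlation(S1, S2, include_diagonal_blocks: bool = True) -> float:
    """Pearson correlation of corresponding landmark-block entries."""
    S1 = np.asarray(S1, dtype=float)
    S2 = np.asarray(S2, dtype=float)
    if S1.shape != S2.shape or S1.shape[0] != S1.shape[1]:
        raise ValueError("matrices must be square and of equal shape")
    if S1.shape[0] % 3 != 0:
        raise ValueError("matrix dimension must be divisible by 3")
    a = _block_entries(S1, include_diagonal_blocks)
    b = _block_entries(S2, include_diagonal_blocks)
    return float(np.corrcoef(a, b)[0, 1])


def matrix_correlation_test(
    S1,
    S2,
    include_diagonal_blocks: bool = True,
    n_perm: int = 10000,
    seed: int | None = None,
) -> MatrixCorrResult:
    """Matrix correlation with a landmark-permutation null.

    The null applies a random landmark-order permutation to the rows and
    columns of the second matrix (whole 3x3 blocks move together) and
    recomputes the correlation; p is the share of null correlations at
    least as large as observed, observed included.
    """
    S1 = np.asarray(S1, dtype=float)
    S2 = np.asarray(S2, dtype=float)
    obs = matrix_correlation(S1, S2, include_diagonal_blocks)
    k = S1.shape[0] // 3
    rng = np.random.default_rng(seed)
    exceed = 1
    for _ in range(n_perm):
        perm = rng.permutation(k)
        null = matrix_correlation(
            S1, _permute_landmarks(S2, perm), include_diagonal_blocks
        )
        if null >= obs:
            exceed += 1
    return MatrixCorrResult(
        correlation=obs,
        p_value=exceed / (n_perm + 1),
        include_diagonal_blocks=include_diagonal_blocks,
        n_perm=n_perm,
        seed=seed,
    )


def reexpress_in_pooled_space(vector_block: np.ndarray, block_columns: np.ndarray,
                              total_dim: int) -> np.ndarray:
    """Embed a per-block axis vector into the pooled shape-variable space.

    Used when PLS axes from per-group refits must be compared across
    groups: each block vector is zero-padded to the full variable space
    so that angles are computed between commensurable vectors.
    """
    out = np.zeros(total_dim)
    out[block_columns] = np.asarray(vector_block, dtype=float).ravel()
    return out
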