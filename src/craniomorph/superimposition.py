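"""Generalized Procrustes analysis with object symmetry.

A cranium has object symmetry: the midsagittal plane runs through the
structure itself, so each configuration carries both halves of the
bilateral signal. Superimposing every configuration jointly with its
reflected-and-relabeled copy splits shape variation into a symmetric
component (the left-right average, used for among-individual "static"
variation) and an asymmetric component (the deviation from that average,
the signal of developmental instability).

The module also provides a Procrustes ANOVA for duplicate digitizations,
quantifying measurement error as repeatability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .landmark_io import LandmarkDataset, SymmetryMap

logger = logging.getLogger(__name__)


class DegenerateConfigurationError(ValueError):
    """Configuration with rank < 2 cannot be superimposed."""


def center(config: np.ndarray) -> np.ndarray:
    """Translate a k x 3 configuration so its centroid is at the origin."""
    config = np.asarray(config, dtype=float)
    return config - config.mean(axis=0)


def centroid_size(config: np.ndarray) -> float:
    """Root summed squared distance of landmarks from their centroid."""
    c = center(config)
    return float(np.sqrt((c**2).sum()))


def align_pair(source, target, allow_scaling: bool = False):
    """Optimally superimpose ``source`` onto ``target``.

    Both configurations are centered first. The rotation is constrained
    to be proper (determinant +1, no reflection), as required when
    reflected copies carry meaning of their own.

    Returns
    -------
    rotation : (3, 3) ndarray with det +1
    scale : float
        Applied to source (1.0 when ``allow_scaling`` is off).
    distance : float
        Root-summed-squared residual after superimposition.
    """
    S = center(source)
    T = center(target)
    for name, M in (("source", S), ("target", T)):
        if np.linalg.matrix_rank(M, tol=1e-12 * max(1.0, np.abs(M).max())) < 2:
            raise DegenerateConfigurationError(f"{name} configuration has rank < 2")
    H = S.T @ T
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    if allow_scaling:
        beta = float((s * np.diag(D)).sum() / (S**2).sum())
    else:
        beta = 1.0
    resid = beta * S @ R.T - T
    return R, beta, float(np.sqrt((resid**2).sum()))


def _fit_to_consensus(configs: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    out = np.empty_like(configs)
    for i, cfg in enumerate(configs):
        R, _, _ = align_pair(cfg, consensus, allow_scaling=False)
        out[i] = cfg @ R.T
    return out


def _gpa_core(configs, tol: float = 1e-10, max_iter: int = 200,
              consensus_postprocess=None):
    """Iterative GPA of pre-validated configurations.

    All configurations are centered and scaled to unit centroid size,
    then rotated to the running consensus until the consensus stops
    moving. The consensus is the plain mean of the aligned shapes (so
    aligned residuals sum to zero at convergence); an optional
    postprocess hook constrains it each round (e.g. symmetrization,
    which pins the symmetry plane to a coordinate plane).
    Returns (aligned, consensus, iterations, converged).
    """
    X = np.array([center(c) for c in configs], dtype=float)
    sizes = np.sqrt((X**2).sum(axis=(1, 2)))
    if np.any(sizes <= 0):
        raise DegenerateConfigurationError("zero centroid size")
    X /= sizes[:, None, None]
    consensus = X[0].copy()
    if consensus_postprocess is not None:
        consensus = consensus_postprocess(consensus)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        X = _fit_to_consensus(X, consensus)
        new = center(X.mean(axis=0))
        if consensus_postprocess is not None:
            new = consensus_postprocess(new)
        if np.sqrt((new**2).sum()) <= 0:
            raise DegenerateConfigurationError("degenerate consensus")
        delta = float(np.sqrt(((new - consensus) ** 2).sum()))
        consensus = new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning("GPA did not converge in %d iterations", max_iter)
    return X, consensus, it, converged


def reflect_relabel(configs: np.ndarray, sym: SymmetryMap) -> np.ndarray:
    """Mirror configurations: negate x, then swap paired landmark labels.

    Works on a single k x 3 configuration or a stack of them.
    """
    configs = np.asarray(configs, dtype=float)
    k = configs.shape[-2]
    perm = sym.relabel_permutation(k)
    mirrored = configs.copy()
    mirrored[..., 0] *= -1.0
    return mirrored[..., perm, :]


@dataclass
class ProcrustesResults:
    """Aligned shapes and their symmetric/asymmetric decomposition.

    Attributes
    ----------
    aligned : (n, k, 3) ndarray
        Procrustes-aligned original configurations (unit centroid size).
    aligned_mirrored : (n, k, 3) ndarray or None
        Aligned reflected-relabeled copies (object-symmetry fits only).
    consensus : (k, 3) ndarray
    centroid_sizes : (n,) ndarray of the raw configurations.
    symmetric, asymmetric : (n, k, 3) ndarrays or None
        symmetric + asymmetric == aligned exactly.
    """

    aligned: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    iterations: int
    converged: bool
    aligned_mirrored: np.ndarray | None = None
    symmetric: np.ndarray | None = None
    asymmetric: np.ndarray | None = None
    dataset: LandmarkDataset | None = None
    symmetry: SymmetryMap | None = None

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned.shape[1]

    def component_matrix(self, component: str = "full") -> np.ndarray:
        """Flattened (n, 3k) shape matrix of a variation component."""
        comp = {
            "full": self.aligned,
            "symmetric": self.symmetric,
            "asymmetric": self.asymmetric,
        }[component]
        if comp is None:
            raise ValueError(
                f"component {component!r} requires an object-symmetry fit"
            )
        return comp.reshape(comp.shape[0], -1)

    def summary(self) -> str:
        lines = [
            "Generalized Procrustes fit",
            f"  specimens:      {self.n_specimens}",
            f"  landmarks:      {self.n_landmarks}",
            f"  object symmetry: {self.symmetry is not None}",
            f"  iterations:     {self.iterations}",
            f"  converged:      {self.converged}",
            f"  mean centroid size: {self.centroid_sizes.mean():.4f}",
        ]
        return "\n".join(lines)


class GeneralizedProcrustes:
    """Generalized Procrustes superimposition model.

    Parameters
    ----------
    dataset : LandmarkDataset or (n, k, 3) array
    symmetry : SymmetryMap, optional
        When given, each configuration is jointly superimposed with its
        reflected-relabeled copy and the fit exposes symmetric and
        asymmetric components.

    Examples
    --------
    >>> fit = GeneralizedProcrustes(dataset, symmetry=sym).fit()
    >>> X_sym = fit.component_matrix("symmetric")
    """

    def __init__(self, dataset, symmetry: SymmetryMap | None = None,
                 tol: float = 1e-10, max_iter: int = 200):
        if isinstance(dataset, LandmarkDataset):
            self.dataset = dataset
            self.coords = dataset.coords
        else:
            self.dataset = None
            self.coords = np.asarray(dataset, dtype=float)
        if self.coords.shape[0] < 2:
            raise ValueError("GPA requires at least two specimens")
        self.symmetry = symmetry
        self.tol = tol
        self.max_iter = max_iter
        if symmetry is not None:
            problems = symmetry.coverage_problems(self.coords.shape[1])
            if problems:
                raise ValueError("; ".join(problems))

    def fit(self) -> ProcrustesResults:
        sizes = np.array([centroid_size(c) for c in self.coords])
        if self.symmetry is None:
            aligned, consensus, it, conv = _gpa_core(
                self.coords, self.tol, self.max_iter
            )
            return ProcrustesResults(
                aligned=aligned,
                consensus=consensus,
                centroid_sizes=sizes,
                iterations=it,
                converged=conv,
                dataset=self.dataset,
            )
        n = self.coords.shape[0]
        mirrored = reflect_relabel(self.coords, self.symmetry)
        stacked = np.concatenate([self.coords, mirrored], axis=0)

        def _symmetrize(C):
            return 0.5 * (C + reflect_relabel(C, self.symmetry))

        aligned_all, consensus, it, conv = _gpa_core(
            stacked, self.tol, self.max_iter, consensus_postprocess=_symmetrize
        )
        aligned = aligned_all[:n]
        aligned_mir = aligned_all[n:]
        symmetric = 0.5 * (aligned + aligned_mir)
        asymmetric = aligned - symmetric
        return ProcrustesResults(
            aligned=aligned,
            consensus=consensus,
            centroid_sizes=sizes,
            iterations=it,
            converged=conv,
            aligned_mirrored=aligned_mir,
            symmetric=symmetric,
            asymmetric=asymmetric,
            dataset=self.dataset,
            symmetry=self.symmetry,
        )


def gpa(dataset) -> ProcrustesResults:
    """Plain generalized Procrustes analysis (no symmetry handling)."""
    return GeneralizedProcrustes(dataset).fit()


def gpa_object_symmetry(dataset, sym: SymmetryMap) -> ProcrustesResults:
    """GPA of originals jointly with reflected-relabeled copies."""
    return GeneralizedProcrustes(dataset, symmetry=sym).fit()


# ---------------------------------------------------------------------------
# Measurement-error Procrustes ANOVA
# ---------------------------------------------------------------------------


@dataclass
class ErrorAnovaResults:
    """Procrustes ANOVA of duplicate digitizations.

    ``repeatability`` is the among-individual variance share
    s2_among / (s2_among + s2_error) with
    s2_among = (MS_individual - MS_error) / r, clipped to [0, 1].
    """

    ms_individual: float
    ms_error: float
    df_individual: int
    df_error: int
    f_ratio: float
    repeatability: float
    n_specimens: int
    n_replicates: int
    n_excluded: int = 0
    component: str = "full"

    def summary(self) -> str:
        return "\n".join(
            [
                "Procrustes ANOVA (measurement error)",
                f"  component:     {self.component}",
                f"  specimens:     {self.n_specimens} (excluded: {self.n_excluded})",
                f"  replicates:    {self.n_replicates}",
                f"  MS individual: {self.ms_individual:.6e} (df {self.df_individual})",
                f"  MS error:      {self.ms_error:.6e} (df {self.df_error})",
                f"  F:             {self.f_ratio:.3f}",
                f"  repeatability: {self.repeatability:.4f}",
            ]
        )

    def to_dict(self) -> dict:
        return {
            "ms_individual": self.ms_individual,
            "ms_error": self.ms_error,
            "df_individual": self.df_individual,
            "df_error": self.df_error,
            "f_ratio": self.f_ratio,
            "repeatability": self.repeatability,
            "n_specimens": self.n_specimens,
            "n_replicates": self.n_replicates,
            "n_excluded": self.n_excluded,
        }


def procrustes_anova_error(
    dataset: LandmarkDataset,
    sym: SymmetryMap | None = None,
    component: str = "full",
) -> ErrorAnovaResults:
    """Decompose shape variation into among-individual and digitization error.

    All (specimen, replicate) records are superimposed in one fit (with
    object symmetry when ``sym`` is given); the Procrustes coordinates of
    the chosen component are then decomposed into among-individual and
    residual (measurement error) sums of squares. Specimens lacking the
    modal replicate count are excluded with a logged count.
    """
    sids = np.asarray(dataset.specimen_ids)
    uniq, counts = np.unique(sids, return_counts=True)
    r = int(np.max(counts))
    if r < 2:
        raise ValueError("measurement-error ANOVA needs >= 2 replicates per specimen")
    keep_ids = uniq[counts == r]
    n_excluded = len(uniq) - len(keep_ids)
    if n_excluded:
        logger.warning(
            "excluding %d specimens without %d replicates", n_excluded, r
        )
    if len(keep_ids) == 0:
        raise ValueError("no specimens with a complete set of replicates")
    mask = np.isin(sids, keep_ids)
    sub = dataset.subset(mask)

    fit = GeneralizedProcrustes(sub, symmetry=sym).fit()
    X = fit.component_matrix(component if sym is not None else "full")

    order = np.lexsort((sub.replicates, sub.specimen_ids))
    X = X[order]
    n = len(keep_ids)
    m = X.shape[1]
    X = X.reshape(n, r, m)

    grand = X.mean(axis=(0, 1))
    ind_means = X.mean(axis=1)
    ss_among = r * float(((ind_means - grand) ** 2).sum())
    ss_error = float(((X - ind_means[:, None, :]) ** 2).sum())

    k = fit.n_landmarks
    dims = 3 * k - 7  # translation 3, rotation 3, scale 1
    df_ind = (n - 1) * dims
    df_err = n * (r - 1) * dims
    ms_ind = ss_among / df_ind
    ms_err = ss_error / df_err if df_err > 0 else 0.0

    if ms_err == 0.0:
        f_ratio = np.inf
        repeatability = 1.0
    else:
        f_ratio = ms_ind / ms_err
        s2_among = (ms_ind - ms_err) / r
        repeatability = float(np.clip(s2_among / (s2_among + ms_err), 0.0, 1.0))

    return ErrorAnovaResults(
        ms_individual=ms_ind,
        ms_error=ms_err,
        df_individual=df_ind,
        df_error=df_err,
        f_ratio=float(f_ratio),
        repeatability=repeatability,
        n_specimens=n,
        n_replicates=r,
        n_excluded=n_excluded,
        component=component if sym is not None else "full",
    )
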