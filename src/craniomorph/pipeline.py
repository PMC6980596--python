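"""End-to-end analysis pipeline.

Runs the full chain on a landmark dataset: validation, object-symmetry
Procrustes superimposition, measurement-error ANOVA (when replicate
digitizations are present), PCA, CVA with cross-validated
classification, pairwise PERMANOVA, covariance-ratio modularity tests
and two-block PLS integration analyses (both variation components,
pooled and per cranial category), angular comparisons of PC/PLS axes,
and matrix correlations between covariance matrices. Every stochastic
stage takes an explicit seed; rerunning a config reproduces the bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .covariation import angle_test, matrix_correlation_test
from .group_tests import pairwise_permanova, permanova_table
from .integration import run_integration_suite
from .landmark_io import (
    LandmarkDataset,
    load_schema_config,
    read_landmarks,
    validate_dataset,
)
from .modularity import cr_permutation_test
from .ordination import (
    ShapePCA,
    broken_stick_retain,
    CanonicalVariates,
    cross_validated_classification,
)
from .superimposition import GeneralizedProcrustes, procrustes_anova_error

logger = logging.getLogger(__name__)

COMPONENTS = ("symmetric", "asymmetric")


@dataclass
class AnalysisConfig:
    """Everything a pipeline run needs, resolved and seeded."""

    input_path: str | None = None
    input_format: str = "csv_long"
    metadata_path: str | None = None
    schema_config: str | dict | None = None  # symmetry + partition block
    n_perm: int = 999
    seed: int = 0
    refit_per_group: bool = True
    include_diagonal_blocks: bool = True
    contiguous_null: bool = False
    cv_scheme: str = "loo"
    pc_cutoff: str = "all"  # 'all' or 'broken_stick' for PERMANOVA distances
    me_component: str = "full"
    alpha: float = 0.05
    output_dir: str | None = None

    def validate(self) -> list[str]:
        problems = []
        if self.input_path is not None and not Path(self.input_path).exists():
            problems.append(f"input file not found: {self.input_path}")
        if isinstance(self.schema_config, str) and not Path(self.schema_config).exists():
            problems.append(f"schema config not found: {self.schema_config}")
        if self.schema_config is None:
            problems.append("config missing symmetry/partition block")
        if self.n_perm < 1:
            problems.append("n_perm must be >= 1")
        return problems

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(**cfg)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    return obj


def _pls_block(res) -> dict:
    return {
        "r_pls": res.r_pls,
        "n_axes": res.n_axes,
        "singular_values": res.singular_values,
        "percent_total_covariance": res.percent_total_covariance,
        "axis_correlations": res.axis_correlations,
        "p_singular": res.p_singular,
        "p_correlation": res.p_correlation,
        "n_perm": res.n_perm,
    }


def _embed_pls_axis(res, part, total_dim: int, axis: int = 0) -> np.ndarray:
    """Joint left+right PLS axis embedded in the pooled variable space."""
    v = np.zeros(total_dim)
    v[part.column_indices(res.block_labels[0])] = res.left_vectors[axis]
    v[part.column_indices(res.block_labels[1])] = res.right_vectors[axis]
    return v / np.linalg.norm(v)


def run_pipeline(config: AnalysisConfig, dataset: LandmarkDataset | None = None) -> dict:
    """Execute all stages; returns the report bundle as a nested dict.

    ``dataset`` may be passed directly (e.g. a synthetic one); otherwise
    it is read from ``config.input_path``. When ``config.output_dir`` is
    set, stage tables are written as CSV plus a single summary JSON.
    """
    problems = config.validate() if dataset is None else (
        ["config missing symmetry/partition block"] if config.schema_config is None else []
    )
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))

    sym, part = load_schema_config(config.schema_config)
    rng = np.random.default_rng(config.seed)
    seeds = {name: int(rng.integers(2**31 - 1)) for name in
             ("cva", "classification", "permanova", "cr", "pls", "matrix")}

    bundle: dict = {
        "meta": {
            "version": __version__,
            "seed": config.seed,
            "stage_seeds": seeds,
            "n_perm": config.n_perm,
            "alpha": config.alpha,
            "flags": {
                "refit_per_group": config.refit_per_group,
                "include_diagonal_blocks": config.include_diagonal_blocks,
                "contiguous_null": config.contiguous_null,
                "cv_scheme": config.cv_scheme,
                "pc_cutoff": config.pc_cutoff,
            },
        },
        "partial": False,
    }

    # --- load & validate ----------------------------------------------------
    if dataset is None:
        dataset = read_landmarks(
            config.input_path, config.input_format, metadata=config.metadata_path
        )
    report = validate_dataset(dataset, sym, part)
    bundle["validation"] = {"problems": report, "n_records": dataset.n_records,
                            "n_landmarks": dataset.n_landmarks}
    if report:
        bundle["partial"] = True
        logger.error("validation failed: %s", report)
        return bundle

    # --- measurement error (replicates), then collapse to first replicate ---
    reps = np.asarray(dataset.replicates)
    if (reps > 1).any():
        me = procrustes_anova_error(dataset, sym, component=config.me_component)
        bundle["measurement_error"] = me.to_dict()
        dataset = dataset.subset(reps == reps.min())
    else:
        bundle["measurement_error"] = None

    groups = np.asarray(dataset.groups)

    # --- object-symmetry GPA -------------------------------------------------
    fit = GeneralizedProcrustes(dataset, symmetry=sym).fit()
    bundle["gpa"] = {
        "iterations": fit.iterations,
        "converged": fit.converged,
        "n_specimens": fit.n_specimens,
        "mean_centroid_size": float(fit.centroid_sizes.mean()),
    }
    X_sym = fit.component_matrix("symmetric")
    X_asym = fit.component_matrix("asymmetric")

    # --- PCA of the symmetric component --------------------------------------
    pca_res = ShapePCA(X_sym).fit()
    n_retain = broken_stick_retain(pca_res.eigenvalues)
    bundle["pca"] = {
        "percent_variance": pca_res.percent_variance[:20],
        "eigenvalues": pca_res.eigenvalues[:20],
        "broken_stick_retained": n_retain,
    }
    pos = pca_res.eigenvalues > 1e-12 * pca_res.eigenvalues[0]
    scores_all = pca_res.scores[:, pos]
    scores_retained = pca_res.scores[:, : max(n_retain, 1)]

    # --- CVA + classification -------------------------------------------------
    # rank guard: the pooled within-group covariance must stay invertible,
    # so the CVA space is capped at n - g - 1 leading PCs
    n_groups = len(np.unique(groups))
    cva_dims = min(scores_all.shape[1], len(groups) - n_groups - 1)
    try:
        cva = CanonicalVariates(scores_all[:, :cva_dims], groups).fit(
            n_perm=config.n_perm, seed=seeds["cva"]
        )
        bundle["cva"] = {
            "groups": cva.groups,
            "mahalanobis": cva.mahalanobis,
            "perm_pvalues": cva.perm_pvalues,
            "n_perm": cva.n_perm,
        }
        clf = cross_validated_classification(
            scores_retained, groups, scheme=config.cv_scheme,
            seed=seeds["classification"],
        )
        bundle["classification"] = {
            "confusion": clf.confusion,
            "accuracy": clf.accuracy,
            "kappa": clf.kappa,
            "scheme": clf.scheme,
            "n_pcs": scores_retained.shape[1],
        }
    except ValueError as exc:
        logger.error("CVA stage failed: %s", exc)
        bundle["cva"] = {"error": str(exc)}
        bundle["classification"] = {"error": str(exc)}
        bundle["partial"] = True

    # --- pairwise PERMANOVA ---------------------------------------------------
    perm_scores = scores_retained if config.pc_cutoff == "broken_stick" else scores_all
    perm_results = pairwise_permanova(
        perm_scores, groups, n_perm=config.n_perm, seed=seeds["permanova"]
    )
    bundle["permanova"] = permanova_table(perm_results)

    # --- modularity (CR), per component, pooled and per category --------------
    cr_rng = np.random.default_rng(seeds["cr"])
    cr_block: dict = {}
    for comp, X in (("symmetric", X_sym), ("asymmetric", X_asym)):
        cr_block[comp] = {}
        scopes = [("all", np.ones(len(groups), dtype=bool))] + [
            (g, groups == g) for g in np.unique(groups)
        ]
        for scope, mask in scopes:
            if mask.sum() < 3:
                continue
            res = cr_permutation_test(
                X[mask], part, n_perm=config.n_perm,
                seed=int(cr_rng.integers(2**31 - 1)),
                contiguous_null=config.contiguous_null,
                component=comp, group_scope=scope,
            )
            cr_block[comp][scope] = res.to_dict()
    bundle["modularity"] = cr_block

    # --- integration (two-block PLS) -------------------------------------------
    pls_rng = np.random.default_rng(seeds["pls"])
    pls_block: dict = {}
    pls_results: dict = {}
    for comp in COMPONENTS:
        suite = run_integration_suite(
            fit, part, groups, component=comp,
            refit_per_group=config.refit_per_group,
            n_perm=config.n_perm, seed=int(pls_rng.integers(2**31 - 1)),
        )
        pls_results[comp] = suite
        pls_block[comp] = {scope: _pls_block(res) for scope, res in suite.items()}
    bundle["integration"] = pls_block

    # --- angular comparisons ----------------------------------------------------
    total_dim = X_sym.shape[1]
    angles = []
    for comp, X in (("symmetric", X_sym), ("asymmetric", X_asym)):
        comp_pca = ShapePCA(X).fit()
        pooled = pls_results[comp]["all"]
        for axis in range(min(2, pooled.n_axes)):
            pls_vec = _embed_pls_axis(pooled, part, total_dim, axis)
            res = angle_test(
                comp_pca.loadings[axis], pls_vec,
                vector_a_id=f"{comp}:PC{axis + 1}",
                vector_b_id=f"{comp}:PLS{axis + 1}",
            )
            angles.append(res)
        # cross-category PLS1 comparisons in the pooled variable space
        cats = [s for s in pls_results[comp] if s != "all"]
        for i in range(len(cats)):
            for j in range(i + 1, len(cats)):
                va = _embed_pls_axis(pls_results[comp][cats[i]], part, total_dim)
                vb = _embed_pls_axis(pls_results[comp][cats[j]], part, total_dim)
                angles.append(
                    angle_test(va, vb,
                               vector_a_id=f"{comp}:PLS1:{cats[i]}",
                               vector_b_id=f"{comp}:PLS1:{cats[j]}")
                )
    bundle["angles"] = pd.DataFrame([asdict(a) for a in angles])

    # --- matrix correlations ------------------------------------------------------
    mat_rng = np.random.default_rng(seeds["matrix"])
    mat_block = []
    S = {comp: np.cov(X, rowvar=False) for comp, X in
         (("symmetric", X_sym), ("asymmetric", X_asym))}
    res = matrix_correlation_test(
        S["symmetric"], S["asymmetric"],
        include_diagonal_blocks=config.include_diagonal_blocks,
        n_perm=config.n_perm, seed=int(mat_rng.integers(2**31 - 1)),
    )
    mat_block.append({"comparison": "symmetric vs asymmetric", "scope": "all",
                      "correlation": res.correlation, "p_value": res.p_value})
    cats = list(np.unique(groups))
    for comp, X in (("symmetric", X_sym), ("asymmetric", X_asym)):
        covs = {g: np.cov(X[groups == g], rowvar=False) for g in cats
                if (groups == g).sum() >= 3}
        for i in range(len(cats)):
            for j in range(i + 1, len(cats)):
                a, b = cats[i], cats[j]
                if a not in covs or b not in covs:
                    continue
                res = matrix_correlation_test(
                    covs[a], covs[b],
                    include_diagonal_blocks=config.include_diagonal_blocks,
                    n_perm=config.n_perm,
                    seed=int(mat_rng.integers(2**31 - 1)),
                )
                mat_block.append({
                    "comparison": f"{a} vs {b}", "scope": comp,
                    "correlation": res.correlation, "p_value": res.p_value,
                })
    bundle["matrix_correlations"] = pd.DataFrame(mat_block)

    if config.output_dir:
        _write_bundle(bundle, config.output_dir)
    return bundle


def _write_bundle(bundle: dict, output_dir) -> None:
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key in ("permanova", "angles", "matrix_correlations"):
        if isinstance(bundle.get(key), pd.DataFrame):
            bundle[key].to_csv(out / f"{key}.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump(_jsonable(bundle), fh, indent=2)
    logger.info("report bundle written to %s", out)
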