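"""Synthetic cranial landmark data with controlled covariance structure.

Generates 3D landmark datasets that carry the statistical features the
analysis chain assumes: a mirror-symmetric template, mean-shift group
deformations emulating artificial cranial deformation (antero-posterior
flattening and oblique shearing of the braincase), a shared
cross-module factor whose variance sets the integration level, module
specific factors, directional and fluctuating asymmetry, and replicate
digitization error.

The factor construction makes the integration level interpretable: the
shared factor and the module factors act along the same unit loading
field within each module, so the population cross-block score
correlation on the leading covariation axis is

    rho = s / (s + v)

with s = ``integration_strength`` and v = ``within_module_variance``
(plus a small attenuation from residual noise). All loading fields are
projected out of the similarity tangent space (translation, rotation,
scale) of the template so Procrustes superimposition does not absorb
the signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import yaml

from .landmark_io import (
    CRANIAL31_NAMES,
    LandmarkDataset,
    ModulePartition,
    SymmetryMap,
    cranial31_partition,
    cranial31_symmetry,
)
from .superimposition import centroid_size, reflect_relabel

# ---------------------------------------------------------------------------
# Templates
# ---------------------------------------------------------------------------

# Stylized adult cranium, coordinates in mm. Axes: x lateral (right +),
# y antero-posterior (anterior +), z vertical (superior +). Midsagittal
# landmarks lie exactly in the x = 0 plane; bilateral pairs are exact
# mirror images.
_CRANIAL31_MIDLINE_XYZ = {
    1: (0.0, 95.0, -35.0),   # prosthion
    2: (0.0, 93.0, -15.0),   # nasospinale
    3: (0.0, 90.0, 5.0),     # nasion
    4: (0.0, 92.0, 12.0),    # glabella
    5: (0.0, 30.0, 70.0),    # bregma
    6: (0.0, -65.0, 45.0),   # lambda
    7: (0.0, -78.0, 10.0),   # inion
    8: (0.0, -55.0, -30.0),  # opisthion
    9: (0.0, -20.0, -35.0),  # basion
    10: (0.0, 5.0, -32.0),   # sphenobasion
    28: (0.0, -40.0, 62.0),  # obelion
}
# right-side member of each pair; the left is the x-negated copy
_CRANIAL31_RIGHT_XYZ = {
    11: (45.0, 60.0, -25.0),  # zygomaxillare
    12: (40.0, 68.0, -5.0),   # zygoorbitale
    13: (48.0, 70.0, 8.0),    # frontomalare orbitale
    14: (60.0, 0.0, -10.0),   # auriculare
    15: (62.0, -15.0, 15.0),  # entomion
    16: (52.0, -55.0, 5.0),   # asterion
    17: (50.0, -5.0, -35.0),  # mastoideale
    25: (58.0, 35.0, 25.0),   # krotaphion
    26: (56.0, 40.0, 20.0),   # sphenion
    27: (45.0, 45.0, 45.0),   # stephanion
}
_CRANIAL31_PAIR_MAP = {11: 18, 12: 19, 13: 20, 14: 21, 15: 22,
                       16: 23, 17: 24, 25: 29, 26: 30, 27: 31}


def _cranial31_template() -> np.ndarray:
    coords = np.zeros((31, 3))
    for idx, xyz in _CRANIAL31_MIDLINE_XYZ.items():
        coords[idx - 1] = xyz
    for r, xyz in _CRANIAL31_RIGHT_XYZ.items():
        coords[r - 1] = xyz
        mirrored = (-xyz[0], xyz[1], xyz[2])
        coords[_CRANIAL31_PAIR_MAP[r] - 1] = mirrored
    return coords


def _toy_template():
    """Eight landmarks (4 midline, 2 pairs) for fast tests."""
    coords = np.array(
        [
            [0.0, 3.0, 0.0],
            [0.0, 1.5, 2.0],
            [0.0, -1.5, 2.0],
            [0.0, -3.0, 0.0],
            [2.0, 1.0, 0.5],   # right anterior
            [2.0, -1.0, 0.5],  # right posterior
            [-2.0, 1.0, 0.5],  # left anterior
            [-2.0, -1.0, 0.5],  # left posterior
        ]
    )
    sym = SymmetryMap.from_one_based(pairs=[(5, 7), (6, 8)], midline=[1, 2, 3, 4])
    part = ModulePartition.from_one_based(
        {"anterior": (1, 2, 5, 7), "posterior": (3, 4, 6, 8)}
    )
    return coords, sym, part


def make_template(schema: str = "cranial31"):
    """Template configuration plus its symmetry map and module partition.

    Parameters
    ----------
    schema : {'cranial31', 'toy'}
        'cranial31' is the standard 31-landmark cranial schema (11
        midsagittal points, 10 bilateral pairs; 9 facial vs 22 braincase
        landmarks); 'toy' is an 8-landmark configuration for fast tests.

    Returns
    -------
    (template, SymmetryMap, ModulePartition)
    """
    if schema == "cranial31":
        return _cranial31_template(), cranial31_symmetry(), cranial31_partition()
    if schema == "toy":
        return _toy_template()
    raise ValueError(f"unknown schema {schema!r}")


# ---------------------------------------------------------------------------
# Loading fields
# ---------------------------------------------------------------------------


def _similarity_basis(template: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the similarity tangent space at the template.

    Seven directions: 3 translations, 3 infinitesimal rotations, 1
    scaling, as flattened (3k,) vectors.
    """
    k = template.shape[0]
    Xc = template - template.mean(axis=0)
    vecs = []
    for ax in range(3):
        t = np.zeros((k, 3))
        t[:, ax] = 1.0
        vecs.append(t.ravel())
    for ax in range(3):
        a = np.zeros(3)
        a[ax] = 1.0
        vecs.append(np.cross(np.broadcast_to(a, (k, 3)), Xc).ravel())
    vecs.append(Xc.ravel())
    B = np.array(vecs).T
    Q, _ = np.linalg.qr(B)
    return Q  # (3k, 7)


def _project_out_similarity(field: np.ndarray, Q: np.ndarray) -> np.ndarray:
    v = field.ravel()
    v = v - Q @ (Q.T @ v)
    return v.reshape(field.shape)


def _smooth_field(template: np.ndarray, scales, phases) -> np.ndarray:
    """Mirror-symmetric smooth displacement field over the template."""
    x, y, z = template.T
    sx, sy, sz = scales
    px, py, pz = phases
    field = np.column_stack(
        [
            0.5 * np.sign(x) * np.cos(y / sx + px),
            np.sin(z / sy + py),
            0.8 * np.cos(y / sz + pz),
        ]
    )
    return field


def _unit_module_field(raw_field, module_idx, Q, antisymmetric=False, sym=None,
                       n_alternate: int = 200):
    """Restrict a field to one module, fix its symmetry type, remove
    similarity components, and normalize to unit Frobenius norm.

    Module support and orthogonality to the similarity space are both
    linear constraints; alternating the two projections converges to a
    field satisfying both exactly, so neither the factor signal leaks
    into the other module nor does Procrustes alignment absorb it.
    """
    field = np.zeros_like(raw_field)
    field[module_idx] = raw_field[module_idx]
    if sym is not None:
        mirrored = reflect_relabel(field, sym)
        field = 0.5 * (field - mirrored) if antisymmetric else 0.5 * (field + mirrored)
    mask = np.zeros(field.shape[0], dtype=bool)
    mask[module_idx] = True
    for _ in range(n_alternate):
        field[~mask] = 0.0
        field = _project_out_similarity(field, Q)
        if np.linalg.norm(field[~mask]) < 1e-14 * max(np.linalg.norm(field), 1e-30):
            break
    field[~mask] = 0.0
    norm = np.linalg.norm(field)
    if norm < 1e-12:
        raise ValueError("degenerate loading field")
    return field / norm


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSpec:
    """All generative parameters of a synthetic landmark dataset.

    Variances are in squared template length units (mm^2 for the
    standard cranial template) along unit-norm loading fields; standard
    deviations are in template length units.
    """

    schema: str = "cranial31"
    n_per_group: dict = dc_field(
        default_factory=lambda: {
            "antero-posterior": 74,
            "non-deformed": 118,
            "oblique": 77,
        }
    )
    integration_strength: float = 34.0
    within_module_variance: dict = dc_field(
        default_factory=lambda: {"viscerocranium": 6.0, "neurocranium": 6.0}
    )
    fa_variance: float = 0.8
    fa_integration_strength: float = 0.0
    fa_module_variance: float = 0.0
    da_scale: float = 0.0
    ap_compression: float = 0.08
    oblique_shear: float = 0.08
    deformation_sd_frac: float = 0.5
    measurement_error_sd: float = 0.3
    residual_sd: float = 0.5
    n_replicates: int = 1
    seed: int = 0

    def validate(self) -> list[str]:
        problems = []
        for name in (
            "integration_strength", "fa_variance", "fa_integration_strength",
            "fa_module_variance", "measurement_error_sd", "residual_sd",
        ):
            if getattr(self, name) < 0:
                problems.append(f"{name} must be >= 0")
        for lab, v in self.within_module_variance.items():
            if v < 0:
                problems.append(f"within_module_variance[{lab!r}] must be >= 0")
        if not 0 <= self.ap_compression < 1:
            problems.append("ap_compression must lie in [0, 1)")
        if self.deformation_sd_frac < 0:
            problems.append("deformation_sd_frac must be >= 0")
        if self.n_replicates < 1:
            problems.append("n_replicates must be >= 1")
        for g, n in self.n_per_group.items():
            if n < 0:
                problems.append(f"n_per_group[{g!r}] must be >= 0")
        return problems

    @classmethod
    def with_target_integration(cls, rho: float, within: float = 6.0,
                                **kwargs) -> "SyntheticSpec":
        """Spec whose implied cross-block score correlation is ``rho``."""
        if not 0 < rho < 1:
            raise ValueError("rho must lie in (0, 1)")
        strength = within * rho / (1.0 - rho)
        wm = kwargs.pop("within_module_variance", None)
        spec = cls(integration_strength=strength, **kwargs)
        labels = list(spec.within_module_variance) if wm is None else list(wm)
        spec.within_module_variance = {lab: within for lab in labels}
        return spec

    @classmethod
    def from_yaml(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(**cfg)

    def to_yaml(self, path) -> None:
        cfg = {
            "schema": self.schema,
            "n_per_group": dict(self.n_per_group),
            "integration_strength": self.integration_strength,
            "within_module_variance": dict(self.within_module_variance),
            "fa_variance": self.fa_variance,
            "fa_integration_strength": self.fa_integration_strength,
            "fa_module_variance": self.fa_module_variance,
            "da_scale": self.da_scale,
            "ap_compression": self.ap_compression,
            "oblique_shear": self.oblique_shear,
            "deformation_sd_frac": self.deformation_sd_frac,
            "measurement_error_sd": self.measurement_error_sd,
            "residual_sd": self.residual_sd,
            "n_replicates": self.n_replicates,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(cfg, fh, sort_keys=False)


def reference_cohort_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """The bundled reference-cohort preset with the standard cranial schema."""
    from importlib.resources import files

    path = files("craniomorph").joinpath("presets/reference_cohort.yaml")
    with path.open() as fh:
        cfg = yaml.safe_load(fh)
    cfg["seed"] = seed
    cfg.update(overrides)
    return SyntheticSpec(**cfg)


# ---------------------------------------------------------------------------
# Deformation fields
# ---------------------------------------------------------------------------


def _deform_antero_posterior(template, neuro_idx, compression):
    """Flatten the braincase antero-posteriorly, expanding laterally so
    the overall centroid size is preserved."""
    X = template - template.mean(axis=0)
    out = X.copy()
    y = X[neuro_idx, 1]
    out[neuro_idx, 1] = (1.0 - compression) * y
    deficit = float((y**2).sum() - (out[neuro_idx, 1] ** 2).sum())
    xx = float((X[neuro_idx, 0] ** 2).sum())
    if xx > 0:
        lam = np.sqrt(1.0 + deficit / xx)
        out[neuro_idx, 0] = lam * X[neuro_idx, 0]
    # the compression shifts the centroid slightly; a uniform rescale makes
    # the centroid-size preservation exact
    out *= centroid_size(template) / centroid_size(out)
    return out + template.mean(axis=0)


def _deform_oblique(template, neuro_idx, shear):
    """Shear the braincase posterosuperiorly (conical vault)."""
    X = template - template.mean(axis=0)
    out = X.copy()
    out[neuro_idx, 1] = X[neuro_idx, 1] - shear * X[neuro_idx, 2]
    out[neuro_idx, 2] = X[neuro_idx, 2] + 0.4 * shear * np.abs(X[neuro_idx, 2])
    # rescale the whole configuration back to the template centroid size
    cs_ratio = centroid_size(template) / centroid_size(out)
    return out * cs_ratio + template.mean(axis=0)


def default_da_shift(template, sym: SymmetryMap, scale: float = 1.0) -> np.ndarray:
    """A fixed antisymmetric directional-asymmetry field of given norm."""
    x, y, z = template.T
    raw = np.column_stack(
        [np.cos(z / 40.0), 0.4 * np.sign(x) * np.sin(y / 55.0),
         0.3 * np.sign(x) * np.cos(y / 35.0)]
    )
    anti = 0.5 * (raw - reflect_relabel(raw, sym))
    norm = np.linalg.norm(anti)
    return scale * anti / norm if norm > 0 else anti


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def simulate_dataset(spec: SyntheticSpec) -> LandmarkDataset:
    """Generate a landmark dataset from a :class:`SyntheticSpec`.

    Per specimen the template receives, in order: the group deformation
    (a mean shift whose intensity varies between specimens by
    ``deformation_sd_frac``), the shared cross-module factor, module-specific
    factors, symmetric individual noise, directional plus fluctuating
    asymmetry, and finally per-replicate digitization noise. Identical
    specs (same seed) produce identical datasets.
    """
    problems = spec.validate()
    if problems:
        raise ValueError("invalid SyntheticSpec: " + "; ".join(problems))

    template, sym, part = make_template(spec.schema)
    k = template.shape[0]
    rng = np.random.default_rng(spec.seed)
    Q = _similarity_basis(template)

    labels = part.labels
    mod_idx = {lab: part.indices(lab) for lab in labels}
    neuro_label = "neurocranium" if "neurocranium" in labels else labels[-1]
    neuro_idx = mod_idx[neuro_label]

    shared_raw = _smooth_field(template, (60.0, 50.0, 45.0), (0.0, 0.3, 0.0))
    sym_fields = {
        lab: _unit_module_field(shared_raw, mod_idx[lab], Q, sym=sym)
        for lab in labels
    }
    asym_raw = _smooth_field(template, (35.0, 65.0, 55.0), (1.1, 0.0, 0.7))
    asym_raw[:, 0] = np.cos(template[:, 2] / 30.0)  # break mirror symmetry
    asym_fields = {
        lab: _unit_module_field(
            asym_raw, mod_idx[lab], Q, antisymmetric=True, sym=sym
        )
        for lab in labels
    }
    da = (
        spec.da_scale * default_da_shift(template, sym)
        if spec.da_scale
        else np.zeros_like(template)
    )

    def _deformed_base(grp: str) -> np.ndarray:
        # deformation intensity varies between specimens: artificially
        # deformed skulls form a morphological continuum with the
        # non-deformed (which themselves show slight vault-shape
        # deviations along the same axes), so intensities get a relative
        # spread, truncated at zero
        frac = spec.deformation_sd_frac
        if grp == "antero-posterior" and spec.ap_compression > 0:
            c = spec.ap_compression * max(0.0, 1.0 + frac * rng.standard_normal())
            return _deform_antero_posterior(template, neuro_idx, min(c, 0.99))
        if grp == "oblique" and spec.oblique_shear != 0:
            sh = spec.oblique_shear * max(0.0, 1.0 + frac * rng.standard_normal())
            return _deform_oblique(template, neuro_idx, sh)
        base = template.copy()
        if frac > 0:
            c = spec.ap_compression * frac * abs(rng.standard_normal())
            sh = spec.oblique_shear * frac * abs(rng.standard_normal())
            if c > 0:
                base = _deform_antero_posterior(base, neuro_idx, min(c, 0.99))
            if sh > 0:
                base = _deform_oblique(base, neuro_idx, sh)
        return base

    coords, sids, groups, reps = [], [], [], []
    counter = 0
    for grp, n in spec.n_per_group.items():
        for _ in range(n):
            counter += 1
            X = _deformed_base(grp)
            f = rng.normal(0.0, np.sqrt(spec.integration_strength))
            for lab in labels:
                X += f * sym_fields[lab]
            for lab in labels:
                v = spec.within_module_variance.get(lab, 0.0)
                X += rng.normal(0.0, np.sqrt(v)) * sym_fields[lab]
            E = rng.normal(0.0, spec.residual_sd, size=(k, 3))
            X += 0.5 * (E + reflect_relabel(E, sym))
            # asymmetric terms: directional offset, structured FA factors,
            # and isotropic FA noise antisymmetrized into the asymmetric
            # subspace
            X += da
            fa = rng.normal(0.0, np.sqrt(spec.fa_integration_strength))
            for lab in labels:
                X += fa * asym_fields[lab]
                X += rng.normal(0.0, np.sqrt(spec.fa_module_variance)) * asym_fields[lab]
            A = rng.normal(0.0, np.sqrt(spec.fa_variance), size=(k, 3))
            X += 0.5 * (A - reflect_relabel(A, sym))
            sid = f"{grp[:2]}{counter:04d}"
            for r in range(1, spec.n_replicates + 1):
                Xr = X + rng.normal(0.0, spec.measurement_error_sd, size=(k, 3))
                coords.append(Xr)
                sids.append(sid)
                groups.append(grp)
                reps.append(r)

    names = CRANIAL31_NAMES if spec.schema == "cranial31" else [
        f"lm{i + 1}" for i in range(k)
    ]
    return LandmarkDataset(np.array(coords), sids, groups, reps, landmark_names=names)
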