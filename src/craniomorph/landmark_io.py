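"""Reading, writing and validating 3D landmark datasets.

Supports the file dialects commonly used in geometric morphometrics:
TPS (``LM3=`` records), Morphologika-style text, and two CSV layouts
(wide: one row per specimen; long: one row per landmark). Landmark
indices are 1-based in every file and configuration block, matching
standard osteometric tables; internal arrays are 0-based.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

KNOWN_GROUPS = ("antero-posterior", "non-deformed", "oblique")


class SchemaError(ValueError):
    """Inconsistent landmark structure across specimens."""


class ParseError(ValueError):
    """Malformed content in a landmark file."""


# ---------------------------------------------------------------------------
# Core containers
# ---------------------------------------------------------------------------


@dataclass
class LandmarkDataset:
    """A collection of landmark configurations with specimen metadata.

    Parameters
    ----------
    coords : ndarray, shape (n, k, 3)
        Landmark coordinates for n records (specimen x replicate) of k
        landmarks, in any consistent length unit.
    specimen_ids : list of str
    groups : list of str
        Deformation category per record.
    replicates : list of int
        Digitization replicate number (>= 1) per record.
    landmark_names : list of str, optional
    """

    coords: np.ndarray
    specimen_ids: list[str]
    groups: list[str]
    replicates: list[int]
    landmark_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise SchemaError(
                f"coords must have shape (n, k, 3); got {self.coords.shape}"
            )
        n, k, _ = self.coords.shape
        if not (len(self.specimen_ids) == len(self.groups) == len(self.replicates) == n):
            raise SchemaError("metadata lists must match the number of records")
        if not self.landmark_names:
            self.landmark_names = [f"lm{i + 1}" for i in range(k)]
        if len(self.landmark_names) != k:
            raise SchemaError("landmark_names must have one entry per landmark")

    @property
    def n_records(self) -> int:
        return self.coords.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.coords.shape[1]

    def to_matrix(self) -> np.ndarray:
        """Flatten to (n, 3k) with columns x1,y1,z1,x2,... order."""
        n = self.n_records
        return self.coords.reshape(n, -1)

    def subset(self, mask) -> "LandmarkDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return LandmarkDataset(
            coords=self.coords[idx],
            specimen_ids=[self.specimen_ids[i] for i in idx],
            groups=[self.groups[i] for i in idx],
            replicates=[self.replicates[i] for i in idx],
            landmark_names=list(self.landmark_names),
        )

    def validate(self) -> list[str]:
        """Basic structural invariants; returns a list of violations."""
        problems = []
        if not np.all(np.isfinite(self.coords)):
            bad = np.unique(np.nonzero(~np.isfinite(self.coords))[0])
            names = [self.specimen_ids[i] for i in bad]
            problems.append(f"non-finite coordinates in specimens {names}")
        seen = set()
        for sid, rep in zip(self.specimen_ids, self.replicates):
            key = (sid, rep)
            if key in seen:
                problems.append(f"duplicate (specimen_id, replicate): {key}")
            seen.add(key)
        for rec in range(self.n_records):
            X = self.coords[rec]
            Xc = X - X.mean(axis=0)
            if np.linalg.matrix_rank(Xc, tol=1e-9 * max(1.0, np.abs(Xc).max())) < 2:
                problems.append(
                    f"degenerate (collinear) configuration: {self.specimen_ids[rec]}"
                )
        return problems


@dataclass(frozen=True)
class SymmetryMap:
    """Bilateral-pair structure of a landmark configuration.

    ``pairs`` holds 0-based (right, left) landmark index pairs and
    ``midline`` the indices lying on the sagittal plane. Together they
    must partition {0..k-1}.
    """

    pairs: tuple
    midline: tuple

    @classmethod
    def from_one_based(cls, pairs, midline) -> "SymmetryMap":
        return cls(
            pairs=tuple((int(a) - 1, int(b) - 1) for a, b in pairs),
            midline=tuple(int(i) - 1 for i in midline),
        )

    @property
    def n_landmarks(self) -> int:
        return 2 * len(self.pairs) + len(self.midline)

    def coverage_problems(self, k: int) -> list[str]:
        problems = []
        used = list(self.midline)
        for a, b in self.pairs:
            used.extend([a, b])
        if len(used) != len(set(used)):
            problems.append("symmetry map repeats a landmark index")
        missing = sorted(set(range(k)) - set(used))
        extra = sorted(set(used) - set(range(k)))
        if missing:
            problems.append(
                f"symmetry map omits landmark indices {[i + 1 for i in missing]} (1-based)"
            )
        if extra:
            problems.append(
                f"symmetry map uses out-of-range indices {[i + 1 for i in extra]} (1-based)"
            )
        return problems

    def relabel_permutation(self, k: int) -> np.ndarray:
        """Index permutation that swaps each pair (midline fixed)."""
        perm = np.arange(k)
        for a, b in self.pairs:
            perm[a], perm[b] = b, a
        return perm

    def to_config(self) -> dict:
        return {
            "pairs": [[a + 1, b + 1] for a, b in self.pairs],
            "midline": [i + 1 for i in self.midline],
        }


@dataclass(frozen=True)
class ModulePartition:
    """Two-module assignment of landmarks (0-based index tuples)."""

    modules: dict  # label -> tuple of 0-based landmark indices

    @classmethod
    def from_one_based(cls, modules: dict) -> "ModulePartition":
        return cls({lab: tuple(int(i) - 1 for i in idx) for lab, idx in modules.items()})

    @property
    def labels(self) -> list[str]:
        return list(self.modules)

    def indices(self, label: str) -> np.ndarray:
        return np.asarray(self.modules[label], dtype=int)

    def column_indices(self, label: str) -> np.ndarray:
        """Flattened (x,y,z)-column indices of a module in a (n, 3k) matrix."""
        lm = self.indices(label)
        return np.concatenate([3 * lm, 3 * lm + 1, 3 * lm + 2]).reshape(3, -1).T.ravel()

    def coverage_problems(self, k: int) -> list[str]:
        problems = []
        if len(self.modules) != 2:
            problems.append(f"expected exactly two modules, got {len(self.modules)}")
        used = [i for idx in self.modules.values() for i in idx]
        for lab, idx in self.modules.items():
            if len(idx) == 0:
                problems.append(f"module '{lab}' is empty")
        if len(used) != len(set(used)):
            problems.append("partition assigns a landmark to more than one module")
        missing = sorted(set(range(k)) - set(used))
        if missing:
            problems.append(
                f"partition omits landmark indices {[i + 1 for i in missing]} (1-based)"
            )
        extra = sorted(set(used) - set(range(k)))
        if extra:
            problems.append(
                f"partition uses out-of-range indices {[i + 1 for i in extra]} (1-based)"
            )
        return problems

    def to_config(self) -> dict:
        return {lab: [i + 1 for i in idx] for lab, idx in self.modules.items()}


# ---------------------------------------------------------------------------
# The standard 31-landmark cranial schema
# ---------------------------------------------------------------------------

#: Bilateral pairs of the 31-landmark cranial schema, 1-based (right, left).
CRANIAL31_PAIRS = (
    (11, 18), (12, 19), (13, 20), (14, 21), (15, 22),
    (16, 23), (17, 24), (25, 29), (26, 30), (27, 31),
)
#: Midsagittal landmarks of the 31-landmark schema, 1-based.
CRANIAL31_MIDLINE = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 28)
#: Facial-skeleton (viscerocranium) landmarks, 1-based; the rest form the
#: braincase (neurocranium).
CRANIAL31_VISCEROCRANIUM = (1, 2, 3, 11, 12, 13, 18, 19, 20)

CRANIAL31_NAMES = [
    "prosthion", "nasospinale", "nasion", "glabella", "bregma", "lambda",
    "inion", "opisthion", "basion", "sphenobasion",
    "zygomaxillare_r", "zygoorbitale_r", "frontomalare_orbitale_r",
    "auriculare_r", "entomion_r", "asterion_r", "mastoideale_r",
    "zygomaxillare_l", "zygoorbitale_l", "frontomalare_orbitale_l",
    "auriculare_l", "entomion_l", "asterion_l", "mastoideale_l",
    "krotaphion_r", "sphenion_r", "stephanion_r", "obelion",
    "krotaphion_l", "sphenion_l", "stephanion_l",
]


def cranial31_symmetry() -> SymmetryMap:
    return SymmetryMap.from_one_based(CRANIAL31_PAIRS, CRANIAL31_MIDLINE)


def cranial31_partition() -> ModulePartition:
    viscero = set(CRANIAL31_VISCEROCRANIUM)
    neuro = tuple(sorted(set(range(1, 32)) - viscero))
    return ModulePartition.from_one_based(
        {"viscerocranium": tuple(sorted(viscero)), "neurocranium": neuro}
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_dataset(
    dataset: LandmarkDataset,
    sym: SymmetryMap | None = None,
    part: ModulePartition | None = None,
) -> list[str]:
    """Collect every invariant violation of a dataset and its schema.

    Returns an empty list when the dataset, symmetry map and module
    partition are mutually consistent.
    """
    problems = dataset.validate()
    k = dataset.n_landmarks
    if sym is not None:
        problems.extend(sym.coverage_problems(k))
    if part is not None:
        problems.extend(part.coverage_problems(k))
    for g in dataset.groups:
        if g not in KNOWN_GROUPS and g != "other":
            # unusual labels are allowed but logged once per label
            logger.debug("group label outside standard categories: %r", g)
    return problems


# ---------------------------------------------------------------------------
# Metadata sidecar
# ---------------------------------------------------------------------------


def _apply_metadata(dataset: LandmarkDataset, metadata) -> LandmarkDataset:
    """Merge a specimen_id -> (group, replicate) sidecar table.

    The sidecar wins on conflict with in-file metadata, with a warning.
    """
    if metadata is None:
        return dataset
    if isinstance(metadata, (str,)) or hasattr(metadata, "read"):
        metadata = pd.read_csv(metadata)
    meta = metadata.set_index(metadata["specimen_id"].astype(str))
    groups = list(dataset.groups)
    reps = list(dataset.replicates)
    for i, sid in enumerate(dataset.specimen_ids):
        if sid not in meta.index:
            continue
        row = meta.loc[sid]
        if "group" in meta.columns and not pd.isna(row["group"]):
            new = str(row["group"])
            if groups[i] not in ("other", new):
                warnings.warn(
                    f"sidecar overrides group for {sid}: {groups[i]} -> {new}",
                    stacklevel=2,
                )
            groups[i] = new
        if "replicate" in meta.columns and not pd.isna(row["replicate"]):
            reps[i] = int(row["replicate"])
    bad = sorted(set(groups) - set(KNOWN_GROUPS) - {"other"})
    if bad:
        raise ValueError(f"unknown group labels in metadata: {bad}")
    return LandmarkDataset(
        dataset.coords, dataset.specimen_ids, groups, reps, dataset.landmark_names
    )


# ---------------------------------------------------------------------------
# TPS
# ---------------------------------------------------------------------------


def _read_tps(path) -> LandmarkDataset:
    coords, sids, groups, reps = [], [], [], []
    cur = None
    cur_id = None
    expected = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3=") or upper.startswith("LM="):
                if cur is not None:
                    _finish_tps_record(cur, cur_id, expected, coords, sids, groups, reps)
                n_pts = int(line.split("=", 1)[1])
                if expected is None:
                    expected = n_pts
                cur = {"n": n_pts, "pts": []}
                cur_id = None
            elif upper.startswith("ID="):
                cur_id = line.split("=", 1)[1].strip()
            elif upper.startswith(("SCALE=", "IMAGE=", "COMMENT=")):
                continue
            else:
                if cur is None:
                    raise ParseError(f"{path}: line {lineno}: coordinates before LM3=")
                parts = line.split()
                try:
                    xyz = [float(v) for v in parts]
                except ValueError:
                    raise ParseError(
                        f"{path}: line {lineno}: non-numeric coordinate {line!r}"
                    ) from None
                if len(xyz) != 3:
                    raise ParseError(
                        f"{path}: line {lineno}: expected 3 coordinates, got {len(xyz)}"
                    )
                cur["pts"].append(xyz)
    if cur is not None:
        _finish_tps_record(cur, cur_id, expected, coords, sids, groups, reps)
    if not coords:
        raise ParseError(f"{path}: no landmark records found")
    return LandmarkDataset(np.array(coords), sids, groups, reps)


def _finish_tps_record(cur, cur_id, expected, coords, sids, groups, reps):
    sid = cur_id if cur_id else f"spec{len(coords) + 1}"
    if len(cur["pts"]) != cur["n"]:
        raise SchemaError(
            f"specimen {sid!r}: header declares {cur['n']} landmarks but "
            f"{len(cur['pts'])} were read"
        )
    if expected is not None and cur["n"] != expected:
        raise SchemaError(
            f"specimen {sid!r}: has {cur['n']} landmarks, expected {expected}"
        )
    # ID fields may carry group/replicate as "name;group;replicate"
    group, rep = "other", 1
    if sid and ";" in sid:
        bits = sid.split(";")
        sid = bits[0]
        if len(bits) > 1 and bits[1]:
            group = bits[1]
        if len(bits) > 2 and bits[2]:
            rep = int(bits[2])
    coords.append(cur["pts"])
    sids.append(sid)
    groups.append(group)
    reps.append(rep)


def _write_tps(dataset: LandmarkDataset, path):
    with open(path, "w") as fh:
        for rec in range(dataset.n_records):
            fh.write(f"LM3={dataset.n_landmarks}\n")
            for x, y, z in dataset.coords[rec]:
                fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")
            fh.write(
                f"ID={dataset.specimen_ids[rec]};{dataset.groups[rec]};"
                f"{dataset.replicates[rec]}\n"
            )


# ---------------------------------------------------------------------------
# Morphologika-style text
# ---------------------------------------------------------------------------


def _read_morphologika(path) -> LandmarkDataset:
    sections: dict[str, list[str]] = {}
    current = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                current = line[1:-1].lower()
                sections[current] = []
            elif current is not None:
                sections[current].append(line)
    try:
        n = int(sections["individuals"][0])
        k = int(sections["landmarks"][0])
        d = int(sections["dimensions"][0])
    except (KeyError, IndexError, ValueError) as exc:
        raise ParseError(f"{path}: malformed morphologika header: {exc}") from None
    if d != 3:
        raise ParseError(f"{path}: only 3D data supported, file declares {d}D")
    names = sections.get("names", [f"spec{i + 1}" for i in range(n)])
    raw_rows = sections.get("rawpoints", [])
    pts, labels = [], []
    for line in raw_rows:
        if line.startswith("'"):
            labels.append(line.lstrip("'").strip())
            continue
        try:
            pts.append([float(v) for v in line.split()])
        except ValueError:
            raise ParseError(f"{path}: non-numeric coordinate row {line!r}") from None
    if len(pts) != n * k:
        raise SchemaError(
            f"{path}: expected {n * k} coordinate rows, found {len(pts)}"
        )
    coords = np.array(pts).reshape(n, k, 3)
    sids, groups, reps = [], [], []
    for name in names[:n]:
        bits = name.split(";")
        sids.append(bits[0])
        groups.append(bits[1] if len(bits) > 1 and bits[1] else "other")
        reps.append(int(bits[2]) if len(bits) > 2 and bits[2] else 1)
    return LandmarkDataset(coords, sids, groups, reps)


def _write_morphologika(dataset: LandmarkDataset, path):
    with open(path, "w") as fh:
        fh.write(f"[individuals]\n{dataset.n_records}\n")
        fh.write(f"[landmarks]\n{dataset.n_landmarks}\n")
        fh.write("[dimensions]\n3\n")
        fh.write("[names]\n")
        for rec in range(dataset.n_records):
            fh.write(
                f"{dataset.specimen_ids[rec]};{dataset.groups[rec]};"
                f"{dataset.replicates[rec]}\n"
            )
        fh.write("[rawpoints]\n")
        for rec in range(dataset.n_records):
            fh.write(f"'{dataset.specimen_ids[rec]}\n")
            for x, y, z in dataset.coords[rec]:
                fh.write(f"{float(x)!r} {float(y)!r} {float(z)!r}\n")


# ---------------------------------------------------------------------------
# CSV dialects
# ---------------------------------------------------------------------------


def _read_csv_wide(path) -> LandmarkDataset:
    df = pd.read_csv(path, float_precision="round_trip")
    meta_cols = [c for c in ("specimen_id", "group", "replicate") if c in df.columns]
    if "specimen_id" not in meta_cols:
        raise ParseError(f"{path}: csv_wide requires a specimen_id column")
    coord_cols = [c for c in df.columns if c not in meta_cols]
    if len(coord_cols) % 3 != 0:
        raise SchemaError(f"{path}: coordinate column count not divisible by 3")
    # columns are x_<name>, y_<name>, z_<name> per landmark
    names = []
    for c in coord_cols[::3]:
        if not c.startswith("x_"):
            raise ParseError(f"{path}: expected x_/y_/z_ column triplets, got {c!r}")
        names.append(c[2:])
    coords = df[coord_cols].to_numpy(dtype=float).reshape(len(df), len(names), 3)
    return LandmarkDataset(
        coords,
        df["specimen_id"].astype(str).tolist(),
        df["group"].astype(str).tolist() if "group" in df else ["other"] * len(df),
        df["replicate"].astype(int).tolist() if "replicate" in df else [1] * len(df),
        landmark_names=names,
    )


def _write_csv_wide(dataset: LandmarkDataset, path):
    data = {
        "specimen_id": dataset.specimen_ids,
        "group": dataset.groups,
        "replicate": dataset.replicates,
    }
    for j, name in enumerate(dataset.landmark_names):
        for axis, ax_name in enumerate("xyz"):
            data[f"{ax_name}_{name}"] = dataset.coords[:, j, axis]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def _read_csv_long(path) -> LandmarkDataset:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"specimen_id", "replicate", "landmark", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: csv_long missing columns {sorted(missing)}")
    has_group = "group" in df.columns
    names = list(dict.fromkeys(df["landmark"].astype(str)))
    k = len(names)
    recs, sids, groups, reps = [], [], [], []
    for (sid, rep), sub in df.groupby(["specimen_id", "replicate"], sort=False):
        if len(sub) != k:
            raise SchemaError(
                f"specimen {sid!r} replicate {rep}: has {len(sub)} landmarks, expected {k}"
            )
        sub = sub.set_index(sub["landmark"].astype(str)).loc[names]
        recs.append(sub[["x", "y", "z"]].to_numpy(dtype=float))
        sids.append(str(sid))
        groups.append(str(sub["group"].iloc[0]) if has_group else "other")
        reps.append(int(rep))
    return LandmarkDataset(np.array(recs), sids, groups, reps, landmark_names=names)


def _write_csv_long(dataset: LandmarkDataset, path):
    rows = []
    for rec in range(dataset.n_records):
        for j, name in enumerate(dataset.landmark_names):
            x, y, z = dataset.coords[rec, j]
            rows.append(
                {
                    "specimen_id": dataset.specimen_ids[rec],
                    "replicate": dataset.replicates[rec],
                    "group": dataset.groups[rec],
                    "landmark": name,
                    "x": x,
                    "y": y,
                    "z": z,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


_READERS = {
    "tps": _read_tps,
    "morphologika": _read_morphologika,
    "csv_wide": _read_csv_wide,
    "csv_long": _read_csv_long,
}
_WRITERS = {
    "tps": _write_tps,
    "morphologika": _write_morphologika,
    "csv_wide": _write_csv_wide,
    "csv_long": _write_csv_long,
}

FORMATS = tuple(_READERS)


def read_landmarks(path, format: str, metadata=None) -> LandmarkDataset:
    """Read a landmark file in the named dialect.

    Parameters
    ----------
    path : path-like
    format : {'tps', 'morphologika', 'csv_wide', 'csv_long'}
    metadata : DataFrame or path, optional
        Sidecar table with columns specimen_id and optionally group,
        replicate; overrides in-file metadata on conflict.
    """
    try:
        reader = _READERS[format]
    except KeyError:
        raise ValueError(f"unknown format {format!r}; choose from {FORMATS}") from None
    dataset = reader(path)
    return _apply_metadata(dataset, metadata)


def write_landmarks(dataset: LandmarkDataset, path, format: str) -> None:
    try:
        writer = _WRITERS[format]
    except KeyError:
        raise ValueError(f"unknown format {format!r}; choose from {FORMATS}") from None
    writer(dataset, path)


def load_schema_config(path_or_dict) -> tuple[SymmetryMap, ModulePartition]:
    """Load a symmetry map and module partition from YAML/JSON config.

    Expected block (1-based indices)::

        symmetry:
          pairs: [[11, 18], ...]
          midline: [1, 2, ...]
        partition:
          viscerocranium: [1, 2, 3, ...]
          neurocranium: [4, 5, ...]
    """
    if isinstance(path_or_dict, dict):
        cfg = path_or_dict
    else:
        with open(path_or_dict) as fh:
            cfg = yaml.safe_load(fh)
    sym = SymmetryMap.from_one_based(
        cfg["symmetry"]["pairs"], cfg["symmetry"]["midline"]
    )
    part = ModulePartition.from_one_based(cfg["partition"])
    return sym, part
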