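"""Reading, validating and writing connectome matrices, labels and manifests.

A connectome here is an undirected weighted network on brain regions: node
*i* is a region of a parcellation atlas (by default the 116-region AAL
atlas), and the edge weight ``w_ij`` is the streamline count between regions
*i* and *j* from deterministic tractography.  Matrices are stored as dense
plain-text tables (116 × 116 is small); an edge exists wherever the weight is
strictly positive — no streamline-count threshold is applied.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Connectome",
    "SubjectRecord",
    "Cohort",
    "read_connectome",
    "write_connectome",
    "read_labels",
    "write_labels",
    "find_isolated_nodes",
    "read_manifest",
    "write_cohort",
    "GENDER_CODES",
    "MANIFEST_COLUMNS",
]

#: gender coding used in all design matrices (arbitrary but fixed)
GENDER_CODES = {"M": 1, "F": 0}

MANIFEST_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "gender",
    "pdss",
    "hamd",
    "duration_months",
    "matrix_file",
]

_SYMMETRY_TOL = 1e-9


@dataclass(frozen=True)
class Connectome:
    """A single subject's weighted undirected network.

    Parameters
    ----------
    labels
        Ordered region names; node order everywhere follows this list
        (0-based internally, reported 1-based with region names in outputs).
    W
        Symmetric nonnegative weight matrix with zero diagonal, shape
        ``(len(labels), len(labels))``.
    """

    labels: tuple[str, ...]
    W: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        object.__setattr__(self, "W", W)
        object.__setattr__(self, "labels", tuple(self.labels))
        n = len(self.labels)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"weight matrix must be square, got shape {W.shape}")
        if W.shape[0] != n:
            raise ValueError(
                f"matrix has {W.shape[0]} nodes but {n} labels were given"
            )
        if not np.all(np.isfinite(W)):
            raise ValueError("weight matrix contains non-finite entries")
        if np.any(W < 0):
            raise ValueError("weight matrix contains negative entries")
        asym = np.abs(W - W.T).max(initial=0.0)
        if asym > _SYMMETRY_TOL:
            raise ValueError(
                f"weight matrix is asymmetric (max |w_ij - w_ji| = {asym:g})"
            )
        if np.any(np.diag(W) != 0):
            raise ValueError("weight matrix has nonzero diagonal entries")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def degrees(self) -> np.ndarray:
        """Binary degree k_i: number of strictly positive off-diagonal weights."""
        return (self.W > 0).sum(axis=1)


@dataclass(frozen=True)
class SubjectRecord:
    """One subject: connectome plus group label, covariates and clinical scores."""

    subject_id: str
    group: str  # "PD" or "HC"
    age: float
    gender: str  # "M" or "F"
    hamd: float
    connectome: Connectome
    pdss: float | None = None  # nullable for HC
    duration_months: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("PD", "HC"):
            raise ValueError(
                f"subject {self.subject_id!r}: unknown group {self.group!r} "
                "(expected 'PD' or 'HC')"
            )
        if self.gender not in GENDER_CODES:
            raise ValueError(
                f"subject {self.subject_id!r}: unknown gender {self.gender!r}"
            )
        if not (18 <= self.age <= 60):
            raise ValueError(
                f"subject {self.subject_id!r}: age {self.age} outside [18, 60]"
            )
        if self.pdss is not None and self.pdss < 0:
            raise ValueError(f"subject {self.subject_id!r}: negative PDSS")
        if self.hamd < 0:
            raise ValueError(f"subject {self.subject_id!r}: negative HAMD")

    @property
    def gender_code(self) -> int:
        return GENDER_CODES[self.gender]


@dataclass(frozen=True)
class Cohort:
    """All subjects of a study; every connectome shares one label list."""

    subjects: tuple[SubjectRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "subjects", tuple(self.subjects))
        if not self.subjects:
            raise ValueError("cohort is empty")
        labels = self.subjects[0].connectome.labels
        for s in self.subjects[1:]:
            if s.connectome.labels != labels:
                raise ValueError(
                    f"subject {s.subject_id!r} has a different node label list"
                )
        ids = [s.subject_id for s in self.subjects]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate subject ids: {sorted(dupes)}")

    @property
    def labels(self) -> tuple[str, ...]:
        return self.subjects[0].connectome.labels

    def group(self, name: str) -> list[SubjectRecord]:
        return [s for s in self.subjects if s.group == name]

    def __len__(self) -> int:
        return len(self.subjects)

    def to_frame(self) -> pd.DataFrame:
        """Covariate/clinical table, one row per subject (no matrices)."""
        return pd.DataFrame(
            {
                "subject_id": [s.subject_id for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "age": [s.age for s in self.subjects],
                "gender": [s.gender for s in self.subjects],
                "gender_code": [s.gender_code for s in self.subjects],
                "pdss": [s.pdss for s in self.subjects],
                "hamd": [s.hamd for s in self.subjects],
                "duration_months": [s.duration_months for s in self.subjects],
            }
        )


def read_connectome(path: str | os.PathLike, labels: Sequence[str]) -> Connectome:
    """Read a whitespace- or comma-delimited N×N weight matrix.

    Validation failures (non-square, asymmetric beyond 1e-9, negative or
    non-finite entries, dimension mismatch with *labels*) raise ``ValueError``.
    """
    try:
        W = np.loadtxt(path, delimiter=None)
    except ValueError:
        W = np.loadtxt(path, delimiter=",")
    W = np.atleast_2d(np.asarray(W, dtype=float))
    return Connectome(labels=tuple(labels), W=W)


def write_connectome(c: Connectome, path: str | os.PathLike) -> None:
    """Write the weight matrix as TSV; integer weights are written as integers."""
    W = c.W
    if np.all(W == np.round(W)):
        np.savetxt(path, W.astype(np.int64), fmt="%d", delimiter="\t")
    else:
        np.savetxt(path, W, fmt="%.12g", delimiter="\t")


def read_labels(path: str | os.PathLike) -> tuple[str, ...]:
    """One region name per line (AAL-style, e.g. ``Precentral_L``)."""
    with open(path) as fh:
        labels = tuple(line.strip() for line in fh if line.strip())
    if not labels:
        raise ValueError(f"label file {path!s} is empty")
    return labels


def write_labels(labels: Sequence[str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("\n".join(labels) + "\n")


def find_isolated_nodes(c: Connectome) -> list[int]:
    """Indices of nodes with degree zero (no strictly positive weight).

    An empty list means the network is fully usable for path-based metrics.
    """
    return list(np.flatnonzero(c.degrees == 0))


def _parse_optional(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and value.strip() in ("", "NA", "nan", "None"):
        return None
    return float(value)


def read_manifest(
    path: str | os.PathLike,
    labels: Sequence[str],
    matrix_dir: str | os.PathLike | None = None,
) -> Cohort:
    """Load a subject manifest CSV and every referenced matrix.

    The manifest must have columns ``subject_id, group, age, gender, pdss,
    hamd, duration_months, matrix_file``; ``matrix_file`` paths are resolved
    relative to *matrix_dir* (default: the manifest's directory).  PDSS may be
    missing for HC subjects only.
    """
    path = os.fspath(path)
    if matrix_dir is None:
        matrix_dir = os.path.dirname(path) or "."
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    subjects = []
    for idx, row in df.iterrows():
        if row["group"] not in ("PD", "HC"):
            raise ValueError(
                f"manifest row {idx} (subject {row['subject_id']!r}): "
                f"unknown group {row['group']!r}"
            )
        mpath = os.path.join(matrix_dir, row["matrix_file"])
        if not os.path.exists(mpath):
            raise FileNotFoundError(
                f"manifest row {idx} (subject {row['subject_id']!r}): "
                f"matrix file {mpath!s} not found"
            )
        pdss = _parse_optional(row["pdss"])
        if pdss is None and row["group"] == "PD":
            raise ValueError(
                f"manifest row {idx} (subject {row['subject_id']!r}): "
                "PDSS is required for PD subjects"
            )
        subjects.append(
            SubjectRecord(
                subject_id=str(row["subject_id"]),
                group=str(row["group"]),
                age=float(row["age"]),
                gender=str(row["gender"]),
                pdss=pdss,
                hamd=float(row["hamd"]),
                duration_months=_parse_optional(row["duration_months"]),
                connectome=read_connectome(mpath, labels),
            )
        )
    return Cohort(subjects=tuple(subjects))


def write_cohort(cohort: Cohort, out_dir: str | os.PathLike) -> str:
    """Write matrices, the label list and the manifest CSV; returns manifest path."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    write_labels(cohort.labels, os.path.join(out_dir, "labels.txt"))
    rows = []
    for s in cohort.subjects:
        fname = f"{s.subject_id}.tsv"
        write_connectome(s.connectome, os.path.join(out_dir, fname))
        rows.append(
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "age": s.age,
                "gender": s.gender,
                "pdss": s.pdss,
                "hamd": s.hamd,
                "duration_months": s.duration_months,
                "matrix_file": fname,
            }
        )
    manifest = os.path.join(out_dir, "manifest.csv")
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest
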