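"""Subject-level structural connectivity matrices.

Probabilistic tractography seeds a fixed number of streamline samples per
voxel (``samples_per_voxel``, conventionally 5000) in every atlas region.
The directed connectivity strength from region *i* to region *j* is the
streamline count ``m_ij`` normalized by the total number of samples seeded
in *i* (``samples_per_voxel * n_i`` for a region of ``n_i`` voxels).  The
undirected strength of an edge is the average of its two directed
estimates, and a fixed floor (default 0.01) zeroes entries too weak to be
distinguished from tracking noise.  The result is a symmetric, zero-diagonal
matrix with all entries in ``[0, 1]``.

This module also fixes the edge <-> feature-vector bijection used by the
classification stages: unordered pairs ``{i, j}`` with ``i < j`` are laid
out in row-major upper-triangle order, giving ``R(R-1)/2`` features
(4005 for a 90-region atlas).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_SAMPLES_PER_VOXEL = 5000
DEFAULT_THRESHOLD = 0.01

PATIENT = "patient"
CONTROL = "control"
VALID_LABELS = (PATIENT, CONTROL)


# ---------------------------------------------------------------------------
# Region atlas
# ---------------------------------------------------------------------------

class RegionAtlas:
    """Parcellation lookup table: 1-based region index -> name/abbrev/side/lobe.

    The packaged default is the 90-region automated anatomical labeling
    (AAL) cerebrum parcellation, 45 regions per hemisphere, with a coarse
    lobe tag per region (frontal / limbic / occipital / parietal /
    temporal) used only for annotating reported connections.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"index", "name", "abbrev", "hemisphere", "lobe"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"atlas table missing columns: {sorted(missing)}")
        table = table.sort_values("index").reset_index(drop=True)
        idx = table["index"].to_numpy()
        if len(np.unique(idx)) != len(idx):
            raise ValueError("atlas region indices are not unique")
        if not np.array_equal(idx, np.arange(1, len(idx) + 1)):
            raise ValueError("atlas indices must be contiguous from 1")
        self.table = table

    @classmethod
    def aal90(cls) -> "RegionAtlas":
        """Load the packaged 90-region AAL atlas."""
        with resources.files("connclass.data").joinpath("aal90.csv").open() as fh:
            atlas = cls(pd.read_csv(fh))
        counts = atlas.table["hemisphere"].value_counts()
        assert counts.get("L") == 45 and counts.get("R") == 45
        return atlas

    @property
    def n_regions(self) -> int:
        return len(self.table)

    def _row(self, index: int) -> pd.Series:
        if not 1 <= index <= self.n_regions:
            raise IndexError(f"region index {index} outside 1..{self.n_regions}")
        return self.table.iloc[index - 1]

    def name(self, index: int) -> str:
        return str(self._row(index)["name"])

    def abbrev(self, index: int) -> str:
        return str(self._row(index)["abbrev"])

    def hemisphere(self, index: int) -> str:
        return str(self._row(index)["hemisphere"])

    def lobe(self, index: int) -> str:
        return str(self._row(index)["lobe"])

    def label(self, index: int) -> str:
        """Human-readable label, e.g. ``"Hippocampus L"``."""
        row = self._row(index)
        return f"{row['name']} {row['hemisphere']}"


# ---------------------------------------------------------------------------
# Fiber counts and strengths
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FiberCountData:
    """Directed streamline counts for one subject.

    ``counts[i, j]`` is the number of streamlines seeded in region ``i``
    that reached region ``j`` (the diagonal is unused).  ``voxel_counts[i]``
    is the voxel size ``n_i`` of region ``i``; ``samples_per_voxel`` is the
    number of streamline samples seeded per voxel.
    """

    counts: np.ndarray
    voxel_counts: np.ndarray
    samples_per_voxel: int = DEFAULT_SAMPLES_PER_VOXEL

    def __post_init__(self):
        counts = np.asarray(self.counts)
        voxels = np.asarray(self.voxel_counts)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "voxel_counts", voxels)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError(f"counts must be square, got shape {counts.shape}")
        if voxels.shape != (counts.shape[0],):
            raise ValueError("voxel_counts length must match counts dimension")
        if np.any(voxels <= 0):
            raise ValueError("voxel_counts must be positive")
        if self.samples_per_voxel <= 0:
            raise ValueError("samples_per_voxel must be positive")
        if np.any(counts < 0):
            raise ValueError("fiber counts must be nonnegative")
        ceiling = self.samples_per_voxel * voxels[:, None]
        if np.any(counts > ceiling):
            raise ValueError("count exceeds samples seeded in its region")

    @property
    def n_regions(self) -> int:
        return self.counts.shape[0]


def directed_strength(data: FiberCountData, i: int, j: int) -> float:
    """Strength of the directed connection i -> j (0-based regions).

    Defined as ``m_ij / (samples_per_voxel * n_i)``, the fraction of the
    samples seeded in region ``i`` that reached region ``j``; lies in [0, 1].
    """
    if i == j:
        raise ValueError("directed strength is undefined on the diagonal")
    denom = data.samples_per_voxel * float(data.voxel_counts[i])
    return float(data.counts[i, j]) / denom


@dataclass
class ConnectivityMatrix:
    """Symmetric, thresholded, normalized connectivity matrix."""

    strengths: np.ndarray
    threshold: float = DEFAULT_THRESHOLD
    atlas: RegionAtlas | None = None

    def __post_init__(self):
        self.strengths = np.asarray(self.strengths, dtype=float)
        self.validate()

    def validate(self) -> None:
        s = self.strengths
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValueError(f"strength matrix must be square, got {s.shape}")
        if not np.allclose(s, s.T, atol=1e-12):
            raise ValueError("strength matrix must be symmetric")
        if np.any(np.diag(s) != 0):
            raise ValueError("diagonal entries must be zero")
        if np.any(s < 0):
            raise ValueError("strengths must be nonnegative")
        if np.any(s > 1 + 1e-12):
            raise ValueError("strengths must not exceed 1")
        nz = s[s > 0]
        if nz.size and nz.min() < self.threshold - 1e-12:
            raise ValueError(
                f"nonzero strength {nz.min():g} below threshold {self.threshold:g}"
            )
        if self.atlas is not None and self.atlas.n_regions != s.shape[0]:
            raise ValueError("atlas size does not match matrix size")

    @property
    def n_regions(self) -> int:
        return self.strengths.shape[0]


def build_matrix(
    data: FiberCountData,
    threshold: float = DEFAULT_THRESHOLD,
    atlas: RegionAtlas | None = None,
) -> ConnectivityMatrix:
    """Symmetrize directed strengths and apply the strength floor.

    Each unordered edge {i, j} gets the mean of its two directed strengths;
    entries below ``threshold`` are then zeroed (thresholding happens after
    averaging).
    """
    denom = data.samples_per_voxel * data.voxel_counts.astype(float)[:, None]
    directed = data.counts / denom
    sym = 0.5 * (directed + directed.T)
    np.fill_diagonal(sym, 0.0)
    sym[sym < threshold] = 0.0
    return ConnectivityMatrix(sym, threshold=threshold, atlas=atlas)


# ---------------------------------------------------------------------------
# Edge <-> feature-vector bijection
# ---------------------------------------------------------------------------

class EdgeIndex:
    """Bijection between unordered region pairs and feature positions.

    Pairs {i, j} with i < j (0-based) are enumerated in row-major
    upper-triangle order: (0,1), (0,2), ..., (0,R-1), (1,2), ...
    """

    def __init__(self, n_regions: int):
        if n_regions < 2:
            raise ValueError("need at least two regions")
        self.n_regions = n_regions
        self._rows, self._cols = np.triu_indices(n_regions, k=1)
        self._pos = {}
        for pos, (i, j) in enumerate(zip(self._rows, self._cols)):
            self._pos[(int(i), int(j))] = pos

    @property
    def n_edges(self) -> int:
        return self._rows.size

    def position(self, i: int, j: int) -> int:
        if i == j:
            raise ValueError("diagonal pairs have no feature position")
        a, b = (i, j) if i < j else (j, i)
        try:
            return self._pos[(a, b)]
        except KeyError:
            raise IndexError(f"pair ({i}, {j}) outside atlas of {self.n_regions}")

    def pair(self, position: int) -> tuple[int, int]:
        return int(self._rows[position]), int(self._cols[position])

    def pairs(self) -> np.ndarray:
        """(n_edges, 2) array of 0-based (i, j) pairs, i < j."""
        return np.column_stack([self._rows, self._cols])


def vectorize(matrix: ConnectivityMatrix | np.ndarray) -> np.ndarray:
    """Flatten the upper triangle of a symmetric matrix into a feature vector."""
    s = matrix.strengths if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    if s.ndim != 2 or s.shape[0] != s.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {s.shape}")
    if not np.allclose(s, s.T, atol=1e-12):
        raise ValueError("cannot vectorize an asymmetric matrix")
    rows, cols = np.triu_indices(s.shape[0], k=1)
    return s[rows, cols].copy()


def devectorize(vector: np.ndarray, n_regions: int | None = None) -> np.ndarray:
    """Inverse of :func:`vectorize`; rebuilds the symmetric zero-diagonal matrix."""
    vector = np.asarray(vector)
    if n_regions is None:
        # solve R(R-1)/2 = len
        n_regions = int(round((1 + np.sqrt(1 + 8 * vector.size)) / 2))
    if n_regions * (n_regions - 1) // 2 != vector.size:
        raise ValueError(f"vector of length {vector.size} is not an upper triangle")
    out = np.zeros((n_regions, n_regions), dtype=float)
    rows, cols = np.triu_indices(n_regions, k=1)
    out[rows, cols] = vector
    out[cols, rows] = vector
    return out


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    """Labeled collection of per-subject connectivity matrices."""

    matrices: list[np.ndarray]
    labels: np.ndarray
    subject_ids: list[str] = field(default_factory=list)
    threshold: float = DEFAULT_THRESHOLD
    atlas: RegionAtlas | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        if len(self.matrices) != len(self.labels):
            raise ValueError("one label per subject required")
        bad = set(self.labels) - set(VALID_LABELS)
        if bad:
            raise ValueError(f"unknown labels {sorted(bad)}; expected {VALID_LABELS}")
        if not self.subject_ids:
            self.subject_ids = [f"sub{i:03d}" for i in range(len(self.matrices))]
        shapes = {m.shape for m in self.matrices}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent matrix shapes across subjects: {shapes}")

    def __len__(self) -> int:
        return len(self.matrices)

    @property
    def n_regions(self) -> int:
        return self.matrices[0].shape[0]

    @property
    def y(self) -> np.ndarray:
        """Numeric labels, patient = 1 (positive class), control = 0."""
        return (self.labels == PATIENT).astype(int)

    @property
    def n_patients(self) -> int:
        return int(np.sum(self.labels == PATIENT))

    @property
    def n_controls(self) -> int:
        return int(np.sum(self.labels == CONTROL))

    def feature_matrix(self) -> np.ndarray:
        """Stack vectorized matrices into an (n_subjects, n_edges) array."""
        return np.vstack([vectorize(m) for m in self.matrices])

    def group(self, label: str) -> list[np.ndarray]:
        return [m for m, l in zip(self.matrices, self.labels) if l == label]

    def relabeled(self, labels: Sequence[str]) -> "Cohort":
        """Same subjects with a new label vector (used by permutation tests)."""
        return Cohort(
            matrices=self.matrices,
            labels=np.asarray(labels, dtype=object),
            subject_ids=list(self.subject_ids),
            threshold=self.threshold,
            atlas=self.atlas,
        )


def read_matrix(path: str | Path) -> np.ndarray:
    """Read a whitespace- or comma-delimited numeric matrix."""
    text = Path(path).read_text()
    delimiter = "," if "," in text.splitlines()[0] else None
    return np.atleast_2d(np.loadtxt(io.StringIO(text), delimiter=delimiter))


def write_matrix(path: str | Path, matrix: np.ndarray) -> None:
    np.savetxt(path, np.asarray(matrix), fmt="%.10g", delimiter=",")


def load_cohort(
    manifest: str | Path,
    threshold: float = DEFAULT_THRESHOLD,
    atlas: RegionAtlas | None = None,
    validate: bool = True,
) -> Cohort:
    """Load a cohort from a manifest CSV with columns subject_id,label,path.

    Relative paths are resolved against the manifest's directory.  Each
    matrix is checked against the connectivity-matrix invariants (symmetry,
    zero diagonal, entries in [0,1], nonzeros >= threshold); the diagonal is
    forced to zero on read.
    """
    manifest = Path(manifest)
    table = pd.read_csv(manifest)
    required = {"subject_id", "label", "path"}
    if not required <= set(table.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    matrices, labels, ids = [], [], []
    n_regions = None
    for _, row in table.iterrows():
        label = str(row["label"]).strip().lower()
        if label not in VALID_LABELS:
            raise ValueError(
                f"{row['path']}: unknown label {row['label']!r}; expected {VALID_LABELS}"
            )
        path = Path(row["path"])
        if not path.is_absolute():
            path = manifest.parent / path
        mat = read_matrix(path)
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise ValueError(f"{path}: matrix is {mat.shape[0]}x{mat.shape[1]}, not square")
        if n_regions is None:
            n_regions = mat.shape[0]
        elif mat.shape[0] != n_regions:
            raise ValueError(
                f"{path}: matrix is {mat.shape[0]}x{mat.shape[1]}, "
                f"expected {n_regions}x{n_regions}"
            )
        np.fill_diagonal(mat, 0.0)
        if validate:
            try:
                ConnectivityMatrix(mat, threshold=threshold, atlas=atlas)
            except ValueError as exc:
                raise ValueError(f"{path}: {exc}") from exc
        matrices.append(mat)
        labels.append(label)
        ids.append(str(row["subject_id"]))
    if not matrices:
        raise ValueError(f"{manifest}: empty manifest")
    return Cohort(matrices, np.asarray(labels, dtype=object), ids,
                  threshold=threshold, atlas=atlas)
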