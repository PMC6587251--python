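"""Numerical characteristics of CGR curves.

Each curve is split by quadrant; the pairwise Euclidean distance matrix
of the points in each quadrant is summarised by its leading eigenvalue
(real and non-negative for a symmetric non-negative matrix, by
Perron-Frobenius).  One curve yields 4 numbers; a k-index catalog yields
a 4k-dimensional feature vector per sequence (632 for k = 158).  The
frequency-only variant (point counts per quadrant divided by curve
length) is kept as an ablation baseline: it discards the within-quadrant
distribution information that the eigenvalue captures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

import numpy as np
from scipy.linalg import eigh
from scipy.sparse.linalg import eigsh
from scipy.spatial.distance import pdist, squareform

from .aaindex import IndexCatalog
from .cgr import CGRCurve, arrange_amino_acids, build_cgr_curve

#: Above this size the dense symmetric solver gives way to a Lanczos
#: largest-eigenpair iteration (tolerance 1e-10).
_DENSE_LIMIT = 512


@dataclass(frozen=True)
class QuadrantPartition:
    """Curve points split by quadrant, with the half-open convention
    Q1: x>0, y>=0;  Q2: x<=0, y>0;  Q3: x<0, y<=0;  Q4: x>=0, y<0."""

    groups: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return tuple(len(g) for g in self.groups)


def assign_quadrants(curve: CGRCurve) -> QuadrantPartition:
    """Partition a curve's points into the four quadrants (total: no point
    lies at the origin, so every point lands in exactly one group)."""
    if curve.length == 0:
        raise ValueError("empty curve")
    x, y = curve.points[:, 0], curve.points[:, 1]
    masks = (
        (x > 0) & (y >= 0),
        (x <= 0) & (y > 0),
        (x < 0) & (y <= 0),
        (x >= 0) & (y < 0),
    )
    return QuadrantPartition(tuple(curve.points[m] for m in masks))


def pairwise_distance_matrix(points: np.ndarray | Sequence) -> np.ndarray:
    """Euclidean distance matrix of a point set; empty input gives a 0x0
    matrix and a single point gives [[0]]."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n == 0:
        return np.zeros((0, 0))
    if n == 1:
        return np.zeros((1, 1))
    return squareform(pdist(pts))


def leading_eigenvalue(matrix: np.ndarray) -> float:
    """Largest eigenvalue of a symmetric non-negative matrix.

    Empty and 1x1 matrices return 0.  Dense symmetric decomposition up to
    512x512, Lanczos above; both return the same quantity to well below
    the 1e-10 iteration tolerance.

    Raises
    ------
    ValueError
        If the matrix is not symmetric.
    """
    m = np.asarray(matrix, dtype=float)
    n = m.shape[0]
    if m.shape != (n, n):
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    if n <= 1:
        return 0.0
    if not np.allclose(m, m.T, rtol=0.0, atol=1e-12):
        raise ValueError("matrix is not symmetric")
    if n <= _DENSE_LIMIT:
        return float(eigh(m, eigvals_only=True, subset_by_index=[n - 1, n - 1])[0])
    return float(eigsh(m, k=1, which="LA", tol=1e-10)[0][0])


def curve_features(curve: CGRCurve) -> np.ndarray:
    """4-vector of leading eigenvalues for quadrants Q1..Q4 of one curve."""
    part = assign_quadrants(curve)
    return np.array(
        [leading_eigenvalue(pairwise_distance_matrix(g)) for g in part.groups]
    )


def fcgr_baseline_features(curve: CGRCurve) -> np.ndarray:
    """Frequency ablation: quadrant point counts divided by curve length (Q1..Q4)."""
    part = assign_quadrants(curve)
    return np.array(part.counts, dtype=float) / curve.length


def sequence_features(
    sequence: str,
    catalog: IndexCatalog,
    sequence_id: str = "",
    baseline: bool = False,
    normalize_eigen: str = "none",
) -> np.ndarray:
    """Full feature vector of one sequence: 4 values per catalog index,
    concatenated in catalog order (quadrants Q1..Q4 within each index).

    ``normalize_eigen='by_n'`` divides each quadrant's eigenvalue by its
    point count; the default keeps raw eigenvalues, which grow with
    sequence length.  ``baseline=True`` swaps in the 4-frequency ablation.
    """
    if len(catalog) == 0:
        raise ValueError("empty catalog")
    if normalize_eigen not in ("none", "by_n"):
        raise ValueError(f"unknown normalize_eigen mode {normalize_eigen!r}")
    blocks = []
    for index in catalog:
        arrangement = arrange_amino_acids(index)
        curve = build_cgr_curve(sequence, arrangement, sequence_id=sequence_id)
        if baseline:
            blocks.append(fcgr_baseline_features(curve))
            continue
        part = assign_quadrants(curve)
        vals = np.array(
            [leading_eigenvalue(pairwise_distance_matrix(g)) for g in part.groups]
        )
        if normalize_eigen == "by_n":
            counts = np.array(part.counts, dtype=float)
            vals = np.divide(vals, counts, out=np.zeros_like(vals), where=counts > 0)
        blocks.append(vals)
    return np.concatenate(blocks)


@dataclass
class FeatureMatrix:
    """N sequences x 4k features; columns labelled ``<accession>_Q<1..4>``
    in catalog order."""

    sequence_ids: list[str]
    index_accessions: list[str]
    values: np.ndarray  # (N, 4k)

    @property
    def column_labels(self) -> list[str]:
        return [f"{acc}_Q{q}" for acc in self.index_accessions for q in (1, 2, 3, 4)]

    def write_tsv(self, stream: TextIO) -> None:
        stream.write("sequence_id\t" + "\t".join(self.column_labels) + "\n")
        for sid, row in zip(self.sequence_ids, self.values):
            stream.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def read_tsv(cls, stream: TextIO) -> "FeatureMatrix":
        header = stream.readline().rstrip("\n").split("\t")
        if header[0] != "sequence_id" or (len(header) - 1) % 4:
            raise ValueError("not a feature TSV: unexpected header")
        accessions = [c[:-3] for c in header[1::4]]
        ids, rows = [], []
        for line in stream:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
        return cls(ids, accessions, np.array(rows, dtype=float))


def feature_matrix(
    records: Iterable[tuple[str, str]],
    catalog: IndexCatalog,
    baseline: bool = False,
    normalize_eigen: str = "none",
) -> FeatureMatrix:
    """Feature matrix for (id, sequence) pairs under one catalog."""
    ids, rows = [], []
    for sid, seq in records:
        ids.append(sid)
        rows.append(
            sequence_features(
                seq, catalog, sequence_id=sid, baseline=baseline,
                normalize_eigen=normalize_eigen,
            )
        )
    return FeatureMatrix(ids, list(catalog.accessions), np.array(rows, dtype=float))
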