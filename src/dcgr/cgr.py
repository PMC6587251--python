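"""Chaos-game-representation curves on the unit circle.

A physicochemical index strictly orders the 20 amino acids; the amino
acid with the i-th smallest value is placed at vertex
(cos 2*pi*i/20, sin 2*pi*i/20), i = 1..20, counterclockwise from the
positive x axis.  A protein sequence then traces a curve by repeated
midpoint moves toward the vertex of each residue, starting from the
circle's centre:

    psi_0 = (0, 0),   psi_i = (psi_{i-1} + phi(s_i)) / 2.

Every curve point lies strictly inside the unit disk and never at the
origin, so downstream quadrant assignment is total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .aaindex import AMINO_ACIDS, PhysicochemicalIndex

logger = logging.getLogger(__name__)

#: Fixed 20-gon vertex positions, row i-1 = (cos 2*pi*i/20, sin 2*pi*i/20), i = 1..20.
_RANK_VERTICES = np.column_stack(
    [
        np.cos(2 * np.pi * np.arange(1, 21) / 20),
        np.sin(2 * np.pi * np.arange(1, 21) / 20),
    ]
)

_STANDARD = set(AMINO_ACIDS)


@dataclass(frozen=True)
class Arrangement:
    """Assignment of the 20 amino acids to the fixed unit-circle 20-gon.

    ``vertex[aa]`` is the planar coordinate of amino acid ``aa``.  Only the
    assignment varies between indices; the point set itself is always the
    same 20-gon.
    """

    index_accession: str
    vertex: dict[str, tuple[float, float]]

    def vertex_array(self) -> np.ndarray:
        """20 x 2 array of vertices in alphabetical amino-acid order."""
        return np.array([self.vertex[aa] for aa in AMINO_ACIDS])


@dataclass(frozen=True)
class CGRCurve:
    """CGR curve of one sequence under one arrangement: ordered points, one per residue."""

    sequence_id: str
    index_accession: str
    points: np.ndarray  # (N, 2)

    @property
    def length(self) -> int:
        return self.points.shape[0]


def arrange_amino_acids(index: PhysicochemicalIndex) -> Arrangement:
    """Place the 20 amino acids on the unit circle by ascending index value.

    The amino acid with the i-th smallest value gets vertex
    (cos 2*pi*i/20, sin 2*pi*i/20); the largest therefore sits at (1, 0).

    Raises
    ------
    ValueError
        If the index has missing or tied values (such indices must have
        been removed by the redundancy filter).
    """
    vals = index.value_array()
    if np.isnan(vals).any():
        raise ValueError(f"index {index.accession!r} has missing values")
    if len(np.unique(vals)) < 20:
        raise ValueError(f"index {index.accession!r} has tied values")
    order = np.argsort(vals)  # order[r] = alphabet position of the rank-(r+1) amino acid
    vertex = {
        AMINO_ACIDS[pos]: (float(_RANK_VERTICES[r, 0]), float(_RANK_VERTICES[r, 1]))
        for r, pos in enumerate(order)
    }
    return Arrangement(index_accession=index.accession, vertex=vertex)


def clean_sequence(sequence: str, strict: bool = False) -> str:
    """Uppercase a residue string and drop non-standard symbols.

    Residues outside the 20-letter alphabet (B, J, O, U, X, Z, gaps, ...)
    are skipped with a warning; with ``strict=True`` they raise instead.
    """
    seq = sequence.upper()
    bad = sorted({c for c in seq if c not in _STANDARD})
    if bad:
        if strict:
            raise ValueError(f"non-standard residues {bad} in sequence")
        logger.warning("skipping non-standard residues %s", bad)
        seq = "".join(c for c in seq if c in _STANDARD)
    return seq


def build_cgr_curve(
    sequence: str,
    arrangement: Arrangement,
    sequence_id: str = "",
    strict: bool = False,
) -> CGRCurve:
    """Build the CGR curve of a protein sequence under one arrangement.

    Point i is the midpoint of point i-1 and the vertex of residue i;
    the iteration starts at the origin, so point 1 is half the first
    residue's vertex.  The recursion is evaluated as the linear filter
    y_i = 0.5 * y_{i-1} + 0.5 * x_i applied to the vertex coordinates.

    Raises
    ------
    ValueError
        If the sequence is empty after residue filtering.
    """
    seq = clean_sequence(sequence, strict=strict)
    if not seq:
        raise ValueError(f"sequence {sequence_id!r}: no encodable residues")
    verts = arrangement.vertex_array()
    codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lookup = np.full(128, -1, dtype=np.int64)
    for pos, aa in enumerate(AMINO_ACIDS):
        lookup[ord(aa)] = pos
    targets = verts[lookup[codes]]  # (N, 2) vertex of each residue
    points = lfilter([0.5], [1.0, -0.5], targets, axis=0)
    return CGRCurve(
        sequence_id=sequence_id,
        index_accession=arrangement.index_accession,
        points=points,
    )


def write_curve_tsv(curve: CGRCurve, stream) -> None:
    """Export a curve as TSV (sequence_id, index_accession, i, x, y) for plotting."""
    stream.write("sequence_id\tindex_accession\ti\tx\ty\n")
    for i, (x, y) in enumerate(curve.points, start=1):
        stream.write(
            f"{curve.sequence_id}\t{curve.index_accession}\t{i}\t"
            f"{float(x)!r}\t{float(y)!r}\n"
        )
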