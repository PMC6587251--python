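"""AAindex physicochemical amino-acid index catalogs.

An amino-acid index assigns one real number to each of the 20 standard
amino acids (hydropathy, volume, polarity, ...).  The AAindex database
distributes these as flat-text records ("aaindex1" format).  This module
parses that format, filters out indices that cannot induce a strict
ordering of the alphabet (missing values, or ties between amino acids),
and provides a deterministic synthetic catalog for self-contained runs.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, TextIO

import numpy as np

logger = logging.getLogger(__name__)

#: The 20 standard amino acids, alphabetical one-letter codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Column order of the two value rows under an AAindex1 "I" line:
# header reads A/L R/K N/M D/F C/P Q/S E/T G/W H/Y I/V.
_I_ROW1 = "ARNDCQEGHI"
_I_ROW2 = "LKMFPSTVWY"


class AAindexParseError(ValueError):
    """Raised on a malformed AAindex1 record; message names accession and line."""


@dataclass(frozen=True)
class PhysicochemicalIndex:
    """One amino-acid index: accession, description and 20 values.

    ``values`` maps every standard one-letter code to a float; missing
    database entries are stored as ``nan`` and flagged by ``complete``.
    """

    accession: str
    description: str
    values: dict[str, float]
    complete: bool

    def __post_init__(self) -> None:
        if set(self.values) != set(AMINO_ACIDS):
            raise ValueError(
                f"index {self.accession!r}: values must cover exactly {AMINO_ACIDS}"
            )

    def value_array(self) -> np.ndarray:
        """Values in alphabetical amino-acid order."""
        return np.array([self.values[aa] for aa in AMINO_ACIDS])

    @property
    def has_ties(self) -> bool:
        """True if two amino acids share a value (or any value is missing)."""
        v = self.value_array()
        if np.isnan(v).any():
            return True
        return len(np.unique(v)) < len(v)


@dataclass
class IndexCatalog:
    """Ordered collection of :class:`PhysicochemicalIndex` (source file order)."""

    indices: list[PhysicochemicalIndex] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self) -> Iterable[PhysicochemicalIndex]:
        return iter(self.indices)

    def __getitem__(self, key):
        if isinstance(key, str):
            for idx in self.indices:
                if idx.accession == key:
                    return idx
            raise KeyError(key)
        return self.indices[key]

    @property
    def accessions(self) -> list[str]:
        return [idx.accession for idx in self.indices]


def parse_aaindex1(stream: TextIO | str) -> IndexCatalog:
    """Parse zero or more AAindex1 flat-file records into a catalog.

    Records carry ``H`` (accession), ``D`` (description) and ``I`` lines;
    the two rows of ten values under ``I`` follow the database's column
    order (A R N D C Q E G H I / L K M F P S T V W Y).  ``NA`` marks a
    missing value.  Duplicate accessions keep the first occurrence with a
    warning.

    Raises
    ------
    AAindexParseError
        On a wrong value count or an unparsable token, naming the
        offending accession and line number.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)

    catalog = IndexCatalog()
    seen: set[str] = set()

    accession = ""
    description_parts: list[str] = []
    value_tokens: list[str] = []
    in_values = False
    in_record = False

    def finish(lineno: int) -> None:
        nonlocal accession, description_parts, value_tokens, in_values, in_record
        if not in_record:
            return
        if len(value_tokens) != 20:
            raise AAindexParseError(
                f"record {accession or '<no accession>'!r} ending at line {lineno}: "
                f"expected 20 values, got {len(value_tokens)}"
            )
        values: dict[str, float] = {}
        for aa, tok in zip(_I_ROW1 + _I_ROW2, value_tokens):
            if tok.upper() in {"NA", "NA."}:
                values[aa] = float("nan")
            else:
                try:
                    values[aa] = float(tok)
                except ValueError as exc:
                    raise AAindexParseError(
                        f"record {accession!r} near line {lineno}: bad token {tok!r}"
                    ) from exc
        complete = not any(np.isnan(v) for v in values.values())
        idx = PhysicochemicalIndex(
            accession=accession,
            description=" ".join(description_parts),
            values=values,
            complete=complete,
        )
        if accession in seen:
            logger.warning("duplicate accession %s: keeping first occurrence", accession)
        else:
            seen.add(accession)
            catalog.indices.append(idx)
        accession, description_parts, value_tokens = "", [], []
        in_values = in_record = False

    lineno = 0
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        tag, rest = line[:1], line[2:] if len(line) > 2 else ""
        if line.startswith("//"):
            finish(lineno)
            continue
        if tag == "H" and not line.startswith(" "):
            in_record = True
            accession = rest.strip()
            in_values = False
        elif tag == "D" and not line.startswith(" "):
            description_parts.append(rest.strip())
            in_values = False
        elif tag == "I" and not line.startswith(" "):
            in_record = True
            in_values = True
        elif line.startswith(" ") or line.startswith("\t"):
            if in_values:
                value_tokens.extend(line.split())
        else:
            # other record lines (R, A, T, J, C, *) end any value block
            in_values = False
            in_record = in_record or tag.isalpha()
    if in_record:
        raise AAindexParseError(
            f"record {accession or '<no accession>'!r}: unterminated (missing '//') "
            f"at line {lineno}"
        )
    return catalog


def filter_nonredundant(catalog: IndexCatalog) -> IndexCatalog:
    """Drop indices with missing values or with any value shared by two amino acids.

    An index only induces a usable circle arrangement when its 20 values
    can be strictly sorted; ties make the ordering ambiguous, and missing
    values make it undefined.  Order is preserved; the operation is
    idempotent.  An empty result triggers a warning, not an error.
    """
    kept = [idx for idx in catalog if idx.complete and not idx.has_ties]
    if not kept:
        warnings.warn("redundancy filter removed every index", stacklevel=2)
    return IndexCatalog(kept)


def synthetic_catalog(n: int = 158, seed: int = 20) -> IndexCatalog:
    """Deterministic synthetic catalog of ``n`` complete, tie-free indices.

    A stand-in for a curated non-redundant AAindex selection: each entry
    assigns 20 distinct values drawn from a seeded generator, standardised
    to zero mean and unit variance (AAindex scales vary arbitrarily, so
    only the induced amino-acid ordering matters downstream).  The default
    ``n=158`` matches the size of a fully de-duplicated working catalog,
    giving 4 x 158 = 632 features per sequence.
    """
    rng = np.random.default_rng(seed)
    indices = []
    for j in range(n):
        while True:
            vals = rng.normal(size=20)
            if len(np.unique(vals)) == 20:
                break
        vals = (vals - vals.mean()) / vals.std()
        indices.append(
            PhysicochemicalIndex(
                accession=f"SYNX{j + 1:03d}01",
                description=f"Synthetic physicochemical scale {j + 1}",
                values=dict(zip(AMINO_ACIDS, vals.tolist())),
                complete=True,
            )
        )
    return IndexCatalog(indices)


def write_catalog_tsv(catalog: IndexCatalog, stream: TextIO) -> None:
    """Dump a catalog as TSV: accession, description, then one column per amino acid."""
    stream.write("accession\tdescription\t" + "\t".join(AMINO_ACIDS) + "\n")
    for idx in catalog:
        vals = "\t".join(repr(idx.values[aa]) for aa in AMINO_ACIDS)
        stream.write(f"{idx.accession}\t{idx.description}\t{vals}\n")


def read_catalog_tsv(stream: TextIO) -> IndexCatalog:
    """Read a catalog written by :func:`write_catalog_tsv`."""
    header = stream.readline().rstrip("\n").split("\t")
    if header[:2] != ["accession", "description"] or header[2:] != list(AMINO_ACIDS):
        raise ValueError("not a catalog TSV: unexpected header")
    indices = []
    for line in stream:
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        accession, description, vals = parts[0], parts[1], parts[2:]
        values = {aa: float(v) for aa, v in zip(AMINO_ACIDS, vals)}
        complete = not any(np.isnan(v) for v in values.values())
        indices.append(PhysicochemicalIndex(accession, description, values, complete))
    return IndexCatalog(indices)
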