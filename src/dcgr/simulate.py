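"""Synthetic protein families for end-to-end testing without downloads.

A common ancestor is mutated once per family (at the between-family
rate) to give family roots, and each root is mutated independently per
descendant (at the within-family rate).  Mutation replaces each selected
site with a letter drawn uniformly from the full 20-letter alphabet, so
a per-site rate p changes a site with probability p * 19/20 and two
descendants of one root differ at an expected fraction of roughly
2 * p * 19/20 of sites (ignoring double hits).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .aaindex import AMINO_ACIDS
from .io import SequenceRecord

_ALPHABET = np.frombuffer(AMINO_ACIDS.encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticFamilySpec:
    """Parameters of one synthetic-family draw.

    ``within_divergence`` and ``between_divergence`` are per-site
    substitution probabilities in [0, 1]; meaningful family-recovery
    tests need within < between.
    """

    n_families: int = 3
    seqs_per_family: int = 5
    root_length: int = 300
    within_divergence: float = 0.05
    between_divergence: float = 0.40
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_divergence", "between_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if min(self.n_families, self.seqs_per_family, self.root_length) < 1:
            raise ValueError("family count, family size and length must be >= 1")


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    out[hit] = rng.choice(_ALPHABET, size=int(hit.sum()))
    return out


def generate_synthetic_families(spec: SyntheticFamilySpec) -> list[SequenceRecord]:
    """Draw ``n_families * seqs_per_family`` sequences; ids encode membership
    as ``fam<F>_seq<S>``.  Fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    ancestor = rng.choice(_ALPHABET, size=spec.root_length)
    records = []
    for f in range(1, spec.n_families + 1):
        root = _mutate(ancestor, spec.between_divergence, rng)
        for s in range(1, spec.seqs_per_family + 1):
            child = _mutate(root, spec.within_divergence, rng)
            records.append(
                SequenceRecord(
                    id=f"fam{f}_seq{s}",
                    description=f"synthetic family {f} member {s}",
                    residues=child.tobytes().decode("ascii"),
                )
            )
    return records
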