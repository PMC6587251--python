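"""End-to-end convenience wrapper: features -> PCA -> distances -> tree."""

from __future__ import annotations

from dataclasses import dataclass

import dendropy

from .aaindex import IndexCatalog
from .features import FeatureMatrix, feature_matrix
from .io import SequenceRecord
from .similarity import (
    ReducedFeatures,
    SequenceDistanceMatrix,
    build_tree,
    distance_matrix,
    pca_reduce,
)


@dataclass
class PipelineResult:
    features: FeatureMatrix
    reduced: ReducedFeatures
    distances: SequenceDistanceMatrix
    tree: dendropy.Tree


def run_pipeline(
    records: list[SequenceRecord],
    catalog: IndexCatalog,
    n_components: int = 6,
    metric: str = "euclidean",
    method: str = "upgma",
    baseline: bool = False,
    normalize_eigen: str = "none",
    scale: bool = False,
) -> PipelineResult:
    """Run feature extraction, PCA, distance computation and tree building.

    ``n_components`` is clipped to the feasible maximum min(N, columns)
    when it exceeds it, since small data sets cannot support 6 components.
    """
    feats = feature_matrix(
        [(r.id, r.residues) for r in records],
        catalog,
        baseline=baseline,
        normalize_eigen=normalize_eigen,
    )
    c = min(n_components, min(feats.values.shape))
    reduced = pca_reduce(feats, n_components=c, scale=scale)
    dist = distance_matrix(reduced, metric=metric)
    tree = build_tree(dist, method=method)
    return PipelineResult(feats, reduced, dist, tree)


def family_recovery_study(
    seeds: list[int],
    catalog: IndexCatalog,
    baseline: bool = False,
    n_components: int = 6,
    metric: str = "euclidean",
    method: str = "upgma",
    **family_kwargs,
) -> list[bool]:
    """For each seed, draw synthetic families, run the pipeline and record
    whether every family came back as a clade in the tree.

    ``family_kwargs`` override :class:`~dcgr.simulate.SyntheticFamilySpec`
    defaults (3 families x 5 descendants, 300 residues, 5% within / 40%
    between divergence).
    """
    from .simulate import SyntheticFamilySpec, generate_synthetic_families

    outcomes = []
    for seed in seeds:
        spec = SyntheticFamilySpec(seed=seed, **family_kwargs)
        records = generate_synthetic_families(spec)
        families: dict[str, list[str]] = {}
        for rec in records:
            families.setdefault(rec.id.split("_")[0], []).append(rec.id)
        result = run_pipeline(
            records, catalog, n_components=n_components, metric=metric,
            method=method, baseline=baseline,
        )
        outcomes.append(families_are_clades(result.tree, families))
    return outcomes


def families_are_clades(tree: dendropy.Tree, families: dict[str, list[str]]) -> bool:
    """True iff every family's leaf set forms a clade (is monophyletic) in ``tree``."""
    for members in families.values():
        taxa = [t for t in tree.taxon_namespace if t.label in set(members)]
        if len(taxa) != len(members):
            return False
        mrca = tree.mrca(taxa=taxa)
        if len(mrca.leaf_nodes()) != len(members):
            return False
    return True
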