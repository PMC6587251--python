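"""Similarity analysis: PCA reduction, inter-sequence distances, trees.

Feature vectors are high-dimensional (4 per index, 632 for a 158-index
catalog) and partly redundant, so they are first projected onto a few
principal components; pairwise distances between the reduced vectors —
Euclidean, Manhattan, cosine or standardized Euclidean — then drive
distance-based tree construction (UPGMA by default, neighbor joining as
an alternative).  Merge ties are broken by the lexicographically
smallest leaf label so that identical inputs always yield identical
trees, regardless of row order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TextIO

import dendropy
import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.decomposition import PCA

METRICS = ("euclidean", "manhattan", "cosine", "seuclidean")


@dataclass
class ReducedFeatures:
    """PCA scores: N sequences x c components, plus per-component explained variance."""

    sequence_ids: list[str]
    components: np.ndarray  # (N, c)
    explained_variance: np.ndarray  # (c,) non-increasing

    def write_tsv(self, stream: TextIO) -> None:
        c = self.components.shape[1]
        stream.write("sequence_id\t" + "\t".join(f"PC{i+1}" for i in range(c)) + "\n")
        ev = "\t".join(repr(float(v)) for v in self.explained_variance)
        stream.write(f"#explained_variance\t{ev}\n")
        for sid, row in zip(self.sequence_ids, self.components):
            stream.write(sid + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def read_tsv(cls, stream: TextIO) -> "ReducedFeatures":
        stream.readline()  # header
        ids, rows, ev = [], [], None
        for line in stream:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "#explained_variance":
                ev = np.array([float(v) for v in parts[1:]])
                continue
            ids.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
        comps = np.array(rows, dtype=float)
        if ev is None:
            ev = np.full(comps.shape[1], np.nan)
        return cls(ids, comps, ev)


def pca_reduce(features, n_components: int, scale: bool = False) -> ReducedFeatures:
    """Project a feature matrix onto its top ``n_components`` principal components.

    Columns are mean-centered (optionally standardized with ``scale=True``);
    components follow a deterministic sign convention: the loading of
    largest magnitude in each component is made positive.

    Parameters
    ----------
    features : FeatureMatrix
        N x 4k feature matrix (any object with ``sequence_ids`` and ``values``).
    n_components : int
        Must satisfy ``1 <= n_components <= min(N, 4k)``.
    """
    X = np.asarray(features.values, dtype=float)
    n, p = X.shape
    bound = min(n, p)
    if not 1 <= n_components <= bound:
        raise ValueError(
            f"n_components={n_components} out of range: must be in [1, {bound}] "
            f"(min of {n} sequences and {p} columns)"
        )
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = (X - X.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(
        pca.components_[np.arange(n_components),
                        np.argmax(np.abs(pca.components_), axis=1)]
    )
    flip[flip == 0] = 1.0
    scores = scores * flip
    return ReducedFeatures(
        sequence_ids=list(features.sequence_ids),
        components=scores,
        explained_variance=pca.explained_variance_.copy(),
    )


@dataclass
class SequenceDistanceMatrix:
    """Symmetric, zero-diagonal N x N dissimilarity matrix with row labels."""

    labels: list[str]
    entries: np.ndarray  # (N, N)
    metric: str

    def write_tsv(self, stream: TextIO) -> None:
        stream.write("#metric\t" + self.metric + "\n")
        stream.write("\t" + "\t".join(self.labels) + "\n")
        for lab, row in zip(self.labels, self.entries):
            stream.write(lab + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def read_tsv(cls, stream: TextIO) -> "SequenceDistanceMatrix":
        metric = "unknown"
        first = stream.readline()
        if first.startswith("#metric"):
            metric = first.rstrip("\n").split("\t")[1]
            first = stream.readline()
        labels = first.rstrip("\n").split("\t")[1:]
        rows = []
        for line in stream:
            if line.strip():
                rows.append([float(v) for v in line.rstrip("\n").split("\t")[1:]])
        return cls(labels, np.array(rows, dtype=float), metric)

    def write_phylip(self, stream: TextIO) -> None:
        """Square PHYLIP distance matrix for interoperability."""
        stream.write(f"{len(self.labels)}\n")
        for lab, row in zip(self.labels, self.entries):
            stream.write(f"{lab:<10s} " + " ".join(f"{v:.6f}" for v in row) + "\n")


def distance_matrix(reduced: ReducedFeatures, metric: str) -> SequenceDistanceMatrix:
    """Pairwise distances between reduced feature vectors.

    ``seuclidean`` divides each coordinate by its sample (n-1) standard
    deviation across the N rows first; zero-variance coordinates are
    dropped with a warning (they contribute nothing to any pair).
    ``cosine`` refuses zero vectors, naming the offending sequence.
    """
    X = np.asarray(reduced.components, dtype=float)
    labels = list(reduced.sequence_ids)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 sequences")
    if metric == "euclidean":
        cond = pdist(X, "euclidean")
    elif metric == "manhattan":
        cond = pdist(X, "cityblock")
    elif metric == "cosine":
        norms = np.linalg.norm(X, axis=1)
        if (norms == 0).any():
            bad = labels[int(np.argmin(norms))]
            raise ValueError(f"cosine distance undefined for zero vector {bad!r}")
        cond = pdist(X, "cosine")
    elif metric == "seuclidean":
        sd = X.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            warnings.warn(
                f"dropping {int((~keep).sum())} zero-variance column(s) "
                "for standardized Euclidean distance",
                stacklevel=2,
            )
        if not keep.any():
            cond = np.zeros(len(labels) * (len(labels) - 1) // 2)
        else:
            cond = pdist(X[:, keep] / sd[keep], "euclidean")
    else:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    full = squareform(cond)
    return SequenceDistanceMatrix(labels=labels, entries=full, metric=metric)


def _new_leaf(taxon_namespace, label: str) -> dendropy.Node:
    node = dendropy.Node()
    node.taxon = taxon_namespace.require_taxon(label=label)
    return node


def _upgma(labels: list[str], d: np.ndarray, tns) -> dendropy.Tree:
    n = len(labels)
    nodes = {i: _new_leaf(tns, labels[i]) for i in range(n)}
    height = {i: 0.0 for i in range(n)}
    size = {i: 1 for i in range(n)}
    minlab = {i: labels[i] for i in range(n)}
    dist = {(min(i, j), max(i, j)): float(d[i, j]) for i in range(n) for j in range(i + 1, n)}
    active = set(range(n))
    nxt = n
    while len(active) > 1:
        best = None
        for (i, j), dij in dist.items():
            a, b = sorted((minlab[i], minlab[j]))
            key = (dij, a, b)
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        dij = dist[(min(i, j), max(i, j))]
        h = dij / 2.0
        parent = dendropy.Node()
        for child in sorted((i, j), key=lambda k: minlab[k]):
            nodes[child].edge.length = h - height[child]
            parent.add_child(nodes[child])
        nodes[nxt] = parent
        height[nxt] = h
        size[nxt] = size[i] + size[j]
        minlab[nxt] = min(minlab[i], minlab[j])
        active -= {i, j}
        for k in active:
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            dist[(min(nxt, k), max(nxt, k))] = (
                size[i] * dik + size[j] * djk
            ) / (size[i] + size[j])
        del dist[(min(i, j), max(i, j))]
        active.add(nxt)
        nxt += 1
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = nodes[active.pop()]
    tree.is_rooted = True
    return tree


def _nj(labels: list[str], d: np.ndarray, tns) -> dendropy.Tree:
    n = len(labels)
    nodes = {i: _new_leaf(tns, labels[i]) for i in range(n)}
    minlab = {i: labels[i] for i in range(n)}
    D = {(min(i, j), max(i, j)): float(d[i, j]) for i in range(n) for j in range(i + 1, n)}
    active = list(range(n))
    nxt = n

    def dd(i, j):
        return D[(min(i, j), max(i, j))]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(dd(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dd(i, j) - r[i] - r[j]
                a, b = sorted((minlab[i], minlab[j]))
                key = (q, a, b)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = dd(i, j)
        li = dij / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        for child in sorted((i, j), key=lambda k: minlab[k]):
            parent.add_child(nodes[child])
        nodes[nxt] = parent
        minlab[nxt] = min(minlab[i], minlab[j])
        for k in active:
            if k in (i, j):
                continue
            D[(min(nxt, k), max(nxt, k))] = 0.5 * (dd(i, k) + dd(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [nxt]
        nxt += 1

    root = dendropy.Node()
    if len(active) == 3:
        a, b, c = active
        la = 0.5 * (dd(a, b) + dd(a, c) - dd(b, c))
        lb = 0.5 * (dd(a, b) + dd(b, c) - dd(a, c))
        lc = 0.5 * (dd(a, c) + dd(b, c) - dd(a, b))
        for k, lk in sorted(((a, la), (b, lb), (c, lc)), key=lambda t: minlab[t[0]]):
            nodes[k].edge.length = lk
            root.add_child(nodes[k])
    elif len(active) == 2:
        a, b = active
        nodes[a].edge.length = 0.0
        nodes[b].edge.length = dd(a, b)
        root.add_child(nodes[a])
        root.add_child(nodes[b])
    else:
        root = nodes[active[0]]
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def build_tree(dist: SequenceDistanceMatrix, method: str = "upgma") -> dendropy.Tree:
    """Distance-based tree: UPGMA (rooted, ultrametric) or neighbor joining
    (unrooted; exact on additive matrices).

    Merge ties are resolved toward the lexicographically smallest leaf
    label, making the topology a pure function of the labelled matrix.
    """
    entries = np.asarray(dist.entries, dtype=float)
    if not np.isfinite(entries).all():
        raise ValueError("distance matrix contains non-finite entries")
    n = len(dist.labels)
    if method == "upgma":
        if n < 2:
            raise ValueError("UPGMA needs at least 2 leaves")
        return _upgma(dist.labels, entries, dendropy.TaxonNamespace())
    if method == "nj":
        if n < 3:
            raise ValueError("neighbor joining needs at least 3 leaves")
        return _nj(dist.labels, entries, dendropy.TaxonNamespace())
    raise ValueError(f"unknown tree method {method!r}; choose 'upgma' or 'nj'")


def write_newick(tree: dendropy.Tree, stream: TextIO) -> None:
    """Serialize a tree as Newick with branch lengths (labels quoted as needed)."""
    stream.write(
        tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n"
    )


def read_newick(stream: TextIO) -> dendropy.Tree:
    return dendropy.Tree.get(file=stream, schema="newick")


def cophenetic_matrix(tree: dendropy.Tree) -> SequenceDistanceMatrix:
    """Leaf-to-leaf path-length (patristic) distances of a tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    n = len(taxa)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(taxa[i], taxa[j])
    return SequenceDistanceMatrix([t.label for t in taxa], out, metric="patristic")
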