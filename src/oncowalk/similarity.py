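"""Disease-based functional similarity for RNAs and k-nearest-neighbour networks.

Two miRNAs (or lncRNAs) are considered functionally similar when the disease
groups they are associated with are similar.  Given a precomputed pairwise
disease-disease similarity matrix, the similarity between an RNA pair is the
symmetric average of best-match disease similarities::

    sim(R1, R2) = ( sum_{d in D1} max_{d' in D2} DSim(d, d')
                  + sum_{d in D2} max_{d' in D1} DSim(d, d') ) / (|D1| + |D2|)

where ``D1``/``D2`` are the disease sets of the two RNAs.  The per-layer
similarity networks of the heterogeneous walk (cancer, miRNA, lncRNA layers)
are then built by linking every entity to its k most similar partners.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Set
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DiseaseSimilarity",
    "group_similarity",
    "rna_functional_similarity",
    "rna_similarity_matrix",
    "build_knn_network",
]


@dataclass(frozen=True)
class DiseaseSimilarity:
    """Square pairwise disease similarity matrix with entries in [0, 1].

    The matrix must be symmetric with a unit diagonal; these invariants are
    checked at construction time.
    """

    diseases: tuple[str, ...]
    values: np.ndarray
    _pos: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        k = len(self.diseases)
        if len(set(self.diseases)) != k:
            raise ValueError("duplicate disease identifiers")
        if values.shape != (k, k):
            raise ValueError(f"similarity matrix shape {values.shape} does not match {k} diseases")
        if values.size:
            if values.min() < 0 or values.max() > 1:
                raise ValueError("similarity values must lie in [0, 1]")
            if not np.allclose(values, values.T, atol=1e-12):
                raise ValueError("similarity matrix must be symmetric")
            if not np.allclose(np.diag(values), 1.0, atol=1e-12):
                raise ValueError("similarity matrix must have a unit diagonal")
        object.__setattr__(self, "_pos", {d: i for i, d in enumerate(self.diseases)})

    def index_of(self, disease: str) -> int:
        try:
            return self._pos[disease]
        except KeyError:
            raise KeyError(f"unknown disease identifier: {disease!r}") from None

    def sim(self, a: str, b: str) -> float:
        return float(self.values[self.index_of(a), self.index_of(b)])

    @classmethod
    def from_tsv(cls, path) -> "DiseaseSimilarity":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        ids = tuple(str(c) for c in frame.columns)
        if tuple(str(i) for i in frame.index) != ids:
            raise ValueError("row and column disease identifiers differ")
        return cls(ids, frame.to_numpy(dtype=float))

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.values, index=list(self.diseases), columns=list(self.diseases)).to_csv(
            path, sep="\t", index_label="disease"
        )


def group_similarity(disease: str, group: Set[str] | Iterable[str], dsim: DiseaseSimilarity) -> float:
    """Best-match similarity between ``disease`` and a non-empty disease group."""
    members = list(group)
    if not members:
        raise ValueError("disease group must be non-empty")
    row = dsim.values[dsim.index_of(disease)]
    return float(max(row[dsim.index_of(d)] for d in members))


def rna_functional_similarity(
    group_a: Set[str] | Iterable[str],
    group_b: Set[str] | Iterable[str],
    dsim: DiseaseSimilarity,
) -> float:
    """Similarity between two RNAs given their associated disease groups.

    Symmetric average of best-match disease similarities; both groups must be
    non-empty (the measure is undefined for an RNA with no known disease).
    """
    a = [dsim.index_of(d) for d in group_a]
    b = [dsim.index_of(d) for d in group_b]
    if not a or not b:
        raise ValueError("both disease groups must be non-empty")
    block = dsim.values[np.ix_(a, b)]
    return float((block.max(axis=1).sum() + block.max(axis=0).sum()) / (len(a) + len(b)))


def rna_similarity_matrix(
    associations: Mapping[str, Set[str]],
    dsim: DiseaseSimilarity,
    rna_ids: Iterable[str] | None = None,
) -> tuple[tuple[str, ...], np.ndarray]:
    """Pairwise functional similarity matrix over a set of RNAs.

    ``associations`` maps RNA id -> set of associated disease ids.  RNAs with
    an empty disease group are kept in the output (so they become isolated
    nodes of the similarity network) but all their off-diagonal similarities
    are 0; pairs of annotated RNAs get the functional similarity score.
    """
    ids = tuple(rna_ids) if rna_ids is not None else tuple(sorted(associations))
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate RNA identifiers")
    groups = [sorted(associations.get(r, ())) for r in ids]
    idx = [[dsim.index_of(d) for d in g] for g in groups]
    k = len(ids)
    sim = np.zeros((k, k))
    for i in range(k):
        if not idx[i]:
            continue
        sim[i, i] = 1.0
        for j in range(i + 1, k):
            if not idx[j]:
                continue
            block = dsim.values[np.ix_(idx[i], idx[j])]
            value = (block.max(axis=1).sum() + block.max(axis=0).sum()) / (len(idx[i]) + len(idx[j]))
            sim[i, j] = sim[j, i] = value
    return ids, sim


def build_knn_network(
    entities: Iterable[str],
    sim_matrix: np.ndarray,
    k: int,
    weighted: bool = True,
) -> nx.Graph:
    """Undirected k-nearest-neighbour graph from a pairwise similarity matrix.

    Every node selects its ``k`` highest-similarity partners (self excluded;
    zero-similarity candidates never selected, so a node with fewer than ``k``
    positive similarities gets a smaller neighbourhood, possibly empty).  The
    edge set is the union over nodes: an edge exists when either endpoint
    selects the other.  Ties at the k-th position are broken by lexicographic
    node identifier, which keeps the construction deterministic.

    Edge weights carry the similarity value when ``weighted`` (default), or
    1.0 when binary adjacency is preferred.
    """
    ids = list(entities)
    n = len(ids)
    sim = np.asarray(sim_matrix, dtype=float)
    if sim.shape != (n, n):
        raise ValueError(f"similarity matrix shape {sim.shape} does not match {n} entities")
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < {n}, got {k}")
    if not np.allclose(sim, sim.T, atol=1e-9):
        raise ValueError("similarity matrix must be symmetric")

    graph = nx.Graph()
    graph.add_nodes_from(ids)
    for i in range(n):
        candidates = [(-sim[i, j], ids[j], j) for j in range(n) if j != i and sim[i, j] > 0]
        candidates.sort()
        for neg, _, j in candidates[:k]:
            weight = -neg if weighted else 1.0
            existing = graph.get_edge_data(ids[i], ids[j])
            if existing is None or existing["weight"] < weight:
                graph.add_edge(ids[i], ids[j], weight=weight)
    return graph
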