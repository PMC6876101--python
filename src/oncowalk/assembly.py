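"""Assembly of the quadruple-layer heterogeneous network.

The network has four typed node layers -- genes, miRNAs, lncRNAs, cancers --
with intra-layer adjacency blocks G, M, L, C on the diagonal and six bipartite
coupling blocks (GM, GL, GC, ML, MC, LC) off the diagonal:

    H = [[G   , GM , GL , GC ],
         [GM.T, M  , ML , MC ],
         [GL.T, ML.T, L  , LC ],
         [GC.T, MC.T, LC.T, C ]]

The gene layer is the union of a protein-protein interaction (PPI) network
and a pathway co-membership network; which source contributed each gene is
recorded because the transition-matrix builder weights the two evidence
channels separately.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence, Set
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "LayeredNodeIndex",
    "AssociationTable",
    "ComplexCatalog",
    "MergedGeneNetwork",
    "HeterogeneousNetwork",
    "merge_gene_networks",
    "assemble_heterogeneous",
    "edges_to_adjacency",
]

LAYERS = ("gene", "mirna", "lncrna", "cancer")


def _canonical_edges(edges: Iterable[tuple[str, str]]) -> set[tuple[str, str]]:
    """Deduplicate an undirected edge list and drop self-loops."""
    out: set[tuple[str, str]] = set()
    for u, v in edges:
        if u == v:
            continue
        out.add((u, v) if u <= v else (v, u))
    return out


def edges_to_adjacency(edges: Iterable[tuple[str, str]], ids: Sequence[str]) -> np.ndarray:
    """Symmetric binary adjacency over ``ids`` from an undirected edge list."""
    pos = {g: i for i, g in enumerate(ids)}
    adj = np.zeros((len(ids), len(ids)))
    for u, v in edges:
        if u in pos and v in pos and u != v:
            adj[pos[u], pos[v]] = adj[pos[v], pos[u]] = 1.0
    return adj


@dataclass(frozen=True)
class LayeredNodeIndex:
    """Ordered node identifiers of the four layers and their offsets."""

    gene_ids: tuple[str, ...]
    mirna_ids: tuple[str, ...]
    lncrna_ids: tuple[str, ...]
    cancer_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        for name in LAYERS:
            ids = self.layer_ids(name)
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate identifiers in {name} layer")

    def layer_ids(self, layer: str) -> tuple[str, ...]:
        return getattr(self, f"{layer}_ids")

    @property
    def sizes(self) -> tuple[int, int, int, int]:
        return tuple(len(self.layer_ids(layer)) for layer in LAYERS)  # type: ignore[return-value]

    @property
    def offsets(self) -> tuple[int, int, int, int]:
        sizes = self.sizes
        return (0, sizes[0], sizes[0] + sizes[1], sizes[0] + sizes[1] + sizes[2])

    @property
    def total(self) -> int:
        return sum(self.sizes)

    def layer_slice(self, layer: str) -> slice:
        i = LAYERS.index(layer)
        start = self.offsets[i]
        return slice(start, start + self.sizes[i])

    def position(self, layer: str, node: str) -> int:
        """Global position of ``node`` in the concatenated index."""
        ids = self.layer_ids(layer)
        try:
            return self.offsets[LAYERS.index(layer)] + ids.index(node)
        except ValueError:
            raise KeyError(f"unknown {layer} identifier: {node!r}") from None


@dataclass(frozen=True)
class AssociationTable:
    """Binary association pairs between two entity universes.

    ``left_ids``/``right_ids`` define the universes (they may contain
    identifiers that appear in no pair); ``pairs`` holds distinct
    (left, right) associations drawn from those universes.
    """

    left_ids: tuple[str, ...]
    right_ids: tuple[str, ...]
    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        left, right = set(self.left_ids), set(self.right_ids)
        for a, b in self.pairs:
            if a not in left or b not in right:
                raise ValueError(f"pair {(a, b)!r} references an identifier outside the id lists")

    @classmethod
    def from_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        left_ids: Iterable[str] | None = None,
        right_ids: Iterable[str] | None = None,
    ) -> "AssociationTable":
        pairs = frozenset((str(a), str(b)) for a, b in pairs)
        left = tuple(left_ids) if left_ids is not None else tuple(sorted({a for a, _ in pairs}))
        right = tuple(right_ids) if right_ids is not None else tuple(sorted({b for _, b in pairs}))
        return cls(left, right, pairs)

    def groups_left(self) -> dict[str, set[str]]:
        """Map every left identifier to its set of right partners."""
        groups: dict[str, set[str]] = {a: set() for a in self.left_ids}
        for a, b in self.pairs:
            groups[a].add(b)
        return groups

    def matrix(self, left_index: Sequence[str], right_index: Sequence[str], label: str = "") -> np.ndarray:
        """Binary coupling matrix aligned to layer node orders.

        Pairs whose endpoints are absent from the layer indices are dropped
        with a logged count, mirroring the filtering of associations against
        the layer similarity networks.
        """
        lpos = {g: i for i, g in enumerate(left_index)}
        rpos = {g: i for i, g in enumerate(right_index)}
        out = np.zeros((len(left_index), len(right_index)))
        dropped = 0
        for a, b in self.pairs:
            if a in lpos and b in rpos:
                out[lpos[a], rpos[b]] = 1.0
            else:
                dropped += 1
        if dropped:
            logger.warning("%s: dropped %d association pair(s) with unresolvable endpoints", label or "associations", dropped)
        return out

    @classmethod
    def from_tsv(cls, path) -> "AssociationTable":
        frame = pd.read_csv(path, sep="\t", dtype=str)
        if frame.shape[1] != 2:
            raise ValueError(f"{path}: expected a two-column association TSV")
        return cls.from_pairs(frame.itertuples(index=False, name=None))

    def to_tsv(self, path, columns: tuple[str, str] = ("left_id", "right_id")) -> None:
        pd.DataFrame(sorted(self.pairs), columns=list(columns)).to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ComplexCatalog:
    """Protein-complex memberships; complexes with fewer than two members are discarded."""

    complexes: tuple[frozenset[str], ...]

    @classmethod
    def from_memberships(cls, memberships: Iterable[Iterable[str]]) -> "ComplexCatalog":
        kept = []
        for members in memberships:
            members = frozenset(str(m) for m in members)
            if len(members) >= 2:
                kept.append(members)
        return cls(tuple(kept))

    def restricted(self, genes: Set[str], warn: bool = False) -> "ComplexCatalog":
        """Drop members outside ``genes``; complexes shrinking below two members are removed.

        ``warn`` logs the dropped-member count; it is set when loading
        user-supplied catalogs (unknown members indicate mismatched inputs)
        but not for deliberate subsetting such as the round-two restriction.
        """
        before = sum(len(c) for c in self.complexes)
        kept = [c & genes for c in self.complexes]
        after = sum(len(c) for c in kept)
        if warn and after < before:
            logger.warning("complex catalog: ignored %d member(s) absent from the gene index", before - after)
        return ComplexCatalog(tuple(c for c in kept if len(c) >= 2))

    @classmethod
    def from_tsv(cls, path) -> "ComplexCatalog":
        rows = []
        with open(path) as handle:
            for line in handle:
                members = [tok for tok in line.rstrip("\n").split("\t") if tok]
                if members:
                    rows.append(members)
        return cls.from_memberships(rows)

    def to_tsv(self, path) -> None:
        with open(path, "w") as handle:
            for members in self.complexes:
                handle.write("\t".join(sorted(members)) + "\n")

    def __len__(self) -> int:
        return len(self.complexes)


@dataclass(frozen=True)
class MergedGeneNetwork:
    """Union of the PPI and pathway gene networks with per-source membership flags."""

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str]]
    ppi_edges: frozenset[tuple[str, str]]
    pathway_edges: frozenset[tuple[str, str]]

    @property
    def in_ppi(self) -> frozenset[str]:
        return frozenset(n for e in self.ppi_edges for n in e)

    @property
    def in_pathway(self) -> frozenset[str]:
        return frozenset(n for e in self.pathway_edges for n in e)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g


def merge_gene_networks(
    ppi_edges: Iterable[tuple[str, str]],
    pathway_edges: Iterable[tuple[str, str]],
) -> MergedGeneNetwork:
    """Merge the PPI and pathway networks into one gene network.

    Self-loops are removed, duplicate edges (within or across sources)
    collapse to one, and the node set is the union of both sources.  The
    original per-source edge sets are retained so the transition builder can
    weight PPI and pathway evidence separately.
    """
    ppi = frozenset(_canonical_edges(ppi_edges))
    pathway = frozenset(_canonical_edges(pathway_edges))
    merged = ppi | pathway
    nodes = tuple(sorted({n for e in merged for n in e}))
    if not nodes:
        raise ValueError("merged gene network is empty")
    return MergedGeneNetwork(nodes, merged, ppi, pathway)


@dataclass(frozen=True)
class HeterogeneousNetwork:
    """Quadruple-layer heterogeneous network as dense block matrices.

    ``gene_ppi``/``gene_pathway`` carry the per-source gene adjacencies used
    by the evidence-fused gene transition; when absent the gene block ``G``
    is treated as a single undifferentiated network.
    """

    index: LayeredNodeIndex
    G: np.ndarray
    M: np.ndarray
    L: np.ndarray
    C: np.ndarray
    GM: np.ndarray
    GL: np.ndarray
    GC: np.ndarray
    ML: np.ndarray
    MC: np.ndarray
    LC: np.ndarray
    gene_ppi: np.ndarray | None = None
    gene_pathway: np.ndarray | None = None
    _block_names: tuple[str, ...] = field(
        default=("G", "M", "L", "C", "GM", "GL", "GC", "ML", "MC", "LC"), init=False, repr=False
    )

    def __post_init__(self) -> None:
        n, m, l, c = self.index.sizes
        shapes = {
            "G": (n, n), "M": (m, m), "L": (l, l), "C": (c, c),
            "GM": (n, m), "GL": (n, l), "GC": (n, c),
            "ML": (m, l), "MC": (m, c), "LC": (l, c),
        }
        for name, shape in shapes.items():
            block = np.asarray(getattr(self, name), dtype=float)
            if block.shape != shape:
                raise ValueError(f"block {name} has shape {block.shape}, expected {shape}")
            if block.size and block.min() < 0:
                raise ValueError(f"block {name} contains negative entries")
            object.__setattr__(self, name, block)
        for name in ("G", "M", "L", "C"):
            block = getattr(self, name)
            if block.size:
                if not np.allclose(block, block.T, atol=1e-12):
                    raise ValueError(f"intra-layer block {name} must be symmetric")
                if np.any(np.diag(block) != 0):
                    raise ValueError(f"intra-layer block {name} must have a zero diagonal")
        for name in ("gene_ppi", "gene_pathway"):
            block = getattr(self, name)
            if block is not None:
                block = np.asarray(block, dtype=float)
                if block.shape != (n, n):
                    raise ValueError(f"{name} must be an {n}x{n} gene adjacency")
                object.__setattr__(self, name, block)

    def adjacency(self) -> np.ndarray:
        """Full symmetric block adjacency H over all layers."""
        return np.block([
            [self.G, self.GM, self.GL, self.GC],
            [self.GM.T, self.M, self.ML, self.MC],
            [self.GL.T, self.ML.T, self.L, self.LC],
            [self.GC.T, self.MC.T, self.LC.T, self.C],
        ])

    # -- association lookups -------------------------------------------------

    def cancer_position(self, disease: str) -> int:
        try:
            return self.index.cancer_ids.index(disease)
        except ValueError:
            raise KeyError(f"unknown cancer identifier: {disease!r}") from None

    def cancer_associated(self, layer: str, disease: str | None = None) -> tuple[str, ...]:
        """Entities of ``layer`` associated with ``disease`` (or with any cancer)."""
        block = {"gene": self.GC, "mirna": self.MC, "lncrna": self.LC}[layer]
        ids = self.index.layer_ids(layer)
        if disease is None:
            mask = block.sum(axis=1) > 0 if block.size else np.zeros(len(ids), dtype=bool)
        else:
            j = self.cancer_position(disease)
            mask = block[:, j] > 0 if block.size else np.zeros(len(ids), dtype=bool)
        return tuple(g for g, keep in zip(ids, mask) if keep)

    def without_association(self, gene: str, disease: str) -> "HeterogeneousNetwork":
        """Copy of the network with one gene-cancer association removed."""
        i = self.index.position("gene", gene)
        j = self.cancer_position(disease)
        gc = self.GC.copy()
        gc[i, j] = 0.0
        return replace(self, GC=gc)

    def restrict_genes(self, keep: Set[str]) -> "HeterogeneousNetwork":
        """Induced subnetwork on a gene subset; other layers are unchanged."""
        if not keep:
            raise ValueError("gene restriction set is empty")
        unknown = set(keep) - set(self.index.gene_ids)
        if unknown:
            raise KeyError(f"unknown gene identifiers: {sorted(unknown)[:5]}")
        mask = np.array([g in keep for g in self.index.gene_ids])
        index = LayeredNodeIndex(
            tuple(g for g in self.index.gene_ids if g in keep),
            self.index.mirna_ids,
            self.index.lncrna_ids,
            self.index.cancer_ids,
        )
        return HeterogeneousNetwork(
            index=index,
            G=self.G[np.ix_(mask, mask)],
            M=self.M, L=self.L, C=self.C,
            GM=self.GM[mask], GL=self.GL[mask], GC=self.GC[mask],
            ML=self.ML, MC=self.MC, LC=self.LC,
            gene_ppi=None if self.gene_ppi is None else self.gene_ppi[np.ix_(mask, mask)],
            gene_pathway=None if self.gene_pathway is None else self.gene_pathway[np.ix_(mask, mask)],
        )


def _intra_adjacency(net: nx.Graph, ids: Sequence[str]) -> np.ndarray:
    if len(ids) == 0:
        return np.zeros((0, 0))
    adj = nx.to_numpy_array(net, nodelist=list(ids), weight="weight")
    np.fill_diagonal(adj, 0.0)
    return adj


def assemble_heterogeneous(
    gene_net: MergedGeneNetwork,
    mirna_net: nx.Graph,
    lncrna_net: nx.Graph,
    cancer_net: nx.Graph,
    associations: Mapping[str, AssociationTable],
) -> HeterogeneousNetwork:
    """Assemble the block adjacency from the four layer networks and six coupling tables.

    ``associations`` must provide the keys ``gene_cancer``, ``mirna_cancer``,
    ``lncrna_cancer``, ``mirna_gene``, ``lncrna_gene`` and ``mirna_lncrna``,
    each oriented as named.  Pairs whose endpoints cannot be resolved to layer
    nodes are dropped with a logged count; a non-empty table none of whose
    pairs resolves indicates mismatched inputs and raises.
    """
    required = {"gene_cancer", "mirna_cancer", "lncrna_cancer", "mirna_gene", "lncrna_gene", "mirna_lncrna"}
    missing = required - set(associations)
    if missing:
        raise KeyError(f"missing association tables: {sorted(missing)}")

    index = LayeredNodeIndex(
        tuple(gene_net.nodes),
        tuple(sorted(mirna_net.nodes)),
        tuple(sorted(lncrna_net.nodes)),
        tuple(sorted(cancer_net.nodes)),
    )
    gene_ids, mirna_ids, lncrna_ids, cancer_ids = (index.layer_ids(layer) for layer in LAYERS)

    orientations = {
        "gene_cancer": (gene_ids, cancer_ids),
        "mirna_cancer": (mirna_ids, cancer_ids),
        "lncrna_cancer": (lncrna_ids, cancer_ids),
        "mirna_gene": (mirna_ids, gene_ids),
        "lncrna_gene": (lncrna_ids, gene_ids),
        "mirna_lncrna": (mirna_ids, lncrna_ids),
    }
    blocks: dict[str, np.ndarray] = {}
    for name, (left, right) in orientations.items():
        table = associations[name]
        blocks[name] = table.matrix(left, right, label=name)
        if table.pairs and blocks[name].sum() == 0:
            raise ValueError(f"association table {name!r} references entirely unknown entities")

    return HeterogeneousNetwork(
        index=index,
        G=edges_to_adjacency(gene_net.edges, gene_ids),
        M=_intra_adjacency(mirna_net, mirna_ids),
        L=_intra_adjacency(lncrna_net, lncrna_ids),
        C=_intra_adjacency(cancer_net, cancer_ids),
        GM=blocks["mirna_gene"].T,
        GL=blocks["lncrna_gene"].T,
        GC=blocks["gene_cancer"],
        ML=blocks["mirna_lncrna"],
        MC=blocks["mirna_cancer"],
        LC=blocks["lncrna_cancer"],
        gene_ppi=edges_to_adjacency(gene_net.ppi_edges, gene_ids),
        gene_pathway=edges_to_adjacency(gene_net.pathway_edges, gene_ids),
    )
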