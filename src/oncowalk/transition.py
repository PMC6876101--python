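"""Transition operators for the heterogeneous random walk.

The gene-layer transition fuses three evidence channels:

* the row-normalised PPI transition ``W_P``,
* the row-normalised pathway transition ``W_Path``,
* a protein-complex feedback ``W_com`` whose row ``i`` equals, for every
  merged-network neighbour ``j`` of gene ``i``, the best cancer-gene fraction
  among the complexes containing ``i``.

For gene ``i`` present in ``N(i)`` of the two networks (N in {0, 1, 2}) the
pre-normalised row is ``(1/N) W_P(i,.) + (1/N) W_Path(i,.) + W_com(i,.)``;
the final gene transition ``W_G`` is its row normalisation.  A gene isolated
in both networks has ``1/N`` taken as 0, leaving at most the complex term.

The global transition over all four layers scales intra-layer transitions by
``1 - delta`` and splits ``delta`` across the inter-layer blocks.  Rows whose
node lacks couplings to some layers redistribute the missing mass: ``delta``
is shared equally among only the non-empty inter-layer blocks of that row;
with no inter-layer couplings the intra-layer block keeps full mass, and with
no intra-layer neighbours the inter-layer blocks share mass 1.  Every
non-dangling row of the result is therefore exactly stochastic.
"""

from __future__ import annotations

from collections.abc import Sequence, Set
from dataclasses import dataclass

import numpy as np

from .assembly import ComplexCatalog, HeterogeneousNetwork, LayeredNodeIndex

__all__ = [
    "GeneTransitionInputs",
    "TransitionMatrix",
    "row_normalize",
    "single_network_transition",
    "membership_count",
    "complex_ratios",
    "complex_weight",
    "gene_transition",
    "global_transition",
]


def row_normalize(matrix: np.ndarray) -> np.ndarray:
    """Divide each row by its sum; all-zero rows stay zero.

    Raises on negative entries; the operator is only meaningful for
    nonnegative adjacency-like matrices.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.size and matrix.min() < 0:
        raise ValueError("row_normalize requires nonnegative entries")
    sums = matrix.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sums > 0, matrix / np.where(sums > 0, sums, 1.0), 0.0)
    return out


def single_network_transition(adjacency: np.ndarray) -> np.ndarray:
    """Plain single-network transition: each row divided by its degree sum."""
    return row_normalize(adjacency)


def membership_count(ppi_adj: np.ndarray, pathway_adj: np.ndarray) -> np.ndarray:
    """Per-gene count of networks (PPI, pathway) in which the gene has neighbours."""
    ppi_adj = np.asarray(ppi_adj, dtype=float)
    pathway_adj = np.asarray(pathway_adj, dtype=float)
    if ppi_adj.shape != pathway_adj.shape:
        raise ValueError("PPI and pathway adjacencies must share one gene index")
    return (ppi_adj.sum(axis=1) > 0).astype(int) + (pathway_adj.sum(axis=1) > 0).astype(int)


@dataclass(frozen=True)
class GeneTransitionInputs:
    """Evidence feeding the gene-layer transition builder."""

    gene_ids: tuple[str, ...]
    ppi_adj: np.ndarray
    pathway_adj: np.ndarray
    complexes: ComplexCatalog
    cancer_genes: frozenset[str]

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        for name in ("ppi_adj", "pathway_adj"):
            block = np.asarray(getattr(self, name), dtype=float)
            if block.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")
            object.__setattr__(self, name, block)
        unknown = self.cancer_genes - set(self.gene_ids)
        if unknown:
            raise ValueError(f"cancer genes outside the gene index: {sorted(unknown)[:5]}")

    @property
    def merged_adj(self) -> np.ndarray:
        return ((self.ppi_adj + self.pathway_adj) > 0).astype(float)


def complex_ratios(
    complexes: ComplexCatalog,
    gene_ids: Sequence[str],
    cancer_genes: Set[str],
) -> np.ndarray:
    """Best cancer-gene fraction per gene over the complexes containing it.

    Complex members absent from ``gene_ids`` are ignored (the catalog warns
    when restricting); genes in no complex get ratio 0.
    """
    catalog = complexes.restricted(set(gene_ids))
    pos = {g: i for i, g in enumerate(gene_ids)}
    ratios = np.zeros(len(gene_ids))
    for members in catalog.complexes:
        ratio = len(members & set(cancer_genes)) / len(members)
        for g in members:
            i = pos[g]
            if ratio > ratios[i]:
                ratios[i] = ratio
    return ratios


def complex_weight(inputs: GeneTransitionInputs) -> np.ndarray:
    """Complex feedback matrix: row i carries gene i's best complex ratio on its neighbours."""
    ratios = complex_ratios(inputs.complexes, inputs.gene_ids, inputs.cancer_genes)
    return ratios[:, None] * (inputs.merged_adj > 0)


def gene_transition(inputs: GeneTransitionInputs) -> np.ndarray:
    """Evidence-fused, row-stochastic gene-layer transition matrix."""
    w_ppi = single_network_transition(inputs.ppi_adj)
    w_path = single_network_transition(inputs.pathway_adj)
    counts = membership_count(inputs.ppi_adj, inputs.pathway_adj)
    with np.errstate(divide="ignore"):
        inv = np.where(counts > 0, 1.0 / np.maximum(counts, 1), 0.0)
    initial = inv[:, None] * w_ppi + inv[:, None] * w_path + complex_weight(inputs)
    return row_normalize(initial)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic global walk operator over all layers."""

    index: LayeredNodeIndex
    W: np.ndarray
    delta: float

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.shape != (self.index.total, self.index.total):
            raise ValueError("transition matrix shape does not match the node index")
        object.__setattr__(self, "W", W)

    def row_sums(self) -> np.ndarray:
        return self.W.sum(axis=1)


def global_transition(
    net: HeterogeneousNetwork,
    gene_W: np.ndarray,
    delta: float,
) -> TransitionMatrix:
    """Assemble the global transition matrix from a heterogeneous network.

    ``gene_W`` is the (already stochastic) gene-layer transition; the miRNA,
    lncRNA and cancer intra-layer transitions are the row normalisations of
    their similarity-network adjacencies, and each bipartite block is row
    normalised independently.  ``delta`` is the inter-layer jump probability;
    see the module docstring for the per-row mass reallocation rule.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError(f"delta must lie in [0, 1], got {delta}")
    index = net.index
    n, m, l, c = index.sizes
    gene_W = np.asarray(gene_W, dtype=float)
    if gene_W.shape != (n, n):
        raise ValueError("gene transition shape does not match the gene layer")

    intra = [gene_W, row_normalize(net.M), row_normalize(net.L), row_normalize(net.C)]
    coupling = [
        [None, net.GM, net.GL, net.GC],
        [net.GM.T, None, net.ML, net.MC],
        [net.GL.T, net.ML.T, None, net.LC],
        [net.GC.T, net.MC.T, net.LC.T, None],
    ]
    sizes = index.sizes
    offsets = index.offsets
    total = index.total
    W = np.zeros((total, total))

    for i in range(4):
        ni = sizes[i]
        if ni == 0:
            continue
        rows = slice(offsets[i], offsets[i] + ni)
        intra_ok = intra[i].sum(axis=1) > 1e-15
        inter: list[tuple[int, np.ndarray, np.ndarray]] = []
        for j in range(4):
            if j == i or sizes[j] == 0:
                continue
            block = coupling[i][j]
            ok = block.sum(axis=1) > 0
            if ok.any():
                inter.append((j, row_normalize(block), ok))
        k = np.zeros(ni, dtype=int)
        for _, _, ok in inter:
            k += ok.astype(int)

        intra_coef = np.where(intra_ok, np.where(k > 0, 1.0 - delta, 1.0), 0.0)
        share = np.where(k > 0, np.where(intra_ok, delta, 1.0) / np.maximum(k, 1), 0.0)

        W[rows, rows] = intra_coef[:, None] * intra[i]
        for j, block_T, ok in inter:
            cols = slice(offsets[j], offsets[j] + sizes[j])
            W[rows, cols] = (share * ok)[:, None] * block_T
    return TransitionMatrix(index=index, W=W, delta=float(delta))
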