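"""Synthetic input bundles with planted cancer-gene signal.

The generator emulates the statistical structure of the curated inputs the
method consumes: a merged PPI + pathway gene network with modular cancer-gene
neighbourhoods, disease-clustered RNA associations, protein complexes
enriched for cancer genes, and a block-structured disease-disease similarity
matrix.  Every quantity is driven by one integer seed through a single
``numpy`` generator, so bundles are bit-reproducible.

Planted structure (signal mode): each cancer owns one module of genes that
are (a) mutually enriched in both gene networks by a configurable factor,
(b) associated with their cancer at the signal rate, and (c) co-members of
cancer-enriched complexes; miRNAs and lncRNAs are themed to cancers and
interact with the planted genes of their theme at the signal rate.  The
matched null (``shuffle_labels=True``) keeps every layer size and expected
edge/association count but draws all of them uniformly, erasing the
gene-disease signal; it is the calibration condition under which LOOCV AUC
should sit near 0.5.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .assembly import (
    AssociationTable,
    ComplexCatalog,
    HeterogeneousNetwork,
    MergedGeneNetwork,
    assemble_heterogeneous,
    merge_gene_networks,
)
from .similarity import DiseaseSimilarity, build_knn_network, rna_similarity_matrix

__all__ = [
    "FixtureConfig",
    "FixtureBundle",
    "generate",
    "null_fixture",
    "calibration_config",
    "build_network",
]


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of a synthetic bundle.

    The defaults describe the standard benchmarking condition: 300 genes with
    six planted 10-gene cancer modules, 40 miRNAs and 40 lncRNAs themed to
    six cancers, association signal 0.8 against background noise 0.02, and a
    within-module edge enrichment of 5x over the background density.
    """

    n_genes: int = 300
    n_mirnas: int = 40
    n_lncrnas: int = 40
    n_cancers: int = 6
    n_modules: int = 6
    module_size: int = 10
    ppi_degree: float = 5.0        # mean background degree of the PPI network
    pathway_degree: float = 5.0    # mean background degree of the pathway network
    enrichment: float = 5.0        # within-module edge probability multiplier
    signal: float = 0.8            # planted gene/RNA -> own cancer association probability
    noise: float = 0.02            # background association probability per pair
    n_complexes: int = 30
    complex_size: tuple[int, int] = (3, 8)
    complex_planted_fraction: float = 0.5
    mirna_lncrna_rate: float = 0.25  # same-theme miRNA-lncRNA interaction probability
    knn_cancer: int = 3
    knn_mirna: int = 10
    knn_lncrna: int = 10
    seed: int = 0
    shuffle_labels: bool = False

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_mirnas, self.n_lncrnas) < 2 or self.n_cancers < 1:
            raise ValueError("layer sizes are too small")
        if self.module_size > self.n_genes or self.n_modules * self.module_size > self.n_genes:
            raise ValueError("planted modules do not fit in the gene layer")
        if self.n_modules < 1:
            raise ValueError("at least one module is required")
        for name in ("signal", "noise", "complex_planted_fraction", "mirna_lncrna_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.enrichment < 0:
            raise ValueError("enrichment must be nonnegative")


@dataclass(frozen=True)
class FixtureBundle:
    """All inputs of one synthetic study, plus the planted ground truth."""

    config: FixtureConfig
    ppi_edges: tuple[tuple[str, str], ...]
    pathway_edges: tuple[tuple[str, str], ...]
    disease_sim: DiseaseSimilarity
    gene_cancer: AssociationTable
    mirna_cancer: AssociationTable
    lncrna_cancer: AssociationTable
    mirna_gene: AssociationTable
    lncrna_gene: AssociationTable
    mirna_lncrna: AssociationTable
    complexes: ComplexCatalog
    truth: tuple[tuple[str, str], ...] = field(default=())  # (gene, cancer) planted pairs

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(f"g{i:04d}" for i in range(self.config.n_genes))

    def association_tables(self) -> dict[str, AssociationTable]:
        return {
            "gene_cancer": self.gene_cancer,
            "mirna_cancer": self.mirna_cancer,
            "lncrna_cancer": self.lncrna_cancer,
            "mirna_gene": self.mirna_gene,
            "lncrna_gene": self.lncrna_gene,
            "mirna_lncrna": self.mirna_lncrna,
        }

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, edges in (("ppi_edges", self.ppi_edges), ("pathway_edges", self.pathway_edges)):
            with open(directory / f"{name}.tsv", "w") as handle:
                handle.write("gene_a\tgene_b\n")
                for u, v in sorted(edges):
                    handle.write(f"{u}\t{v}\n")
        self.disease_sim.to_tsv(directory / "disease_similarity.tsv")
        columns = {
            "gene_cancer": ("gene_id", "cancer_id"),
            "mirna_cancer": ("mirna_id", "cancer_id"),
            "lncrna_cancer": ("lncrna_id", "cancer_id"),
            "mirna_gene": ("mirna_id", "gene_id"),
            "lncrna_gene": ("lncrna_id", "gene_id"),
            "mirna_lncrna": ("mirna_id", "lncrna_id"),
        }
        for name, table in self.association_tables().items():
            table.to_tsv(directory / f"{name}.tsv", columns=columns[name])
        self.complexes.to_tsv(directory / "complexes.tsv")
        with open(directory / "truth.tsv", "w") as handle:
            handle.write("gene_id\tcancer_id\n")
            for g, d in sorted(self.truth):
                handle.write(f"{g}\t{d}\n")
        with open(directory / "config.json", "w") as handle:
            json.dump(dataclasses.asdict(self.config), handle, indent=2, sort_keys=True)

    @classmethod
    def read(cls, directory) -> "FixtureBundle":
        import pandas as pd

        directory = Path(directory)
        with open(directory / "config.json") as handle:
            raw = json.load(handle)
        raw["complex_size"] = tuple(raw["complex_size"])
        config = FixtureConfig(**raw)
        edges = {}
        for name in ("ppi_edges", "pathway_edges"):
            frame = pd.read_csv(directory / f"{name}.tsv", sep="\t", dtype=str)
            edges[name] = tuple(frame.itertuples(index=False, name=None))
        tables = {
            name: AssociationTable.from_tsv(directory / f"{name}.tsv")
            for name in ("gene_cancer", "mirna_cancer", "lncrna_cancer", "mirna_gene", "lncrna_gene", "mirna_lncrna")
        }
        truth_frame = pd.read_csv(directory / "truth.tsv", sep="\t", dtype=str)
        return cls(
            config=config,
            ppi_edges=edges["ppi_edges"],
            pathway_edges=edges["pathway_edges"],
            disease_sim=DiseaseSimilarity.from_tsv(directory / "disease_similarity.tsv"),
            complexes=ComplexCatalog.from_tsv(directory / "complexes.tsv"),
            truth=tuple(truth_frame.itertuples(index=False, name=None)),
            **tables,
        )

    def to_network(self) -> tuple[HeterogeneousNetwork, ComplexCatalog]:
        return build_network(self)


def _sample_edges(
    rng: np.random.Generator,
    ids: list[str],
    p_background: float,
    modules: list[list[int]],
    p_within: float,
) -> tuple[tuple[str, str], ...]:
    """Upper-triangle Bernoulli edge sampling with elevated within-module probability."""
    n = len(ids)
    prob = np.full((n, n), p_background)
    for members in modules:
        idx = np.ix_(members, members)
        prob[idx] = p_within
    draws = rng.random((n, n))
    upper = np.triu(np.ones((n, n), dtype=bool), k=1)
    mask = upper & (draws < prob)
    return tuple((ids[i], ids[j]) for i, j in zip(*np.nonzero(mask)))


def _sample_pairs(
    rng: np.random.Generator,
    left: list[str],
    right: list[str],
    prob: np.ndarray,
) -> set[tuple[str, str]]:
    draws = rng.random((len(left), len(right)))
    return {(left[i], right[j]) for i, j in zip(*np.nonzero(draws < prob))}


def generate(config: FixtureConfig) -> FixtureBundle:
    """Deterministically generate one synthetic bundle from its configuration."""
    rng = np.random.default_rng(config.seed)
    n, m, l, c = config.n_genes, config.n_mirnas, config.n_lncrnas, config.n_cancers
    genes = [f"g{i:04d}" for i in range(n)]
    mirnas = [f"mi{i:03d}" for i in range(m)]
    lncrnas = [f"ln{i:03d}" for i in range(l)]
    cancers = [f"ca{i:02d}" for i in range(c)]
    null = config.shuffle_labels

    # planted modules: consecutive gene blocks, module t themed to cancer t mod c
    modules = [
        list(range(t * config.module_size, (t + 1) * config.module_size))
        for t in range(config.n_modules)
    ]
    module_theme = [t % c for t in range(config.n_modules)]
    planted_for_cancer: list[list[int]] = [[] for _ in range(c)]
    for t, members in enumerate(modules):
        planted_for_cancer[module_theme[t]].extend(members)

    # gene networks: background ER density, modules enriched unless null
    def edge_net(mean_degree: float) -> tuple[tuple[str, str], ...]:
        p_bg = min(1.0, mean_degree / max(n - 1, 1))
        p_in = p_bg if null else min(1.0, config.enrichment * p_bg)
        return _sample_edges(rng, genes, p_bg, [] if null else modules, p_in)

    ppi_edges = edge_net(config.ppi_degree)
    pathway_edges = edge_net(config.pathway_degree)

    # disease similarity: consecutive pairs form high-similarity groups
    dsim = np.zeros((c, c))
    for i in range(c):
        dsim[i, i] = 1.0
        for j in range(i + 1, c):
            same_group = (i // 2) == (j // 2)
            low, high = (0.6, 0.9) if same_group else (0.05, 0.35)
            dsim[i, j] = dsim[j, i] = rng.uniform(low, high)
    disease_sim = DiseaseSimilarity(tuple(cancers), dsim)

    # gene-cancer associations
    gc_prob = np.full((n, c), config.noise)
    if null:
        for d in range(c):
            gc_prob[:, d] += config.signal * len(planted_for_cancer[d]) / n
    else:
        for d in range(c):
            gc_prob[planted_for_cancer[d], d] = config.signal
    gene_cancer = _sample_pairs(rng, genes, cancers, gc_prob)

    # RNA themes: round-robin over cancers for even coverage
    mirna_theme = [i % c for i in range(m)]
    lncrna_theme = [i % c for i in range(l)]

    def rna_cancer(rna: list[str], themes: list[int]) -> set[tuple[str, str]]:
        prob = np.full((len(rna), c), config.noise)
        if null:
            prob += config.signal / c
        else:
            for i, t in enumerate(themes):
                prob[i, t] = config.signal
        return _sample_pairs(rng, rna, cancers, prob)

    mirna_cancer = rna_cancer(mirnas, mirna_theme)
    lncrna_cancer = rna_cancer(lncrnas, lncrna_theme)

    def rna_gene(rna: list[str], themes: list[int]) -> set[tuple[str, str]]:
        prob = np.full((len(rna), n), config.noise)
        matched = sum(len(planted_for_cancer[t]) for t in themes)
        if null:
            prob += config.signal * matched / (len(rna) * n)
        else:
            for i, t in enumerate(themes):
                prob[i, planted_for_cancer[t]] = config.signal
        return _sample_pairs(rng, rna, genes, prob)

    mirna_gene = rna_gene(mirnas, mirna_theme)
    lncrna_gene = rna_gene(lncrnas, lncrna_theme)

    ml_prob = np.full((m, l), config.noise)
    if null:
        same = sum(1 for i in range(m) for j in range(l) if mirna_theme[i] == lncrna_theme[j])
        ml_prob += config.mirna_lncrna_rate * same / (m * l)
    else:
        for i in range(m):
            for j in range(l):
                if mirna_theme[i] == lncrna_theme[j]:
                    ml_prob[i, j] = config.mirna_lncrna_rate
    mirna_lncrna = _sample_pairs(rng, mirnas, lncrnas, ml_prob)

    # protein complexes: a planted fraction drawn from single modules, rest random
    lo, hi = config.complex_size
    memberships: list[list[str]] = []
    n_planted = 0 if null else int(round(config.complex_planted_fraction * config.n_complexes))
    for i in range(config.n_complexes):
        size = int(rng.integers(lo, hi + 1))
        if i < n_planted:
            t = int(rng.integers(0, config.n_modules))
            core = rng.choice(modules[t], size=min(size, len(modules[t])), replace=False)
            members = [genes[j] for j in core]
            while len(members) < size:
                extra = genes[int(rng.integers(0, n))]
                if extra not in members:
                    members.append(extra)
        else:
            members = [genes[j] for j in rng.choice(n, size=size, replace=False)]
        memberships.append(members)

    truth = () if null else tuple(
        (genes[i], cancers[d]) for d in range(c) for i in planted_for_cancer[d]
    )

    return FixtureBundle(
        config=config,
        ppi_edges=ppi_edges,
        pathway_edges=pathway_edges,
        disease_sim=disease_sim,
        gene_cancer=AssociationTable.from_pairs(gene_cancer, genes, cancers),
        mirna_cancer=AssociationTable.from_pairs(mirna_cancer, mirnas, cancers),
        lncrna_cancer=AssociationTable.from_pairs(lncrna_cancer, lncrnas, cancers),
        mirna_gene=AssociationTable.from_pairs(mirna_gene, mirnas, genes),
        lncrna_gene=AssociationTable.from_pairs(lncrna_gene, lncrnas, genes),
        mirna_lncrna=AssociationTable.from_pairs(mirna_lncrna, mirnas, lncrnas),
        complexes=ComplexCatalog.from_memberships(memberships),
        truth=truth,
    )


def null_fixture(config: FixtureConfig) -> FixtureBundle:
    """Matched no-signal bundle: same sizes and expected densities, labels uniform."""
    return generate(dataclasses.replace(config, shuffle_labels=True))


def calibration_config(seed: int = 0) -> FixtureConfig:
    """Label-shuffled single-cancer condition for rank-score calibration.

    With one cancer, every LOOCV candidate is a non-seed gene, so the
    withheld gene is exchangeable with its candidate pool and its rank score
    is uniform by construction.  The sizes give roughly 220 associations,
    enough records for a stable Kolmogorov-Smirnov test.
    """
    return FixtureConfig(
        n_genes=400,
        n_mirnas=30,
        n_lncrnas=30,
        n_cancers=1,
        n_modules=1,
        module_size=265,
        seed=seed,
        shuffle_labels=True,
    )


def build_network(bundle: FixtureBundle) -> tuple[HeterogeneousNetwork, ComplexCatalog]:
    """Turn a bundle into the assembled heterogeneous network and complex catalog.

    RNA-layer similarity networks are computed from the bundle's disease
    associations and the disease similarity matrix; the cancer layer links
    every cancer to its nearest peers.  kNN neighbourhood sizes are clamped
    to the layer size minus one (a layer of one node yields no intra edges).
    """
    config = bundle.config
    gene_net = merge_gene_networks(bundle.ppi_edges, bundle.pathway_edges)
    # genes appearing only in association tables still belong to the gene layer
    extra_nodes = set(bundle.gene_cancer.left_ids) - set(gene_net.nodes)
    if extra_nodes:
        gene_net = MergedGeneNetwork(
            tuple(sorted(set(gene_net.nodes) | extra_nodes)),
            gene_net.edges,
            gene_net.ppi_edges,
            gene_net.pathway_edges,
        )

    def knn_net(ids, sim, k):
        import networkx as nx

        k = min(k, len(ids) - 1)
        if k < 1:
            g = nx.Graph()
            g.add_nodes_from(ids)
            return g
        return build_knn_network(ids, sim, k)

    mirna_ids, mirna_sim = rna_similarity_matrix(
        bundle.mirna_cancer.groups_left(), bundle.disease_sim, bundle.mirna_cancer.left_ids
    )
    lncrna_ids, lncrna_sim = rna_similarity_matrix(
        bundle.lncrna_cancer.groups_left(), bundle.disease_sim, bundle.lncrna_cancer.left_ids
    )
    cancer_sim = bundle.disease_sim.values.copy()
    np.fill_diagonal(cancer_sim, 0.0)  # self-similarity is not a candidate edge

    mirna_net = knn_net(mirna_ids, mirna_sim, config.knn_mirna)
    lncrna_net = knn_net(lncrna_ids, lncrna_sim, config.knn_lncrna)
    cancer_net = knn_net(bundle.disease_sim.diseases, cancer_sim, config.knn_cancer)

    net = assemble_heterogeneous(
        gene_net, mirna_net, lncrna_net, cancer_net, bundle.association_tables()
    )
    catalog = bundle.complexes.restricted(set(net.index.gene_ids), warn=True)
    return net, catalog
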