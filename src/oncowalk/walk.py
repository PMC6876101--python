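"""Two-round random walk with restart on the quadruple-layer network.

Round one seeds the walk with every cancer-associated gene, miRNA and lncRNA
plus all cancer nodes, and keeps the top ``sigma * n`` genes by stationary
probability.  Round two rebuilds the heterogeneous network on those genes
(the miRNA, lncRNA and cancer layers are untouched), reseeds it with the
entities of one specific cancer, and walks again.  The final per-gene score
is the convex combination ``alpha * P1 + (1 - alpha) * P2``; genes discarded
after round one contribute ``P2 = 0`` so that all genes remain rankable.

The walk iterates ``P(t+1) = (1 - gamma) W^T P(t) + gamma P(0)`` to a fixed
point.  The transition matrix is row stochastic, so probability is propagated
through its transpose (mass flows in along edges); with a dangling-free
operator the iterate remains a distribution at every step.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Set
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assembly import ComplexCatalog, HeterogeneousNetwork, LayeredNodeIndex
from .transition import GeneTransitionInputs, TransitionMatrix, gene_transition, global_transition

__all__ = [
    "WalkParams",
    "SeedSet",
    "ScoreVector",
    "ConvergenceError",
    "initial_probability",
    "rwr",
    "build_transition",
    "first_round",
    "build_second_round_network",
    "second_round",
    "combine_scores",
    "two_round_prioritize",
    "FirstRoundResult",
    "PrioritizationResult",
]


class ConvergenceError(RuntimeError):
    """Raised when the walk fails to reach the convergence threshold."""

    def __init__(self, iterations: int, residual: float, tol: float):
        self.iterations = iterations
        self.residual = residual
        super().__init__(
            f"random walk did not converge within {iterations} iterations "
            f"(residual {residual:.3e}, tolerance {tol:.1e})"
        )


@dataclass(frozen=True)
class WalkParams:
    """Hyperparameters of the two-round walk.

    delta    inter-layer jump probability of the global transition
    eta      per-layer restart weights (gene, miRNA, lncRNA, cancer), sum 1
    gamma    restart probability
    sigma    fraction of genes kept after round one
    alpha    weight of the round-one scores in the final combination
    tol      Euclidean convergence threshold of the iteration
    max_iter iteration cap before a ConvergenceError is raised
    """

    delta: float = 0.5
    eta: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    gamma: float = 0.6
    sigma: float = 0.6
    alpha: float = 0.9
    tol: float = 1e-6
    max_iter: int = 1000

    def __post_init__(self) -> None:
        for name in ("delta", "gamma", "sigma", "alpha"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        eta = tuple(float(e) for e in self.eta)
        if len(eta) != 4 or any(e < 0 for e in eta):
            raise ValueError("eta must be four nonnegative weights")
        if abs(sum(eta) - 1.0) > 1e-9:
            raise ValueError(f"eta must sum to 1, got {sum(eta)}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be at least 1")
        object.__setattr__(self, "eta", eta)


@dataclass(frozen=True)
class SeedSet:
    """Per-layer seed identifiers defining the restart distribution."""

    gene_seeds: tuple[str, ...] = ()
    mirna_seeds: tuple[str, ...] = ()
    lncrna_seeds: tuple[str, ...] = ()
    cancer_seeds: tuple[str, ...] = ()

    def layer_seeds(self, layer: str) -> tuple[str, ...]:
        return getattr(self, f"{layer}_seeds")

    @property
    def total(self) -> int:
        return sum(len(self.layer_seeds(layer)) for layer in ("gene", "mirna", "lncrna", "cancer"))


@dataclass(frozen=True)
class ScoreVector:
    """Per-node stationary probabilities over a layered node index."""

    index: LayeredNodeIndex
    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if p.shape != (self.index.total,):
            raise ValueError("probability vector length does not match the node index")
        object.__setattr__(self, "p", p)

    def layer_values(self, layer: str) -> np.ndarray:
        return self.p[self.index.layer_slice(layer)]

    def as_series(self, layer: str) -> pd.Series:
        return pd.Series(self.layer_values(layer), index=list(self.index.layer_ids(layer)))


def initial_probability(
    index: LayeredNodeIndex,
    seeds: SeedSet,
    eta: tuple[float, float, float, float],
) -> ScoreVector:
    """Restart distribution: layer mass ``eta_i`` spread uniformly over that layer's seeds.

    Layers without seeds contribute nothing; their eta weight is redistributed
    proportionally over the seeded layers so the vector sums to one.
    """
    layers = ("gene", "mirna", "lncrna", "cancer")
    seeded = [layer for layer in layers if seeds.layer_seeds(layer)]
    if not seeded:
        raise ValueError("seed set is empty in every layer")
    weight = {layer: eta[i] for i, layer in enumerate(layers)}
    total = sum(weight[layer] for layer in seeded)
    if total <= 0:
        raise ValueError("eta assigns zero weight to every seeded layer")

    p = np.zeros(index.total)
    for layer in seeded:
        ids = index.layer_ids(layer)
        offset = index.layer_slice(layer).start
        mass = weight[layer] / total
        share = mass / len(seeds.layer_seeds(layer))
        for node in seeds.layer_seeds(layer):
            try:
                p[offset + ids.index(node)] += share
            except ValueError:
                raise KeyError(f"seed {node!r} is not a {layer}-layer node") from None
    return ScoreVector(index, p)


def rwr(
    W: TransitionMatrix | np.ndarray,
    p0: ScoreVector | np.ndarray,
    gamma: float,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> np.ndarray:
    """Iterate the restart walk to its fixed point.

    Returns the stationary vector of
    ``P(t+1) = (1 - gamma) W^T P(t) + gamma P(0)``, stopping when the
    Euclidean norm of successive differences drops below ``tol``.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    matrix = W.W if isinstance(W, TransitionMatrix) else np.asarray(W, dtype=float)
    start = p0.p if isinstance(p0, ScoreVector) else np.asarray(p0, dtype=float)
    if not math.isclose(float(start.sum()), 1.0, abs_tol=1e-6):
        raise ValueError("initial probability vector must sum to 1")
    WT = matrix.T
    p = start.copy()
    residual = math.inf
    for _ in range(max_iter):
        p_next = (1.0 - gamma) * (WT @ p) + gamma * start
        residual = float(np.linalg.norm(p_next - p))
        p = p_next
        if residual < tol:
            return p
    raise ConvergenceError(max_iter, residual, tol)


def build_transition(
    net: HeterogeneousNetwork,
    complexes: ComplexCatalog,
    cancer_genes: Set[str],
    delta: float,
) -> TransitionMatrix:
    """Global transition of ``net`` with the evidence-fused gene layer.

    When the network carries no PPI/pathway split, the merged gene block
    stands in for both channels (the fusion then reduces to its plain row
    normalisation plus the complex feedback).
    """
    ppi = net.gene_ppi if net.gene_ppi is not None else net.G
    pathway = net.gene_pathway if net.gene_pathway is not None else np.zeros_like(net.G)
    inputs = GeneTransitionInputs(
        gene_ids=net.index.gene_ids,
        ppi_adj=ppi,
        pathway_adj=pathway,
        complexes=complexes,
        cancer_genes=frozenset(cancer_genes) & set(net.index.gene_ids),
    )
    return global_transition(net, gene_transition(inputs), delta)


@dataclass(frozen=True)
class FirstRoundResult:
    scores: ScoreVector
    topk_genes: tuple[str, ...]
    seeds: SeedSet
    cancer_genes: frozenset[str]


def _top_fraction(gene_ids: Iterable[str], scores: np.ndarray, sigma: float) -> tuple[str, ...]:
    """Top ``round(sigma * n)`` genes (at least one), ties broken by identifier."""
    ids = list(gene_ids)
    k = max(1, int(math.floor(sigma * len(ids) + 0.5)))
    order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
    return tuple(ids[i] for i in order[:k])


def first_round(
    net: HeterogeneousNetwork,
    complexes: ComplexCatalog,
    params: WalkParams,
    exclude_genes: Set[str] = frozenset(),
) -> FirstRoundResult:
    """Global walk seeded by every cancer-associated entity and all cancer nodes.

    ``exclude_genes`` removes genes from both the seed set and the
    cancer-gene set that feeds the complex feedback (the cross-validation
    leakage guard).
    """
    gene_seeds = tuple(g for g in net.cancer_associated("gene") if g not in exclude_genes)
    seeds = SeedSet(
        gene_seeds=gene_seeds,
        mirna_seeds=net.cancer_associated("mirna"),
        lncrna_seeds=net.cancer_associated("lncrna"),
        cancer_seeds=net.index.cancer_ids,
    )
    if seeds.total == 0:
        raise ValueError("no cancer-associated entities to seed the first round")
    cancer_genes = frozenset(gene_seeds)
    W = build_transition(net, complexes, cancer_genes, params.delta)
    p0 = initial_probability(net.index, seeds, params.eta)
    p = rwr(W, p0, params.gamma, params.tol, params.max_iter)
    scores = ScoreVector(net.index, p)
    topk = _top_fraction(net.index.gene_ids, scores.layer_values("gene"), params.sigma)
    return FirstRoundResult(scores, topk, seeds, cancer_genes)


def build_second_round_network(
    net: HeterogeneousNetwork, topk_genes: Set[str] | Iterable[str]
) -> HeterogeneousNetwork:
    """Reconstructed network whose gene layer is restricted to the round-one survivors."""
    keep = set(topk_genes)
    if not keep:
        raise ValueError("top-k gene set is empty")
    return net.restrict_genes(keep)


def second_round(
    subnet: HeterogeneousNetwork,
    complexes: ComplexCatalog,
    disease: str,
    params: WalkParams,
    cancer_genes: Set[str],
    exclude_genes: Set[str] = frozenset(),
) -> ScoreVector:
    """Walk on the reconstructed network seeded by one cancer and its entities.

    ``cancer_genes`` is the global cancer-gene set of round one (restricted
    here to surviving genes) feeding the complex feedback; seeds are the
    cancer node itself plus its associated genes, miRNAs and lncRNAs present
    in the subnetwork.
    """
    gene_seeds = tuple(
        g for g in subnet.cancer_associated("gene", disease) if g not in exclude_genes
    )
    seeds = SeedSet(
        gene_seeds=gene_seeds,
        mirna_seeds=subnet.cancer_associated("mirna", disease),
        lncrna_seeds=subnet.cancer_associated("lncrna", disease),
        cancer_seeds=(disease,),
    )
    W = build_transition(subnet, complexes, frozenset(cancer_genes) - set(exclude_genes), params.delta)
    p0 = initial_probability(subnet.index, seeds, params.eta)
    return ScoreVector(subnet.index, rwr(W, p0, params.gamma, params.tol, params.max_iter))


def combine_scores(
    p1_genes: pd.Series,
    p2_genes: pd.Series,
    alpha: float,
) -> pd.Series:
    """Per-gene score ``alpha * P1 + (1 - alpha) * P2``.

    ``p1_genes`` covers the full gene universe; ``p2_genes`` covers the
    round-two subnetwork and is taken as zero elsewhere, so all genes remain
    comparable in one ranking.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    p2_full = p2_genes.reindex(p1_genes.index, fill_value=0.0)
    return alpha * p1_genes + (1.0 - alpha) * p2_full


@dataclass(frozen=True)
class PrioritizationResult:
    """Outcome of a full two-round run for one cancer."""

    gene_ids: tuple[str, ...]
    p1: np.ndarray
    p2: np.ndarray
    score: np.ndarray
    topk_genes: tuple[str, ...]
    first: FirstRoundResult = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        from .evaluation import rank_score

        return pd.DataFrame(
            {
                "gene_id": list(self.gene_ids),
                "P1": self.p1,
                "P2": self.p2,
                "Score": self.score,
                "Rank_score": rank_score(self.score),
            }
        )


def two_round_prioritize(
    net: HeterogeneousNetwork,
    complexes: ComplexCatalog,
    disease: str,
    params: WalkParams = WalkParams(),
    exclude_genes: Set[str] = frozenset(),
) -> PrioritizationResult:
    """Run both walk rounds for one cancer and combine the scores."""
    net.cancer_position(disease)  # fail fast on an unknown disease
    first = first_round(net, complexes, params, exclude_genes=exclude_genes)
    subnet = build_second_round_network(net, first.topk_genes)
    p2 = second_round(
        subnet, complexes, disease, params, first.cancer_genes, exclude_genes=exclude_genes
    )
    p1_genes = first.scores.as_series("gene")
    p2_genes = p2.as_series("gene")
    score = combine_scores(p1_genes, p2_genes, params.alpha)
    return PrioritizationResult(
        gene_ids=net.index.gene_ids,
        p1=p1_genes.to_numpy(),
        p2=p2_genes.reindex(p1_genes.index, fill_value=0.0).to_numpy(),
        score=score.to_numpy(),
        topk_genes=first.topk_genes,
        first=first,
    )
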