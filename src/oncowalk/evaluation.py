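"""Rank scores, leave-one-out cross-validation, ROC/AUC and top-k% counting.

Each known gene-cancer association is withheld in turn; the full two-round
pipeline runs for that cancer with the association removed, and the withheld
gene is ranked against every gene with no association to that cancer.  The
rank score of a gene is the fraction of its candidate universe it strictly
outranks, so it is invariant under monotone transforms of the raw scores.
ROC curves pool the withheld genes (positives) against genes never associated
with any cancer (negatives, one global set per network).
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence, Set
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve

from .assembly import ComplexCatalog, HeterogeneousNetwork
from .transition import global_transition, row_normalize
from .walk import (
    SeedSet,
    WalkParams,
    initial_probability,
    rwr,
    two_round_prioritize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LoocvRecord",
    "RocResult",
    "rank_score",
    "global_negative_genes",
    "loocv",
    "roc_auc",
    "topk_counts",
    "calibration_ks",
]


def rank_score(scores: np.ndarray | Sequence[float]) -> np.ndarray:
    """Fraction of the universe each entry strictly outranks.

    For universe size ``n``, entry ``i`` gets ``#{j != i : s_j < s_i} / n``;
    ties contribute nothing, so identical scores all map to the same value
    and a constant vector maps to zeros.  Values lie in [0, (n-1)/n].
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n < 1:
        raise ValueError("rank_score requires at least one score")
    order = np.sort(scores)
    below = np.searchsorted(order, scores, side="left")
    return below / n


@dataclass(frozen=True)
class LoocvRecord:
    """One withheld association and the ranking it produced."""

    disease_id: str
    held_out_gene: str
    candidate_ids: tuple[str, ...]
    rank_scores: np.ndarray
    held_out_rank_score: float
    held_out_rank: int  # 1-based, by strict score comparison

    @property
    def candidate_count(self) -> int:
        return len(self.candidate_ids)


@dataclass(frozen=True)
class RocResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def global_negative_genes(net: HeterogeneousNetwork) -> frozenset[str]:
    """Genes with no association to any cancer (the ROC negative set)."""
    associated = set(net.cancer_associated("gene"))
    return frozenset(set(net.index.gene_ids) - associated)


def _gene_score_map(gene_ids: Sequence[str], scores: np.ndarray) -> dict[str, float]:
    return {g: float(s) for g, s in zip(gene_ids, scores)}


def _baseline_rwr_scores(
    net: HeterogeneousNetwork,
    disease: str,
    params: WalkParams,
    exclude: Set[str],
) -> dict[str, float] | None:
    """Single-layer walk on the merged gene network with disease-gene seeds."""
    seeds = [g for g in net.cancer_associated("gene", disease) if g not in exclude]
    if not seeds:
        return None
    ids = net.index.gene_ids
    W = row_normalize(net.G)
    p0 = np.zeros(len(ids))
    pos = {g: i for i, g in enumerate(ids)}
    for g in seeds:
        p0[pos[g]] = 1.0 / len(seeds)
    p = rwr(W, p0, params.gamma, params.tol, params.max_iter)
    return _gene_score_map(ids, p)


def _baseline_rwrh_scores(
    net: HeterogeneousNetwork,
    disease: str,
    params: WalkParams,
    exclude: Set[str],
) -> dict[str, float] | None:
    """Two-layer gene + cancer walk: plain gene transition, disease-specific seeds."""
    from .assembly import HeterogeneousNetwork as HN, LayeredNodeIndex

    gene_seeds = tuple(g for g in net.cancer_associated("gene", disease) if g not in exclude)
    if not gene_seeds:
        return None
    n = len(net.index.gene_ids)
    c = len(net.index.cancer_ids)
    index = LayeredNodeIndex(net.index.gene_ids, (), (), net.index.cancer_ids)
    stripped = HN(
        index=index,
        G=net.G,
        M=np.zeros((0, 0)), L=np.zeros((0, 0)), C=net.C,
        GM=np.zeros((n, 0)), GL=np.zeros((n, 0)), GC=net.GC,
        ML=np.zeros((0, 0)), MC=np.zeros((0, c)), LC=np.zeros((0, c)),
    )
    W = global_transition(stripped, row_normalize(net.G), params.delta)
    seeds = SeedSet(gene_seeds=gene_seeds, cancer_seeds=(disease,))
    p0 = initial_probability(index, seeds, params.eta)
    p = rwr(W, p0, params.gamma, params.tol, params.max_iter)
    return _gene_score_map(index.gene_ids, p[index.layer_slice("gene")])


def loocv(
    net: HeterogeneousNetwork,
    complexes: ComplexCatalog,
    params: WalkParams = WalkParams(),
    method: str = "trwr",
    leakage_guard: bool = True,
) -> list[LoocvRecord]:
    """Leave-one-out cross-validation over all gene-cancer associations.

    For each association (gene g, cancer d): the association is removed; with
    the leakage guard on (default) g is also excluded from every seed set and
    from the cancer-gene set behind the complex feedback; the scoring method
    runs for d; and g is ranked against the genes with no remaining
    association to d.  Records whose cancer retains no associated entity
    after the removal are skipped with a warning.

    ``method`` selects the scorer: ``"trwr"`` (the two-round walk), or the
    comparison baselines ``"rwr"`` (single-layer gene walk) and ``"rwrh"``
    (gene + cancer two-layer walk).
    """
    if method not in ("trwr", "rwr", "rwrh"):
        raise ValueError(f"unknown LOOCV method: {method!r}")
    gene_ids = net.index.gene_ids
    records: list[LoocvRecord] = []
    for disease in net.index.cancer_ids:
        assoc_genes = net.cancer_associated("gene", disease)
        for gene in assoc_genes:
            net_cv = net.without_association(gene, disease)
            remaining = (
                len(net_cv.cancer_associated("gene", disease))
                + len(net_cv.cancer_associated("mirna", disease))
                + len(net_cv.cancer_associated("lncrna", disease))
            )
            if remaining == 0:
                logger.warning(
                    "skipping (%s, %s): no disease evidence remains after removal", disease, gene
                )
                continue
            exclude = frozenset({gene}) if leakage_guard else frozenset()
            if method == "trwr":
                result = two_round_prioritize(net_cv, complexes, disease, params, exclude_genes=exclude)
                score_map = _gene_score_map(result.gene_ids, result.score)
            elif method == "rwr":
                score_map = _baseline_rwr_scores(net_cv, disease, params, exclude)
            else:
                score_map = _baseline_rwrh_scores(net_cv, disease, params, exclude)
            if score_map is None:
                logger.warning("skipping (%s, %s): no usable seeds for method %s", disease, gene, method)
                continue
            other_assoc = set(assoc_genes) - {gene}
            candidates = tuple(g for g in gene_ids if g not in other_assoc)
            cand_scores = np.array([score_map[g] for g in candidates])
            ranks = rank_score(cand_scores)
            held_idx = candidates.index(gene)
            held_rank = 1 + int(np.sum(cand_scores > cand_scores[held_idx]))
            records.append(
                LoocvRecord(
                    disease_id=disease,
                    held_out_gene=gene,
                    candidate_ids=candidates,
                    rank_scores=ranks,
                    held_out_rank_score=float(ranks[held_idx]),
                    held_out_rank=held_rank,
                )
            )
    return records


def roc_auc(records: Iterable[LoocvRecord], negatives: Set[str]) -> RocResult:
    """ROC over withheld-gene rank scores (positives) vs never-associated genes.

    Each record contributes its withheld gene's rank score as one positive
    and the rank scores of the global negative genes in its candidate set as
    negatives.  Equal scores share one threshold; the AUC is the trapezoidal
    area under the resulting curve.
    """
    records = list(records)
    if not records:
        raise ValueError("no LOOCV records")
    if not negatives:
        raise ValueError("negative gene set is empty")
    scores: list[float] = []
    labels: list[int] = []
    for record in records:
        scores.append(record.held_out_rank_score)
        labels.append(1)
        for g, r in zip(record.candidate_ids, record.rank_scores):
            if g in negatives:
                scores.append(float(r))
                labels.append(0)
    if sum(labels) == len(labels):
        raise ValueError("no negative observations pooled from the records")
    fpr, tpr, thresholds = _roc_curve(labels, scores)
    return RocResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=float(_auc(fpr, tpr)))


def topk_counts(
    records: Iterable[LoocvRecord], k_percents: Sequence[float] = (5, 7, 10, 15)
) -> dict[float, int]:
    """Number of withheld genes recovered within the top k% of their candidate set."""
    records = list(records)
    counts: dict[float, int] = {}
    for k in k_percents:
        counts[k] = sum(
            1 for r in records if r.held_out_rank <= k / 100.0 * r.candidate_count
        )
    return counts


def calibration_ks(records: Iterable[LoocvRecord]) -> tuple[float, float]:
    """Kolmogorov-Smirnov test of withheld rank scores against Uniform[0, 1].

    Returns ``(statistic, p_value)``.  On a label-shuffled fixture in which
    the withheld gene is exchangeable with its candidates, the rank scores
    are uniform up to the 1/n discretisation of the rank grid.
    """
    values = np.array([r.held_out_rank_score for r in records])
    if values.size == 0:
        raise ValueError("no LOOCV records")
    result = stats.kstest(values, "uniform")
    return float(result.statistic), float(result.pvalue)
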