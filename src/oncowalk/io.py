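"""Serialization of assembled networks, transition matrices and result tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .assembly import LAYERS, HeterogeneousNetwork, LayeredNodeIndex
from .transition import TransitionMatrix

__all__ = [
    "save_network",
    "load_network",
    "save_transition",
    "save_records",
    "save_roc",
]

_BLOCKS = ("G", "M", "L", "C", "GM", "GL", "GC", "ML", "MC", "LC")
_BLOCK_AXES = {
    "G": ("gene", "gene"), "M": ("mirna", "mirna"), "L": ("lncrna", "lncrna"),
    "C": ("cancer", "cancer"), "GM": ("gene", "mirna"), "GL": ("gene", "lncrna"),
    "GC": ("gene", "cancer"), "ML": ("mirna", "lncrna"), "MC": ("mirna", "cancer"),
    "LC": ("lncrna", "cancer"),
}


def _triplets(block: np.ndarray, row_ids, col_ids) -> pd.DataFrame:
    rows, cols = np.nonzero(block)
    return pd.DataFrame(
        {
            "id_a": [row_ids[i] for i in rows],
            "id_b": [col_ids[j] for j in cols],
            "weight": block[rows, cols],
        }
    )


def save_network(net: HeterogeneousNetwork, directory) -> None:
    """Write the ten block matrices as triplet TSVs plus a layer manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in _BLOCKS:
        row_layer, col_layer = _BLOCK_AXES[name]
        frame = _triplets(
            getattr(net, name), net.index.layer_ids(row_layer), net.index.layer_ids(col_layer)
        )
        frame.to_csv(directory / f"{name}.tsv", sep="\t", index=False)
    manifest = {
        "layers": {layer: list(net.index.layer_ids(layer)) for layer in LAYERS},
        "sizes": dict(zip(LAYERS, net.index.sizes)),
    }
    with open(directory / "manifest.json", "w") as handle:
        json.dump(manifest, handle, indent=2)


def load_network(directory) -> HeterogeneousNetwork:
    """Read a network bundle written by :func:`save_network`.

    The PPI/pathway split is not part of the block serialization; the loaded
    gene layer is treated as one merged network.
    """
    directory = Path(directory)
    with open(directory / "manifest.json") as handle:
        manifest = json.load(handle)
    index = LayeredNodeIndex(*(tuple(manifest["layers"][layer]) for layer in LAYERS))
    positions = {
        layer: {g: i for i, g in enumerate(index.layer_ids(layer))} for layer in LAYERS
    }
    blocks = {}
    for name in _BLOCKS:
        row_layer, col_layer = _BLOCK_AXES[name]
        shape = (len(positions[row_layer]), len(positions[col_layer]))
        block = np.zeros(shape)
        frame = pd.read_csv(directory / f"{name}.tsv", sep="\t", dtype={"id_a": str, "id_b": str})
        for a, b, w in frame.itertuples(index=False, name=None):
            block[positions[row_layer][a], positions[col_layer][b]] = float(w)
        blocks[name] = block
    return HeterogeneousNetwork(index=index, **blocks)


def save_transition(tm: TransitionMatrix, directory) -> None:
    """Sparse triplet export of the global transition matrix plus a manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ids = [node for layer in LAYERS for node in tm.index.layer_ids(layer)]
    frame = _triplets(tm.W, ids, ids)
    frame.rename(columns={"id_a": "row_id", "id_b": "col_id", "weight": "prob"}).to_csv(
        directory / "transition.tsv", sep="\t", index=False
    )
    with open(directory / "manifest.json", "w") as handle:
        json.dump({"delta": tm.delta, "sizes": dict(zip(LAYERS, tm.index.sizes))}, handle, indent=2)


def save_records(records, path) -> None:
    pd.DataFrame(
        {
            "disease_id": [r.disease_id for r in records],
            "held_out_gene": [r.held_out_gene for r in records],
            "rank_score": [r.held_out_rank_score for r in records],
            "rank": [r.held_out_rank for r in records],
            "candidate_count": [r.candidate_count for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def save_roc(roc, path) -> None:
    pd.DataFrame({"threshold": roc.thresholds, "fpr": roc.fpr, "tpr": roc.tpr}).to_csv(
        path, sep="\t", index=False
    )
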