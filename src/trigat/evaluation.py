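"""Ensemble prediction, metrics, whole-graph ranking and external validation.

The disease-gene score of a node is the arithmetic mean of the five
cross-validation members' sigmoid outputs. Test-set AUROC/AUPR use the
standard implementations (AUROC is the Mann–Whitney probability that a random
positive outscores a random negative, ties counting one half; AUPR is the
step-wise average precision without interpolation). The whole-graph ranking
sorts every gene except the known positives by descending probability, and
external validation scores a disjoint, never-seen disease-gene set against an
equal-size seeded sample of unlabeled genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .model import model_forward
from .omics import KnowledgeGraph
from .training import EnsembleModel

__all__ = [
    "PredictionRanking",
    "ensemble_predict",
    "compute_metrics",
    "rank_unlabeled",
    "external_validation",
]


def ensemble_predict(ensemble: EnsembleModel, graph: KnowledgeGraph) -> np.ndarray:
    """Per-node probability: mean of the five members' sigmoid outputs."""
    if graph.X.shape[1] != ensemble.members[0].params.layers[0][
            ensemble.members[0].params.views[0]].W[0].data.shape[0]:
        raise ValueError("graph feature dimension does not match the trained model")
    outs = [model_forward(graph, m.params, ensemble.config, training=False).data
            for m in ensemble.members]
    return np.mean(outs, axis=0)


def compute_metrics(y_true, scores) -> dict:
    """AUROC and AUPR of binary labels against real-valued scores."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    if len(np.unique(y_true)) < 2:
        raise ValueError("both classes must be present to compute AUROC/AUPR")
    return {"AUROC": float(roc_auc_score(y_true, scores)),
            "AUPR": float(average_precision_score(y_true, scores))}


@dataclass
class PredictionRanking:
    """Genes ordered by descending disease probability, known positives excluded."""

    entries: list  # (gene id, probability), non-increasing probability
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        probs = [p for _, p in self.entries]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if any(a < b for a, b in zip(probs, probs[1:])):
            raise ValueError("ranking must be non-increasing in probability")

    @property
    def genes(self) -> list:
        return [g for g, _ in self.entries]

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [(i + 1, g, p) for i, (g, p) in enumerate(self.entries)],
            columns=["rank", "gene", "probability"],
        ).to_csv(path, sep="\t", index=False)


def rank_unlabeled(probabilities: np.ndarray, graph: KnowledgeGraph,
                   exclude_sampled_negatives: bool = False,
                   metadata: dict | None = None) -> PredictionRanking:
    """Sort all genes except known positives by descending probability.

    Genes that served as sampled training negatives stay in the ranking by
    default (only *known* disease genes are excluded); ties are broken by
    gene id ascending so the order is reproducible.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    if probabilities.shape[0] != graph.n_nodes:
        raise ValueError("need one probability per node")
    excluded = {graph.node_ids[i] for i in np.flatnonzero(graph.y == 1)}
    if exclude_sampled_negatives:
        excluded |= graph.provenance.get("sampled_negative", set())
    entries = [(g, float(probabilities[i])) for i, g in enumerate(graph.node_ids)
               if g not in excluded]
    entries.sort(key=lambda gp: (-gp[1], gp[0]))
    return PredictionRanking(entries, metadata or {})


def external_validation(probabilities: np.ndarray, graph: KnowledgeGraph,
                        external_positives, seen_genes, seed: int) -> dict:
    """Score an external disease-gene set never seen during training/testing.

    Positives are the external genes present in the graph after removing every
    gene that appeared in the train or test set; negatives are an equal-size
    seeded sample of the remaining genes that are neither external positives
    nor seen. Returns AUROC/AUPR plus the evaluated set sizes.
    """
    probabilities = np.asarray(probabilities, dtype=float)
    external = {str(g).strip().upper() for g in external_positives}
    seen = {str(g).strip().upper() for g in seen_genes}
    node_pos = {g: i for i, g in enumerate(graph.node_ids)}
    pos_genes = sorted((external - seen) & set(graph.node_ids))
    if not pos_genes:
        raise ValueError("no novel genes to validate: the external set is fully "
                         "contained in the train/test genes (or absent from the graph)")
    candidates = sorted(set(graph.node_ids) - external - seen)
    if len(candidates) < len(pos_genes):
        raise ValueError("not enough unlabeled genes to sample negatives")
    rng = np.random.default_rng(seed)
    neg_genes = list(rng.choice(candidates, size=len(pos_genes), replace=False))
    idx = np.array([node_pos[g] for g in pos_genes + neg_genes])
    y = np.array([1] * len(pos_genes) + [0] * len(neg_genes))
    metrics = compute_metrics(y, probabilities[idx])
    metrics["n_positives"] = len(pos_genes)
    metrics["n_negatives"] = len(neg_genes)
    return metrics
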