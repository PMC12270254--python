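"""Positive-unlabeled training: negative sampling, splits, ensemble fitting.

Only known disease genes carry a positive label; since very few genes are
disease-related, an equal number of negatives is sampled uniformly from the
unlabeled genes. The labeled set is split 80/20 into train/test preserving
the class ratio, the training part is divided into five stratified folds, and
five models are trained, each holding out one fold for validation and early
stopping. The test set is fixed before cross-validation and never touches
training or early stopping.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .autodiff import Adam, gather
from .model import ModelConfig, TriGATParams, cross_entropy_loss, derive_graph_views, model_forward
from .omics import UNLABELED, KnowledgeGraph

__all__ = [
    "LabeledSplit",
    "EnsembleModel",
    "EarlyStopper",
    "sample_negatives",
    "stratified_split",
    "train_ensemble",
]

logger = logging.getLogger("trigat")

N_FOLDS = 5
TEST_FRACTION = 0.2


def sample_negatives(graph: KnowledgeGraph, seed: int) -> KnowledgeGraph:
    """Label a random unlabeled subset, equal in size to the positives, as 0.

    Returns a copy of the graph; the sampled set is disjoint from the
    positives by construction and recorded in ``provenance``.
    """
    positives = np.flatnonzero(graph.y == 1)
    unlabeled = np.flatnonzero(graph.y == UNLABELED)
    if len(unlabeled) < len(positives):
        raise ValueError(
            f"cannot sample {len(positives)} negatives from {len(unlabeled)} unlabeled genes")
    rng = np.random.default_rng(seed)
    sampled = rng.choice(unlabeled, size=len(positives), replace=False)
    out = copy.deepcopy(graph)
    out.y[sampled] = 0
    out.provenance.setdefault("positive", {graph.node_ids[i] for i in positives})
    out.provenance["sampled_negative"] = {graph.node_ids[i] for i in sampled}
    return out


@dataclass
class LabeledSplit:
    """Fixed 80/20 train/test indices plus a 5-fold partition of the train set."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    folds: list
    seed: int

    def __post_init__(self):
        self.train_idx = np.asarray(self.train_idx, dtype=np.int64)
        self.test_idx = np.asarray(self.test_idx, dtype=np.int64)
        self.folds = [np.asarray(f, dtype=np.int64) for f in self.folds]
        if np.intersect1d(self.train_idx, self.test_idx).size:
            raise ValueError("train and test overlap")
        joined = np.sort(np.concatenate(self.folds))
        if not np.array_equal(joined, np.sort(self.train_idx)):
            raise ValueError("folds do not partition the training set")

    def to_dict(self) -> dict:
        return {"seed": self.seed,
                "train_idx": self.train_idx.tolist(),
                "test_idx": self.test_idx.tolist(),
                "folds": [f.tolist() for f in self.folds]}

    @classmethod
    def from_dict(cls, d: dict) -> "LabeledSplit":
        return cls(np.array(d["train_idx"]), np.array(d["test_idx"]),
                   [np.array(f) for f in d["folds"]], d["seed"])


def stratified_split(y: np.ndarray, seed: int) -> LabeledSplit:
    """80/20 stratified train/test split plus 5 stratified folds of the train set.

    ``y`` holds 1/0 for labeled nodes and -1 for unlabeled ones; indices in
    the returned split refer to positions in ``y``.
    """
    y = np.asarray(y)
    labeled = np.flatnonzero(y != UNLABELED)
    if len(labeled) < 10:
        raise ValueError(f"need >= 10 labeled nodes, have {len(labeled)}")
    classes = y[labeled]
    if len(np.unique(classes)) < 2:
        raise ValueError("both classes must be present")
    train, test = train_test_split(labeled, test_size=TEST_FRACTION,
                                   stratify=classes, random_state=seed)
    if min(np.bincount(y[train].astype(int))) < N_FOLDS:
        raise ValueError("too few labeled nodes per class to form 5 stratified folds")
    skf = StratifiedKFold(n_splits=N_FOLDS, shuffle=True, random_state=seed)
    folds = [train[val] for _, val in skf.split(train, y[train])]
    return LabeledSplit(np.sort(train), np.sort(test), folds, seed)


class EarlyStopper:
    """Min-mode early stopping: stop after `patience` epochs without a strict
    improvement of the best value; remembers the best epoch."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = -1
        self.bad_epochs = 0

    def update(self, value: float, epoch: int) -> bool:
        """Record this epoch's validation value; return True to stop."""
        if value < self.best:
            self.best = value
            self.best_epoch = epoch
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
        return self.bad_epochs >= self.patience


@dataclass
class EnsembleMember:
    params: TriGATParams
    val_fold: int
    best_epoch: int
    history: pd.DataFrame


@dataclass
class EnsembleModel:
    """Five cross-validation models, each tagged with its held-out fold."""

    members: list
    config: ModelConfig
    seed: int
    split: LabeledSplit | None = None

    def __post_init__(self):
        if len(self.members) != N_FOLDS:
            raise ValueError(f"expected {N_FOLDS} members, got {len(self.members)}")
        folds = [m.val_fold for m in self.members]
        if sorted(folds) != list(range(N_FOLDS)):
            raise ValueError("members must hold out distinct folds")

    @property
    def history(self) -> pd.DataFrame:
        return pd.concat([m.history for m in self.members], ignore_index=True)


def _train_member(graph: KnowledgeGraph, views, train_idx: np.ndarray,
                  val_idx: np.ndarray, config: ModelConfig, fold: int,
                  seed: int) -> EnsembleMember:
    rng = np.random.default_rng(seed)
    params = TriGATParams.init(config, in_dim=graph.X.shape[1],
                               edge_dim=graph.edge_features.shape[1], rng=rng)
    opt = Adam(params.parameters(), lr=config.learning_rate,
               weight_decay=config.weight_decay)
    stopper = EarlyStopper(config.patience)
    y_train = graph.y[train_idx].astype(float)
    y_val = graph.y[val_idx].astype(float)
    best_snapshot = params.snapshot()
    records = []
    for epoch in range(config.max_epochs):
        opt.zero_grad()
        h = model_forward(graph, params, config, views=views, training=True, rng=rng)
        loss = cross_entropy_loss(y_train, gather(h, train_idx))
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"fold {fold}: non-finite training loss at epoch {epoch}")
        loss.backward()
        opt.step()
        h_eval = model_forward(graph, params, config, views=views, training=False)
        val_loss = float(cross_entropy_loss(y_val, gather(h_eval, val_idx)).data)
        records.append({"fold": fold, "epoch": epoch,
                        "train_loss": float(loss.data), "val_loss": val_loss})
        improved = val_loss < stopper.best
        stop = stopper.update(val_loss, epoch)
        if improved:
            best_snapshot = params.snapshot()
        if stop:
            break
    params.load_snapshot(best_snapshot)
    logger.info("fold %d: stopped at epoch %d, best epoch %d (val loss %.4f)",
                fold, records[-1]["epoch"], stopper.best_epoch, stopper.best)
    return EnsembleMember(params, fold, stopper.best_epoch, pd.DataFrame(records))


def train_ensemble(graph: KnowledgeGraph, split: LabeledSplit,
                   config: ModelConfig) -> EnsembleModel:
    """Train the five-fold ensemble with ADAM and early stopping.

    Member m trains on the training set minus fold m and uses fold m's
    validation loss for early stopping, restoring the best checkpoint. The
    test set is untouched.
    """
    views = derive_graph_views(graph.edge_src, graph.edge_dst, graph.edge_features)
    members = []
    for fold, val_fold in enumerate(split.folds):
        train_idx = np.setdiff1d(split.train_idx, val_fold)
        member_seed = int(np.random.default_rng([config.seed, fold]).integers(2**31))
        members.append(_train_member(graph, views, train_idx, val_fold,
                                     config, fold, member_seed))
    return EnsembleModel(members, config, config.seed, split)
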