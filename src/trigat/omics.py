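"""Omics preprocessing and knowledge-graph assembly.

Expression (or other omics) matrices provide the node features of the graph.
Preprocessing averages duplicate gene rows and removes genes whose expression
is zero in every sample; multiple omics types are combined by concatenating
their feature columns over the intersection of covered genes. The final
training object intersects the integrated interaction network with omics
coverage: genes without omics data are dropped from the graph together with
their edges, and known disease genes absent from the graph are discarded from
the positive set.

Labels use the positive-unlabeled convention: 1 = known disease gene,
0 = sampled negative, -1 = unlabeled.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .networks import IntegratedNetwork

__all__ = [
    "OmicsMatrix",
    "KnowledgeGraph",
    "preprocess_expression",
    "concat_omics",
    "build_knowledge_graph",
    "UNLABELED",
]

logger = logging.getLogger("trigat")

UNLABELED = -1


@dataclass
class OmicsMatrix:
    """A genes × features real matrix with row (gene) and column labels."""

    gene_ids: list[str]
    feature_labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.gene_ids), len(self.feature_labels)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.feature_labels)} features"
            )

    @classmethod
    def from_table(cls, path: str | Path, sep: str = "\t") -> "OmicsMatrix":
        """Read a table whose first column is the gene id, header = sample ids."""
        df = pd.read_csv(path, sep=sep, index_col=0)
        genes = [str(g).strip().upper() for g in df.index]
        return cls(genes, [str(c) for c in df.columns], df.to_numpy(dtype=np.float64))

    def to_table(self, path: str | Path, sep: str = "\t") -> None:
        pd.DataFrame(self.values, index=self.gene_ids,
                     columns=self.feature_labels).to_csv(path, sep=sep, index_label="gene")

    @property
    def shape(self):
        return self.values.shape


def preprocess_expression(raw: OmicsMatrix) -> OmicsMatrix:
    """Average duplicate gene rows and drop genes that are zero in all samples.

    Output rows are sorted by gene id, making the result independent of input
    row order. Raises if nothing survives.
    """
    if raw.values.shape[1] < 1:
        raise ValueError("expression matrix has no sample columns")
    df = pd.DataFrame(raw.values, index=raw.gene_ids)
    df = df.groupby(level=0, sort=True).mean()
    nonzero = (df != 0).any(axis=1)
    dropped = int((~nonzero).sum())
    if dropped:
        logger.info("preprocess_expression: removed %d all-zero gene rows", dropped)
    df = df.loc[nonzero]
    if df.empty:
        raise ValueError("expression matrix is empty after removing all-zero genes")
    return OmicsMatrix(list(df.index), list(raw.feature_labels), df.to_numpy())


def concat_omics(mats: list[OmicsMatrix], names: list[str] | None = None) -> OmicsMatrix:
    """Concatenate omics feature columns over the intersection of gene ids.

    Feature labels are prefixed with the omics name to stay unique.
    """
    if not mats:
        raise ValueError("concat_omics requires at least one matrix")
    if names is None:
        names = [f"omics{i}" for i in range(len(mats))]
    if len(mats) == 1:
        return mats[0]
    common = set(mats[0].gene_ids)
    for m in mats[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise ValueError("no genes shared by all omics matrices")
    genes = sorted(common)
    blocks, labels = [], []
    for name, m in zip(names, mats):
        pos = {g: i for i, g in enumerate(m.gene_ids)}
        blocks.append(m.values[[pos[g] for g in genes]])
        labels.extend(f"{name}:{lab}" for lab in m.feature_labels)
    return OmicsMatrix(genes, labels, np.concatenate(blocks, axis=1))


@dataclass
class KnowledgeGraph:
    """The training object: digraph + node features + edge features + labels.

    ``edge_src``/``edge_dst`` index into ``node_ids``; ``X`` is aligned to
    ``node_ids`` row by row; ``y`` is 1 for known positives, 0 for sampled
    negatives and -1 for unlabeled genes; ``provenance`` distinguishes
    known positives from sampled negatives.
    """

    node_ids: list[str]
    edge_src: np.ndarray
    edge_dst: np.ndarray
    edge_features: np.ndarray
    X: np.ndarray
    y: np.ndarray
    provenance: dict[str, set[str]] = field(default_factory=dict)
    feature_labels: list[str] = field(default_factory=list)
    database_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.edge_src = np.asarray(self.edge_src, dtype=np.int64)
        self.edge_dst = np.asarray(self.edge_dst, dtype=np.int64)
        self.edge_features = np.asarray(self.edge_features, dtype=np.float64)
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        n = len(self.node_ids)
        if self.X.shape[0] != n or self.y.shape[0] != n:
            raise ValueError("X and y must have one row/entry per node")
        if len(self.edge_src) != len(self.edge_dst) or \
                len(self.edge_src) != self.edge_features.shape[0]:
            raise ValueError("edge arrays misaligned")
        if len(self.edge_src):
            if self.edge_src.max() >= n or self.edge_dst.max() >= n:
                raise ValueError("edge endpoint outside node set")
            if (self.edge_src == self.edge_dst).any():
                raise ValueError("self-loop in knowledge graph")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edge_src)

    @property
    def positives(self) -> np.ndarray:
        return np.flatnonzero(self.y == 1)

    @property
    def labeled(self) -> np.ndarray:
        return np.flatnonzero(self.y != UNLABELED)

    def node_index(self, genes) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.node_ids)}
        return np.array([pos[g] for g in genes if g in pos], dtype=np.int64)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.Series(self.node_ids, name="gene").to_csv(outdir / "nodes.tsv", sep="\t", index=False)
        pd.DataFrame({"source": self.edge_src, "target": self.edge_dst}).to_csv(
            outdir / "edges.tsv", sep="\t", index=False)
        cols = self.database_names or [f"db{k}" for k in range(self.edge_features.shape[1])]
        pd.DataFrame(self.edge_features.astype(int), columns=cols).to_csv(
            outdir / "edge_features.tsv", sep="\t", index=False)
        labels = self.feature_labels or [f"f{k}" for k in range(self.X.shape[1])]
        pd.DataFrame(self.X, index=self.node_ids, columns=labels).to_csv(
            outdir / "X.tsv", sep="\t", index_label="gene")
        pd.DataFrame({"gene": self.node_ids, "label": self.y}).to_csv(
            outdir / "labels.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, indir: str | Path) -> "KnowledgeGraph":
        indir = Path(indir)
        nodes = pd.read_csv(indir / "nodes.tsv", sep="\t", dtype=str)["gene"].tolist()
        edges = pd.read_csv(indir / "edges.tsv", sep="\t")
        feats = pd.read_csv(indir / "edge_features.tsv", sep="\t")
        Xdf = pd.read_csv(indir / "X.tsv", sep="\t", index_col=0)
        labels = pd.read_csv(indir / "labels.tsv", sep="\t")
        return cls(nodes, edges["source"].to_numpy(), edges["target"].to_numpy(),
                   feats.to_numpy(), Xdf.to_numpy(), labels["label"].to_numpy(),
                   provenance={"positive": set(labels.loc[labels["label"] == 1, "gene"])},
                   feature_labels=[str(c) for c in Xdf.columns],
                   database_names=list(feats.columns))


def _scale_features(X: np.ndarray, scaling: str) -> np.ndarray:
    if scaling == "none":
        return X
    if scaling == "zscore":
        mu = X.mean(axis=0, keepdims=True)
        sd = X.std(axis=0, keepdims=True)
        sd[sd == 0] = 1.0
        return (X - mu) / sd
    if scaling == "minmax":
        lo = X.min(axis=0, keepdims=True)
        rng = X.max(axis=0, keepdims=True) - lo
        rng[rng == 0] = 1.0
        return (X - lo) / rng
    raise ValueError(f"unknown scaling: {scaling}")


def build_knowledge_graph(net: IntegratedNetwork, omics: OmicsMatrix,
                          positives, scaling: str = "zscore") -> KnowledgeGraph:
    """Intersect network, omics coverage and known positives into one graph.

    Nodes are the network genes that have omics data; edges with a dropped
    endpoint are removed (their database features with them); known disease
    genes not covered by the surviving graph are discarded with a warning.
    Feature columns are scaled after the overlap (default z-score).
    """
    if not net.edges or not len(omics.gene_ids):
        raise ValueError("network and omics must be nonempty")
    positives = {str(g).strip().upper() for g in positives}
    omics_pos = {g: i for i, g in enumerate(omics.gene_ids)}
    nodes = [g for g in net.node_ids if g in omics_pos]
    node_pos = {g: i for i, g in enumerate(nodes)}
    n_dropped_nodes = len(net.node_ids) - len(nodes)
    if not nodes:
        raise ValueError("no network gene has omics data")

    keep = [i for i, (u, v) in enumerate(net.edges)
            if u in node_pos and v in node_pos]
    n_dropped_edges = len(net.edges) - len(keep)
    edge_src = np.array([node_pos[net.edges[i][0]] for i in keep], dtype=np.int64)
    edge_dst = np.array([node_pos[net.edges[i][1]] for i in keep], dtype=np.int64)
    edge_features = np.asarray(net.edge_features, dtype=np.float64)[keep]

    X = _scale_features(omics.values[[omics_pos[g] for g in nodes]], scaling)

    kept_pos = positives & set(nodes)
    lost = positives - kept_pos
    if lost:
        warnings.warn(f"{len(lost)} known disease genes not covered by the graph; dropped")
    if not kept_pos:
        raise ValueError("no known disease gene survives the network/omics overlap; "
                         "the model cannot be trained")
    y = np.full(len(nodes), UNLABELED, dtype=np.int64)
    y[[node_pos[g] for g in kept_pos]] = 1

    logger.info("build_knowledge_graph: dropped %d nodes, %d edges, %d positives",
                n_dropped_nodes, n_dropped_edges, len(lost))
    return KnowledgeGraph(
        nodes, edge_src, edge_dst, edge_features, X, y,
        provenance={"positive": kept_pos, "sampled_negative": set()},
        feature_labels=list(omics.feature_labels),
        database_names=list(net.database_names),
    )
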