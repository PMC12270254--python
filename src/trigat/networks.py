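"""Multi-database gene interaction network integration.

Each source database contributes one edge list (directed regulatory links or
undirected protein–protein interactions). Undirected networks are converted to
paired reverse directed edges, every network is stripped of duplicate edges and
self-loops, and the cleaned networks are unioned into one directed graph. Each
union edge carries a d-dimensional 0/1 membership vector marking which of the
d databases record that interaction; this vector later enters the attention
coefficients as an edge feature.

Gene identifiers are treated as opaque case-normalized strings (uppercased,
whitespace-stripped). Cross-database identifier harmonization (e.g. gene
symbol vs. Entrez) is the caller's responsibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GeneNetwork",
    "IntegratedNetwork",
    "load_edge_list",
    "filter_by_confidence",
    "symmetrize_undirected",
    "clean_network",
    "union_networks",
    "build_from_manifest",
]


def _norm_gene(g) -> str:
    s = str(g).strip().upper()
    if not s or s == "NAN":
        raise ValueError(f"empty or invalid gene identifier: {g!r}")
    return s


@dataclass
class GeneNetwork:
    """One source database's edge list.

    ``edges`` is an ordered list of (source, target) gene-id pairs; ``scores``
    optionally carries per-edge confidence (numeric or category label) aligned
    with ``edges``.
    """

    name: str
    edges: list[tuple[str, str]]
    directed: bool
    scores: list | None = None

    def __post_init__(self):
        if self.scores is not None and len(self.scores) != len(self.edges):
            raise ValueError(
                f"{self.name}: {len(self.scores)} scores for {len(self.edges)} edges"
            )

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def is_clean(self) -> bool:
        seen = set()
        for u, v in self.edges:
            if u == v or (u, v) in seen:
                return False
            seen.add((u, v))
        return True


@dataclass
class IntegratedNetwork:
    """Union digraph with per-edge database-membership 0/1 features."""

    node_ids: list[str]
    edges: list[tuple[str, str]]
    edge_features: np.ndarray  # (n_edges, d) over {0, 1}
    database_names: list[str]

    def __post_init__(self):
        self.edge_features = np.asarray(self.edge_features, dtype=np.int8)
        if self.edge_features.shape != (len(self.edges), len(self.database_names)):
            raise ValueError("edge_features shape inconsistent with edges/databases")
        if len(self.edges) and not self.edge_features.any(axis=1).all():
            raise ValueError("every edge must belong to at least one database")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def d(self) -> int:
        return len(self.database_names)

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.edges, columns=["source", "target"]).to_csv(
            outdir / "edges.tsv", sep="\t", index=False
        )
        pd.DataFrame(self.edge_features, columns=self.database_names).to_csv(
            outdir / "edge_features.tsv", sep="\t", index=False
        )

    @classmethod
    def load(cls, indir: str | Path) -> "IntegratedNetwork":
        indir = Path(indir)
        ed = pd.read_csv(indir / "edges.tsv", sep="\t", dtype=str)
        feats = pd.read_csv(indir / "edge_features.tsv", sep="\t")
        edges = list(zip(ed["source"], ed["target"]))
        nodes = sorted({g for e in edges for g in e})
        return cls(nodes, edges, feats.to_numpy(), list(feats.columns))


def load_edge_list(path: str | Path, dialect: dict | None = None,
                   directed: bool = True, name: str | None = None) -> GeneNetwork:
    """Read an edge list from a delimited text file.

    ``dialect`` may specify ``sep`` (default tab/whitespace), and column
    positions or names for ``source``, ``target`` and optional ``score``.
    No cleaning is applied.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = dict(dialect or {})
    sep = dialect.get("sep", r"\s+")
    src_col = dialect.get("source", 0)
    tgt_col = dialect.get("target", 1)
    score_col = dialect.get("score", None)
    has_header = dialect.get("header", False)
    try:
        df = pd.read_csv(path, sep=sep, header=0 if has_header else None,
                         dtype=str, comment="#", engine="python")
    except pd.errors.EmptyDataError:
        df = pd.DataFrame()
    if df.empty:
        warnings.warn(f"{path}: empty edge list")
        return GeneNetwork(name or path.stem, [], directed, None)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 columns, found {df.shape[1]}")

    def col(spec):
        return df[spec] if isinstance(spec, str) else df.iloc[:, spec]

    edges, scores = [], []
    src, tgt = col(src_col), col(tgt_col)
    sc = col(score_col) if score_col is not None else None
    for i in range(len(df)):
        try:
            edges.append((_norm_gene(src.iloc[i]), _norm_gene(tgt.iloc[i])))
        except ValueError as exc:
            raise ValueError(f"{path}: unparseable row {i + 1}: {exc}") from exc
        if sc is not None:
            val = sc.iloc[i]
            try:
                scores.append(float(val))
            except (TypeError, ValueError):
                scores.append(str(val).strip())
    return GeneNetwork(name or path.stem, edges, directed,
                       scores if sc is not None else None)


def filter_by_confidence(net: GeneNetwork, threshold, mode: str) -> GeneNetwork:
    """Keep high-confidence edges.

    ``mode="numeric"`` keeps edges with score strictly greater than
    ``threshold`` (e.g. >0.5 or >0.85 for scored interaction databases);
    ``mode="categorical"`` keeps edges whose label is in the retained set
    (e.g. {"high", "middle"} for confidence-graded regulatory links).
    """
    if mode not in ("numeric", "categorical"):
        raise ValueError(f"unknown filter mode: {mode}")
    if not net.edges:
        return replace(net, edges=[], scores=[] if net.scores is not None else None)
    if net.scores is None:
        raise ValueError(f"{net.name}: cannot filter a network without scores")
    keep_edges, keep_scores = [], []
    if mode == "numeric":
        for e, s in zip(net.edges, net.scores):
            if float(s) > float(threshold):
                keep_edges.append(e)
                keep_scores.append(s)
    else:
        retained = {str(t).strip().lower() for t in
                    (threshold if isinstance(threshold, (set, list, tuple)) else [threshold])}
        for e, s in zip(net.edges, net.scores):
            label = str(s).strip().lower()
            if label in retained:
                keep_edges.append(e)
                keep_scores.append(s)
    return replace(net, edges=keep_edges, scores=keep_scores)


def symmetrize_undirected(net: GeneNetwork) -> GeneNetwork:
    """Convert an undirected network into paired reverse directed edges.

    Every undirected pair (u, v) yields directed edges (u, v) and (v, u); the
    output is marked directed. Calling on an already-directed network is a
    warned no-op.
    """
    if net.directed:
        warnings.warn(f"{net.name}: symmetrize_undirected called on a directed network")
        return net
    edges, scores = [], [] if net.scores is not None else None
    for i, (u, v) in enumerate(net.edges):
        edges.append((u, v))
        edges.append((v, u))
        if scores is not None:
            scores.extend([net.scores[i], net.scores[i]])
    return replace(net, edges=edges, scores=scores, directed=True)


def clean_network(net: GeneNetwork) -> GeneNetwork:
    """Remove self-loops and duplicate ordered edges (first occurrence kept)."""
    seen: set[tuple[str, str]] = set()
    edges, scores = [], [] if net.scores is not None else None
    for i, (u, v) in enumerate(net.edges):
        if u == v or (u, v) in seen:
            continue
        seen.add((u, v))
        edges.append((u, v))
        if scores is not None:
            scores.append(net.scores[i])
    return replace(net, edges=edges, scores=scores)


def union_networks(nets: list[GeneNetwork]) -> IntegratedNetwork:
    """Union cleaned directed networks into one digraph with membership features.

    The edge set is the union of ordered edges across all databases; the
    feature row of each edge has a 1 in column k iff database k records that
    ordered edge. Edges are sorted by (source, target) so the result is
    independent of input edge order.
    """
    if not nets:
        raise ValueError("union_networks requires at least one network")
    for net in nets:
        if not net.directed:
            raise ValueError(f"{net.name}: undirected network passed to union (symmetrize first)")
        if not net.is_clean():
            raise ValueError(f"{net.name}: network has self-loops or duplicate edges (clean first)")
    all_edges = sorted({e for net in nets for e in net.edges})
    index = {e: i for i, e in enumerate(all_edges)}
    feats = np.zeros((len(all_edges), len(nets)), dtype=np.int8)
    for k, net in enumerate(nets):
        for e in net.edges:
            feats[index[e], k] = 1
    nodes = sorted({g for e in all_edges for g in e})
    return IntegratedNetwork(nodes, all_edges, feats, [net.name for net in nets])


def build_from_manifest(manifest_path: str | Path) -> IntegratedNetwork:
    """Run the full per-database pipeline described by a YAML manifest.

    The manifest is a list of entries with keys ``name``, ``path``,
    ``directed`` and optionally ``filter`` ({mode, threshold}) and
    ``dialect``; paths are resolved relative to the manifest file.
    """
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        entries = yaml.safe_load(fh)
    nets = []
    for entry in entries:
        path = Path(entry["path"])
        if not path.is_absolute():
            path = manifest_path.parent / path
        net = load_edge_list(path, dialect=entry.get("dialect"),
                             directed=bool(entry["directed"]), name=entry["name"])
        filt = entry.get("filter")
        if filt:
            thr = filt["threshold"]
            if filt["mode"] == "categorical" and isinstance(thr, list):
                thr = set(thr)
            net = filter_by_confidence(net, thr, filt["mode"])
        if not net.directed:
            net = symmetrize_undirected(net)
        nets.append(clean_network(net))
    return union_networks(nets)
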