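"""Three-view graph attention (triGAT) with database-membership edge features.

The model classifies graph nodes (genes) with stacked graph-attention layers.
For a node i, attention runs over its in-neighbors j (edges j→i) plus a self
term; the unnormalized attention logit concatenates the transformed features
of both endpoints and of the edge:

    logit_ij = LeakyReLU( aᵀ [ W x_i ‖ W x_j ‖ W_e e_ij ] )
    α_ij     = softmax_j( logit_ij )        over j ∈ N_in(i) ∪ {i}
    x'_i     = σ( Σ_j α_ij W x_j )

where e_ij is the d-dimensional 0/1 database-membership vector of edge j→i.
The self term uses the all-zero edge vector: a self-interaction is recorded in
no database, which is exactly what the zero vector encodes.

On a directed graph this scheme only moves information along edge direction.
A triGAT layer therefore runs three parallel GATs — on the original digraph
G1, the edge-reversed digraph G2 and the bidirectionalized graph G3 — with
shared input features, and concatenates their outputs, so downstream genes
can feed information back to upstream ones without discarding direction.

Multi-head attention follows the usual convention: hidden layers concatenate
the K head outputs, the final layer averages them before the output head
(a linear map to one logit per node followed by a sigmoid).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .autodiff import Parameter, Tensor, concat, gather, segment_sum

__all__ = [
    "ModelConfig",
    "GraphViews",
    "GATViewParams",
    "TriGATParams",
    "derive_graph_views",
    "attention_coefficients",
    "gat_layer",
    "trigat_layer",
    "model_forward",
    "cross_entropy_loss",
]

ALL_VIEWS = ("G1", "G2", "G3")


@dataclass
class ModelConfig:
    """Hyperparameters of the triGAT classifier.

    ``views`` selects which graph views each layer uses: the default is the
    full three-view model; ``("G1",)`` gives a plain single-direction GAT on
    the original digraph (used in the directionality ablation).
    """

    num_trigat_layers: int = 2
    heads: int = 4                  # K attention heads per view
    hidden_dim: int = 16            # F', per-head output width
    leaky_relu_slope: float = 0.2
    head_combine: str = "auto"      # concat | average | auto (concat hidden, average last)
    dropout: float = 0.1
    learning_rate: float = 1e-3
    weight_decay: float = 0.0
    patience: int = 20
    max_epochs: int = 1000
    seed: int = 0
    views: tuple = ALL_VIEWS
    edge_hidden_dim: int | None = None  # F'_e; defaults to hidden_dim

    def __post_init__(self):
        self.views = tuple(self.views)
        if self.heads < 1 or self.hidden_dim < 1 or self.num_trigat_layers < 1:
            raise ValueError("heads, hidden_dim and num_trigat_layers must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if unknown := set(self.views) - set(ALL_VIEWS):
            raise ValueError(f"unknown views: {unknown}")
        if self.head_combine not in ("auto", "concat", "average"):
            raise ValueError(f"unknown head_combine: {self.head_combine}")

    @property
    def edge_dim_hidden(self) -> int:
        return self.edge_hidden_dim if self.edge_hidden_dim is not None else self.hidden_dim

    def combine_for_layer(self, layer: int) -> str:
        if self.head_combine != "auto":
            return self.head_combine
        return "average" if layer == self.num_trigat_layers - 1 else "concat"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str | Path) -> None:
        data = {**self.__dict__, "views": list(self.views)}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


@dataclass
class GraphViews:
    """Edge arrays and per-edge features of the three graph views.

    G2 reverses every G1 edge, keeping its feature row. G3 is the union of G1
    with its reverse: an edge already present in G1 keeps its own feature row
    and an added reverse edge inherits the feature row of the edge it mirrors.
    """

    views: dict  # name -> (src, dst, edge_features)

    def __getitem__(self, name: str):
        return self.views[name]


def derive_graph_views(edge_src: np.ndarray, edge_dst: np.ndarray,
                       edge_features: np.ndarray) -> GraphViews:
    edge_src = np.asarray(edge_src, dtype=np.int64)
    edge_dst = np.asarray(edge_dst, dtype=np.int64)
    edge_features = np.asarray(edge_features, dtype=np.float64)
    g1 = (edge_src, edge_dst, edge_features)
    g2 = (edge_dst.copy(), edge_src.copy(), edge_features)
    present = {(int(u), int(v)): i for i, (u, v) in enumerate(zip(edge_src, edge_dst))}
    src3 = list(edge_src)
    dst3 = list(edge_dst)
    feat3 = list(edge_features)
    for i, (u, v) in enumerate(zip(edge_src, edge_dst)):
        if (int(v), int(u)) not in present:
            src3.append(v)
            dst3.append(u)
            feat3.append(edge_features[i])
    g3 = (np.asarray(src3, dtype=np.int64), np.asarray(dst3, dtype=np.int64),
          np.asarray(feat3, dtype=np.float64).reshape(len(src3), -1))
    return GraphViews({"G1": g1, "G2": g2, "G3": g3})


# ---------------------------------------------------------------------------
# parameters


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


@dataclass
class GATViewParams:
    """Trainable weights of one GAT view: per head, a linear map W (F→F'),
    attention vector a (split into its destination/source/edge blocks), the
    edge-feature map W_e (d→F'_e) and a bias."""

    W: list          # K of (F_in, F')
    a_dst: list      # K of (F', 1) — block of a applied to W x_i
    a_src: list      # K of (F', 1) — block of a applied to W x_j
    a_e: list        # K of (F'_e, 1) — block of a applied to W_e e_ij
    W_e: list        # K of (d, F'_e)
    bias: list       # K of (1, F')

    @classmethod
    def init(cls, rng: np.random.Generator, in_dim: int, out_dim: int,
             edge_dim: int, edge_out_dim: int, heads: int) -> "GATViewParams":
        mk = lambda *s: Parameter(_glorot(rng, *s))
        return cls(
            W=[mk(in_dim, out_dim) for _ in range(heads)],
            a_dst=[mk(out_dim, 1) for _ in range(heads)],
            a_src=[mk(out_dim, 1) for _ in range(heads)],
            a_e=[mk(edge_out_dim, 1) for _ in range(heads)],
            W_e=[mk(edge_dim, edge_out_dim) for _ in range(heads)],
            bias=[Parameter(np.zeros((1, out_dim))) for _ in range(heads)],
        )

    def parameters(self) -> list[Tensor]:
        return [*self.W, *self.a_dst, *self.a_src, *self.a_e, *self.W_e, *self.bias]

    @property
    def heads(self) -> int:
        return len(self.W)


@dataclass
class TriGATParams:
    """All trainable weights: per layer one GATViewParams per view (the view
    parameter sets are independent, not tied), plus the output head."""

    layers: list          # per layer: dict view name -> GATViewParams
    W_out: Tensor
    b_out: Tensor
    views: tuple = ALL_VIEWS

    @classmethod
    def init(cls, config: ModelConfig, in_dim: int, edge_dim: int,
             rng: np.random.Generator | None = None) -> "TriGATParams":
        rng = rng if rng is not None else np.random.default_rng(config.seed)
        layers = []
        dim = in_dim
        for layer in range(config.num_trigat_layers):
            layers.append({
                view: GATViewParams.init(rng, dim, config.hidden_dim, edge_dim,
                                         config.edge_dim_hidden, config.heads)
                for view in config.views
            })
            per_view = (config.hidden_dim * config.heads
                        if config.combine_for_layer(layer) == "concat"
                        else config.hidden_dim)
            dim = per_view * len(config.views)
        return cls(layers, W_out=Parameter(_glorot(rng, dim, 1)),
                   b_out=Parameter(np.zeros((1, 1))), views=config.views)

    def parameters(self) -> list[Tensor]:
        params = []
        for layer in self.layers:
            for view in self.views:
                params.extend(layer[view].parameters())
        params.extend([self.W_out, self.b_out])
        return params

    def snapshot(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_snapshot(self, snap: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), snap, strict=True):
            p.data = s.copy()

    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": a for i, a in enumerate(self.snapshot())}
        np.savez(path, n_layers=len(self.layers), views="|".join(self.views), **arrays)


# ---------------------------------------------------------------------------
# forward pass


def _attention_parts(X: Tensor, E: Tensor, src: np.ndarray, dst: np.ndarray,
                     params: GATViewParams, head: int, slope: float):
    """Edge and self attention weights plus the transformed features z = XW.

    Returns (alpha_edge (M,1), alpha_self (N,1), z (N,F')) as Tensors; the
    softmax for node i runs over its in-edges plus the self term, with the
    self term's edge feature fixed at the zero vector.
    """
    n = X.shape[0]
    z = X @ params.W[head]
    s_dst = (z @ params.a_dst[head]).reshape(n)
    s_src = (z @ params.a_src[head]).reshape(n)
    edge_logits = (gather(s_dst, dst) + gather(s_src, src)
                   + ((E @ params.W_e[head]) @ params.a_e[head]).reshape(len(src))
                   ).leaky_relu(slope)
    self_logits = (s_dst + s_src).leaky_relu(slope)  # zero edge vector: no edge term

    # per-node max over the neighborhood, detached, for softmax stability
    m = self_logits.data.copy()
    if len(src):
        np.maximum.at(m, dst, edge_logits.data)
    exp_edge = (edge_logits - Tensor(m[dst])).exp() if len(src) else None
    exp_self = (self_logits - Tensor(m)).exp()
    denom = exp_self
    if exp_edge is not None:
        denom = denom + segment_sum(exp_edge, dst, n)
    alpha_self = (exp_self / denom).reshape(n, 1)
    alpha_edge = ((exp_edge / gather(denom, dst)).reshape(len(src), 1)
                  if exp_edge is not None else Tensor(np.zeros((0, 1))))
    return alpha_edge, alpha_self, z


def attention_coefficients(X, E, src, dst, params: GATViewParams, head: int = 0,
                           slope: float = 0.2):
    """Normalized attention weights for one head on one graph view.

    Returns ``(alpha_edge, alpha_self)`` numpy arrays: ``alpha_edge[m]`` is
    the weight of edge ``src[m]→dst[m]`` at node ``dst[m]``; ``alpha_self[i]``
    is node i's self-attention weight. For every node the weights over its
    in-edges plus self sum to 1.
    """
    X = X if isinstance(X, Tensor) else Tensor(np.asarray(X, dtype=np.float64))
    E = E if isinstance(E, Tensor) else Tensor(np.asarray(E, dtype=np.float64))
    if X.data.shape[1] != params.W[head].data.shape[0]:
        raise ValueError("node feature dimension does not match W")
    ae, aself, _ = _attention_parts(X, E, np.asarray(src), np.asarray(dst),
                                    params, head, slope)
    out_e, out_s = ae.data.ravel(), aself.data.ravel()
    if not (np.isfinite(out_e).all() and np.isfinite(out_s).all()):
        raise FloatingPointError("non-finite attention coefficients")
    return out_e, out_s


def gat_layer(X: Tensor, E: Tensor, src: np.ndarray, dst: np.ndarray,
              params: GATViewParams, slope: float = 0.2, combine: str = "concat",
              activation: str = "elu") -> Tensor:
    """One multi-head GAT layer on a single graph view.

    Per head: x'_i = σ(Σ_{j∈N_in(i)∪{i}} α_ij W x_j). Heads are concatenated
    (output width K·F') or averaged (width F') before σ in the average case.
    """
    n = X.shape[0]
    heads_out = []
    for k in range(params.heads):
        alpha_edge, alpha_self, z = _attention_parts(X, E, src, dst, params, k, slope)
        agg = alpha_self * z
        if len(src):
            agg = agg + segment_sum(alpha_edge * gather(z, src), dst, n)
        heads_out.append(agg + params.bias[k])

    def act(t: Tensor) -> Tensor:
        if activation == "elu":
            return t.elu()
        if activation == "none":
            return t
        raise ValueError(f"unknown activation: {activation}")

    if combine == "concat":
        return concat([act(h) for h in heads_out], axis=1)
    if combine == "average":
        total = heads_out[0]
        for h in heads_out[1:]:
            total = total + h
        return act(total * (1.0 / len(heads_out)))
    raise ValueError(f"unknown head combine: {combine}")


def trigat_layer(X: Tensor, views: GraphViews, params: dict,
                 slope: float = 0.2, combine: str = "concat",
                 activation: str = "elu", view_names: tuple = ALL_VIEWS) -> Tensor:
    """One triGAT layer: per-view GATs on shared inputs, outputs concatenated."""
    outs = []
    for name in view_names:
        src, dst, feats = views[name]
        outs.append(gat_layer(X, Tensor(feats), src, dst, params[name],
                              slope=slope, combine=combine, activation=activation))
    return concat(outs, axis=1) if len(outs) > 1 else outs[0]


def model_forward(graph, params: TriGATParams, config: ModelConfig,
                  views: GraphViews | None = None, training: bool = False,
                  rng: np.random.Generator | None = None) -> Tensor:
    """Full forward pass: stacked triGAT layers, linear output head, sigmoid.

    Returns a Tensor of per-node probabilities in (0, 1). ``graph`` is a
    KnowledgeGraph (or anything with X, edge_src, edge_dst, edge_features).
    Dropout is applied to layer inputs only when ``training`` is True.
    """
    if views is None:
        views = derive_graph_views(graph.edge_src, graph.edge_dst, graph.edge_features)
    h = Tensor(np.asarray(graph.X, dtype=np.float64))
    for layer_idx, layer_params in enumerate(params.layers):
        if training and config.dropout > 0:
            if rng is None:
                rng = np.random.default_rng(config.seed)
            keep = (rng.random(h.shape) >= config.dropout) / (1.0 - config.dropout)
            h = h * Tensor(keep)
        h = trigat_layer(h, views, layer_params, slope=config.leaky_relu_slope,
                         combine=config.combine_for_layer(layer_idx),
                         view_names=params.views)
        if not np.isfinite(h.data).all():
            raise FloatingPointError(f"non-finite activations after layer {layer_idx}")
    logits = h @ params.W_out + params.b_out
    out = logits.sigmoid().reshape(h.shape[0])
    if not np.isfinite(out.data).all():
        raise FloatingPointError("non-finite model output")
    return out


def cross_entropy_loss(y, h: Tensor) -> Tensor:
    """Mean binary cross-entropy −y·log(h) − (1−y)·log(1−h) over labeled nodes.

    Probabilities are clamped to [1e-7, 1−1e-7] before the logs.
    """
    y = np.asarray(y, dtype=np.float64)
    if y.shape != h.data.shape:
        raise ValueError(f"label shape {y.shape} != prediction shape {h.data.shape}")
    if y.size == 0:
        raise ValueError("empty label set")
    if ((y != 0) & (y != 1)).any():
        raise ValueError("labels must be 0 or 1")
    hc = h.clip(1e-7, 1.0 - 1e-7)
    yt = Tensor(y)
    one = Tensor(np.ones_like(y))
    return -(yt * hc.log() + (one - yt) * (one - hc).log()).mean()
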