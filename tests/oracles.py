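"""Independent brute-force reference implementations used by the tests.

Everything here is written with explicit Python loops over nodes and dense
per-neighborhood arithmetic, deliberately sharing no code with the package's
vectorized/autodiff path, so oracle agreement is a meaningful check.
"""

import numpy as np


def leaky_relu(x, slope):
    return np.where(x > 0, x, slope * x)


def elu(x):
    return np.where(x > 0, x, np.exp(np.minimum(x, 0)) - 1.0)


def dense_attention(X, E, edges, W, a_dst, a_src, a_e, W_e, slope):
    """Attention weights by explicit per-node softmax over in-neighbors + self.

    ``edges`` is a list of (src, dst) node indices; ``E[m]`` the feature of
    edge m. Returns (alpha_edge, alpha_self) like the package API. The self
    term uses a zero edge-feature vector.
    """
    n = X.shape[0]
    logits_per_node = {i: {} for i in range(n)}
    for m, (j, i) in enumerate(edges):
        vec = np.concatenate([W.T @ X[i], W.T @ X[j], W_e.T @ E[m]])
        att = np.concatenate([a_dst.ravel(), a_src.ravel(), a_e.ravel()])
        logits_per_node[i][("edge", m)] = leaky_relu(float(att @ vec), slope)
    for i in range(n):
        vec = np.concatenate([W.T @ X[i], W.T @ X[i], W_e.T @ np.zeros(E.shape[1])])
        att = np.concatenate([a_dst.ravel(), a_src.ravel(), a_e.ravel()])
        logits_per_node[i][("self", i)] = leaky_relu(float(att @ vec), slope)
    alpha_edge = np.zeros(len(edges))
    alpha_self = np.zeros(n)
    for i in range(n):
        keys = list(logits_per_node[i])
        vals = np.array([logits_per_node[i][k] for k in keys])
        ex = np.exp(vals - vals.max())
        soft = ex / ex.sum()
        for k, s in zip(keys, soft):
            if k[0] == "edge":
                alpha_edge[k[1]] = s
            else:
                alpha_self[i] = s
    return alpha_edge, alpha_self


def dense_gat_layer(X, E, edges, params_np, slope, combine, activation="elu"):
    """One multi-head GAT layer via the dense attention oracle.

    ``params_np`` is a list of per-head dicts with numpy arrays
    W, a_dst, a_src, a_e, W_e, bias.
    """
    n = X.shape[0]
    head_outs = []
    for p in params_np:
        ae, aself = dense_attention(X, E, edges, p["W"], p["a_dst"], p["a_src"],
                                    p["a_e"], p["W_e"], slope)
        out = np.zeros((n, p["W"].shape[1]))
        for i in range(n):
            out[i] = aself[i] * (p["W"].T @ X[i])
        for m, (j, i) in enumerate(edges):
            out[i] += ae[m] * (p["W"].T @ X[j])
        head_outs.append(out + p["bias"])
    act = elu if activation == "elu" else (lambda x: x)
    if combine == "concat":
        return np.concatenate([act(h) for h in head_outs], axis=1)
    return act(np.mean(head_outs, axis=0))


def view_edges(edges, E, view):
    """Edge list and features of a graph view, by explicit set operations."""
    if view == "G1":
        return list(edges), np.array(E)
    if view == "G2":
        return [(i, j) for (j, i) in edges], np.array(E)
    present = {tuple(e): m for m, e in enumerate(edges)}
    out_edges, out_feats = list(edges), [np.array(f) for f in E]
    for m, (j, i) in enumerate(edges):
        if (i, j) not in present:
            out_edges.append((i, j))
            out_feats.append(np.array(E[m]))
    return out_edges, np.array(out_feats)


def dense_trigat_layer(X, E, edges, params_np_by_view, slope, combine, views):
    blocks = []
    for view in views:
        ve, vf = view_edges(edges, E, view)
        blocks.append(dense_gat_layer(X, vf, ve, params_np_by_view[view],
                                      slope, combine))
    return np.concatenate(blocks, axis=1)


def dense_forward(X, E, edges, layers_np, W_out, b_out, slope, combines, views):
    """Full forward pass via the dense oracle; returns sigmoid probabilities."""
    h = np.array(X)
    for layer, combine in zip(layers_np, combines):
        h = dense_trigat_layer(h, E, edges, layer, slope, combine, views)
    logits = h @ W_out + b_out
    return (1.0 / (1.0 + np.exp(-logits))).ravel()


def params_to_numpy(view_params):
    """Extract per-head numpy dicts from a GATViewParams."""
    return [
        {"W": view_params.W[k].data, "a_dst": view_params.a_dst[k].data,
         "a_src": view_params.a_src[k].data, "a_e": view_params.a_e[k].data,
         "W_e": view_params.W_e[k].data, "bias": view_params.bias[k].data}
        for k in range(view_params.heads)
    ]


def pairwise_auroc(y, scores):
    """AUROC by exhaustive positive/negative pair comparison (ties = 1/2)."""
    y = np.asarray(y)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y == 1]
    neg = scores[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def random_graph(rng, n_nodes, n_edges, feat_dim, edge_dim):
    """A random digraph with features, for oracle-equivalence trials."""
    edges = set()
    guard = 0
    while len(edges) < n_edges and guard < 50 * n_edges:
        guard += 1
        u, v = rng.integers(n_nodes, size=2)
        if u != v:
            edges.add((int(u), int(v)))
    edges = sorted(edges)
    X = rng.standard_normal((n_nodes, feat_dim))
    E = (rng.random((len(edges), edge_dim)) < 0.5).astype(float)
    E[E.sum(axis=1) == 0, 0] = 1.0  # membership vectors have >= one database
    return X, E, edges
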