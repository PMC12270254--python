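"""Seeded synthetic benchmarks with the statistical structure the method assumes.

The generator emulates the real inputs end to end: a ground-truth gene
interaction digraph, several overlapping pseudo-databases derived from it
(partial coverage plus uniformly random false edges, some emitted as
undirected PPI-style lists), an expression matrix in which planted disease
genes carry a mean shift, and a known-positive list with a held-out fraction
of planted genes withheld as "novel disease gene" ground truth.

A second scenario plants held-out disease genes strictly upstream or strictly
downstream of the training positives (layered construction, so reachability
is guaranteed by edge orientation alone); it exists to expose the
directionality bias of single-direction message passing and how the
three-view model removes it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .networks import GeneNetwork
from .omics import OmicsMatrix

__all__ = [
    "SyntheticSpec",
    "Benchmark",
    "generate_benchmark",
    "generate_updown_scenario",
    "write_benchmark",
]


@dataclass
class SyntheticSpec:
    """Parameters of the synthetic benchmark.

    ``coverage`` is the fraction of ground-truth edges each pseudo-database
    samples; ``false_edge_rate`` the fraction of extra random non-edges mixed
    in; ``effect_size`` the disease-gene expression mean shift in SD units of
    the per-sample Gaussian noise; ``propagation_depth`` how many directed
    hops from a disease gene still receive an (exponentially decaying) share
    of the shift; ``n_positives`` counts all planted disease genes, of which
    ``held_out_fraction`` is withheld from the known-positive list.
    """

    n_genes: int = 400
    n_edges: int = 2000
    n_databases: int = 4
    coverage: float = 0.6
    false_edge_rate: float = 0.05
    n_positives: int = 40
    n_samples: int = 20
    effect_size: float = 1.0
    propagation_depth: int = 1
    propagation_decay: float = 0.5
    held_out_fraction: float = 0.25
    graph_model: str = "er"  # er | pa (preferential attachment)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_genes, self.n_edges, self.n_databases,
               self.n_positives, self.n_samples) < 1:
            raise ValueError("all counts must be positive")
        if not (0 <= self.coverage <= 1 and 0 <= self.false_edge_rate <= 1
                and 0 <= self.held_out_fraction < 1):
            raise ValueError("coverage, false_edge_rate and held_out_fraction "
                             "must lie in [0, 1]")
        if self.n_positives >= self.n_genes:
            raise ValueError("disease module larger than the gene set")
        if self.graph_model not in ("er", "pa"):
            raise ValueError(f"unknown graph model: {self.graph_model}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticSpec":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class Benchmark:
    """One generated dataset: pseudo-database networks, omics, labels, truth."""

    networks: list             # GeneNetwork per pseudo-database (raw, uncleaned)
    omics: OmicsMatrix
    positives: list            # known (training) disease genes
    held_out: list             # withheld disease genes = novel-gene ground truth
    disease_genes: list        # all planted disease genes
    true_edges: list           # ground-truth digraph edge list
    spec: SyntheticSpec
    strata: dict = field(default_factory=dict)  # upstream/downstream, when planted


def _gene_ids(n: int) -> list:
    return [f"G{i:04d}" for i in range(n)]


def _sample_digraph(rng: np.random.Generator, n: int, m: int,
                    model: str) -> list:
    """Distinct ordered non-self pairs: uniform (er) or preferential attachment."""
    if m > n * (n - 1):
        raise ValueError("more edges requested than ordered pairs available")
    edges: set = set()
    if model == "pa":
        # grow with degree-biased target choice, random orientation
        degree = np.ones(n)
        while len(edges) < m:
            u = int(rng.integers(n))
            v = int(rng.choice(n, p=degree / degree.sum()))
            if u == v:
                continue
            e = (u, v) if rng.random() < 0.5 else (v, u)
            if e not in edges:
                edges.add(e)
                degree[u] += 1
                degree[v] += 1
    else:
        while len(edges) < m:
            u, v = rng.integers(n, size=2)
            if u != v:
                edges.add((int(u), int(v)))
    return sorted(edges)


def _connected_module(rng: np.random.Generator, n: int, edges: list,
                      size: int) -> list:
    """BFS over the underlying undirected graph from a random start node."""
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    order = rng.permutation(n)
    start = next((int(g) for g in order if adj.get(int(g))), int(order[0]))
    module, frontier, seen = [], [start], {start}
    while frontier and len(module) < size:
        node = frontier.pop(0)
        module.append(node)
        nbrs = sorted(adj.get(node, ()))
        rng.shuffle(nbrs)
        for nb in nbrs:
            if nb not in seen:
                seen.add(nb)
                frontier.append(nb)
    # top up from arbitrary unvisited genes if the component was too small
    for g in order:
        if len(module) >= size:
            break
        if int(g) not in set(module):
            module.append(int(g))
    return module[:size]


def _disease_genes(rng: np.random.Generator, spec: SyntheticSpec,
                   edges: list) -> list:
    """A connected module plus a decaying sample of its 1-hop out-neighbors."""
    core_size = max(1, int(round(0.7 * spec.n_positives)))
    core = _connected_module(rng, spec.n_genes, edges, core_size)
    chosen = list(core)
    out_nbrs = sorted({v for u, v in edges if u in set(core)} - set(core))
    rng.shuffle(out_nbrs)
    for nb in out_nbrs:
        if len(chosen) >= spec.n_positives:
            break
        if rng.random() < spec.propagation_decay:
            chosen.append(nb)
    if len(chosen) < spec.n_positives:  # sparse neighborhoods: widen the module
        chosen = _connected_module(rng, spec.n_genes, edges, spec.n_positives)
    return chosen[:spec.n_positives]


def _expression(rng: np.random.Generator, spec: SyntheticSpec, edges: list,
                disease: list) -> np.ndarray:
    """Gaussian noise plus a mean shift on disease genes, decaying along edges."""
    X = rng.standard_normal((spec.n_genes, spec.n_samples))
    shift = np.zeros(spec.n_genes)
    dist = np.full(spec.n_genes, np.inf)
    frontier = list(disease)
    for g in frontier:
        dist[g] = 0
    succ: dict = {}
    for u, v in edges:
        succ.setdefault(u, []).append(v)
    depth = 0
    while frontier and depth < spec.propagation_depth:
        nxt = []
        for u in frontier:
            for v in succ.get(u, ()):
                if dist[v] > depth + 1:
                    dist[v] = depth + 1
                    nxt.append(v)
        frontier = nxt
        depth += 1
    reached = np.isfinite(dist)
    shift[reached] = spec.effect_size * spec.propagation_decay ** dist[reached]
    return X + shift[:, None]


def _pseudo_databases(rng: np.random.Generator, spec: SyntheticSpec,
                      edges: list, genes: list,
                      allow_false: bool = True,
                      allow_undirected: bool = True,
                      false_pool: list | None = None) -> list:
    """Per database: coverage subsample of true edges plus random false edges.

    Every odd-indexed database is emitted as an undirected PPI-style list
    (when allowed); the rest keep direction.
    """
    true_set = set(edges)
    nets = []
    for k in range(spec.n_databases):
        m = max(1, int(round(spec.coverage * len(edges))))
        take = rng.choice(len(edges), size=min(m, len(edges)), replace=False)
        db_edges = [edges[i] for i in sorted(take)]
        if allow_false and spec.false_edge_rate > 0:
            n_false = int(round(spec.false_edge_rate * len(db_edges)))
            added = 0
            while added < n_false:
                if false_pool is not None:
                    u, v = false_pool[int(rng.integers(len(false_pool)))]
                else:
                    u, v = (int(x) for x in rng.integers(spec.n_genes, size=2))
                if u != v and (u, v) not in true_set:
                    db_edges.append((u, v))
                    added += 1
        undirected = allow_undirected and (k % 2 == 1)
        pairs = [(genes[u], genes[v]) for u, v in db_edges]
        if undirected:
            seen, unique_pairs = set(), []
            for u, v in pairs:  # one record per unordered pair
                key = frozenset((u, v))
                if key not in seen:
                    seen.add(key)
                    unique_pairs.append((u, v))
            pairs = unique_pairs
        order = rng.permutation(len(pairs))
        nets.append(GeneNetwork(f"db{k + 1}", [pairs[i] for i in order],
                                directed=not undirected))
    return nets


def generate_benchmark(spec: SyntheticSpec) -> Benchmark:
    """Generate the standard planted-signal benchmark (seed-deterministic)."""
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)
    edges = _sample_digraph(rng, spec.n_genes, spec.n_edges, spec.graph_model)
    disease = _disease_genes(rng, spec, edges)
    n_held = int(round(spec.held_out_fraction * len(disease)))
    held_idx = set(rng.choice(len(disease), size=n_held, replace=False).tolist())
    held_out = [disease[i] for i in sorted(held_idx)]
    training = [d for i, d in enumerate(disease) if i not in held_idx]
    X = _expression(rng, spec, edges, disease)
    nets = _pseudo_databases(rng, spec, edges, genes)
    omics = OmicsMatrix(genes, [f"S{j + 1}" for j in range(spec.n_samples)], X)
    return Benchmark(
        networks=nets, omics=omics,
        positives=[genes[i] for i in training],
        held_out=[genes[i] for i in held_out],
        disease_genes=[genes[i] for i in disease],
        true_edges=[(genes[u], genes[v]) for u, v in edges],
        spec=spec,
    )


def generate_updown_scenario(spec: SyntheticSpec, seed: int | None = None) -> Benchmark:
    """Benchmark whose held-out disease genes sit strictly upstream or strictly
    downstream of every training positive they can reach.

    Genes are arranged in layers (background A → upstream stratum → positive
    module → downstream stratum → background B) and every edge points from a
    lower to a strictly higher layer, except inside A, the module and B. Edge
    orientation alone then guarantees that no training positive can reach an
    upstream gene and no downstream gene can reach a training positive. All
    pseudo-databases are emitted directed and false edges are suppressed:
    either could silently break the strict stratification.
    """
    if seed is not None:
        spec = SyntheticSpec(**{**spec.__dict__, "seed": seed})
    rng = np.random.default_rng(spec.seed)
    genes = _gene_ids(spec.n_genes)

    n_train = max(2, int(round((1 - spec.held_out_fraction) * spec.n_positives)))
    n_held = spec.n_positives - n_train
    n_up = n_held // 2
    n_down = n_held - n_up
    if n_up < 1 or n_down < 1:
        raise ValueError("graph too small to realize both an upstream and a "
                         "downstream stratum; increase n_positives or held_out_fraction")
    n_bg = spec.n_genes - spec.n_positives
    if n_bg < 4:
        raise ValueError("not enough background genes")
    n_a = n_bg // 2

    perm = rng.permutation(spec.n_genes)
    bg_a = perm[:n_a].tolist()
    upstream = perm[n_a:n_a + n_up].tolist()
    positives = perm[n_a + n_up:n_a + n_up + n_train].tolist()
    downstream = perm[n_a + n_up + n_train:n_a + n_up + n_train + n_down].tolist()
    bg_b = perm[n_a + n_up + n_train + n_down:].tolist()
    layer = np.empty(spec.n_genes, dtype=int)
    for lay, members in enumerate((bg_a, upstream, positives, downstream, bg_b)):
        layer[members] = lay

    edges: set = set()

    def add(u, v):
        if u != v:
            edges.add((int(u), int(v)))

    # guaranteed strata attachments and a weakly connected positive module
    for u in upstream:
        add(u, rng.choice(positives))
    for v in downstream:
        add(rng.choice(positives), v)
    for i, p in enumerate(positives[1:], start=1):
        q = positives[int(rng.integers(i))]
        add(*((q, p) if rng.random() < 0.5 else (p, q)))
    for u in upstream:  # upstream genes get background in-neighbors too
        add(rng.choice(bg_a), u)
    for v in downstream:
        add(v, rng.choice(bg_b))

    # fill the edge budget with layer-respecting random pairs
    same_layer_ok = {0, 2, 4}
    guard = 0
    while len(edges) < spec.n_edges and guard < 100 * spec.n_edges:
        guard += 1
        u, v = (int(x) for x in rng.integers(spec.n_genes, size=2))
        if u == v:
            continue
        if layer[u] < layer[v] or (layer[u] == layer[v] and layer[u] in same_layer_ok):
            add(u, v)
    edge_list = sorted(edges)

    disease = positives + upstream + downstream
    X = _expression(rng, spec, edge_list, disease)
    spec_no_false = SyntheticSpec(**{**spec.__dict__, "false_edge_rate": 0.0})
    nets = _pseudo_databases(rng, spec_no_false, edge_list, genes,
                             allow_false=False, allow_undirected=False)
    omics = OmicsMatrix(genes, [f"S{j + 1}" for j in range(spec.n_samples)], X)
    return Benchmark(
        networks=nets, omics=omics,
        positives=[genes[i] for i in positives],
        held_out=[genes[i] for i in upstream + downstream],
        disease_genes=[genes[i] for i in disease],
        true_edges=[(genes[u], genes[v]) for u, v in edge_list],
        spec=spec,
        strata={"upstream": [genes[i] for i in upstream],
                "downstream": [genes[i] for i in downstream]},
    )


def write_benchmark(bench: Benchmark, outdir: str | Path) -> None:
    """Write the benchmark in the same TSV dialects the real pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for net in bench.networks:
        fname = f"{net.name}.tsv"
        with open(outdir / fname, "w") as fh:
            for u, v in net.edges:
                fh.write(f"{u}\t{v}\n")
        manifest.append({"name": net.name, "path": fname, "directed": net.directed})
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    bench.omics.to_table(outdir / "expression.tsv")
    for fname, genes in (("positives.txt", bench.positives),
                         ("held_out_truth.txt", bench.held_out),
                         ("disease_genes_truth.txt", bench.disease_genes)):
        (outdir / fname).write_text("".join(f"{g}\n" for g in genes))
    if bench.strata:
        for name, genes in bench.strata.items():
            (outdir / f"stratum_{name}.txt").write_text("".join(f"{g}\n" for g in genes))
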