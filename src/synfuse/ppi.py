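"""Protein–protein interaction network embedding via biased random walks.

The cell-line feature genes double as the node set of a protein–protein
interaction (PPI) network.  Each protein is embedded into 128 dimensions
with the node2vec procedure: second-order biased random walks (return
parameter p, in–out parameter q) generate node "sentences", and a
skip-gram model with negative sampling fits vectors whose inner products
preserve walk co-occurrence, i.e. network neighborhoods.  The embeddings
are computed once from the network alone and stay frozen during model
training.

The skip-gram objective is optimized in its expectation form: window
co-occurrence counts are accumulated from the walks and the negative-
sampling loss, weighted by those counts and the unigram^0.75 noise
distribution, is minimized by full-batch Adam on the (in, out) vector
matrices.  At the ~10^3-node scale of a landmark-gene network this is a
dense problem, and the full-batch form makes the result deterministic for
a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class PPINetwork:
    """Undirected PPI graph over gene symbols (no self-loops, no duplicates)."""

    graph: nx.Graph

    @classmethod
    def from_edges(cls, edges, nodes=None) -> "PPINetwork":
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        for u, v in edges:
            if u == v:
                continue
            g.add_edge(u, v)
        return cls(g)

    @classmethod
    def from_edge_list_file(cls, path, nodes=None) -> "PPINetwork":
        """Read a two-column tab-separated gene-symbol edge list."""
        edges = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if len(parts) >= 2:
                    edges.append((parts[0], parts[1]))
        return cls.from_edges(edges, nodes=nodes)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class WalkConfig:
    """node2vec hyperparameters; p = q = 1 reduces to uniform random walks."""

    p: float = 1.0
    q: float = 1.0
    walks_per_node: int = 10
    walk_length: int = 80
    window: int = 10
    dim: int = 128
    seed: int = 0
    iterations: int = 150
    negatives: int = 5
    lr: float = 0.05

    def __post_init__(self):
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")

    def key(self) -> str:
        return json.dumps(
            {k: getattr(self, k) for k in (
                "p", "q", "walks_per_node", "walk_length", "window", "dim",
                "seed", "iterations", "negatives", "lr")},
            sort_keys=True,
        )


@dataclass
class NodeEmbeddingTable:
    """gene symbol → embedding vector, with a fixed gene order."""

    genes: list[str]
    vectors: np.ndarray  # (n_genes, dim)

    def __post_init__(self):
        self._index = {g: i for i, g in enumerate(self.genes)}

    def __len__(self):
        return len(self.genes)

    def __getitem__(self, gene: str) -> np.ndarray:
        return self.vectors[self._index[gene]]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    def matrix_for(self, genes: list[str]) -> np.ndarray:
        """Embedding rows in the requested gene order.

        Genes absent from the network fall back to zero vectors with a
        logged warning (they carry no interaction information).
        """
        out = np.zeros((len(genes), self.dim))
        missing = []
        for i, g in enumerate(genes):
            if g in self._index:
                out[i] = self.vectors[self._index[g]]
            else:
                missing.append(g)
        if missing:
            logger.warning(
                "%d genes absent from the PPI network, using zero vectors: %s",
                len(missing), missing[:5],
            )
        return out

    def save(self, prefix: Path) -> None:
        prefix = Path(prefix)
        np.save(prefix.with_suffix(".npy"), self.vectors)
        prefix.with_suffix(".genes.txt").write_text("\n".join(self.genes) + "\n")

    @classmethod
    def load(cls, prefix: Path) -> "NodeEmbeddingTable":
        prefix = Path(prefix)
        vectors = np.load(prefix.with_suffix(".npy"))
        genes = prefix.with_suffix(".genes.txt").read_text().split()
        return cls(genes=genes, vectors=vectors)


# ---------------------------------------------------------------------------
# Biased second-order walks
# ---------------------------------------------------------------------------


def transition_probs(network: PPINetwork, prev, cur, config: WalkConfig):
    """Second-order transition distribution from state (prev → cur).

    Candidate x is weighted 1/p when it returns to ``prev``, 1 when x is
    also a neighbor of ``prev`` (triangle step), and 1/q otherwise, then
    normalized over the neighbors of ``cur``.
    """
    g = network.graph
    neighbors = sorted(g.neighbors(cur))
    if not neighbors:
        return [], np.array([])
    weights = np.empty(len(neighbors))
    for i, x in enumerate(neighbors):
        if x == prev:
            weights[i] = 1.0 / config.p
        elif prev is not None and g.has_edge(x, prev):
            weights[i] = 1.0
        else:
            weights[i] = 1.0 / config.q
    return neighbors, weights / weights.sum()


def _uniform_walks(adj_offsets, adj_targets, deg, n, config, rng):
    """All walks stepped in parallel (first-order case p = q = 1)."""
    starts = np.tile(np.arange(n), config.walks_per_node)
    walks = np.full((len(starts), config.walk_length), -1, dtype=np.int64)
    walks[:, 0] = starts
    cur = starts.copy()
    alive = deg[cur] > 0
    for step in range(1, config.walk_length):
        if not alive.any():
            break
        u = rng.random(alive.sum())
        c = cur[alive]
        pick = adj_offsets[c] + np.minimum((u * deg[c]).astype(np.int64), deg[c] - 1)
        nxt = adj_targets[pick]
        cur = cur.copy()
        cur[alive] = nxt
        walks[alive, step] = nxt
        alive = alive & (deg[cur] > 0)
    return walks


def generate_biased_walks(network: PPINetwork, config: WalkConfig) -> list[list]:
    """``walks_per_node`` biased walks from every node, seeded.

    Isolated nodes yield length-1 walks; a walk ends early only at a dead
    end.  Returns walks as lists of node labels.
    """
    idx_walks, nodes = _walks_as_indices(network, config)
    out = []
    for row in idx_walks:
        out.append([nodes[i] for i in row if i >= 0])
    return out


def _walks_as_indices(network: PPINetwork, config: WalkConfig):
    """Walk matrix (n_walks × walk_length, -1 padded) over node indices."""
    if network.n_nodes == 0:
        raise ValueError("network is empty")
    rng = np.random.default_rng(config.seed)
    g = network.graph
    nodes = list(g.nodes)
    index = {node: i for i, node in enumerate(nodes)}
    n = len(nodes)
    adj = [sorted(index[x] for x in g.neighbors(node)) for node in nodes]
    deg = np.array([len(a) for a in adj], dtype=np.int64)
    offsets = np.zeros(n, dtype=np.int64)
    offsets[1:] = np.cumsum(deg)[:-1]
    targets = np.concatenate([np.asarray(a, dtype=np.int64) for a in adj]) if deg.sum() else np.empty(0, np.int64)

    if config.p == 1.0 and config.q == 1.0:
        return _uniform_walks(offsets, targets, deg, n, config, rng), nodes

    nbr_sets = [set(a) for a in adj]
    walks = np.full((n * config.walks_per_node, config.walk_length), -1, dtype=np.int64)
    w = 0
    for _ in range(config.walks_per_node):
        for start in range(n):
            walks[w, 0] = start
            prev = -1
            cur = start
            for step in range(1, config.walk_length):
                nbrs = adj[cur]
                if not nbrs:
                    break
                if prev < 0:
                    nxt = nbrs[rng.integers(len(nbrs))]
                else:
                    weights = np.empty(len(nbrs))
                    for i, x in enumerate(nbrs):
                        if x == prev:
                            weights[i] = 1.0 / config.p
                        elif x in nbr_sets[prev]:
                            weights[i] = 1.0
                        else:
                            weights[i] = 1.0 / config.q
                    weights /= weights.sum()
                    nxt = nbrs[rng.choice(len(nbrs), p=weights)]
                walks[w, step] = nxt
                prev, cur = cur, nxt
            w += 1
    return walks, nodes


# ---------------------------------------------------------------------------
# Skip-gram with negative sampling (expectation form)
# ---------------------------------------------------------------------------


def _cooccurrence(idx_walks: np.ndarray, n: int, window: int) -> np.ndarray:
    """Symmetric window co-occurrence counts over the walk corpus."""
    C = np.zeros((n, n))
    for off in range(1, window + 1):
        a = idx_walks[:, :-off].ravel()
        b = idx_walks[:, off:].ravel()
        ok = (a >= 0) & (b >= 0)
        if ok.any():
            flat = np.bincount(a[ok] * n + b[ok], minlength=n * n).reshape(n, n)
            C += flat + flat.T
    return C


def train_skipgram(walks, config: WalkConfig, nodes=None) -> NodeEmbeddingTable:
    """Fit skip-gram negative-sampling vectors from a walk corpus.

    ``walks`` may be lists of node labels (as returned by
    :func:`generate_biased_walks`).  Every requested node must occur in the
    corpus.  The loss

        −Σ_ij C_ij log σ(v_i·u_j) − k Σ_i (Σ_j C_ij) Σ_j P_j log σ(−v_i·u_j)

    (C the co-occurrence counts, P the unigram^0.75 noise distribution,
    k the negative-sample rate) is minimized with full-batch Adam, so the
    table is bit-reproducible for a fixed seed.
    """
    if nodes is None:
        nodes = sorted({x for w in walks for x in w})
    index = {x: i for i, x in enumerate(nodes)}
    n = len(nodes)
    maxlen = max(len(w) for w in walks)
    idx_walks = np.full((len(walks), maxlen), -1, dtype=np.int64)
    seen = set()
    for r, w in enumerate(walks):
        for cidx, x in enumerate(w):
            if x not in index:
                raise ValueError(f"walk node {x!r} not in node list")
            idx_walks[r, cidx] = index[x]
            seen.add(x)
    missing = [x for x in nodes if x not in seen]
    if missing:
        raise ValueError(f"nodes absent from all walks: {missing[:5]}")

    C = _cooccurrence(idx_walks, n, config.window)
    if C.sum() == 0:
        logger.warning(
            "degenerate walk corpus (no co-occurrence pairs); returning "
            "untrained initialization vectors"
        )
    rng = np.random.default_rng(config.seed + 1)
    d = config.dim
    V = rng.normal(scale=0.1, size=(n, d))
    U = rng.normal(scale=0.1, size=(n, d))

    pos_rows = C.sum(axis=1)                       # per-center pair counts
    unigram = C.sum(axis=0)
    noise = unigram ** 0.75
    noise_sum = noise.sum()
    if noise_sum > 0:
        noise /= noise_sum
    neg_weight = config.negatives * np.outer(pos_rows, noise)
    total = C.sum() + neg_weight.sum() + 1e-12

    mV = np.zeros_like(V); vV = np.zeros_like(V)
    mU = np.zeros_like(U); vU = np.zeros_like(U)
    b1, b2, eps = 0.9, 0.999, 1e-8
    for t in range(1, config.iterations + 1):
        S = V @ U.T
        sig = 1.0 / (1.0 + np.exp(-np.clip(S, -30, 30)))
        # d(loss)/dS, normalized by total weight
        G = (neg_weight * sig - C * (1.0 - sig)) / total
        gV = G @ U
        gU = G.T @ V
        for M, vv, gg, P in ((mV, vV, gV, V), (mU, vU, gU, U)):
            M += (1 - b1) * (gg - M)
            vv += (1 - b2) * (gg * gg - vv)
            P -= config.lr * (M / (1 - b1 ** t)) / (np.sqrt(vv / (1 - b2 ** t)) + eps)
    return NodeEmbeddingTable(genes=list(nodes), vectors=V)


def embed_network(network: PPINetwork, config: WalkConfig,
                  cache_dir: Path | None = None) -> NodeEmbeddingTable:
    """Walks + skip-gram, with an optional on-disk cache.

    The cache key hashes the edge set, node set, and the full walk/training
    configuration, so a hit is guaranteed to be the identical table.
    """
    if cache_dir is not None:
        cache_dir = Path(cache_dir)
        payload = json.dumps(
            {
                "nodes": sorted(map(str, network.nodes)),
                "edges": sorted(tuple(sorted(map(str, e))) for e in network.graph.edges),
                "config": config.key(),
            },
            sort_keys=True,
        )
        digest = hashlib.sha256(payload.encode()).hexdigest()[:24]
        prefix = cache_dir / f"ppi_embedding_{digest}"
        if prefix.with_suffix(".npy").exists():
            return NodeEmbeddingTable.load(prefix)
    walks = generate_biased_walks(network, config)
    table = train_skipgram(walks, config, nodes=network.nodes)
    if cache_dir is not None:
        cache_dir.mkdir(parents=True, exist_ok=True)
        table.save(prefix)
    return table
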