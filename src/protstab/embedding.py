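"""Random-walk node embeddings for interaction networks.

Each non-isolated node of the network is embedded as a fixed-length
vector that preserves random-walk neighborhood structure, in the style
of node2vec: second-order biased random walks (return parameter ``p``,
in-out parameter ``q``; the defaults p = q = 1 reduce to uniform walks)
are generated from every node, windowed node-context co-occurrences are
counted over the walks, and the positive pointwise-mutual-information
(PPMI) matrix of those counts is factorized by truncated SVD. This
factorization optimizes the same objective family as skip-gram training
on the walks while being exactly reproducible under a fixed seed.
Isolated nodes receive the zero vector.
"""

from __future__ import annotations

import warnings

import networkx as nx
import numpy as np
from scipy import sparse
from sklearn.decomposition import TruncatedSVD


def generate_walks(
    graph: nx.Graph,
    walk_length: int = 80,
    num_walks: int = 10,
    p: float = 1.0,
    q: float = 1.0,
    seed: int = 0,
) -> list[list]:
    """Seeded second-order random walks from every non-isolated node.

    Transition weights out of node v having arrived from node u are
    1/p back to u, 1 to common neighbors of u and v, and 1/q to the
    remaining neighbors of v.
    """
    rng = np.random.default_rng(seed)
    nodes = sorted(graph.nodes(), key=str)
    nbrs = {v: sorted(graph.neighbors(v), key=str) for v in nodes}
    nbr_sets = {v: set(ns) for v, ns in nbrs.items()}
    uniform = p == 1.0 and q == 1.0
    walks: list[list] = []
    for _ in range(num_walks):
        for start in nodes:
            if not nbrs[start]:
                continue
            walk = [start]
            while len(walk) < walk_length:
                cur = walk[-1]
                cur_nbrs = nbrs[cur]
                if not cur_nbrs:
                    break
                if uniform or len(walk) == 1:
                    nxt = cur_nbrs[int(rng.integers(len(cur_nbrs)))]
                else:
                    prev = walk[-2]
                    w = np.empty(len(cur_nbrs))
                    prev_nbrs = nbr_sets[prev]
                    for i, cand in enumerate(cur_nbrs):
                        if cand == prev:
                            w[i] = 1.0 / p
                        elif cand in prev_nbrs:
                            w[i] = 1.0
                        else:
                            w[i] = 1.0 / q
                    w /= w.sum()
                    nxt = cur_nbrs[int(rng.choice(len(cur_nbrs), p=w))]
                walk.append(nxt)
            walks.append(walk)
    return walks


def embed_network(
    graph: nx.Graph,
    dims: int = 128,
    walk_length: int = 80,
    num_walks: int = 10,
    window: int = 10,
    p: float = 1.0,
    q: float = 1.0,
    seed: int = 0,
) -> dict:
    """Embed every node of ``graph`` into ``dims`` dimensions.

    Returns a dict mapping node -> ndarray of length ``dims``. Isolated
    nodes (and every node of an empty graph) map to the zero vector.
    When the co-occurrence matrix has rank below ``dims`` the trailing
    dimensions are zero-padded, so the output length is always ``dims``.
    """
    result = {v: np.zeros(dims) for v in graph.nodes()}
    active = sorted((v for v in graph.nodes() if graph.degree(v) > 0),
                    key=str)
    if not active:
        warnings.warn("graph has no edges; all embeddings are zero")
        return result

    index = {v: i for i, v in enumerate(active)}
    walks = generate_walks(graph, walk_length, num_walks, p, q, seed)

    rows, cols = [], []
    for walk in walks:
        idx = [index[v] for v in walk]
        L = len(idx)
        for i, vi in enumerate(idx):
            for j in range(max(0, i - window), min(L, i + window + 1)):
                if j != i:
                    rows.append(vi)
                    cols.append(idx[j])
    n = len(active)
    counts = sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n)
    ).tocsr()

    total = counts.sum()
    row_sum = np.asarray(counts.sum(axis=1)).ravel()
    col_sum = np.asarray(counts.sum(axis=0)).ravel()
    coo = counts.tocoo()
    pmi = np.log(coo.data * total / (row_sum[coo.row] * col_sum[coo.col]))
    keep = pmi > 0
    ppmi = sparse.coo_matrix(
        (pmi[keep], (coo.row[keep], coo.col[keep])), shape=(n, n)
    ).tocsr()

    k = min(dims, n - 1)
    if k < 1:
        vecs = np.zeros((n, 0))
    else:
        svd = TruncatedSVD(n_components=k, random_state=seed)
        u = svd.fit_transform(ppmi)  # U * Sigma
        # scale to U * sqrt(Sigma), the symmetric factorization
        sv = np.sqrt(np.maximum(svd.singular_values_, 0))
        with np.errstate(divide="ignore", invalid="ignore"):
            vecs = np.where(svd.singular_values_ > 0, u / svd.singular_values_ * sv, 0.0)
    emb = np.zeros((n, dims))
    emb[:, : vecs.shape[1]] = vecs
    for v, i in index.items():
        result[v] = emb[i]
    return result
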