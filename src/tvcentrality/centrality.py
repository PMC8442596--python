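"""Node centralities on the binary undirected brain network.

Implements the three graph metrics the pipeline uses:

* eigenvector centrality (EC) — leading eigenvector of the adjacency
  matrix, EC = (1/lambda_1) A mu_1, non-negative, unit Euclidean norm;
* participation coefficient (PC) — PC_i = 1 - sum_m (K_i(m)/K_i)^2 over
  the communities of a Louvain partition; high PC marks connector hubs;
* flow coefficient — fraction of a node's neighbour pairs *not* directly
  connected (for a binary undirected graph this is 1 minus the local
  clustering coefficient); its mean over nodes drives density selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import scipy.linalg

from .connectome import AdjacencyMatrix, ValidationError

__all__ = [
    "Partition",
    "CentralityVector",
    "eigenvector_centrality",
    "louvain_partition",
    "participation_coefficient",
    "flow_coefficient",
]


@dataclass
class Partition:
    """Community assignment of every node plus its modularity score.

    ``labels`` are contiguous positive integers 1..K; communities are
    numbered by their smallest member node so the labelling is
    deterministic given the partition.
    """

    labels: np.ndarray
    modularity: float
    gamma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if uniq.size and (uniq[0] != 1 or not np.array_equal(
                uniq, np.arange(1, uniq.size + 1))):
            raise ValidationError("labels must be contiguous 1..K")

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) if self.labels.size else 0


@dataclass
class CentralityVector:
    """Per-node centrality values.

    ``kind`` is one of ``"ec"``, ``"pc"``, ``"flow"``.  For EC the
    leading eigenvalue is recorded; for PC the node degrees are.
    """

    values: np.ndarray
    kind: str
    eigenvalue: float | None = None
    degrees: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("ec", "pc", "flow"):
            raise ValidationError(f"unknown centrality kind {self.kind!r}")


def eigenvector_centrality(A: AdjacencyMatrix) -> CentralityVector:
    """Leading-eigenvector centrality of a binary undirected network.

    Solves the symmetric eigenproblem of the full adjacency matrix and
    returns the eigenvector of the globally largest eigenvalue, sign
    fixed non-negative and normalised to unit Euclidean norm, so that
    EC = (1/lambda_1) A EC componentwise.  On a disconnected graph the
    vector concentrates on the component with the largest eigenvalue;
    other components receive (near-)zero weight.
    """
    if A.n_edges == 0:
        raise ValidationError("eigenvector centrality undefined on an "
                              "edgeless graph (lambda_1 = 0)")
    M = A.values.astype(float)
    n = M.shape[0]
    w, v = scipy.linalg.eigh(M, subset_by_index=(n - 1, n - 1))
    lam = float(w[0])
    vec = v[:, 0]
    # orient along the dominant entry; residual negatives are numerical
    if vec[int(np.argmax(np.abs(vec)))] < 0:
        vec = -vec
    vec = np.where(vec < 0, 0.0, vec)
    vec = vec / np.linalg.norm(vec)
    return CentralityVector(values=vec, kind="ec", eigenvalue=lam)


def _labels_from_communities(comms, n: int) -> np.ndarray:
    labels = np.zeros(n, dtype=int)
    # deterministic numbering: communities ordered by their smallest node
    for new, com in enumerate(sorted(map(sorted, comms)), start=1):
        labels[list(com)] = new
    return labels


def louvain_partition(
    A: AdjacencyMatrix,
    gamma: float = 1.0,
    seed: int = 0,
    n_restarts: int = 100,
) -> Partition:
    """Louvain modularity maximisation, best of ``n_restarts`` runs.

    Greedy two-phase Louvain at resolution ``gamma``; each restart uses
    a node-sweep order derived from ``seed``, and the partition with the
    highest Newman-Girvan modularity Q is returned.  An edgeless graph
    yields singleton communities with Q = 0.
    """
    n = A.n_nodes
    if A.n_edges == 0:
        return Partition(labels=np.arange(1, n + 1), modularity=0.0,
                         gamma=gamma, seed=seed)
    G = nx.from_numpy_array(A.values)
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF]))
    best_q = -np.inf
    best = None
    for _ in range(max(1, n_restarts)):
        run_seed = int(rng.integers(0, 2**31 - 1))
        comms = nx.community.louvain_communities(
            G, resolution=gamma, seed=run_seed)
        q = nx.community.modularity(G, comms, resolution=gamma)
        if q > best_q:
            best_q, best = q, comms
    return Partition(
        labels=_labels_from_communities(best, n),
        modularity=float(best_q),
        gamma=gamma,
        seed=seed,
    )


def participation_coefficient(
    A: AdjacencyMatrix, P: Partition
) -> CentralityVector:
    """Participation coefficient PC_i = 1 - sum_m (K_i(m)/K_i)^2.

    K_i is the degree of node i and K_i(m) its number of edges into
    community m of the partition.  Nodes with no edges get PC = 0 by
    convention (the defining ratio is 0/0 there).
    """
    n = A.n_nodes
    if P.labels.shape[0] != n:
        raise ValidationError(
            f"partition labels {P.labels.shape[0]} nodes, adjacency has {n}")
    M = A.values.astype(float)
    K = M.sum(axis=1)
    n_com = P.n_communities
    onehot = np.zeros((n, n_com))
    onehot[np.arange(n), P.labels - 1] = 1.0
    Km = M @ onehot  # (n, n_com): edges of node i into community m
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = Km / K[:, None]
        pc = 1.0 - np.sum(frac**2, axis=1)
    pc[K == 0] = 0.0
    return CentralityVector(values=pc, kind="pc", degrees=K.astype(int))


def flow_coefficient(A: AdjacencyMatrix) -> CentralityVector:
    """Fraction of each node's neighbour pairs with no direct edge.

    For node i of degree k_i >= 2, f_i = (# ordered pairs of distinct
    neighbours (a, b) with no edge a-b) / (k_i (k_i - 1)); on a binary
    undirected graph this equals 1 minus the local clustering
    coefficient.  Nodes of degree < 2 get 0.
    """
    M = A.values.astype(float)
    k = M.sum(axis=1)
    # (A^3)_ii counts ordered connected neighbour pairs of i
    closed = np.einsum("ij,jk,ki->i", M, M, M)
    denom = k * (k - 1)
    f = np.zeros_like(k)
    ok = denom > 0
    f[ok] = 1.0 - closed[ok] / denom[ok]
    return CentralityVector(values=np.clip(f, 0.0, 1.0), kind="flow")
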