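"""Community structure and node centrality for symptom networks.

Community detection uses Newman's spectral method on the generalized
modularity matrix B_ij = A_ij - gamma * k_i k_j / (2m) with a resolution
parameter gamma (default 0.4), recursive sign-of-leading-eigenvector
bisection, and Kernighan-Lin style single-node refinement after every
split.  Centrality follows the usual weighted-network conventions: edge
weights |w| are converted to lengths 1/|w|, betweenness uses Brandes
accumulation over weighted shortest paths, and closeness uses the
Wasserman-Faust component correction.  Negative correlations enter all
graph measures through their absolute value (shortest paths and the
modularity null model are undefined for negative weights); a ``discard``
mode that drops them instead is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import SymptomNetwork

MEASURES = ("betweenness", "degree", "closeness")

_DQ_TOL = 1e-10


class UndefinedConsistencyError(ValueError):
    """Centrality consistency is undefined (too few shared items or a
    zero-variance centrality vector)."""


def _adjacency(net: SymptomNetwork, negative_edges: str = "absolute") -> np.ndarray:
    if negative_edges == "absolute":
        return np.abs(net.weights)
    if negative_edges == "discard":
        return np.where(net.weights > 0, net.weights, 0.0)
    raise ValueError("negative_edges must be 'absolute' or 'discard'")


# ---------------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------------

@dataclass
class ModulePartition:
    """Community assignment (contiguous ids from 0) with its modularity Q."""

    assignment: np.ndarray
    q_score: float
    gamma: float

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)

    @property
    def n_communities(self) -> int:
        return int(self.assignment.max()) + 1 if self.assignment.size else 0

    def members(self, community: int) -> np.ndarray:
        return np.where(self.assignment == community)[0]


def modularity_q(
    net: SymptomNetwork,
    assignment: np.ndarray,
    gamma: float = 0.4,
    negative_edges: str = "absolute",
) -> float:
    """Generalized modularity Q of a partition.

    Q = (1/2m) sum_ij [A_ij - gamma k_i k_j/(2m)] delta(c_i, c_j), with
    A = |weights|, k the weighted node strengths and 2m the total weight.
    """
    A = _adjacency(net, negative_edges)
    assignment = np.asarray(assignment)
    if assignment.shape[0] != net.n_items:
        raise ValueError("assignment must cover every node")
    k = A.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        raise ValueError("modularity undefined: the network has no edges")
    same = assignment[:, None] == assignment[None, :]
    B = A - gamma * np.outer(k, k) / two_m
    return float(np.sum(B[same]) / two_m)


def _relabel_contiguous(assignment: np.ndarray) -> np.ndarray:
    """Relabel community ids to 0..C-1 in order of first appearance."""
    seen: dict[int, int] = {}
    out = np.empty_like(assignment)
    for i, c in enumerate(assignment):
        out[i] = seen.setdefault(int(c), len(seen))
    return out


def _kl_refine(Bg: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Greedy single-node sign flips until no flip increases s' Bg s."""
    s = s.copy()
    while True:
        Bs = Bg @ s
        delta = -4.0 * s * Bs + 4.0 * np.diag(Bg)
        best = int(np.argmax(delta))
        if delta[best] <= _DQ_TOL:
            return s
        s[best] = -s[best]


def newman_spectral_communities(
    net: SymptomNetwork,
    gamma: float = 0.4,
    seed: int = 0,
    negative_edges: str = "absolute",
) -> ModulePartition:
    """Newman spectral community detection with resolution parameter gamma.

    Recursive spectral bisection of the generalized modularity matrix:
    each group is split by the sign of the leading eigenvector of its
    (subgraph-corrected) modularity matrix, refined by Kernighan-Lin style
    single-node moves, and the recursion continues while a split increases
    Q by more than 1e-10.  Deterministic for a fixed network: the sign of
    the eigenvector is anchored so the lowest-index node of the group is
    on the positive side (the ``seed`` argument is accepted for interface
    symmetry; the algorithm itself is tie-broken deterministically).
    """
    del seed  # deterministic algorithm; kept for a uniform call signature
    A = _adjacency(net, negative_edges)
    n = net.n_items
    k = A.sum(axis=1)
    two_m = k.sum()
    if n == 0:
        return ModulePartition(np.empty(0, dtype=int), 0.0, gamma)
    if two_m == 0:
        return ModulePartition(np.zeros(n, dtype=int), 0.0, gamma)

    B = A - gamma * np.outer(k, k) / two_m
    assignment = np.zeros(n, dtype=int)
    next_id = 1
    stack = [np.arange(n)]

    while stack:
        g = stack.pop()
        if g.size < 2:
            continue
        Bsub = B[np.ix_(g, g)]
        # Newman's subgraph correction keeps within-group moves Q-exact
        Bg = Bsub - np.diag(Bsub.sum(axis=1))
        vals, vecs = np.linalg.eigh(Bg)
        lead = vecs[:, -1]
        if vals[-1] <= _DQ_TOL:
            continue  # indivisible: no positive eigenvalue
        s = np.where(lead >= 0, 1.0, -1.0)
        if s[0] < 0:  # anchor: lowest-index node on the positive side
            s = -s
        s = _kl_refine(Bg, s)
        dq = float(s @ Bg @ s) / (2.0 * two_m)
        if dq <= _DQ_TOL or np.all(s == s[0]):
            continue
        plus = g[s > 0]
        minus = g[s < 0]
        assignment[minus] = next_id
        next_id += 1
        stack.append(plus)
        stack.append(minus)

    assignment = _relabel_contiguous(assignment)
    q = modularity_q(net, assignment, gamma=gamma, negative_edges=negative_edges)
    return ModulePartition(assignment, q, gamma)


# ---------------------------------------------------------------------------
# centrality
# ---------------------------------------------------------------------------

def weight_to_length(
    net: SymptomNetwork, negative_edges: str = "absolute"
) -> np.ndarray:
    """Edge lengths 1/|w|; absent edges get infinite length."""
    A = _adjacency(net, negative_edges)
    with np.errstate(divide="ignore"):
        lengths = np.where(A > 0, 1.0 / A, np.inf)
    np.fill_diagonal(lengths, np.inf)
    return lengths


def to_graph(net: SymptomNetwork, negative_edges: str = "absolute") -> nx.Graph:
    """networkx view with a ``length`` attribute (1/|w|) on every edge."""
    A = _adjacency(net, negative_edges)
    G = nx.Graph()
    G.add_nodes_from(range(net.n_items))
    iu, ju = np.triu_indices(net.n_items, k=1)
    for i, j in zip(iu, ju):
        if A[i, j] > 0:
            G.add_edge(int(i), int(j), weight=A[i, j], length=1.0 / A[i, j])
    return G


def betweenness_centrality(
    net: SymptomNetwork, negative_edges: str = "absolute"
) -> np.ndarray:
    """Brandes betweenness over weighted shortest paths (lengths 1/|w|).

    Unordered node pairs, fractional credit across tied shortest paths,
    no normalization; unreachable pairs contribute nothing.
    """
    G = to_graph(net, negative_edges)
    bc = nx.betweenness_centrality(G, weight="length", normalized=False)
    return np.array([bc[i] for i in range(net.n_items)], dtype=float)


def degree_centrality(
    net: SymptomNetwork, weighted: bool = False, negative_edges: str = "absolute"
) -> np.ndarray:
    """Number of connections per node (or weighted strength if requested)."""
    A = _adjacency(net, negative_edges)
    if weighted:
        return A.sum(axis=1)
    return np.count_nonzero(A, axis=1).astype(int)


def closeness_centrality(
    net: SymptomNetwork, negative_edges: str = "absolute"
) -> np.ndarray:
    """Closeness with the Wasserman-Faust component correction.

    closeness(v) = ((R_v - 1)/(M - 1)) * ((R_v - 1)/sum_u d(v, u)) over the
    R_v nodes in v's component; reduces to (M-1)/sum d on a connected
    network, and is 0 for an isolated node.
    """
    G = to_graph(net, negative_edges)
    cc = nx.closeness_centrality(G, distance="length", wf_improved=True)
    return np.array([cc[i] for i in range(net.n_items)], dtype=float)


@dataclass
class CentralityProfile:
    """Per-item betweenness, degree and closeness for one network."""

    betweenness: np.ndarray
    degree: np.ndarray
    closeness: np.ndarray
    item_labels: list[str]

    def __post_init__(self) -> None:
        m = len(self.item_labels)
        for name in MEASURES:
            v = np.asarray(getattr(self, name))
            if v.shape != (m,):
                raise ValueError(f"{name} vector does not match the item list")
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, v)

    @classmethod
    def from_network(
        cls, net: SymptomNetwork, negative_edges: str = "absolute"
    ) -> "CentralityProfile":
        return cls(
            betweenness=betweenness_centrality(net, negative_edges),
            degree=degree_centrality(net, negative_edges=negative_edges),
            closeness=closeness_centrality(net, negative_edges),
            item_labels=net.labels,
        )

    def values(self, measure: str) -> np.ndarray:
        if measure not in MEASURES:
            raise ValueError(f"measure must be one of {MEASURES}")
        return np.asarray(getattr(self, measure), dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "item": self.item_labels,
                "betweenness": self.betweenness,
                "degree": self.degree,
                "closeness": self.closeness,
            }
        )


def top_items(profile: CentralityProfile, measure: str, k: int = 3) -> list[str]:
    """The k most central items, ties broken lexicographically by label."""
    if k > len(profile.item_labels):
        raise ValueError("k exceeds the number of items")
    vals = profile.values(measure)
    order = sorted(zip(profile.item_labels, vals), key=lambda t: (-t[1], t[0]))
    return [label for label, _ in order[:k]]


def hub_frequency(
    profiles: list[CentralityProfile], measure: str, k: int = 3
) -> dict[str, int]:
    """How many profiles place each item in their top-k for the measure.

    Profiles may have different item sets; every label seen anywhere gets a
    count (0 if it never ranks)."""
    counts: dict[str, int] = {}
    for p in profiles:
        for label in p.item_labels:
            counts.setdefault(label, 0)
        for label in top_items(p, measure, min(k, len(p.item_labels))):
            counts[label] += 1
    return counts


def centrality_consistency(
    a: CentralityProfile, b: CentralityProfile, measure: str
) -> float:
    """Pearson correlation of a centrality measure over shared items.

    Raises :class:`UndefinedConsistencyError` when fewer than 3 items are
    shared or either side has zero variance on them."""
    shared = [l for l in a.item_labels if l in set(b.item_labels)]
    if len(shared) < 3:
        raise UndefinedConsistencyError(
            f"only {len(shared)} shared items; need at least 3"
        )
    va = a.values(measure)[[a.item_labels.index(l) for l in shared]]
    vb = b.values(measure)[[b.item_labels.index(l) for l in shared]]
    if np.std(va) == 0 or np.std(vb) == 0:
        raise UndefinedConsistencyError(
            "centrality has zero variance over the shared items"
        )
    return float(np.corrcoef(va, vb)[0, 1])
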