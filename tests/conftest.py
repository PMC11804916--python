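"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (exhaustive enumeration, direct
formula evaluation) and never call the code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from symptomnet import CohortSpec, ItemSpec, apply_threshold
from symptomnet.network import SymptomNetwork


# ---------------------------------------------------------------------------
# network construction helpers
# ---------------------------------------------------------------------------

def net_from(w, threshold: float = 0.0) -> SymptomNetwork:
    """Wrap a raw symmetric weight matrix as a network."""
    return apply_threshold(np.asarray(w, dtype=float), threshold)


def sym(m: int, entries: dict[tuple[int, int], float]) -> np.ndarray:
    w = np.zeros((m, m))
    for (i, j), v in entries.items():
        w[i, j] = w[j, i] = v
    return w


def clique_pair(bridge: float = 0.0) -> np.ndarray:
    """Two 4-cliques of unit weight, optionally joined by one weak edge."""
    w = np.zeros((8, 8))
    for block in (range(4), range(4, 8)):
        for i in block:
            for j in block:
                if i != j:
                    w[i, j] = 1.0
    if bridge:
        w[0, 4] = w[4, 0] = bridge
    return w


@pytest.fixture
def two_cliques() -> SymptomNetwork:
    return net_from(clique_pair())


@pytest.fixture
def bridged_cliques() -> SymptomNetwork:
    return net_from(clique_pair(bridge=0.05))


def small_network_suite() -> list[SymptomNetwork]:
    """Fixture networks with <= 8 nodes used for oracle-equivalence checks."""
    nets = [
        net_from(clique_pair()),                       # two components
        net_from(clique_pair(bridge=0.05)),            # weakly bridged
        net_from(sym(3, {(0, 1): 1.0, (1, 2): 1.0})),  # path
        net_from(sym(4, {(0, 1): 1.0, (0, 2): 1.0, (0, 3): 1.0})),  # star
        net_from(sym(6, {(0, 1): 1, (0, 2): 1, (1, 2): 1,
                         (3, 4): 1, (3, 5): 1, (4, 5): 1})),  # 2 triangles
    ]
    # seeded random weighted networks
    for seed in (11, 12, 13):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(6, 9))
        w = np.zeros((m, m))
        iu, ju = np.triu_indices(m, k=1)
        keep = rng.random(iu.size) < 0.55
        vals = rng.uniform(0.2, 0.9, iu.size)
        w[iu[keep], ju[keep]] = vals[keep]
        w += w.T
        nets.append(net_from(w))
    return nets


# ---------------------------------------------------------------------------
# exhaustive oracles
# ---------------------------------------------------------------------------

def set_partitions(n: int):
    """All partitions of {0..n-1} into nonempty blocks (Bell(n) of them)."""
    def rec(i, parts):
        if i == n:
            yield [list(p) for p in parts]
            return
        for p in parts:
            p.append(i)
            yield from rec(i + 1, parts)
            p.pop()
        parts.append([i])
        yield from rec(i + 1, parts)
        parts.pop()

    yield from rec(0, [])


def partition_to_assignment(parts, n: int) -> np.ndarray:
    a = np.empty(n, dtype=int)
    for c, block in enumerate(parts):
        for i in block:
            a[i] = c
    return a


def modularity_oracle(weights: np.ndarray, assignment, gamma: float) -> float:
    """Direct double-sum evaluation of generalized modularity on A=|w|."""
    A = np.abs(np.asarray(weights, dtype=float))
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    two_m = k.sum()
    q = 0.0
    n = A.shape[0]
    for i in range(n):
        for j in range(n):
            if assignment[i] == assignment[j]:
                q += A[i, j] - gamma * k[i] * k[j] / two_m
    return q / two_m


def max_modularity_exhaustive(weights: np.ndarray, gamma: float) -> float:
    """Best Q over every partition (feasible for <= 8 nodes)."""
    n = weights.shape[0]
    best = -np.inf
    for parts in set_partitions(n):
        a = partition_to_assignment(parts, n)
        best = max(best, modularity_oracle(weights, a, gamma))
    return best


def betweenness_oracle(weights: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Betweenness by exhaustive simple-path enumeration.

    For every unordered pair, enumerate all simple paths, find the minimum
    total length (1/|w| per edge), and credit interior nodes fractionally
    across the tied-shortest paths."""
    A = np.abs(np.asarray(weights, dtype=float))
    n = A.shape[0]
    neighbors = [np.where(A[i] > 0)[0] for i in range(n)]

    def all_paths(s, t):
        stack = [(s, [s], 0.0)]
        while stack:
            node, path, dist = stack.pop()
            if node == t:
                yield path, dist
                continue
            for nb in neighbors[node]:
                if nb not in path:
                    stack.append((nb, path + [int(nb)], dist + 1.0 / A[node, nb]))

    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = list(all_paths(s, t))
        if not paths:
            continue
        dmin = min(d for _, d in paths)
        shortest = [p for p, d in paths if d <= dmin + tol]
        for p in shortest:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(shortest)
    return bc


def closeness_oracle(weights: np.ndarray) -> np.ndarray:
    """Wasserman-Faust closeness from Dijkstra distances (scipy)."""
    from scipy.sparse.csgraph import dijkstra

    A = np.abs(np.asarray(weights, dtype=float))
    n = A.shape[0]
    with np.errstate(divide="ignore"):
        lengths = np.where(A > 0, 1.0 / A, 0.0)
    d = dijkstra(lengths, directed=False)
    out = np.zeros(n)
    for v in range(n):
        reach = np.isfinite(d[v]) & (np.arange(n) != v)
        r = int(reach.sum())
        if r == 0:
            continue
        total = d[v][reach].sum()
        out[v] = (r / (n - 1)) * (r / total)
    return out


# ---------------------------------------------------------------------------
# synthetic specs
# ---------------------------------------------------------------------------

def planted_spec(
    n_subjects: int = 1000,
    seed: int = 0,
    n_factors: int = 3,
    items_per_factor: int = 5,
    within: float = 0.5,
    between: float = 0.1,
) -> tuple[CohortSpec, np.ndarray]:
    """Continuous-item cohort with a planted module structure.

    Loading 0.7 and noise 0.7 give within-module correlations of
    ``0.5 * phi_within`` form: with phi=1 within (same factor) the item
    correlation is ~0.5, and factor correlation ``between/within`` yields
    between-module correlations of ~``between``.  Returns the cohort recipe and the
    planted factor labels per item."""
    phi = np.full((n_factors, n_factors), between / within)
    phi[np.diag_indices(n_factors)] = 1.0
    items = []
    labels = []
    for f in range(n_factors):
        for i in range(items_per_factor):
            load = [0.0] * n_factors
            load[f] = 0.7
            items.append(
                ItemSpec(
                    f"f{f}_item{i}",
                    "psychopathology",
                    loadings=tuple(load),
                )
            )
            labels.append(f)
    spec = CohortSpec(
        n_subjects=n_subjects,
        items=items,
        factor_correlations=phi,
        noise_sd=0.7,
        missing_rate=0.0,
        seed=seed,
        cohort_id="planted",
    )
    return spec, np.array(labels)
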