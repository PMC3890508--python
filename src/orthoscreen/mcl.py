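"""Markov clustering (MCL) of the weighted orthology graph.

MCL simulates random walks on the graph: *expansion* (matrix squaring)
spreads walk probability along paths, *inflation* (entrywise powering
followed by column renormalization) sharpens it toward attractors.  The
inflation exponent controls granularity; the pipeline default of 1.5 is
the inclusive setting appropriate for deeply diverged proteomes.

Clusters are read off the limit matrix as attractor basins; overlapping
nodes (rare) go to the basin holding more of their limit mass.  Clusters
smaller than ``min_cluster_size`` are reported as singletons, matching
the convention that an orthologous group has at least two members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .graph import OrthologyGraph


@dataclass
class ClusteringParams:
    inflation: float = 1.5
    pruning_threshold: float = 1e-5
    convergence_tol: float = 1e-6
    max_iterations: int = 100
    min_cluster_size: int = 2

    def validate(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must be > 1")
        if self.pruning_threshold <= 0 or self.convergence_tol <= 0:
            raise ValueError("tolerances must be > 0")


@dataclass
class ClusterSet:
    """Disjoint clusters (id -> sorted member tuple) plus singletons."""

    clusters: dict[str, tuple[str, ...]] = field(default_factory=dict)
    singletons: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.clusters)

    def all_proteins(self) -> set[str]:
        out = set(self.singletons)
        for members in self.clusters.values():
            out.update(members)
        return out

    def cluster_of(self) -> dict[str, str]:
        return {pid: cid for cid, members in self.clusters.items()
                for pid in members}

    def members_with_species(self, cid: str, species: str,
                             species_of: dict[str, str]) -> list[str]:
        return [p for p in self.clusters[cid] if species_of[p] == species]


def _assign_cluster_ids(groups: list[list[str]],
                        singles: list[str]) -> ClusterSet:
    """Stable ids: descending size, then lexicographic smallest member."""
    groups = [sorted(g) for g in groups]
    groups.sort(key=lambda g: (-len(g), g[0]))
    clusters = {f"CLUSTER_{i + 1:04d}": tuple(g) for i, g in enumerate(groups)}
    return ClusterSet(clusters=clusters, singletons=tuple(sorted(singles)))


def _column_normalize(m: np.ndarray) -> np.ndarray:
    s = m.sum(axis=0)
    s[s == 0] = 1.0
    return m / s


def _mcl_matrix(m: np.ndarray, params: ClusteringParams) -> np.ndarray:
    """Iterate expansion / inflation / pruning to (near) convergence."""
    m = _column_normalize(m)
    for _ in range(params.max_iterations):
        prev = m
        m = m @ m
        m = _column_normalize(np.power(m, params.inflation))
        m[m < params.pruning_threshold] = 0.0
        m = _column_normalize(m)
        if np.abs(m - prev).max() < params.convergence_tol:
            return m
    warnings.warn("MCL did not converge within max_iterations; "
                  "reading clusters from the current matrix")
    return m


def _read_clusters(m: np.ndarray, labels: list[str],
                   eps: float) -> list[list[str]]:
    """Attractor basins of the limit matrix.

    Attractors are nodes with positive diagonal mass; attractors whose
    rows overlap form one attractor system.  Every node joins the system
    holding the largest share of its column mass (ties: the system with
    the lexicographically smallest member).
    """
    n = m.shape[0]
    attractors = [i for i in range(n) if m[i, i] > eps]
    if not attractors:
        # non-converged fallback: connected components of the support
        return _support_components(m, labels, eps)

    # union attractors sharing any supported column
    parent = {a: a for a in attractors}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for j in range(n):
        owners = [a for a in attractors if m[a, j] > eps]
        for a in owners[1:]:
            ra, rb = find(owners[0]), find(a)
            if ra != rb:
                parent[rb] = ra

    systems: dict[int, list[int]] = {}
    for a in attractors:
        systems.setdefault(find(a), []).append(a)
    system_ids = sorted(systems)

    assignment: dict[int, int] = {}
    for j in range(n):
        masses = []
        for sid in system_ids:
            mass = float(sum(m[a, j] for a in systems[sid]))
            if mass > eps:
                key = min(labels[a] for a in systems[sid])
                masses.append((-mass, key, sid))
        if masses:
            masses.sort()
            assignment[j] = masses[0][2]

    groups: dict[int, list[str]] = {}
    for j, sid in assignment.items():
        groups.setdefault(sid, []).append(labels[j])
    out = [sorted(g) for g in groups.values()]
    # nodes never touched by an attractor row become their own group
    unassigned = [labels[j] for j in range(n) if j not in assignment]
    out.extend([[u] for u in unassigned])
    return out


def _support_components(m: np.ndarray, labels: list[str],
                        eps: float) -> list[list[str]]:
    n = m.shape[0]
    sup = (m > eps) | (m.T > eps)
    seen = [False] * n
    comps = []
    for i in range(n):
        if seen[i]:
            continue
        stack, comp = [i], []
        seen[i] = True
        while stack:
            x = stack.pop()
            comp.append(labels[x])
            for y in np.flatnonzero(sup[x]):
                if not seen[y]:
                    seen[y] = True
                    stack.append(int(y))
        comps.append(sorted(comp))
    return comps


def mcl(graph: OrthologyGraph,
        params: ClusteringParams | None = None) -> ClusterSet:
    """Cluster the orthology graph by Markov clustering.

    The stochastic matrix uses normalized edge weights with a self-loop
    per node equal to its maximum incident weight (1 for isolated
    nodes), the standard stabilization.  Each connected component is
    clustered independently (the walk cannot cross components).
    """
    params = params or ClusteringParams()
    params.validate()
    if not graph.nodes:
        raise ValueError("graph has no nodes")

    adj = graph.neighbors()
    weight: dict[tuple[str, str], float] = {}
    for (u, v), e in graph.edges.items():
        weight[(u, v)] = weight[(v, u)] = e.normalized_weight

    # connected components of the input graph
    seen: set[str] = set()
    components: list[list[str]] = []
    for node in sorted(graph.nodes):
        if node in seen:
            continue
        stack, comp = [node], []
        seen.add(node)
        while stack:
            x = stack.pop()
            comp.append(x)
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        components.append(sorted(comp))

    groups: list[list[str]] = []
    singles: list[str] = []
    for comp in components:
        if len(comp) == 1:
            singles.append(comp[0])
            continue
        idx = {n: i for i, n in enumerate(comp)}
        m = np.zeros((len(comp), len(comp)))
        for u in comp:
            for v in adj[u]:
                m[idx[u], idx[v]] = weight[(u, v)]
        loops = m.max(axis=0)
        loops[loops == 0] = 1.0
        np.fill_diagonal(m, loops)
        limit = _mcl_matrix(m, params)
        for g in _read_clusters(limit, comp, params.pruning_threshold):
            if len(g) >= params.min_cluster_size:
                groups.append(g)
            else:
                singles.extend(g)
    return _assign_cluster_ids(groups, singles)


def cluster_proteomes(proteomes: dict[str, dict[str, str]],
                      sim_params=None, clustering_params=None,
                      redundancy_threshold: float = 0.99):
    """Redundancy screen -> all-vs-all -> graph -> MCL, end to end.

    Returns ``(cluster_set, hit_table, graph, removal_logs)``.
    """
    from .align import SimilarityParams, all_vs_all, redundancy_filter
    from .graph import build_graph

    sim_params = sim_params or SimilarityParams()
    clustering_params = clustering_params or ClusteringParams()
    filtered: dict[str, dict[str, str]] = {}
    removal_logs: dict[str, list] = {}
    for sp in sorted(proteomes):
        filtered[sp], removal_logs[sp] = redundancy_filter(
            proteomes[sp], redundancy_threshold, sim_params)
    hits = all_vs_all(filtered, sim_params)
    graph = build_graph(hits, sim_params)
    # proteins with no edges at all never enter the matrix; keep them as
    # singletons so clusters + singletons still cover the input
    clusters = mcl(graph, clustering_params)
    return clusters, hits, graph, removal_logs
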