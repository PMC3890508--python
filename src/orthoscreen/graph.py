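"""OrthoMCL-style orthology graph construction.

From the all-vs-all hit table, three edge classes are built:

* **ortholog** — cross-species reciprocal best hits, both directions
  significant;
* **in-paralog** — same-species pairs mutually scoring at least as well
  as either member's best cross-species hit (recent, lineage-specific
  duplicates), kept only when connected to the ortholog graph;
* **co-ortholog** — cross-species pairs joined through one in-paralog
  step on either side of an ortholog edge, with a significant direct hit.

Edges are weighted by the mean -log10(E-value) over the two directions
and normalized per species pair (orthologs/co-orthologs) or per species
(in-paralogs), the published OrthoMCL scheme, before Markov clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import EVALUE_FLOOR, HitTable, SimilarityHit, SimilarityParams

import math

EDGE_CLASSES = ("ortholog", "in_paralog", "co_ortholog")


@dataclass
class Edge:
    u: str
    v: str
    edge_class: str
    raw_weight: float = 0.0
    normalized_weight: float = 0.0

    @property
    def key(self) -> tuple[str, str]:
        return (self.u, self.v) if self.u < self.v else (self.v, self.u)


@dataclass
class OrthologyGraph:
    nodes: list[str]
    species_of: dict[str, str]
    edges: dict[tuple[str, str], Edge] = field(default_factory=dict)

    def add_edge(self, edge: Edge) -> None:
        self.edges[edge.key] = edge

    def edges_of_class(self, edge_class: str) -> list[Edge]:
        return [e for e in self.edges.values() if e.edge_class == edge_class]

    def neighbors(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for (u, v) in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return adj


def best_hits(hits: HitTable) -> dict[tuple[str, str], SimilarityHit]:
    """Best stored hit per (query, subject species), by the tie-break rule."""
    out: dict[tuple[str, str], SimilarityHit] = {}
    queries = hits.queries()
    for q in queries:
        per_species: dict[str, SimilarityHit] = {}
        for h in hits.hits_from(q):
            sp = hits.species_of[h.subject_id]
            cur = per_species.get(sp)
            if cur is None or h.sort_key() < cur.sort_key():
                per_species[sp] = h
        for sp, h in per_species.items():
            out[(q, sp)] = h
    return out


def putative_orthologs(hits: HitTable,
                       params: SimilarityParams | None = None,
                       best: dict | None = None) -> set[tuple[str, str]]:
    """Cross-species reciprocal best hits with both E-values significant."""
    params = params or SimilarityParams()
    best = best if best is not None else best_hits(hits)
    sig = params.significance_evalue
    edges: set[tuple[str, str]] = set()
    for (q, sp), h in best.items():
        if hits.species_of[q] == sp:
            continue
        b = h.subject_id
        back = best.get((b, hits.species_of[q]))
        if back is None or back.subject_id != q:
            continue
        if h.evalue <= sig and back.evalue <= sig:
            edges.add((q, b) if q < b else (b, q))
    return edges


def _best_cross_key(q: str, hits: HitTable, best: dict):
    """Tie-break key of q's best cross-species hit (None if no such hit)."""
    own = hits.species_of[q]
    keys = [best[(q, sp)].sort_key()
            for sp in set(hits.species_of.values())
            if sp != own and (q, sp) in best]
    return min(keys) if keys else None


def in_paralogs(hits: HitTable, ortholog_edges: set[tuple[str, str]],
                params: SimilarityParams | None = None,
                best: dict | None = None) -> set[tuple[str, str]]:
    """Same-species recent-duplicate pairs anchored to the ortholog graph.

    (a, a') is an in-paralog edge iff both mutual hits are significant,
    each hit is at least as good (tie-break rule) as that member's best
    cross-species hit, and at least one member has an ortholog edge.
    """
    params = params or SimilarityParams()
    best = best if best is not None else best_hits(hits)
    sig = params.significance_evalue
    has_ortholog = {n for e in ortholog_edges for n in e}

    cross_key: dict[str, tuple | None] = {}
    pairs: set[tuple[str, str]] = set()
    for (q, s) in hits.pairs():
        if q >= s or hits.species_of[q] != hits.species_of[s]:
            continue
        fwd, rev = hits.get(q, s), hits.get(s, q)
        if fwd is None or rev is None:
            continue
        if fwd.evalue > sig or rev.evalue > sig:
            continue
        for x in (q, s):
            if x not in cross_key:
                cross_key[x] = _best_cross_key(x, hits, best)
        kq, ks = cross_key[q], cross_key[s]
        if kq is not None and fwd.sort_key() > kq:
            continue
        if ks is not None and rev.sort_key() > ks:
            continue
        if q in has_ortholog or s in has_ortholog:
            pairs.add((q, s))
    return pairs


def co_orthologs(ortholog_edges: set[tuple[str, str]],
                 in_paralog_edges: set[tuple[str, str]],
                 hits: HitTable,
                 params: SimilarityParams | None = None) -> set[tuple[str, str]]:
    """Cross-species pairs linked through an in-paralog expansion.

    (a, b) qualifies iff it is not already an ortholog edge, both
    directed hits exist and are significant, and a path
    a -[in-paralog]- a' -[ortholog]- b (or the mirror, or with one
    in-paralog step on both sides) connects them.
    """
    params = params or SimilarityParams()
    sig = params.significance_evalue
    para_of: dict[str, set[str]] = {}
    for (u, v) in in_paralog_edges:
        para_of.setdefault(u, set()).add(v)
        para_of.setdefault(v, set()).add(u)

    candidates: set[tuple[str, str]] = set()
    for (a, b) in ortholog_edges:
        group_a = {a} | para_of.get(a, set())
        group_b = {b} | para_of.get(b, set())
        for x in group_a:
            for y in group_b:
                pair = (x, y) if x < y else (y, x)
                if pair not in ortholog_edges:
                    candidates.add(pair)

    edges: set[tuple[str, str]] = set()
    for (x, y) in candidates:
        if hits.species_of[x] == hits.species_of[y]:
            continue
        fwd, rev = hits.get(x, y), hits.get(y, x)
        if fwd is None or rev is None:
            continue
        if fwd.evalue <= sig and rev.evalue <= sig:
            edges.add((x, y))
    return edges


def _raw_weight(u: str, v: str, hits: HitTable) -> float:
    fwd, rev = hits.get(u, v), hits.get(v, u)
    vals = []
    for h in (fwd, rev):
        if h is not None:
            vals.append(-math.log10(max(h.evalue, EVALUE_FLOOR)))
    if not vals:
        return 0.0
    return sum(vals) / len(vals)


def build_graph(hits: HitTable,
                params: SimilarityParams | None = None) -> OrthologyGraph:
    """Classify edges and compute raw + normalized weights."""
    params = params or SimilarityParams()
    best = best_hits(hits)
    orth = putative_orthologs(hits, params, best)
    para = in_paralogs(hits, orth, params, best)
    coorth = co_orthologs(orth, para, hits, params)

    nodes = sorted(hits.species_of)
    g = OrthologyGraph(nodes=nodes, species_of=dict(hits.species_of))
    for (u, v) in sorted(orth):
        g.add_edge(Edge(u, v, "ortholog", raw_weight=_raw_weight(u, v, hits)))
    for (u, v) in sorted(para):
        g.add_edge(Edge(u, v, "in_paralog", raw_weight=_raw_weight(u, v, hits)))
    for (u, v) in sorted(coorth):
        g.add_edge(Edge(u, v, "co_ortholog", raw_weight=_raw_weight(u, v, hits)))
    normalize_weights(g)
    return g


def normalize_weights(g: OrthologyGraph) -> None:
    """OrthoMCL weight normalization, in place.

    Ortholog and co-ortholog edges are divided by the mean raw weight of
    the *ortholog* edges of their species pair; in-paralog edges by the
    mean raw weight of the in-paralog edges of their species whose
    members have orthologs.  Groups with no ortholog anchor fall back to
    divisor 1.
    """
    pair_means: dict[tuple[str, str], float] = {}
    sums: dict[tuple[str, str], list[float]] = {}
    for e in g.edges_of_class("ortholog"):
        sp = tuple(sorted((g.species_of[e.u], g.species_of[e.v])))
        sums.setdefault(sp, []).append(e.raw_weight)
    for sp, vals in sums.items():
        pair_means[sp] = sum(vals) / len(vals)

    has_orth = {n for e in g.edges_of_class("ortholog") for n in (e.u, e.v)}
    para_sums: dict[str, list[float]] = {}
    for e in g.edges_of_class("in_paralog"):
        if e.u in has_orth or e.v in has_orth:
            para_sums.setdefault(g.species_of[e.u], []).append(e.raw_weight)
    para_means = {sp: sum(v) / len(v) for sp, v in para_sums.items()}

    for e in g.edges.values():
        if e.edge_class in ("ortholog", "co_ortholog"):
            sp = tuple(sorted((g.species_of[e.u], g.species_of[e.v])))
            div = pair_means.get(sp, 1.0)
        else:
            div = para_means.get(g.species_of[e.u], 1.0)
        e.normalized_weight = e.raw_weight / div if div > 0 else e.raw_weight
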