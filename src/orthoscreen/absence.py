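"""Decision-tree verification of gene absence in a target species.

For a query protein (typically a C. elegans gene) and a target species
(typically one of the dorylaims), the tree is:

1. the query's cluster contains a target-species member
   -> ``orthologue_present``;
2. otherwise, no hit to the target proteome reaches significance
   (strictly E < threshold; E exactly at the threshold is *not*
   significant) -> ``confirmed_absent``;
3. otherwise, the best significant target hit belongs to a cluster that
   contains a *different* query-species protein — the match is that
   other gene's orthologue, so the query is still unique
   -> ``confirmed_unique_via_cross_cluster`` (partner recorded);
4. otherwise -> ``divergent_candidate_manual_review`` with the best
   hit's E-value/identity/coverage recorded.  This flag stands in for a
   manual follow-up database search; the pipeline performs none.

Absence in this screen maximally implies gene loss and minimally implies
sequence divergence beyond recognition; the shared-loss combinator
therefore carries a caveat flag whenever a manual-review status
contributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import HitTable, SimilarityHit
from .mcl import ClusterSet

STATUS_PRESENT = "orthologue_present"
STATUS_ABSENT = "confirmed_absent"
STATUS_UNIQUE = "confirmed_unique_via_cross_cluster"
STATUS_REVIEW = "divergent_candidate_manual_review"
STATUSES = (STATUS_PRESENT, STATUS_ABSENT, STATUS_UNIQUE, STATUS_REVIEW)
NON_PRESENT = (STATUS_ABSENT, STATUS_UNIQUE, STATUS_REVIEW)


@dataclass
class VerificationParams:
    evalue_threshold: float = 1e-5
    # reporting-only thresholds used to annotate the evidence block
    min_identity_note: float = 0.25
    min_coverage_note: float = 0.5

    def validate(self) -> None:
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be > 0")


@dataclass
class AbsenceCall:
    query_id: str
    target_species: str
    status: str
    best_hit: SimilarityHit | None = None
    cross_cluster_partner: str | None = None
    notes: tuple[str, ...] = ()

    @property
    def present(self) -> bool:
        return self.status == STATUS_PRESENT

    def evidence(self) -> dict:
        out: dict = {"query_id": self.query_id,
                     "target_species": self.target_species,
                     "status": self.status}
        if self.best_hit is not None:
            out["best_hit"] = {
                "subject_id": self.best_hit.subject_id,
                "evalue": self.best_hit.evalue,
                "percent_identity": self.best_hit.percent_identity,
                "query_coverage": self.best_hit.query_coverage,
                "subject_coverage": self.best_hit.subject_coverage,
            }
        if self.cross_cluster_partner is not None:
            out["cross_cluster_partner"] = self.cross_cluster_partner
        if self.notes:
            out["notes"] = list(self.notes)
        return out


def verify_absence(query_id: str, target_species: str, clusters: ClusterSet,
                   hits: HitTable,
                   params: VerificationParams | None = None) -> AbsenceCall:
    """Run the decision tree for one (query, target species) pair."""
    params = params or VerificationParams()
    params.validate()
    if query_id not in hits.species_of:
        raise KeyError(f"unknown query id {query_id!r}")
    query_species = hits.species_of[query_id]
    cluster_of = clusters.cluster_of()

    target_hits = hits.hits_to_species(query_id, target_species)
    best = min(target_hits, key=lambda h: h.sort_key()) if target_hits else None

    notes: list[str] = []
    if best is not None:
        if best.percent_identity < params.min_identity_note:
            notes.append(f"best-hit identity below {params.min_identity_note:.2f}")
        if min(best.query_coverage, best.subject_coverage) < params.min_coverage_note:
            notes.append(f"best-hit coverage below {params.min_coverage_note:.2f}")

    # 1. clustered with a target-species member?
    cid = cluster_of.get(query_id)
    if cid is not None:
        members = clusters.clusters[cid]
        if any(hits.species_of[m] == target_species for m in members):
            return AbsenceCall(query_id, target_species, STATUS_PRESENT,
                               best_hit=best, notes=tuple(notes))

    # 2. any significant hit to the target proteome? (strict <)
    significant = [h for h in target_hits if h.evalue < params.evalue_threshold]
    if not significant:
        return AbsenceCall(query_id, target_species, STATUS_ABSENT,
                           best_hit=best, notes=tuple(notes))

    # 3. best significant target hit clusters with a different query-species
    #    protein -> the query is still unique
    best_sig = min(significant, key=lambda h: h.sort_key())
    t_cid = cluster_of.get(best_sig.subject_id)
    if t_cid is not None:
        partners = [m for m in clusters.clusters[t_cid]
                    if hits.species_of[m] == query_species and m != query_id]
        if partners:
            return AbsenceCall(query_id, target_species, STATUS_UNIQUE,
                               best_hit=best_sig,
                               cross_cluster_partner=sorted(partners)[0],
                               notes=tuple(notes))

    # 4. significant similarity with no orthology assignment either way
    return AbsenceCall(query_id, target_species, STATUS_REVIEW,
                       best_hit=best_sig, notes=tuple(notes))


@dataclass
class AbsencePanel:
    """Presence/absence matrix: one call per (query, target species)."""

    queries: tuple[str, ...]
    target_species: tuple[str, ...]
    calls: dict[tuple[str, str], AbsenceCall] = field(default_factory=dict)

    def call(self, query_id: str, target: str) -> AbsenceCall:
        return self.calls[(query_id, target)]

    def sign(self, query_id: str, target: str) -> str:
        """'+' for orthologue present, '-' for any non-present status."""
        return "+" if self.calls[(query_id, target)].present else "-"

    def to_rows(self) -> list[dict]:
        rows = []
        for q in self.queries:
            row: dict = {"protein": q}
            for t in self.target_species:
                call = self.calls[(q, t)]
                row[t] = "+" if call.present else "-"
                row[f"{t}_status"] = call.status
            rows.append(row)
        return rows


def verify_panel(query_ids, target_species_list, clusters: ClusterSet,
                 hits: HitTable,
                 params: VerificationParams | None = None) -> AbsencePanel:
    """Run the decision tree over a panel of queries and targets."""
    params = params or VerificationParams()
    queries = tuple(query_ids)
    targets = tuple(target_species_list)
    calls = {}
    for q in queries:
        for t in targets:
            calls[(q, t)] = verify_absence(q, t, clusters, hits, params)
    return AbsencePanel(queries=queries, target_species=targets, calls=calls)


@dataclass(frozen=True)
class SharedLossCall:
    query_id: str
    shared_loss: bool
    caveat: bool  # a manual-review status contributed to the absence call


def shared_loss(calls_a: dict[str, AbsenceCall],
                calls_b: dict[str, AbsenceCall]) -> dict[str, SharedLossCall]:
    """Absence inferred only when the query is non-present in both species.

    A divergent-candidate status counts as non-present but raises the
    caveat flag: such absence minimally implies strong divergence rather
    than outright loss.
    """
    if set(calls_a) != set(calls_b):
        raise ValueError("shared_loss requires the same query set on both sides")
    out = {}
    for q in sorted(calls_a):
        a, b = calls_a[q], calls_b[q]
        lost = (not a.present) and (not b.present)
        caveat = lost and (a.status == STATUS_REVIEW or b.status == STATUS_REVIEW)
        out[q] = SharedLossCall(q, lost, caveat)
    return out
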