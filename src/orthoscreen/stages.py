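"""Stage-expression analyses: genus-restricted proportions and the
refinement of phylotypic-stage candidate genes.

Two questions are asked of the C. elegans stage-expression table:

* per developmental stage, what fraction of the genes elevated at that
  stage is apparently unique to the genus (no orthologue in the
  dorylaims or the outgroup)?  Taxon-restricted genes concentrating in
  particular stages argue against uniform conservation of the
  developmental toolkit.
* of the genes elevated in the phylotypic window (stages 6-8, around
  ventral enclosure), which are conserved, and do their clusters extend
  to the outgroup (ecdysozoan core) or stop within Nematoda
  (nematode-restricted)?

"Elevated between stages 6 to 8" is read as elevated at *any* stage in
the window (union).  "No orthologue" for the dorylaim targets uses the
full absence decision tree (a divergent candidate still counts as
potentially conserved); outgroup orthology is judged by cluster
co-membership with a significant-hit fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .absence import (STATUS_ABSENT, STATUS_UNIQUE, VerificationParams,
                      verify_absence)
from .align import HitTable
from .mcl import ClusterSet
from .partition import pattern_of
from .tree import SPECIES


@dataclass
class StageParams:
    phylotypic_range: tuple[int, int] = (6, 8)
    n_stages: int = 10

    def validate(self) -> None:
        lo, hi = self.phylotypic_range
        if not (1 <= lo <= hi <= self.n_stages):
            raise ValueError("phylotypic_range must lie within 1..n_stages")


@dataclass
class ClassSummary:
    n_clusters: int = 0
    cluster_ids: tuple[str, ...] = ()
    members_per_species: dict[str, int] = field(default_factory=dict)
    n_candidates: int = 0  # candidate genes whose cluster falls in this class


@dataclass
class PhylotypicReport:
    n_candidates: int
    n_no_orthologue: int
    n_conserved: int
    n_clusters: int
    nematode_restricted: ClassSummary
    ecdysozoan_core: ClassSummary
    residual: ClassSummary  # outgroup present but a nematode missing
    n_conserved_unclustered: int
    per_stage_restricted_proportion: dict[int, float | None]

    def to_dict(self) -> dict:
        def cls(c: ClassSummary) -> dict:
            return {"n_clusters": c.n_clusters,
                    "cluster_ids": list(c.cluster_ids),
                    "members_per_species": dict(sorted(c.members_per_species.items())),
                    "n_candidates": c.n_candidates}
        return {
            "n_candidates": self.n_candidates,
            "n_no_orthologue": self.n_no_orthologue,
            "n_conserved": self.n_conserved,
            "n_clusters": self.n_clusters,
            "nematode_restricted": cls(self.nematode_restricted),
            "ecdysozoan_core": cls(self.ecdysozoan_core),
            "residual": cls(self.residual),
            "n_conserved_unclustered": self.n_conserved_unclustered,
            "per_stage_restricted_proportion": {
                str(s): v for s, v in
                sorted(self.per_stage_restricted_proportion.items())
            },
        }


def _has_orthologue(gene: str, clusters: ClusterSet, hits: HitTable,
                    verify_params: VerificationParams) -> bool:
    """Orthologue anywhere outside the query's own species?

    Dorylaim targets (rc, ts) use the absence decision tree: only
    confirmed-absent and confirmed-unique count as "no orthologue" (a
    divergent candidate may still be a true orthologue).  The outgroup
    is judged by cluster co-membership, falling back to any significant
    hit.
    """
    for target in ("rc", "ts"):
        call = verify_absence(gene, target, clusters, hits, verify_params)
        if call.status not in (STATUS_ABSENT, STATUS_UNIQUE):
            return True
    cid = clusters.cluster_of().get(gene)
    if cid is not None and any(hits.species_of[m] == "tc"
                               for m in clusters.clusters[cid]):
        return True
    return any(h.evalue < verify_params.evalue_threshold
               for h in hits.hits_to_species(gene, "tc"))


def genus_restricted_proportion(stage_table, clusters: ClusterSet,
                                hits: HitTable,
                                verify_params: VerificationParams | None = None,
                                params: StageParams | None = None
                                ) -> dict[int, float | None]:
    """Per stage: fraction of elevated genes with no orthologue at all.

    Stages with no elevated gene report ``None``.
    """
    params = params or StageParams()
    params.validate()
    verify_params = verify_params or VerificationParams()
    bad = {s for _g, s, _e in stage_table.records
           if not 1 <= s <= params.n_stages}
    if bad:
        raise ValueError(f"stage(s) outside 1..{params.n_stages}: {sorted(bad)}")

    cache: dict[str, bool] = {}

    def restricted(gene: str) -> bool:
        if gene not in cache:
            cache[gene] = not _has_orthologue(gene, clusters, hits, verify_params)
        return cache[gene]

    out: dict[int, float | None] = {}
    for stage in range(1, params.n_stages + 1):
        elevated = stage_table.elevated_at(stage)
        if not elevated:
            out[stage] = None
        else:
            out[stage] = sum(restricted(g) for g in elevated) / len(elevated)
    return out


def refine_phylotypic(stage_table, clusters: ClusterSet,
                      species_of: dict[str, str], hits: HitTable,
                      verify_params: VerificationParams | None = None,
                      params: StageParams | None = None) -> PhylotypicReport:
    """Split phylotypic-window candidates by conservation depth.

    Candidates are the genes elevated at any stage of the phylotypic
    window.  Genes with no orthologue anywhere form the taxon-restricted
    fraction; the remainder map to their clusters, which are classified
    as nematode-restricted (no outgroup member), ecdysozoan core (all
    four species) or residual (outgroup present, some nematode absent).
    Member counts per species include co-orthologues, so they may exceed
    the candidate count.
    """
    params = params or StageParams()
    params.validate()
    verify_params = verify_params or VerificationParams()
    lo, hi = params.phylotypic_range
    candidates = stage_table.elevated_in_range(lo, hi)

    cluster_of = clusters.cluster_of()
    no_orth: list[str] = []
    conserved: list[str] = []
    for gene in candidates:
        if _has_orthologue(gene, clusters, hits, verify_params):
            conserved.append(gene)
        else:
            no_orth.append(gene)

    cluster_candidates: dict[str, list[str]] = {}
    unclustered = 0
    for gene in conserved:
        cid = cluster_of.get(gene)
        if cid is None:
            unclustered += 1
        else:
            cluster_candidates.setdefault(cid, []).append(gene)

    def summarize(cids: list[str]) -> ClassSummary:
        per_species = {sp: 0 for sp in SPECIES}
        n_cand = 0
        for cid in cids:
            for m in clusters.clusters[cid]:
                per_species[species_of[m]] += 1
            n_cand += len(cluster_candidates[cid])
        return ClassSummary(
            n_clusters=len(cids), cluster_ids=tuple(sorted(cids)),
            members_per_species=per_species, n_candidates=n_cand)

    nem_restricted, ecdyso, residual = [], [], []
    for cid in sorted(cluster_candidates):
        pat = pattern_of(clusters.clusters[cid], species_of).species
        if "tc" not in pat:
            nem_restricted.append(cid)
        elif pat == frozenset(SPECIES):
            ecdyso.append(cid)
        else:
            residual.append(cid)

    report = PhylotypicReport(
        n_candidates=len(candidates),
        n_no_orthologue=len(no_orth),
        n_conserved=len(conserved),
        n_clusters=len(cluster_candidates),
        nematode_restricted=summarize(nem_restricted),
        ecdysozoan_core=summarize(ecdyso),
        residual=summarize(residual),
        n_conserved_unclustered=unclustered,
        per_stage_restricted_proportion=genus_restricted_proportion(
            stage_table, clusters, hits, verify_params, params),
    )
    assert report.n_no_orthologue + report.n_conserved == report.n_candidates
    return report
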