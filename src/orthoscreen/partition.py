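"""Species-membership partition of orthology clusters.

Each cluster is summarized by the set of species contributing members
(its membership pattern); counting clusters per pattern reproduces the
four-way Venn partition used to separate the conserved nematode core,
the conserved ecdysozoan core, pairwise-exclusive classes, and
species-restricted clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .mcl import ClusterSet
from .tree import SPECIES

NEMATODES = ("rc", "ts", "ce")
OUTGROUP = "tc"


@dataclass(frozen=True)
class MembershipPattern:
    species: frozenset[str]

    def __post_init__(self):
        if not self.species:
            raise ValueError("membership pattern cannot be empty")
        unknown = self.species - set(SPECIES)
        if unknown:
            raise ValueError(f"unknown species in pattern: {sorted(unknown)}")

    @property
    def all_nematodes(self) -> bool:
        return set(NEMATODES) <= self.species

    @property
    def has_outgroup(self) -> bool:
        return OUTGROUP in self.species

    @property
    def key(self) -> str:
        return "+".join(sp for sp in SPECIES if sp in self.species)


def pattern_of(members, species_of: dict[str, str]) -> MembershipPattern:
    """The set of species with at least one member in the cluster."""
    try:
        return MembershipPattern(frozenset(species_of[p] for p in members))
    except KeyError as exc:
        raise KeyError(f"protein {exc.args[0]!r} has no species assignment") from exc


def all_patterns() -> list[str]:
    """The 15 possible nonempty patterns, in canonical order."""
    out = []
    for r in range(1, 5):
        for combo in combinations(SPECIES, r):
            out.append("+".join(combo))
    return out


@dataclass
class PartitionReport:
    pattern_counts: dict[str, int] = field(default_factory=dict)
    n_clusters: int = 0
    n_singletons: int = 0

    @property
    def conserved_nematode_core(self) -> int:
        """Clusters with members from all three nematodes (with or without tc)."""
        return sum(c for pat, c in self.pattern_counts.items()
                   if set(NEMATODES) <= set(pat.split("+")))

    @property
    def conserved_ecdysozoan_core(self) -> int:
        """Clusters with members from all three nematodes plus the outgroup."""
        return self.pattern_counts.get("+".join(SPECIES), 0)

    def pairwise_exclusive(self, a: str, b: str) -> int:
        """Clusters containing exactly species {a, b}."""
        key = "+".join(sp for sp in SPECIES if sp in (a, b))
        return self.pattern_counts.get(key, 0)

    def single_species(self, sp: str, with_outgroup: bool | None = None) -> int:
        """Clusters whose only nematode is *sp* (optionally split by tc)."""
        if sp == OUTGROUP:
            return self.pattern_counts.get(OUTGROUP, 0)
        n_alone = self.pattern_counts.get(sp, 0)
        key_tc = "+".join(s for s in SPECIES if s in (sp, OUTGROUP))
        n_with_tc = self.pattern_counts.get(key_tc, 0)
        if with_outgroup is None:
            return n_alone + n_with_tc
        return n_with_tc if with_outgroup else n_alone

    def to_rows(self) -> list[dict]:
        return [{"pattern": pat, "count": self.pattern_counts.get(pat, 0)}
                for pat in all_patterns()]


def partition_counts(clusters: ClusterSet,
                     species_of: dict[str, str]) -> PartitionReport:
    """Count clusters per membership pattern.

    Singletons are excluded from the pattern counts (a cluster has at
    least two members) and reported separately.
    """
    counts: dict[str, int] = {}
    for members in clusters.clusters.values():
        key = pattern_of(members, species_of).key
        counts[key] = counts.get(key, 0) + 1
    report = PartitionReport(
        pattern_counts=counts,
        n_clusters=len(clusters.clusters),
        n_singletons=len(clusters.singletons),
    )
    assert sum(counts.values()) == report.n_clusters
    return report


def select_clusters(clusters: ClusterSet, species_of: dict[str, str],
                    require: set[str] = frozenset(),
                    forbid: set[str] = frozenset()) -> ClusterSet:
    """Clusters whose pattern includes *require* and avoids *forbid*."""
    require, forbid = set(require), set(forbid)
    if require & forbid:
        raise ValueError("require and forbid overlap")
    selected = {}
    for cid, members in clusters.clusters.items():
        pat = pattern_of(members, species_of).species
        if require <= pat and not (forbid & pat):
            selected[cid] = members
    return ClusterSet(clusters=selected, singletons=())


def member_proteins(clusters: ClusterSet, species: str,
                    species_of: dict[str, str]) -> list[str]:
    """Deduplicated, sorted members of the given species across clusters."""
    out = {p for members in clusters.clusters.values() for p in members
           if species_of[p] == species}
    return sorted(out)
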