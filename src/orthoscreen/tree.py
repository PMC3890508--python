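"""Fixed four-taxon species tree for the orthology screen.

The comparison set is two enoplean (dorylaim) nematodes, *Romanomermis
culicivorax* (``rc``) and *Trichinella spiralis* (``ts``), the rhabditid
model *Caenorhabditis elegans* (``ce``), and the beetle outgroup
*Tribolium castaneum* (``tc``), related as ``(((rc,ts),ce),tc)``.

Seven branches carry gene-family events: the four terminal branches
(named after their leaf), the dorylaim stem ``n2`` (ancestor of rc+ts),
the nematode stem ``n3`` (ancestor of rc+ts+ce), and ``root`` (above the
last common ancestor of all four; a family born there is ancestrally
present in every species).
"""

from __future__ import annotations

from dataclasses import dataclass, field

SPECIES: tuple[str, ...] = ("rc", "ts", "ce", "tc")

#: branch -> species descending from (below) that branch
_DESCENDANTS: dict[str, frozenset[str]] = {
    "root": frozenset({"rc", "ts", "ce", "tc"}),
    "n3": frozenset({"rc", "ts", "ce"}),
    "n2": frozenset({"rc", "ts"}),
    "rc": frozenset({"rc"}),
    "ts": frozenset({"ts"}),
    "ce": frozenset({"ce"}),
    "tc": frozenset({"tc"}),
}

#: branches on the path from the root node down to each leaf (root branch excluded)
_PATHS: dict[str, tuple[str, ...]] = {
    "rc": ("n3", "n2", "rc"),
    "ts": ("n3", "n2", "ts"),
    "ce": ("n3", "ce"),
    "tc": ("tc",),
}


@dataclass(frozen=True)
class SpeciesTree:
    """The rooted shape (((rc,ts),ce),tc) with unit-length branches."""

    labels: tuple[str, ...] = SPECIES

    @property
    def branches(self) -> tuple[str, ...]:
        return ("root", "n3", "n2", "rc", "ts", "ce", "tc")

    def descendants(self, branch: str) -> frozenset[str]:
        """Species whose terminal branches lie below *branch*."""
        return _DESCENDANTS[branch]

    def subtree_branches(self, branch: str) -> tuple[str, ...]:
        """Branches strictly below *branch* (candidate loss locations)."""
        below = _DESCENDANTS[branch]
        return tuple(
            b for b in self.branches
            if b not in (branch, "root") and _DESCENDANTS[b] <= below
        )

    def path_to_leaf(self, species: str) -> tuple[str, ...]:
        """Branches from the root node down to *species*."""
        return _PATHS[species]

    def leaf_depth(self, species: str) -> int:
        return len(_PATHS[species])

    def leaf_distance(self, a: str, b: str) -> int:
        """Number of unit branches separating two leaves."""
        if a == b:
            return 0
        pa, pb = _PATHS[a], _PATHS[b]
        shared = 0
        for x, y in zip(pa, pb):
            if x != y:
                break
            shared += 1
        return (len(pa) - shared) + (len(pb) - shared)

    @property
    def max_leaf_distance(self) -> int:
        """The full tree depth, leaf to leaf through the root (= 4)."""
        return max(
            self.leaf_distance(a, b) for a in self.labels for b in self.labels
        )

    def present_species(self, birth_branch: str, lost_branches) -> frozenset[str]:
        """Species retaining a family born on *birth_branch* after the losses.

        A species is present iff it descends from the birth branch and no
        branch on the path from the birth branch down to it carries a loss.
        """
        lost = frozenset(lost_branches)
        out = set()
        for sp in self.descendants(birth_branch):
            if birth_branch == "root":
                below = _PATHS[sp]
            else:
                # strict suffix of the root->leaf path after the birth branch
                idx = _PATHS[sp].index(birth_branch)
                below = _PATHS[sp][idx + 1:]
            if not lost.intersection(below):
                out.add(sp)
        return frozenset(out)
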