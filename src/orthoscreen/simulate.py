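"""Gene-family birth/loss/duplication simulator with known truth.

Generates four-taxon proteomes whose gene-family history is recorded
exactly, so every downstream inference (clustering, membership patterns,
absence calls, enrichment, phylotypic refinement) can be scored against
ground truth.

The model: each family is born on one branch of the fixed species tree,
is lost independently on each branch below its birth, and gains extra
copies (recent paralogs) in surviving terminal lineages.  Protein
sequences evolve from a random ancestral sequence by per-site uniform
replacement over the 19 alternative residues, with the per-branch
substitution probability calibrated so that orthologs separated by the
full tree depth (four unit branches, e.g. rc vs tc) show a chosen
expected percent identity.  Under that chain the expected identity after
``m`` unit branches is ``1/20 + (19/20) * r**m`` with ``r`` the per-branch
retention factor, which makes the calibration closed-form.

Lineage-specific "novel" genes (i.i.d. random sequences belonging to no
family) emulate taxonomically restricted genes; a designated subset of
conserved families provides the planted phylotypic-stage gene set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .tree import SPECIES, SpeciesTree

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline configuration."""


@dataclass
class SimulationParams:
    """Study-design knobs for the synthetic four-taxon data set.

    Defaults describe the standard benchmark: 50 families born at the
    root with stochastic loss (10% per branch) and rare duplication,
    plus engineered family classes that every analysis stage needs to
    exist — 20 families lost on the dorylaim stem (``n2``; these play the
    role of C. elegans-restricted developmental genes in the absence
    panel), 10 families lost on the ``ce`` branch (the dorylaim-specific
    class used for enrichment), and 10 extreme-divergence families that
    stress the remote-homology edge of the decision tree.
    """

    n_families: int = 50
    birth_branch_weights: dict[str, float] = field(
        default_factory=lambda: {"root": 1.0}
    )
    loss_prob: float = 0.1
    dup_rate: float = 0.05
    seq_length_range: tuple[int, int] = (60, 100)
    target_identity: float = 0.7
    n_novel_per_species: int = 5
    n_divergent_families: int = 10
    divergent_identity: float = 0.20
    forced_loss_families: dict[str, int] = field(
        default_factory=lambda: {"n2": 20, "ce": 10}
    )
    # GO annotation layer
    n_go_terms: int = 40
    go_background_freq: float = 0.05
    enriched_term_freq: float = 0.8
    # stage-expression layer
    n_stages: int = 10
    n_phylotypic_families: int = 20
    conserved_elevated_per_stage: int = 3
    novel_elevated_per_stage: int = 1
    rng_seed: int = 42

    def validate(self) -> None:
        if self.n_families <= 0:
            raise ConfigurationError("n_families must be positive")
        if not 0.0 <= self.loss_prob <= 1.0:
            raise ConfigurationError("loss_prob must lie in [0, 1]")
        if self.dup_rate < 0:
            raise ConfigurationError("dup_rate must be >= 0")
        lo, hi = self.seq_length_range
        if lo < 30 or hi < lo:
            raise ConfigurationError("seq_length_range min must be >= 30 and <= max")
        for t in (self.target_identity, self.divergent_identity):
            if not 0.05 <= t <= 1.0:
                raise ConfigurationError(
                    "identity targets must lie in [0.05, 1] (0.05 is the "
                    "random-match floor of the 20-letter alphabet)"
                )
        if not self.birth_branch_weights:
            raise ConfigurationError("birth_branch_weights must be nonempty")
        if any(w < 0 for w in self.birth_branch_weights.values()):
            raise ConfigurationError("birth weights must be >= 0")
        for n in (self.n_novel_per_species, self.n_divergent_families,
                  self.n_go_terms, self.n_phylotypic_families):
            if n < 0:
                raise ConfigurationError("counts must be >= 0")


def _rng(params: SimulationParams, stream: int) -> np.random.Generator:
    """Named substream so partial re-runs stay reproducible."""
    return np.random.default_rng(
        np.random.SeedSequence(params.rng_seed, spawn_key=(stream,))
    )


@dataclass(frozen=True)
class FamilyRecord:
    family_id: str
    birth_branch: str
    lost_branches: frozenset[str]
    members: dict[str, tuple[str, ...]]  # species -> protein ids
    divergent: bool = False

    @property
    def present_species(self) -> frozenset[str]:
        return frozenset(sp for sp, ids in self.members.items() if ids)

    @property
    def member_ids(self) -> tuple[str, ...]:
        out: list[str] = []
        for sp in SPECIES:
            out.extend(self.members.get(sp, ()))
        return tuple(out)


class FamilyTruthTable:
    """Ground-truth gene-family history: one record per family."""

    def __init__(self, families: list[FamilyRecord], tree: SpeciesTree):
        self.families = list(families)
        self.tree = tree
        self.by_id = {f.family_id: f for f in self.families}
        self.family_of: dict[str, str] = {}
        for fam in self.families:
            for pid in fam.member_ids:
                if pid in self.family_of:
                    raise ValueError(f"protein {pid} appears in two families")
                self.family_of[pid] = fam.family_id

    def __len__(self) -> int:
        return len(self.families)

    def __iter__(self):
        return iter(self.families)

    def check_consistency(self) -> None:
        """Assert presence/absence matches the recorded event history."""
        for fam in self.families:
            expected = self.tree.present_species(fam.birth_branch, fam.lost_branches)
            if fam.present_species != expected:
                raise AssertionError(
                    f"{fam.family_id}: members in {set(fam.present_species)} "
                    f"but events predict {set(expected)}"
                )

    def to_rows(self) -> list[dict]:
        rows = []
        for fam in self.families:
            rows.append({
                "family_id": fam.family_id,
                "birth_branch": fam.birth_branch,
                "lost_branches": ",".join(sorted(fam.lost_branches)) or "-",
                "members": ";".join(fam.member_ids) or "-",
                "divergent": int(fam.divergent),
            })
        return rows

    @classmethod
    def from_rows(cls, rows, tree: SpeciesTree | None = None) -> "FamilyTruthTable":
        tree = tree or SpeciesTree()
        fams = []
        for r in rows:
            members: dict[str, tuple[str, ...]] = {sp: () for sp in SPECIES}
            if r["members"] != "-":
                for pid in r["members"].split(";"):
                    sp = pid.split("|", 1)[0]
                    members[sp] = members[sp] + (pid,)
            lost = frozenset() if r["lost_branches"] == "-" else frozenset(
                r["lost_branches"].split(","))
            fams.append(FamilyRecord(
                family_id=r["family_id"], birth_branch=r["birth_branch"],
                lost_branches=lost, members=members,
                divergent=bool(int(r["divergent"])),
            ))
        return cls(fams, tree)


def simulate_family_events(tree: SpeciesTree,
                           params: SimulationParams) -> FamilyTruthTable:
    """Draw the birth/loss/duplication history for every family.

    Regular families sample their birth branch from
    ``birth_branch_weights`` and lose descendant branches independently
    with ``loss_prob``; engineered classes (forced losses, divergent
    families) are born at the root with their events fixed by design.
    Duplication counts per surviving terminal lineage are Poisson with
    mean ``dup_rate``.
    """
    params.validate()
    rng = _rng(params, 0)

    branches = list(params.birth_branch_weights)
    weights = np.array([params.birth_branch_weights[b] for b in branches], float)
    if weights.sum() <= 0:
        raise ConfigurationError("birth weights sum to zero")
    weights = weights / weights.sum()

    counters = {sp: 0 for sp in SPECIES}

    def new_id(sp: str) -> str:
        counters[sp] += 1
        return f"{sp}|g{counters[sp]:06d}"

    def make_family(fid: str, birth: str, lost: frozenset[str],
                    divergent: bool, with_dups: bool) -> FamilyRecord:
        present = tree.present_species(birth, lost)
        members: dict[str, tuple[str, ...]] = {sp: () for sp in SPECIES}
        for sp in SPECIES:
            if sp not in present:
                continue
            n_extra = rng.poisson(params.dup_rate) if with_dups else 0
            members[sp] = tuple(new_id(sp) for _ in range(1 + n_extra))
        return FamilyRecord(fid, birth, lost, members, divergent)

    fams: list[FamilyRecord] = []
    idx = 0
    for _ in range(params.n_families):
        idx += 1
        birth = branches[rng.choice(len(branches), p=weights)]
        below = tree.subtree_branches(birth)
        lost = frozenset(b for b in below if rng.random() < params.loss_prob)
        fams.append(make_family(f"F{idx:04d}", birth, lost, False, True))
    for branch, count in sorted(params.forced_loss_families.items()):
        if branch not in tree.branches or branch == "root":
            raise ConfigurationError(f"cannot force loss on branch {branch!r}")
        for _ in range(count):
            idx += 1
            fams.append(make_family(f"F{idx:04d}", "root",
                                    frozenset({branch}), False, True))
    for _ in range(params.n_divergent_families):
        idx += 1
        fams.append(make_family(f"F{idx:04d}", "root", frozenset(), True, False))

    truth = FamilyTruthTable(fams, tree)
    truth.check_consistency()
    return truth


def retention_factor(target_identity: float, depth: int) -> float:
    """Per-unit-branch retention ``r`` giving the target identity at *depth*.

    Solves ``target = 1/20 + (19/20) r**depth`` for r.
    """
    base = (target_identity - 0.05) / 0.95
    return float(base ** (1.0 / depth))


def expected_identity(target_identity: float, depth: int, distance: int) -> float:
    """Expected ortholog identity at *distance* unit branches."""
    r = retention_factor(target_identity, depth)
    return 0.05 + 0.95 * r ** distance


def _substitution_prob(r: float) -> float:
    """Per-branch per-site substitution probability for retention *r*.

    The uniform 20-state chain has eigenvalue ``1 - 20 q / 19`` for
    substitution probability q per branch.
    """
    return 19.0 / 20.0 * (1.0 - r)


def _evolve(seq: np.ndarray, q: float, rng: np.random.Generator) -> np.ndarray:
    """One branch of per-site substitution: replace with one of 19 others."""
    out = seq.copy()
    hit = rng.random(seq.size) < q
    if hit.any():
        # uniform over the 19 non-identical residues
        shift = rng.integers(1, 20, size=int(hit.sum()))
        out[hit] = (out[hit] + shift) % 20
    return out


def _to_str(seq: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in seq)


def evolve_sequences(truth: FamilyTruthTable, tree: SpeciesTree,
                     params: SimulationParams):
    """Evolve protein sequences down the tree for every family member.

    Returns ``(proteomes, novel)``: per-species ``{id: sequence}`` dicts
    (truth members plus novel singletons) and the per-species novel-gene
    id lists.  Deterministic given ``params.rng_seed``.
    """
    params.validate()
    rng = _rng(params, 1)
    depth = tree.max_leaf_distance
    q_regular = _substitution_prob(retention_factor(params.target_identity, depth))
    q_divergent = _substitution_prob(retention_factor(params.divergent_identity, depth))

    lo, hi = params.seq_length_range
    proteomes: dict[str, dict[str, str]] = {sp: {} for sp in SPECIES}

    for fam in truth:
        q = q_divergent if fam.divergent else q_regular
        length = int(rng.integers(lo, hi + 1))
        root_seq = rng.integers(0, 20, size=length)
        # sequences at internal nodes along each root->leaf path, cached so
        # shared branches evolve exactly once per family
        node_seqs: dict[tuple[str, ...], np.ndarray] = {(): root_seq}
        if fam.birth_branch == "root":
            birth_path: tuple[str, ...] = ()
        else:
            # family appears at the bottom node of its birth branch; the
            # ancestral sequence is assigned there (no evolution above)
            birth_path = None  # filled per leaf below
        for sp in SPECIES:
            ids = fam.members.get(sp, ())
            if not ids:
                continue
            full_path = tree.path_to_leaf(sp)
            if fam.birth_branch == "root":
                path = full_path
            else:
                cut = full_path.index(fam.birth_branch) + 1
                path = full_path[cut:]
            seq = root_seq
            prefix: tuple[str, ...] = ()
            for b in path:
                prefix = prefix + (b,)
                if prefix not in node_seqs:
                    node_seqs[prefix] = _evolve(node_seqs[prefix[:-1]], q, rng)
                seq = node_seqs[prefix]
            proteomes[sp][ids[0]] = _to_str(seq)
            for dup_id in ids[1:]:
                # recent paralog: one extra unit branch of divergence
                proteomes[sp][dup_id] = _to_str(_evolve(seq, q, rng))

    novel: dict[str, list[str]] = {sp: [] for sp in SPECIES}
    for sp in SPECIES:
        for i in range(params.n_novel_per_species):
            pid = f"{sp}|n{i + 1:04d}"
            length = int(rng.integers(lo, hi + 1))
            proteomes[sp][pid] = _to_str(rng.integers(0, 20, size=length))
            novel[sp].append(pid)

    return proteomes, novel


@dataclass
class GOAnnotationTable:
    """protein -> GO term assignments plus the planted enrichment truth."""

    rows: list[tuple[str, str]]
    designated_enriched: dict[str, tuple[tuple[str, ...], float]] = field(
        default_factory=dict
    )

    def terms_of(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for pid, term in self.rows:
            out.setdefault(pid, set()).add(term)
        return out


def assign_annotations(truth: FamilyTruthTable, params: SimulationParams,
                       enriched: dict[str, tuple[list[str], float]] | None = None,
                       novel: dict[str, list[str]] | None = None
                       ) -> GOAnnotationTable:
    """Assign background GO terms at random and plant enriched terms.

    Background terms attach to each protein independently with
    ``go_background_freq``.  Each entry of *enriched* maps a term id to a
    family-id subset and a planting frequency: member proteins of those
    families additionally carry the term with that frequency.
    """
    if len(truth) == 0:
        raise ConfigurationError("truth table is empty")
    rng = _rng(params, 2)
    proteins: list[str] = []
    for fam in truth:
        proteins.extend(fam.member_ids)
    if novel:
        for sp in SPECIES:
            proteins.extend(novel.get(sp, []))

    terms = [f"GO:{i + 1:07d}" for i in range(params.n_go_terms)]
    rows: list[tuple[str, str]] = []
    for term in terms:
        mask = rng.random(len(proteins)) < params.go_background_freq
        rows.extend((proteins[i], term) for i in np.flatnonzero(mask))

    designated: dict[str, tuple[tuple[str, ...], float]] = {}
    for term, (family_ids, freq) in (enriched or {}).items():
        subset_proteins: list[str] = []
        for fid in family_ids:
            subset_proteins.extend(truth.by_id[fid].member_ids)
        mask = rng.random(len(subset_proteins)) < freq
        rows.extend((subset_proteins[i], term) for i in np.flatnonzero(mask))
        designated[term] = (tuple(family_ids), freq)

    # deduplicate (a planted term can coincide with a background draw)
    rows = sorted(set(rows))
    return GOAnnotationTable(rows=rows, designated_enriched=designated)


@dataclass
class StageExpressionTable:
    """Per-stage elevated-expression flags for C. elegans genes.

    ``records`` holds one row per (gene, stage) with an elevated flag;
    ``planted`` records the construction: the phylotypic gene set (family
    members elevated within the phylotypic window) and the per-stage
    novel (genus-restricted) gene sets, so recovery can be checked
    exactly.
    """

    records: list[tuple[str, int, bool]]
    n_stages: int = 10
    planted: dict = field(default_factory=dict)

    def elevated_at(self, stage: int) -> list[str]:
        return sorted({g for g, s, e in self.records if s == stage and e})

    def elevated_in_range(self, lo: int, hi: int) -> list[str]:
        return sorted({g for g, s, e in self.records if lo <= s <= hi and e})


def assign_stage_expression(truth: FamilyTruthTable, params: SimulationParams,
                            novel_ce: list[str] | None = None
                            ) -> StageExpressionTable:
    """Plant the developmental stage-expression layer on the ce proteome.

    A designated subset of conserved families (ce member present, not
    divergent, not an engineered-loss family) forms the phylotypic truth
    set: each of its ce genes is elevated at one stage in 6-8 (cycling).
    Every stage additionally receives conserved background genes and
    novel (genus-restricted) genes, so the per-stage restricted
    proportion has a known planted value.
    """
    rng = _rng(params, 3)
    novel_ce = list(novel_ce or [])

    eligible = [f for f in truth
                if f.members.get("ce") and not f.divergent and not f.lost_branches]
    phylo_fams = eligible[:params.n_phylotypic_families]
    if len(phylo_fams) < params.n_phylotypic_families:
        warnings.warn(
            f"only {len(phylo_fams)} eligible families for the phylotypic set "
            f"(requested {params.n_phylotypic_families})"
        )
    phylo_genes: list[str] = []
    for f in phylo_fams:
        phylo_genes.extend(f.members["ce"])

    records: list[tuple[str, int, bool]] = []
    stages_67_8 = [6, 7, 8]
    for i, g in enumerate(phylo_genes):
        records.append((g, stages_67_8[i % 3], True))

    used = set(phylo_genes)
    phylo_ids = {f.family_id for f in phylo_fams}
    # background genes come from conserved families only (an orthologue
    # retained in rc, ts or tc), so the taxon-restricted genes of every
    # stage are exactly the planted novel genes
    background_pool = sorted(
        pid for f in truth
        if f.members.get("ce") and not f.divergent
        and f.family_id not in phylo_ids
        and f.present_species & {"rc", "ts", "tc"}
        for pid in f.members["ce"] if pid not in used
    )
    rng.shuffle(background_pool)
    novel_pool = list(novel_ce)

    per_stage_novel: dict[int, list[str]] = {s: [] for s in range(1, params.n_stages + 1)}
    bg_i = 0
    for stage in range(1, params.n_stages + 1):
        for _ in range(params.conserved_elevated_per_stage):
            if bg_i < len(background_pool):
                records.append((background_pool[bg_i], stage, True))
                bg_i += 1
        for j in range(params.novel_elevated_per_stage):
            if novel_pool:
                # recycle the pool: a gene may be elevated at several stages
                g = novel_pool[((stage - 1) * params.novel_elevated_per_stage + j)
                               % len(novel_pool)]
                if g not in per_stage_novel[stage]:
                    records.append((g, stage, True))
                    per_stage_novel[stage].append(g)

    records.sort()
    return StageExpressionTable(
        records=records, n_stages=params.n_stages,
        planted={
            "phylotypic_family_ids": tuple(f.family_id for f in phylo_fams),
            "phylotypic_gene_ids": tuple(sorted(phylo_genes)),
            "per_stage_novel": {s: tuple(v) for s, v in per_stage_novel.items()},
        },
    )


@dataclass
class SimulatedStudy:
    """Bundle of everything one simulated study produces."""

    params: SimulationParams
    tree: SpeciesTree
    truth: FamilyTruthTable
    proteomes: dict[str, dict[str, str]]
    novel: dict[str, list[str]]
    annotations: GOAnnotationTable
    stage_table: StageExpressionTable

    @property
    def species_of(self) -> dict[str, str]:
        return {pid: sp for sp, prot in self.proteomes.items() for pid in prot}

    def rcts_only_families(self) -> list[str]:
        """Families whose true pattern contains rc and ts but not ce."""
        return [f.family_id for f in self.truth
                if {"rc", "ts"} <= f.present_species
                and "ce" not in f.present_species]


ENRICHED_TERM = "GO:9999001"


def simulate_study(params: SimulationParams | None = None) -> SimulatedStudy:
    """Run the full generator: events, sequences, GO and stage layers.

    The designated enriched GO term (``GO:9999001``) is planted in the
    families whose true membership pattern is rc+ts-without-ce, the class
    the dorylaim-specific enrichment analysis targets.
    """
    params = params or SimulationParams()
    tree = SpeciesTree()
    truth = simulate_family_events(tree, params)
    proteomes, novel = evolve_sequences(truth, tree, params)
    study_tmp = [f.family_id for f in truth
                 if {"rc", "ts"} <= f.present_species
                 and "ce" not in f.present_species]
    enriched = {ENRICHED_TERM: (study_tmp, params.enriched_term_freq)} \
        if study_tmp else {}
    annotations = assign_annotations(truth, params, enriched=enriched, novel=novel)
    stage_table = assign_stage_expression(truth, params, novel_ce=novel["ce"])
    return SimulatedStudy(params, tree, truth, proteomes, novel,
                          annotations, stage_table)
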