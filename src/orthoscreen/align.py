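"""All-vs-all protein similarity: local alignment, E-values, redundancy.

Local alignment is affine-gap Smith-Waterman (via ``Bio.Align``), scored
with a named substitution matrix (BLOSUM62 by default, with ``X`` scored
0 against everything).  Significance follows Karlin-Altschul statistics,

    E = kappa * m * n * exp(-lambda * S),

with fixed, configurable ``lambda``/``kappa`` (the standard gapped
BLOSUM62 values) rather than values estimated per database — scores and
E-values are therefore exactly reproducible.  The pipeline-wide
significance convention is E < 1e-5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

EVALUE_FLOOR = 1e-180  # clamp before logarithms in edge weighting


class InputError(ValueError):
    """Malformed sequence or record input."""


@dataclass
class SimilarityParams:
    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lambda_: float = 0.267
    kappa: float = 0.041
    report_evalue_max: float = 10.0
    significance_evalue: float = 1e-5
    kmer_prefilter: bool = False
    kmer_size: int = 4
    min_shared_kmers: int = 1

    def validate(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise InputError("gap penalties must be positive")
        if self.lambda_ <= 0 or self.kappa <= 0:
            raise InputError("Karlin-Altschul parameters must be positive")
        if self.significance_evalue > self.report_evalue_max:
            raise InputError("significance_evalue must be <= report_evalue_max")


@lru_cache(maxsize=4)
def _matrix_with_neutral_x(name: str):
    m = substitution_matrices.load(name).copy()
    if "X" in m.alphabet:
        i = m.alphabet.index("X")
        m[i, :] = 0.0
        m[:, i] = 0.0
    return m


@lru_cache(maxsize=8)
def _aligner(matrix_name: str, gap_open: int, gap_extend: int) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _matrix_with_neutral_x(matrix_name)
    # BLAST convention: a gap of length k costs gap_open + k * gap_extend
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def _check_sequence(seq: str, label: str) -> None:
    if not seq:
        raise InputError(f"empty sequence for record {label!r}")
    bad = set(seq) - VALID_RESIDUES
    if bad:
        raise InputError(
            f"record {label!r} contains illegal residue(s) {sorted(bad)}"
        )


@dataclass(frozen=True)
class AlignmentStats:
    raw_score: float
    percent_identity: float  # fraction over all alignment columns
    query_coverage: float    # aligned query span / query length
    subject_coverage: float
    length: int              # alignment columns incl. internal gaps


def local_align(a: str, b: str, params: SimilarityParams | None = None,
                a_label: str = "query", b_label: str = "subject"
                ) -> AlignmentStats:
    """Optimal affine-gap local alignment of two protein sequences.

    Returns the optimal score plus identity/coverage statistics of one
    optimal alignment (the aligner's first, deterministically).
    """
    params = params or SimilarityParams()
    params.validate()
    _check_sequence(a, a_label)
    _check_sequence(b, b_label)
    aligner = _aligner(params.matrix_name, params.gap_open, params.gap_extend)
    score = float(aligner.score(a, b))
    if score <= 0:
        return AlignmentStats(0.0, 0.0, 0.0, 0.0, 0)
    aln = next(iter(aligner.align(a, b)))
    blocks = aln.aligned  # shape (2, nblocks, 2)
    qstart, qend = int(blocks[0][0][0]), int(blocks[0][-1][1])
    sstart, send = int(blocks[1][0][0]), int(blocks[1][-1][1])
    aligned_cols = int(sum(e - s for s, e in blocks[0]))
    identities = sum(
        1
        for (qs, qe), (ss, _) in zip(blocks[0], blocks[1])
        for k in range(qe - qs)
        if a[qs + k] == b[ss + k]
    )
    qspan, sspan = qend - qstart, send - sstart
    length = aligned_cols + (qspan - aligned_cols) + (sspan - aligned_cols)
    return AlignmentStats(
        raw_score=score,
        percent_identity=identities / length,
        query_coverage=qspan / len(a),
        subject_coverage=sspan / len(b),
        length=length,
    )


def evalue(raw_score: float, m: int, n: int,
           params: SimilarityParams | None = None) -> float:
    """Karlin-Altschul expectation for a local score over lengths m, n."""
    params = params or SimilarityParams()
    if raw_score < 0:
        raise InputError("raw_score must be >= 0")
    return params.kappa * m * n * math.exp(-params.lambda_ * raw_score)


def bitscore(raw_score: float, params: SimilarityParams | None = None) -> float:
    params = params or SimilarityParams()
    return (params.lambda_ * raw_score - math.log(params.kappa)) / math.log(2.0)


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    raw_score: float
    bitscore: float
    evalue: float
    percent_identity: float
    query_coverage: float
    subject_coverage: float
    length: int
    qlen: int
    slen: int

    def sort_key(self):
        """Global tie-break: lower E, then higher bitscore, then subject id."""
        return (self.evalue, -self.bitscore, self.subject_id)


class HitTable:
    """Best stored hit per ordered (query, subject) pair, with indexes."""

    def __init__(self, species_of: dict[str, str]):
        self.species_of = dict(species_of)
        self._hits: dict[tuple[str, str], SimilarityHit] = {}
        self._by_query: dict[str, list[str]] = {}

    def add(self, hit: SimilarityHit) -> None:
        if hit.query_id == hit.subject_id:
            raise InputError(f"self-hit for {hit.query_id!r}")
        key = (hit.query_id, hit.subject_id)
        old = self._hits.get(key)
        if old is None or hit.sort_key() < old.sort_key():
            if old is None:
                self._by_query.setdefault(hit.query_id, []).append(hit.subject_id)
            self._hits[key] = hit

    def get(self, query_id: str, subject_id: str) -> SimilarityHit | None:
        return self._hits.get((query_id, subject_id))

    def hits_from(self, query_id: str) -> list[SimilarityHit]:
        subjects = self._by_query.get(query_id, [])
        return [self._hits[(query_id, s)] for s in sorted(subjects)]

    def hits_to_species(self, query_id: str, species: str) -> list[SimilarityHit]:
        return [h for h in self.hits_from(query_id)
                if self.species_of[h.subject_id] == species]

    def queries(self) -> list[str]:
        return sorted(self._by_query)

    def pairs(self) -> list[tuple[str, str]]:
        return sorted(self._hits)

    def __len__(self) -> int:
        return len(self._hits)

    def __iter__(self):
        for key in sorted(self._hits):
            yield self._hits[key]


def _kmers(seq: str, k: int) -> frozenset[str]:
    return frozenset(seq[i:i + k] for i in range(len(seq) - k + 1))


def all_vs_all(proteomes: dict[str, dict[str, str]],
               params: SimilarityParams | None = None) -> HitTable:
    """Align every ordered protein pair across and within species.

    Scores are computed once per unordered pair (the substitution matrix
    is symmetric); hits with E-value <= ``report_evalue_max`` and score
    > 0 are stored in both directions.
    """
    params = params or SimilarityParams()
    params.validate()
    if len(proteomes) < 2:
        raise InputError("need at least two proteomes")
    species_of: dict[str, str] = {}
    for sp, prot in proteomes.items():
        for pid in prot:
            if pid in species_of:
                raise InputError(f"duplicate protein id across species: {pid!r}")
            species_of[pid] = sp
        for pid, seq in prot.items():
            _check_sequence(seq, pid)

    seqs = {pid: proteomes[sp][pid] for pid, sp in species_of.items()}
    ids = sorted(seqs)
    kmer_index = (
        {pid: _kmers(seqs[pid], params.kmer_size) for pid in ids}
        if params.kmer_prefilter else None
    )

    table = HitTable(species_of)
    for i, qid in enumerate(ids):
        a = seqs[qid]
        for sid in ids[i + 1:]:
            b = seqs[sid]
            if kmer_index is not None and len(
                    kmer_index[qid] & kmer_index[sid]) < params.min_shared_kmers:
                continue
            stats = local_align(a, b, params, qid, sid)
            if stats.raw_score <= 0:
                continue
            e = evalue(stats.raw_score, len(a), len(b), params)
            if e > params.report_evalue_max:
                continue
            bs = bitscore(stats.raw_score, params)
            table.add(SimilarityHit(
                qid, sid, stats.raw_score, bs, e, stats.percent_identity,
                stats.query_coverage, stats.subject_coverage, stats.length,
                len(a), len(b)))
            table.add(SimilarityHit(
                sid, qid, stats.raw_score, bs, e, stats.percent_identity,
                stats.subject_coverage, stats.query_coverage, stats.length,
                len(b), len(a)))
    return table


def pairwise_identity_short(a: str, b: str,
                            params: SimilarityParams | None = None) -> float:
    """Identity over the shorter sequence's length (cd-hit convention)."""
    params = params or SimilarityParams()
    if a == b:
        return 1.0
    aligner = _aligner(params.matrix_name, params.gap_open, params.gap_extend)
    if aligner.score(a, b) <= 0:
        return 0.0
    aln = next(iter(aligner.align(a, b)))
    blocks = aln.aligned
    identities = sum(
        1
        for (qs, qe), (ss, _) in zip(blocks[0], blocks[1])
        for k in range(qe - qs)
        if a[qs + k] == b[ss + k]
    )
    return identities / min(len(a), len(b))


def redundancy_filter(proteome: dict[str, str],
                      identity_threshold: float = 0.99,
                      params: SimilarityParams | None = None):
    """Greedy longest-first redundancy screen at a fixed identity cutoff.

    A sequence is removed if its identity to an already-retained sequence
    (measured over the shorter sequence) reaches the threshold — the
    cd-hit style screen applied to each proteome before clustering.
    Returns ``(retained, removal_log)`` with the log recording
    (removed_id, retained_id, identity).
    """
    if not proteome:
        raise InputError("proteome is empty")
    params = params or SimilarityParams()
    order = sorted(proteome, key=lambda pid: (-len(proteome[pid]), pid))
    k = 5
    kmer_index = {pid: _kmers(proteome[pid], k) for pid in order}
    retained: dict[str, str] = {}
    removal_log: list[tuple[str, str, float]] = []
    for pid in order:
        seq = proteome[pid]
        hit = None
        for rid in retained:
            # near-identical sequences share almost all distinct 5-mers;
            # skip the alignment when they clearly cannot reach the threshold
            n_short = min(len(kmer_index[pid]), len(kmer_index[rid]))
            shared = len(kmer_index[pid] & kmer_index[rid])
            if shared < 0.5 * max(1, n_short):
                continue
            ident = pairwise_identity_short(seq, retained[rid], params)
            if ident >= identity_threshold:
                hit = (rid, ident)
                break
        if hit is None:
            retained[pid] = seq
        else:
            removal_log.append((pid, hit[0], hit[1]))
    return retained, removal_log
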