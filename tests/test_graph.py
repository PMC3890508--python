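"""Edge-classification and weighting rules of the orthology graph."""

from __future__ import annotations

import math

import pytest

from orthoscreen.align import HitTable, SimilarityHit
from orthoscreen.graph import (best_hits, build_graph, co_orthologs,
                               in_paralogs, putative_orthologs)


def mk_hit(q: str, s: str, e: float, bits: float | None = None) -> SimilarityHit:
    bits = bits if bits is not None else max(1.0, -math.log10(max(e, 1e-300)))
    return SimilarityHit(
        query_id=q, subject_id=s, raw_score=bits, bitscore=bits, evalue=e,
        percent_identity=0.5, query_coverage=0.9, subject_coverage=0.9,
        length=100, qlen=100, slen=100)


def table(species: dict[str, str], *hits: SimilarityHit) -> HitTable:
    t = HitTable(species)
    for h in hits:
        t.add(h)
    return t


def mutual(t: HitTable, a: str, b: str, e: float) -> None:
    t.add(mk_hit(a, b, e))
    t.add(mk_hit(b, a, e))


SPECIES = {"ce|1": "ce", "ce|2": "ce", "rc|1": "rc", "rc|2": "rc", "ts|1": "ts"}


class TestBestHits:
    def test_single_hit_is_best(self):
        t = table(SPECIES, mk_hit("ce|1", "rc|1", 1e-10))
        assert best_hits(t)[("ce|1", "rc")].subject_id == "rc|1"

    def test_lower_evalue_wins(self):
        t = table(SPECIES, mk_hit("ce|1", "rc|1", 1e-8),
                  mk_hit("ce|1", "rc|2", 1e-10))
        assert best_hits(t)[("ce|1", "rc")].subject_id == "rc|2"

    def test_equal_evalue_higher_bitscore_wins(self):
        t = table(SPECIES, mk_hit("ce|1", "rc|1", 1e-8, bits=50),
                  mk_hit("ce|1", "rc|2", 1e-8, bits=40))
        assert best_hits(t)[("ce|1", "rc")].subject_id == "rc|1"


class TestOrthologEdges:
    def test_mutual_best_significant_pair_is_edge(self):
        t = table(SPECIES)
        mutual(t, "ce|1", "rc|1", 1e-50)
        assert putative_orthologs(t) == {("ce|1", "rc|1")}

    def test_non_reciprocal_best_is_no_edge(self):
        t = table(SPECIES)
        t.add(mk_hit("ce|1", "rc|1", 1e-30))
        t.add(mk_hit("rc|1", "ce|2", 1e-40))  # rc|1 prefers a different ce
        t.add(mk_hit("rc|1", "ce|1", 1e-30))
        t.add(mk_hit("ce|2", "rc|1", 1e-40))
        assert ("ce|1", "rc|1") not in putative_orthologs(t)
        assert ("ce|2", "rc|1") in putative_orthologs(t)

    def test_insignificant_mutual_best_is_no_edge(self):
        t = table(SPECIES)
        mutual(t, "ce|1", "rc|1", 1e-3)
        assert putative_orthologs(t) == set()


class TestInParalogEdges:
    def test_recent_duplicates_with_ortholog_anchor(self):
        t = table(SPECIES)
        mutual(t, "rc|1", "rc|2", 1e-80)
        mutual(t, "rc|1", "ce|1", 1e-40)
        mutual(t, "rc|2", "ce|1", 1e-35)
        orth = putative_orthologs(t)
        assert in_paralogs(t, orth) == {("rc|1", "rc|2")}

    def test_no_ortholog_anchor_means_no_edge(self):
        t = table(SPECIES)
        mutual(t, "rc|1", "rc|2", 1e-80)  # no cross-species hits at all
        assert in_paralogs(t, set()) == set()

    def test_weaker_than_cross_species_hit_is_no_edge(self):
        t = table(SPECIES)
        mutual(t, "rc|1", "rc|2", 1e-10)
        mutual(t, "rc|1", "ce|1", 1e-20)
        mutual(t, "rc|2", "ce|1", 1e-20)
        orth = putative_orthologs(t)
        assert in_paralogs(t, orth) == set()


class TestCoOrthologEdges:
    def _base(self) -> HitTable:
        t = table(SPECIES)
        mutual(t, "rc|1", "rc|2", 1e-80)   # in-paralog pair
        mutual(t, "rc|2", "ce|1", 1e-40)   # ortholog edge
        mutual(t, "rc|1", "ce|1", 1e-12)   # direct hit for the co-ortholog
        return t

    def test_in_paralog_of_ortholog_with_hit(self):
        t = self._base()
        orth = putative_orthologs(t)
        para = in_paralogs(t, orth)
        assert ("ce|1", "rc|1") in co_orthologs(orth, para, t)

    def test_no_stored_hit_means_no_edge(self):
        t = table(SPECIES)
        mutual(t, "rc|1", "rc|2", 1e-80)
        mutual(t, "rc|2", "ce|1", 1e-40)
        mutual(t, "rc|1", "ce|1", 1e-3)  # present but not significant
        orth = putative_orthologs(t)
        para = in_paralogs(t, orth)
        assert co_orthologs(orth, para, t) == set()

    def test_existing_ortholog_edge_not_duplicated(self):
        t = self._base()
        orth = putative_orthologs(t)
        para = in_paralogs(t, orth)
        assert ("ce|1", "rc|2") not in co_orthologs(orth, para, t)


class TestWeights:
    def test_raw_weight_is_mean_neg_log10(self):
        t = table(SPECIES)
        mutual(t, "ce|1", "rc|1", 1e-10)
        g = build_graph(t)
        assert g.edges[("ce|1", "rc|1")].raw_weight == pytest.approx(10.0)

    def test_pair_normalization(self):
        t = table(SPECIES)
        mutual(t, "ce|1", "rc|1", 1e-10)
        mutual(t, "ce|2", "rc|2", 1e-30)
        g = build_graph(t)
        w = {k: e.normalized_weight for k, e in g.edges.items()}
        assert w[("ce|1", "rc|1")] == pytest.approx(0.5)
        assert w[("ce|2", "rc|2")] == pytest.approx(1.5)

    def test_zero_evalue_clamped_to_180(self):
        t = table(SPECIES)
        mutual(t, "ce|1", "rc|1", 0.0)
        g = build_graph(t)
        assert g.edges[("ce|1", "rc|1")].raw_weight == pytest.approx(180.0)

    def test_edge_classes_respect_species(self):
        t = self_table = table(SPECIES)
        mutual(t, "rc|1", "rc|2", 1e-80)
        mutual(t, "rc|2", "ce|1", 1e-40)
        mutual(t, "rc|1", "ce|1", 1e-12)
        g = build_graph(self_table)
        for e in g.edges.values():
            same = g.species_of[e.u] == g.species_of[e.v]
            assert (e.edge_class == "in_paralog") == same
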