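"""Absence-verification decision tree on constructed fixtures."""

from __future__ import annotations

import pytest

from orthoscreen.absence import (NON_PRESENT, STATUS_ABSENT, STATUS_PRESENT,
                                 STATUS_REVIEW, STATUS_UNIQUE,
                                 VerificationParams, shared_loss,
                                 verify_absence, verify_panel)
from orthoscreen.align import HitTable
from orthoscreen.mcl import ClusterSet
from test_graph import mk_hit

SPECIES = {"ce|q": "ce", "ce|other": "ce", "rc|1": "rc", "rc|2": "rc",
           "ts|1": "ts"}


def table(*hits) -> HitTable:
    t = HitTable(SPECIES)
    for h in hits:
        t.add(h)
    return t


class TestDecisionTree:
    def test_cluster_comembership_means_present(self):
        clusters = ClusterSet(clusters={"CLUSTER_0001": ("ce|q", "rc|1")})
        hits = table(mk_hit("ce|q", "rc|1", 1e-40))
        call = verify_absence("ce|q", "rc", clusters, hits)
        assert call.status == STATUS_PRESENT

    def test_no_significant_hit_means_confirmed_absent(self):
        clusters = ClusterSet(singletons=("ce|q",))
        hits = table(mk_hit("ce|q", "rc|1", 0.3))
        call = verify_absence("ce|q", "rc", clusters, hits)
        assert call.status == STATUS_ABSENT
        assert call.best_hit.evalue == 0.3  # evidence still recorded

    def test_evalue_exactly_at_threshold_is_not_significant(self):
        clusters = ClusterSet(singletons=("ce|q",))
        hits = table(mk_hit("ce|q", "rc|1", 1e-5))
        call = verify_absence("ce|q", "rc", clusters, hits)
        assert call.status == STATUS_ABSENT

    def test_cross_cluster_match_confirms_uniqueness(self):
        clusters = ClusterSet(
            clusters={"CLUSTER_0001": ("ce|other", "rc|1")},
            singletons=("ce|q",))
        hits = table(mk_hit("ce|q", "rc|1", 1e-12))
        call = verify_absence("ce|q", "rc", clusters, hits)
        assert call.status == STATUS_UNIQUE
        assert call.cross_cluster_partner == "ce|other"

    def test_unexplained_significant_hit_goes_to_manual_review(self):
        clusters = ClusterSet(clusters={"CLUSTER_0001": ("rc|1", "ts|1")},
                              singletons=("ce|q",))
        hits = table(mk_hit("ce|q", "rc|1", 1e-12))
        call = verify_absence("ce|q", "rc", clusters, hits)
        assert call.status == STATUS_REVIEW

    def test_unknown_query_rejected(self):
        with pytest.raises(KeyError):
            verify_absence("ce|ghost", "rc", ClusterSet(), table())

    def test_exactly_one_status_per_call(self):
        clusters = ClusterSet(clusters={"CLUSTER_0001": ("ce|q", "rc|1")})
        hits = table(mk_hit("ce|q", "rc|1", 1e-40))
        call = verify_absence("ce|q", "rc", clusters, hits)
        assert call.status in (STATUS_PRESENT,) + NON_PRESENT

    def test_tightening_threshold_moves_toward_absent(self):
        """Shrinking the E-value threshold can only push calls away from
        hit-supported statuses toward confirmed_absent."""
        clusters = ClusterSet(
            clusters={"CLUSTER_0001": ("ce|other", "rc|1")},
            singletons=("ce|q",))
        hits = table(mk_hit("ce|q", "rc|1", 1e-12))
        rank = {STATUS_PRESENT: 0, STATUS_UNIQUE: 1, STATUS_REVIEW: 1,
                STATUS_ABSENT: 2}
        last = -1
        for thr in (1e-3, 1e-8, 1e-14):
            call = verify_absence("ce|q", "rc", clusters, hits,
                                  VerificationParams(evalue_threshold=thr))
            assert rank[call.status] >= last
            last = rank[call.status]


class TestPanelAndSharedLoss:
    def _fixture(self):
        clusters = ClusterSet(
            clusters={"CLUSTER_0001": ("ce|q", "rc|1"),
                      "CLUSTER_0002": ("ce|other", "ts|1")})
        hits = table(mk_hit("ce|q", "rc|1", 1e-40),
                     mk_hit("ce|q", "ts|1", 0.5),
                     mk_hit("ce|other", "ts|1", 1e-30))
        return clusters, hits

    def test_panel_reproduces_constructed_truth(self):
        clusters, hits = self._fixture()
        panel = verify_panel(["ce|q", "ce|other"], ["rc", "ts"], clusters, hits)
        assert panel.sign("ce|q", "rc") == "+"
        assert panel.sign("ce|q", "ts") == "-"
        assert panel.sign("ce|other", "ts") == "+"
        assert panel.call("ce|other", "rc").status == STATUS_ABSENT

    def test_empty_panel(self):
        panel = verify_panel([], ["rc"], ClusterSet(), table())
        assert panel.to_rows() == []

    def test_shared_loss_requires_absence_in_both(self):
        clusters, hits = self._fixture()
        panel = verify_panel(["ce|q", "ce|other"], ["rc", "ts"], clusters, hits)
        calls_rc = {q: panel.call(q, "rc") for q in panel.queries}
        calls_ts = {q: panel.call(q, "ts") for q in panel.queries}
        out = shared_loss(calls_rc, calls_ts)
        assert not out["ce|q"].shared_loss        # present in rc
        assert not out["ce|other"].shared_loss    # present in ts

    def test_divergent_candidate_sets_caveat(self):
        clusters = ClusterSet(clusters={"CLUSTER_0001": ("rc|1", "ts|1")},
                              singletons=("ce|q",))
        hits = table(mk_hit("ce|q", "rc|1", 1e-12),
                     mk_hit("ce|q", "ts|1", 0.9))
        panel = verify_panel(["ce|q"], ["rc", "ts"], clusters, hits)
        out = shared_loss({"ce|q": panel.call("ce|q", "rc")},
                          {"ce|q": panel.call("ce|q", "ts")})
        assert out["ce|q"].shared_loss and out["ce|q"].caveat

    def test_mismatched_query_sets_rejected(self):
        with pytest.raises(ValueError):
            shared_loss({"a": None}, {"b": None})
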