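"""Alignment, E-value and redundancy-screen tests."""

from __future__ import annotations

import math
import random

import pytest

from oracles import sw_affine_score, sw_enumerate_score
from orthoscreen.align import (InputError, SimilarityParams, all_vs_all,
                               bitscore, evalue, local_align,
                               redundancy_filter)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestLocalAlign:
    def test_identical_four_mer_scores_blosum_diagonal(self):
        stats = local_align("ACDE", "ACDE")
        assert stats.raw_score == 24  # 4 + 9 + 6 + 5
        assert stats.percent_identity == 1.0
        assert stats.query_coverage == 1.0
        assert stats.subject_coverage == 1.0

    def test_single_mismatch_four_mer(self):
        assert local_align("ACDE", "ACME").raw_score == 15

    def test_score_is_symmetric(self):
        rng = random.Random(0)
        for _ in range(20):
            a = "".join(rng.choices(AA, k=rng.randint(5, 30)))
            b = "".join(rng.choices(AA, k=rng.randint(5, 30)))
            assert local_align(a, b).raw_score == local_align(b, a).raw_score

    def test_x_is_scored_neutral(self):
        assert local_align("AXA", "AAA").raw_score == 8  # 4 + 0 + 4

    def test_identical_sequences_have_identity_one(self):
        rng = random.Random(1)
        for _ in range(10):
            s = "".join(rng.choices(AA, k=rng.randint(10, 40)))
            stats = local_align(s, s)
            assert stats.percent_identity == 1.0
            assert stats.raw_score >= local_align(s, s[::-1]).raw_score

    @pytest.mark.parametrize("a,b,label", [
        ("", "ACDE", "query"), ("ACDE", "", "subject"),
        ("AC1E", "ACDE", "query"), ("ACDE", "ACJE", "subject"),
    ])
    def test_bad_input_names_offending_record(self, a, b, label):
        with pytest.raises(InputError, match=label):
            local_align(a, b, a_label="query", b_label="subject")

    def test_matches_independent_dp_oracle(self):
        """Engine equals a hand-written affine-gap DP on random short pairs."""
        rng = random.Random(42)
        for _ in range(100):
            a = "".join(rng.choices(AA, k=rng.randint(3, 12)))
            b = "".join(rng.choices(AA, k=rng.randint(3, 12)))
            assert local_align(a, b).raw_score == sw_affine_score(a, b)

    def test_dp_oracle_matches_exhaustive_enumeration(self):
        """The DP oracle itself equals brute-force path enumeration."""
        rng = random.Random(7)
        for _ in range(30):
            a = "".join(rng.choices(AA, k=rng.randint(2, 5)))
            b = "".join(rng.choices(AA, k=rng.randint(2, 5)))
            assert sw_affine_score(a, b) == sw_enumerate_score(a, b)


class TestEvalue:
    def test_closed_form_value(self):
        assert evalue(40, 100, 100) == pytest.approx(9.4e-3, rel=5e-3)

    def test_zero_score_gives_kappa_mn(self):
        p = SimilarityParams()
        assert evalue(0, 50, 80, p) == pytest.approx(p.kappa * 50 * 80)

    def test_linear_in_query_length(self):
        assert evalue(30, 200, 100) == pytest.approx(2 * evalue(30, 100, 100))

    def test_strictly_decreasing_in_score(self):
        es = [evalue(s, 100, 100) for s in range(0, 200, 7)]
        assert all(x > y for x, y in zip(es, es[1:]))

    def test_bitscore_is_affine_in_raw_score(self):
        p = SimilarityParams()
        expected = (p.lambda_ * 100 - math.log(p.kappa)) / math.log(2)
        assert bitscore(100, p) == pytest.approx(expected)


class TestAllVsAll:
    def test_identical_protein_across_two_species(self):
        seq = "MKTLVAGGWLL" * 4
        hits = all_vs_all({"rc": {"rc|a": seq}, "ce": {"ce|b": seq}})
        assert len(hits) == 2
        fwd, rev = hits.get("rc|a", "ce|b"), hits.get("ce|b", "rc|a")
        assert fwd.raw_score == rev.raw_score
        assert fwd.percent_identity == 1.0

    def test_hopeless_pair_is_absent(self):
        hits = all_vs_all({"rc": {"rc|w": "W" * 40}, "ce": {"ce|p": "P" * 40}})
        assert len(hits) == 0

    def test_duplicate_id_across_species_rejected(self):
        with pytest.raises(InputError, match="duplicate"):
            all_vs_all({"rc": {"x|1": "ACDEF" * 8}, "ce": {"x|1": "ACDEF" * 8}})

    def test_no_self_hits_and_deterministic(self):
        rng = random.Random(3)
        proteomes = {
            sp: {f"{sp}|g{i}": "".join(rng.choices(AA, k=50)) for i in range(4)}
            for sp in ("rc", "ce")
        }
        h1 = all_vs_all(proteomes)
        h2 = all_vs_all(proteomes)
        assert [(h.query_id, h.subject_id, h.evalue) for h in h1] == \
               [(h.query_id, h.subject_id, h.evalue) for h in h2]
        assert all(h.query_id != h.subject_id for h in h1)


class TestRedundancyFilter:
    def test_identical_pair_keeps_one(self):
        kept, log = redundancy_filter({"a": "ACDEF" * 10, "b": "ACDEF" * 10})
        assert set(kept) == {"a"}  # tie broken lexicographically
        assert log == [("b", "a", 1.0)]

    def test_below_threshold_pair_survives(self):
        base = list("ACDEFGHIKLMNPQRSTVWY" * 5)
        variant = base.copy()
        for i in range(0, 100, 20):  # 5 substitutions -> 95% identity
            variant[i] = "W" if base[i] != "W" else "Y"
        kept, _ = redundancy_filter({"a": "".join(base), "b": "".join(variant)},
                                    identity_threshold=0.99)
        assert set(kept) == {"a", "b"}

    def test_copies_collapse_unrelated_survive(self):
        rng = random.Random(9)
        seq = "".join(rng.choices(AA, k=60))
        proteome = {f"c{i}": seq for i in range(10)}
        for i in range(5):
            proteome[f"u{i}"] = "".join(rng.choices(AA, k=60))
        kept, log = redundancy_filter(proteome)
        assert len(kept) == 6
        assert len(log) == 9

    def test_empty_proteome_rejected(self):
        with pytest.raises(InputError):
            redundancy_filter({})
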