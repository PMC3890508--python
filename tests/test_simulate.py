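"""Generator tests: event model, sequence calibration, planted layers."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from orthoscreen.simulate import (ConfigurationError, SimulationParams,
                                  assign_annotations, assign_stage_expression,
                                  evolve_sequences, expected_identity,
                                  simulate_family_events, simulate_study)
from orthoscreen.tree import SPECIES, SpeciesTree


def params(**kw) -> SimulationParams:
    base = dict(n_families=10, loss_prob=0.0, dup_rate=0.0,
                n_novel_per_species=0, n_divergent_families=0,
                forced_loss_families={}, rng_seed=1)
    base.update(kw)
    return SimulationParams(**base)


class TestFamilyEvents:
    def test_no_event_limit_gives_one_member_per_species(self):
        truth = simulate_family_events(SpeciesTree(), params())
        for fam in truth:
            assert all(len(fam.members[sp]) == 1 for sp in SPECIES)

    def test_terminal_birth_restricts_membership(self):
        truth = simulate_family_events(
            SpeciesTree(), params(birth_branch_weights={"ce": 1.0}))
        for fam in truth:
            assert fam.present_species == frozenset({"ce"})

    def test_zero_families_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_family_events(SpeciesTree(), params(n_families=0))

    def test_forced_loss_on_dorylaim_stem(self):
        truth = simulate_family_events(
            SpeciesTree(), params(forced_loss_families={"n2": 5}))
        forced = [f for f in truth if f.lost_branches == frozenset({"n2"})]
        assert len(forced) == 5
        for fam in forced:
            assert fam.present_species == frozenset({"ce", "tc"})

    def test_single_species_loss_fraction_matches_enumeration(self):
        """Fraction of root families absent in exactly one species agrees
        with the closed-form probability from enumerating all loss
        configurations of the six below-root branches."""
        tree = SpeciesTree()
        p = 0.1
        n = 1000
        below = tree.subtree_branches("root")
        assert len(below) == 6
        target = 0.0
        for pattern in itertools.product([False, True], repeat=6):
            lost = frozenset(b for b, flag in zip(below, pattern) if flag)
            prob = math.prod(p if flag else 1 - p for flag in pattern)
            if len(tree.present_species("root", lost)) == 3:
                target += prob
        truth = simulate_family_events(
            SpeciesTree(), params(n_families=n, loss_prob=p, rng_seed=11))
        observed = sum(
            1 for f in truth if len(f.present_species) == 3) / n
        se = math.sqrt(target * (1 - target) / n)
        assert abs(observed - target) < 3 * se

    @pytest.mark.parametrize("seed", [1, 5, 9])
    def test_truth_table_is_event_consistent(self, seed):
        truth = simulate_family_events(
            SpeciesTree(),
            SimulationParams(n_families=40, loss_prob=0.3, dup_rate=0.2,
                             rng_seed=seed))
        truth.check_consistency()  # raises on any inconsistency
        # every member id belongs to exactly one family
        seen = set()
        for fam in truth:
            for pid in fam.member_ids:
                assert pid not in seen
                seen.add(pid)


class TestSequenceEvolution:
    def test_zero_divergence_limit_gives_identical_sequences(self):
        p = params(target_identity=1.0)
        truth = simulate_family_events(SpeciesTree(), p)
        proteomes, _ = evolve_sequences(truth, SpeciesTree(), p)
        for fam in truth:
            seqs = {proteomes[sp][fam.members[sp][0]] for sp in SPECIES}
            assert len(seqs) == 1

    def test_identity_calibrated_at_full_tree_depth(self):
        """Mean rc-tc ortholog identity (four unit branches apart) matches
        the 0.7 target within Monte-Carlo error."""
        p = params(n_families=200, target_identity=0.7, rng_seed=3)
        truth = simulate_family_events(SpeciesTree(), p)
        proteomes, _ = evolve_sequences(truth, SpeciesTree(), p)
        idents = []
        for fam in truth:
            a = proteomes["rc"][fam.members["rc"][0]]
            b = proteomes["tc"][fam.members["tc"][0]]
            idents.append(np.mean([x == y for x, y in zip(a, b)]))
        idents = np.array(idents)
        se = idents.std(ddof=1) / math.sqrt(len(idents))
        assert abs(idents.mean() - 0.7) < 3 * se

    def test_closer_leaves_are_more_similar_in_expectation(self):
        assert expected_identity(0.7, 4, 2) > expected_identity(0.7, 4, 4)

    def test_determinism_same_seed_same_sequences(self):
        p = params(n_novel_per_species=3, rng_seed=13)
        out = []
        for _ in range(2):
            truth = simulate_family_events(SpeciesTree(), p)
            proteomes, novel = evolve_sequences(truth, SpeciesTree(), p)
            out.append((proteomes, novel))
        assert out[0] == out[1]

    def test_novel_genes_present_and_outside_families(self):
        p = params(n_novel_per_species=4)
        truth = simulate_family_events(SpeciesTree(), p)
        proteomes, novel = evolve_sequences(truth, SpeciesTree(), p)
        for sp in SPECIES:
            assert len(novel[sp]) == 4
            for pid in novel[sp]:
                assert pid in proteomes[sp]
                assert pid not in truth.family_of


class TestAnnotations:
    def test_planting_at_frequency_one_and_zero_background(self):
        p = params(n_go_terms=0)
        truth = simulate_family_events(SpeciesTree(), p)
        subset = [truth.families[0].family_id, truth.families[1].family_id]
        table = assign_annotations(truth, p, enriched={"GO:X": (subset, 1.0)})
        carriers = {pid for pid, t in table.rows if t == "GO:X"}
        expected = set()
        for fid in subset:
            expected.update(truth.by_id[fid].member_ids)
        assert carriers == expected

    def test_empty_designated_set_gives_background_only(self):
        p = params(n_go_terms=5, go_background_freq=0.2)
        truth = simulate_family_events(SpeciesTree(), p)
        table = assign_annotations(truth, p)
        assert table.designated_enriched == {}
        assert {t for _p, t in table.rows} <= {f"GO:{i+1:07d}" for i in range(5)}

    def test_background_count_is_binomial(self):
        """One background term over 500 proteins at frequency 0.1."""
        p = params(n_families=125, n_go_terms=1, go_background_freq=0.1,
                   rng_seed=21)
        truth = simulate_family_events(SpeciesTree(), p)
        n_prot = sum(len(f.member_ids) for f in truth)
        assert n_prot == 500
        table = assign_annotations(truth, p)
        count = len(table.rows)
        se = math.sqrt(500 * 0.1 * 0.9)
        assert abs(count - 50) < 3 * se


class TestStageExpression:
    def test_phylotypic_truth_set_size_is_exact(self):
        p = params(n_families=50, n_phylotypic_families=10,
                   conserved_elevated_per_stage=0, novel_elevated_per_stage=0)
        truth = simulate_family_events(SpeciesTree(), p)
        table = assign_stage_expression(truth, p)
        in_window = table.elevated_in_range(6, 8)
        assert set(in_window) == set(table.planted["phylotypic_gene_ids"])
        assert len(in_window) == 10  # one member per family, no dups

    def test_empty_truth_set_means_no_window_elevation(self):
        p = params(n_phylotypic_families=0, conserved_elevated_per_stage=0,
                   novel_elevated_per_stage=0)
        truth = simulate_family_events(SpeciesTree(), p)
        table = assign_stage_expression(truth, p)
        assert table.elevated_in_range(6, 8) == []

    def test_planted_novel_fraction_is_exact_per_stage(self):
        p = params(n_families=60, n_phylotypic_families=5,
                   n_novel_per_species=10, conserved_elevated_per_stage=3,
                   novel_elevated_per_stage=1)
        truth = simulate_family_events(SpeciesTree(), p)
        novel_ce = [f"ce|n{i+1:04d}" for i in range(10)]
        table = assign_stage_expression(truth, p, novel_ce=novel_ce)
        for stage in range(1, 11):
            novel_here = set(table.planted["per_stage_novel"][stage])
            elevated = set(table.elevated_at(stage))
            assert novel_here <= elevated
            assert {g for g in elevated if g.startswith("ce|n")} == novel_here


def test_full_study_is_reproducible_and_consistent():
    p = SimulationParams(n_families=10, forced_loss_families={"n2": 2},
                         n_divergent_families=1, n_novel_per_species=2,
                         rng_seed=5)
    s1 = simulate_study(p)
    s2 = simulate_study(p)
    assert s1.proteomes == s2.proteomes
    assert s1.annotations.rows == s2.annotations.rows
    assert s1.stage_table.records == s2.stage_table.records
    s1.truth.check_consistency()
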