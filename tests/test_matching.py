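"""Genotype matching, the brute-force oracle, and individual clustering."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_replicates
from _oracles import oracle_match_class
from wolfscr.genotypes import (
    DISTINCT,
    MATCH,
    NO_CALL,
    POSSIBLE_MATCH,
    ConsensusGenotype,
    ConsensusGenotyper,
    IndividualClusterer,
    cluster_individuals,
    consensus_call,
    match_genotypes,
)
from wolfscr.synthetic import simulate_genotype_dataset


def geno(pairs, ambiguous=None, sample_id="g"):
    pairs = [p if p is not None else (NO_CALL, NO_CALL) for p in pairs]
    n = len(pairs)
    return ConsensusGenotype(
        sample_id=sample_id, alleles=np.array(pairs),
        ambiguous=np.array(ambiguous or [False] * n),
        locus_ids=[f"L{l:02d}" for l in range(n)])


class TestMatchGenotypes:
    def test_identical_sixteen_loci(self):
        pairs = [(100 + 2 * l, 102 + 2 * l) for l in range(16)]
        res = match_genotypes(geno(pairs, sample_id="a"),
                              geno(pairs, sample_id="b"))
        assert (res.n_dropout_mismatches, res.n_false_allele_mismatches) == (0, 0)
        assert res.match_class == MATCH

    def test_single_dropout_mismatch_is_match(self):
        g1 = geno([(150, 154), (160, 162)])
        g2 = geno([(150, 150), (160, 162)])
        res = match_genotypes(g1, g2)
        assert (res.n_dropout_mismatches, res.n_false_allele_mismatches) == (1, 0)
        assert res.match_class == MATCH

    def test_false_allele_mismatch_is_possible_match(self):
        g1 = geno([(150, 154), (160, 162)])
        g2 = geno([(150, 158), (160, 162)])
        res = match_genotypes(g1, g2)
        assert (res.n_dropout_mismatches, res.n_false_allele_mismatches) == (0, 1)
        assert res.match_class == POSSIBLE_MATCH

    def test_budgets(self):
        # 4 dropout-style mismatches exceed the possible-match budget
        g1 = geno([(1, 2)] * 4 + [(5, 5)])
        g2 = geno([(1, 1)] * 4 + [(5, 5)])
        assert match_genotypes(g1, g2).match_class == DISTINCT
        # 2 dropouts + 1 false allele is still a possible match
        g3 = geno([(1, 2), (1, 2), (3, 4), (5, 5)])
        g4 = geno([(1, 1), (2, 2), (3, 7), (5, 5)])
        res = match_genotypes(g3, g4)
        assert (res.n_dropout_mismatches, res.n_false_allele_mismatches) == (2, 1)
        assert res.match_class == POSSIBLE_MATCH

    def test_no_shared_loci_error(self):
        g1 = geno([(1, 2), None])
        g2 = geno([None, (3, 4)])
        with pytest.raises(ValueError):
            match_genotypes(g1, g2)

    def test_exhaustive_toy_space_agrees_with_oracle(self):
        """All 2-locus genotypes over alleles {1,2,3} vs the single-error
        enumeration oracle: classes and counts agree everywhere."""
        locus_genotypes = list(
            itertools.combinations_with_replacement((1, 2, 3), 2))
        toy = [geno([p, q], sample_id=f"t{k}")
               for k, (p, q) in enumerate(
                   itertools.product(locus_genotypes, repeat=2))]
        assert len(toy) == 36
        checked = 0
        for g1, g2 in itertools.product(toy, repeat=2):
            res = match_genotypes(g1, g2)
            o_drop, o_false, o_cls = oracle_match_class(g1, g2)
            assert (res.n_dropout_mismatches, res.n_false_allele_mismatches,
                    res.match_class) == (o_drop, o_false, o_cls)
            checked += 1
        assert checked == 36 * 36

    @given(st.lists(
        st.tuples(st.sampled_from([1, 2, 3, 4]), st.sampled_from([1, 2, 3, 4])),
        min_size=1, max_size=6))
    @settings(max_examples=200, deadline=None)
    def test_symmetry(self, pairs):
        g1 = geno(pairs, sample_id="a")
        g2 = geno(list(reversed(pairs)), sample_id="b")
        r12 = match_genotypes(g1, g2)
        r21 = match_genotypes(g2, g1)
        assert r12.match_class == r21.match_class
        assert r12.n_dropout_mismatches == r21.n_dropout_mismatches


class TestClustering:
    def test_three_matching_samples_one_individual(self):
        pairs = [(1, 2), (3, 3)]
        gs = [geno(pairs, sample_id=f"s{i}") for i in range(3)]
        individuals, _ = cluster_individuals(gs)
        assert len(individuals) == 1
        assert sorted(individuals[0].sample_ids) == ["s0", "s1", "s2"]

    def test_distinct_samples_stay_separate(self):
        g1 = geno([(1, 2), (3, 4), (5, 6), (7, 8)], sample_id="a")
        g2 = geno([(2, 9), (4, 9), (6, 9), (8, 9)], sample_id="b")
        individuals, audit = cluster_individuals([g1, g2])
        assert len(individuals) == 2
        assert audit.iloc[0]["match_class"] == DISTINCT

    def test_sex_conflict_raises(self):
        g1 = geno([(1, 2)], sample_id="a")
        g2 = geno([(1, 2)], sample_id="b")
        g1.sex, g2.sex = "F", "M"
        with pytest.raises(ValueError, match="sex"):
            cluster_individuals([g1, g2])

    def test_intransitive_component_flagged_and_split(self):
        # a-b match and b-c match on their shared loci (b failed to type two
        # loci), but a-c is distinct there: the single-linkage component is
        # flagged for review and split so every final group is consistent
        g_a = geno([(1, 2), (3, 4), (5, 6), (9, 10)], sample_id="a")
        g_b = geno([(1, 2), (3, 4), None, None], sample_id="b")
        g_c = geno([(1, 2), (3, 4), (7, 8), (11, 12)], sample_id="c")
        assert match_genotypes(g_a, g_b).match_class == MATCH
        assert match_genotypes(g_b, g_c).match_class == MATCH
        assert match_genotypes(g_a, g_c).match_class == DISTINCT
        individuals, _ = cluster_individuals([g_a, g_b, g_c],
                                             resolve_possible=False)
        assert len(individuals) == 2
        assert all(ind.flagged_for_review for ind in individuals)
        by_id = {g.sample_id: g for g in (g_a, g_b, g_c)}
        for ind in individuals:
            for i, sa in enumerate(ind.sample_ids):
                for sb in ind.sample_ids[i + 1:]:
                    assert match_genotypes(
                        by_id[sa], by_id[sb]).match_class == MATCH

    def test_possible_match_not_merged_without_upgrade(self):
        # three dropout mismatches stay a possible match against the merged
        # component consensus too, so the samples remain distinct individuals
        g1 = geno([(1, 2), (3, 4), (5, 6), (7, 8)], sample_id="a")
        g2 = geno([(1, 2), (3, 4), (5, 6), (7, 8)], sample_id="b")
        g3 = geno([(1, 1), (3, 3), (5, 5), (7, 8)],
                  ambiguous=[True, True, True, False], sample_id="c")
        assert match_genotypes(g1, g3).match_class == POSSIBLE_MATCH
        individuals, _ = cluster_individuals([g1, g2, g3])
        assert len(individuals) == 2
        # resolution is conservative: disabling it gives the same partition
        individuals_off, _ = cluster_individuals([g1, g2, g3],
                                                 resolve_possible=False)
        assert len(individuals_off) == 2

    def test_simulated_partition_recovery_quick(self, rng):
        """Five individuals x four samples at study error rates: the true
        partition is recovered in nearly every run (quick check; the full
        500-dataset version backs the acceptance suite)."""
        ok = 0
        for rep in range(25):
            reps, labels, rates = simulate_genotype_dataset(
                5, 4, np.random.default_rng(900 + rep))
            genotyper = ConsensusGenotyper(rates=rates).fit(reps)
            clusterer = IndividualClusterer().fit(genotyper.accepted_)
            ok += _partition_exact(reps, labels, clusterer)
        assert ok >= 23

    def test_clusterer_labels_shape(self, rng):
        reps, labels, rates = simulate_genotype_dataset(4, 3, rng)
        genotyper = ConsensusGenotyper(rates=rates).fit(reps)
        clusterer = IndividualClusterer().fit(genotyper.accepted_)
        assert len(clusterer.labels_) == len(genotyper.accepted_)


def _partition_exact(reps, labels, clusterer) -> bool:
    truth = {r.sample_id: int(l) for r, l in zip(reps, labels)}
    est = {}
    for ind in clusterer.individuals_:
        for sid in ind.sample_ids:
            est[sid] = ind.individual_id
    true_to_est = {}
    est_to_true = {}
    for sid, el in est.items():
        tl = truth[sid]
        if true_to_est.setdefault(tl, el) != el:
            return False
        if est_to_true.setdefault(el, tl) != tl:
            return False
    return True
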