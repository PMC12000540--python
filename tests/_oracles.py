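"""Independent brute-force oracles used by the test suite.

These enumerate the elementary outcomes of the replicate error model and the
single-error explanations of genotype mismatches, independently of the
closed-form expressions in the package.
"""

from __future__ import annotations

import itertools

import numpy as np

from wolfscr.genotypes import NO_CALL


def oracle_call_prob(call, truth, p_dropout, p_false, pool) -> float:
    """P(observed call | truth) by enumerating dropout patterns and
    single false-allele substitutions, conditioned on amplification."""
    a, b = sorted(truth)
    target = tuple(sorted(call))
    if a != b:
        patterns = [((a, b), (1 - p_dropout) ** 2),
                    ((a, a), p_dropout * (1 - p_dropout)),
                    ((b, b), p_dropout * (1 - p_dropout))]
        norm = 1.0 - p_dropout ** 2
    else:
        patterns = [((a, a), 1.0)]
        norm = 1.0
    total = 0.0
    for base, p_base in patterns:
        if tuple(sorted(base)) == target:
            total += p_base * (1.0 - p_false)
        distinct = sorted(set(base))
        for victim in distinct:
            for inserted in pool:
                if inserted == victim:
                    continue
                res = list(base)
                res.remove(victim)
                res.append(inserted)
                if tuple(sorted(res)) == target:
                    total += (p_base * p_false
                              / len(distinct) / (len(pool) - 1))
    return total / norm


def oracle_reliability(consensus, replicates, rates, allele_values) -> float:
    """Posterior of the consensus genotype by exhaustive enumeration of all
    unordered allele pairs of the full locus pool (uniform prior)."""
    pool = list(allele_values)
    total = 1.0
    for l in range(replicates.calls.shape[1]):
        if consensus.alleles[l, 0] == NO_CALL:
            continue
        amplified = [tuple(int(x) for x in c)
                     for c in replicates.calls[:, l, :] if c[0] != NO_CALL]
        target = tuple(int(x) for x in consensus.alleles[l])
        num = den = 0.0
        for g in itertools.combinations_with_replacement(pool, 2):
            lik = 1.0
            for c in amplified:
                lik *= oracle_call_prob(c, g, float(rates.dropout[l]),
                                        rates.false_allele, pool)
            den += lik
            if tuple(sorted(g)) == target:
                num = lik
        total *= num / den if den > 0 else 0.0
    return total


def _dropout_images(call):
    """Calls reachable from ``call`` by one allelic dropout (het -> hom)."""
    a, b = sorted(call)
    if a == b:
        return set()
    return {(a, a), (b, b)}


def oracle_match_class(g1, g2) -> tuple[int, int, str]:
    """Classify two genotypes by enumerating single-error explanations.

    Per shared locus: identical calls cost nothing; if applying one dropout
    to one of the two calls makes them identical, the locus is a dropout
    mismatch; any other difference is a false-allele mismatch.  Classes use
    the <=1 dropout / 0 false (match) and <=3 dropout / <=1 false
    (possible match) budgets.
    """
    n_drop = n_false = 0
    shared = 0
    for l in range(g1.alleles.shape[0]):
        c1 = tuple(int(x) for x in g1.alleles[l])
        c2 = tuple(int(x) for x in g2.alleles[l])
        if c1[0] == NO_CALL or c2[0] == NO_CALL:
            continue
        shared += 1
        if c1 == c2:
            continue
        if c1 in _dropout_images(c2) or c2 in _dropout_images(c1):
            n_drop += 1
        else:
            n_false += 1
    if shared == 0:
        raise ValueError("no shared locus")
    if n_drop <= 1 and n_false == 0:
        cls = "match"
    elif n_drop <= 3 and n_false <= 1:
        cls = "possible_match"
    else:
        cls = "distinct"
    return n_drop, n_false, cls


def greedy_day_filter(points, radius):
    """Reference greedy earliest-first thinning of one individual-day."""
    kept = []
    for p in points:
        if all(np.hypot(p[0] - q[0], p[1] - q[1]) >= radius for q in kept):
            kept.append(p)
    return kept
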