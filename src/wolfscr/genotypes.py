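"""Replicate-aware microsatellite consensus genotyping and individual matching.

Noninvasive DNA samples (scat, urine, hair) yield low-quality template, so
each sample is PCR-amplified several times (the multiple-tube approach) and a
consensus genotype is assembled across replicates.  Two error modes dominate:
*allelic dropout* (one allele of a heterozygote fails to amplify, so the call
looks homozygous) and *false alleles* (PCR artifacts).  This module

* builds per-sample consensus genotypes under the two-observation allele rule,
* scores them with a quality index (mean replicate/consensus agreement) and a
  model-based reliability (posterior probability the consensus is the true
  genotype under an explicit dropout/false-allele error model),
* decides sample acceptance against reliability/quality thresholds,
* matches consensus genotypes allowing dropout-compatible mismatches, and
* clusters accepted samples into individuals.

Genotypes are stored as integer allele-length pairs per locus; ``-1`` marks a
missing (non-amplified or unresolved) locus.  Molecular sex comes from the
Amelogenin locus, with the Y allele subject to the same two-observation rule
as autosomal alleles (a dropped Y would otherwise feminize males).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

NO_CALL = -1

MATCH = "match"
POSSIBLE_MATCH = "possible_match"
DISTINCT = "distinct"

ACCEPTED = "accepted"
DISCARD_LOW_QUALITY = "discard_low_quality"
DISCARD_UNRELIABLE = "discard_unreliable"

MAX_REPLICATES = 8


@dataclass
class ErrorRates:
    """Per-locus allelic dropout probabilities and a global false-allele rate.

    ``dropout[l]`` is the probability that either allele of a heterozygote
    independently fails to amplify in one replicate at locus ``l``;
    ``false_allele`` is the per-replicate probability that one allele of an
    amplified call is replaced by a random wrong allele.  ``pool_size`` is the
    number of alleles segregating at each locus, used to spread the
    false-allele insertion probability.
    """

    dropout: np.ndarray
    false_allele: float = 0.004
    pool_size: int = 8

    def __post_init__(self) -> None:
        self.dropout = np.asarray(self.dropout, dtype=float)
        if np.any((self.dropout < 0) | (self.dropout > 1)):
            raise ValueError("dropout probabilities must be in [0, 1]")
        if not 0.0 <= self.false_allele <= 1.0:
            raise ValueError("false_allele must be in [0, 1]")
        if self.pool_size < 2:
            raise ValueError("pool_size must be >= 2")


@dataclass
class ReplicateSet:
    """All PCR replicates of one sample.

    ``calls`` has shape (n_replicates, n_loci, 2); allele pairs are sorted,
    with ``NO_CALL`` in both slots for a non-amplified locus.  ``amel`` holds
    the Amelogenin call per replicate: ``"XX"``, ``"XY"`` or ``None``.
    """

    sample_id: str
    calls: np.ndarray
    amel: list
    locus_ids: list

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=int)
        if self.calls.ndim != 3 or self.calls.shape[2] != 2:
            raise ValueError("calls must have shape (replicates, loci, 2)")
        if self.calls.shape[0] < 1:
            raise ValueError("at least one replicate is required")
        if self.calls.shape[0] > MAX_REPLICATES:
            raise ValueError(f"more than {MAX_REPLICATES} replicates")
        if self.calls.shape[1] != len(self.locus_ids):
            raise ValueError("locus_ids length does not match calls")
        if len(self.amel) != self.calls.shape[0]:
            raise ValueError("amel length does not match replicate count")
        self.calls = np.sort(self.calls, axis=2)

    @property
    def n_replicates(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]


@dataclass
class ConsensusGenotype:
    """Per-sample consensus: allele pairs, quality, reliability and sex."""

    sample_id: str
    alleles: np.ndarray  # (n_loci, 2), NO_CALL for missing
    ambiguous: np.ndarray  # (n_loci,) bool: provisional homozygote
    locus_ids: list
    quality_index: float = np.nan
    reliability: float = np.nan
    sex: str = "U"
    n_replicates: int = 0

    def __post_init__(self) -> None:
        self.alleles = np.sort(np.asarray(self.alleles, dtype=int), axis=1)
        self.ambiguous = np.asarray(self.ambiguous, dtype=bool)

    @property
    def missing(self) -> np.ndarray:
        return self.alleles[:, 0] == NO_CALL

    @property
    def n_typed_loci(self) -> int:
        return int((~self.missing).sum())


@dataclass
class MatchResult:
    sample_a: str
    sample_b: str
    n_dropout_mismatches: int
    n_false_allele_mismatches: int
    match_class: str


@dataclass
class Individual:
    """A cluster of samples sharing one genotype."""

    individual_id: str
    consensus: ConsensusGenotype
    sex: str
    sample_ids: list
    flagged_for_review: bool = False
    hybrid_q: float | None = None
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Consensus calling
# ---------------------------------------------------------------------------

def consensus_call(replicates: ReplicateSet) -> ConsensusGenotype:
    """Build the consensus genotype of one sample across its PCR replicates.

    An allele enters the consensus only if observed in at least two distinct
    replicates.  Per locus:

    * two or more confirmed alleles -> heterozygote of the two most-observed;
    * exactly one confirmed allele -> provisional homozygote, flagged
      dropout-ambiguous (an undetected second allele cannot be excluded);
    * fewer than two amplified replicates, or no confirmed allele -> missing.

    Sex is female if every non-missing Amelogenin call is X/X, male if X/Y was
    confirmed in two or more replicates, unknown otherwise.
    """
    calls = replicates.calls
    n_rep, n_loci = calls.shape[0], calls.shape[1]
    alleles = np.full((n_loci, 2), NO_CALL, dtype=int)
    ambiguous = np.zeros(n_loci, dtype=bool)

    for l in range(n_loci):
        locus_calls = calls[:, l, :]
        amplified = locus_calls[locus_calls[:, 0] != NO_CALL]
        if amplified.shape[0] < 2:
            continue
        counts: dict[int, int] = {}
        for rep in amplified:
            for a in set(int(x) for x in rep):
                counts[a] = counts.get(a, 0) + 1
        confirmed = sorted(
            (a for a, c in counts.items() if c >= 2),
            key=lambda a: (-counts[a], a),
        )
        if len(confirmed) >= 2:
            alleles[l] = sorted(confirmed[:2])
        elif len(confirmed) == 1:
            alleles[l] = (confirmed[0], confirmed[0])
            ambiguous[l] = True
        # 0 confirmed: replicates disagree entirely -> unresolved/missing

    sex = _call_sex(replicates.amel)
    cons = ConsensusGenotype(
        sample_id=replicates.sample_id,
        alleles=alleles,
        ambiguous=ambiguous,
        locus_ids=list(replicates.locus_ids),
        sex=sex,
        n_replicates=n_rep,
    )
    cons.quality_index = quality_index(replicates, cons)
    return cons


def _call_sex(amel_calls: list) -> str:
    observed = [c for c in amel_calls if c not in (None, "", "NA")]
    if not observed:
        return "U"
    if sum(c == "XY" for c in observed) >= 2:
        return "M"
    if all(c == "XX" for c in observed):
        return "F"
    return "U"


def quality_index(replicates: ReplicateSet, consensus: ConsensusGenotype) -> float:
    """Mean per-locus fraction of amplified replicates matching the consensus.

    Loci with a missing consensus (or no amplification) are excluded.  Returns
    0.0 if no locus is usable.
    """
    calls = replicates.calls
    per_locus = []
    for l in range(calls.shape[1]):
        if consensus.alleles[l, 0] == NO_CALL:
            continue
        locus_calls = calls[:, l, :]
        amplified = locus_calls[locus_calls[:, 0] != NO_CALL]
        if amplified.shape[0] == 0:
            continue
        agree = np.all(amplified == consensus.alleles[l], axis=1)
        per_locus.append(float(agree.mean()))
    return float(np.mean(per_locus)) if per_locus else 0.0


# ---------------------------------------------------------------------------
# Reliability under the dropout / false-allele error model
# ---------------------------------------------------------------------------

def call_probability(
    call: tuple[int, int],
    truth: tuple[int, int],
    dropout: float,
    false_allele: float,
    pool_size: int,
) -> float:
    """P(observed replicate call | true genotype), conditioned on amplification.

    Generative model per replicate: each allele of a true heterozygote drops
    independently with probability ``dropout`` (homozygotes cannot visibly
    drop); if anything amplified, with probability ``false_allele`` one of the
    distinct alleles in the call is replaced by an allele drawn uniformly from
    the remaining ``pool_size - 1`` alleles of the locus pool.  Probabilities
    are renormalized by the amplification probability (1 for homozygotes,
    1 - dropout^2 for heterozygotes) because non-amplified replicates carry no
    genotype information here.
    """
    p, q, k = dropout, false_allele, pool_size - 1
    a, b = sorted(truth)
    x, y = sorted(call)
    if a == b:  # true homozygote
        if (x, y) == (a, a):
            return 1.0 - q
        if x == a or y == a:  # (a, u) after one false allele
            return q / k
        return 0.0
    # true heterozygote, condition on amplification
    s = (1.0 - p) ** 2
    h = p * (1.0 - p)
    norm = 1.0 - p * p
    if (x, y) == (a, b):
        pr = s * (1.0 - q) + 2.0 * h * q / k
    elif (x, y) == (a, a) or (x, y) == (b, b):
        pr = h * (1.0 - q) + s * q / (2.0 * k)
    elif x == y:
        pr = 0.0  # homozygous for an allele outside the truth: needs 2 errors
    elif x in (a, b) or y in (a, b):
        # heterozygote sharing exactly one true allele
        if x in (a, b) and y in (a, b):
            pr = 0.0  # cannot happen: (a,b) handled above
        else:
            pr = s * q / (2.0 * k) + h * q / k
    else:
        pr = 0.0
    return pr / norm


def _candidate_genotypes(observed: list[int], pool_size: int):
    """Candidate true genotypes at a locus: all pairs of observed alleles,
    plus pairs of one observed allele with a representative unseen allele
    (weighted by the number of unseen pool alleles)."""
    obs = sorted(set(observed))
    phantom = max(obs) + 1  # representative allele not observed at this locus
    n_unseen = max(pool_size - len(obs), 0)
    candidates: list[tuple[tuple[int, int], float]] = []
    for i, x in enumerate(obs):
        for y in obs[i:]:
            candidates.append(((x, y), 1.0))
    if n_unseen > 0:
        for x in obs:
            candidates.append(((x, phantom), float(n_unseen)))
    return candidates


def reliability(
    consensus: ConsensusGenotype,
    replicates: ReplicateSet,
    rates: ErrorRates,
) -> float:
    """Posterior probability that the consensus genotype is correct.

    Product over typed loci of P(consensus | replicate calls) under the
    dropout/false-allele model, with a uniform prior over candidate true
    genotypes (pairs of observed alleles, plus observed-with-unseen pairs).
    Non-decreasing in the number of concordant replicates; equals 1 when both
    error rates are zero.
    """
    if len(rates.dropout) != len(consensus.locus_ids):
        raise ValueError("error rates must cover every locus")
    calls = replicates.calls
    total = 1.0
    for l in range(calls.shape[1]):
        if consensus.alleles[l, 0] == NO_CALL:
            continue
        locus_calls = calls[:, l, :]
        amplified = [tuple(int(x) for x in c) for c in locus_calls if c[0] != NO_CALL]
        observed = [a for c in amplified for a in c]
        cands = _candidate_genotypes(observed, rates.pool_size)
        cons = tuple(int(x) for x in consensus.alleles[l])
        p_d, p_f = float(rates.dropout[l]), rates.false_allele
        num = 0.0
        den = 0.0
        for g, w in cands:
            lik = w
            for c in amplified:
                lik *= call_probability(c, g, p_d, p_f, rates.pool_size)
            den += lik
            if g == cons:
                num = lik
        total *= num / den if den > 0 else 0.0
    return float(total)


def accept_sample(
    consensus: ConsensusGenotype,
    matched_to_reliable_sample: bool,
    reliability_threshold: float = 0.98,
    quality_threshold: float = 0.4,
) -> str:
    """Acceptance decision for one consensus genotype.

    A sample matched to another reliably genotyped sample is accepted whatever
    its own reliability.  Unmatched samples with quality index below the
    quality threshold are discarded regardless of reliability; otherwise the
    sample is accepted only once its reliability reaches the threshold, and
    discarded as unreliable after the replicate cap.
    """
    if matched_to_reliable_sample:
        return ACCEPTED
    if consensus.quality_index < quality_threshold:
        return DISCARD_LOW_QUALITY
    if consensus.reliability >= reliability_threshold:
        return ACCEPTED
    return DISCARD_UNRELIABLE


# ---------------------------------------------------------------------------
# Genotype matching
# ---------------------------------------------------------------------------

def _classify_locus(a: np.ndarray, b: np.ndarray) -> int:
    """0 = identical, 1 = dropout-compatible mismatch, 2 = false-allele mismatch.

    Dropout-compatible: the genotypes share at least one allele and one of
    them is homozygous (or a dropout-ambiguous provisional homozygote), i.e.,
    a single dropout in one of the two observations explains the difference.
    """
    if a[0] == b[0] and a[1] == b[1]:
        return 0
    shares = a[0] in (b[0], b[1]) or a[1] in (b[0], b[1])
    one_hom = a[0] == a[1] or b[0] == b[1]
    if shares and one_hom:
        return 1
    return 2


def match_genotypes(g1: ConsensusGenotype, g2: ConsensusGenotype) -> MatchResult:
    """Compare two consensus genotypes over their shared typed loci.

    Each mismatching locus counts once, as a dropout mismatch if a single
    allelic dropout in one of the two genotypes explains it, else as a
    false-allele mismatch.  Classes: ``match`` (<=1 dropout, 0 false),
    ``possible_match`` (<=3 dropout, <=1 false), else ``distinct``.
    """
    shared = ~g1.missing & ~g2.missing
    if not shared.any():
        raise ValueError("genotypes share no typed locus")
    n_drop = 0
    n_false = 0
    for l in np.flatnonzero(shared):
        kind = _classify_locus(g1.alleles[l], g2.alleles[l])
        if kind == 1:
            n_drop += 1
        elif kind == 2:
            n_false += 1
    return MatchResult(g1.sample_id, g2.sample_id, n_drop, n_false,
                       classify_mismatches(n_drop, n_false))


def classify_mismatches(n_dropout: int, n_false: int) -> str:
    if n_dropout <= 1 and n_false == 0:
        return MATCH
    if n_dropout <= 3 and n_false <= 1:
        return POSSIBLE_MATCH
    return DISTINCT


def _pairwise_counts(alleles: np.ndarray):
    """Vectorized pairwise mismatch counts.

    ``alleles``: (n, L, 2) sorted allele pairs with NO_CALL for missing.
    Returns (n_dropout, n_false, n_shared) integer matrices of shape (n, n).
    """
    a1 = alleles[:, :, 0]
    a2 = alleles[:, :, 1]
    missing = a1 == NO_CALL
    shared = ~missing[:, None, :] & ~missing[None, :, :]
    ident = (a1[:, None] == a1[None, :]) & (a2[:, None] == a2[None, :])
    shares = (
        (a1[:, None] == a1[None, :]) | (a1[:, None] == a2[None, :])
        | (a2[:, None] == a1[None, :]) | (a2[:, None] == a2[None, :])
    )
    hom = a1 == a2
    one_hom = hom[:, None] | hom[None, :]
    dropout_l = shared & ~ident & shares & one_hom
    false_l = shared & ~ident & ~(shares & one_hom)
    return dropout_l.sum(axis=2), false_l.sum(axis=2), shared.sum(axis=2)


# ---------------------------------------------------------------------------
# Clustering samples into individuals
# ---------------------------------------------------------------------------

def _component_consensus(members: list[ConsensusGenotype]) -> ConsensusGenotype:
    """Merge member consensus genotypes into one per-component genotype.

    Per locus, heterozygous (fully resolved) calls dominate provisional
    homozygotes; among equally resolved calls the most frequent wins, ties
    broken by allele values for determinism.
    """
    n_loci = len(members[0].locus_ids)
    alleles = np.full((n_loci, 2), NO_CALL, dtype=int)
    ambiguous = np.zeros(n_loci, dtype=bool)
    for l in range(n_loci):
        votes: dict[tuple[int, int, bool], int] = {}
        for g in members:
            if g.alleles[l, 0] == NO_CALL:
                continue
            key = (int(g.alleles[l, 0]), int(g.alleles[l, 1]), bool(g.ambiguous[l]))
            votes[key] = votes.get(key, 0) + 1
        if not votes:
            continue
        best = sorted(votes, key=lambda k: (k[2], -votes[k], k[0], k[1]))[0]
        alleles[l] = best[:2]
        ambiguous[l] = best[2]
    return ConsensusGenotype(
        sample_id="+".join(g.sample_id for g in members),
        alleles=alleles,
        ambiguous=ambiguous,
        locus_ids=list(members[0].locus_ids),
    )


def _merge_sex(members: list[ConsensusGenotype]) -> str:
    sexes = {g.sex for g in members} - {"U"}
    if len(sexes) > 1:
        ids = [g.sample_id for g in members]
        raise ValueError(f"conflicting sex calls within one individual: {ids}")
    return sexes.pop() if sexes else "U"


def _split_intransitive(idx: list[int], cls: np.ndarray) -> list[list[int]]:
    """Split a connected component containing 'distinct' pairs.

    Greedy complete linkage by total concordance: samples (ordered by their
    number of within-component matches, descending) join the first group whose
    every member they match; otherwise they seed a new group.
    """
    order = sorted(idx, key=lambda i: (-sum(cls[i, j] == 0 for j in idx if j != i), i))
    groups: list[list[int]] = []
    for i in order:
        placed = False
        for grp in groups:
            if all(cls[i, j] == 0 for j in grp):
                grp.append(i)
                placed = True
                break
        if not placed:
            groups.append([i])
    return groups


def cluster_individuals(
    genotypes: list[ConsensusGenotype],
    resolve_possible: bool = True,
):
    """Cluster accepted samples into individuals.

    Individuals are connected components of the graph whose edges are
    ``match``-class pairs.  ``possible_match`` pairs between components are
    re-evaluated against the merged component consensus genotypes and upgraded
    to a merge only if they then reach ``match`` class.  Components containing
    an internally ``distinct`` pair (match intransitivity) are flagged for
    review and split by best total concordance.

    Returns ``(individuals, audit)`` where ``audit`` is a DataFrame of all
    pairwise comparisons (sample_a, sample_b, n_dropout, n_false, class).
    """
    import networkx as nx

    n = len(genotypes)
    if n == 0:
        return [], pd.DataFrame(
            columns=["sample_a", "sample_b", "n_dropout", "n_false", "match_class"])
    alleles = np.stack([g.alleles for g in genotypes])
    n_drop, n_false, n_shared = _pairwise_counts(alleles)
    cls = np.full((n, n), 2, dtype=int)  # 0 match, 1 possible, 2 distinct
    cls[(n_drop <= 1) & (n_false == 0)] = 0
    cls[(cls != 0) & (n_drop <= 3) & (n_false <= 1)] = 1

    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            if n_shared[i, j] == 0:
                raise ValueError(
                    f"no shared typed locus between {genotypes[i].sample_id} "
                    f"and {genotypes[j].sample_id}")
            rows.append((genotypes[i].sample_id, genotypes[j].sample_id,
                         int(n_drop[i, j]), int(n_false[i, j]),
                         [MATCH, POSSIBLE_MATCH, DISTINCT][cls[i, j]]))
    audit = pd.DataFrame(
        rows, columns=["sample_a", "sample_b", "n_dropout", "n_false", "match_class"])

    graph = nx.Graph()
    graph.add_nodes_from(range(n))
    graph.add_edges_from(zip(*np.nonzero(np.triu(cls == 0, k=1))))
    components = [sorted(c) for c in nx.connected_components(graph)]

    if resolve_possible:
        changed = True
        while changed:
            changed = False
            cons = [_component_consensus([genotypes[i] for i in comp])
                    for comp in components]
            for ci in range(len(components)):
                for cj in range(ci + 1, len(components)):
                    has_possible = any(
                        cls[i, j] == 1
                        for i in components[ci] for j in components[cj])
                    if not has_possible:
                        continue
                    res = match_genotypes(cons[ci], cons[cj])
                    if res.match_class == MATCH:
                        components[ci] = sorted(components[ci] + components[cj])
                        del components[cj]
                        changed = True
                        break
                if changed:
                    break

    individuals = []
    final_groups: list[tuple[list[int], bool]] = []
    for comp in components:
        has_distinct = any(
            cls[i, j] == 2 for i in comp for j in comp if i < j)
        if has_distinct:
            for grp in _split_intransitive(comp, cls):
                final_groups.append((grp, True))
        else:
            final_groups.append((comp, False))
    final_groups.sort(key=lambda g: genotypes[g[0][0]].sample_id)
    for k, (grp, flagged) in enumerate(final_groups, start=1):
        members = [genotypes[i] for i in grp]
        individuals.append(Individual(
            individual_id=f"ind_{k:03d}",
            consensus=_component_consensus(members),
            sex=_merge_sex(members),
            sample_ids=[g.sample_id for g in members],
            flagged_for_review=flagged,
        ))
    return individuals, audit


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

class ConsensusGenotyper(BaseEstimator):
    """Transformer from replicate call sets to accepted consensus genotypes.

    Parameters
    ----------
    rates : ErrorRates or None
        Dropout / false-allele rates used for reliability scoring.  If None,
        reliability is not computed (NaN) and acceptance falls back to the
        quality index only.
    reliability_threshold, quality_threshold : float
        Acceptance cutoffs for unmatched samples.
    """

    def __init__(self, rates: ErrorRates | None = None,
                 reliability_threshold: float = 0.98,
                 quality_threshold: float = 0.4):
        self.rates = rates
        self.reliability_threshold = reliability_threshold
        self.quality_threshold = quality_threshold

    def fit(self, replicate_sets, y=None):
        self.genotypes_ = [consensus_call(r) for r in replicate_sets]
        if self.rates is not None:
            for g, r in zip(self.genotypes_, replicate_sets):
                g.reliability = reliability(g, r, self.rates)
        self.decisions_ = self._accept(self.genotypes_)
        self.accepted_ = [g for g in self.genotypes_
                          if self.decisions_[g.sample_id] == ACCEPTED]
        return self

    def transform(self, replicate_sets):
        return self.fit(replicate_sets).accepted_

    def _accept(self, genotypes: list[ConsensusGenotype]) -> dict:
        """Two-pass acceptance: establish the reliable samples, then accept
        any sample whose genotype matches a reliable one."""
        usable = [g for g in genotypes if g.n_typed_loci > 0]
        reliable = {g.sample_id for g in usable
                    if g.reliability >= self.reliability_threshold}
        matched: dict[str, bool] = {g.sample_id: False for g in genotypes}
        for i in range(len(usable)):
            for j in range(len(usable)):
                if i == j or usable[j].sample_id not in reliable:
                    continue
                shared = ~usable[i].missing & ~usable[j].missing
                if not shared.any():
                    continue
                if match_genotypes(usable[i], usable[j]).match_class == MATCH:
                    matched[usable[i].sample_id] = True
        decisions = {}
        for g in genotypes:
            if g.n_typed_loci == 0:
                decisions[g.sample_id] = DISCARD_LOW_QUALITY
                continue
            decisions[g.sample_id] = accept_sample(
                g, matched[g.sample_id],
                self.reliability_threshold, self.quality_threshold)
        return decisions


class IndividualClusterer(BaseEstimator):
    """Clusterer grouping accepted consensus genotypes into individuals."""

    def __init__(self, resolve_possible: bool = True):
        self.resolve_possible = resolve_possible

    def fit(self, genotypes, y=None):
        self.individuals_, self.audit_ = cluster_individuals(
            genotypes, resolve_possible=self.resolve_possible)
        label_of = {}
        for k, ind in enumerate(self.individuals_):
            for sid in ind.sample_ids:
                label_of[sid] = k
        self.labels_ = np.array([label_of[g.sample_id] for g in genotypes])
        return self

    def fit_predict(self, genotypes, y=None):
        return self.fit(genotypes).labels_
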