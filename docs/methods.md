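# Methods

`wolfscr` implements the full analysis chain of a noninvasive-DNA wolf
monitoring campaign: replicated microsatellite genotyping of scat/urine/hair
samples, matching samples to individuals, assembling packs from pedigree
relations plus a spatial proximity rule, and estimating abundance and
density with a Bayesian data-augmented Poisson spatial capture–recapture
(SCR) model. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic experiments do and do not show.

## Consensus genotyping

Noninvasive samples are amplified in up to 8 PCR replicates (a first
screening of two, then more as needed). Two error modes are modeled:

* **allelic dropout** — each allele of a true heterozygote independently
  fails to amplify in a replicate with locus-specific probability
  `p_d` (defaults drawn from 0.017–0.073, the empirically observed
  single-PCR range for this marker panel); a homozygote cannot visibly drop;
* **false alleles** — with probability `p_f = 0.004` per amplified call, one
  of the distinct alleles in the call is replaced by a uniformly random
  other allele of the locus pool (default pool size 8).

**Two-observation rule.** An allele enters the consensus only when seen in
two distinct replicates. One confirmed allele gives a *provisional
homozygote* flagged dropout-ambiguous; fewer than two amplified replicates,
or complete disagreement, leaves the locus missing. The same rule guards
molecular sexing: an X/Y Amelogenin call must be confirmed twice before a
sample is called male, because a dropped Y feminizes the call; a sample is
called female only if every amplified Amelogenin call is X/X.

**Quality index.** Mean over typed loci of the fraction of amplified
replicates whose call equals the consensus call — a model-free agreement
score in [0, 1].

**Reliability.** The probability that the consensus genotype is correct,
computed per locus as the posterior probability of the consensus under the
dropout/false-allele model with a uniform prior over candidate true
genotypes (all pairs of observed alleles, plus each observed allele paired
with an unseen pool allele, weighted by the number of unseen alleles;
genotypes with no observed allele are excluded — they require two
simultaneous errors per replicate and carry negligible likelihood).
Replicates that did not amplify are treated as uninformative (likelihoods
are conditioned on amplification) because amplification failure is dominated
by template quality, not genotype. The per-locus posteriors multiply across
loci. This is a deliberately self-contained surrogate for maximum-likelihood
reliability scoring: it preserves the operational thresholds (accept at
reliability ≥ 0.98) and its closed forms are validated in the test suite
against brute-force enumeration of every atomic error event. A useful
emergent property: a homozygous locus seen in two replicates cannot clear
0.98 (a hidden second allele is too likely), but a third concordant
replicate can — reproducing the lab practice of repeating until reliable.

**Acceptance.** A sample matched (see below) to a reliably genotyped sample
is accepted whatever its own reliability; otherwise quality index < 0.4
discards it regardless of reliability, and reliability ≥ 0.98 accepts it.

## Matching and individual clustering

Two consensus genotypes are compared over shared typed loci. A mismatching
locus is *dropout-compatible* when the calls share an allele and one of them
is homozygous (equivalently: a single dropout applied to one of the two
observations reconciles them — the reading under which two disjoint
homozygotes are *not* a dropout pair); any other difference is a
false-allele mismatch. Classes: **match** (≤ 1 dropout, 0 false),
**possible match** (≤ 3 dropout, ≤ 1 false), else **distinct**. Individuals
are connected components of the match graph. Possible matches between
components are re-evaluated against merged component consensus genotypes
(additional wet-lab repeats not being available to software) and upgraded
only if they then reach match class. Components containing an internally
distinct pair — possible when a poorly typed sample bridges two genotypes —
are flagged for review and split greedily by complete linkage, ordered by
within-component concordance. Sexes within an individual must agree;
a confirmed conflict is an error.

## Pack assembly

The package consumes a pedigree-relations table (parent–offspring, full-sib,
half-sib with assignment probabilities, e.g. exported from a
parentage/sibship program); it never infers pedigrees itself. Edges with
probability < 0.8 (configurable) are ignored. Packs are connected components
of the parent–offspring/full-sib graph (half-sibs do not connect packs —
they arise across breeder changes). Parents are breeders; pedigree
individuals never sampled are retained as `undetected_inferred`
placeholders. Unassigned individuals are adopted into a pack when one of
their samples lies within 500 m of a pack member's sample on the same
calendar day with the same field-estimated sample age; ties across packs
break by minimum distance, an exact tie leaves the individual out, making
the result independent of processing order. Breeder tenures are dated by
litter years when the relations table carries them; a turnover event is a
change of the breeding individual of a role between consecutive years.
Dispersal is tracked by year-to-year attendance: the pack whose members'
samples an individual is proximate to in a given year, falling back to its
static pack.

## SCR data preparation

Detections of the SCR season (November–May of the estimation year) are
thinned for autocorrelation: per individual per day, a greedy earliest-first
scan (ties by sample id) removes any event strictly within 1 km of an
already retained one. The sampling area is divided into 2.5 × 2.5 km cells
aligned to the event bounding box (snapped outward to cell multiples; cells
half-open). Cells holding ≥ 1 retained sample become detectors; effort `E_j`
is the GPS-track length clipped to the cell (shapely segment clipping)
divided by the cell area, in km/km². Scat, urine and hair are assumed
equally detectable. The habitat mask is the union of 10 km (≈ 3σ) disks
around detectors, discretized to 500 m cells by centroid inclusion; its area
converges to the exact union-of-disks area as the resolution shrinks
(checked at two resolutions in the tests).

## The SCR model

With `M` augmented individuals (default 4× the detected count),

    z_i ~ Bernoulli(psi),   s_i ~ Uniform(mask cells),
    y_ij | z_i = 1 ~ Poisson(lambda_ij),
    lambda_ij = exp(alpha0 + alpha1 E_j) * exp(-d_ij^2 / (2 sigma^2)),

and N = Σ z_i, D = N / mask area × 100 km². Sex enters only the reporting
split: detected individuals keep their molecular sex, augmented ones draw
from `theta` (probability female, uniform prior), giving posterior `N_f`,
`N_m` with `N_f + N_m = N` draw by draw.

Priors: `alpha0, alpha1 ~ Normal(0, 10²)`; `sigma ~ Uniform(100 m, 20 km)`;
`psi, theta ~ Uniform(0, 1)`. Sampling is Metropolis-within-Gibbs:
random-walk proposals for `alpha0`, `alpha1`, `log sigma` (scales adapted
toward ~35 % acceptance during burn-in only, then frozen so the chain stays
valid), exact categorical Gibbs draws of every activity center over the mask
(Gumbel-max over per-cell log-likelihoods — detected individuals use their
encounter rows, included-undetected individuals the exposure term only,
excluded individuals the uniform prior), Bernoulli Gibbs for `z`, and
conjugate Beta updates for `psi` and `theta`. The default schedule is
3 chains × 50,000 iterations with 1,000 burn-in kept separate and thinning
5 (30,000 retained draws). One integer seed drives everything; per-chain
streams derive from it deterministically, so runs are exactly reproducible.

Convergence is summarized by the classic split-free Gelman–Rubin statistic
(< 1.1 taken as converged). Model fit uses three posterior-predictive
Bayesian p-values based on the Freeman–Tukey discrepancy, evaluated on the
included augmented population (detected rows keep their counts, included-
but-undetected individuals contribute structural zero rows) at three
aggregations: individual × detector cells, per-individual totals, and
per-detector totals. The density surface is the posterior mean count of
included activity centers per mask cell, rescaled to wolves per 100 km²; its
integral equals the posterior mean of N by construction.

## Synthetic campaigns

The generator emulates the study conditions end to end: a ~1,400 km²
sampled region centered in a ~3,000 km² habitat rectangle; 70 wolves in six
packs (pack centers uniform, member centers Normal with 6 km scale,
truncated; a `None` scale gives the homogeneous case of the fitted model);
even sex ratio; one breeding pair per pack with full-sib litters and ~12 %
unrelated individuals. Fourteen gently meandering 15 km search transects
define the searched 2.5 km cells and their effort; detections are Poisson
from the half-normal model with σ = 3.3 km, α0 = −0.4, α1 = 0.8 — calibrated
once so a campaign yields roughly 30 detected individuals with ~3 genotyped
samples each, the observed scale of a single winter season. Events get
distinct random days per individual (November–May), so the only
same-day-close pairs are deliberately injected duplicates (rate 0.2, ≤ 141 m
offset) that exercise the autocorrelation filter and are flagged in the
truth. Genotypes: founders Hardy–Weinberg at Dirichlet(1) frequencies over
8 alleles × 16 loci, offspring Mendelian, replicates corrupted by the same
dropout/false-allele process the reliability model assumes (the
generator-model agreement is itself tested by Monte Carlo), plus a 5 %
per-locus amplification-failure rate.

What the synthetic data do *not* emulate: movement-driven detection
correlation within packs (each individual is detected independently given
its activity center), open-population turnover within a season, sample-type
detectability differences, and laboratory artifacts beyond the two modeled
error modes. Passing recovery tests therefore show internal consistency of
the estimator at field-realistic scale, not robustness to gregarious
detection patterns — a known caveat of SCR applied to social canids.

## Recovery and calibration experiments

The parameter-recovery study simulates activity centers uniformly on a
square habitat mask that is passed to the model directly, with the full
searched grid (including its zero-count cells) as the detector array, so the
model's estimand — N inside the mask — coincides with the bookkept truth and
empty searched cells keep their information. (Restricting detectors to
sampled cells, as the field protocol must, discards those zeros and is
provided as an option.) The mask cell size is adjusted to tile the habitat
exactly; a half-cell overhang otherwise inflates the state space by ~2 %.
At the default conditions the posterior mean of N carries a mild upward
skew (a few percent) — the usual behavior of data-augmented abundance
posteriors under detection-parameter uncertainty — while 95 % interval
coverage sits near nominal.

The test suite and the acceptance script run these studies at smoke scale:
16 replicate fits with 3 × 2,500 iterations on a ~1.5 km mask for recovery
in the tests (5 fits at 3 × 4,000 in the script), 20 (tests) or 8 (script)
replicates with 3 × 2,000 iterations for GoF calibration, and 500 (tests)
or 200 (script) simulated 20-individual genotype datasets for clustering
recovery. These sizes were chosen as the package's
default smoke experiments; the full-scale schedule (3 × 50,000, 500 m mask,
50+ replicates) is an overnight run with the same code paths.

## Numerical and design choices

* Exact integer allele comparison; input calls are assumed binned upstream.
* Grid origin snapped outward from the data bounding box; cell membership
  half-open; ties in consensus votes broken by allele value — all for
  bit-reproducibility.
* Activity centers are discrete over mask cells. Halving the default
  experiment resolution (750 m vs 1.5 km) leaves recovery statistically
  unchanged, so the default is kept coarse for speed.
* The autocorrelation filter keeps the earliest sample (ties by id); the
  alternative — comparing every pair within a day — differs only for rare
  chains of samples ~1 km apart.
* Augmentation M = 4 × detected by default, with a warning when the
  posterior of N piles above 0.9 M.
* Effort is used raw (km/km²), matching the units of the log-linear link.
* Percentages in the sample-accounting report round half-up to one decimal;
  with the field campaign's printed per-type counts the mixed-sample column
  computes to 5.5 % (the source table prints 5.6 %, an internal rounding
  inconsistency of that table which the report does not force).

## Known limitations

* Group-structured observation models (aggregation/cohesion of pack
  members) are out of scope; density estimates on strongly clustered data
  inherit the mild underestimation documented for standard SCR on social
  species.
* Reliability scoring assumes independent replicates and the two modeled
  error modes only.
* Pack assembly trusts the supplied pedigree; assignment errors upstream
  propagate.
* Single-season (closed-population) estimation only.
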