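# Methods

## Survey model and coding

Surveys are respondent × item tables of ordinal codes, 1 = most negative
to `n_levels` = most positive; 5-level items carry a neutral middle level,
4-level items do not. The three vaccine items are mandatory and 5-level;
the rest of the roster (trust in science / institutions, 4-level) is
supplied by a YAML schema. Unparseable or out-of-range cells become
missing and are tallied in a load report. The summed vaccine score is
3–15 (all-strong-distrust = 3, all-neutral = 9, all-strong-trust = 15);
scores and Cronbach's alpha use complete cases, network edges use
pairwise-complete respondents per item pair. No survey weights and no
imputation are applied.

## Attitude network

Every response level is dummy-coded to a binary indicator; cross-item
edges carry the phi coefficient of the two indicators and within-item
pairs (structurally exclusive) are excluded. Indicators that never vary
give undefined edges; these are omitted rather than zero-filled, and the
permutation scheme preserves column counts, so the same edges are omitted
in every bootstrap resample. Negative edges are retained in all analyses;
the graph export offers a drop-negative mode only because force-directed
layout tools cannot render them.

The bootstrap permutes each item's categorical response column
independently across respondents. This is exactly equivalent to permuting
the item's whole dummy block row-wise: per-column counts of ones, the
one-answer-per-item constraint, and each respondent's missingness pattern
per item are all preserved while every cross-item association is
destroyed. The statistic is Σ|φ| over defined edges; the p-value uses the
add-one estimator (1 + #{null ≥ observed})/(1 + n_iter), so it is never
exactly zero, and ties count against the observed value (conservative).

Attitude-isolation is −1 × the mean phi between the three strong-trust
vaccine attitudes and the remaining vaccine attitudes. By default the
average runs over the 24 cross-item pairs, consistent with the network's
exclusion of within-item pairs; an alternative mode includes the
within-item pairs (36 pairs), computing their phi directly, for
sensitivity analysis. With the default convention the isolation value is
identical (to machine precision) to −1 × the mean of the strong-trust row
of the band-average matrix, because every band contributes the same
number (6) of cross-item pairs.

## Confirmation analyses

* Band averages: the 15 vaccine attitudes are grouped into the five trust
  bands and the mean cross-item phi is taken between each pair of bands
  (diagonals use cross-item pairs within the band).
* Ward clustering treats the 15 binary indicator columns as objects and
  complete-case respondents as features, with Euclidean distance (Ward's
  validity condition; a correlation-distance mode exists as a
  sensitivity check) and SciPy's Ward linkage. The "final split" is the
  two-cluster cut just before the last merge.
* Neutral overlap: for each non-neutral band, the share of
  complete-vaccine respondents holding ≥ 1 attitude of that band who also
  hold ≥ 1 neutral vaccine attitude. The neutral band itself is excluded
  (trivially 1).

## Synthetic-data generator

Each respondent draws a latent trust trait t ~ Normal(country mean,
`latent_sd`); each item observes t plus independent Normal item noise
(`item_noise_sd`, default 1.0) and discretizes through fixed cut-points
chosen for equal level occupancy at the default scale. The shared latent
trait produces the level-banded, same-level-positive correlation
structure seen in real attitude networks; the item noise controls how
strongly items cohere (small noise ⇒ strongly structured data, e.g. for
bootstrap power checks).

The decoupling knob d ∈ [0, 1] emulates the isolation of strong trust by
*profile resolution*: with probability d a respondent polarizes — if the
latent trait is above the top cut-point they answer the top level on
every item, otherwise any top-level answer is re-drawn uniformly from the
interior levels. Mixed strong/weak profiles are exactly what couple the
strong-trust attitudes to the rest of the system (the same mechanism the
policy simulations manipulate), so removing them raises isolation
monotonically; an alternative per-item redraw of top answers was tested
and discarded because it leaves the first item's top answer positively
correlated with the re-drawn mid-level answers and therefore *lowers*
the isolation statistic. The gradient generator assigns one d per
country, giving a controlled isolation gradient (rank correlation with
per-country isolation ≈ 0.97–0.98 at 20 × 1000).

What the generator does not emulate: real item wording effects,
demographic covariates, country-specific response styles, survey weights,
and informative missingness (missing cells are uniform at `missing_rate`).
Passing tests therefore demonstrate the estimators and dynamics behave
correctly under a known latent structure, not that real surveys satisfy
that structure.

## Influence models

All five models are seeded by bootstrap-resampling (with replacement) the
complete-vaccine respondents of one country; skeptics are agents with an
initial score ≤ 9, and their flag is frozen at initialization so later
dynamics cannot redefine the group.

* Deffuant: random pairs; if |xᵢ − xⱼ| < ε (open threshold, the model's
  canonical form) both move toward each other by μ·difference. μ defaults
  to 0.5 (midpoint meeting). The update is symmetric, so the population
  mean is conserved and opinions stay in the initial convex hull.
* HK / HK-G / HK-H: synchronous updates to the arithmetic / geometric /
  harmonic mean of all opinions within ε (closed neighbourhood, self
  included). Scores are ≥ 3 > 0 so the non-arithmetic means are defined;
  the AM–GM–HM inequality orders the three updates pointwise.
* Axelrod: 3 features (the raw vaccine codes) × 5 traits; pairs interact
  with probability equal to their shared-feature fraction and copy one
  differing feature; the absorbing state (every pair shares all or no
  features) is detected via the ≤ 125 distinct cultures.

Mixing is complete (any pair can meet) — interaction topology is a known
free choice. Step budgets default to 100·n pairwise events (Deffuant,
Axelrod) or 100 sweeps (HK); Deffuant convergence is declared when every
ε-separated opinion cluster has spread ≤ tol/μ (no admissible pair can
move more than tol), HK convergence when the largest per-sweep change is
below tol (default 1e-4). The pairwise inner loops are numba-compiled.

A study runs the model many times, each time drawing a country uniformly
at random, and correlates (Pearson; Spearman available) the seeding
country's isolation with the skeptics' final mean score. Runs without
skeptics record an undefined final mean and are excluded from r. One
master seed spawns independent per-run seeds, so studies are exactly
reproducible.

## Policy simulations

Both policies give ⌊coverage·N⌋ people (+5% default) a one-point increment
on one uniformly chosen vaccine attitude that is not already at the
maximum; (5,5,5) profiles are never targeted, sampling is without
replacement, and one person receives exactly one increment. Policy 1
targets mixed profiles holding at least one strong-trust and at least one
weak-trust attitude (the "almost convinced"); policy 2 targets pure
(4,4,4) profiles. The outcome is the isolation change,
100·(after − before)/|before|, so the sign reflects direction even if the
baseline were negative. If the eligible pool is smaller than the coverage
count, all eligible respondents are targeted.

## Country-level analysis

Country trust is the proportion of strong-trust answers among all vaccine
answers given (a per-respondent all-three-strong mode exists, since
"people providing strongly positive answers" admits both readings).
Year-over-year increments are later minus earlier; where multiple
datapoints exist for a country-year the earliest-dated one is kept (ties:
first in input order, warned). Partial correlation residualizes both
variables on the controls with an intercept by least squares and
correlates the residuals; the p-value uses n − 2 − k degrees of freedom.
This is numerically identical to the inverse-correlation-matrix closed
form, which the tests use as an independent oracle (along with pingouin).
Country joins are inner joins on the supplied country codes; no fuzzy
name matching.

## Problem sizes

The test suite and `scripts/acceptance.py` use 20-country gradients with
1000 respondents per country, 200–300 bootstrap resamples (100 replicates
for the calibration experiment at n = 1000), 150–200 runs × 1000 agents
per influence-model study, and 20 seeds for the Ward-split and
policy-direction frequency checks. These sizes give stable signs and rank
correlations while keeping a full run in minutes on one CPU.

## Known limitations

* The generator's latent-probit structure is one plausible mechanism for
  the observed attitude-space geometry, not an estimate fitted to any
  real survey's marginals.
* Influence models use complete mixing and homogeneous agents — no
  stubbornness, zealotry or network structure.
* The country-level analysis is correlational; it supports prediction
  claims, not causal ones.
* Bounded-confidence thresholds (ε = 3, 6, 9) are interpreted on the 3–15
  summed-score scale; results for other scales require rescaling ε.
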