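# Methods

## Data model

Participants are profiled on a declarative `FeatureSchema`. The default
schema has 5 categorical variables (sex, marital status, position,
department, shift type; codes are opaque labels compared by equality)
and 17 numerical variables (age, hospital-size code, clinical-experience
band, overtime band, turnover intention, job stress, stress response,
coping total and its three subscales, the three normalized burnout
subdimensions, and three reserved slots). Only the *counts* — 5 and
17 — are fixed by the design the package implements; the exact
composition of the numerical block is a configuration default, and the
engine works for any declared schema.

Ranges of the coded demographics were chosen so the shipped defaults
reproduce the published worked example of the similarity measure:
hospital size coded 1–5 (R = 4 gives the printed 0.50 and 0.25
contributions), clinical-experience bands 1–6 (R = 5 gives 0.40 and
0.20), and age 22–60 (R = 38 gives 0.39 and 0.53). Ranges are
theoretical, never estimated from data, so dissimilarities are stable
as the knowledge base grows.

Burnout scores follow the Copenhagen Burnout Inventory: personal
(0–31.5), work-related (0–37) and client-related (0–31.5) subdimensions
whose raw scores sum to the 0–100 total. All comparison and validity
logic runs on the *normalized* per-subdimension scale
(raw / subdomain-max × 100): the published validity examples quote
subdimension scores (e.g. personal 45) that exceed the raw subdomain
ranges, and the 5-point criterion is stated on a 0–100 scale, so the
normalized scale is the only consistent reading. Profiles carry the
subdimensions as normalized 0–100 variables (R = 100 in the
dissimilarity).

One known discrepancy in the published worked example: its sex row
prints contribution 1 for three pairs of matching codes, contradicting
the stated match → 0 rule. This implementation follows the stated rule.

## Similarity and ranking

Per-element dissimilarities (0/1 for categoricals, range-scaled absolute
difference for numericals, clipped to [0, 1]) are summed with unit
weight; no learned weighting exists in the described method beyond the
implicit 1/R scaling. A value outside its declared range at similarity
time contributes 1 and logs a warning rather than failing — validation
happens at ingest, and robustness is preferred at query time. Degenerate
(zero-range) variables fall back to the equality rule. Ties in the
ranking are broken by the earliest insertion index, which makes every
recommendation deterministic and auditable.

## Validity screening

A program stage is valid iff exactly one subdimension's normalized
reduction is ≥ 5 (a reduction of exactly 5 counts). Multiple 5-point
reductions are classified `multi_dimension` (improvement attributed to
other causes); none, `insufficient_reduction`. Worsening elsewhere does
not affect the rule — the literal criterion counts only ≥ 5 reductions.
The effective subdimension is not required to equal the participant's
dominant subdimension.

## Recommendation

Stage 1 filters valid records to those whose effective subdimension
equals the new user's dominant subdimension (ties between subdimensions
resolve work > client > personal, consistent with the published
verification anecdote; configurable), then returns the program of the
least-dissimilar record. An empty filtered set falls back to the whole
knowledge base; an empty knowledge base falls back to a configurable
cold-start preallocation (personal → mindfulness, work → storytelling,
client → ACT, fallback order laughter → mindfulness → storytelling →
ACT — the deployed preallocation map was never published, so this is a
package default, not a reconstruction). Stage 2 repeats the procedure on
the posttest-1 profile over the three remaining programs, using the
stage-2 variable subset (demographics, work characteristics, burnout).

The engine is exposed as a scikit-learn-style estimator
(`ProgramRecommender.fit/partial_fit/predict`) whose fitted state is the
knowledge base; the module functions wrap it. The component sometimes
described in this literature as a learning "neural network" is, as
specified, a similarity search over accumulating valid data — no
architecture, loss or training step exists, and none is implemented.

## Simulator

`CohortSpec` declares marginals (category proportions, or mean/SD with
clipping to the variable's range), a per-program response model, an
optional subgroup-heterogeneity block, and a satisfaction model.

The default spec reproduces the published cohort: age 32.81 (SD 5.754),
97.7 % female, the printed marital/position/hospital-size/department/
overtime/shift distributions, clinical experience drawn in months
(95.83, SD 69.66) and banded, turnover intention 4.88 (SD 2.53), job
stress 88.39 (12.65), stress response 42.00 (17.95), coping 70.25
(9.66), and pretest burnout subdimensions 20.40/22.22/19.72 (raw). The
coping subscales scatter around a third of the sampled total; the
reserved slots are constant 0 and contribute nothing to dissimilarity.

Responses are normal draws of per-subdimension reductions on the
normalized scale, truncated so post-scores stay in [0, 100]. The means
come from the published per-program table; the key calibration fact is
that those per-subdimension values, weighted by the subdomain maxima
(0.315, 0.37, 0.315), sum exactly to the published total-scale effects
(e.g. ACT: 4.9·0.315 + 6.4·0.37 + 12.7·0.315 = 7.9), which ties the
response model to the validity threshold's scale. The printed
parenthetical values are used as draw SDs; the source table is ambiguous
about their meaning (they can also be read as percentage reductions) and
prints no other spread for the changes, so normal draws with these SDs
are an explicit modeling choice. Under the defaults roughly 40 % of
simulated stages are valid, close to the published 45.7 %.
Stage 2 reuses the same response model on posttest-1 scores; no
stage-specific effects are modeled. Satisfaction is
`round(clip(N(4.6 + 0.3·match, 0.6), 1, 5))`, calibrated so grand means
sit in the published 4.5–4.7 band; `match` means the assigned program is
the participant's subgroup-best. Dropout is off by default (an optional
uniform rate exists; the deployment mechanism was not described).

Two control scenarios ship alongside the calibrated default.
`structured_cohort_spec` is the positive control: weak identical base
effects (0.5 ± 2.5 normalized points), 20 uniformly sampled
department × shift strata, each assigning three of the four programs to
distinct burnout subdimensions (+14 points on the designated
subdimension for whoever receives the program; one program per stratum
is inert), and per-stratum mean shifts on six numerical covariates so
strata are identifiable in the profile metric. Departments and shifts
are sampled uniformly here — under the real cohort's 57 %-one-department
skew a majority-class prior masquerades as learning and the
subgroup-match control is uninterpretable. `homogeneous_cohort_spec` is
the negative control: all four programs share one response model.

`run_closed_loop_trial` replays the sequential deployment: sample
pretest → stage-1 recommendation → simulated response → validity screen
→ knowledge-base append → stage-2 recommendation (stage-1 program
excluded) → response → screen → append. All randomness flows from one
seeded generator, so a seed fixes the entire trial bit-for-bit.

## What the simulation controls show — and what they do not

With subgroup structure, the similarity policy's late-cohort rate of
assigning each participant's subgroup-best program is ≈ 0.49, against
the 0.25 chance baseline and ≈ 0.24 for the random policy (20 seeded
replicates, n = 300, pilot-seeded knowledge base). With homogeneous
responses the similarity and random policies are statistically
indistinguishable. Both controls behave as designed.

The published trial additionally reported a small negative Spearman
correlation (r = −0.138) between participation order and the stage-2
burnout change — later participants improved more, read as evidence of
ongoing optimization. Extensive instrumented simulation shows the
engine, as specified, does not reproduce a sustained trend of that kind
under stationary cohorts: mean stage-2 order correlation over 20
replicates is +0.007 (SE 0.011) in the structured scenario and −0.010
(SE 0.015) in the calibrated default. The mechanics are instructive.
When an eligible record with the right stratum and effective
subdimension exists, the nearest-record search finds it about 90 % of
the time, so allocation quality is limited by record *supply*, not
search. Supply, however, is generated by the engine's own allocations,
and the deterministic exploit-only loop exhibits rich-get-richer
fixation per dominant-subdimension bin — often collapsing to two of the
four programs within the first few dozen participants — after which
allocation quality is flat in participation order. Improving stage-1
allocation also actively starves stage 2, because the stage-1 program is
excluded there. Reproducing the published order effect in simulation
would require an exploration mechanism the described algorithm does not
have, or a nonstationary scenario; the corresponding acceptance test
asserts the direction faithfully and is expected to fail, documenting
the finding rather than masking it. The pilot phase (10 cold-start
participants) is always used to seed control experiments — without it
the collapse can occur before any program diversity enters the base.

## Evaluation

Paired pre/post comparisons use the two-sided paired *t* test;
zero-variance difference vectors return a flagged degenerate result
(t = 0 when scores are identical) instead of an infinite statistic.
Order effects use Spearman rank correlation (participation order is
ordinal); constant inputs raise. The satisfaction trend uses one-way
ANOVA over consecutive-hundred participant groups with Scheffé
simultaneous pairwise contrasts, computed from the ANOVA mean square
(`F_pair = (m_i − m_j)² / (MSW (1/n_i + 1/n_j) (k − 1))` against
F(k−1, N−k)); Scheffé is hand-implemented because the surrounding
libraries do not expose it. Significance thresholds are report
parameters, never hard-coded. The trial report also prints skewness and
kurtosis of the change scores as normality descriptives, without gating
any test on them.

## Limitations

- Real trial data are not available; every empirical statement above is
  about the simulator, whose response model is calibrated only to
  published group-level means. Passing tests show the engine implements
  the specified procedure and behaves sensibly under controlled
  synthetic conditions — not that the intervention works.
- The simulator draws independent normal responses; real burnout
  trajectories have measurement error, regression to the mean,
  and time effects that are not modeled.
- The engine itself has no exploration and inherits the fixation
  dynamics described above; that is a faithful property of the
  specified algorithm, not of this implementation.
- The cold-start preallocation map and the stage-2 variable subset are
  defaults standing in for unpublished deployment choices; both are
  configurable.
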