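# burnoutrec

A tailored intervention-recommendation engine for nurse burnout, with a
synthetic-cohort simulator and trial evaluation tools.

Nurse burnout is measured on the Copenhagen Burnout Inventory (CBI) in
three subdimensions — personal (0–31.5), work-related (0–37) and
client-related (0–31.5), summing to a 0–100 total. Mobile mind-body
interventions (mindfulness meditation, storytelling and reflective
writing, laughter therapy, acceptance and commitment therapy) help, but
different nurses respond to different programs. `burnoutrec` implements
the recommendation engine behind that kind of adaptive, single-arm
deployment: it picks a program for each new participant by finding the
most similar previous participant for whom a program demonstrably
worked, and it keeps learning as participants complete programs.

The package is for methodologists and engineers who want to study,
stress-test or extend this class of user-based nearest-neighbor
intervention engines — the real trial data are not public, so a
calibrated simulator stands in for the cohort.

## The method

**Profile dissimilarity.** Participants are described by 5 categorical
and 17 numerical variables (demographics, work characteristics, job
stress, stress response, coping, burnout subdimensions). The
dissimilarity between an existing user *i* and a new user *j* is a
Gower-style unit-weighted sum over variables *k*:

- categorical: `d_ijk = 0` if the codes match, `1` otherwise;
- numerical: `d_ijk = |x_ik − x_jk| / R_k`, where `R_k` is the
  variable's theoretical range, clipped to [0, 1].

Totals therefore lie in [0, 22] for the default schema; smaller is more
similar.

**Valid data.** A completed two-week program counts as *valid* evidence
iff exactly one CBI subdimension dropped by ≥ 5 points on the
normalized 0–100 scale. Two or more 5-point drops are attributed to
outside causes; none means the program did not work. Valid records
(profile, program, effective subdimension) accumulate in an append-only
knowledge base.

**Two-stage recommendation.** At pretest the engine recommends 1 of 4
programs: it filters the knowledge base to records whose effective
subdimension matches the new user's dominant (highest) burnout
subdimension, then returns the program of the least-dissimilar record
(fallback to the unfiltered base; cold-start preallocation when the
base is empty). After posttest 1 the procedure repeats over the 3
remaining programs using the updated burnout scores.

**Simulator and evaluation.** `CohortSpec` generates cohorts matching
the published participant table (mean age 32.81, 97.7 % female, …) and
simulates program responses whose expected total reductions match the
published program effects (laughter 5.4, storytelling 4.6, ACT 7.9,
mindfulness 2.6 points). `run_closed_loop_trial` replays the full
sequential deployment under interchangeable policies (similarity,
random, fixed, oracle), and the evaluation module provides the trial's
statistics: paired *t* tests, Spearman correlation of score change with
participation order, and one-way ANOVA with Scheffé post hoc on
satisfaction.

## Worked example

```python
import burnoutrec as br

# the element rules on the published worked example
br.categorical_element_dissimilarity(1, 3)   # marital status 1 vs 3 -> 1.0
br.numerical_element_dissimilarity(3, 5, 4)  # hospital size 3 vs 5, R=4 -> 0.5

# a full closed-loop simulated deployment, 300 participants
spec = br.default_cohort_spec(300)
trial = br.run_closed_loop_trial(spec, policy="similarity", seed=42)
report = br.summarize_trial(trial)
```

With seed 42 this prints (via the snippet in the docstrings):

```
stage 1: 62.03 -> 57.30  t=17.387  p=2.82e-47
stage 2: 57.30 -> 51.93  t=18.090  p=6.35e-50
valid records: 241
```

Reading: the simulated cohort's mean total burnout drops from 62.0 to
57.3 after the first program and to 51.9 after the second (paired *t*
statistics as shown), and 241 of the 600 program stages met the
single-subdimension 5-point validity criterion and entered the
knowledge base.

The same engine is scriptable from the shell:

```bash
burnoutrec replay --seed 42 --pilot-n 10 --n 300 --out trial.csv
burnoutrec evaluate --trial trial.csv --report report.json
burnoutrec recommend --kb kb.jsonl --profile new.json --stage 1 --audit
```

`recommend --audit` and the `similarity` subcommand print the full
ranked candidate table with per-element contributions, reproducing the
manual verification a trial team would do by hand.

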