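# Methods

`pancbn` implements a prognostic Bayesian network for resectable pancreatic
ductal adenocarcinoma (PDAC).  The outcome modelled is *poor prognosis*:
death within 12 months of resection.  The pipeline has four stages —
evidence-weight synthesis, ranked-node network construction, exact inference
under missing data, and ROC/AUC validation — plus a synthetic-data module
that generates every input the pipeline consumes.

## 1. Evidence synthesis

The model's parameters come not from one cohort but from a body of published
multivariate survival analyses.  For each candidate variable *i* extracted
from that literature:

- **Original weight** `w°ᵢ = Pᵢ / Nᵢ`, where `Nᵢ` is the number of studies
  that entered the variable into multivariate analysis and `Pᵢ` the number in
  which it was significantly associated with poor prognosis.  This summarizes
  the evidence including conflicting findings.
- **Normalized weight** `wᵢ = w°ᵢ · (pwᵢ / ps)`, where `pwᵢ` is the summed
  population of the studies reporting the variable and `ps` the summed
  population of all studies in the pool.  A variable supported only by small
  studies is discounted relative to one supported by large ones.

Both weights live in [0, 1] and `wᵢ ≤ w°ᵢ` always.  Variables are ranked by
normalized weight; ties are broken by larger reporting population, then
lexicographically — a deterministic rule, since the ranking feeds directly
into model structure.  Variables never included in any study are dropped
rather than carried at weight zero, so ranks remain a permutation of 1..K.
Some published presentations of this normalization write the two population
quantities with a `max(·)` notation while defining them in prose as sums;
this package implements the sum reading by default and exposes
`normalization="population-max"` for the literal-max alternative.

Significance flags are taken as given in the extraction (the criterion used
at extraction time was P < 0.005); the module never recomputes p-values.

## 2. Network construction

The network is a fixed three-layer DAG: 25 ranked prognostic variables (root
nodes) → 7 category child nodes (Inflammatory Markers, Tumour Markers,
Tumour Factors, Patient Factors, Neoadjuvant Response, Pathology, Adjuvant)
→ one Boolean output node (*Poor Prognosis*).  The pre-operative model uses
the 16 variables knowable before surgery; the post-operative model adds the
9 pathology/adjuvant variables for prognostic updating, leaving the shared
sub-network unchanged (pure augmentation).

Each ranked node's ordered states (low-risk → high-risk) are mapped to the
midpoints of an equal-width partition of [0, 1]: k states get scale values
(j + ½)/k.  This is the standard symmetric ranked-node scale.  Risk
orderings are curated per variable in the shipped YAML (e.g. `R0 Resection:
Yes` is low-risk, `Albumin: Low` is high-risk); they are fully
user-editable.  T stage is treated as pre-operative (imaging T stage) so the
pre-operative model carries a tumour-stage signal; AJCC stage, which needs
nodal pathology, is post-operative.

A child node's conditional distribution, for each joint parent state
configuration, is a doubly truncated Normal on [0, 1]:

- **mean** = weighted mean of the parents' scale values, weights = the
  parents' normalized evidence weights;
- **variance** = `base_variance / Σ weights` (see below);
- the density is discretized over the child's equal-width intervals
  (5 states by default; granularity configurable).

The output node is Boolean: `P(yes | groups)` is the truncated-Normal upper
tail above the classification threshold (0.5), with mean the weighted mean
of the group scale values and group weights the sums of their members'
weights.  Because a truncated Normal with fixed variance is stochastically
increasing in its mean, the construction is *risk-monotone by design*:
raising any single observed variable to a higher-risk state can never lower
the posterior probability of a poor outcome.  This is verified exhaustively
in the tests.

**Variance scale.**  The inverse-weight-sum shape (more corroborating
evidence → tighter conditional) is kept, but the scale matters: with
normalized weights bounded by 1, a raw `1/Σw` gives standard deviations near
1 on a unit interval, leaving children nearly independent of their parents
and the whole model uninformative (end-to-end P(poor) confined to
[0.48, 0.52]).  The default `base_variance = 0.05` places the compiled
default model's self-validation discrimination in the AUC 0.65–0.85 band
typical of clinical prognostic models.  It was fixed once, from a coarse
sweep of {0.02, 0.05, 0.1, 0.2}, and is configurable per spec
(`base_variance`, `variance_rule: fixed`, per-node `variance_overrides`).

**Priors.**  Root nodes carry uniform priors over their states.  With the
symmetric scale mapping this makes the no-evidence prediction exactly
P(poor) = 0.5 — an agnostic baseline; predictions move away from it only as
evidence accumulates.  Empirical cohort-frequency priors can be substituted
by editing the compiled network's root factors.

**Default weights.**  Published sources for this model report the variable
*ranking* but not the weights themselves, and the underlying study
extraction is private.  The shipped default therefore derives its weights
from a deterministic synthetic study table
(`pancbn.synthetic.reference_study_table`) built backwards from the
published rank order: 25 equally sized studies all reporting all variables,
with the rank-r variable significant in 26 − r of them, giving normalized
weight (26 − r)/25 — strictly decreasing, rank-faithful, and transparent.
Supplying a real extraction CSV replaces this entirely.

## 3. Inference and missing data

Exact inference uses variable elimination over dense named-axis factors,
with a greedy min-degree elimination order (ties broken lexicographically
for determinism).  The default networks (22 and 33 nodes, ≤5 states) solve
in ~1–3 ms per query.  Missing data needs no imputation: unobserved nodes
are marginalized out, so the posterior is defined for any evidence subset,
and with no evidence at all the prediction is the model prior.  Evidence
with probability zero under the model raises a typed error rather than
propagating NaN into downstream AUCs.  A full-joint enumeration oracle
(capped at 10⁶ joint states) backs the test suite; every posterior is
checked against it to 1e-9 on enumerable networks.

## 4. Prediction and classification

A patient record maps variables to observed state labels.  Pre-operative
prediction encodes only pre-operative variables; prognostic updating re-runs
the posterior on the post-operative network with pathology and adjuvant
evidence added.  A posterior probability of poor prognosis **≥ 0.5**
(boundary inclusive) classifies the patient as predicted poor prognosis.
Patients found unresectable at operation carry no pathology: they are
encoded with all post-operative variables missing and are excluded from
post-operative validation, while remaining in pre-operative validation.

## 5. Validation

Outcome labelling at the 12-month horizon: died within 12 months → poor;
survival beyond 12 months (dead or alive) → not poor; alive with follow-up
inside the horizon, or survival unknown → excluded (censored before the
horizon cannot be labelled either way).

Discrimination is the AUC, i.e. the Mann–Whitney concordance
P(score_poor > score_not-poor) + ½P(tie).  Inference on the AUC uses the
DeLong structural-components variance with a Wald 95% CI clipped to [0, 1]
and a two-sided test against AUC = 0.5; DeLong is deterministic and the
standard nonparametric choice.  Degenerate variance (perfect separation or
all ties) produces a warning and a collapsed CI, not a crash.

Stratified validation reproduces the cumulative missing-data design: each
stratum admits patients with at most k missing data points per phase, so
strata are nested and n is non-decreasing as the bound loosens.
Cohort-wide absent variables (e.g. tumour markers never assayed) count in
every patient's missing tally.

## 6. Synthetic data

- `simulate_study_table` draws per-study inclusion and significance flags
  from configured probabilities; empirical P/N ratios converge to the truth
  as studies accumulate (binomial).
- `simulate_cohort` forward-samples patients ancestrally from a compiled
  network.  The sampled output state fixes the outcome: "yes" → died, with
  survival uniform on (0, 12]; "no" → survival 12 + Exp(mean 12) months,
  alive at last follow-up with probability 0.4.  The within-class survival
  times are nuisance draws, *not* a clinical survival model — only the
  binary horizon matters to the pipeline.  Masking is applied after the
  outcome is assigned, so missingness never biases labels.
- All generators use numpy's seeded PCG64; identical seeds give
  byte-identical outputs.

What the simulator deliberately does not emulate: correlation between risk
factors beyond the network's own structure, informative missingness,
realistic survival-time shapes, and measurement error in state assignment.
Self-consistency results (the model predicting data sampled from itself)
therefore demonstrate internal correctness — inference, encoding, and the
validation machinery — and upper-bound, not estimate, performance on real
cohorts.

## Problem sizes used in the shipped checks

The self-consistency study uses 2,000-patient cohorts over 5 seeds at
masking levels {0, 3, 6, 9} on the pre-operative network; inference
exactness is checked on 200 random ≤6-node networks; AUC code on inputs up
to n = 500 against an O(n²) oracle; DeLong coverage on 500 binormal
replicates at n = 200.  These sizes give stable medians and tight Monte
Carlo error while keeping the default test run fast.

## Known limitations

- The default weights are rank-faithful but synthetic in magnitude (see
  §2); absolute probabilities from the default model should not be read
  clinically.
- The output node takes the category child nodes as parents; reading the
  construction as all 25 variables feeding the output directly is possible
  but explodes the output NPT (≈10¹⁰ cells) and is not implemented.
- Structure is declared, not learned; the package deliberately contains no
  structure-learning code.
- Continuous-node inference and approximate inference are out of scope; the
  exact engine is ample at this scale.
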