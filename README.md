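# pancbn

A prognostic Bayesian network for resectable pancreatic ductal
adenocarcinoma (PDAC).  The package predicts **poor prognostic outcome** —
death within 12 months of resection — for individual patients, makes the
prediction *pre-operatively*, updates it *post-operatively* once pathology
and adjuvant-therapy information exist, and keeps working under arbitrary
missing data by probabilistic inference rather than imputation.

It is aimed at clinical-modelling researchers who want a transparent,
fully inspectable alternative to black-box survival models: every
conditional probability in the network is generated from published
evidence weights by a closed-form rule, and every stage (evidence
synthesis → network construction → inference → validation) is a plain
Python API with a thin CLI on top.

## The model

1. **Evidence synthesis.**  Each candidate prognostic variable *i* is
   weighted from a table of published multivariate survival analyses:
   original weight `w°ᵢ = Pᵢ/Nᵢ` (significant findings over inclusions) and
   normalized weight `wᵢ = w°ᵢ · pwᵢ/ps` (scaled by the population share of
   the studies reporting the variable).  Variables are ranked by `wᵢ`; the
   top 25 build the network.
2. **Ranked-node network.**  Variables are root nodes grouped under
   category child nodes (Inflammatory Markers, Tumour Factors, Pathology,
   …) that feed a Boolean output node.  Ordered states map to the unit
   interval; each child's conditional table is a truncated Normal
   TNormal(μ, σ²) on [0, 1] with μ the weight-weighted mean of parent scale
   values and σ² = base_variance/Σw, discretized over the child's
   intervals.  The output P(poor) is the TNormal mass above 0.5.
3. **Inference.**  Exact variable elimination; unobserved variables are
   marginalized out, so any evidence subset yields a valid posterior.
   A posterior ≥ 0.5 classifies the patient as predicted poor prognosis.
4. **Validation.**  Outcomes are labelled at the 12-month horizon, and
   discrimination is summarized as the ROC AUC with DeLong standard errors,
   95% CIs, and tests against AUC = 0.5, stratified by per-patient
   missing-data burden.

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

```python
from pancbn import PatientRecord, default_networks, prognostic_update

pre_net, post_net = default_networks()

patient = PatientRecord(
    "example-1",
    observations={
        "mGPS": "2", "Albumin": "Low", "Tumour Size": ">2cm", "T Stage": "T3",
        "Age": ">70", "Performance Status": "Moderate", "Jaundice": "Yes",
        "Lymph Node Positive": "Yes", "Tumour Grade": "G3/G4",
        "R0 Resection": "No", "Adjuvant Therapy": "No",
    },
)
pre, post = prognostic_update(pre_net, post_net, patient)
print(pre.probability_poor, post.probability_poor)
```

prints (see `examples/02_predict_patient.py`):

```
pre-operative  P(death within 12 months) = 0.797 (classified poor: True, 9 pre-op gaps)
post-operative P(death within 12 months) = 0.882 (classified poor: True, 5 post-op gaps)
```

The pre-operative posterior 0.797 uses only the 7 observed pre-operative
findings (tumour markers and the rest are marginalized out); adding the
adverse pathology raises it to 0.882.  Both exceed the 0.5 threshold, so
the patient is classified predicted-poor-prognosis in both phases.

The other scripts in `examples/` show variable ranking from a study table,
graceful degradation toward the prior P(poor) = 0.5 as observations are
removed one by one, and a stratified AUC table on a simulated cohort.

The CLI mirrors the pipeline: `pancbn synthesize`, `build`, `predict`,
`update`, `validate`, `simulate studies|cohort`, and `pancbn run --config
run.yaml` for the whole chain.

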