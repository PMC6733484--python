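"""Prediction under increasing missing data.

The same high-risk patient is re-predicted as observations are removed one
at a time.  With no evidence at all the prediction falls back to the model
prior — missing data shrinks predictions toward the population average
rather than breaking them.
"""

from pancbn import PatientRecord, default_networks, predict

pre_net, _ = default_networks()

observations = {
    "mGPS": "2",
    "Albumin": "Low",
    "Neutrophil Lymphocyte Ratio": ">5",
    "Tumour Size": ">2cm",
    "T Stage": "T4",
    "Jaundice": "Yes",
    "Age": ">70",
    "Performance Status": "Poor",
}

order = list(observations)
print(f"{'observed':>8}  {'P(poor)':>8}")
for k in range(len(order), -1, -1):
    kept = {v: observations[v] for v in order[:k]}
    result = predict(pre_net, PatientRecord("p", kept), "pre_operative")
    print(f"{k:>8}  {result.probability_poor:>8.3f}")
print(
    "\nEvery row is a valid posterior: unobserved nodes are marginalized out. "
    "With zero observations the prediction equals the prior P(poor) = 0.5."
)
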