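"""Pre-operative prediction and post-operative prognostic updating.

Builds the shipped default networks, enters one patient's pre-operative
findings, then updates the prediction once pathology is available.
Unobserved variables (here the tumour markers) are handled by
probabilistic inference — no imputation step is needed.
"""

from pancbn import PatientRecord, default_networks, prognostic_update

pre_net, post_net = default_networks()

patient = PatientRecord(
    "example-1",
    observations={
        # pre-operative picture: inflamed, locally advanced
        "mGPS": "2",
        "Albumin": "Low",
        "Tumour Size": ">2cm",
        "T Stage": "T3",
        "Age": ">70",
        "Performance Status": "Moderate",
        "Jaundice": "Yes",
        # post-operative pathology
        "Lymph Node Positive": "Yes",
        "Tumour Grade": "G3/G4",
        "R0 Resection": "No",
        "Adjuvant Therapy": "No",
    },
)

pre, post = prognostic_update(pre_net, post_net, patient)
print(f"pre-operative  P(death within 12 months) = {pre.probability_poor:.3f} "
      f"(classified poor: {pre.classified_poor}, {pre.n_missing_pre} pre-op gaps)")
print(f"post-operative P(death within 12 months) = {post.probability_poor:.3f} "
      f"(classified poor: {post.classified_poor}, {post.n_missing_post} post-op gaps)")
print(
    "\nAdding adverse pathology (node-positive, high grade, R1 margin, no "
    "adjuvant therapy) raises the posterior probability of a poor outcome; a "
    "probability of 0.5 or more classifies the patient as predicted poor prognosis."
)
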