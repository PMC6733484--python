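"""pancbn: prognostic Bayesian network for pancreatic cancer resection.

Predicts poor prognostic outcome — death within 12 months of resection of
pancreatic ductal adenocarcinoma — from a ranked-node Bayesian network
whose structure and weights are synthesized from published multivariate
survival analyses, with post-operative prognostic updating and exact
inference under arbitrary missing data.
"""

__version__ = "0.1.0"

from .errors import PancbnError
from .evidence import (
    StudyRecord,
    StudyTable,
    VariableEvidence,
    compute_normalized_weight,
    compute_original_weight,
    select_top_k,
    synthesize,
    weight_map,
)
from .network import (
    POST_OPERATIVE,
    PRE_OPERATIVE,
    CompiledNetwork,
    NetworkSpec,
    RankedVariable,
    TNormalParams,
    build_network,
    default_spec,
    discretize_truncated_normal,
    map_states_to_scale,
    weighted_mean,
)
from .inference import enumerate_joint, posterior_marginal
from .prediction import (
    PatientRecord,
    PredictionResult,
    classify,
    encode_patient,
    predict,
    prognostic_update,
    read_cohort,
    write_cohort,
)
from .validation import (
    OutcomeLabel,
    ROCResult,
    Stratum,
    auc_inference,
    compute_auc,
    label_outcome,
    stratified_validation,
)
from .synthetic import (
    CohortSimConfig,
    StudySimConfig,
    VariableSimSpec,
    mask_cohort,
    reference_study_table,
    simulate_cohort,
    simulate_study_table,
)


def default_networks() -> tuple[CompiledNetwork, CompiledNetwork]:
    """Compile the shipped default model: (pre-operative, post-operative).

    Weights come from the packaged synthetic reference study table, whose
    synthesis reproduces the published variable ranking.
    """
    spec = default_spec()
    evidence = synthesize(reference_study_table())
    return (
        build_network(spec, evidence, PRE_OPERATIVE),
        build_network(spec, evidence, POST_OPERATIVE),
    )
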