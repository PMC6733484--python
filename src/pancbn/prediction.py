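"""Patient-level prediction and post-operative prognostic updating.

A patient record maps observed variables to state labels; anything
unobserved is handled by probabilistic inference.  The pre-operative
prediction uses only pre-operative variables; prognostic updating re-runs
the posterior on the post-operative network with pathology and adjuvant
evidence added.  A posterior probability of poor prognosis of 50% or
greater classifies the patient as predicted poor prognosis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import RecordValidationError, SchemaError
from .inference import posterior_marginal
from .network import PRE_OPERATIVE, POST_OPERATIVE, CompiledNetwork

logger = logging.getLogger(__name__)

#: classification threshold: "50% or greater" probability of poor prognosis
POOR_PROGNOSIS_THRESHOLD = 0.5


def classify(probability_poor: float, threshold: float = POOR_PROGNOSIS_THRESHOLD) -> bool:
    """True iff the probability meets the threshold (boundary inclusive)."""
    return probability_poor >= threshold


@dataclass(frozen=True)
class PatientRecord:
    """One patient: observed variable states, survival, and vital status."""

    patient_id: str
    observations: Mapping[str, str] = field(default_factory=dict)
    survival_months: float | None = None
    alive: bool | None = None
    resected: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "observations",
            {k: v for k, v in dict(self.observations).items() if v is not None},
        )
        if self.survival_months is not None and self.survival_months < 0:
            raise RecordValidationError(
                f"patient {self.patient_id!r}: negative survival time {self.survival_months}"
            )
        if self.alive is not None and self.survival_months is None:
            raise RecordValidationError(
                f"patient {self.patient_id!r}: vital status without a survival time"
            )


@dataclass(frozen=True)
class PredictionResult:
    phase: str
    probability_poor: float
    classified_poor: bool
    n_missing_pre: int
    n_missing_post: int


def encode_patient(
    network: CompiledNetwork, record: PatientRecord, phase: str
) -> tuple[dict[str, str], int, int]:
    """Build the evidence map for one phase and tally missing data per phase.

    Only variables belonging to the requested phase enter the evidence
    (post-operative evidence is ignored, with a log line, when making a
    pre-operative prediction).  Variables unknown to the network are
    skipped with a warning; illegal state labels raise.
    """
    if network.spec is None:
        raise RecordValidationError("network carries no variable spec; cannot encode patients")
    spec = network.spec
    known = {v.name: v for v in spec.variables}
    phase_vars = {v.name for v in spec.phase_variables(phase)}

    evidence: dict[str, str] = {}
    for name, state in record.observations.items():
        if name not in known:
            logger.warning(
                "patient %s: unknown variable %r ignored", record.patient_id, name
            )
            continue
        if state not in known[name].states:
            raise RecordValidationError(
                f"patient {record.patient_id!r}: illegal state {state!r} for variable "
                f"{name!r} (legal: {list(known[name].states)})"
            )
        if name not in phase_vars:
            logger.debug(
                "patient %s: %r not in phase %s; dropped", record.patient_id, name, phase
            )
            continue
        if name in network.nodes:
            evidence[name] = state

    observed = set(evidence)
    n_missing_pre = sum(
        1 for v in spec.phase_variables(PRE_OPERATIVE) if v.name not in observed
    )
    n_missing_post = sum(
        1
        for v in spec.variables
        if v.phase == POST_OPERATIVE and v.name not in observed
    )
    return evidence, n_missing_pre, n_missing_post


def predict(
    network: CompiledNetwork, record: PatientRecord, phase: str | None = None
) -> PredictionResult:
    """Posterior probability of poor prognosis for one patient."""
    phase = phase or network.phase
    if phase == POST_OPERATIVE and network.phase == PRE_OPERATIVE:
        raise RecordValidationError(
            "post-operative prediction requested on a pre-operative network"
        )
    evidence, n_missing_pre, n_missing_post = encode_patient(network, record, phase)
    posterior = posterior_marginal(network, network.output_name, evidence)
    yes_index = network.state_index(network.output_name, "yes")
    p_poor = float(posterior[yes_index])
    return PredictionResult(
        phase=phase,
        probability_poor=p_poor,
        classified_poor=classify(p_poor, network.threshold),
        n_missing_pre=n_missing_pre,
        n_missing_post=n_missing_post,
    )


def prognostic_update(
    pre_network: CompiledNetwork,
    post_network: CompiledNetwork,
    record: PatientRecord,
) -> tuple[PredictionResult, PredictionResult]:
    """Pre-operative prediction plus its post-operative update for one patient."""
    pre = predict(pre_network, record, PRE_OPERATIVE)
    post = predict(post_network, record, POST_OPERATIVE)
    return pre, post


# ------------------------------------------------------------------ cohort I/O
_META_COLUMNS = ("patient_id", "survival_months", "alive", "resected")


def _parse_bool(value) -> bool | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, (bool,)):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1", "yes", "t"):
        return True
    if text in ("false", "0", "no", "f"):
        return False
    if text == "":
        return None
    raise SchemaError(f"cannot parse boolean value {value!r}")


def read_cohort(path: str | Path, variables: Sequence[str] | None = None) -> list[PatientRecord]:
    """Read a cohort CSV: one row per patient, one column per variable.

    Empty cells are missing observations.  ``variables`` (when given)
    restricts which columns are treated as observations; otherwise every
    non-metadata column is.
    """
    try:
        df = pd.read_csv(path, comment="#", dtype=str)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise SchemaError(f"cannot parse cohort {path}: {exc}") from exc
    missing_cols = {"patient_id", "survival_months", "alive"} - set(df.columns)
    if missing_cols:
        raise SchemaError(f"cohort is missing columns {sorted(missing_cols)}")
    var_columns = [
        c
        for c in df.columns
        if c not in _META_COLUMNS and (variables is None or c in variables)
    ]
    records = []
    for _, row in df.iterrows():
        observations = {
            c: row[c]
            for c in var_columns
            if isinstance(row[c], str) and row[c].strip() != ""
        }
        survival = row["survival_months"]
        survival_months = float(survival) if isinstance(survival, str) and survival else None
        alive = _parse_bool(row["alive"])
        resected = _parse_bool(row.get("resected", "true"))
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                observations=observations,
                survival_months=survival_months,
                alive=alive,
                resected=True if resected is None else resected,
            )
        )
    return records


def write_cohort(
    records: Iterable[PatientRecord], path: str | Path, variables: Sequence[str]
) -> None:
    rows = []
    for r in records:
        row = {"patient_id": r.patient_id}
        for v in variables:
            row[v] = r.observations.get(v, "")
        row["survival_months"] = "" if r.survival_months is None else r.survival_months
        row["alive"] = "" if r.alive is None else r.alive
        row["resected"] = r.resected
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def predictions_to_frame(
    records: Sequence[PatientRecord], results: Sequence[PredictionResult]
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": rec.patient_id,
                "phase": res.phase,
                "probability_poor": res.probability_poor,
                "classified_poor": res.classified_poor,
                "n_missing_pre": res.n_missing_pre,
                "n_missing_post": res.n_missing_post,
            }
            for rec, res in zip(records, results)
        ]
    )
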