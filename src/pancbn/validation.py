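"""Model validation: outcome labelling, ROC/AUC, DeLong CIs, missing-data strata.

A patient is a *poor prognosis* case when death occurred within 12 months
of resection; survival beyond 12 months (dead or alive) is *not poor*;
patients still alive inside the horizon, or without survival data, cannot
be labelled and are excluded.  Discrimination is summarised by the AUC
(Mann-Whitney concordance, ties at half credit) with DeLong variance for
confidence intervals and a two-sided test against AUC = 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

from .errors import RecordValidationError, UndefinedAUCError
from .network import PRE_OPERATIVE, POST_OPERATIVE, CompiledNetwork
from .prediction import PatientRecord, PredictionResult, predict

#: outcome horizon in months
HORIZON_MONTHS = 12.0

LABEL_POOR = "poor"
LABEL_NOT_POOR = "not_poor"
LABEL_EXCLUDED = "excluded"


@dataclass(frozen=True)
class OutcomeLabel:
    label: str
    reason: str = ""


@dataclass(frozen=True)
class ROCResult:
    auc: float
    std_error: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


def label_outcome(record: PatientRecord, horizon: float = HORIZON_MONTHS) -> OutcomeLabel:
    """Poor prognosis = died within the horizon; censored inside it = excluded."""
    if record.survival_months is None:
        return OutcomeLabel(LABEL_EXCLUDED, "no survival data recorded")
    if record.survival_months < 0:
        raise RecordValidationError(
            f"patient {record.patient_id!r}: negative survival {record.survival_months}"
        )
    if record.survival_months > horizon:
        return OutcomeLabel(LABEL_NOT_POOR)
    if record.alive is None:
        return OutcomeLabel(LABEL_EXCLUDED, "vital status unknown within the horizon")
    if record.alive:
        return OutcomeLabel(
            LABEL_EXCLUDED, f"alive with follow-up within {horizon:g} months"
        )
    return OutcomeLabel(LABEL_POOR)


def compute_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """AUC as the Mann-Whitney concordance P(score_pos > score_neg) + P(tie)/2."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        raise UndefinedAUCError("AUC undefined: only one outcome class present")
    return float(roc_auc_score(labels, scores))


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (1-based), ties averaged."""
    order = np.argsort(x, kind="mergesort")
    sorted_x = x[order]
    n = len(x)
    ranks = np.empty(n, dtype=float)
    i = 0
    while i < n:
        j = i
        while j < n and sorted_x[j] == sorted_x[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n, dtype=float)
    out[order] = ranks
    return out


def delong_variance(scores: Sequence[float], labels: Sequence[int]) -> tuple[float, float]:
    """(AUC, DeLong variance of the AUC estimator)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise UndefinedAUCError("AUC undefined: only one outcome class present")
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n          # structural components for positives
    v01 = 1.0 - (tz[m:] - ty) / m    # and for negatives
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(auc), float(s10 / m + s01 / n)


def auc_inference(
    scores: Sequence[float], labels: Sequence[int], alpha: float = 0.05
) -> ROCResult:
    """AUC with DeLong standard error, Wald CI (clipped to [0,1]) and p vs 0.5."""
    auc, variance = delong_variance(scores, labels)
    se = float(np.sqrt(max(variance, 0.0)))
    labels_arr = np.asarray(labels, dtype=int)
    n = int(len(labels_arr))
    if se == 0.0:
        warnings.warn(
            "degenerate DeLong variance (perfect separation or all ties); "
            "confidence interval collapses",
            RuntimeWarning,
            stacklevel=2,
        )
        p = 1.0 if auc == 0.5 else 0.0
        return ROCResult(auc=auc, std_error=0.0, ci_low=auc, ci_high=auc, p_value=p, n=n)
    z = norm.ppf(1.0 - alpha / 2.0)
    ci_low = max(0.0, auc - z * se)
    ci_high = min(1.0, auc + z * se)
    p_value = float(2.0 * norm.sf(abs(auc - 0.5) / se))
    return ROCResult(auc=auc, std_error=se, ci_low=ci_low, ci_high=ci_high, p_value=p_value, n=n)


# ---------------------------------------------------------------- strata
@dataclass(frozen=True)
class Stratum:
    """A cumulative missing-data stratum: patients with at most the given gaps."""

    name: str
    max_missing_pre: int | None = None
    max_missing_post: int | None = None


def stratified_validation(
    network: CompiledNetwork,
    cohort: Sequence[PatientRecord],
    strata: Sequence[Stratum],
    phase: str | None = None,
    horizon: float = HORIZON_MONTHS,
) -> pd.DataFrame:
    """One AUC row per cumulative missing-data stratum (the Tables 2-3 design).

    Patients are first outcome-labelled; excluded patients never enter any
    stratum.  For post-operative validation, unresected patients (no
    pathology possible) are excluded as well.  Each stratum keeps patients
    whose per-phase missing counts are within its bounds; loosening a bound
    can only grow the stratum.
    """
    phase = phase or network.phase
    labelled: list[tuple[PatientRecord, PredictionResult, int]] = []
    for record in cohort:
        outcome = label_outcome(record, horizon)
        if outcome.label == LABEL_EXCLUDED:
            continue
        if phase == POST_OPERATIVE and not record.resected:
            continue
        result = predict(network, record, phase)
        labelled.append((record, result, 1 if outcome.label == LABEL_POOR else 0))

    rows = []
    for stratum in strata:
        members = [
            (res.probability_poor, y)
            for _, res, y in labelled
            if (stratum.max_missing_pre is None or res.n_missing_pre <= stratum.max_missing_pre)
            and (
                stratum.max_missing_post is None
                or res.n_missing_post <= stratum.max_missing_post
            )
        ]
        row: dict[str, object] = {"stratum": stratum.name, "n": len(members)}
        scores = [s for s, _ in members]
        ys = [y for _, y in members]
        if len(members) >= 2 and len(set(ys)) == 2:
            roc = auc_inference(scores, ys)
            row.update(
                auc=roc.auc,
                se=roc.std_error,
                p_value=roc.p_value,
                ci_low=roc.ci_low,
                ci_high=roc.ci_high,
            )
        else:
            row.update(auc=np.nan, se=np.nan, p_value=np.nan, ci_low=np.nan, ci_high=np.nan)
        rows.append(row)
    return pd.DataFrame(rows, columns=["stratum", "n", "auc", "se", "p_value", "ci_low", "ci_high"])


def strata_from_bounds(
    bounds: Iterable[Mapping[str, object]]
) -> list[Stratum]:
    """Build strata from dicts like {"name": ..., "max_missing_pre": k, ...}."""
    out = []
    for b in bounds:
        out.append(
            Stratum(
                name=str(b.get("name", "stratum")),
                max_missing_pre=(
                    None if b.get("max_missing_pre") is None else int(b["max_missing_pre"])
                ),
                max_missing_post=(
                    None if b.get("max_missing_post") is None else int(b["max_missing_post"])
                ),
            )
        )
    return out
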