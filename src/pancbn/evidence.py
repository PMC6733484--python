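"""Two-stage weighting of literature evidence for prognostic variables.

Each candidate variable i is scored from an extracted-study table:

* **original weight**  ``w0_i = P_i / N_i`` — the fraction of multivariate
  survival analyses that included the variable in which it was significantly
  associated with poor prognosis,
* **normalized weight** ``w_i = w0_i * (pw_i / ps)`` — the original weight
  scaled by the share of the total synthesized patient population contributed
  by the studies that reported the variable (``pw_i`` = summed population of
  reporting studies, ``ps`` = summed population of all studies).

Both weights live on [0, 1]; variables are ranked by normalized weight.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import EmptySynthesisError, ExtractionError, SchemaError, UndefinedVariableError

logger = logging.getLogger(__name__)

#: legal extraction flags for one (study, variable) pair
STATUS_EXCLUDED = "excluded"            # not entered into the multivariate analysis
STATUS_INCLUDED = "included"            # entered, not significant
STATUS_SIGNIFICANT = "significant"      # entered and significant
_STATUSES = frozenset({STATUS_EXCLUDED, STATUS_INCLUDED, STATUS_SIGNIFICANT})

#: normalization denominators: prose reading (population sums) vs literal-max reading
NORM_SUM = "population-sum"
NORM_MAX = "population-max"


@dataclass(frozen=True)
class StudyRecord:
    """One study's extraction: population and per-variable inclusion flags."""

    study_id: str
    population: int
    variable_results: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.population < 1:
            raise ExtractionError(
                f"study {self.study_id!r}: population must be >= 1, got {self.population}"
            )
        bad = {s for s in self.variable_results.values() if s not in _STATUSES}
        if bad:
            raise ExtractionError(f"study {self.study_id!r}: unknown status flags {sorted(bad)}")
        if not any(s != STATUS_EXCLUDED for s in self.variable_results.values()):
            raise ExtractionError(
                f"study {self.study_id!r}: no variable was included in multivariate analysis"
            )

    def included(self, variable: str) -> bool:
        return self.variable_results.get(variable, STATUS_EXCLUDED) != STATUS_EXCLUDED

    def significant(self, variable: str) -> bool:
        return self.variable_results.get(variable) == STATUS_SIGNIFICANT


@dataclass(frozen=True)
class StudyTable:
    """An ordered collection of study records forming the evidence pool."""

    records: tuple[StudyRecord, ...]

    def __post_init__(self) -> None:
        ids = [r.study_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ExtractionError(f"duplicate study ids: {dupes}")
        if self.total_population <= 0:
            raise EmptySynthesisError("study table has zero total population")

    @property
    def variables(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for rec in self.records:
            for v in rec.variable_results:
                seen.setdefault(v, None)
        return tuple(seen)

    @property
    def total_population(self) -> int:
        return sum(r.population for r in self.records)

    # ---------------------------------------------------------------- I/O
    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "StudyTable":
        required = {"study_id", "population", "variable", "status"}
        missing = required - set(df.columns)
        if missing:
            raise SchemaError(f"study table is missing columns {sorted(missing)}")
        records = []
        for study_id, grp in df.groupby("study_id", sort=False):
            pops = grp["population"].unique()
            if len(pops) != 1:
                raise SchemaError(f"study {study_id!r}: conflicting population values {pops}")
            results = dict(zip(grp["variable"].astype(str), grp["status"].astype(str)))
            records.append(StudyRecord(str(study_id), int(pops[0]), results))
        return cls(tuple(records))

    @classmethod
    def from_csv(cls, path: str | Path) -> "StudyTable":
        try:
            df = pd.read_csv(path, comment="#")
        except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
            raise SchemaError(f"cannot parse study table {path}: {exc}") from exc
        return cls.from_frame(df)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"study_id": r.study_id, "population": r.population, "variable": v, "status": s}
            for r in self.records
            for v, s in r.variable_results.items()
        ]
        return pd.DataFrame(rows, columns=["study_id", "population", "variable", "status"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class VariableEvidence:
    """A variable's pooled evidence summary and its rank in the synthesis."""

    variable: str
    n_included: int
    n_significant: int
    reporting_population: int
    original_weight: float
    normalized_weight: float
    rank: int = field(default=0)

    def __post_init__(self) -> None:
        if not 0 <= self.n_significant <= self.n_included:
            raise ExtractionError(
                f"{self.variable}: significant count {self.n_significant} outside "
                f"[0, {self.n_included}]"
            )


def compute_original_weight(n_significant: int, n_included: int) -> float:
    """Fraction of multivariate analyses in which the variable was significant."""
    if n_included == 0:
        raise UndefinedVariableError("variable was never included in any multivariate analysis")
    if n_significant < 0 or n_significant > n_included:
        raise ExtractionError(
            f"significant count {n_significant} inconsistent with included count {n_included}"
        )
    return n_significant / n_included


def compute_normalized_weight(
    original_weight: float, reporting_population: int, total_population: int
) -> float:
    """Scale the original weight by the reporting-population share of the pool."""
    if total_population == 0:
        raise EmptySynthesisError("total population is zero")
    if reporting_population > total_population:
        raise ExtractionError(
            f"reporting population {reporting_population} exceeds total {total_population}"
        )
    if reporting_population < 0:
        raise ExtractionError(f"negative reporting population {reporting_population}")
    return original_weight * (reporting_population / total_population)


def synthesize(table: StudyTable, normalization: str = NORM_SUM) -> list[VariableEvidence]:
    """Weight and rank every variable with at least one inclusion.

    Variables never included in any study are dropped (with a logged warning)
    rather than carried at weight zero, so ranks remain a permutation of 1..K.
    Ties in normalized weight are broken by larger reporting population, then
    lexicographically by variable name.
    """
    if normalization not in (NORM_SUM, NORM_MAX):
        raise ValueError(f"unknown normalization mode {normalization!r}")
    if not table.records:
        raise EmptySynthesisError("empty study table")

    if normalization == NORM_SUM:
        denominator = table.total_population
    else:
        denominator = max(r.population for r in table.records)

    entries = []
    for variable in table.variables:
        including = [r for r in table.records if r.included(variable)]
        if not including:
            logger.warning("variable %r never included in any study; dropped", variable)
            continue
        n_included = len(including)
        n_significant = sum(r.significant(variable) for r in including)
        if normalization == NORM_SUM:
            reporting_population = sum(r.population for r in including)
        else:
            reporting_population = max(r.population for r in including)
        w0 = compute_original_weight(n_significant, n_included)
        wn = compute_normalized_weight(w0, reporting_population, denominator)
        entries.append(
            VariableEvidence(
                variable=variable,
                n_included=n_included,
                n_significant=n_significant,
                reporting_population=reporting_population,
                original_weight=w0,
                normalized_weight=wn,
            )
        )

    entries.sort(key=lambda e: (-e.normalized_weight, -e.reporting_population, e.variable))
    return [
        VariableEvidence(
            variable=e.variable,
            n_included=e.n_included,
            n_significant=e.n_significant,
            reporting_population=e.reporting_population,
            original_weight=e.original_weight,
            normalized_weight=e.normalized_weight,
            rank=i + 1,
        )
        for i, e in enumerate(entries)
    ]


def select_top_k(evidence: Sequence[VariableEvidence], k: int = 25) -> list[VariableEvidence]:
    """The k best-ranked variables, rank order preserved (clamped to the list)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ordered = sorted(evidence, key=lambda e: e.rank)
    if k > len(ordered):
        logger.warning("requested top %d of only %d ranked variables", k, len(ordered))
    return ordered[:k]


# ------------------------------------------------------------------ export
def evidence_to_frame(evidence: Iterable[VariableEvidence]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "variable": e.variable,
                "n_included": e.n_included,
                "n_significant": e.n_significant,
                "reporting_population": e.reporting_population,
                "original_weight": e.original_weight,
                "normalized_weight": e.normalized_weight,
                "rank": e.rank,
            }
            for e in evidence
        ]
    )


def write_evidence(evidence: Sequence[VariableEvidence], path: str | Path) -> None:
    """Write the synthesis as CSV or JSON depending on the file suffix."""
    path = Path(path)
    df = evidence_to_frame(evidence)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=2))
    else:
        df.to_csv(path, index=False)


def weight_map(evidence: Iterable[VariableEvidence]) -> dict[str, float]:
    """Variable -> normalized weight, as consumed by network construction."""
    return {e.variable: e.normalized_weight for e in evidence}
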