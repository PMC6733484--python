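"""Pipeline orchestration: synthesize -> build -> predict -> validate.

`run_pipeline` ties the library stages together from a single RunConfig,
writing each stage's artifact with a provenance header (tool version +
config hash) and failing fast — with a typed error and no partial output
for the failing stage — on malformed input.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigurationError, SchemaError
from .evidence import StudyTable, evidence_to_frame, select_top_k, synthesize, weight_map
from .network import PRE_OPERATIVE, POST_OPERATIVE, CompiledNetwork, NetworkSpec, default_spec
from .prediction import predict, predictions_to_frame, read_cohort
from .validation import Stratum, strata_from_bounds, stratified_validation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    study_table: str | None = None
    network_spec: str | None = None  # None -> shipped default topology
    cohort: str | None = None
    out_dir: str = "pancbn_out"
    top_k: int = 25
    threshold: float = 0.5
    normalization: str = "population-sum"
    strata: tuple[dict, ...] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.top_k < 1:
            raise ConfigurationError("top_k must be >= 1")
        if not 0.0 < self.threshold < 1.0:
            raise ConfigurationError("threshold must be in (0,1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        strata = tuple(data.pop("strata", ()) or ())
        try:
            return cls(strata=strata, **data)
        except TypeError as exc:
            raise ConfigurationError(f"bad run config {path}: {exc}") from exc

    def hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # output location does not affect content
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()
        return digest[:12]


def provenance_header(config_hash: str) -> str:
    return f"# pancbn {__version__} config_hash={config_hash}\n"


def write_frame(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_header(config_hash))
        df.to_csv(fh, index=False)


def default_strata(spec: NetworkSpec, phase: str) -> list[Stratum]:
    """Nested strata 0..K missing (per-phase), mirroring the cumulative design."""
    n_pre = len(spec.phase_variables(PRE_OPERATIVE))
    n_post = len(spec.variables) - n_pre
    bound = n_pre if phase == PRE_OPERATIVE else n_pre + n_post
    strata = []
    for k in range(bound + 1):
        if phase == PRE_OPERATIVE:
            strata.append(Stratum(name=f"<= {k} pre-operative missing", max_missing_pre=k))
        else:
            strata.append(
                Stratum(
                    name=f"<= {k} missing (any phase)",
                    max_missing_pre=min(k, n_pre),
                    max_missing_post=min(k, n_post),
                )
            )
    return strata


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every configured stage; returns the artifact paths written.

    Stages: evidence synthesis (requires ``study_table``), network
    compilation (pre- and post-operative JSON), and — when a cohort is
    given — per-patient predictions and stratified validation tables.
    """
    if config.study_table is None:
        raise ConfigurationError("run_pipeline requires a study table")
    for attr in ("study_table", "network_spec", "cohort"):
        value = getattr(config, attr)
        if value is not None and not Path(value).exists():
            raise ConfigurationError(f"{attr} file not found: {value}")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config_hash = config.hash()
    artifacts: dict[str, Path] = {}

    # 1. evidence synthesis
    table = StudyTable.from_csv(config.study_table)
    evidence = synthesize(table, normalization=config.normalization)
    top = select_top_k(evidence, config.top_k)
    evidence_path = out_dir / "evidence.csv"
    write_frame(evidence_to_frame(evidence), evidence_path, config_hash)
    artifacts["evidence"] = evidence_path

    # 2. network compilation
    spec = (
        NetworkSpec.from_yaml(config.network_spec)
        if config.network_spec
        else default_spec()
    )
    spec_names = {v.name for v in spec.variables}
    weights = weight_map(top)
    missing = sorted(spec_names - set(weights))
    if missing:
        raise ConfigurationError(
            f"network spec names variables absent from the top-{config.top_k} "
            f"synthesis: {missing}"
        )
    networks: dict[str, CompiledNetwork] = {}
    for phase, stem in ((PRE_OPERATIVE, "network_pre"), (POST_OPERATIVE, "network_post")):
        net = networks[phase] = _build(spec, weights, phase)
        path = out_dir / f"{stem}.json"
        doc = net.to_dict()
        doc["_meta"] = {"tool": f"pancbn {__version__}", "config_hash": config_hash}
        path.write_text(json.dumps(doc, sort_keys=True))
        artifacts[stem] = path

    # 3. predictions + validation
    if config.cohort is not None:
        cohort = read_cohort(config.cohort, variables=[v.name for v in spec.variables])
        pred_rows = []
        for phase in (PRE_OPERATIVE, POST_OPERATIVE):
            results = [predict(networks[phase], r, phase) for r in cohort]
            pred_rows.append(predictions_to_frame(cohort, results))
        predictions_path = out_dir / "predictions.csv"
        write_frame(pd.concat(pred_rows, ignore_index=True), predictions_path, config_hash)
        artifacts["predictions"] = predictions_path

        strata = (
            strata_from_bounds(config.strata)
            if config.strata
            else None
        )
        validation_frames = []
        for phase in (PRE_OPERATIVE, POST_OPERATIVE):
            table_strata = strata if strata is not None else default_strata(spec, phase)
            df = stratified_validation(networks[phase], cohort, table_strata, phase)
            df.insert(0, "phase", phase)
            validation_frames.append(df)
        validation_path = out_dir / "validation.csv"
        write_frame(pd.concat(validation_frames, ignore_index=True), validation_path, config_hash)
        artifacts["validation"] = validation_path

    logger.info("pipeline complete: %s", {k: str(v) for k, v in artifacts.items()})
    return artifacts


def _build(spec: NetworkSpec, weights: dict[str, float], phase: str) -> CompiledNetwork:
    from .network import build_network

    return build_network(spec, weights, phase)
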