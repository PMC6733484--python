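"""Ranked-node Bayesian network construction with truncated-Normal NPTs.

The model has a fixed three-layer topology: ranked prognostic variables
(root "parent" nodes) feed category child nodes (e.g. Pathology,
Inflammatory Markers), which feed a single Boolean output node
("poor prognosis": death within 12 months of resection).

Every ranked node's ordered states are mapped onto the unit interval as the
midpoints of an equal-width partition (low-risk end near 0, high-risk end
near 1).  A child node's conditional distribution, for each joint parent
configuration, is a doubly truncated Normal on [0, 1] whose mean is the
weighted mean of the parents' scale values (weights = the parents'
normalized evidence weights) discretized over the child's intervals.  The
output node is Boolean: P(yes) is the truncated-Normal mass above the 50%
threshold.

The default variance is sigma^2 = base_variance / sum(parent weights): more
corroborating evidence behind a child's parents gives a tighter conditional
distribution.  The base variance (default 0.05 on the unit scale) sets the
overall noise level of the ranked-node regression; at 0.05 the compiled
default model discriminates in the AUC 0.65-0.85 band typical of clinical
prognostic models, while sigma^2 = 1/sum(w) (base 1.0) would leave the
children nearly independent of their parents.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from scipy.stats import truncnorm

from .errors import (
    ConfigurationError,
    DegenerateNodeError,
    ParameterError,
    StructureError,
)
from .evidence import VariableEvidence, weight_map
from .factors import Factor

PRE_OPERATIVE = "pre_operative"
POST_OPERATIVE = "post_operative"
_PHASES = (PRE_OPERATIVE, POST_OPERATIVE)

#: state labels for 5-state category child nodes
_FIVE_LEVELS = ("very_low", "low", "medium", "high", "very_high")


def group_state_labels(k: int) -> tuple[str, ...]:
    if k == 5:
        return _FIVE_LEVELS
    return tuple(f"level_{i + 1}" for i in range(k))


def map_states_to_scale(states: Sequence[str]) -> np.ndarray:
    """Midpoints of the equal-width partition of [0, 1] into len(states) bins."""
    k = len(states)
    if k < 2:
        raise DegenerateNodeError(f"ranked node needs >= 2 states, got {list(states)}")
    return (np.arange(k) + 0.5) / k


def interval_edges(k: int) -> np.ndarray:
    return np.linspace(0.0, 1.0, k + 1)


@dataclass(frozen=True)
class RankedVariable:
    """A prognostic variable as a ranked root node.

    ``states`` are ordered from lowest to highest risk; ``weight`` is the
    normalized evidence weight (filled in at compile time if None).
    """

    name: str
    states: tuple[str, ...]
    phase: str
    group: str
    weight: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if len(self.states) < 2:
            raise DegenerateNodeError(f"variable {self.name!r} has < 2 states")
        if self.phase not in _PHASES:
            raise ConfigurationError(f"variable {self.name!r}: unknown phase {self.phase!r}")
        if self.weight is not None and self.weight <= 0:
            raise ConfigurationError(f"variable {self.name!r}: weight must be positive")

    @property
    def scale_values(self) -> np.ndarray:
        return map_states_to_scale(self.states)


@dataclass(frozen=True)
class TNormalParams:
    """Normal distribution doubly truncated to ``support`` (default [0, 1])."""

    mean: float
    variance: float
    support: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ParameterError(f"variance must be positive, got {self.variance}")
        lo, hi = self.support
        if not lo <= self.mean <= hi:
            raise ParameterError(f"mean {self.mean} outside support [{lo}, {hi}]")


@dataclass(frozen=True)
class NetworkSpec:
    """Declarative network topology: variables, their groups, and the output node."""

    variables: tuple[RankedVariable, ...]
    output_name: str = "Poor Prognosis"
    output_states: tuple[str, str] = ("no", "yes")
    n_group_states: int = 5
    threshold: float = 0.5
    variance_rule: str = "inverse-weight-sum"
    base_variance: float = 0.05
    fixed_variance: float | None = None
    variance_overrides: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            raise StructureError("duplicate variable names in network spec")
        reserved = set(self.group_names) | {self.output_name}
        clash = reserved & set(names)
        if clash:
            raise StructureError(f"group/output names clash with variables: {sorted(clash)}")
        if not 0.0 < self.threshold < 1.0:
            raise ConfigurationError(f"threshold must be in (0,1), got {self.threshold}")
        if self.n_group_states < 2:
            raise DegenerateNodeError("category child nodes need >= 2 states")
        if self.variance_rule not in ("inverse-weight-sum", "fixed"):
            raise ConfigurationError(f"unknown variance rule {self.variance_rule!r}")
        if self.variance_rule == "fixed" and not self.fixed_variance:
            raise ConfigurationError("variance_rule 'fixed' requires fixed_variance")
        if self.base_variance <= 0:
            raise ConfigurationError("base_variance must be positive")

    @property
    def group_names(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for v in self.variables:
            seen.setdefault(v.group, None)
        return tuple(seen)

    def groups(self, phase: str = POST_OPERATIVE) -> dict[str, list[RankedVariable]]:
        """Group -> member variables, restricted to the given phase's variable set."""
        members: dict[str, list[RankedVariable]] = {}
        for v in self.phase_variables(phase):
            members.setdefault(v.group, []).append(v)
        return members

    def phase_variables(self, phase: str) -> tuple[RankedVariable, ...]:
        if phase == PRE_OPERATIVE:
            return tuple(v for v in self.variables if v.phase == PRE_OPERATIVE)
        if phase == POST_OPERATIVE:
            return self.variables
        raise ConfigurationError(f"unknown phase {phase!r}")

    def variable(self, name: str) -> RankedVariable:
        for v in self.variables:
            if v.name == name:
                return v
        raise ConfigurationError(f"unknown variable {name!r}")

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_dict(cls, data: Mapping) -> "NetworkSpec":
        try:
            variables = tuple(
                RankedVariable(
                    name=v["name"],
                    states=tuple(str(s) for s in v["states"]),
                    phase=v["phase"],
                    group=v["group"],
                    weight=v.get("weight"),
                )
                for v in data["variables"]
            )
        except KeyError as exc:
            raise ConfigurationError(f"network spec missing key {exc}") from exc
        return cls(
            variables=variables,
            output_name=data.get("output_name", "Poor Prognosis"),
            output_states=tuple(data.get("output_states", ("no", "yes"))),
            n_group_states=int(data.get("n_group_states", 5)),
            threshold=float(data.get("threshold", 0.5)),
            variance_rule=data.get("variance_rule", "inverse-weight-sum"),
            base_variance=float(data.get("base_variance", 0.05)),
            fixed_variance=data.get("fixed_variance"),
            variance_overrides=dict(data.get("variance_overrides", {})),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NetworkSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "variables": [
                {
                    "name": v.name,
                    "states": list(v.states),
                    "phase": v.phase,
                    "group": v.group,
                    **({"weight": v.weight} if v.weight is not None else {}),
                }
                for v in self.variables
            ],
            "output_name": self.output_name,
            "output_states": list(self.output_states),
            "n_group_states": self.n_group_states,
            "threshold": self.threshold,
            "variance_rule": self.variance_rule,
            "base_variance": self.base_variance,
            "fixed_variance": self.fixed_variance,
            "variance_overrides": dict(self.variance_overrides),
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


# ---------------------------------------------------------------- TNormal math
def weighted_mean(parent_values: Sequence[float], weights: Sequence[float]) -> float:
    """Weighted mean of parent scale values; the TNormal mean of a child cell."""
    values = np.asarray(parent_values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if values.shape != w.shape:
        raise ConfigurationError("values and weights must have equal length")
    total = w.sum()
    if total <= 0:
        raise ConfigurationError("weights must sum to a positive value")
    return float((values * w).sum() / total)


def _truncnorm(mean, variance, support=(0.0, 1.0)):
    sd = np.sqrt(variance)
    lo, hi = support
    a = (lo - np.asarray(mean)) / sd
    b = (hi - np.asarray(mean)) / sd
    return truncnorm(a, b, loc=mean, scale=sd)


def discretize_truncated_normal(params: TNormalParams, edges: Sequence[float]) -> np.ndarray:
    """Probability mass of the truncated Normal in each interval of a partition."""
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ParameterError("interval edges must be strictly increasing")
    lo, hi = params.support
    if not (np.isclose(edges[0], lo) and np.isclose(edges[-1], hi)):
        raise ParameterError("intervals must partition the support")
    dist = _truncnorm(params.mean, params.variance, params.support)
    cdf = dist.cdf(edges)
    probs = np.diff(cdf)
    total = probs.sum()
    if total <= 0:
        raise ParameterError("degenerate discretization (zero total mass)")
    return probs / total


def _cell_variance(spec_like, node_name: str, weights: Sequence[float]) -> float:
    """Variance for one child node per the spec's variance rule."""
    overrides = getattr(spec_like, "variance_overrides", {}) or {}
    if node_name in overrides:
        return float(overrides[node_name])
    if getattr(spec_like, "variance_rule", "inverse-weight-sum") == "fixed":
        return float(spec_like.fixed_variance)
    total = float(np.sum(weights))
    if total <= 0:
        raise ConfigurationError(f"node {node_name!r}: parent weights sum to zero")
    return float(getattr(spec_like, "base_variance", 0.05)) / total


def _config_means(scale_values: Sequence[np.ndarray], weights: Sequence[float]) -> np.ndarray:
    """Weighted-mean grid over the cartesian product of parent states.

    Returns an array of shape (k1, ..., kp) of TNormal means.
    """
    w = np.asarray(weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ConfigurationError("parent weights must sum to a positive value")
    shape = tuple(len(s) for s in scale_values)
    means = np.zeros(shape)
    for i, (scales, wi) in enumerate(zip(scale_values, w)):
        view = [1] * len(shape)
        view[i] = shape[i]
        means = means + wi * np.asarray(scales).reshape(view)
    return means / total


def build_child_npt(
    child_name: str,
    n_child_states: int,
    parents: Sequence[RankedVariable],
    variance: float,
    child_states: Sequence[str] | None = None,
) -> Factor:
    """Conditional probability table of a category child given its ranked parents."""
    for p in parents:
        if p.weight is None:
            raise ConfigurationError(f"parent {p.name!r} of {child_name!r} has no weight")
    weights = [p.weight for p in parents]
    means = _config_means([p.scale_values for p in parents], weights)
    edges = interval_edges(n_child_states)
    flat_means = means.reshape(-1, 1)
    dist = _truncnorm(flat_means, variance)
    cdf = dist.cdf(edges.reshape(1, -1))
    probs = np.diff(cdf, axis=1)
    probs = probs / probs.sum(axis=1, keepdims=True)
    table = probs.reshape(means.shape + (n_child_states,))
    scope = tuple(p.name for p in parents) + (child_name,)
    return Factor(scope, table)


def build_output_npt(
    output_name: str,
    groups: Sequence[tuple[str, Sequence[str]]],
    weights: Sequence[float],
    variance: float,
    threshold: float = 0.5,
) -> Factor:
    """Boolean output NPT: P(yes) = TNormal mass above the classification threshold.

    ``groups`` is a sequence of (group node name, ordered state labels).
    """
    if not 0.0 < threshold < 1.0:
        raise ConfigurationError(f"threshold must be in (0,1), got {threshold}")
    scales = [map_states_to_scale(states) for _, states in groups]
    means = _config_means(scales, weights)
    dist = _truncnorm(means.reshape(-1), variance)
    p_yes = dist.sf(threshold)
    table = np.stack([1.0 - p_yes, p_yes], axis=-1).reshape(means.shape + (2,))
    scope = tuple(name for name, _ in groups) + (output_name,)
    return Factor(scope, table)


# ---------------------------------------------------------------- compilation
@dataclass(frozen=True)
class CompiledNetwork:
    """A fully parameterized discrete network: nodes, parent sets, and factors.

    ``factors[node]`` has scope ``parents[node] + (node,)``; root nodes carry
    their prior as a one-variable factor.
    """

    nodes: Mapping[str, tuple[str, ...]]
    parents: Mapping[str, tuple[str, ...]]
    factors: Mapping[str, Factor]
    phase: str = POST_OPERATIVE
    output_name: str | None = None
    threshold: float = 0.5
    spec: NetworkSpec | None = None

    def __post_init__(self) -> None:
        for node, pars in self.parents.items():
            factor = self.factors[node]
            if factor.scope != tuple(pars) + (node,):
                raise StructureError(f"factor scope mismatch for node {node!r}")
        self.topological_order()  # raises on cycles

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(self.nodes)

    def states(self, node: str) -> tuple[str, ...]:
        try:
            return tuple(self.nodes[node])
        except KeyError:
            raise ConfigurationError(f"unknown node {node!r}") from None

    def state_index(self, node: str, state: str) -> int:
        states = self.states(node)
        try:
            return states.index(state)
        except ValueError:
            raise ConfigurationError(
                f"node {node!r} has no state {state!r} (states: {list(states)})"
            ) from None

    def topological_order(self) -> tuple[str, ...]:
        order: list[str] = []
        placed: set[str] = set()
        pending = dict(self.parents)
        while pending:
            ready = sorted(n for n, ps in pending.items() if all(p in placed for p in ps))
            if not ready:
                raise StructureError("network graph contains a cycle")
            for n in ready:
                order.append(n)
                placed.add(n)
                del pending[n]
        return tuple(order)

    # ------------------------------------------------------------------ I/O
    def to_dict(self) -> dict:
        return {
            "format": "pancbn-network",
            "phase": self.phase,
            "output_name": self.output_name,
            "threshold": self.threshold,
            "nodes": [
                {
                    "name": node,
                    "states": list(self.nodes[node]),
                    "parents": list(self.parents[node]),
                    "table": self.factors[node].table.reshape(-1).tolist(),
                }
                for node in self.nodes
            ],
            "spec": self.spec.to_dict() if self.spec is not None else None,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, data: Mapping) -> "CompiledNetwork":
        nodes: dict[str, tuple[str, ...]] = {}
        parents: dict[str, tuple[str, ...]] = {}
        tables: dict[str, list[float]] = {}
        for entry in data["nodes"]:
            nodes[entry["name"]] = tuple(entry["states"])
            parents[entry["name"]] = tuple(entry["parents"])
            tables[entry["name"]] = entry["table"]
        factors = {}
        for node in nodes:
            scope = parents[node] + (node,)
            shape = tuple(len(nodes[v]) for v in scope)
            factors[node] = Factor(scope, np.asarray(tables[node]).reshape(shape))
        spec = NetworkSpec.from_dict(data["spec"]) if data.get("spec") else None
        return cls(
            nodes=nodes,
            parents=parents,
            factors=factors,
            phase=data.get("phase", POST_OPERATIVE),
            output_name=data.get("output_name"),
            threshold=float(data.get("threshold", 0.5)),
            spec=spec,
        )

    @classmethod
    def load(cls, path: str | Path) -> "CompiledNetwork":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_network(
    spec: NetworkSpec,
    evidence: Iterable[VariableEvidence] | Mapping[str, float],
    phase: str = POST_OPERATIVE,
) -> CompiledNetwork:
    """Compile the three-layer ranked-node network for one phase.

    The pre-operative network contains only pre-operative variables (and the
    groups they populate); the post-operative network contains all variables.
    Root priors are uniform over states.
    """
    weights = dict(evidence) if isinstance(evidence, Mapping) else weight_map(evidence)
    variables = spec.phase_variables(phase)
    if not variables:
        raise ConfigurationError(f"no variables in phase {phase!r}")
    missing = [v.name for v in variables if v.name not in weights]
    if missing:
        raise ConfigurationError(f"no evidence weight for variables: {missing}")

    weighted = [replace(v, weight=float(weights[v.name])) for v in variables]
    groups = {}
    for v in weighted:
        groups.setdefault(v.group, []).append(v)

    group_states = group_state_labels(spec.n_group_states)
    nodes: dict[str, tuple[str, ...]] = {}
    parents: dict[str, tuple[str, ...]] = {}
    factors: dict[str, Factor] = {}

    for v in weighted:
        nodes[v.name] = v.states
        parents[v.name] = ()
        k = len(v.states)
        factors[v.name] = Factor((v.name,), np.full(k, 1.0 / k))

    for gname, members in groups.items():
        nodes[gname] = group_states
        parents[gname] = tuple(m.name for m in members)
        variance = _cell_variance(spec, gname, [m.weight for m in members])
        factors[gname] = build_child_npt(
            gname, spec.n_group_states, members, variance, group_states
        )

    group_weights = [sum(m.weight for m in members) for members in groups.values()]
    out = spec.output_name
    nodes[out] = tuple(spec.output_states)
    parents[out] = tuple(groups)
    out_variance = _cell_variance(spec, out, group_weights)
    factors[out] = build_output_npt(
        out,
        [(g, group_states) for g in groups],
        group_weights,
        out_variance,
        spec.threshold,
    )

    return CompiledNetwork(
        nodes=nodes,
        parents=parents,
        factors=factors,
        phase=phase,
        output_name=out,
        threshold=spec.threshold,
        spec=spec,
    )


def default_spec() -> NetworkSpec:
    """The shipped 25-variable network topology (packaged YAML)."""
    from importlib.resources import files

    path = files("pancbn.data").joinpath("default_network.yaml")
    return NetworkSpec.from_dict(yaml.safe_load(path.read_text()))
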