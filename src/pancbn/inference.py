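"""Exact inference on compiled networks by variable elimination.

Missing data needs no special handling: unobserved nodes are simply
marginalized out, so the posterior of the output node is always defined
however sparse a patient's evidence is.  Elimination order is chosen
greedily by minimum degree, ties broken lexicographically, so results and
runtimes are deterministic.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .errors import ConfigurationError, ZeroProbabilityEvidenceError
from .factors import Factor, product
from .network import CompiledNetwork

#: refuse full-joint enumeration beyond this many joint states
ENUMERATION_CAP = 10**6

EvidenceMap = Mapping[str, str]


def validate_evidence(network: CompiledNetwork, evidence: EvidenceMap) -> dict[str, int]:
    """Check node/state names and return node -> state index."""
    return {node: network.state_index(node, state) for node, state in evidence.items()}


def _min_degree_order(scopes: list[set[str]], to_eliminate: set[str]) -> list[str]:
    scopes = [set(s) for s in scopes if s]
    remaining = set(to_eliminate)
    order: list[str] = []
    while remaining:
        degrees = {}
        for v in remaining:
            neigh: set[str] = set()
            for s in scopes:
                if v in s:
                    neigh |= s
            neigh.discard(v)
            degrees[v] = len(neigh)
        best = min(sorted(remaining), key=lambda v: degrees[v])
        order.append(best)
        remaining.discard(best)
        merged = {v for s in scopes if best in s for v in s} - {best}
        scopes = [s for s in scopes if best not in s]
        if merged:
            scopes.append(merged)
    return order


def _eliminate(factors: list[Factor], to_eliminate: set[str]) -> list[Factor]:
    order = _min_degree_order([set(f.scope) for f in factors], to_eliminate)
    for var in order:
        related = [f for f in factors if var in f.scope]
        factors = [f for f in factors if var not in f.scope]
        if related:
            factors.append(product(related).sum_out(var))
    return factors


def posterior_marginal(
    network: CompiledNetwork, query: str, evidence: EvidenceMap | None = None
) -> np.ndarray:
    """Posterior distribution of ``query`` given partial evidence.

    Raises :class:`ZeroProbabilityEvidenceError` if the evidence has
    probability zero under the model (never returns NaN).
    """
    evidence = dict(evidence or {})
    if query not in network.nodes:
        raise ConfigurationError(f"unknown query node {query!r}")
    index_map = validate_evidence(network, evidence)

    factors = [f.reduce_evidence(index_map) for f in network.factors.values()]

    if query in evidence:
        # conditioning on the query itself: degenerate posterior, but the
        # evidence must still be possible under the model
        remaining = _eliminate(factors, set(network.nodes) - set(evidence))
        mass = float(product(remaining).table)
        if mass <= 0.0:
            raise ZeroProbabilityEvidenceError("evidence has probability zero under the model")
        out = np.zeros(len(network.states(query)))
        out[index_map[query]] = 1.0
        return out

    to_eliminate = set(network.nodes) - set(evidence) - {query}
    remaining = _eliminate(factors, to_eliminate)
    result = product(remaining).marginalize_to((query,))
    vec = result.values_for((query,))
    total = vec.sum()
    if total <= 0.0:
        raise ZeroProbabilityEvidenceError("evidence has probability zero under the model")
    return vec / total


def enumerate_joint(network: CompiledNetwork, cap: int = ENUMERATION_CAP) -> Factor:
    """Full joint distribution as one factor (test-scale oracle only)."""
    size = 1
    for states in network.nodes.values():
        size *= len(states)
        if size > cap:
            raise ConfigurationError(
                f"joint state space exceeds enumeration cap ({cap}); "
                "the oracle is for small networks only"
            )
    return product(list(network.factors.values()))


def posterior_from_joint(
    network: CompiledNetwork, query: str, evidence: EvidenceMap | None = None
) -> np.ndarray:
    """Brute-force posterior via full enumeration (oracle for tests)."""
    evidence = dict(evidence or {})
    index_map = validate_evidence(network, evidence)
    joint = enumerate_joint(network)
    reduced = joint.reduce_evidence(index_map)
    if query in evidence:
        if float(reduced.marginalize_to(()).table) <= 0.0:
            raise ZeroProbabilityEvidenceError("evidence has probability zero under the model")
        out = np.zeros(len(network.states(query)))
        out[index_map[query]] = 1.0
        return out
    marg = reduced.marginalize_to((query,)).values_for((query,))
    total = marg.sum()
    if total <= 0.0:
        raise ZeroProbabilityEvidenceError("evidence has probability zero under the model")
    return marg / total
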