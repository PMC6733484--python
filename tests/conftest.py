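"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pancbn.factors import Factor
from pancbn.network import (
    CompiledNetwork,
    NetworkSpec,
    RankedVariable,
    build_network,
)

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


# ------------------------------------------------------------------ oracles
def tnormal_cell_quadrature(mean: float, variance: float, lo: float, hi: float) -> float:
    """Mass of the [0,1]-truncated Normal in [lo, hi] by adaptive quadrature.

    Independent of the implementation's truncnorm-cdf route: integrates the
    raw Normal pdf numerically and normalizes by the [0,1] mass.
    """
    from scipy.integrate import quad
    from scipy.stats import norm

    sd = math.sqrt(variance)
    pdf = lambda x: norm.pdf(x, mean, sd)  # noqa: E731
    num, _ = quad(pdf, lo, hi, epsabs=1e-13, limit=200)
    den, _ = quad(pdf, 0.0, 1.0, epsabs=1e-13, limit=200)
    return num / den


def brute_force_synthesis(table) -> dict[str, tuple[float, float]]:
    """Independent recomputation of both evidence weights from the definitions."""
    from pancbn.evidence import STATUS_EXCLUDED, STATUS_SIGNIFICANT

    out = {}
    total_pop = sum(r.population for r in table.records)
    for var in table.variables:
        n_inc = n_sig = rep = 0
        for r in table.records:
            status = r.variable_results.get(var, STATUS_EXCLUDED)
            if status == STATUS_EXCLUDED:
                continue
            n_inc += 1
            rep += r.population
            if status == STATUS_SIGNIFICANT:
                n_sig += 1
        if n_inc:
            w0 = n_sig / n_inc
            out[var] = (w0, w0 * rep / total_pop)
    return out


def auc_bruteforce(scores, labels) -> float:
    """O(n^2) pairwise concordance with half-credit ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


# ------------------------------------------------------- network generators
def random_discrete_network(rng: np.random.Generator, max_nodes: int = 6,
                            max_states: int = 4) -> CompiledNetwork:
    """A random small DAG with Dirichlet CPTs (for inference oracle tests)."""
    n = int(rng.integers(2, max_nodes + 1))
    names = [f"n{i}" for i in range(n)]
    cards = [int(rng.integers(2, max_states + 1)) for _ in range(n)]
    nodes = {name: tuple(f"s{j}" for j in range(c)) for name, c in zip(names, cards)}
    parents: dict[str, tuple[str, ...]] = {}
    factors: dict[str, Factor] = {}
    for i, name in enumerate(names):
        pool = list(range(i))
        k = int(rng.integers(0, min(2, len(pool)) + 1))
        chosen = sorted(rng.choice(pool, size=k, replace=False).tolist()) if k else []
        pars = tuple(names[j] for j in chosen)
        parents[name] = pars
        shape = tuple(cards[j] for j in chosen) + (cards[i],)
        table = rng.dirichlet(np.ones(cards[i]), size=shape[:-1] or (1,))
        table = table.reshape(shape)
        factors[name] = Factor(pars + (name,), table)
    return CompiledNetwork(nodes=nodes, parents=parents, factors=factors)


def toy_spec(n_group_states: int = 3) -> NetworkSpec:
    """A 3-variable, 2-group ranked spec small enough for full enumeration."""
    return NetworkSpec(
        variables=(
            RankedVariable("inflammation", ("low", "high"), "pre_operative", "bloods"),
            RankedVariable("anaemia", ("no", "yes"), "pre_operative", "bloods"),
            RankedVariable("margin involved", ("no", "yes"), "post_operative", "pathology"),
        ),
        n_group_states=n_group_states,
    )


TOY_WEIGHTS = {"inflammation": 0.6, "anaemia": 0.3, "margin involved": 0.8}


@pytest.fixture(scope="session")
def toy_networks():
    spec = toy_spec()
    return (
        build_network(spec, TOY_WEIGHTS, "pre_operative"),
        build_network(spec, TOY_WEIGHTS, "post_operative"),
    )


@pytest.fixture(scope="session")
def default_networks_cached():
    import pancbn

    return pancbn.default_networks()
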