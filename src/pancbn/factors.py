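"""Dense discrete factors over named variables.

A :class:`Factor` is an ndarray with one axis per variable in ``scope``.
This is the minimal algebra (multiply, marginalize, reduce) that exact
inference on small clinical networks needs; axes stay aligned by name.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import reduce as _reduce
from typing import Iterable, Mapping, Sequence

import numpy as np


@dataclass(frozen=True)
class Factor:
    scope: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        table = np.asarray(self.table, dtype=float)
        object.__setattr__(self, "table", table)
        if table.ndim != len(self.scope):
            raise ValueError(
                f"table has {table.ndim} axes but scope names {len(self.scope)} variables"
            )
        if len(set(self.scope)) != len(self.scope):
            raise ValueError(f"duplicate variables in scope {self.scope}")
        if np.any(table < 0):
            raise ValueError("factor entries must be non-negative")

    @property
    def cards(self) -> dict[str, int]:
        return dict(zip(self.scope, self.table.shape))

    def _expand(self, scope: Sequence[str]) -> np.ndarray:
        """View of the table broadcastable over ``scope`` (a superset, in order)."""
        own = {v: i for i, v in enumerate(self.scope)}
        order = [own[v] for v in scope if v in own]
        # transpose puts owned axes in scope order, so reshape just inserts 1s
        t = self.table.transpose(order)
        shape: list[int] = []
        it = iter(t.shape)
        for v in scope:
            shape.append(next(it) if v in own else 1)
        return t.reshape(shape)

    def multiply(self, other: "Factor") -> "Factor":
        scope = self.scope + tuple(v for v in other.scope if v not in self.scope)
        return Factor(scope, self._expand(scope) * other._expand(scope))

    def sum_out(self, variable: str) -> "Factor":
        i = self.scope.index(variable)
        return Factor(self.scope[:i] + self.scope[i + 1 :], self.table.sum(axis=i))

    def marginalize_to(self, keep: Sequence[str]) -> "Factor":
        f = self
        for v in self.scope:
            if v not in keep:
                f = f.sum_out(v)
        return f

    def reduce(self, variable: str, state_index: int) -> "Factor":
        i = self.scope.index(variable)
        return Factor(
            self.scope[:i] + self.scope[i + 1 :], np.take(self.table, state_index, axis=i)
        )

    def reduce_evidence(self, index_map: Mapping[str, int]) -> "Factor":
        f = self
        for v, idx in index_map.items():
            if v in f.scope:
                f = f.reduce(v, idx)
        return f

    def normalize(self) -> "Factor":
        total = self.table.sum()
        if total <= 0:
            raise ValueError("cannot normalize a zero factor")
        return Factor(self.scope, self.table / total)

    def values_for(self, scope: Sequence[str]) -> np.ndarray:
        """Table transposed to the given ordering of the same scope."""
        if set(scope) != set(self.scope):
            raise ValueError(f"scope mismatch: {scope} vs {self.scope}")
        own = {v: i for i, v in enumerate(self.scope)}
        return self.table.transpose([own[v] for v in scope])


def product(factors: Iterable[Factor]) -> Factor:
    factors = list(factors)
    if not factors:
        return Factor((), np.asarray(1.0))
    return _reduce(Factor.multiply, factors)
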