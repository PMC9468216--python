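"""Discrete Bayesian networks: representation, ML parameter fitting, exact inference.

A network is a DAG over named categorical variables plus one conditional
probability table (CPT) per node, so the joint distribution factorizes as
``P(x_1..x_n) = prod_i P(x_i | parents(x_i))``. Inference is exact: either
brute-force enumeration of the joint (the test oracle, capped by state-space
size) or variable elimination with a greedy min-fill order.

Variables take integer codes that need not start at zero (e.g. smoking is
0/1 while sex is 1/2); each node carries its ordered code list (``states``)
and CPT axes are indexed by state position.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "AcyclicityError",
    "EstimationError",
    "InferenceError",
    "CPT",
    "Factor",
    "Posterior",
    "BayesianNetwork",
    "topological_order",
    "fit_mle",
]

_ROW_TOL = 1e-9


class AcyclicityError(ValueError):
    """A graph supposed to be a DAG contains a directed cycle."""


class EstimationError(ValueError):
    """Parameter learning received unusable data."""


class InferenceError(ValueError):
    """A query is ill-posed (e.g. zero-probability evidence)."""


def topological_order(dag: nx.DiGraph) -> list[str]:
    """Deterministic topological order: parents first, ties broken lexicographically."""
    try:
        return list(nx.lexicographical_topological_sort(dag))
    except nx.NetworkXUnfeasible:
        cycle = nx.find_cycle(dag)
        path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[-1][1]}"
        raise AcyclicityError(f"graph contains a directed cycle: {path}") from None


@dataclass(frozen=True)
class CPT:
    """Conditional probability table for one node.

    ``table`` has one leading axis per parent (in ``parents`` order) and a
    trailing axis over the child's categories; every row sums to 1.
    """

    child: str
    parents: tuple[str, ...]
    table: np.ndarray

    def __post_init__(self) -> None:
        if self.table.ndim != len(self.parents) + 1:
            raise ValueError(
                f"{self.child}: table has {self.table.ndim} axes for "
                f"{len(self.parents)} parents"
            )
        rows = self.table.reshape(-1, self.table.shape[-1])
        if not np.allclose(rows.sum(axis=1), 1.0, atol=_ROW_TOL):
            raise ValueError(f"{self.child}: CPT rows must sum to 1")
        if (self.table < 0).any():
            raise ValueError(f"{self.child}: negative probability")

    @property
    def n_states(self) -> int:
        return self.table.shape[-1]


@dataclass
class Factor:
    """Non-negative table over a set of variables; the VE workspace object."""

    scope: tuple[str, ...]
    cards: tuple[int, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.cards:
            self.values = self.values.reshape(self.cards)

    def multiply(self, other: "Factor") -> "Factor":
        scope = self.scope + tuple(v for v in other.scope if v not in self.scope)
        cards = self.cards + tuple(
            c for v, c in zip(other.scope, other.cards) if v not in self.scope
        )
        a = self.values.reshape(self.cards + (1,) * (len(scope) - len(self.scope)))
        # transpose other's axes into increasing joint-scope position, then
        # reshape with unit axes so broadcasting lines the variables up
        pos = [scope.index(v) for v in other.scope]
        order = sorted(range(len(other.scope)), key=lambda i: pos[i])
        shape = [1] * len(scope)
        for i in order:
            shape[pos[i]] = other.cards[i]
        b = np.transpose(other.values, order).reshape(shape)
        return Factor(scope, cards, a * b)

    def marginalize(self, var: str) -> "Factor":
        i = self.scope.index(var)
        return Factor(
            self.scope[:i] + self.scope[i + 1:],
            self.cards[:i] + self.cards[i + 1:],
            self.values.sum(axis=i),
        )

    def reduce(self, var: str, index: int) -> "Factor":
        i = self.scope.index(var)
        return Factor(
            self.scope[:i] + self.scope[i + 1:],
            self.cards[:i] + self.cards[i + 1:],
            np.take(self.values, index, axis=i),
        )


@dataclass(frozen=True)
class Posterior:
    """Distribution of ``target`` given ``evidence`` (codes, not positions)."""

    target: str
    evidence: dict[str, int]
    states: tuple[int, ...]
    probabilities: np.ndarray

    def __getitem__(self, code: int) -> float:
        return float(self.probabilities[self.states.index(code)])

    def as_dict(self) -> dict[int, float]:
        return {s: float(p) for s, p in zip(self.states, self.probabilities)}


class BayesianNetwork:
    """A DAG plus one CPT per node, with exact inference methods."""

    def __init__(
        self,
        cpts: Iterable[CPT],
        states: Mapping[str, Sequence[int]],
    ) -> None:
        self.cpts: dict[str, CPT] = {c.child: c for c in cpts}
        self.states: dict[str, tuple[int, ...]] = {
            n: tuple(int(s) for s in sorted(states[n])) for n in states
        }
        if set(self.cpts) != set(self.states):
            raise ValueError("states and CPTs must cover the same node set")
        dag = nx.DiGraph()
        dag.add_nodes_from(self.cpts)
        for cpt in self.cpts.values():
            for p in cpt.parents:
                dag.add_edge(p, cpt.child)
        self.dag = dag
        self._order = topological_order(dag)  # also validates acyclicity
        for cpt in self.cpts.values():
            expected = tuple(len(self.states[p]) for p in cpt.parents) + (
                len(self.states[cpt.child]),
            )
            if cpt.table.shape != expected:
                raise ValueError(
                    f"{cpt.child}: CPT shape {cpt.table.shape} != {expected}"
                )

    # -- basic structure ---------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return list(self._order)

    def parents(self, node: str) -> tuple[str, ...]:
        return self.cpts[node].parents

    def card(self, node: str) -> int:
        return len(self.states[node])

    def state_index(self, node: str, code: int) -> int:
        try:
            return self.states[node].index(int(code))
        except ValueError:
            raise InferenceError(
                f"{node}: code {code} not in states {self.states[node]}"
            ) from None

    def _factor(self, node: str) -> Factor:
        cpt = self.cpts[node]
        scope = cpt.parents + (node,)
        cards = tuple(len(self.states[v]) for v in scope)
        return Factor(scope, cards, cpt.table)

    # -- joint probability -------------------------------------------------

    def joint_probability(self, assignment: Mapping[str, int]) -> float:
        """P(full assignment) = product of CPT entries; computed in log space."""
        if set(assignment) != set(self.cpts):
            missing = set(self.cpts) - set(assignment)
            extra = set(assignment) - set(self.cpts)
            raise ValueError(
                f"assignment must cover all nodes exactly (missing={sorted(missing)}, "
                f"extra={sorted(extra)})"
            )
        log_p = 0.0
        for node in self._order:
            cpt = self.cpts[node]
            idx = tuple(self.state_index(p, assignment[p]) for p in cpt.parents)
            p = cpt.table[idx + (self.state_index(node, assignment[node]),)]
            if p == 0.0:
                return 0.0
            log_p += math.log(p)
        return math.exp(log_p)

    def enumerate_joint(self, cap: int = 10**7) -> Factor:
        """Exact joint table over all nodes (brute force). Refuses above ``cap`` states."""
        size = math.prod(self.card(n) for n in self._order)
        if size > cap:
            raise InferenceError(
                f"state space {size} exceeds enumeration cap {cap}"
            )
        factor = Factor((), (), np.array(1.0))
        for node in self._order:
            factor = factor.multiply(self._factor(node))
        # canonical axis order = topological order
        perm = [factor.scope.index(n) for n in self._order]
        return Factor(
            tuple(self._order),
            tuple(self.card(n) for n in self._order),
            np.transpose(factor.values, perm),
        )

    # -- variable elimination ----------------------------------------------

    @staticmethod
    def _min_fill_order(scopes: list[tuple[str, ...]], to_eliminate: set[str]) -> list[str]:
        """Greedy min-fill elimination order, lexicographic tie-break."""
        neighbors: dict[str, set[str]] = {v: set() for s in scopes for v in s}
        for s in scopes:
            for v in s:
                neighbors[v].update(u for u in s if u != v)
        order: list[str] = []
        remaining = set(to_eliminate)
        while remaining:
            best, best_fill = None, None
            for v in sorted(remaining):
                nbrs = [u for u in neighbors.get(v, ()) if u != v]
                fill = sum(
                    1
                    for i, a in enumerate(nbrs)
                    for b in nbrs[i + 1:]
                    if b not in neighbors[a]
                )
                if best_fill is None or fill < best_fill:
                    best, best_fill = v, fill
            order.append(best)  # type: ignore[arg-type]
            nbrs = neighbors.pop(best, set())
            for a in nbrs:
                neighbors[a].discard(best)
                neighbors[a].update(b for b in nbrs if b != a)
            remaining.discard(best)  # type: ignore[arg-type]
        return order

    def eliminate_query(
        self, target: str, evidence: Mapping[str, int] | None = None
    ) -> Posterior:
        """Exact posterior P(target | evidence) by variable elimination."""
        evidence = dict(evidence or {})
        if target in evidence:
            raise ValueError(f"target {target!r} appears in evidence")
        for node in evidence:
            self.state_index(node, evidence[node])  # validates node and code

        factors = [self._factor(n) for n in self._order]
        reduced: list[Factor] = []
        for f in factors:
            for node, code in evidence.items():
                if node in f.scope:
                    f = f.reduce(node, self.state_index(node, code))
            reduced.append(f)

        hidden = set(self.cpts) - set(evidence) - {target}
        order = self._min_fill_order([f.scope for f in reduced if f.scope], hidden)
        work = reduced
        for var in order:
            involved = [f for f in work if var in f.scope]
            rest = [f for f in work if var not in f.scope]
            if not involved:
                continue
            prod = involved[0]
            for f in involved[1:]:
                prod = prod.multiply(f)
            work = rest + [prod.marginalize(var)]
        result = Factor((), (), np.array(1.0))
        for f in work:
            result = result.multiply(f)
        if result.scope != (target,):
            result = Factor(
                (target,),
                (self.card(target),),
                np.transpose(result.values, [result.scope.index(target)]),
            )
        total = result.values.sum()
        if total <= 0.0:
            raise InferenceError(
                f"evidence {evidence} has zero probability; conditional undefined"
            )
        return Posterior(
            target=target,
            evidence=evidence,
            states=self.states[target],
            probabilities=result.values / total,
        )

    def prior_marginals(self) -> dict[str, Posterior]:
        """Marginal distribution of every node (empty-evidence posteriors)."""
        return {n: self.eliminate_query(n) for n in self._order}


def fit_mle(
    dag: nx.DiGraph,
    data: pd.DataFrame,
    states: Mapping[str, Sequence[int]] | None = None,
    pseudo_count: float = 0.0,
) -> BayesianNetwork:
    """Maximum-likelihood CPT estimation on complete coded data.

    Each CPT entry is ``(N(child=k, pa=j) + pseudo_count) /
    (N(pa=j) + pseudo_count * K)``. With ``pseudo_count=0`` (pure MLE, the
    default) unobserved parent configurations get a uniform row and a log
    message; ``pseudo_count>0`` is Laplace smoothing.

    ``states`` fixes each node's code list; by default codes observed in the
    data are used.
    """
    if len(data) == 0:
        raise EstimationError("cannot fit CPTs on an empty dataset")
    if pseudo_count < 0:
        raise EstimationError("pseudo_count must be >= 0")
    nodes = list(dag.nodes)
    missing_cols = [n for n in nodes if n not in data.columns]
    if missing_cols:
        raise EstimationError(f"data lacks column(s): {missing_cols}")
    if data[nodes].isna().any().any():
        raise EstimationError("data must be complete (no missing values)")

    if states is None:
        states = {n: sorted(int(v) for v in data[n].unique()) for n in nodes}
    states = {n: tuple(sorted(int(s) for s in states[n])) for n in nodes}

    # positional codes per column
    pos = {
        n: np.searchsorted(np.asarray(states[n]), data[n].to_numpy(dtype=int))
        for n in nodes
    }
    for n in nodes:
        bad = ~np.isin(data[n].to_numpy(dtype=int), states[n])
        if bad.any():
            raise EstimationError(f"{n}: value(s) outside declared states")

    cpts = []
    for node in nodes:
        parents = tuple(sorted(dag.predecessors(node)))
        cards = [len(states[p]) for p in parents] + [len(states[node])]
        flat = np.zeros(int(np.prod(cards)), dtype=float)
        idx = np.ravel_multi_index(
            [pos[p] for p in parents] + [pos[node]], cards
        )
        np.add.at(flat, idx, 1.0)
        counts = flat.reshape(cards)
        counts += pseudo_count
        totals = counts.sum(axis=-1, keepdims=True)
        empty = totals[..., 0] == 0
        if empty.any():
            logger.info(
                "%s: %d unobserved parent configuration(s) set to uniform",
                node,
                int(empty.sum()),
            )
            counts[empty] = 1.0
            totals = counts.sum(axis=-1, keepdims=True)
        cpts.append(CPT(node, parents, counts / totals))
    return BayesianNetwork(cpts, states)
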