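"""Hybrid Bayesian-network structure learning (Max-Min Hill-Climbing).

The hybrid recipe: Max-Min Parents-and-Children (MMPC) first learns an
undirected skeleton from G² conditional-independence tests, then a greedy
BIC-scored hill climb — restricted to skeleton-adjacent pairs — orients and
prunes edges. Constraint tests shrink the search space; the score search
picks the best network inside it.

Also provides structure-evaluation utilities: the CPDAG (Markov-equivalence
class representative, Meek-closed) and the structural Hamming distance.

Everything is deterministic: candidate loops, subset enumeration, move
selection and all tie-breaks are lexicographic, so a fixed dataset always
yields the same graph.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .citest import CITestResult, g2_test, infer_levels

__all__ = [
    "Skeleton",
    "Move",
    "CPDAG",
    "max_min_heuristic",
    "mmpc",
    "bic_score",
    "hill_climb",
    "mmhc",
    "cpdag",
    "shd",
    "skeleton_f1",
    "trace_to_frame",
]

_EPS = 1e-10


@dataclass
class Skeleton:
    """Undirected candidate structure: symmetric adjacency + per-node CPC sets."""

    nodes: tuple[str, ...]
    edges: set[frozenset]
    cpc: dict[str, set[str]] = field(default_factory=dict)

    def adjacent(self, u: str, v: str) -> bool:
        return frozenset((u, v)) in self.edges


@dataclass(frozen=True)
class Move:
    """One accepted hill-climbing move; deltas of accepted moves are > 0."""

    op: str  # "add" | "delete" | "reverse"
    edge: tuple[str, str]
    delta: float


@dataclass(frozen=True)
class CPDAG:
    """Pattern of a Markov-equivalence class: compelled edges stay directed."""

    nodes: tuple[str, ...]
    directed: frozenset  # of (u, v) tuples
    undirected: frozenset  # of frozenset({u, v})


# ---------------------------------------------------------------------------
# MMPC
# ---------------------------------------------------------------------------


class _AssocCache:
    """Memo of G² p-values keyed by (x, y, conditioning set), symmetric in x,y."""

    def __init__(self, data: pd.DataFrame, levels, max_cond: int, adequacy: float):
        self.data = data
        self.levels = levels
        self.max_cond = max_cond
        self.adequacy = adequacy
        self._memo: dict[tuple, CITestResult] = {}

    def test(self, x: str, y: str, s: tuple[str, ...]) -> CITestResult:
        key = (frozenset((x, y)), frozenset(s))
        if key not in self._memo:
            if len(s) > self.max_cond:
                res = CITestResult(0.0, 1, 1.0, performed=False)
            else:
                res = g2_test(
                    self.data, x, y, list(s),
                    levels=self.levels, adequacy=self.adequacy,
                )
            self._memo[key] = res
        return self._memo[key]

    def min_assoc(
        self, x: str, target: str, cpc: Sequence[str],
        stop_above: tuple[float, float] = (2.0, math.inf),
    ) -> tuple[float, float]:
        """Worst-case association of x with target over subsets S of cpc.

        Association strength is primarily the G² p-value (smaller =
        stronger), with the negated statistic as tie-break for p-values that
        saturate at 0 or 1; the returned key ``(p, -G²)`` is the candidate's
        weakest association over subsets. Stops early once the running
        worst reaches ``stop_above``.
        """
        worst = (0.0, -math.inf)
        pool = sorted(cpc)
        for size in range(0, min(len(pool), self.max_cond) + 1):
            for s in itertools.combinations(pool, size):
                res = self.test(x, target, s)
                worst = max(worst, (res.p_value, -res.statistic))
                if worst >= stop_above:
                    return worst
        return worst


def max_min_heuristic(
    data: pd.DataFrame,
    target: str,
    cpc: Sequence[str],
    candidates: Sequence[str],
    alpha: float = 0.05,
    *,
    levels=None,
    max_cond: int = 3,
    adequacy: float = 5.0,
    _cache: _AssocCache | None = None,
) -> tuple[str | None, float]:
    """Pick the candidate maximizing the minimum association with ``target``.

    Returns ``(best_candidate, its worst-case p-value)``; ``(None, 1.0)``
    when the candidate set is empty. The caller should discard the winner
    when its p-value exceeds ``alpha`` (no candidate is reliably dependent).
    """
    if set(candidates) & (set(cpc) | {target}):
        raise ValueError("candidates must be disjoint from cpc and target")
    cache = _cache or _AssocCache(
        data, levels or infer_levels(data), max_cond, adequacy
    )
    best: str | None = None
    best_key = (1.0, math.inf)
    for x in sorted(candidates):
        worst = cache.min_assoc(x, target, cpc, stop_above=best_key)
        if worst < best_key:
            best, best_key = x, worst
    if best is None and len(candidates) > 0:
        # all candidates hit the early-stop ceiling; report the first
        best = sorted(candidates)[0]
        best_key = cache.min_assoc(best, target, cpc)
    return best, best_key[0]


def _mmpc_one(target: str, cache: _AssocCache, nodes: Sequence[str], alpha: float) -> set[str]:
    cpc: list[str] = []
    candidates = sorted(n for n in nodes if n != target)
    # forward: grow CPC by the max-min heuristic
    while candidates:
        best, best_p = max_min_heuristic(
            cache.data, target, cpc, candidates, alpha, _cache=cache
        )
        if best is None or best_p > alpha:
            break
        cpc.append(best)
        candidates.remove(best)
        # drop candidates already separated from the target by some subset
        stop = (alpha, -math.inf)
        candidates = [
            x for x in candidates
            if cache.min_assoc(x, target, cpc, stop_above=stop)[0] <= alpha
        ]
    # backward: remove members separated given a subset of the others
    stop = (alpha, -math.inf)
    changed = True
    while changed:
        changed = False
        for x in sorted(cpc):
            rest = [c for c in cpc if c != x]
            if cache.min_assoc(x, target, rest, stop_above=stop)[0] > alpha:
                cpc.remove(x)
                changed = True
    return set(cpc)


def mmpc(
    data: pd.DataFrame,
    alpha: float = 0.05,
    *,
    max_cond: int = 3,
    adequacy: float = 5.0,
    levels=None,
) -> Skeleton:
    """Max-Min Parents-and-Children skeleton over all columns of ``data``.

    Forward phase adds, per target, the candidate with the strongest
    worst-case association until none is dependent at level ``alpha``;
    backward phase prunes false positives; the final AND symmetry
    correction keeps {X, T} only if each lies in the other's CPC.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if data.isna().any().any():
        raise ValueError("mmpc requires complete data")
    for col in data.columns:
        if not np.issubdtype(data[col].dtype, np.integer):
            raise ValueError(f"column {col!r} is not integer-coded categorical")
    levels = levels or infer_levels(data)
    cache = _AssocCache(data, levels, max_cond, adequacy)
    nodes = tuple(data.columns)
    cpc = {t: _mmpc_one(t, cache, nodes, alpha) for t in nodes}
    edges = {
        frozenset((u, v))
        for u in nodes
        for v in cpc[u]
        if u in cpc[v]
    }
    # make CPC sets consistent with the symmetric adjacency
    sym_cpc = {t: {v for v in nodes if frozenset((t, v)) in edges} for t in nodes}
    return Skeleton(nodes=nodes, edges=edges, cpc=sym_cpc)


# ---------------------------------------------------------------------------
# BIC scoring and hill climbing
# ---------------------------------------------------------------------------


class _ScoreCache:
    """Decomposable BIC family scores, memoized per (node, parent set)."""

    def __init__(self, data: pd.DataFrame, levels):
        self.levels = {c: np.asarray(levels[c]) for c in data.columns}
        self.n = len(data)
        self._pos = {
            c: np.searchsorted(self.levels[c], data[c].to_numpy(dtype=int))
            for c in data.columns
        }
        self._memo: dict[tuple[str, frozenset], float] = {}

    def family(self, node: str, parents: frozenset) -> float:
        key = (node, parents)
        if key in self._memo:
            return self._memo[key]
        pa = sorted(parents)
        k = len(self.levels[node])
        q = int(np.prod([len(self.levels[p]) for p in pa])) if pa else 1
        idx = self._pos[node].astype(np.int64).copy()
        stride = k
        for p in pa:
            idx += self._pos[p].astype(np.int64) * stride
            stride *= len(self.levels[p])
        counts = np.bincount(idx, minlength=q * k).reshape(q, k).astype(float)
        row = counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = float(
                np.where(counts > 0, counts * np.log(counts / np.maximum(row, 1.0)), 0.0).sum()
            )
        score = ll - 0.5 * math.log(self.n) * (k - 1) * q
        self._memo[key] = score
        return score


def bic_score(
    dag: nx.DiGraph, data: pd.DataFrame, *, levels=None, _cache: _ScoreCache | None = None
) -> float:
    """BIC of a DAG on complete data: log-likelihood minus (ln n)/2 per free parameter.

    Decomposes over node families, so move deltas during search touch only
    the families whose parent sets change.
    """
    cache = _cache or _ScoreCache(data, levels or infer_levels(data))
    return sum(
        cache.family(node, frozenset(dag.predecessors(node))) for node in dag.nodes
    )


def _creates_cycle(dag: nx.DiGraph, u: str, v: str) -> bool:
    """Would adding u->v close a directed cycle (i.e. v already reaches u)?"""
    return u == v or nx.has_path(dag, v, u)


def hill_climb(
    data: pd.DataFrame,
    skeleton: Skeleton,
    *,
    levels=None,
    max_iter: int = 10_000,
) -> tuple[nx.DiGraph, list[Move]]:
    """Greedy BIC hill climb from the empty graph inside the skeleton.

    Moves are: add a directed edge between skeleton-adjacent nodes, delete
    an existing edge, or reverse one; the single best strictly-improving
    move is applied per iteration until none improves. Deterministic:
    moves are enumerated in sorted order and ties keep the first.
    """
    cache = _ScoreCache(data, levels or infer_levels(data))
    dag = nx.DiGraph()
    dag.add_nodes_from(skeleton.nodes)
    trace: list[Move] = []

    def fam(node: str) -> float:
        return cache.family(node, frozenset(dag.predecessors(node)))

    # score-equivalent orientations differ only by float noise; deltas within
    # this tolerance count as ties and the first candidate in sorted order wins
    tie_tol = 1e-6

    for _ in range(max_iter):
        pairs = sorted(tuple(sorted(e)) for e in skeleton.edges)
        candidates: list[tuple[str, tuple[str, str]]] = []
        for a, b in pairs:
            for u, v in ((a, b), (b, a)):
                if not dag.has_edge(u, v) and not dag.has_edge(v, u):
                    candidates.append(("add", (u, v)))
        for u, v in sorted(dag.edges):
            candidates.append(("delete", (u, v)))
            candidates.append(("reverse", (u, v)))
        deltas: list[tuple[str, tuple[str, str], float]] = []
        for op, (u, v) in candidates:
            if op == "add":
                if _creates_cycle(dag, u, v):
                    continue
                old = fam(v)
                new = cache.family(v, frozenset(dag.predecessors(v)) | {u})
                delta = new - old
            elif op == "delete":
                old = fam(v)
                new = cache.family(v, frozenset(dag.predecessors(v)) - {u})
                delta = new - old
            else:  # reverse u->v  =>  v->u
                dag.remove_edge(u, v)
                ok = not _creates_cycle(dag, v, u)
                if not ok:
                    dag.add_edge(u, v)
                    continue
                delta = (
                    cache.family(v, frozenset(dag.predecessors(v)))
                    - cache.family(v, frozenset(dag.predecessors(v)) | {u})
                    + cache.family(u, frozenset(dag.predecessors(u)) | {v})
                    - cache.family(u, frozenset(dag.predecessors(u)))
                )
                dag.add_edge(u, v)
            deltas.append((op, (u, v), delta))
        if not deltas:
            break
        top = max(d for _, _, d in deltas)
        if top <= tie_tol:
            break
        op, (u, v), delta = next(
            m for m in deltas if m[2] >= top - tie_tol
        )
        if op == "add":
            dag.add_edge(u, v)
        elif op == "delete":
            dag.remove_edge(u, v)
        else:
            dag.remove_edge(u, v)
            dag.add_edge(v, u)
        trace.append(Move(op, (u, v), delta))
    return dag, trace


def mmhc(
    data: pd.DataFrame,
    alpha: float = 0.05,
    *,
    max_cond: int = 3,
    adequacy: float = 5.0,
) -> tuple[nx.DiGraph, Skeleton, list[Move]]:
    """Max-Min Hill-Climbing: MMPC skeleton, then skeleton-restricted hill climb."""
    levels = infer_levels(data)
    skeleton = mmpc(data, alpha, max_cond=max_cond, adequacy=adequacy, levels=levels)
    dag, trace = hill_climb(data, skeleton, levels=levels)
    return dag, skeleton, trace


# ---------------------------------------------------------------------------
# Equivalence-class utilities
# ---------------------------------------------------------------------------


def cpdag(dag: nx.DiGraph) -> CPDAG:
    """CPDAG of a DAG: v-structure arcs stay directed, closure under Meek rules.

    Two DAGs are Markov equivalent iff their CPDAGs are equal.
    """
    order_check = list(nx.topological_sort(dag))  # raises on cycles
    del order_check
    nodes = tuple(sorted(dag.nodes))
    adj = {frozenset(e) for e in dag.edges}
    directed: set[tuple[str, str]] = set()
    # v-structures a -> c <- b with a, b non-adjacent
    for c in nodes:
        preds = sorted(dag.predecessors(c))
        for a, b in itertools.combinations(preds, 2):
            if frozenset((a, b)) not in adj:
                directed.add((a, c))
                directed.add((b, c))
    undirected = {e for e in adj if tuple(sorted(e)) not in _both_dirs(directed)}

    def is_adj(u, v):
        return frozenset((u, v)) in adj

    changed = True
    while changed:
        changed = False
        for e in sorted(undirected, key=sorted):
            u, v = sorted(e)
            for x, y in ((u, v), (v, u)):
                # Meek R1: w -> x, w not adjacent y  =>  x -> y
                r1 = any(
                    (w, x) in directed and not is_adj(w, y)
                    for w in dag.nodes if w not in (x, y)
                )
                # Meek R2: x -> w -> y already directed  =>  x -> y
                r2 = any(
                    (x, w) in directed and (w, y) in directed
                    for w in dag.nodes if w not in (x, y)
                )
                # Meek R3: x - w1 -> y, x - w2 -> y, w1,w2 non-adjacent  =>  x -> y
                r3 = False
                ws = [
                    w for w in dag.nodes
                    if w not in (x, y)
                    and frozenset((x, w)) in undirected
                    and (w, y) in directed
                ]
                for w1, w2 in itertools.combinations(sorted(ws), 2):
                    if not is_adj(w1, w2):
                        r3 = True
                        break
                if r1 or r2 or r3:
                    directed.add((x, y))
                    undirected.discard(e)
                    changed = True
                    break
            if changed:
                break
    return CPDAG(
        nodes=nodes,
        directed=frozenset(directed),
        undirected=frozenset(undirected),
    )


def _both_dirs(directed: set[tuple[str, str]]) -> set[tuple[str, str]]:
    return {tuple(sorted(e)) for e in directed}


def _pair_type(graph: nx.DiGraph | CPDAG, u: str, v: str) -> str:
    if isinstance(graph, CPDAG):
        if frozenset((u, v)) in graph.undirected:
            return "undirected"
        if (u, v) in graph.directed:
            return f"{u}->{v}"
        if (v, u) in graph.directed:
            return f"{v}->{u}"
        return "none"
    if graph.has_edge(u, v):
        return f"{u}->{v}"
    if graph.has_edge(v, u):
        return f"{v}->{u}"
    return "none"


def shd(a: nx.DiGraph | CPDAG, b: nx.DiGraph | CPDAG) -> int:
    """Structural Hamming distance: per node pair, 1 if the edge type differs.

    Accepts DAGs or CPDAGs; an insertion, deletion or re-orientation each
    costs one edit.
    """
    nodes_a = set(a.nodes)
    nodes_b = set(b.nodes)
    if nodes_a != nodes_b:
        raise ValueError("graphs must share a node set")
    dist = 0
    for u, v in itertools.combinations(sorted(nodes_a), 2):
        if _pair_type(a, u, v) != _pair_type(b, u, v):
            dist += 1
    return dist


def skeleton_f1(estimated: Skeleton | nx.DiGraph, truth: nx.DiGraph) -> float:
    """F1 of undirected edge recovery against a ground-truth DAG's skeleton."""
    if isinstance(estimated, Skeleton):
        est = set(estimated.edges)
    else:
        est = {frozenset(e) for e in estimated.edges}
    true = {frozenset(e) for e in truth.edges}
    tp = len(est & true)
    if tp == 0:
        return 0.0
    precision = tp / len(est)
    recall = tp / len(true)
    return 2 * precision * recall / (precision + recall)


def trace_to_frame(trace: Sequence[Move]) -> pd.DataFrame:
    """Search trace as a tidy table (iteration, operator, edge, score delta)."""
    return pd.DataFrame(
        {
            "iteration": range(1, len(trace) + 1),
            "operator": [m.op for m in trace],
            "edge": [f"{m.edge[0]}->{m.edge[1]}" for m in trace],
            "delta": [m.delta for m in trace],
        }
    )
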