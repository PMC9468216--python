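"""Synthetic CHARLS-like cohorts from a configurable ground-truth network.

The generator emulates an 11-variable categorical cohort of Chinese adults
aged 45+ whose dependence structure follows the network the analysis is
meant to recover: age, sleep duration and physical activity are parents of
multimorbidity; sex and age drive education and marital status; education
drives residence, which drives sleep. The published baseline table pins the
single-variable marginals; conditional rows are a log-linear association
model around those marginals, re-calibrated by iterative proportional
fitting so every pooled marginal is hit exactly (and P(MMD=1) = 0.538).

Also provides ancestral (forward) sampling, MCAR/MAR missingness injection
for testing imputation, and small fixed benchmark networks (chain, fork,
collider, sprinkler) used throughout the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .bn import CPT, BayesianNetwork, Factor, topological_order
from .codebook import CODEBOOK, MISSING, VARIABLES

__all__ = [
    "TABLE1_COUNTS",
    "GROUND_TRUTH_EDGES",
    "MissingnessSpec",
    "pooled_marginals",
    "dataset_from_table1",
    "charls_like_network",
    "ancestral_sample",
    "inject_missingness",
    "benchmark_networks",
]

#: Published stratified baseline counts: variable -> {code: (n without MMD,
#: n with MMD)}. Strata sizes are 9,129 (without) and 10,623 (with).
TABLE1_COUNTS: dict[str, dict[int, tuple[int, int]]] = {
    "sex": {1: (4507, 4806), 2: (4622, 5817)},
    "age": {1: (2018, 1466), 2: (3202, 3334), 3: (2514, 3719), 4: (1395, 2104)},
    "physical_activity": {1: (324, 454), 2: (2832, 3605), 3: (5973, 6564)},
    "education": {1: (3744, 4844), 2: (4101, 4554), 3: (1200, 1142), 4: (84, 83)},
    "residence": {1: (1709, 1892), 2: (640, 788), 3: (6738, 7898), 4: (42, 45)},
    "marital_status": {1: (7977, 8912), 2: (111, 130), 3: (982, 1522), 4: (59, 59)},
    "sleep": {
        1: (2408, 3951), 2: (2082, 2235), 3: (1754, 1630),
        4: (1957, 1860), 5: (928, 947),
    },
    "nap": {1: (3589, 3992), 2: (1573, 1910), 3: (3967, 4721)},
    "smoking": {0: (5315, 6215), 1: (3814, 4408)},
    "alcohol": {0: (5800, 7310), 1: (3329, 3313)},
}

#: The ground-truth DAG: 18 directed (parent, child, effect) triples.
#: The first ten edges are those documented for the study network; the
#: remaining eight are plausible lifestyle links frozen here so tests have a
#: fixed truth. ``effect`` is the log-linear association coefficient between
#: centred category scores (sign = direction of the association).
GROUND_TRUTH_EDGES: tuple[tuple[str, str, float], ...] = (
    ("age", "mmd", 0.55),
    ("sleep", "mmd", -0.45),
    ("physical_activity", "mmd", -0.45),
    ("age", "physical_activity", -0.60),
    ("sex", "education", -0.60),
    ("age", "education", -0.60),
    ("sex", "marital_status", 0.50),
    ("age", "marital_status", 0.80),
    ("education", "residence", -0.70),
    ("residence", "sleep", -0.45),
    # --- frozen plausible completions up to 18 edges ---
    ("age", "residence", 0.35),
    ("age", "nap", 0.40),
    ("nap", "sleep", -0.35),
    ("education", "physical_activity", 0.35),
    ("sex", "smoking", -1.50),
    ("age", "smoking", 0.25),
    ("smoking", "alcohol", 1.20),
    ("sex", "alcohol", -1.00),
)


def pooled_marginals() -> dict[str, dict[int, float]]:
    """Whole-cohort category frequencies implied by the baseline table."""
    n0 = sum(v[0] for v in TABLE1_COUNTS["sex"].values())
    n1 = sum(v[1] for v in TABLE1_COUNTS["sex"].values())
    total = n0 + n1
    out = {
        var: {code: (a + b) / total for code, (a, b) in counts.items()}
        for var, counts in TABLE1_COUNTS.items()
    }
    out["mmd"] = {0: n0 / total, 1: n1 / total}
    return out


def dataset_from_table1() -> pd.DataFrame:
    """Deterministic expansion of the baseline counts into a coded table.

    Each MMD stratum's columns independently reproduce the stratified
    counts exactly, so every per-variable summary (and the MMD prevalence)
    matches the published table; the within-stratum joint structure is
    arbitrary by construction.
    """
    frames = []
    for stratum in (0, 1):
        cols: dict[str, np.ndarray] = {}
        for var, counts in TABLE1_COUNTS.items():
            codes = np.repeat(
                [code for code in sorted(counts)],
                [counts[code][stratum] for code in sorted(counts)],
            )
            cols[var] = codes
        n = len(cols["sex"])
        cols["mmd"] = np.full(n, stratum)
        frames.append(pd.DataFrame(cols))
    df = pd.concat(frames, ignore_index=True)
    return df[list(VARIABLES)].astype(int)


# ---------------------------------------------------------------------------
# Ground-truth network construction
# ---------------------------------------------------------------------------


def _z_scores(k: int) -> np.ndarray:
    """Centred category scores in [-1, 1] (0 for a 1-category variable)."""
    if k == 1:
        return np.zeros(1)
    return (np.arange(k) - (k - 1) / 2) / ((k - 1) / 2)


def _calibrate_cpt(
    child: str,
    parents: tuple[str, ...],
    parent_joint: Factor,
    target: np.ndarray,
    effects: Mapping[tuple[str, str], float],
    cards: Mapping[str, int],
    tol: float = 1e-12,
    max_iter: int = 500,
) -> np.ndarray:
    """Log-linear CPT rows scaled (IPF) until the implied marginal hits target."""
    k = cards[child]
    zc = _z_scores(k)
    shape = tuple(cards[p] for p in parents) + (k,)
    log_w = np.zeros(shape)
    for i, p in enumerate(parents):
        zp = _z_scores(cards[p])
        ax = [1] * len(shape)
        ax[i] = cards[p]
        term = effects[(p, child)] * zp.reshape(ax) * zc.reshape([1] * len(parents) + [k])
        log_w = log_w + term
    w = np.exp(log_w)

    # parent joint aligned to `parents` axis order
    if parents:
        pj = parent_joint
        perm = [pj.scope.index(p) for p in parents]
        pvals = np.transpose(pj.values, perm)
    else:
        pvals = np.array(1.0)

    t = target.copy()
    for _ in range(max_iter):
        rows = w * t
        rows /= rows.sum(axis=-1, keepdims=True)
        implied = (pvals[..., None] * rows).reshape(-1, k).sum(axis=0)
        if np.max(np.abs(implied - target)) < tol:
            break
        t *= target / np.maximum(implied, 1e-300)
        t /= t.sum()
    rows = w * t
    rows /= rows.sum(axis=-1, keepdims=True)
    return rows


@lru_cache(maxsize=1)
def charls_like_network() -> BayesianNetwork:
    """The fixed 11-node / 18-edge ground-truth network.

    Every single-variable marginal equals the pooled baseline frequency
    (IPF-calibrated, so P(MMD=1) = 0.538 by construction); association
    strengths are the frozen coefficients in :data:`GROUND_TRUTH_EDGES`.
    """
    marg = pooled_marginals()
    states = {v: tuple(sorted(marg[v])) for v in VARIABLES}
    cards = {v: len(states[v]) for v in VARIABLES}
    effects = {(p, c): e for p, c, e in GROUND_TRUTH_EDGES}
    parents_of: dict[str, tuple[str, ...]] = {v: () for v in VARIABLES}
    for p, c, _ in GROUND_TRUTH_EDGES:
        parents_of[c] = parents_of[c] + (p,)

    import networkx as nx

    dag = nx.DiGraph()
    dag.add_nodes_from(VARIABLES)
    dag.add_edges_from((p, c) for p, c, _ in GROUND_TRUTH_EDGES)
    order = topological_order(dag)

    cpts: dict[str, CPT] = {}
    joint = Factor((), (), np.array(1.0))
    for node in order:
        parents = tuple(sorted(parents_of[node]))
        target = np.array([marg[node][code] for code in states[node]])
        if parents:
            pj = joint
            for v in pj.scope:
                if v not in parents:
                    pj = pj.marginalize(v)
        else:
            pj = Factor((), (), np.array(1.0))
        table = _calibrate_cpt(node, parents, pj, target, effects, cards)
        cpts[node] = CPT(node, parents, table)
        joint = joint.multiply(
            Factor(parents + (node,), tuple(cards[p] for p in parents) + (cards[node],), table)
        )
    return BayesianNetwork(cpts.values(), states)


# ---------------------------------------------------------------------------
# Sampling and missingness
# ---------------------------------------------------------------------------


def ancestral_sample(bn: BayesianNetwork, n: int, seed: int) -> pd.DataFrame:
    """Forward-sample ``n`` coded rows in topological order; seed-deterministic."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    order = bn.nodes
    cols: dict[str, np.ndarray] = {}
    for node in order:
        cpt = bn.cpts[node]
        k = bn.card(node)
        if cpt.parents:
            idx = np.zeros(n, dtype=np.int64)
            for p in cpt.parents:
                idx = idx * bn.card(p) + cols[f"__pos_{p}"]
            rows = cpt.table.reshape(-1, k)[idx]
        else:
            rows = np.broadcast_to(cpt.table, (n, k))
        cum = np.cumsum(rows, axis=1)
        u = rng.random(n)
        pos = (u[:, None] > cum).sum(axis=1).clip(0, k - 1)
        cols[f"__pos_{node}"] = pos
        cols[node] = np.asarray(bn.states[node])[pos]
    data = pd.DataFrame({v: cols[v] for v in order}).astype(int)
    canonical = [v for v in VARIABLES if v in data.columns]
    rest = [v for v in data.columns if v not in canonical]
    return data[canonical + rest] if canonical else data


@dataclass(frozen=True)
class MissingnessSpec:
    """How to punch holes into a complete dataset.

    MCAR masks each maskable cell independently at ``rate``; MAR masks a
    cell with probability ``sigmoid(a + slope * z(driver))`` where ``z`` is
    the driver's centred category score and ``a`` is solved so that the
    overall masked fraction equals ``rate``. The driver (and any column in
    ``exclude``) is never masked.
    """

    mechanism: str = "MCAR"  # "MCAR" | "MAR"
    rate: float = 0.1
    driver: str | None = None
    seed: int = 0
    exclude: tuple[str, ...] = ()
    slope: float = 1.0

    def __post_init__(self) -> None:
        if self.mechanism not in ("MCAR", "MAR"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not 0.0 <= self.rate <= 0.5:
            raise ValueError("rate must lie in [0, 0.5]")
        if self.mechanism == "MAR" and self.driver is None:
            raise ValueError("MAR requires a driver column")


def inject_missingness(
    data: pd.DataFrame, spec: MissingnessSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Return (masked copy with the MISSING sentinel, boolean mask frame)."""
    if (data.to_numpy() == MISSING).any():
        raise ValueError("input data must be complete")
    protected = set(spec.exclude)
    if spec.mechanism == "MAR":
        protected.add(spec.driver)
    maskable = [c for c in data.columns if c not in protected]
    rng = np.random.default_rng(spec.seed)
    mask = pd.DataFrame(False, index=data.index, columns=data.columns)
    if spec.rate > 0 and maskable:
        if spec.mechanism == "MCAR":
            m = rng.random((len(data), len(maskable))) < spec.rate
        else:
            driver_codes = np.sort(data[spec.driver].unique())
            z = _z_scores(len(driver_codes))
            zrow = z[np.searchsorted(driver_codes, data[spec.driver].to_numpy())]
            weights = np.bincount(
                np.searchsorted(driver_codes, data[spec.driver].to_numpy())
            ) / len(data)

            def mean_rate(a: float) -> float:
                return float(weights @ expit(a + spec.slope * z)) - spec.rate

            a = brentq(mean_rate, -40, 40)
            p = expit(a + spec.slope * zrow)
            m = rng.random((len(data), len(maskable))) < p[:, None]
        mask.loc[:, maskable] = m
    masked = data.copy()
    masked[mask] = MISSING
    return masked.astype(int), mask


# ---------------------------------------------------------------------------
# Fixed benchmark networks
# ---------------------------------------------------------------------------


def benchmark_networks() -> dict[str, BayesianNetwork]:
    """Small fixed networks (binary states 0/1) used by the test-suite.

    ``chain`` A->B->C, ``fork`` A<-C->B, ``collider`` A->C<-B, and a 4-node
    ``sprinkler`` (cloudy -> sprinkler/rain -> wet). CPTs are printed
    constants with strong effects so the structures are recoverable.
    """
    b = (0, 1)

    def node(child, parents, table):
        return CPT(child, parents, np.asarray(table, dtype=float))

    chain = BayesianNetwork(
        [
            node("A", (), [0.7, 0.3]),
            node("B", ("A",), [[0.8, 0.2], [0.2, 0.8]]),
            node("C", ("B",), [[0.75, 0.25], [0.25, 0.75]]),
        ],
        {"A": b, "B": b, "C": b},
    )
    fork = BayesianNetwork(
        [
            node("C", (), [0.5, 0.5]),
            node("A", ("C",), [[0.85, 0.15], [0.15, 0.85]]),
            node("B", ("C",), [[0.8, 0.2], [0.2, 0.8]]),
        ],
        {"A": b, "B": b, "C": b},
    )
    collider = BayesianNetwork(
        [
            node("A", (), [0.6, 0.4]),
            node("B", (), [0.4, 0.6]),
            node(
                "C",
                ("A", "B"),
                [[[0.95, 0.05], [0.5, 0.5]], [[0.5, 0.5], [0.05, 0.95]]],
            ),
        ],
        {"A": b, "B": b, "C": b},
    )
    sprinkler = BayesianNetwork(
        [
            node("cloudy", (), [0.5, 0.5]),
            node("sprinkler", ("cloudy",), [[0.5, 0.5], [0.9, 0.1]]),
            node("rain", ("cloudy",), [[0.8, 0.2], [0.2, 0.8]]),
            node(
                "wet",
                ("rain", "sprinkler"),
                [[[0.99, 0.01], [0.1, 0.9]], [[0.1, 0.9], [0.01, 0.99]]],
            ),
        ],
        {"cloudy": b, "sprinkler": b, "rain": b, "wet": b},
    )
    return {"chain": chain, "fork": fork, "collider": collider, "sprinkler": sprinkler}
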