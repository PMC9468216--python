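"""Export of learned structures and parameters.

Structure goes out as Graphviz DOT; structure plus CPTs as BIF-compatible
text; CPTs additionally as a tidy table (child, parent configuration,
category, probability) convenient for spreadsheets and plotting.
"""

from __future__ import annotations

import itertools
from typing import Iterable

import networkx as nx
import pandas as pd

from .bn import BayesianNetwork, topological_order

__all__ = ["to_dot", "to_bif", "cpts_to_frame"]


def to_dot(graph: nx.DiGraph | BayesianNetwork, name: str = "bn") -> str:
    """Render the directed structure as a DOT digraph (nodes sorted, stable output)."""
    dag = graph.dag if isinstance(graph, BayesianNetwork) else graph
    lines = [f"digraph {name} {{"]
    for node in sorted(dag.nodes):
        lines.append(f'  "{node}";')
    for u, v in sorted(dag.edges):
        lines.append(f'  "{u}" -> "{v}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def _fmt(p: float) -> str:
    return f"{p:.10g}"


def to_bif(bn: BayesianNetwork, name: str = "network") -> str:
    """Serialize structure and CPTs in the Interchange Format (BIF) dialect.

    States are the integer codes rendered as strings (``s0`` prefixes keep
    them valid identifiers for strict readers).
    """
    out = [f"network {name} {{\n}}"]
    for node in topological_order(bn.dag):
        states = ", ".join(f"s{c}" for c in bn.states[node])
        out.append(
            f"variable {node} {{\n"
            f"  type discrete [ {bn.card(node)} ] {{ {states} }};\n"
            f"}}"
        )
    for node in topological_order(bn.dag):
        cpt = bn.cpts[node]
        if not cpt.parents:
            row = ", ".join(_fmt(p) for p in cpt.table)
            out.append(f"probability ( {node} ) {{\n  table {row};\n}}")
            continue
        header = ", ".join(cpt.parents)
        body = []
        parent_states = [bn.states[p] for p in cpt.parents]
        for combo in itertools.product(*[range(len(s)) for s in parent_states]):
            labels = ", ".join(
                f"s{parent_states[i][j]}" for i, j in enumerate(combo)
            )
            row = ", ".join(_fmt(p) for p in cpt.table[combo])
            body.append(f"  ( {labels} ) {row};")
        out.append(f"probability ( {node} | {header} ) {{\n" + "\n".join(body) + "\n}}")
    return "\n".join(out) + "\n"


def cpts_to_frame(bn: BayesianNetwork) -> pd.DataFrame:
    """Tidy long-format CPTs: one row per (child, parent configuration, category)."""
    records: list[dict[str, object]] = []
    for node in topological_order(bn.dag):
        cpt = bn.cpts[node]
        parent_states = [bn.states[p] for p in cpt.parents]
        for combo in itertools.product(*[range(len(s)) for s in parent_states]):
            config = "; ".join(
                f"{p}={parent_states[i][j]}" for i, (p, j) in enumerate(zip(cpt.parents, combo))
            )
            for k, code in enumerate(bn.states[node]):
                records.append(
                    {
                        "child": node,
                        "parents": config,
                        "category": code,
                        "probability": float(cpt.table[combo + (k,)]),
                    }
                )
    return pd.DataFrame.from_records(
        records, columns=["child", "parents", "category", "probability"]
    )
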