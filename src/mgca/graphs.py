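"""Degree and hub analysis of significant causal graphs.

In-degree counts significant afferent (incoming) links of a node,
out-degree the efferent (outgoing) links, and total degree their sum.
A node is a hub of a given kind when its degree is at least one sample
standard deviation above the mean degree across nodes: target hubs by
in-degree, source hubs by out-degree, network hubs by total degree.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .significance import CausalGraph

__all__ = ["degrees", "detect_hubs", "hub_table", "compare_degrees", "DEGREE_KINDS"]

DEGREE_KINDS = ("in", "out", "total")
_KIND_COLUMN = {"in": "in_degree", "out": "out_degree", "total": "total_degree"}
_KIND_FLAG = {"in": "is_target_hub", "out": "is_source_hub", "total": "is_network_hub"}


def degrees(graph: CausalGraph) -> pd.DataFrame:
    """Count significant directed links per node.

    Returns a DataFrame indexed by node with ``in_degree``,
    ``out_degree`` and ``total_degree`` columns.  The handshake identity
    (sum of in-degrees = sum of out-degrees = number of significant
    links) is asserted on every call.
    """
    nodes = list(graph.node_labels)
    sig = graph.significant_edges
    in_deg = sig["target"].value_counts().reindex(nodes, fill_value=0)
    out_deg = sig["source"].value_counts().reindex(nodes, fill_value=0)
    table = pd.DataFrame(
        {
            "in_degree": in_deg.astype(int),
            "out_degree": out_deg.astype(int),
        },
        index=pd.Index(nodes, name="node"),
    )
    table["total_degree"] = table["in_degree"] + table["out_degree"]
    n_links = len(sig)
    assert table["in_degree"].sum() == table["out_degree"].sum() == n_links
    return table


def detect_hubs(
    table: pd.DataFrame, kind: str = "total", ddof: int = 1
) -> pd.Series:
    """Flag hubs of one kind: degree >= mean + 1 SD across nodes.

    Sample standard deviation (``ddof=1``) by default, appropriate for
    the small node counts of ROI networks.  When the SD is zero (all
    degrees equal) no node is a hub — otherwise every node would
    trivially qualify.
    """
    if kind not in DEGREE_KINDS:
        raise ValueError(f"kind must be one of {DEGREE_KINDS}")
    if len(table) < 2:
        raise ValueError("need at least 2 nodes")
    values = table[_KIND_COLUMN[kind]].to_numpy(dtype=float)
    sd = values.std(ddof=ddof)
    if sd == 0:
        flags = np.zeros(len(values), dtype=bool)
    else:
        flags = values >= values.mean() + sd
    return pd.Series(flags, index=table.index, name=_KIND_FLAG[kind])


def hub_table(graph: CausalGraph, ddof: int = 1) -> pd.DataFrame:
    """Degree table with all three hub flags attached."""
    table = degrees(graph)
    for kind in DEGREE_KINDS:
        table[_KIND_FLAG[kind]] = detect_hubs(table, kind, ddof=ddof)
    return table


def compare_degrees(
    tables_a: list[pd.DataFrame], tables_b: list[pd.DataFrame]
) -> pd.DataFrame:
    """Pooled-variance two-sample t-test of each node's degrees across groups.

    ``tables_a`` / ``tables_b`` are per-subject degree tables sharing a
    node index.  Returns one row per (node, kind) with t and two-sided p.
    """
    if len(tables_a) < 2 or len(tables_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    nodes = list(tables_a[0].index)
    for tbl in list(tables_a) + list(tables_b):
        if list(tbl.index) != nodes:
            raise ValueError("all degree tables must share the same node set")
    rows = []
    for kind in DEGREE_KINDS:
        col = _KIND_COLUMN[kind]
        a = np.array([tbl[col].to_numpy(dtype=float) for tbl in tables_a])
        b = np.array([tbl[col].to_numpy(dtype=float) for tbl in tables_b])
        for idx, node in enumerate(nodes):
            t, p = pooled_t_test(a[:, idx], b[:, idx])
            rows.append(
                {"node": node, "kind": kind, "t": float(t), "p": float(p)}
            )
    return pd.DataFrame(rows)


def pooled_t_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Classic pooled-variance two-sample t with two-sided p.

    Degenerate inputs (zero pooled variance) give t = 0, p = 1 for equal
    means and +/-inf, p = 0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    df = na + nb - 2
    diff = a.mean() - b.mean()
    pooled = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    if se == 0:
        return (0.0, 1.0) if diff == 0 else (float(np.sign(diff)) * np.inf, 0.0)
    t = diff / se
    return float(t), float(2.0 * stats.t.sf(abs(t), df))
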