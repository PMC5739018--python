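"""Cross-year conservation of module networks via graph intersection.

For each module, its correlation subnetwork is extracted per year, a
per-module edge threshold is chosen by scanning |rho| cut-offs for the
largest value that still leaves the network dominated by one connected
component, the two filtered yearly graphs are intersected (only vertices
and edges present in both years survive), and conservation is reported as
the percentage of shared vertices and edges relative to the two-year
union — the Venn-diagram reading of "shared".
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd


def module_graph(rho: pd.DataFrame, members, pvals: pd.DataFrame = None, year=None) -> nx.Graph:
    """Complete weighted subnetwork of a module from a full correlation matrix."""
    members = [m for m in members if m in rho.columns]
    g = nx.Graph(year=year)
    g.add_nodes_from(members)
    sub = rho.loc[members, members]
    for i, a in enumerate(members):
        for b in members[i + 1 :]:
            attrs = {"rho": float(sub.loc[a, b])}
            if pvals is not None:
                attrs["p"] = float(pvals.loc[a, b])
            g.add_edge(a, b, **attrs)
    return g


def filter_graph(g: nx.Graph, threshold: float, max_p: float = None) -> nx.Graph:
    """Drop edges with |rho| below the threshold (and optionally weak p), then isolates."""
    h = nx.Graph(**g.graph)
    h.add_nodes_from(g.nodes(data=True))
    for a, b, attrs in g.edges(data=True):
        if abs(attrs["rho"]) < threshold:
            continue
        if max_p is not None and attrs.get("p", 0.0) > max_p:
            continue
        h.add_edge(a, b, **attrs)
    h.remove_nodes_from(list(nx.isolates(h)))
    return h


def threshold_scan(g: nx.Graph, grid=None, max_p: float = None) -> pd.DataFrame:
    """Component structure of the filtered graph along a threshold grid.

    Returns a DataFrame with columns ``t``, ``n_components``,
    ``largest_fraction`` (fraction of surviving vertices in the largest
    component; 0 for an empty graph) and ``main_fraction`` (largest
    component relative to the module's FULL vertex set — the quantity that
    measures whether filtration has broken the module network apart).
    """
    n_total = g.number_of_nodes()
    if n_total == 0:
        raise ValueError("empty graph")
    if grid is None:
        grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)
    rows = []
    for t in grid:
        h = filter_graph(g, float(t), max_p=max_p)
        n = h.number_of_nodes()
        if n == 0:
            rows.append(
                {"t": float(t), "n_components": 0, "largest_fraction": 0.0,
                 "main_fraction": 0.0}
            )
            continue
        comps = list(nx.connected_components(h))
        largest = max(len(c) for c in comps)
        rows.append(
            {
                "t": float(t),
                "n_components": len(comps),
                "largest_fraction": largest / n,
                "main_fraction": largest / n_total,
            }
        )
    return pd.DataFrame(rows)


def choose_threshold(
    curve: pd.DataFrame, floor: float = 0.5, main_fraction: float = 0.8
) -> tuple[float, bool]:
    """Largest threshold >= floor keeping the main component intact.

    Returns ``(t_star, degraded)``; if no threshold at or above the floor
    retains at least ``main_fraction`` of surviving vertices in the largest
    component, the floor is returned with ``degraded=True``.
    """
    if curve.empty:
        raise ValueError("empty threshold curve")
    col = "main_fraction" if "main_fraction" in curve.columns else "largest_fraction"
    ok = curve[
        (curve["t"] >= floor)
        & (curve[col] >= main_fraction)
        & (curve["n_components"] > 0)
    ]
    if ok.empty:
        return float(floor), True
    return float(ok["t"].max()), False


def intersect_graphs(ga: nx.Graph, gb: nx.Graph) -> tuple[nx.Graph, float, float]:
    """Venn intersection of two filtered yearly graphs.

    Shared vertices/edges are expressed as percentages of the two-year
    UNION of vertices/edges.  Intersected edges carry both years'
    correlations and their mean.
    """
    va, vb = set(ga.nodes), set(gb.nodes)
    v_common, v_union = va & vb, va | vb
    ea = {frozenset(e) for e in ga.edges}
    eb = {frozenset(e) for e in gb.edges}
    e_common = {e for e in ea & eb if e <= v_common}
    e_union = ea | eb
    gi = nx.Graph()
    gi.add_nodes_from(v_common)
    for e in e_common:
        a, b = tuple(e)
        ra, rb = ga.edges[a, b]["rho"], gb.edges[a, b]["rho"]
        gi.add_edge(a, b, rho_a=ra, rho_b=rb, rho=(ra + rb) / 2.0)
    vertex_pct = 100.0 * len(v_common) / len(v_union) if v_union else 0.0
    edge_pct = 100.0 * len(e_common) / len(e_union) if e_union else 0.0
    return gi, vertex_pct, edge_pct


@dataclass
class ModuleConservation:
    module: int
    threshold_a: float
    threshold_b: float
    degraded_a: bool
    degraded_b: bool
    intersected: nx.Graph
    vertex_pct: float
    edge_pct: float


def conserve_module(
    rho_a: pd.DataFrame,
    rho_b: pd.DataFrame,
    members,
    module: int = 0,
    floor: float = 0.5,
    main_fraction: float = 0.8,
    pvals_a: pd.DataFrame = None,
    pvals_b: pd.DataFrame = None,
    max_p: float = None,
) -> ModuleConservation:
    """End-to-end conservation analysis for one module."""
    ga = module_graph(rho_a, members, pvals=pvals_a, year="a")
    gb = module_graph(rho_b, members, pvals=pvals_b, year="b")
    ta, da = choose_threshold(threshold_scan(ga, max_p=max_p), floor, main_fraction)
    tb, db = choose_threshold(threshold_scan(gb, max_p=max_p), floor, main_fraction)
    gi, v_pct, e_pct = intersect_graphs(
        filter_graph(ga, ta, max_p=max_p), filter_graph(gb, tb, max_p=max_p)
    )
    return ModuleConservation(
        module=module,
        threshold_a=ta,
        threshold_b=tb,
        degraded_a=da,
        degraded_b=db,
        intersected=gi,
        vertex_pct=v_pct,
        edge_pct=e_pct,
    )


def conservation_summary(vertex_pcts, edge_pcts=None) -> dict:
    """Aggregate per-module shared-vertex/-edge percentages.

    Accepts either two sequences of percentages or a list of
    :class:`ModuleConservation` reports as the first argument.
    """
    if edge_pcts is None:
        reports = list(vertex_pcts)
        if not reports:
            raise ValueError("need at least one module report")
        vertex_pcts = [r.vertex_pct for r in reports]
        edge_pcts = [r.edge_pct for r in reports]
    v = np.asarray(list(vertex_pcts), dtype=float)
    e = np.asarray(list(edge_pcts), dtype=float)
    if v.size == 0 or e.size == 0:
        raise ValueError("need at least one module")
    return {
        "mean_vertex_pct": float(v.mean()),
        "mean_edge_pct": float(e.mean()),
        "min_vertex_pct": float(v.min()),
        "max_vertex_pct": float(v.max()),
        "min_edge_pct": float(e.min()),
        "max_edge_pct": float(e.max()),
        "n_modules": int(v.size),
    }
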