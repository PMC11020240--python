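"""Multi-edge trait network combining the four phenomics analyses.

Edge types: GC (genetic correlation), PC (phenotypic correlation),
pleiotropy (VSI > 0), and directed MR edges.  Following the display rule
used for this kind of summary figure, PC and MR edges are emitted only
when the trait pair also carries a GC or pleiotropy edge; GC and
pleiotropy edges are unconditional.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd


def export_network(
    pc: pd.DataFrame | None = None,
    gc: pd.DataFrame | None = None,
    vsi: pd.DataFrame | None = None,
    mr: pd.DataFrame | None = None,
) -> nx.MultiDiGraph:
    """Assemble the trait-pair multigraph.

    Inputs are the significant-pair frames of each analysis: ``pc``
    (trait_i, trait_j, r, significant), ``gc`` (trait_i, trait_j, rg,
    significant), ``vsi`` (trait_i, trait_j, vsi), ``mr`` (exposure,
    outcome, consensus_significant, ivw_estimate).  Undirected edge types
    are stored as single directed edges with ``directed=False``.
    """
    g = nx.MultiDiGraph()
    anchored: set[frozenset] = set()

    if gc is not None:
        sig = gc[gc.get("significant", pd.Series(True, index=gc.index))]
        for _, r in sig.iterrows():
            g.add_edge(r["trait_i"], r["trait_j"], key="GC", type="GC",
                       weight=abs(float(r["rg"])), directed=False)
            anchored.add(frozenset((r["trait_i"], r["trait_j"])))
    if vsi is not None:
        for _, r in vsi.iterrows():
            if r["vsi"] <= 0:
                continue
            g.add_edge(r["trait_i"], r["trait_j"], key="pleiotropy",
                       type="pleiotropy", weight=float(r["vsi"]), directed=False)
            anchored.add(frozenset((r["trait_i"], r["trait_j"])))
    if pc is not None:
        sig = pc[pc.get("significant", pd.Series(True, index=pc.index))]
        for _, r in sig.iterrows():
            if frozenset((r["trait_i"], r["trait_j"])) not in anchored:
                continue
            g.add_edge(r["trait_i"], r["trait_j"], key="PC", type="PC",
                       weight=abs(float(r["r"])), directed=False)
    if mr is not None:
        sig = mr[mr.get("consensus_significant", pd.Series(True, index=mr.index))]
        for _, r in sig.iterrows():
            if frozenset((r["exposure"], r["outcome"])) not in anchored:
                continue
            g.add_edge(r["exposure"], r["outcome"], key="MR", type="MR",
                       weight=abs(float(r["ivw_estimate"])), directed=True)
    return g


def write_network(graph: nx.MultiDiGraph, path) -> None:
    """Write as GraphML (attributes are kept primitive for portability)."""
    nx.write_graphml(graph, str(path))


def edge_list(graph: nx.MultiDiGraph) -> pd.DataFrame:
    rows = [
        {"trait_i": u, "trait_j": v, "type": d["type"],
         "weight": d["weight"], "directed": d["directed"]}
        for u, v, d in graph.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["trait_i", "trait_j", "type", "weight", "directed"])
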