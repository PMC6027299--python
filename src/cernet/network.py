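"""Tripartite ceRNA network, betweenness hubs, and subnetwork coverage.

The network built from ceRNA triples is tripartite in nodes but bipartite
in edges: every edge joins a miRNA to either a lncRNA or an mRNA (never
lncRNA–mRNA directly — that relationship is mediated by the shared
miRNA).  Hub lncRNAs are ranked by unnormalized betweenness centrality
BC(i) = Σ_{s≠i≠t} p_st(i)/p_st, the fraction of shortest paths between
other node pairs passing through i, with each unordered pair counted
once and endpoints excluded.  For each hub, the associated subnetwork is
by default *triple-scoped*: its members are the miRNAs and mRNAs of the
triples containing the hub.  A pure graph-neighborhood alternative
(first-neighbor miRNAs, their mRNA neighbors) is available via
``scope="graph"``.

Coverage statistics report what fraction of the full network's miRNAs,
mRNAs and triples each hub subnetwork (and their union) accounts for,
as percentages rounded to two decimals.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd


def pct(count: int, total: int) -> float:
    """Percentage rounded to two decimals; 0.0 (with warning) when total is 0."""
    if total == 0:
        warnings.warn("percentage of an empty total reported as 0", stacklevel=2)
        return 0.0
    return round(100.0 * count / total, 2)


def build_network(triples: pd.DataFrame) -> nx.Graph:
    """Graph from a triple table: nodes carry a ``cls`` attribute.

    Edges are the unique {lnc, mirna} and {mirna, mrna} pairs appearing
    in any triple (idempotent under duplicated triples).  An id used in
    two different roles is a class conflict and raises.
    """
    if len(triples) == 0:
        warnings.warn("building a network from zero triples", stacklevel=2)
    g = nx.Graph()
    cls_of: dict[str, str] = {}

    def add_node(node: str, cls: str) -> None:
        prev = cls_of.get(node)
        if prev is not None and prev != cls:
            raise ValueError(f"node {node!r} appears as both {prev} and {cls}")
        cls_of[node] = cls
        g.add_node(node, cls=cls)

    for row in triples.itertuples(index=False):
        add_node(row.lnc_id, "lncRNA")
        add_node(row.mirna_id, "miRNA")
        add_node(row.mrna_id, "mRNA")
        g.add_edge(row.lnc_id, row.mirna_id, kind="lnc-mirna")
        g.add_edge(row.mirna_id, row.mrna_id, kind="mirna-mrna")
    return g


def betweenness(graph: nx.Graph, *, normalized: bool = False) -> dict[str, float]:
    """Betweenness centrality; unnormalized path counts by default.

    Undirected convention: each unordered (s, t) pair contributes once,
    endpoints excluded.  On disconnected graphs, pairs with no connecting
    path simply contribute nothing.
    """
    return nx.betweenness_centrality(graph, normalized=normalized)


def rank_bc(graph: nx.Graph, bc: dict[str, float] | None = None) -> pd.DataFrame:
    """Nodes sorted by descending BC with cumulative percentage.

    Ties are broken lexicographically by node id so that rankings are
    deterministic.  If total BC is zero the cumulative column is reported
    as 0 with a warning.
    """
    if bc is None:
        bc = betweenness(graph)
    cls = nx.get_node_attributes(graph, "cls")
    rows = sorted(bc.items(), key=lambda kv: (-kv[1], kv[0]))
    out = pd.DataFrame(rows, columns=["node", "bc"])
    out.insert(1, "cls", [cls.get(n, "") for n in out["node"]])
    total = out["bc"].sum()
    if total == 0:
        if len(out):
            warnings.warn("total betweenness is 0; cumulative_pct reported as 0",
                          stacklevel=2)
        out["cumulative_pct"] = 0.0
    else:
        out["cumulative_pct"] = out["bc"].cumsum() / total * 100.0
    return out


def select_hubs(ranked: pd.DataFrame, k: int = 3, restrict_class: str = "lncRNA") -> list[str]:
    """Top-k nodes of one class by BC from a :func:`rank_bc` table."""
    if k < 0:
        raise ValueError("k must be non-negative")
    candidates = ranked.loc[ranked["cls"] == restrict_class, "node"].tolist()
    if len(candidates) < k:
        warnings.warn(
            f"only {len(candidates)} {restrict_class} candidate(s) for k={k}",
            stacklevel=2,
        )
    return candidates[:k]


@dataclass
class SubnetworkReport:
    """Members and coverage of one hub lncRNA's associated subnetwork."""

    hub_id: str
    mirnas: frozenset[str]
    mrnas: frozenset[str]
    triples: tuple[tuple[str, str, str], ...]
    coverage: dict[str, float] = field(default_factory=dict)


def _triple_tuples(triples: pd.DataFrame) -> list[tuple[str, str, str]]:
    return list(zip(triples["lnc_id"], triples["mirna_id"], triples["mrna_id"]))


def network_totals(triples: pd.DataFrame) -> dict[str, int]:
    """Full-network miRNA / mRNA / triple counts used as coverage denominators."""
    return {
        "mirnas": int(triples["mirna_id"].nunique()),
        "mrnas": int(triples["mrna_id"].nunique()),
        "triples": int(len(triples.drop_duplicates(["lnc_id", "mirna_id", "mrna_id"]))),
    }


def coverage_pcts(n_mirnas: int, n_mrnas: int, n_triples: int,
                  totals: dict[str, int]) -> dict[str, float]:
    return {
        "demi_pct": pct(n_mirnas, totals["mirnas"]),
        "dem_pct": pct(n_mrnas, totals["mrnas"]),
        "triple_pct": pct(n_triples, totals["triples"]),
    }


def extract_subnetwork(
    triples: pd.DataFrame,
    hub_id: str,
    *,
    graph: nx.Graph | None = None,
    scope: str = "triples",
) -> SubnetworkReport:
    """Subnetwork of one hub lncRNA with coverage percentages.

    ``scope="triples"`` (default): members are the miRNAs and mRNAs of
    triples containing the hub.  ``scope="graph"``: members are the hub's
    graph neighbors (miRNAs) and their mRNA neighbors — the full two-hop
    neighborhood, which can be larger because a neighboring miRNA drags
    in mRNAs from triples with other lncRNAs.
    """
    hub_triples = triples.loc[triples["lnc_id"] == hub_id]
    if len(hub_triples) == 0 and (graph is None or hub_id not in graph):
        raise ValueError(f"hub {hub_id!r} not present in the network")
    if scope == "triples":
        mirnas = frozenset(hub_triples["mirna_id"])
        mrnas = frozenset(hub_triples["mrna_id"])
    elif scope == "graph":
        if graph is None:
            graph = build_network(triples)
        cls = nx.get_node_attributes(graph, "cls")
        mirnas = frozenset(n for n in graph.neighbors(hub_id) if cls[n] == "miRNA")
        mrnas = frozenset(
            g for m in mirnas for g in graph.neighbors(m) if cls[g] == "mRNA"
        )
    else:
        raise ValueError("scope must be 'triples' or 'graph'")
    totals = network_totals(triples)
    report = SubnetworkReport(
        hub_id=hub_id,
        mirnas=mirnas,
        mrnas=mrnas,
        triples=tuple(_triple_tuples(hub_triples)),
    )
    report.coverage = coverage_pcts(len(mirnas), len(mrnas), len(report.triples), totals)
    return report


def coverage_union(reports: list[SubnetworkReport], triples: pd.DataFrame) -> dict:
    """Union coverage across hubs (member sets united, then percentaged)."""
    if not reports:
        raise ValueError("need at least one subnetwork report")
    mirnas = frozenset().union(*(r.mirnas for r in reports))
    mrnas = frozenset().union(*(r.mrnas for r in reports))
    trips = set().union(*(set(r.triples) for r in reports))
    totals = network_totals(triples)
    out = {"mirnas": len(mirnas), "mrnas": len(mrnas), "triples": len(trips)}
    out.update(coverage_pcts(len(mirnas), len(mrnas), len(trips), totals))
    return out


def coverage_table(reports: list[SubnetworkReport], triples: pd.DataFrame) -> pd.DataFrame:
    """Coverage summary: union row, one row per hub, full-network row.

    Columns: network, n_demis, demi_pct, n_dems, dem_pct, n_triples,
    triple_pct.  The full-network row is 100% in every column by
    construction.
    """
    totals = network_totals(triples)
    rows = []
    union = coverage_union(reports, triples)
    rows.append((f"{len(reports)} hub lncRNAs", union["mirnas"], union["demi_pct"],
                 union["mrnas"], union["dem_pct"], union["triples"], union["triple_pct"]))
    for r in reports:
        rows.append((r.hub_id, len(r.mirnas), r.coverage["demi_pct"],
                     len(r.mrnas), r.coverage["dem_pct"],
                     len(r.triples), r.coverage["triple_pct"]))
    rows.append(("full network", totals["mirnas"], pct(totals["mirnas"], totals["mirnas"]),
                 totals["mrnas"], pct(totals["mrnas"], totals["mrnas"]),
                 totals["triples"], pct(totals["triples"], totals["triples"])))
    return pd.DataFrame(rows, columns=[
        "network", "n_demis", "demi_pct", "n_dems", "dem_pct",
        "n_triples", "triple_pct",
    ])


def coverage_table_from_counts(counts: dict) -> pd.DataFrame:
    """Coverage table recomputed from member *counts* alone.

    ``counts`` has the layout of the packaged worked-example fixture:
    ``{"totals": {...}, "union": {...}, "hubs": {hub: {...}}}`` where each
    inner dict carries ``mirnas``, ``mrnas`` and ``triples`` counts.  The
    percentages are computed here (same :func:`pct` path as the set-based
    table), so a transcribed count table can be checked against its
    published percentages.
    """
    totals = counts["totals"]
    rows = []

    def add(name: str, c: dict) -> None:
        rows.append((name, c["mirnas"], pct(c["mirnas"], totals["mirnas"]),
                     c["mrnas"], pct(c["mrnas"], totals["mrnas"]),
                     c["triples"], pct(c["triples"], totals["triples"])))

    add(f'{len(counts["hubs"])} hub lncRNAs', counts["union"])
    for hub, c in counts["hubs"].items():
        add(hub, c)
    add("full network", totals)
    return pd.DataFrame(rows, columns=[
        "network", "n_demis", "demi_pct", "n_dems", "dem_pct",
        "n_triples", "triple_pct",
    ])


def is_connected(graph: nx.Graph) -> bool:
    """Whether the network is a single connected component (reported, never required)."""
    return graph.number_of_nodes() > 0 and nx.is_connected(graph)


# -- exports -------------------------------------------------------------------


def write_sif(graph: nx.Graph, path: str | Path) -> Path:
    """Simple-interaction-format export (``node1<TAB>kind<TAB>node2``)."""
    path = Path(path)
    with path.open("w") as fh:
        for u, v, data in sorted(graph.edges(data=True)):
            fh.write(f"{u}\t{data.get('kind', 'interacts')}\t{v}\n")
    return path


def write_graphml(graph: nx.Graph, path: str | Path,
                  bc: dict[str, float] | None = None) -> Path:
    """GraphML export with class and (optionally) betweenness attributes."""
    path = Path(path)
    g = graph.copy()
    if bc is not None:
        nx.set_node_attributes(g, bc, "bc")
    nx.write_graphml(g, path)
    return path
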