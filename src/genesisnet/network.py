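"""Build the simple undirected interaction graph and per-protein statistics.

The graph contains exactly the genes that retain at least one interaction;
genes with no interaction data are handled upstream via the "fraction with
interactions" attribute, never as isolated vertices at build time.

Betweenness centrality is reported as a fraction of vertex pairs: for vertex
``v`` in a graph with ``n`` vertices,

    bc(v) = [ sum over unordered pairs s < t (s, t != v) of
              sigma_st(v) / sigma_st ] / [ (n - 1)(n - 2) / 2 ]

with disconnected pairs contributing zero.  This makes "fraction of all
shortest paths containing v" literal; only relative group comparisons are
used downstream, which are invariant to the normalization choice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from genesisnet.dataio import EdgeTable, GeneCatalog

logger = logging.getLogger(__name__)


def build_network(
    edges: EdgeTable,
    restrict_to: Iterable | None = None,
    source_filter: str | None = None,
) -> nx.Graph:
    """Simple undirected graph from a canonical edge table.

    *restrict_to* keeps only edges with both endpoints in the given gene set;
    *source_filter* keeps only edges with a matching source tag.  The vertex
    set is exactly the endpoints of retained edges.
    """
    keep = set(restrict_to) if restrict_to is not None else None
    net = nx.Graph()
    for a, b, source in edges.edges:
        if source_filter is not None and source != source_filter:
            continue
        if keep is not None and (a not in keep or b not in keep):
            continue
        net.add_edge(a, b, source=source)
    if net.number_of_edges() == 0:
        logger.warning("network is empty after filtering")
    return net


@dataclass
class StickyFilterLog:
    """Per-round record of vertices removed by the sticky-protein filter."""

    threshold: int
    rounds: list = field(default_factory=list)  # list of sorted id lists

    @property
    def removed(self) -> set:
        return {g for rnd in self.rounds for g in rnd}

    @property
    def n_rounds(self) -> int:
        return len(self.rounds)


def filter_sticky(net: nx.Graph, threshold: int = 50) -> tuple[nx.Graph, StickyFilterLog]:
    """Iteratively remove likely experimental-artifact hub proteins.

    Each round removes *all* vertices whose current degree exceeds
    *threshold* simultaneously, then recomputes degrees; rounds repeat until
    no vertex exceeds the threshold.  Simultaneous-per-round removal is
    order-independent.  Vertices isolated by a removal stay in the graph with
    degree zero.
    """
    filtered = net.copy()
    log = StickyFilterLog(threshold=threshold)
    while True:
        over = sorted(v for v, d in filtered.degree() if d > threshold)
        if not over:
            break
        filtered.remove_nodes_from(over)
        log.rounds.append(over)
    if log.rounds:
        logger.info(
            "sticky filter removed %d vertices in %d round(s) at threshold %d",
            len(log.removed),
            log.n_rounds,
            threshold,
        )
    return filtered, log


def degree_centrality(net: nx.Graph) -> dict:
    """Incident-edge count per vertex."""
    return dict(net.degree())


def betweenness_centrality(net: nx.Graph) -> dict:
    """Pair-normalized betweenness (see module docstring); all zeros for n < 3."""
    n = net.number_of_nodes()
    if n < 3:
        return {v: 0.0 for v in net}
    # networkx's normalized undirected betweenness divides by (n-1)(n-2)/2,
    # excludes endpoints, and gives disconnected pairs zero weight — exactly
    # the definition above.
    return nx.betweenness_centrality(net, normalized=True)


def normalize_by_length(values: Mapping, catalog: GeneCatalog) -> dict:
    """Divide each gene's statistic by its protein length in amino acids."""
    out = {}
    for gene, value in values.items():
        if gene not in catalog:
            raise KeyError(f"no length available for gene {gene!r}")
        out[gene] = value / catalog[gene].length_aa
    return out


def centrality_table(net: nx.Graph, catalog: GeneCatalog) -> pd.DataFrame:
    """Per-gene degree, betweenness, and their length-normalized variants."""
    deg = degree_centrality(net)
    btw = betweenness_centrality(net)
    genes = sorted(net.nodes())
    return pd.DataFrame(
        {
            "gene_id": genes,
            "degree": [deg[g] for g in genes],
            "betweenness": [btw[g] for g in genes],
            "degree_per_aa": [deg[g] / catalog[g].length_aa for g in genes],
            "betweenness_per_aa": [btw[g] / catalog[g].length_aa for g in genes],
        }
    )


def group_summary(values: Mapping, labels: Mapping) -> pd.DataFrame:
    """Per-group count, mean, and standard error of a per-gene statistic.

    Only genes present in both *values* and *labels* contribute.  The
    standard error uses the sample standard deviation (ddof=1); groups with
    n < 2 get NaN standard error, n = 0 rows get NaN mean.
    """
    by_group: dict[str, list[float]] = {}
    # iterate in sorted gene order so floating-point sums (and hence the
    # output) are independent of input dict order
    for gene in sorted(values):
        group = labels.get(gene)
        if group is not None:
            by_group.setdefault(group, []).append(float(values[gene]))
    rows = []
    for group in sorted(set(labels.values())):
        vals = by_group.get(group, [])
        n = len(vals)
        mean = sum(vals) / n if n else math.nan
        if n >= 2:
            sd = math.sqrt(sum((x - mean) ** 2 for x in vals) / (n - 1))
            se = sd / math.sqrt(n)
        else:
            se = math.nan
        rows.append({"group": group, "n": n, "mean": mean, "se": se})
    return pd.DataFrame(rows)


@dataclass
class ComponentReport:
    """One connected component of an ego subnetwork."""

    size: int
    members: list
    n_seeds: int
    group_counts: dict


def ego_subnetwork(
    net: nx.Graph,
    seeds: Iterable,
    radius: int = 1,
    labels: Mapping | None = None,
) -> tuple[nx.Graph, list]:
    """Induced subgraph on seed vertices plus neighbors within *radius* hops.

    Seeds absent from the network (no interactions) are logged and excluded.
    Returns the subgraph and per-component reports (size, members, seed
    count, and per-group membership counts when *labels* is given), sorted by
    decreasing size.
    """
    seeds = set(seeds)
    present = seeds & set(net.nodes())
    missing = seeds - present
    if missing:
        logger.info("%d seed gene(s) have no interactions and were excluded", len(missing))
    if not present:
        logger.warning("no seed genes present in network; empty ego subnetwork")
        return nx.Graph(), []
    nodes = set(present)
    frontier = set(present)
    for _ in range(radius):
        nxt = set()
        for v in frontier:
            nxt.update(net.neighbors(v))
        nxt -= nodes
        nodes.update(nxt)
        frontier = nxt
    sub = net.subgraph(nodes).copy()
    reports = []
    for comp in nx.connected_components(sub):
        members = sorted(comp)
        group_counts: dict[str, int] = {}
        if labels is not None:
            for g in members:
                group = labels.get(g, "unclassified")
                group_counts[group] = group_counts.get(group, 0) + 1
        reports.append(
            ComponentReport(
                size=len(members),
                members=members,
                n_seeds=len(comp & present),
                group_counts=group_counts,
            )
        )
    reports.sort(key=lambda r: (-r.size, r.members))
    return sub, reports
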