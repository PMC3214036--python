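"""Protein–protein interaction network construction and summary statistics.

The interaction network is a simple undirected graph: self-interactions are
dropped and duplicate reports (in either order, from any source database)
collapse to one edge. Category subnetworks follow two membership rules —
``one_or_both`` (an edge survives if at least one endpoint belongs to the
category; this is the rule behind all quantitative statistics) and ``both``
(both endpoints must belong; used only for visual exports). Degree and
component statistics are computed within the extracted subnetwork, over
interacting proteins only.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats as sps

from .classify import ClassifiedGeneTable, Group, round_half_up
from .io import EdgeList, EdgePair, write_edge_list

#: Report row order for group subnetwork summaries.
GROUP_ROW_ORDER = (Group.DL, Group.DV, Group.L, Group.V, Group.DU)


def build_network(edges: EdgeList) -> nx.Graph:
    """Clean a raw edge list into a simple undirected graph.

    Self-pairs are ignored; A–B and B–A collapse; the node set consists of
    the endpoints of surviving edges (no isolated nodes are introduced).
    """
    g = nx.Graph()
    for pair in edges:
        if pair.a == pair.b:
            continue
        g.add_edge(pair.a, pair.b)
    return g


def category_subnetwork(network: nx.Graph, members: Iterable[str], mode: str = "one_or_both") -> nx.Graph:
    """Extract the subnetwork induced by a category's membership rule."""
    member_set = set(members)
    if mode == "one_or_both":
        keep = [(u, v) for u, v in network.edges if u in member_set or v in member_set]
    elif mode == "both":
        keep = [(u, v) for u, v in network.edges if u in member_set and v in member_set]
    else:
        raise ValueError(f"unknown subnetwork mode '{mode}'")
    sub = nx.Graph()
    sub.add_edges_from(keep)
    return sub


@dataclass
class NetworkSummary:
    """Degree and component statistics of one (sub)network.

    ``avg_degree`` is the mean degree over interacting proteins (2E/N).
    The LCC percentages are of the whole subnetwork's proteins/interactions.
    """

    proteins: int
    interactions: int
    max_degree: int
    avg_degree: float
    components: int
    lcc_protein_pct: float
    lcc_interaction_pct: float
    lcc_avg_degree: float


def _lcc(network: nx.Graph) -> set[str]:
    # largest by node count; ties broken by edge count, then smallest member
    comps = list(nx.connected_components(network))
    comps.sort(key=lambda c: (-len(c), -network.subgraph(c).number_of_edges(), min(c)))
    return comps[0]


def summarize(network: nx.Graph) -> NetworkSummary:
    n, e = network.number_of_nodes(), network.number_of_edges()
    if n == 0:
        return NetworkSummary(0, 0, 0, 0.0, 0, 0.0, 0.0, 0.0)
    degrees = [d for _, d in network.degree]
    comps = nx.number_connected_components(network)
    lcc_nodes = _lcc(network)
    lcc = network.subgraph(lcc_nodes)
    lcc_n, lcc_e = lcc.number_of_nodes(), lcc.number_of_edges()
    return NetworkSummary(
        proteins=n,
        interactions=e,
        max_degree=max(degrees),
        avg_degree=2.0 * e / n,
        components=comps,
        lcc_protein_pct=100.0 * lcc_n / n,
        lcc_interaction_pct=100.0 * lcc_e / e if e else 0.0,
        lcc_avg_degree=2.0 * lcc_e / lcc_n,
    )


def degree_sequence(network: nx.Graph, restrict_to: Optional[Iterable[str]] = None) -> list[int]:
    """Degrees within the network; optionally only of nodes in ``restrict_to``."""
    if restrict_to is None:
        return sorted((d for _, d in network.degree), reverse=True)
    allowed = set(restrict_to)
    return sorted((d for v, d in network.degree if v in allowed), reverse=True)


_EXACT_ASSIGNMENT_LIMIT = 50_000  # enumerate rank assignments up to this many


def _wmw_exact_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided rank-sum p by full enumeration of group assignments.

    Midranks handle ties; extremeness is |W − E[W]| of the rank sum of the
    first sample, so the p-value is exact for any tie pattern.
    """
    pooled = np.asarray(list(x) + list(y), dtype=float)
    m, n_tot = len(x), len(pooled)
    ranks = sps.rankdata(pooled)
    ew = m * (n_tot + 1) / 2.0
    obs = abs(ranks[:m].sum() - ew)
    count = total = 0
    for idx in itertools.combinations(range(n_tot), m):
        total += 1
        if abs(ranks[list(idx)].sum() - ew) >= obs - 1e-9:
            count += 1
    return count / total


def compare_degree_distributions(seq1: Sequence[float], seq2: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon–Mann–Whitney and Kolmogorov–Smirnov p-values.

    Small samples get an exact WMW p by enumerating all group assignments
    (valid under ties); larger samples use the tie-corrected normal
    approximation. Returns ``(wmw_p, ks_p)``.
    """
    if len(seq1) == 0 or len(seq2) == 0:
        raise ValueError("degree sequences must be non-empty")
    if math.comb(len(seq1) + len(seq2), len(seq1)) <= _EXACT_ASSIGNMENT_LIMIT:
        wmw_p = _wmw_exact_p(seq1, seq2)
    else:
        wmw_p = float(sps.mannwhitneyu(seq1, seq2, alternative="two-sided", method="asymptotic").pvalue)
    ks_p = float(sps.ks_2samp(seq1, seq2).pvalue)
    return wmw_p, ks_p


def export_subnetworks(
    classified: ClassifiedGeneTable,
    network: nx.Graph,
    out_dir: Optional[str | Path] = None,
    groups: Sequence[Group] = GROUP_ROW_ORDER,
):
    """Per-group summary rows (one-or-both rule) plus both-mode edge exports.

    Returns the summary DataFrame in the standard row order; when ``out_dir``
    is given, also writes ``<group>_edges.tsv`` files containing the
    both-endpoint subnetworks used for visualization.
    """
    import pandas as pd

    rows = []
    for group in groups:
        members = classified.members(group)
        sub = category_subnetwork(network, members, "one_or_both")
        s = summarize(sub)
        rows.append(
            {
                "group": group.value,
                "proteins": s.proteins,
                "interactions": s.interactions,
                "max_degree": s.max_degree,
                "avg_degree": round_half_up(s.avg_degree, 1),
                "components": s.components,
                "lcc_protein_pct": round_half_up(s.lcc_protein_pct, 0),
                "lcc_interaction_pct": round_half_up(s.lcc_interaction_pct, 0),
                "lcc_avg_degree": round_half_up(s.lcc_avg_degree, 1),
            }
        )
        if out_dir is not None:
            both = category_subnetwork(network, members, "both")
            pairs = EdgeList([EdgePair(*sorted(e)) for e in sorted(map(tuple, map(sorted, both.edges)))])
            write_edge_list(Path(out_dir) / f"{group.value}_edges.tsv", pairs)
    return pd.DataFrame(rows)
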