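"""Node centrality and bridge-edge extraction.

Five measures per node: betweenness, closeness, weighted degree, and the
two ratio measures betweenness/degree and closeness/degree (node-stability
indicators: a node with high betweenness but low degree is easy to perturb
and may propagate that perturbation widely).  Shortest paths use edge
length 1/weight on edge magnitudes; signs are ignored for path metrics.

All five measures are min-max scaled to [0, 1] and ranked individually
(dense ranking, descending); a node ranking in the top 3 of at least one
measure is flagged as highly central.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .variables import SpecificationError
from .mgm import Network

__all__ = [
    "weighted_degree",
    "shortest_path_centralities",
    "ratio_measures",
    "scale_and_rank",
    "centrality_table",
    "extract_bridges",
    "BridgeReport",
    "MEASURES",
]

logger = logging.getLogger(__name__)

MEASURES = (
    "betweenness",
    "closeness",
    "weighted_degree",
    "betweenness_degree_ratio",
    "closeness_degree_ratio",
)


def weighted_degree(net: Network, node: str) -> float:
    """Sum of incident edge weight magnitudes."""
    net.spec(node)                                     # raises on unknown node
    return float(sum(w for _, w in net.incident(node)))


def shortest_path_centralities(net: Network) -> tuple[dict[str, float], dict[str, float]]:
    """Betweenness and closeness under edge length = 1/weight.

    Betweenness counts, with fractional credit for tied shortest paths, how
    often a node lies strictly inside the shortest path of an (unordered)
    node pair.  Closeness is the inverse of the mean distance to the other
    *reachable* nodes; unreachable pairs are skipped (component sizes are
    logged when the graph is disconnected).
    """
    if not net.nodes:
        raise SpecificationError("empty network")
    for (a, b), (w, _) in net.edges.items():
        if w <= 0:
            raise SpecificationError(f"zero-weight edge ({a}, {b}) present")
    g = net.to_networkx()
    betw = nx.betweenness_centrality(g, weight="length", normalized=False)
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        logger.info("network has %d components of sizes %s",
                    len(comps), sorted(map(len, comps)))
    close = {}
    for node in g:
        dists = nx.single_source_dijkstra_path_length(g, node, weight="length")
        del dists[node]
        close[node] = (len(dists) / sum(dists.values())) if dists else 0.0
    return betw, close


def ratio_measures(
    betweenness: dict[str, float],
    closeness: dict[str, float],
    degree: dict[str, float],
) -> tuple[dict[str, float], dict[str, float]]:
    """Elementwise betweenness/degree and closeness/degree on raw values;
    zero-degree nodes get ratio 0 (with a logged note)."""
    bd, cd = {}, {}
    for node, d in degree.items():
        if d == 0:
            logger.info("node %s has zero degree; ratio measures set to 0", node)
            bd[node] = cd[node] = 0.0
        else:
            bd[node] = betweenness[node] / d
            cd[node] = closeness[node] / d
    return bd, cd


def scale_and_rank(raw: pd.DataFrame, top_k: int = 3) -> pd.DataFrame:
    """Min-max scale each measure to [0,1] and rank descending (dense ties).

    A constant measure scales to all 0.5 (with a warning).  Returns a frame
    with ``<measure>``, ``<measure>_scaled``, ``<measure>_rank`` columns and
    a boolean ``top3`` flag for nodes ranked <= ``top_k`` in any measure.
    """
    if len(raw) < 2:
        raise SpecificationError("scale_and_rank needs >= 2 nodes")
    out = raw.copy()
    top = pd.Series(False, index=raw.index)
    for m in raw.columns:
        x = raw[m].astype(float)
        span = x.max() - x.min()
        if span == 0:
            logger.warning("measure %s is constant; scaled values set to 0.5", m)
            out[m + "_scaled"] = 0.5
        else:
            out[m + "_scaled"] = (x - x.min()) / span
        ranks = x.rank(method="dense", ascending=False).astype(int)
        out[m + "_rank"] = ranks
        top |= ranks <= top_k
    out["top3"] = top
    return out


def centrality_table(net: Network, ratio_on_raw: bool = True, top_k: int = 3) -> pd.DataFrame:
    """The five measures, scaled, ranked, and top-3 flagged, per node.

    ``ratio_on_raw`` computes the two ratio measures on the raw (pre-
    scaling) betweenness/closeness/degree; the alternative divides the
    min-max scaled values (sensitivity mode).
    """
    names = net.node_names()
    betw, close = shortest_path_centralities(net)
    degree = {n: weighted_degree(net, n) for n in names}
    if ratio_on_raw:
        bd, cd = ratio_measures(betw, close, degree)
        raw = pd.DataFrame(
            {
                "betweenness": pd.Series(betw),
                "closeness": pd.Series(close),
                "weighted_degree": pd.Series(degree),
                "betweenness_degree_ratio": pd.Series(bd),
                "closeness_degree_ratio": pd.Series(cd),
            }
        ).loc[names]
        return scale_and_rank(raw, top_k=top_k)
    raw3 = pd.DataFrame(
        {
            "betweenness": pd.Series(betw),
            "closeness": pd.Series(close),
            "weighted_degree": pd.Series(degree),
        }
    ).loc[names]
    scaled3 = scale_and_rank(raw3, top_k=top_k)
    bd, cd = ratio_measures(
        scaled3["betweenness_scaled"].to_dict(),
        scaled3["closeness_scaled"].to_dict(),
        scaled3["weighted_degree_scaled"].to_dict(),
    )
    raw = raw3.assign(
        betweenness_degree_ratio=pd.Series(bd),
        closeness_degree_ratio=pd.Series(cd),
    )
    return scale_and_rank(raw, top_k=top_k)


@dataclass
class BridgeReport:
    """Cross-partition (symptom-metabolite) edges and group coverage."""

    edges: list[tuple[str, str, float, str]] = field(default_factory=list)
    symptoms_touched: set[str] = field(default_factory=set)
    metabolites_touched: set[str] = field(default_factory=set)
    somatic_touched: set[str] = field(default_factory=set)
    mood_cognition_touched: set[str] = field(default_factory=set)
    n_somatic: int = 0
    n_mood_cognition: int = 0
    n_metabolites: int = 0

    @property
    def n_bridges(self) -> int:
        return len(self.edges)

    def coverage(self, group: str) -> float:
        """Percentage of a symptom subgroup touched by a bridge edge."""
        if group == "somatic":
            return 100.0 * len(self.somatic_touched) / self.n_somatic
        if group == "mood_cognition":
            return 100.0 * len(self.mood_cognition_touched) / self.n_mood_cognition
        raise SpecificationError(f"unknown symptom group {group!r}")


def extract_bridges(net: Network) -> BridgeReport:
    """Edges whose endpoints straddle the symptom/metabolite partition.

    Nodes must carry a symptom group (somatic / mood_cognition), be a
    metabolite, or be explicitly ungrouped (counted in neither subgroup).
    """
    unlabeled = [s.name for s in net.nodes if not s.group]
    if unlabeled:
        raise SpecificationError(f"nodes without a group label: {unlabeled}")
    report = BridgeReport(
        n_somatic=sum(1 for s in net.nodes if s.group == "somatic"),
        n_mood_cognition=sum(1 for s in net.nodes if s.group == "mood_cognition"),
        n_metabolites=sum(1 for s in net.nodes if s.is_metabolite),
    )
    for (a, b), (w, sign) in sorted(net.edges.items(), key=lambda kv: -kv[1][0]):
        sa, sb = net.spec(a), net.spec(b)
        pair = None
        if sa.is_symptom and sb.is_metabolite:
            pair = (sa, sb, a, b)
        elif sb.is_symptom and sa.is_metabolite:
            pair = (sb, sa, b, a)
        if pair is None:
            continue
        sym_spec, met_spec, sym, met = pair
        report.edges.append((sym, met, w, sign))
        report.symptoms_touched.add(sym)
        report.metabolites_touched.add(met)
        if sym_spec.group == "somatic":
            report.somatic_touched.add(sym)
        elif sym_spec.group == "mood_cognition":
            report.mood_cognition_touched.add(sym)
    return report
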