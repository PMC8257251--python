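"""Multi-evidence transcription-factor centrality ranking.

Candidate TFs are scored against each stage-specific signature with
eight parameters from four knowledge sources:

* PPI direct connections — number of signature genes sharing an edge
  with the TF at confidence > 0.2 (all evidence channels).
* Anchored subnetwork — the TF is the anchor, signature genes the
  targets; each anchor-target pair contributes its minimum-cost path
  under edge cost -ln(confidence), and the union of those paths is the
  TF's subnetwork.  From it: direct (1st-neighbor) target count,
  characteristic path length (mean unweighted hop distance from the TF
  to every reachable subnetwork node), and Freeman degree
  centralization (1 for a star, 0 for a regular graph).
* Regulon — number of signature genes registered as targets of the TF.
* Relatedness scores — count and mean score of directly related
  signature genes, and mean score of indirectly related ones.

Parameters are Z-scored across TFs per (comparison, parameter), after
replacing the characteristic path length by its reciprocal so that
shorter paths score higher.  Each TF's Z-scores are pooled into a mean
and compared across TFs by one-way ANOVA with Tukey's HSD.
"""

from __future__ import annotations

import logging
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .containers import TF_PARAMETERS, KnowledgeNetworks, TFMetrics, TFRanking
from .signatures import ppi_graph

logger = logging.getLogger(__name__)

__all__ = [
    "ppi_direct_connections",
    "infer_anchored_subnetwork",
    "subnetwork_metrics",
    "regulon_target_count",
    "relatedness_summary",
    "compute_tf_metrics",
    "consolidate_ranking",
    "anova_tukey",
]

_RELTOL = 1e-9


def ppi_direct_connections(tf: str, signature: set, ppi: pd.DataFrame,
                           min_conf: float = 0.2) -> int:
    """Distinct signature genes adjacent to ``tf`` at confidence > min_conf."""
    g = ppi_graph(ppi, min_conf=min_conf)
    if tf not in g:
        logger.warning("TF %s absent from PPI network", tf)
        return 0
    return len(set(g.neighbors(tf)) & set(signature))


def _shortest_path_dag(g: nx.Graph, dist: dict) -> dict:
    """Successor lists of the shortest-path DAG rooted at the Dijkstra source."""
    succ: dict = {v: [] for v in dist}
    for u, d in dist.items():
        for v in g.neighbors(u):
            if v in dist and np.isclose(d + g[u][v]["cost"], dist[v],
                                        rtol=_RELTOL, atol=1e-12):
                succ[u].append(v)
    return succ


def _lex_smallest_path(anchor: str, target: str, succ: dict) -> list:
    """Lexicographically smallest node sequence among shortest paths.

    Walks the shortest-path DAG forward, always taking the smallest
    successor from which the target is still reachable.
    """
    reaches = {target}
    stack = [target]
    pred: dict = {}
    for u, vs in succ.items():
        for v in vs:
            pred.setdefault(v, []).append(u)
    while stack:
        v = stack.pop()
        for u in pred.get(v, []):
            if u not in reaches:
                reaches.add(u)
                stack.append(u)
    path = [anchor]
    node = anchor
    while node != target:
        node = min(v for v in succ[node] if v in reaches)
        path.append(node)
    return path


def infer_anchored_subnetwork(anchors, targets, ppi: pd.DataFrame,
                              min_conf: float = 0.2):
    """Union of minimum-cost anchor-to-target paths in the confidence graph.

    Edges with confidence <= ``min_conf`` are removed; remaining edges
    cost -ln(confidence), so a path's cost is -ln of its confidence
    product and the minimum-cost path is the most confident chain.
    Ties are broken by the lexicographically smallest node sequence.

    Returns (subnetwork graph, unreachable target list).  Edge attribute
    ``confidence`` is preserved on the subnetwork.
    """
    anchors = [anchors] if isinstance(anchors, str) else list(anchors)
    g = ppi_graph(ppi, min_conf=min_conf)
    for u, v, data in g.edges(data=True):
        data["cost"] = -np.log(data["confidence"])
    present = [a for a in anchors if a in g]
    if not present:
        raise ValueError(f"no anchor among {anchors} is present in the network")
    subnet = nx.Graph()
    subnet.add_nodes_from(present)
    unreachable = []
    for anchor in present:
        dist = nx.single_source_dijkstra_path_length(g, anchor, weight="cost")
        succ = _shortest_path_dag(g, dist)
        for target in sorted(set(targets)):
            if target == anchor:
                continue
            if target not in dist:
                unreachable.append((anchor, target))
                continue
            path = _lex_smallest_path(anchor, target, succ)
            for u, v in zip(path, path[1:]):
                subnet.add_edge(u, v, confidence=g[u][v]["confidence"])
    if unreachable:
        logger.info("anchored subnetwork: %d unreachable (anchor, target) pairs",
                    len(unreachable))
    return subnet, unreachable


def subnetwork_metrics(subnet: nx.Graph, tf: str, targets) -> tuple[int, float, float]:
    """(direct target count, characteristic path length, centralization).

    Characteristic path length is the mean unweighted shortest-path
    length from ``tf`` to every other reachable subnetwork node
    (directly and indirectly connected alike); NaN when nothing is
    reachable.  Centralization is Freeman's degree centralization,
    NaN for subnetworks of fewer than three nodes.
    """
    targets = set(targets)
    if tf not in subnet:
        return 0, float("nan"), float("nan")
    direct = len(set(subnet.neighbors(tf)) & targets)
    hops = nx.single_source_shortest_path_length(subnet, tf)
    hops.pop(tf)
    cpl = float(np.mean(list(hops.values()))) if hops else float("nan")
    n = subnet.number_of_nodes()
    if n < 3:
        centralization = float("nan")
    else:
        degrees = np.array([d for _, d in subnet.degree()])
        centralization = float((degrees.max() - degrees).sum() / ((n - 1) * (n - 2)))
    return direct, cpl, centralization


def regulon_target_count(tf: str, signature: set, regulon: pd.DataFrame) -> int:
    """Number of signature genes registered as targets of ``tf``."""
    targets = set(regulon.loc[regulon["tf"] == tf, "target"])
    return len(targets & set(signature))


def relatedness_summary(tf: str, signature: set, relatedness: pd.DataFrame):
    """(n direct, mean direct score, mean indirect score) over signature genes.

    An empty class yields mean 0.0 (logged); the count distinguishes a
    genuine zero mean from absence.
    """
    rows = relatedness[(relatedness["tf"] == tf)
                       & relatedness["gene"].isin(signature)]
    direct = rows.loc[rows["flag"] == "direct", "score"]
    indirect = rows.loc[rows["flag"] == "indirect", "score"]
    if direct.empty:
        logger.info("TF %s: no directly related signature genes", tf)
    if indirect.empty:
        logger.info("TF %s: no indirectly related signature genes", tf)
    return (len(direct),
            float(direct.mean()) if len(direct) else 0.0,
            float(indirect.mean()) if len(indirect) else 0.0)


def compute_tf_metrics(tf: str, comparison: str, signature: set,
                       networks: KnowledgeNetworks, string_conf: float = 0.2,
                       anat_conf: float = 0.2) -> TFMetrics:
    """All eight ranking parameters for one TF against one signature."""
    subnet, _ = infer_anchored_subnetwork(tf, signature, networks.ppi,
                                          min_conf=anat_conf)
    direct, cpl, centralization = subnetwork_metrics(subnet, tf, signature)
    n_direct, mean_direct, mean_indirect = relatedness_summary(
        tf, signature, networks.relatedness)
    return TFMetrics(
        tf=tf, comparison=comparison,
        string_degree=ppi_direct_connections(tf, signature, networks.ppi,
                                             min_conf=string_conf),
        anat_direct=direct, anat_cpl=cpl, anat_centralization=centralization,
        regnet_targets=regulon_target_count(tf, signature, networks.regulon),
        var_n_direct=n_direct, var_mean_direct=mean_direct,
        var_mean_indirect=mean_indirect,
    )


def _zscore_population(values: np.ndarray) -> np.ndarray:
    sd = values.std(ddof=0)
    if sd == 0:
        return np.zeros_like(values)
    return (values - values.mean()) / sd


def consolidate_ranking(metrics: list[TFMetrics]) -> TFRanking:
    """Z-score the parameter table and rank TFs by mean Z.

    The characteristic path length is replaced by its reciprocal before
    Z-scoring (shorter paths rank higher); undefined path lengths or
    centralizations are imputed as 0 after the transform, i.e. worst
    case.  Each TF's observations for the ANOVA/Tukey comparison are its
    Z-scores over all (comparison, parameter) cells.
    """
    table = pd.DataFrame([m.as_row() for m in metrics])
    if table.duplicated(subset=["tf", "comparison"]).any():
        raise ValueError("duplicate (tf, comparison) metric rows")
    tfs = sorted(table["tf"].unique())
    if len(tfs) < 3:
        raise ValueError("need >= 3 TFs to rank")
    table = table.set_index(["tf", "comparison"])
    table["anat_cpl"] = 1.0 / table["anat_cpl"]
    table = table.fillna(0.0)

    z_rows = []
    for comparison, block in table.groupby(level="comparison"):
        block = block.droplevel("comparison").loc[tfs]
        for param in TF_PARAMETERS:
            z = _zscore_population(block[param].to_numpy(dtype=float))
            if np.all(z == 0) and block[param].nunique() == 1:
                logger.warning("parameter %s constant across TFs in %s",
                               param, comparison)
            z_rows.append(pd.Series(z, index=tfs, name=(comparison, param)))
    zscores = pd.DataFrame(z_rows)
    zscores.index = pd.MultiIndex.from_tuples(zscores.index,
                                              names=["comparison", "parameter"])
    non_constant = int((zscores.std(axis=1, ddof=0) > 0).sum())
    if non_constant < 2:
        logger.warning("fewer than two non-constant ranking parameters; "
                       "the ranking is degenerate")
    mean_z = zscores.mean(axis=0).sort_values(ascending=False, kind="stable")
    f, p, tukey = anova_tukey({tf: zscores[tf].to_numpy() for tf in tfs})
    return TFRanking(zscores=zscores, mean_z=mean_z, anova_f=f, anova_p=p,
                     tukey_p=tukey)


def anova_tukey(groups: dict):
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    ``groups`` maps label -> 1-D array of observations (>= 2 each).
    Returns (F, p, pairwise adjusted-p DataFrame with NaN diagonal).
    When every observation is identical the ANOVA is degenerate; by
    convention F = 0 and all p-values are 1.
    """
    labels = sorted(groups)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if any(len(a) < 2 for a in arrays):
        raise ValueError("each group needs >= 2 observations")
    pairwise = pd.DataFrame(np.nan, index=labels, columns=labels)
    flat = np.concatenate(arrays)
    if np.ptp(flat) == 0:
        for a, b in combinations(labels, 2):
            pairwise.loc[a, b] = pairwise.loc[b, a] = 1.0
        return 0.0, 1.0, pairwise
    f, p = stats.f_oneway(*arrays)
    hsd = stats.tukey_hsd(*arrays)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i != j:
                pairwise.loc[a, b] = float(hsd.pvalue[i, j])
    return float(f), float(p), pairwise
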