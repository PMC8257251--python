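"""Stage-specific signature selection and network-connectivity pruning.

A signature is the set of genes whose linear fold change between two
stage groups passes a directional cutoff (2.0 for the macrometastasis
contrasts, 1.5 for the subtler micrometastasis vs normal contrast).
Signatures are then partitioned Venn-style across comparisons and pruned
to their interconnected core on the protein-protein interaction network:
edges with confidence <= 0.3 or from the text-mining channel are
discarded and connected components of fewer than four genes dropped.
"""

from __future__ import annotations

import itertools
import logging

import networkx as nx
import pandas as pd

from .containers import ComparisonSpec, GeneSignature, NormalizedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "group_fold_change",
    "select_signature",
    "venn_partition",
    "ppi_graph",
    "prune_by_connectivity",
]


def group_fold_change(matrix: NormalizedMatrix, comparison: ComparisonSpec) -> pd.Series:
    """Per-gene ratio of group means, numerator over denominator.

    Computed on the linear floored scale so ratios are finite and damped
    for lowly expressed genes.
    """
    groups = matrix.groups()
    for g in (comparison.numerator, comparison.denominator):
        if g not in groups:
            raise KeyError(f"group {g!r} not in design (has {sorted(groups)})")
    num = matrix.values[groups[comparison.numerator]].mean(axis=1)
    den = matrix.values[groups[comparison.denominator]].mean(axis=1)
    fc = num / den
    fc.name = comparison.name
    return fc


def select_signature(fc: pd.Series, comparison: ComparisonSpec,
                     inclusive: bool = True) -> GeneSignature:
    """Directional cutoff selection: up at FC >= cutoff, down at FC <= 1/cutoff.

    Boundary genes are included by default (set ``inclusive=False`` for
    strict inequalities); on continuous data the choice is measure-zero.
    """
    c = comparison.fc_cutoff
    if inclusive:
        up, down = fc[fc >= c], fc[fc <= 1 / c]
    else:
        up, down = fc[fc > c], fc[fc < 1 / c]
    sig = GeneSignature(
        comparison=comparison.name,
        up=set(up.index),
        down=set(down.index),
        fc=fc.to_dict(),
    )
    logger.info("%s: %d up, %d down at cutoff %g", comparison.name,
                len(sig.up), len(sig.down), c)
    return sig


def venn_partition(signatures: list[GeneSignature]) -> dict[str, set]:
    """Disjoint Venn regions over the per-comparison gene sets (up+down).

    Keys are '&'-joined sorted comparison names; region sizes sum to the
    size of the union.
    """
    if len(signatures) < 2:
        raise ValueError("need at least two signatures for a Venn partition")
    sets = {s.comparison: s.genes for s in signatures}
    names = sorted(sets)
    regions: dict[str, set] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            for n in names:
                if n not in combo:
                    inside = inside - sets[n]
            regions["&".join(combo)] = inside
    return regions


def ppi_graph(ppi: pd.DataFrame, min_conf: float = 0.0,
              excluded_channels: set | frozenset = frozenset()) -> nx.Graph:
    """Undirected graph from a PPI edge table, filtered by confidence and
    evidence channel.  Parallel edges surviving from several channels are
    collapsed, keeping the maximum confidence."""
    keep = ppi[(ppi["confidence"] > min_conf)
               & ~ppi["channel"].isin(excluded_channels)]
    g = nx.Graph()
    for a, b, conf in zip(keep["gene_a"], keep["gene_b"], keep["confidence"]):
        if g.has_edge(a, b):
            if conf > g[a][b]["confidence"]:
                g[a][b]["confidence"] = conf
        else:
            g.add_edge(a, b, confidence=conf)
    return g


def prune_by_connectivity(genes: set, ppi: pd.DataFrame, min_conf: float = 0.3,
                          excluded_channels=frozenset({"textmining"}),
                          min_component: int = 4) -> set:
    """Keep only genes in sufficiently large connected components of the
    filtered PPI subgraph induced on ``genes``.

    Genes absent from the network are isolated singletons and are dropped
    (counted in the log) whenever ``min_component`` > 1.
    """
    g = ppi_graph(ppi, min_conf=min_conf, excluded_channels=set(excluded_channels))
    sub = g.subgraph(genes)
    survivors: set = set()
    for comp in nx.connected_components(sub):
        if len(comp) >= min_component:
            survivors |= comp
    absent = len(genes - set(g.nodes))
    logger.info("connectivity pruning: %d/%d genes retained (%d absent from network)",
                len(survivors), len(genes), absent)
    return survivors
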