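"""Over-representation analysis and cross-database term consolidation.

Each directional gene list (up/down per stage comparison) is tested
against every term of each gene-set database with the hypergeometric
upper tail; q-values are Benjamini-Hochberg within one
(database x comparison x direction) family, matching how per-run web
platforms report them.  Significant terms (p < 0.01, q < 0.05,
coverage > 3%) from different databases are then fused into annotation
groups whenever they share at least two genes with a relative overlap
above 0.2, and groups need at least three terms spanning at least two
databases to survive.  The group score is the signed mean -log10(q).
"""

from __future__ import annotations

import logging
import re
from collections import Counter

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .containers import EnrichmentRecord, GeneSetDB, TermGroup

logger = logging.getLogger(__name__)

__all__ = [
    "ora_test",
    "filter_records",
    "consolidate_terms",
    "summarize_groups",
]

_STOPWORDS = frozenset(
    "of the and in to a an by via for with regulation process activity "
    "pathway signaling positive negative cellular response".split()
)


def ora_test(query: set, universe: set, db: GeneSetDB, comparison: str = "",
             direction: str = "", max_term_size: int = 500) -> list[EnrichmentRecord]:
    """Hypergeometric over-representation of ``query`` in each term of ``db``.

    Terms are first intersected with the universe; terms that end up
    empty or larger than ``max_term_size`` are skipped.  p is the exact
    upper tail P(X >= overlap) for X ~ Hypergeom(N=|universe|, K=|term|,
    n=|query|); q is BH-adjusted across the tested terms of this call.
    Coverage uses the within-universe term size as denominator.
    """
    query, universe = set(query), set(universe)
    if not query <= universe:
        extra = sorted(query - universe)[:5]
        raise ValueError(f"query genes outside the universe: {extra} ...")
    n_universe, n_query = len(universe), len(query)
    records = []
    for term, members in db.sets.items():
        in_univ = members & universe
        if not in_univ or len(in_univ) > max_term_size:
            continue
        overlap = in_univ & query
        p = float(hypergeom.sf(len(overlap) - 1, n_universe, len(in_univ), n_query))
        records.append(EnrichmentRecord(
            term=term, database=db.name, comparison=comparison,
            direction=direction, overlap=frozenset(overlap),
            term_size=len(in_univ), p=min(p, 1.0),
            description=db.descriptions.get(term, ""),
        ))
    if records:
        qvals = multipletests([r.p for r in records], method="fdr_bh")[1]
        for r, q in zip(records, qvals):
            r.q = float(q)
    logger.info("ORA %s/%s/%s: %d terms tested", db.name, comparison, direction,
                len(records))
    return records


def filter_records(records: list[EnrichmentRecord], p_max: float = 0.01,
                   q_max: float = 0.05, coverage_min: float = 0.03) -> list[EnrichmentRecord]:
    """Keep records passing all of p < p_max, q < q_max, coverage > coverage_min."""
    kept = [r for r in records
            if r.p < p_max and r.q < q_max and r.coverage > coverage_min]
    logger.info("significance filter: %d/%d records kept", len(kept), len(records))
    return kept


def _auto_label(members: list[EnrichmentRecord]) -> str:
    """Most frequent informative word across member term names."""
    counts: Counter = Counter()
    for r in members:
        text = (r.description or r.term).lower()
        for word in re.findall(r"[a-z]{3,}", text):
            if word not in _STOPWORDS:
                counts[word] += 1
    if not counts:
        return members[0].term
    top = max(counts, key=lambda w: (counts[w], w))
    return top


def consolidate_terms(records: list[EnrichmentRecord], min_overlap: float = 0.2,
                      min_shared: int = 2, min_group: int = 3,
                      similarity: str = "overlap",
                      labels: dict | None = None) -> list[TermGroup]:
    """Fuse enriched terms across databases into annotation groups.

    Two terms from *different* databases are linked when their overlap
    gene sets share >= ``min_shared`` genes and the relative overlap
    exceeds ``min_overlap``; relative overlap is the overlap coefficient
    |A&B|/min(|A|,|B|) by default, or Jaccard with ``similarity="jaccard"``.
    Groups are the connected components of this term graph; components
    with fewer than ``min_group`` terms or drawn from a single database
    are dropped.  Records must share one (comparison, direction) family.

    ``labels`` optionally maps a member term ID to a curated group label;
    otherwise the most frequent informative keyword is used.
    """
    if not records:
        return []
    families = {(r.comparison, r.direction) for r in records}
    if len(families) > 1:
        raise ValueError(f"records span multiple comparison/direction families: {families}")
    comparison, direction = next(iter(families))
    ordered = sorted(records, key=lambda r: (r.database, r.term))
    g = nx.Graph()
    g.add_nodes_from(range(len(ordered)))
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            a, b = ordered[i], ordered[j]
            if a.database == b.database:
                continue
            shared = a.overlap & b.overlap
            if len(shared) < min_shared:
                continue
            if similarity == "jaccard":
                sim = len(shared) / len(a.overlap | b.overlap)
            else:
                sim = len(shared) / min(len(a.overlap), len(b.overlap))
            if sim > min_overlap:
                g.add_edge(i, j)
    groups = []
    for comp in nx.connected_components(g):
        members = [ordered[i] for i in sorted(comp)]
        if len(members) < min_group or len({r.database for r in members}) < 2:
            continue
        label = None
        if labels:
            label = next((labels[r.term] for r in members if r.term in labels), None)
        groups.append(TermGroup(label=label or _auto_label(members),
                                members=members, comparison=comparison,
                                direction=direction))
    groups.sort(key=lambda t: (-t.n_terms, t.label))
    logger.info("consolidation: %d/%d terms grouped into %d groups",
                sum(t.n_terms for t in groups), len(records), len(groups))
    return groups


def summarize_groups(groups: list[TermGroup], q_floor: float = 1e-300) -> pd.DataFrame:
    """Bubble-plot table: one row per group with its signed mean -log10 q.

    Scores for groups from a downregulated gene list carry a negative
    sign.  q-values are floored at ``q_floor`` before the log.
    """
    rows = [{
        "group": t.label,
        "comparison": t.comparison,
        "direction": t.direction,
        "n_terms": t.n_terms,
        "n_databases": len(t.databases),
        "signed_score": t.signed_score(q_floor=q_floor),
    } for t in groups]
    return pd.DataFrame(rows, columns=["group", "comparison", "direction",
                                       "n_terms", "n_databases", "signed_score"])
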