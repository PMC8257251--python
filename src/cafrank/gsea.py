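"""Gene-set enrichment analysis with gene-set permutation.

Implements the weighted Kolmogorov-Smirnov-like running-sum statistic:
walking down a ranked gene list, the sum gains |metric|^w / N_R at each
set member ("hit") and loses 1/(L-H) at each non-member; the enrichment
score (ES) is the signed maximum deviation from zero and the leading
edge is the hit prefix up to that extremum.  Ranking uses the
signal-to-noise ratio on log2 expression with the conventional sigma
floor.  Because the stage groups hold only 3-4 replicates, significance
comes from gene_set permutation: null scores from random same-size gene
sets, normalized enrichment scores (NES) from sign-matched null means,
and a sign-stratified ratio-of-tails FDR.  Defaults: 1000 permutations,
set sizes 5-500, significance at FDR < 0.05 and |NES| > 2.
"""

from __future__ import annotations

import logging

import numpy as np

from .containers import ComparisonSpec, GeneSetDB, GseaResult, NormalizedMatrix, RankedList

logger = logging.getLogger(__name__)

__all__ = [
    "rank_genes",
    "enrichment_score",
    "run_gsea",
    "select_hallmarks",
]


def rank_genes(matrix: NormalizedMatrix, comparison: ComparisonSpec,
               sigma_floor: float = 0.2) -> RankedList:
    """Rank genes by signal-to-noise (mu1-mu2)/(s1+s2) on log2 values.

    Each group standard deviation is floored at ``sigma_floor * |mu|``
    (at ``sigma_floor`` absolute when the mean is zero), the convention
    that keeps low-variance genes from dominating the ranking.  Ties are
    broken lexicographically by gene ID (inside RankedList).
    """
    groups = matrix.groups()
    for g in (comparison.numerator, comparison.denominator):
        if g not in groups:
            raise KeyError(f"group {g!r} not in design")
        if len(groups[g]) < 2:
            raise ValueError(f"group {g!r} has < 2 replicates")
    logv = np.log2(matrix.values.to_numpy(dtype=float))
    cols = {s: i for i, s in enumerate(matrix.samples)}
    idx1 = [cols[s] for s in groups[comparison.numerator]]
    idx2 = [cols[s] for s in groups[comparison.denominator]]

    def _stats(idx):
        sub = logv[:, idx]
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1, ddof=1)
        floor = sigma_floor * np.abs(mu)
        floor[floor == 0] = sigma_floor
        return mu, np.maximum(sd, floor)

    mu1, sd1 = _stats(idx1)
    mu2, sd2 = _stats(idx2)
    metric = (mu1 - mu2) / (sd1 + sd2)
    return RankedList(genes=list(matrix.genes), metric=metric)


def enrichment_score(ranked: RankedList, gene_set, weight_exp: float = 1.0):
    """Running-sum enrichment score of ``gene_set`` in ``ranked``.

    Returns (ES, running sum array, leading-edge gene set).  With
    weight_exp=0 the statistic reduces to the classical KS statistic
    between hit and miss rank distributions (up to sign).
    """
    hits = np.fromiter((g in gene_set for g in ranked.genes), bool, len(ranked))
    n_hits = int(hits.sum())
    if n_hits == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hits == len(ranked):
        raise ValueError("gene set covers the whole ranked list (no misses)")
    weights = np.abs(ranked.metric) ** weight_exp
    n_r = weights[hits].sum()
    if n_r == 0:  # all hit metrics are exactly zero: fall back to equal steps
        steps = hits / n_hits
    else:
        steps = np.where(hits, weights / n_r, 0.0)
    running = np.cumsum(steps - (~hits) / (len(ranked) - n_hits))
    i_max = int(np.argmax(np.abs(running)))
    es = float(running[i_max])
    if es >= 0:
        leading = {g for g, h in zip(ranked.genes[: i_max + 1], hits[: i_max + 1]) if h}
    else:
        leading = {g for g, h in zip(ranked.genes[i_max:], hits[i_max:]) if h}
    return es, running, frozenset(leading)


def _null_es(weights: np.ndarray, set_size: int, n_perm: int,
             rng: np.random.Generator) -> np.ndarray:
    """ES of ``n_perm`` random gene sets of ``set_size``, vectorized.

    Exploits that the running sum is piecewise linear between hits: its
    maximum lies just after a hit, its minimum just before one, so only
    the 2 * set_size candidate values per permutation are evaluated.
    """
    n = len(weights)
    # sample without replacement: k smallest of a random row
    keys = rng.random((n_perm, n))
    pos = np.sort(np.argpartition(keys, set_size - 1, axis=1)[:, :set_size], axis=1)
    w = weights[pos]
    cw = np.cumsum(w, axis=1)
    n_r = cw[:, -1:].copy()
    degenerate = n_r[:, 0] == 0
    if degenerate.any():
        w[degenerate] = 1.0
        cw[degenerate] = np.arange(1, set_size + 1)
        n_r[degenerate] = set_size
    miss_step = 1.0 / (n - set_size)
    j = np.arange(1, set_size + 1)
    after_hit = cw / n_r - (pos + 1 - j) * miss_step
    before_hit = (cw - w) / n_r - (pos - (j - 1)) * miss_step
    es_pos = after_hit.max(axis=1)
    es_neg = before_hit.min(axis=1)
    return np.where(es_pos >= -es_neg, es_pos, es_neg)


def _signed_mean(null: np.ndarray, sign: int) -> float:
    same = null[null >= 0] if sign >= 0 else -null[null < 0]
    if len(same) == 0:
        return float(np.mean(np.abs(null)))
    return float(np.mean(same))


def run_gsea(ranked: RankedList, dbs: list[GeneSetDB] | GeneSetDB,
             n_perm: int = 1000, min_size: int = 5, max_size: int = 500,
             weight_exp: float = 1.0, seed: int = 0) -> list[GseaResult]:
    """GSEA over all sets of the given databases with gene_set permutation.

    Sets are intersected with the ranked universe and kept when the
    intersection size lies in [min_size, max_size].  Per set the null ES
    distribution comes from ``n_perm`` random same-size gene sets; NES
    divides ES by the mean same-sign |null ES|, the nominal p is the
    same-sign null tail fraction, and FDR is the canonical
    sign-stratified ratio of normalized-null to observed tail fractions,
    clipped to [0, 1].  Deterministic given ``seed``.
    """
    if isinstance(dbs, GeneSetDB):
        dbs = [dbs]
    universe = set(ranked.genes)
    weights = np.abs(ranked.metric) ** weight_exp
    candidates = []
    for db in dbs:
        for term in sorted(db.sets):
            members = db.sets[term] & universe
            if min_size <= len(members) <= max_size and len(members) < len(universe):
                candidates.append((f"{db.name}:{term}" if len(dbs) > 1 else term,
                                   members))
    if not candidates:
        raise ValueError("no gene set survives the size filter")
    rng = np.random.default_rng(seed)
    results, null_nes_pool = [], []
    es_obs, nes_obs = [], []
    for name, members in candidates:
        es, _, leading = enrichment_score(ranked, members, weight_exp=weight_exp)
        null = _null_es(weights, len(members), n_perm, rng)
        mean_pos = _signed_mean(null, +1)
        mean_neg = _signed_mean(null, -1)
        nes = es / mean_pos if es >= 0 else es / mean_neg
        same = null[null >= 0] if es >= 0 else null[null < 0]
        p = float(np.mean(np.abs(same) >= abs(es))) if len(same) else 1.0
        null_nes = np.where(null >= 0, null / mean_pos, null / mean_neg)
        null_nes_pool.append(null_nes)
        es_obs.append(es)
        nes_obs.append(nes)
        results.append(GseaResult(set_name=name, es=es, nes=float(nes), p=p,
                                  fdr=np.nan, leading_edge=leading,
                                  set_size=len(members), n_permutations=n_perm))
    pool = np.concatenate(null_nes_pool)
    nes_arr = np.asarray(nes_obs)
    pos_pool, neg_pool = pool[pool >= 0], pool[pool < 0]
    n_pos_obs = int((nes_arr >= 0).sum())
    n_neg_obs = int((nes_arr < 0).sum())
    for r in results:
        if r.nes >= 0:
            num = np.mean(pos_pool >= r.nes) if len(pos_pool) else 0.0
            den = (nes_arr >= r.nes).sum() / n_pos_obs if n_pos_obs else 1.0
        else:
            num = np.mean(neg_pool <= r.nes) if len(neg_pool) else 0.0
            den = (nes_arr <= r.nes).sum() / n_neg_obs if n_neg_obs else 1.0
        r.fdr = float(np.clip(num / den if den > 0 else 0.0, 0.0, 1.0))
    results.sort(key=lambda r: (-r.nes, r.set_name))
    return results


def select_hallmarks(results: list[GseaResult], fdr_max: float = 0.05,
                     nes_min: float = 2.0) -> list[GseaResult]:
    """Keep significant results: |NES| > nes_min and FDR < fdr_max."""
    return [r for r in results if abs(r.nes) > nes_min and r.fdr < fdr_max]
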