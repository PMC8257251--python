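"""Synthetic data with planted ground truth for every pipeline stage.

The generator emulates the study design the pipeline targets: a small
bulk RNA-seq cohort with three fibroblast stage groups (normal lung,
micrometastatic, macrometastatic; 4/3/4 replicates), negative-binomial
counts with library-size variation, planted stage-specific and shared
differentially expressed genes, and knowledge networks (PPI, regulon,
relatedness scores) in which one designated central TF is more
connected to the planted signature than decoy TFs through every
evidence channel.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneSetDB, KnowledgeNetworks

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "simulate_counts",
    "simulate_knowledge",
    "simulate_gene_sets",
    "write_fixtures",
]

#: (comparison name, numerator group, denominator group) planted contrasts.
_COMPARISONS = (
    ("MIF_vs_NLF", "MIF", "NLF"),
    ("MAF_vs_NLF", "MAF", "NLF"),
    ("MAF_vs_MIF", "MAF", "MIF"),
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; defaults mirror the targeted study design.

    ``n_stage_unique`` genes per comparison (half up, half down) have
    the numerator group's mean scaled by 2^(+-effect_log2fc);
    ``n_shared`` genes change monotonically across all three stages so
    they pass every contrast.  TF edge probabilities apply independently
    in each of the three knowledge channels (PPI edge, regulon edge,
    direct-relatedness row).
    """

    n_genes: int = 1000
    groups: tuple = (("NLF", 4), ("MIF", 3), ("MAF", 4))
    n_stage_unique: int = 40
    n_shared: int = 20
    effect_log2fc: float = 2.0
    nb_dispersion: float = 0.1
    libsize_sigma: float = 0.2
    baseline_meanlog: float = np.log(150.0)
    baseline_sdlog: float = 1.0
    n_tfs: int = 5
    central_tf_edge_prob: float = 0.4
    decoy_tf_edge_prob: float = 0.1
    background_edge_prob: float = 0.004
    signature_edge_prob: float = 0.02
    fraction_textmining: float = 0.2
    indirect_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name, n in self.groups:
            if n < 3:
                raise ValueError(f"group {name} has {n} < 3 replicates; the "
                                 "downstream min-sample filter assumes 3")
        for p in (self.central_tf_edge_prob, self.decoy_tf_edge_prob,
                  self.background_edge_prob, self.signature_edge_prob,
                  self.fraction_textmining, self.indirect_fraction):
            if not 0 <= p <= 1:
                raise ValueError(f"probability out of [0,1]: {p}")
        if self.central_tf_edge_prob <= self.decoy_tf_edge_prob:
            raise ValueError("central_tf_edge_prob must exceed decoy_tf_edge_prob")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be >= 0")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")

    @property
    def comparisons(self):
        return _COMPARISONS

    @property
    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"g{i:0{width}d}" for i in range(self.n_genes)]

    @property
    def tf_ids(self) -> list[str]:
        return [f"TF{i + 1}" for i in range(self.n_tfs)]


@dataclass
class GroundTruth:
    """What was planted: per-comparison DE sets, the central TF, library factors."""

    planted_up: dict = field(default_factory=dict)
    planted_down: dict = field(default_factory=dict)
    central_tf: str = ""
    library_factors: dict = field(default_factory=dict)

    @property
    def signature(self) -> set:
        out: set = set()
        for s in self.planted_up.values():
            out |= s
        for s in self.planted_down.values():
            out |= s
        return out

    def to_json(self) -> str:
        return json.dumps({
            "planted_up": {k: sorted(v) for k, v in self.planted_up.items()},
            "planted_down": {k: sorted(v) for k, v in self.planted_down.items()},
            "central_tf": self.central_tf,
            "library_factors": self.library_factors,
        }, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(planted_up={k: set(v) for k, v in d["planted_up"].items()},
                   planted_down={k: set(v) for k, v in d["planted_down"].items()},
                   central_tf=d["central_tf"],
                   library_factors=d["library_factors"])


def _sample_ids(spec: SyntheticSpec) -> tuple[list[str], list[str]]:
    samples, labels = [], []
    for group, n in spec.groups:
        for r in range(n):
            samples.append(f"{group}_{r + 1}")
            labels.append(group)
    return samples, labels


def simulate_counts(spec: SyntheticSpec) -> tuple[CountMatrix, GroundTruth]:
    """Negative-binomial counts with planted fold changes.

    Baseline gene means are log-normal; planted genes have the
    comparison's numerator-group mean multiplied by 2^(+-effect_log2fc)
    (shared genes ramp monotonically across stages); counts are NB with
    var = mu + mu^2 * dispersion, scaled by per-sample library factors
    (log-normal, renormalized to geometric mean 1).
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids
    samples, labels = _sample_ids(spec)
    group_names = [g for g, _ in spec.groups]

    base = rng.lognormal(spec.baseline_meanlog, spec.baseline_sdlog, spec.n_genes)
    # per-group mean multipliers, genes x groups
    mult = np.ones((spec.n_genes, len(group_names)))
    col = {g: i for i, g in enumerate(group_names)}

    n_planted = 3 * spec.n_stage_unique + spec.n_shared
    if n_planted > spec.n_genes:
        raise ValueError("more planted genes than genes")
    planted_idx = rng.choice(spec.n_genes, size=n_planted, replace=False)
    cursor = 0
    truth = GroundTruth(central_tf=spec.tf_ids[0] if spec.n_tfs else "")
    fold = 2.0 ** spec.effect_log2fc
    for name, num, _den in spec.comparisons:
        idx = planted_idx[cursor:cursor + spec.n_stage_unique]
        cursor += spec.n_stage_unique
        half = len(idx) // 2
        up, down = idx[:half], idx[half:]
        mult[up, col[num]] *= fold
        mult[down, col[num]] /= fold
        truth.planted_up[name] = {genes[i] for i in up}
        truth.planted_down[name] = {genes[i] for i in down}
    shared = planted_idx[cursor:cursor + spec.n_shared]
    half = len(shared) // 2
    # monotone ramp NLF -> MIF -> MAF: passes every pairwise contrast
    for stage, g in enumerate(group_names):
        mult[shared[:half], col[g]] *= fold ** stage
        mult[shared[half:], col[g]] /= fold ** stage
    for name, num, den in spec.comparisons:
        truth.planted_up[name] |= {genes[i] for i in shared[:half]}
        truth.planted_down[name] |= {genes[i] for i in shared[half:]}

    lib = rng.lognormal(0.0, spec.libsize_sigma, len(samples))
    lib /= np.exp(np.mean(np.log(lib)))  # geometric mean 1
    truth.library_factors = {s: float(f) for s, f in zip(samples, lib)}

    mu = base[:, None] * mult[:, [col[g] for g in labels]] * lib[None, :]
    if spec.nb_dispersion > 0:
        r = 1.0 / spec.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    values = pd.DataFrame(counts.astype(np.int64), index=genes, columns=samples)
    design = pd.Series(labels, index=samples, name="group")
    return CountMatrix(values=values, design=design), truth


def simulate_knowledge(spec: SyntheticSpec, truth: GroundTruth) -> KnowledgeNetworks:
    """Knowledge networks in which the central TF outlinks the decoys.

    PPI: Erdos-Renyi background among genes, a denser layer among the
    planted signature genes (``signature_edge_prob``, emulating the
    functional coherence of co-regulated programs that the connectivity
    pruning stage relies on), and TF-signature edges; confidences
    ~ U(0.15, 0.95); a ``fraction_textmining`` of gene-gene edges is
    labeled "textmining", the rest "experimental" (TF edges are always
    non-textmining so channel exclusion cannot erase the plant).
    Regulon: TF->signature-gene edges with the same per-TF probability.
    Relatedness: linked (direct) rows score U(5, 30); a random
    ``indirect_fraction`` of unlinked pairs get indirect rows U(0, 5).
    """
    rng = np.random.default_rng(spec.seed + 1)
    genes = spec.gene_ids
    signature = sorted(truth.signature)
    ppi_rows = []

    n = len(genes)
    iu = np.triu_indices(n, k=1)
    mask = rng.random(len(iu[0])) < spec.background_edge_prob
    for a, b in zip(iu[0][mask], iu[1][mask]):
        channel = ("textmining" if rng.random() < spec.fraction_textmining
                   else "experimental")
        ppi_rows.append((genes[a], genes[b],
                         rng.uniform(0.15, 0.95), channel))
    # coherence layer: extra edges among planted signature genes
    seen = {(genes[a], genes[b]) for a, b in zip(iu[0][mask], iu[1][mask])}
    for i, a in enumerate(signature):
        for b in signature[i + 1:]:
            if (a, b) in seen:
                continue
            if rng.random() < spec.signature_edge_prob:
                channel = ("textmining" if rng.random() < spec.fraction_textmining
                           else "experimental")
                ppi_rows.append((a, b, rng.uniform(0.15, 0.95), channel))

    regulon_rows, relatedness_rows = [], []
    for tf in spec.tf_ids:
        p_link = (spec.central_tf_edge_prob if tf == truth.central_tf
                  else spec.decoy_tf_edge_prob)
        for gene in signature:
            if rng.random() < p_link:  # PPI channel
                ppi_rows.append((tf, gene, rng.uniform(0.15, 0.95), "experimental"))
            if rng.random() < p_link:  # regulon channel
                regulon_rows.append((tf, gene))
            if rng.random() < p_link:  # direct-relatedness channel
                relatedness_rows.append((gene, tf, rng.uniform(5.0, 30.0), "direct"))
            elif rng.random() < spec.indirect_fraction:
                relatedness_rows.append((gene, tf, rng.uniform(0.0, 5.0), "indirect"))

    ppi = pd.DataFrame(ppi_rows, columns=["gene_a", "gene_b", "confidence", "channel"])
    regulon = pd.DataFrame(regulon_rows, columns=["tf", "target"])
    relatedness = pd.DataFrame(relatedness_rows,
                               columns=["gene", "tf", "score", "flag"])
    return KnowledgeNetworks(ppi=ppi, regulon=regulon, relatedness=relatedness)


def simulate_gene_sets(spec: SyntheticSpec, truth: GroundTruth,
                       n_random: int = 30, set_size: int = 25,
                       databases: tuple = ("GO_BP", "KEGG", "Reactome")) -> list[GeneSetDB]:
    """Gene-set databases with planted-signature terms plus random decoys.

    Each database carries, per comparison, one term enriched for the
    planted up genes and one for the down genes (signature genes plus
    random padding), and ``n_random`` terms drawn uniformly from the
    gene universe.  The shared planted core makes the corresponding
    terms overlap across databases, exercising term consolidation.
    """
    rng = np.random.default_rng(spec.seed + 2)
    genes = np.array(spec.gene_ids)
    dbs = []
    for db_name in databases:
        sets, desc = {}, {}
        for name, _, _ in spec.comparisons:
            for direction, planted in (("up", truth.planted_up[name]),
                                       ("down", truth.planted_down[name])):
                planted = sorted(planted)
                core = [p for p in planted
                        if rng.random() < 0.8][: set_size]
                pad = rng.choice(genes, size=max(set_size - len(core), 3),
                                 replace=False)
                term = f"{db_name}_{name}_{direction}"
                sets[term] = set(core) | set(pad.tolist())
                desc[term] = f"planted {direction} program {name}"
        for k in range(n_random):
            term = f"{db_name}_random_{k:02d}"
            sets[term] = set(rng.choice(genes, size=set_size, replace=False).tolist())
            desc[term] = f"random term {k}"
        dbs.append(GeneSetDB(name=db_name, sets=sets, descriptions=desc))
    return dbs


def write_fixtures(counts: CountMatrix, truth: GroundTruth,
                   networks: KnowledgeNetworks, out_dir,
                   gene_sets: list[GeneSetDB] | None = None) -> dict:
    """Write all inputs as the plain-text formats the io module reads.

    Returns a dict of logical name -> written path.  The directory must
    already exist.
    """
    out = Path(out_dir)
    if not out.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {out}")
    from . import io as pio

    paths = {
        "counts": out / "counts.tsv",
        "design": out / "design.tsv",
        "ppi": out / "ppi.tsv",
        "regulon": out / "regulon.tsv",
        "relatedness": out / "relatedness.tsv",
        "truth": out / "ground_truth.json",
        "coding": out / "coding_genes.txt",
    }
    pio.write_counts(counts, paths["counts"], paths["design"])
    pio.write_network(networks.ppi, paths["ppi"])
    pio.write_network(networks.regulon, paths["regulon"])
    pio.write_network(networks.relatedness, paths["relatedness"])
    paths["truth"].write_text(truth.to_json())
    paths["coding"].write_text("\n".join(counts.genes) + "\n")
    if gene_sets is not None:
        for db in gene_sets:
            p = out / f"{db.name}.gmt"
            pio.write_gmt(db, p)
            paths[f"gmt_{db.name}"] = p
    return paths
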