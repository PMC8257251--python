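"""End-to-end orchestration: configuration, the full analysis chain,
and the provenance manifest.

``run_analysis`` executes the in-memory chain on loaded containers:
preprocessing -> per-comparison fold-change signatures -> connectivity
pruning -> over-representation + cross-database consolidation -> GSEA
-> TF metric computation and Z-score ranking.  ``run_pipeline`` wraps
it with file IO: it reads every input named in the config, writes every
intermediate table as TSV and a JSON manifest recording the seed,
thresholds, config hash, and per-stage counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import enrichment, gsea, io, preprocess, signatures, tfrank
from .containers import ComparisonSpec, GeneSetDB, KnowledgeNetworks

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "AnalysisResult", "run_analysis", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Every input path and threshold of the pipeline, with its default.

    Thresholds: min_count/min_samples and floor for preprocessing, the
    top-CV fraction, per-comparison fold-change cutoffs, pruning
    confidence, ORA significance triple, term-consolidation triple,
    GSEA settings, and the TF-stage confidence cutoffs.
    """

    counts: str = ""
    design: str = ""
    coding_genes: str = ""
    gmt_ora: list = field(default_factory=list)
    gmt_gsea: list = field(default_factory=list)
    ppi: str = ""
    regulon: str = ""
    relatedness: str = ""
    tfs: list = field(default_factory=list)
    out_dir: str = "results"
    seed: int = 0

    min_count: int = 20
    min_samples: int = 3
    floor: float = 20.0
    top_cv_frac: float = 0.01
    comparisons: list = field(default_factory=lambda: [
        ["MIF_vs_NLF", "MIF", "NLF", 1.5],
        ["MAF_vs_NLF", "MAF", "NLF", 2.0],
        ["MAF_vs_MIF", "MAF", "MIF", 2.0],
    ])
    prune_conf: float = 0.3
    prune_excluded_channels: list = field(default_factory=lambda: ["textmining"])
    prune_min_component: int = 4
    ora_p_max: float = 0.01
    ora_q_max: float = 0.05
    ora_coverage_min: float = 0.03
    ora_max_term_size: int = 500
    term_min_overlap: float = 0.2
    term_min_shared: int = 2
    term_min_group: int = 3
    gsea_n_perm: int = 1000
    gsea_min_size: int = 5
    gsea_max_size: int = 500
    gsea_fdr_max: float = 0.05
    gsea_nes_min: float = 2.0
    string_conf: float = 0.2
    anat_conf: float = 0.2

    def __post_init__(self) -> None:
        checks = [
            (self.min_count >= 0, "min_count >= 0"),
            (self.min_samples >= 1, "min_samples >= 1"),
            (self.floor >= 0, "floor >= 0"),
            (0 < self.top_cv_frac < 1, "top_cv_frac in (0,1)"),
            (all(c[3] > 1 for c in self.comparisons), "fc cutoffs > 1"),
            (0 <= self.prune_conf < 1, "prune_conf in [0,1)"),
            (0 < self.ora_p_max <= 1, "ora_p_max in (0,1]"),
            (0 < self.ora_q_max <= 1, "ora_q_max in (0,1]"),
            (0 <= self.ora_coverage_min < 1, "ora_coverage_min in [0,1)"),
            (self.gsea_n_perm >= 1, "gsea_n_perm >= 1"),
            (1 <= self.gsea_min_size <= self.gsea_max_size, "gsea sizes ordered"),
            (0 <= self.string_conf < 1, "string_conf in [0,1)"),
            (0 <= self.anat_conf < 1, "anat_conf in [0,1)"),
        ]
        for ok, rule in checks:
            if not ok:
                raise ValueError(f"config violates: {rule}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def comparison_specs(self) -> list[ComparisonSpec]:
        return [ComparisonSpec(name=c[0], numerator=c[1], denominator=c[2],
                               fc_cutoff=float(c[3])) for c in self.comparisons]

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class AnalysisResult:
    normalized: object
    fold_changes: dict
    signatures: dict
    pruned: dict
    venn: dict
    records: dict  # (comparison, direction, database) -> [EnrichmentRecord]
    groups: dict  # (comparison, direction) -> [TermGroup]
    gsea: dict  # comparison -> [GseaResult]
    metrics: list
    ranking_per_comparison: dict
    ranking_overall: object
    counts_log: dict


def run_analysis(counts, networks: KnowledgeNetworks, config: PipelineConfig,
                 ora_dbs: list[GeneSetDB] | None = None,
                 gsea_dbs: list[GeneSetDB] | None = None,
                 coding_ids=None, tfs: list | None = None) -> AnalysisResult:
    """Run the full in-memory analysis chain and return every product."""
    log: dict = {"n_genes_input": len(counts.genes)}
    norm = preprocess.preprocess_counts(
        counts, min_count=config.min_count, min_samples=config.min_samples,
        floor=config.floor, coding_ids=coding_ids, top_cv_frac=config.top_cv_frac)
    log["n_genes_preprocessed"] = len(norm.genes)
    universe = set(norm.genes)

    comps = config.comparison_specs()
    fold_changes, sigs, pruned = {}, {}, {}
    for comp in comps:
        fc = signatures.group_fold_change(norm, comp)
        fold_changes[comp.name] = fc
        sig = signatures.select_signature(fc, comp)
        sigs[comp.name] = sig
        pruned[comp.name] = signatures.prune_by_connectivity(
            sig.genes, networks.ppi, min_conf=config.prune_conf,
            excluded_channels=set(config.prune_excluded_channels),
            min_component=config.prune_min_component)
        log[f"n_signature_{comp.name}"] = len(sig.genes)
        log[f"n_pruned_{comp.name}"] = len(pruned[comp.name])
    venn = signatures.venn_partition(list(sigs.values()))
    log["n_signature_union"] = len(set().union(*(s.genes for s in sigs.values())))

    records: dict = {}
    groups: dict = {}
    for comp in comps:
        for direction in ("up", "down"):
            query = getattr(sigs[comp.name], direction) & universe
            family = []
            for db in ora_dbs or []:
                recs = enrichment.ora_test(
                    query, universe, db, comparison=comp.name,
                    direction=direction, max_term_size=config.ora_max_term_size)
                records[(comp.name, direction, db.name)] = recs
                family.extend(enrichment.filter_records(
                    recs, p_max=config.ora_p_max, q_max=config.ora_q_max,
                    coverage_min=config.ora_coverage_min))
            if family:
                groups[(comp.name, direction)] = enrichment.consolidate_terms(
                    family, min_overlap=config.term_min_overlap,
                    min_shared=config.term_min_shared,
                    min_group=config.term_min_group)
    log["n_term_groups"] = sum(len(g) for g in groups.values())

    gsea_results: dict = {}
    if gsea_dbs:
        for i, comp in enumerate(comps):
            ranked = gsea.rank_genes(norm, comp)
            gsea_results[comp.name] = gsea.run_gsea(
                ranked, gsea_dbs, n_perm=config.gsea_n_perm,
                min_size=config.gsea_min_size, max_size=config.gsea_max_size,
                seed=config.seed + 1000 + i)
        log["n_gsea_significant"] = sum(
            len(gsea.select_hallmarks(r, fdr_max=config.gsea_fdr_max,
                                      nes_min=config.gsea_nes_min))
            for r in gsea_results.values())

    tf_list = tfs or config.tfs
    if not tf_list:
        tf_list = sorted(set(networks.regulon["tf"]) | set(networks.relatedness["tf"]))
    metrics = []
    for comp in comps:
        target_genes = pruned[comp.name] or sigs[comp.name].genes
        for tf in tf_list:
            metrics.append(tfrank.compute_tf_metrics(
                tf, comp.name, target_genes, networks,
                string_conf=config.string_conf, anat_conf=config.anat_conf))
    ranking_per_comparison = {
        comp.name: tfrank.consolidate_ranking(
            [m for m in metrics if m.comparison == comp.name])
        for comp in comps
    } if len(tf_list) >= 3 else {}
    ranking_overall = (tfrank.consolidate_ranking(metrics)
                       if len(tf_list) >= 3 else None)
    if ranking_overall is not None:
        log["top_tf"] = ranking_overall.top

    return AnalysisResult(
        normalized=norm, fold_changes=fold_changes, signatures=sigs,
        pruned=pruned, venn=venn, records=records, groups=groups,
        gsea=gsea_results, metrics=metrics,
        ranking_per_comparison=ranking_per_comparison,
        ranking_overall=ranking_overall, counts_log=log)


def _write_outputs(result: AnalysisResult, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digest = config.digest()
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        if old.get("config_hash") not in (None, digest):
            raise FileExistsError(
                f"{out} holds results for config {old['config_hash']}; "
                f"refusing to overwrite with config {digest}")

    norm = result.normalized
    df = norm.values.copy()
    df.index.name = "gene"
    df.to_csv(out / "normalized.tsv", sep="\t", float_format="%.6g")

    rows = []
    for name, sig in result.signatures.items():
        for direction in ("up", "down"):
            for gene in sorted(getattr(sig, direction)):
                rows.append({"gene": gene, "comparison": name,
                             "direction": direction, "fc": sig.fc[gene],
                             "pruned_in": gene in result.pruned[name]})
    pd.DataFrame(rows).to_csv(out / "signatures.tsv", sep="\t", index=False,
                              float_format="%.6g")
    (out / "venn.json").write_text(json.dumps(
        {k: sorted(v) for k, v in result.venn.items()}, indent=2))

    rows = []
    for (comp, direction), groups in result.groups.items():
        for g in groups:
            rows.append({"group": g.label, "comparison": comp,
                         "direction": direction, "n_terms": g.n_terms,
                         "n_databases": len(g.databases),
                         "signed_score": g.signed_score(),
                         "terms": ";".join(r.term for r in g.members)})
    pd.DataFrame(rows).to_csv(out / "term_groups.tsv", sep="\t", index=False,
                              float_format="%.6g")

    rows = []
    for comp, results in result.gsea.items():
        for r in results:
            rows.append({"comparison": comp, "set": r.set_name, "es": r.es,
                         "nes": r.nes, "p": r.p, "fdr": r.fdr,
                         "set_size": r.set_size,
                         "leading_edge_size": len(r.leading_edge)})
    pd.DataFrame(rows).to_csv(out / "gsea.tsv", sep="\t", index=False,
                              float_format="%.6g")

    pd.DataFrame([m.as_row() for m in result.metrics]).to_csv(
        out / "tf_metrics.tsv", sep="\t", index=False, float_format="%.6g")
    if result.ranking_overall is not None:
        rows = []
        for rank, (tf, z) in enumerate(result.ranking_overall.mean_z.items(), 1):
            tuk = result.ranking_overall.tukey_p[tf].dropna()
            rows.append({"tf": tf, "mean_z": z, "rank": rank,
                         "anova_p": result.ranking_overall.anova_p,
                         "min_tukey_p": tuk.min() if len(tuk) else float("nan")})
        pd.DataFrame(rows).to_csv(out / "tf_ranking.tsv", sep="\t", index=False,
                                  float_format="%.6g")

    manifest = {
        "config_hash": digest,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stage_counts": result.counts_log,
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> AnalysisResult:
    """File-level entry point: read inputs, run the chain, write outputs."""
    counts = io.read_counts(config.counts, config.design)
    networks = io.read_knowledge(config.ppi, config.regulon, config.relatedness)
    coding = io.read_gene_list(config.coding_genes) if config.coding_genes else None
    ora_dbs = [io.read_gmt(p) for p in config.gmt_ora]
    gsea_dbs = [io.read_gmt(p) for p in config.gmt_gsea]
    result = run_analysis(counts, networks, config, ora_dbs=ora_dbs or None,
                          gsea_dbs=gsea_dbs or None, coding_ids=coding)
    _write_outputs(result, config)
    return result
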