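"""Shared domain containers for the pipeline.

Every stage of the analysis exchanges one of the small typed containers
defined here: expression matrices with their sample->group design,
directional fold-change signatures, knowledge networks (protein-protein
interactions, transcription-factor regulons, gene-TF relatedness scores),
enrichment records/groups, and the consolidated TF ranking.

Containers are thin wrappers over pandas structures; they validate their
own invariants at construction time and otherwise stay out of the way.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "ComparisonSpec",
    "GeneSignature",
    "GeneSetDB",
    "EnrichmentRecord",
    "TermGroup",
    "KnowledgeNetworks",
    "RankedList",
    "GseaResult",
    "TFMetrics",
    "TFRanking",
    "TF_PARAMETERS",
]


def _check_design(values: pd.DataFrame, design: pd.Series) -> None:
    if values.index.has_duplicates:
        dupes = values.index[values.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene IDs: {dupes[:5]}")
    if values.columns.has_duplicates:
        raise ValueError("duplicate sample IDs")
    missing = [s for s in values.columns if s not in design.index]
    if missing:
        raise ValueError(f"samples missing from design: {missing}")


@dataclass
class CountMatrix:
    """Raw gene-by-sample integer counts plus the sample->group design."""

    values: pd.DataFrame
    design: pd.Series

    def __post_init__(self) -> None:
        _check_design(self.values, self.design)
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("count matrix must hold integers")
            self.values = self.values.round().astype(np.int64)
        if (self.values.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.design = self.design.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def groups(self) -> dict[str, list[str]]:
        """Group name -> list of sample IDs, in design order."""
        out: dict[str, list[str]] = {}
        for sample, group in self.design.items():
            out.setdefault(group, []).append(sample)
        return out


@dataclass
class NormalizedMatrix:
    """Normalized gene-by-sample expression with provenance flags.

    ``provenance`` records which transforms have been applied
    (``normalized``, ``floored``, ``coding_filtered``, ``cv_filtered``)
    so downstream stages can assert their preconditions.
    """

    values: pd.DataFrame
    design: pd.Series
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_design(self.values, self.design)
        if (self.values.to_numpy() < 0).any():
            raise ValueError("normalized values must be non-negative")
        self.design = self.design.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def groups(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for sample, group in self.design.items():
            out.setdefault(group, []).append(sample)
        return out

    def with_values(self, values: pd.DataFrame, **flags) -> "NormalizedMatrix":
        prov = dict(self.provenance)
        prov.update(flags)
        return NormalizedMatrix(values=values, design=self.design, provenance=prov)


@dataclass(frozen=True)
class ComparisonSpec:
    """A two-group contrast with its fold-change cutoff.

    Fold change is numerator-group mean over denominator-group mean on
    the linear (floored) scale; ``fc_cutoff`` > 1 selects genes with
    FC >= cutoff (up) or FC <= 1/cutoff (down).
    """

    name: str
    numerator: str
    denominator: str
    fc_cutoff: float = 2.0

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ValueError("numerator and denominator groups must differ")
        if not self.fc_cutoff > 1:
            raise ValueError(f"fc_cutoff must be > 1, got {self.fc_cutoff}")

    def reversed(self) -> "ComparisonSpec":
        return ComparisonSpec(
            name=f"{self.denominator}_vs_{self.numerator}",
            numerator=self.denominator,
            denominator=self.numerator,
            fc_cutoff=self.fc_cutoff,
        )


#: The default three-stage contrasts: macrometastasis-associated (MAF),
#: micrometastasis-associated (MIF) and normal lung fibroblasts (NLF).
#: The MIF vs NLF contrast uses the softer 1.5 cutoff because early-stage
#: expression shifts are subtler.
DEFAULT_COMPARISONS = (
    ComparisonSpec("MIF_vs_NLF", "MIF", "NLF", 1.5),
    ComparisonSpec("MAF_vs_NLF", "MAF", "NLF", 2.0),
    ComparisonSpec("MAF_vs_MIF", "MAF", "MIF", 2.0),
)


@dataclass
class GeneSignature:
    comparison: str
    up: set
    down: set
    fc: dict

    def __post_init__(self) -> None:
        overlap = self.up & self.down
        if overlap:
            raise ValueError(f"genes in both directions: {sorted(overlap)[:5]}")

    @property
    def genes(self) -> set:
        return self.up | self.down


@dataclass
class GeneSetDB:
    """Named collection of gene sets (one source database, e.g. GO-BP)."""

    name: str
    sets: dict  # term id -> frozenset of gene ids
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, members in self.sets.items():
            if not members:
                raise ValueError(f"empty gene set: {term}")
            self.sets[term] = frozenset(members)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class EnrichmentRecord:
    """One term's over-representation statistics for one query list."""

    term: str
    database: str
    comparison: str
    direction: str  # "up" | "down"
    overlap: frozenset
    term_size: int  # size within the universe
    p: float
    q: float = float("nan")
    description: str = ""

    @property
    def coverage(self) -> float:
        return len(self.overlap) / self.term_size


@dataclass
class TermGroup:
    """Cross-database annotation group of consolidated enriched terms."""

    label: str
    members: list  # EnrichmentRecord
    comparison: str
    direction: str

    @property
    def n_terms(self) -> int:
        return len(self.members)

    @property
    def databases(self) -> set:
        return {r.database for r in self.members}

    def signed_score(self, q_floor: float = 1e-300) -> float:
        logq = [-np.log10(max(r.q, q_floor)) for r in self.members]
        score = float(np.mean(logq))
        return -score if self.direction == "down" else score


@dataclass
class KnowledgeNetworks:
    """The three knowledge inputs for TF ranking.

    ppi: undirected weighted edges (gene_a, gene_b, confidence, channel);
    regulon: directed TF->target pairs; relatedness: per (gene, tf) a
    non-negative score and a direct/indirect flag.
    """

    ppi: pd.DataFrame
    regulon: pd.DataFrame
    relatedness: pd.DataFrame

    def __post_init__(self) -> None:
        ppi = self.ppi
        need = {"gene_a", "gene_b", "confidence", "channel"}
        if not need.issubset(ppi.columns):
            raise ValueError(f"ppi table needs columns {sorted(need)}")
        conf = ppi["confidence"].to_numpy(dtype=float)
        if ((conf <= 0) | (conf > 1)).any():
            raise ValueError("ppi confidence must lie in (0, 1]")
        if (ppi["gene_a"] == ppi["gene_b"]).any():
            raise ValueError("ppi self-loops are not allowed")
        # collapse duplicate (unordered pair, channel) edges to max confidence
        a = ppi["gene_a"].astype(str)
        b = ppi["gene_b"].astype(str)
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        key = pd.DataFrame({"gene_a": lo, "gene_b": hi,
                            "confidence": conf, "channel": ppi["channel"].values})
        self.ppi = (
            key.groupby(["gene_a", "gene_b", "channel"], as_index=False)["confidence"]
            .max()[["gene_a", "gene_b", "confidence", "channel"]]
        )
        if not {"tf", "target"}.issubset(self.regulon.columns):
            raise ValueError("regulon table needs columns tf, target")
        self.regulon = self.regulon.drop_duplicates(subset=["tf", "target"]).reset_index(drop=True)
        need = {"gene", "tf", "score", "flag"}
        if not need.issubset(self.relatedness.columns):
            raise ValueError(f"relatedness table needs columns {sorted(need)}")
        if self.relatedness.duplicated(subset=["gene", "tf"]).any():
            raise ValueError("duplicate (gene, tf) relatedness rows")
        if (self.relatedness["score"].to_numpy(dtype=float) < 0).any():
            raise ValueError("relatedness scores must be >= 0")
        bad = set(self.relatedness["flag"]) - {"direct", "indirect"}
        if bad:
            raise ValueError(f"relatedness flag must be direct/indirect, got {bad}")


@dataclass
class RankedList:
    """Genes ordered by a real-valued metric, descending; ties broken by ID."""

    genes: list
    metric: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("ranked list genes must be unique")
        self.metric = np.asarray(self.metric, dtype=float)
        if not np.isfinite(self.metric).all():
            raise ValueError("ranking metric must be finite")
        order = sorted(range(len(self.genes)),
                       key=lambda i: (-self.metric[i], self.genes[i]))
        self.genes = [self.genes[i] for i in order]
        self.metric = self.metric[order]

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GseaResult:
    set_name: str
    es: float
    nes: float
    p: float
    fdr: float
    leading_edge: frozenset
    set_size: int
    n_permutations: int


#: Column order of the eight per-TF ranking parameters.
TF_PARAMETERS = (
    "string_degree",
    "anat_direct",
    "anat_cpl",
    "anat_centralization",
    "regnet_targets",
    "var_n_direct",
    "var_mean_direct",
    "var_mean_indirect",
)


@dataclass
class TFMetrics:
    """Per-TF parameter vector across the evidence sources, one comparison."""

    tf: str
    comparison: str
    string_degree: int
    anat_direct: int
    anat_cpl: float  # NaN when no node is reachable
    anat_centralization: float  # NaN when subnet < 3 nodes
    regnet_targets: int
    var_n_direct: int
    var_mean_direct: float
    var_mean_indirect: float

    def as_row(self) -> dict:
        row = {"tf": self.tf, "comparison": self.comparison}
        for p in TF_PARAMETERS:
            row[p] = getattr(self, p)
        return row


@dataclass
class TFRanking:
    """Z-scored consolidation of TF metrics with ANOVA/Tukey statistics."""

    zscores: pd.DataFrame  # index (comparison, parameter), columns TFs
    mean_z: pd.Series  # per TF, descending
    anova_f: float
    anova_p: float
    tukey_p: pd.DataFrame  # TF x TF adjusted p, NaN on diagonal

    @property
    def order(self) -> list:
        return list(self.mean_z.index)

    @property
    def top(self) -> str:
        return self.mean_z.index[0]
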