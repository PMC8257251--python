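"""Readers and writers for the pipeline's plain-text interchange formats.

Counts and design are TSV with headers; gene-set databases are GMT
(set name, description, then tab-separated members); the knowledge
inputs are TSVs whose header determines their kind (PPI edge list,
regulon pairs, relatedness rows).  Readers validate the container
invariants on load and report malformed input with file and line.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .containers import CountMatrix, GeneSetDB, KnowledgeNetworks

__all__ = [
    "read_counts",
    "write_counts",
    "read_design",
    "read_gmt",
    "write_gmt",
    "read_network",
    "write_network",
    "read_gene_list",
    "read_knowledge",
]

_NETWORK_COLUMNS = {
    "ppi": ["gene_a", "gene_b", "confidence", "channel"],
    "regulon": ["tf", "target"],
    "relatedness": ["gene", "tf", "score", "flag"],
}


def read_design(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample", "group"]:
        raise ValueError(f"{path}: design header must be 'sample\\tgroup'")
    if df["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample IDs in design")
    return pd.Series(df["group"].values, index=df["sample"].values, name="group")


def read_counts(counts_path, design_path) -> CountMatrix:
    """Counts TSV (first column = gene ID, remaining = samples) + design TSV."""
    df = pd.read_csv(counts_path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{counts_path}: duplicate gene IDs {dupes[:5]}")
    design = read_design(design_path)
    return CountMatrix(values=df, design=design)


def write_counts(counts: CountMatrix, counts_path, design_path=None) -> None:
    df = counts.values.copy()
    df.index.name = "gene"
    df.to_csv(counts_path, sep="\t")
    if design_path is not None:
        pd.DataFrame({"sample": counts.design.index,
                      "group": counts.design.values}) \
            .to_csv(design_path, sep="\t", index=False)


def read_gmt(path, name: str | None = None) -> GeneSetDB:
    """GMT: one set per line, 'name<TAB>description<TAB>member...'."""
    path = Path(path)
    sets, descriptions = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >= 3 "
                                 f"tab-separated fields, got {len(fields)}")
            term, desc, members = fields[0], fields[1], fields[2:]
            if term in sets:
                raise ValueError(f"{path}:{lineno}: duplicate term {term!r}")
            sets[term] = set(m for m in members if m)
            descriptions[term] = desc
    return GeneSetDB(name=name or path.stem, sets=sets, descriptions=descriptions)


def write_gmt(db: GeneSetDB, path) -> None:
    with open(path, "w") as fh:
        for term in sorted(db.sets):
            desc = db.descriptions.get(term, "")
            fh.write("\t".join([term, desc, *sorted(db.sets[term])]) + "\n")


def read_network(path, kind: str) -> pd.DataFrame:
    """Read one knowledge table; ``kind`` in {'ppi', 'regulon', 'relatedness'}."""
    if kind not in _NETWORK_COLUMNS:
        raise ValueError(f"unknown network kind {kind!r}")
    cols = _NETWORK_COLUMNS[kind]
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != cols:
        raise ValueError(f"{path}: expected header {cols}, got {list(df.columns)}")
    if kind == "ppi":
        df["confidence"] = pd.to_numeric(df["confidence"], errors="raise")
        bad = df[(df["confidence"] <= 0) | (df["confidence"] > 1)]
        if len(bad):
            raise ValueError(f"{path}: line {bad.index[0] + 2}: "
                             f"confidence {bad['confidence'].iloc[0]} outside (0,1]")
    elif kind == "relatedness":
        df["score"] = pd.to_numeric(df["score"], errors="raise")
    return df


def write_network(df: pd.DataFrame, path) -> None:
    kind = next((k for k, cols in _NETWORK_COLUMNS.items()
                 if set(cols) == set(df.columns)), None)
    if kind is None:
        raise ValueError(f"table columns {list(df.columns)} match no network kind")
    df[_NETWORK_COLUMNS[kind]].to_csv(path, sep="\t", index=False,
                                      float_format="%.10g")
    return None


def read_knowledge(ppi_path, regulon_path, relatedness_path) -> KnowledgeNetworks:
    return KnowledgeNetworks(
        ppi=read_network(ppi_path, "ppi"),
        regulon=read_network(regulon_path, "regulon"),
        relatedness=read_network(relatedness_path, "relatedness"),
    )


def read_gene_list(path) -> list[str]:
    """One gene ID per line; blank lines ignored."""
    with open(path) as fh:
        genes = [line.strip() for line in fh if line.strip()]
    if not genes:
        raise ValueError(f"{path}: empty gene list")
    return genes
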