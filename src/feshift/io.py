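"""File I/O: count tables, expression tables, gene sets, configs, manifests.

Conventions: tab-separated inputs, comma-separated results, UTF-8, '.'
decimal separator. Gene identifiers are matched case-insensitively
(uppercased) across counts, expression tables and gene sets.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .shift import GeneSetCollection
from .simulate import ScreenDataset, TMTDataset

__all__ = [
    "read_counts_tsv",
    "write_counts_tsv",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "read_impurity_csv",
    "read_design_yaml",
    "read_peptides_tsv",
    "write_tmt_dataset",
    "write_manifest",
    "builtin_genesets",
]


def read_counts_tsv(path) -> ScreenDataset:
    """Read a guide count table (columns: guide, gene, one per sample)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"guide": str, "gene": str})
    for col in ("guide", "gene"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    sample_cols = [c for c in df.columns if c not in ("guide", "gene")]
    if len(sample_cols) < 2:
        raise ValueError(f"{path}: need at least 2 sample columns")
    dupes = df["guide"][df["guide"].duplicated()]
    if len(dupes):
        raise ValueError(f"{path}: duplicate guide id {dupes.iloc[0]!r}")
    counts = df[sample_cols]
    for col in sample_cols:
        as_float = pd.to_numeric(counts[col], errors="raise")
        if not np.allclose(as_float, np.round(as_float)):
            raise ValueError(f"{path}: non-integer counts in column {col!r}")
        bad = np.flatnonzero(as_float < 0)
        if bad.size:
            raise ValueError(
                f"{path}: negative count in column {col!r}, row {bad[0] + 2}")
    counts = counts.astype(np.int64)
    counts.index = pd.Index(df["guide"], name="guide")
    guide_map = pd.Series(df["gene"].str.upper().to_numpy(),
                          index=counts.index, name="gene")
    return ScreenDataset(counts=counts, guide_map=guide_map)


def write_counts_tsv(dataset: ScreenDataset, path) -> None:
    out = dataset.counts.copy()
    out.insert(0, "gene", dataset.guide_map)
    out.to_csv(path, sep="\t", index=True)


def read_expression_tsv(path) -> pd.Series:
    """Read a 2-column gene / log2 FPKM table."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (gene, log2 FPKM)")
    gene_col, value_col = df.columns[:2]
    expr = pd.Series(pd.to_numeric(df[value_col], errors="raise").to_numpy(),
                     index=pd.Index(df[gene_col].astype(str).str.upper(),
                                    name="gene"),
                     name="log2_fpkm")
    return expr


def write_expression_tsv(expression: pd.Series, path) -> None:
    expression.rename("log2_fpkm").to_csv(path, sep="\t", header=True)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file (name <tab> description <tab> members...)."""
    path = Path(path)
    sets = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: malformed GMT line "
                    f"(need name, description and >= 1 member)")
            name = fields[0]
            members = frozenset(m.upper() for m in fields[2:] if m)
            if not members:
                raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = members
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GeneSetCollection(sets=sets, provenance=str(path))


def write_gmt(sets: GeneSetCollection, path, description: str = "") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def read_impurity_csv(path) -> pd.DataFrame:
    """Read a channel x channel impurity matrix (CSV, labeled rows/cols)."""
    m = pd.read_csv(path, index_col=0)
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: impurity matrix must be square")
    return m.astype(float)


def read_design_yaml(path) -> dict:
    """Read a channel -> condition design mapping from YAML."""
    with open(path, encoding="utf-8") as fh:
        design = yaml.safe_load(fh)
    if not isinstance(design, dict) or not design:
        raise ValueError(f"{path}: design must be a non-empty mapping")
    return {str(k): str(v) for k, v in design.items()}


def read_peptides_tsv(path) -> pd.DataFrame:
    """Read a peptide SN table (columns: peptide, protein, channels...)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("peptide", "protein"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    channels = [c for c in df.columns if c not in ("peptide", "protein")]
    if not channels:
        raise ValueError(f"{path}: no channel columns")
    df[channels] = df[channels].astype(float)
    return df


def write_tmt_dataset(dataset: TMTDataset, outdir) -> dict:
    """Write peptide table, impurity matrix, design and truth; return paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "peptides": outdir / "peptides.tsv",
        "impurity": outdir / "impurity.csv",
        "design": outdir / "design.yaml",
        "truth": outdir / "protein_truth.tsv",
    }
    dataset.peptides.to_csv(paths["peptides"], sep="\t", index=False)
    dataset.impurity.to_csv(paths["impurity"])
    with open(paths["design"], "w", encoding="utf-8") as fh:
        yaml.safe_dump(dataset.design, fh)
    dataset.truth.to_csv(paths["truth"], sep="\t")
    return {k: str(v) for k, v in paths.items()}


def write_manifest(outdir, stage: str, params: dict, inputs: dict,
                   outputs: dict, seed: int | None = None) -> Path:
    """Write a run manifest sufficient to reproduce the stage."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    from . import __version__

    manifest = {
        "stage": stage,
        "seed": seed,
        "parameters": params,
        "inputs": {k: str(v) for k, v in inputs.items()},
        "outputs": {k: str(v) for k, v in outputs.items()},
        "versions": {
            "feshift": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    path = outdir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return path


def builtin_genesets() -> GeneSetCollection:
    """Curated Fe-S / mitoribosome gene sets shipped with the package."""
    return read_gmt(Path(__file__).parent / "data" / "genesets.gmt")
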