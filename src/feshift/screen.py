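"""Pooled CRISPR screen scoring with an empirical null of non-expressed genes.

Raw guide counts are normalized to reads per million and log2 transformed as
``log2(r / R * 1e6 + 1)``; each guide's log2 fold-change (LFC) is taken
against its abundance in the plasmid library; gene LFC is the unweighted mean
over the gene's guides within each replicate, then the mean across paired
replicates. Per treatment arm, gene LFCs are Z-transformed against the mean
and sample SD of an empirical null set of genes — genes with no detectable
expression, whose knockout can have no fitness consequence. The genetic
interaction score is ``delta_z = z_treat - z_ctrl``: strongly positive genes
are buffering (less essential on the sensitized background), strongly
negative ones synthetic sick.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "normalize_counts",
    "guide_lfc",
    "gene_scores",
    "define_null_genes",
    "z_transform",
    "gi_scores",
    "score_screen",
]

#: Default replicate layout of a two-background screen against one shared
#: plasmid reference.
DEFAULT_ARMS = {
    "ctrl": ("ctrl_rep1", "ctrl_rep2"),
    "treat": ("treat_rep1", "treat_rep2"),
}


def normalize_counts(counts: pd.Series, pseudocount: float = 1.0) -> pd.Series:
    """Reads-per-million log2 abundance: ``log2(r / R * 1e6 + pseudocount)``.

    With the default pseudocount of 1 the value is 0 exactly for unobserved
    guides and monotone non-decreasing in the read count.
    """
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("negative counts")
    total = arr.sum()
    if total <= 0:
        raise ValueError("all-zero sample: total reads must be positive")
    return pd.Series(np.log2(arr / total * 1e6 + pseudocount),
                     index=counts.index, name=counts.name)


def guide_lfc(sample: pd.Series, reference: pd.Series) -> pd.Series:
    """Per-guide log2 fold-change of a sample vs. the library reference."""
    if not sample.index.equals(reference.index):
        if set(sample.index) != set(reference.index):
            raise ValueError("sample and reference guide sets differ")
        reference = reference.reindex(sample.index)
    return sample - reference


def gene_scores(replicate_lfcs: dict[str, pd.Series] | pd.DataFrame,
                guide_map: pd.Series, min_guides: int = 2) -> pd.DataFrame:
    """Aggregate guide LFCs to genes: per-replicate unweighted mean over each
    gene's guides, then the unweighted mean across (paired) replicates.

    Genes with fewer than ``min_guides`` guides are flagged (``low_guides``)
    but kept. Returns a DataFrame indexed by gene with one ``lfc_<rep>``
    column per replicate, the across-replicate mean ``lfc`` and ``n_guides``.
    """
    lfcs = pd.DataFrame(replicate_lfcs)
    if lfcs.isna().any().any():
        raise ValueError("guide LFCs contain missing values")
    unmapped = lfcs.index.difference(guide_map.index)
    if len(unmapped):
        raise ValueError(f"guides missing from guide_map: {list(unmapped[:5])}")
    genes = guide_map.reindex(lfcs.index)
    per_rep = lfcs.groupby(genes.values, sort=True).mean()
    per_rep.index.name = "gene"
    n_guides = lfcs.groupby(genes.values).size()
    if (n_guides < 1).any():
        raise ValueError("gene with zero guides")
    out = per_rep.add_prefix("lfc_")
    out["lfc"] = per_rep.mean(axis=1)
    out["n_guides"] = n_guides
    out["low_guides"] = n_guides < min_guides
    return out


def define_null_genes(expression: pd.Series, threshold: float = -7.0) -> pd.Index:
    """Genes with log2 FPKM at or below ``threshold`` (the table floor).

    These non-expressed genes define the empirical null distribution of gene
    LFCs: their knockouts are phenotypically inert, so their score spread
    measures pure technical noise.
    """
    null = expression.index[expression <= threshold]
    if len(null) == 0:
        raise ValueError(
            f"no genes at or below log2 FPKM {threshold}; empty null set")
    return null


def z_transform(gene_lfc: pd.Series, null_genes) -> pd.Series:
    """Z-score gene LFCs against the null genes' mean and sample SD (ddof=1).

    By construction the returned values of the null genes themselves have
    mean 0 and sample SD 1 exactly.
    """
    null_genes = pd.Index(null_genes)
    missing = null_genes.difference(gene_lfc.index)
    if len(missing):
        raise ValueError(f"null genes absent from scores: {list(missing[:5])}")
    null_vals = gene_lfc.loc[null_genes]
    mu = null_vals.mean()
    sd = null_vals.std(ddof=1)
    if not sd > 0:
        raise ValueError("null gene LFC standard deviation is zero")
    return (gene_lfc - mu) / sd


def gi_scores(z_ctrl: pd.Series, z_treat: pd.Series,
              z_cut: float = 2.0) -> pd.DataFrame:
    """Genetic-interaction calls from per-arm Z scores.

    ``delta_z = z_treat - z_ctrl``; class is ``buffering`` if
    ``delta_z >= z_cut``, ``synthetic_sick`` if ``delta_z <= -z_cut``,
    else ``neutral``.
    """
    if z_cut <= 0:
        raise ValueError("z_cut must be positive")
    if set(z_ctrl.index) != set(z_treat.index):
        raise ValueError("gene universes of the two arms differ")
    z_treat = z_treat.reindex(z_ctrl.index)
    delta = z_treat - z_ctrl
    gclass = np.where(delta >= z_cut, "buffering",
                      np.where(delta <= -z_cut, "synthetic_sick", "neutral"))
    return pd.DataFrame(
        {"z_ctrl": z_ctrl, "z_treat": z_treat, "delta_z": delta,
         "gi_class": gclass},
        index=z_ctrl.index,
    )


def score_screen(counts: pd.DataFrame, guide_map: pd.Series,
                 expression: pd.Series | None = None,
                 null_genes=None,
                 reference: str = "plasmid",
                 arms: dict | None = None,
                 null_threshold: float = -7.0,
                 z_cut: float = 2.0,
                 min_guides: int = 2,
                 pseudocount: float = 1.0) -> pd.DataFrame:
    """End-to-end screen scoring for a two-background experiment.

    Parameters
    ----------
    counts:
        Guide x sample integer counts including the ``reference`` column.
    guide_map:
        guide -> gene.
    expression:
        gene -> log2 FPKM; the null set is ``<= null_threshold``. Null genes
        may instead be given directly via ``null_genes``.
    arms:
        Mapping arm name -> replicate column names (default the standard
        ctrl/treat duplicate layout).

    Returns
    -------
    DataFrame indexed by gene with per-arm LFC and Z columns, ``delta_z``
    and the interaction class.
    """
    arms = dict(arms or DEFAULT_ARMS)
    if null_genes is None:
        if expression is None:
            raise ValueError("either expression or null_genes is required")
        null_genes = define_null_genes(expression, null_threshold)
    ref_norm = normalize_counts(counts[reference], pseudocount)

    per_arm_lfc: dict[str, pd.Series] = {}
    per_arm_z: dict[str, pd.Series] = {}
    tables: dict[str, pd.DataFrame] = {}
    for arm, rep_cols in arms.items():
        rep_lfcs = {
            col: guide_lfc(normalize_counts(counts[col], pseudocount), ref_norm)
            for col in rep_cols
        }
        table = gene_scores(rep_lfcs, guide_map, min_guides=min_guides)
        null_present = pd.Index(null_genes).intersection(table.index)
        per_arm_lfc[arm] = table["lfc"]
        per_arm_z[arm] = z_transform(table["lfc"], null_present)
        tables[arm] = table

    gi = gi_scores(per_arm_z["ctrl"], per_arm_z["treat"], z_cut=z_cut)
    out = pd.DataFrame(
        {"lfc_ctrl": per_arm_lfc["ctrl"], "lfc_treat": per_arm_lfc["treat"]})
    out = pd.concat([out, gi], axis=1)
    out["n_guides"] = tables["ctrl"]["n_guides"]
    out["low_guides"] = tables["ctrl"]["low_guides"]
    return out
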