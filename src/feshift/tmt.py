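"""TMT reporter-ion quantification: impurity correction, SN filtering,
protein rollup, channel-loading normalization and log10 fold-changes.

The pipeline starts from a peptide-level table of reporter signal-to-noise
(SN) per channel. Isotope impurities of the labeling reagents mix a fraction
of each channel's signal into its neighbors; with the manufacturer's
column-stochastic impurity matrix ``M`` the observed channel vector of a
peptide is ``M @ true``, so the correction solves the linear system per
peptide row. Proteins are quantified by summing their peptides' corrected SN,
filtered on total summed SN, scaled so every channel carries equal total
signal (equal-loading adjustment), and reported as replicate-averaged log10
fold-changes of treated over control channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "impurity_matrix_from_spillover",
    "correct_impurities",
    "aggregate_psms",
    "rollup_proteins",
    "normalize_loading",
    "protein_log_fold_change",
    "quantify",
]


def impurity_matrix_from_spillover(n_channels: int, spillover: float,
                                   channels=None) -> pd.DataFrame:
    """Tridiagonal column-stochastic impurity matrix.

    A fraction ``spillover`` of each reagent's signal leaks into each
    adjacent channel; edge channels have a single neighbor. Columns sum to 1.
    """
    if n_channels <= 0:
        raise ValueError("n_channels must be positive")
    if not 0 <= spillover < 0.5:
        raise ValueError("spillover must lie in [0, 0.5)")
    m = np.zeros((n_channels, n_channels))
    for j in range(n_channels):
        neighbors = [i for i in (j - 1, j + 1) if 0 <= i < n_channels]
        for i in neighbors:
            m[i, j] = spillover
        m[j, j] = 1.0 - spillover * len(neighbors)
    labels = list(channels) if channels is not None else [
        f"ch{i + 1}" for i in range(n_channels)]
    return pd.DataFrame(m, index=labels, columns=labels)


def _check_impurity(m: pd.DataFrame) -> None:
    arr = np.asarray(m, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("impurity matrix must be square")
    if (arr < 0).any():
        raise ValueError("impurity matrix entries must be non-negative")
    if not np.allclose(arr.sum(axis=0), 1.0, atol=1e-9):
        raise ValueError("impurity matrix columns must sum to 1")


def correct_impurities(sn: pd.DataFrame, m: pd.DataFrame,
                       clip_negative: bool = True):
    """Invert the reagent impurity mixing on each peptide row.

    Solves ``m @ x = observed`` per row. Negative components of the solution
    (possible with measurement noise) are clipped to zero; the number of
    clipped entries is returned for QC logging.

    Parameters
    ----------
    sn:
        Observed SN, rows = peptides (or scans), columns = channels in the
        same order as ``m``.
    m:
        Column-stochastic impurity matrix, entry ``(i, j)`` the fraction of
        reagent *j*'s signal observed in channel *i*.

    Returns
    -------
    (corrected, n_clipped)
    """
    _check_impurity(m)
    arr = np.asarray(m, dtype=float)
    x = sn.to_numpy(dtype=float)
    if x.shape[1] != arr.shape[0]:
        raise ValueError("channel count of the table and the matrix differ")
    if abs(np.linalg.det(arr)) < 1e-12:
        raise np.linalg.LinAlgError("impurity matrix is singular")
    solved = np.linalg.solve(arr, x.T).T
    # QC counter ignores float-precision dust just below zero
    n_clipped = int((solved < -1e-9).sum())
    if clip_negative:
        solved = np.clip(solved, 0.0, None)
    out = pd.DataFrame(solved, index=sn.index, columns=sn.columns)
    return out, n_clipped


def aggregate_psms(psms: pd.DataFrame, channels) -> pd.DataFrame:
    """Sum multiple PSM rows of the same peptide into one peptide row.

    Pass-through pre-aggregator for inputs quantified per spectrum; synthetic
    tables are already peptide-level and do not need it.
    """
    grouped = psms.groupby(["peptide", "protein"], sort=False)[list(channels)].sum()
    return grouped.reset_index()


def rollup_proteins(peptides: pd.DataFrame, channels=None,
                    sn_min: float = 100.0):
    """Sum peptide SN to proteins and filter on total summed SN.

    Proteins whose SN summed across all channels falls below ``sn_min``
    (default 100) are removed; the boundary value is retained.

    Returns
    -------
    (quant, removed):
        ``quant`` indexed by protein with one column per channel plus a
        ``total_sn`` QC column; ``removed`` the index of filtered proteins.
    """
    if len(peptides) == 0:
        raise ValueError("empty peptide table")
    if channels is None:
        channels = [c for c in peptides.columns if c not in ("peptide", "protein")]
    channels = list(channels)
    if (peptides[channels].to_numpy() < 0).any():
        raise ValueError("negative SN values")
    quant = peptides.groupby("protein", sort=True)[channels].sum()
    total = quant.sum(axis=1)
    keep = total >= sn_min
    removed = quant.index[~keep]
    quant = quant.loc[keep].copy()
    quant["total_sn"] = total[keep]
    return quant, removed


def normalize_loading(quant: pd.DataFrame, channels=None):
    """Scale channels so their protein-quantity column sums are equal.

    Each channel is multiplied by ``mean(column sums) / (its column sum)``;
    any common target yields identical fold-changes downstream. Within-channel
    rank order of proteins is unchanged.

    Returns
    -------
    (normalized, factors)
    """
    if len(quant) == 0:
        raise ValueError("empty protein table")
    if channels is None:
        channels = [c for c in quant.columns if c != "total_sn"]
    channels = list(channels)
    sums = quant[channels].sum(axis=0)
    if (sums <= 0).any():
        bad = sums.index[sums <= 0].tolist()
        raise ValueError(f"channel column sum is zero: {bad}")
    factors = sums.mean() / sums
    out = quant.copy()
    out[channels] = quant[channels] * factors
    return out, factors


def _replicate_pairs(design: dict) -> list[tuple[str, str]]:
    """Pair ctrl/treat channels by declared order within each condition."""
    ctrl = [ch for ch, cond in design.items() if cond == "ctrl"]
    treat = [ch for ch, cond in design.items() if cond == "treat"]
    if not ctrl or not treat:
        missing = "ctrl" if not ctrl else "treat"
        raise ValueError(f"condition {missing!r} absent from design")
    if len(ctrl) != len(treat):
        raise ValueError("unequal numbers of ctrl and treat channels")
    return list(zip(ctrl, treat))


def protein_log_fold_change(quant: pd.DataFrame, design: dict) -> pd.DataFrame:
    """Replicate-averaged log10 fold-change, treated over control.

    ``design`` maps channel -> condition ("ctrl" or "treat"); channels are
    paired by declared order within each condition. Proteins with a zero
    quantity in any used channel get ``log10_fc = NaN`` and a ``missing``
    flag instead of being dropped.
    """
    pairs = _replicate_pairs(design)
    used = [ch for pair in pairs for ch in pair]
    x = quant[used].to_numpy(dtype=float)
    ok = (x > 0).all(axis=1)
    per_pair = {}
    with np.errstate(divide="ignore", invalid="ignore"):
        for i, (c, t) in enumerate(pairs):
            per_pair[f"log10_fc_rep{i + 1}"] = np.log10(
                quant[t].to_numpy(dtype=float) / quant[c].to_numpy(dtype=float))
    out = pd.DataFrame(per_pair, index=quant.index)
    out["log10_fc"] = out.mean(axis=1)
    out.loc[~ok, [c for c in out.columns]] = np.nan
    out["missing"] = ~ok
    return out


@dataclass
class TMTQuantResult:
    """Full quantification output with QC counters."""

    proteins: pd.DataFrame
    factors: pd.Series
    n_clipped: int
    removed: pd.Index


def quantify(peptides: pd.DataFrame, impurity: pd.DataFrame, design: dict,
             sn_min: float = 100.0, correct_first: bool = True) -> TMTQuantResult:
    """Peptide SN table -> normalized protein quantities and log10 FC.

    ``correct_first`` applies the impurity correction before the summed-SN
    filter (default); set False to filter on observed SN instead.
    """
    channels = list(design)
    table = peptides[["peptide", "protein", *channels]].copy()
    n_clipped = 0
    if correct_first:
        corrected, n_clipped = correct_impurities(table[channels], impurity)
        table[channels] = corrected
        quant, removed = rollup_proteins(table, channels, sn_min=sn_min)
    else:
        quant, removed = rollup_proteins(table, channels, sn_min=sn_min)
        corrected, n_clipped = correct_impurities(quant[channels], impurity)
        quant[channels] = corrected
    quant, factors = normalize_loading(quant, channels)
    fc = protein_log_fold_change(quant, design)
    proteins = pd.concat([quant, fc], axis=1)
    return TMTQuantResult(proteins=proteins, factors=factors,
                          n_clipped=n_clipped, removed=removed)
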