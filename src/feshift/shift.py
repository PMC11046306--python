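"""Gene-set distribution-shift and over-representation analysis.

Protein log-fold-changes are ranked into a depletion "waterfall"; the
fold-change distribution of a gene set (e.g. Fe-S cluster proteins, the
mitoribosomal small subunit) is compared against the remaining detected
proteins with a two-sample Kolmogorov-Smirnov test; interaction hit lists
are tested for set over-representation with a one-sided hypergeometric test
and Benjamini-Hochberg correction across sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "KsResult",
    "rank_waterfall",
    "ks_two_sample",
    "pathway_shift_report",
    "enrich_hypergeometric",
    "enrich_collection",
    "bh_adjust",
]

#: Sample size at or below which the exact KS null distribution is used.
KS_EXACT_MAX_N = 25


@dataclass(frozen=True)
class GeneSetCollection:
    """Named, non-empty gene sets with uppercased identifiers."""

    sets: dict
    provenance: str = ""

    def __post_init__(self) -> None:
        cleaned = {}
        for name, members in self.sets.items():
            members = frozenset(str(m).upper() for m in members)
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            cleaned[name] = members
        object.__setattr__(self, "sets", cleaned)

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        from .io import read_gmt

        return read_gmt(path)

    def __getitem__(self, name: str) -> frozenset:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def names(self) -> list:
        return list(self.sets)


def _upper_index(fc: pd.Series) -> pd.Series:
    out = fc.copy()
    out.index = out.index.astype(str).str.upper()
    return out


def rank_waterfall(fc: pd.Series,
                   sets: GeneSetCollection | None = None) -> pd.DataFrame:
    """Rank proteins by fold-change, most depleted first.

    Stable ascending sort; ties broken lexicographically by identifier.
    Rank 1 is the most depleted protein. If ``sets`` is given, one boolean
    membership column per set is appended.
    """
    if len(fc) == 0:
        raise ValueError("empty fold-change table")
    if not np.isfinite(fc.to_numpy(dtype=float)).all():
        raise ValueError("fold-changes must be finite")
    fc = _upper_index(fc)
    frame = fc.rename("fc").to_frame()
    frame["_id"] = frame.index
    frame = frame.sort_values(["fc", "_id"], kind="mergesort").drop(columns="_id")
    frame["rank"] = np.arange(1, len(frame) + 1)
    if sets is not None:
        for name, members in sets.sets.items():
            frame[name] = frame.index.isin(members)
    return frame


@dataclass(frozen=True)
class KsResult:
    statistic: float
    pvalue: float
    n_a: int
    n_b: int
    mode: str


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Exact sup |ECDF_a - ECDF_b| over the pooled sample."""
    a = np.sort(a)
    b = np.sort(b)
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / a.size
    cdf_b = np.searchsorted(b, pooled, side="right") / b.size
    return float(np.abs(cdf_a - cdf_b).max())


def _ks_asymptotic_p(d: float, n_a: int, n_b: int, kmax: int = 100) -> float:
    """Kolmogorov survival function at sqrt(n_eff) * D, series |k| <= kmax."""
    en = n_a * n_b / (n_a + n_b)
    lam = np.sqrt(en) * d
    if lam <= 0:
        return 1.0
    k = np.arange(1, kmax + 1)
    p = 2.0 * np.sum((-1.0) ** (k - 1) * np.exp(-2.0 * k ** 2 * lam ** 2))
    return float(min(1.0, max(0.0, p)))


def ks_two_sample(a, b, mode: str = "auto") -> KsResult:
    """Two-sample Kolmogorov-Smirnov test.

    The D statistic is the exact supremum distance between the two empirical
    CDFs evaluated over the pooled sample. The p-value uses the exact
    permutation null (``mode="exact"``, automatic when
    ``min(n) <= KS_EXACT_MAX_N``) or the asymptotic Kolmogorov distribution
    with effective size ``n_a * n_b / (n_a + n_b)``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    d = _ks_statistic(a, b)
    if mode == "auto":
        mode = "exact" if min(a.size, b.size) <= KS_EXACT_MAX_N else "asymp"
    if mode == "exact":
        p = float(stats.ks_2samp(a, b, method="exact").pvalue)
    elif mode == "asymp":
        p = _ks_asymptotic_p(d, a.size, b.size)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return KsResult(statistic=d, pvalue=p, n_a=int(a.size), n_b=int(b.size),
                    mode=mode)


def pathway_shift_report(fc: pd.Series, sets: GeneSetCollection,
                         inclusive: bool = False,
                         mode: str = "auto") -> pd.DataFrame:
    """KS distribution-shift test of every gene set against the background.

    The background is all detected proteins *not* in the tested set (set
    ``inclusive=True`` to compare against all detected proteins including
    the set). ``direction`` is the sign of median(set) - median(background);
    ``n_down`` counts set members with a negative fold-change. Sets with no
    detected member are skipped with a warning.
    """
    fc = _upper_index(fc)
    values = fc.to_numpy(dtype=float)
    rows = []
    for name, members in sets.sets.items():
        in_set = fc.index.isin(members)
        set_vals = values[in_set]
        if set_vals.size == 0:
            warnings.warn(f"gene set {name!r} has no detected members; skipped",
                          stacklevel=2)
            continue
        bg_vals = values if inclusive else values[~in_set]
        res = ks_two_sample(set_vals, bg_vals, mode=mode)
        rows.append({
            "set": name,
            "n_in_set": int(set_vals.size),
            "D": res.statistic,
            "direction": int(np.sign(np.median(set_vals) - np.median(bg_vals))),
            "p": res.pvalue,
            "n_down": int((set_vals < 0).sum()),
        })
    return pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["n_in_set", "D", "direction", "p", "n_down"])


def enrich_hypergeometric(hits, annotation, universe):
    """One-sided (upper tail) hypergeometric over-representation test.

    Returns ``(p, overlap, expected)`` where ``p = P(X >= overlap)`` for a
    draw of ``len(hits)`` genes from the universe containing
    ``len(annotation)`` annotated genes.
    """
    hits = frozenset(str(g).upper() for g in hits)
    annotation = frozenset(str(g).upper() for g in annotation)
    universe = frozenset(str(g).upper() for g in universe)
    if not hits <= universe:
        raise ValueError("hits must be a subset of the universe")
    if not annotation <= universe:
        raise ValueError("annotation must be a subset of the universe")
    overlap = len(hits & annotation)
    n_u, n_a, n_h = len(universe), len(annotation), len(hits)
    p = float(stats.hypergeom.sf(overlap - 1, n_u, n_a, n_h))
    expected = n_h * n_a / n_u
    return min(1.0, p), overlap, expected


def enrich_collection(hits, sets: GeneSetCollection, universe,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric test of each set with BH adjustment across sets."""
    rows = []
    for name, members in sets.sets.items():
        annotation = frozenset(members) & frozenset(
            str(g).upper() for g in universe)
        if not annotation:
            continue
        p, overlap, expected = enrich_hypergeometric(hits, annotation, universe)
        rows.append({"set": name, "n_annotation": len(annotation),
                     "overlap": overlap, "expected": expected, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["q"] <= alpha
        out = out.sort_values("p").set_index("set")
    return out


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (monotone, q >= p elementwise)."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_bh")[1]
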