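"""Closed-form quantification utilities for supporting assays.

Small, pure helpers: relative qPCR quantification by the delta-delta-Ct
method, reference-gene normalization (e.g. to TBP for qPCR or TUBB for
hybridization counts), formaldehyde-RIP enrichment normalization, and metal
stoichiometry from ICP-MS concentrations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CtQuartet",
    "ddct_ratio",
    "reference_normalize",
    "frip_enrichment",
    "fe_per_polypeptide",
]

_CT_RANGE = (5.0, 40.0)


@dataclass(frozen=True)
class CtQuartet:
    """The four threshold-cycle values of a delta-delta-Ct comparison."""

    ct_target_test: float
    ct_ref_test: float
    ct_target_ctrl: float
    ct_ref_ctrl: float

    def __post_init__(self) -> None:
        vals = (self.ct_target_test, self.ct_ref_test,
                self.ct_target_ctrl, self.ct_ref_ctrl)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("Ct values must be finite")
        if any(v < _CT_RANGE[0] or v > _CT_RANGE[1] for v in vals):
            warnings.warn(
                f"Ct value outside the typical range {_CT_RANGE}", stacklevel=2)


def ddct_ratio(q: CtQuartet, efficiency: float = 2.0) -> float:
    """Relative abundance ``efficiency ** -ddCt``.

    ``ddCt = (ct_target_test - ct_ref_test) - (ct_target_ctrl - ct_ref_ctrl)``.
    The default efficiency of 2 assumes perfect doubling per cycle (standard
    TaqMan delta-delta-Ct without efficiency correction).
    """
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    ddct = ((q.ct_target_test - q.ct_ref_test)
            - (q.ct_target_ctrl - q.ct_ref_ctrl))
    return float(efficiency ** -ddct)


def reference_normalize(values, reference):
    """Elementwise value / reference (normalization to a reference gene)."""
    values = pd.Series(values, dtype=float)
    reference = pd.Series(reference, dtype=float)
    if not values.index.equals(reference.index):
        reference = reference.reindex(values.index)
    if reference.isna().any() or (reference <= 0).any():
        raise ValueError("reference values must be positive for every sample")
    return values / reference


def frip_enrichment(ip_12s: float, input_12s: float,
                    construct_level: float) -> float:
    """RNA-IP enrichment normalized to input RNA and bait protein level:
    ``(ip / input) / construct_level``."""
    if input_12s <= 0 or construct_level <= 0:
        raise ValueError("input and construct levels must be positive")
    return (ip_12s / input_12s) / construct_level


def fe_per_polypeptide(fe_conc: float, protein_conc: float) -> float:
    """Iron stoichiometry: molar Fe concentration per molar polypeptide."""
    if protein_conc <= 0:
        raise ValueError("protein concentration must be positive")
    if fe_conc < 0:
        raise ValueError("Fe concentration must be non-negative")
    return fe_conc / protein_conc
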