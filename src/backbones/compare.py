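"""Pairwise backbone comparison: confusion counts, phi, Cohen's kappa, Jaccard, FDR.

Two backbones on the same agent set are compared as binary classifications
of the nA(nA-1)/2 unordered agent pairs.  ``ref`` plays the role of the
positive truth (in the empirical study: the maximally-constrained
backbone), so FP counts edges present in ``test`` but absent in ``ref``
and the false discovery rate is FP / (FP + TP).

phi is the Pearson correlation of the two edge-indicator vectors; kappa is
chance-corrected agreement; Jaccard is TP / (TP + FP + FN).  When an
indicator vector is constant, phi and kappa are undefined and reported as
NaN with a warning.  Two empty backbones get Jaccard 1 (perfect agreement
of empty edge sets), so replicate averages in the synthetic sweep stay
well-defined.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .significance import Backbone

__all__ = ["ComparisonResult", "confusion", "fdr", "phi_kappa_jaccard"]


@dataclass
class ComparisonResult:
    """Confusion counts and agreement indices for a (test, ref) backbone pair."""

    TP: int
    TN: int
    FP: int
    FN: int
    correlation: float  # phi coefficient; NaN when undefined
    kappa: float
    jaccard: float
    fdr: float

    @property
    def n_pairs(self) -> int:
        return self.TP + self.TN + self.FP + self.FN

    def to_row(self) -> dict:
        return {
            "TP": self.TP,
            "TN": self.TN,
            "FP": self.FP,
            "FN": self.FN,
            "correlation": self.correlation,
            "kappa": self.kappa,
            "jaccard": self.jaccard,
            "fdr": self.fdr,
        }


def _indices_from_counts(TP: int, TN: int, FP: int, FN: int) -> tuple[float, float, float, float]:
    n = TP + TN + FP + FN
    # a constant indicator vector leaves phi and kappa undefined
    constant = (TP + FP) in (0, n) or (TP + FN) in (0, n)
    if constant:
        warnings.warn("constant edge indicator(s): phi and kappa undefined", stacklevel=3)
        phi = math.nan
        kap = math.nan
    else:
        denom2 = (TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
        phi = (TP * TN - FP * FN) / math.sqrt(denom2)
        po = (TP + TN) / n
        pe = ((TP + FP) * (TP + FN) + (FN + TN) * (FP + TN)) / (n * n)
        kap = (po - pe) / (1.0 - pe)
    # Jaccard over edge sets
    if TP + FP + FN == 0:
        warnings.warn("both backbones empty: Jaccard defined as 1", stacklevel=3)
        jac = 1.0
    else:
        jac = TP / (TP + FP + FN)
    # false discovery rate
    if TP + FP == 0:
        warnings.warn("no positives in test backbone: FDR undefined", stacklevel=3)
        f = math.nan
    else:
        f = FP / (FP + TP)
    return phi, kap, jac, f


def confusion(test: Backbone, ref: Backbone) -> ComparisonResult:
    """Confusion matrix and agreement indices of ``test`` against ``ref``.

    ``ref`` is the positive-truth side: TP = edge in both, FP = edge only in
    ``test``, FN = edge only in ``ref``, TN = edge in neither, counted over
    unordered agent pairs.
    """
    if test.row_labels != ref.row_labels:
        raise ValueError("backbones are defined on different node sets")
    t = test.edge_indicator()
    r = ref.edge_indicator()
    TP = int(((t == 1) & (r == 1)).sum())
    TN = int(((t == 0) & (r == 0)).sum())
    FP = int(((t == 1) & (r == 0)).sum())
    FN = int(((t == 0) & (r == 1)).sum())
    phi, kap, jac, f = _indices_from_counts(TP, TN, FP, FN)
    return ComparisonResult(TP, TN, FP, FN, phi, kap, jac, f)


def fdr(c: ComparisonResult) -> float:
    """False discovery rate FP / (FP + TP); NaN (with warning) when no positives."""
    if c.FP + c.TP == 0:
        warnings.warn("FP + TP = 0: FDR undefined", stacklevel=2)
        return math.nan
    return c.FP / (c.FP + c.TP)


def phi_kappa_jaccard(test: Backbone, ref: Backbone) -> tuple[float, float, float]:
    """The three agreement indices (phi, kappa, Jaccard) for a backbone pair."""
    c = confusion(test, ref)
    return c.correlation, c.kappa, c.jaccard
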