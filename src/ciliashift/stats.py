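"""Small-sample cohort statistics.

Goodness-of-fit and 2x2 association tests used for genotype ratios of
intercross litters, motile/immotile bundle proportions, and pooled
ultrastructural defect counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = ["ChisqResult", "mendelian_chisq", "fisher_exact_2x2", "pearson_chisq_2x2"]


@dataclass(frozen=True)
class ChisqResult:
    chi2: float
    df: int
    p: float


def mendelian_chisq(observed, expected_ratio=(1, 2, 1)) -> ChisqResult:
    """Pearson chi-square of observed genotype counts against a Mendelian ratio.

    ``expected_ratio`` gives positive weights (default 1:2:1 for an
    intercross); expected counts are the ratio-proportional split of the
    total.  df = number of classes - 1.
    """
    obs = np.asarray(observed, dtype=float)
    ratio = np.asarray(expected_ratio, dtype=float)
    if obs.shape != ratio.shape:
        raise ValueError("observed counts and expected ratio differ in length")
    if (obs < 0).any() or not np.allclose(obs, np.round(obs)):
        raise ValueError("observed counts must be non-negative integers")
    if (ratio < 0).any() or ratio.sum() <= 0:
        raise ValueError("expected ratio weights must be non-negative with positive sum")
    n = obs.sum()
    if n <= 0:
        raise ValueError("total observed count must be positive")
    if ((ratio == 0) & (obs > 0)).any():
        raise ValueError("zero expected weight for a class with positive observed count")
    keep = ratio > 0
    expected = n * ratio[keep] / ratio[keep].sum()
    chi2, p = sps.chisquare(obs[keep], expected)
    return ChisqResult(chi2=float(chi2), df=int(keep.sum() - 1), p=float(p))


def _as_2x2(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("table cells must be non-negative integers")
    if t.sum() <= 0:
        raise ValueError("table must contain at least one count")
    return t


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact test p-value for a 2x2 table.

    Sums hypergeometric probabilities of all tables with the observed margins
    whose probability does not exceed the observed table's
    (probability-ordering convention).
    """
    t = _as_2x2(table)
    return float(sps.fisher_exact(t, alternative="two-sided")[1])


def pearson_chisq_2x2(table, yates: bool = False) -> ChisqResult:
    """Pearson chi-square on a 2x2 table: n(ad - bc)^2 / product of margins.

    Requires all four margins positive (otherwise expected cells are zero).
    Yates continuity correction optional, off by default.
    """
    t = _as_2x2(table)
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("2x2 chi-square requires all margins to be positive")
    chi2, p, df, _ = sps.chi2_contingency(t, correction=yates)
    return ChisqResult(chi2=float(chi2), df=int(df), p=float(p))
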