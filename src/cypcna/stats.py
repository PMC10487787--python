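"""Association and concordance statistics.

Two small, pre-specified analyses sit downstream of the caller:

* Fisher's exact test of independence between functional CYP multiplication
  and therapy response in a 2x2 table, with the conventional two-sided
  p-value (sum of hypergeometric point probabilities no larger than that of
  the observed table, margins fixed).
* Ordinary least-squares concordance between copy numbers measured by qPCR
  and by whole-genome sequencing, summarized by slope and squared Pearson
  correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import CypCnaError, DegenerateFitError


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 counts with the two-sided Fisher exact p-value."""

    table: tuple
    p_two_sided: float
    odds_ratio: float  # NaN when a margin is zero

    def __str__(self):
        (a, b), (c, d) = self.table
        return (
            f"2x2 table [[{a}, {b}], [{c}, {d}]]: "
            f"p = {self.p_two_sided:.4f} (Fisher's exact test, two-sided)"
        )


@dataclass(frozen=True)
class ConcordanceFit:
    """OLS fit of sequencing copy numbers on qPCR copy numbers."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int


def fisher_exact_two_sided(table) -> ContingencyResult:
    """Exact two-sided test of independence in a 2x2 table.

    The p-value sums, over all tables with the observed margins, the
    hypergeometric point probabilities that do not exceed the observed
    table's probability.

    Raises
    ------
    CypCnaError
        For negative or non-integer counts.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise CypCnaError(f"expected a 2x2 table, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.round(arr)):
            raise CypCnaError("contingency counts must be integers")
        arr = np.round(arr).astype(int)
    if (arr < 0).any():
        raise CypCnaError("contingency counts must be non-negative")
    if arr.sum() == 0:
        raise CypCnaError("contingency table must have at least one count")

    res = sps.fisher_exact(arr, alternative="two-sided")
    odds = float(res.statistic)
    if 0 in arr.sum(axis=0) or 0 in arr.sum(axis=1):
        odds = float("nan")
    return ContingencyResult(
        table=tuple(map(tuple, arr.tolist())),
        p_two_sided=float(res.pvalue),
        odds_ratio=odds,
    )


def concordance_fit(x, y, through_origin: bool = False) -> ConcordanceFit:
    """Least-squares concordance between two copy-number measurements.

    With a free intercept (default) ``r_squared`` is the squared Pearson
    correlation; through the origin it is computed on uncentred sums of
    squares.

    Raises
    ------
    DegenerateFitError
        If fewer than 2 points or the predictor is constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CypCnaError("x and y must be 1-D vectors of equal length")
    if len(x) < 2:
        raise DegenerateFitError("need at least 2 points to fit")
    if np.ptp(x) == 0:
        raise DegenerateFitError("constant predictor: slope is undefined")

    if through_origin:
        slope = float(x @ y / (x @ x))
        ss_res = float(((y - slope * x) ** 2).sum())
        ss_tot = float((y**2).sum())
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        return ConcordanceFit(slope, 0.0, r2, len(x))

    fit = sps.linregress(x, y)
    return ConcordanceFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n_points=len(x),
    )
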