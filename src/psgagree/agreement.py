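"""Chance-corrected agreement statistics: Cohen's kappa and ICC(A,1).

Kappa is the unweighted Cohen statistic on a rater-pair contingency
table.  ICC(A,1) is the two-way, absolute-agreement, single-measures
intraclass correlation of McGraw & Wong (1996), with their case-A,1
confidence interval and the F approximation (Satterthwaite degrees of
freedom) for testing H0: ICC = r0 against the one-sided alternative
ICC > r0.  r0 > 0 matters here because the semi-automatic condition is
tested against the agreement level already achieved manually, not
against zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .discretize import ContingencyTable, LabelSequence, build_contingency
from .errors import AlignmentError, DegenerateDataError, DomainError


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    p_observed: float
    p_expected: float
    n: int
    pair: tuple[str, str] | None = None
    context: str | None = None
    #: set when p_expected == 1 and kappa was assigned by convention
    degenerate: bool = False


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float
    r0: float
    p_value: float
    n_subjects: int
    k_raters: int
    mean_squares: tuple[float, float, float]  # (MSR, MSC, MSE)


def cohen_kappa(t: ContingencyTable, *, pair: tuple[str, str] | None = None,
                context: str | None = None) -> KappaResult:
    """Unweighted Cohen's kappa from a k x k contingency table.

    Degenerate tables with chance agreement p_e = 1 (both raters
    constant) get kappa 1 when agreement is perfect and 0 otherwise,
    with the ``degenerate`` flag set; this arises on quiet recordings
    where an event is absent throughout for both raters.
    """
    n = t.n
    if n == 0:
        raise DomainError("empty contingency table")
    counts = t.counts.astype(np.float64)
    p_o = float(np.trace(counts)) / n
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    p_e = float(rows @ cols) / (n * n)
    if p_e >= 1.0 - 1e-12:
        kappa = 1.0 if p_o >= 1.0 - 1e-12 else 0.0
        return KappaResult(kappa, p_o, p_e, n, pair, context, degenerate=True)
    kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(kappa, p_o, p_e, n, pair, context)


def pairwise_kappa(sequences: Mapping[str, LabelSequence],
                   mask=None, context: str | None = None) -> list[KappaResult]:
    """Kappa for every unordered scorer pair, lexicographic by id.

    Twelve scorers yield C(12,2) = 66 results.
    """
    ids = sorted(sequences)
    if len(ids) < 2:
        raise DomainError("pairwise kappa needs at least two scorers")
    grid = sequences[ids[0]].grid
    for sid in ids[1:]:
        if not sequences[sid].grid.compatible(grid):
            raise AlignmentError(f"scorer {sid} is on a different grid")
    out = []
    for a, b in itertools.combinations(ids, 2):
        table = build_contingency(sequences[a], sequences[b], mask)
        out.append(cohen_kappa(table, pair=(a, b), context=context))
    return out


def average_channel_kappa(left: KappaResult, right: KappaResult) -> KappaResult:
    """Arithmetic mean of the per-channel (left/right leg) kappas of one
    scorer pair; epoch counts are summed."""
    if left.pair != right.pair or left.context != right.context:
        raise DomainError("cannot average kappas of different pairs/contexts")
    return KappaResult(
        kappa=(left.kappa + right.kappa) / 2.0,
        p_observed=math.nan,
        p_expected=math.nan,
        n=left.n + right.n,
        pair=left.pair,
        context=left.context,
        degenerate=left.degenerate or right.degenerate,
    )


def _anova_mean_squares(data: np.ndarray) -> tuple[float, float, float]:
    """Two-way (subjects x raters) ANOVA mean squares (MSR, MSC, MSE)."""
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((data - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, max(mse, 0.0)


def _satterthwaite_df(a: float, b: float, msc: float, mse: float,
                      n: int, k: int) -> float:
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    return num / den


def icc_a1(data: Sequence[Sequence[float]] | np.ndarray, r0: float = 0.0,
           alpha: float = 0.05) -> IccResult:
    """ICC(A,1) with 95% CI and a one-sided test of H0: ICC = r0.

    ``data`` is a complete n_subjects x k_raters matrix (here: 5
    recordings x 12 scorers of one diagnostic index).  The estimate is

        (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE)),

    the confidence interval and the H0 F approximation follow McGraw &
    Wong's case A,1 with Satterthwaite degrees of freedom.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise DomainError("data must be a 2-D subjects x raters matrix")
    n, k = data.shape
    if n < 2 or k < 2:
        raise DomainError("need at least 2 subjects and 2 raters")
    if np.isnan(data).any():
        raise DomainError("matrix must be complete (no NaN)")
    if not 0.0 <= r0 < 1.0:
        raise DomainError("r0 must lie in [0, 1)")
    if np.ptp(data) == 0.0:
        raise DegenerateDataError("ICC undefined: all matrix values equal")

    msr, msc, mse = _anova_mean_squares(data)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        raise DegenerateDataError("ICC undefined: zero total variance")
    icc = (msr - mse) / denom

    # Confidence interval (two-sided, 1 - alpha)
    if icc >= 1.0 - 1e-15:
        ci_low, ci_high = icc, icc
    else:
        a = (k * icc) / (n * (1.0 - icc))
        b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc))
        v = _satterthwaite_df(a, b, msc, mse, n, k)
        f_l = stats.f.ppf(1.0 - alpha / 2.0, n - 1, v)
        f_u = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1)
        ci_low = (n * (msr - f_l * mse)
                  / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
        ci_high = (n * (f_u * msr - mse)
                   / (k * msc + (k * n - k - n) * mse + n * f_u * msr))
        ci_low = min(max(ci_low, -1.0), 1.0)
        ci_high = min(max(ci_high, ci_low), 1.0)

    # One-sided test of H0: ICC = r0 (alternative ICC > r0)
    a0 = (k * r0) / (n * (1.0 - r0))
    b0 = 1.0 + (k * r0 * (n - 1)) / (n * (1.0 - r0))
    denom0 = a0 * msc + b0 * mse
    if denom0 <= 0:
        p_value = 0.0
    else:
        f_obs = msr / denom0
        v0 = _satterthwaite_df(a0, b0, msc, mse, n, k) if a0 > 0 \
            else (n - 1) * (k - 1)
        p_value = float(stats.f.sf(f_obs, n - 1, v0))

    return IccResult(float(icc), float(ci_low), float(ci_high), r0, p_value,
                     n, k, (msr, msc, mse))
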