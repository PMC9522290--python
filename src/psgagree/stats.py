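"""The manual vs semi-automatic comparison battery.

Distributions are summarized as median [q1, q3] (linear-interpolation
percentiles).  Matched manual/semi-automatic samples are compared with
the paired Wilcoxon signed-rank test (zero differences dropped; exact
null for small n, normal approximation with continuity correction
otherwise) and the paired Cohen's D effect size d_z =
mean(diff)/sd(diff), whose sign is positive when the manual values are
larger.  Variance comparisons use the Brown-Forsythe test (Levene with
median centering) after dividing each group by its own mean, removing
location differences from the spread comparison.  Significance is
declared per test at alpha = 0.05 with no multiplicity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DesignError, DomainError

ALPHA = 0.05
#: paired-sample size threshold above which the Wilcoxon normal
#: approximation replaces exact enumeration
WILCOXON_EXACT_MAX_N = 25


@dataclass(frozen=True)
class PairedSample:
    """Matched manual / semi-automatic measurements (same length, same
    matching key, e.g. scorer x recording or scorer-pair x recording)."""

    manual: tuple[float, ...]
    semiauto: tuple[float, ...]
    unit: str = ""
    matching_key: str = ""

    def __post_init__(self) -> None:
        if len(self.manual) != len(self.semiauto):
            raise DomainError("paired sample vectors must have equal length")

    def __len__(self) -> int:
        return len(self.manual)

    @property
    def differences(self) -> np.ndarray:
        return np.asarray(self.manual) - np.asarray(self.semiauto)


class WilcoxonResult(NamedTuple):
    statistic: float
    p_value: float
    degenerate: bool = False


@dataclass(frozen=True)
class ComparisonRow:
    label: str
    manual_median_iqr: tuple[float, float, float]    # (median, q1, q3)
    semiauto_median_iqr: tuple[float, float, float]
    p_value: float
    effect_size: float
    gain_factor: float | None = None
    n: int = 0
    significant: bool = False


def median_iqr(x: Sequence[float]) -> tuple[float, float, float]:
    """(median, q1, q3) with linear interpolation between order stats."""
    arr = np.asarray(x, dtype=np.float64)
    if arr.size == 0:
        raise DomainError("median_iqr of empty sample")
    med, q1, q3 = np.percentile(arr, [50, 25, 75])
    return float(med), float(q1), float(q3)


def gain_factor(manual_times: Sequence[float],
                semiauto_times: Sequence[float]) -> float:
    """Ratio of median manual to median semi-automatic scoring time,
    reported to 2 decimals."""
    if len(manual_times) == 0 or len(semiauto_times) == 0:
        raise DomainError("gain_factor of empty sample")
    med_m = float(np.median(manual_times))
    med_s = float(np.median(semiauto_times))
    if med_s == 0:
        raise DomainError("semi-automatic median time is zero")
    return round(med_m / med_s, 2)


def wilcoxon_paired(s: PairedSample) -> WilcoxonResult:
    """Two-sided paired Wilcoxon signed-rank test on manual - semiauto."""
    diffs = s.differences
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return WilcoxonResult(0.0, 1.0, degenerate=True)
    method = "exact" if nonzero.size <= WILCOXON_EXACT_MAX_N else "approx"
    if method == "exact" and len(set(np.abs(nonzero))) < nonzero.size:
        # tied absolute differences: the exact null is unavailable
        method = "approx"
    res = sps.wilcoxon(nonzero, zero_method="wilcox", correction=True,
                       method=method)
    return WilcoxonResult(float(res.statistic), float(res.pvalue))


def cohens_d_paired(s: PairedSample) -> float:
    """Paired Cohen's D (d_z): mean(manual - semiauto) / sd(differences),
    sample sd with n-1.  NaN when the difference variance is zero."""
    diffs = s.differences
    if diffs.size < 2:
        raise DomainError("cohens_d_paired needs at least 2 pairs")
    sd = float(np.std(diffs, ddof=1))
    if sd == 0.0:
        return math.nan
    return float(np.mean(diffs)) / sd


def brown_forsythe(manual: Sequence[float],
                   semiauto: Sequence[float]) -> tuple[float, float]:
    """Brown-Forsythe variance-homogeneity test after dividing each
    group by its own mean."""
    m = np.asarray(manual, dtype=np.float64)
    a = np.asarray(semiauto, dtype=np.float64)
    if m.size < 2 or a.size < 2:
        raise DomainError("brown_forsythe needs at least 2 values per group")
    if m.mean() == 0 or a.mean() == 0:
        raise DomainError("cannot mean-normalize a zero-mean group")
    m = m / m.mean()
    a = a / a.mean()
    zm = np.abs(m - np.median(m))
    za = np.abs(a - np.median(a))
    if np.ptp(zm) == 0 and np.ptp(za) == 0:
        return 0.0, 1.0
    f, p = sps.levene(m, a, center="median")
    return float(f), float(p)


def build_comparison_table(
    per_task_samples: Mapping[str, PairedSample],
    expected_n: int | None = None,
    alpha: float = ALPHA,
    with_gain: bool = False,
) -> list[ComparisonRow]:
    """One comparison row per task/context, in input order.

    ``expected_n`` asserts the study-design sample size (60 matched
    scoring times, 330 matched kappas per task); a mismatch raises a
    :class:`~psgagree.errors.DesignError` naming the offending cell.
    """
    rows: list[ComparisonRow] = []
    for label, sample in per_task_samples.items():
        if expected_n is not None and len(sample) != expected_n:
            raise DesignError(
                f"{label}: expected n = {expected_n} matched pairs, "
                f"got {len(sample)}")
        wres = wilcoxon_paired(sample)
        rows.append(ComparisonRow(
            label=label,
            manual_median_iqr=median_iqr(sample.manual),
            semiauto_median_iqr=median_iqr(sample.semiauto),
            p_value=wres.p_value,
            effect_size=cohens_d_paired(sample),
            gain_factor=(gain_factor(sample.manual, sample.semiauto)
                         if with_gain else None),
            n=len(sample),
            significant=wres.p_value < alpha,
        ))
    return rows
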