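"""Per-length aging index and the fragment length-shift trend test.

The aging index ``I_a(L)`` of a fragment length ``L`` is the Spearman
rank correlation between that length's expression (RPM) and sample age.
The length-shift statistic is the Spearman correlation between the
``I_a`` curve and length itself: a positive value means longer fragments
gain expression with age while shorter ones lose it. An ordinary
least-squares line through the (L, I_a) points is attached for display.

Both statistics are rank-based, so they are invariant to any strictly
increasing re-expression of either expression values or ages; mouse
weeks and human years are treated identically.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

EXACT_N_MAX = 8  # exact permutation p-value up to this sample count


class AgingStatsError(ValueError):
    pass


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    pvalue: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.rho)


def _avg_ranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def spearman(x: Sequence[float], y: Sequence[float],
             exact: bool | None = None) -> SpearmanResult:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive average ranks. The p-value is exact (full permutation
    enumeration of the rank vector) for n <= 8 and the standard
    asymptotic t approximation otherwise; ``exact`` overrides the switch.
    Zero variance in either vector yields an undefined (NaN) result
    rather than an exception.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AgingStatsError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise AgingStatsError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return SpearmanResult(float("nan"), float("nan"))
    rx, ry = _avg_ranks(x), _avg_ranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    use_exact = exact if exact is not None else n <= EXACT_N_MAX
    if use_exact:
        rxc = rx - rx.mean()
        denom = math.sqrt((rxc ** 2).sum())
        perms = np.array(list(itertools.permutations(ry)))
        pc = perms - ry.mean()
        rhos = (pc @ rxc) / (denom * np.sqrt((pc ** 2).sum(axis=1)))
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        res = stats.spearmanr(x, y)
        p = float(res.pvalue)
    return SpearmanResult(rho, p)


@dataclass
class AgingIndexCurve:
    """I_a per fragment length, with bookkeeping.

    ``values`` holds NaN where I_a is undefined (zero expression
    variance); ``excluded`` lists lengths dropped because their RPM was
    zero in every sample.
    """

    lengths: np.ndarray
    values: np.ndarray
    n: int
    excluded: list[int]

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.lengths, name="I_a")

    @property
    def defined_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)


def aging_index(profile: pd.DataFrame, ages: Mapping[str, float] | pd.Series,
                ) -> AgingIndexCurve:
    """Compute the aging index curve from a samples x lengths RPM table.

    ``I_a(L)`` is the Spearman correlation between column ``L`` of the
    profile and the sample ages. Lengths whose RPM is zero in all samples
    are excluded (and listed); lengths with nonzero but constant RPM get
    a NaN entry.
    """
    ages = pd.Series(ages)
    if not set(profile.index) <= set(ages.index):
        raise AgingStatsError("profile samples missing from the age vector")
    if len(profile) < 3:
        raise AgingStatsError("need at least 3 samples")
    age_vec = ages.loc[profile.index].to_numpy(dtype=float)
    if len(np.unique(age_vec)) < 3:
        raise AgingStatsError("need at least 3 distinct ages")
    lengths, values, excluded = [], [], []
    rank_age = _avg_ranks(age_vec)
    for col in profile.columns:
        v = profile[col].to_numpy(dtype=float)
        if (v == 0).all():
            excluded.append(int(col))
            continue
        lengths.append(int(col))
        if np.ptp(v) == 0:
            values.append(float("nan"))
        else:
            values.append(float(np.corrcoef(_avg_ranks(v), rank_age)[0, 1]))
    return AgingIndexCurve(np.array(lengths), np.array(values),
                           len(profile), excluded)


@dataclass
class LengthShiftResult:
    """Spearman trend of I_a against fragment length, with an OLS line
    (slope/intercept) for plotting only."""

    rho: float
    pvalue: float
    slope: float
    intercept: float
    lengths_used: list[int]

    @property
    def n_lengths(self) -> int:
        return len(self.lengths_used)


def length_shift_test(curve: AgingIndexCurve,
                      exact: bool | None = None) -> LengthShiftResult:
    """Test whether the aging index increases with fragment length."""
    mask = curve.defined_mask
    ls = curve.lengths[mask]
    ia = curve.values[mask]
    if len(ls) < 3:
        raise AgingStatsError("need at least 3 lengths with defined I_a")
    res = spearman(ia, ls, exact=exact)
    slope, intercept = np.polyfit(ls, ia, 1)
    return LengthShiftResult(res.rho, res.pvalue, float(slope),
                             float(intercept), [int(l) for l in ls])


# --------------------------------------------------------------------------
# group summaries (boxplot statistics)


@dataclass(frozen=True)
class BoxplotStats:
    median: float
    q1: float
    q3: float
    iqr: float
    lower_whisker: float
    upper_whisker: float
    outliers: tuple[float, ...]


def _box(values: Sequence[float]) -> BoxplotStats:
    v = np.asarray(sorted(values), dtype=float)
    if len(v) == 0:
        raise AgingStatsError("empty group")
    q1, med, q3 = np.percentile(v, [25, 50, 75])  # linear interpolation
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = tuple(float(x) for x in v[(v < lo_fence) | (v > hi_fence)])
    return BoxplotStats(float(med), float(q1), float(q3), float(iqr),
                        float(inside.min()), float(inside.max()), outliers)


def group_boxplot_stats(groups: Mapping[str, Sequence[float]],
                        ) -> dict[str, BoxplotStats]:
    """Median/quartile/whisker summaries per age group.

    Quartiles use the linear-interpolation convention; whiskers reach the
    most extreme data points within Q1 - 1.5*IQR and Q3 + 1.5*IQR, and
    points outside are outliers.
    """
    return {g: _box(v) for g, v in groups.items()}
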