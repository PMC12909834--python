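"""Aging-cliff ordination: Clark divergence, PCoA, and stage F-statistics.

Samples are compared by the Clark divergence of their composition
profiles, embedded by classical metric scaling (principal coordinate
analysis), and candidate early/late age partitions are scored by the
one-way ANOVA F-statistic (between- over within-group variance) of the
Axis-1 scores. An abrupt "aging cliff" shows up as one contiguous split
of the age-ordered groups dominating all others.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


class OrdinationError(ValueError):
    pass


def clark_divergence(M: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Clark divergence between sample rows of a composition
    matrix.

    For samples j, k: ``d_jk = sqrt( (1/NZ) * sum_i ((x_ij - x_ik) /
    (x_ij + x_ik))^2 )`` over the NZ features with ``x_ij + x_ik > 0``
    (double-zero features are excluded). Values lie in [0, 1]. Feature
    columns that are zero in every sample are dropped up front.
    """
    if len(M) < 2:
        raise OrdinationError("need at least 2 samples")
    X = M.to_numpy(dtype=float)
    if (X < 0).any():
        raise OrdinationError("composition matrix has negative entries")
    keep = X.sum(axis=0) > 0
    if not keep.all():
        logger.info("clark_divergence: dropping %d all-zero features",
                    int((~keep).sum()))
        X = X[:, keep]
    n = len(X)
    D = np.zeros((n, n))
    for j in range(n):
        for k in range(j + 1, n):
            s = X[j] + X[k]
            nz = s > 0
            if not nz.any():
                raise OrdinationError(
                    f"samples {M.index[j]!r} and {M.index[k]!r} share no "
                    "nonzero feature; Clark divergence is undefined")
            ratio = (X[j, nz] - X[k, nz]) / s[nz]
            D[j, k] = D[k, j] = np.sqrt((ratio ** 2).sum() / nz.sum())
    return pd.DataFrame(D, index=M.index, columns=M.index)


@dataclass
class PCoAResult:
    """Classical-scaling embedding of a dissimilarity matrix.

    Coordinates exist only for positive eigenvalues; negative eigenvalues
    (non-Euclidean input) are counted, not corrected.
    """

    coordinates: pd.DataFrame  # samples x axes ("Axis 1", "Axis 2", ...)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # over positive eigenvalues
    n_negative: int

    def axis(self, k: int = 1) -> pd.Series:
        return self.coordinates[f"Axis {k}"]


def pcoa(D: pd.DataFrame) -> PCoAResult:
    """Principal coordinate analysis by Gower double-centering.

    ``B = -1/2 * J (D o D) J`` is eigendecomposed; coordinate k equals
    eigenvector k scaled by sqrt(eigenvalue k) for each positive
    eigenvalue. No Cailliez/Lingoes correction is applied. Axis signs
    follow the convention that the largest-magnitude loading is positive.
    """
    A = D.to_numpy(dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise OrdinationError("dissimilarity matrix must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise OrdinationError("dissimilarity matrix must be symmetric")
    if (A < 0).any():
        raise OrdinationError("dissimilarity matrix has negative entries")
    n = len(A)
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (A ** 2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals).max(), 1.0) * 1e-9 if n else 0.0
    pos = vals > tol
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    for k in range(coords.shape[1]):  # sign convention
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]
    n_neg = int((vals < -tol).sum())
    if n_neg:
        logger.info("pcoa: %d negative eigenvalues (non-Euclidean input)",
                    n_neg)
    prop = vals[pos] / vals[pos].sum() if pos.any() else np.array([])
    cols = [f"Axis {k + 1}" for k in range(coords.shape[1])]
    return PCoAResult(pd.DataFrame(coords, index=D.index, columns=cols),
                      vals, prop, n_neg)


# --------------------------------------------------------------------------
# stage F-statistic and cliff scan


def stage_f(values: Mapping[str, float] | pd.Series,
            labels: Mapping[str, str] | pd.Series) -> tuple[float, float]:
    """One-way ANOVA F (between/within variance ratio) of per-sample axis
    scores grouped by stage labels, with its parametric p-value.

    Zero within-group variance yields (inf, 0.0).
    """
    values = pd.Series(values)
    labels = pd.Series(labels)
    groups = [values.loc[labels.index[labels == g]].to_numpy(dtype=float)
              for g in labels.unique()]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise OrdinationError("need >= 2 groups with >= 2 samples each")
    if all(np.ptp(g) == 0 for g in groups):
        if len({g[0] for g in groups}) == 1:
            return 0.0, 1.0
        return float("inf"), 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        f, p = stats.f_oneway(*groups)
    if np.isnan(f):  # degenerate within-variance
        return float("inf"), 0.0
    return float(f), float(p)


@dataclass
class CliffStat:
    """Best contiguous early/late split of the age-ordered groups."""

    early_ages: tuple[float, ...]
    late_ages: tuple[float, ...]
    F: float
    pvalue: float  # raw parametric p of the winning split
    p_adjusted: float  # Bonferroni over candidate splits
    candidates: pd.DataFrame  # split, F, p_raw, p_adj

    @property
    def cutpoint(self) -> tuple[float, float]:
        return self.early_ages[-1], self.late_ages[0]


def scan_cliff(axis_values: Mapping[str, float] | pd.Series,
               ages: Mapping[str, float] | pd.Series) -> CliffStat:
    """Scan every contiguous early/late split of the age-ordered groups
    and return the one maximizing the Axis-1 F-statistic.

    Because the winning split is selected by maximizing F over all
    candidate splits, p-values are Bonferroni-adjusted for the number of
    candidates.
    """
    axis_values = pd.Series(axis_values)
    ages = pd.Series(ages).loc[axis_values.index]
    distinct = sorted(float(a) for a in ages.unique())
    if len(distinct) < 2:
        raise OrdinationError("need at least 2 distinct ages")
    m = len(distinct) - 1
    rows = []
    for cut in range(1, len(distinct)):
        early = tuple(distinct[:cut])
        labels = pd.Series(np.where(ages.isin(early), "early", "late"),
                           index=ages.index)
        F, p = stage_f(axis_values, labels)
        rows.append({"split": f"{early[-1]:g}|{distinct[cut]:g}",
                     "early": early, "late": tuple(distinct[cut:]),
                     "F": F, "p_raw": p, "p_adj": min(1.0, p * m)})
    cand = pd.DataFrame(rows)
    best = cand.loc[cand["F"].idxmax()]
    return CliffStat(best["early"], best["late"], float(best["F"]),
                     float(best["p_raw"]), float(best["p_adj"]),
                     cand[["split", "F", "p_raw", "p_adj"]])
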