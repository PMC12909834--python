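import numpy as np
import pandas as pd
import pytest

from sncaging.reference import build_reference_panel
from sncaging.simulate import CohortDesign, simulate_cohort

TSRS = ("rRNA", "tRNA", "mt_rRNA", "mt_tRNA")


@pytest.fixture(scope="session")
def panel():
    return build_reference_panel(0)


@pytest.fixture(scope="session")
def small_cohort():
    """Mouse-design cohort at modest depth, with materialized reads."""
    design = CohortDesign.preset("mouse_5group", seed=11, depth=20_000)
    return simulate_cohort(design)


@pytest.fixture(scope="session")
def counts_cohort():
    """Mouse-design cohort at full default depth, counts only."""
    design = CohortDesign.preset("mouse_5group", seed=7, depth=200_000)
    return simulate_cohort(design, materialize_reads=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def spearman_bruteforce(x, y):
    """Independent Spearman rho: Pearson on average ranks, from scratch."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)

    def ranks(v):
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v), float)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r[order[i:j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


def clark_bruteforce(M: pd.DataFrame) -> np.ndarray:
    """Direct per-pair evaluation of the Clark divergence formula."""
    X = M.to_numpy(float)
    n = len(X)
    D = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            if j == k:
                continue
            total, nz = 0.0, 0
            for i in range(X.shape[1]):
                s = X[j, i] + X[k, i]
                if s > 0:
                    total += ((X[j, i] - X[k, i]) / s) ** 2
                    nz += 1
            D[j, k] = np.sqrt(total / nz)
    return D


def fisher_bruteforce(a, b, c, d):
    """Two-sided Fisher p by explicit hypergeometric enumeration."""
    from math import comb

    n = a + b + c + d
    r1, c1 = a + b, a + c
    denom = comb(n, c1)
    p_obs = comb(r1, a) * comb(n - r1, c1 - a) / denom
    p = 0.0
    for x in range(max(0, c1 - (n - r1)), min(r1, c1) + 1):
        px = comb(r1, x) * comb(n - r1, c1 - x) / denom
        if px <= p_obs * (1 + 1e-9):
            p += px
    return min(1.0, p)
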