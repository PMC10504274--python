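"""Group statistics: exact Wilcoxon rank-sum test and simple OLS fits.

The headline comparison of the pipeline is a two-tailed Wilcoxon rank-sum
test on per-animal mean strain ratios at α = 0.05.  For the study's group
sizes (5 vs 6) the null distribution is enumerated exactly — all
C(n1+n2, n1) assignments of the pooled midranks — so the inference never
depends on a normal approximation.  Larger pooled samples fall back to the
tie-corrected normal approximation with continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from numpy.random import SeedSequence, default_rng
from scipy.stats import norm, rankdata

from .phantom import stable_seed

ALPHA = 0.05
EXACT_LIMIT = 14          # enumerate when n1+n2 <= 14 (C(14,7)=3432)
_TIE_TOL = 1e-9


@dataclass
class RankSumResult:
    """Two-tailed rank-sum test on the designated (first) group."""

    w: float                  # rank-sum of group a (midranks for ties)
    p_two_sided: float
    method: str               # "exact-enumeration" | "normal-approx"
    n1: int
    n2: int
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_two_sided < self.alpha


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r2: float


def rank_sum_test(group_a, group_b, exact_limit: int = EXACT_LIMIT) -> RankSumResult:
    """Two-tailed Wilcoxon rank-sum test with midranks for ties.

    The two-sided p doubles the smaller tail probability and caps at 1,
    matching the common convention for exact rank tests.
    """
    a = np.asarray(group_a, float)
    b = np.asarray(group_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)            # midranks
    w = float(ranks[:n1].sum())

    if n1 + n2 <= exact_limit:
        sums = np.fromiter(
            (sum(c) for c in combinations(ranks, n1)), dtype=float,
        )
        total = sums.size
        p_le = np.count_nonzero(sums <= w + _TIE_TOL) / total
        p_ge = np.count_nonzero(sums >= w - _TIE_TOL) / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        method = "exact-enumeration"
    else:
        n = n1 + n2
        mean = n1 * (n + 1) / 2.0
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = float(((counts ** 3 - counts)).sum()) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            return RankSumResult(w=w, p_two_sided=1.0, method="normal-approx", n1=n1, n2=n2)
        # continuity correction toward the mean
        z = (w - mean - 0.5 * np.sign(w - mean)) / np.sqrt(var)
        p = min(1.0, 2.0 * norm.sf(abs(z)))
        method = "normal-approx"
    return RankSumResult(w=w, p_two_sided=float(p), method=method, n1=n1, n2=n2)


def ols_fit(x, y) -> LinearFit:
    """Closed-form simple linear regression with coefficient of determination."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 2:
        raise ValueError("x and y must have equal length >= 2")
    if np.allclose(x, x[0]):
        raise ValueError("x must contain at least 2 distinct values")
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid ** 2).sum()) / ss_tot
    return LinearFit(slope=float(slope), intercept=float(intercept), r2=r2)


def sample_score_table(
    n_planes: int = 6,
    slope: float = 0.08,
    intercept: float = 0.12,
    noise_sd: float = 0.03,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic myelomalacia score table for regression exercises.

    Each imaging plane contributes a dorsal and a ventral region with an
    ordinal malacia score (0–4, higher = more disrupted architecture) and a
    strain ratio generated as intercept + slope·score + noise: structurally
    disrupted (softer) cord strains more, so SR rises with the score.
    """
    rng = default_rng(SeedSequence([int(seed), stable_seed("score-table")]))
    rows = []
    for plane in range(n_planes):
        for region in ("dorsal", "ventral"):
            score = int(rng.integers(0, 5))
            sr = intercept + slope * score + rng.normal(0.0, noise_sd)
            rows.append({
                "plane_id": f"plane_{plane:02d}",
                "region": region,
                "malacia_score": score,
                "strain_ratio": max(float(sr), 0.01),
            })
    return pd.DataFrame(rows)


def score_regression(table: pd.DataFrame, region: str | None = None) -> LinearFit:
    """OLS of strain ratio on malacia score, optionally per region."""
    df = table if region is None else table[table["region"] == region]
    return ols_fit(df["malacia_score"].to_numpy(), df["strain_ratio"].to_numpy())
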