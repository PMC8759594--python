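"""Nonparametric and multiple-comparison statistics for imaging read-outs.

The comparisons used throughout the dispersion analyses: two-tailed
Mann-Whitney U for sample pairs (exact p by enumeration for small tie-free
samples, normal approximation with tie correction otherwise),
Kruskal-Wallis with Dunn's post hoc for multi-group comparisons, per-pair
Welch t tests with optional Holm-Sidak adjustment, and the star coding

    ns  p > 0.05   *  p <= 0.05   **  p <= 0.01
    *** p <= 0.001 **** p <= 0.0001

Figure legends in this field often say "nonparametric multiple t tests";
the named commercial software actually runs per-pair t tests, so both a t
backend (default) and a Mann-Whitney backend are exposed and the backend
used is recorded on each result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "star_code",
    "mann_whitney_u",
    "kruskal_wallis_dunn",
    "multiple_t_tests",
]

#: Exact Mann-Whitney enumeration bound: feasible for min(n1, n2) <= this.
EXACT_N_MAX = 8

_STAR_LADDER = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    n1: int | tuple[int, ...]
    n2: int | None
    method_detail: str
    stars: str


def star_code(p: float) -> str:
    """Star coding of a p-value on the printed significance ladder."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value must be in [0, 1], got {p}")
    for threshold, stars in _STAR_LADDER:
        if p <= threshold:
            return stars
    return "ns"


def _has_ties(a: np.ndarray, b: np.ndarray) -> bool:
    combined = np.concatenate([a, b])
    return np.unique(combined).size < combined.size


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    mode: str = "auto",
    alternative: str = "two-sided",
) -> TestResult:
    """Mann-Whitney U test, two-tailed by default, U reported as min(U1, U2).

    ``mode='auto'`` uses the exact null distribution when
    min(n1, n2) <= 8 and there are no ties, and the normal approximation
    with tie correction otherwise; ``'exact'`` / ``'normal'`` force a method.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = _has_ties(a, b)
    if mode == "auto":
        use_exact = min(a.size, b.size) <= EXACT_N_MAX and not ties
    elif mode == "exact":
        if ties:
            raise ValueError("exact Mann-Whitney p is undefined with ties; use mode='normal'")
        use_exact = True
    elif mode == "normal":
        use_exact = False
    else:
        raise ValueError(f"unknown mode {mode!r}")
    method = "exact" if use_exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative=alternative, method=method)
    u1 = float(res.statistic)
    u2 = a.size * b.size - u1
    p = float(min(res.pvalue, 1.0))
    detail = "exact enumeration" if use_exact else (
        "normal approximation, tie-corrected" + (", ties present" if ties else "")
    )
    return TestResult(
        test_name="mann_whitney_u",
        statistic=min(u1, u2),
        p_value=p,
        n1=a.size,
        n2=b.size,
        method_detail=f"{detail}; alternative={alternative}",
        stars=star_code(p),
    )


def kruskal_wallis_dunn(
    groups: Sequence[Sequence[float]],
    adjust: str = "none",
    group_names: Sequence[str] | None = None,
) -> tuple[TestResult, pd.DataFrame]:
    """Kruskal-Wallis omnibus test with Dunn's pairwise post hoc.

    Returns the tie-corrected H statistic against the chi-square reference
    and a tidy DataFrame of Dunn z statistics on mean ranks with the chosen
    adjustment (``none`` or ``bonferroni``).
    """
    if len(groups) < 3:
        raise ValueError("kruskal_wallis_dunn needs >= 3 groups; use mann_whitney_u for pairs")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in arrays):
        raise ValueError("all groups must be non-empty")
    if adjust not in ("none", "bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    names = list(group_names) if group_names is not None else [f"group{i + 1}" for i in range(len(arrays))]

    pooled = np.concatenate(arrays)
    if np.unique(pooled).size == 1:
        h, p_omni = 0.0, 1.0
    else:
        h, p_omni = sps.kruskal(*arrays)
    omnibus = TestResult(
        test_name="kruskal_wallis",
        statistic=float(h),
        p_value=float(p_omni),
        n1=tuple(g.size for g in arrays),
        n2=None,
        method_detail="tie-corrected H, chi-square reference",
        stars=star_code(float(p_omni)),
    )

    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    mean_ranks, sizes = [], []
    start = 0
    for g in arrays:
        mean_ranks.append(ranks[start : start + g.size].mean())
        sizes.append(g.size)
        start += g.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    m = len(arrays) * (len(arrays) - 1) // 2
    rows = []
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            se = math.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * sps.norm.sf(abs(z))
            p_adj = min(1.0, p * m) if adjust == "bonferroni" else p
            rows.append(
                {"group_a": names[i], "group_b": names[j], "z": z,
                 "p_raw": p, "p_adjusted": p_adj, "stars": star_code(p_adj)}
            )
    return omnibus, pd.DataFrame(rows)


def multiple_t_tests(
    pairs: Sequence[tuple[Sequence[float], Sequence[float]]],
    correction: str = "none",
    backend: str = "t",
    zero_variance: str = "error",
) -> list[TestResult]:
    """Per-pair Welch t tests (or Mann-Whitney with ``backend='mwu'``).

    Holm-Sidak adjusted p-values when selected; adjusted p is never smaller
    than the raw p.  A pair of constant, equal samples has an undefined
    (0/0) t statistic: by default this raises; ``zero_variance='p_one'``
    reports p = 1 instead (appropriate when such pairs arise structurally,
    e.g. the origin locus of a fold-change table, which is 1 by definition
    in every replicate).
    """
    if correction not in ("none", "holm_sidak"):
        raise ValueError(f"unknown correction {correction!r}")
    raw: list[TestResult] = []
    for a, b in pairs:
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("each sample needs n >= 2")
        if backend == "mwu":
            raw.append(mann_whitney_u(a, b))
            continue
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and a.mean() == b.mean():
            if zero_variance != "p_one":
                raise ValueError(
                    "both samples are constant and equal; the t statistic is undefined (0/0)"
                )
            raw.append(
                TestResult(
                    test_name="welch_t",
                    statistic=0.0,
                    p_value=1.0,
                    n1=a.size,
                    n2=b.size,
                    method_detail="degenerate: constant equal samples, p set to 1",
                    stars="ns",
                )
            )
            continue
        t, p = sps.ttest_ind(a, b, equal_var=False)
        p = float(p) if np.isfinite(p) else 0.0
        raw.append(
            TestResult(
                test_name="welch_t",
                statistic=float(t),
                p_value=p,
                n1=a.size,
                n2=b.size,
                method_detail="Welch t, unequal variances",
                stars=star_code(p),
            )
        )
    if correction == "none" or len(raw) == 0:
        return raw
    pvals = [r.p_value for r in raw]
    _, p_adj, _, _ = multipletests(pvals, method="holm-sidak")
    adjusted = []
    for r, pa in zip(raw, p_adj):
        pa = float(max(pa, r.p_value))
        adjusted.append(
            TestResult(
                test_name=r.test_name,
                statistic=r.statistic,
                p_value=pa,
                n1=r.n1,
                n2=r.n2,
                method_detail=r.method_detail + "; Holm-Sidak adjusted",
                stars=star_code(pa),
            )
        )
    return adjusted
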