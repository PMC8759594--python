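"""3C-qPCR quantification and the dispersion-expression correlation screen.

Chromosome conformation capture (3C) ligation products are quantified by
qPCR crossing points (Cp).  Per sample and replicate, Cp values are
normalized by subtracting the mean Cp across all tested loci (a log2-scale
centering that leaves all pairwise Cp differences unchanged), and the
enrichment of a locus over the origin self-ligation product is

    fold_change = 2 ** (Cp - Cp_origin)

with Cp the normalized signal for the locus and Cp_origin the normalized
origin signal.  The formula is applied exactly as stated; note that under
the usual qPCR convention a *higher* Cp means *less* product, so the sign
convention is surfaced in the output metadata rather than silently flipped.

The expression screen computes, for every transcript in a transcripts x
alleles reads-per-million matrix, the Pearson correlation with a per-allele
dispersion covariate (ordinal ranking by default, mean skeleton dot length
as an alternative) and reports hits at r > 0.6 (positive) and r < -0.6
(negative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import multiple_t_tests

__all__ = [
    "CpTable",
    "FoldChangeResult",
    "CorrelationHit",
    "normalize_cp",
    "fold_change",
    "fold_changes",
    "aggregate_and_compare",
    "qpcr_expression_fold_change",
    "correlate_dispersion_expression",
]

_REQUIRED_COLUMNS = ("sample", "replicate", "locus", "cp")


@dataclass
class CpTable:
    """Long-format Cp table (columns: sample, replicate, locus, cp)."""

    data: pd.DataFrame
    origin_locus: str
    normalized: bool = False
    truth_deltas: dict | None = None

    def __post_init__(self) -> None:
        missing = [c for c in _REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"CpTable is missing columns {missing}")
        if not np.isfinite(self.data["cp"]).all():
            raise ValueError("CpTable contains non-finite Cp values")
        by_rep = self.data.groupby(["sample", "replicate"])["locus"]
        if not by_rep.apply(lambda s: self.origin_locus in set(s)).all():
            raise ValueError(
                f"origin locus {self.origin_locus!r} missing from some sample/replicate"
            )


@dataclass
class FoldChangeResult:
    """Per-locus fold-change summary for one condition."""

    condition: str
    table: pd.DataFrame  # columns: locus, replicate, fold_change
    summary: pd.DataFrame  # index: locus; columns: mean, sem, n
    sign_convention: str = "2**(Cp - Cp_origin) as stated; higher Cp gives larger value"


@dataclass(frozen=True)
class CorrelationHit:
    transcript: str
    r: float
    direction: str | None  # "positive" | "negative" | None (undefined r)
    passes: bool


def normalize_cp(table: CpTable) -> CpTable:
    """Center Cp values on the per-sample/replicate mean over all loci."""
    counts = table.data.groupby(["sample", "replicate"])["locus"].nunique()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"normalization needs >= 2 loci per sample/replicate; got one at {bad}")
    data = table.data.copy()
    data["cp"] = data["cp"] - data.groupby(["sample", "replicate"])["cp"].transform("mean")
    return CpTable(data=data, origin_locus=table.origin_locus, normalized=True,
                   truth_deltas=table.truth_deltas)


def fold_change(cp: float, cp_origin: float) -> float:
    """2**(cp - cp_origin), the enrichment over the origin self-ligation."""
    if not (np.isfinite(cp) and np.isfinite(cp_origin)):
        raise ValueError("fold_change requires finite Cp values")
    return float(2.0 ** (cp - cp_origin))


def fold_changes(table: CpTable, condition: str = "", normalize: bool = True) -> FoldChangeResult:
    """Per-replicate and mean +/- SEM fold-changes for every locus.

    The origin locus's fold-change is exactly 1 in every replicate, and the
    result is invariant to adding a constant to all Cp values of a replicate.
    """
    if normalize and not table.normalized:
        table = normalize_cp(table)
    data = table.data.copy()
    origin = (
        data[data["locus"] == table.origin_locus]
        .set_index(["sample", "replicate"])["cp"]
    )
    keys = list(zip(data["sample"], data["replicate"]))
    data["fold_change"] = 2.0 ** (data["cp"].to_numpy() - origin.loc[keys].to_numpy())
    summary = (
        data.groupby("locus")["fold_change"]
        .agg(mean="mean", sem=lambda x: x.std(ddof=1) / math.sqrt(len(x)) if len(x) > 1 else 0.0,
             n="count")
    )
    return FoldChangeResult(
        condition=condition,
        table=data[["sample", "replicate", "locus", "fold_change"]],
        summary=summary,
    )


def aggregate_and_compare(
    results: Mapping[str, FoldChangeResult],
    correction: str = "holm_sidak",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Compare per-locus fold-changes between two conditions.

    Returns one row per locus with mean +/- SEM per condition and the Welch
    t p-value (optionally Holm-Sidak adjusted across loci).
    """
    if len(results) != 2:
        raise ValueError(f"expected exactly 2 conditions, got {len(results)}")
    (name_a, res_a), (name_b, res_b) = results.items()
    loci = sorted(set(res_a.summary.index) & set(res_b.summary.index))
    pairs = []
    for locus in loci:
        a = res_a.table.loc[res_a.table["locus"] == locus, "fold_change"].to_numpy()
        b = res_b.table.loc[res_b.table["locus"] == locus, "fold_change"].to_numpy()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"locus {locus!r} has a single replicate; need >= 2 per condition")
        pairs.append((a, b))
    tests = multiple_t_tests(pairs, correction=correction, zero_variance="p_one")
    rows = []
    for locus, test in zip(loci, tests):
        rows.append(
            {
                "locus": locus,
                f"mean_{name_a}": res_a.summary.loc[locus, "mean"],
                f"sem_{name_a}": res_a.summary.loc[locus, "sem"],
                f"mean_{name_b}": res_b.summary.loc[locus, "mean"],
                f"sem_{name_b}": res_b.summary.loc[locus, "sem"],
                "statistic": test.statistic,
                "p_value": test.p_value,
                "stars": test.stars,
                "significant": test.p_value <= alpha,
            }
        )
    return pd.DataFrame(rows).set_index("locus")


def qpcr_expression_fold_change(
    target_cp: Mapping[str, float] | pd.Series,
    control_cp: Mapping[str, float] | pd.Series,
    baseline: str,
) -> pd.Series:
    """Relative expression by the delta-delta-Cp method.

    fold(t) = 2 ** -((Cp_target - Cp_control)_t - (Cp_target - Cp_control)_baseline),
    with the internal-control gene (e.g. beta-actin) measured at every
    timepoint; the baseline timepoint's fold-change is 1 by construction.
    """
    target = pd.Series(target_cp, dtype=float)
    control = pd.Series(control_cp, dtype=float)
    missing = [t for t in target.index if t not in control.index]
    if missing:
        raise ValueError(f"control gene Cp missing for timepoints {missing}")
    if baseline not in target.index:
        raise ValueError(f"baseline timepoint {baseline!r} not measured")
    delta = target - control.loc[target.index]
    ddct = delta - delta.loc[baseline]
    return (2.0 ** (-ddct)).rename("fold_change")


def correlate_dispersion_expression(
    ranking,
    expr: pd.DataFrame,
    covariate: str = "rank",
    pos_thresh: float = 0.6,
    neg_thresh: float = -0.6,
) -> list[CorrelationHit]:
    """Pearson-correlate every transcript with the dispersion covariate.

    ``expr`` is transcripts x alleles; its columns must match the ranking's
    alleles (>= 3).  ``covariate`` selects the ordinal ranking (``"rank"``,
    the default) or the per-allele mean skeleton dot length
    (``"mean_length"``).  Transcripts with zero variance have undefined r
    and are reported with ``direction=None, passes=False``.
    """
    cov_series = ranking.covariate(covariate) if hasattr(ranking, "covariate") else pd.Series(ranking)
    alleles = set(cov_series.index)
    cols = set(expr.columns)
    if alleles != cols:
        diff = sorted(alleles.symmetric_difference(cols))
        raise ValueError(f"allele mismatch between ranking and matrix: {diff}")
    if len(alleles) < 3:
        raise ValueError("need >= 3 alleles for correlation")
    x = cov_series.loc[list(expr.columns)].to_numpy(dtype=float)
    xc = x - x.mean()
    xnorm = math.sqrt((xc**2).sum())
    mat = expr.to_numpy(dtype=float)
    yc = mat - mat.mean(axis=1, keepdims=True)
    ynorm = np.sqrt((yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (yc @ xc) / (ynorm * xnorm)
    hits = []
    for name, ri in zip(expr.index, r):
        if not np.isfinite(ri):
            hits.append(CorrelationHit(str(name), float("nan"), None, False))
            continue
        ri = float(np.clip(ri, -1.0, 1.0))
        if ri > pos_thresh:
            hits.append(CorrelationHit(str(name), ri, "positive", True))
        elif ri < neg_thresh:
            hits.append(CorrelationHit(str(name), ri, "negative", True))
        else:
            direction = "positive" if ri >= 0 else "negative"
            hits.append(CorrelationHit(str(name), ri, direction, False))
    return hits
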