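"""Dispersion categories, condition summaries, and disperser ranking.

Skeleton dot lengths are partitioned into categorical bins with
probe-class-specific cutoffs (micrometres):

* heterochromatin (alpha-satellite probes): < 0.75 compact, 0.75-1.25
  diffused, > 1.25 dispersed;
* euchromatin (oligopaint probes): < 1.5 compact/diffused, 1.5-2.5
  dispersed, > 2.5 scattered;
* whole-chromosome probes: user-supplied bin edges (no canonical default).

Printed ranges are taken closed on both ends, with strict inequalities for
the outer bins, so a length exactly on a boundary falls in the middle bin.

Alleles (e.g. monophosphorylated RB variants) are ranked by mean skeleton
dot length and classified as high / medium / low dispersers relative to a
low-dispersing and a high-dispersing reference condition: an allele whose
lengths are not significantly greater than the low reference (one-sided
Mann-Whitney) is a low disperser, one not significantly less than the high
reference is a high disperser, anything else is medium.  A plain tertile
rule is available as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .morphometry import FocusMeasurement
from .stats import mann_whitney_u

__all__ = [
    "CategoryCutoffs",
    "DispersionSummary",
    "DispersionRanking",
    "assign_category",
    "summarize_condition",
    "rank_dispersers",
]

HETEROCHROMATIN_BOUNDARIES_UM = (0.75, 1.25)
HETEROCHROMATIN_LABELS = ("compact", "diffused", "dispersed")
EUCHROMATIN_BOUNDARIES_UM = (1.5, 2.5)
EUCHROMATIN_LABELS = ("compact/diffused", "dispersed", "scattered")


@dataclass(frozen=True)
class CategoryCutoffs:
    """Ordered micrometre boundaries and the category labels they delimit."""

    probe_class: str
    boundaries_um: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.boundaries_um) + 1:
            raise ValueError("need exactly one more label than boundaries")
        if any(b2 <= b1 for b1, b2 in zip(self.boundaries_um, self.boundaries_um[1:])):
            raise ValueError("boundaries must be strictly increasing")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")

    @classmethod
    def heterochromatin(cls) -> "CategoryCutoffs":
        return cls("heterochromatin", HETEROCHROMATIN_BOUNDARIES_UM, HETEROCHROMATIN_LABELS)

    @classmethod
    def euchromatin(cls) -> "CategoryCutoffs":
        return cls("euchromatin", EUCHROMATIN_BOUNDARIES_UM, EUCHROMATIN_LABELS)

    @classmethod
    def whole_chromosome(cls, boundaries_um: Sequence[float], labels: Sequence[str]) -> "CategoryCutoffs":
        """Whole-chromosome signals are binned with explicit user edges."""
        return cls("whole_chromosome", tuple(boundaries_um), tuple(labels))


def assign_category(length_um: float, cutoffs: CategoryCutoffs) -> str:
    """Category of a skeleton dot length.

    The lowest bin is strict (< first boundary) and the top bin is strict
    (> last boundary); boundary values fall in the adjoining middle bin.
    """
    if length_um < 0:
        raise ValueError(f"skeleton dot length cannot be negative, got {length_um}")
    bounds = cutoffs.boundaries_um
    if length_um < bounds[0]:
        return cutoffs.labels[0]
    for j in range(1, len(bounds)):
        if length_um <= bounds[j]:
            return cutoffs.labels[j]
    return cutoffs.labels[-1]


@dataclass
class DispersionSummary:
    """Per-condition summary of skeleton dot lengths."""

    condition: str
    n_foci: int
    mean_length_um: float
    sem_length_um: float
    category_percentages: dict[str, float]
    lengths_um: np.ndarray


def _as_lengths(measurements) -> np.ndarray:
    if len(measurements) and isinstance(measurements[0], FocusMeasurement):
        return np.asarray([m.skeleton_dot_length_um for m in measurements], dtype=float)
    return np.asarray(measurements, dtype=float)


def summarize_condition(
    measurements: Sequence[FocusMeasurement] | Sequence[float],
    cutoffs: CategoryCutoffs,
    condition: str = "",
) -> DispersionSummary:
    """Mean, SEM and exact category percentages for one condition."""
    lengths = _as_lengths(measurements)
    if lengths.size == 0:
        raise ValueError("cannot summarize an empty condition")
    n = lengths.size
    sem = float(lengths.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    counts = {label: 0 for label in cutoffs.labels}
    for x in lengths:
        counts[assign_category(float(x), cutoffs)] += 1
    percentages = {label: 100.0 * c / n for label, c in counts.items()}
    return DispersionSummary(
        condition=condition,
        n_foci=int(n),
        mean_length_um=float(lengths.mean()),
        sem_length_um=sem,
        category_percentages=percentages,
        lengths_um=lengths,
    )


@dataclass
class DispersionRanking:
    """Allele -> (mean length, ordinal rank, disperser class).

    Ranks are 1..n ascending in mean length (ties broken by allele name), so
    a larger rank means a stronger disperser; ``covariate()`` returns the
    per-allele vector used downstream as the correlation covariate.
    """

    table: pd.DataFrame  # index: allele; columns: mean_length_um, rank, disperser_class
    rule: str

    def covariate(self, kind: str = "rank") -> pd.Series:
        if kind == "rank":
            return self.table["rank"].astype(float)
        if kind == "mean_length":
            return self.table["mean_length_um"].astype(float)
        raise ValueError(f"unknown covariate kind {kind!r}")


def rank_dispersers(
    summaries: Mapping[str, DispersionSummary],
    low_reference: str,
    high_reference: str,
    alpha: float = 0.05,
    method: str = "significance",
) -> DispersionRanking:
    """Rank alleles by mean skeleton dot length and classify high/medium/low.

    With ``method='significance'`` (default) each allele's per-focus lengths
    are compared against the references by one-sided Mann-Whitney tests at
    ``alpha``; ``method='tertile'`` simply splits the mean-length order into
    thirds.
    """
    for ref in (low_reference, high_reference):
        if ref not in summaries:
            raise ValueError(f"reference condition {ref!r} not among summaries")
    alleles = sorted(summaries)
    means = {a: summaries[a].mean_length_um for a in alleles}
    order = sorted(alleles, key=lambda a: (means[a], a))
    ranks = {a: i + 1 for i, a in enumerate(order)}

    classes: dict[str, str] = {}
    if method == "significance":
        low = summaries[low_reference].lengths_um
        high = summaries[high_reference].lengths_um
        for a in alleles:
            x = summaries[a].lengths_um
            p_gt_low = mann_whitney_u(x, low, alternative="greater").p_value
            if p_gt_low >= alpha:
                classes[a] = "low"
                continue
            p_lt_high = mann_whitney_u(x, high, alternative="less").p_value
            classes[a] = "high" if p_lt_high >= alpha else "medium"
    elif method == "tertile":
        n = len(order)
        for i, a in enumerate(order):
            classes[a] = "low" if i < n / 3 else ("medium" if i < 2 * n / 3 else "high")
    else:
        raise ValueError(f"unknown ranking method {method!r}")

    table = pd.DataFrame(
        {
            "mean_length_um": [means[a] for a in alleles],
            "rank": [ranks[a] for a in alleles],
            "disperser_class": [classes[a] for a in alleles],
        },
        index=pd.Index(alleles, name="allele"),
    )
    return DispersionRanking(table=table, rule=f"{method}; alpha={alpha}; "
                             f"low_ref={low_reference}; high_ref={high_reference}")
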