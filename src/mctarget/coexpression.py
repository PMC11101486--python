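"""Pairwise co-expression contingency summaries and expressor distributions.

The counting unit is the lesion: one distinct metastatic site per patient,
with the site's H-score for a marker taken as the aggregate over its
samples (maximum by default).  Lesions missing a call for either marker of
a pair are excluded from that pair's denominator, so denominators are
per-analysis evaluable sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_io import Cohort, CohortValidationError
from .scoring import (
    DEFAULT_THRESHOLD,
    ExpressorCategory,
    MolecularSubtype,
    SubtypeRule,
    classify_expressor,
    site_level_scores,
)

__all__ = [
    "CoexpressionSummary",
    "coexpression_counts",
    "summarize_percentages",
    "format_percentage",
    "expressor_distribution",
]


@dataclass(frozen=True)
class CoexpressionSummary:
    """2x2 positivity counts for a marker pair over evaluable lesions."""

    marker_a: str
    marker_b: str
    subtype_filter: str  # a MolecularSubtype value or "all"
    n_dual: int
    n_a_only: int
    n_b_only: int
    n_neither: int

    @property
    def n_total(self) -> int:
        return self.n_dual + self.n_a_only + self.n_b_only + self.n_neither

    def counts(self) -> tuple[int, int, int, int]:
        return (self.n_dual, self.n_a_only, self.n_b_only, self.n_neither)


def coexpression_counts(
    cohort: Cohort | pd.DataFrame,
    marker_a: str,
    marker_b: str,
    subtype_filter: str | MolecularSubtype = "all",
    threshold: float = DEFAULT_THRESHOLD,
    unit: str = "site",
    aggregate: str = "max",
    rule: SubtypeRule | None = None,
) -> CoexpressionSummary:
    """Count dual/single/neither positivity for a marker pair.

    ``unit='site'`` counts lesions (site-level aggregates, default);
    ``unit='sample'`` counts individual samples.  ``subtype_filter``
    restricts to lesions of one molecular subtype.
    """
    if marker_a == marker_b:
        raise ValueError("marker_a and marker_b must differ")
    if unit not in ("site", "sample"):
        raise ValueError(f"unit must be 'site' or 'sample', got {unit!r}")
    if isinstance(subtype_filter, MolecularSubtype):
        subtype_filter = subtype_filter.value

    if unit == "site":
        table = site_level_scores(cohort, threshold=threshold, aggregate=aggregate, rule=rule)
    else:
        from .scoring import score_cohort

        df = score_cohort(cohort, threshold=threshold, rule=rule) if isinstance(cohort, Cohort) else cohort
        table = df.pivot_table(
            index=["patient_id", "site_label", "block_id", "sample_id"],
            columns="marker", values="h_score", aggfunc="first",
        )
        sub = df.groupby(["patient_id", "site_label", "block_id", "sample_id"])["subtype"].first()
        table["subtype"] = sub
        table = table.reset_index()

    for m in (marker_a, marker_b):
        if m not in table.columns:
            table[m] = np.nan
    if subtype_filter != "all":
        table = table[table["subtype"] == subtype_filter]
    table = table.dropna(subset=[marker_a, marker_b])

    a_pos = table[marker_a] >= threshold
    b_pos = table[marker_b] >= threshold
    return CoexpressionSummary(
        marker_a=marker_a,
        marker_b=marker_b,
        subtype_filter=subtype_filter,
        n_dual=int((a_pos & b_pos).sum()),
        n_a_only=int((a_pos & ~b_pos).sum()),
        n_b_only=int((~a_pos & b_pos).sum()),
        n_neither=int((~a_pos & ~b_pos).sum()),
    )


def format_percentage(value: float, decimal_band: tuple[float, float] = (3.5, 5.0)) -> float:
    """Round a percentage for reporting.

    Percentages are rounded half-away-from-zero to the nearest integer,
    except values in ``decimal_band`` (default [3.5, 5)), which keep one
    decimal so that small fractions just under the 5% reporting threshold
    are not overstated — e.g. 3/71 is reported as 4.2, while 7/304 rounds
    to 2 and 61/304 to 20.
    """
    if decimal_band[0] <= value < decimal_band[1]:
        return np.floor(value * 10.0 + 0.5) / 10.0
    return float(np.floor(value + 0.5))


def summarize_percentages(
    summary: CoexpressionSummary,
    decimal_band: tuple[float, float] = (3.5, 5.0),
) -> tuple[float, float, float, float]:
    """Percentages (dual, a_only, b_only, neither) of the evaluable lesions.

    Raises when the summary has no eligible lesions (undefined percentages).
    """
    if summary.n_total == 0:
        raise CohortValidationError("no eligible lesions: percentages undefined")
    return tuple(
        format_percentage(100.0 * c / summary.n_total, decimal_band)
        for c in summary.counts()
    )


def expressor_distribution(
    cohort: Cohort | pd.DataFrame,
    marker: str,
    threshold: float = DEFAULT_THRESHOLD,
    aggregate: str = "max",
) -> dict[ExpressorCategory, int]:
    """Per-patient expressor-category counts for one marker.

    Each patient with at least one scored site contributes exactly one count:
    uniformly negative (all sites below the cut), heterogeneous (sites on
    both sides) or uniformly positive.
    """
    table = site_level_scores(cohort, threshold=threshold, aggregate=aggregate)
    if marker not in table.columns:
        raise CohortValidationError(f"marker {marker!r} not scored in this cohort")
    counts = {cat: 0 for cat in ExpressorCategory}
    for _, grp in table.groupby("patient_id"):
        scores = grp[marker].dropna()
        if scores.empty:
            continue
        counts[classify_expressor(scores, threshold)] += 1
    return counts
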