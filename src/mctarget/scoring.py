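"""H-score computation, positivity calls, molecular subtyping, expressor categories.

The H-score here follows the two-level intensity convention: each cell is
graded 0 (no chromogen), 1 (faint/fine deposition) or 2 (prominent
deposition), and the score is the intensity-weighted sum of cell
percentages, giving a 0-200 range:

    H = 0 * pct0 + 1 * pct1 + 2 * pct2.

Positivity uses an inclusive cut-off of H >= 20 throughout the package.
Molecular subtype is the cross of an androgen-receptor signaling axis
(AR, NKX3.1) and a neuroendocrine axis (SYP, INSM1): a sample is
axis-positive when any scored marker on the axis reaches its threshold
(configurable to require all markers, or per-marker thresholds).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import Cohort, CohortValidationError

__all__ = [
    "AR_AXIS_MARKERS",
    "NE_AXIS_MARKERS",
    "DEFAULT_THRESHOLD",
    "StainingProfile",
    "PositivityCall",
    "MolecularSubtype",
    "ExpressorCategory",
    "SubtypeRule",
    "UnclassifiableError",
    "compute_h_score",
    "binarize_expression",
    "classify_subtype",
    "classify_expressor",
    "score_cohort",
    "site_level_scores",
]

DEFAULT_THRESHOLD = 20.0
AR_AXIS_MARKERS: tuple[str, ...] = ("AR", "NKX3.1")
NE_AXIS_MARKERS: tuple[str, ...] = ("SYP", "INSM1")

#: tolerance on the staining-profile percentage sum (absorbs rounding by scorers)
PROFILE_SUM_TOL = 0.5


class UnclassifiableError(ValueError):
    """Raised when a subtype cannot be assigned (an axis has no scored marker)."""


@dataclass(frozen=True)
class StainingProfile:
    """Percent of cells at staining intensity levels 0, 1 and 2.

    Levels: 0 = no brown chromogen, 1 = faint and fine deposition,
    2 = prominent deposition.  Percentages must lie in [0, 100] and sum to
    100 within ±0.5.
    """

    pct_level0: float
    pct_level1: float
    pct_level2: float

    def validate(self) -> None:
        for name in ("pct_level0", "pct_level1", "pct_level2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0) or math.isnan(v):
                raise CohortValidationError(f"{name} = {v!r} outside [0, 100]")
        total = self.pct_level0 + self.pct_level1 + self.pct_level2
        if abs(total - 100.0) > PROFILE_SUM_TOL:
            raise CohortValidationError(
                f"staining fractions sum to {total:g}, outside 100 ± {PROFILE_SUM_TOL}"
            )


def compute_h_score(profile: StainingProfile) -> float:
    """Intensity-weighted H-score on the 0-200 scale.

    H = 1 * pct_level1 + 2 * pct_level2; equals 200 iff all cells are at
    level 2 and 0 iff all are at level 0.
    """
    profile.validate()
    h = profile.pct_level1 + 2.0 * profile.pct_level2
    return float(min(max(h, 0.0), 200.0))


@dataclass(frozen=True)
class PositivityCall:
    marker: str
    h_score: float
    positive: bool
    threshold: float = DEFAULT_THRESHOLD


def binarize_expression(
    h_score: float, threshold: float = DEFAULT_THRESHOLD, marker: str = ""
) -> PositivityCall:
    """Positive iff ``h_score >= threshold`` (inclusive cut, default 20)."""
    if not (0.0 <= h_score <= 200.0):
        raise CohortValidationError(f"h_score {h_score!r} outside [0, 200]")
    if not (0.0 < threshold <= 200.0):
        raise CohortValidationError(f"threshold {threshold!r} outside (0, 200]")
    return PositivityCall(
        marker=marker, h_score=float(h_score), positive=bool(h_score >= threshold),
        threshold=float(threshold),
    )


class MolecularSubtype(enum.Enum):
    """Four-way AR/NE classification of CRPC.

    AR+/NE- prostatic adenocarcinoma, AR-/NE+ neuroendocrine (NEPC),
    AR+/NE+ amphicrine, AR-/NE- double-negative.
    """

    AR_pos_NE_neg = "AR_pos_NE_neg"
    AR_neg_NE_pos = "AR_neg_NE_pos"
    AR_pos_NE_pos = "AR_pos_NE_pos"
    AR_neg_NE_neg = "AR_neg_NE_neg"

    @classmethod
    def from_axes(cls, ar_positive: bool, ne_positive: bool) -> "MolecularSubtype":
        return {
            (True, False): cls.AR_pos_NE_neg,
            (False, True): cls.AR_neg_NE_pos,
            (True, True): cls.AR_pos_NE_pos,
            (False, False): cls.AR_neg_NE_neg,
        }[(bool(ar_positive), bool(ne_positive))]


class ExpressorCategory(enum.Enum):
    """Per-patient marker pattern across metastatic sites."""

    uniform_negative = "uniform_negative"   # all sites H < threshold
    heterogeneous = "heterogeneous"         # sites on both sides of the cut
    uniform_positive = "uniform_positive"   # all sites H >= threshold


@dataclass(frozen=True)
class SubtypeRule:
    """Axis-positivity rule for subtype assignment.

    mode: ``any_marker`` (axis positive when any scored axis marker meets its
    threshold, default) or ``all_markers`` (conjunction over scored markers).
    ``thresholds`` may override the default cut per marker.
    """

    mode: str = "any_marker"
    default_threshold: float = DEFAULT_THRESHOLD
    thresholds: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("any_marker", "all_markers"):
            raise ValueError(f"unknown subtype rule mode {self.mode!r}")

    def threshold_for(self, marker: str) -> float:
        return float(self.thresholds.get(marker, self.default_threshold))

    def axis_positive(self, scores: Mapping[str, float]) -> bool:
        calls = [
            h >= self.threshold_for(m)
            for m, h in scores.items()
            if h is not None and not (isinstance(h, float) and math.isnan(h))
        ]
        if not calls:
            raise UnclassifiableError("no scored marker on axis")
        return any(calls) if self.mode == "any_marker" else all(calls)


def classify_subtype(
    ar_scores: Mapping[str, float],
    ne_scores: Mapping[str, float],
    rule: SubtypeRule | None = None,
) -> MolecularSubtype:
    """Assign the four-class AR/NE molecular subtype from axis marker H-scores.

    Raises :class:`UnclassifiableError` when either axis has no scored marker.
    """
    rule = rule or SubtypeRule()
    try:
        ar_pos = rule.axis_positive(ar_scores)
    except UnclassifiableError:
        raise UnclassifiableError("AR axis has no scored marker") from None
    try:
        ne_pos = rule.axis_positive(ne_scores)
    except UnclassifiableError:
        raise UnclassifiableError("NE axis has no scored marker") from None
    return MolecularSubtype.from_axes(ar_pos, ne_pos)


def classify_expressor(
    site_h_scores: Iterable[float], threshold: float = DEFAULT_THRESHOLD
) -> ExpressorCategory:
    """Categorize one patient-marker from its per-site (aggregated) H-scores."""
    scores = [s for s in site_h_scores if not (isinstance(s, float) and math.isnan(s))]
    if not scores:
        raise CohortValidationError("classify_expressor requires at least one scored site")
    calls = [s >= threshold for s in scores]
    if all(calls):
        return ExpressorCategory.uniform_positive
    if not any(calls):
        return ExpressorCategory.uniform_negative
    return ExpressorCategory.heterogeneous


# ---------------------------------------------------------------------------
# cohort-level scoring


def score_cohort(
    cohort: Cohort,
    threshold: float = DEFAULT_THRESHOLD,
    rule: SubtypeRule | None = None,
) -> pd.DataFrame:
    """Resolve H-scores and positivity for every sample-marker, plus subtype.

    Returns the long-format table with ``h_score`` filled in from staining
    profiles where absent, a boolean ``positive`` column, and a per-sample
    ``subtype`` column (NaN where an axis has no scored marker).  Rows with
    neither an H-score nor a profile keep NaN (missing per sample-marker).
    """
    rule = rule or SubtypeRule()
    df = cohort.data.copy()
    needs = (
        df["h_score"].isna()
        & df["pct_level0"].notna()
        & df["pct_level1"].notna()
        & df["pct_level2"].notna()
    )
    if needs.any():
        sub = df.loc[needs]
        df.loc[needs, "h_score"] = [
            compute_h_score(StainingProfile(r.pct_level0, r.pct_level1, r.pct_level2))
            for r in sub.itertuples(index=False)
        ]
    df["positive"] = pd.array(df["h_score"] >= threshold, dtype="boolean")
    df.loc[df["h_score"].isna(), "positive"] = pd.NA

    # per-sample subtype from that sample's own axis markers
    wide = df.pivot_table(
        index=["patient_id", "site_label", "block_id", "sample_id"],
        columns="marker", values="h_score", aggfunc="first",
    )
    subtype = {}
    for key, row in wide.iterrows():
        ar = {m: row[m] for m in AR_AXIS_MARKERS if m in row.index}
        ne = {m: row[m] for m in NE_AXIS_MARKERS if m in row.index}
        try:
            subtype[key] = classify_subtype(ar, ne, rule).value
        except UnclassifiableError:
            subtype[key] = np.nan
    idx = pd.MultiIndex.from_frame(df[["patient_id", "site_label", "block_id", "sample_id"]])
    df["subtype"] = idx.map(subtype)
    return df


def site_level_scores(
    cohort: Cohort | pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    aggregate: str = "max",
    rule: SubtypeRule | None = None,
) -> pd.DataFrame:
    """Aggregate sample H-scores to the lesion (patient, site) level.

    A site "expresses" a marker when any of its samples does, so the default
    aggregate is the maximum over the site's samples (``mean`` available).
    Returns one row per (patient_id, site_label) with one column per marker
    (aggregated H-score; NaN when unscored) plus a ``subtype`` column
    classified from the site-aggregated axis markers.
    """
    if aggregate not in ("max", "mean"):
        raise ValueError(f"aggregate must be 'max' or 'mean', got {aggregate!r}")
    rule = rule or SubtypeRule()
    df = score_cohort(cohort, threshold=threshold, rule=rule) if isinstance(cohort, Cohort) else cohort
    agg = df.pivot_table(
        index=["patient_id", "site_label"],
        columns="marker", values="h_score", aggfunc=aggregate,
    )
    subtypes = []
    for _, row in agg.iterrows():
        ar = {m: row[m] for m in AR_AXIS_MARKERS if m in row.index}
        ne = {m: row[m] for m in NE_AXIS_MARKERS if m in row.index}
        try:
            subtypes.append(classify_subtype(ar, ne, rule).value)
        except UnclassifiableError:
            subtypes.append(np.nan)
    agg["subtype"] = subtypes
    agg.columns.name = None
    return agg.reset_index()
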