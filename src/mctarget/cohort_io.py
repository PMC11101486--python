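"""Data model, readers/writers and validation for cohort and genomics tables.

The canonical on-disk format is a long ("tidy") CSV with one row per
(patient, site, block, sample, marker) measurement: either a precomputed
H-score on the 0-200 scale, staining-level fractions (percent of cells at
intensity levels 0/1/2), or both.  This mirrors the spreadsheets produced
when pathologists score tissue microarrays, and keeps missingness per
(sample, marker) rather than per sample.

Genomics tables are per-patient gene alteration calls with a four-level
status vocabulary distinguishing monoallelic from biallelic events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortFormatError",
    "CohortValidationError",
    "DEFAULT_MARKERS",
    "DEFAULT_SITES",
    "DEFAULT_GENES",
    "GENOMICS_STATUSES",
    "Cohort",
    "GenomicsTable",
    "SampleRecord",
    "read_cohort",
    "read_genomics",
    "write_cohort",
    "write_genomics",
]

H_SCORE_MIN = 0.0
H_SCORE_MAX = 200.0

#: Default 11-entry anatomic-site vocabulary for metastatic CRPC cohorts.
DEFAULT_SITES: tuple[str, ...] = (
    "vertebral_bone",
    "nonvertebral_bone",
    "liver",
    "lung",
    "lymph_node",
    "prostate",
    "adrenal",
    "soft_tissue",
    "brain",
    "peritoneum",
    "other",
)

#: Cell-surface targets plus the AR-axis and NE-axis subtyping markers.
DEFAULT_MARKERS: tuple[str, ...] = (
    "TROP2",
    "DLL3",
    "CEACAM5",
    "PSMA",
    "AR",
    "NKX3.1",
    "SYP",
    "INSM1",
)

DEFAULT_GENES: tuple[str, ...] = ("AR", "BRCA2", "CHD1", "PTEN", "RB1", "SPOP", "TP53")

GENOMICS_STATUSES: tuple[str, ...] = (
    "WT",
    "ALT_MONOALLELIC",
    "ALT_BIALLELIC",
    "ALT_UNSPECIFIED",
)

COHORT_COLUMNS: tuple[str, ...] = (
    "patient_id",
    "site_label",
    "block_id",
    "sample_id",
    "marker",
    "h_score",
    "pct_level0",
    "pct_level1",
    "pct_level2",
)

PROFILE_COLUMNS: tuple[str, ...] = ("pct_level0", "pct_level1", "pct_level2")

IDENTITY_COLUMNS: tuple[str, ...] = ("patient_id", "block_id", "sample_id")


class CohortFormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


class CohortValidationError(ValueError):
    """Table content violates a documented invariant (range, duplicate, vocabulary)."""


@dataclass(frozen=True)
class SampleRecord:
    """One tissue sample inside the patient -> site -> block hierarchy.

    ``measurements`` maps marker name to a dict with keys ``h_score`` (float
    or NaN) and ``profile`` (tuple of the three level percentages, or None).
    """

    patient_id: str
    site_label: str
    block_id: str
    sample_id: str
    measurements: Mapping[str, dict]


@dataclass
class Cohort:
    """A validated cohort: long-format measurement table plus marker metadata.

    ``data`` always carries the full canonical column set (missing profile or
    H-score cells are NaN).  Use :func:`read_cohort` / :func:`write_cohort`
    for I/O; direct construction validates eagerly.
    """

    data: pd.DataFrame
    markers: tuple[str, ...] = DEFAULT_MARKERS
    site_vocabulary: tuple[str, ...] = DEFAULT_SITES
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = _validate_cohort_frame(
            self.data, markers=self.markers, site_vocabulary=self.site_vocabulary
        )

    @property
    def n_patients(self) -> int:
        return self.data["patient_id"].nunique()

    @property
    def n_sites(self) -> int:
        """Distinct (patient, anatomic site) combinations."""
        return len(self.data[["patient_id", "site_label"]].drop_duplicates())

    @property
    def n_samples(self) -> int:
        return len(self.data[list(IDENTITY_COLUMNS)].drop_duplicates())

    def samples(self) -> Iterator[SampleRecord]:
        """Iterate over :class:`SampleRecord` views of the table."""
        for (pid, blk, smp), grp in self.data.groupby(list(IDENTITY_COLUMNS), sort=False):
            meas = {}
            for row in grp.itertuples(index=False):
                profile = (row.pct_level0, row.pct_level1, row.pct_level2)
                if all(pd.isna(v) for v in profile):
                    profile = None
                meas[row.marker] = {"h_score": row.h_score, "profile": profile}
            yield SampleRecord(
                patient_id=pid,
                site_label=grp["site_label"].iloc[0],
                block_id=blk,
                sample_id=smp,
                measurements=meas,
            )

    def equals(self, other: "Cohort") -> bool:
        """Field-by-field equality (NaN-aware) of data and metadata."""
        if self.markers != other.markers or self.site_vocabulary != other.site_vocabulary:
            return False
        a = self.data.sort_values(list(IDENTITY_COLUMNS) + ["marker"]).reset_index(drop=True)
        b = other.data.sort_values(list(IDENTITY_COLUMNS) + ["marker"]).reset_index(drop=True)
        if len(a) != len(b):
            return False
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False)
        except AssertionError:
            return False
        return True


def _validate_cohort_frame(
    df: pd.DataFrame,
    markers: Sequence[str],
    site_vocabulary: Sequence[str],
) -> pd.DataFrame:
    missing = [c for c in ("patient_id", "site_label", "block_id", "sample_id", "marker") if c not in df.columns]
    if missing:
        raise CohortFormatError(f"missing required column(s): {', '.join(missing)}")
    df = df.copy()
    for col in ("h_score",) + PROFILE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("patient_id", "site_label", "block_id", "sample_id", "marker"):
        df[col] = df[col].astype(str)
    df = df[list(COHORT_COLUMNS)]

    if len(df) == 0:
        raise CohortValidationError("cohort must contain at least one sample")

    unknown_markers = sorted(set(df["marker"]) - set(markers))
    if unknown_markers:
        raise CohortValidationError(
            f"undeclared marker(s): {', '.join(unknown_markers)}; declared: {', '.join(markers)}"
        )

    bad = df.index[(df["h_score"] < H_SCORE_MIN) | (df["h_score"] > H_SCORE_MAX)]
    if len(bad):
        raise CohortValidationError(
            f"h_score outside [{H_SCORE_MIN:g}, {H_SCORE_MAX:g}] at row index {bad[0]}"
            f" (value {df.loc[bad[0], 'h_score']!r})"
        )
    for col in PROFILE_COLUMNS:
        bad = df.index[(df[col] < 0) | (df[col] > 100)]
        if len(bad):
            raise CohortValidationError(
                f"{col} outside [0, 100] at row index {bad[0]} (value {df.loc[bad[0], col]!r})"
            )

    dup = df.duplicated(subset=list(IDENTITY_COLUMNS) + ["marker"])
    if dup.any():
        first = df.index[dup][0]
        key = tuple(df.loc[first, list(IDENTITY_COLUMNS) + ["marker"]])
        raise CohortValidationError(f"duplicate (patient, block, sample, marker) row: {key}")

    # sample_id unique within block, block within patient: implied by the
    # duplicate check above; site consistency per sample must hold though.
    sites_per_sample = df.groupby(list(IDENTITY_COLUMNS))["site_label"].nunique()
    if (sites_per_sample > 1).any():
        key = sites_per_sample.index[sites_per_sample > 1][0]
        raise CohortValidationError(f"sample {key} assigned to multiple site labels")

    unknown_sites = set(df["site_label"]) - set(site_vocabulary)
    if unknown_sites:
        warnings.warn(
            f"unknown site label(s) mapped to 'other': {', '.join(sorted(unknown_sites))}",
            stacklevel=3,
        )
        df.loc[df["site_label"].isin(unknown_sites), "site_label"] = "other"
    return df.reset_index(drop=True)


def read_cohort(
    path,
    format_config: Mapping[str, str] | None = None,
    markers: Sequence[str] = DEFAULT_MARKERS,
    site_vocabulary: Sequence[str] = DEFAULT_SITES,
) -> Cohort:
    """Read a long-format cohort CSV.

    Parameters
    ----------
    path
        CSV file with a header row (UTF-8).
    format_config
        Optional map from canonical column names (``patient_id`` ...) to the
        names used in the file.  A special key ``marker_columns`` may map
        wide-format H-score column names to marker names; those columns are
        melted into long format.
    """
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise CohortFormatError(f"could not parse {path}: {exc}") from exc

    format_config = dict(format_config or {})
    marker_columns = format_config.pop("marker_columns", None)
    if format_config:
        rename = {v: k for k, v in format_config.items()}
        df = df.rename(columns=rename)
    if marker_columns:
        missing = [c for c in marker_columns if c not in df.columns]
        if missing:
            raise CohortFormatError(f"missing wide marker column(s): {', '.join(missing)}")
        id_cols = [c for c in ("patient_id", "site_label", "block_id", "sample_id") if c in df.columns]
        df = df.melt(
            id_vars=id_cols,
            value_vars=list(marker_columns),
            var_name="marker",
            value_name="h_score",
        )
        df["marker"] = df["marker"].map(marker_columns)
    return Cohort(df, markers=tuple(markers), site_vocabulary=tuple(site_vocabulary))


def write_cohort(cohort: Cohort, path) -> None:
    """Write the cohort losslessly as a long-format CSV (canonical column order)."""
    cohort.data.to_csv(path, index=False, columns=list(COHORT_COLUMNS))


@dataclass
class GenomicsTable:
    """Per-patient gene alteration statuses.

    One row per (patient, gene); status one of ``WT``, ``ALT_MONOALLELIC``,
    ``ALT_BIALLELIC``, ``ALT_UNSPECIFIED``.
    """

    data: pd.DataFrame
    genes: tuple[str, ...] = DEFAULT_GENES

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in ("patient_id", "gene", "status") if c not in df.columns]
        if missing:
            raise CohortFormatError(f"genomics table missing column(s): {', '.join(missing)}")
        df["patient_id"] = df["patient_id"].astype(str)
        df["gene"] = df["gene"].astype(str)
        df["status"] = df["status"].astype(str).str.upper().str.strip()
        unknown = sorted(set(df["status"]) - set(GENOMICS_STATUSES))
        if unknown:
            raise CohortValidationError(
                f"unknown status token(s) {', '.join(unknown)}; allowed: {', '.join(GENOMICS_STATUSES)}"
            )
        bad_genes = sorted(set(df["gene"]) - set(self.genes))
        if bad_genes:
            raise CohortValidationError(
                f"gene(s) outside declared list: {', '.join(bad_genes)}; declared: {', '.join(self.genes)}"
            )
        dup = df.duplicated(subset=["patient_id", "gene"])
        if dup.any():
            first = df.index[dup][0]
            raise CohortValidationError(
                f"duplicate status for (patient, gene) = "
                f"({df.loc[first, 'patient_id']}, {df.loc[first, 'gene']})"
            )
        self.data = df[["patient_id", "gene", "status"]].reset_index(drop=True)

    def status_of(self, patient_id: str, gene: str) -> str | None:
        sel = self.data[(self.data["patient_id"] == patient_id) & (self.data["gene"] == gene)]
        return None if sel.empty else sel["status"].iloc[0]


def read_genomics(path, genes: Sequence[str] = DEFAULT_GENES) -> GenomicsTable:
    """Read a genomics CSV with columns (patient_id, gene, status)."""
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise CohortFormatError(f"could not parse {path}: {exc}") from exc
    return GenomicsTable(df, genes=tuple(genes))


def write_genomics(table: GenomicsTable, path) -> None:
    table.data.to_csv(path, index=False)
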