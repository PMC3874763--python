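"""Reading, normalising and cleaning metabolite profile tables.

A profile table holds GC-MS peak areas for a set of samples (rows) and
metabolite peaks (columns), together with per-sample metadata: the
experimental condition (e.g. normoxia / hypoxia), the cohort (e.g. cell
line) and whether the sample is a pooled quality-control (QC) injection.
Missing cells mean the metabolite was not detected in that sample; they
are carried as NaN and are never silently converted to zero (a zero peak
area is valid data).

Preprocessing follows the standard GC-MS profiling workflow:

1. division by an internal standard (here typically succinic acid-d4),
2. removal of metabolites whose coefficient of variation across pooled
   QC injections exceeds a threshold (default 30%),
3. single-pass replacement of statistical outliers (values more than
   ``k`` standard deviations from their condition x cohort group mean)
   by the mean of the remaining group members.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ProfileMatrix",
    "MetaboliteAnnotation",
    "QCFilterReport",
    "read_profile",
    "write_profile",
    "read_annotations",
    "normalise_internal_standard",
    "qc_cv_filter",
    "replace_outliers",
]

#: cell contents treated as missing on input (zeros are data, not missing)
DEFAULT_MISSING_TOKENS = ("", "NA", "NaN", "nan")


@dataclass
class ProfileMatrix:
    """Samples x metabolites peak-area matrix with group metadata.

    Parameters
    ----------
    values
        DataFrame indexed by sample id, one column per metabolite peak,
        float dtype, NaN for missing cells. All non-missing values must
        be >= 0.
    condition
        Per-sample condition tag (e.g. ``"normoxia"``). May be empty for
        QC samples only.
    cohort
        Per-sample cohort tag (e.g. cell line). May be empty for QC
        samples only.
    is_qc
        Per-sample boolean; QC samples are excluded from group statistics
        and carry no condition requirement.
    """

    values: pd.DataFrame
    condition: pd.Series
    cohort: pd.Series
    is_qc: pd.Series

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.has_duplicates:
            dupes = idx[idx.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if self.values.columns.has_duplicates:
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate metabolite ids: {dupes}")
        for name in ("condition", "cohort", "is_qc"):
            series = getattr(self, name)
            if not series.index.equals(idx):
                raise ValueError(f"{name} index does not match sample ids")
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValueError("negative peak areas are not allowed")
        non_qc = ~self.is_qc.astype(bool)
        missing_cond = self.condition[non_qc].isna() | (self.condition[non_qc] == "")
        if missing_cond.any():
            bad = missing_cond[missing_cond].index.tolist()
            raise ValueError(f"non-QC samples without a condition tag: {bad}")

    # -- convenience accessors -------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.values.columns)

    def group_mask(self, condition: str, cohort: str | None = None) -> pd.Series:
        """Boolean mask of non-QC samples in one condition (x cohort) cell."""
        mask = (~self.is_qc.astype(bool)) & (self.condition == condition)
        if cohort is not None:
            mask &= self.cohort.fillna("") == cohort
        return mask

    def group_values(self, condition: str, cohort: str | None = None) -> pd.DataFrame:
        return self.values.loc[self.group_mask(condition, cohort)]

    def groups(self) -> list[tuple[str, str]]:
        """All (condition, cohort) cells present among non-QC samples."""
        non_qc = ~self.is_qc.astype(bool)
        pairs = set(zip(self.condition[non_qc], self.cohort[non_qc].fillna("")))
        return sorted(pairs)

    def with_values(self, values: pd.DataFrame) -> "ProfileMatrix":
        return ProfileMatrix(
            values=values,
            condition=self.condition.copy(),
            cohort=self.cohort.copy(),
            is_qc=self.is_qc.copy(),
        )


@dataclass(frozen=True)
class MetaboliteAnnotation:
    """Identity assignment for one chromatographic peak.

    ``kegg_ids`` is ordered and may hold several candidates for
    multi-identity peaks ("Galactose/Glucose"), or be empty when no
    database identity was assigned.
    """

    metabolite_id: str
    display_name: str
    kegg_ids: tuple[str, ...] = ()
    pathway_label: str = ""


@dataclass
class QCFilterReport:
    """Per-metabolite CV-on-QC decisions from :func:`qc_cv_filter`."""

    table: pd.DataFrame  # columns: cv, kept
    threshold: float

    @property
    def removed(self) -> list[str]:
        return list(self.table.index[~self.table["kept"]])


def read_profile(
    path,
    *,
    sep: str = "\t",
    sample_col: str = "sample_id",
    condition_col: str = "condition",
    cohort_col: str = "cohort",
    qc_col: str = "is_qc",
    missing_tokens: tuple[str, ...] = DEFAULT_MISSING_TOKENS,
) -> ProfileMatrix:
    """Read a delimited profile table into a :class:`ProfileMatrix`.

    The table has one header row; metadata columns (sample id, condition,
    cohort, QC flag) are named via keyword arguments and every remaining
    column is taken as a metabolite peak. Empty cells and ``missing_tokens``
    become missing values, never zeros.
    """
    df = pd.read_csv(
        path,
        sep=sep,
        dtype=str,
        keep_default_na=False,
        na_values=list(missing_tokens),
    )
    for col in (sample_col, condition_col, qc_col):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r}")
    df = df.set_index(sample_col)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")

    condition = df[condition_col]
    cohort = df[cohort_col] if cohort_col in df.columns else pd.Series("", index=df.index)
    is_qc = df[qc_col].fillna("").str.strip().str.lower().isin({"1", "true", "yes", "qc"})

    meta_cols = [c for c in (condition_col, cohort_col, qc_col) if c in df.columns]
    raw = df.drop(columns=meta_cols)
    try:
        values = raw.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cell that is not a missing token: {exc}") from exc
    return ProfileMatrix(values=values, condition=condition, cohort=cohort, is_qc=is_qc)


def write_profile(p: ProfileMatrix, path, *, sep: str = "\t") -> None:
    """Write a profile matrix back to the delimited layout of :func:`read_profile`."""
    out = pd.DataFrame(
        {
            "condition": p.condition,
            "cohort": p.cohort,
            "is_qc": p.is_qc.astype(bool).map({True: "1", False: "0"}),
        },
        index=p.values.index,
    )
    out = pd.concat([out, p.values], axis=1)
    out.index.name = "sample_id"
    out.to_csv(path, sep=sep, na_rep="NA")


def read_annotations(path, *, sep: str = "\t") -> dict[str, MetaboliteAnnotation]:
    """Read a metabolite annotation table.

    Expected columns: ``metabolite_id``, ``name``, ``kegg_ids``
    (semicolon-separated candidate KEGG compound ids; empty or ``-`` for
    unassigned peaks) and ``pathway``.
    """
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = {"metabolite_id", "name", "kegg_ids"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    if df["metabolite_id"].duplicated().any():
        raise ValueError("duplicate metabolite_id in annotation table")
    out: dict[str, MetaboliteAnnotation] = {}
    for row in df.itertuples(index=False):
        raw = getattr(row, "kegg_ids", "").strip()
        kegg = tuple(k.strip() for k in raw.split(";") if k.strip() and k.strip() != "-")
        out[row.metabolite_id] = MetaboliteAnnotation(
            metabolite_id=row.metabolite_id,
            display_name=row.name,
            kegg_ids=kegg,
            pathway_label=getattr(row, "pathway", ""),
        )
    return out


def normalise_internal_standard(p: ProfileMatrix, standard_id: str) -> ProfileMatrix:
    """Divide every metabolite by the per-sample internal-standard peak area.

    The standard column is removed from the output. The standard must be
    present (non-missing, non-zero) in every sample.
    """
    if standard_id not in p.values.columns:
        raise ValueError(f"internal standard {standard_id!r} not in profile")
    std = p.values[standard_id]
    if std.isna().any():
        bad = std.index[std.isna()].tolist()
        raise ValueError(f"internal standard missing in samples: {bad}")
    if (std == 0).any():
        bad = std.index[std == 0].tolist()
        raise ValueError(f"internal standard is zero in samples: {bad}")
    values = p.values.drop(columns=[standard_id]).div(std, axis=0)
    return p.with_values(values)


def qc_cv_filter(
    p: ProfileMatrix, cv_max: float = 0.30
) -> tuple[ProfileMatrix, QCFilterReport]:
    """Remove metabolites whose CV across QC samples exceeds ``cv_max``.

    CV = sample standard deviation / mean over the QC injections
    (non-missing values). Metabolites with fewer than 2 non-missing QC
    values have undefined CV and are kept (reported as NaN). Retained
    values are never altered; only whole columns are dropped.
    """
    qc = p.values.loc[p.is_qc.astype(bool)]
    if len(qc) < 2:
        raise ValueError(f"need at least 2 QC samples, found {len(qc)}")
    mean = qc.mean(axis=0)
    zero_mean = (mean == 0) & (qc.notna().sum(axis=0) >= 2)
    if zero_mean.any():
        bad = list(mean.index[zero_mean])
        raise ValueError(f"QC mean of zero for metabolites: {bad}")
    sd = qc.std(axis=0, ddof=1)
    cv = sd / mean
    cv[qc.notna().sum(axis=0) < 2] = np.nan
    kept = cv.isna() | (cv <= cv_max)
    report = QCFilterReport(
        table=pd.DataFrame({"cv": cv, "kept": kept}), threshold=cv_max
    )
    filtered = p.with_values(p.values.loc[:, kept[kept].index])
    return filtered, report


def replace_outliers(
    p: ProfileMatrix, k: float = 3.0
) -> tuple[ProfileMatrix, int]:
    """Single-pass replacement of per-group statistical outliers.

    For every metabolite within every condition x cohort group of non-QC
    samples, values with ``|x - mean| > k * SD`` — mean and sample SD
    computed on the original group values — are replaced by the mean of
    the non-outlier group members. One pass only: means are never
    recomputed after a replacement, so the operation is reproducible but
    not idempotent by construction. Missing values are untouched.
    Groups with fewer than 3 non-missing values are skipped with a
    warning (their SD is unreliable).
    """
    values = p.values.copy()
    n_replaced = 0
    for condition, cohort in p.groups():
        mask = p.group_mask(condition, cohort)
        block = p.values.loc[mask]
        for met in block.columns:
            col = block[met]
            obs = col.dropna()
            if len(obs) < 3:
                warnings.warn(
                    f"group ({condition}, {cohort}) has {len(obs)} non-missing "
                    f"values for {met!r}; outlier screen skipped",
                    stacklevel=2,
                )
                continue
            mean, sd = obs.mean(), obs.std(ddof=1)
            if sd == 0:
                continue
            outlier = (obs - mean).abs() > k * sd
            if not outlier.any():
                continue
            keepers = obs[~outlier]
            if keepers.empty:  # pathological: everything flagged
                continue
            values.loc[outlier[outlier].index, met] = keepers.mean()
            n_replaced += int(outlier.sum())
    return p.with_values(values), n_replaced
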