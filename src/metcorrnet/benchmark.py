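"""Import recipe for the published supplementary GC-MS dataset.

The reference dataset ("GC-MS data after normalisation to internal
standard and filtering based on QCs") is distributed as a spreadsheet
with one sheet per cell line (MDA-MB-231, HCT116) and sample labels
beginning with N, H or A for the normoxia, hypoxia and anoxia
treatments. It is already internal-standard normalised and QC-filtered,
so reproducing the published differential correlations requires only
outlier replacement, pairwise correlation and the decision rule.

The workbook is not redistributable with this package; place it at
``data/benchmark/additional_file_1.xlsx`` (or pass an explicit path) to
run the reproduction.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .corrstats import ThresholdConfig, differential_correlations, pairwise_correlation_matrix
from .profiles import ProfileMatrix, replace_outliers

__all__ = ["DEFAULT_BENCHMARK_PATH", "load_benchmark_sheet", "run_benchmark"]

DEFAULT_BENCHMARK_PATH = Path("data/benchmark/additional_file_1.xlsx")

_LABEL = re.compile(r"^[NHA]\d*$", re.IGNORECASE)

_CONDITION = {"N": "normoxia", "H": "hypoxia", "A": "anoxia"}


def _looks_like_labels(values) -> float:
    vals = [str(v).strip() for v in values if str(v).strip() not in ("", "nan")]
    if not vals:
        return 0.0
    return sum(bool(_LABEL.match(v)) for v in vals) / len(vals)


def load_benchmark_sheet(path, sheet: str | int, cohort: str) -> ProfileMatrix:
    """Read one cell-line sheet into a :class:`ProfileMatrix`.

    Samples are recognised by their N/H/A labels; the sheet is
    transposed automatically if metabolites are stored as rows. Labels
    may repeat within a sheet (replicate numbering is added).
    """
    df = pd.read_excel(path, sheet_name=sheet, header=0, index_col=0)
    if _looks_like_labels(df.columns) > _looks_like_labels(df.index):
        df = df.T
    labels = [str(v).strip() for v in df.index]
    keep = [i for i, v in enumerate(labels) if _LABEL.match(v)]
    if not keep:
        raise ValueError(f"no N/H/A sample labels found in sheet {sheet!r}")
    df = df.iloc[keep]
    labels = [labels[i] for i in keep]
    sample_ids = [f"{cohort}_{lab}_{i}" for i, lab in enumerate(labels)]
    condition = [_CONDITION[lab[0].upper()] for lab in labels]
    values = df.apply(pd.to_numeric, errors="coerce")
    values.index = sample_ids
    values.columns = [str(c).strip() for c in values.columns]
    return ProfileMatrix(
        values=values,
        condition=pd.Series(condition, index=sample_ids),
        cohort=pd.Series(cohort, index=sample_ids),
        is_qc=pd.Series(False, index=sample_ids),
    )


def run_benchmark(
    path=DEFAULT_BENCHMARK_PATH,
    sheets: dict[str, str | int] | None = None,
    cfg: ThresholdConfig | None = None,
    mode: str = "paper",
):
    """Differential correlations (normoxia vs hypoxia) per cell line.

    Returns ``{cohort: list[DifferentialCorrelation]}`` after the
    standard outlier replacement. ``sheets`` maps cohort name to sheet
    name/index (default: first two sheets as MDA-MB-231 and HCT116).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"benchmark workbook not found at {path}; see module docstring "
            "for where to place the supplementary dataset"
        )
    if sheets is None:
        sheets = {"MDA-MB-231": 0, "HCT116": 1}
    cfg = cfg or ThresholdConfig()
    out = {}
    for cohort, sheet in sheets.items():
        profile = load_benchmark_sheet(path, sheet, cohort)
        cleaned, _ = replace_outliers(profile)
        m_n = pairwise_correlation_matrix(cleaned, "normoxia", cohort, cfg)
        m_h = pairwise_correlation_matrix(cleaned, "hypoxia", cohort, cfg)
        out[cohort] = differential_correlations(m_n, m_h, cfg, mode=mode)
    return out
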