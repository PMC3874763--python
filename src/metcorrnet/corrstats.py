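"""Correlation statistics for differential correlation analysis.

The machinery here implements the significance framework for comparing
pairwise Pearson correlations between two experimental conditions:

* Fisher z-transformation ``z = ½ ln((1+r)/(1−r))``, which approximately
  normalises the sampling distribution of r with standard error
  ``1/sqrt(N−3)``;
* the correlation significance threshold ``C_T = tanh(z_T / sqrt(N−3))``
  for a Gaussian quantile ``z_T``;
* the large-sample standard error ``SE = (1 − ρ²)/sqrt(n−1)`` used to fix
  a minimum sample size;
* the two-sample Fisher-z statistic
  ``(z_1 − z_2) / sqrt(1/(N_1−3) + 1/(N_2−3))`` from which the minimum
  detectable correlation difference is derived.

At the defaults used throughout (reference correlation 0.7, 27 complete
observations per group, two-sided 5% level) the decision rule for a
differentially correlated metabolite pair reads: one of the two
correlations must exceed 0.7 in magnitude and the correlations must
differ by more than 0.407.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import ProfileMatrix

__all__ = [
    "ThresholdConfig",
    "CorrelationEstimate",
    "CorrelationMatrix",
    "DifferentialCorrelation",
    "pearson",
    "fisher_z",
    "fisher_z_inverse",
    "correlation_threshold",
    "standard_error",
    "min_samples",
    "differential_threshold",
    "pairwise_correlation_matrix",
    "differential_correlations",
    "differential_table",
]


def pearson(x, y) -> float:
    """Pearson product-moment correlation on pairwise-complete observations.

    Pairs where either value is missing are dropped first. Raises
    ``ValueError`` when fewer than 3 complete pairs remain or when either
    vector has zero variance — callers building matrices catch this and
    flag the estimate invalid rather than propagating NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"only {x.size} complete pairs; need >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = stats.pearsonr(x, y).statistic
    return float(min(1.0, max(-1.0, r)))


def fisher_z(c: float) -> float:
    """Fisher z-transformation, ``½ ln((1+C)/(1−C)) = atanh(C)``."""
    if abs(c) >= 1:
        raise ValueError(f"|C| must be < 1, got {c}")
    return math.atanh(c)


def fisher_z_inverse(z: float) -> float:
    """Inverse Fisher transform, ``(e^{2z}−1)/(e^{2z}+1) = tanh(z)``."""
    return math.tanh(z)


def correlation_threshold(z_t: float, n: int) -> float:
    """Smallest correlation significant at Gaussian quantile ``z_t`` with ``n`` samples.

    ``C_T = tanh(z_t / sqrt(n − 3))``: the Fisher z of the observed r is
    compared against ``z_t`` after scaling by its standard error
    ``1/sqrt(n−3)``.
    """
    if n <= 3:
        raise ValueError(f"need n > 3, got {n}")
    return fisher_z_inverse(z_t / math.sqrt(n - 3))


def standard_error(rho: float, n: int) -> float:
    """Large-sample standard error of r, ``(1 − ρ²)/sqrt(n − 1)``."""
    if n < 2:
        raise ValueError(f"need n >= 2, got {n}")
    if abs(rho) > 1:
        raise ValueError(f"|rho| must be <= 1, got {rho}")
    return (1 - rho**2) / math.sqrt(n - 1)


def min_samples(
    rho: float, se_max: float, decimals: int | None = 4, n_max: int = 100_000
) -> int:
    """Smallest n whose standard error at ``rho`` does not exceed ``se_max``.

    ``decimals`` rounds the standard error before the comparison
    (default 4, under which SE(0.7, 27) = 0.100019 → 0.1000 passes and
    the answer is 27; with ``decimals=None`` the strict inequality gives
    28).
    """
    if not 0 <= rho < 1:
        raise ValueError(f"need 0 <= rho < 1, got {rho}")
    if se_max <= 0:
        raise ValueError("se_max must be positive")
    for n in range(4, n_max + 1):
        se = standard_error(rho, n)
        if decimals is not None:
            se = round(se, decimals)
        if se <= se_max:
            return n
    raise ValueError(f"no n <= {n_max} attains SE <= {se_max}")


def differential_threshold(c_ref: float, n1: int, n2: int, z_t: float) -> float:
    """Minimum correlation difference significant against a reference correlation.

    With ``z1 = atanh(c_ref)`` and
    ``z2 = z1 − z_t * sqrt(1/(n1−3) + 1/(n2−3))``, returns
    ``c_ref − tanh(z2)``: the smallest drop from ``c_ref`` that the
    two-sample Fisher-z statistic calls significant at quantile ``z_t``.
    At ``c_ref=0.7``, ``n1=n2=27``, ``z_t=1.959964`` this is 0.407.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("both group sizes must exceed 3")
    if not 0 < c_ref < 1:
        raise ValueError(f"need 0 < c_ref < 1, got {c_ref}")
    z1 = fisher_z(c_ref)
    z2 = z1 - z_t * math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    return c_ref - fisher_z_inverse(z2)


@dataclass
class ThresholdConfig:
    """All tunable constants of the differential-correlation decision.

    Defaults reproduce the reference analysis: two-sided 5% level
    (``z_T`` = 1.959964), a minimum of 27 complete observations per
    correlation (below which estimates are discarded), a reference
    correlation of 0.7 (chosen so its standard error at n=27 is ~0.1) and
    the implied minimum difference of 0.407.
    """

    alpha: float = 0.05
    min_n: int = 27
    r_ref: float = 0.7
    se_max: float = 0.1
    z_t: float | None = None  # two-sided normal quantile; derived from alpha if None
    min_diff: float | None = None  # derived from r_ref/min_n/z_t if None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.min_n < 4:
            raise ValueError("min_n must be >= 4")
        if not 0 < self.r_ref < 1:
            raise ValueError("r_ref must be in (0, 1)")
        if self.z_t is None:
            self.z_t = float(stats.norm.ppf(1 - self.alpha / 2))
        if self.min_diff is None:
            self.min_diff = round(
                differential_threshold(self.r_ref, self.min_n, self.min_n, self.z_t), 3
            )


@dataclass(frozen=True)
class CorrelationEstimate:
    pair: tuple[str, str]
    r: float | None
    n_complete: int
    valid: bool


@dataclass
class CorrelationMatrix:
    """Symmetric pairwise Pearson estimates for one sample group.

    ``r`` holds the coefficients (NaN where undefined), ``n`` the
    pairwise-complete observation counts and ``valid`` whether the
    estimate is usable downstream (defined and ``n >= min_n``).
    """

    r: pd.DataFrame
    n: pd.DataFrame
    valid: pd.DataFrame
    group: tuple[str, str]

    def __post_init__(self) -> None:
        ids = list(self.r.index)
        for name in ("r", "n", "valid"):
            df = getattr(self, name)
            if list(df.index) != ids or list(df.columns) != ids:
                raise ValueError(f"{name} is not square/aligned")
        rv = self.r.to_numpy(dtype=float)
        if not np.allclose(rv, rv.T, equal_nan=True):
            raise ValueError("correlation matrix not symmetric")

    @property
    def metabolite_ids(self) -> list[str]:
        return list(self.r.index)

    def estimate(self, a: str, b: str) -> CorrelationEstimate:
        r = self.r.at[a, b]
        return CorrelationEstimate(
            pair=(a, b),
            r=None if pd.isna(r) else float(r),
            n_complete=int(self.n.at[a, b]),
            valid=bool(self.valid.at[a, b]),
        )


def pairwise_correlation_matrix(
    p: ProfileMatrix,
    condition: str,
    cohort: str | None = None,
    cfg: ThresholdConfig | None = None,
) -> CorrelationMatrix:
    """All-pairs Pearson correlations within one sample group.

    Every pair is computed on its pairwise-complete observations; pairs
    with fewer than ``cfg.min_n`` complete observations (or undefined
    correlation) are marked invalid — matching the rule that correlations
    built on fewer than 27 entries are discarded.
    """
    cfg = cfg or ThresholdConfig()
    block = p.group_values(condition, cohort)
    if block.empty:
        raise ValueError(f"no samples in group ({condition}, {cohort})")
    if len(block) < cfg.min_n:
        warnings.warn(
            f"group ({condition}, {cohort}) has {len(block)} samples "
            f"< min_n={cfg.min_n}; all pairs will be invalid",
            stacklevel=2,
        )
    # pairwise-complete Pearson; min_periods=3 leaves short pairs NaN
    r = block.corr(method="pearson", min_periods=3)
    present = block.notna().astype(int)
    n = pd.DataFrame(
        present.T.to_numpy() @ present.to_numpy(),
        index=block.columns,
        columns=block.columns,
    )
    np.fill_diagonal(r.values, 1.0)
    valid = r.notna() & (n >= cfg.min_n)
    return CorrelationMatrix(r=r, n=n, valid=valid, group=(condition, cohort or ""))


@dataclass(frozen=True)
class DifferentialCorrelation:
    """One metabolite pair compared between two conditions."""

    pair: tuple[str, str]
    r_a: float
    r_b: float
    n_a: int
    n_b: int
    passes_magnitude: bool
    passes_difference: bool
    significant: bool

    @property
    def diff(self) -> float:
        return abs(self.r_a - self.r_b)


def _decide(
    r_a: float, r_b: float, n_a: int, n_b: int, cfg: ThresholdConfig, mode: str
) -> tuple[bool, bool, bool]:
    if mode == "paper":
        mag = max(abs(r_a), abs(r_b)) > cfg.r_ref
        diff = abs(r_a - r_b) > cfg.min_diff
        return mag, diff, mag and diff
    if mode == "exact":
        z_stat = abs(fisher_z(r_a) - fisher_z(r_b)) / math.sqrt(
            1 / (n_a - 3) + 1 / (n_b - 3)
        )
        mag = max(abs(r_a), abs(r_b)) > cfg.r_ref
        sig = mag and z_stat > cfg.z_t
        return mag, z_stat > cfg.z_t, sig
    raise ValueError(f"unknown mode {mode!r}; expected 'paper' or 'exact'")


def differential_correlations(
    m_a: CorrelationMatrix,
    m_b: CorrelationMatrix,
    cfg: ThresholdConfig | None = None,
    mode: str = "paper",
    significant_only: bool = True,
) -> list[DifferentialCorrelation]:
    """Metabolite pairs whose correlation differs between two groups.

    Both estimates must be valid for a pair to be testable. In ``paper``
    mode a pair is significant when one correlation exceeds ``r_ref`` in
    magnitude and the correlations differ by more than ``min_diff``; in
    ``exact`` mode the magnitude gate is combined with the two-sample
    Fisher-z statistic tested against ``z_t`` at the pair's own sample
    sizes. Results are sorted by descending difference, ties broken by
    the metabolite-id pair.
    """
    cfg = cfg or ThresholdConfig()
    if m_a.metabolite_ids != m_b.metabolite_ids:
        raise ValueError("correlation matrices cover different metabolite sets")
    out: list[DifferentialCorrelation] = []
    for a, b in combinations(m_a.metabolite_ids, 2):
        if not (m_a.valid.at[a, b] and m_b.valid.at[a, b]):
            continue
        r_a, r_b = float(m_a.r.at[a, b]), float(m_b.r.at[a, b])
        n_a, n_b = int(m_a.n.at[a, b]), int(m_b.n.at[a, b])
        mag, diff_ok, sig = _decide(r_a, r_b, n_a, n_b, cfg, mode)
        if significant_only and not sig:
            continue
        out.append(
            DifferentialCorrelation(
                pair=(a, b),
                r_a=r_a,
                r_b=r_b,
                n_a=n_a,
                n_b=n_b,
                passes_magnitude=mag,
                passes_difference=diff_ok,
                significant=sig,
            )
        )
    out.sort(key=lambda d: (-d.diff, d.pair))
    return out


def differential_table(
    diffs: list[DifferentialCorrelation], mode: str = "paper"
) -> pd.DataFrame:
    """Tabular form of differential-correlation records for TSV export."""
    rows = [
        {
            "metabolite_a": d.pair[0],
            "metabolite_b": d.pair[1],
            "r_A": d.r_a,
            "n_A": d.n_a,
            "r_B": d.r_b,
            "n_B": d.n_b,
            "diff": d.diff,
            "significant": d.significant,
            "mode": mode,
        }
        for d in diffs
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "metabolite_a",
            "metabolite_b",
            "r_A",
            "n_A",
            "r_B",
            "n_B",
            "diff",
            "significant",
            "mode",
        ],
    )
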