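"""Epiallele quantification: pattern tables, k-of-n distributions, summaries.

All statistics here operate on the *eligible* reads of one sample x
amplicon x replicate stratum: calls that passed QC and whose pattern is
N-free, so every denominator is well defined. The headline statistic of
the TSDR assay is the Treg-like fraction — the percentage of reads with
at least ``min_k`` of n CpG sites demethylated (8-of-9 at FOXP3;
all-7-of-7 at CTLA4) — reported across PCR replicates as median with
range. Because the FOXP3 TSDR is X-linked and demethylated on only the
active X, female samples run at half dosage; an explicit x2 adjustment
is provided to put female estimates on the male scale.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ampmeth.calling import MethylationCall


def eligible_calls(calls: Iterable[MethylationCall]) -> list[MethylationCall]:
    """Passed, N-free calls — the denominator of every frequency here."""
    return [c for c in calls if c.passed and "N" not in c.pattern]


def pattern_frequencies(calls: Iterable[MethylationCall]) -> pd.DataFrame:
    """Count and percentage of every distinct epiallele pattern.

    One row per observed M/U pattern with columns ``pattern``, ``count``,
    ``frequency`` (percent of eligible reads; sums to 100). Rows are
    ordered by descending count, ties broken lexicographically by
    pattern. An empty input yields an empty table with a warning.
    """
    elig = eligible_calls(calls)
    if not elig:
        warnings.warn("pattern_frequencies: no eligible reads", stacklevel=2)
        return pd.DataFrame(columns=["pattern", "count", "frequency"])
    counts = Counter(c.pattern for c in elig)
    total = sum(counts.values())
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {
            "pattern": [p for p, _ in rows],
            "count": [c for _, c in rows],
            "frequency": [100.0 * c / total for _, c in rows],
        }
    )


def k_distribution(calls: Iterable[MethylationCall], n_sites: int | None = None) -> np.ndarray:
    """Fraction of reads with exactly k demethylated sites, k = 0..n.

    Returns a length ``n+1`` vector summing to 1. ``n_sites`` defaults to
    the pattern length of the first eligible call.
    """
    elig = eligible_calls(calls)
    if not elig:
        warnings.warn("k_distribution: no eligible reads", stacklevel=2)
        if n_sites is None:
            return np.array([])
        return np.zeros(n_sites + 1)
    n = len(elig[0].pattern) if n_sites is None else n_sites
    vec = np.zeros(n + 1)
    for c in elig:
        vec[c.k_demethylated] += 1
    return vec / len(elig)


def treg_like_fraction(calls: Iterable[MethylationCall], min_k: int) -> float:
    """Percentage of eligible reads demethylated at >= ``min_k`` sites.

    The assay's Treg enumeration statistic: with ``min_k = n - 1`` at a
    nine-site TSDR amplicon this is the "eight or nine of nine sites
    demethylated" readout; with ``min_k = n`` it requires complete
    demethylation (the CTLA4 convention).
    """
    elig = eligible_calls(calls)
    if not elig:
        warnings.warn("treg_like_fraction: no eligible reads", stacklevel=2)
        return float("nan")
    return 100.0 * sum(c.k_demethylated >= min_k for c in elig) / len(elig)


def intermediate_fraction(calls: Iterable[MethylationCall], k_set: Iterable[int]) -> float:
    """Percentage of eligible reads whose demethylated-site count is in ``k_set``.

    Used e.g. to bin partially demethylated epialleles (3T-6T on a
    seven-site amplicon) separately from the fully methylated and fully
    demethylated classes.
    """
    k_set = frozenset(k_set)
    elig = eligible_calls(calls)
    if not elig:
        warnings.warn("intermediate_fraction: no eligible reads", stacklevel=2)
        return float("nan")
    return 100.0 * sum(c.k_demethylated in k_set for c in elig) / len(elig)


@dataclass
class ReplicateSummary:
    """Median-with-range of one statistic across PCR replicates."""

    statistic: str
    median: float
    minimum: float
    maximum: float
    n_replicates: int


def replicate_summary(statistic: str, values: Sequence[float]) -> ReplicateSummary:
    """Median (midpoint of the central pair for even counts), min and max."""
    if len(values) == 0:
        raise ValueError("replicate_summary: no replicate values")
    arr = np.asarray(values, dtype=float)
    return ReplicateSummary(
        statistic=statistic,
        median=float(np.median(arr)),
        minimum=float(arr.min()),
        maximum=float(arr.max()),
        n_replicates=len(values),
    )


@dataclass
class RegressionResult:
    """OLS fit of estimated vs true mixture fraction."""

    slope: float
    intercept: float
    r_squared: float


def mixture_regression(
    known_fractions: Sequence[float], estimated_demethylation: Sequence[float]
) -> RegressionResult:
    """Ordinary least squares of the pipeline estimate on the known truth.

    Used for titration series (defined Treg / naive mixtures): a
    well-behaved assay gives slope ~1 and r-squared >= 0.99. r-squared is
    the coefficient of determination; a zero-variance response is
    degenerate and returns r_squared = 0 with a warning.
    """
    x = np.asarray(known_fractions, dtype=float)
    y = np.asarray(estimated_demethylation, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("mixture_regression needs equal-length inputs with >= 3 points")
    if np.ptp(y) == 0.0:
        warnings.warn("mixture_regression: zero-variance response; r^2 set to 0", stacklevel=2)
        return RegressionResult(slope=0.0, intercept=float(y.mean()), r_squared=0.0)
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
    )


def sex_adjusted_treg_estimate(
    demethylated_fraction: float, sex: str, factor: float = 2.0
) -> float:
    """Put a TSDR demethylated fraction on the male (single-dose) scale.

    FOXP3 is X-linked and the TSDR is demethylated only on the active X,
    so a pure female Treg population still shows ~50% demethylated
    molecules. Female estimates are multiplied by ``factor`` (default 2)
    and capped at 1; male estimates pass through unchanged.
    """
    if not 0.0 <= demethylated_fraction <= 1.0:
        raise ValueError("demethylated_fraction must be in [0, 1]")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    if sex == "male":
        return demethylated_fraction
    return min(1.0, factor * demethylated_fraction)
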