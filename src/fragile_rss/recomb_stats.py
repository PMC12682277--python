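"""Recombination-frequency statistics for the episomal colony assay.

The assay transforms recovered episomes into bacteria and counts colonies on
double selection (chloramphenicol + ampicillin, "CA": recombined substrate)
versus single selection (ampicillin, "A": all recovered substrate).  The
recombination frequency is ``CA / A * 100`` percent.  Because CA counts are
tiny (often 0–5), intervals are exact binomial (Clopper–Pearson) rather than
normal-approximation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class ColonyCount:
    condition: str
    ca: int
    a: int
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.ca < 0:
            raise ValueError("CA count must be >= 0")
        if self.ca > self.a > 0:
            warnings.warn(
                f"{self.condition}: CA ({self.ca}) exceeds A ({self.a}); "
                "frequency will exceed 100%"
            )


@dataclass(frozen=True)
class FrequencyEstimate:
    frequency: float  # percent
    ci_low: float
    ci_high: float
    n_replicates: int = 1


class UndefinedFrequencyError(ZeroDivisionError):
    pass


def clopper_pearson(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for a proportion (as a fraction)."""
    alpha = 1.0 - confidence
    low = 0.0 if k == 0 else stats.beta.ppf(alpha / 2, k, n - k + 1)
    high = 1.0 if k == n else stats.beta.ppf(1 - alpha / 2, k + 1, n - k)
    return float(low), float(high)


def recombination_frequency(count: ColonyCount, confidence: float = 0.95) -> FrequencyEstimate:
    """Percent recombination frequency ``CA / A * 100`` with an exact
    binomial 95% interval."""
    if count.a <= 0:
        raise UndefinedFrequencyError(
            f"{count.condition}: no Amp-resistant colonies, frequency undefined"
        )
    f = count.ca / count.a * 100.0
    low, high = clopper_pearson(count.ca, count.a, confidence)
    return FrequencyEstimate(f, low * 100.0, high * 100.0, 1)


def fold_change(f_num: float, f_den: float) -> float:
    """Ratio of two frequencies (same units).  A zero denominator — a
    condition yielding no recombinants — is reported as ``inf`` with a
    warning rather than an error."""
    if f_num < 0 or f_den < 0:
        raise ValueError("frequencies must be non-negative")
    if f_den == 0:
        warnings.warn("zero denominator frequency: fold change reported as infinite")
        return math.inf
    return f_num / f_den


STAR_THRESHOLDS = ((0.0001, "***"), (0.005, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    stars: str
    df: float


def compare_replicates(
    group1: Sequence[float], group2: Sequence[float], welch: bool = False
) -> TTestResult:
    """Unpaired two-sample Student's t test (pooled variance by default,
    Welch via flag) with the assay's star convention:
    ``*`` p<0.05, ``**`` p<0.005, ``***`` p<0.0001, else ``ns``.

    Two identical-mean groups with zero pooled variance are reported as
    t=0, p=1 by convention.
    """
    x, y = np.asarray(group1, float), np.asarray(group2, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 replicates")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0 and np.mean(x) == np.mean(y):
        df = len(x) + len(y) - 2
        return TTestResult(0.0, 1.0, "ns", float(df))
    res = stats.ttest_ind(x, y, equal_var=not welch)
    return TTestResult(float(res.statistic), float(res.pvalue), significance_stars(res.pvalue), float(res.df))


def frequency_table(counts: Sequence[ColonyCount]):
    """Per-row frequency estimates as a pandas DataFrame."""
    import pandas as pd

    rows = []
    for c in counts:
        est = recombination_frequency(c)
        rows.append(
            (c.condition, c.replicate, c.ca, c.a, est.frequency, est.ci_low, est.ci_high)
        )
    return pd.DataFrame(
        rows,
        columns=["condition", "replicate", "CA", "A", "f_percent", "ci_low", "ci_high"],
    )
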