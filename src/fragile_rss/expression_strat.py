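"""Two-gene percentile stratification of a cohort expression matrix.

Samples are classified per gene as Low (< 25th percentile), Medium
(25th–75th, boundaries inclusive per the strict </> cutoff wording) or High
(> 75th percentile) on log2(x+1)-transformed FPKM/RPKM values, yielding nine
combined groups (e.g. ``R1H/R2M``).  Quantiles use linear interpolation
between order statistics (numpy's default, the "type 7" convention); since
quantile classification depends only on ranks, any strictly increasing
transform of the values yields identical labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

CLASSES = ("L", "M", "H")
#: the nine combined labels, gene-1 class varying slowest
COMBINED_LABELS = tuple(f"R1{a}/R2{b}" for a in CLASSES for b in CLASSES)


@dataclass(frozen=True)
class StratificationThresholds:
    q25: float
    q75: float

    def __post_init__(self) -> None:
        if self.q25 > self.q75:
            raise ValueError("q25 must be <= q75")

    def classify(self, value: float) -> str:
        if value < self.q25:
            return "L"
        if value > self.q75:
            return "H"
        return "M"


@dataclass(frozen=True)
class StratumLabel:
    sample_id: str
    gene1_class: str
    gene2_class: str

    @property
    def combined(self) -> str:
        return f"R1{self.gene1_class}/R2{self.gene2_class}"


def percentile_thresholds(values: Sequence[float]) -> StratificationThresholds:
    """25th/75th percentile cutoffs of a (transformed) expression vector."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot compute thresholds on an empty vector")
    q25, q75 = np.quantile(v, [0.25, 0.75])  # linear interpolation (type 7)
    return StratificationThresholds(float(q25), float(q75))


def log_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """log2(x + 1) on a genes-by-samples matrix of non-negative values."""
    if (matrix.values < 0).any():
        raise ValueError("expression values must be non-negative before log2(x+1)")
    return np.log2(matrix + 1.0)


def stratify_cohort(
    matrix: pd.DataFrame,
    genes: tuple[str, str] = ("RAG1", "RAG2"),
    log_transformed: bool = False,
) -> list[StratumLabel]:
    """Per-sample Low/Medium/High call for each of two genes.

    ``matrix`` is genes-by-samples; the log2(x+1) transform is applied
    unless ``log_transformed`` says it already was.  Thresholds are computed
    per gene across the cohort.
    """
    for g in genes:
        if g not in matrix.index:
            raise KeyError(f"gene {g!r} not in matrix")
    if matrix.columns.duplicated().any():
        raise ValueError("sample ids must be unique")
    sub = matrix.loc[list(genes)]
    if not log_transformed:
        sub = log_transform(sub)
    th1 = percentile_thresholds(sub.loc[genes[0]].values)
    th2 = percentile_thresholds(sub.loc[genes[1]].values)
    return [
        StratumLabel(str(s), th1.classify(sub.at[genes[0], s]), th2.classify(sub.at[genes[1], s]))
        for s in sub.columns
    ]


def group_counts(labels: Sequence[StratumLabel]) -> dict[str, int]:
    """Counts over all nine combined groups (absent groups reported as 0)."""
    counts = {lab: 0 for lab in COMBINED_LABELS}
    for label in labels:
        counts[label.combined] += 1
    return counts


def labels_to_table(labels: Sequence[StratumLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.sample_id, l.gene1_class, l.gene2_class, l.combined) for l in labels],
        columns=["sample_id", "gene1_class", "gene2_class", "group"],
    )
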