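"""Per-cell aggregation and condition-level comparison.

The headline statistic is the per-cell fraction of cytoplasmic mRNAs
classified as associated with SunTag signal.  Cells contribute only if they
hold more than five and fewer than 36 mRNAs (6 <= n <= 35); conditions are
summarized by the mean fraction with its standard error, and compared by a
two-sided two-sample t-test (Welch by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .quantify import TranslationSite

CELL_MIN_MRNA = 6   # "more than five"
CELL_MAX_MRNA = 35  # "fewer than 36"


@dataclass
class CellStats:
    cell_id: str
    condition: str
    n_mrna: int
    n_associated: int
    fraction: float  # NaN when n_mrna == 0
    included: bool


@dataclass
class ConditionSummary:
    condition: str
    n_cells: int
    mean_fraction: float
    sem_fraction: float


def cell_inclusion(n_mrna: int) -> bool:
    """More than five and fewer than 36 mRNAs."""
    return CELL_MIN_MRNA <= n_mrna <= CELL_MAX_MRNA


def cell_summary(sites: list[TranslationSite], cell_id: str, condition: str) -> CellStats:
    """Counts, colocalized fraction and inclusion flag for one cell."""
    n = len(sites)
    n_assoc = sum(1 for s in sites if s.associated)
    fraction = n_assoc / n if n > 0 else float("nan")
    return CellStats(
        cell_id=cell_id,
        condition=condition,
        n_mrna=n,
        n_associated=n_assoc,
        fraction=fraction,
        included=cell_inclusion(n) if n > 0 else False,
    )


def condition_summary(cells: list[CellStats]) -> ConditionSummary:
    """Mean fraction with SEM over the included cells of one condition."""
    included = [c for c in cells if c.included]
    if len(included) < 2:
        raise ValueError(f"need >= 2 included cells for a summary; got {len(included)}")
    conditions = {c.condition for c in included}
    if len(conditions) != 1:
        raise ValueError("cells span multiple conditions")
    fr = np.array([c.fraction for c in included])
    return ConditionSummary(
        condition=included[0].condition,
        n_cells=len(included),
        mean_fraction=float(fr.mean()),
        sem_fraction=float(fr.std(ddof=1) / np.sqrt(len(fr))),
    )


def two_sample_ttest(
    a: "list[float] | np.ndarray",
    b: "list[float] | np.ndarray",
    equal_var: bool = False,
) -> tuple[float, float]:
    """Two-sided two-sample t-test; Welch (unequal variances) by default.

    Degenerate samples (zero variance in both) return p = 1 for equal means
    and raise otherwise, so constant inputs never produce a silent NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both samples with unequal means")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)
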