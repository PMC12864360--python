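"""Between-subject scoring: z-scores, kurtosis, correlation, accuracy summaries."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError
from .models import PerformanceProfile
from .options import ALL_OPTIONS

__all__ = [
    "zscores",
    "excess_kurtosis",
    "pearson",
    "reverse_demand_scale",
    "accuracy_summary",
]


def zscores(values: Sequence[float]) -> np.ndarray:
    """Standardize against the between-subject mean and sample (n-1) SD."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("z-scores need at least two values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("z-scores undefined for zero spread")
    return (x - x.mean()) / sd


def excess_kurtosis(values: Sequence[float]) -> float:
    """Fisher (excess) kurtosis, population-moment estimator; normal -> 0."""
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise DegenerateInputError("kurtosis needs at least four values")
    return float(stats.kurtosis(x, fisher=True, bias=True))


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise DegenerateInputError("correlation needs at least three pairs")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("correlation undefined for zero spread")
    return float(stats.pearsonr(x, y).statistic)


def reverse_demand_scale(z):
    """Flip the demand-phase z scale so both phases read in the same direction."""
    return -np.asarray(z, dtype=float) if np.ndim(z) else -z


def accuracy_summary(profiles: Iterable[PerformanceProfile]) -> pd.DataFrame:
    """Per-option mean accuracy and standard error across a cohort.

    SE is sample SD / sqrt(n); reported as NaN when n < 2 (flagged by the
    ``n`` column).
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    rows = []
    for opt in ALL_OPTIONS:
        acc = np.array([p[opt] for p in profiles], dtype=float)
        n = acc.size
        se = float(acc.std(ddof=1) / np.sqrt(n)) if n >= 2 else float("nan")
        rows.append(
            {
                "option": opt.key,
                "task": opt.task.value,
                "level": opt.level.value,
                "mean": float(acc.mean()),
                "se": se,
                "n": n,
            }
        )
    return pd.DataFrame(rows)
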