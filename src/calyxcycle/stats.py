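"""Per-cell aggregation (mean ± SEM), Student's t tests, and the
depression-ratio comparison of per-pulse capacitance and fluorescence jumps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .capacitance import JumpSeries

__all__ = ["GroupSummary", "mean_sem", "t_test", "depression_ratio"]


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sem: float
    values: np.ndarray

    def __str__(self) -> str:
        return f"{self.label}: {self.mean:.3g} ± {self.sem:.3g} (n={self.n})"


def mean_sem(values, label: str = "") -> GroupSummary:
    """Sample mean and standard error (sd with n-1 denominator)."""
    values = np.asarray(values, float)
    if values.size == 0:
        raise ValueError("mean_sem needs at least one value")
    sem = float(values.std(ddof=1) / np.sqrt(values.size)) if values.size > 1 else 0.0
    return GroupSummary(label, int(values.size), float(values.mean()), sem, values)


def t_test(a, b, paired: bool = False, welch: bool = False) -> tuple[float, float]:
    """Two-sided Student's t test; pooled variance for unpaired groups.

    ``welch=True`` drops the equal-variance assumption.  Returns (t, p);
    identical groups give t = 0, p = 1, and a fully degenerate comparison
    (zero variance, different means) raises.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test needs equal group sizes")
        d = a - b
        if d.std(ddof=1) == 0:
            if np.allclose(d, 0):
                return 0.0, 1.0
            raise ValueError("degenerate variance: constant non-zero differences")
        t, p = sps.ttest_rel(a, b)
    else:
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            if a.mean() == b.mean():
                return 0.0, 1.0
            raise ValueError("degenerate variance: both groups constant")
        t, p = sps.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def depression_ratio(jumps: JumpSeries | np.ndarray, dFs) -> np.ndarray:
    """Elementwise normalized-dCm / normalized-dF per stimulus.

    Both series must be first-normalized (first element 1); a ratio of 1
    throughout means membrane and reporter exocytosis depress together.
    """
    cm_norm = jumps.normalized if isinstance(jumps, JumpSeries) else np.asarray(jumps, float)
    d_f = np.asarray(dFs, float)
    if cm_norm.size != d_f.size or cm_norm.size < 2:
        raise ValueError("need equal-length series with at least 2 stimuli")
    if np.any(d_f == 0):
        raise ValueError("zero deltaF: ratio undefined")
    return cm_norm / d_f
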