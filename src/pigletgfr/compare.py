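"""Age and technique comparisons of log-transformed GFR.

Within each measurement technique, the effect of age is tested by one-way
ANOVA across age groups on log GFR, followed by pairwise two-sample
t-tests with Bonferroni adjustment (multiplier = number of pairs).
Within each age, the three techniques are compared by within-subject
paired t-tests on log GFR, Bonferroni multiplier 3.  These paired
contrasts preserve the estimable quantities of a repeated-measures
analysis (which pairs of techniques differ) without its full mixed-model
machinery.  All contrasts are invariant to the logarithm base.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError

ALPHA = 0.05


@dataclass(frozen=True)
class Contrast:
    level_a: str
    level_b: str
    estimate: float  # difference of mean log GFR, a - b
    raw_p: float
    adjusted_p: float
    significant: bool

    def __post_init__(self) -> None:
        if self.adjusted_p < self.raw_p - 1e-12:
            raise DomainError("Bonferroni adjustment cannot decrease a p-value")


@dataclass(frozen=True)
class ComparisonTable:
    factor: str  # age_within_technique | technique_within_age
    label: str  # the technique or age the table conditions on
    anova_f: float | None
    anova_p: float | None
    contrasts: tuple[Contrast, ...] = ()
    degenerate: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "factor": self.factor,
                "label": self.label,
                "level_a": c.level_a,
                "level_b": c.level_b,
                "estimate": c.estimate,
                "raw_p": c.raw_p,
                "adjusted_p": c.adjusted_p,
                "significant": c.significant,
            }
            for c in self.contrasts
        ]
        return pd.DataFrame(rows)


def bonferroni(raw_p: float, n_comparisons: int) -> float:
    """Multiply by the number of comparisons, capped at 1."""
    if n_comparisons < 1:
        raise DomainError("need at least one comparison")
    return min(1.0, raw_p * n_comparisons)


def _log(values: np.ndarray, base: float) -> np.ndarray:
    if np.any(values <= 0):
        raise DomainError("GFR values must be positive for the log transform")
    return np.log10(values) if base == 10.0 else np.log(values) / math.log(base)


def anova_age_within_technique(
    gfr: pd.DataFrame, technique: str, value_col: str, log_base: float = 10.0
) -> ComparisonTable:
    """One-way ANOVA of log GFR across ages, plus Bonferroni pairwise t-tests.

    ``gfr`` needs columns age_days, technique and ``value_col``.  With no
    within-group variance anywhere the F statistic is undefined and the
    table is flagged degenerate.
    """
    sub = gfr[gfr["technique"] == technique]
    groups = {age: _log(g[value_col].to_numpy(dtype=float), log_base)
              for age, g in sub.groupby("age_days")}
    if len(groups) < 2:
        raise DomainError("need at least two age groups")
    if any(len(v) < 2 for v in groups.values()):
        raise DomainError("each age group needs at least two subjects")
    arrays = list(groups.values())
    if all(np.ptp(a) == 0 for a in arrays):
        return ComparisonTable(
            factor="age_within_technique",
            label=technique,
            anova_f=None,
            anova_p=None,
            degenerate=True,
        )
    f_stat, f_p = stats.f_oneway(*arrays)
    pairs = list(combinations(sorted(groups), 2))
    contrasts = []
    for a, b in pairs:
        res = stats.ttest_ind(groups[a], groups[b])
        raw = float(res.pvalue)
        if math.isnan(raw):  # both groups constant and equal
            raw = 1.0
        adj = bonferroni(raw, len(pairs))
        contrasts.append(
            Contrast(
                level_a=f"{a}d",
                level_b=f"{b}d",
                estimate=float(np.mean(groups[a]) - np.mean(groups[b])),
                raw_p=raw,
                adjusted_p=adj,
                significant=adj < ALPHA,
            )
        )
    return ComparisonTable(
        factor="age_within_technique",
        label=technique,
        anova_f=float(f_stat),
        anova_p=float(f_p),
        contrasts=tuple(contrasts),
    )


def paired_technique_within_age(
    gfr: pd.DataFrame, age_days: int, value_col: str, log_base: float = 10.0
) -> ComparisonTable:
    """Within-subject paired t-tests between techniques at one age.

    Subjects missing any technique are dropped with a warning.  A
    zero-variance nonzero paired difference is an exact separation
    (p -> 0); a zero difference everywhere gives p = 1.
    """
    sub = gfr[gfr["age_days"] == age_days]
    wide = sub.pivot_table(index="subject_id", columns="technique", values=value_col)
    techniques = sorted(wide.columns)
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        warnings.warn(
            f"{dropped} subject(s) missing a technique at age {age_days}d dropped",
            stacklevel=2,
        )
    if len(complete) < 2:
        raise DomainError("need at least two complete subjects for paired contrasts")
    pairs = list(combinations(techniques, 2))
    contrasts = []
    for a, b in pairs:
        da = _log(complete[a].to_numpy(dtype=float), log_base)
        db = _log(complete[b].to_numpy(dtype=float), log_base)
        diff = da - db
        if np.ptp(diff) == 0:
            raw = 1.0 if diff[0] == 0 else 0.0
        else:
            raw = float(stats.ttest_rel(da, db).pvalue)
        adj = bonferroni(raw, len(pairs))
        contrasts.append(
            Contrast(
                level_a=a,
                level_b=b,
                estimate=float(np.mean(diff)),
                raw_p=raw,
                adjusted_p=adj,
                significant=adj < ALPHA,
            )
        )
    return ComparisonTable(
        factor="technique_within_age",
        label=f"{age_days}d",
        anova_f=None,
        anova_p=None,
        contrasts=tuple(contrasts),
    )
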