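"""Clearance normalization: indexing to bodyweight, surface area, kidney weight.

Absolute clearances (mL/min) are divided by the subject's bodyweight (kg),
body surface area (m^2) and kidney weight (g) to give comparable indexed
values across body sizes, and groups are summarized as mean +/- sample SD
per age and measurement technique.  No standardization to the human
1.73 m^2 reference surface is applied by default; a flag emits it for
cross-species tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import SubjectRecord
from .errors import DomainError

TECHNIQUES = ("jaffe", "enzymatic", "exo_iohexol")
HUMAN_BSA_M2 = 1.73

INDEX_COLUMNS = ("per_bw_ml_min_kg", "per_bsa_ml_min_m2", "per_kw_ml_min_g")


@dataclass(frozen=True)
class ClearanceResult:
    """A clearance with its technique label and indexed variants."""

    subject_id: str
    technique: str
    clearance_ml_min: float
    per_bw_ml_min_kg: float
    per_bsa_ml_min_m2: float
    per_kw_ml_min_g: float

    def __post_init__(self) -> None:
        if self.technique not in TECHNIQUES:
            raise DomainError(f"technique must be one of {TECHNIQUES}")
        if self.clearance_ml_min <= 0:
            raise DomainError("clearance must be positive")


def index_clearance(
    clearance_ml_min: float, subject: SubjectRecord, technique: str
) -> ClearanceResult:
    """Divide a clearance by each of the subject's size metrics."""
    if min(subject.bw_kg, subject.bsa_m2, subject.kw_g) <= 0:
        raise DomainError("subject metrics must be positive")
    if clearance_ml_min <= 0:
        raise DomainError("clearance must be positive")
    return ClearanceResult(
        subject_id=subject.subject_id,
        technique=technique,
        clearance_ml_min=clearance_ml_min,
        per_bw_ml_min_kg=clearance_ml_min / subject.bw_kg,
        per_bsa_ml_min_m2=clearance_ml_min / subject.bsa_m2,
        per_kw_ml_min_g=clearance_ml_min / subject.kw_g,
    )


def summarize_group(results: list[ClearanceResult]) -> dict[str, tuple[float, float | None, int]]:
    """(mean, sample SD, n) per index; SD is None when n < 2."""
    if not results:
        raise DomainError("at least one result required")
    out: dict[str, tuple[float, float | None, int]] = {}
    for col in ("clearance_ml_min", *INDEX_COLUMNS):
        vals = np.array([getattr(r, col) for r in results], dtype=float)
        sd = float(np.std(vals, ddof=1)) if vals.size >= 2 else None
        out[col] = (float(np.mean(vals)), sd, vals.size)
    return out


def summary_table(indexed: pd.DataFrame, standardize_1p73: bool = False) -> pd.DataFrame:
    """Age x technique summary of indexed clearances (mean +/- SD surface).

    ``indexed`` needs columns subject_id, age_days, technique,
    clearance_ml_min and the three index columns.  With
    ``standardize_1p73`` the per-BSA values are also expressed per 1.73 m^2.
    """
    df = indexed.copy()
    if standardize_1p73:
        df["per_1p73m2_ml_min"] = df["per_bsa_ml_min_m2"] * HUMAN_BSA_M2
    value_cols = [c for c in df.columns if c.startswith(("clearance", "per_"))]
    grouped = df.groupby(["age_days", "technique"])[value_cols]
    summary = grouped.agg(["mean", "std", "count"])
    summary.columns = [f"{col}_{stat}" for col, stat in summary.columns]
    return summary.reset_index()
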