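"""Endogenous creatinine clearance from plasma samples and timed urine collections.

Clearance of creatinine (mL/min) = (U_cr * U_vol) / (P_cr * T_min), with
urinary creatinine U_cr and plasma creatinine P_cr in mg/dL, urine volume
U_vol in mL and the timed collection interval T_min in minutes (the
concentration units cancel).

Plasma creatinine measured with the Jaffe (alkaline picrate) assay carries a
protein error: below a total plasma protein of 75 g/L the measured value is
corrected upward by

    corrected P_cr = (P_cr + 0.23) - (0.23/75) * total protein  [mg/dL]

which vanishes at the 75 g/L reference.  Piglets have markedly lower total
protein than adult animals, so the correction is material in young groups.

A plausibility screen on the urine collections converts each interval to a
24-h creatinine load (mg/24h), divides by bodyweight, and flags values
outside the Tukey 1.5*IQR fences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import DomainError

#: Total plasma protein (g/L) at which the Jaffe protein error vanishes.
JAFFE_REFERENCE_TP_G_L = 75.0
#: Full Jaffe offset (mg/dL) at zero total protein.
JAFFE_OFFSET_MG_DL = 0.23

ASSAYS = ("jaffe", "enzymatic")
CLOCK_LABELS = ("10am", "2pm", "6pm")


@dataclass(frozen=True)
class PlasmaCreatinine:
    """One plasma creatinine measurement at a labelled time of day."""

    subject_id: str
    clock_label: str
    p_cr_mg_dl: float
    assay: str

    def __post_init__(self) -> None:
        if self.p_cr_mg_dl <= 0:
            raise DomainError("plasma creatinine must be positive")
        if self.assay not in ASSAYS:
            raise DomainError(f"assay must be one of {ASSAYS}")


@dataclass(frozen=True)
class UrineCollection:
    """One timed urine collection with its creatinine concentration."""

    subject_id: str
    interval_start_min: float
    interval_end_min: float
    u_vol_ml: float
    u_cr_mg_dl: float

    def __post_init__(self) -> None:
        if self.interval_end_min <= self.interval_start_min:
            raise DomainError("collection interval must have positive duration")
        if self.u_vol_ml < 0 or self.u_cr_mg_dl < 0:
            raise DomainError("urine volume and creatinine must be non-negative")

    @property
    def t_min(self) -> float:
        return self.interval_end_min - self.interval_start_min


def correct_jaffe_pcr(p_cr_mg_dl: float, total_protein_g_l: float) -> float:
    """Protein-error correction of a Jaffe plasma creatinine value.

    Applied only below the 75 g/L total-protein reference; above it the
    value is returned unchanged.  The correction is continuous at 75 g/L.
    """
    if p_cr_mg_dl <= 0:
        raise DomainError("plasma creatinine must be positive")
    if total_protein_g_l < 0:
        raise DomainError("total protein must be non-negative")
    if total_protein_g_l >= JAFFE_REFERENCE_TP_G_L:
        return p_cr_mg_dl
    return (p_cr_mg_dl + JAFFE_OFFSET_MG_DL) - (
        JAFFE_OFFSET_MG_DL / JAFFE_REFERENCE_TP_G_L
    ) * total_protein_g_l


def mean_plasma_creatinine(samples: Sequence[PlasmaCreatinine]) -> float:
    """Arithmetic mean P_cr over the times of day, for a single subject/assay."""
    if not samples:
        raise DomainError("at least one plasma sample required")
    if len({s.subject_id for s in samples}) > 1:
        raise DomainError("samples must come from a single subject")
    if len({s.assay for s in samples}) > 1:
        raise DomainError("samples must come from a single assay; do not mix jaffe/enzymatic")
    return float(np.mean([s.p_cr_mg_dl for s in samples]))


def creatinine_clearance(
    u_cr_mg_dl: float, u_vol_ml: float, p_cr_mg_dl: float, t_min: float
) -> float:
    """(U_cr * U_vol) / (P_cr * T_min) in mL/min."""
    if p_cr_mg_dl <= 0 or t_min <= 0:
        raise DomainError("plasma creatinine and collection time must be positive")
    if u_cr_mg_dl < 0 or u_vol_ml < 0:
        raise DomainError("urinary inputs must be non-negative")
    if u_vol_ml == 0:
        warnings.warn("zero urine volume (anuria?); clearance reported as 0", stacklevel=2)
        return 0.0
    return (u_cr_mg_dl * u_vol_ml) / (p_cr_mg_dl * t_min)


def creatinine_load_24h(u_cr_mg_dl: float, u_vol_ml: float, t_min: float) -> float:
    """Creatinine mass excreted in the interval, scaled to 24 h (mg/24h).

    Mass collected is U_cr (mg/dL) * U_vol/100 (dL) = mg; scaling by
    24 / (T_min/60) extrapolates the interval to a full day.
    """
    if t_min <= 0:
        raise DomainError("collection time must be positive")
    if u_cr_mg_dl < 0 or u_vol_ml < 0:
        raise DomainError("urinary inputs must be non-negative")
    mass_mg = u_cr_mg_dl * (u_vol_ml / 100.0)
    return mass_mg * 24.0 / (t_min / 60.0)


def flag_load_outliers(loads_per_bw: Sequence[float]) -> list[bool]:
    """Tukey-fence screen of bodyweight-normalized 24-h creatinine loads.

    Values outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR] are flagged.  With fewer
    than four values the fences are too unstable: a warning is issued and
    nothing is flagged.
    """
    loads = np.asarray(list(loads_per_bw), dtype=float)
    if loads.size < 4:
        warnings.warn("fewer than 4 loads; outlier screen skipped", stacklevel=2)
        return [False] * loads.size
    q1, q3 = np.percentile(loads, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return [bool(v < lo or v > hi) for v in loads]


def subject_clearance(
    collections: Iterable[UrineCollection], mean_p_cr_mg_dl: float
) -> float:
    """Per-subject clearance: mean of the per-interval clearances at mean P_cr."""
    cls = [
        creatinine_clearance(c.u_cr_mg_dl, c.u_vol_ml, mean_p_cr_mg_dl, c.t_min)
        for c in collections
    ]
    if not cls:
        raise DomainError("at least one urine collection required")
    return float(np.mean(cls))
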