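"""Synthetic piglet cohorts for exercising the GFR pipeline end to end.

Generates subjects whose body metrics match published descriptive
statistics of growing conventional piglets at 8, 28, 49 and 180 days of
age (mean +/- SD of bodyweight, body surface area, kidney weight, plasma
creatinine and total plasma protein), together with the measurements the
pipeline consumes: plasma creatinine samples at three times of day, three
1-h timed urine collections, and an 11-point iohexol plasma
concentration-time profile after a single IV bolus.

Body metrics are drawn from normals truncated at zero; BSA is not sampled
independently but derived from bodyweight through an allometric surface
law k * BW**(2/3), with k calibrated once by log-log least squares against
the group mean (BW, BSA) pairs, keeping surface area physically consistent
with weight.  Each subject carries a latent true GFR, set from a
power-law model of bodyweight and plasma creatinine times lognormal
noise; the simulated urine and iohexol data are constructed to be exactly
consistent with that true value before measurement noise, so the whole
pipeline closes on the configured truth when all noise terms are zero.

Iohexol disposition is a two-compartment biexponential
C(t) = A exp(-alpha t) + B exp(-beta t), parameterized by the two rate
constants and the fraction of the total AUC carried by the fast phase;
A and B are solved so that dose/AUC equals the subject's assigned
clearance.  The alpha == beta limit degenerates to a monoexponential.

Reproducibility: one master seed; each subject draws from an independent
stream keyed by (seed, subject index), so cohorts are byte-identical
across runs and robust to regeneration order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .creatinine import (
    JAFFE_OFFSET_MG_DL,
    JAFFE_REFERENCE_TP_G_L,
    PlasmaCreatinine,
    UrineCollection,
)
from .egfr import PowerLawModel
from .errors import ConfigurationError, DomainError, SchemaError
from .nca import ConcentrationProfile, DEFAULT_EXO_FRACTION

#: IV bolus dose of iohexol (mg per kg bodyweight).
DEFAULT_DOSE_MG_PER_KG = 64.7

#: Blood sampling schedule, minutes post administration (0 = pre-dose).
DEFAULT_SCHEDULE_MIN = (0, 5, 15, 30, 60, 120, 180, 360, 480, 600, 1440)

#: Three 1-h urine collections (minutes from midnight: 10-11am, 2-3pm, 6-7pm).
DEFAULT_URINE_INTERVALS = ((600, 660), (840, 900), (1080, 1140))

#: Basal urine flow used to draw collection volumes (mL per kg per hour).
URINE_FLOW_ML_PER_KG_H = 1.5
URINE_VOLUME_CV = 0.30

#: Bodyweight threshold below which study animals were withdrawn.
BW_EXCLUSION_KG = 1.50


@dataclass(frozen=True)
class AgeGroupSpec:
    """Body-metric distribution (mean, SD) of one age group."""

    age_days: int
    n: int
    bw_mean: float
    bw_sd: float
    bsa_mean: float
    bsa_sd: float
    kw_mean: float
    kw_sd: float
    pcr_mean: float
    pcr_sd: float
    tp_mean: float
    tp_sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError("group size must be at least 1")
        for name in ("bw", "bsa", "kw", "pcr", "tp"):
            if getattr(self, f"{name}_mean") <= 0:
                raise ConfigurationError(f"{name}_mean must be positive")
            if getattr(self, f"{name}_sd") < 0:
                raise ConfigurationError(f"{name}_sd must be non-negative")


#: Reference cohort: growing male conventional piglets, mean +/- SD per age.
DEFAULT_AGE_GROUPS: tuple[AgeGroupSpec, ...] = (
    AgeGroupSpec(8, 14, 2.01, 0.43, 0.16, 0.02, 14.0, 2.94, 0.43, 0.08, 28.4, 5.60),
    AgeGroupSpec(28, 8, 10.0, 1.69, 0.46, 0.05, 20.25, 3.30, 0.46, 0.11, 31.7, 5.59),
    AgeGroupSpec(49, 16, 13.9, 2.74, 0.59, 0.08, 38.0, 3.16, 0.45, 0.10, 31.6, 6.39),
    AgeGroupSpec(180, 8, 112.88, 9.11, 2.42, 0.13, 121.24, 20.97, 0.99, 0.11, 49.2, 6.83),
)

#: Reference power-law GFR model used as the simulation ground truth.
DEFAULT_GFR_MODEL = PowerLawModel(a=1.879, b=1.092, c=0.600)


@dataclass(frozen=True)
class KineticsSpec:
    """Two-compartment iohexol disposition parameters.

    ``fast_fraction`` is the share of the total AUC contributed by the
    fast (alpha) phase.  alpha == beta is allowed and collapses to a
    monoexponential.
    """

    alpha_per_min: float = 0.05
    beta_per_min: float = 0.004
    fast_fraction: float = 0.4

    def __post_init__(self) -> None:
        if not self.alpha_per_min >= self.beta_per_min > 0:
            raise ConfigurationError("require alpha >= beta > 0")
        if not 0 < self.fast_fraction < 1:
            raise ConfigurationError("fast-phase fraction must lie in (0, 1)")


@dataclass(frozen=True)
class SubjectRecord:
    """One piglet's body metrics plus latent simulation-only quantities."""

    subject_id: str
    age_days: int
    bw_kg: float
    bsa_m2: float
    kw_g: float
    total_protein_g_per_l: float
    pcr_mg_dl: float
    true_gfr_ml_min: float

    def __post_init__(self) -> None:
        if min(self.bw_kg, self.bsa_m2, self.kw_g) <= 0:
            raise DomainError("body metrics must be positive")
        if self.total_protein_g_per_l < 0:
            raise DomainError("total protein must be non-negative")
        if self.pcr_mg_dl <= 0 or self.true_gfr_ml_min <= 0:
            raise DomainError("latent creatinine and GFR must be positive")


@dataclass(frozen=True)
class SimulationConfig:
    groups: tuple[AgeGroupSpec, ...] = DEFAULT_AGE_GROUPS
    seed: int = 0
    gfr_model: PowerLawModel = DEFAULT_GFR_MODEL
    gfr_log_sd: float = 0.15
    kinetics: KineticsSpec = field(default_factory=KineticsSpec)
    assay_cv: float = 0.05
    sampling_schedule_min: tuple[float, ...] = DEFAULT_SCHEDULE_MIN
    urine_intervals: tuple[tuple[float, float], ...] = DEFAULT_URINE_INTERVALS
    dose_mg_per_kg: float = DEFAULT_DOSE_MG_PER_KG
    exo_fraction: float = DEFAULT_EXO_FRACTION
    bsa_k: float | None = None  # None: calibrate against the group means
    bsa_exponent: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ConfigurationError("at least one age group required")
        if not 0 <= self.assay_cv < 1:
            raise ConfigurationError("assay CV must lie in [0, 1)")
        if self.gfr_log_sd < 0:
            raise ConfigurationError("GFR log-SD must be non-negative")
        sched = np.asarray(self.sampling_schedule_min, dtype=float)
        if sched[0] != 0 or np.any(np.diff(sched) <= 0):
            raise ConfigurationError("schedule must start at 0 and increase strictly")
        for start, end in self.urine_intervals:
            if end <= start:
                raise ConfigurationError("urine intervals must have positive duration")
        if self.dose_mg_per_kg <= 0:
            raise ConfigurationError("dose must be positive")

    def resolved_bsa_k(self) -> float:
        if self.bsa_k is not None:
            return self.bsa_k
        pairs = [(g.bw_mean, g.bsa_mean) for g in self.groups]
        return calibrate_bsa_k(pairs, self.bsa_exponent)


def calibrate_bsa_k(pairs: Sequence[tuple[float, float]], exponent: float) -> float:
    """Least-squares coefficient of log(BSA) = log(k) + e*log(BW) at fixed e."""
    if not pairs:
        raise ConfigurationError("need at least one (BW, BSA) pair")
    logs = [math.log(bsa) - exponent * math.log(bw) for bw, bsa in pairs]
    return math.exp(float(np.mean(logs)))


def allometric_bsa(bw_kg: float, k: float, e: float) -> float:
    """Body surface area (m^2) from the allometric law k * BW**e."""
    if bw_kg <= 0:
        raise DomainError("bodyweight must be positive")
    if k <= 0:
        raise DomainError("allometric coefficient must be positive")
    return k * bw_kg**e


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Normal(mean, sd) truncated at zero by rejection; degenerate at sd=0."""
    if sd == 0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)
    raise ConfigurationError(
        f"truncated normal rejection failed for mean={mean}, sd={sd}"
    )


def _subject_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(index)])


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Mean-one multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return float(math.exp(rng.normal(0.0, sigma) - 0.5 * sigma * sigma))


def generate_cohort(config: SimulationConfig) -> list[SubjectRecord]:
    """Draw a full cohort; deterministic given the config (incl. seed)."""
    k = config.resolved_bsa_k()
    subjects: list[SubjectRecord] = []
    index = 0
    for group in config.groups:
        for i in range(group.n):
            rng = _subject_rng(config.seed, index)
            bw = _truncated_normal(rng, group.bw_mean, group.bw_sd)
            kw = _truncated_normal(rng, group.kw_mean, group.kw_sd)
            pcr = _truncated_normal(rng, group.pcr_mean, group.pcr_sd)
            tp = _truncated_normal(rng, group.tp_mean, group.tp_sd)
            bsa = allometric_bsa(bw, k, config.bsa_exponent)
            eps = rng.normal(0.0, config.gfr_log_sd) if config.gfr_log_sd > 0 else 0.0
            true_gfr = config.gfr_model.predict(bw, pcr) * math.exp(eps)
            subjects.append(
                SubjectRecord(
                    subject_id=f"pig{group.age_days:03d}d_{i:02d}",
                    age_days=group.age_days,
                    bw_kg=bw,
                    bsa_m2=bsa,
                    kw_g=kw,
                    total_protein_g_per_l=tp,
                    pcr_mg_dl=pcr,
                    true_gfr_ml_min=true_gfr,
                )
            )
            index += 1
    return subjects


def apply_bw_exclusion(
    cohort: Sequence[SubjectRecord], threshold_kg: float = BW_EXCLUSION_KG
) -> tuple[list[SubjectRecord], list[SubjectRecord]]:
    """Withdraw subjects below the bodyweight threshold; exhaustive partition."""
    if threshold_kg <= 0:
        raise DomainError("threshold must be positive")
    kept = [s for s in cohort if s.bw_kg >= threshold_kg]
    withdrawn = [s for s in cohort if s.bw_kg < threshold_kg]
    return kept, withdrawn


def simulate_iohexol_profile(
    subject: SubjectRecord,
    dose_mg_per_kg: float,
    clearance_ml_min: float,
    kinetics: KineticsSpec,
    schedule_min: Sequence[float],
    assay_cv: float,
    rng: np.random.Generator,
    exo_fraction: float = DEFAULT_EXO_FRACTION,
) -> ConcentrationProfile:
    """Biexponential profile constructed so dose/AUC equals the clearance.

    With A/alpha + B/beta = AUC = exo dose / CL and the fast phase holding
    ``fast_fraction`` of the AUC, the analytic clearance is exact by
    construction; multiplicative mean-one lognormal assay noise with the
    given CV is then applied per post-dose point.  The pre-dose sample is
    exactly zero.
    """
    if clearance_ml_min <= 0:
        raise DomainError("clearance must be positive")
    sched = np.asarray(schedule_min, dtype=float)
    if sched.size == 0 or sched[0] != 0:
        raise SchemaError("schedule must include a pre-dose point at t=0")
    dose_mg = dose_mg_per_kg * subject.bw_kg
    auc = dose_mg * exo_fraction * 1000.0 / clearance_ml_min  # ug*min/mL
    t = sched[1:]
    a_rate, b_rate = kinetics.alpha_per_min, kinetics.beta_per_min
    if a_rate == b_rate:
        conc = auc * b_rate * np.exp(-b_rate * t)
    else:
        A = kinetics.fast_fraction * auc * a_rate
        B = (1.0 - kinetics.fast_fraction) * auc * b_rate
        conc = A * np.exp(-a_rate * t) + B * np.exp(-b_rate * t)
    noisy = np.array([c * _lognormal_factor(rng, assay_cv) for c in conc])
    return ConcentrationProfile(
        subject_id=subject.subject_id,
        times_min=tuple(sched),
        conc_ug_ml=(0.0, *noisy),
        total_dose_mg=dose_mg,
        exo_fraction=exo_fraction,
    )


def simulate_urine_collections(
    subject: SubjectRecord,
    true_clcr_ml_min: float,
    pcr_mg_dl: float,
    intervals: Sequence[tuple[float, float]],
    noise_cv: float,
    rng: np.random.Generator,
) -> list[UrineCollection]:
    """Timed collections exactly consistent with the true clearance.

    The collection volume is drawn around a basal urine flow; the urinary
    creatinine concentration is then solved from
    (U_cr * U_vol)/(P_cr * T) = CL_cr, so the clearance equation inverts
    the construction exactly before the multiplicative noise on U_cr.
    """
    if true_clcr_ml_min <= 0 or pcr_mg_dl <= 0:
        raise DomainError("clearance and plasma creatinine must be positive")
    collections = []
    for start, end in intervals:
        t_min = end - start
        base_vol = URINE_FLOW_ML_PER_KG_H * subject.bw_kg * (t_min / 60.0)
        u_vol = base_vol * _lognormal_factor(rng, URINE_VOLUME_CV)
        u_cr = true_clcr_ml_min * pcr_mg_dl * t_min / u_vol
        u_cr *= _lognormal_factor(rng, noise_cv)
        collections.append(
            UrineCollection(
                subject_id=subject.subject_id,
                interval_start_min=start,
                interval_end_min=end,
                u_vol_ml=u_vol,
                u_cr_mg_dl=u_cr,
            )
        )
    return collections


def simulate_plasma_samples(
    subject: SubjectRecord,
    noise_cv: float,
    rng: np.random.Generator,
    clock_labels: Sequence[str] = ("10am", "2pm", "6pm"),
) -> list[PlasmaCreatinine]:
    """Plasma creatinine samples for both assays at each time of day.

    The enzymatic assay reads the latent creatinine directly; the Jaffe
    assay is simulated with the protein error (its reading is depressed by
    0.23 * (1 - TP/75) mg/dL below 75 g/L total protein), so that the
    protein correction recovers the latent value exactly at zero noise.
    """
    tp = subject.total_protein_g_per_l
    jaffe_error = (
        JAFFE_OFFSET_MG_DL * (1.0 - tp / JAFFE_REFERENCE_TP_G_L)
        if tp < JAFFE_REFERENCE_TP_G_L
        else 0.0
    )
    samples = []
    for label in clock_labels:
        for assay in ("jaffe", "enzymatic"):
            true_reading = (
                subject.pcr_mg_dl - jaffe_error if assay == "jaffe" else subject.pcr_mg_dl
            )
            samples.append(
                PlasmaCreatinine(
                    subject_id=subject.subject_id,
                    clock_label=label,
                    p_cr_mg_dl=true_reading * _lognormal_factor(rng, noise_cv),
                    assay=assay,
                )
            )
    return samples


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Convenience: same study conditions under a different master seed."""
    return replace(config, seed=seed)
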