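"""Power-law eGFR estimating equations fitted by stepwise log-log regression.

The estimating equation has the form

    eGFR = a * BW**b / Pcr**c        [mL/min]

with bodyweight BW in kg and plasma creatinine Pcr in mg/dL.  It is derived
by regressing log(GFR) on log-transformed candidate predictors

    log(GFR) = a0 + b*log(BW) - c*log(Pcr) + d*log(age) + interactions

with bidirectional stepwise selection (enter while the best partial-F
p-value is below ``p_in``, prune any retained term whose p-value exceeds
``p_out``).  Exponents are invariant to the logarithm base; only the
back-transform of the intercept into the multiplicative constant ``a``
depends on it.

Model quality is summarized by the adjusted R-squared of the log-scale fit
and by the P10/P30 relative-accuracy statistics (percentage of predictions
within 10% / 30% of the measured GFR), the standard validation metrics for
GFR estimating equations.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ConvergenceError, DomainError, InsufficientDataError

#: Candidate terms in their canonical (tie-breaking) order.
CANONICAL_TERMS: tuple[str, ...] = (
    "log_pcr",
    "log_bw",
    "log_age",
    "log_age_x_log_pcr",
    "log_age_x_log_bw",
)

_INTERACTIONS: Mapping[str, tuple[str, str]] = {
    "log_age_x_log_pcr": ("log_age", "log_pcr"),
    "log_age_x_log_bw": ("log_age", "log_bw"),
}

_MAINS: Mapping[str, str] = {"log_pcr": "pcr", "log_bw": "bw", "log_age": "age"}


@dataclass(frozen=True)
class RegressionSpec:
    """Stepwise-selection settings for the log-linear GFR regression."""

    candidate_terms: tuple[str, ...] = CANONICAL_TERMS
    p_in: float = 0.05
    p_out: float = 0.10
    log_base: float = 10.0

    def __post_init__(self) -> None:
        if not self.candidate_terms:
            raise DomainError("candidate term set must be non-empty")
        unknown = set(self.candidate_terms) - set(CANONICAL_TERMS)
        if unknown:
            raise DomainError(f"unknown candidate terms: {sorted(unknown)}")
        if not 0 < self.p_in < self.p_out:
            raise DomainError("require 0 < p_in < p_out")
        if self.log_base not in (10.0, math.e):
            raise DomainError("log_base must be 10 or e")

    def ordered_candidates(self) -> tuple[str, ...]:
        return tuple(t for t in CANONICAL_TERMS if t in self.candidate_terms)


@dataclass(frozen=True)
class PowerLawModel:
    """Back-transformed power-law eGFR model ``a * BW**b / Pcr**c``.

    ``c`` is stored as the positive denominator exponent; the raw regression
    coefficient of log(Pcr) is ``-c``.  ``age_coefs`` holds coefficients of
    any selected age terms, which fall outside the two-predictor power-law
    form and are reported for transparency only.
    """

    a: float
    b: float
    c: float
    adj_r2: float | None = None
    p10: float | None = None
    p30: float | None = None
    included_terms: tuple[str, ...] = ("log_bw", "log_pcr")
    log_base: float = 10.0
    age_coefs: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise DomainError("scale constant a must be positive")
        if self.p10 is not None and self.p30 is not None and self.p10 > self.p30:
            raise DomainError("P10 cannot exceed P30")

    def predict(self, bw_kg, pcr_mg_dl):
        """Estimated GFR in mL/min; vectorized over numpy inputs."""
        bw = np.asarray(bw_kg, dtype=float)
        pcr = np.asarray(pcr_mg_dl, dtype=float)
        if np.any(bw <= 0) or np.any(pcr <= 0):
            raise DomainError("bodyweight and plasma creatinine must be positive")
        out = self.a * bw**self.b / pcr**self.c
        return float(out) if out.ndim == 0 else out

    def to_json(self) -> str:
        payload = {
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "adj_r2": self.adj_r2,
            "p10": self.p10,
            "p30": self.p30,
            "included_terms": list(self.included_terms),
            "log_base": "e" if self.log_base == math.e else self.log_base,
            "age_coefs": dict(self.age_coefs),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PowerLawModel":
        d = json.loads(text)
        base = math.e if d.get("log_base") == "e" else float(d.get("log_base", 10.0))
        return cls(
            a=d["a"],
            b=d["b"],
            c=d["c"],
            adj_r2=d.get("adj_r2"),
            p10=d.get("p10"),
            p30=d.get("p30"),
            included_terms=tuple(d.get("included_terms", ("log_bw", "log_pcr"))),
            log_base=base,
            age_coefs=d.get("age_coefs", {}),
        )


@dataclass(frozen=True)
class StepwiseFit:
    """Result of a stepwise log-linear fit (log-scale parameterization)."""

    intercept: float
    coefs: Mapping[str, float]
    included_terms: tuple[str, ...]
    adj_r2: float
    r2: float
    n: int
    log_base: float

    def predict_log(self, design: pd.DataFrame) -> np.ndarray:
        out = np.full(len(design), self.intercept)
        for term, coef in self.coefs.items():
            out = out + coef * design[term].to_numpy()
        return out


def build_design(rows: pd.DataFrame, spec: RegressionSpec) -> tuple[pd.DataFrame, pd.Series]:
    """Log-transform (gfr, pcr, bw, age) rows into a design matrix and response.

    ``rows`` must have columns ``gfr``, ``pcr``, ``bw``, ``age``; every value
    must be strictly positive (log transform).  Interaction columns are
    elementwise products of the logged main effects.
    """
    required = ("gfr", "pcr", "bw", "age")
    missing = [c for c in required if c not in rows.columns]
    if missing:
        raise DomainError(f"missing columns: {missing}")
    for col in required:
        vals = rows[col].to_numpy(dtype=float)
        bad = np.flatnonzero(~(vals > 0))
        if bad.size:
            raise DomainError(
                f"non-positive {col} at row {int(bad[0])}: {vals[bad[0]]!r} "
                "(log transform requires positive values)"
            )

    def _log(x):
        return np.log10(x) if spec.log_base == 10.0 else np.log(x)

    logged = {name: _log(rows[col].to_numpy(dtype=float)) for name, col in _MAINS.items()}
    columns: dict[str, np.ndarray] = {}
    for term in spec.ordered_candidates():
        if term in _MAINS:
            columns[term] = logged[term]
        else:
            left, right = _INTERACTIONS[term]
            columns[term] = logged[left] * logged[right]
    design = pd.DataFrame(columns, index=rows.index)
    response = pd.Series(_log(rows["gfr"].to_numpy(dtype=float)), index=rows.index, name="log_gfr")
    return design, response


def _ols_ssr(y: np.ndarray, X: np.ndarray) -> float:
    """Residual sum of squares of an OLS fit (intercept included in X)."""
    return float(sm.OLS(y, X).fit().ssr)


def _with_intercept(design: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    X = np.column_stack([np.ones(len(design))] + [design[t].to_numpy() for t in terms])
    return X


def _partial_f_pvalue(ssr_reduced: float, ssr_full: float, df_full: int, scale: float) -> float:
    """p-value for dropping/adding one term, robust to perfect fits.

    ``scale`` is the total sum of squares of the response, used to decide
    when a residual is numerically zero.
    """
    tiny = 1e-12 * max(scale, 1.0)
    improvement = ssr_reduced - ssr_full
    if ssr_full <= tiny:
        # Saturated fit: the term matters iff it removed residual variance.
        return 0.0 if improvement > tiny else 1.0
    if improvement <= 0:
        return 1.0
    f = improvement / (ssr_full / df_full)
    return float(stats.f.sf(f, 1, df_full))


def stepwise_fit(design: pd.DataFrame, response: pd.Series, spec: RegressionSpec) -> StepwiseFit:
    """Bidirectional stepwise OLS on the log scale.

    Forward steps enter the candidate with the smallest partial-F p-value
    while it is below ``spec.p_in``; after every entry, any included term
    whose p-value (partial F of dropping it) exceeds ``spec.p_out`` is
    removed, worst first.  The intercept is always retained.  Sweeps are
    bounded, so pathological enter/remove cycles raise ``ConvergenceError``.
    """
    candidates = [t for t in spec.ordered_candidates() if t in design.columns]
    n = len(design)
    if n <= len(candidates) + 1:
        raise InsufficientDataError(
            f"n={n} rows cannot support {len(candidates)} candidate terms plus intercept"
        )
    y = response.to_numpy(dtype=float)
    scale = float(np.sum((y - y.mean()) ** 2))

    included: list[str] = []
    max_sweeps = 4 * len(candidates) + 4
    for _ in range(max_sweeps):
        changed = False
        # Forward step: best candidate not yet included.
        ssr_current = _ols_ssr(y, _with_intercept(design, included))
        best_term, best_p = None, 1.0
        for term in candidates:
            if term in included:
                continue
            ssr_with = _ols_ssr(y, _with_intercept(design, included + [term]))
            p = _partial_f_pvalue(ssr_current, ssr_with, n - len(included) - 2, scale)
            if p < best_p:
                best_term, best_p = term, p
        if best_term is not None and best_p < spec.p_in:
            included.append(best_term)
            changed = True
        # Backward step(s): prune while the worst retained term exceeds p_out.
        while included:
            ssr_full = _ols_ssr(y, _with_intercept(design, included))
            worst_term, worst_p = None, -1.0
            for term in included:
                others = [t for t in included if t != term]
                ssr_without = _ols_ssr(y, _with_intercept(design, others))
                p = _partial_f_pvalue(ssr_without, ssr_full, n - len(included) - 1, scale)
                if p > worst_p:
                    worst_term, worst_p = term, p
            if worst_term is not None and worst_p > spec.p_out:
                included.remove(worst_term)
                changed = True
            else:
                break
        if not changed:
            break
    else:
        raise ConvergenceError(f"stepwise selection did not stabilize in {max_sweeps} sweeps")

    included = [t for t in spec.ordered_candidates() if t in included]
    fit = sm.OLS(y, _with_intercept(design, included)).fit()
    params = np.asarray(fit.params, dtype=float)
    r2 = float(fit.rsquared) if scale > 0 else 1.0
    n_params = len(included)
    adj = adjusted_r2(r2, n, n_params) if n_params else r2
    return StepwiseFit(
        intercept=float(params[0]),
        coefs={t: float(params[i + 1]) for i, t in enumerate(included)},
        included_terms=tuple(included),
        adj_r2=adj,
        r2=r2,
        n=n,
        log_base=spec.log_base,
    )


def back_transform(fit: StepwiseFit, spec: RegressionSpec) -> PowerLawModel | None:
    """Convert a log-scale fit into the power-law form a*BW**b/Pcr**c.

    Requires both main effects log_bw and log_pcr; otherwise a structural
    warning is issued and no power-law model is emitted.  Selected age terms
    are carried along in ``age_coefs`` but flagged as outside the
    two-predictor form.
    """
    if "log_bw" not in fit.coefs or "log_pcr" not in fit.coefs:
        warnings.warn(
            "fitted model lacks log_bw and/or log_pcr; no power-law form emitted",
            stacklevel=2,
        )
        return None
    a = spec.log_base**fit.intercept
    age_coefs = {t: v for t, v in fit.coefs.items() if "age" in t}
    if age_coefs:
        warnings.warn(
            "age terms selected; reported separately, outside the a*BW^b/Pcr^c form",
            stacklevel=2,
        )
    return PowerLawModel(
        a=float(a),
        b=fit.coefs["log_bw"],
        c=-fit.coefs["log_pcr"],
        adj_r2=fit.adj_r2,
        included_terms=fit.included_terms,
        log_base=spec.log_base,
        age_coefs=age_coefs,
    )


def adjusted_r2(r2: float, n: int, n_params: int) -> float:
    """Adjusted R-squared: 1 - (1 - R2)(n - 1)/(n - n_params - 1)."""
    if n <= n_params + 1:
        raise DomainError("adjusted R2 requires n > n_params + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - n_params - 1)


def relative_accuracy(pred, obs, band: float) -> float:
    """Percentage of predictions within ``band`` (fraction) of the observed value."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape:
        raise DomainError("pred and obs must have equal length")
    if np.any(obs <= 0):
        raise DomainError("observed values must be positive")
    inside = np.abs(pred - obs) / obs <= band
    return 100.0 * float(np.mean(inside))


def evaluate_accuracy(model: PowerLawModel, bw_kg, pcr_mg_dl, gfr_ml_min) -> PowerLawModel:
    """Fill in P10/P30 of ``model`` against measured GFR values."""
    pred = model.predict(bw_kg, pcr_mg_dl)
    return replace(
        model,
        p10=relative_accuracy(pred, gfr_ml_min, 0.10),
        p30=relative_accuracy(pred, gfr_ml_min, 0.30),
    )
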