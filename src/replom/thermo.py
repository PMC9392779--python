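"""Arrhenius analysis of per-aggregate growth rates across temperatures.

Rates of one kinetic phase, measured on many individual aggregates at
several incubation temperatures, are pooled per temperature into a mean
ln-rate with its standard error.  A weighted linear regression of mean
ln-rate on 1/T (K) gives the activation energy Ea = -slope * R.  A
straight Arrhenius line is used throughout (no heat-capacity
curvature).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .growth_models import Phase, RateRecord

__all__ = ["R_GAS", "ArrheniusFit", "fit_arrhenius", "celsius_to_kelvin"]

R_GAS = 8.314  # J / (mol K)


def celsius_to_kelvin(t_c: float | np.ndarray) -> float | np.ndarray:
    return np.asarray(t_c, dtype=float) + 273.15


@dataclass
class ArrheniusFit:
    """Activation energy and prefactor from a ln(rate) vs 1/T regression."""

    ea_kj_mol: float
    ea_se_kj_mol: float
    ln_a: float
    ln_a_se: float
    temperatures_k: np.ndarray
    mean_ln_rate: np.ndarray
    se_ln_rate: np.ndarray
    n_per_temperature: np.ndarray
    slope_intercept_cov: np.ndarray
    weighted: bool
    n_excluded_nonpositive: int = 0
    flags: list[str] = field(default_factory=list)


def fit_arrhenius(
    records: list[RateRecord],
    phase: Phase | str | None = None,
    weighted: bool = True,
) -> ArrheniusFit:
    """Fit the Arrhenius law to per-aggregate rate records of one phase.

    Per temperature: mean of ln(rate) and its standard error.  Then a
    linear regression of mean ln-rate on 1/T (K), weighted by 1/SE^2
    (falling back to an unweighted fit if any SE is zero, e.g. for
    noiseless inputs).  Ea = -slope * R, reported in kJ/mol with its
    SE from the regression covariance.  Temperatures are stored on the
    records in Celsius and converted internally.
    """
    if phase is not None:
        phase = Phase(phase)
        records = [r for r in records if r.phase is phase]
    n_excluded = sum(1 for r in records if not (r.rate > 0))
    records = [r for r in records if r.rate > 0]
    if not records:
        raise ValueError("no positive-rate records to fit")
    if any(r.temperature_c is None for r in records):
        raise ValueError("every record needs a temperature")

    temps_c = np.array(sorted({float(r.temperature_c) for r in records}))
    if len(temps_c) < 2:
        raise ValueError(f"need >= 2 distinct temperatures, got {len(temps_c)}")
    T = np.asarray(celsius_to_kelvin(temps_c), dtype=float)
    mean_ln = np.empty(len(temps_c))
    se_ln = np.empty(len(temps_c))
    n_per = np.empty(len(temps_c), dtype=np.int64)
    for i, tc in enumerate(temps_c):
        lr = np.log([r.rate for r in records if float(r.temperature_c) == tc])
        n_per[i] = lr.size
        mean_ln[i] = lr.mean()
        se_ln[i] = lr.std(ddof=1) / np.sqrt(lr.size) if lr.size > 1 else 0.0

    flags: list[str] = []
    use_weights = weighted and np.all(se_ln > 0)
    if weighted and not use_weights:
        flags.append("unweighted_fallback_zero_se")
    w = 1.0 / se_ln**2 if use_weights else np.ones_like(se_ln)

    x = 1.0 / T
    X = np.column_stack([x, np.ones_like(x)])
    W = np.diag(w)
    xtwx = X.T @ W @ X
    cov_unscaled = np.linalg.inv(xtwx)
    beta = cov_unscaled @ (X.T @ W @ mean_ln)
    slope, intercept = float(beta[0]), float(beta[1])

    resid = mean_ln - X @ beta
    dof = len(x) - 2
    if use_weights:
        # SEs propagate the per-temperature input SEs through the weights
        cov = cov_unscaled
    else:
        s2 = float(resid @ resid) / dof if dof > 0 else 0.0
        cov = cov_unscaled * s2
        if dof == 0:
            flags.append("two_point_unweighted_zero_dof")

    ea = -slope * R_GAS / 1000.0  # kJ/mol
    ea_se = float(np.sqrt(max(cov[0, 0], 0.0))) * R_GAS / 1000.0
    return ArrheniusFit(
        ea_kj_mol=ea, ea_se_kj_mol=ea_se,
        ln_a=intercept, ln_a_se=float(np.sqrt(max(cov[1, 1], 0.0))),
        temperatures_k=T, mean_ln_rate=mean_ln, se_ln_rate=se_ln,
        n_per_temperature=n_per, slope_intercept_cov=np.asarray(cov),
        weighted=bool(use_weights), n_excluded_nonpositive=n_excluded,
        flags=flags,
    )
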