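"""Piecewise growth laws for single protein aggregates and their fitting.

Projected aggregate area A(t) is modelled as a piecewise ODE with an
initial reaction-limited (linear) phase, a second phase that is either
reaction-limited with a new rate (``A_lin``) or diffusion-limited, i.e.
parabolic in area (``A_par``), and a final sigmoidal saturation set by a
time constant tau.  The rate laws are

``A_lin``::

    dA/dt = r1                                   t < t0
          = r2                                   t0 <= t < t1
          = r2 / (1 + exp(5 (t - tau - t1)/tau)) t >= t1

``A_par``::

    dA/dt = r1                                       t < t0
          = r2 t / 2                                 t0 <= t < t1
          = (r2 t / 2) / (1 + exp(5 (t-tau-t1)/tau)) t >= t1

Anisotropic spherulites (linear core, then branching) are described by
``A_lin`` — r1 is the rate of the linear dendrite core, r2 the rate of
the branching part.  Isotropic spherulites are described by ``A_par``,
whose initial linear rate is reported as the isotropic growth rate r_x.

Curves are fitted by numerically integrating the rate law and running a
two-pass chi-square scheme: an unweighted pass whose residual SD sets a
single uniform sigma, then a weighted pass from which parameters and
curvature-based errors are taken.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ModelKind",
    "Morphology",
    "Phase",
    "GrowthModelParams",
    "GrowthFit",
    "RateRecord",
    "growth_rate",
    "integrate_model",
    "fit_growth_curve",
    "classify_morphology",
    "extract_rates",
]


class ModelKind(str, Enum):
    A_LIN = "A_lin"
    A_PAR = "A_par"


class Morphology(str, Enum):
    ISOTROPIC = "isotropic"
    ANISOTROPIC = "anisotropic"


class Phase(str, Enum):
    """Kinetic phase a reported rate belongs to."""

    LINEAR = "linear"        # r1 of anisotropic growth
    BRANCHING = "branching"  # r2 of anisotropic growth
    ISOTROPIC = "isotropic"  # r_x of isotropic growth


@dataclass
class GrowthModelParams:
    """Parameters of the piecewise growth law.

    r1 is always in um^2/s.  r2 is um^2/s for ``A_lin`` and um^2/s^2
    (the parabolic slope coefficient) for ``A_par``.  t0 and t1 are the
    phase-switch times (s), tau the saturation time constant (s), A0
    the area at the first observation time (um^2).
    """

    r1: float
    r2: float
    t0: float
    t1: float
    tau: float
    A0: float = 0.0
    kind: ModelKind = ModelKind.A_LIN

    def __post_init__(self) -> None:
        self.kind = ModelKind(self.kind)
        vals = (self.r1, self.r2, self.t0, self.t1, self.tau, self.A0)
        if not all(math.isfinite(v) or v == math.inf for v in vals):
            raise ValueError("growth-model parameters must not be NaN")
        if self.r1 < 0 or self.r2 < 0:
            raise ValueError("growth rates must be non-negative")
        if not (0 <= self.t0 <= self.t1):
            raise ValueError(f"need 0 <= t0 <= t1, got t0={self.t0}, t1={self.t1}")
        if not self.tau > 0:
            raise ValueError("tau must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([self.r1, self.r2, self.t0, self.t1, self.tau, self.A0])


PARAM_NAMES = ("r1", "r2", "t0", "t1", "tau", "A0")


@dataclass
class GrowthFit:
    """Result of the two-pass chi-square fit of one growth curve."""

    params: GrowthModelParams
    param_errors: dict[str, float]
    chi2: float
    reduced_chi2: float
    residual_sd: float
    n_points: int
    converged: bool
    flags: list[str] = field(default_factory=list)


@dataclass
class RateRecord:
    """One extracted per-aggregate growth rate, input to Arrhenius analysis."""

    aggregate_id: int | str
    morphology: Morphology
    phase: Phase
    rate: float
    rate_units: str
    rate_se: float
    temperature_c: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.morphology = Morphology(self.morphology)
        self.phase = Phase(self.phase)
        iso = self.morphology is Morphology.ISOTROPIC
        if iso != (self.phase is Phase.ISOTROPIC):
            raise ValueError(f"phase {self.phase} inconsistent with morphology {self.morphology}")


def _sigmoid_tail(t: np.ndarray, t1: float, tau: float) -> np.ndarray:
    # logistic cut-off centred at t1 + tau, width tau/5
    z = np.clip(5.0 * (t - tau - t1) / tau, -700.0, 700.0)
    return 1.0 / (1.0 + np.exp(z))


def _phase_rate(p: GrowthModelParams, t: np.ndarray, phase: np.ndarray) -> np.ndarray:
    """Rate evaluated with the branch forced per element (phase 0/1/2).

    Forcing the branch lets the integrator evaluate one-sided limits at
    the switch times, where the A_lin law is discontinuous.
    """
    t = np.asarray(t, dtype=float)
    out = np.empty_like(t)
    m0, m1, m2 = (phase == 0), (phase == 1), (phase == 2)
    out[m0] = p.r1
    if p.kind is ModelKind.A_LIN:
        out[m1] = p.r2
        out[m2] = p.r2 * _sigmoid_tail(t[m2], p.t1, p.tau)
    else:
        out[m1] = 0.5 * p.r2 * t[m1]
        out[m2] = 0.5 * p.r2 * t[m2] * _sigmoid_tail(t[m2], p.t1, p.tau)
    return out


def growth_rate(params: GrowthModelParams, t: float | np.ndarray) -> float | np.ndarray:
    """dA/dt of the piecewise growth law at time(s) ``t``."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if not np.all(np.isfinite(t_arr)):
        raise ValueError("t must be finite")
    phase = np.digitize(t_arr, [params.t0, params.t1])  # right-closed at switches
    out = _phase_rate(params, t_arr, phase)
    return float(out[0]) if np.isscalar(t) or np.ndim(t) == 0 else out


def integrate_model(
    params: GrowthModelParams,
    times: Sequence[float],
    A0: float | None = None,
    substeps: int = 20,
) -> np.ndarray:
    """Areas A(t) at ``times`` by integrating the rate law from times[0].

    Composite trapezoid with ``substeps`` sub-intervals per observation
    interval; the switch times t0 and t1 are inserted exactly into the
    mesh and each mesh interval is evaluated on its own branch, so the
    rate discontinuity of A_lin at t0 costs no accuracy.  The trapezoid
    is exact on the constant and linear-in-t branches.
    """
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise ValueError("times must be a 1-D sequence")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    if A0 is None:
        A0 = params.A0
    if t.size == 1:
        return np.array([A0])

    # fine mesh: substeps points per observation interval, then the exact
    # switch times; built without np.unique (already sorted by construction)
    frac = np.linspace(0.0, 1.0, substeps + 1)[:-1]
    mesh = (t[:-1, None] + np.diff(t)[:, None] * frac[None, :]).ravel()
    mesh = np.append(mesh, t[-1])
    for brk in (params.t0, params.t1):
        if t[0] < brk < t[-1]:
            j = int(np.searchsorted(mesh, brk))
            if mesh[j] != brk:
                mesh = np.insert(mesh, j, brk)

    mids = 0.5 * (mesh[:-1] + mesh[1:])
    phase = np.digitize(mids, [params.t0, params.t1])
    ra = _phase_rate(params, mesh[:-1], phase)
    rb = _phase_rate(params, mesh[1:], phase)
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (ra + rb) * np.diff(mesh))])
    A_mesh = A0 + cum
    return A_mesh[np.searchsorted(mesh, t)]


# ---------------------------------------------------------------------------
# fitting


def _unpack(x: np.ndarray, kind: ModelKind) -> GrowthModelParams:
    r1, r2, t0, dt1, tau, A0 = x
    return GrowthModelParams(r1=r1, r2=r2, t0=t0, t1=t0 + dt1, tau=tau, A0=A0, kind=kind)


def _residuals(x: np.ndarray, kind: ModelKind, t: np.ndarray, A: np.ndarray) -> np.ndarray:
    return integrate_model(_unpack(x, kind), t) - A


def _start_grid(t: np.ndarray, A: np.ndarray, kind: ModelKind) -> list[np.ndarray]:
    """Multi-start initial guesses over (t0, t1) quantile pairs."""
    span = t[-1] - t[0]
    starts = []
    for q0, q1 in ((0.2, 0.6), (0.15, 0.85), (0.35, 0.7), (0.3, 0.95), (0.5, 0.9), (0.05, 0.5)):
        t0 = t[0] + q0 * span
        t1 = t[0] + q1 * span
        i0 = np.searchsorted(t, t0)
        i1 = np.searchsorted(t, t1)
        i0 = int(np.clip(i0, 1, t.size - 2))
        i1 = int(np.clip(i1, i0 + 1, t.size - 1))
        r1 = max((A[i0] - A[0]) / (t[i0] - t[0]), 0.0)
        slope2 = max((A[i1] - A[i0]) / (t[i1] - t[i0]), 0.0)
        if kind is ModelKind.A_PAR:
            tmid = 0.5 * (t[i0] + t[i1])
            r2 = 2.0 * slope2 / max(tmid, 1e-12)
        else:
            r2 = slope2
        tau = max(0.2 * span, 1e-6)
        starts.append(np.array([r1, r2, t0, t1 - t0, tau, A[0]]))
    return starts


def fit_growth_curve(curve, kind: ModelKind | str) -> GrowthFit:
    """Fit one growth curve with the two-pass chi-square scheme.

    Pass 1 is an unweighted least-squares fit; the SD of its residuals
    gives the single measurement sigma.  Pass 2 refits with uniform
    weights 1/sigma^2; parameter errors come from the curvature (J'J)
    of the weighted problem.  Multiple starts over a grid of (t0, t1)
    quantile pairs guard against the switch-time local minima.
    """
    kind = ModelKind(kind)
    t = np.asarray(curve.times, dtype=float)
    A = np.asarray(curve.areas, dtype=float)
    ok = np.isfinite(A)
    t, A = t[ok], A[ok]
    if t.size < 8:
        raise ValueError(f"growth curve has {t.size} valid points; need >= 8 to fit")

    span = t[-1] - t[0]
    dt_min = float(np.min(np.diff(t)))
    lo = np.array([0.0, 0.0, t[0], 0.0, dt_min, 0.0])
    hi = np.array([np.inf, np.inf, t[-1], span, span, np.inf])

    best = None
    for x0 in _start_grid(t, A, kind):
        x0 = np.clip(x0, lo + 1e-12, np.where(np.isinf(hi), x0 + 1.0, hi - 1e-12))
        x0 = np.maximum(x0, lo + 1e-12)
        try:
            # coarse exploration run per start; the winner is polished below
            sol = least_squares(_residuals, x0, bounds=(lo, hi), args=(kind, t, A),
                                method="trf", x_scale="jac", max_nfev=60,
                                ftol=1e-6, xtol=1e-6, gtol=1e-6)
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is not None:
        best = least_squares(_residuals, best.x, bounds=(lo, hi), args=(kind, t, A),
                             method="trf", x_scale="jac", max_nfev=400)
    if best is None:
        return GrowthFit(
            params=GrowthModelParams(0, 0, t[0], t[0], max(span, 1.0), float(A[0]), kind),
            param_errors={k: float("nan") for k in PARAM_NAMES},
            chi2=float("nan"), reduced_chi2=float("nan"), residual_sd=float("nan"),
            n_points=int(t.size), converged=False, flags=["no_start_converged"],
        )

    res1 = _residuals(best.x, kind, t, A)
    sigma = float(np.std(res1, ddof=1))
    flags: list[str] = []
    if sigma <= 0 or not np.isfinite(sigma):
        sigma = max(1e-12, 1e-9 * max(abs(A).max(), 1.0))
        flags.append("zero_residual_pass1")

    def wres(x: np.ndarray) -> np.ndarray:
        return _residuals(x, kind, t, A) / sigma

    sol2 = least_squares(wres, best.x, bounds=(lo, hi), method="trf",
                         x_scale="jac", max_nfev=400)
    params = _unpack(sol2.x, kind)
    chi2 = float(2.0 * sol2.cost)
    dof = max(t.size - 6, 1)

    J = sol2.jac
    errors = {}
    try:
        cov = np.linalg.inv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(6, np.nan)
        flags.append("singular_curvature")
    # x is (r1, r2, t0, dt1, tau, A0); t1 = t0 + dt1
    for i, name in enumerate(("r1", "r2", "t0", "t1", "tau", "A0")):
        errors[name] = float(se[i])
    if np.isfinite(se[2]) and np.isfinite(se[3]):
        errors["t1"] = float(np.hypot(se[2], se[3]))

    total_growth = abs(integrate_model(params, t)[-1] - params.A0)
    if total_growth < 2.0 * sigma:
        flags.append("degenerate_flat")

    return GrowthFit(
        params=params, param_errors=errors, chi2=chi2,
        reduced_chi2=chi2 / dof, residual_sd=sigma, n_points=int(t.size),
        converged=bool(sol2.success), flags=flags,
    )


def classify_morphology(curve) -> tuple[Morphology | None, dict[ModelKind, GrowthFit]]:
    """Fit both growth laws and pick the morphology of the better one.

    The models are compared by chi-square on a COMMON measurement
    sigma, which reduces to comparing the unweighted residual SDs:
    each fit's own reduced chi-square is ~1 by construction (its sigma
    is self-calibrated from its pass-1 residuals) and cannot rank
    models.  The lower residual SD wins; ties within 1% go to A_par
    (isotropic), which has fewer effective shape degrees of freedom.
    Returns (morphology or None if both fits failed, fits per kind).
    """
    fits: dict[ModelKind, GrowthFit] = {}
    for kind in (ModelKind.A_LIN, ModelKind.A_PAR):
        try:
            fits[kind] = fit_growth_curve(curve, kind)
        except ValueError:
            raise
    ok = {k: f for k, f in fits.items() if f.converged and np.isfinite(f.residual_sd)}
    if not ok:
        return None, fits
    if len(ok) == 1:
        kind = next(iter(ok))
    else:
        c_lin = ok[ModelKind.A_LIN].residual_sd
        c_par = ok[ModelKind.A_PAR].residual_sd
        if c_par <= c_lin or abs(c_lin - c_par) <= 0.01 * min(c_lin, c_par):
            kind = ModelKind.A_PAR
        else:
            kind = ModelKind.A_LIN
    morph = Morphology.ANISOTROPIC if kind is ModelKind.A_LIN else Morphology.ISOTROPIC
    return morph, fits


def extract_rates(
    fit: GrowthFit,
    morphology: Morphology | str,
    temperature_c: float | None = None,
    aggregate_id: int | str = 0,
) -> list[RateRecord]:
    """Deconvolute phase rates from a converged fit.

    Anisotropic fits yield two records: r1 (linear dendrite core) and
    r2 (branching part), both um^2/s.  Isotropic fits yield one record
    r_x, taken as the fitted r1 of the A_par model, i.e. the rate of
    the initial linear area-growth phase.
    """
    morphology = Morphology(morphology)
    p = fit.params
    flags = list(fit.flags)
    if morphology is Morphology.ANISOTROPIC:
        return [
            RateRecord(aggregate_id, morphology, Phase.LINEAR, p.r1, "um^2/s",
                       fit.param_errors.get("r1", float("nan")), temperature_c, flags),
            RateRecord(aggregate_id, morphology, Phase.BRANCHING, p.r2, "um^2/s",
                       fit.param_errors.get("r2", float("nan")), temperature_c, flags),
        ]
    return [
        RateRecord(aggregate_id, morphology, Phase.ISOTROPIC, p.r1, "um^2/s",
                   fit.param_errors.get("r1", float("nan")), temperature_c, flags),
    ]
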