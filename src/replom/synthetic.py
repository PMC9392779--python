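"""Synthetic spherulite-growth movies and calibration ensembles.

Generates localization-event tables from growing aggregates with known
ground truth, so every downstream stage (segmentation, area
estimation, model fitting, Arrhenius analysis, PSF metrics) can be
validated without microscope data.

The generator emulates the measurement process of real-time binding /
photobleaching localization microscopy: newly bound labeled monomers
appear as localization events whose per-frame count is Poisson with
mean ``label_density`` times the newly grown area; events are placed
uniformly in the newly grown region (an annulus for isotropic radial
growth; an elongating then branching strip pattern for anisotropic
growth); positions carry isotropic Gaussian localization jitter; each
emitter stays visible for a continuous-exponential on-time before
photobleaching.

Per-temperature rate ensembles for Arrhenius calibration, single-spot
pixel stacks for resolution estimation, and bleaching traces for
lifetime estimation are generated by the same module.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .growth_models import (
    GrowthModelParams, ModelKind, Morphology, Phase, RateRecord, integrate_model,
)
from .io_render import LocalizationTable
from .psf_metrics import FWHM_PER_SIGMA, SpotStack
from .thermo import R_GAS

__all__ = [
    "CORE_DIAMETER_NM",
    "SimulationConfig",
    "GroundTruth",
    "ArrheniusSimSpec",
    "simulate_aggregate",
    "simulate_background",
    "merge_tables",
    "simulate_rate_ensemble",
    "simulate_spot_stack",
    "simulate_bleach_traces",
]

CORE_DIAMETER_NM = 200.0  # initial condensate footprint
CORE_AREA_UM2 = math.pi * (CORE_DIAMETER_NM / 2000.0) ** 2

# anisotropic geometry: strip width equals the core diameter; branches
# spawn as a Poisson process along newly grown length with rate growing
# linearly in distance from the core, at +-70 degrees from the parent.
BRANCH_RATE_PER_UM2 = 0.5
BRANCH_MAX_ANGLE = math.radians(70.0)
MAX_TIPS = 128


@dataclass
class SimulationConfig:
    """Parameters of one simulated growing aggregate.

    Rates follow the growth laws: r1 in um^2/s; r2 in um^2/s for
    anisotropic (A_lin) growth and um^2/s^2 (parabolic slope) for
    isotropic (A_par) growth.  frame_interval defaults to the 20 s
    cadence typical of slow spherulite growth recordings;
    bleach_lifetime to the sub-frame mean on-time of Alexa Fluor 647
    without imaging buffer.
    """

    morphology: Morphology | str = Morphology.ISOTROPIC
    r1: float = 0.01
    r2: float = 0.0004
    t0: float = 1000.0
    t1: float = 4000.0
    tau: float = 600.0
    core_position: tuple[float, float] = (0.0, 0.0)  # nm
    frame_interval: float = 20.0  # s
    n_frames: int = 300
    label_density: float = 50.0  # events / um^2 of newly grown area
    loc_sigma: float = 28.0  # nm
    bleach_lifetime: float = 0.7845  # frames
    seed: int = 0

    def __post_init__(self) -> None:
        self.morphology = Morphology(self.morphology)
        vals = (self.r1, self.r2, self.t0, self.t1, self.tau,
                self.frame_interval, self.label_density, self.loc_sigma,
                self.bleach_lifetime)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("simulation parameters must be finite")
        if self.r1 < 0 or self.r2 < 0:
            raise ValueError("growth rates must be non-negative")
        if not (0 <= self.t0 <= self.t1):
            raise ValueError("need 0 <= t0 <= t1")
        if self.tau <= 0 or self.frame_interval <= 0:
            raise ValueError("tau and frame_interval must be positive")
        if self.label_density <= 0:
            raise ValueError("label_density must be positive")
        if self.loc_sigma < 0:
            raise ValueError("loc_sigma must be non-negative")
        if self.bleach_lifetime <= 0:
            raise ValueError("bleach_lifetime must be positive")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")

    @property
    def model_kind(self) -> ModelKind:
        return (ModelKind.A_LIN if self.morphology is Morphology.ANISOTROPIC
                else ModelKind.A_PAR)

    def model_params(self) -> GrowthModelParams:
        return GrowthModelParams(self.r1, self.r2, self.t0, self.t1, self.tau,
                                 A0=CORE_AREA_UM2, kind=self.model_kind)


@dataclass
class GroundTruth:
    """Everything the generator knows about a simulated aggregate."""

    times: np.ndarray        # s
    areas: np.ndarray        # um^2, the generating model's integral
    events: pd.DataFrame     # one row per emitter: frame, x, y (true, nm)
    morphology: Morphology
    params: GrowthModelParams
    config: SimulationConfig

    def to_json(self, path: str | Path) -> None:
        payload = {
            "morphology": self.morphology.value,
            "model_kind": self.params.kind.value,
            "params": {k: getattr(self.params, k)
                       for k in ("r1", "r2", "t0", "t1", "tau", "A0")},
            "area_curve": {"t_s": self.times.tolist(),
                           "area_um2": self.areas.tolist()},
            "n_events": int(len(self.events)),
            "config": {k: (v.value if isinstance(v, Morphology) else v)
                       for k, v in asdict(self.config).items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class ArrheniusSimSpec:
    """Per-temperature rate ensemble with log-normal scatter.

    Per-aggregate ln-rates are Normal(lnA - Ea/RT, sigma) with sigma
    chosen so the rate coefficient of variation equals
    ``rate_scatter_cv``; the per-temperature mean ln-rate then lies
    exactly on the Arrhenius line.
    """

    ea_kj_mol: float
    ln_a: float
    temperatures_k: tuple[float, ...]
    n_per_temperature: tuple[int, ...] | int
    rate_scatter_cv: float = 0.3
    phase: Phase | str = Phase.ISOTROPIC
    seed: int = 0

    def __post_init__(self) -> None:
        self.phase = Phase(self.phase)
        if len(self.temperatures_k) == 0:
            raise ValueError("temperature list must not be empty")
        if any(t <= 0 for t in self.temperatures_k):
            raise ValueError("temperatures must be positive kelvin")
        if self.ea_kj_mol < 0:
            raise ValueError("activation energy must be non-negative")
        if isinstance(self.n_per_temperature, int):
            self.n_per_temperature = (self.n_per_temperature,) * len(self.temperatures_k)
        if len(self.n_per_temperature) != len(self.temperatures_k):
            raise ValueError("n_per_temperature must match temperatures")
        if any(n < 2 for n in self.n_per_temperature):
            raise ValueError("need >= 2 rates per temperature")
        if self.rate_scatter_cv < 0:
            raise ValueError("rate_scatter_cv must be non-negative")


# ---------------------------------------------------------------------------
# aggregate simulation


def _place_isotropic(rng, counts, areas_um2, core):
    """Uniform placement in the newly grown annulus, frame by frame."""
    radii_nm = 1000.0 * np.sqrt(areas_um2 / math.pi)
    xs, ys, frames = [], [], []
    r_prev = 0.0
    for f, (cnt, r_now) in enumerate(zip(counts, radii_nm)):
        if cnt > 0:
            rr = np.sqrt(rng.uniform(r_prev**2, r_now**2, size=cnt))
            th = rng.uniform(0.0, 2.0 * math.pi, size=cnt)
            xs.append(core[0] + rr * np.cos(th))
            ys.append(core[1] + rr * np.sin(th))
            frames.append(np.full(cnt, f, dtype=np.int64))
        r_prev = r_now
    return frames, xs, ys


class _Tip:
    __slots__ = ("pos", "direction", "dist_um")

    def __init__(self, pos, direction, dist_um):
        self.pos = np.asarray(pos, dtype=float)
        self.direction = np.asarray(direction, dtype=float)
        self.dist_um = float(dist_um)


def _place_anisotropic(rng, counts, areas_um2, t0, frame_interval, core):
    """Elongating linear strip, then a branching tree of strips.

    Total strip length tracks L = A / w with w the core diameter, so
    the occupied area follows the generating model.  During phase 1 the
    structure is one bidirectional segment through the core; from t0 on
    the active tips share the growth and spawn branches as a Poisson
    process along newly grown length with rate BRANCH_RATE_PER_UM2 *
    (distance from core, um), each at a uniform angle within +-70
    degrees of its parent.
    """
    w = CORE_DIAMETER_NM
    core = np.asarray(core, dtype=float)
    theta = rng.uniform(0.0, 2.0 * math.pi)
    u = np.array([math.cos(theta), math.sin(theta)])

    lengths_nm = areas_um2 * 1e6 / w  # total strip length per frame
    xs, ys, frames = [], [], []
    tips: list[_Tip] = []
    half_prev = 0.0
    phase2 = False
    for f, cnt in enumerate(counts):
        t = f * frame_interval
        L_now = lengths_nm[f]
        L_prev = lengths_nm[f - 1] if f > 0 else 0.0
        dL = max(L_now - L_prev, 0.0)
        new_strips = []  # (start_pos, direction, length)
        if t < t0 and not phase2:
            half_now = L_now / 2.0
            if half_now > half_prev:
                for sign in (+1.0, -1.0):
                    start = core + sign * half_prev * u
                    new_strips.append((start, sign * u, half_now - half_prev))
            half_prev = half_now
        else:
            if not phase2:  # hand the two segment ends to the tip machinery
                phase2 = True
                tips = [_Tip(core + half_prev * u, u, half_prev / 1000.0),
                        _Tip(core - half_prev * u, -u, half_prev / 1000.0)]
            if dL > 0 and tips:
                ext = dL / len(tips)
                spawned = []
                for tip in tips:
                    start = tip.pos.copy()
                    tip.pos = tip.pos + ext * tip.direction
                    tip.dist_um += ext / 1000.0
                    new_strips.append((start, tip.direction, ext))
                    lam = BRANCH_RATE_PER_UM2 * tip.dist_um * (ext / 1000.0)
                    for _ in range(rng.poisson(lam)):
                        if len(tips) + len(spawned) >= MAX_TIPS:
                            break
                        frac = rng.uniform()
                        origin = start + frac * ext * tip.direction
                        ang = rng.uniform(-BRANCH_MAX_ANGLE, BRANCH_MAX_ANGLE)
                        c, s = math.cos(ang), math.sin(ang)
                        d = tip.direction
                        ndir = np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])
                        spawned.append(_Tip(origin, ndir, tip.dist_um))
                tips.extend(spawned)
        if cnt > 0:
            if not new_strips:  # no growth this frame: place in the core
                new_strips = [(core - (w / 2.0) * u, u, w)]
            seg_len = np.array([s[2] for s in new_strips])
            pick = rng.choice(len(new_strips), size=cnt, p=seg_len / seg_len.sum())
            along = rng.uniform(0.0, 1.0, size=cnt)
            lat = rng.uniform(-w / 2.0, w / 2.0, size=cnt)
            pos = np.empty((cnt, 2))
            for i, (k, a, l) in enumerate(zip(pick, along, lat)):
                start, d, ln = new_strips[k]
                normal = np.array([-d[1], d[0]])
                pos[i] = start + a * ln * d + l * normal
            xs.append(pos[:, 0])
            ys.append(pos[:, 1])
            frames.append(np.full(cnt, f, dtype=np.int64))
    return frames, xs, ys


def simulate_aggregate(config: SimulationConfig) -> tuple[LocalizationTable, GroundTruth]:
    """Simulate one growing aggregate's localization-event movie.

    Returns the localization table (with jitter, bleaching-limited
    redetections and photon intensities) and the exact ground truth
    (area curve from the generating model's integral and true emitter
    positions/frames).
    """
    rng = np.random.default_rng(config.seed)
    params = config.model_params()
    times = np.arange(config.n_frames) * config.frame_interval
    areas = integrate_model(params, times, A0=CORE_AREA_UM2)

    # frame 0 deposits the pre-formed core; afterwards only new growth emits
    delta = np.diff(areas, prepend=0.0)
    delta[0] = areas[0]
    counts = rng.poisson(config.label_density * np.clip(delta, 0.0, None))

    core = np.asarray(config.core_position, dtype=float)
    if config.morphology is Morphology.ISOTROPIC:
        frames, xs, ys = _place_isotropic(rng, counts, areas, core)
    else:
        frames, xs, ys = _place_anisotropic(
            rng, counts, areas, config.t0, config.frame_interval, core)

    if frames:
        ev_frame = np.concatenate(frames)
        ev_x = np.concatenate(xs)
        ev_y = np.concatenate(ys)
    else:
        ev_frame = np.empty(0, dtype=np.int64)
        ev_x = ev_y = np.empty(0)
    events = pd.DataFrame({"frame": ev_frame, "x": ev_x, "y": ev_y})

    # photobleaching: an emitter bound in frame f is detected in frames
    # f .. f + ceil(L) - 1 for an exponential on-time L (frames)
    n_ev = len(ev_frame)
    on_frames = np.maximum(
        np.ceil(rng.exponential(config.bleach_lifetime, size=n_ev)), 1.0
    ).astype(np.int64)
    det_frame, det_x, det_y = [], [], []
    for i in range(n_ev):
        stop = min(int(ev_frame[i]) + int(on_frames[i]), config.n_frames)
        ff = np.arange(ev_frame[i], stop, dtype=np.int64)
        det_frame.append(ff)
        det_x.append(np.full(ff.size, ev_x[i]))
        det_y.append(np.full(ff.size, ev_y[i]))
    if det_frame:
        det_frame = np.concatenate(det_frame)
        det_x = np.concatenate(det_x)
        det_y = np.concatenate(det_y)
    else:
        det_frame = np.empty(0, dtype=np.int64)
        det_x = det_y = np.empty(0)
    n_det = len(det_frame)
    det_x = det_x + rng.normal(0.0, config.loc_sigma, size=n_det)
    det_y = det_y + rng.normal(0.0, config.loc_sigma, size=n_det)
    intensity = rng.gamma(4.0, 125.0, size=n_det)  # mean 500 photons
    unc = np.full(n_det, config.loc_sigma)

    table = LocalizationTable(det_frame, det_x, det_y, intensity, unc,
                              frame_interval=config.frame_interval)
    truth = GroundTruth(times, areas, events, config.morphology, params, config)
    return table, truth


def simulate_background(
    bbox_nm: tuple[float, float, float, float],
    n_frames: int,
    total_events: int,
    loc_sigma: float = 28.0,
    seed: int = 0,
) -> LocalizationTable:
    """Sparse background localizations uniform over a field of view.

    Emulates the false positives and transiently bound monomers that
    pepper a real recording away from any aggregate.  ``bbox_nm`` is
    (xmin, ymin, xmax, ymax).
    """
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = bbox_nm
    x = rng.uniform(xmin, xmax, size=total_events)
    y = rng.uniform(ymin, ymax, size=total_events)
    frame = np.sort(rng.integers(0, n_frames, size=total_events))
    intensity = rng.gamma(4.0, 125.0, size=total_events)
    return LocalizationTable(frame, x, y, intensity,
                             np.full(total_events, loc_sigma))


def merge_tables(tables: list[LocalizationTable]) -> LocalizationTable:
    """Pool several localization tables into one field of view."""
    if not tables:
        raise ValueError("nothing to merge")
    unc = None
    if all(t.uncertainty is not None for t in tables):
        unc = np.concatenate([t.uncertainty for t in tables])
    return LocalizationTable(
        np.concatenate([t.frame for t in tables]),
        np.concatenate([t.x for t in tables]),
        np.concatenate([t.y for t in tables]),
        np.concatenate([t.intensity for t in tables]),
        unc,
        frame_interval=tables[0].frame_interval,
        temperature_c=tables[0].temperature_c,
    )


# ---------------------------------------------------------------------------
# calibration ensembles


def simulate_rate_ensemble(spec: ArrheniusSimSpec) -> list[RateRecord]:
    """Draw per-aggregate rates per temperature along an Arrhenius law."""
    rng = np.random.default_rng(spec.seed)
    sigma = math.sqrt(math.log1p(spec.rate_scatter_cv**2))
    morph = (Morphology.ISOTROPIC if spec.phase is Phase.ISOTROPIC
             else Morphology.ANISOTROPIC)
    records: list[RateRecord] = []
    agg_id = 0
    for T, n in zip(spec.temperatures_k, spec.n_per_temperature):
        mu = spec.ln_a - spec.ea_kj_mol * 1000.0 / (R_GAS * T)
        ln_rates = mu + sigma * rng.standard_normal(n)
        for lr in ln_rates:
            records.append(RateRecord(
                aggregate_id=agg_id, morphology=morph, phase=spec.phase,
                rate=float(np.exp(lr)), rate_units="um^2/s",
                rate_se=float("nan"), temperature_c=float(T - 273.15),
            ))
            agg_id += 1
    return records


def simulate_spot_stack(
    n_spots: int,
    fwhm: float,
    photons: float,
    background: float = 0.0,
    pixel_size: float = 20.0,
    seed: int = 0,
    patch_size: int | None = None,
) -> SpotStack:
    """Pixel patches of Poisson-sampled isotropic Gaussian spots.

    fwhm, pixel_size in nm; photons is the mean photon count per spot;
    background in photons/pixel.  Each spot's center is offset by a
    uniform sub-pixel amount.  The patch must span at least 3 x FWHM.
    """
    if fwhm <= 0 or pixel_size <= 0:
        raise ValueError("fwhm and pixel_size must be positive")
    if n_spots < 1:
        raise ValueError("need at least one spot")
    min_pix = int(math.ceil(3.0 * fwhm / pixel_size))
    if patch_size is None:
        patch_size = min_pix + (1 - min_pix % 2)  # round up to odd
    if patch_size * pixel_size < 3.0 * fwhm:
        raise ValueError(
            f"patch of {patch_size} px ({patch_size * pixel_size:g} nm) cannot "
            f"contain 3 x FWHM = {3 * fwhm:g} nm")
    rng = np.random.default_rng(seed)
    sigma = fwhm / FWHM_PER_SIGMA
    from scipy.special import ndtr

    edges = np.arange(patch_size + 1) * pixel_size
    patches = np.empty((n_spots, patch_size, patch_size))
    centers = np.empty((n_spots, 2))
    mid = patch_size * pixel_size / 2.0
    for i in range(n_spots):
        cx = mid + rng.uniform(-0.5, 0.5) * pixel_size
        cy = mid + rng.uniform(-0.5, 0.5) * pixel_size
        fx = ndtr((edges[1:] - cx) / sigma) - ndtr((edges[:-1] - cx) / sigma)
        fy = ndtr((edges[1:] - cy) / sigma) - ndtr((edges[:-1] - cy) / sigma)
        mu = photons * np.outer(fy, fx) + background
        patches[i] = rng.poisson(mu)
        centers[i] = (cx, cy)
    return SpotStack(patches, pixel_size, centers_nm=None)


def simulate_bleach_traces(
    n: int, mean_lifetime: float, seed: int = 0,
) -> list[np.ndarray]:
    """Frame spans of emitters with continuous-exponential on-times.

    An emitter switches on at a frame boundary; with on-time L (in
    frame units) it is detected in ceil(L) consecutive frames (at
    least one).  Start frames are randomized for realism; only spans
    matter to the lifetime estimator.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if mean_lifetime <= 0:
        raise ValueError("mean_lifetime must be positive")
    rng = np.random.default_rng(seed)
    on = np.maximum(np.ceil(rng.exponential(mean_lifetime, size=n)), 1.0).astype(np.int64)
    starts = rng.integers(0, 1000, size=n)
    return [np.arange(s, s + k, dtype=np.int64) for s, k in zip(starts, on)]
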