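"""Per-frame aggregate area from a Gaussian-mixture density estimate.

The aggregate's area in a frame is estimated by fitting a Gaussian
mixture to its retained localizations — one component per 5 points,
never fewer than 25 (and never more than n/2, to keep the fit
identifiable) — and measuring the region of the plane whose fitted
probability density lies above the average density evaluated at the
member points.  The region is measured by counting pixels of a 20 nm
grid over the padded bounding box.  Repeating per frame yields the
(time, area) growth curve fitted by :mod:`replom.growth_models`.

Growth curves carry jumps and fluctuations from mixture fitting and
segmentation; no smoothing is applied before model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .io_render import LocalizationTable
from .segmentation import AggregateCluster, frame_membership

__all__ = [
    "AreaEstimate",
    "GrowthCurve",
    "n_gmm_components",
    "estimate_area_gmm",
    "build_growth_curve",
]

MIN_POINTS = 50  # below this the 25-component floor is ill-posed


@dataclass
class AreaEstimate:
    frame: int
    area_um2: float
    n_points: int
    n_components: int
    threshold_density: float  # nm^-2
    flags: list[str] = field(default_factory=list)


@dataclass
class GrowthCurve:
    """Per-aggregate (time, area) series; the object the models fit.

    times in s (strictly increasing), areas in um^2.  Frames skipped
    for having too few points are simply absent (gaps allowed).
    """

    aggregate_id: int | str
    times: np.ndarray
    areas: np.ndarray
    frames: np.ndarray | None = None
    n_points: np.ndarray | None = None
    frame_interval: float | None = None
    temperature_c: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.times.shape != self.areas.shape:
            raise ValueError("times/areas shape mismatch")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.areas)):
            raise ValueError("areas must be finite")

    def __len__(self) -> int:
        return len(self.times)


def n_gmm_components(n_points: int) -> int:
    """Mixture size rule: one component per 5 points, floor 25, cap n/2."""
    return int(min(max(n_points // 5, 25), n_points // 2))


def estimate_area_gmm(
    points: np.ndarray,
    grid_pixel: float = 20.0,
    seed: int | None = 0,
    frame: int = -1,
) -> AreaEstimate | None:
    """Area of a point cloud as the super-mean-density region of a GMM fit.

    points: (n, 2) nm.  Returns None when n < 50 (the frame is recorded
    as a gap by the caller).  The fitted density is evaluated at every
    member point; their mean is the threshold; the area is the number
    of grid pixels (bounding box padded by 3x the largest mixture SD)
    whose density is >= threshold, times pixel^2, reported in um^2.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    if grid_pixel <= 0:
        raise ValueError("grid_pixel must be positive")
    n = len(pts)
    if n < MIN_POINTS:
        return None
    n_comp = n_gmm_components(n)

    # covariance floor at the sampling scale: structure below the point
    # spacing is unresolvable, and without a floor components collapse
    # into density spikes that wreck the average-density threshold.
    # The 3rd-NN distance is used because repeat detections of one
    # emitter (bleaching takes > 1 frame) sit at jitter distance and
    # corrupt the 1st-NN spacing.
    from scipy.spatial import cKDTree

    k3 = cKDTree(pts).query(pts, k=4)[0][:, 3]
    h = 0.7 * float(np.median(k3))
    reg0 = max(h * h, 1e-2)

    flags: list[str] = []
    gm = None
    for mult in (1.0, 10.0, 100.0):  # escalate on singular fits
        try:
            cand = GaussianMixture(
                n_components=n_comp, covariance_type="full",
                init_params="k-means++", random_state=seed,
                reg_covar=reg0 * mult, max_iter=200,
            ).fit(pts)
        except ValueError:
            continue
        gm = cand
        if mult > 1.0:
            flags.append(f"reg_covar_raised_x{mult:g}")
        break
    if gm is None:
        raise RuntimeError("Gaussian mixture fit failed at all regularizations")

    sds = np.sqrt(np.linalg.eigvalsh(gm.covariances_).max(axis=1))
    pad = 3.0 * float(sds.max())
    x0, x1 = pts[:, 0].min() - pad, pts[:, 0].max() + pad
    y0, y1 = pts[:, 1].min() - pad, pts[:, 1].max() + pad
    gx = np.arange(x0 + grid_pixel / 2, x1, grid_pixel)
    gy = np.arange(y0 + grid_pixel / 2, y1, grid_pixel)
    # evaluate the density by grid rows to bound memory on large maps
    # (score_samples allocates n_points x n_components internally)
    dens_rows = []
    chunk = max(1, int(4_000_000 / max(n_comp * len(gx), 1)))
    for start in range(0, len(gy), chunk):
        yy = gy[start:start + chunk]
        XX, YY = np.meshgrid(gx, yy)
        dens_rows.append(
            np.exp(gm.score_samples(np.column_stack([XX.ravel(), YY.ravel()])))
        )
    dens = np.concatenate(dens_rows)
    # the aggregate is the region denser than the average fitted density
    # over the padded bounding box
    threshold = float(dens.mean())
    area_um2 = int(np.sum(dens >= threshold)) * (grid_pixel ** 2) / 1e6
    return AreaEstimate(frame, area_um2, n, n_comp, threshold, flags)


def build_growth_curve(
    cluster: AggregateCluster,
    table: LocalizationTable,
    frame_interval: float | None = None,
    refine_k: int = 10,
    refine_cutoff: float = 400.0,
    grid_pixel: float = 20.0,
    frame_stride: int = 1,
    seed: int | None = 0,
    min_curve_points: int = 8,
) -> GrowthCurve:
    """Assemble an aggregate's (time, area) growth curve.

    For every ``frame_stride``-th frame: refine the cluster's cumulative
    membership (:func:`frame_membership`) and estimate the area of the
    retained points.  Frames with fewer than 50 retained points are
    gaps.  Raises ValueError when fewer than ``min_curve_points`` frames
    yield an area (unfittable curve).
    """
    if frame_interval is None:
        frame_interval = table.frame_interval
    if frame_interval is None or frame_interval <= 0:
        raise ValueError("frame_interval must be provided (s/frame)")
    member_frames = table.frame[cluster.members]
    f_lo, f_hi = int(member_frames.min()), int(member_frames.max())
    frames, times, areas, npts = [], [], [], []
    for f in range(f_lo, f_hi + 1, max(frame_stride, 1)):
        fm = frame_membership(cluster, table, f, k=refine_k, cutoff=refine_cutoff)
        if len(fm) < MIN_POINTS:
            continue
        est = estimate_area_gmm(table.points[fm.retained], grid_pixel, seed=seed, frame=f)
        if est is None:
            continue
        frames.append(f)
        times.append(f * frame_interval)
        areas.append(est.area_um2)
        npts.append(est.n_points)
    if len(frames) < min_curve_points:
        raise ValueError(
            f"cluster {cluster.cluster_id}: only {len(frames)} valid area points "
            f"(< {min_curve_points}); curve unfittable"
        )
    return GrowthCurve(
        aggregate_id=cluster.cluster_id,
        times=np.array(times), areas=np.array(areas),
        frames=np.array(frames), n_points=np.array(npts),
        frame_interval=frame_interval, temperature_c=table.temperature_c,
    )
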