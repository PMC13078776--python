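"""Trajectory statistics for surface-swimming bacteria in lanes.

All operations act on :class:`Trajectory` objects — uniformly sampled 2-D
tracks (default 20 fps) — and apply identically to particle-tracking exports
and simulator output:

* per-frame velocity by a fourth-order central difference,
* ensemble drift velocity by regression of mean lagged displacement on lag
  time,
* mean-squared orientational displacement (MSOD) and its power-law exponent
  ``gamma_R``, which separates straight (0), diffusive (~1) and circular (~2)
  motion,
* algebraic (Kasa) circle fitting after Savitzky-Golay smoothing,
* tumble detection from speed drops,
* classification of tracks into left-sidewall / middle-area / right-sidewall
  regions by mean transverse position,
* truncated-exponential fits to tumble-angle magnitudes on [0, pi].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar
from scipy.signal import savgol_filter

__all__ = [
    "Trajectory",
    "DriftEstimate",
    "RotationalFit",
    "CircleFit",
    "TumbleEvent",
    "RegionLabel",
    "instantaneous_velocity",
    "trajectory_speed",
    "drift_velocity",
    "msod",
    "rotational_exponent",
    "detect_tumbles",
    "tumble_events_from_speeds",
    "fit_circle",
    "classify_region",
    "region_proportions",
    "rsw_direction_split",
    "fit_truncated_exponential",
]

DEFAULT_DT = 0.05  # s, 20 fps
DEFAULT_LAGS = tuple(range(1, 40, 2))  # n = 1, 3, ..., 39
MSOD_SPEED_FLOOR = 1.0  # um/s; below this the heading is ill-defined
MSOD_ZERO_FLOOR = 1e-12  # rad^2; all-below means a perfectly straight track


class TooShortError(ValueError):
    """Trajectory has too few frames for the requested statistic."""


@dataclass
class Trajectory:
    """A uniformly time-stamped 2-D track (simulated or from tracking software)."""

    track_id: str
    times: np.ndarray  # s
    xs: np.ndarray  # um
    ys: np.ndarray  # um
    source: str = "simulation"  # "experiment" | "simulation"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.xs = np.asarray(self.xs, dtype=float)
        self.ys = np.asarray(self.ys, dtype=float)
        if not (self.times.shape == self.xs.shape == self.ys.shape):
            raise ValueError("times, xs, ys must have equal length")
        if self.times.size >= 2:
            steps = np.diff(self.times)
            if np.ptp(steps) > 1e-6:
                raise ValueError("trajectory must be uniformly sampled (within 1e-6 s)")

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            raise TooShortError("need at least 2 frames to define dt")
        return float(self.times[1] - self.times[0])

    def mean_y(self) -> float:
        return float(np.mean(self.ys))

    def net_dx(self) -> float:
        return float(self.xs[-1] - self.xs[0])


@dataclass(frozen=True)
class DriftEstimate:
    v_d: float  # um/s, slope of <x(i+n) - x(i)> vs n*dt
    sd: float  # um/s, standard error of the slope
    intercept: float  # um
    lags_used: tuple = DEFAULT_LAGS


@dataclass(frozen=True)
class RotationalFit:
    c_r: float  # rad^2 / s^gamma
    gamma_r: float
    tau_max: float = 0.4


@dataclass(frozen=True)
class CircleFit:
    center: tuple  # (a, b) um
    radius: float  # um
    residual: float  # um, rms distance of points from the fitted circle


@dataclass(frozen=True)
class TumbleEvent:
    start_idx: int
    end_idx: int
    duration: float  # s
    angle: float  # rad, signed heading change across the event


@dataclass(frozen=True)
class RegionLabel:
    region: str  # "LSW" | "MA" | "RSW"
    d_threshold: float
    lane_width: float


# ---------------------------------------------------------------------------
# velocity and speed


def instantaneous_velocity(traj: Trajectory) -> np.ndarray:
    """Per-frame velocity vectors (um/s) by the 5-point central difference.

    Returns an ``(n_frames - 4, 2)`` array for the interior frames
    ``2 .. n-3``; the first and last two frames have no estimate.
    """
    n = traj.n_frames
    if n < 5:
        raise TooShortError(f"need >= 5 frames for the 5-point stencil, got {n}")
    dt = traj.dt
    out = np.empty((n - 4, 2))
    for j, u in enumerate((traj.xs, traj.ys)):
        out[:, j] = (8.0 * (u[3:-1] - u[1:-3]) - (u[4:] - u[:-4])) / (12.0 * dt)
    return out


def _speeds(traj: Trajectory) -> np.ndarray:
    return np.linalg.norm(instantaneous_velocity(traj), axis=1)


def trajectory_speed(traj: Trajectory) -> float:
    """Mean speed (um/s): the average of |v_i| over interior frames."""
    return float(np.mean(_speeds(traj)))


# ---------------------------------------------------------------------------
# drift


def drift_velocity(trajs, lags=DEFAULT_LAGS, dt: float | None = None,
                   weighting: str = "track") -> DriftEstimate:
    """Ensemble drift velocity from lag regression of mean x-displacement.

    For each lag ``n`` the displacement ``x(i+n) - x(i)`` is averaged within
    each trajectory and the per-trajectory means are averaged with equal
    weight (``weighting="track"``, the convention of per-trajectory
    displacement curves); ``weighting="pooled"`` instead pools all frame
    pairs, which weights trajectories by their length.  An ordinary
    least-squares line of the mean displacement against ``n*dt`` (with
    intercept) gives the drift velocity as its slope.  Trajectories shorter
    than a lag simply contribute nothing to it.
    """
    if isinstance(trajs, Trajectory):
        trajs = [trajs]
    trajs = list(trajs)
    if not trajs:
        raise ValueError("need at least one trajectory")
    if weighting not in ("track", "pooled"):
        raise ValueError("weighting must be 'track' or 'pooled'")
    if dt is None:
        dt = next(t.dt for t in trajs if t.n_frames >= 2)
    lags = tuple(int(n) for n in lags)

    sums = np.zeros(len(lags))
    counts = np.zeros(len(lags), dtype=np.int64)
    for t in trajs:
        x = t.xs
        for k, n in enumerate(lags):
            if x.size > n:
                d = x[n:] - x[:-n]
                if weighting == "track":
                    sums[k] += d.mean()
                    counts[k] += 1
                else:
                    sums[k] += d.sum()
                    counts[k] += d.size
    valid = counts > 0
    if not np.any(valid):
        raise ValueError("no trajectory long enough for any requested lag")
    tau = np.array(lags, dtype=float)[valid] * dt
    mean_disp = sums[valid] / counts[valid]
    if tau.size < 2:
        raise ValueError("need at least two lags with data for a linear fit")
    design = np.column_stack([tau, np.ones_like(tau)])
    coef, res, *_ = np.linalg.lstsq(design, mean_disp, rcond=None)
    slope, intercept = coef
    dof = tau.size - 2
    if dof > 0 and res.size:
        s2 = res[0] / dof
        sxx = np.sum((tau - tau.mean()) ** 2)
        sd = float(np.sqrt(s2 / sxx))
    else:
        sd = np.nan
    return DriftEstimate(
        v_d=float(slope), sd=sd, intercept=float(intercept),
        lags_used=tuple(np.array(lags)[valid]),
    )


# ---------------------------------------------------------------------------
# orientation statistics


def _headings(traj: Trajectory):
    """Headings (rad) from velocity direction; low-speed frames are masked."""
    v = instantaneous_velocity(traj)
    speed = np.linalg.norm(v, axis=1)
    theta = np.arctan2(v[:, 1], v[:, 0])
    return theta, speed >= MSOD_SPEED_FLOOR


def _wrap_angle(a):
    """Wrap angle differences to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(a), 2.0 * np.pi)


def msod(traj: Trajectory, tau_max: float = 0.4):
    """Mean-squared orientational displacement curve.

    Returns ``(taus, msod_values)`` for lag times ``k*dt < tau_max``.  Heading
    differences are wrapped to (-pi, pi]; frames slower than 1 um/s are
    excluded (their direction is ill-defined).
    """
    theta, ok = _headings(traj)
    dt = traj.dt
    k_max = int(np.ceil(tau_max / dt)) - 1
    if k_max < 1 or theta.size < 2:
        raise TooShortError("trajectory too short for any MSOD lag")
    taus, values = [], []
    for k in range(1, min(k_max, theta.size - 1) + 1):
        pair_ok = ok[k:] & ok[:-k]
        if not np.any(pair_ok):
            continue
        dth = _wrap_angle(theta[k:] - theta[:-k])[pair_ok]
        taus.append(k * dt)
        values.append(np.mean(dth**2))
    if not taus:
        raise TooShortError("no usable frame pairs for MSOD")
    return np.array(taus), np.array(values)


def rotational_exponent(msod_curve, tau_max: float = 0.4) -> RotationalFit:
    """Power-law fit ``MSOD = C_R * tau^gamma_R`` by log-log least squares.

    ``msod_curve`` is a ``(taus, values)`` pair as returned by :func:`msod`.
    If every MSOD value is below a tiny floor the track is straight and
    ``gamma_R = 0`` is returned by convention.
    """
    taus, values = msod_curve
    taus = np.asarray(taus, dtype=float)
    values = np.asarray(values, dtype=float)
    if np.all(values < MSOD_ZERO_FLOOR):
        return RotationalFit(c_r=0.0, gamma_r=0.0, tau_max=tau_max)
    keep = values > MSOD_ZERO_FLOOR
    if keep.sum() < 3:
        raise ValueError("need >= 3 positive MSOD points for a power-law fit")
    coef = np.polyfit(np.log(taus[keep]), np.log(values[keep]), 1)
    return RotationalFit(c_r=float(np.exp(coef[1])), gamma_r=float(coef[0]), tau_max=tau_max)


# ---------------------------------------------------------------------------
# tumbles


def tumble_events_from_speeds(speeds, thetas, dt: float, alpha: float = 1.0 / 6.0) -> list:
    """The tumble rule on a speed (and heading) series.

    A tumble is a maximal run of >= 2 consecutive samples with speed below
    the series mean ``<v_i>`` in which every sample sits substantially below
    the last pre-event speed: ``v_t0 - v_t > <v_i> * alpha`` for all event
    samples ``t`` (``t0`` is the sample preceding the event).  Events at the
    very start of the series have no ``t0`` and are discarded.  The event
    angle is the heading change from ``t0`` to the sample after the event,
    wrapped to (-pi, pi]; indices refer to the input series.
    """
    speeds = np.asarray(speeds, dtype=float)
    thetas = np.asarray(thetas, dtype=float)
    v_mean = speeds.mean()
    below = speeds < v_mean
    events: list[TumbleEvent] = []
    i = 0
    n = speeds.size
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and below[j + 1]:
            j += 1
        length = j - i + 1
        if length >= 2 and i >= 1:
            v0 = speeds[i - 1]
            if np.all(v0 - speeds[i : j + 1] > v_mean * alpha):
                pre = thetas[i - 1]
                post = thetas[j + 1] if j + 1 < n else thetas[j]
                events.append(
                    TumbleEvent(
                        start_idx=i,
                        end_idx=j,
                        duration=length * dt,
                        angle=float(_wrap_angle(post - pre)),
                    )
                )
        i = j + 1
    return events


def detect_tumbles(traj: Trajectory, alpha: float = 1.0 / 6.0) -> list:
    """Tumble events of a trajectory: slow stretches entered by a sharp drop.

    Speeds and headings come from :func:`instantaneous_velocity`; the rule is
    :func:`tumble_events_from_speeds`.  Event indices are converted to raw
    frame numbers (the stencil drops the first two frames).
    """
    speeds = _speeds(traj)
    theta, _ = _headings(traj)
    events = tumble_events_from_speeds(speeds, theta, traj.dt, alpha)
    return [
        TumbleEvent(start_idx=e.start_idx + 2, end_idx=e.end_idx + 2,
                    duration=e.duration, angle=e.angle)
        for e in events
    ]


# ---------------------------------------------------------------------------
# circle fit


def fit_circle(traj: Trajectory, smooth_window: int = 5, min_gamma: float | None = None) -> CircleFit:
    """Algebraic (Kasa) circle fit after Savitzky-Golay smoothing.

    Writing the circle as ``x^2 + y^2 = 2 a x + 2 b y + c`` turns the fit into
    the linear least-squares problem ``B = A @ [2a, 2b, c]`` with rows
    ``A = [x, y, 1]`` and ``B = x^2 + y^2``; the radius is
    ``sqrt(c + a^2 + b^2)``.  With ``min_gamma`` set, tracks whose rotational
    exponent does not exceed it are rejected (the gate used to select
    circular middle-area tracks).
    """
    if min_gamma is not None:
        gamma = rotational_exponent(msod(traj)).gamma_r
        if gamma <= min_gamma:
            raise ValueError(
                f"track rejected by the circularity gate: gamma_R={gamma:.3f} <= {min_gamma}"
            )
    xs, ys = traj.xs, traj.ys
    if smooth_window >= 5 and xs.size >= smooth_window:
        xs = savgol_filter(xs, smooth_window, polyorder=2)
        ys = savgol_filter(ys, smooth_window, polyorder=2)
    design = np.column_stack([xs, ys, np.ones_like(xs)])
    rhs = xs**2 + ys**2
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("degenerate geometry: points are collinear (or too few)")
    coef, *_ = np.linalg.lstsq(design, rhs, rcond=None)
    a, b = coef[0] / 2.0, coef[1] / 2.0
    r2 = coef[2] + a**2 + b**2
    if r2 <= 0:
        raise ValueError("degenerate geometry: non-positive squared radius")
    radius = float(np.sqrt(r2))
    dist = np.hypot(xs - a, ys - b)
    return CircleFit(center=(float(a), float(b)), radius=radius,
                     residual=float(np.sqrt(np.mean((dist - radius) ** 2))))


# ---------------------------------------------------------------------------
# regions


def classify_region(traj: Trajectory, lane_width: float, d: float = 3.0) -> RegionLabel:
    """Assign LSW / MA / RSW by mean transverse position.

    ``<y> <= d`` is LSW, ``<y> >= w - d`` is RSW, strictly between is MA
    (boundary values go to the walls).  For ``w <= 2d`` the MA region is
    empty, which is allowed but warned about.
    """
    if lane_width <= 0:
        raise ValueError("lane width must be positive")
    if lane_width <= 2 * d:
        warnings.warn(
            f"lane width {lane_width} <= 2*d = {2 * d}: the MA region is empty",
            stacklevel=2,
        )
    y = traj.mean_y()
    if y <= d:
        region = "LSW"
    elif y >= lane_width - d:
        region = "RSW"
    else:
        region = "MA"
    return RegionLabel(region=region, d_threshold=d, lane_width=lane_width)


def region_proportions(trajs, lane_width: float, d: float = 3.0):
    """Fractions of trajectories in (LSW, MA, RSW); they sum to 1."""
    trajs = list(trajs)
    if not trajs:
        raise ValueError("need at least one trajectory")
    counts = {"LSW": 0, "MA": 0, "RSW": 0}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # warn once at most, not per track
        if lane_width <= 2 * d:
            warnings.simplefilter("default")
        for t in trajs:
            counts[classify_region(t, lane_width, d).region] += 1
    n = len(trajs)
    return counts["LSW"] / n, counts["MA"] / n, counts["RSW"] / n


def rsw_direction_split(trajs):
    """(up-gradient, down-gradient) fractions of RSW tracks by net x sign.

    A track counts as up-gradient when its net x displacement is positive
    (ties count as down-gradient); the caller supplies tracks already
    classified as RSW.
    """
    trajs = list(trajs)
    if not trajs:
        raise ValueError("need at least one RSW trajectory")
    up = sum(1 for t in trajs if t.net_dx() > 0)
    return up / len(trajs), 1.0 - up / len(trajs)


# ---------------------------------------------------------------------------
# tumble-angle distribution


def truncated_exponential_norm(b: float) -> float:
    """Normalization ``a = (1/b) / (1 - exp(-pi/b))`` of the angle density."""
    return (1.0 / b) / (1.0 - np.exp(-np.pi / b))


def _truncexp_pdf(x, b):
    return truncated_exponential_norm(b) * np.exp(-x / b)


def fit_truncated_exponential(angles, n_bins: int = 18, method: str = "histogram"):
    """Fit the characteristic angle ``b`` of ``a * exp(-x/b)`` on [0, pi].

    ``method="histogram"`` least-squares fits the density-normalized
    histogram (18 equal bins on [0, pi] by default), mirroring how measured
    tumble-angle distributions are usually fitted; ``method="mle"`` maximizes
    the truncated-exponential likelihood directly and avoids binning.

    Returns ``(b, norm_a)``.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size < 50:
        raise ValueError(f"need >= 50 angles, got {angles.size}")
    if np.any((angles < 0) | (angles > np.pi)):
        raise ValueError("angles must lie in [0, pi]")
    mean = angles.mean()
    if mean < 1e-3:
        warnings.warn("all angles ~ 0: the fitted b is degenerate", stacklevel=2)
        b = max(mean, 1e-6)
        return float(b), float(truncated_exponential_norm(b))

    if method == "mle":
        def nll(b):
            return angles.sum() / b + angles.size * np.log(
                b * (1.0 - np.exp(-np.pi / b))
            )
        res = minimize_scalar(nll, bounds=(1e-4, 50.0), method="bounded")
        b = float(res.x)
    elif method == "histogram":
        density, edges = np.histogram(angles, bins=n_bins, range=(0.0, np.pi), density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        popt, _ = curve_fit(_truncexp_pdf, centers, density, p0=[mean], bounds=(1e-4, 50.0))
        b = float(popt[0])
    else:
        raise ValueError("method must be 'histogram' or 'mle'")
    return b, float(truncated_exponential_norm(b))
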