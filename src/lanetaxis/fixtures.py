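"""Synthetic tracked trajectories with known ground truth.

The raw experimental tracks behind lane-chemotaxis studies are rarely
deposited, so every analysis routine in :mod:`lanetaxis.trajstats` is
validated against tracks generated here: straight runs, circular surface
swimming, run-and-tumble paths, and ensembles with prescribed drift or
region placement.  Each generator records the parameters it used, making
recovery tolerances checkable.

Frame rate defaults to 20 fps (dt = 0.05 s) and positional noise to
isotropic Gaussian jitter of 0.1 um per frame — sub-pixel at typical
20x / 6.5-um-pixel optics — emulating tracking jitter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajstats import Trajectory

__all__ = [
    "FixtureSpec",
    "make_straight",
    "make_circular",
    "make_run_tumble",
    "make_region_ensemble",
    "make_drift_ensemble",
    "sample_truncated_exponential",
]


@dataclass
class FixtureSpec:
    """Shared knobs of all generators."""

    kind: str = "straight"  # straight | circular | run_tumble | drift_ensemble
    dt: float = 0.05  # s
    n_frames: int = 200
    noise_sd: float = 0.0  # um, per-frame isotropic Gaussian jitter
    seed: int | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_frames < 5:
            raise ValueError("n_frames must be >= 5")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _finish(xs, ys, spec: FixtureSpec, rng, track_id: str, truth: dict) -> Trajectory:
    if spec.noise_sd > 0:
        xs = xs + rng.normal(0.0, spec.noise_sd, xs.size)
        ys = ys + rng.normal(0.0, spec.noise_sd, ys.size)
    spec.ground_truth = dict(truth)
    times = np.arange(xs.size) * spec.dt
    return Trajectory(track_id=track_id, times=times, xs=xs, ys=ys, source="simulation")


def make_straight(speed: float, heading: float = 0.0, spec: FixtureSpec | None = None,
                  start=(0.0, 0.0), track_id: str = "straight-0") -> Trajectory:
    """Constant-velocity track: x(t) = v cos(h) t, y(t) = v sin(h) t (+ noise)."""
    if speed < 0:
        raise ValueError("speed must be non-negative")
    spec = spec or FixtureSpec(kind="straight")
    rng = spec.rng()
    t = np.arange(spec.n_frames) * spec.dt
    xs = start[0] + speed * np.cos(heading) * t
    ys = start[1] + speed * np.sin(heading) * t
    return _finish(xs, ys, spec, rng, track_id,
                   {"speed": speed, "heading": heading, "drift": speed * np.cos(heading)})


def make_circular(radius: float, speed: float = 20.0, spec: FixtureSpec | None = None,
                  center=(0.0, 0.0), phase: float = 0.0, track_id: str = "circle-0") -> Trajectory:
    """Circular track of the simulator's chirality (CCW in math coordinates)."""
    if radius <= 0 or speed <= 0:
        raise ValueError("radius and speed must be positive")
    spec = spec or FixtureSpec(kind="circular")
    rng = spec.rng()
    omega = speed / radius
    t = np.arange(spec.n_frames) * spec.dt
    xs = center[0] + radius * np.cos(phase + omega * t)
    ys = center[1] + radius * np.sin(phase + omega * t)
    return _finish(xs, ys, spec, rng, track_id,
                   {"radius": radius, "speed": speed, "omega": omega, "center": center})


def sample_truncated_exponential(b: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Angle magnitudes from the exponential on [0, pi], by inverse CDF."""
    if b <= 0:
        raise ValueError("b must be positive")
    u = rng.uniform(0.0, 1.0, size)
    return -b * np.log1p(-u * (1.0 - np.exp(-np.pi / b)))


def make_run_tumble(run_rate: float, tumble_angle_b: float = 1.35,
                    spec: FixtureSpec | None = None, speed: float = 20.0,
                    tumble_exit_rate: float = 5.0, track_id: str = "rt-0") -> Trajectory:
    """Alternating constant-speed runs and stationary tumbles.

    Run and tumble episodes end with per-step probabilities ``run_rate*dt``
    and ``tumble_exit_rate*dt``; at each tumble end the heading jumps by a
    truncated-exponential angle of characteristic scale ``tumble_angle_b``
    with a uniform random sign.  The realized event log is stored in
    ``spec.ground_truth`` for oracle use.
    """
    if run_rate < 0 or tumble_exit_rate <= 0:
        raise ValueError("rates must be positive (run_rate may be 0)")
    spec = spec or FixtureSpec(kind="run_tumble", n_frames=2000)
    rng = spec.rng()
    n, dt = spec.n_frames, spec.dt
    xs = np.empty(n)
    ys = np.empty(n)
    xs[0] = ys[0] = 0.0
    theta = rng.uniform(-np.pi, np.pi)
    tumbling = False
    events = []  # (start_frame, end_frame, angle)
    t_start = None
    for i in range(1, n):
        if tumbling:
            xs[i], ys[i] = xs[i - 1], ys[i - 1]
            if rng.random() < tumble_exit_rate * dt:
                dth = sample_truncated_exponential(tumble_angle_b, 1, rng)[0]
                dth *= rng.choice((-1.0, 1.0))
                theta += dth
                events.append((t_start, i, dth))
                tumbling = False
        else:
            if run_rate > 0 and rng.random() < run_rate * dt:
                tumbling = True
                t_start = i
                xs[i], ys[i] = xs[i - 1], ys[i - 1]
            else:
                xs[i] = xs[i - 1] + speed * np.cos(theta) * dt
                ys[i] = ys[i - 1] + speed * np.sin(theta) * dt
    return _finish(xs, ys, spec, rng, track_id,
                   {"run_rate": run_rate, "b": tumble_angle_b, "speed": speed,
                    "tumble_exit_rate": tumble_exit_rate, "events": events})


def make_drift_ensemble(drift: float, n_tracks: int = 50, spec: FixtureSpec | None = None,
                        noise_sd_step: float = 1.0) -> list:
    """Tracks drifting at a known mean velocity with per-step Gaussian scatter.

    ``x`` performs a biased random walk of mean step ``drift*dt`` and step
    noise ``noise_sd_step * sqrt(dt)``; the lag-regression estimator should
    recover ``drift``.
    """
    spec = spec or FixtureSpec(kind="drift_ensemble", n_frames=120)
    rng = spec.rng()
    tracks = []
    for i in range(n_tracks):
        steps = drift * spec.dt + rng.normal(0.0, noise_sd_step * np.sqrt(spec.dt), spec.n_frames - 1)
        xs = np.concatenate([[0.0], np.cumsum(steps)])
        ys = np.zeros(spec.n_frames)
        t = np.arange(spec.n_frames) * spec.dt
        tracks.append(Trajectory(track_id=f"drift-{i}", times=t, xs=xs, ys=ys))
    spec.ground_truth = {"drift": drift, "n_tracks": n_tracks}
    return tracks


def make_region_ensemble(proportions, lane_width: float, n_tracks: int = 100,
                         spec: FixtureSpec | None = None, d: float = 3.0) -> list:
    """Straight tracks placed to realize exact (LSW, MA, RSW) count fractions.

    Counts are ``round(p * n_tracks)`` adjusted to sum to ``n_tracks``; each
    requested region must be constructible (``lane_width > 2*d`` whenever the
    MA fraction is positive).
    """
    proportions = tuple(float(p) for p in proportions)
    if len(proportions) != 3 or abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must be three fractions summing to 1")
    if proportions[1] > 0 and lane_width <= 2 * d:
        raise ValueError(
            f"MA tracks requested but lane width {lane_width} <= 2*d = {2 * d}"
        )
    spec = spec or FixtureSpec(kind="drift_ensemble", n_frames=40)
    counts = [int(round(p * n_tracks)) for p in proportions]
    counts[1] = n_tracks - counts[0] - counts[2]
    ys_by_region = {
        0: d / 2.0,  # LSW: <y> <= d
        1: lane_width / 2.0,  # MA
        2: lane_width - d / 2.0,  # RSW: <y> >= w - d
    }
    tracks = []
    k = 0
    for region, count in enumerate(counts):
        for _ in range(count):
            t = make_straight(10.0, 0.0, FixtureSpec(dt=spec.dt, n_frames=spec.n_frames,
                                                     noise_sd=0.0),
                              start=(0.0, ys_by_region[region]), track_id=f"region-{k}")
            tracks.append(t)
            k += 1
    spec.ground_truth = {"proportions": proportions, "counts": tuple(counts)}
    return tracks
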