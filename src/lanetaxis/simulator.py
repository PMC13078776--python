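"""Agent-based 2-D simulation of chiral run-and-tumble swimmers in a lane.

Cells are active particles at constant run speed ``v0`` whose heading drifts
at the constant angular velocity of near-surface circular swimming and
diffuses rotationally; an internal signaling pathway (:mod:`lanetaxis.pathway`)
modulates the run-to-tumble switching rate as each cell samples the local
attractant concentration of a linear gradient.  Sidewalls at y = 0 and
y = w align colliding cells with the wall; cells leave a wall only by
tumbling (spontaneous, or forced once a maximum detention time is exceeded).
Crossing an x boundary re-enters the cell on the other side at a uniformly
random y, and recorded tracks are split there.

Coordinate convention: math coordinates (y up).  The default ``chirality=+1``
turns headings counterclockwise here, which is the clockwise circling of
E. coli seen in image coordinates; it makes up-gradient swimmers accumulate
on the right sidewall (y = w).  ``chirality=-1`` mirrors the system.

All operations are vectorized over an :class:`AgentEnsemble` (a struct of
arrays); a single cell is simply an ensemble of size one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import pathway as pw
from .trajstats import DEFAULT_LAGS, Trajectory

__all__ = [
    "MotilityParams",
    "LaneConfig",
    "TumbleAngleModel",
    "AgentEnsemble",
    "EnsembleResult",
    "SIDEWALL_ANGLE_MODEL",
    "MIDDLE_ANGLE_MODEL",
    "concentration_at",
    "sample_tumble_angle",
    "run_step",
    "handle_wall_collision",
    "handle_x_boundary",
    "tumble_step",
    "mode_switch",
    "simulate",
]

RUN, TUMBLE = 0, 1


@dataclass(frozen=True)
class MotilityParams:
    """Motility constants of one simulated cell.

    ``wall_max_detention`` is calibrated so that together with the adapted
    switching rate (~0.485 1/s) the mean wall residence is ~2 s:
    E[min(Exp(k*), T)] = (1 - exp(-k* T))/k* ~ 2.0 s at T = 7 s.
    """

    v0: float = 20.0  # um/s
    r: float = 10.0  # um, circular-swimming radius
    d_rot: float = 0.062  # rad^2/s
    dt: float = 0.05  # s
    tumble_exit_rate: float = 5.0  # 1/s  (mean tumble 0.2 s)
    wall_max_detention: float = 7.0  # s, forced-detachment time
    chirality: int = 1  # +1: CCW in math coords (E. coli seen in image coords)

    def __post_init__(self) -> None:
        for name in ("v0", "r", "dt", "tumble_exit_rate", "wall_max_detention"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.d_rot < 0:
            raise ValueError("d_rot must be non-negative")
        if self.chirality not in (1, -1):
            raise ValueError("chirality must be +1 or -1")


@dataclass(frozen=True)
class LaneConfig:
    """Lane geometry and the linear attractant field c(x) = slope*x + c0."""

    width: float
    length: float = 160.0  # um
    grad_slope: float = 0.05  # uM/um
    c_intercept: float = 22.0  # uM

    def __post_init__(self) -> None:
        if self.width <= 0 or self.length <= 0:
            raise ValueError("lane width and length must be positive")
        if min(self.c_intercept, self.c_intercept + self.grad_slope * self.length) < 0:
            raise ValueError("concentration must be non-negative over the lane")


@dataclass(frozen=True)
class TumbleAngleModel:
    """Truncated-exponential tumble-angle magnitude model on [0, pi]."""

    b: float  # rad, characteristic angle

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("b must be positive")

    @property
    def norm_a(self) -> float:
        return (1.0 / self.b) / (1.0 - np.exp(-np.pi / self.b))


SIDEWALL_ANGLE_MODEL = TumbleAngleModel(b=0.25)
MIDDLE_ANGLE_MODEL = TumbleAngleModel(b=1.35)


def _wrap_angle(a):
    return np.pi - np.mod(np.pi - a, 2.0 * np.pi)


class AgentEnsemble:
    """Struct-of-arrays state of ``n`` independent cells."""

    def __init__(self, x, y, theta, m):
        self.x = np.asarray(x, dtype=float).copy()
        self.y = np.asarray(y, dtype=float).copy()
        self.theta = _wrap_angle(np.asarray(theta, dtype=float).copy())
        self.m = np.asarray(m, dtype=float).copy()
        n = self.x.size
        self.x_unwrapped = self.x.copy()
        self.mode = np.full(n, RUN, dtype=np.uint8)
        self.on_wall = np.zeros(n, dtype=np.int8)  # 0 none, -1 left (y=0), +1 right (y=w)
        self.wall_clock = np.zeros(n)
        self.wrapped = np.zeros(n, dtype=bool)  # x-boundary crossing this step
        self.wrap_censored_clock = np.empty(0)  # residences interrupted by a wrap

    @property
    def n(self) -> int:
        return self.x.size

    @classmethod
    def initialize(cls, n: int, lane: LaneConfig, rng: np.random.Generator,
                   params: pw.PathwayParams = pw.PathwayParams()) -> "AgentEnsemble":
        """Uniform positions and headings, pathway adapted to the local c."""
        x = rng.uniform(0.0, lane.length, n)
        y = rng.uniform(0.0, lane.width, n)
        theta = rng.uniform(-np.pi, np.pi, n)
        m = _adapted_m(concentration_at(x, lane), params)
        return cls(x, y, theta, m)


def _adapted_m(c, params: pw.PathwayParams):
    """Closed-form adapted methylation (vectorized): a(m*, c) = k_R/(k_R+k_B).

    Same fixed point as :func:`lanetaxis.pathway.adapted_state` (the bisection
    route); asserted equal in tests.
    """
    a_star = pw.adapted_activity(params)
    ligand = np.log1p(np.asarray(c, float) / params.k_off) - np.log1p(
        np.asarray(c, float) / params.k_on
    )
    # invert a = 1/(1+exp(N(alpha(m0-m)+L))) at a = a_star
    m_star = params.m0 + (ligand - np.log((1.0 - a_star) / a_star) / params.n_cluster) / params.alpha
    return np.clip(m_star, params.m_min, params.m_max)


# ---------------------------------------------------------------------------
# elementary operations (vectorized; optional masks select the affected cells)


def concentration_at(x, lane: LaneConfig):
    """Attractant concentration (uM) sensed at x; clipped to the lane extent."""
    return lane.grad_slope * np.clip(x, 0.0, lane.length) + lane.c_intercept


def sample_tumble_angle(model: TumbleAngleModel, rng: np.random.Generator, size=None):
    """Signed tumble angle: truncated-exponential magnitude, uniform +/- sign."""
    scalar = size is None
    n = 1 if scalar else size
    u = rng.uniform(0.0, 1.0, n)
    mag = -model.b * np.log1p(-u * (1.0 - np.exp(-np.pi / model.b)))
    sign = rng.integers(0, 2, n) * 2.0 - 1.0
    out = sign * mag
    return float(out[0]) if scalar else out


def handle_wall_collision(agents: AgentEnsemble, lane: LaneConfig) -> AgentEnsemble:
    """Clamp wall-crossing cells to the wall and align them with it.

    The aligned heading preserves the sign of the incoming x-velocity
    (``cos(theta) >= 0 -> theta = 0``, ties toward +x); the wall clock
    restarts at attachment.
    """
    hit_left = agents.y < 0.0
    hit_right = agents.y > lane.width
    hit = hit_left | hit_right
    if not np.any(hit):
        return agents
    agents.y = np.where(hit_left, 0.0, np.where(hit_right, lane.width, agents.y))
    aligned = np.where(np.cos(agents.theta) >= 0.0, 0.0, np.pi)
    agents.theta = np.where(hit, aligned, agents.theta)
    agents.on_wall = np.where(hit_left, -1, np.where(hit_right, 1, agents.on_wall)).astype(np.int8)
    agents.wall_clock = np.where(hit, 0.0, agents.wall_clock)
    return agents


def handle_x_boundary(agents: AgentEnsemble, lane: LaneConfig,
                      rng: np.random.Generator,
                      pathway_params: pw.PathwayParams | None = None) -> AgentEnsemble:
    """Periodic x with random re-entry y; flags the crossing for track splits.

    The heading is preserved and the unwrapped x keeps the true displacement.
    The recycled cell stands in for a fresh cell entering the lane, so its
    pathway state is re-adapted to the concentration at the re-entry point
    (when ``pathway_params`` is given): carrying the old methylation across
    the teleport would impose an artificial ~8 uM ligand shock on every
    recycled up-gradient swimmer, flooding the population with spurious
    tumbles.  Because the cell re-enters at a random transverse position it
    is no longer wall-attached; the wall clock of such a cell is stashed in
    ``wrap_censored_clock`` so that the interrupted residence episode can be
    treated as right-censored rather than silently dropped.
    """
    out = (agents.x < 0.0) | (agents.x > lane.length)
    agents.wrapped = out
    agents.wrap_censored_clock = agents.wall_clock[out & (agents.on_wall != 0)].copy()
    if not np.any(out):
        return agents
    agents.x = np.where(out, agents.x - lane.length * np.floor(agents.x / lane.length), agents.x)
    agents.y = np.where(out, rng.uniform(0.0, lane.width, agents.n), agents.y)
    agents.on_wall = np.where(out, 0, agents.on_wall).astype(np.int8)
    agents.wall_clock = np.where(out, 0.0, agents.wall_clock)
    if pathway_params is not None:
        m_fresh = _adapted_m(concentration_at(agents.x, lane), pathway_params)
        agents.m = np.where(out, m_fresh, agents.m)
    return agents


def run_step(agents: AgentEnsemble, params: MotilityParams, lane: LaneConfig,
             rng: np.random.Generator, mask=None,
             pathway_params: pw.PathwayParams | None = None) -> AgentEnsemble:
    """Advance running cells one step.

    Free cells update the heading by the chiral term plus rotational
    diffusion, then translate; wall-attached cells advance along the wall
    with the heading frozen (no chiral or diffusive rotation).  Wall and
    x-boundary interactions are applied afterwards.
    """
    if mask is None:
        mask = agents.mode == RUN
    free = mask & (agents.on_wall == 0)
    attached = mask & (agents.on_wall != 0)

    dtheta = params.chirality * (params.v0 / params.r) * params.dt
    noise = rng.normal(0.0, np.sqrt(2.0 * params.d_rot * params.dt), agents.n)
    agents.theta = _wrap_angle(np.where(free, agents.theta + dtheta + noise, agents.theta))

    step = params.v0 * params.dt
    dx = np.where(mask, step * np.cos(agents.theta), 0.0)
    dy = np.where(free, step * np.sin(agents.theta), 0.0)
    agents.x = agents.x + dx
    agents.x_unwrapped = agents.x_unwrapped + dx
    agents.y = agents.y + dy
    agents.wall_clock = np.where(attached, agents.wall_clock + params.dt, agents.wall_clock)

    handle_wall_collision(agents, lane)
    handle_x_boundary(agents, lane, rng, pathway_params)
    return agents


def mode_switch(agents: AgentEnsemble, pathway_params: pw.PathwayParams,
                lane: LaneConfig, params: MotilityParams,
                rng: np.random.Generator, mask=None):
    """Sense, adapt, and decide run -> tumble for running cells.

    Each runner senses the local concentration, updates its methylation by
    one Euler step, maps activity -> CheY-P -> CW bias -> switching rate k,
    and tumbles with probability ``k*dt``; a wall-attached runner whose
    detention exceeds the maximum is forced to tumble regardless.

    Returns the boolean mask of cells that switched this step.
    """
    if mask is None:
        mask = agents.mode == RUN
    c = concentration_at(agents.x, lane)
    a = pw.receptor_activity(agents.m, c, pathway_params)
    m_new = np.clip(
        agents.m
        + (pathway_params.k_r * (1.0 - a) - pathway_params.k_b * a) * params.dt,
        pathway_params.m_min,
        pathway_params.m_max,
    )
    agents.m = np.where(mask, m_new, agents.m)
    k = pw.run_to_tumble_rate(pw.cw_bias(pw.cheyp(a, pathway_params), pathway_params),
                              pathway_params)
    spontaneous = rng.uniform(0.0, 1.0, agents.n) < k * params.dt
    forced = (agents.on_wall != 0) & (agents.wall_clock > params.wall_max_detention)
    switch = mask & (spontaneous | forced)
    agents.mode = np.where(switch, TUMBLE, agents.mode).astype(np.uint8)
    return switch


def tumble_step(agents: AgentEnsemble, params: MotilityParams,
                rng: np.random.Generator, lane: LaneConfig,
                sidewall_model: TumbleAngleModel = SIDEWALL_ANGLE_MODEL,
                middle_model: TumbleAngleModel = MIDDLE_ANGLE_MODEL,
                mask=None, region_d: float = 3.0):
    """Advance tumbling cells one step (no translation).

    With probability ``tumble_exit_rate*dt`` the tumble ends and the heading
    jumps once by a signed tumble angle.  The angle magnitude model follows
    the region the cell tumbles in — the sidewall model within ``region_d``
    of either wall, the middle-area model elsewhere — mirroring how the
    empirical angle distributions are measured on region-classified tracks.
    A wall-attached cell whose post-tumble heading still points into the
    wall re-aligns and stays attached with a fresh wall clock; otherwise it
    detaches.

    Returns the boolean mask of cells whose tumble ended this step.
    """
    if mask is None:
        mask = agents.mode == TUMBLE
    exit_draw = rng.uniform(0.0, 1.0, agents.n) < params.tumble_exit_rate * params.dt
    ends = mask & exit_draw
    idx = np.flatnonzero(ends)
    dtheta = np.zeros(agents.n)
    if idx.size:
        near_wall = (agents.y[idx] <= region_d) | (agents.y[idx] >= lane.width - region_d)
        angles = np.where(
            near_wall,
            sample_tumble_angle(sidewall_model, rng, idx.size),
            sample_tumble_angle(middle_model, rng, idx.size),
        )
        dtheta[idx] = angles
    theta_new = _wrap_angle(agents.theta + dtheta)

    on_wall = agents.on_wall != 0
    into_wall = np.where(
        agents.on_wall == 1, np.sin(theta_new) >= 0.0, np.sin(theta_new) <= 0.0
    )
    stays = ends & on_wall & into_wall
    detaches = ends & on_wall & ~into_wall
    free_end = ends & ~on_wall

    aligned = np.where(np.cos(theta_new) >= 0.0, 0.0, np.pi)
    agents.theta = np.where(stays, aligned,
                            np.where(detaches | free_end, theta_new, agents.theta))
    agents.on_wall = np.where(detaches, 0, agents.on_wall).astype(np.int8)
    agents.wall_clock = np.where(stays | detaches, 0.0, agents.wall_clock)
    agents.mode = np.where(ends, RUN, agents.mode).astype(np.uint8)
    return ends


# ---------------------------------------------------------------------------
# ensemble simulation


@dataclass
class EnsembleResult:
    """Trajectories and summary statistics of a simulated ensemble."""

    drift_velocity: float  # um/s, mean over repeats of the lag-regression drift
    drift_sem: float  # um/s, SEM over repeats
    drift_per_rep: np.ndarray
    mean_step_drift: float  # um/s, <dx>/dt cross-check from unwrapped x
    region_proportions: tuple  # (LSW, MA, RSW) fractions of wrap-split tracks
    run_durations: np.ndarray  # s, all completed run episodes
    tumble_durations: np.ndarray  # s, completed tumble episodes
    wall_residences: np.ndarray  # s, wall episodes ended by a tumble
    wall_residences_censored: np.ndarray  # s, wall episodes cut short by an x-wrap
    trajectories: list = field(default_factory=list)
    n_cells: int = 0
    reps: int = 0
    seed: int | None = None

    def mean_wall_residence(self) -> float:
        """Kaplan-Meier mean wall residence, treating wrap-interrupted episodes
        as right-censored.

        The periodic x boundary teleports a wall-running cell to a random
        transverse position, interrupting its residence for a reason unrelated
        to its tumble clock; ignoring those episodes (or averaging them in)
        would bias the residence short.  Censoring-aware estimation recovers
        the model's residence distribution min(Exp(k), wall_max_detention).
        """
        return km_mean(self.wall_residences, self.wall_residences_censored)


def km_mean(event_durations, censored_durations) -> float:
    """Mean of a duration distribution from event + right-censored samples."""
    from lifelines import KaplanMeierFitter
    from lifelines.utils import restricted_mean_survival_time

    durations = np.concatenate([event_durations, censored_durations])
    observed = np.concatenate(
        [np.ones(len(event_durations)), np.zeros(len(censored_durations))]
    )
    if durations.size == 0:
        return float("nan")
    if censored_durations.size == 0:
        return float(np.mean(event_durations))
    kmf = KaplanMeierFitter().fit(durations, event_observed=observed)
    return float(restricted_mean_survival_time(kmf, t=float(durations.max())))


def _track_bounds(seg):
    """(cell, first_step, last_step) for every wrap-split track in ``seg``."""
    seg_t = seg.T  # (n_cells_total, n_steps+1)
    n, s1 = seg_t.shape
    new = np.ones_like(seg_t, dtype=bool)
    new[:, 1:] = seg_t[:, 1:] != seg_t[:, :-1]
    cells, starts = np.nonzero(new)  # row-major: grouped by cell, starts ascending
    ends = np.empty_like(starts)
    if starts.size:
        same_cell = cells[1:] == cells[:-1]
        ends[:-1] = np.where(same_cell, starts[1:] - 1, s1 - 1)
        ends[-1] = s1 - 1
    return cells, starts, ends


def _drift_per_rep(xu, seg, reps, n_cells, dt, lags=DEFAULT_LAGS):
    """Lag-regression drift per repeat over wrap-split tracks.

    For each lag the displacement ``x(i+n) - x(i)`` is first averaged within
    each track and the track means are then averaged with equal weight, the
    convention of per-trajectory displacement curves (pairs never span a
    wrap).  Per-track sums use prefix sums, so the cost is one cumulative sum
    plus O(tracks) per lag.
    """
    lags = [n for n in lags if n < xu.shape[0]]
    if len(lags) < 2:
        raise ValueError("simulation too short for the drift lag regression")
    taus = np.array(lags, dtype=float) * dt

    prefix = np.zeros((xu.shape[0] + 1, xu.shape[1]), dtype=np.float64)
    np.cumsum(xu, axis=0, out=prefix[1:])
    cells, starts, ends = _track_bounds(seg)
    lengths = ends - starts + 1
    rep_of_track = cells // n_cells

    means = np.empty((reps, len(taus)))
    for k, n in enumerate(lags):
        ok = lengths > n
        c, a, b = cells[ok], starts[ok], ends[ok]
        # sum_i (x[i+n] - x[i]) over the track telescopes into prefix sums
        sums = (prefix[b + 1, c] - prefix[a + n, c]) - (prefix[b + 1 - n, c] - prefix[a, c])
        track_mean = sums / (lengths[ok] - n)
        rep_sum = np.bincount(rep_of_track[ok], weights=track_mean, minlength=reps)
        rep_cnt = np.bincount(rep_of_track[ok], minlength=reps)
        means[:, k] = rep_sum / np.maximum(rep_cnt, 1)
    tc = taus - taus.mean()
    slopes = (means - means.mean(axis=1, keepdims=True)) @ tc / (tc @ tc)
    return slopes


def _region_proportions_from_arrays(y, seg, width, d=3.0):
    """(LSW, MA, RSW) fractions over wrap-split tracks, via per-segment mean y."""
    n_steps, n = y.shape
    max_seg = int(seg.max()) + 1
    flat = (np.arange(n, dtype=np.int64) * max_seg)[None, :] + seg.astype(np.int64)
    counts = np.bincount(flat.ravel(), minlength=n * max_seg)
    sums = np.bincount(flat.ravel(), weights=y.ravel().astype(np.float64),
                       minlength=n * max_seg)
    present = counts > 0
    mean_y = sums[present] / counts[present]
    is_lsw = mean_y <= d  # same precedence as classify_region when w <= 2d
    is_rsw = ~is_lsw & (mean_y >= width - d)
    lsw, rsw = np.mean(is_lsw), np.mean(is_rsw)
    return float(lsw), float(1.0 - lsw - rsw), float(rsw)


def _split_trajectories(x, y, seg, dt, n_cells):
    """Build wrap-split Trajectory objects from the recorded arrays."""
    trajs = []
    n_steps, n = x.shape
    for c in range(n):
        s = seg[:, c]
        breaks = np.flatnonzero(np.diff(s)) + 1
        starts = np.concatenate([[0], breaks])
        stops = np.concatenate([breaks, [n_steps]])
        rep, cell = divmod(c, n_cells)
        for k, (i0, i1) in enumerate(zip(starts, stops)):
            if i1 - i0 < 2:
                continue
            trajs.append(Trajectory(
                track_id=f"rep{rep}-cell{cell}-seg{k}",
                times=np.arange(i1 - i0) * dt,
                xs=x[i0:i1, c].astype(float),
                ys=y[i0:i1, c].astype(float),
                source="simulation",
            ))
    return trajs


def simulate(lane: LaneConfig, motility: MotilityParams = MotilityParams(),
             pathway_params: pw.PathwayParams = pw.PathwayParams(),
             n_cells: int = 100, duration: float = 150.0, reps: int = 50,
             seed: int | None = None,
             sidewall_model: TumbleAngleModel = SIDEWALL_ANGLE_MODEL,
             middle_model: TumbleAngleModel = MIDDLE_ANGLE_MODEL,
             record_trajectories: bool = False) -> EnsembleResult:
    """Simulate ``reps`` independent repeats of ``n_cells`` cells for ``duration`` s.

    Cells start uniformly distributed with uniform headings, adapted to the
    local concentration.  Each step applies the switching decision first and
    then the run or tumble kinematics.  All randomness comes from ``seed``;
    identical seeds give identical results.

    ``record_trajectories=True`` additionally returns wrap-split
    :class:`~lanetaxis.trajstats.Trajectory` objects (memory scales with
    ``n_cells * reps * duration/dt``); the summary statistics are always
    computed.
    """
    if duration <= motility.dt:
        raise ValueError("duration must exceed one time step")
    if n_cells < 1 or reps < 1:
        raise ValueError("n_cells and reps must be >= 1")
    dt = motility.dt
    n_steps = int(round(duration / dt))
    n_total = n_cells * reps
    rng = np.random.default_rng(seed)

    agents = AgentEnsemble.initialize(n_total, lane, rng, pathway_params)

    xu = np.empty((n_steps + 1, n_total), dtype=np.float32)
    yy = np.empty((n_steps + 1, n_total), dtype=np.float32)
    seg = np.empty((n_steps + 1, n_total), dtype=np.int16)
    xw = np.empty((n_steps + 1, n_total), dtype=np.float32) if record_trajectories else None
    xu[0] = agents.x_unwrapped
    yy[0] = agents.y
    seg[0] = 0
    if xw is not None:
        xw[0] = agents.x

    run_start = np.zeros(n_total, dtype=np.int64)
    tumble_start = np.zeros(n_total, dtype=np.int64)
    runs, tumbles, residences, residences_cens = [], [], [], []

    for s in range(1, n_steps + 1):
        was_tumbling = agents.mode == TUMBLE
        runners = ~was_tumbling

        switched = mode_switch(agents, pathway_params, lane, motility, rng, mask=runners)
        if np.any(switched):
            idx = np.flatnonzero(switched)
            runs.append((s - run_start[idx]) * dt)
            attached = agents.on_wall[idx] != 0
            if np.any(attached):
                residences.append(agents.wall_clock[idx[attached]].copy())
            tumble_start[idx] = s

        movers = runners & ~switched
        run_step(agents, motility, lane, rng, mask=movers, pathway_params=pathway_params)
        if agents.wrap_censored_clock.size:
            residences_cens.append(agents.wrap_censored_clock)

        ended = tumble_step(agents, motility, rng, lane, sidewall_model, middle_model,
                            mask=was_tumbling)
        if np.any(ended):
            idx = np.flatnonzero(ended)
            tumbles.append((s - tumble_start[idx]) * dt)
            run_start[idx] = s

        xu[s] = agents.x_unwrapped
        yy[s] = agents.y
        seg[s] = seg[s - 1] + agents.wrapped
        if xw is not None:
            xw[s] = agents.x
        agents.wrapped = np.zeros(n_total, dtype=bool)

    drift_reps = _drift_per_rep(xu, seg, reps, n_cells, dt)
    drift = float(drift_reps.mean())
    sem = float(drift_reps.std(ddof=1) / np.sqrt(reps)) if reps > 1 else float("nan")
    mean_step_drift = float((xu[-1].astype(np.float64) - xu[0]).mean() / (n_steps * dt))
    props = _region_proportions_from_arrays(yy, seg, lane.width)

    trajs = _split_trajectories(xw, yy, seg, dt, n_cells) if record_trajectories else []
    return EnsembleResult(
        drift_velocity=drift,
        drift_sem=sem,
        drift_per_rep=drift_reps,
        mean_step_drift=mean_step_drift,
        region_proportions=props,
        run_durations=np.concatenate(runs) if runs else np.empty(0),
        tumble_durations=np.concatenate(tumbles) if tumbles else np.empty(0),
        wall_residences=np.concatenate(residences) if residences else np.empty(0),
        wall_residences_censored=(
            np.concatenate(residences_cens) if residences_cens else np.empty(0)
        ),
        trajectories=trajs,
        n_cells=n_cells,
        reps=reps,
        seed=seed,
    )
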