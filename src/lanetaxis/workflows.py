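"""Experiment drivers: width sweeps, radius sweeps, and track analysis.

``sweep_width`` maps chemotactic drift against lane width for one circular-
swimming radius; ``sweep_radius`` repeats that over several radii, extracts
the drift-maximizing width per radius by a Gaussian peak fit, and fits the
proportionality law ``w* = k r``.  ``analyze`` runs the full trajectory-
statistics battery on a trajectory CSV or an in-memory track collection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from . import io as lio
from . import trajstats as ts
from .pathway import PathwayParams
from .simulator import LaneConfig, MotilityParams, simulate

__all__ = [
    "SweepResult",
    "sweep_width",
    "sweep_radius",
    "default_width_grid",
    "gaussian_peak_width",
    "analyze",
]

log = logging.getLogger("lanetaxis")


@dataclass
class SweepResult:
    """Drift-vs-width curves and the width-radius law extracted from them."""

    radii: np.ndarray  # um
    widths: dict  # radius -> width grid (um)
    drift: dict  # radius -> drift per width (um/s)
    drift_sem: dict  # radius -> SEM per width
    peak_width: dict = field(default_factory=dict)  # radius -> Gaussian-fit peak (um)
    argmax_width: dict = field(default_factory=dict)  # radius -> raw grid argmax (um)
    peak_method: dict = field(default_factory=dict)  # radius -> "gaussian" | "argmax"
    slope: float = float("nan")  # k of w* = k r
    slope_sd: float = float("nan")
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: one row per (radius, width)."""
        rows = []
        for r in self.radii:
            for w, d, s in zip(self.widths[r], self.drift[r], self.drift_sem[r]):
                rows.append({"radius_um": r, "width_um": w,
                             "drift_um_per_s": d, "drift_sem": s})
        return pd.DataFrame(rows)


def _gauss(x, a, mu, sigma):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def gaussian_peak_width(widths, drifts, window: int = 2):
    """Drift-maximizing width from a Gaussian fit around the curve's top.

    Fits ``a*exp(-(w-mu)^2/(2 sigma^2))`` to the grid points within
    ``window`` of the raw argmax (at least the top three points and their
    neighbors).  Returns ``(peak, "gaussian")`` or falls back to the raw
    argmax with a warning when the fit cannot be performed or converges
    outside the grid.
    """
    widths = np.asarray(widths, float)
    drifts = np.asarray(drifts, float)
    i = int(np.argmax(drifts))
    sel = np.zeros(widths.size, dtype=bool)
    for j in np.argsort(drifts)[-3:]:
        sel[max(0, j - 1):j + 2] = True
    sel[max(0, i - window):i + window + 1] = True
    if sel.sum() >= 3:
        try:
            p0 = [drifts[i], widths[i], max(0.3 * np.ptp(widths[sel]), 1.0)]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # covariance warnings are irrelevant here
                popt, _ = curve_fit(_gauss, widths[sel], drifts[sel], p0=p0, maxfev=5000)
            mu = float(popt[1])
            if widths.min() - 1.0 <= mu <= widths.max() + 1.0:
                return mu, "gaussian"
        except (RuntimeError, ValueError):
            pass
    warnings.warn("Gaussian peak fit failed; falling back to the grid argmax",
                  stacklevel=2)
    return float(widths[i]), "argmax"


def default_width_grid(r: float) -> np.ndarray:
    """Width grid for one radius: 1-um steps around the expected peak
    (~0.66 r), coarser out to 1.5 r."""
    fine = np.arange(max(2.0, np.round(0.35 * r)), np.round(1.1 * r) + 0.5, 1.0)
    coarse = np.arange(fine[-1] + 2.0, 1.5 * r + 0.6, 2.0)
    return np.unique(np.concatenate([fine, coarse, [np.round(1.5 * r)]]))


def _run_width_point(width, motility, pathway_params, lane_kwargs,
                     n_cells, duration, reps, seeds):
    """Drift at one width, averaged over one or more simulation seeds."""
    drifts, sems = [], []
    for s in seeds:
        lane = LaneConfig(width=float(width), **lane_kwargs)
        res = simulate(lane, motility=motility, pathway_params=pathway_params,
                       n_cells=n_cells, duration=duration, reps=reps, seed=int(s))
        drifts.append(res.drift_velocity)
        sems.append(res.drift_sem)
    return float(np.mean(drifts)), float(np.mean(sems) / np.sqrt(len(seeds)))


def sweep_width(radius: float, widths, seed: int | None = None,
                motility: MotilityParams | None = None,
                pathway_params: PathwayParams = PathwayParams(),
                n_cells: int = 100, duration: float = 150.0, reps: int = 50,
                n_seeds: int = 1, lane_kwargs: dict | None = None) -> SweepResult:
    """Drift vs lane width for one circular-swimming radius.

    Each width runs the full ensemble simulation; ``n_seeds > 1`` averages
    several independently seeded runs per width.  Reports both the raw
    argmax width and a Gaussian-fit peak.
    """
    widths = np.asarray(list(widths), float)
    if widths.size < 3:
        raise ValueError("need at least 3 widths for a sweep")
    motility = motility or MotilityParams(r=radius)
    if motility.r != radius:
        motility = MotilityParams(**{**motility.__dict__, "r": radius})
    lane_kwargs = lane_kwargs or {}
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(n_seeds) >> 1]  # keep < 2**31

    drift = np.empty(widths.size)
    sem = np.empty(widths.size)
    for k, w in enumerate(widths):
        drift[k], sem[k] = _run_width_point(
            w, motility, pathway_params, lane_kwargs, n_cells, duration, reps, seeds)
        log.info("width %.1f um: drift %.3f +- %.3f um/s", w, drift[k], sem[k])
    peak, method = gaussian_peak_width(widths, drift)
    result = SweepResult(
        radii=np.array([radius]),
        widths={radius: widths}, drift={radius: drift}, drift_sem={radius: sem},
        peak_width={radius: peak}, argmax_width={radius: float(widths[np.argmax(drift)])},
        peak_method={radius: method},
        provenance=lio.provenance(
            {"radius": radius, "widths": widths.tolist(), "n_cells": n_cells,
             "duration": duration, "reps": reps, "n_seeds": n_seeds}, seed),
    )
    return result


def sweep_radius(radii=(5.0, 7.5, 10.0, 12.5, 15.0), seed: int | None = None,
                 width_grids: dict | None = None,
                 pathway_params: PathwayParams = PathwayParams(),
                 n_cells: int = 100, duration: float = 150.0, reps: int = 20,
                 n_seeds: int = 1, lane_kwargs: dict | None = None) -> SweepResult:
    """Width sweeps across radii and the origin-constrained fit ``w* = k r``.

    Per radius the width grid defaults to :func:`default_width_grid`; the
    drift-maximizing width is extracted by the Gaussian peak fit (argmax
    fallback) and the slope ``k`` is the least-squares line through the
    origin, with its standard error from the fit residuals.
    """
    radii = np.asarray(list(radii), float)
    if radii.size < 3:
        raise ValueError("need at least 3 radii to fit the width-radius law")
    if np.unique(radii).size < 2:
        raise ValueError("degenerate fit: all radii equal")
    ss = np.random.SeedSequence(seed)
    sub = ss.spawn(radii.size)
    result = SweepResult(radii=radii, widths={}, drift={}, drift_sem={})
    for r, child in zip(radii, sub):
        grid = np.asarray(width_grids[r], float) if width_grids else default_width_grid(r)
        sw = sweep_width(r, grid, seed=int(child.generate_state(1)[0] >> 1),
                         pathway_params=pathway_params, n_cells=n_cells,
                         duration=duration, reps=reps, n_seeds=n_seeds,
                         lane_kwargs=lane_kwargs)
        result.widths[r] = sw.widths[r]
        result.drift[r] = sw.drift[r]
        result.drift_sem[r] = sw.drift_sem[r]
        result.peak_width[r] = sw.peak_width[r]
        result.argmax_width[r] = sw.argmax_width[r]
        result.peak_method[r] = sw.peak_method[r]
        log.info("radius %.1f um: peak width %.2f um (%s)", r,
                 sw.peak_width[r], sw.peak_method[r])
    peaks = np.array([result.peak_width[r] for r in radii])
    k = float(radii @ peaks / (radii @ radii))
    dof = radii.size - 1
    resid = peaks - k * radii
    k_sd = float(np.sqrt((resid @ resid) / dof / (radii @ radii))) if dof > 0 else float("nan")
    result.slope, result.slope_sd = k, k_sd
    result.provenance = lio.provenance(
        {"radii": radii.tolist(), "n_cells": n_cells, "duration": duration,
         "reps": reps, "n_seeds": n_seeds}, seed)
    return result


def analyze(trajs, lane_width: float, frame_interval: float = 0.05,
            out_dir=None, d: float = 3.0):
    """Run the trajectory-statistics battery on tracks.

    ``trajs`` may be a trajectory CSV path or an iterable of
    :class:`~lanetaxis.trajstats.Trajectory`.  Returns a dict with per-track
    tables and ensemble summaries; with ``out_dir`` set, one tidy CSV per
    statistic plus ``summary.json`` are written.
    """
    if isinstance(trajs, (str, Path)):
        trajs = lio.read_trajectories(trajs)
    trajs = list(trajs)
    if not trajs:
        raise ValueError("no trajectories to analyze")

    per_track = []
    region_map = {}
    for t in trajs:
        row = {"track_id": t.track_id, "n_frames": t.n_frames,
               "mean_y_um": t.mean_y(), "net_dx_um": t.net_dx()}
        label = ts.classify_region(t, lane_width, d=d)
        region_map[t.track_id] = label.region
        row["region"] = label.region
        if t.n_frames >= 5:
            row["speed_um_per_s"] = ts.trajectory_speed(t)
            try:
                curve = ts.msod(t)
                fit = ts.rotational_exponent(curve)
                row["gamma_r"] = fit.gamma_r
                row["c_r"] = fit.c_r
            except (ts.TooShortError, ValueError):
                row["gamma_r"] = np.nan
                row["c_r"] = np.nan
            tumbles = ts.detect_tumbles(t)
            row["n_tumbles"] = len(tumbles)
        per_track.append(row)
    per_track = pd.DataFrame(per_track)

    summary = {"n_tracks": len(trajs), "lane_width_um": lane_width}
    drift_all = ts.drift_velocity(trajs, dt=frame_interval)
    summary["drift_um_per_s"] = drift_all.v_d
    summary["drift_sd"] = drift_all.sd
    lsw, ma, rsw = ts.region_proportions(trajs, lane_width, d=d)
    summary["proportions"] = {"LSW": lsw, "MA": ma, "RSW": rsw}
    for region in ("LSW", "MA", "RSW"):
        sub = [t for t in trajs if region_map[t.track_id] == region]
        if sub:
            try:
                summary[f"drift_{region}"] = ts.drift_velocity(sub, dt=frame_interval).v_d
            except ValueError:
                summary[f"drift_{region}"] = None
    rsw_tracks = [t for t in trajs if region_map[t.track_id] == "RSW"]
    if rsw_tracks:
        up, down = ts.rsw_direction_split(rsw_tracks)
        summary["rsw_up_fraction"] = up
        summary["rsw_down_fraction"] = down

    tumble_rows = []
    for t in trajs:
        if t.n_frames >= 5:
            for ev in ts.detect_tumbles(t):
                tumble_rows.append({"track_id": t.track_id, "start_idx": ev.start_idx,
                                    "end_idx": ev.end_idx, "duration_s": ev.duration,
                                    "angle_rad": ev.angle})
    tumbles = pd.DataFrame(tumble_rows)
    if len(tumbles) >= 50:
        b, _ = ts.fit_truncated_exponential(np.abs(tumbles["angle_rad"]).clip(0, np.pi))
        summary["tumble_angle_b_rad"] = b

    results = {"per_track": per_track, "tumbles": tumbles, "summary": summary}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        per_track.to_csv(out_dir / "per_track.csv", index=False)
        tumbles.to_csv(out_dir / "tumbles.csv", index=False)
        lio.write_provenance_json(out_dir / "summary.json", {
            **summary, "provenance": lio.provenance(
                {"lane_width": lane_width, "frame_interval": frame_interval, "d": d}),
        })
    return results
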