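"""Coarse-grained chemotaxis signaling: receptor activity, adaptation, motor bias.

The model maps local attractant concentration ``c`` and the slow methylation
level ``m`` of an MWC receptor cluster to kinase activity ``a``, from there
algebraically to CheY-P concentration and motor clockwise (CW) bias, and
finally to the run-to-tumble switching rate used by the simulator.

Activity of a cluster of ``N`` coupled receptors::

    a = 1 / (1 + exp(N * (alpha*(m0 - m) + ln((1 + c/K_off)/(1 + c/K_on)))))

Methylation adapts slowly, ``dm/dt = k_R*(1 - a) - k_B*a``, which pins the
adapted activity at ``a* = k_R/(k_R + k_B) = 1/3`` for the default rates.

Note on the free-energy sign: we use ``alpha*(m0 - m)`` so that activity
increases with methylation (``da/dm > 0``), which makes the adaptation loop
stable.  The opposite sign is sometimes printed in the literature but renders
``dm/dt`` above a positive-feedback loop; all adapted-state quantities are
identical under either convention.  See docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "PathwayParams",
    "PathwayState",
    "receptor_activity",
    "methylation_step",
    "cheyp",
    "cw_bias",
    "run_to_tumble_rate",
    "adapted_state",
    "adapted_activity",
]


@dataclass(frozen=True)
class PathwayParams:
    """Constants of the signaling model (defaults are the standard E. coli set).

    Attributes
    ----------
    n_cluster : float
        Number of Tar receptors per MWC cluster (dimensionless).
    k_off, k_on : float
        Ligand dissociation constants of the inactive / active receptor
        state (uM); ``k_off < k_on`` for an attractant.
    alpha : float
        Free energy per unit methylation (dimensionless, in units of kT).
    m0 : float
        Reference methylation level.
    k_r, k_b : float
        Methylation / demethylation rates (1/s); the adapted activity is
        ``k_r / (k_r + k_b)``.
    yp_gain : float
        CheY-P concentration per unit activity (uM).
    hill_k, hill_n : float
        Half-point (uM) and Hill coefficient of the motor CW-bias curve.
    motor_rate_scale : float
        Divisor converting CW bias to a run-to-tumble rate (s).
    m_min, m_max : float
        Clip bounds for the methylation level.
    """

    n_cluster: float = 4.6
    k_off: float = 1.7
    k_on: float = 12.0
    alpha: float = 1.7
    m0: float = 1.0
    k_r: float = 0.005
    k_b: float = 0.010
    yp_gain: float = 7.86
    hill_k: float = 3.1
    hill_n: float = 10.3
    motor_rate_scale: float = 0.31
    m_min: float = 0.0
    m_max: float = 4.0

    def __post_init__(self) -> None:
        positive = (
            ("n_cluster", self.n_cluster),
            ("k_off", self.k_off),
            ("k_on", self.k_on),
            ("alpha", self.alpha),
            ("k_r", self.k_r),
            ("k_b", self.k_b),
            ("yp_gain", self.yp_gain),
            ("hill_k", self.hill_k),
            ("hill_n", self.hill_n),
            ("motor_rate_scale", self.motor_rate_scale),
        )
        for name, value in positive:
            if not value > 0:
                raise ValueError(f"{name} must be strictly positive, got {value}")
        if not self.k_off < self.k_on:
            raise ValueError(
                f"k_off must be < k_on for an attractant, got {self.k_off} >= {self.k_on}"
            )
        if not self.m_min < self.m_max:
            raise ValueError("m_min must be < m_max")


@dataclass(frozen=True)
class PathwayState:
    """Slow internal state of one cell: the receptor methylation level."""

    m: float


def _ligand_free_energy(c, params: PathwayParams):
    """ln((1 + c/K_off)/(1 + c/K_on)), the per-receptor ligand term (>= 0)."""
    c = np.asarray(c, dtype=float)
    return np.log1p(c / params.k_off) - np.log1p(c / params.k_on)


def receptor_activity(m, c, params: PathwayParams = PathwayParams()):
    """Kinase activity ``a`` in (0, 1) for methylation ``m`` and ligand ``c`` (uM).

    Vectorized over ``m`` and ``c``.  Activity decreases with attractant and
    increases with methylation.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("ligand concentration must be non-negative")
    m = np.asarray(m, dtype=float)
    f = params.n_cluster * (params.alpha * (params.m0 - m) + _ligand_free_energy(c, params))
    a = 1.0 / (1.0 + np.exp(f))
    if a.ndim == 0:
        return float(a)
    return a


def methylation_step(state: PathwayState, a, dt: float, params: PathwayParams = PathwayParams()) -> PathwayState:
    """One explicit-Euler update of ``dm/dt = k_R(1 - a) - k_B a``, clipped."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    a = np.asarray(a, dtype=float)
    if np.any((a <= 0) | (a >= 1)):
        raise ValueError("activity must lie strictly inside (0, 1)")
    m_new = np.clip(
        state.m + (params.k_r * (1.0 - a) - params.k_b * a) * dt,
        params.m_min,
        params.m_max,
    )
    return replace(state, m=float(m_new) if np.ndim(m_new) == 0 else m_new)


def cheyp(a, params: PathwayParams = PathwayParams()):
    """CheY-P concentration (uM): the algebraic map ``Yp = yp_gain * a``."""
    a = np.asarray(a, dtype=float)
    if np.any((a < 0) | (a > 1)):
        raise ValueError("activity must lie in [0, 1]")
    yp = params.yp_gain * a
    return float(yp) if yp.ndim == 0 else yp


def cw_bias(yp, params: PathwayParams = PathwayParams()):
    """Motor CW bias ``B = Yp^h / (Yp^h + K^h)`` with h = hill_n, K = hill_k."""
    yp = np.asarray(yp, dtype=float)
    if np.any(yp < 0):
        raise ValueError("CheY-P concentration must be non-negative")
    # work in log space to keep large Hill exponents well-conditioned
    with np.errstate(divide="ignore"):
        ratio = np.exp(params.hill_n * (np.log(yp) - np.log(params.hill_k)))
    b = ratio / (1.0 + ratio)
    b = np.where(yp == 0, 0.0, b)
    return float(b) if b.ndim == 0 else b


def run_to_tumble_rate(b, params: PathwayParams = PathwayParams()):
    """Run-to-tumble switching rate (1/s), linear in CW bias: ``k = B / 0.31``."""
    b = np.asarray(b, dtype=float)
    if np.any((b < 0) | (b >= 1)):
        raise ValueError("CW bias must lie in [0, 1)")
    k = b / params.motor_rate_scale
    return float(k) if k.ndim == 0 else k


def switching_rate_at(m, c, params: PathwayParams = PathwayParams()):
    """Convenience chain m, c -> activity -> CheY-P -> bias -> rate (1/s)."""
    return run_to_tumble_rate(cw_bias(cheyp(receptor_activity(m, c, params), params), params), params)


def adapted_activity(params: PathwayParams = PathwayParams()) -> float:
    """The adapted set-point activity, ``k_R / (k_R + k_B)``."""
    return params.k_r / (params.k_r + params.k_b)


def adapted_state(c: float, params: PathwayParams = PathwayParams()) -> PathwayState:
    """Methylation level m* at which the cell is adapted to concentration ``c``.

    Solves ``receptor_activity(m*, c) = k_R/(k_R + k_B)`` by bisection on the
    clip range.  If the root falls outside [m_min, m_max] the nearer bound is
    returned with a warning.
    """
    if c < 0:
        raise ValueError("ligand concentration must be non-negative")
    a_star = adapted_activity(params)

    def g(m: float) -> float:
        return receptor_activity(m, c, params) - a_star

    lo, hi = params.m_min, params.m_max
    g_lo, g_hi = g(lo), g(hi)
    if g_lo * g_hi > 0:
        m_clip = lo if abs(g_lo) < abs(g_hi) else hi
        warnings.warn(
            f"adapted methylation for c={c} uM lies outside [{lo}, {hi}]; clipping",
            stacklevel=2,
        )
        return PathwayState(m=m_clip)
    m_star = brentq(g, lo, hi, xtol=1e-10)
    return PathwayState(m=float(m_star))
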