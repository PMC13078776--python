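# Methods

This note documents the model implemented in `lanetaxis`, the estimators,
the numerical choices, and the places where the design was genuinely open.

## Signaling pathway

A cell's internal state is a single slow variable, the receptor methylation
level `m`. Kinase activity is the two-state MWC cluster response

    a(m, c) = 1 / (1 + exp(N [α (m₀ − m) + ln((1 + c/K_off)/(1 + c/K_on))]))

and methylation adapts as `dm/dt = k_R (1 − a) − k_B a`, integrated by
explicit Euler at the global time step (pathway timescales, 1/(k_R + k_B) ≈
67 s, are far slower than dt = 0.05 s, so no sub-stepping is needed). The
adapted activity is `a* = k_R/(k_R+k_B) = 1/3` independent of `c`; CheY-P,
motor CW bias and the run-to-tumble rate follow algebraically
(`Yp = 7.86 a`, Hill function with K = 3.1 μM and coefficient 10.3,
`k = B/0.31`). With defaults this gives B* ≈ 0.150 and k* ≈ 0.485 s⁻¹ —
a mean run of about 2 s.

**Sign of the methylation free energy.** We use `α (m₀ − m)`, under which
activity rises with methylation and the adaptation loop is a stable negative
feedback. The opposite sign, which sometimes appears in print, makes
`dm/dt = k_R(1−a) − k_B a` a positive feedback with runaway methylation; no
adapted state below the clip bound would exist. All adapted-state quantities
(a*, B*, k*) are identical under either convention, so the choice only
affects dynamics, not fixed points.

**Clipping.** `m` is clipped to [0, 4] (configurable). Adapted values over
the lane's concentration range (22–30 μM) are ≈ 1.85–1.90, far from the
bounds, so the clips never bind in normal use.

**`adapted_state`** solves `a(m*, c) = a*` by bisection (Brent) on the clip
interval with tolerance 1e-10; the vectorized simulator initialization uses
the equivalent closed-form inversion, and a test asserts the two agree.

## Motility and lane interactions

Cells are point-like active particles at constant run speed v₀ = 20 μm/s.
In math coordinates (y up) the heading of a free runner evolves as

    θ ← θ + χ (v₀/r) dt + Normal(0, 2 D_r dt),

with χ = +1 by default: counterclockwise here, which is the clockwise
circling of E. coli seen in image coordinates. This sign makes up-gradient
swimmers accumulate on the right sidewall (y = w, the "RSW"), which is the
orientation convention used throughout (the `chirality` flag mirrors the
whole system, and a test asserts the LSW/RSW mirror symmetry).

Tumbles do not translate; each step a tumbling cell exits with probability
(5 s⁻¹)·dt, so tumble durations are geometric with mean 0.2 s. The tumble
exit applies one signed reorientation whose magnitude follows a truncated
exponential on [0, π] and whose sign is a fair coin (only magnitudes are
identifiable from tracked data). The magnitude scale is chosen by the
*region* the cell tumbles in — b = 0.25 rad within 3 μm of a sidewall,
b = 1.35 rad in the middle area — mirroring how the two empirical angle
distributions are measured on region-classified tracks. This region rule
matters: selecting the sidewall distribution only for wall-*attached* cells
leaves mid-lane reorientation active at every width and the drift then
grows monotonically as the lane narrows; with the region rule, lanes
narrower than twice the 3-μm band lose mid-lane re-randomization and the
drift peaks at w ≈ 0.7 r, as observed.

**Walls.** A runner crossing y = 0 or y = w is clamped to the wall and its
heading aligned with the wall, preserving the sign of its x-velocity (ties
break toward +x). While attached, the chiral and diffusive heading terms
are suppressed (the wall fixes the orientation); the cell leaves only by
tumbling. After a wall tumble, a heading that still points into the wall
re-aligns and stays attached with a fresh wall clock; otherwise the cell
detaches. A wall-attached runner whose detention exceeds 7 s is forced to
tumble. The 7-s default is calibrated so that the gradient-free mean wall
residence E[min(Exp(k*), T)] = (1 − e^(−k*T))/k* ≈ 2.0 s.

**x boundary.** A cell crossing x = 0 or x = 160 μm re-enters on the other
side at a uniformly random y with its heading preserved; recorded tracks
are split there (a new track id), and the unwrapped x keeps the true
displacement. The recycled cell stands in for a fresh cell entering the
lane, so its methylation is re-adapted to the concentration at re-entry.
Carrying the old methylation across the teleport would impose an ~8 μM
artificial ligand step on every recycled up-gradient swimmer — a transient
switching rate of ~2.7 s⁻¹ sustained for tens of seconds by the slow
adaptation — which floods the lane with spurious tumbles and even reverses
the sign of the ensemble drift. Because re-entry also randomizes y, a
recycled wall swimmer is no longer attached; its interrupted residence
episode is recorded as right-censored (below).

**Per-step order.** Runners first sense and decide (methylation update,
switching draw, forced-detention check), then move; tumblers (cells already
tumbling at the step start) draw their exit. A cell that switches in a step
neither moves nor can exit in that same step, which makes run and tumble
durations dt·Geometric with means 1/k and 0.2 s exactly.

## Trajectory statistics

All estimators run identically on tracking-software exports and simulated
tracks (CSV schema `track_id,frame,time_s,x_um,y_um`, 20 fps).

* **Velocity**: 5-point central difference, exact for polynomials to degree
  4; the first/last two frames have no estimate.
* **Drift velocity**: for lags n = 1, 3, …, 39, the displacement
  x(i+n) − x(i) is averaged *within* each track and the track means are
  averaged with equal weight; OLS of that curve against nΔt (with
  intercept) gives the drift as its slope. Equal track weighting matches
  per-trajectory displacement averaging (SEM across trajectories); the
  pooled-pairs alternative (`weighting="pooled"`) down-weights short
  wall-hugging tracks relative to long circling ones and roughly halves
  wide-lane drift. Ensemble runs compute the same estimator per repeat
  (prefix-sum implementation over wrap-split segments) and report the mean
  and SEM over repeats.
* **MSOD / rotational exponent**: headings come from the velocity direction
  (frames slower than 1 μm/s are excluded as directionless); heading
  differences are wrapped to (−π, π]; ⟨(θ(t+τ) − θ(t))²⟩ for τ < 0.4 s is
  fitted as C_R τ^γ in log–log space. Straight (γ = 0 by the 1e-12 floor
  convention), diffusive (γ ≈ 1) and circular (γ ≈ 2) motions separate
  cleanly.
* **Tumble detection**: a tumble is a maximal run of ≥ 2 consecutive frames
  with speed below the track mean ⟨v⟩ in which every frame sits at least
  ⟨v⟩/6 below the last pre-event speed. The printed form of the second
  condition is ambiguous; this reading (each event frame substantially
  below the pre-event speed) is the one consistent with a hand-traced
  example and with the role of α = 1/6 as a drop threshold — requiring
  each *successive* in-event drop to exceed ⟨v⟩/6 would forbid multi-frame
  tumbles, whose internal speeds are all small. The event angle is the
  wrapped heading change from the frame before to the frame after the
  event.
* **Circle fit**: Savitzky–Golay smoothing (window 5, order 2 — the lowest
  meaningful order for that window) followed by the algebraic Kåsa fit,
  which solves the linear system [x y 1]·[2a 2b c]ᵀ = x²+y²; radius
  √(c + a² + b²). Collinear input raises a degenerate-geometry error. An
  optional gate rejects tracks with γ ≤ 1.6 before fitting.
* **Regions**: tracks are classified by mean transverse position with
  d = 3 μm (≈ one cell body): ⟨y⟩ ≤ d → LSW, ⟨y⟩ ≥ w − d → RSW, otherwise
  MA; boundary values go to the walls, and for w ≤ 2d the (empty-MA) lane
  triggers a warning. RSW tracks are split into up-/down-gradient by the
  sign of their net x displacement (ties count as down).
* **Tumble-angle scale**: the truncated-exponential scale b is fitted
  either by least squares on the density-normalized histogram (18 equal
  bins on [0, π]) or by maximum likelihood (no binning); both are exposed
  because histogram binning is a free choice.
* **Wall residence**: episodes end at a tumble (event) or at an x-boundary
  recycling (censored — the teleport interrupts the episode for reasons
  unrelated to the tumble clock; a wall swimmer traverses the lane in ≤ 8 s,
  so ignoring censoring biases the mean low by ~25%). The mean is the
  Kaplan–Meier restricted mean over both kinds of episode.

## Synthetic data

The generators in `lanetaxis.fixtures` emulate tracked trajectories with
known ground truth: straight runs, circles of the simulator's chirality,
run-and-tumble paths with an exact event log, ensembles with prescribed
drift, and region placements realizing exact LSW/MA/RSW fractions.
Positional noise is isotropic Gaussian per frame (0.1 μm default,
sub-pixel at 20×/6.5-μm-pixel optics). They reproduce tracking *geometry*
but none of the failure modes of real tracking — no detection dropout,
no linking errors, no z-escape, no uneven illumination — so passing
recovery tests demonstrates estimator correctness on clean input, not
robustness to tracking artifacts.

## Problem sizes and tolerances

The ensemble protocol is 100 cells for 150 s at dt = 0.05 s. The width-grid
scan runs 50 repeats per width and averages four independently seeded
scans; the drift difference between the 6- and 8-μm lanes is a few tenths
of a μm/s against a per-scan SEM of ≈ 0.2 μm/s, hence the seed averaging.
The radius sweep uses 20 repeats per width with 1-μm width resolution
around the expected peak (0.35r–1.1r) and 2-μm steps out to 1.5r; peak
widths come from a Gaussian fit to the grid points around the maximum
(argmax fallback with a warning), and the w* = k·r law is fitted through
the origin. Kinematic calibrations (run ≈ 2 s, tumble ≈ 0.2 s, residence
≈ 2 s) use 10 gradient-free repeats in a 44-μm lane. The Monte-Carlo
geometry oracle uses 10⁶ noiseless orbits per m-point, agreeing with the
closed form within 4 binomial standard errors; the two branches of P(m)
agree at m = 1 to 1e-12 and the argmax is located by dense grid plus
golden-section refinement (tolerance 1e-6).

## Known limitations

* Cells are points: no steric exclusion of the cell body or flagella, so
  very narrow lanes (w ≲ 6 μm) are idealized — real cells cannot reorient
  freely there and real drift falls off faster.
* The chiral circular motion is imposed as a constant angular velocity, not
  derived from hydrodynamics; wall alignment is instantaneous.
* No cell–cell interactions, growth, or 3-D escape from the surface.
* The x-boundary recycling is a steady-state device; quantities measured
  across a recycling event (wall residence) require the censoring-aware
  estimator described above.
* Wall-attached cells carry their heading frozen along the wall; whether
  rotational diffusion should persist on the wall is unresolved by the
  available evidence, and the frozen choice is the simpler one.
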