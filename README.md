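# lanetaxis

Chemotaxis of *Escherichia coli* on surfaces inside confined microfluidic
lanes: an agent-based run-and-tumble simulator with intracellular signaling,
the trajectory statistics used to analyze tracked cells, and the closed-form
first-collision geometry that explains why chemotactic drift is maximal when
the lane width is about 0.7–0.8 times the radius of circular surface
swimming.

The package is for quantitative microbiologists and biophysicists who study
bacterial motility in confinement: it simulates lane-confined chemotaxis
assays, analyzes particle-tracking exports (e.g. TrackMate spots tables) with
the same estimators applied to simulated tracks, and evaluates the geometric
theory of the optimal lane width.

## The model

**Signaling.** Each cell carries a coarse-grained two-state (MWC) receptor
cluster of N = 4.6 Tar receptors. Kinase activity depends on methylation `m`
and local attractant concentration `c`:

    a = 1 / (1 + exp(N [α (m₀ − m) + ln((1 + c/K_off)/(1 + c/K_on))]))
    dm/dt = k_R (1 − a) − k_B a

with K_off = 1.7 μM, K_on = 12 μM, α = 1.7, m₀ = 1, k_R = 0.005 s⁻¹,
k_B = 0.010 s⁻¹, so the adapted activity is a* = k_R/(k_R + k_B) = 1/3.
CheY-P follows algebraically, Yp = 7.86 a; the motor CW bias is a Hill
function B = Yp^10.3 / (Yp^10.3 + 3.1^10.3); and the run-to-tumble rate is
k = B / 0.31 s⁻¹. At the adapted state B ≈ 0.15 and k ≈ 0.49 s⁻¹ (mean run
≈ 2 s).

**Motility.** During runs cells swim at v₀ = 20 μm/s while the heading turns
at the constant angular speed v₀/r of near-surface circular swimming
(r ≈ 10 μm) plus rotational diffusion (D_r = 0.062 rad²/s). Tumbles are
stationary, exit at 5 s⁻¹ (mean 0.2 s), and reorient by a random angle drawn
from a truncated exponential on [0, π] — characteristic angle b = 0.25 rad
near the sidewalls, 1.35 rad in the middle of the lane. Cells colliding with
a sidewall align with it and leave only by tumbling; a maximum detention
time (7 s) caps wall trapping so that the mean wall residence is ≈ 2 s.
The lane (160 μm × w) carries a linear attractant field c(x) = 0.05 x + 22
μM, and cells crossing an x boundary re-enter on the other side at a random
transverse position.

**Geometry.** For an ideal circular swimmer dropped uniformly in the lane
with a uniform heading, the probability that its first wall contact is
up-gradient on the right sidewall is, with m = w/r,

    P(m) = (1/2πm) [ −(1−m) arccos(1−m) + √(1−(1−m)²) + m arccos m − √(1−m²) + 1 ]   (m ≤ 1)
    P(m) = 1/(πm)                                                                    (m > 1)

which peaks at m* ≈ 0.78 — the geometric origin of the optimal lane width.

## Worked example

```python
from lanetaxis import geometry, simulator

best = geometry.optimal_m()
print(f"P(m) is maximal at m* = {best.m:.3f} with P = {best.p:.4f}")

p_mc, se = geometry.mc_first_collision_oracle(0.78, n_samples=1_000_000, seed=0)
print(f"Monte-Carlo check at m = 0.78: {p_mc:.4f} ± {se:.4f}")

lane = simulator.LaneConfig(width=8.0)          # 8-um lane, c(x) = 0.05x + 22
out = simulator.simulate(lane, n_cells=100, duration=150.0, reps=10, seed=1)
print(f"drift = {out.drift_velocity:.2f} ± {out.drift_sem:.2f} um/s")
print("proportions LSW/MA/RSW =", tuple(round(p, 3) for p in out.region_proportions))
```

prints

```
P(m) is maximal at m* = 0.778 with P = 0.3225
Monte-Carlo check at m = 0.78: 0.3223 ± 0.0005
drift = 5.73 ± 0.60 um/s
proportions LSW/MA/RSW = (0.376, 0.042, 0.583)
```

The geometric optimum m* ≈ 0.78 says the best lane is a little narrower than
the swimming radius; the Monte-Carlo oracle confirms the closed form. The
simulated 8-μm lane (w/r = 0.8) shows strong up-gradient drift, with most
trajectories hugging the right sidewall (RSW) — the wall that chiral
clockwise swimmers reach when moving toward the attractant — while the same
ensemble in a 44-μm lane drifts about five times slower. A command-line
interface exposes the same operations (`lanetaxis simulate`,
`sweep-width`, `sweep-radius`, `analyze`, `geometry`, `fixtures`).

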