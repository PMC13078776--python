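"""Agent dynamics: kinematics, walls, boundaries, switching, and ensembles."""

import numpy as np
import pytest

from lanetaxis import pathway as pw
from lanetaxis import simulator as sim
from lanetaxis import trajstats as ts

WIDE = sim.LaneConfig(width=44.0, grad_slope=0.0)


def agents_at(x, y, theta, m=1.8487):
    n = np.size(x)
    return sim.AgentEnsemble(np.full(n, x, float), np.full(n, y, float),
                             np.full(n, theta, float), np.full(n, m, float))


class TestConcentration:
    @pytest.mark.parametrize("x, expected", [(0.0, 22.0), (160.0, 30.0), (80.0, 26.0)])
    def test_linear_field(self, x, expected):
        assert sim.concentration_at(x, sim.LaneConfig(width=8.0)) == pytest.approx(expected)

    def test_no_gradient_control(self):
        lane = sim.LaneConfig(width=8.0, grad_slope=0.0)
        assert sim.concentration_at(100.0, lane) == pytest.approx(22.0)

    def test_clipped_outside_lane(self):
        lane = sim.LaneConfig(width=8.0)
        assert sim.concentration_at(-5.0, lane) == pytest.approx(22.0)
        assert sim.concentration_at(500.0, lane) == pytest.approx(30.0)


class TestTumbleAngles:
    def test_sample_magnitude_mean_matches_analytic(self, rng):
        model = sim.TumbleAngleModel(b=1.35)
        draws = sim.sample_tumble_angle(model, rng, 100_000)
        analytic = 1.35 - np.pi * np.exp(-np.pi / 1.35) / (1 - np.exp(-np.pi / 1.35))
        assert np.abs(draws).mean() == pytest.approx(analytic, rel=0.01)
        assert abs(np.mean(np.sign(draws))) < 0.02  # symmetric signs

    def test_sample_distribution_matches_truncated_cdf(self, rng):
        from scipy.stats import kstest

        b = 0.25
        draws = np.abs(sim.sample_tumble_angle(sim.TumbleAngleModel(b=b), rng, 20_000))
        cdf = lambda x: (1 - np.exp(-x / b)) / (1 - np.exp(-np.pi / b))
        assert kstest(draws, cdf).pvalue > 0.01

    def test_norm_constant(self):
        m = sim.TumbleAngleModel(b=0.25)
        assert m.norm_a == pytest.approx((1 / 0.25) / (1 - np.exp(-np.pi / 0.25)))


class TestRunKinematics:
    def test_closes_into_circle_of_configured_radius(self, rng):
        mot = sim.MotilityParams(d_rot=0.0)
        lane = sim.LaneConfig(width=200.0, length=1000.0, grad_slope=0.0)
        ag = agents_at(500.0, 100.0, 0.0)
        xs, ys = [ag.x[0]], [ag.y[0]]
        n_steps = int(round(2 * np.pi * mot.r / (mot.v0 * mot.dt)))
        for _ in range(n_steps):
            sim.run_step(ag, mot, lane, rng)
            xs.append(ag.x[0]); ys.append(ag.y[0])
        traj = ts.Trajectory("circle", np.arange(len(xs)) * mot.dt, xs, ys)
        assert ts.fit_circle(traj).radius == pytest.approx(mot.r, rel=0.02)
        assert np.hypot(xs[-1] - xs[0], ys[-1] - ys[0]) < 1.5  # orbit closes

    def test_infinite_radius_goes_straight(self, rng):
        mot = sim.MotilityParams(d_rot=0.0, r=1e12)
        lane = sim.LaneConfig(width=200.0, length=10_000.0, grad_slope=0.0)
        ag = agents_at(100.0, 100.0, 0.0)
        for _ in range(200):
            sim.run_step(ag, mot, lane, rng)
        assert ag.y[0] == pytest.approx(100.0, abs=1e-6)
        assert ag.x_unwrapped[0] == pytest.approx(100.0 + 200 * mot.v0 * mot.dt, rel=1e-9)

    def test_heading_decorrelates_at_rotational_diffusion_rate(self, rng):
        mot = sim.MotilityParams(r=1e12)  # suppress the chiral term
        lane = sim.LaneConfig(width=1e6, length=1e9, grad_slope=0.0)
        n = 3000
        ag = agents_at(np.full(n, 5e8), np.full(n, 5e5), 0.0)
        steps = 40
        for _ in range(steps):
            sim.run_step(ag, mot, lane, rng)
        tau = steps * mot.dt
        assert np.cos(ag.theta).mean() == pytest.approx(np.exp(-mot.d_rot * tau), abs=0.02)


class TestWalls:
    @pytest.mark.parametrize("theta_in, expected", [(np.pi / 4, 0.0),
                                                    (3 * np.pi / 4, np.pi),
                                                    (np.pi / 2, 0.0)])
    def test_alignment_preserves_x_direction(self, theta_in, expected):
        lane = sim.LaneConfig(width=8.0)
        ag = agents_at(50.0, 8.5, theta_in)  # proposed position beyond y = w
        sim.handle_wall_collision(ag, lane)
        assert ag.y[0] == 8.0
        assert ag.theta[0] == pytest.approx(expected)
        assert ag.on_wall[0] == 1
        assert ag.wall_clock[0] == 0.0

    def test_left_wall_symmetric(self):
        lane = sim.LaneConfig(width=8.0)
        ag = agents_at(50.0, -0.5, -3 * np.pi / 4)
        sim.handle_wall_collision(ag, lane)
        assert ag.y[0] == 0.0 and ag.on_wall[0] == -1
        assert ag.theta[0] == pytest.approx(np.pi)

    def test_wall_runner_stays_frozen_on_wall(self, rng):
        lane = sim.LaneConfig(width=8.0, grad_slope=0.0)
        mot = sim.MotilityParams()
        ag = agents_at(50.0, 8.0, 0.0)
        ag.on_wall[:] = 1
        for _ in range(10):
            sim.run_step(ag, mot, lane, rng)
        assert ag.theta[0] == 0.0 and ag.y[0] == 8.0
        assert ag.x[0] == pytest.approx(50.0 + 10 * mot.v0 * mot.dt)
        assert ag.wall_clock[0] == pytest.approx(0.5)

    def test_post_tumble_heading_into_wall_reattaches(self):
        lane = sim.LaneConfig(width=8.0)
        mot = sim.MotilityParams(tumble_exit_rate=1e9)  # exit immediately
        n = 4000
        ag = agents_at(np.full(n, 50.0), np.full(n, 8.0), 0.0)
        ag.on_wall[:] = 1
        ag.mode[:] = sim.TUMBLE
        rng = np.random.default_rng(0)
        ended = sim.tumble_step(ag, mot, rng, lane)
        assert ended.all()
        attached = ag.on_wall == 1
        detached = ~attached
        assert np.all(np.isin(ag.theta[attached], (0.0, np.pi)))
        assert np.all(np.sin(ag.theta[detached]) < 0)  # moving away from y = w
        assert np.all(ag.wall_clock == 0.0)
        # with the sidewall model's symmetric signs, about half re-attach
        assert 0.4 < attached.mean() < 0.6


class TestXBoundary:
    def test_wrap_right_and_left(self, rng):
        lane = sim.LaneConfig(width=8.0)
        ag = agents_at([161.0, -2.0], [4.0, 4.0], [0.0, np.pi])
        sim.handle_x_boundary(ag, lane, rng)
        assert ag.x[0] == pytest.approx(1.0)
        assert ag.x[1] == pytest.approx(158.0)
        assert np.all((ag.y >= 0) & (ag.y <= 8.0))
        assert ag.wrapped.all()

    def test_unwrapped_displacement_survives_wrapping(self, rng):
        # a forced-drift runner: unwrapped x grows linearly despite many wraps
        lane = sim.LaneConfig(width=8.0, grad_slope=0.0)
        mot = sim.MotilityParams(d_rot=0.0, r=1e12)
        ag = agents_at(0.0, 8.0, 0.0)
        ag.on_wall[:] = 1
        steps = 1000
        for _ in range(steps):
            sim.run_step(ag, mot, lane, rng)
        assert ag.x_unwrapped[0] >= steps * mot.v0 * mot.dt * 0.99
        assert 0 <= ag.x[0] <= lane.length

    def test_pathway_readapted_at_reentry(self, rng):
        lane = sim.LaneConfig(width=8.0)  # gradient on
        ag = agents_at(161.0, 4.0, 0.0, m=3.5)
        sim.handle_x_boundary(ag, lane, rng, pw.PathwayParams())
        c_local = sim.concentration_at(ag.x[0], lane)
        a = pw.receptor_activity(ag.m[0], c_local)
        assert a == pytest.approx(1 / 3, abs=1e-6)


class TestModeSwitch:
    def test_gradient_free_switch_probability(self):
        lane = WIDE
        mot = sim.MotilityParams()
        n = 200_000
        ag = agents_at(np.full(n, 80.0), np.full(n, 22.0), 0.0,
                       m=pw.adapted_state(22.0).m)
        rng = np.random.default_rng(3)
        switched = sim.mode_switch(ag, pw.PathwayParams(), lane, mot, rng)
        # k* ~ 0.485 1/s -> per-step probability ~ 0.024
        assert switched.mean() == pytest.approx(0.485 * 0.05, rel=0.05)

    def test_up_gradient_motion_suppresses_switching(self):
        lane = sim.LaneConfig(width=44.0)
        mot = sim.MotilityParams()
        m22 = pw.adapted_state(22.0).m
        ag = agents_at(100.0, 22.0, 0.0, m=m22)  # adapted to 22 but senses ~27
        c = sim.concentration_at(100.0, lane)
        k_up = pw.switching_rate_at(m22, c)
        k_star = pw.switching_rate_at(pw.adapted_state(c).m, c)
        assert k_up < 0.25 * k_star

    def test_forced_tumble_after_max_detention(self):
        lane = WIDE
        mot = sim.MotilityParams()
        ag = agents_at(80.0, 44.0, 0.0, m=pw.adapted_state(22.0).m)
        ag.on_wall[:] = 1
        ag.wall_clock[:] = mot.wall_max_detention + 0.1
        rng = np.random.default_rng(4)
        switched = sim.mode_switch(ag, pw.PathwayParams(), lane, mot, rng)
        assert switched.all()
        assert (ag.mode == sim.TUMBLE).all()


@pytest.fixture(scope="module")
def small_run():
    return sim.simulate(WIDE, n_cells=40, duration=40.0, reps=2, seed=5,
                        record_trajectories=True)


class TestEnsemble:
    def test_deterministic_given_seed(self, small_run):
        again = sim.simulate(WIDE, n_cells=40, duration=40.0, reps=2, seed=5,
                             record_trajectories=True)
        assert again.drift_velocity == small_run.drift_velocity
        assert len(again.trajectories) == len(small_run.trajectories)
        for a, b in zip(again.trajectories[:50], small_run.trajectories[:50]):
            assert np.array_equal(a.xs, b.xs) and np.array_equal(a.ys, b.ys)

    def test_confinement_invariant(self, small_run):
        for t in small_run.trajectories:
            assert np.all((t.ys >= 0.0) & (t.ys <= 44.0))

    def test_region_proportions_sum_to_one(self, small_run):
        assert sum(small_run.region_proportions) == pytest.approx(1.0)

    def test_tumble_durations_have_rate_5_mean(self, small_run):
        assert small_run.tumble_durations.mean() == pytest.approx(0.2, abs=0.02)

    def test_control_has_no_drift(self, small_run):
        # a 2-repeat run has a noisy SEM; the sharp 2-SEM check runs on the
        # full-size gradient-free ensemble in the acceptance suite
        assert abs(small_run.drift_velocity) < 1.0

    def test_adapted_initialization_matches_bisection(self):
        cs = np.linspace(22.0, 30.0, 9)
        m_vec = sim._adapted_m(cs, pw.PathwayParams())
        m_ref = [pw.adapted_state(c).m for c in cs]
        assert np.allclose(m_vec, m_ref, atol=1e-8)

    def test_chirality_mirror_symmetry(self):
        up = sim.simulate(WIDE, motility=sim.MotilityParams(chirality=1),
                          n_cells=100, duration=100.0, reps=3, seed=7)
        down = sim.simulate(WIDE, motility=sim.MotilityParams(chirality=-1),
                            n_cells=100, duration=100.0, reps=3, seed=7)
        # flipping the chirality mirrors the lane: LSW and RSW swap roles
        assert up.region_proportions[0] == pytest.approx(down.region_proportions[2], abs=0.03)
        assert up.region_proportions[2] == pytest.approx(down.region_proportions[0], abs=0.03)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            sim.LaneConfig(width=0.0)
        with pytest.raises(ValueError):
            sim.simulate(WIDE, duration=0.01)
        with pytest.raises(ValueError):
            sim.MotilityParams(chirality=2)
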