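"""Search-Capture-Pull model: presets, forces, integrator, motor rules."""

import dataclasses

import numpy as np
import pytest

from scpsim import _kernel
from scpsim import simulation as sim


@pytest.fixture(scope="module")
def vivo():
    return sim.in_vivo_params()


@pytest.fixture(scope="module")
def vitro():
    return sim.in_vitro_params()


class TestPresets:
    def test_node_drag_ratio_is_100(self, vivo, vitro):
        assert vivo.zeta_node / vitro.zeta_node == pytest.approx(100.0)

    def test_elongation_ratio_is_7_5(self, vivo, vitro):
        assert vivo.elong_rate / vitro.elong_rate == pytest.approx(7.5)

    def test_in_vitro_initial_separation_is_5um(self, vitro):
        assert vitro.initial_separation == 5000.0

    def test_viscosities(self, vivo, vitro):
        assert vitro.medium_viscosity == 0.012
        assert vivo.medium_viscosity == 0.3

    def test_rod_drag_formula(self, vitro):
        # hand evaluation of 4 pi eta l0 / (ln(l0/2a) + 0.84)
        eta = 0.012e-6
        expected = 4 * np.pi * eta * 100.0 / (np.log(100.0 / 7.0) + 0.84)
        assert vitro.zeta_particle == pytest.approx(expected, rel=1e-12)

    def test_kappa_from_persistence_length(self, vitro):
        assert vitro.kappa == pytest.approx(vitro.kBT * 10_000.0 / 100.0, rel=1e-12)

    def test_dt_must_be_below_event_interval(self):
        with pytest.raises(ValueError):
            sim.SimParams(dt=0.1, t_event=0.05)


class TestInitState:
    def test_fixed_seed_is_identical(self, vivo):
        a = sim.init_state(vivo, seed=4)
        b = sim.init_state(vivo, seed=4)
        np.testing.assert_array_equal(a.pos, b.pos)
        np.testing.assert_array_equal(a.noise_parts, b.noise_parts)

    def test_second_filament_diametrically_opposite(self, vivo):
        st = sim.init_state(vivo, seed=8)
        assert st.theta0[1] - st.theta0[0] == pytest.approx(np.pi)
        d0 = st.pos[0, 0] - st.node_pos[0]
        d1 = st.pos[1, 0] - st.node_pos[0]
        np.testing.assert_allclose(d0, -d1, atol=1e-9)

    def test_first_particle_on_node_surface(self, vivo):
        st = sim.init_state(vivo, seed=2)
        r = np.hypot(*(st.pos[0, 0] - st.node_pos[0]))
        assert r == pytest.approx(vivo.node_diameter / 2)

    def test_initial_angles_uniform_pm60(self, vivo):
        from scipy import stats

        angles = np.array([sim.init_state(vivo, seed=s).theta0[0] for s in range(3000)])
        assert np.abs(angles).max() <= np.deg2rad(60) + 1e-12
        u = (angles + np.deg2rad(60)) / np.deg2rad(120)
        assert stats.kstest(u, "uniform").pvalue > 0.01


class TestForces:
    def test_straight_rest_configuration_has_no_internal_force(self, vivo):
        st = sim.init_state(vivo, seed=1, n_init_particles=5)
        fn, fp = sim.total_forces(st, vivo)
        assert np.abs(fn).max() < 1e-9
        assert np.abs(fp).max() < 1e-9

    def test_stretched_spring_pair(self, vivo):
        st = sim.init_state(vivo, seed=1, n_init_particles=2)
        # stretch the distal (regular) segment by displacing the tip 1 nm
        # along the filament axis is the growing segment; use 3 particles
        st = sim.init_state(vivo, seed=1, n_init_particles=3)
        u = np.array([np.cos(st.theta0[0]), np.sin(st.theta0[0])])
        st.pos[0, 2] += 1.0 * u
        fn, fp = sim.total_forces(st, vivo)
        # regular segment stiffness 0.25 pN/nm -> 0.25 pN pair along the bond
        np.testing.assert_allclose(fp[0, 2], -0.25 * u, atol=1e-9)
        np.testing.assert_allclose(np.abs(fp[0, 1] @ u), 0.25, atol=1e-9)

    def test_forces_match_energy_gradient(self, vivo):
        """Analytic forces equal central differences of U on random configurations."""
        params = dataclasses.replace(vivo, k_rot=1e-12)  # conservative part only
        st = sim.init_state(params, seed=3, n_init_particles=6, thermal_init=True)
        rng = np.random.default_rng(0)
        st.pos[:, :6] += rng.normal(0, 8, size=(2, 6, 2))
        st.node_pos += rng.normal(0, 3, size=(2, 2))
        st.link_on[0] = True
        st.link_seg[0], st.link_frac[0] = 2, 0.37
        st.link_rest[0], st.link_k[0] = 120.0, params.k_spring
        fn, fp = sim.total_forces(st, params)
        eps = 1e-5

        def num(arr, idx):
            arr[idx] += eps
            e_plus = sim.spring_bend_energy(st, params)
            arr[idx] -= 2 * eps
            e_minus = sim.spring_bend_energy(st, params)
            arr[idx] += eps
            return -(e_plus - e_minus) / (2 * eps)

        scale = max(np.abs(fp).max(), 1.0)
        for i in range(2):
            for c in range(2):
                assert fn[i, c] == pytest.approx(num(st.node_pos, (i, c)), abs=1e-6 * scale)
        for f in range(2):
            for j in range(6):
                for c in range(2):
                    assert fp[f, j, c] == pytest.approx(
                        num(st.pos, (f, j, c)), abs=1e-6 * scale
                    )

    def test_newtons_third_law_including_torque_and_motor(self, vivo):
        st = sim.init_state(vivo, seed=5, n_init_particles=7, thermal_init=True)
        st.link_on[1] = True
        st.link_seg[1], st.link_frac[1] = 3, 0.8
        st.link_rest[1], st.link_k[1] = 90.0, vivo.k_spring
        fn, fp = sim.total_forces(st, vivo)
        np.testing.assert_allclose(fn.sum(axis=0) + fp.sum(axis=(0, 1)), 0.0, atol=1e-9)

    def test_kernel_step_matches_reference_forces(self, vivo):
        """One deterministic kernel step equals the explicit Euler update."""
        st = sim.init_state(vivo, seed=5, n_init_particles=6)
        st.link_on[0] = True
        st.link_seg[0], st.link_frac[0] = 2, 0.5
        st.link_rest[0], st.link_k[0] = 110.0, vivo.k_spring
        ref = st.copy()
        fn, fp = sim.total_forces(ref, vivo)
        buf = np.zeros(64)
        status = _kernel.advance(
            st.node_pos, st.pos, st.n_particles, st.rest1, st.theta0,
            st.link_on, st.link_seg, st.link_frac, st.link_rest, st.link_k,
            st.noise_nodes, st.noise_parts, buf,
            1, vivo.dt, 0.0, vivo.k_spring, vivo.l0, vivo.kappa, vivo.k_rot,
            vivo.zeta_node, vivo.zeta_particle, vivo.node_diameter,
            0.0, vivo.f_cut_formin, vivo.smooth_alpha, st.ema_load, st.ema_motor,
            True, True, False, st.arrest_latch, st.counters,
        )
        assert status == _kernel.OK
        np.testing.assert_allclose(
            st.node_pos, ref.node_pos + vivo.dt * fn / vivo.zeta_node, atol=1e-12
        )
        n = 6
        np.testing.assert_allclose(
            st.pos[:, :n], ref.pos[:, :n] + vivo.dt * fp[:, :n] / vivo.zeta_particle,
            atol=1e-12,
        )

    def test_zero_temperature_constant_force_displacement(self, vivo):
        # kBT = 0 with only the tether spring stretched: deterministic drift
        st = sim.init_state(vivo, seed=1, n_init_particles=2)
        u = np.array([np.cos(st.theta0[0]), np.sin(st.theta0[0])])
        st.pos[0, :2] += 10.0 * u  # stretch the tether by 10 nm
        f_expected = (vivo.k_spring * vivo.l0 / (vivo.node_diameter / 2)) * 10.0
        before = st.pos[0, 0].copy()
        fn, fp = sim.total_forces(st, vivo)
        assert np.hypot(*fp[0, 0]) == pytest.approx(f_expected, rel=1e-9)


class TestMotorRules:
    def test_force_velocity_endpoints(self, vivo):
        assert sim.motor_speed(0.0, vivo) == vivo.v_myo0
        assert sim.motor_speed(vivo.f_stall_myo, vivo) == 0.0
        assert sim.motor_speed(-vivo.f_stall_myo, vivo) == 2 * vivo.v_myo0

    def test_speed_clamped(self, vivo):
        assert sim.motor_speed(10 * vivo.f_stall_myo, vivo) == 0.0
        assert sim.motor_speed(-10 * vivo.f_stall_myo, vivo) == 2 * vivo.v_myo0

    def test_capture_requires_radius(self, vivo):
        st = sim.init_state(vivo, seed=1)
        sim.myosin_update(st, vivo)
        assert not st.link_on.any()  # tip starts far from the myosin node

    def test_capture_within_radius_and_born_force_free(self, vivo):
        st = sim.init_state(vivo, seed=1, n_init_particles=3)
        st.pos[0, 2] = st.node_pos[1] + np.array([vivo.capture_radius * 0.9, 0.0])
        sim.myosin_update(st, vivo)
        assert st.link_on[0]
        assert sim.motor_force(st, vivo, 0) == pytest.approx(0.0, abs=1e-9)

    def test_walk_advances_toward_barbed_end_under_zero_load(self, vivo):
        st = sim.init_state(vivo, seed=1, n_init_particles=4)
        st.link_on[0] = True
        st.link_seg[0], st.link_frac[0] = 2, 1.0
        # place the myosin node exactly at rest distance: zero load
        p = st.pos[0]
        attach = p[3]
        st.node_pos[1] = attach + np.array([0.0, 50.0])
        st.link_rest[0], st.link_k[0] = 50.0, vivo.k_spring
        sim.myosin_update(st, vivo)
        walked = vivo.v_myo0 * vivo.t_event
        seg_len = vivo.l0
        expected_frac = 1.0 - walked / seg_len
        assert st.link_seg[0] == 2
        assert st.link_frac[0] == pytest.approx(expected_frac, rel=1e-9)

    def test_walk_carries_across_segments(self, vivo):
        params = dataclasses.replace(vivo, v_myo0=3000.0)  # walks 150 nm per event
        st = sim.init_state(params, seed=1, n_init_particles=4)
        st.link_on[0] = True
        st.link_seg[0], st.link_frac[0] = 2, 0.5
        attach = 0.5 * (st.pos[0, 2] + st.pos[0, 3])
        st.node_pos[1] = attach  # compressed spring -> assisting load, clamped 2v0
        st.link_rest[0], st.link_k[0] = 50.0, params.k_spring
        sim.myosin_update(st, params)
        assert st.link_seg[0] < 2

    def test_clamp_at_barbed_end(self, vivo):
        params = dataclasses.replace(vivo, v_myo0=1e5)
        st = sim.init_state(params, seed=1, n_init_particles=4)
        st.link_on[0] = True
        st.link_seg[0], st.link_frac[0] = 2, 0.9
        st.node_pos[1] = st.pos[0, 2]
        st.link_rest[0], st.link_k[0] = 50.0, params.k_spring
        sim.myosin_update(st, params)
        assert st.link_seg[0] == 0
        assert st.link_frac[0] == 0.0


class TestPolymerization:
    def test_growth_kinematics_and_insertion_time(self, vitro):
        """At 10 subs/s x 2.7 nm the first segment doubles in ~3.70 s."""
        params = dataclasses.replace(vitro, kBT=1e-12, n_filaments=1)
        st = sim.init_state(params, seed=1)
        rng = np.random.default_rng(0)
        t_insert = params.l0 / params.growth_rate_nm  # 100/27 s
        n_steps = int(t_insert / params.dt) + 10
        sim.polymerize_step(st, params, n_steps, rng)
        assert st.n_particles[0] == 3
        assert st.rest1[0] == pytest.approx(params.l0, abs=1.0)

    def test_instantaneous_arrest_pauses_growth(self, vivo):
        params = dataclasses.replace(vivo, kBT=1e-12, n_filaments=1, f_smooth_tau=0.0)
        st = sim.init_state(params, seed=1)
        # stretch the growing segment so F_formin > f_cut, then step once
        u = np.array([np.cos(st.theta0[0]), np.sin(st.theta0[0])])
        st.pos[0, 1] += 5.0 * u  # extension 5 nm -> F = 1.25 pN >> 0.1
        assert sim.formin_load(st, params, 0) > params.f_cut_formin
        rest_before = st.rest1[0]
        sim.polymerize_step(st, params, 1, np.random.default_rng(0))
        assert st.rest1[0] == rest_before

    def test_smoothed_arrest_blocks_growth_while_average_load_high(self, vivo):
        """Growth pauses while the smoothed load is above F_cut and resumes below."""
        params = dataclasses.replace(vivo, kBT=1e-12, n_filaments=1)
        st = sim.init_state(params, seed=1)
        st.ema_load[0] = 1.0  # smoothed load well above the 0.1 pN threshold
        rest_before = float(st.rest1[0])
        sim.polymerize_step(st, params, 1, np.random.default_rng(0))
        assert st.rest1[0] == rest_before
        st.ema_load[0] = 0.0
        sim.polymerize_step(st, params, 1, np.random.default_rng(0))
        assert st.rest1[0] == pytest.approx(rest_before + params.growth_rate_nm * params.dt)

    def test_ema_integrates_instantaneous_load(self, vivo):
        """One step moves the smoothed load by alpha times the instantaneous load."""
        params = dataclasses.replace(vivo, kBT=1e-12, n_filaments=1)
        st = sim.init_state(params, seed=1)
        u = np.array([np.cos(st.theta0[0]), np.sin(st.theta0[0])])
        st.pos[0, 1] += 5.0 * u  # instantaneous extension force 1.25 pN
        f_inst = sim.formin_load(st, params, 0)
        sim.polymerize_step(st, params, 1, np.random.default_rng(0))
        assert st.ema_load[0] == pytest.approx(params.smooth_alpha * f_inst, rel=0.05)

    def test_engaged_motor_load_feeds_arrest_channel(self, vivo):
        """A pulling motor's projected load accumulates in its smoothing channel."""
        params = dataclasses.replace(vivo, kBT=1e-12, n_filaments=1)
        st = sim.init_state(params, seed=1, n_init_particles=4)
        st.link_on[0] = True
        st.link_seg[0], st.link_frac[0] = 1, 0.5
        attach = 0.5 * (st.pos[0, 1] + st.pos[0, 2])
        walk_dir = st.pos[0, 1] - st.pos[0, 2]
        walk_dir /= np.hypot(*walk_dir)
        # myosin node placed so the stretched spring opposes barbed-end walking
        st.node_pos[1] = attach - 120.0 * walk_dir
        st.link_rest[0], st.link_k[0] = 100.0, params.k_spring
        from scpsim.simulation import _motor_load

        load = _motor_load(st, params, 0)
        assert load > 0
        sim.polymerize_step(st, params, 1, np.random.default_rng(0))
        assert st.ema_motor[0] == pytest.approx(params.smooth_alpha * load, rel=0.05)

    def test_inhibition_disabled_grows_under_load(self, vivo):
        params = dataclasses.replace(
            vivo, kBT=1e-12, n_filaments=1, formin_inhibition_enabled=False
        )
        st = sim.init_state(params, seed=1)
        u = np.array([np.cos(st.theta0[0]), np.sin(st.theta0[0])])
        st.pos[0, 1] += 5.0 * u
        rest_before = st.rest1[0]
        sim.polymerize_step(st, params, 1, np.random.default_rng(0))
        assert st.rest1[0] == pytest.approx(
            rest_before + params.growth_rate_nm * params.dt
        )

    def test_formin_load_zero_at_rest(self, vivo):
        st = sim.init_state(vivo, seed=1)
        assert sim.formin_load(st, vivo, 0) == pytest.approx(0.0, abs=1e-9)

    def test_formin_load_linear_in_extension(self, vivo):
        st = sim.init_state(vivo, seed=1)
        u = np.array([np.cos(st.theta0[0]), np.sin(st.theta0[0])])
        st.pos[0, 1] += 0.2 * u
        k1 = vivo.k_spring * vivo.l0 / vivo.l0
        assert sim.formin_load(st, vivo, 0) == pytest.approx(k1 * 0.2, rel=1e-6)


class TestRunAndScan:
    def test_fixed_seed_bit_identical(self):
        params = sim.in_vivo_params(max_time=1.0)
        a = sim.run(params, seed=11)
        b = sim.run(params, seed=11)
        np.testing.assert_array_equal(a.separation, b.separation)
        np.testing.assert_array_equal(a.formin_force, b.formin_force)

    def test_no_capture_gives_none_speed(self):
        params = sim.in_vivo_params(max_time=0.5)
        res = sim.run(params, seed=1, disable_capture=True)
        assert res.capture_time is None
        assert res.coalescence_speed is None

    def test_coalescence_speed_linear_decay(self):
        res = _synthetic_result(np.linspace(0, 10, 101), 1000.0 - 50.0 * np.linspace(0, 10, 101))
        assert sim.coalescence_speed(res) == pytest.approx(50.0, rel=1e-9)

    def test_coalescence_speed_constant_separation(self):
        res = _synthetic_result(np.linspace(0, 10, 101), np.full(101, 800.0))
        assert sim.coalescence_speed(res) == pytest.approx(0.0, abs=1e-9)

    def test_short_post_capture_window_undefined(self):
        res = _synthetic_result(np.linspace(0, 3, 31), 1000.0 - np.linspace(0, 3, 31))
        assert sim.coalescence_speed(res) is None

    def test_scan_requires_speeds_and_reps(self):
        params = sim.in_vivo_params(max_time=0.5)
        with pytest.raises(ValueError):
            sim.scan_motor_speed(params, [], n_reps=8)
        with pytest.raises(ValueError):
            sim.scan_motor_speed(params, [50.0], n_reps=1)

    def test_speed_interpolation(self):
        import pandas as pd

        scan = pd.DataFrame(
            {"v_myo0": [40.0, 80.0], "mean_coalescence": [20.0, 40.0]}
        )
        assert sim.speed_for_target_coalescence(scan, 30.0) == pytest.approx(60.0)
        assert sim.speed_for_target_coalescence(scan, 50.0) is None


def _synthetic_result(times, separation):
    n = times.size
    return sim.SimResult(
        times=times,
        node_positions=np.zeros((n, 2, 2)),
        separation=separation,
        formin_force=np.zeros((n, 2)),
        motor_force=np.zeros((n, 2)),
        captured=np.ones(n, dtype=bool),
        tension=np.ones(n),
        capture_time=float(times[0]),
        taut_time=float(times[0]),
        coalescence_speed=None,
        arrested_fraction_of_time=0.0,
        coalesced=False,
        params=sim.in_vivo_params(max_time=1.0),
        seed=0,
    )


class TestEquilibriumStatistics:
    def test_latched_vs_per_step_equivalence_at_infinite_threshold(self):
        """With f_cut -> infinity, arrest never triggers in either mode."""
        base = sim.in_vivo_params(max_time=0.5, f_cut_formin=1e12)
        res_a = sim.run(base, seed=3)
        res_b = sim.run(dataclasses.replace(base, latched_arrest=True), seed=3)
        np.testing.assert_array_equal(res_a.separation, res_b.separation)
        res_c = sim.run(
            dataclasses.replace(base, formin_inhibition_enabled=False), seed=3
        )
        np.testing.assert_array_equal(res_a.separation, res_c.separation)
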