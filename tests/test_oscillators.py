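import numpy as np
import pytest

from groovenet import oscillators as osc
from groovenet.rhythms import RhythmPattern


@pytest.fixture(scope="module")
def small_model():
    cfg = osc.ModelConfig(n_oscillators=31, f_min=0.5, f_max=8.0)
    return osc.build_default_model(cfg)


class TestFrequencyGrid:
    def test_study_grid(self):
        f = osc.make_frequency_grid()
        assert f.size == 321
        assert f[0] == pytest.approx(0.375) and f[-1] == pytest.approx(12.0)
        ratios = f[1:] / f[:-1]
        assert np.allclose(ratios, (12 / 0.375) ** (1 / 320))

    def test_forced_three_point_grid(self):
        assert np.allclose(osc.make_frequency_grid(1, 4, 3), [1, 2, 4])

    def test_grid_contains_two_hz_within_one_step(self):
        f = osc.make_frequency_grid()
        step = f[1] / f[0]
        nearest = f[np.argmin(np.abs(f - 2.0))]
        assert max(nearest / 2.0, 2.0 / nearest) < step

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            osc.make_frequency_grid(4, 1, 10)


class TestDerivatives:
    def test_origin_is_intrinsic_equilibrium(self):
        p = osc.LayerParams(-0.8, 4.0, -3.0)
        assert osc.oscillator_derivative(0.0, p, 2 * np.pi, 0.0) == 0

    def test_escape_raises(self):
        p = osc.LayerParams(-0.8, 4.0, -3.0)
        with pytest.raises(ValueError):
            osc.oscillator_derivative(1.0 + 0j, p, 1.0, 0.0)

    def test_coupling_reductions(self):
        z_src = np.array([0.3 + 0.1j, 0.2 - 0.2j])
        c = np.array([0.5 + 0j, 0.1 + 0.1j])
        x = osc.coupling_input(z_src, 0.4 + 0.2j, c, ratios=((1, 1),))
        assert x == pytest.approx(np.sum(c * z_src))
        x2 = osc.coupling_input(z_src, 0.4 + 0.2j, c, ratios=((2, 1),))
        assert x2 == pytest.approx(np.sum(c * z_src**2))
        assert osc.coupling_input(z_src, 0.1 + 0j, np.zeros(2, complex)) == 0

    def test_hebbian_small_c_linearizes_to_decay(self):
        rate = osc.hebbian_derivative(1e-4 + 0j, -1.0, 4.0, -2.2, 0.0, 1.0, 0.0, 0.0)
        assert rate == pytest.approx(-1e-4, rel=1e-3)

    def test_hebbian_zero_fixed_point(self):
        assert osc.hebbian_derivative(0.0, -1.0, 4.0, -2.2, 0.2, 1.0, 0.0, 0.0) == 0


class TestRadialEquilibria:
    def test_bistable_regime_roots(self):
        roots = osc.radial_equilibria(osc.LayerParams(-0.8, 4.0, -3.0))
        assert np.allclose(np.sort(roots) ** 2, [2.0 / 7.0, 0.4], atol=1e-9)

    def test_spontaneous_regime_root(self):
        roots = osc.radial_equilibria(osc.LayerParams(1e-4, 0.0, -3.0))
        assert roots.size == 1
        # alpha = 3 r^4 / (1 - r^2) at the root
        r = roots[0]
        assert 3 * r**4 / (1 - r**2) == pytest.approx(1e-4, rel=1e-9)

    def test_integration_settles_to_stable_root(self):
        # independent stiff-integrator oracle on the radial equation
        from scipy.integrate import solve_ivp

        p = osc.LayerParams(-0.8, 4.0, -3.0)

        def rhs(t, y):
            r = y[0]
            return [r * (p.alpha + p.beta1 * r**2 + p.beta2 * r**4 / (1 - r**2))]

        sol = solve_ivp(rhs, (0, 60), [0.55], method="LSODA", rtol=1e-10, atol=1e-12)
        assert sol.y[0, -1] == pytest.approx(np.sqrt(0.4), abs=1e-6)
        sol_lo = solve_ivp(rhs, (0, 60), [0.52], method="LSODA", rtol=1e-10, atol=1e-12)
        assert sol_lo.y[0, -1] == pytest.approx(0.0, abs=1e-6)

    def test_intermediate_root_is_never_an_attractor(self):
        from scipy.integrate import solve_ivp

        p = osc.LayerParams(-0.8, 4.0, -3.0)
        saddle = np.sqrt(2.0 / 7.0)

        def rhs(t, y):
            r = y[0]
            return [r * (p.alpha + p.beta1 * r**2 + p.beta2 * r**4 / (1 - r**2))]

        up = solve_ivp(rhs, (0, 80), [saddle + 1e-3], method="LSODA", rtol=1e-10).y[0, -1]
        dn = solve_ivp(rhs, (0, 80), [saddle - 1e-3], method="LSODA", rtol=1e-10).y[0, -1]
        assert up == pytest.approx(np.sqrt(0.4), abs=1e-4)
        assert dn == pytest.approx(0.0, abs=1e-4)


class TestKernelAgainstReference:
    def test_one_rk4_step_matches_reference_functions(self, small_model):
        from groovenet._oscillator_kernel import rk4_network

        m = small_model
        cfg = m.config
        rng = np.random.default_rng(3)
        z0 = 0.2 * (rng.standard_normal((3, m.n)) + 1j * rng.standard_normal((3, m.n)))
        c0 = 0.3 * np.exp(1j * rng.random(m.conn_targets.size) * 2 * np.pi)
        stim = np.array([0.1 + 0.05j, 0.12 + 0.04j, 0.14 + 0.03j])
        dt = 1e-3
        lp = np.array([[p.alpha, p.beta1, p.beta2, p.delta1, p.delta2]
                       for p in (cfg.layer1, cfg.layer2, cfg.layer3)])

        def reference_rhs(z, c, s):
            dz = np.empty_like(z)
            params = (cfg.layer1, cfg.layer2, cfg.layer3)
            x1 = np.zeros(m.n, complex)
            for e in range(m.conn_targets.size):
                i, j = m.conn_targets[e], m.conn_sources[e]
                x1[i] += osc.coupling_input(
                    z[0, [j]], z[1, i], c[[e]], ratios=((m.conn_k[e], m.conn_m[e]),)
                )
            for layer in range(3):
                for i in range(m.n):
                    x = s if layer == 0 else (
                        x1[i] if layer == 1 else cfg.w_23 * z[1, i] + cfg.w_13 * z[0, i]
                    )
                    om = 2 * np.pi if cfg.freq_scaling else 2 * np.pi * m.freqs[i]
                    scale = m.freqs[i] if cfg.freq_scaling else 1.0
                    dz[layer, i] = scale * osc.oscillator_derivative(
                        z[layer, i], params[layer], om, x
                    )
            dc = np.empty_like(c)
            for e in range(m.conn_targets.size):
                i, j = m.conn_targets[e], m.conn_sources[e]
                dc[e] = osc.hebbian_derivative(
                    c[e], cfg.lambda_, cfg.mu1, cfg.mu2, cfg.kappa, cfg.tau,
                    z[1, i], z[0, j], k=m.conn_k[e], m=m.conn_m[e],
                )
            return dz, dc

        k1z, k1c = reference_rhs(z0, c0, stim[0])
        k2z, k2c = reference_rhs(z0 + dt / 2 * k1z, c0 + dt / 2 * k1c, stim[1])
        k3z, k3c = reference_rhs(z0 + dt / 2 * k2z, c0 + dt / 2 * k2c, stim[1])
        k4z, k4c = reference_rhs(z0 + dt * k3z, c0 + dt * k3c, stim[2])
        z_ref = z0 + dt / 6 * (k1z + 2 * k2z + 2 * k3z + k4z)
        c_ref = c0 + dt / 6 * (k1c + 2 * k2c + 2 * k3c + k4c)

        mf, zf, cf, _, status, _ = rk4_network(
            z0.copy(), c0.copy(),
            m.conn_targets.astype(np.int64), m.conn_sources.astype(np.int64),
            m.conn_k.astype(np.int64), m.conn_m.astype(np.int64),
            m.freqs, lp, cfg.w_23, cfg.w_13, cfg.lambda_, cfg.mu1, cfg.mu2,
            cfg.kappa, cfg.tau, stim, dt, 1, cfg.freq_scaling,
            cfg.hebbian_freq_scaling, 0,
        )
        assert status == 0
        assert np.allclose(zf, z_ref, atol=1e-13)
        assert np.allclose(cf, c_ref, atol=1e-13)
        assert np.allclose(mf[:, 1], z_ref.mean(axis=1), atol=1e-13)


def sinusoid_stimulus(freq, amp, duration, dt, phase=0.0):
    t = np.arange(2 * int(round(duration / dt)) + 1) * dt / 2
    return amp * np.exp(1j * (2 * np.pi * freq * t + phase))


class TestSimulate:
    def test_determinism(self, small_model):
        stim = sinusoid_stimulus(2.0, 0.1, 4.0, small_model.config.dt)
        a = osc.simulate(small_model, stim, duration=4.0, seed=9)
        b = osc.simulate(small_model, stim, duration=4.0, seed=9)
        assert np.array_equal(a.mean_fields, b.mean_fields)
        assert np.array_equal(a.final_connections, b.final_connections)

    def test_zero_stimulus_layers_two_three_stay_at_rest(self, small_model):
        stim = np.zeros(2 * int(round(8.0 / small_model.config.dt)) + 1, complex)
        for seed in (1, 2, 3):
            res = osc.simulate(small_model, stim, duration=8.0, seed=seed)
            assert np.abs(res.mean_fields[1]).max() < 0.05
            assert np.abs(res.mean_fields[2]).max() < 0.05

    def test_entrainment_phase_locks_near_drive(self, small_model):
        # oscillator within 2% of the 2-Hz drive phase-locks: the drive-relative
        # phase stops drifting over the last 4 s
        stim = sinusoid_stimulus(2.0, 0.2, 12.0, small_model.config.dt)
        res = osc.simulate(small_model, stim, duration=12.0, seed=0,
                           keep_trajectories=True, trajectory_stride=24)
        i2 = np.argmin(np.abs(small_model.freqs - 2.0))
        assert abs(small_model.freqs[i2] - 2.0) / 2.0 < 0.02
        traj = res.trajectories[0][i2]
        tt = res.trajectory_times
        tail = tt > 8.0
        rel = np.angle(traj[tail] * np.exp(-1j * 2 * np.pi * 2.0 * tt[tail]))
        assert np.std(np.unwrap(rel)) < 0.1

    def test_insufficient_stimulus_raises(self, small_model):
        with pytest.raises(ValueError, match="half-step"):
            osc.simulate(small_model, np.zeros(10, complex), duration=4.0)

    def test_mean_field_equals_oscillator_average(self, small_model):
        stim = sinusoid_stimulus(2.0, 0.1, 2.0, small_model.config.dt)
        res = osc.simulate(small_model, stim, duration=2.0, seed=4,
                           keep_trajectories=True, trajectory_stride=48)
        k = 5  # spot-check a recorded stride
        step = 5 * 48
        for layer in range(3):
            assert res.mean_fields[layer][step] == pytest.approx(
                res.trajectories[layer][:, k].mean(), abs=1e-12
            )

    def test_dt_convergence_of_beat_amplitude(self):
        cfg = osc.ModelConfig(n_oscillators=81, f_min=0.5, f_max=8.0)
        model = osc.build_default_model(cfg)
        from groovenet.rhythms import BeatGrid

        grid = BeatGrid(2.0, 2, 4, 2)
        onsets = np.zeros(grid.n_positions, bool)
        onsets[::2] = True
        pat = RhythmPattern(grid, onsets)
        amps = []
        for dt in (1 / 480, 1 / 960):
            cfg_dt = osc.ModelConfig(**{**cfg.to_dict(), "dt": dt})
            cfg_dt = osc.ModelConfig.from_dict(cfg_dt.to_dict())
            m = osc.build_default_model(cfg_dt)
            stim = osc._melody_stimulus(pat, cfg_dt, 4.0)
            res = osc.simulate(m, stim, duration=4.0, seed=11)
            amps.append(osc.amplitude_at_beat(res.mean_fields[0], res.sample_rate,
                                              window=(2.0, 4.0)))
        assert abs(amps[1] - amps[0]) / amps[0] < 0.005


class TestAmplitudeAtBeat:
    def test_complex_phasor_amplitude(self):
        sr = 480.0
        t = np.arange(0, 16, 1 / sr)
        mf = 0.3 * np.exp(1j * 2 * np.pi * 2 * t)
        assert osc.amplitude_at_beat(mf, sr) == pytest.approx(0.3, rel=1e-6)

    def test_zero_mean_field(self):
        assert osc.amplitude_at_beat(np.zeros(480 * 16, complex), 480.0) == 0.0

    def test_global_phase_invariance(self):
        sr = 480.0
        t = np.arange(0, 16, 1 / sr)
        mf = 0.3 * np.exp(1j * 2 * np.pi * 2 * t)
        a = osc.amplitude_at_beat(mf, sr)
        b = osc.amplitude_at_beat(mf * np.exp(1j * 1.234), sr)
        assert a == pytest.approx(b, rel=1e-12)

    def test_window_beyond_simulation_raises(self):
        with pytest.raises(ValueError):
            osc.amplitude_at_beat(np.zeros(100, complex), 480.0, window=(2.0, 16.0))


class TestRunProtocol:
    def test_bookkeeping_and_determinism(self, on_beat_pattern):
        cfg = osc.ModelConfig(n_oscillators=31, f_min=0.5, f_max=8.0)
        model = osc.build_default_model(cfg)
        t1 = osc.run_protocol(model, [on_beat_pattern], n_runs=2, base_seed=5, duration=4.0)
        assert len(t1) == 6  # 1 melody x 2 runs x 3 layers
        assert set(t1["layer"]) == {1, 2, 3}
        assert (t1["amplitude_2hz"] >= 0).all()
        t2 = osc.run_protocol(model, [on_beat_pattern], n_runs=2, base_seed=5, duration=4.0)
        assert t1.equals(t2)

    def test_empty_melody_list_raises(self, small_model):
        with pytest.raises(ValueError):
            osc.run_protocol(small_model, [], n_runs=1)
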