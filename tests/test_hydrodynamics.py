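import numpy as np
import pytest

from reefconnect.core_grids import BathymetryGrid
from reefconnect.hydrodynamics import (
    G,
    M2_PERIOD_S,
    RHO_WATER,
    BoundaryForcing,
    FlowState,
    ShallowWaterModel,
    SolverConfig,
    SolverError,
    diagnose_sticky_water,
)
from reefconnect.synthetic_domain import make_forcing


def flat_basin(ny, nx, depth, dx=500.0):
    return BathymetryGrid(depth=np.full((ny, nx), float(depth)),
                          land_mask=np.zeros((ny, nx), bool), dx=dx)


def closed_forcing(duration=10 * 86400.0, wind=(0.0, 0.0), swell=(0.0, 90.0)):
    t = np.arange(0.0, duration, 3600.0)
    return BoundaryForcing(time=t, eta=np.zeros_like(t), closed=True,
                           wind_speed=wind[0], wind_dir_from_deg=wind[1],
                           swell_height=swell[0], swell_dir_from_deg=swell[1])


class TestStepFlow:
    def test_still_closed_basin_stays_still(self):
        grid = flat_basin(8, 12, 30.0)
        model = ShallowWaterModel(grid, SolverConfig(dt=10.0, ramp_s=0.0))
        state = model.initial_state()
        for _ in range(50):
            state = model.step(state, closed_forcing())
        assert np.all(state.eta == 0.0)
        assert np.all(state.u == 0.0)
        assert np.all(state.v == 0.0)

    def test_unstable_dt_rejected(self):
        grid = flat_basin(8, 8, 80.0)
        with pytest.raises(SolverError, match="stability"):
            ShallowWaterModel(grid, SolverConfig(dt=60.0))

    def test_wind_setup_matches_analytic_slope(self):
        # steady wind over a closed basin tilts the surface by tau/(rho g H)
        H, L = 10.0, 30
        grid = flat_basin(6, L, H)
        cfg = SolverConfig(dt=20.0, ramp_s=3600.0)
        model = ShallowWaterModel(grid, cfg)
        forcing = closed_forcing(wind=(10.0, 270.0))  # westerly -> blows east
        state = model.initial_state()
        n_steps = int(24 * 3600 / cfg.dt)
        eta_sum = np.zeros_like(state.eta)
        n_avg = 0
        for k in range(n_steps):
            state = model.step(state, forcing)
            if k >= n_steps // 2:   # average away the seiche
                eta_sum += state.eta
                n_avg += 1
        eta_mean = (eta_sum / n_avg).mean(axis=0)
        x = np.arange(L) * grid.dx
        slope = np.polyfit(x, eta_mean, 1)[0]
        tau = 1.2 * cfg.wind_drag * 10.0 ** 2
        expected = tau / (RHO_WATER * G * H)
        assert slope == pytest.approx(expected, rel=0.05)

    def test_uniform_flow_limit(self, flat_grid):
        # open flat ocean under a steady far-field current: the interior
        # velocity relaxes to the boundary value
        cfg = SolverConfig(dt=10.0, ramp_s=2 * 3600.0)
        model = ShallowWaterModel(flat_grid, cfg)
        f = make_forcing(tidal_range=0.0, mean_current=(-0.12, 0.0),
                         tidal_current_amp=(0.0, 0.0), wind=(0.0, 0.0),
                         swell=(0.0, 90.0), duration=3 * 86400.0)
        flow = model.run(f, duration=6 * 3600.0, spinup=12 * 3600.0,
                        output_interval=3600.0)
        interior_u = flow.u[-1, 10:-10, 10:-10]
        assert np.abs(interior_u.mean() - (-0.12)) < 0.05 * 0.12
        assert np.abs(flow.v[-1]).max() < 0.02

    def test_volume_conservation_each_step(self, flat_grid):
        model = ShallowWaterModel(flat_grid, SolverConfig(dt=10.0))
        f = make_forcing(duration=86400.0)
        state = model.initial_state()
        for _ in range(400):
            state = model.step(state, f)
            assert state.residual < 1e-8


class TestOpenBoundaries:
    def test_additive_boundary_current_decomposition(self, flat_grid):
        f = make_forcing(mean_current=(0.10, 0.0), tidal_current_amp=(0.05, 0.0),
                         duration=2 * 86400.0, dt=60.0)
        cfg = SolverConfig(dt=10.0, ramp_s=0.0)
        model = ShallowWaterModel(flat_grid, cfg)
        state = model.initial_state()
        t_peak = M2_PERIOD_S / 4.0  # tidal current maximum
        model.apply_open_boundaries(state, f, t_peak)
        assert state.u[:, -1] == pytest.approx(0.15, abs=1e-3)

    def test_zero_tide_boundary_carries_mean_current_only(self, flat_grid):
        f = make_forcing(tidal_range=0.0, mean_current=(0.08, -0.03),
                         tidal_current_amp=(0.0, 0.0), duration=86400.0)
        model = ShallowWaterModel(flat_grid, SolverConfig(dt=10.0, ramp_s=0.0))
        state = model.initial_state()
        model.apply_open_boundaries(state, f, 3600.0)
        assert np.allclose(state.u[:, -1], 0.08)
        assert np.allclose(state.v[0, :], -0.03)
        assert np.allclose(state.v[-1, :], -0.03)

    def test_time_outside_forcing_base_rejected(self, flat_grid):
        f = make_forcing(duration=3600.0, dt=600.0)
        with pytest.raises(ValueError, match="outside"):
            f.eta_at(10 * 86400.0)


class TestRunFlow:
    def test_archive_time_stamps_regular(self, flat_grid):
        model = ShallowWaterModel(flat_grid, SolverConfig(dt=10.0))
        f = make_forcing(duration=2 * 86400.0)
        flow = model.run(f, duration=6 * 3600.0, spinup=3600.0,
                        output_interval=1800.0)
        assert flow.times[0] == 0.0
        assert np.allclose(np.diff(flow.times), 1800.0)
        assert flow.times[-1] >= 6 * 3600.0 - 1e-6

    def test_interior_elevation_spectrum_peaks_at_forcing_period(self):
        grid = flat_basin(40, 40, 30.0)
        model = ShallowWaterModel(grid, SolverConfig(dt=14.0))
        f = make_forcing(tidal_range=1.6, mean_current=(0.0, 0.0),
                         tidal_current_amp=(0.0, 0.0), wind=(0.0, 0.0),
                         swell=(0.0, 90.0), duration=6 * 86400.0)
        flow = model.run(f, duration=3 * 86400.0, spinup=12 * 3600.0,
                        output_interval=1800.0)
        series = flow.eta[:, 20, 20] - flow.eta[:, 20, 20].mean()
        freqs = np.fft.rfftfreq(len(series), d=1800.0)
        power = np.abs(np.fft.rfft(series)) ** 2
        peak = freqs[1:][np.argmax(power[1:])]
        assert peak == pytest.approx(1.0 / M2_PERIOD_S, rel=0.1)

    def test_sponge_damps_reflected_waves(self):
        # a westward-going wave should leave through the western boundary
        # instead of bouncing back into the domain: compare the elevation
        # left in the western half after the reflection would have returned
        grid = flat_basin(6, 80, 50.0)
        f = make_forcing(tidal_range=0.0, mean_current=(0.0, 0.0),
                         tidal_current_amp=(0.0, 0.0), wind=(0.0, 0.0),
                         swell=(0.0, 90.0), duration=86400.0)
        t = np.arange(0.0, 86400.0, 600.0)
        untreated = BoundaryForcing(time=t, eta=np.zeros_like(t), closed=True)
        xs = np.arange(80)
        bump = np.tile(0.5 * np.exp(-((xs - 25.0) ** 2) / 18.0), (6, 1))
        rms = {}
        for label, forcing, width in (("wall", untreated, 0), ("sponge", f, 10)):
            cfg = SolverConfig(dt=10.0, sponge_width=width, ramp_s=0.0)
            model = ShallowWaterModel(grid, cfg)
            # probe the western half once the reflection has returned but
            # before the east-wall reflection re-enters it
            flow = model.run(forcing, duration=1200.0, spinup=0.0,
                            output_interval=300.0, initial_eta=bump)
            rms[label] = float(np.sqrt((flow.eta[-1, :, :40] ** 2).mean()))
        assert rms["sponge"] < 0.2 * rms["wall"]

    def test_flow_archive_round_trips_through_netcdf(self, tmp_path, flat_grid):
        from reefconnect.hydrodynamics import FlowField

        model = ShallowWaterModel(flat_grid, SolverConfig(dt=10.0))
        f = make_forcing(duration=86400.0)
        flow = model.run(f, duration=2 * 3600.0, spinup=0.0,
                        output_interval=1800.0)
        path = str(tmp_path / "flow.nc")
        flow.save(path)
        back = FlowField.load(path)
        assert np.array_equal(back.times, flow.times)
        assert np.array_equal(back.u, flow.u)
        assert back.grid.dx == flow.grid.dx


class TestSymmetry:
    def test_mirrored_domain_gives_mirrored_solution(self):
        rng = np.random.default_rng(0)
        depth = rng.uniform(20.0, 50.0, (20, 24))
        land = np.zeros((20, 24), bool)
        land[8:12, 10:14] = True
        depth[land] = np.nan
        grid = BathymetryGrid(depth=depth, land_mask=land, dx=500.0)
        mirrored = BathymetryGrid(depth=np.flipud(depth).copy(),
                                  land_mask=np.flipud(land).copy(), dx=500.0)
        f = make_forcing(tidal_range=1.0, mean_current=(-0.1, 0.0),
                         tidal_current_amp=(0.05, 0.0), wind=(0.0, 0.0),
                         swell=(0.0, 90.0), duration=86400.0)
        cfg = SolverConfig(dt=10.0)
        a = ShallowWaterModel(grid, cfg).run(f, duration=6 * 3600.0,
                                             spinup=0.0, output_interval=3600.0)
        b = ShallowWaterModel(mirrored, cfg).run(f, duration=6 * 3600.0,
                                                 spinup=0.0,
                                                 output_interval=3600.0)
        assert np.allclose(a.eta[-1], np.flipud(b.eta[-1]), atol=1e-10)
        assert np.allclose(a.u[-1], np.flipud(b.u[-1]), atol=1e-10)
        assert np.allclose(a.v[-1], -np.flipud(b.v[-1]), atol=1e-10)


class TestStickyWaterDiagnostics:
    def test_uniform_flow_regions_indistinguishable(self, flat_grid):
        from _support import make_uniform_flow

        flow = make_uniform_flow(flat_grid, u=0.1, t_max=86400.0)
        masks = {
            "far_field": np.zeros((30, 30), bool),
            "boundary_layer": np.zeros((30, 30), bool),
            "interior": np.zeros((30, 30), bool),
        }
        masks["far_field"][2:5, 2:5] = True
        masks["boundary_layer"][10:14, 10:14] = True
        masks["interior"][20:25, 20:25] = True
        out = diagnose_sticky_water(flow, masks)
        assert out["far_field"] == pytest.approx(out["interior"], rel=1e-6)
        assert out["far_field"] == pytest.approx(out["boundary_layer"], rel=1e-6)

    def test_land_enclosed_interior_is_stagnant(self):
        depth = np.full((20, 20), 40.0)
        land = np.zeros((20, 20), bool)
        land[6:14, 6] = land[6:14, 13] = True
        land[6, 6:14] = land[13, 6:14] = True
        depth[land] = np.nan
        grid = BathymetryGrid(depth=depth, land_mask=land, dx=500.0)
        model = ShallowWaterModel(grid, SolverConfig(dt=12.0, ramp_s=3600.0))
        f = make_forcing(tidal_range=0.0, mean_current=(-0.1, 0.0),
                         tidal_current_amp=(0.0, 0.0), wind=(0.0, 0.0),
                         swell=(0.0, 90.0), duration=2 * 86400.0)
        flow = model.run(f, duration=6 * 3600.0, spinup=6 * 3600.0,
                        output_interval=3600.0)
        inner = np.zeros((20, 20), bool)
        inner[8:12, 8:12] = True
        outer = np.zeros((20, 20), bool)
        outer[1:4, :] = True
        out = diagnose_sticky_water(flow, {"inner": inner, "outer": outer})
        assert out["inner"] < 0.05 * out["outer"]

    def test_empty_mask_rejected(self, flat_grid):
        from _support import make_uniform_flow

        flow = make_uniform_flow(flat_grid, u=0.1, t_max=7200.0)
        with pytest.raises(ValueError, match="empty"):
            diagnose_sticky_water(flow, {"m": np.zeros((30, 30), bool)})
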