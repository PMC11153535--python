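import numpy as np
import pytest

import ivoct
from ivoct.flush import (
    Grid,
    mass_balance_report,
    solve_flushing,
    wall_stress,
)
from ivoct.schedules import FlowWaveform


def _steady(flow_ml_s):
    return FlowWaveform(np.array([0.0, 100.0]), np.full(2, float(flow_ml_s)))


class TestGrid:
    def test_guiding_catheter_blocks_cells_upstream_only(self, base_config):
        g = Grid.from_geometry(base_config.geometry, 32, 200)
        assert g.solid.any()
        # blocked band sits between the catheter radii and upstream of z = 0
        i, j = np.nonzero(g.solid)
        assert np.all(g.z_c[j] < 0.0)
        assert np.all((g.r_c[i] > 0.9e-3) & (g.r_c[i] < 1.0e-3))

    def test_inlet_channels_are_disjoint_and_flank_the_catheter(self, base_config):
        g = Grid.from_geometry(base_config.geometry, 32, 200)
        assert not np.any(g.inlet_saline & g.inlet_blood)
        assert g.r_c[g.inlet_saline].max() < 0.9e-3
        assert g.r_c[g.inlet_blood].min() > 1.0e-3


class TestEquilibrium:
    def test_zero_flow_keeps_fields_constant(self, base_config):
        res = solve_flushing(
            base_config,
            blood_waveform=None,
            injection_waveform=None,
            fidelity="laminar",
            nr=12,
            nz=40,
            t_end=0.05,
        )
        assert np.abs(res.final_state.w).max() == 0.0
        assert np.abs(res.final_state.u).max() == 0.0
        np.testing.assert_allclose(
            res.haematocrit_frames[-1], res.haematocrit_frames[0], atol=1e-12
        )

    def test_quiescent_wall_stress_is_zero_shear(self, base_config):
        res = solve_flushing(
            base_config,
            fidelity="laminar",
            nr=12,
            nz=40,
            t_end=0.02,
        )
        prof = res.wall_stress_profile(0.02)
        assert np.abs(prof.shear).max() == 0.0

    def test_closed_box_conserves_erythrocyte_mass(self, base_config):
        # no inflow; start from a radially nonuniform field and let the
        # solver run: the only mass-balance error is discretization drift
        g = Grid.from_geometry(base_config.geometry, 12, 40)
        X0 = 0.45 * (g.r_c[:, None] - g.r_in) / (g.r_out - g.r_in) * np.ones(40)
        res = solve_flushing(
            base_config,
            fidelity="laminar",
            nr=12,
            nz=40,
            t_end=0.1,
            initial_haematocrit=X0,
        )
        assert mass_balance_report(res).max() < 1e-6
        np.testing.assert_allclose(
            res.mass_total, res.mass_total[0], rtol=1e-12
        )


class TestPoiseuilleOracle:
    def test_velocity_profile_within_two_percent(self, poiseuille_fine):
        assert poiseuille_fine["velocity_l2"] < 0.02

    def test_wall_shear_within_three_percent(self, poiseuille_fine):
        assert poiseuille_fine["wall_shear_rel"] < 0.03

    def test_refinement_reduces_the_error(self, poiseuille_fine, poiseuille_coarse):
        assert (
            poiseuille_fine["velocity_l2"] < poiseuille_coarse["velocity_l2"]
        )

    def test_divergence_free_after_projection(self, poiseuille_fine):
        res = poiseuille_fine["result"]
        g = res.grid
        st = res.final_state
        div = (
            g.r_f[1:, None] * st.u[1:, :] - g.r_f[:-1, None] * st.u[:-1, :]
        ) / (g.r_c[:, None] * g.dr) + (st.w[:, 1:] - st.w[:, :-1]) / g.dz
        fluid = ~g.solid
        scale = np.abs(st.w).max() / g.dz
        assert np.abs(div[fluid]).max() / scale < 1e-8


class TestFlushingRun:
    def test_species_stays_within_physical_bounds(self, continuous_run):
        X = continuous_run.flush.haematocrit_frames
        assert X.min() > -1e-3
        assert X.max() < 0.45 + 1e-3

    def test_lumen_clears_near_the_lens_after_injection_starts(self, continuous_run):
        res = continuous_run.flush
        lum = res.lumen_mean_haematocrit(55.0, 65.0)
        assert lum[res.frame_index(0.8)] == pytest.approx(0.45, abs=1e-6)
        cleared = res.times[lum < 0.05]
        cleared = cleared[cleared > 0.8]
        assert cleared.size > 0
        assert 0.9 <= cleared[0] <= 2.0  # about a second after injection starts

    def test_lumen_average_decreases_during_first_injection_cycle(
        self, continuous_run
    ):
        res = continuous_run.flush
        lum = res.lumen_mean_haematocrit(0.0, 80.0)
        i0, i1 = res.frame_index(1.0), res.frame_index(1.6)
        assert lum[i1] < lum[i0]

    def test_mass_balance_closes_on_the_desk_grid(self, continuous_run):
        assert mass_balance_report(continuous_run.flush).max() < 1e-2

    def test_reflux_wall_shear_is_elevated_upstream_and_localized(
        self, continuous_run
    ):
        """During the reflux phase the jet/vortex drives wall shear well
        above the 1.0-2.5 Pa physiological range, directed upstream and
        concentrated within a centimetre of the guiding catheter outlet."""
        res = continuous_run.flush
        g = res.grid
        downstream = g.z_c > 0.0
        sel = (res.times >= 1.02) & (res.times <= 1.18)
        shear = res.wall_shear[sel][:, downstream]
        flat = np.argmax(np.abs(shear))
        _, j = np.unravel_index(flat, shear.shape)
        peak = shear.ravel()[flat]
        assert abs(peak) > 3.0
        assert peak < 0.0  # upstream, against the mean flow
        assert g.z_c[downstream][j] < 0.010  # within 10 mm of the outlet

    def test_wall_stress_function_matches_stored_profiles(self, continuous_run):
        res = continuous_run.flush
        state = res.final_state
        i = res.frame_index(state.time)
        prof = wall_stress(
            state, res.grid, res.haematocrit_frames[i], res.constants
        )
        np.testing.assert_allclose(prof.shear, res.wall_shear[i], rtol=1e-6)

    def test_xarray_export_carries_named_coordinates(self, continuous_run):
        ds = continuous_run.flush.to_xarray()
        assert set(ds.coords) == {"t", "r", "z"}
        assert ds["haematocrit"].dims == ("t", "r", "z")


class TestKomegaFidelity:
    def test_short_run_is_stable_with_nonnegative_turbulence(self, base_config):
        sch = ivoct.default_schemes(base_config)
        res = solve_flushing(
            base_config,
            blood_waveform=ivoct.blood_inflow_waveform(),
            injection_waveform=sch["continuous"].waveform,
            fidelity="rans_komega",
            nr=16,
            nz=80,
            t_end=1.0,
        )
        st = res.final_state
        assert np.isfinite(st.w).all()
        assert st.k.min() >= 0.0
        assert st.omega.min() > 0.0
        assert st.nu_t.min() >= 0.0
        # the saline jet has started clearing the near-catheter lumen
        lum = res.lumen_mean_haematocrit(0.0, 20.0)
        assert lum[-1] < lum[res.frame_index(0.8)]


def test_solver_is_deterministic(base_config):
    kwargs = dict(
        blood_waveform=ivoct.blood_inflow_waveform(),
        injection_waveform=ivoct.default_schemes(base_config)["continuous"].waveform,
        fidelity="laminar_eddy",
        nr=12,
        nz=48,
        t_end=0.9,
    )
    a = solve_flushing(base_config, **kwargs)
    b = solve_flushing(base_config, **kwargs)
    np.testing.assert_array_equal(a.haematocrit_frames, b.haematocrit_frames)
    np.testing.assert_array_equal(a.final_state.w, b.final_state.w)
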