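"""Fluctuation–dissipation response profiles, multipole split, spectra."""

import numpy as np
import pytest

from sfgmultipole.core_io import (DepthGrid, SpectralGrid, Trajectory,
                                  TrajectoryError, block_slices)
from sfgmultipole import response as rsp
from sfgmultipole.response import (APPLIES_QUANTUM_CORRECTION,
                                   LinearResponseProfile, ResponseError,
                                   SecondOrderProfile, SFGSpectrum,
                                   apply_redshift, band_integral, chi2_dl,
                                   dielectric_profiles, integrate_spectrum,
                                   effective_eps_relations,
                                   lorentz_oscillator_epsilon,
                                   magnetic_bulk_contribution,
                                   molecular_hyperpolarizability,
                                   second_order_dipole_profile,
                                   second_order_quadrupole_profile,
                                   split_dd_dq, total_spectrum)
from sfgmultipole.synthetic import (ToyWaterModel, _assemble_frame,
                                    langevin_dynamics, mirror_trajectory)
from sfgmultipole.units import C0_CM_FS


def _subtraj(traj, sl):
    return Trajectory(traj.frames[sl], traj.topology, dt=traj.dt,
                      temperature=traj.temperature)


class TestLinearResponse:
    def test_gas_of_oscillators_matches_lorentz_epsilon(self, model,
                                                        vibrating_bulk):
        """Uncoupled vibrating dipoles: ε_xx from the FD route matches the
        closed-form Lorentz-oscillator dielectric function.

        The xx (E-driving) map is the consistent one for a gas without
        dipole–dipole coupling in the dynamics; the zz map presupposes
        interacting dipole fluctuations.  The residual tolerance covers
        the window bias of the finite lag range plus sampling noise.
        """
        traj = vibrating_bulk
        grid = DepthGrid.regular(0.0, traj.box[2], traj.box[2],
                                 reference="lab")
        depths = traj.com_positions()[..., 2]
        sg = SpectralGrid(dt=traj.dt, n_lags=4096, nu_max=4100.0)
        lin = rsp.linear_polarization_response(traj, model, depths, grid,
                                               sg, conjugate="self")
        got = dielectric_profiles(lin).eps_xx[0]
        density = traj.topology.n_molecules / np.prod(traj.box)
        want = lorentz_oscillator_epsilon(model, density, sg.frequencies)
        for lo, hi in ((1500, 1800), (3400, 3900)):
            band = (sg.frequencies > lo) & (sg.frequencies < hi)
            l2 = (np.linalg.norm(got[band] - want[band])
                  / np.linalg.norm(want[band] - 1.0))
            assert l2 < 0.15
            pk_got = sg.frequencies[band][np.argmax(got.imag[band])]
            pk_want = sg.frequencies[band][np.argmax(want.imag[band])]
            assert abs(pk_got - pk_want) <= 2 * sg.dnu

    def test_isotropic_bulk_xx_equals_zz(self, model, vibrating_bulk):
        traj = vibrating_bulk
        grid = DepthGrid.regular(0.0, traj.box[2], traj.box[2],
                                 reference="lab")
        depths = traj.com_positions()[..., 2]
        sg = SpectralGrid(dt=traj.dt, n_lags=1024, nu_max=4100.0)
        lin = rsp.linear_polarization_response(traj, model, depths, grid,
                                               sg)
        band = (sg.frequencies > 1550) & (sg.frequencies < 1750)
        sxx = lin.s_xx[0, band]
        szz = lin.s_zz[0, band]
        assert np.abs(sxx - szz).max() < 0.5 * np.abs(sxx).max()


class TestDielectricMaps:
    def _lin(self, sxx, szz):
        grid = DepthGrid.regular(0, 1, 1.0)
        return LinearResponseProfile(
            np.full((1, 1), sxx, dtype=complex),
            np.full((1, 1), szz, dtype=complex), grid, np.array([100.0]))

    def test_zero_response_gives_vacuum(self):
        eps = dielectric_profiles(self._lin(0.0, 0.0))
        assert eps.eps_xx[0, 0] == 1.0 and eps.eps_zz[0, 0] == 1.0
        assert eps.eps_iso[0, 0] == 1.0

    def test_zz_map_arithmetic(self):
        eps = dielectric_profiles(self._lin(0.0, 0.4350))
        np.testing.assert_allclose(eps.eps_zz[0, 0], 1.0 / (1 - 0.4350))
        np.testing.assert_allclose(eps.eps_zz[0, 0].real, 1.770, atol=5e-3)

    def test_xx_map_arithmetic(self):
        eps = dielectric_profiles(self._lin(0.77, 0.0))
        np.testing.assert_allclose(eps.eps_xx[0, 0], 1.77)

    def test_pole_masked_with_warning(self):
        with pytest.warns(UserWarning, match="pole"):
            eps = dielectric_profiles(self._lin(0.0, 1.0))
        assert np.isnan(eps.eps_zz[0, 0])


class TestSecondOrderDipole:
    def test_constant_polarizability_gives_zero(self, model, small_slab):
        """With dα/dq = 0 the dressed polarizability never fluctuates and
        the D channel vanishes identically."""
        quiet = ToyWaterModel(
            dalpha_dq=(np.zeros((3, 3)),) * 3)
        traj = langevin_dynamics(small_slab.frames[0], quiet, steps=2048,
                                 dt=1.0, T=298.0, seed=5)
        grid = DepthGrid.regular(0, 45, 1.0, reference="lab")
        depths = traj.com_positions()[..., 2]
        sg = SpectralGrid(dt=1.0, n_lags=512, nu_max=4100.0)
        prof = second_order_dipole_profile(traj, quiet, depths, grid, sg,
                                           ("yyz",))
        np.testing.assert_allclose(prof["yyz"].values, 0.0, atol=1e-14)

    def test_oriented_molecules_match_double_harmonic_closed_form(
            self, model, oriented_replicas, lab_grid):
        """Ensemble of θ=0 molecules: the FD line shape equals the
        double-harmonic expression Σ_m (dα/dq)(dμ/dq)/(m(ω₀²−ω²−iγω))."""
        traj = oriented_replicas
        depths = traj.com_positions()[..., 2]
        sg = SpectralGrid(dt=traj.dt, n_lags=4096, nu_max=4100.0)
        prof = second_order_dipole_profile(traj, model, depths, lab_grid,
                                           sg, ("yyz",), conjugate="self")
        S = integrate_spectrum(prof["yyz"])
        beta = molecular_hyperpolarizability(model, sg.frequencies)
        closed = 100 * beta[1, 1, 2, :] / traj.area
        for lo, hi, tol in ((1500, 1800, 0.10), (3450, 3900, 0.15)):
            sel = (sg.frequencies > lo) & (sg.frequencies < hi)
            l2 = (np.linalg.norm(S.values[sel] - closed[sel])
                  / np.linalg.norm(closed[sel]))
            assert l2 < tol
        ip = np.argmax(np.abs(closed))
        assert np.sign(S.values[ip].imag) == np.sign(closed[ip].imag)
        peak = sg.frequencies[np.argmax(np.abs(S.values))]
        assert abs(peak - sg.frequencies[ip]) <= 2 * sg.dnu

    def test_nyquist_guard(self, model, vibrating_slab, lab_grid):
        sg = SpectralGrid(dt=6.0, n_lags=256)
        with pytest.raises(ResponseError, match="Nyquist"):
            second_order_dipole_profile(
                vibrating_slab, model,
                vibrating_slab.com_positions()[..., 2], lab_grid, sg)

    def test_z_mirror_antisymmetry(self, model, vibrating_slab):
        """Reflecting every configuration through the slab midplane negates
        the yyz and zzz response profiles (depth axis reversed)."""
        traj = vibrating_slab
        grid = DepthGrid.regular(0.0, traj.box[2], 0.5, reference="lab")
        sg = SpectralGrid(dt=traj.dt, n_lags=512, nu_max=2200.0)
        mirr = mirror_trajectory(traj)
        p0 = second_order_dipole_profile(
            traj, model, traj.com_positions()[..., 2], grid, sg,
            ("yyz", "zzz"))
        p1 = second_order_dipole_profile(
            mirr, model, mirr.com_positions()[..., 2], grid, sg,
            ("yyz", "zzz"))
        for comp in ("yyz", "zzz"):
            np.testing.assert_allclose(p1[comp].values,
                                       -p0[comp].values[::-1],
                                       atol=1e-10 * np.abs(
                                           p0[comp].values).max())


class TestQuadrupoleChannel:
    def test_no_quadrupole_polarizability_gives_zero(self, model,
                                                     small_slab):
        quiet = ToyWaterModel(alphaq_e=0.0, dalphaq_dq=(0.0, 0.0, 0.0))
        traj = langevin_dynamics(small_slab.frames[0], quiet, steps=2048,
                                 dt=1.0, T=298.0, seed=6)
        grid = DepthGrid.regular(0, 45, 1.0, reference="lab")
        sg = SpectralGrid(dt=1.0, n_lags=512, nu_max=4100.0)
        prof = second_order_quadrupole_profile(
            traj, quiet, traj.com_positions()[..., 2], grid, sg, ("yyz",))
        np.testing.assert_allclose(prof["yyz"].values, 0.0, atol=1e-14)

    def test_full_box_integral_telescopes_to_zero(self, model,
                                                  vibrating_slab):
        """s(2,Q) is a z-derivative: its integral over a grid whose ends
        sit in vacuum reduces to the (vanishing) boundary values."""
        traj = vibrating_slab
        grid = DepthGrid.regular(0.0, traj.box[2], 0.5, reference="lab")
        sg = SpectralGrid(dt=traj.dt, n_lags=512, nu_max=2200.0)
        prof = second_order_quadrupole_profile(
            traj, model, traj.com_positions()[..., 2], grid, sg, ("yyz",))
        total = prof["yyz"].values.sum(axis=0) * grid.width
        scale = np.abs(prof["yyz"].values).sum(axis=0).max() * grid.width
        assert np.abs(total).max() < 2e-2 * scale


class TestDDDQSplit:
    def test_split_conserves_d_channel(self, model, vibrating_slab):
        traj = vibrating_slab
        grid = DepthGrid.regular(0.0, traj.box[2], 1.0, reference="lab")
        depths = traj.com_positions()[..., 2]
        sg = SpectralGrid(dt=traj.dt, n_lags=512, nu_max=2200.0)
        d = second_order_dipole_profile(traj, model, depths, grid, sg,
                                        ("yyz",))
        dd, dq = split_dd_dq(traj, model, d, depths, grid, sg,
                             coupling=False)
        np.testing.assert_allclose(
            dd["yyz"].values + dq["yyz"].values, d["yyz"].values,
            rtol=1e-12, atol=1e-15)
        assert np.abs(dq["yyz"].values).max() > 0.0

    def test_model_without_quadrupoles_degenerates_with_warning(
            self, model, small_slab):
        quiet = ToyWaterModel(alphaq_e=0.0, dalphaq_dq=(0.0, 0.0, 0.0))
        traj = langevin_dynamics(small_slab.frames[0], quiet, steps=1024,
                                 dt=1.0, T=298.0, seed=6)
        grid = DepthGrid.regular(0, 45, 1.0, reference="lab")
        depths = traj.com_positions()[..., 2]
        sg = SpectralGrid(dt=1.0, n_lags=256, nu_max=4100.0)
        d = second_order_dipole_profile(traj, quiet, depths, grid, sg,
                                        ("yyz",))
        with pytest.warns(UserWarning, match="DD = D"):
            dd, dq = split_dd_dq(traj, quiet, d, depths, grid, sg)
        np.testing.assert_allclose(dq["yyz"].values, 0.0)
        np.testing.assert_array_equal(dd["yyz"].values, d["yyz"].values)


class TestOriginShift:
    def test_d_plus_q_invariant_at_zero_mismatch(self, model,
                                                 vibrating_slab):
        """Shifting all molecular expansion origins by a fixed body-frame
        offset changes the D and Q profiles individually but not the
        full-box D+Q spectrum at Δk_z = 0."""
        traj = vibrating_slab
        grid = DepthGrid.regular(0.0, traj.box[2], 0.5, reference="lab")
        depths = traj.com_positions()[..., 2]
        sg = SpectralGrid(dt=traj.dt, n_lags=512, nu_max=2200.0)
        offset = np.array([0.0, 0.1, 0.25])
        res = {}
        for tag, off in (("com", None), ("shifted", offset)):
            d = second_order_dipole_profile(traj, model, depths, grid, sg,
                                            ("yyz",), origin_offset=off)
            q = second_order_quadrupole_profile(
                traj, model, depths, grid, sg, ("yyz",), origin_offset=off)
            res[tag] = (d["yyz"].values, q["yyz"].values)
        S = {tag: (v[0] + v[1]).sum(axis=0) * grid.width
             for tag, v in res.items()}
        scale = np.abs(S["com"]).max()
        assert np.abs(S["shifted"] - S["com"]).max() < 1e-6 * scale
        # the individual profiles do change
        assert np.abs(res["shifted"][0] - res["com"][0]).max() > 1e-3 * \
            np.abs(res["com"][0]).max()
        assert np.abs(res["shifted"][1] - res["com"][1]).max() > 1e-3 * \
            np.abs(res["com"][1]).max()


class TestSpectraUtilities:
    def _delta_profile(self, z0=4.25, nbins=20, width=0.5):
        grid = DepthGrid.regular(0, nbins * width, width, reference="lab")
        vals = np.zeros((nbins, 3), dtype=complex)
        idx = grid.assign(np.array([z0]))[0]
        vals[idx] = 2.0 + 1.0j
        return SecondOrderProfile(vals, grid, np.array([1.0, 2.0, 3.0]))

    def test_zero_mismatch_plain_integral(self):
        prof = self._delta_profile()
        S = integrate_spectrum(prof, dkz=0.0)
        np.testing.assert_allclose(S.values, (2 + 1j) * 0.5)

    def test_delta_layer_phase_factor(self):
        prof = self._delta_profile(z0=4.25)
        dkz = 0.8            # nm⁻¹
        S = integrate_spectrum(prof, dkz=dkz)
        want = (2 + 1j) * 0.5 * np.exp(-1j * dkz / 10.0 * 4.25)
        np.testing.assert_allclose(S.values, want)

    def test_beta_channels_sum_to_total(self):
        nu = np.linspace(0, 10, 5)
        parts = [SFGSpectrum(np.random.default_rng(k).normal(size=5)
                             + 0j, nu, beta=b)
                 for k, b in enumerate(("DD", "DQ", "Q", "M"))]
        tot = total_spectrum(parts)
        np.testing.assert_allclose(
            tot.values, sum(p.values for p in parts))

    def test_boundary_warning_for_non_decayed_profile(self):
        grid = DepthGrid.regular(0, 10, 1.0, reference="lab")
        vals = np.ones((10, 2), dtype=complex)
        prof = SecondOrderProfile(vals, grid, np.array([1.0, 2.0]))
        with pytest.warns(UserWarning, match="tail"):
            integrate_spectrum(prof)


class TestChi2DL:
    def _dd(self):
        grid = DepthGrid.regular(0, 3, 1.0, reference="lab")
        vals = np.full((3, 2), 1.0 + 0.5j)
        return SecondOrderProfile(vals, grid, np.array([1.0, 2.0]), "yyz",
                                  "DD")

    def test_unit_factors_identity(self):
        f = {"f_x": np.ones(3), "f_y": np.ones(3), "f_z": np.ones(3)}
        chi = chi2_dl(self._dd(), f)
        np.testing.assert_allclose(chi.values, self._dd().values)

    def test_reconstruction_identity(self):
        f = {"f_x": np.array([1.2, 1.1, 1.0]),
             "f_y": np.array([1.2, 1.1, 1.0]),
             "f_z": np.array([0.7, 0.8, 1.0])}
        chi = chi2_dl(self._dd(), f)
        np.testing.assert_allclose(chi.reconstruct_sdd(),
                                   self._dd().values, rtol=1e-14)

    def test_lorentz_plateau_scaling(self):
        """Bulk-plateau χ_yyz = s/( ((2+ε)/3)²·(2+ε)/(3ε) )."""
        eps = 1.77
        fx = (2 + eps) / 3
        fz = (2 + eps) / (3 * eps)
        f = {"f_x": np.full(3, fx), "f_y": np.full(3, fx),
             "f_z": np.full(3, fz)}
        chi = chi2_dl(self._dd(), f)
        np.testing.assert_allclose(chi.values,
                                   self._dd().values / (fx * fx * fz))

    def test_low_field_bins_masked(self):
        f = {"f_x": np.ones(3),
             "f_y": np.array([1.0, 0.001, 1.0]), "f_z": np.ones(3)}
        chi = chi2_dl(self._dd(), f)
        assert np.isnan(chi.values[1]).all()


class TestBandIntegral:
    def test_constant_band(self):
        nu = np.linspace(1400, 1900, 501)
        chi = np.full((1, 501), 0.0 + 2.5j)
        got = band_integral(chi, nu)
        np.testing.assert_allclose(got, C0_CM_FS * 2.5 * (1772 - 1507),
                                   rtol=1e-6)

    def test_zero_is_zero(self):
        nu = np.linspace(1400, 1900, 100)
        assert band_integral(np.zeros((1, 100), complex), nu)[0] == 0.0

    def test_narrow_lorentzian_area(self):
        """Lorentzian fully inside the band integrates to π·a·HWHM."""
        nu = np.linspace(1400, 1900, 8001)
        a, hw, nu0 = 3.0, 1.5, 1639.5
        chi = (a * hw ** 2 / ((nu - nu0) ** 2 + hw ** 2))[None, :] * 1j
        got = band_integral(chi, nu)
        np.testing.assert_allclose(got, C0_CM_FS * np.pi * a * hw,
                                    rtol=0.01)

    def test_band_outside_grid_rejected(self):
        nu = np.linspace(1600, 1700, 10)
        with pytest.raises(ValueError, match="band"):
            band_integral(np.zeros((1, 10), complex), nu)


class TestEffectiveEps:
    def _spec(self, comp):
        return SFGSpectrum(np.array([1.0 + 1.0j]), np.array([1650.0]),
                           component=comp)

    def test_unit_eps_identity(self):
        out = effective_eps_relations(self._spec("yyz"),
                                      {"IR": 1.0, "VIS": 1.0, "SFG": 1.0})
        np.testing.assert_allclose(out, self._spec("yyz").values)

    def test_yyz_scales_with_ir_only(self):
        out1 = effective_eps_relations(self._spec("yyz"), {"IR": 1.0})
        out2 = effective_eps_relations(self._spec("yyz"), {"IR": 2.0})
        np.testing.assert_allclose(out2, 2.0 * out1)

    def test_zzz_triple_product(self):
        out = effective_eps_relations(self._spec("zzz"),
                                      {"IR": 2.0, "VIS": 2.0, "SFG": 2.0})
        np.testing.assert_allclose(out, 8.0 * self._spec("zzz").values)


class TestRedshift:
    def _spec(self):
        nu = np.linspace(1000, 4000, 301)
        vals = np.exp(-((nu - 1700) / 30.0) ** 2) + 0j
        return SFGSpectrum(vals, nu, component="yyz", beta="total")

    def test_zero_shift_identity(self):
        s = apply_redshift(self._spec(), 0.0, 0.0, 2500.0)
        np.testing.assert_allclose(s.frequencies, self._spec().frequencies)

    def test_bend_peak_relabeled(self):
        s = apply_redshift(self._spec(), 28.0, 166.0, 2500.0)
        peak = s.frequencies[np.argmax(np.abs(s.values))]
        np.testing.assert_allclose(peak, 1672.0, atol=s.frequencies[1]
                                   - s.frequencies[0])

    def test_intensity_integral_preserved_uniform_shift(self):
        spec = self._spec()
        s = apply_redshift(spec, 28.0, 28.0, 5000.0)   # boundary past grid
        before = np.trapezoid(np.abs(spec.values), spec.frequencies)
        after = np.trapezoid(np.abs(s.values), s.frequencies)
        np.testing.assert_allclose(after, before, rtol=1e-12)

    def test_overlapping_segments_with_signal_rejected(self):
        nu = np.linspace(2300, 2700, 401)
        vals = np.ones(401, dtype=complex)
        spec = SFGSpectrum(vals, nu)
        with pytest.raises(ResponseError, match="overlap"):
            apply_redshift(spec, 28.0, 166.0, 2500.0)


class TestMagneticChannel:
    def test_zero_velocities_give_zero(self, model, small_slab):
        frozen = langevin_dynamics(small_slab.frames[0],
                                   ToyWaterModel(friction=0.0), steps=512,
                                   dt=0.4, T=0.0, seed=1)
        sg = SpectralGrid(dt=0.4, n_lags=128, nu_max=4100.0)
        out = magnetic_bulk_contribution(frozen, model, sg)
        np.testing.assert_allclose(out["yyz"].values, 0.0, atol=1e-14)

    def test_zzz_vanishes_by_symmetry(self, model, vibrating_bulk):
        fine = langevin_dynamics(vibrating_bulk.frames[0], model,
                                 steps=1024, dt=0.4, T=298.0, seed=9)
        sg = SpectralGrid(dt=0.4, n_lags=256, nu_max=4100.0)
        out = magnetic_bulk_contribution(fine, model, sg)
        np.testing.assert_array_equal(out["zzz"].values, 0.0)
        assert np.abs(out["yyz"].values).max() > 0.0

    def test_linear_in_molecular_currents(self, model, vibrating_bulk):
        fine = langevin_dynamics(vibrating_bulk.frames[0], model,
                                 steps=1024, dt=0.4, T=298.0, seed=9)
        doubled = Trajectory(
            [type(f)(f.positions, f.box, velocities=2.0 * f.velocities,
                     charges=f.charges, time=f.time) for f in fine.frames],
            fine.topology, dt=fine.dt, temperature=fine.temperature)
        sg = SpectralGrid(dt=0.4, n_lags=256, nu_max=4100.0)
        s1 = magnetic_bulk_contribution(fine, model, sg)["yyz"].values
        s2 = magnetic_bulk_contribution(doubled, model, sg)["yyz"].values
        np.testing.assert_allclose(s2, 2.0 * s1, rtol=1e-9)

    def test_coarse_writeout_rejected(self, model, vibrating_bulk):
        sg = SpectralGrid(dt=1.0, n_lags=256, nu_max=4100.0)
        with pytest.raises(ResponseError, match="fine"):
            magnetic_bulk_contribution(vibrating_bulk, model, sg)

    def test_missing_velocities_rejected(self, model, small_slab):
        sg = SpectralGrid(dt=0.4, n_lags=16, nu_max=4100.0)
        with pytest.raises(TrajectoryError):
            magnetic_bulk_contribution(small_slab, model, sg)


def test_no_quantum_correction_anywhere():
    """Spectra are classical response functions; no harmonic
    quantum-correction factor exists in the API."""
    assert APPLIES_QUANTUM_CORRECTION is False
    import inspect
    for fn in (second_order_dipole_profile,
               second_order_quadrupole_profile,
               rsp.linear_polarization_response, magnetic_bulk_contribution):
        params = inspect.signature(fn).parameters
        assert not any("quantum" in p.lower() for p in params)
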