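"""Monte Carlo transport: determinism, physics limits, and scaling."""

import numpy as np
import pytest

from margindrs.forward import (MCConfig, ProbeGeometry, Spectrum,
                               build_baseline, radial_profile,
                               run_direct_mc, scale_reflectance,
                               simulate_spectrum)
from margindrs.spectra import (ChromophoreConcentrations, OpticalProperties,
                               calibrate_amplitude, compose_mua,
                               default_grid, musp_power_law)


def _diffusion_reflectance(rho_cm, mua, musp, n_rel):
    """Independent oracle: steady-state diffusion dipole reflectance
    R(rho) per cm^2 for a pencil source on a semi-infinite medium."""
    mutr = mua + musp
    d_coef = 1.0 / (3.0 * mutr)
    mueff = np.sqrt(3.0 * mua * mutr)
    z0 = 1.0 / mutr
    rd = (-1.440 / n_rel ** 2 + 0.710 / n_rel + 0.668 + 0.0636 * n_rel)
    a_coef = (1.0 + rd) / (1.0 - rd)
    zb = 2.0 * a_coef * d_coef
    r1 = np.sqrt(z0 ** 2 + rho_cm ** 2)
    r2 = np.sqrt((z0 + 2.0 * zb) ** 2 + rho_cm ** 2)
    return (1.0 / (4.0 * np.pi)) * (
        z0 * (mueff + 1.0 / r1) * np.exp(-mueff * r1) / r1 ** 2
        + (z0 + 2.0 * zb) * (mueff + 1.0 / r2) * np.exp(-mueff * r2) / r2 ** 2)


class TestGeometry:
    def test_default_separations_inside_instrument_span(self, geometry):
        lo, hi = geometry.separation_span_mm
        assert 0.23 <= lo and hi <= 1.10

    def test_out_of_span_geometry_rejected(self):
        with pytest.raises(ValueError):
            ProbeGeometry(collection_offset_cm=0.5)

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            MCConfig(photon_count=100)
        with pytest.raises(ValueError):
            MCConfig(g=1.0)


class TestBaseline:
    def test_same_seed_is_bit_identical(self, geometry):
        cfg = MCConfig(photon_count=50_000, rng_seed=77)
        b1 = build_baseline(geometry, cfg)
        b2 = build_baseline(geometry, cfg)
        for attr in ("r0", "d", "cospsi", "path", "weight"):
            assert np.array_equal(getattr(b1, attr), getattr(b2, attr))
        assert b1.total_exit_weight == b2.total_exit_weight

    def test_record_count_bounded_and_energy_conserved(self, baseline):
        assert 0 < baseline.n_records <= baseline.n_photons
        assert baseline.total_exit_weight / baseline.n_photons <= 1.0
        collected = baseline.collected_reflectance()
        assert 0 < collected <= baseline.total_exit_weight / baseline.n_photons

    def test_halving_collection_na_reduces_collected_fraction(self):
        """Oracle: direct re-simulation at both numerical apertures."""
        cfg = MCConfig(photon_count=150_000, rng_seed=5)
        full = build_baseline(ProbeGeometry(), cfg)
        half = build_baseline(ProbeGeometry(na=0.11), cfg)
        assert half.collected_reflectance(0.1) < full.collected_reflectance(0.1)

    def test_save_load_round_trip(self, small_baseline, tmp_path):
        p = str(tmp_path / "baseline.h5")
        small_baseline.save(p)
        loaded = type(small_baseline).load(p)
        assert np.array_equal(loaded.r0, small_baseline.r0)
        assert np.array_equal(loaded.path, small_baseline.path)
        assert loaded.config == small_baseline.config
        assert loaded.geometry == small_baseline.geometry


class TestDirectMC:
    def test_opaque_limit(self, geometry):
        cfg = MCConfig(photon_count=20_000, rng_seed=3)
        assert run_direct_mc(1000.0, 6.68, geometry, cfg) < 1e-4

    def test_reflectance_in_unit_interval(self, geometry):
        cfg = MCConfig(photon_count=20_000, rng_seed=3)
        r = run_direct_mc(1.0, 6.68, geometry, cfg)
        assert 0.0 <= r <= 1.0

    def test_nonphysical_properties_rejected(self, geometry):
        cfg = MCConfig(photon_count=20_000, rng_seed=3)
        with pytest.raises(ValueError):
            run_direct_mc(-0.1, 6.68, geometry, cfg)
        with pytest.raises(ValueError):
            run_direct_mc(1.0, 0.0, geometry, cfg)

    def test_agrees_with_diffusion_theory_at_low_absorption(self):
        """mua/mus' = 0.01 at the largest separation: the probe-free radial
        profile must match the diffusion dipole formula within 15%.

        Uses a near-point source and an index-matched boundary, where the
        dipole boundary condition (A = 1) is exact; collection fibers play
        no role in the radial tally.
        """
        musp, mua = 6.68, 0.0668
        geom = ProbeGeometry(illum_core_radius_cm=1e-4,
                             fiber_radius_cm=5e-5, n_ext=1.37)
        cfg = MCConfig(photon_count=400_000, rng_seed=11)
        rho = 0.11  # cm, the 1.10 mm maximum separation
        edges = np.array([rho - 0.01, rho + 0.01])
        r_mc = radial_profile(mua, musp, geom, cfg, edges)[0]
        r_th = _diffusion_reflectance(rho, mua, musp, 1.0)
        assert r_mc == pytest.approx(r_th, rel=0.15)


class TestScaling:
    def test_identity_scaling_matches_baseline(self, baseline):
        r = scale_reflectance(baseline, baseline.mua_ref, baseline.musp_ref)
        assert r == baseline.collected_reflectance()

    def test_strictly_decreasing_in_absorption(self, baseline):
        mus = [scale_reflectance(baseline, m, 6.68)
               for m in (0.0, 0.5, 1.0, 2.0, 5.0, 10.0)]
        assert all(a > b for a, b in zip(mus, mus[1:]))

    def test_doubling_mua_attenuates_every_record(self, baseline):
        r1 = scale_reflectance(baseline, 1.0, baseline.musp_ref)
        r2 = scale_reflectance(baseline, 2.0, baseline.musp_ref)
        assert 0 < r2 < r1

    def test_out_of_range_musp_rejected_when_strict(self, baseline):
        with pytest.raises(ValueError):
            scale_reflectance(baseline, 0.1, 30.0, strict=True)
        # non-strict extrapolation used inside the fitter stays finite
        assert np.isfinite(scale_reflectance(baseline, 0.1, 30.0,
                                             strict=False))

    @pytest.mark.parametrize("musp,mua", [(4.85, 0.5), (9.15, 3.0)])
    def test_matches_direct_mc_within_3_se(self, baseline, geometry,
                                           musp, mua):
        """Oracle: independent direct simulation at the study's extreme
        scattering levels."""
        r_s, se_s = scale_reflectance(baseline, mua, musp, return_se=True)
        cfg = MCConfig(photon_count=400_000,
                       rng_seed=int(1000 * musp + 10 * mua))
        r_d, se_d = run_direct_mc(mua, musp, geometry, cfg, return_se=True)
        assert abs(r_s - r_d) < 3.0 * np.hypot(se_s, se_d)


class TestSimulateSpectrum:
    def test_flat_properties_give_flat_spectrum(self, baseline, geometry,
                                                grid):
        props = OpticalProperties(grid, np.full(31, 1.0), np.full(31, 6.68))
        spec = simulate_spectrum(props, geometry, baseline.config, baseline)
        assert spec.provenance == "simulated"
        assert np.ptp(spec.values) / np.mean(spec.values) < 0.02

    def test_dye_reshapes_only_the_red_side(self, baseline, geometry, grid,
                                            library):
        """Adding mapping dye must depress reflectance increasingly toward
        600 nm relative to the dye-free spectrum."""
        scat = musp_power_law(calibrate_amplitude(6.68, 1.2, grid), grid)
        clean = ChromophoreConcentrations(15.5, 15.5, 16.29, 0.0)
        dyed = ChromophoreConcentrations(15.5, 15.5, 16.29, 40.0)
        s0 = simulate_spectrum(OpticalProperties(
            grid, compose_mua(clean, library, grid), scat),
            geometry, baseline.config, baseline)
        s1 = simulate_spectrum(OpticalProperties(
            grid, compose_mua(dyed, library, grid), scat),
            geometry, baseline.config, baseline)
        ratio = s1.values / s0.values
        upper = ratio[grid.values >= 520]
        assert np.all(np.diff(upper) < 0)
        assert ratio[-1] < 0.5 < ratio[0]

    def test_spectrum_value_bounds_enforced(self, grid):
        with pytest.raises(ValueError):
            Spectrum(grid, np.full(31, 1.5))
        with pytest.raises(ValueError):
            Spectrum(grid, np.full(30, 0.5))
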