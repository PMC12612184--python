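"""Clamped-membrane inflation solver against closed-form and series oracles."""

import numpy as np
import pytest

from curvchip import geometry
from curvchip.mechanics import (
    MembraneSpec,
    StressProfile,
    hencky_profile,
    laplace_residual,
    region_partition,
    solve_for_apex_height,
    solve_inflation,
)

CHIP = dict(radius_mm=4.0, thickness_um=100.0, youngs_kpa=530.0)


@pytest.fixture(scope="module")
def inflated():
    """One converged neo-Hookean solve at a chip-typical pressure."""
    return solve_inflation(MembraneSpec(pressure_kpa=1.0, **CHIP))


class TestSpecValidation:
    def test_exactly_one_load(self):
        with pytest.raises(ValueError):
            MembraneSpec(**CHIP)
        with pytest.raises(ValueError):
            MembraneSpec(pressure_kpa=1.0, target_apex_height_mm=1.0, **CHIP)

    def test_positive_material(self):
        with pytest.raises(ValueError):
            MembraneSpec(pressure_kpa=1.0, radius_mm=-1.0)

    def test_poisson_clamped(self):
        spec = MembraneSpec(pressure_kpa=1.0, poisson=0.5, **CHIP)
        assert spec.poisson <= 0.4999


class TestSolveInflation:
    def test_zero_pressure_is_flat_and_unstressed(self):
        prof = solve_inflation(MembraneSpec(pressure_kpa=0.0, **CHIP))
        assert prof.apex_height_mm == 0.0
        assert np.all(prof.sigma_meridional_kpa == 0.0)
        assert np.all(prof.sigma_hoop_kpa == 0.0)

    def test_apex_isotropy(self, inflated):
        """Axisymmetry forces equal principal stresses at the apex."""
        ratio = inflated.sigma_meridional_kpa[0] / inflated.sigma_hoop_kpa[0]
        assert ratio == pytest.approx(1.0, abs=1e-6)

    def test_laplace_equilibrium_residual(self, inflated):
        """sigma_m/rho1 + sigma_h/rho2 = p/t pointwise on the deformed dome."""
        res = laplace_residual(inflated)
        scale = inflated.pressure_kpa / inflated.spec.thickness_mm
        assert np.max(np.abs(res)) < 1e-3 * scale

    def test_clamped_edge(self, inflated):
        """Zero in-plane radial displacement at the rim: hoop stretch 1."""
        assert inflated.stretch_hoop[-1] == pytest.approx(1.0, abs=1e-9)
        assert inflated.r_deformed_mm[-1] == pytest.approx(4.0, abs=1e-8)

    def test_ratio_gradient_center_to_edge(self, inflated):
        """Meridional/hoop ratio grows monotonically from apex to clamp."""
        ratio = inflated.sigma_meridional_kpa / inflated.sigma_hoop_kpa
        assert np.all(np.diff(ratio) > -1e-9)
        assert ratio[-1] > 1.5  # near 1/nu for an incompressible membrane

    def test_grid_refinement_stability(self):
        spec = MembraneSpec(pressure_kpa=0.8, **CHIP)
        h1 = solve_inflation(spec, n_grid=100).apex_height_mm
        h2 = solve_inflation(spec, n_grid=200).apex_height_mm
        assert abs(h2 - h1) / h1 < 1e-3

    def test_small_pressure_matches_hencky_series(self):
        """Finite-rotation solver reduces to the FvK series at small load."""
        p = 0.001  # apex deflection ~0.025 a
        prof = solve_inflation(MembraneSpec(pressure_kpa=p, material="linear", **CHIP))
        oracle = hencky_profile(p, **CHIP)
        assert prof.apex_height_mm < 0.05 * 4.0
        assert prof.apex_height_mm == pytest.approx(oracle.apex_deflection_mm, rel=0.01)
        # stresses agree at the apex and mid-radius too
        mid = len(prof.r_mm) // 2
        assert prof.sigma_meridional_kpa[0] == pytest.approx(
            oracle.sigma_meridional_kpa[0], rel=0.02
        )
        assert prof.sigma_meridional_kpa[mid] == pytest.approx(
            np.interp(prof.r_mm[mid], oracle.r_mm, oracle.sigma_meridional_kpa), rel=0.02
        )

    def test_linear_scale_consistency(self):
        """Scaling p and E together leaves strain unchanged, scales stress."""
        small = solve_inflation(MembraneSpec(pressure_kpa=0.002, material="linear", **CHIP))
        scaled = solve_inflation(
            MembraneSpec(pressure_kpa=0.010, material="linear", radius_mm=4.0,
                         thickness_um=100.0, youngs_kpa=530.0 * 5)
        )
        assert scaled.apex_height_mm == pytest.approx(small.apex_height_mm, rel=1e-6)
        assert scaled.sigma_meridional_kpa[0] == pytest.approx(
            5.0 * small.sigma_meridional_kpa[0], rel=1e-6
        )


class TestSolveForApexHeight:
    def test_zero_target_is_zero_pressure(self):
        p, prof = solve_for_apex_height(MembraneSpec(target_apex_height_mm=0.0, **CHIP))
        assert p == 0.0
        assert prof.apex_height_mm == 0.0

    def test_matches_medium_curvature_dome(self):
        """Pressure found for the 15-degree dome reproduces its apex height."""
        h = geometry.angle_to_geometry(15.0, 4.0).apex_height_mm  # ~1.072 mm
        p, prof = solve_for_apex_height(MembraneSpec(target_apex_height_mm=h, **CHIP))
        assert p > 0
        assert prof.apex_height_mm == pytest.approx(h, abs=1e-4 * 4.0)

    def test_pressure_monotone_in_height(self):
        p_low, _ = solve_for_apex_height(MembraneSpec(target_apex_height_mm=0.5, **CHIP))
        p_high, _ = solve_for_apex_height(MembraneSpec(target_apex_height_mm=1.0, **CHIP))
        assert p_high > p_low

    def test_unattainable_target(self):
        with pytest.raises(ValueError):
            solve_for_apex_height(MembraneSpec(target_apex_height_mm=5.0, **CHIP))


def _synthetic_profile(r, sig_m, sig_h):
    n = r.size
    spec = MembraneSpec(pressure_kpa=1.0, **CHIP)
    return StressProfile(
        r_mm=r,
        sigma_meridional_kpa=sig_m,
        sigma_hoop_kpa=sig_h,
        deflection_mm=np.zeros(n),
        slope_rad=np.zeros(n),
        stretch_meridional=np.ones(n),
        stretch_hoop=np.ones(n),
        r_deformed_mm=r.copy(),
        pressure_kpa=1.0,
        spec=spec,
    )


class TestRegionPartition:
    def test_uniform_profile_gives_100_percent_everywhere(self):
        r = np.linspace(0, 4, 201)
        prof = _synthetic_profile(r, np.full_like(r, 3.0), np.full_like(r, 3.0))
        regions = region_partition(prof)
        for reg in regions.values():
            assert reg.ratio_percent == pytest.approx(100.0, rel=1e-9)
            assert reg.mean_meridional_kpa == pytest.approx(3.0, rel=1e-9)

    def test_linear_ramp_matches_annulus_integral(self):
        """Area-weighted mean of k*r over [lo, hi] is 2k(hi^3-lo^3)/(3(hi^2-lo^2))."""
        r = np.linspace(0, 4, 2001)
        k = 2.5
        prof = _synthetic_profile(r, k * r, np.full_like(r, 1.0))
        regions = region_partition(prof, bounds=(1.0, 3.0))
        for reg in regions.values():
            lo, hi = reg.r_inner_mm, reg.r_outer_mm
            expected = 2.0 * k * (hi**3 - lo**3) / (3.0 * (hi**2 - lo**2))
            assert reg.mean_meridional_kpa == pytest.approx(expected, rel=1e-5)

    def test_edge_ratio_exceeds_center_on_converged_solution(self, inflated):
        regions = region_partition(inflated)
        assert regions["A3"].ratio_percent > regions["A1"].ratio_percent

    def test_bounds_validation(self, inflated):
        with pytest.raises(ValueError):
            region_partition(inflated, bounds=(3.0, 1.0))


class TestHenckySeries:
    def test_cube_root_load_scaling(self):
        """FvK membrane deflection grows as p^(1/3)."""
        w1 = hencky_profile(0.001, **CHIP).apex_deflection_mm
        w8 = hencky_profile(0.008, **CHIP).apex_deflection_mm
        assert w8 / w1 == pytest.approx(2.0, rel=1e-6)

    def test_edge_condition_hoop_to_radial(self):
        """Zero rim displacement pins N_theta = nu * N_r at the edge."""
        hk = hencky_profile(0.001, poisson=0.3, **CHIP)
        assert hk.sigma_hoop_kpa[-1] / hk.sigma_meridional_kpa[-1] == pytest.approx(
            0.3, abs=1e-6
        )

    def test_apex_isotropy_and_positive_deflection(self):
        hk = hencky_profile(0.002, **CHIP)
        assert hk.sigma_hoop_kpa[0] == pytest.approx(hk.sigma_meridional_kpa[0], rel=1e-9)
        assert hk.apex_deflection_mm > 0
        assert hk.deflection_mm[-1] == 0.0
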