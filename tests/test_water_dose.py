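"""Dose-to-water engine: depth dose, tank grids, chamber array sampling."""

import dataclasses

import numpy as np
import pytest

from epid2water import (
    ArraySpec,
    FieldSpec,
    FluenceMap,
    GridSpec,
    TankGrid,
    WaterModel,
    compute_array_dose,
    compute_watertank_dose,
    depth_dose_weight,
    extract_pdd,
    total_head_fluence,
)

SMALL_TANK = TankGrid(voxel_mm=2.0, z_step_mm=2.0, half_extent_mm=70.0, depth_mm=250.0)


@pytest.fixture
def fluence_10x10(config_10x10, small_grid):
    return total_head_fluence(config_10x10, small_grid)


class TestDepthDose:
    def test_zero_surface_dose_without_contaminants(self, water_model):
        assert depth_dose_weight(0.0, FieldSpec.square(10.0), water_model) == 0.0

    def test_contaminants_raise_surface_dose_only_at_shallow_depth(self, water_model):
        f = FieldSpec.square(10.0)
        z = np.linspace(0.0, 10.0, 101)
        base = depth_dose_weight(z, f, water_model, include_contaminants=False)
        with_c = depth_dose_weight(z, f, water_model, include_contaminants=True)
        excess = (with_c - base) / with_c.max()
        assert excess[0] > 0.01
        assert np.all(excess[z > 2.0] < 0.005)

    def test_monotone_beyond_dmax(self, water_model):
        f = FieldSpec.square(10.0)
        z = np.arange(water_model.dmax_cm(f) + 0.5, 35.0, 0.1)
        w = depth_dose_weight(z, f, water_model)
        assert np.all(np.diff(w) < 0)

    def test_negative_depth_rejected(self, water_model):
        with pytest.raises(ValueError):
            depth_dose_weight(-1.0, FieldSpec.square(10.0), water_model)


class TestWaterTank:
    @pytest.mark.parametrize("side,dmax_mm", [(10.0, 14.0), (20.0, 12.0)])
    def test_pdd_maximum_depth(self, water_model, side, dmax_mm):
        """CAX depth-dose maximum at 14 mm (10x10) and 12 mm (20x20)."""
        from epid2water import BeamConfig

        cfg = BeamConfig(field=FieldSpec.square(side), mu=100.0)
        grid = GridSpec.at_isocenter(2.0, 160.0)
        f = total_head_fluence(cfg, grid)
        tank = TankGrid(voxel_mm=2.0, z_step_mm=1.0, half_extent_mm=130.0, depth_mm=60.0)
        d = compute_watertank_dose(f, water_model, field=cfg.field, tank=tank)
        pdd = extract_pdd(d)
        assert pdd.values.max() == pytest.approx(100.0)
        z_at_max = pdd.positions_mm[np.argmax(pdd.values)]
        assert z_at_max == pytest.approx(dmax_mm, abs=tank.z_step_mm)

    def test_linearity_in_fluence(self, fluence_10x10, water_model, config_10x10):
        d1 = compute_watertank_dose(
            fluence_10x10, water_model, field=config_10x10.field, tank=SMALL_TANK
        )
        f2 = FluenceMap(2.0 * fluence_10x10.values, fluence_10x10.grid)
        d2 = compute_watertank_dose(f2, water_model, field=config_10x10.field, tank=SMALL_TANK)
        np.testing.assert_allclose(d2.values, 2.0 * d1.values, rtol=1e-12)

    def test_cax_depth_curve_matches_analytic_product(self, water_model):
        """For a broad field, CAX dose = depth weight x inverse square."""
        cfg_field = FieldSpec.square(10.0)
        from epid2water import BeamConfig

        cfg = BeamConfig(field=cfg_field, mu=100.0, horn_coeffs=(), extrafocal_fraction=0.0)
        f = total_head_fluence(cfg, GridSpec.at_isocenter(1.0, 80.0))
        d = compute_watertank_dose(f, water_model, field=cfg_field, tank=SMALL_TANK)
        c = SMALL_TANK.n_lateral // 2
        cax = d.values[:, c, c]
        z = SMALL_TANK.z_coords_mm / 10.0
        analytic = depth_dose_weight(z, cfg_field, water_model) * (100.0 / (100.0 + z)) ** 2
        ratio = cax[1:] / (analytic[1:] * f.cax_value)
        assert np.max(np.abs(ratio / ratio.mean() - 1.0)) < 0.005

    def test_symmetric_fluence_gives_symmetric_slices(self, fluence_10x10, water_model):
        d = compute_watertank_dose(fluence_10x10, water_model, tank=SMALL_TANK)
        mid = d.values[d.tank.nz // 2]
        np.testing.assert_allclose(mid, mid[:, ::-1], atol=1e-12 * mid.max())
        np.testing.assert_allclose(mid, mid[::-1, :], atol=1e-12 * mid.max())

    def test_lateral_kernel_conserves_slice_integral(self, water_model):
        # transmission-free narrow beam fully inside the tank: the lateral
        # kernel must redistribute, not create or destroy, dose in a slice
        from epid2water import BeamConfig

        cfg = BeamConfig(
            field=FieldSpec.square(6.0),
            mu=100.0,
            extrafocal_fraction=0.0,
            jaw_transmission=0.0,
        )
        f = total_head_fluence(cfg, GridSpec.at_isocenter(1.0, 80.0))
        d = compute_watertank_dose(f, water_model, field=cfg.field, tank=SMALL_TANK)
        z = SMALL_TANK.z_coords_mm / 10.0
        w = depth_dose_weight(z, cfg.field, water_model)
        voxel_area = SMALL_TANK.voxel_mm**2
        for i in (5, 30, 60):
            # slice integral = transported fluence integral x depth weight
            expected = f.integral() * w[i]
            assert d.values[i].sum() * voxel_area == pytest.approx(expected, rel=5e-3)

    def test_tank_wider_than_fluence_rejected(self, fluence_10x10, water_model):
        big = TankGrid(voxel_mm=2.0, z_step_mm=5.0, half_extent_mm=200.0, depth_mm=50.0)
        with pytest.raises(ValueError, match="support"):
            compute_watertank_dose(fluence_10x10, water_model, tank=big)


class TestChamberArray:
    def test_uniform_plane_gives_uniform_readings(self, water_model):
        grid = GridSpec(1.0, 160.0, 100.0)
        f = FluenceMap(np.ones((grid.n, grid.n)), grid)
        arr = ArraySpec(n_chambers=15)
        img = compute_array_dose(f, water_model, arr, field=FieldSpec.square(20.0))
        np.testing.assert_allclose(img.values, img.values[7, 7], rtol=1e-6)

    def test_linear_gradient_preserved_by_chamber_averaging(self, water_model):
        grid = GridSpec(1.0, 160.0, 100.0)
        X, _ = np.meshgrid(grid.coords_mm, grid.coords_mm)
        f = FluenceMap(1.0 + 1e-3 * X, grid)
        arr = ArraySpec(n_chambers=15)
        img = compute_array_dose(f, water_model, arr, field=FieldSpec.square(20.0))
        c = 7
        row = img.values[c, :] / img.values[c, c]
        expected = 1.0 + 1e-3 * arr.positions_mm
        np.testing.assert_allclose(row, expected, rtol=1e-4)

    def test_point_spike_contribution_bounded_by_aperture_fraction(self, water_model):
        grid = GridSpec(1.0, 160.0, 100.0)
        vals = np.ones((grid.n, grid.n))
        c = grid.n // 2
        spike_offset = 4  # 4 mm: between the CAX chamber and its neighbour
        vals[c, c + spike_offset] += 100.0
        wm = dataclasses.replace(water_model, lateral_sigma0_mm=1e-6, lateral_growth_mm_per_cm=1e-9)
        f = FluenceMap(vals, grid)
        arr = ArraySpec(n_chambers=15)
        img = compute_array_dose(f, water_model, arr, field=FieldSpec.square(20.0))
        base = compute_array_dose(FluenceMap(np.ones_like(vals), grid), water_model, arr,
                                  field=FieldSpec.square(20.0))
        excess = img.values - base.values
        # the spike carries 100x a pixel's fluence; a chamber can at most see
        # its aperture-average share of that integral
        aperture_px = np.pi * (arr.aperture_diameter_mm / 2.0) ** 2
        assert excess.max() <= 100.0 / aperture_px * 1.5

    def test_chamber_grid_must_fit_dose_plane(self, water_model):
        grid = GridSpec(1.0, 40.0, 100.0)
        f = FluenceMap(np.ones((grid.n, grid.n)), grid)
        with pytest.raises(ValueError, match="chamber grid"):
            compute_array_dose(f, water_model, ArraySpec(n_chambers=31),
                               field=FieldSpec.square(20.0))
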