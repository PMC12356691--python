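"""Two-source head-fluence model: apertures, horns, tilts, transport."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from epid2water import (
    BeamConfig,
    FieldSpec,
    GridSpec,
    build_aperture_mask,
    extrafocal_fluence,
    focal_fluence,
    total_head_fluence,
    transport_fluence,
)
from epid2water.geometry_fluence import radial_poly


class TestFieldSpec:
    def test_degenerate_field_rejected(self):
        with pytest.raises(ValueError):
            FieldSpec(5.0, 5.0, -5.0, 5.0)

    def test_half_blocked_is_valid(self):
        f = FieldSpec(-10.0, 0.0, -10.0, 10.0)
        assert f.width_x_cm == 10.0 and f.width_y_cm == 20.0


class TestApertureMask:
    def test_inside_outside_values(self, small_grid):
        mask = build_aperture_mask(FieldSpec.square(10.0), small_grid, transmission=0.002)
        c = small_grid.n // 2
        assert mask.values[c, c] == 1.0
        # 7 cm off-axis is outside a 10x10 field
        j = c + int(70 / small_grid.spacing_mm)
        assert mask.values[c, j] == pytest.approx(0.002)

    def test_projection_by_similar_triangles(self):
        # a 10x10 field projected to 150 cm has its edge at +/-7.5 cm
        grid = GridSpec(1.5, 120.0, 150.0)
        mask = build_aperture_mask(FieldSpec.square(10.0), grid, transmission=0.0)
        c = grid.n // 2
        row = mask.values[c, :]
        x = grid.coords_mm
        inside = x[row > 0.5]
        assert inside.min() == pytest.approx(-74.25, abs=grid.spacing_mm)
        assert inside.max() == pytest.approx(74.25, abs=grid.spacing_mm)
        # 50% crossing by interpolation sits at the projected jaw position
        right = np.interp(0.5, row[c:][::-1], x[c:][::-1])  # row decreasing right of CAX
        assert right == pytest.approx(75.0, abs=grid.spacing_mm)


class TestFocalFluence:
    def test_flat_beam_limit_is_mask_times_mu(self, flat_config, small_grid):
        f = focal_fluence(flat_config, small_grid)
        mask = build_aperture_mask(flat_config.field, small_grid, 0.0)
        np.testing.assert_allclose(f.values, mask.values * flat_config.mu)

    def test_linearity_in_mu(self, config_10x10, small_grid):
        f1 = total_head_fluence(config_10x10, small_grid)
        f2 = total_head_fluence(dataclasses.replace(config_10x10, mu=200.0), small_grid)
        np.testing.assert_allclose(f2.values, 2.0 * f1.values, rtol=1e-12)

    def test_horn_value_off_axis(self):
        # h(r) = 1 + 0.002 r^2 doubles the relative fluence rise: 1.2x at 10 cm
        assert radial_poly(10.0, (0.0, 0.002)) == pytest.approx(1.2)
        cfg = BeamConfig(
            field=FieldSpec.square(24.0),
            mu=1.0,
            horn_coeffs=(0.0, 0.002),
            source_sigma_mm=0.0,
            extrafocal_fraction=0.0,
            jaw_transmission=0.0,
        )
        grid = GridSpec.at_isocenter(1.0, 140.0)
        f = focal_fluence(cfg, grid)
        c = grid.n // 2
        assert f.values[c, c + 100] / f.values[c, c] == pytest.approx(1.2, rel=1e-9)

    def test_negative_horn_in_field_rejected(self, small_grid):
        cfg = BeamConfig(field=FieldSpec.square(10.0), mu=1.0, horn_coeffs=(0.0, -0.05))
        with pytest.raises(ValueError, match="horn"):
            focal_fluence(cfg, small_grid)

    def test_penumbra_half_value_at_jaw_edge(self, config_10x10, small_grid):
        f = focal_fluence(config_10x10, small_grid)
        c = small_grid.n // 2
        row = f.values[c, :]
        x = small_grid.coords_mm
        cax = row[c]
        # 50% crossing of the blurred edge lies at the geometric edge (+/-50 mm)
        right = np.interp(-cax / 2, -row[c:], -x[c:])
        assert -right == pytest.approx(50.0, abs=small_grid.spacing_mm)


class TestExtrafocal:
    def test_zero_fraction_gives_zero_map(self, config_10x10, small_grid):
        cfg = dataclasses.replace(config_10x10, extrafocal_fraction=0.0)
        assert extrafocal_fluence(cfg, small_grid).values.sum() == 0.0

    def test_integral_matches_weighted_mask(self, config_10x10):
        # grid margin of >3 sigma around the field edge: convolution conserves
        grid = GridSpec.at_isocenter(1.0, 140.0)
        ef = extrafocal_fluence(config_10x10, grid)
        mask = build_aperture_mask(config_10x10.field, grid, 0.0)
        expected = config_10x10.extrafocal_fraction * config_10x10.mu * mask.integral()
        assert ef.integral() == pytest.approx(expected, rel=5e-3)

    def test_tail_beyond_field_edge(self, config_10x10, small_grid):
        ef = extrafocal_fluence(config_10x10, small_grid)
        c = small_grid.n // 2
        j = c + int(70 / small_grid.spacing_mm)  # 2 cm beyond the 5 cm edge
        assert ef.values[c, j] > 0.0


class TestTiltAndTotal:
    def test_no_tilt_no_extrafocal_equals_focal(self, config_10x10, small_grid):
        cfg = dataclasses.replace(config_10x10, extrafocal_fraction=0.0)
        np.testing.assert_allclose(
            total_head_fluence(cfg, small_grid).values, focal_fluence(cfg, small_grid).values
        )

    def test_tilt_two_percent_at_ten_cm(self):
        cfg = BeamConfig(
            field=FieldSpec.square(24.0),
            mu=1.0,
            tilt_crossplane=0.002,
            horn_coeffs=(),
            source_sigma_mm=0.0,
            extrafocal_fraction=0.0,
            jaw_transmission=0.0,
        )
        grid = GridSpec.at_isocenter(1.0, 140.0)
        f = total_head_fluence(cfg, grid)
        c = grid.n // 2
        assert f.values[c, c + 100] / f.values[c, c] == pytest.approx(1.02, rel=1e-9)

    def test_opposite_tilt_mirrors_map(self, config_10x10, small_grid):
        pos = total_head_fluence(
            dataclasses.replace(config_10x10, tilt_crossplane=0.002), small_grid
        )
        neg = total_head_fluence(
            dataclasses.replace(config_10x10, tilt_crossplane=-0.002), small_grid
        )
        np.testing.assert_allclose(neg.values, pos.values[:, ::-1], atol=1e-12)

    def test_overwhelming_tilt_rejected(self, config_10x10, small_grid):
        cfg = dataclasses.replace(config_10x10, tilt_crossplane=0.5)
        with pytest.raises(ValueError, match="tilt"):
            total_head_fluence(cfg, small_grid)

    def test_mirror_symmetry_of_symmetric_beam(self, config_10x10, small_grid):
        f = total_head_fluence(config_10x10, small_grid)
        np.testing.assert_allclose(f.values, f.values[:, ::-1], atol=1e-12)
        np.testing.assert_allclose(f.values, f.values[::-1, :], atol=1e-12)


class TestTransport:
    def test_identity_at_same_plane(self, config_10x10, small_grid):
        f = total_head_fluence(config_10x10, small_grid)
        ft = transport_fluence(f, 100.0)
        np.testing.assert_allclose(ft.values, f.values)

    @given(to_cm=st.floats(min_value=50.0, max_value=250.0))
    def test_inverse_square_and_conservation(self, to_cm):
        cfg = BeamConfig(field=FieldSpec.square(10.0), mu=100.0)
        grid = GridSpec.at_isocenter(2.0, 80.0)
        f = total_head_fluence(cfg, grid)
        ft = transport_fluence(f, to_cm)
        assert ft.cax_value / f.cax_value == pytest.approx((100.0 / to_cm) ** 2, rel=1e-3)
        assert ft.integral() == pytest.approx(f.integral(), rel=5e-3)

    def test_nonpositive_distance_rejected(self, config_10x10, small_grid):
        f = total_head_fluence(config_10x10, small_grid)
        with pytest.raises(ValueError):
            transport_fluence(f, 0.0)
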