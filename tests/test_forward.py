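import numpy as np
import pytest

from mpilocate import (AppliedFieldZ, applied_field_at, build_lead_field,
                       field_map, gaussian_source, lead_field_entry,
                       make_cuboid_bem, make_sensor_plane, moment_at,
                       stack_field_maps, stack_lead_fields)
from mpilocate.forward import MU0_OVER_4PI


def dipole_field_projection(m, r_p, r_s, n_s):
    """Independent transcription of the dipole-field sensor projection.

    B.n = mu0/4pi * (3 (m.d) d / |d|^5 - m / |d|^3) . n,  d = r_s - r_p (m).
    Written directly from the textbook expression as the oracle for the
    production implementation (which uses the unit-vector form).
    """
    m = np.asarray(m, float)
    d = (np.asarray(r_s, float) - np.asarray(r_p, float)) * 1e-2
    nd = np.linalg.norm(d)
    b = MU0_OVER_4PI * (3.0 * np.dot(m, d) * d / nd ** 5 - m / nd ** 3)
    return float(np.dot(b, np.asarray(n_s, float)))


class TestAppliedField:
    @pytest.mark.parametrize("g,b,z,expect", [
        (0.0, 0.5, 3.0, 0.5),
        (-0.25, 0.5, 0.0, 0.5),
        (-0.25, 0.5, 2.0, 0.0),
    ])
    def test_linear_profile(self, g, b, z, expect):
        assert applied_field_at(AppliedFieldZ(g, b), z) == pytest.approx(expect)

    def test_moment_zero_field(self):
        assert np.allclose(moment_at(AppliedFieldZ(-0.25, 0.5), 2.0), 0.0)

    def test_moment_linear_in_bias(self):
        m1 = moment_at(AppliedFieldZ(0.0, 0.5), 1.0)
        m2 = moment_at(AppliedFieldZ(0.0, 1.0), 1.0)
        assert np.allclose(m2, 2 * m1)

    def test_moment_sign_follows_field(self):
        fld = AppliedFieldZ(-0.25, 0.5)
        assert moment_at(fld, 1.0)[2] > 0    # below zero crossing at z=2
        assert moment_at(fld, 3.0)[2] < 0


class TestLeadFieldEntry:
    def test_on_axis_closed_form(self):
        # unit moment, sensor 1 m above on axis: B_z = 2e-7 T
        val = lead_field_entry([0, 0, 1], [0, 0, 0], [0, 0, 100], [0, 0, 1])
        assert val == pytest.approx(2e-7, rel=1e-12)

    def test_equatorial_closed_form(self):
        val = lead_field_entry([0, 0, 1], [0, 0, 0], [100, 0, 0], [0, 0, 1])
        assert val == pytest.approx(-1e-7, rel=1e-12)

    def test_zero_moment(self):
        assert lead_field_entry([0, 0, 0], [0, 0, 0], [1, 2, 3], [0, 0, 1]) == 0

    def test_coincident_positions_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            lead_field_entry([0, 0, 1], [1, 1, 1], [1, 1, 1], [0, 0, 1])

    def test_matches_independent_transcription(self, rng):
        for _ in range(200):
            m = rng.normal(size=3)
            r_p = rng.uniform(0, 5, 3)
            r_s = rng.uniform(0, 5, 3) + [0, 0, 5]
            n_s = rng.normal(size=3)
            n_s /= np.linalg.norm(n_s)
            expect = dipole_field_projection(m, r_p, r_s, n_s)
            # abs floor guards near-cancelling projections, where a
            # relative comparison is meaningless
            assert lead_field_entry(m, r_p, r_s, n_s) == pytest.approx(
                expect, rel=1e-12, abs=1e-15)


class TestBuildLeadField:
    def test_shape(self, tiny_lead_field, tiny_grid, tiny_plane):
        assert tiny_lead_field.matrix.shape == (tiny_plane.n_sensors,
                                                tiny_grid.n_masked)

    def test_kappa_scales_entries(self, tiny_grid, tiny_plane):
        fld = AppliedFieldZ(0.0, 0.5)
        a1 = build_lead_field(tiny_grid, tiny_plane, fld, kappa=1.0)
        a3 = build_lead_field(tiny_grid, tiny_plane, fld, kappa=3.0)
        assert np.allclose(a3.matrix, 3 * a1.matrix)

    def test_bias_kappa_reciprocity(self, tiny_grid, tiny_plane):
        a = build_lead_field(tiny_grid, tiny_plane, AppliedFieldZ(0.0, 0.5),
                             kappa=2.0)
        b = build_lead_field(tiny_grid, tiny_plane, AppliedFieldZ(0.0, 1.5),
                             kappa=2.0 / 3.0)
        assert np.allclose(a.matrix, b.matrix)

    def test_matches_entrywise_oracle(self, rng):
        grid = make_cuboid_bem([2, 2, 1], 1.0)
        plane = make_sensor_plane([2, 2], 1.0, plane_z=3.0, center_xy=[1, 1])
        fld = AppliedFieldZ(-0.1, 0.4)
        lf = build_lead_field(grid, plane, fld, kappa=1.7)
        for j in rng.choice(plane.n_sensors, 5, replace=False):
            for k in rng.choice(grid.n_masked, 6, replace=False):
                m = moment_at(fld, grid.masked_positions[k][2], kappa=1.7)
                expect = dipole_field_projection(
                    m, grid.masked_positions[k], plane.positions[j],
                    plane.direction)
                assert lf.matrix[j, k] == pytest.approx(expect, rel=1e-12)

    def test_on_axis_inverse_cube_decay(self):
        # constant field: entry under a sensor is positive, decays as h^-3
        grid = make_cuboid_bem([2, 2, 2], 1.0)
        fld = AppliedFieldZ(0.0, 0.5)
        vals = []
        for plane_z in (3.0, 4.0, 5.0, 6.0):
            plane = make_sensor_plane([2, 2], 1.0, plane_z, center_xy=[1, 1])
            lf = build_lead_field(grid, plane, fld)
            k = int(np.flatnonzero(np.all(
                grid.masked_positions == [1, 1, 2], axis=1))[0])
            j = int(np.flatnonzero(np.all(
                plane.positions[:, :2] == [1, 1], axis=1))[0])
            vals.append(lf.matrix[j, k])
        vals = np.array(vals)
        assert np.all(vals > 0)
        assert np.all(np.diff(vals) < 0)
        heights = np.array([1.0, 2.0, 3.0, 4.0])
        assert np.allclose(vals * heights ** 3, vals[0], rtol=1e-12)


class TestFieldMapAndStacking:
    def test_zero_source_zero_map(self, tiny_lead_field, tiny_grid):
        from mpilocate import SourceDistribution
        u = SourceDistribution(tiny_grid, np.zeros(tiny_grid.n_masked))
        assert np.all(field_map(tiny_lead_field, u).values == 0)

    def test_superposition(self, tiny_lead_field, tiny_grid, rng):
        from mpilocate import SourceDistribution
        u1 = SourceDistribution(tiny_grid, rng.uniform(size=tiny_grid.n_masked))
        u2 = SourceDistribution(tiny_grid, rng.uniform(size=tiny_grid.n_masked))
        both = SourceDistribution(tiny_grid, u1.amplitude + u2.amplitude)
        assert np.allclose(field_map(tiny_lead_field, both).values,
                           field_map(tiny_lead_field, u1).values
                           + field_map(tiny_lead_field, u2).values)

    def test_unit_voxel_source_reads_column(self, tiny_lead_field, tiny_grid):
        from mpilocate import SourceDistribution
        amp = np.zeros(tiny_grid.n_masked)
        amp[37] = 1.0
        fm = field_map(tiny_lead_field, SourceDistribution(tiny_grid, amp))
        assert np.allclose(fm.values, tiny_lead_field.matrix[:, 37])

    def test_stack_single_is_identity(self, tiny_lead_field):
        s = stack_lead_fields([tiny_lead_field])
        assert np.array_equal(s.matrix, tiny_lead_field.matrix)
        assert s.block_offsets == (0,)

    def test_stack_rows_and_block_consistency(self, tiny_grid, tiny_plane,
                                              tiny_lead_field):
        other = build_lead_field(tiny_grid, tiny_plane,
                                 AppliedFieldZ(-0.2, 0.5))
        stacked = stack_lead_fields([tiny_lead_field, other])
        assert stacked.n_rows == 2 * tiny_plane.n_sensors
        assert stacked.block_offsets == (0, tiny_plane.n_sensors)
        src = gaussian_source(tiny_grid, [2, 2, 2], 0.8)
        fm = field_map(stacked, src)
        parts = stack_field_maps([field_map(tiny_lead_field, src),
                                  field_map(other, src)])
        assert np.allclose(fm.values, parts.values)

    def test_grid_mismatch_rejected(self, tiny_lead_field):
        grid2 = make_cuboid_bem([2, 2, 2], 1.0)
        plane2 = make_sensor_plane([2, 2], 1.0, plane_z=4.0, center_xy=[1, 1])
        other = build_lead_field(grid2, plane2, AppliedFieldZ(0.0, 0.5))
        with pytest.raises(ValueError, match="grid"):
            stack_lead_fields([tiny_lead_field, other])
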