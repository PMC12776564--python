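"""FEM forward-solver correctness: geometry, physics identities, sensitivity."""

import numpy as np
import pytest

from eitsep.forward import (MeshError, N_MEASUREMENTS, ForwardOperator,
                            StimulationProtocol, VoltageFrame,
                            analytic_disk_potential, build_mesh,
                            compute_jacobian, element_conductivities,
                            solve_forward)
from eitsep.phantoms import HEART, OrganInclusion, ThoraxPhantom


def _phantom(inclusions, background=1.0):
    ph = object.__new__(ThoraxPhantom)
    object.__setattr__(ph, "background_conductivity", background)
    object.__setattr__(ph, "inclusions", tuple(inclusions))
    return ph


class TestMesh:
    def test_electrodes_on_boundary_equally_spaced(self, mesh):
        pts = mesh.nodes[mesh.electrode_nodes]
        radii = np.linalg.norm(pts, axis=1)
        assert np.allclose(radii, 1.0, atol=1e-12)
        angles = np.arctan2(pts[:, 1], pts[:, 0])
        gaps = np.diff(np.unwrap(angles))
        assert np.allclose(gaps, 2 * np.pi / 16, atol=1e-9)

    def test_triangle_areas_positive(self, mesh):
        assert np.all(mesh.element_areas() > 0)

    def test_total_area_approximates_unit_disk(self, mesh):
        assert abs(mesh.element_areas().sum() - np.pi) / np.pi < 0.02

    def test_element_count_near_target(self):
        for target in (400, 1024, 2048):
            m = build_mesh(target)
            assert 0.5 * target <= m.n_elements <= 2 * target

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(MeshError):
            build_mesh(100)
        with pytest.raises(MeshError):
            build_mesh(1024, electrode_count=8)


class TestProtocol:
    def test_measurement_count_is_208(self, protocol):
        assert protocol.n_measurements == N_MEASUREMENTS
        for d in range(16):
            pairs = protocol.measurement_pairs(d)
            assert len(pairs) == 13
            drive = {d, (d + 1) % 16}
            for a, b in pairs:
                assert not ({a, b} & drive)

    def test_voltage_frame_validation(self):
        with pytest.raises(ValueError, match="208"):
            VoltageFrame(np.zeros(10))
        with pytest.raises(ValueError, match="finite"):
            VoltageFrame(np.full(208, np.nan))


class TestElementConductivities:
    def test_homogeneous_phantom_constant(self, mesh):
        sigma = element_conductivities(mesh, _phantom([], background=1.5))
        assert np.all(sigma == 1.5)

    def test_heart_elements_get_heart_conductivity(self, mesh):
        ph = _phantom([OrganInclusion(HEART, (0.0, 0.0), 0.25, 2.0)])
        sigma = element_conductivities(mesh, ph)
        c = mesh.element_centroids()
        inside = c[:, 0] ** 2 + c[:, 1] ** 2 <= 0.25**2
        assert np.all(sigma[inside] == 2.0)
        assert np.all(sigma[~inside] == 1.0)

    def test_assigned_area_fraction_matches_geometry(self, mesh):
        ph = _phantom([OrganInclusion(HEART, (0.0, 0.0), 0.3, 2.0)])
        sigma = element_conductivities(mesh, ph)
        areas = mesh.element_areas()
        frac = areas[sigma == 2.0].sum() / areas.sum()
        expected = 0.3**2  # area ratio of the disk inclusion
        assert abs(frac - expected) / expected < 0.15  # mesh resolution

class TestForwardSolve:
    def test_homogeneous_disk_matches_analytic_solution(self):
        mesh = build_mesh(4096)
        op = ForwardOperator(mesh)
        sigma = np.ones(mesh.n_elements)
        fields = op.solve_fields(sigma)
        electrodes = mesh.nodes[mesh.electrode_nodes]
        worst = 0.0
        for d in (0, 5):
            u_fem = fields[mesh.electrode_nodes][:, d]
            u_ref = analytic_disk_potential(
                electrodes, electrodes[d], electrodes[(d + 1) % 16],
                sigma=1.0, current_a=1e-3)
            for m, m1 in op.protocol.measurement_pairs(d):
                rel = abs((u_fem[m] - u_fem[m1]) - (u_ref[m] - u_ref[m1])) \
                    / abs(u_ref[m] - u_ref[m1])
                worst = max(worst, rel)
        assert worst < 0.02

    def test_mesh_refinement_reduces_analytic_error(self):
        def max_err(target):
            mesh = build_mesh(target)
            op = ForwardOperator(mesh)
            fields = op.solve_fields(np.ones(mesh.n_elements))
            el = mesh.nodes[mesh.electrode_nodes]
            u = fields[mesh.electrode_nodes][:, 0]
            ref = analytic_disk_potential(el, el[0], el[1], 1.0, 1e-3)
            return max(
                abs((u[m] - u[m1]) - (ref[m] - ref[m1])) / abs(ref[m] - ref[m1])
                for m, m1 in op.protocol.measurement_pairs(0))
        assert max_err(2048) < max_err(512)

    def test_conductivity_scaling_halves_voltages_exactly(self, forward_op,
                                                          mesh):
        sigma = np.ones(mesh.n_elements)
        v1 = forward_op.voltages(sigma).voltages
        v2 = forward_op.voltages(2 * sigma).voltages
        assert np.allclose(2 * v2, v1, rtol=1e-12, atol=0)

    def test_reciprocity_on_inhomogeneous_field(self, forward_op, mesh,
                                                protocol):
        ph = _phantom([OrganInclusion(HEART, (0.2, 0.1), 0.25, 2.0)])
        sigma = element_conductivities(mesh, ph)
        v = forward_op.voltages(sigma).voltages
        worst = 0.0
        for d in range(16):
            for m, m1 in protocol.measurement_pairs(d):
                # reciprocal configuration: drive at (m, m+1), measure (d, d+1)
                if d in {(m - 1) % 16, m, (m + 1) % 16}:
                    continue
                a = v[protocol.index(d, (m, m1))]
                b = v[protocol.index(m, (d, (d + 1) % 16))]
                worst = max(worst, abs(a - b) / max(abs(a), abs(b)))
        assert worst <= 1e-8

    def test_positive_conductivity_required(self, small_forward_op,
                                            small_mesh):
        sigma = np.ones(small_mesh.n_elements)
        sigma[0] = -1.0
        with pytest.raises(Exception, match="positive"):
            small_forward_op.voltages(sigma)


class TestJacobian:
    def test_matches_finite_differences(self, small_forward_op, small_mesh):
        sigma = np.ones(small_mesh.n_elements)
        J = small_forward_op.jacobian(sigma)
        rng = np.random.default_rng(5)
        for e in rng.integers(0, small_mesh.n_elements, size=4):
            d = 1e-4
            sp = sigma.copy(); sp[e] += d
            sm = sigma.copy(); sm[e] -= d
            fd = (small_forward_op.voltages(sp).voltages
                  - small_forward_op.voltages(sm).voltages) / (2 * d)
            rel = np.max(np.abs(J[:, e] - fd)) / np.max(np.abs(fd))
            assert rel < 1e-3

    def test_zero_perturbation_predicts_zero_change(self, small_forward_op,
                                                    small_mesh):
        J = small_forward_op.jacobian(np.ones(small_mesh.n_elements))
        assert np.allclose(J @ np.zeros(small_mesh.n_elements), 0)

    def test_rotational_symmetry_of_sensitivity(self, small_forward_op,
                                                small_mesh):
        """Rotating an element by one electrode pitch permutes its Jacobian
        column (drive/measurement indices shift by one)."""
        J = small_forward_op.jacobian(np.ones(small_mesh.n_elements))
        cent = small_mesh.element_centroids()
        theta = 2 * np.pi / 16
        R = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        rot = cent @ R.T
        prot = small_forward_op.protocol
        # permutation of measurement indices under a one-pitch rotation
        perm = np.empty(N_MEASUREMENTS, dtype=int)
        for d in range(16):
            for m, m1 in prot.measurement_pairs(d):
                perm[prot.index(d, (m, m1))] = prot.index(
                    (d + 1) % 16, ((m + 1) % 16, (m1 + 1) % 16))
        radii = np.linalg.norm(cent, axis=1)
        band = np.flatnonzero((radii > 0.35) & (radii < 0.85))
        rng = np.random.default_rng(2)
        checked = 0
        for e in band[rng.integers(0, band.size, size=12)]:
            dist = np.linalg.norm(cent - rot[e], axis=1)
            e_rot = int(np.argmin(dist))
            if dist[e_rot] > 1e-9:   # Delaunay tie-break split the partner
                continue
            # invariance: J[(d, m), e] == J[(d+1, m+1), rot(e)]
            col = J[:, e]
            col_rot = J[perm, e_rot]
            scale = np.max(np.abs(col))
            assert np.max(np.abs(col - col_rot)) / scale < 0.05
            checked += 1
        assert checked >= 6

    def test_one_shot_helpers_agree_with_operator(self, small_mesh):
        sigma = np.ones(small_mesh.n_elements)
        op = ForwardOperator(small_mesh)
        assert np.array_equal(solve_forward(small_mesh, sigma).voltages,
                              op.voltages(sigma).voltages)
        assert np.array_equal(compute_jacobian(small_mesh, sigma),
                              op.jacobian(sigma))
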