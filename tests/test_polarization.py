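"""Wavevector enumeration and polarization-component contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

import phonliq as pq
from phonliq.polarization import molecular_reference_points


class TestEnumerateWavevectors:
    def test_unit_box_combinatorics(self):
        ks = pq.enumerate_wavevectors(2 * np.pi, 1)
        assert ks.n_vectors == 26  # 3^3 - 1
        assert ks.n_shells == 3
        np.testing.assert_allclose(
            ks.shell_magnitudes, [1.0, np.sqrt(2), np.sqrt(3)]
        )

    def test_first_shell_has_six_axis_vectors(self):
        ks = pq.enumerate_wavevectors(5.0, 2)
        assert len(ks.shells[0]) == 6
        np.testing.assert_allclose(
            np.linalg.norm(ks.vectors[ks.shells[0]], axis=1), 2 * np.pi / 5.0
        )

    def test_smallest_k_for_small_water_box(self):
        # 1.97 nm box: smallest |k| = 2 pi / 1.97 ~ 3.19 nm^-1 = 0.319 A^-1
        ks = pq.enumerate_wavevectors(1.97, 1)
        assert ks.shell_magnitudes[0] == pytest.approx(3.1895, abs=2e-4)

    def test_each_vector_in_exactly_one_shell(self):
        ks = pq.enumerate_wavevectors(3.0, 2)
        all_idx = np.concatenate(ks.shells)
        assert sorted(all_idx) == list(range(ks.n_vectors))

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            pq.enumerate_wavevectors(2.0, 0)
        with pytest.raises(ValueError):
            pq.enumerate_wavevectors(-1.0, 1)


class TestLongitudinalPolarization:
    def test_zero_charges_give_zero(self):
        topo = pq.Topology([0.0, 0.0], [0, 0])
        pos = np.array([[0.1, 0.2, 0.3], [0.4, 0.5, 0.6]])
        assert pq.longitudinal_polarization(pos, topo, [0, 0, 1.0]) == 0

    @pytest.mark.parametrize("kmag,d", [(0.5, 0.01), (2.0, 0.1), (8.0, 0.05)])
    def test_point_dipole_closed_form(self, kmag, d):
        # +q and -q straddling the origin along k: P_L = 2 q sin(k d/2)/k
        topo = pq.Topology([1.0, -1.0], [0, 0])
        pos = np.array([[0, 0, d / 2], [0, 0, -d / 2]])
        got = pq.longitudinal_polarization(pos, topo, [0, 0, kmag])
        assert got == pytest.approx(2 * np.sin(kmag * d / 2) / kmag, rel=1e-12)
        # k -> 0 limit approaches the bare dipole q d
        small = pq.longitudinal_polarization(pos, topo, [0, 0, 1e-4])
        assert small == pytest.approx(d, rel=1e-6)

    def test_matches_high_precision_direct_sum(self, rng):
        nmol = 10
        charges = np.tile([-0.8, 0.5, 0.3], nmol)
        topo = pq.Topology(charges, np.repeat(np.arange(nmol), 3))
        pos = rng.uniform(0, 2.0, (30, 3))
        k = 2 * np.pi / 2.0 * np.array([1.0, 2.0, -1.0])
        got = pq.longitudinal_polarization(pos, topo, k)
        # oracle: defining sum accumulated in extended precision
        qs = np.asarray(charges, dtype=np.longdouble)
        phases = np.asarray(pos @ k, dtype=np.longdouble)
        rho = np.sum(qs * np.cos(phases)) - 1j * np.sum(qs * np.sin(phases))
        expect = 1j / np.linalg.norm(k) * complex(rho)
        assert abs(got - expect) < 1e-12 * max(abs(expect), 1.0)

    def test_zero_k_rejected(self):
        topo = pq.Topology([0.0], [0])
        with pytest.raises(ValueError):
            pq.longitudinal_polarization(np.zeros((1, 3)), topo, [0, 0, 0])

    def test_lattice_translation_invariance(self, rng, water_like_topology):
        pos = rng.uniform(0, 2.0, (6, 3))
        k = 2 * np.pi / 2.0 * np.array([1.0, 0.0, 0.0])
        a = pq.longitudinal_polarization(pos, water_like_topology, k)
        b = pq.longitudinal_polarization(pos + np.array([2.0, 4.0, 0]),
                                         water_like_topology, k)
        assert a == pytest.approx(b, rel=1e-10)


class TestMolecularPolarization:
    def test_small_kd_reduces_to_point_dipole(self, water_like_topology):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 5.0, (2, 1, 3)) + 0.05 * rng.normal(size=(2, 3, 3))
        pos = pos.reshape(6, 3)
        k = np.array([1e-5, 0, 0])
        p = pq.molecular_polarization(pos, water_like_topology, k, 5.0)
        for i in range(2):
            sites = water_like_topology.sites_of_molecule(i)
            mu = (water_like_topology.site_charges[sites, None] * pos[sites]).sum(0)
            np.testing.assert_allclose(p[i].real, mu, atol=1e-8)

    def test_divergence_identity(self, rng, water_like_topology):
        # i k . sum_i p_i(k) = -sum_j q_j exp(-i k . r_j)
        pos = rng.uniform(0, 2.0, (6, 3))
        for nvec in ([1, 0, 0], [1, 2, -1], [0, 3, 1]):
            k = 2 * np.pi / 2.0 * np.array(nvec, dtype=float)
            p = pq.molecular_polarization(pos, water_like_topology, k, 2.0)
            lhs = 1j * (p.sum(axis=0) @ k)
            rhs = -np.sum(
                water_like_topology.site_charges * np.exp(-1j * pos @ k)
            )
            assert abs(lhs - rhs) < 1e-9 * max(abs(rhs), 1.0)

    def test_matches_line_integral_quadrature(self, water_like_topology):
        # p_i = sum_alpha q_alpha d_alpha int_0^1 ds exp(-i k.(r_c + s d_alpha))
        rng = np.random.default_rng(9)
        pos = rng.uniform(0, 3.0, (6, 3))
        k = np.array([1.7, -0.6, 2.2])
        p = pq.molecular_polarization(pos, water_like_topology, k, 30.0)
        ref, _ = molecular_reference_points(pos, water_like_topology, 30.0)
        for i in range(2):
            sites = water_like_topology.sites_of_molecule(i)
            expect = np.zeros(3, dtype=complex)
            for s_idx in sites:
                d = pos[s_idx] - ref[i]
                q = water_like_topology.site_charges[s_idx]

                def integrand(s, comp, part):
                    val = np.exp(-1j * (k @ (ref[i] + s * d))) * d[comp]
                    return val.real if part == "re" else val.imag

                for c in range(3):
                    re = quad(integrand, 0, 1, args=(c, "re"))[0]
                    im = quad(integrand, 0, 1, args=(c, "im"))[0]
                    expect[c] += q * (re + 1j * im)
            np.testing.assert_allclose(p[i], expect, atol=1e-9)

    def test_wrapped_molecule_handled_by_minimum_image(self, water_like_topology):
        box = 2.0
        pos = np.array(
            [[0.01, 1.0, 1.0], [1.99, 1.0, 1.0], [0.07, 1.0, 1.0],
             [1.0, 1.0, 1.0], [1.05, 1.0, 1.0], [0.95, 1.0, 1.0]]
        )
        k = 2 * np.pi / box * np.array([1.0, 0, 0])
        p = pq.molecular_polarization(pos, water_like_topology, k, box)
        # first molecule straddles the boundary; its dipole magnitude must be
        # that of the compact image, not ~ box-sized
        assert np.linalg.norm(p[0]) < 0.2


class TestTransverseProjection:
    def test_parallel_vector_has_no_transverse_part(self):
        k = np.array([0.0, 0.0, 2.0])
        c1, c2 = pq.transverse_projection(np.array([0, 0, 5.0]), k)
        assert abs(c1) < 1e-12 and abs(c2) < 1e-12

    def test_perpendicular_vector_fully_preserved(self):
        k = np.array([0.0, 0.0, 2.0])
        p = np.array([3.0, 4.0, 0.0])
        c1, c2 = pq.transverse_projection(p, k)
        assert abs(c1) ** 2 + abs(c2) ** 2 == pytest.approx(25.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(-5, 5), min_size=6, max_size=6),
           st.lists(st.floats(-3, 3), min_size=3, max_size=3))
    def test_parseval(self, pvals, kvals):
        k = np.array(kvals)
        if np.linalg.norm(k) < 1e-3:
            return
        p = np.array(pvals[:3]) + 1j * np.array(pvals[3:])
        khat = k / np.linalg.norm(k)
        pl = p @ khat
        c1, c2 = pq.transverse_projection(p, k)
        total = abs(pl) ** 2 + abs(c1) ** 2 + abs(c2) ** 2
        expect = float(np.sum(np.abs(p) ** 2))
        assert total == pytest.approx(expect, rel=1e-12, abs=1e-12)

    def test_basis_orthonormal_and_deterministic(self):
        for kvals in ([1.0, 0.1, 0.1], [0.3, -2.0, 0.5], [1.0, 1.0, 1.0]):
            k = np.array(kvals)
            e1, e2 = pq.transverse_basis(k)
            assert abs(e1 @ e2) < 1e-12
            assert abs(e1 @ k) < 1e-12 and abs(e2 @ k) < 1e-12
            e1b, e2b = pq.transverse_basis(k)
            np.testing.assert_array_equal(e1, e1b)


class TestSeriesContracts:
    def test_vector_field_conjugate_symmetry(self, rng, water_like_topology):
        pos = rng.uniform(0, 2.0, (6, 3))
        k = 2 * np.pi / 2.0 * np.array([1.0, 1.0, 0.0])
        p_plus = pq.molecular_polarization(pos, water_like_topology, k, 2.0)
        p_minus = pq.molecular_polarization(pos, water_like_topology, -k, 2.0)
        np.testing.assert_allclose(
            p_minus.sum(axis=0), np.conj(p_plus.sum(axis=0)), atol=1e-12
        )

    def test_charge_and_molecular_longitudinal_routes_agree(
        self, rng, water_like_topology
    ):
        pos = rng.uniform(0, 2.0, (6, 3))
        k = 2 * np.pi / 2.0 * np.array([0.0, 1.0, 1.0])
        khat = k / np.linalg.norm(k)
        via_charges = pq.longitudinal_polarization(pos, water_like_topology, k)
        p = pq.molecular_polarization(pos, water_like_topology, k, 2.0)
        assert complex(p.sum(axis=0) @ khat) == pytest.approx(via_charges, rel=1e-10)

    def test_three_site_emission_matches_point_dipoles(self):
        cfg_p = pq.LangevinDipoleConfig(n_cells=2, n_frames=16, stride=2, seed=5,
                                        burn_in_ps=0.05, emit="point")
        cfg_s = pq.LangevinDipoleConfig(n_cells=2, n_frames=16, stride=2, seed=5,
                                        burn_in_ps=0.05, emit="3site")
        dip, _ = pq.generate_langevin_trajectory(cfg_p)
        sit, _ = pq.generate_langevin_trajectory(cfg_s)
        kset = pq.enumerate_wavevectors(dip.box_edge, 1)
        s_dip = pq.compute_polarization(dip, kset)
        s_sit = pq.compute_polarization(sit, kset)
        # finite charge separation gives O((k d)^2) deviations, well under 1%
        ratio = np.abs(s_sit.PL[0] - s_dip.PL[0]).max() / np.abs(s_dip.PL[0]).max()
        assert ratio < 0.01
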