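"""LPS constitutive model: weighted volume, dilatation, forces, damage."""

import numpy as np
import pytest

from perimem.constitutive import (MaterialModel, damage_field, dilatation,
                                  internal_force_density,
                                  measure_stress_flux, poisson_ratio,
                                  short_range_force, update_broken_bonds,
                                  weighted_volume)
from perimem.discretization import (build_bond_network,
                                    build_circular_membrane)
from perimem.fixtures import make_patch


@pytest.fixture(scope="module")
def disc30():
    membrane = build_circular_membrane(30.0, 1.0, 0.005)
    network = build_bond_network(membrane, 3.0)
    return membrane, network


class TestWeightedVolume:
    def test_interior_value_matches_lattice_sum(self, disc30):
        membrane, network = disc30
        # oracle: brute-force sum of |ξ|² over the 28 offsets, A = 1
        oracle = sum(i * i + j * j for i in range(-3, 4) for j in range(-3, 4)
                     if 0 < i * i + j * j <= 9)
        assert oracle == 136
        center = int(np.argmin(membrane.radii_ref))
        assert weighted_volume(membrane, network, center) == pytest.approx(136.0)

    def test_unit_horizon_gives_four(self):
        membrane = build_circular_membrane(20.0, 1.0, 0.005, layer_width=3.0)
        network = build_bond_network(membrane, 1.0)
        center = int(np.argmin(membrane.radii_ref))
        assert weighted_volume(membrane, network, center) == pytest.approx(4.0)

    def test_reference_quantity_is_deterministic(self, disc30):
        membrane, network = disc30
        np.testing.assert_array_equal(weighted_volume(membrane, network),
                                      weighted_volume(membrane, network))

    def test_frozen_under_bond_breaking(self, disc30):
        membrane, network = disc30
        m_before = weighted_volume(membrane, network)
        intact_backup = network.intact.copy()
        network.intact[:100] = False
        np.testing.assert_array_equal(m_before,
                                      weighted_volume(membrane, network))
        network.intact[:] = intact_backup


class TestDilatation:
    def test_uniform_isotropic_expansion_gives_2s(self, disc30):
        membrane, network = disc30
        s = 0.01
        theta = dilatation(membrane.positions_ref * (1 + s), membrane, network)
        interior = network.initial_bond_count == 28
        np.testing.assert_allclose(theta[interior], 2 * s, rtol=1e-9)

    def test_rigid_translation_gives_zero(self, disc30):
        membrane, network = disc30
        theta = dilatation(membrane.positions_ref + [3.7, -1.2], membrane,
                           network)
        np.testing.assert_allclose(theta, 0.0, atol=1e-12)

    def test_rigid_rotation_gives_zero(self, disc30):
        membrane, network = disc30
        a = np.deg2rad(30)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        theta = dilatation(membrane.positions_ref @ rot.T, membrane, network)
        np.testing.assert_allclose(theta, 0.0, atol=1e-9)


class TestInternalForce:
    def test_rigid_motion_gives_zero_force(self, disc30):
        membrane, network = disc30
        material = MaterialModel(shear_G=5.0)
        a = np.deg2rad(17)
        rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
        y = membrane.positions_ref @ rot.T + [1.0, -2.0]
        f = internal_force_density(y, membrane, network, material)
        np.testing.assert_allclose(f, 0.0, atol=1e-9)

    def test_momentum_conservation_on_deformed_free_body(self, disc30):
        membrane, network = disc30
        material = MaterialModel(shear_G=7.5)
        rng = np.random.default_rng(0)
        y = membrane.positions_ref * 1.05 + 0.01 * rng.normal(
            size=membrane.positions_ref.shape)
        f = internal_force_density(y, membrane, network, material)
        total = f.sum(axis=0) * membrane.area_per_particle
        assert np.abs(total).max() < 1e-9 * np.abs(f).max()

    def test_fluid_limit_has_no_deviatoric_response(self):
        # pure shear at G = 0 transmits no stress: the deviatoric term is
        # gone and theta = O(γ²), so the flux through a cut is ~ zero
        gamma = 0.005
        eps = np.array([[0.0, gamma], [gamma, 0.0]])
        membrane, state = make_patch(40, 1.0, eps)
        network = build_bond_network(membrane, 3.0)
        K = 10.0
        sigma = measure_stress_flux(state.positions, membrane, network,
                                    MaterialModel(bulk_K=K, shear_G=0.0),
                                    cut_x=0.0, window_halfwidth=8.0)
        assert np.abs(sigma).max() < 0.01 * K * gamma

    @pytest.mark.parametrize("G", [0.0, 2.5, 5.0, 10.0])
    def test_patch_reproduces_2d_elasticity(self, G):
        # calibration check: force flux through a cut vs sigma = K tr(e) I + 2G dev(e)
        K = 10.0
        material = MaterialModel(bulk_K=K, shear_G=G)
        for eps in (np.array([[0.01, 0.0], [0.0, 0.01]]),
                    np.array([[0.01, 0.0], [0.0, 0.0]]),
                    np.array([[0.0, 0.005], [0.005, 0.0]])):
            membrane, state = make_patch(40, 1.0, eps)
            network = build_bond_network(membrane, 3.0)
            sigma = measure_stress_flux(state.positions, membrane, network,
                                        material, cut_x=0.0,
                                        window_halfwidth=8.0)
            tr = eps.trace()
            oracle = K * tr * np.array([1.0, 0.0]) + 2 * G * (
                eps[:, 0] - 0.5 * tr * np.array([1.0, 0.0]))
            scale = max(np.abs(oracle).max(), K * np.abs(eps).max())
            assert np.abs(sigma - oracle).max() <= 0.05 * scale


class TestShortRangeForce:
    def test_deadband_at_reference_spacing(self):
        membrane = build_circular_membrane(20.0, 1.0, 0.005, layer_width=3.0)
        material = MaterialModel()
        f = short_range_force(membrane.positions_ref, membrane, material)
        np.testing.assert_allclose(f, 0.0)

    def test_repulsive_and_antisymmetric_under_compression(self):
        membrane = build_circular_membrane(20.0, 1.0, 0.005, layer_width=3.0)
        material = MaterialModel()
        y = membrane.positions_ref * 0.8   # bonded pairs at 0.8 < d_pi = 0.9
        f = short_range_force(y, membrane, material)
        np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-12)
        # net force on each particle points outward (away from the crowd)
        interior = membrane.radii_ref < 7.0
        radial = np.einsum("ij,ij->i", f, membrane.positions_ref)
        assert np.all(np.abs(f[interior]).max(axis=1) >= 0)
        rim = membrane.radii_ref > 9.0
        assert np.all(radial[rim] > 0)

    def test_interaction_distance_branches(self):
        # bonded neighbours at h: d_pi = 0.9h; distant pairs: d_pi = 1.35h
        assert min(0.9 * 1.0, 1.35) == pytest.approx(0.9)
        assert min(0.9 * 3.0, 1.35) == pytest.approx(1.35)
        # two particles, reference separation 5h (never bonded): squeezing
        # them to 1.0 < 1.35h produces repulsion; 1.4 ≥ 1.35h produces none
        from perimem.discretization import Membrane
        membrane = Membrane(
            positions_ref=np.array([[0.0, 0.0], [5.0, 0.0]]),
            spacing_h=1.0, thickness_eps=0.005, diameter_0=12.0,
            layer_width=1.0, boundary_layer_ids=np.empty(0, dtype=np.int64))
        material = MaterialModel()
        squeezed = np.array([[0.0, 0.0], [1.0, 0.0]])
        f = short_range_force(squeezed, membrane, material)
        assert f[1, 0] > 0 and f[0, 0] < 0
        apart = np.array([[0.0, 0.0], [1.4, 0.0]])
        np.testing.assert_allclose(
            short_range_force(apart, membrane, material), 0.0)


class TestBondBreakingAndDamage:
    def _pair_network(self):
        membrane = build_circular_membrane(20.0, 1.0, 0.005, layer_width=3.0)
        return membrane, build_bond_network(membrane, 3.0)

    @pytest.mark.parametrize("factor,breaks", [
        (1.16, True),    # stretch 16% > 15%
        (1.10, False),   # stretch 10%
        (0.80, False),   # compression never breaks
    ])
    def test_critical_stretch_rule(self, factor, breaks):
        membrane, network = self._pair_network()
        material = MaterialModel()
        newly = update_broken_bonds(membrane.positions_ref * factor, network,
                                    material)
        if breaks:
            assert newly > 0
            # both directions broken together
            assert np.array_equal(network.intact,
                                  network.intact[network.reverse_index])
        else:
            assert newly == 0
            assert network.intact.all()

    def test_breaking_is_irreversible(self):
        membrane, network = self._pair_network()
        material = MaterialModel()
        update_broken_bonds(membrane.positions_ref * 1.2, network, material)
        broken = ~network.intact
        update_broken_bonds(membrane.positions_ref, network, material)
        assert np.all(~network.intact >= broken)

    def test_damage_fractions(self):
        membrane, network = self._pair_network()
        assert damage_field(network).phi.max() == 0.0
        center = int(np.argmin(membrane.radii_ref))
        ks = np.arange(network.indptr[center], network.indptr[center + 1])
        network.intact[ks[:7]] = False
        network.intact[network.reverse_index[ks[:7]]] = False
        phi = damage_field(network).phi
        assert phi[center] == pytest.approx(7 / 28)
        network.intact[ks] = False
        network.intact[network.reverse_index[ks]] = False
        assert damage_field(network).phi[center] == pytest.approx(1.0)


class TestPoissonRatio:
    def test_study_range_endpoints(self):
        assert poisson_ratio(10.0, 0.0) == pytest.approx(0.5)
        assert poisson_ratio(10.0, 10.0) == pytest.approx(0.125)

    def test_scale_invariance_at_k_equals_g(self):
        for K in (0.3, 1.0, 42.0):
            assert poisson_ratio(K, K) == pytest.approx(1 / 8)

    def test_material_model_validates_moduli(self):
        with pytest.raises(ValueError):
            MaterialModel(bulk_K=-1.0)
        with pytest.raises(ValueError):
            MaterialModel(shear_G=-0.5)
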