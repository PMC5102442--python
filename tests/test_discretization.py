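"""Lattice construction, bond network and pinning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from perimem.discretization import (ConfigurationError, assign_pinning,
                                    build_bond_network,
                                    build_circular_membrane)


def brute_force_disc_count(radius_in_h: int) -> int:
    """Independent enumeration of integer lattice points inside a circle."""
    r2 = radius_in_h * radius_in_h
    return sum(1 for i in range(-radius_in_h, radius_in_h + 1)
               for j in range(-radius_in_h, radius_in_h + 1)
               if i * i + j * j <= r2)


class TestCircularMembrane:
    def test_full_scale_particle_count_matches_enumeration(self):
        membrane = build_circular_membrane(200.0, 1.0, 0.005)
        assert membrane.n_particles == brute_force_disc_count(100)
        # frozen regression constant from the enumeration oracle
        assert membrane.n_particles == 31417

    def test_tiny_disc_has_13_particles(self):
        # (0,0), 4 axis points at 1, 4 diagonals, 4 axis points at 2
        membrane = build_circular_membrane(4.0, 1.0, 0.005, layer_width=1.0)
        assert membrane.n_particles == 13

    def test_all_reference_positions_inside_disc(self):
        membrane = build_circular_membrane(60.0, 1.0, 0.005)
        assert np.all(membrane.radii_ref <= 30.0 + 1e-9)

    def test_boundary_layer_is_outer_annulus(self):
        membrane = build_circular_membrane(200.0, 1.0, 0.005, layer_width=10.0)
        r = membrane.radii_ref
        in_layer = np.zeros(membrane.n_particles, dtype=bool)
        in_layer[membrane.boundary_layer_ids] = True
        assert np.all(r[in_layer] > 90.0)
        assert np.all(r[~in_layer] <= 90.0)

    def test_area_per_particle_is_h_squared(self):
        membrane = build_circular_membrane(30.0, 0.5, 0.005, layer_width=5.0)
        assert membrane.area_per_particle == pytest.approx(0.25)

    @pytest.mark.parametrize("kwargs,field", [
        (dict(diameter=-1.0, spacing=1.0, thickness=0.005), "diameter"),
        (dict(diameter=10.0, spacing=0.0, thickness=0.005), "spacing"),
        (dict(diameter=10.0, spacing=20.0, thickness=0.005), "spacing"),
        (dict(diameter=10.0, spacing=1.0, thickness=-2.0), "thickness"),
        (dict(diameter=10.0, spacing=1.0, thickness=0.005, layer_width=9.0),
         "layer_width"),
    ])
    def test_bad_geometry_names_offending_field(self, kwargs, field):
        with pytest.raises(ConfigurationError, match=field):
            build_circular_membrane(**kwargs)


class TestBondNetwork:
    def test_interior_particle_has_28_bonds_at_delta_3h(self):
        # independent oracle: lattice offsets with 0 < i²+j² <= 9
        oracle = sum(1 for i in range(-3, 4) for j in range(-3, 4)
                     if 0 < i * i + j * j <= 9)
        assert oracle == 28
        membrane = build_circular_membrane(30.0, 1.0, 0.005)
        network = build_bond_network(membrane, 3.0)
        center = int(np.argmin(membrane.radii_ref))
        assert network.initial_bond_count[center] == 28

    def test_rim_particle_has_fewer_bonds(self):
        membrane = build_circular_membrane(30.0, 1.0, 0.005)
        network = build_bond_network(membrane, 3.0)
        rim = int(np.argmax(membrane.radii_ref))
        assert network.initial_bond_count[rim] < 28

    def test_unit_horizon_gives_von_neumann_neighbourhood(self):
        membrane = build_circular_membrane(30.0, 1.0, 0.005)
        network = build_bond_network(membrane, 1.0)
        center = int(np.argmin(membrane.radii_ref))
        assert network.initial_bond_count[center] == 4

    def test_bond_symmetry_and_reverse_index(self):
        membrane = build_circular_membrane(20.0, 1.0, 0.005, layer_width=3.0)
        network = build_bond_network(membrane, 3.0)
        src = np.repeat(np.arange(network.n_particles),
                        np.diff(network.indptr))
        dst = network.indices
        rev = network.reverse_index
        assert np.array_equal(src, dst[rev])
        assert np.array_equal(dst, src[rev])
        np.testing.assert_allclose(network.ref_vectors,
                                   -network.ref_vectors[rev])

    def test_ref_lengths_within_horizon(self):
        membrane = build_circular_membrane(20.0, 1.0, 0.005, layer_width=3.0)
        network = build_bond_network(membrane, 3.0)
        assert np.all(network.ref_lengths > 0)
        assert np.all(network.ref_lengths <= 3.0 * (1 + 1e-9))

    def test_horizon_below_spacing_rejected(self):
        membrane = build_circular_membrane(20.0, 1.0, 0.005, layer_width=3.0)
        with pytest.raises(ConfigurationError):
            build_bond_network(membrane, 0.5)

    def test_full_scale_bond_count_matches_enumeration(self):
        # per-offset enumeration over all particle pairs (vectorised oracle)
        membrane = build_circular_membrane(60.0, 1.0, 0.005)
        network = build_bond_network(membrane, 3.0)
        pts = membrane.positions_ref
        count = 0
        for di in range(-3, 4):
            for dj in range(-3, 4):
                if 0 < di * di + dj * dj <= 9:
                    shifted = pts + [di, dj]
                    r = np.linalg.norm(shifted, axis=1)
                    count += int(np.sum(r <= 30.0 + 1e-9))
        assert network.n_directed_bonds == count


class TestPinning:
    @pytest.fixture
    def membrane(self):
        return build_circular_membrane(60.0, 1.0, 0.005)

    def test_seventeen_pins_reproducible(self, membrane):
        pins_a = assign_pinning(membrane, 17, seed=5)
        pins_b = assign_pinning(membrane, 17, seed=5)
        assert pins_a.indices.shape == (17,)
        assert len(set(pins_a.indices.tolist())) == 17
        np.testing.assert_array_equal(pins_a.indices, pins_b.indices)

    def test_zero_pins(self, membrane):
        pins = assign_pinning(membrane, 0, seed=1)
        assert pins.indices.size == 0

    def test_region_constrained_pins_inside_disc(self, membrane):
        pins = assign_pinning(membrane, 6, seed=2, region=(0.0, 0.0, 20.0))
        assert np.all(np.linalg.norm(pins.coordinates, axis=1) <= 20.0)

    def test_pins_never_in_driven_layer(self, membrane):
        pins = assign_pinning(membrane, 40, seed=3)
        driven = set(membrane.boundary_layer_ids.tolist())
        assert not driven.intersection(pins.indices.tolist())

    def test_explicit_coordinates_map_to_nearest_particle(self, membrane):
        pins = assign_pinning(membrane, 0, coordinates=[(2.2, 3.4), (-5.0, 0.4)])
        np.testing.assert_allclose(
            sorted(pins.coordinates.tolist()), [[-5.0, 0.0], [2.0, 3.0]])

    def test_too_many_pins_rejected(self, membrane):
        with pytest.raises(ConfigurationError):
            assign_pinning(membrane, membrane.n_particles, seed=0)

    @settings(max_examples=20, deadline=None)
    @given(n=st.integers(0, 30), seed=st.integers(0, 2**31 - 1))
    def test_pinning_determinism_property(self, n, seed):
        membrane = build_circular_membrane(40.0, 1.0, 0.005)
        a = assign_pinning(membrane, n, seed=seed)
        b = assign_pinning(membrane, n, seed=seed)
        np.testing.assert_array_equal(a.indices, b.indices)
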