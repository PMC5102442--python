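"""State-based Linear Peridynamic Solid (LPS) constitutive model in 2D.

The membrane is an isotropic 2D elastic film with areal bulk modulus ``K``
and shear modulus ``G`` (MPa).  The scalar bond force state is

    t = (2K/m) θ ω ‖ξ‖ + (8G/m) ω e^d ,      ω ≡ 1,

with weighted volume ``m = Σ ω ‖ξ‖² A`` and dilatation
``θ = (2/m) Σ ω ‖ξ‖ e A``; ``e = ‖y'-y‖ - ‖ξ‖`` is the bond extension and
``e^d = e - θ‖ξ‖/2`` its deviatoric part.  The coefficients are calibrated
so that a uniformly strained patch reproduces 2D isotropic elasticity
``σ = K tr(ε) I + 2G dev(ε)`` (energy matching in the continuum limit of the
horizon integrals).  A fluid membrane is the ``G = 0`` limit and retains its
areal stiffness ``K``.

Bonds stretched beyond the critical stretch ``s_c`` (tensile only) break
irreversibly; short-range repulsive contact forces prevent unphysical
particle interpenetration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import _kernels
from .discretization import BondNetwork, Membrane

logger = logging.getLogger(__name__)

#: kg/m³ → kg/μm³
_DENSITY_SI_TO_UM = 1e-18


@dataclass
class MaterialModel:
    """Material parameters of the membrane.

    Parameters
    ----------
    bulk_K, shear_G : float
        Areal bulk and shear moduli, MPa.
    density_rho : float
        Physical mass density, kg/m³ (converted internally to kg/μm³).
    mass_scale : float
        Artificial density multiplier that enlarges the stable time step of
        the slow expansion process.
    critical_stretch_sc : float
        Tensile bond stretch beyond which a bond breaks.
    contact_scale_c : float
        Dimensionless record of the short-range scale constant ``c``; kept
        for provenance, see :meth:`contact_c_sr`.
    contact_cutoff_mult : float
        Contact search radius in multiples of the lattice spacing.
    contact_prefactor : float or None
        Explicit short-range stiffness C_sr (force density per μm of
        overlap).  When None it defaults to the bond-based micromodulus
        scale ``18K/(πδ⁵)``, which makes the repulsion comparable to the
        bond stiffness so that it actually prevents interpenetration (see
        docs/methods.md for the reasoning).
    """

    bulk_K: float = 10.0
    shear_G: float = 0.0
    density_rho: float = 1000.0
    mass_scale: float = 1e8
    critical_stretch_sc: float = 0.15
    contact_scale_c: float = 2.7e-8
    contact_cutoff_mult: float = 6.0
    contact_prefactor: float | None = None

    def __post_init__(self):
        if self.bulk_K <= 0:
            raise ValueError(f"bulk_K must be positive, got {self.bulk_K}")
        if self.shear_G < 0:
            raise ValueError(f"shear_G must be non-negative, got {self.shear_G}")
        if self.critical_stretch_sc <= 0:
            raise ValueError("critical_stretch_sc must be positive")
        nu = poisson_ratio(self.bulk_K, max(self.shear_G, 0.0))
        if not (-1.0 < nu <= 0.5):
            raise ValueError(f"Poisson ratio {nu} outside (-1, 0.5]")

    @property
    def scaled_density(self) -> float:
        """Mass-scaled density in kg/μm³."""
        return self.density_rho * _DENSITY_SI_TO_UM * self.mass_scale

    def contact_c_sr(self, horizon: float) -> float:
        """Short-range stiffness; default 18K/(πδ⁵) (micromodulus scale)."""
        if self.contact_prefactor is not None:
            return self.contact_prefactor
        return 18.0 * self.bulk_K / (np.pi * horizon**5)


@dataclass
class DamageField:
    """Per-particle damage φ ∈ [0, 1]: fraction of initial bonds now broken."""

    phi: np.ndarray


def poisson_ratio(K: float, G: float) -> float:
    """3D isotropic Poisson ratio ν = (3K - 2G) / (2(3K + G)).

    Descriptive mapping between the (K, G) pair and the fluid-to-solid
    character of the membrane: ν = 0.5 at G = 0 (incompressible fluid),
    ν = 0.125 at K = G.
    """
    if K <= 0:
        raise ValueError("K must be positive")
    if G < 0:
        raise ValueError("G must be non-negative")
    return (3 * K - 2 * G) / (2 * (3 * K + G))


def weighted_volume(membrane: Membrane, network: BondNetwork,
                    particle_i: int | None = None):
    """Weighted volume m_i = Σ_j ω ‖ξ‖² A_j (μm⁴), ω ≡ 1.

    A reference-configuration quantity over the *initial* bond set; it is
    frozen after construction and not re-computed as bonds break.  Isolated
    particles (no bonds) get m = 0 and are excluded from force evaluation.
    """
    area = membrane.area_per_particle
    sq = network.ref_lengths**2
    m = np.add.reduceat(
        np.append(sq, 0.0), network.indptr[:-1]) * area
    m[np.diff(network.indptr) == 0] = 0.0
    if np.any(m == 0.0):
        logger.warning("%d isolated particle(s) excluded from force evaluation",
                       int(np.sum(m == 0.0)))
    if particle_i is not None:
        return float(m[particle_i])
    return m


def dilatation(positions: np.ndarray, membrane: Membrane, network: BondNetwork,
               weighted_volumes: np.ndarray | None = None,
               particle_i: int | None = None):
    """2D dilatation θ_i = (2/m_i) Σ_j ω ‖ξ‖ e A_j over intact bonds.

    Frame-indifferent: rigid motions of the deformed positions give θ = 0;
    uniform isotropic expansion ``y = (1+s)x`` gives θ = 2s.
    """
    if weighted_volumes is None:
        weighted_volumes = weighted_volume(membrane, network)
    theta = np.empty(membrane.n_particles)
    _kernels.compute_theta(
        np.ascontiguousarray(positions, dtype=np.float64),
        network.indptr, network.indices, network.ref_lengths,
        network.intact, weighted_volumes, membrane.area_per_particle, theta)
    if particle_i is not None:
        return float(theta[particle_i])
    return theta


def internal_force_density(positions: np.ndarray, membrane: Membrane,
                           network: BondNetwork, material: MaterialModel,
                           weighted_volumes: np.ndarray | None = None,
                           theta: np.ndarray | None = None) -> np.ndarray:
    """LPS internal force density per particle, f_i = Σ_j (t_ij + t_ji) M_ij A_j.

    Pairwise antisymmetric assembly, so the total over a free body is zero to
    machine precision.  Broken bonds contribute exactly zero.  The thickness
    of the film enters the equation of motion on both sides and cancels once
    areal moduli are used (see docs/methods.md); units here are MPa/μm
    (force per volume).
    """
    y = np.ascontiguousarray(positions, dtype=np.float64)
    if weighted_volumes is None:
        weighted_volumes = weighted_volume(membrane, network)
    if theta is None:
        theta = dilatation(y, membrane, network, weighted_volumes)
    force = np.empty_like(y)
    degenerate = _kernels.compute_internal_force(
        y, network.indptr, network.indices, network.ref_lengths,
        network.intact, weighted_volumes, theta, membrane.area_per_particle,
        2.0 * material.bulk_K, 8.0 * material.shear_G, force)
    if degenerate:
        logger.warning("%d bond(s) with coincident deformed endpoints "
                       "contributed zero this step", degenerate)
    return force


class ContactCache:
    """Proximity pair list for short-range forces, rebuilt with a skin margin.

    Pairs within ``cutoff + skin`` of each other (current positions) are
    cached together with their short-range interaction distance
    ``d_pi = min{0.9‖x_j - x_i‖, 1.35h}`` (reference distances); the cache is
    valid until any particle moves more than ``skin/2`` from its position at
    build time.
    """

    def __init__(self, membrane: Membrane, material: MaterialModel,
                 skin: float = 1.0):
        self.membrane = membrane
        self.cutoff = material.contact_cutoff_mult * membrane.spacing_h
        self.skin = skin
        self.pair_i = np.empty(0, dtype=np.int64)
        self.pair_j = np.empty(0, dtype=np.int64)
        self.pair_dpi = np.empty(0, dtype=np.float64)
        self._built_at = None

    def update(self, positions: np.ndarray) -> None:
        if self._built_at is not None and _kernels.max_displacement_since(
                positions, self._built_at) < 0.5 * self.skin:
            return
        tree = cKDTree(positions)
        pairs = tree.query_pairs(self.cutoff + self.skin, output_type="ndarray")
        if pairs.size:
            order = np.lexsort((pairs[:, 1], pairs[:, 0]))
            pairs = pairs[order]
        self.pair_i = np.ascontiguousarray(pairs[:, 0]) if pairs.size else np.empty(0, dtype=np.int64)
        self.pair_j = np.ascontiguousarray(pairs[:, 1]) if pairs.size else np.empty(0, dtype=np.int64)
        ref = self.membrane.positions_ref
        if pairs.size:
            ref_d = np.linalg.norm(ref[self.pair_j] - ref[self.pair_i], axis=1)
            self.pair_dpi = np.minimum(0.9 * ref_d, 1.35 * self.membrane.spacing_h)
        else:
            self.pair_dpi = np.empty(0, dtype=np.float64)
        self._built_at = positions.copy()


def short_range_force(positions: np.ndarray, membrane: Membrane,
                      material: MaterialModel, horizon: float = 3.0,
                      cache: ContactCache | None = None) -> np.ndarray:
    """Short-range repulsive contact force density between all close pairs.

    f = min{0, C_sr(‖y_j − y_i‖ − d_pi)} (y_j − y_i)/‖y_j − y_i‖, applied
    between every pair within the contact cutoff, bonded or not; identically
    zero at separations ≥ d_pi (deadband), strictly repulsive below, and
    pairwise antisymmetric.
    """
    y = np.ascontiguousarray(positions, dtype=np.float64)
    if cache is None:
        cache = ContactCache(membrane, material, skin=0.0)
    cache.update(y)
    force = np.zeros_like(y)
    coincident = _kernels.compute_contact_force(
        y, cache.pair_i, cache.pair_j, cache.pair_dpi,
        material.contact_c_sr(horizon), membrane.area_per_particle, force)
    if coincident:
        logger.warning("%d exactly coincident particle pair(s); repelled along +x",
                       coincident)
    return force


def update_broken_bonds(positions: np.ndarray, network: BondNetwork,
                        material: MaterialModel,
                        broken_count: np.ndarray | None = None) -> int:
    """Break all bonds with tensile stretch above ``s_c``; returns the number
    of newly broken (undirected) bonds.

    Evaluated once per accepted time step; compression never breaks a bond;
    both directions of a pair break together and never heal.
    """
    if broken_count is None:
        broken_count = np.zeros(network.n_particles, dtype=np.int64)
    return int(_kernels.break_bonds(
        np.ascontiguousarray(positions, dtype=np.float64),
        network.indptr, network.indices, network.ref_lengths, network.intact,
        network.reverse_index, material.critical_stretch_sc, broken_count))


def damage_field(network: BondNetwork,
                 broken_count: np.ndarray | None = None) -> DamageField:
    """Damage φ_i = (broken bonds of i) / (initial bonds of i).

    100% damage means every bond of the material point is broken.  A particle
    with no initial bonds is fully disconnected by definition: φ = 1.
    """
    if broken_count is None:
        broken_count = network.broken_count()
    init = network.initial_bond_count
    phi = np.ones(network.n_particles, dtype=float)
    ok = init > 0
    phi[ok] = broken_count[ok] / init[ok]
    if np.any(~ok):
        logger.warning("%d particle(s) with no initial bonds: damage set to 1",
                       int(np.sum(~ok)))
    return DamageField(phi=phi)


class ForceEvaluator:
    """Bundles internal + contact force evaluation into an acceleration field.

    ``accel(y)`` returns (f_internal + f_contact) / (ρ · mass_scale), the
    right-hand side of the discrete equation of motion.  Weighted volumes are
    computed once at construction; the contact pair cache refreshes itself.
    """

    def __init__(self, membrane: Membrane, network: BondNetwork,
                 material: MaterialModel, contact_skin: float = 1.0):
        self.membrane = membrane
        self.network = network
        self.material = material
        self.m = weighted_volume(membrane, network)
        self.contact = ContactCache(membrane, material, skin=contact_skin)
        self._c_sr = material.contact_c_sr(network.horizon_delta)
        self._theta = np.empty(membrane.n_particles)
        self._force = np.empty((membrane.n_particles, 2))
        self._rho = material.scaled_density

    def force_density(self, y: np.ndarray) -> np.ndarray:
        y = np.ascontiguousarray(y, dtype=np.float64)
        net = self.network
        _kernels.compute_theta(y, net.indptr, net.indices, net.ref_lengths,
                               net.intact, self.m,
                               self.membrane.area_per_particle, self._theta)
        _kernels.compute_internal_force(
            y, net.indptr, net.indices, net.ref_lengths, net.intact, self.m,
            self._theta, self.membrane.area_per_particle,
            2.0 * self.material.bulk_K, 8.0 * self.material.shear_G,
            self._force)
        self.contact.update(y)
        _kernels.compute_contact_force(
            y, self.contact.pair_i, self.contact.pair_j, self.contact.pair_dpi,
            self._c_sr, self.membrane.area_per_particle, self._force)
        return self._force

    def accel(self, y: np.ndarray) -> np.ndarray:
        return self.force_density(y) / self._rho


def measure_stress_flux(positions: np.ndarray, membrane: Membrane,
                        network: BondNetwork, material: MaterialModel,
                        cut_x: float, window_halfwidth: float) -> np.ndarray:
    """Stress column (σ_xx, σ_yx) from the bond-force flux through a cut.

    Sums the pair forces of all bonds whose reference endpoints straddle the
    vertical line ``x = cut_x`` within ``|y| < window_halfwidth``, divided by
    the cut length.  Used by the uniform-strain patch test to compare the
    discrete model against 2D elasticity.
    """
    y = np.ascontiguousarray(positions, dtype=np.float64)
    m = weighted_volume(membrane, network)
    theta = dilatation(y, membrane, network, m)
    area = membrane.area_per_particle
    ref = membrane.positions_ref
    src = np.repeat(np.arange(network.n_particles), np.diff(network.indptr))
    dst = network.indices
    crossing = (network.intact
                & (ref[src, 0] < cut_x) & (ref[dst, 0] > cut_x)
                & (np.abs(ref[src, 1]) < window_halfwidth))
    ks = np.nonzero(crossing)[0]
    total = np.zeros(2)
    for k in ks:
        i, j = src[k], dst[k]
        d = y[j] - y[i]
        cur = np.hypot(d[0], d[1])
        if cur == 0:
            continue
        r0 = network.ref_lengths[k]
        e = cur - r0
        t_pair = 0.0
        for p in (i, j):
            if m[p] > 0:
                t_pair += (2 * material.bulk_K * theta[p] * r0
                           + 8 * material.shear_G * (e - 0.5 * theta[p] * r0)) / m[p]
        total += t_pair * d / cur
    # σ = h⁴ Σ t_pair M / L_cut  (thickness cancels; see docs/methods.md)
    return area**2 * total / (2 * window_halfwidth)
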