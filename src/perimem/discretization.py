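"""Particle lattice, bond network and pinning sites for a circular membrane.

The membrane is discretized as a square lattice of material points with
spacing ``h``; every point carries the area ``h**2``.  Points are bonded to
all neighbours within a finite horizon ``delta`` (closed ball: a point
exactly at distance ``delta`` is bonded).  A thin annular layer at the rim
is driven kinematically during a simulation; pinned points are held at
their reference positions and act as rupture nucleation sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree


class ConfigurationError(ValueError):
    """Invalid geometry or discretization parameter."""


@dataclass
class Membrane:
    """Reference (undeformed) particle lattice of the circular membrane.

    Attributes
    ----------
    positions_ref : (N, 2) float array
        Reference coordinates in μm.
    spacing_h : float
        Lattice spacing h in μm.
    thickness_eps : float
        Membrane thickness ϵ in μm (geometry metadata; cancels from the
        in-plane dynamics once areal moduli are used).
    diameter_0 : float
        Initial membrane diameter D_0 in μm.
    layer_width : float
        Width of the driven rim layer in μm.
    boundary_layer_ids : int array
        Indices of particles in the driven rim layer
        (radius > D_0/2 - layer_width).
    pinned_ids : int array
        Indices of pinned particles (empty until pinning is assigned).
    """

    positions_ref: np.ndarray
    spacing_h: float
    thickness_eps: float
    diameter_0: float
    layer_width: float
    boundary_layer_ids: np.ndarray
    pinned_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int64))

    @property
    def n_particles(self) -> int:
        return self.positions_ref.shape[0]

    @property
    def area_per_particle(self) -> float:
        """Area A_j represented by each material point (= h²), μm²."""
        return self.spacing_h**2

    @property
    def radii_ref(self) -> np.ndarray:
        return np.linalg.norm(self.positions_ref, axis=1)

    def interior_ids(self) -> np.ndarray:
        """Indices not in the driven rim layer."""
        mask = np.ones(self.n_particles, dtype=bool)
        mask[self.boundary_layer_ids] = False
        return np.nonzero(mask)[0]


@dataclass
class BondNetwork:
    """Horizon-based bond network in CSR (compressed neighbour list) layout.

    Each bond is stored twice, once per direction.  ``reverse_index[k]``
    locates the opposite direction of bond ``k`` so that the pair breaks
    together.  ``intact`` flags transition only from True to False.
    """

    horizon_delta: float
    indptr: np.ndarray          # (N+1,) int64
    indices: np.ndarray         # (M,) int64, bond targets
    ref_vectors: np.ndarray     # (M, 2) float64, ξ = x_j - x_i
    ref_lengths: np.ndarray     # (M,) float64, ‖ξ‖
    intact: np.ndarray          # (M,) bool
    reverse_index: np.ndarray   # (M,) int64
    initial_bond_count: np.ndarray  # (N,) int64

    @property
    def n_particles(self) -> int:
        return self.indptr.shape[0] - 1

    @property
    def n_directed_bonds(self) -> int:
        return self.indices.shape[0]

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i]:self.indptr[i + 1]]

    def broken_count(self) -> np.ndarray:
        """Per-particle count of broken bonds."""
        out = np.zeros(self.n_particles, dtype=np.int64)
        np.add.at(out, np.repeat(np.arange(self.n_particles),
                                 np.diff(self.indptr)), ~self.intact)
        return out


@dataclass
class PinningSet:
    """Pinned particle indices with the provenance needed to reproduce them."""

    count_n: int
    indices: np.ndarray
    coordinates: np.ndarray     # reference positions of the pinned particles
    seed: int | None = None


def build_circular_membrane(
    diameter: float,
    spacing: float,
    thickness: float,
    layer_width: float = 10.0,
) -> Membrane:
    """Build the circular square-lattice membrane.

    All lattice points ``(i*h, j*h)`` with distance ≤ ``diameter/2`` from the
    origin are included.  Particles with radius > ``diameter/2 - layer_width``
    form the driven boundary layer.

    Parameters are in μm.  Raises :class:`ConfigurationError` on non-positive
    geometry, naming the offending field.
    """
    if diameter <= 0:
        raise ConfigurationError(f"diameter must be positive, got {diameter}")
    if spacing <= 0 or spacing >= diameter:
        raise ConfigurationError(
            f"spacing must satisfy 0 < spacing < diameter, got {spacing}")
    if thickness <= 0:
        raise ConfigurationError(f"thickness must be positive, got {thickness}")
    if layer_width <= 0 or layer_width >= diameter / 2:
        raise ConfigurationError(
            f"layer_width must satisfy 0 < layer_width < diameter/2, "
            f"got {layer_width}")

    radius = diameter / 2.0
    n_half = int(np.floor(radius / spacing))
    coords = np.arange(-n_half, n_half + 1) * spacing
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    # tiny tolerance so points exactly on the circle survive float rounding
    r = np.linalg.norm(pts, axis=1)
    keep = r <= radius * (1 + 1e-12)
    pts = pts[keep]
    r = r[keep]
    # deterministic ordering: lexicographic by (x, y)
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = np.ascontiguousarray(pts[order])
    r = r[order]

    boundary = np.nonzero(r > radius - layer_width)[0]
    return Membrane(
        positions_ref=pts,
        spacing_h=float(spacing),
        thickness_eps=float(thickness),
        diameter_0=float(diameter),
        layer_width=float(layer_width),
        boundary_layer_ids=boundary.astype(np.int64),
    )


def build_bond_network(membrane: Membrane, horizon: float) -> BondNetwork:
    """Bond every particle to all others at distance in ``(0, horizon]``.

    The neighbourhood is a closed ball, so on a square lattice with
    ``horizon = 3h`` an interior particle has exactly 28 bonds.
    """
    if horizon < membrane.spacing_h:
        raise ConfigurationError(
            f"horizon {horizon} < spacing {membrane.spacing_h}: no bonds possible")

    pts = membrane.positions_ref
    tree = cKDTree(pts)
    # small tolerance keeps lattice points exactly at the horizon
    pairs = tree.query_pairs(horizon * (1 + 1e-12), output_type="ndarray")

    n = membrane.n_particles
    # duplicate per direction
    src = np.concatenate([pairs[:, 0], pairs[:, 1]])
    dst = np.concatenate([pairs[:, 1], pairs[:, 0]])
    order = np.lexsort((dst, src))
    src, dst = src[order], dst[order]

    counts = np.bincount(src, minlength=n)
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])

    ref_vec = pts[dst] - pts[src]
    ref_len = np.linalg.norm(ref_vec, axis=1)

    # reverse index via lexicographic rank of the flipped (dst, src) pairs
    key_fwd = src * n + dst
    key_rev = dst * n + src
    rank = np.argsort(key_fwd)
    reverse = rank[np.searchsorted(key_fwd, key_rev, sorter=rank)]

    return BondNetwork(
        horizon_delta=float(horizon),
        indptr=indptr,
        indices=dst.astype(np.int64),
        ref_vectors=ref_vec,
        ref_lengths=ref_len,
        intact=np.ones(src.shape[0], dtype=bool),
        reverse_index=reverse.astype(np.int64),
        initial_bond_count=counts.astype(np.int64),
    )


def assign_pinning(
    membrane: Membrane,
    n: int,
    seed: int | None = None,
    region: tuple[float, float, float] | None = None,
    coordinates: np.ndarray | None = None,
) -> PinningSet:
    """Choose ``n`` pinned particles and record them on the membrane.

    By default pins are drawn uniformly at random (per ``seed``) from the
    non-driven interior particles; pins never fall in the driven rim layer.
    ``region = (cx, cy, r)`` restricts sampling to a disc (the clustered-pin
    case).  An explicit ``coordinates`` array overrides sampling: each point
    maps to the nearest lattice particle, ties broken by lowest index.
    """
    interior = membrane.interior_ids()
    pts = membrane.positions_ref

    if coordinates is not None:
        coordinates = np.atleast_2d(np.asarray(coordinates, dtype=float))
        idx = []
        for c in coordinates:
            d2 = np.einsum("ij,ij->i", pts - c, pts - c)
            idx.append(int(np.argmin(d2)))  # argmin = lowest index on ties
        indices = np.array(sorted(set(idx)), dtype=np.int64)
        if len(indices) != len(coordinates):
            raise ConfigurationError(
                "pinning coordinates map to duplicate lattice particles")
        n = len(indices)
    else:
        if n < 0:
            raise ConfigurationError(f"pin count must be >= 0, got {n}")
        candidates = interior
        if region is not None:
            cx, cy, rr = region
            d = np.linalg.norm(pts[candidates] - np.array([cx, cy]), axis=1)
            candidates = candidates[d <= rr]
        if n > candidates.size:
            raise ConfigurationError(
                f"cannot place {n} pins among {candidates.size} candidate particles")
        rng = np.random.default_rng(seed)
        indices = np.sort(rng.choice(candidates, size=n, replace=False)).astype(np.int64)

    driven = set(membrane.boundary_layer_ids.tolist())
    if any(int(i) in driven for i in indices):
        raise ConfigurationError("a pinned particle falls in the driven rim layer")

    membrane.pinned_ids = indices
    return PinningSet(count_n=int(n), indices=indices,
                      coordinates=pts[indices].copy(), seed=seed)
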