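"""Deterministic synthetic inputs: patches, fractal rasters, scaled membranes.

Everything the test suite consumes is generated here at run time — small
uniformly strained lattice patches for the elasticity calibration, analytic
fractal rasters for validating the box counter, synthetic rupture masks,
and down-scaled membrane run configurations whose only departure from the
study conditions is the diameter.
"""

from __future__ import annotations

import numpy as np

from .analysis import RuptureMask
from .constitutive import MaterialModel
from .discretization import ConfigurationError, Membrane
from .driver import GeometryConfig, PinningConfig, RunConfig
from .integrator import IntegratorSettings, SimulationState


def make_patch(n_side: int, h: float = 1.0,
               strain: np.ndarray | None = None,
               horizon_mult: float = 3.0):
    """Square lattice patch with deformed positions y = (I + strain)·x.

    ``n_side`` must be at least ``12·δ/h`` so that an interior region free
    of boundary effects exists.  Returns ``(membrane, state)`` where the
    membrane is the undeformed patch (no driven layer, no pins) and the
    state carries the uniformly strained positions.
    """
    delta = horizon_mult * h
    if n_side < 12 * delta / h:
        raise ConfigurationError(
            f"patch too small: n_side {n_side} < {12 * delta / h:.0f}")
    coords = (np.arange(n_side) - (n_side - 1) / 2) * h
    xx, yy = np.meshgrid(coords, coords, indexing="ij")
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = np.ascontiguousarray(pts[order])

    membrane = Membrane(
        positions_ref=pts, spacing_h=float(h), thickness_eps=0.005,
        diameter_0=float(n_side * h), layer_width=delta,
        boundary_layer_ids=np.empty(0, dtype=np.int64))

    if strain is None:
        strain = np.zeros((2, 2))
    strain = np.asarray(strain, dtype=float)
    y = pts @ (np.eye(2) + strain).T
    n = pts.shape[0]
    state = SimulationState(positions=y, velocities=np.zeros((n, 2)),
                            accelerations=np.zeros((n, 2)), time=0.0, dt=1e-6)
    return membrane, state


def patch_interior_ids(membrane: Membrane, skin_mult: float = 3.0,
                       horizon: float = 3.0) -> np.ndarray:
    """Indices farther than ``skin_mult·δ`` from the patch edge."""
    pts = membrane.positions_ref
    half = pts[:, 0].max()
    skin = skin_mult * horizon
    keep = (np.abs(pts[:, 0]) <= half - skin) & (np.abs(pts[:, 1]) <= half - skin)
    return np.nonzero(keep)[0]


def _sierpinski(size: int, level: int) -> np.ndarray:
    """Right-triangle Sierpiński gasket raster by recursive subdivision.

    The level-``k`` iterate has 3**k sub-triangles of side ``size / 2**k``
    pixels; each terminal cell is rasterized as the discrete lower-left
    triangle ``i + j < cell``.
    """
    img = np.zeros((size, size), dtype=bool)

    def recurse(x0: int, y0: int, cell: int, lev: int):
        if lev == 0:
            ii, jj = np.meshgrid(np.arange(cell), np.arange(cell), indexing="ij")
            tri = ii + jj < cell
            img[x0:x0 + cell, y0:y0 + cell] |= tri
            return
        half = cell // 2
        recurse(x0, y0, half, lev - 1)
        recurse(x0 + half, y0, half, lev - 1)
        recurse(x0, y0 + half, half, lev - 1)

    recurse(0, 0, size, level)
    return img


def make_fractal_raster(kind: str, level: int = 7, size: int = 512) -> RuptureMask:
    """Deterministic binary raster of a named analytic set.

    kinds: ``line`` (one-pixel horizontal segment spanning the image, D = 1),
    ``square`` (fully occupied block, D = 2), ``sierpinski`` (gasket iterate
    of the given level, D = log 3 / log 2 ≈ 1.585).
    """
    if size < 4 or size & (size - 1):
        raise ValueError(f"size must be a power of two >= 4, got {size}")
    if kind == "line":
        img = np.zeros((size, size), dtype=bool)
        img[size // 2, :] = True
    elif kind == "square":
        img = np.ones((size, size), dtype=bool)
    elif kind == "sierpinski":
        if level < 1:
            raise ValueError("sierpinski needs level >= 1")
        if 2**level > size:
            raise ValueError(f"level {level} too deep for size {size}")
        img = _sierpinski(size, level)
    else:
        raise ValueError(f"unknown fractal kind {kind!r}")
    return RuptureMask(pixels=img, resolution=1.0)


def make_synthetic_hole_mask(image_size: int, holes: list[tuple[float, float, float]],
                             resolution: float = 1.0) -> RuptureMask:
    """Synthetic rupture-contour mask: circles outlining the given holes.

    ``holes`` is a list of ``(cx, cy, radius)`` in pixel units.  The mask
    contains the boundary pixels of each hole (pixels inside the hole
    adjacent to the outside), mimicking what rasterize_rupture produces for
    circular pores.
    """
    from scipy import ndimage
    img = np.zeros((image_size, image_size), dtype=bool)
    ii, jj = np.meshgrid(np.arange(image_size), np.arange(image_size),
                         indexing="ij")
    for cx, cy, r in holes:
        img |= (ii - cx) ** 2 + (jj - cy) ** 2 <= r * r
    boundary = img & ~ndimage.binary_erosion(img, np.ones((3, 3), dtype=bool))
    return RuptureMask(pixels=boundary, resolution=resolution)


def make_scaled_membrane(diameter: float = 60.0, n_pins: int = 4,
                         cluster: bool = False, seed: int = 0,
                         shear_G: float = 0.0, mass_scale: float = 1e8,
                         target_expansion: float = 1.12,
                         cluster_radius_frac: float = 0.35) -> RunConfig:
    """RunConfig equal to the study conditions except for the diameter.

    The scaled membrane is the canonical test vehicle: small enough for
    CPU-minutes runs, large enough for several pores.  ``cluster`` confines
    the pins to a disc of ``cluster_radius_frac`` of the interior radius
    around the centre (the clustered-pin layout); otherwise pins scatter
    uniformly over the interior disc, kept two horizons away from the
    driven layer so a pin never acts as a notch on the loading ring.

    The default stop ratio 1.12 is just below the expansion at which a
    uniformly stretched pin-free membrane reaches the critical stretch
    (D/D₀ ≈ 1.15), so rupture within the run requires nucleation sites.
    """
    if diameter < 20.0:
        raise ConfigurationError(f"scaled membrane diameter {diameter} < 20h")
    geometry = GeometryConfig(diameter=diameter)
    interior_radius = diameter / 2 - geometry.layer_width
    pin_margin = 2.0 * geometry.horizon_delta
    if cluster:
        region = (0.0, 0.0, cluster_radius_frac * interior_radius)
    else:
        region = (0.0, 0.0, max(interior_radius - pin_margin, 2.0))
    return RunConfig(
        geometry=geometry,
        material=MaterialModel(shear_G=shear_G, mass_scale=mass_scale),
        pinning=PinningConfig(n=n_pins, seed=seed, region=region),
        integrator=IntegratorSettings(),
        target_expansion=target_expansion,
        master_seed=seed,
    )
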