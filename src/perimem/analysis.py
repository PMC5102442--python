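"""Rupture-morphology analysis: masks, pores, box-counting fractal dimension.

A trajectory snapshot is rasterized into a binary rupture-contour mask:
surviving material (damage below a threshold) is drawn as discs at the
particle positions, the void is the complement within the convex hull of
all particles, and the mask is the void-side boundary.  The contour
component tracing the outer rim of the expanding membrane is removed
automatically (replacing manual image editing) by dropping every contour
component that touches the hull boundary.  The fractal dimension D of the
remaining contour is the negative slope of log(occupied boxes) versus
log(box size) on a fixed grid anchored at the image origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from scipy.spatial import ConvexHull

logger = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=bool)
_FOUR = ndimage.generate_binary_structure(2, 1)


class EmptyMaskError(ValueError):
    """Box counting refused: the mask has no occupied pixels."""


@dataclass
class RuptureMask:
    """Binary raster of a rupture contour with coordinate metadata.

    ``pixels[i, j]`` covers the square of side ``resolution`` (μm) whose
    lower-left corner is ``origin + (i, j) * resolution``.
    """

    pixels: np.ndarray          # 2D bool
    resolution: float           # μm per pixel
    origin: np.ndarray = field(default_factory=lambda: np.zeros(2))
    rim_removed: bool = False

    def pixel_of(self, point: np.ndarray) -> tuple[int, int]:
        ij = np.floor((np.asarray(point) - self.origin) / self.resolution)
        return int(ij[0]), int(ij[1])

    def center_of(self, i: int, j: int) -> np.ndarray:
        return self.origin + (np.array([i, j]) + 0.5) * self.resolution

    @property
    def occupied_count(self) -> int:
        return int(self.pixels.sum())


@dataclass
class BoxCountResult:
    """Log-log box-count fit: D is the negative slope."""

    sizes: np.ndarray           # box sizes, px
    counts: np.ndarray          # occupied boxes per size
    dimension: float
    intercept: float
    r_squared: float
    warning: str | None = None


@dataclass
class Pore:
    pore_id: int
    area: float                 # μm²
    centroid: np.ndarray        # μm


def _hull_mask(points_px: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Filled convex hull of point coordinates (in pixel units)."""
    hull = ConvexHull(points_px)
    verts = points_px[hull.vertices]
    rr, cc = draw_polygon(verts[:, 0], verts[:, 1], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def rasterize_regions(positions: np.ndarray, damage: np.ndarray,
                      resolution: float = 0.5, spacing_h: float = 1.0,
                      damage_threshold: float = 0.5,
                      fill_factor: float = 1.8):
    """Rasterize a snapshot into (occupied, void, hull) boolean rasters.

    Surviving particles (damage < threshold) are drawn as discs of radius
    ``fill_factor · h/2`` (the default 1.8 keeps a lattice stretched to the 15% critical
    stretch fully covered, so intact membrane never reads as void); the void is the complement of the occupied region
    within the convex hull of *all* particles.  Returns the three rasters
    plus the raster origin (μm).
    """
    pos = np.asarray(positions, dtype=float)
    margin = spacing_h
    lo = pos.min(axis=0) - margin
    hi = pos.max(axis=0) + margin
    shape = tuple(np.ceil((hi - lo) / resolution).astype(int) + 1)

    alive = pos[damage < damage_threshold]
    occupied = np.zeros(shape, dtype=bool)
    if len(alive):
        ij = np.floor((alive - lo) / resolution).astype(int)
        occupied[ij[:, 0], ij[:, 1]] = True
        # dilate by fill_factor·h/2 to bridge the (possibly stretched)
        # inter-particle gaps, then erode back to a half-spacing overhang so
        # pore boundaries sit at their nominal radius (a closing, so the
        # bridged interior stays filled)
        disc_r = max(int(round(fill_factor * spacing_h / 2 / resolution)), 1)
        occupied = ndimage.binary_dilation(
            occupied, structure=_disc_structure(disc_r))
        shrink = disc_r - max(int(round(spacing_h / 2 / resolution)), 1)
        if shrink > 0:
            occupied = ndimage.binary_erosion(
                occupied, structure=_disc_structure(shrink))

    hull = _hull_mask((pos - lo) / resolution, shape)
    void = hull & ~occupied
    return occupied, void, hull, lo


def _disc_structure(r: int) -> np.ndarray:
    ax = np.arange(-r, r + 1)
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    return xx * xx + yy * yy <= r * r


def rasterize_rupture(positions: np.ndarray, damage: np.ndarray,
                      resolution: float = 0.5, spacing_h: float = 1.0,
                      damage_threshold: float = 0.5,
                      fill_factor: float = 1.8,
                      remove_rim: bool = True) -> RuptureMask:
    """Binary rupture-contour mask of a snapshot.

    The mask is the void-side boundary: void pixels 4-adjacent to occupied
    material (4-adjacency keeps the pixel count of a smooth digital curve
    close to its true length; an 8-adjacent border over-counts diagonal
    stretches by up to √2).  With ``remove_rim`` every contour component
    (8-connected) that touches the
    hull boundary — the circular rim of the expanding membrane — is dropped,
    automating the rim removal that would otherwise be manual image editing.
    An undamaged membrane yields an empty mask.
    """
    occupied, void, hull, origin = rasterize_regions(
        positions, damage, resolution, spacing_h, damage_threshold, fill_factor)

    near_occ = ndimage.binary_dilation(occupied, structure=_FOUR)
    contour = void & near_occ

    if remove_rim and contour.any():
        hull_boundary = hull & ~ndimage.binary_erosion(hull, structure=_EIGHT)
        near_hull_edge = ndimage.binary_dilation(hull_boundary | ~hull,
                                                 structure=_EIGHT)
        labels, nlab = ndimage.label(contour, structure=_EIGHT)
        touching = np.unique(labels[near_hull_edge & (labels > 0)])
        if touching.size:
            contour = contour & ~np.isin(labels, touching)

    if not contour.any():
        logger.info("empty rupture mask (no interior void contour)")
    return RuptureMask(pixels=contour, resolution=resolution,
                       origin=np.asarray(origin, dtype=float),
                       rim_removed=remove_rim)


def detect_pores(positions: np.ndarray, damage: np.ndarray,
                 resolution: float = 0.5, spacing_h: float = 1.0,
                 damage_threshold: float = 0.5,
                 fill_factor: float = 1.8) -> list[Pore]:
    """8-connected void components (pores), excluding the exterior.

    The exterior is any void component that touches the hull boundary (the
    sliver between the hull polygon and the outermost particle discs).
    Areas are reported in μm².
    """
    occupied, void, hull, origin = rasterize_regions(
        positions, damage, resolution, spacing_h, damage_threshold, fill_factor)
    labels, nlab = ndimage.label(void, structure=_EIGHT)
    if nlab == 0:
        return []
    hull_boundary = hull & ~ndimage.binary_erosion(hull, structure=_EIGHT)
    exterior = np.unique(labels[(hull_boundary | ~hull) & (labels > 0)])
    pores = []
    px_area = resolution**2
    for lab in range(1, nlab + 1):
        if lab in exterior:
            continue
        where = labels == lab
        npx = int(where.sum())
        com = ndimage.center_of_mass(where)
        centroid = np.asarray(origin) + (np.array(com) + 0.5) * resolution
        pores.append(Pore(pore_id=len(pores) + 1, area=npx * px_area,
                          centroid=centroid))
    return pores


def box_count_dimension(mask: RuptureMask | np.ndarray,
                        sizes: np.ndarray | None = None,
                        offset_average: bool = False) -> BoxCountResult:
    """Box-counting (grid-method) fractal dimension of a binary mask.

    The image is covered by grids of square boxes of side ``s`` anchored at
    the image origin; the number of boxes containing at least one mask pixel
    is recorded per size, and D is the negative least-squares slope of
    log(count) against log(size).  Default sizes are powers of two from 2 px
    up to a quarter of the larger image side.  Fewer than 3 usable sizes is
    an error; a fit with R² < 0.95 attaches a warning.
    """
    pixels = mask.pixels if isinstance(mask, RuptureMask) else np.asarray(mask)
    pixels = pixels.astype(bool)
    if not pixels.any():
        raise EmptyMaskError("cannot box-count an empty mask")

    side = max(pixels.shape)
    if sizes is None:
        sizes = []
        s = 2
        while s <= side // 4:
            sizes.append(s)
            s *= 2
        sizes = np.array(sizes, dtype=int)
    else:
        sizes = np.asarray(sizes, dtype=int)
    sizes = sizes[(sizes >= 1) & (sizes <= side)]
    if sizes.size < 3:
        raise ValueError(f"need at least 3 usable box sizes, got {sizes.size}")

    counts = np.array([_count_boxes(pixels, int(s), offset_average)
                       for s in sizes], dtype=float)

    logs = np.log(sizes.astype(float))
    logc = np.log(counts)
    slope, intercept = np.polyfit(logs, logc, 1)
    pred = slope * logs + intercept
    ss_res = float(np.sum((logc - pred) ** 2))
    ss_tot = float(np.sum((logc - logc.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    warning = None
    if r2 < 0.95:
        warning = f"poor log-log linearity: R² = {r2:.3f}"
        logger.warning(warning)
    return BoxCountResult(sizes=sizes, counts=counts.astype(int),
                          dimension=float(-slope), intercept=float(intercept),
                          r_squared=r2, warning=warning)


def _count_boxes(pixels: np.ndarray, s: int, offset_average: bool) -> float:
    def count_at(arr):
        n0 = -(-arr.shape[0] // s) * s
        n1 = -(-arr.shape[1] // s) * s
        padded = np.zeros((n0, n1), dtype=bool)
        padded[:arr.shape[0], :arr.shape[1]] = arr
        blocks = padded.reshape(n0 // s, s, n1 // s, s)
        return int(blocks.any(axis=(1, 3)).sum())

    if not offset_average:
        return count_at(pixels)
    offsets = [(0, 0), (s // 2, 0), (0, s // 2), (s // 2, s // 2)]
    vals = []
    for ox, oy in offsets:
        shifted = np.zeros((pixels.shape[0] + ox, pixels.shape[1] + oy), dtype=bool)
        shifted[ox:, oy:] = pixels
        vals.append(count_at(shifted))
    return float(np.mean(vals))


@dataclass
class SnapshotMetrics:
    time: float
    expansion: float            # D/D0
    pore_count: int
    void_area: float            # μm²
    dimension: float | None
    label: str | None


@dataclass
class MorphologyReport:
    rows: list[SnapshotMetrics]
    note: str | None = None

    @property
    def final_dimension(self) -> float | None:
        """Headline morphology statistic: box-count D of the final snapshot."""
        for row in reversed(self.rows):
            if row.dimension is not None:
                return row.dimension
        return None

    @property
    def final_label(self) -> str | None:
        for row in reversed(self.rows):
            if row.label is not None:
                return row.label
        return None


def classify_morphology(dimension: float, threshold: float = 1.4) -> str:
    """Convenience label: 'floral-like' below the D threshold, else
    'fractal-like'.  Quantitative conclusions should use D itself."""
    return "floral-like" if dimension < threshold else "fractal-like"


def morphology_report(trajectory, resolution: float = 0.5,
                      damage_threshold: float = 0.5,
                      floral_fractal_threshold: float = 1.4,
                      fill_factor: float = 1.8) -> MorphologyReport:
    """Per-snapshot morphology metrics of a trajectory.

    For each snapshot: pore count, total interior void area, box-count D of
    the rupture contour (None while the mask is empty), the expansion ratio,
    and the floral/fractal convenience label.
    """
    rows = []
    h = trajectory.membrane.spacing_h
    for snap in trajectory.snapshots:
        pores = detect_pores(snap.positions, snap.damage, resolution, h,
                             damage_threshold, fill_factor)
        mask = rasterize_rupture(snap.positions, snap.damage, resolution, h,
                                 damage_threshold, fill_factor)
        dim = None
        label = None
        if mask.pixels.any():
            try:
                res = box_count_dimension(mask)
                dim = res.dimension
                label = classify_morphology(dim, floral_fractal_threshold)
            except (ValueError, EmptyMaskError):
                pass
        rows.append(SnapshotMetrics(
            time=snap.time, expansion=snap.expansion, pore_count=len(pores),
            void_area=float(sum(p.area for p in pores)), dimension=dim,
            label=label))
    note = None
    if all(r.dimension is None for r in rows):
        note = "no rupture contour in any snapshot"
    return MorphologyReport(rows=rows, note=note)
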