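"""Cell-contour geometry: sub-pixel contour extraction, centerline meshing,
and surface areas of rod-shaped bacteria.

A cell is represented by a closed planar polygon in physical units (µm).
The centerline mesh assigns, at stations equally spaced along the cell's
longitudinal axis, a local width measured as the length of the rib segment
perpendicular to the centerline and clipped to the contour.  The turgid
surface area is computed as a surface of revolution of the width profile
about the centerline, so a spherocylinder of length ``l`` and width ``w``
comes out at ``pi*w*l`` (cylinder plus two hemispherical caps).

Conventions
-----------
* Contour vertices are in µm, ``y`` increasing upward, counterclockwise
  after normalization.
* Binary masks are 0/1 arrays with pixel centers at half-integer physical
  coordinates: pixel ``[i, j]`` has its center at
  ``x = (j + 0.5) * pixel_size``, ``y = (i + 0.5) * pixel_size`` with row 0
  at the *bottom* of the scene.
* The iso-contour of a mask is taken at level 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter
from shapely.geometry import LineString, MultiLineString, Point, Polygon
from shapely.geometry.polygon import orient
from skimage import measure


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CellContour:
    """Closed simple polygon outlining one cell, vertices in µm (CCW)."""

    vertices: np.ndarray  # (n, 2) float array, first vertex not repeated

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ValueError("vertices must be an (n, 2) array")
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        if len(v) < 16:
            raise ValueError(f"contour needs >= 16 vertices, got {len(v)}")
        poly = Polygon(v)
        if not poly.is_valid:
            raise ValueError("contour polygon is self-intersecting or degenerate")
        # normalize to counterclockwise
        poly = orient(poly, sign=1.0)
        v = np.asarray(poly.exterior.coords)[:-1]
        object.__setattr__(self, "vertices", v)

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        """Projected (shoelace) area in µm²."""
        return self.polygon.area

    @property
    def perimeter(self) -> float:
        return self.polygon.length

    def transformed(self, *, rotation: float = 0.0, translation=(0.0, 0.0),
                    scale: float = 1.0) -> "CellContour":
        """Rigidly move and/or uniformly scale the contour (radians, µm)."""
        c, s = np.cos(rotation), np.sin(rotation)
        R = np.array([[c, -s], [s, c]])
        v = scale * (self.vertices @ R.T) + np.asarray(translation, float)
        return CellContour(v)


@dataclass
class CenterlineMesh:
    """Centerline stations of a rod-shaped cell.

    ``points`` run pole to pole; ``widths[i]`` is the rib length at station
    ``i`` (zero-ish at the extreme pole stations); ``arclength`` is the
    cumulative centerline arclength starting at 0.
    """

    points: np.ndarray          # (n, 2) µm
    widths: np.ndarray          # (n,) µm
    arclength: np.ndarray       # (n,) µm, strictly increasing
    is_pole: np.ndarray         # (n,) bool
    cell_length: float          # µm, == arclength[-1]
    mean_width: float           # µm, mean over non-pole stations
    is_round: bool = False      # True when aspect ratio < 1.5 (no widths)

    def nonpole_widths(self) -> np.ndarray:
        return self.widths[~self.is_pole]


@dataclass(frozen=True)
class SurfaceAreas:
    """Projected area ``a``, perimeter ``s`` and area of revolution."""

    projected_area: float   # a, µm²
    perimeter: float        # s, µm
    area_of_revolution: float  # A_turgid, µm²


class ContourError(ValueError):
    """Raised for masks or contours the pipeline cannot interpret."""


# --------------------------------------------------------------------------
# mask -> contour
# --------------------------------------------------------------------------

def extract_contour(mask: np.ndarray, pixel_size: float) -> CellContour:
    """Extract the sub-pixel 0.5-level contour of a single-cell binary mask.

    Parameters
    ----------
    mask
        2-D 0/1 (or boolean) array containing exactly one 4-connected
        foreground component of at least 50 px, not touching the border.
    pixel_size
        Physical pixel edge length in µm.

    Returns
    -------
    CellContour in µm, y increasing upward, CCW.
    """
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ContourError("mask must be 2-D")
    fg = m > 0
    if not fg.any():
        raise ContourError("mask is empty: no foreground component")
    labels, n_comp = measure.label(fg, connectivity=1, return_num=True)
    if n_comp != 1:
        raise ContourError(f"mask has {n_comp} foreground components, expected 1")
    if fg.sum() < 50:
        raise ContourError(f"foreground too small ({int(fg.sum())} px < 50 px)")
    if fg[0, :].any() or fg[-1, :].any() or fg[:, 0].any() or fg[:, -1].any():
        raise ContourError("cell touches the image border (truncated cell)")

    contours = measure.find_contours(fg.astype(float), 0.5)
    # keep the longest closed contour (holes, if any, are shorter)
    contours = [c for c in contours if np.allclose(c[0], c[-1])]
    if not contours:
        raise ContourError("no closed iso-contour found")
    rc = max(contours, key=len)
    rows, cols = rc[:, 0], rc[:, 1]
    x = (cols + 0.5) * pixel_size
    y = (rows + 0.5) * pixel_size  # row 0 at the bottom, y up
    return CellContour(np.column_stack([x, y]))


def render_mask(contour: CellContour, pixel_size: float, pad: int = 5) -> np.ndarray:
    """Rasterize a contour to a 0/1 mask at the stated pixel size.

    A pixel is foreground when its center lies inside the polygon; this is
    the inverse convention of :func:`extract_contour`.  Returns an array with
    row 0 at the bottom (y up).
    """
    v = contour.vertices
    xmin, ymin = v.min(axis=0)
    ox = xmin - pad * pixel_size
    oy = ymin - pad * pixel_size
    vx = v[:, 0] - ox
    vy = v[:, 1] - oy
    ncols = int(np.ceil(vx.max() / pixel_size)) + pad + 1
    nrows = int(np.ceil(vy.max() / pixel_size)) + pad + 1
    jj, ii = np.meshgrid(np.arange(ncols), np.arange(nrows))
    cx = (jj + 0.5) * pixel_size
    cy = (ii + 0.5) * pixel_size
    # point-in-polygon via shapely is slow per point; even-odd rule vectorized
    inside = _points_in_polygon(np.column_stack([cx.ravel(), cy.ravel()]),
                                np.column_stack([vx, vy]))
    return inside.reshape(nrows, ncols).astype(np.uint8)


def _points_in_polygon(pts: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Vectorized even-odd point-in-polygon test."""
    x, y = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    n = len(poly)
    px, py = poly[:, 0], poly[:, 1]
    for i in range(n):
        j = (i - 1) % n
        cond = (py[i] > y) != (py[j] > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = (px[j] - px[i]) * (y - py[i]) / (py[j] - py[i]) + px[i]
        inside ^= cond & (x < xint)
    return inside


# --------------------------------------------------------------------------
# centerline meshing
# --------------------------------------------------------------------------

def _principal_axis(v: np.ndarray) -> np.ndarray:
    c = v.mean(axis=0)
    u, _, vt = np.linalg.svd(v - c, full_matrices=False)
    return vt[0]


def _resample_polyline(pts: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    target = np.linspace(0.0, s[-1], n)
    return np.column_stack([np.interp(target, s, pts[:, 0]),
                            np.interp(target, s, pts[:, 1])])


def _rib(poly: Polygon, point: np.ndarray, normal: np.ndarray,
         half_len: float):
    """Chord of `poly` through `point` along `normal`; returns (width, midpoint)."""
    a = point - half_len * normal
    b = point + half_len * normal
    inter = poly.intersection(LineString([a, b]))
    if inter.is_empty:
        return 0.0, point
    pieces = []
    if isinstance(inter, LineString):
        pieces = [inter]
    elif isinstance(inter, MultiLineString):
        pieces = list(inter.geoms)
    else:  # GeometryCollection: keep line pieces
        pieces = [g for g in getattr(inter, "geoms", []) if isinstance(g, LineString)]
    if not pieces:
        return 0.0, point
    p = Point(point)
    piece = min(pieces, key=lambda g: g.distance(p))
    coords = np.asarray(piece.coords)
    width = float(piece.length)
    mid = 0.5 * (coords[0] + coords[-1])
    return width, mid


def _extend_to_boundary(poly: Polygon, p: np.ndarray, direction: np.ndarray,
                        reach: float) -> np.ndarray:
    """First boundary crossing of the ray p + t*direction, t in (0, reach]."""
    ray = LineString([p, p + reach * direction])
    inter = poly.exterior.intersection(ray)
    if inter.is_empty:
        return p
    pts = []
    for g in getattr(inter, "geoms", [inter]):
        if isinstance(g, Point):
            pts.append([g.x, g.y])
        else:
            pts.extend(np.asarray(g.coords))
    pts = np.asarray(pts, float)
    d = np.linalg.norm(pts - p, axis=1)
    keep = d > 1e-9
    if not keep.any():
        return p
    return pts[np.where(keep, d, np.inf).argmin()]


def _smooth_polyline(pts: np.ndarray) -> np.ndarray:
    n = len(pts)
    win = max(5, (n // 5) | 1)  # odd window, ~20 % of stations
    if win >= n:
        win = n - 1 if (n - 1) % 2 == 1 else n - 2
    if win < 5:
        return pts
    return np.column_stack([savgol_filter(pts[:, 0], win, 2),
                            savgol_filter(pts[:, 1], win, 2)])


def mesh_contour(contour: CellContour, n_stations: int = 50,
                 max_iter: int = 20, tol_frac: float = 1e-3) -> CenterlineMesh:
    """Compute the pole-to-pole centerline mesh of a rod-shaped contour.

    The centerline starts as the principal-axis chord through the centroid
    and is refined by iterating "perpendicular rib midpoints -> smoothed
    polyline" until the maximum station movement drops below ``tol_frac``
    of the mean width (at most ``max_iter`` sweeps).  Stations are equally
    spaced in centerline arclength; a station is flagged as a pole when it
    lies within half a mean width of either cell end (the two extreme
    stations are always flagged).

    Cells with measured aspect ratio below 1.5 are returned flagged round,
    with no usable width profile.
    """
    if n_stations < 5:
        raise ValueError("n_stations must be >= 5")
    poly = contour.polygon
    if not poly.is_valid:
        raise ContourError("self-intersecting contour")
    v = contour.vertices
    diag = float(np.linalg.norm(v.max(axis=0) - v.min(axis=0)))
    axis = _principal_axis(v)
    centroid = np.asarray([poly.centroid.x, poly.centroid.y])

    # initial chord along the principal axis
    w0, mid0 = _rib(poly, centroid, axis, diag)
    if w0 <= 0:
        raise ContourError("cannot seed centerline through centroid")
    chord = LineString([centroid - diag * axis, centroid + diag * axis])
    seed = poly.intersection(chord)
    if isinstance(seed, MultiLineString):
        seed = min(seed.geoms, key=lambda g: g.distance(Point(centroid)))
    center = _resample_polyline(np.asarray(seed.coords), n_stations)

    rough_width = poly.area / max(seed.length, 1e-9)
    for _ in range(max_iter):
        tangents = np.gradient(center, axis=0)
        tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
        normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
        mids = center.copy()
        for i in range(1, n_stations - 1):
            _, mids[i] = _rib(poly, center[i], normals[i], diag)
        mids[1:-1] = _smooth_polyline(mids[1:-1])
        # re-extend the interior polyline to the poles along end tangents
        t0 = mids[1] - mids[2]
        t0 /= max(np.linalg.norm(t0), 1e-12)
        t1 = mids[-2] - mids[-3]
        t1 /= max(np.linalg.norm(t1), 1e-12)
        mids[0] = _extend_to_boundary(poly, mids[1], t0, diag)
        mids[-1] = _extend_to_boundary(poly, mids[-2], t1, diag)
        new_center = _resample_polyline(mids, n_stations)
        move = float(np.max(np.linalg.norm(new_center - center, axis=1)))
        center = new_center
        if move < tol_frac * rough_width:
            break

    # final widths at the converged stations
    tangents = np.gradient(center, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    widths = np.zeros(n_stations)
    for i in range(n_stations):
        widths[i], _ = _rib(poly, center[i], normals[i], diag)

    seg = np.linalg.norm(np.diff(center, axis=0), axis=1)
    arclength = np.concatenate([[0.0], np.cumsum(seg)])
    cell_length = float(arclength[-1])

    # provisional mean width from the central half of the cell
    central = (arclength > 0.25 * cell_length) & (arclength < 0.75 * cell_length)
    mean_w = float(widths[central].mean()) if central.any() else float(np.median(widths))

    is_pole = (arclength < mean_w / 2) | (arclength > cell_length - mean_w / 2)
    is_pole[0] = is_pole[-1] = True  # extreme stations always excluded

    nonpole = widths[~is_pole]
    mean_width = float(nonpole.mean()) if nonpole.size else mean_w
    is_round = cell_length / max(mean_width, 1e-12) < 1.5

    return CenterlineMesh(points=center, widths=widths, arclength=arclength,
                          is_pole=is_pole, cell_length=cell_length,
                          mean_width=mean_width, is_round=is_round)


# --------------------------------------------------------------------------
# surface areas
# --------------------------------------------------------------------------

def surface_areas(contour: CellContour, mesh: CenterlineMesh,
                  n_fine: int = 400) -> SurfaceAreas:
    """Projected area, perimeter, and surface of revolution about the centerline.

    ``A_turgid`` is the lateral area of the stack of conical frustums defined
    by the local half-width profile along the centerline, resampled at
    ``n_fine`` stations so that the hemispherical poles are well resolved.
    For a spherocylinder of length ``l`` and width ``w`` this converges to
    ``pi*w*l``.
    """
    if mesh.is_round:
        raise ContourError("round cell: no width profile to revolve")
    poly = contour.polygon
    diag = float(np.linalg.norm(contour.vertices.max(axis=0) -
                                contour.vertices.min(axis=0)))
    center = _resample_polyline(mesh.points, n_fine)
    tangents = np.gradient(center, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    normals = np.column_stack([-tangents[:, 1], tangents[:, 0]])
    r = np.empty(n_fine)
    for i in range(n_fine):
        w, _ = _rib(poly, center[i], normals[i], diag)
        r[i] = 0.5 * w
    r[0] = r[-1] = 0.0  # poles close the surface
    seg = np.linalg.norm(np.diff(center, axis=0), axis=1)
    slant = np.sqrt(seg ** 2 + np.diff(r) ** 2)
    area_rev = float(np.sum(np.pi * (r[:-1] + r[1:]) * slant))
    return SurfaceAreas(projected_area=poly.area, perimeter=poly.length,
                        area_of_revolution=area_rev)
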