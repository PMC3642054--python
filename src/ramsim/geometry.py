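"""Root-tip domain and bounded Voronoi tessellation.

The simulated tissue is a two-dimensional longitudinal section of the root
tip: a rectangle capped below by a parabolic tip.  Fixed generating points
sampled along this outline stand for the epidermal/root-cap cells that
constrain the ground tissue; mobile generating points in the interior stand
for the meristematic cells.  Each cell is the Voronoi region of its
generating point, clipped to the domain outline.

Coordinate convention: the parabola vertex (the apex of the root) sits at
``(0, apex_y)`` and y increases from the apex toward the base of the plant,
so "distance from the tip" is simply ``y - apex_y``.  The top edge of the
rectangle is the only part of the outline that moves: it is translated
upward to make room for newly divided cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import shapely
from scipy.spatial import Voronoi, cKDTree
from shapely.geometry import LineString, Polygon


class GeometryError(ValueError):
    """Raised for degenerate or inconsistent tessellation input."""


# --------------------------------------------------------------------------
# domain
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Domain:
    """The fixed outline of the root-tip section.

    Parameters
    ----------
    width : float
        Transverse extent of the root section (µm).
    tip_depth : float
        Depth of the parabolic cap below the rectangular part (µm).
    rect_height : float
        Initial height of the rectangular part (µm); the *current* height is
        ``top_y - (apex_y + tip_depth)`` and grows during a run.
    boundary_spacing : float
        Approximate arc-length spacing of the fixed boundary generators (µm).
    apex_y : float
        y coordinate of the parabola vertex (µm).  Fixed for a whole run.
    top_y : float
        y coordinate of the (mobile) upper edge (µm).  Non-decreasing.
    """

    width: float
    tip_depth: float
    rect_height: float
    boundary_spacing: float
    apex_y: float = 0.0
    top_y: float = field(default=None)  # type: ignore[assignment]
    _tip_points: np.ndarray = field(default=None, repr=False, compare=False)  # type: ignore[assignment]

    def __post_init__(self):
        for name in ("width", "tip_depth", "rect_height", "boundary_spacing"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.top_y is None:
            object.__setattr__(
                self, "top_y", self.apex_y + self.tip_depth + self.rect_height
            )
        if self._tip_points is None:
            object.__setattr__(self, "_tip_points", self._sample_tip())

    # -- outline construction -------------------------------------------------

    def _sample_tip(self) -> np.ndarray:
        """Sample the parabolic cap at ~boundary_spacing arc-length intervals.

        The parabola is ``y = apex_y + tip_depth * (2x/width)**2`` for
        ``|x| <= width/2``; its shape is fixed for the lifetime of a run.
        """
        w, d = self.width, self.tip_depth
        # dense polyline, then resample by cumulative arc length
        x = np.linspace(-w / 2, w / 2, 512)
        y = self.apex_y + d * (2 * x / w) ** 2
        seg = np.hypot(np.diff(x), np.diff(y))
        s = np.concatenate([[0.0], np.cumsum(seg)])
        n = max(int(round(s[-1] / self.boundary_spacing)), 4)
        si = np.linspace(0, s[-1], n + 1)
        return np.column_stack([np.interp(si, s, x), np.interp(si, s, y)])

    def _cache(self, key, builder):
        # frozen dataclass: lazy derived geometry lives in a plain dict
        store = self.__dict__.setdefault("_derived", {})
        if key not in store:
            store[key] = builder()
        return store[key]

    def boundary_points(self) -> np.ndarray:
        """All fixed boundary generators for the current ``top_y``.

        The parabolic-cap points never move.  Side points sit on a fixed
        vertical grid and are appended as the domain extends; top-edge points
        translate rigidly with ``top_y``.
        """
        return self._cache("bpts", self._boundary_points)

    def _boundary_points(self) -> np.ndarray:
        w, s = self.width, self.boundary_spacing
        y_base = self.apex_y + self.tip_depth
        # fixed side grids (new points appear as top_y grows, old ones stay)
        ys = np.arange(y_base + s, self.top_y - 0.5 * s, s)
        left = np.column_stack([np.full_like(ys, -w / 2), ys])
        right = np.column_stack([np.full_like(ys, w / 2), ys])
        # translating top row
        n_top = max(int(round(w / s)), 2)
        xt = np.linspace(-w / 2, w / 2, n_top + 1)
        top = np.column_stack([xt, np.full_like(xt, self.top_y)])
        return np.vstack([self._tip_points, right, top[::-1], left[::-1]])

    def polygon(self) -> Polygon:
        """The domain outline as a (convex) shapely polygon."""

        def build():
            w = self.width
            ring = np.vstack(
                [self._tip_points, [[w / 2, self.top_y], [-w / 2, self.top_y]]]
            )
            poly = Polygon(ring)
            shapely.prepare(poly)
            return poly

        return self._cache("polygon", build)

    @property
    def area(self) -> float:
        return self._cache("area", lambda: self.polygon().area)

    def contains(self, points: np.ndarray, *, margin: float = 0.0) -> np.ndarray:
        """Vectorized strict point-in-domain test (optionally shrunk by margin)."""
        pts = np.atleast_2d(points)
        if margin == 0.0:
            poly = self.polygon()
        else:
            poly = self.polygon().buffer(-margin)
        return shapely.contains_xy(poly, pts[:, 0], pts[:, 1])


def build_domain(
    n_interior: int,
    width: float,
    rect_height: float,
    tip_depth: float,
    boundary_spacing: float,
    rng_seed: int | np.random.Generator = 0,
    *,
    max_tries: int = 10_000,
) -> tuple[Domain, np.ndarray]:
    """Construct the root-tip domain and uniform-random interior generators.

    Interior points are rejection-sampled uniformly over the domain, kept
    only if they lie strictly inside with a half-spacing margin from the
    outline (so that every mobile cell is shielded from the boundary by an
    epidermal cell).

    Returns the :class:`Domain` and an ``(n_interior, 2)`` coordinate array.
    """
    if n_interior < 1:
        raise GeometryError("n_interior must be >= 1")
    domain = Domain(width, tip_depth, rect_height, boundary_spacing)
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    margin = 0.75 * boundary_spacing
    lo = np.array([-width / 2, domain.apex_y])
    hi = np.array([width / 2, domain.top_y])
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n_interior:
        if tries >= max_tries:
            raise GeometryError(
                f"rejection sampling failed after {max_tries} tries; "
                "geometry too thin for the requested boundary_spacing"
            )
        cand = rng.uniform(lo, hi, size=(n_interior, 2))
        ok = domain.contains(cand, margin=margin)
        for p in cand[ok]:
            if len(pts) < n_interior:
                pts.append(p)
        tries += n_interior
    return domain, np.asarray(pts)


def extend_domain(domain: Domain, added_area: float) -> Domain:
    """Shift the upper edge upward so the outline area grows by ``added_area``.

    The top edge is straight and spans the full width, so the shift is
    exactly ``added_area / width``; all other boundary points are untouched.
    """
    if added_area < 0:
        raise GeometryError("added_area must be >= 0")
    if added_area == 0:
        return domain
    return replace(domain, top_y=domain.top_y + added_area / domain.width)


# --------------------------------------------------------------------------
# tessellation
# --------------------------------------------------------------------------

@dataclass
class Tessellation:
    """Geometry of the current cell packing (interior cells only).

    Interior cells are indexed 0..n-1 in the order of the generator array.
    Edge arrays describe every Voronoi ridge touching at least one interior
    cell; ``edge_cells`` holds interior indices, with -1 marking the cell of
    a fixed boundary generator (geometrically present, dynamically inert).
    """

    generators: np.ndarray          # (n, 2) interior generating points
    areas: np.ndarray               # (n,) polygon areas A_i
    centroids: np.ndarray           # (n, 2) polygon centers of mass c_i
    mean_area: float                # Ā = domain area / n (equilibrium share)
    edge_cells: np.ndarray          # (E, 2) int, interior index or -1
    edge_gen: np.ndarray            # (E, 2, 2) generator coords of both sides
    edge_v1: np.ndarray             # (E, 2) ridge segment endpoints
    edge_v2: np.ndarray             # (E, 2)
    edge_lengths: np.ndarray        # (E,) shared-wall lengths L_ij
    surface: np.ndarray             # (n,) bool, cell touches the epidermis
    polygons: list[np.ndarray]      # per-cell vertex arrays (CCW)

    @property
    def n_cells(self) -> int:
        return len(self.areas)

    def adjacency(self) -> set[tuple[int, int]]:
        """Unordered interior-interior neighbor pairs (i < j), counted once."""
        ii = self.edge_cells[(self.edge_cells >= 0).all(axis=1)]
        return {(int(min(a, b)), int(max(a, b))) for a, b in ii}

    def interior_edges(self) -> np.ndarray:
        """Mask of edges between two interior cells."""
        return (self.edge_cells >= 0).all(axis=1)


def _polygon_area_centroid(verts: np.ndarray) -> tuple[float, np.ndarray]:
    x, y = verts[:, 0], verts[:, 1]
    xr = np.concatenate([x[1:], x[:1]])
    yr = np.concatenate([y[1:], y[:1]])
    cross = x * yr - xr * y
    a = 0.5 * cross.sum()
    if abs(a) < 1e-300:
        return 0.0, verts.mean(axis=0)
    cx = ((x + xr) * cross).sum() / (6 * a)
    cy = ((y + yr) * cross).sum() / (6 * a)
    return abs(a), np.array([cx, cy])


def min_separation(mean_area: float) -> float:
    """Smallest allowed generator separation (guards Delaunay degeneracy)."""
    return 1e-3 * np.sqrt(mean_area)


def tessellate(domain: Domain, generators: np.ndarray) -> Tessellation:
    """Voronoi-tessellate the domain for the given interior generators.

    Fixed boundary generators are appended automatically; their (infinite)
    regions are clipped implicitly by simply not being represented — only
    interior cells carry geometry and dynamics.  Interior regions that poke
    outside the outline (rare, near the sampled parabola) are clipped to it.
    """
    generators = np.asarray(generators, dtype=float)
    if generators.ndim != 2 or generators.shape[1] != 2:
        raise GeometryError("generators must be an (n, 2) array")
    n = len(generators)
    bpts = domain.boundary_points()
    mean_area = domain.area / n

    inside = domain.contains(generators)
    if not inside.all():
        bad = np.flatnonzero(~inside)
        raise GeometryError(f"generators outside the domain: indices {bad.tolist()}")
    eps = min_separation(mean_area)
    all_pts = np.vstack([bpts, generators])
    tree = cKDTree(all_pts)
    pairs = tree.query_pairs(eps, output_type="ndarray")
    if len(pairs):
        a, b = pairs[0]
        raise GeometryError(
            f"coincident generators (separation < {eps:.3g}): "
            f"points {int(a)} and {int(b)} of the combined set"
        )

    nb = len(bpts)
    vor = Voronoi(all_pts)
    poly = domain.polygon()

    # --- per-cell polygons ---------------------------------------------------
    areas = np.empty(n)
    centroids = np.empty((n, 2))
    polygons: list[np.ndarray] = []
    clipped = np.zeros(n, dtype=bool)
    vert_inside = shapely.contains_xy(
        poly, vor.vertices[:, 0], vor.vertices[:, 1]
    )
    for i in range(n):
        region = vor.regions[vor.point_region[nb + i]]
        if -1 in region or len(region) < 3:
            raise GeometryError(
                f"interior generator {i} has an unbounded region; "
                "boundary sampling too sparse"
            )
        verts = vor.vertices[region]
        if not vert_inside[region].all():
            clip = Polygon(verts).buffer(0).intersection(poly)
            if clip.is_empty or clip.geom_type != "Polygon":
                raise GeometryError(f"degenerate clipped cell for generator {i}")
            verts = np.asarray(clip.exterior.coords)[:-1]
            clipped[i] = True
        a, c = _polygon_area_centroid(verts)
        areas[i] = a
        centroids[i] = c
        polygons.append(verts)

    # --- edges ----------------------------------------------------------------
    rp = np.asarray(vor.ridge_points)
    rv = np.asarray(vor.ridge_vertices)
    touch = (rp >= nb).any(axis=1)
    finite = (rv >= 0).all(axis=1)
    keep = touch & finite
    cells = np.where(rp[keep] >= nb, rp[keep] - nb, -1)
    edge_gen = all_pts[rp[keep]]
    v1 = vor.vertices[rv[keep, 0]]
    v2 = vor.vertices[rv[keep, 1]]
    # clip ridge segments of clipped cells so walls match the cell outlines
    needs = clipped[np.clip(cells, 0, None)].any(axis=1) & (
        ~vert_inside[rv[keep, 0]] | ~vert_inside[rv[keep, 1]]
    )
    for k in np.flatnonzero(needs):
        seg = LineString([v1[k], v2[k]]).intersection(poly)
        if seg.is_empty or seg.geom_type != "LineString":
            v2[k] = v1[k]
            continue
        coords = np.asarray(seg.coords)
        v1[k], v2[k] = coords[0], coords[-1]
    lengths = np.hypot(*(v2 - v1).T)
    ok = lengths > 1e-12
    cells, edge_gen, v1, v2, lengths = (
        cells[ok], edge_gen[ok], v1[ok], v2[ok], lengths[ok],
    )

    surface = np.zeros(n, dtype=bool)
    bmask = (cells < 0).any(axis=1)
    surface[cells[bmask].max(axis=1)] = True

    return Tessellation(
        generators=generators,
        areas=areas,
        centroids=centroids,
        mean_area=mean_area,
        edge_cells=cells,
        edge_gen=edge_gen,
        edge_v1=v1,
        edge_v2=v2,
        edge_lengths=lengths,
        surface=surface,
        polygons=polygons,
    )
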