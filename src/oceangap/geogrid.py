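"""Spatial frames: equal-area hexagonal global grid, 5° bands, depth zones.

The hexagonal grid is an icosahedral, aperture-4 discrete global grid.  Each
icosahedron face is mapped to a planar equilateral triangle by an equal-area
projection of the Snyder type (cumulative sector areas on the sphere are
matched to cumulative sector areas in the plane, so the map is exactly
area-preserving).  The plane is tiled with the hexagonal Voronoi cells of an
aperture-4 triangular lattice (edge subdivided into 2**resolution parts), and
cell fragments are projected back to the sphere and merged across faces.
Because the tiling is exact in an equal-area plane, hexagon areas are exactly
equal, the 12 pentagon cells (at icosahedron vertices) have exactly 5/6 of the
hexagon area, and cell areas sum to exactly 4*pi*R**2.

Cell count follows the aperture-4 law 10 * 4**resolution + 2; resolution 3
gives 642 cells of ~7.9e5 km², matching the ~800,000 km² analysis cells used
for global marine biodiversity binning.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .rasters import EARTH_RADIUS_KM, Raster, cell_areas_km2

__all__ = [
    "GridCell", "HexGrid", "build_grid", "assign_cell",
    "assign_band", "band_bounds", "band_centers",
    "DEPTH_ZONES", "assign_depth_zone",
    "aggregate_covariates", "gap_summary",
]

_SIXTY = math.pi / 3.0
_G = math.radians(36.0)  # spherical angle between center->vertex and the face edge, at a vertex


# ---------------------------------------------------------------------------
# icosahedron with a vertex at the north pole

def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    """Unit vertices (12, 3) and CCW-from-outside faces (20, 3)."""
    lat_up = math.atan(0.5)
    verts = [(0.0, 0.0, 1.0)]
    for k in range(5):
        lon = math.radians(72.0 * k)
        verts.append((math.cos(lat_up) * math.cos(lon),
                      math.cos(lat_up) * math.sin(lon),
                      math.sin(lat_up)))
    for k in range(5):
        lon = math.radians(72.0 * k + 36.0)
        verts.append((math.cos(lat_up) * math.cos(lon),
                      math.cos(lat_up) * math.sin(lon),
                      -math.sin(lat_up)))
    verts.append((0.0, 0.0, -1.0))
    v = np.array(verts)

    faces = []
    for k in range(5):
        kn = (k + 1) % 5
        faces.append((0, 1 + k, 1 + kn))                  # polar cap, north
        faces.append((1 + k, 6 + k, 1 + kn))              # upper middle
        faces.append((1 + kn, 6 + k, 6 + kn))             # lower middle
        faces.append((6 + k, 11, 6 + kn))                 # polar cap, south
    f = np.array(faces)
    # orient CCW seen from outside: normal of (a,b,c) points outward
    for i, (a, b, c) in enumerate(f):
        n = np.cross(v[b] - v[a], v[c] - v[a])
        if np.dot(n, v[a] + v[b] + v[c]) < 0:
            f[i] = (a, c, b)
    return v, f


class _Face:
    """One icosahedron face with its equal-area map to a planar triangle.

    The planar triangle is centred at the origin with circumradius 1 and its
    three vertices at planar angles 0°, 120°, 240°, matching the spherical
    azimuths (about the face centre) of the corresponding icosahedron
    vertices.
    """

    # planar geometry: circumradius 1, inradius 1/2
    R_IN = 0.5
    TRI_AREA = 3.0 * math.sqrt(3.0) / 4.0
    SECTOR_AREA = (R_IN ** 2 / 2.0) * math.tan(_SIXTY)   # one of 6 sectors

    def __init__(self, verts: np.ndarray):
        self.v = verts                      # (3, 3) unit vectors, CCW outside
        c = verts.sum(axis=0)
        self.c = c / np.linalg.norm(c)
        ex = verts[0] - np.dot(verts[0], self.c) * self.c
        self.ex = ex / np.linalg.norm(ex)
        self.ey = np.cross(self.c, self.ex)
        # ensure vertex order follows azimuth 0, 120, 240 in this frame
        az1 = self._azimuth(verts[1])
        if not (1.5 < az1 < 2.7):           # ~120 deg
            self.v = verts[[0, 2, 1]]
            az1 = self._azimuth(self.v[1])
        assert abs(az1 - 2 * _SIXTY) < 1e-9
        self.cos_g = float(np.dot(self.c, self.v[0]))
        # spherical area of one of the 6 symmetric sectors (should be pi/30)
        self.sector_sph = self._excess(_SIXTY)
        self.scale = self.SECTOR_AREA / self.sector_sph    # planar area per steradian
        self.A2 = np.array([1.0, 0.0])
        self.B2 = np.array([math.cos(2 * _SIXTY), math.sin(2 * _SIXTY)])
        self.C2 = np.array([math.cos(4 * _SIXTY), math.sin(4 * _SIXTY)])

    def _azimuth(self, p: np.ndarray) -> float:
        t = p - np.dot(p, self.c) * self.c
        return math.atan2(np.dot(t, self.ey), np.dot(t, self.ex)) % (2 * math.pi)

    # --- sector geometry -------------------------------------------------
    def _H(self, a: float) -> float:
        u = math.sin(a) * math.sin(_G) * self.cos_g - math.cos(a) * math.cos(_G)
        return math.acos(max(-1.0, min(1.0, u)))

    def _excess(self, a: float) -> float:
        """Spherical area between azimuth 0 and a, bounded by the face edge."""
        return a + _G + self._H(a) - math.pi

    def _z_edge(self, a: float) -> float:
        """Angular distance from face centre to the edge along azimuth a."""
        sin_g = math.sqrt(max(0.0, 1.0 - self.cos_g ** 2))
        return math.asin(min(1.0, math.sin(_G) * sin_g / math.sin(self._H(a))))

    @staticmethod
    def _ell(beta: float) -> float:
        """Planar distance from centre to triangle edge along azimuth beta."""
        return _Face.R_IN / math.cos(_SIXTY - beta)

    def _beta_of_a(self, a: float) -> float:
        """Planar sector azimuth matching cumulative area up to azimuth a."""
        t = math.tan(_SIXTY) - 2.0 * self.scale * self._excess(a) / self.R_IN ** 2
        return _SIXTY - math.atan(t)

    def _a_of_beta(self, beta: float) -> float:
        target = (self.R_IN ** 2 / 2.0) * (math.tan(_SIXTY) - math.tan(_SIXTY - beta)) / self.scale
        if target <= 0.0:
            return 0.0
        if target >= self.sector_sph:
            return _SIXTY
        return brentq(lambda a: self._excess(a) - target, 0.0, _SIXTY, xtol=1e-14)

    # --- forward / inverse ------------------------------------------------
    def forward(self, p: np.ndarray) -> np.ndarray:
        """Sphere point (unit vector on this face) -> planar (x, y)."""
        return self.forward_many(np.asarray(p, dtype=float).reshape(1, 3))[0]

    def forward_many(self, pts: np.ndarray) -> np.ndarray:
        """Vectorized forward projection of (n, 3) unit vectors."""
        cz = np.clip(pts @ self.c, -1.0, 1.0)
        t = pts - np.outer(cz, self.c)
        az = np.arctan2(t @ self.ey, t @ self.ex) % (2 * math.pi)
        k = np.minimum((az / _SIXTY).astype(int), 5)
        a = az - k * _SIXTY
        odd = (k % 2) == 1
        a = np.where(odd, _SIXTY - a, a)
        E = a + _G + np.arccos(np.clip(
            np.sin(a) * math.sin(_G) * self.cos_g - np.cos(a) * math.cos(_G), -1, 1)) - math.pi
        beta = _SIXTY - np.arctan(math.tan(_SIXTY) - 2.0 * self.scale * E / self.R_IN ** 2)
        sin_g = math.sqrt(max(0.0, 1.0 - self.cos_g ** 2))
        H = np.arccos(np.clip(np.sin(a) * math.sin(_G) * self.cos_g
                              - np.cos(a) * math.cos(_G), -1, 1))
        ze = np.arcsin(np.minimum(1.0, math.sin(_G) * sin_g / np.sin(H)))
        ell = self.R_IN / np.cos(_SIXTY - beta)
        with np.errstate(invalid="ignore"):
            rho = ell * np.sqrt(np.minimum(1.0, (1.0 - cz) / (1.0 - np.cos(ze))))
        rho = np.where(cz > 1.0 - 1e-15, 0.0, rho)
        theta = np.where(odd, (k + 1) * _SIXTY - beta, k * _SIXTY + beta)
        return np.stack([rho * np.cos(theta), rho * np.sin(theta)], axis=-1)

    def inverse(self, xy: np.ndarray) -> np.ndarray:
        """Planar (x, y) in the triangle -> unit vector on the sphere."""
        rho = math.hypot(xy[0], xy[1])
        if rho < 1e-12:
            return self.c.copy()
        theta = math.atan2(xy[1], xy[0]) % (2 * math.pi)
        k = min(int(theta / _SIXTY), 5)
        beta = theta - k * _SIXTY
        if k % 2 == 1:
            beta = _SIXTY - beta
        a = self._a_of_beta(beta)
        ze = self._z_edge(a)
        ratio = min(1.0, rho / self._ell(beta))
        cz = 1.0 - (1.0 - math.cos(ze)) * ratio ** 2
        z = math.acos(max(-1.0, min(1.0, cz)))
        az = k * _SIXTY + a if k % 2 == 0 else (k + 1) * _SIXTY - a
        d = math.cos(az) * self.ex + math.sin(az) * self.ey
        return math.cos(z) * self.c + math.sin(z) * d


# ---------------------------------------------------------------------------
# grid assembly

@dataclass
class GridCell:
    cell_id: int
    center: tuple[float, float]            # (lat, lon) degrees
    boundary: list[tuple[float, float]]    # closed ring, (lat, lon)
    area_km2: float
    is_pentagon: bool
    center_xyz: np.ndarray = field(repr=False, default=None)


@dataclass
class HexGrid:
    cells: list[GridCell]
    resolution: int
    earth_radius_km: float = EARTH_RADIUS_KM
    _tree: cKDTree = field(default=None, repr=False, compare=False)
    _faces: list = field(default=None, repr=False, compare=False)
    _id_grids: list = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self._tree is None:
            xyz = np.array([c.center_xyz for c in self.cells])
            self._tree = cKDTree(xyz)

    def __len__(self) -> int:
        return len(self.cells)

    def assign(self, lat, lon):
        """Cell id containing each point (nearest centre, great-circle)."""
        return assign_cell(self, lat, lon)

    def to_geojson(self, path: str | Path) -> None:
        feats = []
        for c in self.cells:
            ring = [[lon, lat] for lat, lon in c.boundary]
            feats.append({
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {"cell_id": c.cell_id, "area_km2": c.area_km2,
                               "is_pentagon": c.is_pentagon,
                               "center_lat": c.center[0], "center_lon": c.center[1]},
            })
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)


def _latlon(p: np.ndarray) -> tuple[float, float]:
    lat = math.degrees(math.asin(max(-1.0, min(1.0, p[2]))))
    lon = math.degrees(math.atan2(p[1], p[0]))
    if lon >= 180.0:
        lon -= 360.0
    return lat, lon


def _xyz(lat, lon) -> np.ndarray:
    la = np.deg2rad(np.asarray(lat, dtype=float))
    lo = np.deg2rad(np.asarray(lon, dtype=float))
    return np.stack([np.cos(la) * np.cos(lo), np.cos(la) * np.sin(lo), np.sin(la)], axis=-1)


def _on_tri_edge(a0, a1, tri, tol=1e-9) -> bool:
    """True when the segment a0-a1 lies on one of the triangle's edges."""
    for p, q in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
        e = q - p
        L = math.hypot(e[0], e[1])
        d0 = abs((a0[0] - p[0]) * e[1] - (a0[1] - p[1]) * e[0]) / L
        d1 = abs((a1[0] - p[0]) * e[1] - (a1[1] - p[1]) * e[0]) / L
        if d0 < tol and d1 < tol:
            return True
    return False


_GRID_CACHE: dict[tuple[int, float], HexGrid] = {}


def build_grid(resolution: int = 3, earth_radius_km: float = EARTH_RADIUS_KM) -> HexGrid:
    """Build the icosahedral aperture-4 hexagonal grid.

    resolution r yields 10*4**r + 2 cells; r=3 gives the 642-cell global
    analysis grid with mean cell area 4*pi*R^2/642 ~= 7.9e5 km².
    """
    if resolution < 0:
        raise ValueError("resolution must be >= 0")
    key = (resolution, earth_radius_km)
    if key in _GRID_CACHE:
        return _GRID_CACHE[key]

    verts, faces = _icosahedron()
    face_objs = [_Face(verts[list(f)]) for f in faces]
    n = 2 ** resolution
    hex_area_plane = 3.0 * math.sqrt(3.0) / (2.0 * n ** 2)
    km2_per_plane = (4.0 * math.pi * earth_radius_km ** 2 / 20.0) / _Face.TRI_AREA

    cells: dict[tuple, dict] = {}
    face_keys: list[dict] = []
    for face in face_objs:
        A, B, C = face.A2, face.B2, face.C2
        d1 = (B - A) / n
        d2 = (C - A) / n
        hex_offsets = [(d1 + d2) / 3.0, (2 * d2 - d1) / 3.0, (d2 - 2 * d1) / 3.0,
                       -(d1 + d2) / 3.0, (d1 - 2 * d2) / 3.0, (2 * d1 - d2) / 3.0]
        tri = Polygon([tuple(A), tuple(B), tuple(C)])
        keys: dict[tuple[int, int], tuple] = {}
        for i in range(n + 1):
            for j in range(n + 1 - i):
                P = A + i * d1 + j * d2
                hexagon = Polygon([tuple(P + o) for o in hex_offsets])
                frag = hexagon.intersection(tri)
                if frag.is_empty or frag.area <= 0:
                    continue
                center_sph = face.inverse(P)
                ckey = tuple(np.round(center_sph, 6))
                keys[(i, j)] = ckey
                entry = cells.setdefault(ckey, {"center": center_sph, "area": 0.0, "verts": []})
                entry["area"] += frag.area
                ring = np.asarray(frag.exterior.coords)[:-1]
                # densify true cell edges (straight in the equal-area plane,
                # curved on the sphere); chords lying on the face-triangle
                # boundary are cell-interior, keep only their endpoints
                dens = []
                for a0, a1 in zip(ring, np.roll(ring, -1, axis=0)):
                    dens.append(a0)
                    if not _on_tri_edge(a0, a1, (A, B, C)):
                        for s in (1.0 / 3.0, 2.0 / 3.0):
                            dens.append(a0 + s * (a1 - a0))
                for xy in dens:
                    entry["verts"].append(face.inverse(xy))
        face_keys.append(keys)

    expected = 10 * 4 ** resolution + 2
    if len(cells) != expected:
        raise RuntimeError(f"grid assembly produced {len(cells)} cells, expected {expected}")

    # deterministic ids: north to south, then east by longitude
    order = sorted(cells.values(),
                   key=lambda e: (-round(e["center"][2], 6),
                                  round(math.atan2(e["center"][1], e["center"][0]), 6)))
    out: list[GridCell] = []
    for cid, e in enumerate(order):
        center = e["center"]
        lat, lon = _latlon(center)
        # order boundary vertices by azimuth about the centre (cells are
        # star-shaped), dropping duplicates and the centre itself (a triangle
        # corner can appear as a fragment vertex on pentagon cells)
        ex = np.array([1.0, 0.0, 0.0]) if abs(center[2]) > 0.9 else np.array([0.0, 0.0, 1.0])
        ex = ex - np.dot(ex, center) * center
        ex /= np.linalg.norm(ex)
        ey = np.cross(center, ex)
        uniq: dict[tuple, tuple[float, np.ndarray]] = {}
        for p in e["verts"]:
            if np.dot(p, center) > 1.0 - 1e-12:     # the centre itself
                continue
            kk = tuple(np.round(p, 6))
            t = p - np.dot(p, center) * center
            uniq[kk] = (math.atan2(np.dot(t, ey), np.dot(t, ex)), p)
        ring = [pt for _, pt in sorted(uniq.values(), key=lambda q: q[0])]
        boundary = [_latlon(p) for p in ring]
        boundary.append(boundary[0])
        is_pent = e["area"] < 0.9 * hex_area_plane
        out.append(GridCell(cell_id=cid, center=(lat, lon), boundary=boundary,
                            area_km2=e["area"] * km2_per_plane,
                            is_pentagon=is_pent, center_xyz=center))

    n_pent = sum(c.is_pentagon for c in out)
    if n_pent != 12:
        raise RuntimeError(f"expected 12 pentagons, found {n_pent}")

    key2cid = {tuple(np.round(c.center_xyz, 6)): c.cell_id for c in out}
    id_grids = []
    for keys in face_keys:
        grid_ids = np.full((n + 1, n + 1), -1, dtype=np.int64)
        for (i, j), ckey in keys.items():
            grid_ids[i, j] = key2cid[ckey]
        id_grids.append(grid_ids)
    grid = HexGrid(cells=out, resolution=resolution, earth_radius_km=earth_radius_km,
                   _faces=face_objs, _id_grids=id_grids)
    _GRID_CACHE[key] = grid
    return grid


def assign_cell(grid: HexGrid, lat, lon):
    """Cell id of the cell containing each point.

    Exact by construction: the point is projected into its icosahedron
    face's equal-area plane, where the hexagonal cells are the Voronoi cells
    of the triangular lattice, so containment reduces to the nearest lattice
    point in the plane.  Points on cell edges go to the lattice point that
    compares nearest in floating point (ties are measure-zero).  Accepts
    scalars or arrays.
    """
    pts = _xyz(lat, lon)
    scalar = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if grid._faces is None:
        _, idx = grid._tree.query(pts)
        return int(idx[0]) if scalar else idx
    n = 2 ** grid.resolution
    centers = np.array([f.c for f in grid._faces])
    fidx = np.argmax(pts @ centers.T, axis=1)
    out = np.empty(pts.shape[0], dtype=np.int64)
    for f in np.unique(fidx):
        face = grid._faces[f]
        sel = fidx == f
        xy = face.forward_many(pts[sel])
        A = face.A2
        M = np.column_stack([(face.B2 - A) / n, (face.C2 - A) / n])
        fr = np.linalg.solve(M, (xy - A).T).T       # fractional lattice coords
        base = np.floor(fr).astype(int)
        best_d = np.full(fr.shape[0], np.inf)
        best_id = np.full(fr.shape[0], -1, dtype=np.int64)
        for di in (0, 1):
            for dj in (0, 1):
                i = np.clip(base[:, 0] + di, 0, n)
                j = np.clip(base[:, 1] + dj, 0, n)
                over = i + j > n                    # fold onto the triangle
                i = np.where(over, np.clip(n - j, 0, n), i)
                j = np.minimum(j, n - i)
                P = A + np.column_stack([i, j]) @ M.T
                d = np.sum((xy - P) ** 2, axis=1)
                better = d < best_d
                best_d = np.where(better, d, best_d)
                cand = grid._id_grids[f][i, j]
                best_id = np.where(better, cand, best_id)
        out[sel] = best_id
    return int(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# latitude bands and depth zones

N_BANDS = 36
BAND_WIDTH = 5.0


def assign_band(lat):
    """5° band index 0..35; half-open [lower, lower+5), lat=90 in top band."""
    lat = np.asarray(lat, dtype=float)
    if np.any((lat < -90) | (lat > 90)):
        raise ValueError("latitude outside [-90, 90]")
    idx = np.floor((lat + 90.0) / BAND_WIDTH).astype(int)
    idx = np.clip(idx, 0, N_BANDS - 1)
    return idx if idx.ndim else int(idx)


def band_bounds(index: int) -> tuple[float, float]:
    return (-90.0 + BAND_WIDTH * index, -90.0 + BAND_WIDTH * (index + 1))


def band_centers() -> np.ndarray:
    return -90.0 + BAND_WIDTH * (np.arange(N_BANDS) + 0.5)


#: depth zones in metres, half-open on the left-closed side; a record at
#: exactly 200 m is mesopelagic.  Records without depth go to "unknown" and
#: are excluded from depth-specific analyses.
DEPTH_ZONES = {"shallow": (0.0, 200.0), "mesopelagic": (200.0, 500.0), "deep": (500.0, 11000.0)}
MAX_DEPTH = 11000.0


def assign_depth_zone(depth):
    """Zone name for a depth in metres (scalar or array); NaN -> 'unknown'."""
    d = np.asarray(depth, dtype=float)
    if np.any(d[np.isfinite(d)] < 0):
        raise ValueError("depth must be >= 0")
    if np.any(d[np.isfinite(d)] > MAX_DEPTH):
        raise ValueError(f"depth exceeds {MAX_DEPTH} m domain")
    out = np.full(d.shape, "unknown", dtype=object)
    out[np.isfinite(d) & (d < 200.0)] = "shallow"
    out[np.isfinite(d) & (d >= 200.0) & (d < 500.0)] = "mesopelagic"
    out[np.isfinite(d) & (d >= 500.0)] = "deep"
    return out if out.ndim else str(out)


# ---------------------------------------------------------------------------
# covariate aggregation and gap accounting

SHELF_MAX_M = 140.0     # continental shelf: 0 to <=140 m
MARGIN_MAX_M = 3500.0   # continental margin: >140 to 3500 m


def aggregate_covariates(frame, bathymetry: Raster, layers: dict[str, Raster] | None = None,
                         radius_km: float = EARTH_RADIUS_KM) -> pd.DataFrame:
    """Aggregate bathymetric and environmental rasters per grid cell or band.

    ``frame`` is a :class:`HexGrid` (aggregate per hexagonal cell) or the
    string ``"bands"`` (per 5° latitudinal band).  Ocean cells are bathymetry
    cells with finite positive depth.  Per unit the table reports ocean area,
    continental-shelf area (depth 0 to <=140 m), continental-margin area
    (>140 to 3500 m), maximum depth, and area-weighted mean plus min/max of
    every supplied environmental layer (nodata cells excluded).
    """
    layers = layers or {}
    lat_c = bathymetry.lat_centers
    lon_c = bathymetry.lon_centers
    glon, glat = np.meshgrid(lon_c, lat_c)
    areas = cell_areas_km2(bathymetry, radius_km)
    depth = bathymetry.values
    ocean = np.isfinite(depth) & (depth > 0)

    if isinstance(frame, HexGrid):
        unit = assign_cell(frame, glat.ravel(), glon.ravel()).reshape(glat.shape)
        n_units = len(frame)
        index_name = "cell_id"
        centers = {c.cell_id: c.center for c in frame.cells}
    elif frame == "bands":
        unit = assign_band(glat)
        n_units = N_BANDS
        index_name = "band_index"
        centers = {i: (band_centers()[i], 0.0) for i in range(N_BANDS)}
    else:
        raise ValueError("frame must be a HexGrid or 'bands'")

    u = unit[ocean].ravel()
    a = areas[ocean].ravel()
    d = depth[ocean].ravel()

    def wsum(mask_vals, weights):
        return np.bincount(u, weights=np.where(mask_vals, weights, 0.0), minlength=n_units)

    tab = pd.DataFrame(index=pd.RangeIndex(n_units, name=index_name))
    tab["center_lat"] = [centers[i][0] for i in range(n_units)]
    tab["center_lon"] = [centers[i][1] for i in range(n_units)]
    tab["ocean_area_km2"] = np.bincount(u, weights=a, minlength=n_units)
    tab["shelf_area_km2"] = wsum(d <= SHELF_MAX_M, a)
    tab["margin_area_km2"] = wsum((d > SHELF_MAX_M) & (d <= MARGIN_MAX_M), a)
    maxd = np.full(n_units, -np.inf)
    np.maximum.at(maxd, u, np.where(np.isfinite(d), d, -np.inf))
    maxd[~np.isfinite(maxd)] = np.nan
    tab["max_depth_m"] = maxd

    for name, layer in layers.items():
        if (layer.values.shape != depth.shape or layer.resolution != bathymetry.resolution):
            raise ValueError(f"layer {name} does not match bathymetry grid")
        vals = layer.values[ocean].ravel()
        good = np.isfinite(vals)
        wa = np.bincount(u[good], weights=a[good], minlength=n_units)
        ws = np.bincount(u[good], weights=(a[good] * vals[good]), minlength=n_units)
        with np.errstate(invalid="ignore"):
            tab[f"{name}_mean"] = np.where(wa > 0, ws / np.where(wa > 0, wa, 1.0), np.nan)
        vmin = np.full(n_units, np.inf)
        vmax = np.full(n_units, -np.inf)
        np.minimum.at(vmin, u[good], vals[good])
        np.maximum.at(vmax, u[good], vals[good])
        vmin[~np.isfinite(vmin)] = np.nan
        vmax[~np.isfinite(vmax)] = np.nan
        tab[f"{name}_min"] = vmin
        tab[f"{name}_max"] = vmax
    return tab


def gap_summary(cell_summaries: pd.DataFrame, threshold: int = 50) -> pd.DataFrame:
    """Fraction of ocean area in under-sampled cells, per depth zone.

    ``cell_summaries`` must contain one row per (cell, depth_zone) with
    columns ``depth_zone``, ``n_records`` and ``ocean_area_km2`` — including
    zero-record cells.  A cell is a gap when it has fewer than ``threshold``
    records, mirroring the "<50 occurrence records per ~800,000 km²" rule.
    """
    need = {"depth_zone", "n_records", "ocean_area_km2"}
    if not need.issubset(cell_summaries.columns):
        raise ValueError(f"cell_summaries must have columns {sorted(need)}")
    rows = []
    for zone, sub in cell_summaries.groupby("depth_zone", sort=True):
        total = float(sub["ocean_area_km2"].sum())
        gap = float(sub.loc[sub["n_records"] < threshold, "ocean_area_km2"].sum())
        rows.append({"depth_zone": zone, "ocean_area_km2": total,
                     "gap_area_km2": gap,
                     "gap_fraction": gap / total if total > 0 else np.nan,
                     "threshold": threshold})
    return pd.DataFrame(rows)
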