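"""Spatial distances for riverine connectivity analyses.

Three complementary metrics over projected (UTM, meters) coordinates:

* plain Euclidean distances (within-site sample spacing);
* least-cost distances through a binary water/land conductance raster
  (water = 1 passable, land = 0 impassable), shortest paths on the
  8-neighbor cell graph with edge weights of one cell size orthogonally and
  cell * sqrt(2) diagonally (the "type c" geocorrection);
* distances along a densified river midline (points snapped to the nearest
  ~1 m vertex, distance = difference in cumulative arc length).

Cost distances are quantized to the raster cell size: two points inside the
same cell get distance 0, and near pairs are underestimated. That bias is
intentional here — the site-level distance rule takes the element-wise
maximum of the cost and Euclidean matrices so the Euclidean value wins for
near pairs.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra as _sp_dijkstra
from scipy.spatial.distance import cdist, pdist, squareform
from shapely.geometry import LineString

from .differentiation import DistanceMatrix
from .genotype_io import CoordinatesMissingError, MicrosatDataset

UNREACHABLE = float("inf")


# ---------------------------------------------------------------------------
# Euclidean
# ---------------------------------------------------------------------------

def euclidean_pairwise(points: np.ndarray, labels: Optional[list[str]] = None
                       ) -> DistanceMatrix:
    points = np.asarray(points, dtype=float)
    if len(points) < 2:
        raise ValueError("need >= 2 points")
    if np.isnan(points).any():
        raise CoordinatesMissingError("points contain NaN coordinates")
    labels = labels or [str(i) for i in range(len(points))]
    return DistanceMatrix(labels=labels, values=squareform(pdist(points)))


def within_site_spacing(ds: MicrosatDataset) -> pd.DataFrame:
    """Per-site mean nearest-neighbor and mean all-pair sample distances."""
    xy = ds.coords()
    rows = []
    for site, idx in ds.by_site().items():
        if len(idx) < 2:
            rows.append((site, len(idx), float("nan"), float("nan")))
            continue
        d = squareform(pdist(xy[idx]))
        np.fill_diagonal(d, np.inf)
        rows.append((site, len(idx), float(d.min(axis=1).mean()),
                     float(d[np.isfinite(d)].mean())))
    return pd.DataFrame(rows, columns=["site", "n", "mean_nn_m",
                                       "mean_allpair_m"])


def site_centroids(ds: MicrosatDataset) -> pd.DataFrame:
    """Arithmetic mean of sample coordinates per site."""
    xy = ds.coords()
    rows = [(site, float(xy[idx, 0].mean()), float(xy[idx, 1].mean()))
            for site, idx in ds.by_site().items()]
    return pd.DataFrame(rows, columns=["site", "easting", "northing"])


# ---------------------------------------------------------------------------
# cost surface and least-cost distance
# ---------------------------------------------------------------------------

@dataclass
class CostSurface:
    """Binary conductance grid: truthy cells are water (passable).

    ``grid[row, col]``; row 0 is the top (north) edge, as in ESRI grids.
    ``origin`` is the (easting, northing) of the *lower-left corner* of the
    grid; ``cell_size`` in meters.
    """

    grid: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid).astype(bool)
        if self.grid.ndim != 2:
            raise ValueError("grid must be rectangular (2-D)")
        if self.cell_size <= 0:
            raise ValueError("cell size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def cell_of(self, point: Sequence[float]) -> tuple[int, int]:
        """(row, col) of the cell containing a projected point."""
        x, y = float(point[0]), float(point[1])
        nrow = self.grid.shape[0]
        col = int((x - self.origin[0]) // self.cell_size)
        row = nrow - 1 - int((y - self.origin[1]) // self.cell_size)
        if not (0 <= row < nrow and 0 <= col < self.grid.shape[1]):
            raise ValueError(f"point {point} outside the grid")
        return row, col

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        nrow = self.grid.shape[0]
        x = self.origin[0] + (col + 0.5) * self.cell_size
        y = self.origin[1] + (nrow - 1 - row + 0.5) * self.cell_size
        return x, y


def read_ascii_grid(path: str | Path, water_threshold: float = 0.0) -> CostSurface:
    """Read an ESRI ASCII grid; cells with value > threshold are water."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    body_start = 0
    for i, line in enumerate(lines):
        toks = line.split()
        if len(toks) == 2 and toks[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value"}:
            header[toks[0].lower()] = float(toks[1])
            body_start = i + 1
        else:
            break
    grid = np.loadtxt(lines[body_start:])
    grid = np.atleast_2d(grid)
    if "ncols" in header and grid.shape != (int(header["nrows"]),
                                            int(header["ncols"])):
        raise ValueError("ASCII grid body does not match declared shape")
    nodata = header.get("nodata_value")
    vals = grid.copy()
    if nodata is not None:
        vals[vals == nodata] = 0.0
    return CostSurface(grid=vals > water_threshold,
                       cell_size=header.get("cellsize", 1.0),
                       origin=(header.get("xllcorner", 0.0),
                               header.get("yllcorner", 0.0)))


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _snap_to_water(surface: CostSurface, rc: tuple[int, int],
                   radius_cells: int) -> tuple[int, int]:
    if surface.grid[rc]:
        return rc
    nrow, ncol = surface.shape
    best = None
    for dr in range(-radius_cells, radius_cells + 1):
        for dc in range(-radius_cells, radius_cells + 1):
            r, c = rc[0] + dr, rc[1] + dc
            if 0 <= r < nrow and 0 <= c < ncol and surface.grid[r, c]:
                d = math.hypot(dr, dc)
                # deterministic tie-break by cell index
                key = (d, r, c)
                if best is None or key < best[0]:
                    best = (key, (r, c))
    if best is None:
        raise ValueError(
            f"point at cell {rc} is on land and no water cell lies within "
            f"{radius_cells} cells"
        )
    return best[1]


def _water_graph(surface: CostSurface):
    """Sparse 8-neighbor graph over water cells with geocorrected weights."""
    nrow, ncol = surface.shape
    water = surface.grid
    idx = -np.ones((nrow, ncol), dtype=np.int64)
    cells = np.argwhere(water)
    idx[water] = np.arange(len(cells))
    rows_, cols_, w = [], [], []
    for dr, dc in _NEIGHBORS:
        r0 = max(0, -dr); r1 = nrow - max(0, dr)
        c0 = max(0, -dc); c1 = ncol - max(0, dc)
        a = water[r0:r1, c0:c1]
        b = water[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        both = a & b
        src = idx[r0:r1, c0:c1][both]
        dst = idx[r0 + dr:r1 + dr, c0 + dc:c1 + dc][both]
        weight = surface.cell_size * (math.sqrt(2.0) if dr and dc else 1.0)
        rows_.append(src); cols_.append(dst)
        w.append(np.full(len(src), weight))
    n = len(cells)
    graph = coo_matrix(
        (np.concatenate(w), (np.concatenate(rows_), np.concatenate(cols_))),
        shape=(n, n),
    ).tocsr()
    return graph, idx, cells


def cost_distance(surface: CostSurface, src, dst,
                  snap_radius_cells: int = 5) -> float:
    """Least-cost through-water distance between two points (meters).

    Points are snapped to the center of their containing cell (or the
    nearest water cell within ``snap_radius_cells`` if they fall on land).
    Returns ``inf`` when no water path exists.
    """
    m = cost_distance_matrix(surface, [src, dst],
                             snap_radius_cells=snap_radius_cells)
    return float(m.values[0, 1])


def cost_distance_matrix(surface: CostSurface, points,
                         labels: Optional[list[str]] = None,
                         snap_radius_cells: int = 5) -> DistanceMatrix:
    """All-pairs least-cost distances among points over the water graph."""
    pts = [tuple(p) for p in points]
    labels = labels or [str(i) for i in range(len(pts))]
    graph, idx, cells = _water_graph(surface)
    nodes = []
    for p in pts:
        rc = _snap_to_water(surface, surface.cell_of(p), snap_radius_cells)
        nodes.append(int(idx[rc]))
    uniq = sorted(set(nodes))
    dist = _sp_dijkstra(graph, directed=False, indices=uniq)
    lut = {u: i for i, u in enumerate(uniq)}
    n = len(pts)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = dist[lut[nodes[i]], nodes[j]]
    return DistanceMatrix(labels=labels, values=M)


# ---------------------------------------------------------------------------
# river midline distance
# ---------------------------------------------------------------------------

@dataclass
class RiverLine:
    """River midline densified to ~`spacing` m vertices with arc lengths."""

    vertices: np.ndarray    # (k, 2)
    arc_length: np.ndarray  # (k,) cumulative meters from line start

    @classmethod
    def from_coords(cls, coords, spacing: float = 1.0) -> "RiverLine":
        line = LineString(coords)
        if line.length == 0:
            raise ValueError("degenerate river line")
        k = max(int(math.ceil(line.length / spacing)), 1)
        s = np.linspace(0.0, line.length, k + 1)
        pts = np.array([line.interpolate(d).coords[0] for d in s])
        return cls(vertices=pts, arc_length=s)

    @classmethod
    def from_wkt(cls, wkt: str, spacing: float = 1.0) -> "RiverLine":
        from shapely import wkt as _wkt
        line = _wkt.loads(wkt)
        return cls.from_coords(list(line.coords), spacing=spacing)

    def snap(self, point) -> int:
        d = cdist(np.asarray(point, float)[None, :], self.vertices)[0]
        return int(d.argmin())


def river_distance(line: RiverLine, points,
                   labels: Optional[list[str]] = None) -> DistanceMatrix:
    """Along-river distances: |arc length difference| of snapped vertices."""
    pts = np.asarray(points, dtype=float)
    labels = labels or [str(i) for i in range(len(pts))]
    s = np.array([line.arc_length[line.snap(p)] for p in pts])
    M = np.abs(s[:, None] - s[None, :])
    return DistanceMatrix(labels=labels, values=M)


def river_extent(line: RiverLine, points) -> float:
    """Max pairwise along-river distance (the sampled river extent)."""
    m = river_distance(line, points)
    return float(m.values.max())


# ---------------------------------------------------------------------------
# combined site distance
# ---------------------------------------------------------------------------

def site_pairwise_distance(cost: DistanceMatrix,
                           euclid: DistanceMatrix) -> DistanceMatrix:
    """Element-wise max(cost, Euclidean) — the Euclidean value corrects the
    raster quantization of near pairs."""
    if cost.labels != euclid.labels:
        raise ValueError("label mismatch between cost and Euclidean matrices")
    return DistanceMatrix(labels=list(cost.labels),
                          values=np.maximum(cost.values, euclid.values))
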