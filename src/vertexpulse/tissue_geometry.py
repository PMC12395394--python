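"""Periodic polygonal tissues and geometric primitives.

A confluent epithelial monolayer is represented as a polygonal tiling of a
flat torus: cells are polygons, cell-cell junctions are the polygon edges,
and the degrees of freedom are the vertex positions.  Two generators are
provided: a regular hexagonal tiling (every cell a unit-area regular
hexagon) and a disordered tiling obtained from a seeded periodic Voronoi
tessellation followed by mechanical equilibration.

Conventions
-----------
* Lengths are measured in units of sqrt(A0) with the preferred cell area
  A0 = 1, so "a box of width ~14" means ~14 cell diameters.
* All coordinates are reduced into [0, Lx) x [0, Ly); displacements across
  the periodic boundary use the minimum-image convention.
* Cell vertex loops are stored counterclockwise.
* Every vertex is 3-valent (except transiently inside a T1 resolution) and
  every junction is shared by exactly two cells, so V - E + C = 0 on the
  torus and the mean polygon sidedness is exactly 6.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "INACTIVE",
    "ACTIVE",
    "REFRACTORY",
    "PeriodicBox",
    "Tissue",
    "ValidationReport",
    "HEX_EDGE_LENGTH",
    "make_hexagonal_tissue",
    "make_disordered_tissue",
    "junction_geometry",
    "cell_area",
    "cell_areas",
    "validate_tissue",
]

# Junction automaton states (serialized as these integers in snapshots).
INACTIVE = 0
ACTIVE = 1
REFRACTORY = 2

#: Edge length of a regular hexagon of unit area: (3*sqrt(3)/2) a^2 = 1.
HEX_EDGE_LENGTH = (4.0 / 27.0) ** 0.25


@dataclass(frozen=True)
class PeriodicBox:
    """Rectangular periodic domain [0, lx) x [0, ly)."""

    lx: float
    ly: float

    def __post_init__(self) -> None:
        if not (self.lx > 0 and self.ly > 0):
            raise ValueError(f"box dimensions must be positive, got {self.lx}, {self.ly}")

    @property
    def dims(self) -> np.ndarray:
        return np.array([self.lx, self.ly])

    @property
    def area(self) -> float:
        return self.lx * self.ly

    def wrap(self, points: np.ndarray) -> np.ndarray:
        """Reduce coordinates into [0, lx) x [0, ly)."""
        return np.mod(points, self.dims)

    def minimum_image(self, d: np.ndarray) -> np.ndarray:
        """Shortest periodic representative of displacement(s) ``d``."""
        dims = self.dims
        return d - dims * np.round(d / dims)


class Tissue:
    """Periodic polygonal tissue with per-junction mechanical/excitable state.

    Parameters
    ----------
    box : PeriodicBox
    positions : (V, 2) float array of vertex positions (wrapped into the box)
    edges : (E, 2) int array of vertex index pairs, one row per junction
    cells : list of int arrays, counterclockwise vertex loops
    rest_length, gamma, state, timer : optional per-junction arrays; default
        to zero-strain rest lengths, zero contractility, all-inactive states.
    """

    def __init__(self, box, positions, edges, cells,
                 rest_length=None, gamma=None, state=None, timer=None):
        self.box = box
        self.positions = np.ascontiguousarray(positions, dtype=float)
        self.edges = np.ascontiguousarray(edges, dtype=np.int64)
        self.cells = [np.asarray(c, dtype=np.int64) for c in cells]
        n_e = len(self.edges)
        if rest_length is None:
            rest_length = self.edge_lengths().copy()
        self.rest_length = np.ascontiguousarray(rest_length, dtype=float)
        self.gamma = (np.zeros(n_e) if gamma is None
                      else np.ascontiguousarray(gamma, dtype=float))
        self.state = (np.zeros(n_e, dtype=np.int8) if state is None
                      else np.ascontiguousarray(state, dtype=np.int8))
        self.timer = (np.zeros(n_e) if timer is None
                      else np.ascontiguousarray(timer, dtype=float))
        self._cache = None

    # ------------------------------------------------------------------ #
    # basic counts
    @property
    def n_vertices(self) -> int:
        return len(self.positions)

    @property
    def n_junctions(self) -> int:
        return len(self.edges)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    # ------------------------------------------------------------------ #
    # topology cache: flat "slot" arrays, one slot per (cell, loop position)
    def invalidate_topology(self) -> None:
        """Drop derived topology arrays; call after any connectivity change."""
        self._cache = None

    @property
    def topology(self):
        if self._cache is None:
            self._cache = _TopologyCache(self.cells)
        return self._cache

    # ------------------------------------------------------------------ #
    # geometry
    def edge_vectors(self) -> np.ndarray:
        """Minimum-image displacement r_j - r_i for every junction (i, j)."""
        d = self.positions[self.edges[:, 1]] - self.positions[self.edges[:, 0]]
        return self.box.minimum_image(d)

    def edge_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.edge_vectors(), axis=1)

    def edge_midpoints(self) -> np.ndarray:
        d = self.edge_vectors()
        return self.box.wrap(self.positions[self.edges[:, 0]] + 0.5 * d)

    def slot_deltas(self) -> np.ndarray:
        """Minimum-image step to the next vertex along each cell loop."""
        top = self.topology
        r = self.positions
        d = r[top.slot_vertex[top.slot_next]] - r[top.slot_vertex]
        return self.box.minimum_image(d)

    def cell_areas(self) -> np.ndarray:
        """Signed (CCW-positive) polygon areas via per-cell unwrapped loops."""
        top = self.topology
        d = self.slot_deltas()
        # rel[s]: position of slot s relative to the first vertex of its cell,
        # accumulated by minimum-image hops (periodic unwrapping).
        cs = np.vstack([np.zeros((1, 2)), np.cumsum(d, axis=0)])
        rel = cs[:-1] - cs[top.slot_start_of]
        cross = rel[:, 0] * d[:, 1] - rel[:, 1] * d[:, 0]
        return 0.5 * np.add.reduceat(cross, top.cell_start)

    def copy(self) -> "Tissue":
        t = Tissue(self.box, self.positions.copy(), self.edges.copy(),
                   [c.copy() for c in self.cells],
                   rest_length=self.rest_length.copy(), gamma=self.gamma.copy(),
                   state=self.state.copy(), timer=self.timer.copy())
        return t


class _TopologyCache:
    """Flat per-slot arrays for vectorized loops over (cell, loop position)."""

    def __init__(self, cells):
        sizes = np.array([len(c) for c in cells], dtype=np.int64)
        self.cell_sizes = sizes
        self.cell_start = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        n_slots = int(sizes.sum())
        self.slot_vertex = np.concatenate(cells) if cells else np.empty(0, np.int64)
        self.slot_cell = np.repeat(np.arange(len(cells)), sizes)
        self.slot_start_of = np.repeat(self.cell_start, sizes)
        idx = np.arange(n_slots)
        offset = idx - self.slot_start_of
        self.slot_next = self.slot_start_of + (offset + 1) % sizes[self.slot_cell]
        self.slot_prev = self.slot_start_of + (offset - 1) % sizes[self.slot_cell]


# ---------------------------------------------------------------------- #
# free-function geometric primitives


def junction_geometry(tissue: Tissue, junction: int):
    """Minimum-image displacement vector and length of one junction."""
    i, j = tissue.edges[junction]
    d = tissue.box.minimum_image(tissue.positions[j] - tissue.positions[i])
    return d, float(np.linalg.norm(d))


def cell_areas(tissue: Tissue) -> np.ndarray:
    return tissue.cell_areas()


def cell_area(tissue: Tissue, cell: int) -> float:
    """Area of one cell (unwrapped shoelace); raises on invalid geometry."""
    a = float(tissue.cell_areas()[cell])
    if a <= 0:
        raise ValueError(
            f"cell {cell} has non-positive signed area {a}: loop is not a "
            "counterclockwise simple polygon")
    return a


# ---------------------------------------------------------------------- #
# validation


@dataclass
class ValidationReport:
    ok: bool
    failures: list = field(default_factory=list)

    @property
    def first_failure(self):
        return self.failures[0] if self.failures else None

    def __bool__(self) -> bool:
        return self.ok


def validate_tissue(tissue: Tissue, area_tol: float = 1e-9,
                    allow_fourfold: bool = False) -> ValidationReport:
    """Check all Tissue invariants; report the violated ones in order."""
    failures = []
    v, e, c = tissue.n_vertices, tissue.n_junctions, tissue.n_cells

    if v - e + c != 0:
        failures.append(f"Euler relation violated: V-E+C = {v}-{e}+{c} = {v - e + c}")

    # every junction shared by exactly 2 cells, traversed once per direction
    pair_counts: dict = {}
    directed: dict = {}
    for ci, loop in enumerate(tissue.cells):
        for k in range(len(loop)):
            a, b = int(loop[k]), int(loop[(k + 1) % len(loop)])
            pair_counts[frozenset((a, b))] = pair_counts.get(frozenset((a, b)), 0) + 1
            directed[(a, b)] = directed.get((a, b), 0) + 1
    edge_keys = {frozenset(map(int, e_)) for e_ in tissue.edges}
    for key, count in pair_counts.items():
        if count != 2:
            failures.append(f"junction {sorted(key)} not shared by 2 cells (found {count})")
            break
    for key in edge_keys:
        if key not in pair_counts:
            failures.append(f"junction {sorted(key)} borders no cell")
            break
    if len(edge_keys) != len(tissue.edges):
        failures.append("duplicate junctions in edge table")
    if set(pair_counts) != edge_keys:
        extra = set(pair_counts) - edge_keys
        if extra:
            failures.append(f"cell loops traverse unknown junction {sorted(next(iter(extra)))}")
    for (a, b), count in directed.items():
        if count != 1:
            failures.append(f"directed edge ({a},{b}) traversed {count} times "
                            "(inconsistent loop orientation)")
            break

    degree = np.zeros(v, dtype=int)
    np.add.at(degree, tissue.edges.ravel(), 1)
    bad = np.flatnonzero(degree != 3)
    if bad.size and not allow_fourfold:
        failures.append(f"vertex {bad[0]} has degree {degree[bad[0]]} (expected 3)")

    areas = tissue.cell_areas()
    if np.any(areas <= 0):
        failures.append(f"cell {int(np.argmax(areas <= 0))} has non-positive area "
                        "(loop not counterclockwise or self-intersecting)")
    total = float(areas.sum())
    if abs(total - tissue.box.area) > area_tol * max(1.0, tissue.box.area):
        failures.append(f"cell areas sum to {total}, box area is {tissue.box.area}")

    if np.any(tissue.rest_length <= 0):
        failures.append("non-positive junction rest length")
    pos = tissue.positions
    if np.any(pos < 0) or np.any(pos >= tissue.box.dims):
        failures.append("vertex coordinates not reduced into the box")
    if not np.all(np.isin(tissue.state, (INACTIVE, ACTIVE, REFRACTORY))):
        failures.append("invalid junction state code")

    return ValidationReport(ok=not failures, failures=failures)


# ---------------------------------------------------------------------- #
# ordered (hexagonal) tissue


def _hex_grid_choices(n_cells: int):
    """(cols, rows) factorizations with even rows (periodicity in y)."""
    out = []
    for cols in range(2, n_cells // 2 + 1):
        if n_cells % cols:
            continue
        rows = n_cells // cols
        if rows >= 2 and rows % 2 == 0:
            out.append((cols, rows))
    return out


def make_hexagonal_tissue(n_cells: int, box: PeriodicBox | None = None) -> Tissue:
    """Regular hexagonal tiling of ``n_cells`` unit-area cells on a torus.

    The box is adjusted to the nearest dimensions commensurate with a
    regular hexagonal lattice of unit-area cells; the realized box is stored
    on the returned tissue (``tissue.box``) and the requested one under
    ``tissue.requested_box``.  Cells are pointy-top hexagons: columns are
    spaced by sqrt(3)*a and offset rows by 1.5*a, with edge length
    a = (4/27)**(1/4) ~ 0.6204.

    The construction is an exact mechanical equilibrium of the tissue
    energy for any parameter values, by the three-fold symmetry of every
    vertex, and starts with zero strain on every junction (l0 = l).
    """
    a = HEX_EDGE_LENGTH
    dx, dy = math.sqrt(3.0) * a, 1.5 * a
    choices = _hex_grid_choices(n_cells)
    if not choices:
        raise ValueError(
            f"n_cells={n_cells} cannot be factored into cols x rows with "
            "cols >= 2 and an even number of rows >= 2, as required for a "
            "periodic hexagonal tiling")
    if box is None:
        # most nearly square realizable box
        cols, rows = min(choices, key=lambda cr: abs(math.log((cr[0] * dx) / (cr[1] * dy))))
    else:
        cols, rows = min(
            choices,
            key=lambda cr: abs(cr[0] * dx - box.lx) + abs(cr[1] * dy - box.ly))
    realized = PeriodicBox(cols * dx, rows * dy)

    # Integer honeycomb coordinates: x in units of dx/2, y in units of a/2.
    # Hexagon centers: (2i + j%2, 3j); the six CCW vertex offsets below are
    # exact integers, so periodic vertex identification is exact.
    offsets = [(0, 2), (-1, 1), (-1, -1), (0, -2), (1, -1), (1, 1)]
    px, py = 2 * cols, 3 * rows  # integer periods
    vid: dict = {}
    verts = []
    cells = []
    for j in range(rows):
        for i in range(cols):
            cx, cy = 2 * i + (j % 2), 3 * j
            loop = []
            for ox, oy in offsets:
                key = ((cx + ox) % px, (cy + oy) % py)
                if key not in vid:
                    vid[key] = len(verts)
                    verts.append(key)
                loop.append(vid[key])
            cells.append(np.array(loop, dtype=np.int64))
    positions = np.array(verts, dtype=float) * np.array([0.5 * dx, 0.5 * a])

    edge_set: dict = {}
    for loop in cells:
        for k in range(len(loop)):
            pair = (int(loop[k]), int(loop[(k + 1) % len(loop)]))
            key = (min(pair), max(pair))
            edge_set.setdefault(key, None)
    edges = np.array(sorted(edge_set), dtype=np.int64)

    tissue = Tissue(realized, positions, edges, cells)
    tissue.requested_box = box
    tissue.grid_shape = (cols, rows)
    return tissue


# ---------------------------------------------------------------------- #
# disordered tissue (periodic Voronoi + mechanical equilibration)


def _periodic_voronoi(points: np.ndarray, box: PeriodicBox):
    """Cells/vertices of the periodic Voronoi diagram of ``points``.

    Returns (positions, cells) with vertex positions wrapped into the box
    and each cell an index loop in counterclockwise order.
    """
    from scipy.spatial import Voronoi, cKDTree

    n = len(points)
    shifts = [(ix, iy) for iy in (-1, 0, 1) for ix in (-1, 0, 1)]
    tiled = np.concatenate([points + np.array(s) * box.dims for s in shifts])
    # central copy occupies indices [4n, 5n) with shift ordering above
    central = 4 * n
    vor = Voronoi(tiled)

    raw_pts = []      # vertex positions as produced (unwrapped)
    loops_raw = []    # per cell: list of indices into raw_pts
    for i in range(central, central + n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise RuntimeError("periodic Voronoi produced an open region; "
                               "check that points span the box")
        vxy = vor.vertices[region]
        ang = np.arctan2(vxy[:, 1] - tiled[i, 1], vxy[:, 0] - tiled[i, 0])
        order = np.argsort(ang)  # CCW (cells are convex)
        base = len(raw_pts)
        raw_pts.extend(vxy[order])
        loops_raw.append(list(range(base, base + len(order))))

    raw_pts = np.asarray(raw_pts)
    wrapped = box.wrap(raw_pts)
    # merge copies of the same Voronoi vertex (they agree to ~1e-12)
    tree = cKDTree(wrapped, boxsize=box.dims)
    pairs = tree.query_pairs(1e-7, output_type="ndarray")
    parent = np.arange(len(wrapped))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in pairs:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    roots = np.array([find(i) for i in range(len(wrapped))])
    uniq, inverse = np.unique(roots, return_inverse=True)
    positions = wrapped[uniq]
    cells = []
    for loop in loops_raw:
        merged = [int(inverse[k]) for k in loop]
        # drop consecutive duplicates (numerically degenerate vertices)
        cleaned = [v for v, prev in zip(merged, [merged[-1]] + merged[:-1]) if v != prev]
        if len(cleaned) < 3:
            raise RuntimeError("degenerate Voronoi cell after vertex merging")
        cells.append(np.array(cleaned, dtype=np.int64))

    edge_set = {}
    for loop in cells:
        for k in range(len(loop)):
            pair = (int(loop[k]), int(loop[(k + 1) % len(loop)]))
            edge_set.setdefault((min(pair), max(pair)), None)
    edges = np.array(sorted(edge_set), dtype=np.int64)
    return positions, edges, cells


def _periodic_centroids(points: np.ndarray, box: PeriodicBox) -> np.ndarray:
    """Area centroids of the periodic Voronoi cells of ``points``."""
    positions, edges, cells = _periodic_voronoi(points, box)
    t = Tissue(box, positions, edges, cells)
    cent = np.empty_like(points)
    for i, loop in enumerate(cells):
        p0 = positions[loop[0]]
        rel = np.zeros((len(loop), 2))
        for k in range(1, len(loop)):
            rel[k] = rel[k - 1] + box.minimum_image(positions[loop[k]] - positions[loop[k - 1]])
        x, y = rel[:, 0], rel[:, 1]
        xn, yn = np.roll(x, -1), np.roll(y, -1)
        cr = x * yn - xn * y
        a = 0.5 * cr.sum()
        cx = np.sum((x + xn) * cr) / (6.0 * a)
        cy = np.sum((y + yn) * cr) / (6.0 * a)
        cent[i] = box.wrap(p0 + np.array([cx, cy]))
    del t
    return cent


def make_disordered_tissue(n_cells: int, box: PeriodicBox, seed: int,
                           n_lloyd: int = 2, mech_params=None,
                           force_tol: float = 1e-6) -> Tissue:
    """Disordered, mechanically equilibrated periodic tissue.

    Seeded uniform random points are regularized by ``n_lloyd`` Lloyd
    iterations, tessellated into a periodic Voronoi diagram, and then
    relaxed to a mechanical equilibrium of the tissue energy (all
    contractilities zero, default line tension) with T1 exchanges allowed.
    Rest lengths are finally set to the relaxed lengths (zero strain) and
    all junctions are inactive.  Output is a pure function of
    (n_cells, box, seed).
    """
    from . import mechanics

    if n_cells < 3:
        raise ValueError("need at least 3 cells")
    rng = np.random.default_rng(seed)
    pts = rng.uniform([0.0, 0.0], box.dims, size=(n_cells, 2))
    for _ in range(n_lloyd):
        pts = _periodic_centroids(pts, box)
    positions, edges, cells = _periodic_voronoi(pts, box)
    tissue = Tissue(box, positions, edges, cells)
    report = validate_tissue(tissue, area_tol=1e-7)
    if not report.ok:
        raise RuntimeError(f"Voronoi construction invalid: {report.first_failure}")

    params = mech_params if mech_params is not None else mechanics.MechParams()
    mechanics.equilibrate(tissue, params, tol=force_tol)
    return tissue
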