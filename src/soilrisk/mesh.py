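"""Triangulated meshes with a coarser boundary extension.

The SPDE representation of a Matérn field needs a finite-element mesh over
the study domain.  Edge length inside the domain is capped at a configured
maximum (the resolution/cost trade-off knob); a ring of coarser triangles
is added around the domain so that the boundary conditions of the SPDE do
not distort the field inside the study region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay
from shapely.geometry import Point, Polygon

logger = logging.getLogger(__name__)


@dataclass
class Mesh:
    """A conforming triangulation: vertices (km), triangle vertex triples,
    and a mask marking vertices inside the original (unextended) domain."""

    vertices: np.ndarray  # (n, 2)
    triangles: np.ndarray  # (m, 3) int
    interior_mask: np.ndarray  # (n,) bool
    max_edge_interior: float
    _tri_keys: set = field(default_factory=set, repr=False)

    def __post_init__(self) -> None:
        if not len(self._tri_keys):
            self._tri_keys = {tuple(sorted(t)) for t in self.triangles}

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (n_edges, 2) index array."""
        e = np.vstack(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [0, 2]]]
        )
        return np.unique(np.sort(e, axis=1), axis=0)

    def edge_lengths(self, edges: np.ndarray | None = None) -> np.ndarray:
        e = self.edges() if edges is None else edges
        d = self.vertices[e[:, 0]] - self.vertices[e[:, 1]]
        return np.hypot(d[:, 0], d[:, 1])

    def interior_edges(self) -> np.ndarray:
        """Edges whose both endpoints lie inside the original domain."""
        e = self.edges()
        return e[self.interior_mask[e[:, 0]] & self.interior_mask[e[:, 1]]]

    def audit_interior_edges(self) -> float:
        """Brute-force scan: longest interior edge (for constraint audit)."""
        lens = self.edge_lengths(self.interior_edges())
        return float(lens.max()) if len(lens) else 0.0

    def triangle_areas(self) -> np.ndarray:
        p = self.vertices[self.triangles]
        return 0.5 * np.abs(
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )


def _as_polygon(domain) -> Polygon:
    if isinstance(domain, Polygon):
        poly = domain
    else:
        poly = Polygon(np.asarray(domain, dtype=float))
    if not poly.is_valid:
        raise ValueError("domain polygon is not simple (self-intersecting?)")
    return poly


def _lattice_points(poly: Polygon, spacing: float, margin: float = 0.0) -> np.ndarray:
    """Equilateral triangular lattice clipped to a polygon (+margin buffer)."""
    region = poly.buffer(margin) if margin > 0 else poly
    xmin, ymin, xmax, ymax = region.bounds
    dy = spacing * np.sqrt(3.0) / 2.0
    rows = []
    y = ymin
    r = 0
    while y <= ymax + 1e-9:
        xoff = 0.5 * spacing if r % 2 else 0.0
        x = np.arange(xmin + xoff, xmax + 1e-9, spacing)
        rows.append(np.column_stack([x, np.full_like(x, y)]))
        y += dy
        r += 1
    pts = np.vstack(rows) if rows else np.empty((0, 2))
    if len(pts) == 0:
        return pts
    keep = [region.covers(Point(p)) for p in pts]
    return pts[np.asarray(keep, bool)]


def _boundary_points(poly: Polygon, spacing: float) -> np.ndarray:
    """Polygon vertices plus points subdividing each edge to <= spacing."""
    coords = list(poly.exterior.coords)  # closed ring, last == first
    pts = []
    for a, b in zip(coords[:-1], coords[1:]):
        a, b = np.asarray(a), np.asarray(b)
        seg = np.linalg.norm(b - a)
        n = max(int(np.ceil(seg / spacing)), 1)
        for k in range(n):
            pts.append(a + (b - a) * k / n)
    return np.asarray(pts)


def build_mesh(
    domain_polygon,
    max_edge_interior: float,
    extension_width: float,
    max_edge_exterior: float | None = None,
    max_refine_passes: int = 25,
) -> Mesh:
    """Triangulate the domain plus a coarser extension ring.

    Vertices come from an equilateral lattice at the interior spacing, the
    domain boundary, a coarser lattice on the extension ring, and the outer
    boundary; a Delaunay triangulation is then refined by midpoint
    insertion until every edge with both endpoints inside the original
    domain is no longer than ``max_edge_interior``.  Deterministic for
    fixed inputs.
    """
    poly = _as_polygon(domain_polygon)
    if max_edge_interior <= 0:
        raise ValueError("max_edge_interior must be > 0")
    if max_edge_exterior is None:
        max_edge_exterior = 3.0 * max_edge_interior
    if max_edge_exterior < max_edge_interior:
        raise ValueError("max_edge_exterior must be >= max_edge_interior")

    h_in = 0.95 * max_edge_interior
    outer = poly.buffer(extension_width, join_style=2) if extension_width > 0 else poly
    pts = [_lattice_points(poly, h_in), _boundary_points(poly, h_in)]
    if extension_width > 0:
        ring_pts = _lattice_points(outer, 0.95 * max_edge_exterior)
        # keep only lattice points clearly outside the interior zone
        keep = [not poly.buffer(0.25 * max_edge_interior).covers(Point(p)) for p in ring_pts]
        pts.append(ring_pts[np.asarray(keep, bool)] if len(ring_pts) else ring_pts)
        pts.append(_boundary_points(outer, 0.95 * max_edge_exterior))
    verts = _dedupe(np.vstack([p for p in pts if len(p)]), tol=0.05 * h_in)

    for _ in range(max_refine_passes):
        mesh = _triangulate(verts, poly, outer, max_edge_interior)
        e = mesh.interior_edges()
        lens = mesh.edge_lengths(e)
        bad = e[lens > max_edge_interior]
        if not len(bad):
            return mesh
        a, b = mesh.vertices[bad[:, 0]], mesh.vertices[bad[:, 1]]
        mids = 0.5 * (a + b)
        # nudge off the segment: exactly collinear points are dropped by the
        # Delaunay backend as coplanar, which would leave the edge in place
        t = b - a
        perp = np.column_stack([-t[:, 1], t[:, 0]])
        perp /= np.linalg.norm(perp, axis=1, keepdims=True)
        nudged = mids + 0.02 * max_edge_interior * perp
        ok_side = np.array([outer.covers(Point(p)) for p in nudged])
        nudged[~ok_side] = (mids - 0.02 * max_edge_interior * perp)[~ok_side]
        verts = _dedupe(np.vstack([mesh.vertices, nudged]), tol=0.05 * h_in)
    raise RuntimeError("mesh refinement did not converge within the pass limit")


def _dedupe(pts: np.ndarray, tol: float) -> np.ndarray:
    key = np.round(pts / tol).astype(np.int64)
    _, idx = np.unique(key, axis=0, return_index=True)
    return pts[np.sort(idx)]


def _triangulate(verts: np.ndarray, poly: Polygon, outer: Polygon, h: float) -> Mesh:
    tri = Delaunay(verts)
    simplices = tri.simplices
    p = verts[simplices]
    areas = 0.5 * np.abs(
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )
    cent = p.mean(axis=1)
    buf = outer.buffer(1e-9)
    inside = np.array([buf.covers(Point(c)) for c in cent])
    keep = inside & (areas > 1e-10 * h * h)
    tris = simplices[keep]
    used = np.unique(tris)
    remap = -np.ones(len(verts), dtype=int)
    remap[used] = np.arange(len(used))
    verts_used = verts[used]
    interior = np.array([poly.buffer(1e-9).covers(Point(v)) for v in verts_used])
    return Mesh(verts_used, remap[tris], interior, max_edge_interior=h)


def select_max_edge(
    candidate_edges,
    score_fn,
    tolerance: float = 2.0,
) -> tuple:
    """Pick the coarsest candidate edge length within ``tolerance`` of the
    best information-criterion score.

    ``score_fn(edge) -> float`` fits a model on the mesh built with that
    edge length and returns an information criterion (lower is better);
    candidates whose fit raises are skipped with a warning.  Returns
    ``(selected_edge, score_table)`` where the table lists (edge, score).
    """
    candidates = sorted(set(float(e) for e in candidate_edges))
    if not candidates:
        raise ValueError("need at least one candidate edge length")
    table = []
    for edge in candidates:
        try:
            table.append((edge, float(score_fn(edge))))
        except Exception as exc:  # noqa: BLE001 - candidate-level robustness
            logger.warning("candidate edge %.3g failed: %s", edge, exc)
    if not table:
        raise RuntimeError("all candidate edge lengths failed")
    best = min(s for _, s in table)
    admissible = [e for e, s in table if s <= best + tolerance]
    return max(admissible), table
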