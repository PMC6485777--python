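"""Finite-volume meshes for planarian body models.

Builds 1D interval grids and 2D clipped-Voronoi meshes inside a worm-shaped
body outline, carries the cell/face bookkeeping the transport solver needs
(closed outer boundary, per-face adjacency, measures and normals), and
implements virtual amputation: removing a kerf of cells along cut polylines
and re-flagging the newly exposed faces as closed wound boundary.

Coordinate convention: x runs anterior -> posterior with the anterior tip at
x = 0; y is the mediolateral axis with the midline at y = 0.  All lengths are
in meters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Voronoi
import shapely
from shapely.geometry import LineString, Point, Polygon

__all__ = [
    "BodyOutline",
    "CutLine",
    "Fragment",
    "Mesh",
    "MeshGenerationError",
    "build_1d_grid",
    "build_2d_mesh",
    "cut_mesh",
    "make_worm_outline",
]

#: faces with |normal_x| below this are ambiguous anterior/posterior and
#: inherit the majority tag of their cut line
_FACING_TOL = 0.1


class MeshGenerationError(RuntimeError):
    """Raised when a valid mesh cannot be produced for the requested outline."""


@dataclass
class BodyOutline:
    """Closed polygon describing a planarian body silhouette.

    vertices : (n, 2) array of (x, y) in meters, anterior tip at x = 0.
    """

    vertices: np.ndarray
    length: float
    head: np.ndarray = field(default=None)
    tail: np.ndarray = field(default=None)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.length <= 0:
            raise ValueError("body length must be positive")
        poly = self.polygon()
        if not poly.is_valid or poly.area <= 0:
            raise ValueError("outline polygon must be simple and non-degenerate")
        if self.head is None:
            self.head = np.array([self.vertices[:, 0].min(), 0.0])
        if self.tail is None:
            self.tail = np.array([self.vertices[:, 0].max(), 0.0])

    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        return self.polygon().area

    def to_csv(self, path):
        pd.DataFrame(self.vertices, columns=["x", "y"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BodyOutline":
        df = pd.read_csv(path)
        verts = df[["x", "y"]].to_numpy()
        return cls(verts, length=float(verts[:, 0].max() - verts[:, 0].min()))


def make_worm_outline(
    length: float = 0.012, half_width: float = 0.00125, n_points: int = 120
) -> BodyOutline:
    """Synthetic bilaterally symmetric worm silhouette.

    The half-width profile ``w(x) = half_width * (1 - t^2)^0.55`` (t the
    normalized axial coordinate in [-1, 1]) gives a gently tapered, blunt-ended
    body with realistic planarian proportions (about 1:5 width to length).
    """
    if length <= 0 or half_width <= 0:
        raise ValueError("length and half_width must be positive")
    x = np.linspace(0.0, length, n_points // 2)
    t = 2.0 * x / length - 1.0
    w = half_width * np.maximum(1.0 - t**2, 0.0) ** 0.55
    top = np.column_stack([x, w])
    bottom = np.column_stack([x[::-1], -w[::-1]])
    verts = np.vstack([top, bottom[1:-1]])
    return BodyOutline(verts, length=length)


@dataclass
class CutLine:
    """Amputation polyline in body coordinates.

    In 1D a transverse cut at axial position x is represented by a short
    vertical segment through (x, 0) so that the same point-to-polyline
    distance rule applies in both dimensions.
    """

    points: np.ndarray
    label: str

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 2:
            raise ValueError("cut polyline needs at least two points")

    @classmethod
    def transverse(cls, x: float, label: str, half_span: float = 1.0) -> "CutLine":
        return cls(np.array([[x, -half_span], [x, half_span]]), label)

    def linestring(self) -> LineString:
        return LineString(self.points)


class Mesh:
    """Polygonal finite-volume mesh with a closed outer boundary.

    Cell data are flat numpy arrays; faces are stored once with an oriented
    normal pointing from ``face_cells[:, 0]`` toward ``face_cells[:, 1]``
    (outward for boundary faces, which carry ``face_cells[:, 1] == -1``).
    """

    def __init__(
        self,
        points: np.ndarray,
        measure: np.ndarray,
        face_cells: np.ndarray,
        face_normal: np.ndarray,
        face_measure: np.ndarray,
        face_dist: np.ndarray,
        dim: int,
        outline: BodyOutline | None = None,
        face_cut_label: list[str] | None = None,
    ):
        self.points = np.asarray(points, dtype=float)
        self.measure = np.asarray(measure, dtype=float)
        self.face_cells = np.asarray(face_cells, dtype=np.int64)
        self.face_normal = np.asarray(face_normal, dtype=float)
        self.face_measure = np.asarray(face_measure, dtype=float)
        self.face_dist = np.asarray(face_dist, dtype=float)
        self.dim = int(dim)
        self.outline = outline
        self.face_cut_label = (
            list(face_cut_label)
            if face_cut_label is not None
            else [""] * len(self.face_measure)
        )
        self._validate()
        self._build_operators()

    # -- construction ------------------------------------------------------

    def _validate(self):
        if np.any(self.measure <= 0):
            raise ValueError("all cell measures must be positive")
        inter = self.interior_faces
        if inter.size and np.any(
            self.face_cells[inter, 0] == self.face_cells[inter, 1]
        ):
            raise ValueError("interior face joining a cell to itself")
        if self.n_cells > 1 and self.dx <= 0:
            raise ValueError("characteristic spacing must be positive")

    def _build_operators(self):
        """Signed face->cell incidence used to accumulate flux divergences."""
        nf, nc = len(self.face_measure), self.n_cells
        rows, cols, vals = [], [], []
        for f in range(nf):
            a, b = self.face_cells[f]
            rows.append(a)
            cols.append(f)
            vals.append(1.0)
            if b >= 0:
                rows.append(b)
                cols.append(f)
                vals.append(-1.0)
        self._incidence = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(nc, nf)
        )

    # -- basic queries -----------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.measure)

    @property
    def n_faces(self) -> int:
        return len(self.face_measure)

    @property
    def interior_faces(self) -> np.ndarray:
        return np.flatnonzero(self.face_cells[:, 1] >= 0)

    @property
    def boundary_faces(self) -> np.ndarray:
        return np.flatnonzero(self.face_cells[:, 1] < 0)

    @property
    def dx(self) -> float:
        """Characteristic spacing: minimum centroid-to-centroid distance."""
        inter = self.interior_faces
        if inter.size == 0:
            return float(self.measure[0] ** (1.0 / self.dim))
        return float(self.face_dist[inter].min())

    @property
    def h(self) -> float:
        """Mean cell size (used as the default cut kerf width)."""
        return float((self.measure.sum() / self.n_cells) ** (1.0 / self.dim))

    @property
    def total_measure(self) -> float:
        return float(self.measure.sum())

    def divergence(self, face_flux: np.ndarray) -> np.ndarray:
        """Per-cell divergence of a per-face flux (flux positive along the
        stored face normal), via the finite-volume face sum."""
        return (self._incidence @ (face_flux * self.face_measure)) / self.measure

    def adjacency_graph(self) -> sparse.csr_matrix:
        inter = self.interior_faces
        a = self.face_cells[inter, 0]
        b = self.face_cells[inter, 1]
        data = np.ones(len(inter))
        g = sparse.coo_matrix(
            (data, (a, b)), shape=(self.n_cells, self.n_cells)
        )
        return (g + g.T).tocsr()

    def is_connected(self) -> bool:
        if self.n_cells == 1:
            return True
        n, _ = connected_components(self.adjacency_graph(), directed=False)
        return n == 1

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, cells_path, faces_path):
        pd.DataFrame(
            {
                "cell_id": np.arange(self.n_cells),
                "x": self.points[:, 0],
                "y": self.points[:, 1],
                "measure": self.measure,
            }
        ).to_csv(cells_path, index=False)
        cell_b = np.where(self.face_cells[:, 1] >= 0, self.face_cells[:, 1], -1)
        pd.DataFrame(
            {
                "face_id": np.arange(self.n_faces),
                "cell_a": self.face_cells[:, 0],
                "cell_b": [str(b) if b >= 0 else "BOUNDARY" for b in cell_b],
                "nx": self.face_normal[:, 0],
                "ny": self.face_normal[:, 1],
                "measure": self.face_measure,
                "dist": self.face_dist,
                "cut_label": self.face_cut_label,
            }
        ).to_csv(faces_path, index=False)

    @classmethod
    def from_csv(cls, cells_path, faces_path, dim: int) -> "Mesh":
        cells = pd.read_csv(cells_path)
        faces = pd.read_csv(faces_path, keep_default_na=False)
        cell_b = np.array(
            [-1 if str(b) == "BOUNDARY" else int(b) for b in faces["cell_b"]]
        )
        return cls(
            points=cells[["x", "y"]].to_numpy(),
            measure=cells["measure"].to_numpy(),
            face_cells=np.column_stack([faces["cell_a"].to_numpy(), cell_b]),
            face_normal=faces[["nx", "ny"]].to_numpy(),
            face_measure=faces["measure"].to_numpy(),
            face_dist=faces["dist"].to_numpy(),
            dim=dim,
            face_cut_label=[str(s) for s in faces["cut_label"]],
        )


@dataclass
class Fragment:
    """Connected piece of a cut mesh.

    ``wounds`` maps cut label -> facing ("anterior" | "posterior") -> array of
    fragment-local cell ids adjacent to that wound.  ``has_head``/``has_tail``
    flag fragments retaining the original, terminally differentiated body
    ends.
    """

    mesh: Mesh
    orig_cells: np.ndarray
    wounds: dict
    has_head: bool = False
    has_tail: bool = False

    @property
    def cut_labels(self) -> list[str]:
        return sorted(self.wounds)

    def wound_cells(self, label: str, facing: str | None = None) -> np.ndarray:
        if label not in self.wounds:
            raise KeyError(f"fragment has no cut line labelled {label!r}")
        sides = self.wounds[label]
        if facing is not None:
            if facing not in sides:
                raise KeyError(
                    f"cut line {label!r} has no {facing}-facing wound here"
                )
            return sides[facing]
        return np.unique(np.concatenate(list(sides.values())))


def build_1d_grid(L: float, n_cells: int) -> Mesh:
    """Uniform 1D interval grid on [0, L] with closed ends.

    Cells are intervals of width L/n with unit cross-section, so cell measure
    is a length and face measure is 1.
    """
    if L <= 0:
        raise ValueError("L must be positive")
    if n_cells < 1:
        raise ValueError("n_cells must be at least 1")
    dx = L / n_cells
    x = (np.arange(n_cells) + 0.5) * dx
    points = np.column_stack([x, np.zeros(n_cells)])
    measure = np.full(n_cells, dx)
    face_cells, face_normal, face_measure, face_dist = [], [], [], []
    for i in range(n_cells - 1):
        face_cells.append((i, i + 1))
        face_normal.append((1.0, 0.0))
        face_measure.append(1.0)
        face_dist.append(dx)
    # closed ends
    face_cells += [(0, -1), (n_cells - 1, -1)]
    face_normal += [(-1.0, 0.0), (1.0, 0.0)]
    face_measure += [1.0, 1.0]
    face_dist += [dx / 2, dx / 2]
    return Mesh(
        points,
        measure,
        np.array(face_cells),
        np.array(face_normal),
        np.array(face_measure),
        np.array(face_dist),
        dim=1,
    )


def _sample_seeds(
    poly: Polygon, target: int, rng: np.random.Generator
) -> np.ndarray:
    """Dart-throwing with a minimum separation, then fill without it."""
    minx, miny, maxx, maxy = poly.bounds
    r_min = 0.62 * np.sqrt(poly.area / target)
    seeds: list[np.ndarray] = []
    attempts = 0
    max_attempts = 400 * target
    while len(seeds) < target and attempts < max_attempts:
        attempts += 1
        p = rng.uniform([minx, miny], [maxx, maxy])
        if not poly.contains(Point(p)):
            continue
        if seeds and np.min(
            np.linalg.norm(np.asarray(seeds) - p, axis=1)
        ) < r_min:
            continue
        seeds.append(p)
        if attempts > 200 * target:
            r_min *= 0.95
    if len(seeds) < max(10, target // 2):
        raise MeshGenerationError(
            f"could only place {len(seeds)} of {target} seed points; "
            "outline is too thin for the requested resolution"
        )
    return np.asarray(seeds)


def _ghost_ring(poly: Polygon, n: int = 16) -> np.ndarray:
    """Far-away points that bound every real Voronoi region."""
    minx, miny, maxx, maxy = poly.bounds
    cx, cy = (minx + maxx) / 2, (miny + maxy) / 2
    r = 4.0 * max(maxx - minx, maxy - miny)
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)])


def _clipped_regions(seeds: np.ndarray, poly: Polygon):
    """Voronoi regions of ``seeds`` clipped to the outline polygon."""
    ghosts = _ghost_ring(poly)
    vor = Voronoi(np.vstack([seeds, ghosts]))
    cells = []
    for i in range(len(seeds)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            raise MeshGenerationError("unbounded Voronoi region despite ghosts")
        cell = Polygon(vor.vertices[region]).intersection(poly)
        if cell.geom_type == "MultiPolygon":
            # keep the part holding the seed (clipping can sliver at tips)
            cell = max(cell.geoms, key=lambda g: g.area)
        if cell.is_empty or cell.area <= 0:
            raise MeshGenerationError(f"seed {i} produced an empty clipped cell")
        cells.append(cell)
    return vor, cells


def build_2d_mesh(
    outline: BodyOutline,
    target_cells: int,
    seed: int = 0,
    lloyd_iters: int = 4,
    seeds: np.ndarray | None = None,
) -> Mesh:
    """Lloyd-relaxed Voronoi mesh clipped to a body outline.

    Seed points are dart-thrown inside the outline, relaxed toward the
    centroids of their clipped Voronoi cells (``lloyd_iters`` sweeps), and the
    final Voronoi diagram is clipped to the outline.  Outer faces are flagged
    as closed boundary.  Explicit ``seeds`` skip the sampling stage (set
    ``lloyd_iters=0`` to keep them fixed).
    """
    poly = outline.polygon()
    if seeds is None:
        if target_cells < 10:
            raise ValueError("target_cells must be at least 10")
        rng = np.random.default_rng(seed)
        seeds = _sample_seeds(poly, target_cells, rng)
    else:
        seeds = np.asarray(seeds, dtype=float)
    for _ in range(lloyd_iters):
        _, cells = _clipped_regions(seeds, poly)
        seeds = np.array([[c.centroid.x, c.centroid.y] for c in cells])
    vor, cells = _clipped_regions(seeds, poly)
    n = len(seeds)
    points = np.array([[c.centroid.x, c.centroid.y] for c in cells])
    measure = np.array([c.area for c in cells])

    face_cells, face_normal, face_measure, face_dist = [], [], [], []
    seen = {}
    for (pa, pb), ridge in zip(vor.ridge_points, vor.ridge_vertices):
        if pa >= n or pb >= n or -1 in ridge:
            continue
        seg = LineString(vor.vertices[list(ridge)])
        clipped = seg.intersection(poly)
        if clipped.is_empty or clipped.length <= 0:
            continue
        nvec = points[pb] - points[pa]
        d = np.linalg.norm(seeds[pb] - seeds[pa])
        nhat = (seeds[pb] - seeds[pa]) / d
        face_cells.append((pa, pb))
        face_normal.append(nhat)
        face_measure.append(clipped.length)
        # centroid distance projected on the face normal guards against the
        # slight skew clipping introduces near the outline
        face_dist.append(max(abs(float(nvec @ nhat)), 1e-12))
        seen.setdefault(pa, 0.0)
        seen[pa] = seen[pa] + clipped.length
        seen.setdefault(pb, 0.0)
        seen[pb] = seen[pb] + clipped.length

    # boundary faces: cell polygon edges lying on the outline
    boundary = poly.exterior
    tol = 1e-6 * np.sqrt(poly.area)
    for i, cell in enumerate(cells):
        coords = np.asarray(cell.exterior.coords)
        for a, b in zip(coords[:-1], coords[1:]):
            mid = (a + b) / 2
            length = np.linalg.norm(b - a)
            if length <= 0:
                continue
            if boundary.distance(Point(mid)) < tol:
                t = (b - a) / length
                nhat = np.array([t[1], -t[0]])
                if nhat @ (mid - points[i]) < 0:
                    nhat = -nhat
                face_cells.append((i, -1))
                face_normal.append(nhat)
                face_measure.append(length)
                face_dist.append(np.linalg.norm(mid - points[i]))

    mesh = Mesh(
        points,
        measure,
        np.array(face_cells),
        np.array(face_normal, dtype=float),
        np.array(face_measure),
        np.array(face_dist),
        dim=2,
        outline=outline,
    )
    if abs(mesh.total_measure - poly.area) > 5e-3 * poly.area:
        raise MeshGenerationError("clipped cell areas do not tile the outline")
    if not mesh.is_connected():
        raise MeshGenerationError("generated mesh is not connected")
    return mesh


def _head_tail_flags(mesh: Mesh, kept: np.ndarray):
    """Original-mesh cell ids marking the anterior and posterior tips."""
    head_cell = int(np.argmin(mesh.points[:, 0]))
    tail_cell = int(np.argmax(mesh.points[:, 0]))
    return head_cell, tail_cell


def cut_mesh(
    mesh: Mesh, cuts: list[CutLine], kerf: float | None = None
) -> list[Fragment]:
    """Amputate along cut polylines and return the connected fragments.

    Cells whose centroid lies within ``kerf/2`` of a cut polyline are removed
    (default kerf: one mean cell size, which guarantees topological separation
    on Voronoi meshes).  Interior faces left with a single surviving cell
    become closed wound boundary, tagged with the cut label and an
    anterior/posterior facing from the sign of their outward normal's
    x-component.  Fragments are returned ordered by anterior-most cell.
    """
    if not cuts:
        frag_mesh = Mesh(
            mesh.points.copy(),
            mesh.measure.copy(),
            mesh.face_cells.copy(),
            mesh.face_normal.copy(),
            mesh.face_measure.copy(),
            mesh.face_dist.copy(),
            mesh.dim,
            outline=mesh.outline,
            face_cut_label=list(mesh.face_cut_label),
        )
        head, tail = _head_tail_flags(mesh, np.arange(mesh.n_cells))
        return [
            Fragment(
                frag_mesh,
                np.arange(mesh.n_cells),
                {},
                has_head=True,
                has_tail=True,
            )
        ]
    if kerf is None:
        kerf = mesh.h
    if kerf < 0:
        raise ValueError("kerf must be non-negative")

    lines = [c.linestring() for c in cuts]
    pts = [Point(p) for p in mesh.points]
    dists = np.array([[ln.distance(p) for p in pts] for ln in lines])
    removed = np.any(dists <= kerf / 2 + 1e-15, axis=0)
    if removed.all():
        raise ValueError("cuts removed every cell of the mesh")
    nearest_cut = np.argmin(dists, axis=0)

    # faces whose centroid-to-centroid segment crosses a cut polyline are
    # severed even if both cells survive the kerf (guarantees topological
    # separation on irregular Voronoi cells)
    severed = {}
    for f in mesh.interior_faces:
        a, b = mesh.face_cells[f]
        if removed[a] or removed[b]:
            continue
        seg = LineString([mesh.points[a], mesh.points[b]])
        for ci, ln in enumerate(lines):
            if seg.intersects(ln):
                severed[f] = cuts[ci].label
                break
    if not removed.any() and not severed:
        raise ValueError(
            "cuts do not intersect the mesh interior (no cells within kerf "
            "and no faces crossed)"
        )

    kept = np.flatnonzero(~removed)
    new_id = -np.ones(mesh.n_cells, dtype=np.int64)
    new_id[kept] = np.arange(len(kept))

    # classify faces of the cut mesh
    face_rows = []  # (a_new, b_new, normal, measure, dist, label, facing)
    for f in range(mesh.n_faces):
        a, b = mesh.face_cells[f]
        a_alive = not removed[a]
        b_alive = b >= 0 and not removed[b]
        if b < 0:
            if a_alive:
                face_rows.append(
                    (
                        new_id[a],
                        -1,
                        mesh.face_normal[f],
                        mesh.face_measure[f],
                        mesh.face_dist[f],
                        mesh.face_cut_label[f],
                    )
                )
            continue
        if a_alive and b_alive:
            if f in severed:
                # cut passes between the two surviving cells: both sides
                # become closed wound boundary
                face_rows.append(
                    (
                        new_id[a],
                        -1,
                        mesh.face_normal[f],
                        mesh.face_measure[f],
                        mesh.face_dist[f],
                        severed[f],
                    )
                )
                face_rows.append(
                    (
                        new_id[b],
                        -1,
                        -mesh.face_normal[f],
                        mesh.face_measure[f],
                        mesh.face_dist[f],
                        severed[f],
                    )
                )
            else:
                face_rows.append(
                    (
                        new_id[a],
                        new_id[b],
                        mesh.face_normal[f],
                        mesh.face_measure[f],
                        mesh.face_dist[f],
                        "",
                    )
                )
        elif a_alive or b_alive:
            # newly exposed wound face; orient outward from the survivor
            surv, gone = (a, b) if a_alive else (b, a)
            nhat = mesh.face_normal[f] if a_alive else -mesh.face_normal[f]
            label = cuts[nearest_cut[gone]].label
            face_rows.append(
                (
                    new_id[surv],
                    -1,
                    nhat,
                    mesh.face_measure[f],
                    mesh.face_dist[f],
                    label,
                )
            )

    sub_points = mesh.points[kept]
    sub_measure = mesh.measure[kept]
    fc = np.array([(r[0], r[1]) for r in face_rows], dtype=np.int64)
    fn = np.array([r[2] for r in face_rows], dtype=float)
    fm = np.array([r[3] for r in face_rows], dtype=float)
    fd = np.array([r[4] for r in face_rows], dtype=float)
    labels = [r[5] for r in face_rows]

    whole = Mesh(
        sub_points, sub_measure, fc, fn, fm, fd, mesh.dim,
        outline=mesh.outline, face_cut_label=labels,
    )
    n_comp, comp = connected_components(whole.adjacency_graph(), directed=False)

    # majority facing per cut line resolves near-degenerate normals
    wound_faces = [
        i for i, lab in enumerate(labels) if lab and fc[i, 1] < 0
    ]
    majority = {}
    for lab in {labels[i] for i in wound_faces}:
        nx = [fn[i, 0] for i in wound_faces if labels[i] == lab]
        majority[lab] = "anterior" if np.mean(nx) < 0 else "posterior"

    head_cell, tail_cell = _head_tail_flags(mesh, kept)
    frags = []
    for c in range(n_comp):
        cells_c = np.flatnonzero(comp == c)
        local = -np.ones(whole.n_cells, dtype=np.int64)
        local[cells_c] = np.arange(len(cells_c))
        keep_f = [
            i
            for i in range(whole.n_faces)
            if comp[fc[i, 0]] == c
        ]
        f_cells = np.array(
            [
                (local[fc[i, 0]], local[fc[i, 1]] if fc[i, 1] >= 0 else -1)
                for i in keep_f
            ],
            dtype=np.int64,
        )
        fmesh = Mesh(
            whole.points[cells_c],
            whole.measure[cells_c],
            f_cells,
            fn[keep_f],
            fm[keep_f],
            fd[keep_f],
            mesh.dim,
            outline=mesh.outline,
            face_cut_label=[labels[i] for i in keep_f],
        )
        wounds: dict = {}
        for j, i in enumerate(keep_f):
            lab = labels[i]
            if not lab or f_cells[j, 1] >= 0:
                continue
            nx = fn[i, 0]
            if abs(nx) < _FACING_TOL:
                facing = majority[lab]
            else:
                facing = "anterior" if nx < 0 else "posterior"
            wounds.setdefault(lab, {}).setdefault(facing, set()).add(
                int(f_cells[j, 0])
            )
        wounds = {
            lab: {
                facing: np.array(sorted(cells), dtype=np.int64)
                for facing, cells in sides.items()
            }
            for lab, sides in wounds.items()
        }
        orig = kept[cells_c]
        frags.append(
            Fragment(
                fmesh,
                orig,
                wounds,
                has_head=head_cell in orig,
                has_tail=tail_cell in orig,
            )
        )
    frags.sort(key=lambda fr: fr.mesh.points[:, 0].min())
    return frags
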