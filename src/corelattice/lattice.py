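"""Polyhedral core lattices and their proper rotation groups.

The icosahedral 60-mer E2 core of the pyruvate dehydrogenase complex is
modelled as a dodecahedral graph: each vertex is one E2 trimer, each edge is
one twofold "bridge" interface between adjacent trimers (one PX binding
pocket per bridge).  The octahedral 24-mer core is the analogous cube graph.
Because the core scaffold has a fixed handedness, only orientation-preserving
(proper) rotations are admitted as symmetries.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

__all__ = [
    "CoreLattice",
    "RotationGroup",
    "build_core",
    "graph_distance",
    "rotation_group",
    "BUILTIN_CORES",
]

_PHI = (1.0 + math.sqrt(5.0)) / 2.0

#: tolerance for matching rotated vertex coordinates onto the vertex set
_COORD_TOL = 1e-9
#: relative tolerance for the nearest-neighbour edge criterion
_EDGE_TOL = 1e-6


class LatticeError(ValueError):
    """Raised for unknown lattices or inconsistent user polyhedra."""


@dataclass(frozen=True)
class CoreLattice:
    """A polyhedral trimer-site graph.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"icosahedral-60mer"``.
    n_subunits_per_vertex : int
        Number of protein subunits per lattice site (3 for E2 trimers).
    edges : tuple of (int, int)
        Sorted unordered vertex pairs; each edge is one twofold bridge
        binding pocket.
    coords : numpy.ndarray, shape (n, 3)
        Unit-sphere coordinates of the vertices.  Vertex ids are assigned by
        lexicographic sort of the rounded coordinates, so the indexing is
        reproducible.
    dist : numpy.ndarray, shape (n, n)
        All-pairs graph-distance table.
    """

    name: str
    n_subunits_per_vertex: int
    edges: tuple[tuple[int, int], ...]
    coords: np.ndarray = field(repr=False)
    dist: np.ndarray = field(repr=False)

    @property
    def n_vertices(self) -> int:
        return self.coords.shape[0]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_subunits(self) -> int:
        """Total protein subunits in the core (60 for the icosahedral core)."""
        return self.n_vertices * self.n_subunits_per_vertex

    @property
    def vertices(self) -> range:
        return range(self.n_vertices)

    def neighbors(self, v: int) -> tuple[int, ...]:
        self._check_vertex(v)
        return tuple(u for u in self.vertices if self.dist[v, u] == 1)

    def _check_vertex(self, v: int) -> None:
        if not (isinstance(v, (int, np.integer)) and 0 <= v < self.n_vertices):
            raise LatticeError(f"invalid vertex id {v!r} for lattice {self.name!r}")

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.edges)
        return g

    def summary(self) -> dict:
        return {
            "name": self.name,
            "n_vertices": self.n_vertices,
            "n_edges": self.n_edges,
            "n_subunits_per_vertex": self.n_subunits_per_vertex,
            "n_subunits": self.n_subunits,
            "degree": sorted({len(self.neighbors(v)) for v in self.vertices}),
            "diameter": int(self.dist.max()),
        }


@dataclass(frozen=True)
class RotationGroup:
    """Proper rotation group of a lattice as (permutation, matrix) pairs.

    ``elements[0]`` is always the identity.  Every matrix is orthogonal with
    determinant +1; every permutation preserves the edge set.  Reflections
    and the central inversion are excluded because the core handedness is
    fixed.
    """

    elements: tuple[tuple[tuple[int, ...], np.ndarray], ...]

    @property
    def order(self) -> int:
        return len(self.elements)

    @property
    def permutations(self) -> tuple[tuple[int, ...], ...]:
        return tuple(p for p, _ in self.elements)

    def apply(self, perm: tuple[int, ...], occupied) -> frozenset:
        """Image of a vertex set under one group permutation."""
        return frozenset(perm[v] for v in occupied)


def _dodecahedron_coords() -> np.ndarray:
    pts = []
    for sx in (-1, 1):
        for sy in (-1, 1):
            for sz in (-1, 1):
                pts.append((sx, sy, sz))
    for s1 in (-1, 1):
        for s2 in (-1, 1):
            pts.append((0.0, s1 / _PHI, s2 * _PHI))
            pts.append((s1 / _PHI, s2 * _PHI, 0.0))
            pts.append((s1 * _PHI, 0.0, s2 / _PHI))
    return np.asarray(pts, dtype=float)


def _cube_coords() -> np.ndarray:
    return np.asarray(
        [(sx, sy, sz) for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
        dtype=float,
    )


BUILTIN_CORES: dict[str, dict] = {
    "icosahedral-60mer": {"coords": _dodecahedron_coords, "subunits": 3},
    "octahedral-24mer": {"coords": _cube_coords, "subunits": 3},
}


def _edges_from_coords(coords: np.ndarray) -> tuple[tuple[int, int], ...]:
    """Edges = vertex pairs at the minimal inter-vertex separation."""
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.linalg.norm(diff, axis=-1)
    n = coords.shape[0]
    off = d[~np.eye(n, dtype=bool)]
    dmin = off.min()
    edges = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if d[i, j] <= dmin * (1.0 + _EDGE_TOL)
    ]
    return tuple(edges)


def _distance_table(n: int, edges) -> np.ndarray:
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    if not nx.is_connected(g):
        raise LatticeError("lattice graph is not connected")
    dist = np.full((n, n), -1, dtype=int)
    for u, lengths in nx.all_pairs_shortest_path_length(g):
        for v, d in lengths.items():
            dist[u, v] = d
    return dist


def _normalize_and_sort(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    norms = np.linalg.norm(coords, axis=1)
    if np.any(norms == 0):
        raise LatticeError("vertex at the origin cannot be normalized")
    coords = coords / norms[:, None]
    # reproducible vertex indexing: lexicographic order of rounded coordinates
    keys = np.round(coords, 9)
    order = np.lexsort((keys[:, 2], keys[:, 1], keys[:, 0]))
    return coords[order]


def _assemble(name: str, coords: np.ndarray, n_subunits_per_vertex: int) -> CoreLattice:
    coords = _normalize_and_sort(coords)
    n = coords.shape[0]
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    if np.any(d[~np.eye(n, dtype=bool)] < _COORD_TOL):
        raise LatticeError("vertex coordinates are not pairwise distinct")
    edges = _edges_from_coords(coords)
    dist = _distance_table(n, edges)
    coords.setflags(write=False)
    dist.setflags(write=False)
    return CoreLattice(
        name=name,
        n_subunits_per_vertex=n_subunits_per_vertex,
        edges=edges,
        coords=coords,
        dist=dist,
    )


def _load_user_polyhedron(path: Path) -> CoreLattice:
    try:
        spec = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise LatticeError(f"cannot parse polyhedron JSON {path}: {exc}") from exc
    if "coords" not in spec:
        raise LatticeError(f"polyhedron JSON {path} lacks a 'coords' field")
    coords = _normalize_and_sort(np.asarray(spec["coords"], dtype=float))
    derived = set(_edges_from_coords(coords))
    if "edges" in spec:
        # User edges are given against the user's vertex order; remap onto the
        # sorted indexing before comparing with the geometric criterion.
        orig = _user_order_map(np.asarray(spec["coords"], dtype=float), coords)
        user_edges = {
            tuple(sorted((orig[i], orig[j]))) for i, j in spec["edges"]
        }
        if user_edges != derived:
            raise LatticeError(
                "edge list inconsistent with coordinates: edges must connect "
                "exactly the vertex pairs at the minimal (constant) "
                "nearest-neighbour distance"
            )
    return _assemble(str(path), coords, int(spec.get("n_subunits_per_vertex", 3)))


def _user_order_map(raw: np.ndarray, sorted_coords: np.ndarray) -> list[int]:
    raw = raw / np.linalg.norm(raw, axis=1)[:, None]
    mapping = []
    for p in raw:
        hits = np.where(np.linalg.norm(sorted_coords - p, axis=1) < 1e-6)[0]
        if hits.size != 1:
            raise LatticeError("could not match user vertex onto sorted coordinates")
        mapping.append(int(hits[0]))
    return mapping


def build_core(name: str) -> CoreLattice:
    """Construct a built-in core lattice or load a user polyhedron.

    Parameters
    ----------
    name : str
        One of :data:`BUILTIN_CORES` (``"icosahedral-60mer"``,
        ``"octahedral-24mer"``) or a path to a JSON file of the form
        ``{"coords": [[x, y, z], ...], "edges": [[i, j], ...]}`` with 0-based
        vertex ids.

    Returns
    -------
    CoreLattice
    """
    if name in BUILTIN_CORES:
        entry = BUILTIN_CORES[name]
        return _assemble(name, entry["coords"](), entry["subunits"])
    path = Path(name)
    if path.suffix == ".json" and path.exists():
        return _load_user_polyhedron(path)
    raise LatticeError(
        f"unknown core {name!r}; choose one of {sorted(BUILTIN_CORES)} "
        "or a path to a polyhedron JSON file"
    )


def graph_distance(core: CoreLattice, u: int, v: int) -> int:
    """Shortest-path length between two trimer sites."""
    core._check_vertex(u)
    core._check_vertex(v)
    return int(core.dist[u, v])


def _rotation_from_frames(a0, a1, b0, b1) -> np.ndarray | None:
    """Unique rotation mapping unit vectors (a0, a1) onto (b0, b1), if proper."""
    fa = np.column_stack([a0, a1, np.cross(a0, a1)])
    fb = np.column_stack([b0, b1, np.cross(b0, b1)])
    try:
        rot = fb @ np.linalg.inv(fa)
    except np.linalg.LinAlgError:  # pragma: no cover - non-degenerate frames only
        return None
    if not np.allclose(rot @ rot.T, np.eye(3), atol=1e-8):
        return None
    if np.linalg.det(rot) < 0:
        return None
    return rot


def _permutation_of(core: CoreLattice, rot: np.ndarray) -> tuple[int, ...] | None:
    imgs = core.coords @ rot.T
    perm = []
    for p in imgs:
        hits = np.where(np.linalg.norm(core.coords - p, axis=1) < 1e-6)[0]
        if hits.size != 1:
            return None
        perm.append(int(hits[0]))
    if len(set(perm)) != core.n_vertices:
        return None
    # exact coordinate match within the stated tolerance
    if np.max(np.linalg.norm(core.coords[perm] - imgs, axis=1)) > _COORD_TOL * 1e3:
        return None
    return tuple(perm)


def rotation_group(core: CoreLattice) -> RotationGroup:
    """Enumerate all proper rotations mapping the vertex set onto itself.

    Candidates are generated by mapping one reference vertex and one of its
    neighbours to every compatible image pair; each candidate matrix is kept
    if it is a proper rotation that permutes the vertex coordinate set.  For
    the dodecahedral lattice this yields the icosahedral rotation group I
    (order 60); for the cube lattice the octahedral rotation group O
    (order 24).  User polyhedra with no nontrivial symmetry yield the
    trivial group.
    """
    v0 = 0
    nbrs0 = core.neighbors(v0)
    v1 = nbrs0[0]
    a0, a1 = core.coords[v0], core.coords[v1]
    seen: dict[tuple[int, ...], np.ndarray] = {}
    for w0 in core.vertices:
        for w1 in core.neighbors(w0):
            rot = _rotation_from_frames(a0, a1, core.coords[w0], core.coords[w1])
            if rot is None:
                continue
            perm = _permutation_of(core, rot)
            if perm is not None and perm not in seen:
                seen[perm] = rot
    identity = tuple(core.vertices)
    if identity not in seen:  # pragma: no cover - identity always found
        seen[identity] = np.eye(3)
    ordered = [identity] + sorted(p for p in seen if p != identity)
    elements = tuple((p, seen[p]) for p in ordered)
    return RotationGroup(elements=elements)
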