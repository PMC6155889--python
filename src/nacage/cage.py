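"""Deterministic builder for idealized DNA polyhedral cages.

The target architecture is the classic truncated-octahedron nanocage: every
edge of an octahedron is realised as an ideal B-DNA duplex and every vertex
joins its four incident duplexes through short single-stranded linkers, so
that the whole cage threads into eight covalently closed oligonucleotides.
Each nucleotide is reduced to pseudo-atoms on concentric helical tracks:
P (backbone phosphate), O4* (sugar oxygen), C4* (sugar carbon) and C2
(base), which downstream coarse-graining subsets into one-, two- or
three-node representations.

Coordinates are in Angstrom; helices are right-handed.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (InfeasibleGeometryError, InvalidArgumentError,
                     UnsupportedPolyhedronError)
from .structure import Atom, ResidueAnnotation, Structure

# ---------------------------------------------------------------------------
# parameters


@dataclass(frozen=True)
class HelixParams:
    """Idealized B-DNA fiber geometry.

    rise_per_bp and twist_per_bp are the canonical B-form values
    (3.38 A, 36 deg -> 10 bp/turn). The track radii place P outermost,
    the sugar atoms in between and the base C2 innermost; strand2_phase is
    the angular offset of the second backbone, which sets the minor-groove
    width.
    """

    rise_per_bp: float = 3.38      # A
    twist_per_bp: float = 36.0     # deg
    radius_P: float = 8.9          # A
    radius_O4: float = 7.9         # A
    radius_C4: float = 7.0         # A
    radius_C2: float = 3.5         # A
    strand2_phase: float = 154.0   # deg
    #: optional azimuthal offset of each track from the P track (deg);
    #: zero keeps all of a residue's pseudo-atoms on one radial ray
    angle_O4: float = 0.0
    angle_C4: float = 0.0
    angle_C2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("rise_per_bp", "radius_P", "radius_O4", "radius_C4",
                     "radius_C2"):
            if getattr(self, name) <= 0:
                raise InvalidArgumentError(f"{name} must be positive")

    def track_radii(self, include_O4: bool = False) -> dict[str, float]:
        radii = {"P": self.radius_P, "O4*": self.radius_O4,
                 "C4*": self.radius_C4, "C2": self.radius_C2}
        if not include_O4:
            del radii["O4*"]
        return radii

    def track_angles(self) -> dict[str, float]:
        """Azimuthal track offsets (deg) relative to the P track."""
        return {"P": 0.0, "O4*": self.angle_O4, "C4*": self.angle_C4,
                "C2": self.angle_C2}

    def pp_distance(self) -> float:
        """Closed-form intra-strand P-P distance between consecutive bp."""
        half = math.radians(self.twist_per_bp) / 2.0
        chord = 2.0 * self.radius_P * math.sin(half)
        return math.sqrt(self.rise_per_bp ** 2 + chord ** 2)


@dataclass(frozen=True)
class CageSpec:
    """Design parameters of a polyhedral DNA cage.

    The default spec is the 552-nucleotide truncated octahedron: 12 edges
    of 18 bp and 24 single-strand linkers of 5 nt (2*18*12 + 5*24 = 552).
    ``edge_length_scale`` is the centre-to-vertex distance; when None it is
    derived so the helix plus two vertex stand-offs exactly spans an edge.
    ``jitter`` adds Gaussian coordinate noise (A std dev) seeded by ``seed``
    for roughness experiments; the default 0 keeps the builder bitwise
    deterministic.
    """

    polyhedron_name: str = "octahedron"
    edge_bp: int = 18
    linker_nt: int = 5
    edge_length_scale: float | None = None
    helix_params: HelixParams = field(default_factory=HelixParams)
    seed: int = 0
    jitter: float = 0.0
    #: add the O4* sugar-oxygen track (needed for the two-node P/O4*
    #: coarse-graining; the default three-track residue is P, C4*, C2)
    include_O4: bool = False

    def __post_init__(self) -> None:
        if self.edge_bp < 1:
            raise InvalidArgumentError("edge_bp must be >= 1")
        if self.linker_nt < 0:
            raise InvalidArgumentError("linker_nt must be >= 0")
        if self.jitter < 0:
            raise InvalidArgumentError("jitter must be >= 0")

    @property
    def standoff(self) -> float:
        """Vertex stand-off distance of helix termini, in A.

        ~2.8 A of opening per linker nucleotide puts the default truncation
        gap beyond the three-node GNM cutoff, so vertex coupling flows
        through the linkers rather than through direct duplex-duplex
        contacts; the floor of the P-track radius plus a clearance margin
        keeps the four duplex ends meeting at a vertex from clashing even
        with linker_nt=0.
        """
        return max(self.linker_nt * 2.8,
                   self.helix_params.radius_P + 3.9)

    def n_residues(self) -> int:
        vertices, edges = polyhedron_skeleton(self.polyhedron_name)
        degree = 2 * len(edges) // len(vertices)
        n_linkers = degree * len(vertices)
        return 2 * self.edge_bp * len(edges) + self.linker_nt * n_linkers


# ---------------------------------------------------------------------------
# polyhedron skeleton

_POLYHEDRA = {
    "octahedron": (
        np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0],
                  [0, -1.0, 0], [0, 0, 1.0], [0, 0, -1.0]]),
    ),
}


def polyhedron_skeleton(name: str) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Unit vertices and edge list (vertex-index pairs, i < j) of a polyhedron.

    The octahedron has 6 vertices at the signed unit basis vectors and the
    12 edges between every non-antipodal pair; all edges have length
    sqrt(2).
    """
    if name not in _POLYHEDRA:
        raise UnsupportedPolyhedronError(f"unsupported polyhedron: {name!r}")
    (vertices,) = _POLYHEDRA[name]
    edges = []
    for i, j in itertools.combinations(range(len(vertices)), 2):
        if np.allclose(vertices[i], -vertices[j]):
            continue  # antipodal pair, no edge
        edges.append((i, j))
    return vertices.copy(), edges


# ---------------------------------------------------------------------------
# helix construction

#: residue atom tracks in node order (outermost to innermost radius)
_ATOM_ORDER = ("P", "O4*", "C4*", "C2")


def _helix_local(n_bp: int, params: HelixParams, phase: float,
                 include_O4: bool = False) -> list[tuple]:
    """Helix atoms in the canonical frame (axis = +z, first bp at z = 0).

    Returns (strand, residue_index, bp_index, atom_name, xyz) tuples.
    Strand "A" runs 5'->3' with increasing z; strand "B" is antiparallel,
    numbered in reverse so residue 1 of B pairs with residue n_bp of A.
    """
    twist = math.radians(params.twist_per_bp)
    phase = math.radians(phase)
    phase2 = math.radians(params.strand2_phase)
    angles = params.track_angles()
    out = []
    for i in range(n_bp):
        z = i * params.rise_per_bp
        a1 = i * twist + phase
        for name, radius in params.track_radii(include_O4).items():
            off = math.radians(angles[name])
            # strand B mirrors the track offsets (antiparallel geometry)
            aa = a1 + off
            ab = a1 + phase2 - off
            out.append(("A", i + 1, i, name,
                        np.array([radius * math.cos(aa),
                                  radius * math.sin(aa), z])))
            out.append(("B", n_bp - i, i, name,
                        np.array([radius * math.cos(ab),
                                  radius * math.sin(ab), z])))
    return out


def _frame_rotation(axis: np.ndarray, reference: np.ndarray | None = None
                    ) -> np.ndarray:
    """Rotation matrix whose third column is ``axis`` (unit).

    If ``reference`` (not parallel to axis) is given it fixes the in-plane
    x' direction deterministically; otherwise the least-rotation map from
    +z is used.
    """
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise InvalidArgumentError("axis must be non-zero")
    ez = axis / norm
    if reference is not None:
        ex = np.asarray(reference, dtype=float)
        ex = ex - np.dot(ex, ez) * ez
        if np.linalg.norm(ex) < 1e-12:
            raise InvalidArgumentError("reference parallel to axis")
        ex /= np.linalg.norm(ex)
        ey = np.cross(ez, ex)
        return np.column_stack([ex, ey, ez])
    # least rotation taking +z onto ez
    z0 = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(z0, ez))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        return np.diag([1.0, -1.0, -1.0])
    v = np.cross(z0, ez)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def build_helix(n_bp: int, origin, axis, params: HelixParams | None = None,
                phase: float = 0.0, *, reference=None, include_O4: bool = False,
                strand_names: tuple[str, str] = ("A", "B")) -> Structure:
    """Construct an ideal B-DNA duplex of ``n_bp`` base pairs.

    The duplex is generated on the z-axis (first base pair in the z=0
    plane) and rigidly mapped so its axis lies along ``axis`` starting at
    ``origin``. ``phase`` rotates the helix about its own axis (degrees).
    Residues alternate C/G by base-pair parity; sequence plays no role in
    the elastic models.
    """
    if n_bp < 1:
        raise InvalidArgumentError("n_bp must be >= 1")
    params = params or HelixParams()
    rot = _frame_rotation(axis, reference)
    origin = np.asarray(origin, dtype=float)
    atoms = []
    for strand, resi, bp, name, xyz in _helix_local(n_bp, params, phase,
                                                    include_O4):
        label = strand_names[0] if strand == "A" else strand_names[1]
        base = ("C" if bp % 2 == 0 else "G") if strand == "A" else \
               ("G" if bp % 2 == 0 else "C")
        atoms.append(Atom(label, resi, base, name, rot @ xyz + origin))
    atoms.sort(key=lambda a: (a.strand_id, a.residue_index,
                              _ATOM_ORDER.index(a.atom_name)))
    return Structure(atoms=atoms)


# ---------------------------------------------------------------------------
# cage assembly

#: offsets (A) of linker pseudo-atoms from the backbone arc point, along the
#: outward arc normal; a single-strand nucleotide is a compact cluster, so
#: the offsets stay within the ~3 A backbone-to-base span
_LINKER_OFFSETS = {"P": 0.0, "O4*": 0.8, "C4*": 1.5, "C2": 3.0}


def _arc_points(a: np.ndarray, b: np.ndarray, outward: np.ndarray,
                n_points: int, spacing: float = 6.0
                ) -> tuple[np.ndarray, np.ndarray]:
    """Interior points of a circular arc from ``a`` to ``b``.

    The arc lies in the plane of the chord and ``outward`` (the radial
    direction away from the cage centre), bulges outward, and has total
    length (n_points + 1) * spacing so consecutive points keep the
    single-strand backbone spacing. Falls back to straight-line
    interpolation when the chord is already that long. Returns the points
    and their outward normals (for stacking the pseudo-atom tracks).
    """
    from scipy.optimize import brentq
    chord = b - a
    c = float(np.linalg.norm(chord))
    m = 0.5 * (a + b)
    u = outward - np.dot(outward, chord) * chord / c ** 2
    u = u / np.linalg.norm(u)
    length = (n_points + 1) * spacing
    ts = np.arange(1, n_points + 1) / (n_points + 1)
    if length <= c * (1.0 + 1e-9):
        pts = a + np.outer(ts, chord)
        return pts, np.tile(u, (n_points, 1))
    # circle through a and b with arc length `length`:
    # c = 2 R sin(theta/2), length = R theta  ->  solve for theta
    f = lambda th: th / (2.0 * math.sin(th / 2.0)) - length / c
    theta = brentq(f, 1e-9, 2.0 * math.pi - 1e-9)
    radius = length / theta
    sag = math.sqrt(max(radius ** 2 - (c / 2.0) ** 2, 0.0))
    # centre below the chord for a minor arc, above for a major arc
    center = m - u * sag if theta <= math.pi else m + u * sag
    e1 = (a - center) / np.linalg.norm(a - center)
    # rotate from a to b the short way through the outward side
    e2 = u - np.dot(u, e1) * e1
    e2 = e2 / np.linalg.norm(e2)
    angles = ts * theta
    pts = center + radius * (np.outer(np.cos(angles), e1)
                             + np.outer(np.sin(angles), e2))
    normals = pts - center
    normals /= np.linalg.norm(normals, axis=1)[:, None]
    return pts, normals


def _cyclic_order(center: np.ndarray, neighbors: list[int],
                  vertices: np.ndarray) -> list[int]:
    """Order neighbor vertices cyclically around the vertex axis."""
    w = center / np.linalg.norm(center)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, w)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    b1 = ref - np.dot(ref, w) * w
    b1 /= np.linalg.norm(b1)
    b2 = np.cross(w, b1)

    def angle(k: int) -> float:
        u = vertices[k] - center
        return math.atan2(float(np.dot(u, b2)), float(np.dot(u, b1)))

    return sorted(neighbors, key=angle)


def build_cage(spec: CageSpec | None = None) -> Structure:
    """Assemble the full polyhedral cage from a :class:`CageSpec`.

    One duplex per edge, centred on the edge midpoint and aligned with it,
    termini held a stand-off distance from each vertex; at each vertex four
    single-stranded linkers run on outward-bulging arcs from the 3' end of
    one duplex strand to the 5' end of the next duplex (cyclically around
    the vertex axis). Following those connections threads the octahedron
    cage into exactly 8 closed strands, which become the strand_ids.

    Raises :class:`InfeasibleGeometryError` when two duplexes approach
    within 2 A.
    """
    spec = spec or CageSpec()
    params = spec.helix_params
    unit_vertices, edges = polyhedron_skeleton(spec.polyhedron_name)

    helix_len = (spec.edge_bp - 1) * params.rise_per_bp
    unit_edge = float(np.linalg.norm(unit_vertices[edges[0][0]]
                                     - unit_vertices[edges[0][1]]))
    if spec.edge_length_scale is None:
        edge_len = helix_len + 2.0 * spec.standoff
        scale = edge_len / unit_edge
    else:
        scale = spec.edge_length_scale
        edge_len = scale * unit_edge
        if edge_len < helix_len + 2.0 * spec.standoff - 1e-9:
            raise InfeasibleGeometryError(
                "edge_length_scale too small for helix plus stand-offs")
    vertices = unit_vertices * scale

    # --- duplexes, one per edge, in an edge-covariant frame -------------
    # frame: z' along the edge, x' along the outward mid-edge direction;
    # this makes every edge an exact symmetry copy of every other.
    edge_atoms: list[list[tuple]] = []   # per edge: local atom records
    # terminal P positions per (edge, duplex strand, vertex end)
    term_P: dict[tuple[int, str, int], np.ndarray] = {}
    for ei, (i, j) in enumerate(edges):
        v1, v2 = vertices[i], vertices[j]
        axis = v2 - v1
        axis_u = axis / np.linalg.norm(axis)
        outward = v1 + v2
        rot = _frame_rotation(axis_u, reference=outward)
        start = 0.5 * (v1 + v2) - axis_u * (helix_len / 2.0)
        records = []
        for strand, resi, bp, name, xyz in _helix_local(
                spec.edge_bp, params, phase=0.0, include_O4=spec.include_O4):
            pos = rot @ xyz + start
            records.append((strand, resi, bp, name, pos))
            if name == "P":
                # duplex strand "A" runs 5'->3' from v1 to v2; "B" reverse
                if strand == "A" and resi == 1:
                    term_P[(ei, "A", i)] = pos      # A 5' at v1
                if strand == "A" and resi == spec.edge_bp:
                    term_P[(ei, "A", j)] = pos      # A 3' at v2
                if strand == "B" and resi == 1:
                    term_P[(ei, "B", j)] = pos      # B 5' at v2
                if strand == "B" and resi == spec.edge_bp:
                    term_P[(ei, "B", i)] = pos      # B 3' at v1
        edge_atoms.append(records)

    _check_edge_clearance(edge_atoms)

    # --- linker connectivity around each vertex -------------------------
    # at vertex v each incident edge offers one outgoing (3') and one
    # incoming (5') strand terminus; linker k joins outgoing of edge k to
    # incoming of edge k+1 in cyclic order.
    #   outgoing at v: duplex strand whose 3' end sits at v
    #   incoming at v: duplex strand whose 5' end sits at v
    incident: dict[int, list[int]] = {vi: [] for vi in range(len(vertices))}
    for ei, (i, j) in enumerate(edges):
        incident[i].append(ei)
        incident[j].append(ei)

    def out_strand(ei: int, vi: int) -> str:
        i, j = edges[ei]
        return "A" if vi == j else "B"

    def in_strand(ei: int, vi: int) -> str:
        i, j = edges[ei]
        return "A" if vi == i else "B"

    # successor map on (edge, duplex strand): who do we run into next
    successor: dict[tuple[int, str], tuple[int, str]] = {}
    linkers = []  # (vertex, from (edge,strand), to (edge,strand), A, B)
    for vi in range(len(vertices)):
        eis = incident[vi]
        order = _cyclic_order(vertices[vi],
                              [_other(edges[e], vi) for e in eis], vertices)
        ordered = [eis[[_other(edges[e], vi) for e in eis].index(nb)]
                   for nb in order]
        for k, ei in enumerate(ordered):
            ej = ordered[(k + 1) % len(ordered)]
            s_out, s_in = out_strand(ei, vi), in_strand(ej, vi)
            successor[(ei, s_out)] = (ej, s_in)
            linkers.append((vi, (ei, s_out), (ej, s_in),
                            term_P[(ei, s_out, vi)], term_P[(ej, s_in, vi)]))

    # --- thread closed oligonucleotide strands --------------------------
    cycles = _cycles(successor)
    strand_of: dict[tuple[int, str], tuple[str, int]] = {}
    width = len(str(len(cycles)))
    for ci, cycle in enumerate(cycles):
        sid = f"S{ci + 1:0{width}d}"
        for pos, node in enumerate(cycle):
            strand_of[node] = (sid, pos)

    # --- emit atoms with threaded strand ids and residue numbering ------
    atoms: list[Atom] = []
    annotations: dict[tuple[str, int], ResidueAnnotation] = {}
    helix_span = spec.edge_bp + spec.linker_nt  # residues per cycle segment

    for ei, records in enumerate(edge_atoms):
        for strand, resi, bp, name, pos in records:
            sid, seg = strand_of[(ei, strand)]
            resno = seg * helix_span + resi
            base = ("C" if bp % 2 == 0 else "G") if strand == "A" else \
                   ("G" if bp % 2 == 0 else "C")
            atoms.append(Atom(sid, resno, base, name, pos))
            annotations[(sid, resno)] = ResidueAnnotation(
                region="helix", element_index=ei, duplex_strand=strand)

    for vi, src, dst, pa, pb in linkers:
        if spec.linker_nt == 0:
            continue
        sid, seg = strand_of[src]
        # each linker bows outward from its own chord, so the four
        # single-strand loops around a vertex stay mutually separated
        # (the sides of the truncation square) instead of bunching at
        # the apex; pseudo-atom tracks stack along the arc normals
        mid = 0.5 * (pa + pb)
        outward = mid / np.linalg.norm(mid)
        pts, normals = _arc_points(pa, pb, outward, spec.linker_nt)
        for k in range(spec.linker_nt):
            p, d = pts[k], normals[k]
            resno = seg * helix_span + spec.edge_bp + k + 1
            for name, off in _LINKER_OFFSETS.items():
                if name == "O4*" and not spec.include_O4:
                    continue
                atoms.append(Atom(sid, resno, "T", name, p + off * d))
            annotations[(sid, resno)] = ResidueAnnotation(
                region="linker", element_index=vi)

    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        atoms = [replace(a, position=a.position
                         + rng.normal(0.0, spec.jitter, 3)) for a in atoms]

    atoms.sort(key=lambda a: (a.strand_id, a.residue_index,
                              _ATOM_ORDER.index(a.atom_name)))
    return Structure(atoms=atoms, annotations=annotations)


def _other(edge: tuple[int, int], vi: int) -> int:
    return edge[1] if edge[0] == vi else edge[0]


def _cycles(successor: dict) -> list[list]:
    """Cycle decomposition of the strand-threading permutation."""
    seen: set = set()
    cycles = []
    for start in sorted(successor):
        if start in seen:
            continue
        cycle = [start]
        seen.add(start)
        node = successor[start]
        while node != start:
            cycle.append(node)
            seen.add(node)
            node = successor[node]
        cycles.append(cycle)
    return cycles


def _check_edge_clearance(edge_atoms: list[list[tuple]],
                          min_dist: float = 2.0) -> None:
    from scipy.spatial import cKDTree
    coords = [np.array([rec[4] for rec in records])
              for records in edge_atoms]
    trees = [cKDTree(c) for c in coords]
    for a in range(len(coords)):
        for b in range(a + 1, len(coords)):
            d = trees[a].query(coords[b], k=1)[0].min()
            if d <= min_dist:
                raise InfeasibleGeometryError(
                    f"edges {a} and {b} approach within {d:.2f} A")
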