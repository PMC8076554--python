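"""Hierarchical scene geometry: the "what"-pathway half of the model.

A scene is generated top-down.  A categorical prior selects a *room*; the
room determines which *objects* are placed where; each object is defined
recursively as a configuration of simpler parts, bottoming out in a unit
sphere primitive.  Every level of the recursion applies the same three
affine operations, in a fixed order: anisotropic scaling (parameterized on
a log scale so that scales are positive by construction), rotation (an
intrinsic Euler composition, see :func:`rotation_matrix`), and
translation.  The carrier of all of this is a triangulated surface mesh.

Coordinates are right-handed with z up; lengths are meters and angles
radians.  The transforms are deterministic maps (Dirac-delta factors of
the generative density): all uncertainty lives in the priors over their
parameters, not in the geometry itself.

The module also ships a small demonstration world — three candidate rooms
sharing a 5x5x3 m shell, each containing two objects placed in corners —
used throughout the package to illustrate salience-driven gaze selection,
plus a "lesion" operation that deletes an object hypothesis from the
library (a generative-model reading of visual agnosia).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple, Union

import numpy as np

__all__ = [
    "LogScale",
    "EulerAngles",
    "AffineParams",
    "SurfaceMesh",
    "ObjectSpec",
    "Room",
    "RoomLibrary",
    "SceneConfigError",
    "make_sphere_mesh",
    "make_box_mesh",
    "scale_mesh",
    "rotation_matrix",
    "rotate_mesh",
    "translate_mesh",
    "apply_affine",
    "concatenate_meshes",
    "assemble_object",
    "assemble_room",
    "build_demo_library",
    "lesion_object_hypothesis",
    "library_to_dict",
    "library_from_dict",
    "read_scene",
    "write_scene",
    "DEMO_CORNERS",
    "DEMO_EYE_HEIGHT",
]

#: maximum recursion depth when assembling composite objects; specs deeper
#: than this are treated as cyclic.
MAX_ASSEMBLY_DEPTH = 32

#: allocentric (x, y) corner positions of the demo room's object sites,
#: with "east" = +x and "north" = +y.
DEMO_CORNERS = {
    "southeast": (1.8, -1.8),
    "northeast": (1.8, 1.8),
    "southwest": (-1.8, -1.8),
    "northwest": (-1.8, 1.8),
}

#: height (m) of object centres and of the demo viewer's eyes.
DEMO_EYE_HEIGHT = 1.2

_DEMO_ROOM_SIZE = (5.0, 5.0, 3.0)
_DEMO_ROOM_CENTER = (0.0, 0.0, 1.5)


def _as_vec3(v, name: str = "vector") -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must have finite components, got {arr}")
    return arr


@dataclass(frozen=True)
class LogScale:
    """Per-axis log scale parameters; the applied factors are exp of these."""

    alpha: float = 0.0
    beta: float = 0.0
    gamma: float = 0.0

    def factors(self) -> np.ndarray:
        """Strictly positive per-axis scale factors (e^alpha, e^beta, e^gamma)."""
        return np.exp([self.alpha, self.beta, self.gamma])


@dataclass(frozen=True)
class EulerAngles:
    """Intrinsic Euler angles (radians); see :func:`rotation_matrix`."""

    theta: float = 0.0
    phi: float = 0.0
    varphi: float = 0.0


@dataclass(frozen=True)
class AffineParams:
    """One level of the transform chain, applied scale -> rotate -> translate."""

    scale: LogScale = LogScale()
    rotation: EulerAngles = EulerAngles()
    translation: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    @staticmethod
    def identity() -> "AffineParams":
        return AffineParams()


def _face_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Unit normals from vertex winding; degenerate faces get a zero normal."""
    if len(faces) == 0:
        return np.zeros((0, 3))
    v0 = vertices[faces[:, 0]]
    e1 = vertices[faces[:, 1]] - v0
    e2 = vertices[faces[:, 2]] - v0
    n = np.cross(e1, e2)
    norm = np.linalg.norm(n, axis=1)
    good = norm > 1e-15
    out = np.zeros_like(n)
    out[good] = n[good] / norm[good, None]
    return out


@dataclass
class SurfaceMesh:
    """Triangulated surface: vertices (N,3), faces (M,3) indices, unit normals (M,3)."""

    vertices: np.ndarray
    faces: np.ndarray
    normals: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
        if len(self.faces) and self.faces.max(initial=-1) >= len(self.vertices):
            raise ValueError("face index exceeds vertex count")
        if len(self.normals) != len(self.faces):
            raise ValueError("one normal per face required")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def centroid(self) -> np.ndarray:
        if self.n_vertices == 0:
            return np.zeros(3)
        return self.vertices.mean(axis=0)

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy(), self.normals.copy())


def empty_mesh() -> SurfaceMesh:
    return SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), dtype=np.int64), np.zeros((0, 3)))


def _orient_outward(vertices: np.ndarray, faces: np.ndarray,
                    center: np.ndarray, inward: bool = False) -> np.ndarray:
    """Flip face winding so normals point away from (or toward) ``center``."""
    normals = _face_normals(vertices, faces)
    cent = vertices[faces].mean(axis=1)
    outwardness = np.einsum("ij,ij->i", normals, cent - center)
    wrong = outwardness > 0 if inward else outwardness < 0
    faces = faces.copy()
    faces[wrong] = faces[wrong][:, [0, 2, 1]]
    return faces


def make_sphere_mesh(resolution: int) -> SurfaceMesh:
    """Closed latitude-longitude triangulation of the unit sphere at the origin.

    ``resolution`` is the number of latitude bands; there are twice as many
    longitude segments.  Winding is oriented so normals point outward.
    """
    if not isinstance(resolution, (int, np.integer)) or resolution < 3:
        raise ValueError(f"resolution must be an integer >= 3, got {resolution!r}")
    n_lat = int(resolution)
    n_lon = 2 * n_lat

    polar = np.pi * np.arange(1, n_lat) / n_lat           # ring colatitudes
    azim = 2.0 * np.pi * np.arange(n_lon) / n_lon
    st, ct = np.sin(polar), np.cos(polar)
    rings = np.stack(
        [
            np.outer(st, np.cos(azim)),
            np.outer(st, np.sin(azim)),
            np.outer(ct, np.ones(n_lon)),
        ],
        axis=-1,
    ).reshape(-1, 3)
    vertices = np.vstack([[[0.0, 0.0, 1.0]], rings, [[0.0, 0.0, -1.0]]])
    south = len(vertices) - 1

    def ring(i: int, j: int) -> int:          # i-th ring (0-based), j-th azimuth
        return 1 + i * n_lon + (j % n_lon)

    faces = []
    for j in range(n_lon):                    # top cap
        faces.append((0, ring(0, j), ring(0, j + 1)))
    for i in range(n_lat - 2):                # quad bands split into triangles
        for j in range(n_lon):
            a, b = ring(i, j), ring(i, j + 1)
            c, d = ring(i + 1, j), ring(i + 1, j + 1)
            faces.append((a, c, b))
            faces.append((b, c, d))
    for j in range(n_lon):                    # bottom cap
        faces.append((south, ring(n_lat - 2, j + 1), ring(n_lat - 2, j)))

    faces = np.asarray(faces, dtype=np.int64)
    faces = _orient_outward(vertices, faces, np.zeros(3))
    return SurfaceMesh(vertices, faces, _face_normals(vertices, faces))


def make_box_mesh(size: Sequence[float], center: Sequence[float] = (0, 0, 0),
                  inward: bool = False, open_top: bool = False) -> SurfaceMesh:
    """Axis-aligned box of the given (x, y, z) size.

    With ``inward=True`` the normals face the interior — the convention for
    room walls viewed from inside.  ``open_top=True`` omits the +z face,
    leaving a roofless shell that an overhead directional light can reach.
    """
    size = _as_vec3(size, "size")
    center = _as_vec3(center, "center")
    half = size / 2.0
    corners = np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)],
        dtype=float,
    )
    vertices = center + corners * half
    # two triangles per face of the cube, indexed into the corner table
    quads = [
        (0, 1, 3, 2),  # -x
        (4, 6, 7, 5),  # +x
        (0, 4, 5, 1),  # -y
        (2, 3, 7, 6),  # +y
        (0, 2, 6, 4),  # -z
    ]
    if not open_top:
        quads.append((1, 5, 7, 3))  # +z
    faces = []
    for a, b, c, d in quads:
        faces.append((a, b, c))
        faces.append((a, c, d))
    faces = np.asarray(faces, dtype=np.int64)
    faces = _orient_outward(vertices, faces, center, inward=inward)
    return SurfaceMesh(vertices, faces, _face_normals(vertices, faces))


def scale_mesh(mesh: SurfaceMesh, scale: LogScale) -> SurfaceMesh:
    """Multiply vertex coordinates componentwise by exp of the log scales."""
    vertices = mesh.vertices * scale.factors()
    return SurfaceMesh(vertices, mesh.faces.copy(), _face_normals(vertices, mesh.faces))


def rotation_matrix(angles: EulerAngles) -> np.ndarray:
    """Rotation matrix for intrinsic rotations R = Rz(varphi) @ Ry(phi) @ Rx(theta).

    theta rotates about x, phi about y, varphi about z, applied in that
    order.  The result is orthogonal with determinant +1.
    """
    ct, st = math.cos(angles.theta), math.sin(angles.theta)
    cp, sp = math.cos(angles.phi), math.sin(angles.phi)
    cv, sv = math.cos(angles.varphi), math.sin(angles.varphi)
    rx = np.array([[1, 0, 0], [0, ct, -st], [0, st, ct]])
    ry = np.array([[cp, 0, sp], [0, 1, 0], [-sp, 0, cp]])
    rz = np.array([[cv, -sv, 0], [sv, cv, 0], [0, 0, 1]])
    return rz @ ry @ rx


def rotate_mesh(mesh: SurfaceMesh, angles: EulerAngles) -> SurfaceMesh:
    r = rotation_matrix(angles)
    vertices = mesh.vertices @ r.T
    return SurfaceMesh(vertices, mesh.faces.copy(), _face_normals(vertices, mesh.faces))


def translate_mesh(mesh: SurfaceMesh, offset) -> SurfaceMesh:
    offset = _as_vec3(offset, "offset")
    return SurfaceMesh(mesh.vertices + offset, mesh.faces.copy(), mesh.normals.copy())


def apply_affine(mesh: SurfaceMesh, params: AffineParams) -> SurfaceMesh:
    """Scale, then rotate, then translate — the fixed order of the chain."""
    return translate_mesh(
        rotate_mesh(scale_mesh(mesh, params.scale), params.rotation),
        params.translation,
    )


def concatenate_meshes(meshes: Sequence[SurfaceMesh]) -> SurfaceMesh:
    meshes = [m for m in meshes if m.n_vertices or m.n_faces]
    if not meshes:
        return empty_mesh()
    vertices, faces, normals, offset = [], [], [], 0
    for m in meshes:
        vertices.append(m.vertices)
        faces.append(m.faces + offset)
        normals.append(m.normals)
        offset += m.n_vertices
    return SurfaceMesh(np.vstack(vertices), np.vstack(faces), np.vstack(normals))


@dataclass(frozen=True)
class ObjectSpec:
    """Recursive object description.

    Either a primitive (``primitive="sphere"``) or a composite with a
    non-empty list of ``(child ObjectSpec, AffineParams)`` pairs.  The
    label names the object hypothesis (it is what a lesion deletes).
    """

    label: str
    primitive: Optional[str] = None
    children: Tuple[Tuple["ObjectSpec", AffineParams], ...] = ()

    def __post_init__(self) -> None:
        if (self.primitive is None) == (len(self.children) == 0):
            raise ValueError(
                f"object {self.label!r}: exactly one of primitive/children required"
            )
        if self.primitive is not None and self.primitive != "sphere":
            raise ValueError(f"unknown primitive {self.primitive!r}")


def sphere_spec(label: str = "sphere") -> ObjectSpec:
    return ObjectSpec(label=label, primitive="sphere")


@dataclass
class Room:
    """A labelled arrangement of placed objects, optionally enclosed by walls."""

    label: str
    placements: list  # list[(ObjectSpec, AffineParams)]
    walls: Optional[SurfaceMesh] = None


@dataclass
class RoomLibrary:
    """Candidate rooms with a categorical prior over them."""

    rooms: list
    prior: np.ndarray

    def __post_init__(self) -> None:
        self.prior = np.asarray(self.prior, dtype=float)
        if len(self.prior) != len(self.rooms):
            raise ValueError("prior length must match room count")
        if np.any(self.prior < 0) or abs(self.prior.sum() - 1.0) > 1e-12:
            raise ValueError("prior must be non-negative and sum to 1")

    def labels(self) -> list:
        return [room.label for room in self.rooms]


def assemble_object(spec: ObjectSpec, resolution: int = 8,
                    _depth: int = 0) -> SurfaceMesh:
    """Depth-first assembly of an object spec into a single mesh.

    Children are assembled recursively, transformed by their params, and
    concatenated.  Deterministic for a given spec and resolution.
    """
    if _depth > MAX_ASSEMBLY_DEPTH:
        raise RecursionError(
            f"object spec exceeds assembly depth {MAX_ASSEMBLY_DEPTH} "
            f"(cyclic spec?) at {spec.label!r}"
        )
    if spec.primitive == "sphere":
        return make_sphere_mesh(resolution)
    parts = []
    for child, params in spec.children:
        parts.append(apply_affine(assemble_object(child, resolution, _depth + 1), params))
    return concatenate_meshes(parts)


def assemble_room(room: Room, resolution: int = 8) -> SurfaceMesh:
    """Concatenate the assembled, placed objects of a room (plus walls)."""
    parts = [
        apply_affine(assemble_object(spec, resolution), params)
        for spec, params in room.placements
    ]
    if room.walls is not None:
        parts.append(room.walls.copy())
    return concatenate_meshes(parts)


def _iso(r: float) -> LogScale:
    s = math.log(r)
    return LogScale(s, s, s)


def _object1() -> ObjectSpec:
    """A 'snowman': two stacked spheres. Distinctive along z."""
    return ObjectSpec(
        label="object1",
        children=(
            (sphere_spec(), AffineParams(scale=_iso(0.20), translation=(0.0, 0.0, -0.12))),
            (sphere_spec(), AffineParams(scale=_iso(0.14), translation=(0.0, 0.0, 0.16))),
        ),
    )


def _object2() -> ObjectSpec:
    """A 'dumbbell': two spheres side by side. Distinctive along x."""
    return ObjectSpec(
        label="object2",
        children=(
            (sphere_spec(), AffineParams(scale=_iso(0.15), translation=(-0.18, 0.0, 0.0))),
            (sphere_spec(), AffineParams(scale=_iso(0.15), translation=(0.18, 0.0, 0.0))),
        ),
    )


def _place(corner: str) -> AffineParams:
    x, y = DEMO_CORNERS[corner]
    return AffineParams(translation=(x, y, DEMO_EYE_HEIGHT))


def build_demo_library() -> RoomLibrary:
    """The three-room demonstration world.

    All rooms share the same walls; each contains two objects.  The
    southeast site holds object 1 in rooms 2 and 3 but is empty in room 1;
    the northeast site is empty everywhere; rooms 2 and 3 differ only in
    whether their second object sits in the southwest or northwest corner.
    Under a uniform prior, a southeast fixation therefore discriminates
    room 1 from {2, 3}, a northeast fixation discriminates nothing, and
    after seeing object 1 the southwest/northwest corners become the
    informative ones.
    """
    o1, o2 = _object1(), _object2()

    def walls() -> SurfaceMesh:
        # roofless shell: the overhead directional light can reach inside
        return make_box_mesh(_DEMO_ROOM_SIZE, _DEMO_ROOM_CENTER, inward=True,
                             open_top=True)

    rooms = [
        Room("room1", [(o2, _place("southwest")), (o2, _place("northwest"))], walls()),
        Room("room2", [(o1, _place("southeast")), (o2, _place("southwest"))], walls()),
        Room("room3", [(o1, _place("southeast")), (o2, _place("northwest"))], walls()),
    ]
    return RoomLibrary(rooms, np.full(3, 1.0 / 3.0))


def lesion_object_hypothesis(library: RoomLibrary, object_label: str) -> RoomLibrary:
    """Delete every placement of the named object from every room.

    Models an agnosia-style lesion: the generative model loses the ability
    to predict that object's surfaces, so no sample from the lesioned
    library ever contains them.  The room prior is unchanged.
    """
    present = any(
        spec.label == object_label for room in library.rooms for spec, _ in room.placements
    )
    if not present:
        raise KeyError(f"no room places an object labelled {object_label!r}")
    rooms = [
        Room(
            room.label,
            [(spec, params) for spec, params in room.placements if spec.label != object_label],
            room.walls.copy() if room.walls is not None else None,
        )
        for room in library.rooms
    ]
    return RoomLibrary(rooms, library.prior.copy())


# ---------------------------------------------------------------------------
# structured-text (JSON) scene configuration


class SceneConfigError(ValueError):
    """Raised for malformed scene configuration, with a JSON-path location."""


def _cfg_err(path: str, msg: str) -> SceneConfigError:
    return SceneConfigError(f"{path}: {msg}")


def _params_to_dict(params: AffineParams) -> dict:
    s = params.scale
    r = params.rotation
    return {
        "scale": [s.alpha, s.beta, s.gamma],
        "rotation_rad": [r.theta, r.phi, r.varphi],
        "translation": list(map(float, params.translation)),
    }


def _params_from_dict(d: dict, path: str) -> AffineParams:
    def triple(key, default):
        val = d.get(key, default)
        try:
            a, b, c = (float(x) for x in val)
        except (TypeError, ValueError):
            raise _cfg_err(f"{path}.{key}", f"expected a 3-element number list, got {val!r}")
        return a, b, c

    return AffineParams(
        scale=LogScale(*triple("scale", (0, 0, 0))),
        rotation=EulerAngles(*triple("rotation_rad", (0, 0, 0))),
        translation=triple("translation", (0, 0, 0)),
    )


def _object_to_dict(spec: ObjectSpec) -> dict:
    if spec.primitive is not None:
        return {"label": spec.label, "primitive": spec.primitive}
    return {
        "label": spec.label,
        "children": [
            {"object": _object_to_dict(child), **_params_to_dict(params)}
            for child, params in spec.children
        ],
    }


def _object_from_dict(d: dict, path: str) -> ObjectSpec:
    if not isinstance(d, dict):
        raise _cfg_err(path, f"expected an object mapping, got {type(d).__name__}")
    label = d.get("label", "object")
    if "primitive" in d:
        if d["primitive"] != "sphere":
            raise _cfg_err(f"{path}.primitive", f"unknown primitive {d['primitive']!r}")
        return ObjectSpec(label=label, primitive="sphere")
    if "children" not in d or not d["children"]:
        raise _cfg_err(path, "object needs either 'primitive' or non-empty 'children'")
    children = []
    for i, entry in enumerate(d["children"]):
        sub = f"{path}.children[{i}]"
        if "object" not in entry:
            raise _cfg_err(sub, "missing 'object'")
        children.append(
            (_object_from_dict(entry["object"], f"{sub}.object"), _params_from_dict(entry, sub))
        )
    return ObjectSpec(label=label, children=tuple(children))


def _walls_to_dict(walls: SurfaceMesh) -> dict:
    lo = walls.vertices.min(axis=0)
    hi = walls.vertices.max(axis=0)
    top = walls.face_centroids()[:, 2].max() if walls.n_faces else -np.inf
    return {
        "size": list(hi - lo),
        "center": list((hi + lo) / 2.0),
        "open_top": bool(top < hi[2] - 1e-9),
    }


def library_to_dict(library: RoomLibrary) -> dict:
    rooms = []
    for room in library.rooms:
        entry = {
            "label": room.label,
            "placements": [
                {"object": _object_to_dict(spec), **_params_to_dict(params)}
                for spec, params in room.placements
            ],
        }
        if room.walls is not None:
            entry["walls"] = _walls_to_dict(room.walls)
        rooms.append(entry)
    return {"prior": [float(p) for p in library.prior], "rooms": rooms}


def library_from_dict(d: dict) -> RoomLibrary:
    if not isinstance(d, dict):
        raise SceneConfigError("scene config must be a JSON object")
    for key in ("prior", "rooms"):
        if key not in d:
            raise _cfg_err("$", f"missing required key {key!r}")
    rooms = []
    for i, entry in enumerate(d["rooms"]):
        path = f"rooms[{i}]"
        if "label" not in entry:
            raise _cfg_err(path, "missing 'label'")
        placements = []
        for j, pl in enumerate(entry.get("placements", [])):
            sub = f"{path}.placements[{j}]"
            if "object" not in pl:
                raise _cfg_err(sub, "missing 'object'")
            placements.append(
                (_object_from_dict(pl["object"], f"{sub}.object"), _params_from_dict(pl, sub))
            )
        walls = None
        if "walls" in entry:
            w = entry["walls"]
            try:
                walls = make_box_mesh(w["size"], w.get("center", (0, 0, 0)),
                                      inward=True, open_top=w.get("open_top", False))
            except (KeyError, TypeError, ValueError) as exc:
                raise _cfg_err(f"{path}.walls", str(exc))
        rooms.append(Room(entry["label"], placements, walls))
    try:
        return RoomLibrary(rooms, np.asarray(d["prior"], dtype=float))
    except ValueError as exc:
        raise _cfg_err("prior", str(exc))


def read_scene(path) -> RoomLibrary:
    """Load a room library from a JSON scene file.

    Parse errors carry the line/column from the JSON decoder; semantic
    errors carry a JSON-path such as ``rooms[1].placements[0].scale``.
    """
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SceneConfigError(f"{path}: line {exc.lineno} col {exc.colno}: {exc.msg}")
    return library_from_dict(data)


def write_scene(library: RoomLibrary, path) -> None:
    """Write a room library as canonical JSON (read -> write is idempotent)."""
    with open(path, "w") as fh:
        json.dump(library_to_dict(library), fh, indent=2, sort_keys=True)
        fh.write("\n")
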