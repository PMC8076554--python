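"""Ray-cast retinal rendering with Blinn-Phong shading and DCT blurring.

For each retinal cell we trace a ray from the lens out along the cell's
preferred incidence direction and ask which surface it first encounters.
A hit is shaded as

    intensity = ambient + lit * (c1 * max(0, n.z) + c2 * max(0, n.h)^c3)

where z is the (directional) light direction, n the face normal, h the
half-vector between the direction back toward the lens and z, and ``lit``
is a shadow indicator obtained by casting a second ray from the hit point
toward the light.  This is a single-bounce simplification: surfaces
reflect the source to the retina, but do not illuminate one another.

Shaded intensities are written at the retinally *inverted* grid location
(flipped across both image axes, as in a pinhole eye), then low-pass
filtered by attenuating 2-D DCT coefficients with a Gaussian centred on
the DC term — compensating for the artificial high frequencies introduced
by treating the lens as a point.

Two lesion families are supported: monocular blanking of one retina
(pre-chiasm) and deletion of all surfaces on one egocentric side of space,
which silences the corresponding side of *both* retinas (the homonymous
hemianopia pattern of post-chiasm lesions).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Optional, Tuple

import numpy as np
from scipy import fft as spfft

from .scene import SurfaceMesh
from .viewpoint import (
    DEFAULT_BASELINE,
    EyeDirection,
    EyeView,
    FieldOfView,
    HeadPose,
    RetinalArray,
    field_of_view,
)

__all__ = [
    "LightSource",
    "Lesion",
    "RayHit",
    "BinocularRender",
    "cast_ray",
    "eta",
    "shade_point",
    "render_eye",
    "blur_image",
    "remove_scene_side",
    "render_binocular",
    "default_blur_sigma",
    "write_pgm",
    "write_png",
]

log = logging.getLogger(__name__)

_RAY_EPS = 1e-9          # minimum hit distance (self-intersection guard)
_SHADOW_OFFSET = 1e-6    # shadow rays start this far along the surface normal
_CHUNK = 256             # rays per intersection batch (bounds peak memory)


@dataclass(frozen=True)
class LightSource:
    """Directional light: unit vector pointing from the scene toward the source."""

    direction: Tuple[float, float, float] = (0.2, -0.2, 0.95)
    ambient: float = 0.1
    diffuse_coeff: float = 0.6
    specular_coeff: float = 0.3
    specular_exponent: float = 8.0

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            raise ValueError("light direction must be non-zero")
        object.__setattr__(self, "direction", tuple(d / norm))
        if self.ambient < 0 or self.diffuse_coeff < 0 or self.specular_coeff < 0:
            raise ValueError("lighting coefficients must be non-negative")
        if self.specular_exponent <= 0:
            raise ValueError("specular exponent must be positive")

    @property
    def dir_array(self) -> np.ndarray:
        return np.asarray(self.direction)


@dataclass(frozen=True)
class Lesion:
    """Exactly one lesion mode.

    ``monocular(eye)`` blanks one retina; ``scene_side_removal(side)``
    (equivalently ``hemianopia``) deletes all surfaces on one egocentric
    side of space before rendering, yielding same-sided loss in both eyes.
    """

    mode: str = "none"
    side: Optional[str] = None

    _MODES = ("none", "monocular", "hemianopia", "scene_side_removal")

    def __post_init__(self) -> None:
        if self.mode not in self._MODES:
            raise ValueError(f"unknown lesion mode {self.mode!r}")
        if self.mode == "none" and self.side is not None:
            raise ValueError("lesion 'none' takes no side")
        if self.mode != "none" and self.side not in ("left", "right"):
            raise ValueError(f"lesion {self.mode!r} requires side 'left' or 'right'")

    @staticmethod
    def none() -> "Lesion":
        return Lesion("none")

    @staticmethod
    def monocular(eye: str) -> "Lesion":
        return Lesion("monocular", eye)

    @staticmethod
    def hemianopia(side: str) -> "Lesion":
        return Lesion("hemianopia", side)

    @staticmethod
    def scene_side_removal(side: str) -> "Lesion":
        return Lesion("scene_side_removal", side)


class RayHit(NamedTuple):
    face: int
    point: np.ndarray
    distance: float


def _cast_batch(origins: np.ndarray, directions: np.ndarray, mesh: SurfaceMesh
                ) -> Tuple[np.ndarray, np.ndarray]:
    """Nearest-hit of many rays against all faces (Moller-Trumbore).

    Returns (face index, distance) per ray; face index -1 and distance inf
    where nothing is hit.  Ties at identical distance resolve to the
    lowest face index (argmin keeps the first minimum).
    """
    n_rays = len(origins)
    face_idx = np.full(n_rays, -1, dtype=np.int64)
    t_best = np.full(n_rays, np.inf)
    if mesh.n_faces == 0 or n_rays == 0:
        return face_idx, t_best

    v0 = mesh.vertices[mesh.faces[:, 0]]
    e1 = mesh.vertices[mesh.faces[:, 1]] - v0
    e2 = mesh.vertices[mesh.faces[:, 2]] - v0
    area2 = np.linalg.norm(np.cross(e1, e2), axis=1)
    good = area2 > 1e-12
    if not good.all():
        log.warning("skipping %d degenerate (zero-area) face(s)", int((~good).sum()))

    for lo in range(0, n_rays, _CHUNK):
        hi = min(lo + _CHUNK, n_rays)
        d = directions[lo:hi]                                   # (r, 3)
        o = origins[lo:hi]
        pvec = np.cross(d[:, None, :], e2[None, :, :])          # (r, f, 3)
        det = np.einsum("fk,rfk->rf", e1, pvec)
        ok = (np.abs(det) > 1e-12) & good[None, :]
        inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
        tvec = o[:, None, :] - v0[None, :, :]
        u = np.einsum("rfk,rfk->rf", tvec, pvec) * inv_det
        qvec = np.cross(tvec, e1[None, :, :])
        v = np.einsum("rk,rfk->rf", d, qvec) * inv_det
        t = np.einsum("fk,rfk->rf", e2, qvec) * inv_det
        hit = ok & (u >= -1e-12) & (v >= -1e-12) & (u + v <= 1.0 + 1e-12) & (t > _RAY_EPS)
        t = np.where(hit, t, np.inf)
        idx = np.argmin(t, axis=1)
        rows = np.arange(hi - lo)
        tb = t[rows, idx]
        found = np.isfinite(tb)
        face_idx[lo:hi] = np.where(found, idx, -1)
        t_best[lo:hi] = tb
    return face_idx, t_best


def cast_ray(origin, direction, scene: SurfaceMesh) -> Optional[RayHit]:
    """Nearest intersection of a single ray with the scene, or None.

    Hits closer than 1e-9 are ignored (self-intersection guard); ties at
    equal distance return the lowest face index.
    """
    origin = np.asarray(origin, dtype=float).reshape(1, 3)
    direction = np.asarray(direction, dtype=float).reshape(1, 3)
    face, t = _cast_batch(origin, direction, scene)
    if face[0] < 0:
        return None
    point = origin[0] + t[0] * direction[0]
    return RayHit(face=int(face[0]), point=point, distance=float(t[0]))


def eta(from_point, toward, target, scene: SurfaceMesh, tol: float = 1e-6) -> int:
    """Visibility indicator: 1 iff the nearest hit along ``toward`` is ``target``.

    Used both for cell-to-surface visibility and, with the light direction,
    for shadow tests (an occluder strictly in front of the target makes the
    target unlit).
    """
    from_point = np.asarray(from_point, dtype=float)
    target = np.asarray(target, dtype=float)
    hit = cast_ray(from_point, toward, scene)
    if hit is None:
        return 0
    return int(np.linalg.norm(hit.point - target) <= tol)


def shade_point(view_dir, surface_normal, light: LightSource, lit: int) -> float:
    """Blinn-Phong intensity at a surface point.

    ``view_dir`` is the unit vector from the surface back toward the lens;
    ``lit`` is the shadow indicator.  In shadow only the ambient term
    survives.  Degenerate half-vectors (view exactly opposite the light)
    contribute zero specular intensity.
    """
    u = np.asarray(view_dir, dtype=float)
    n = np.asarray(surface_normal, dtype=float)
    z = light.dir_array
    if not lit:
        return float(light.ambient)
    diffuse = light.diffuse_coeff * max(0.0, float(n @ z))
    hvec = u + z
    norm = np.linalg.norm(hvec)
    if norm < 1e-12:
        specular = 0.0
    else:
        specular = light.specular_coeff * max(0.0, float(n @ (hvec / norm))) ** light.specular_exponent
    return float(light.ambient + diffuse + specular)


def render_eye(eye: EyeView, scene: SurfaceMesh, light: LightSource) -> np.ndarray:
    """Shaded image for one eye (pre-blur), with retinal inversion applied.

    Cells whose rays miss every surface read 0; shadowed hits read exactly
    the ambient level.  The intensity of cell (i, j) is written at grid
    location (n_rows-1-i, n_cols-1-j): the image is flipped across both
    the horizontal and vertical planes, as in a pinhole eye.
    """
    n_rows, n_cols, _ = eye.directions.shape
    dirs = eye.directions.reshape(-1, 3)
    origins = np.broadcast_to(eye.origin, dirs.shape)
    face, t = _cast_batch(np.ascontiguousarray(origins), dirs, scene)

    intensity = np.zeros(len(dirs))
    hit = face >= 0
    if hit.any():
        hp = origins[hit] + t[hit, None] * dirs[hit]
        normals = scene.normals[face[hit]]
        z = light.dir_array

        shadow_origins = hp + _SHADOW_OFFSET * normals
        shadow_dirs = np.broadcast_to(z, shadow_origins.shape)
        sface, _ = _cast_batch(shadow_origins, np.ascontiguousarray(shadow_dirs), scene)
        lit = sface < 0

        u = -dirs[hit]                                   # back toward the lens
        diffuse = light.diffuse_coeff * np.maximum(0.0, normals @ z)
        hvec = u + z
        hnorm = np.linalg.norm(hvec, axis=1)
        safe = hnorm > 1e-12
        hunit = np.zeros_like(hvec)
        hunit[safe] = hvec[safe] / hnorm[safe, None]
        specular = light.specular_coeff * np.maximum(
            0.0, np.einsum("ij,ij->i", normals, hunit)
        ) ** light.specular_exponent
        intensity[hit] = light.ambient + lit * (diffuse + specular)

    image = intensity.reshape(n_rows, n_cols)
    return image[::-1, ::-1].copy()


def blur_image(image: np.ndarray, sigma_freq: float) -> np.ndarray:
    """Gaussian low-pass in the 2-D DCT domain.

    Coefficient (p, q) is attenuated by exp(-(p^2+q^2)/(2 sigma^2)); the
    DC coefficient is multiplied by exactly 1, so the image mean is
    preserved.  The operation is linear (no clamping happens here; the
    rendering pipeline clamps small negative ringing to zero afterwards).
    """
    if sigma_freq <= 0:
        raise ValueError("sigma_freq must be positive")
    image = np.asarray(image, dtype=float)
    coeffs = spfft.dctn(image, type=2, norm="ortho")
    p = np.arange(image.shape[0])[:, None]
    q = np.arange(image.shape[1])[None, :]
    coeffs *= np.exp(-(p ** 2 + q ** 2) / (2.0 * sigma_freq ** 2))
    return spfft.idctn(coeffs, type=2, norm="ortho")


def default_blur_sigma(array: RetinalArray) -> float:
    """Default DCT-domain Gaussian width: min(n_rows, n_cols) / 6."""
    return min(array.n_rows, array.n_cols) / 6.0


def remove_scene_side(mesh: SurfaceMesh, pose: HeadPose, side: str) -> SurfaceMesh:
    """Delete every face whose centroid lies on the given egocentric side.

    Laterality is judged in the head frame: with heading h, the viewer's
    left axis is (-sin h, cos h, 0); faces with positive lateral coordinate
    are on the left.  Faces exactly on the midline are kept.
    """
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    if mesh.n_faces == 0:
        return mesh.copy()
    h = pose.head_dir[0]
    left_axis = np.array([-math.sin(h), math.cos(h), 0.0])
    lateral = (mesh.face_centroids() - np.asarray(pose.place)) @ left_axis
    keep = lateral <= 0 if side == "left" else lateral >= 0
    return SurfaceMesh(mesh.vertices.copy(), mesh.faces[keep], mesh.normals[keep])


@dataclass(frozen=True)
class BinocularRender:
    """Shaded (pre-blur) and retinal (blurred, clamped) image pairs."""

    shaded_left: np.ndarray
    shaded_right: np.ndarray
    retinal_left: np.ndarray
    retinal_right: np.ndarray

    @property
    def retinal(self) -> Tuple[np.ndarray, np.ndarray]:
        return self.retinal_left, self.retinal_right


def render_binocular(pose: HeadPose, eyes: EyeDirection, array: RetinalArray,
                     scene: SurfaceMesh, light: LightSource,
                     lesion: Lesion = Lesion.none(),
                     sigma_freq: Optional[float] = None,
                     baseline: float = DEFAULT_BASELINE) -> BinocularRender:
    """Full pipeline: field of view, per-eye shading, blurring, lesioning.

    Scene-side lesions delete surfaces *before* rendering (they are part
    of the generative model, not an image mask); monocular lesions zero
    the affected eye's images last.  Blur ringing is clamped at zero.
    """
    if lesion.mode in ("hemianopia", "scene_side_removal"):
        scene = remove_scene_side(scene, pose, lesion.side)

    fov = field_of_view(pose, eyes, array, baseline=baseline)
    sigma = default_blur_sigma(array) if sigma_freq is None else float(sigma_freq)

    shaded = {}
    retinal = {}
    for name, eye in (("left", fov.left), ("right", fov.right)):
        img = render_eye(eye, scene, light)
        shaded[name] = img
        retinal[name] = np.maximum(blur_image(img, sigma), 0.0)

    if lesion.mode == "monocular":
        shaded[lesion.side] = np.zeros_like(shaded[lesion.side])
        retinal[lesion.side] = np.zeros_like(retinal[lesion.side])

    return BinocularRender(
        shaded_left=shaded["left"],
        shaded_right=shaded["right"],
        retinal_left=retinal["left"],
        retinal_right=retinal["right"],
    )


def write_pgm(image: np.ndarray, path, maxval: int = 65535) -> None:
    """Write an intensity image as plain (ASCII) 16-bit PGM.

    Intensities are clipped to [0, 1] with 1.0 as reference white, so the
    same image always produces byte-identical output.
    """
    img = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    quant = np.rint(img * maxval).astype(np.int64)
    with open(path, "w") as fh:
        fh.write(f"P2\n{img.shape[1]} {img.shape[0]}\n{maxval}\n")
        for row in quant:
            fh.write(" ".join(str(v) for v in row) + "\n")


def write_png(image: np.ndarray, path) -> None:
    """Write an intensity image as 16-bit greyscale PNG (same scaling as PGM)."""
    import imageio.v3 as iio

    img = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(path, np.rint(img * 65535).astype(np.uint16))
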