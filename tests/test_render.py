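import math

import numpy as np
import pytest

from gazesim.render import (
    Lesion,
    LightSource,
    blur_image,
    cast_ray,
    default_blur_sigma,
    eta,
    remove_scene_side,
    render_binocular,
    render_eye,
    shade_point,
    write_pgm,
)
from gazesim.scene import (
    LogScale,
    SurfaceMesh,
    concatenate_meshes,
    make_box_mesh,
    make_sphere_mesh,
    scale_mesh,
    translate_mesh,
)
from gazesim.viewpoint import EyeDirection, HeadPose, build_retinal_array, field_of_view


def small_sphere(radius, center, resolution=8):
    s = math.log(radius)
    return translate_mesh(scale_mesh(make_sphere_mesh(resolution), LogScale(s, s, s)), center)


def quad(p0, p1, p2, p3):
    """Two triangles spanning a quadrilateral."""
    verts = np.array([p0, p1, p2, p3], dtype=float)
    faces = np.array([[0, 1, 2], [0, 2, 3]])
    from gazesim.scene import _face_normals
    return SurfaceMesh(verts, faces, _face_normals(verts, faces))


def oracle_nearest_hit(origin, direction, mesh):
    """Independent nearest-hit: solve the 3x3 barycentric system per face."""
    best = (None, np.inf)
    for f, (i, j, k) in enumerate(mesh.faces):
        v0, v1, v2 = mesh.vertices[i], mesh.vertices[j], mesh.vertices[k]
        a = np.column_stack([-np.asarray(direction, float), v1 - v0, v2 - v0])
        try:
            t, u, v = np.linalg.solve(a, np.asarray(origin, float) - v0)
        except np.linalg.LinAlgError:
            continue
        if t > 1e-9 and u >= -1e-12 and v >= -1e-12 and u + v <= 1 + 1e-12 and t < best[1]:
            best = (f, t)
    return best


class TestCastRay:
    def test_axial_sphere_hit_matches_quadratic_oracle(self):
        mesh = small_sphere(1.0, (0, 0, 5), resolution=64)
        hit = cast_ray((0, 0, 0), (0, 0, 1), mesh)
        # ray-sphere quadratic: t^2 - 2*5*t + 24 = 0 -> nearest root t = 4
        assert hit is not None
        assert hit.distance == pytest.approx(4.0, abs=5e-3)  # faceted approximation
        assert hit.point[2] == pytest.approx(4.0, abs=5e-3)

    def test_random_rays_agree_with_per_face_oracle(self, rng):
        mesh = small_sphere(0.8, (0.2, -0.1, 3.0), resolution=5)
        for _ in range(25):
            d = rng.normal(size=3)
            d[2] = abs(d[2]) + 0.5
            d /= np.linalg.norm(d)
            hit = cast_ray((0, 0, 0), d, mesh)
            face, t = oracle_nearest_hit((0, 0, 0), d, mesh)
            if face is None:
                assert hit is None
            else:
                assert hit is not None
                assert hit.face == face
                assert hit.distance == pytest.approx(t, abs=1e-9)

    def test_miss_returns_none(self):
        mesh = small_sphere(1.0, (0, 0, 5))
        assert cast_ray((0, 0, 0), (0, 0, -1), mesh) is None

    def test_coplanar_tie_breaks_to_lowest_face_index(self):
        sq = quad((-1, -1, 2), (1, -1, 2), (1, 1, 2), (-1, 1, 2))
        stacked = concatenate_meshes([sq, sq.copy()])
        # (0.3, 0.2) lies in the first triangle of the quad, which appears as
        # face 0 and face 2 of the stacked mesh at the same distance
        hit = cast_ray((0.3, 0.2, 0), (0, 0, 1), stacked)
        assert hit.face == 0

    def test_degenerate_faces_skipped_with_warning(self, caplog):
        verts = np.array([[0, 0, 2], [1, 0, 2], [2, 0, 2], [-1, -1, 3], [1, -1, 3], [0, 1, 3]])
        faces = np.array([[0, 1, 2], [3, 4, 5]])  # first face has zero area
        from gazesim.scene import _face_normals
        mesh = SurfaceMesh(verts, faces, _face_normals(verts, faces))
        with caplog.at_level("WARNING", logger="gazesim.render"):
            hit = cast_ray((0, 0, 0), (0, -0.05, 1), mesh)
        assert hit is not None and hit.face == 1
        assert any("degenerate" in rec.message for rec in caplog.records)


class TestEta:
    def setup_method(self):
        self.target_mesh = quad((-1, -1, 4), (1, -1, 4), (1, 1, 4), (-1, 1, 4))
        self.occluder = quad((-1, -1, 2), (1, -1, 2), (1, 1, 2), (-1, 1, 2))

    def test_unobstructed_target_visible(self):
        assert eta((0, 0, 0), (0, 0, 1), (0, 0, 4), self.target_mesh) == 1

    def test_occluder_blocks(self):
        scene = concatenate_meshes([self.target_mesh, self.occluder])
        assert eta((0, 0, 0), (0, 0, 1), (0, 0, 4), scene) == 0

    def test_target_behind_origin_invisible(self):
        assert eta((0, 0, 5), (0, 0, 1), (0, 0, 4), self.target_mesh) == 0


class TestShadePoint:
    light = LightSource(direction=(0, 0, 1), ambient=0.1, diffuse_coeff=0.6,
                        specular_coeff=0.3, specular_exponent=8)

    def test_backfacing_diffuse_clamped(self):
        val = shade_point((0, 0, 1), (0, 0, -1), self.light, lit=1)
        assert val == pytest.approx(self.light.ambient)  # specular also clamps

    def test_aligned_geometry_sums_all_terms(self):
        val = shade_point((0, 0, 1), (0, 0, 1), self.light, lit=1)
        assert val == pytest.approx(0.1 + 0.6 + 0.3)

    def test_shadow_returns_ambient_only(self):
        val = shade_point((0.3, 0.4, 0.5), (1, 0, 0), self.light, lit=0)
        assert val == pytest.approx(self.light.ambient)

    def test_degenerate_half_vector_gives_zero_specular(self):
        val = shade_point((0, 0, -1), (0, 0, 1), self.light, lit=1)
        assert val == pytest.approx(0.1 + 0.6)  # view opposite light: no specular

    def test_never_negative(self, rng):
        for _ in range(50):
            u = rng.normal(size=3); u /= np.linalg.norm(u)
            n = rng.normal(size=3); n /= np.linalg.norm(n)
            assert shade_point(u, n, self.light, lit=int(rng.random() < 0.5)) >= 0


def fov_for(heading=0.0, elevation=0.0, n=15, extent_deg=40, place=(0, 0, 0)):
    arr = build_retinal_array(n, n, math.radians(extent_deg))
    return field_of_view(
        HeadPose(place=place, head_dir=(heading, elevation)),
        EyeDirection(), arr, baseline=0.0,
    )


class TestRenderEye:
    light = LightSource(direction=(0.2, -0.2, 0.95))

    def test_empty_scene_renders_zero(self):
        from gazesim.scene import empty_mesh
        img = render_eye(fov_for().left, empty_mesh(), self.light)
        assert np.all(img == 0)

    def test_matches_exhaustive_shading_oracle(self):
        """Per-pixel reference: nearest hit by per-face enumeration, shadow by
        eta toward the light, Blinn-Phong via the scalar shader, inversion
        applied explicitly."""
        scene = concatenate_meshes([
            quad((-0.6, -0.6, 3), (0.6, -0.6, 3), (0.6, 0.6, 3), (-0.6, 0.6, 3)),
            quad((-1.5, -1.5, 5), (1.5, -1.5, 5), (1.5, 1.5, 5), (-1.5, 1.5, 5)),
        ])
        assert scene.n_faces <= 20
        light = LightSource(direction=(0.1, 0.2, -0.97))  # light from in front
        eye = fov_for(heading=math.pi / 2, elevation=math.pi / 2, n=9).left  # look up +z
        img = render_eye(eye, scene, light)
        n = eye.directions.shape[0]
        expected = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                d = eye.directions[i, j]
                face, t = oracle_nearest_hit(eye.origin, d, scene)
                hit = cast_ray(eye.origin, d, scene)
                assert (hit.face if hit is not None else None) == face
                if face is None:
                    continue
                point = eye.origin + t * d
                shadow = cast_ray(point + 1e-6 * scene.normals[face], light.dir_array, scene)
                expected[n - 1 - i, n - 1 - j] = shade_point(
                    -d, scene.normals[face], light, lit=int(shadow is None)
                )
        np.testing.assert_allclose(img, expected, atol=1e-12)

    def test_shadowed_pixels_read_ambient(self):
        # small quad occludes the light above a large floor quad
        floor = quad((-2, -2, 0), (2, -2, 0), (2, 2, 0), (-2, 2, 0))
        occ = quad((-0.5, -0.5, 2), (0.5, -0.5, 2), (0.5, 0.5, 2), (-0.5, 0.5, 2))
        light = LightSource(direction=(0, 0, 1))
        eye = fov_for(heading=-math.pi / 2, elevation=-math.pi / 2, n=15,
                      place=(0, 0, 1.0)).left  # look straight down from below occluder
        with_occ = render_eye(eye, concatenate_meshes([floor, occ]), light)
        without = render_eye(eye, floor, light)
        shadowed = with_occ < without - 1e-12
        assert shadowed.any()
        assert np.allclose(with_occ[shadowed], light.ambient)

    def test_removing_occluder_never_darkens(self):
        floor = quad((-2, -2, 0), (2, -2, 0), (2, 2, 0), (-2, 2, 0))
        occ = quad((-0.5, -0.5, 2), (0.5, -0.5, 2), (0.5, 0.5, 2), (-0.5, 0.5, 2))
        light = LightSource(direction=(0, 0, 1))
        eye = fov_for(heading=0.0, elevation=-0.6, n=15, place=(-1.5, 0, 1.5)).left
        with_occ = render_eye(eye, concatenate_meshes([floor, occ]), light)
        without = render_eye(eye, floor, light)
        floor_only = without > 0
        assert np.all(without[floor_only] >= with_occ[floor_only] - 1e-12)

    @pytest.mark.parametrize("eye_name", ["left", "right"])
    def test_retinal_inversion_sign(self, eye_name):
        """An object displaced to the viewer's left and above activates the
        right-and-lower quadrant of the image."""
        fov = fov_for(n=21)
        eye = getattr(fov, eye_name)
        obj = small_sphere(0.2, (3.0, 0.5, 0.5))  # +y is the viewer's left at heading 0
        img = render_eye(eye, obj, LightSource())
        rows, cols = np.nonzero(img)
        assert rows.min() > 10 and cols.min() > 10


class TestBlur:
    def test_constant_image_unchanged(self):
        img = np.full((12, 12), 0.7)
        np.testing.assert_allclose(blur_image(img, 2.0), img, atol=1e-9)

    def test_mean_preserved(self, rng):
        img = rng.random((16, 16))
        assert blur_image(img, 1.5).mean() == pytest.approx(img.mean(), abs=1e-9)

    def test_huge_sigma_is_identity(self):
        img = np.zeros((9, 9))
        img[4, 4] = 1.0
        np.testing.assert_allclose(blur_image(img, 1e9), img, atol=1e-6)

    def test_linearity(self, rng):
        a, b = 1.7, -0.4
        i1, i2 = rng.random((10, 10)), rng.random((10, 10))
        lhs = blur_image(a * i1 + b * i2, 2.0)
        rhs = a * blur_image(i1, 2.0) + b * blur_image(i2, 2.0)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_spectral_energy_never_increases(self, rng):
        from scipy import fft as spfft
        img = rng.random((12, 12))
        out = blur_image(img, 1.0)
        e_in = np.sum(spfft.dctn(img, type=2, norm="ortho") ** 2)
        e_out = np.sum(spfft.dctn(out, type=2, norm="ortho") ** 2)
        assert e_out <= e_in + 1e-9

    def test_requires_positive_sigma(self):
        with pytest.raises(ValueError):
            blur_image(np.zeros((4, 4)), 0.0)


class TestRenderBinocular:
    arr = build_retinal_array(15, 15, math.radians(40))
    light = LightSource()
    pose = HeadPose(place=(0, 0, 0), head_dir=(0, 0))

    def scene(self):
        return small_sphere(0.3, (3.0, 0, 0))

    def test_monocular_lesion_blanks_one_eye(self):
        res = render_binocular(self.pose, EyeDirection(), self.arr, self.scene(),
                               self.light, lesion=Lesion.monocular("left"), baseline=0.0)
        assert np.all(res.retinal_left == 0) and np.all(res.shaded_left == 0)
        intact = render_binocular(self.pose, EyeDirection(), self.arr, self.scene(),
                                  self.light, baseline=0.0)
        np.testing.assert_array_equal(res.retinal_right, intact.retinal_right)

    def test_symmetric_scene_degenerate_eyes_match(self):
        res = render_binocular(self.pose, EyeDirection(), self.arr, self.scene(),
                               self.light, baseline=0.0)
        np.testing.assert_allclose(res.retinal_left, res.retinal_right, atol=1e-9)

    def test_scene_side_removal_silences_both_retinas_same_side(self):
        """All surfaces on the viewer's right: removing that side leaves both
        eyes' images identically zero (homonymous hemianopia pattern)."""
        right_scene = small_sphere(0.3, (3.0, -1.0, 0))  # -y: viewer's right
        res = render_binocular(self.pose, EyeDirection(), self.arr, right_scene,
                               self.light, lesion=Lesion.scene_side_removal("right"))
        assert np.all(res.retinal_left == 0)
        assert np.all(res.retinal_right == 0)

    def test_hemianopia_zeroes_one_image_half_in_both_eyes(self):
        # objects on both sides; removing the right side silences the half of
        # BOTH images that right-side surfaces project to
        scene = concatenate_meshes([
            small_sphere(0.3, (3.0, 1.0, 0)), small_sphere(0.3, (3.0, -1.0, 0)),
        ])
        res = render_binocular(self.pose, EyeDirection(), self.arr, scene,
                               self.light, lesion=Lesion.hemianopia("right"))
        intact = render_binocular(self.pose, EyeDirection(), self.arr, scene, self.light)
        for img, ref in ((res.shaded_left, intact.shaded_left),
                         (res.shaded_right, intact.shaded_right)):
            assert np.all(img[:, :7] == 0)       # right-side surfaces gone
            np.testing.assert_array_equal(img[:, 8:], ref[:, 8:])
            assert ref[:, :7].max() > 0          # they were visible before

    def test_blur_ringing_small_and_clamped(self):
        res = render_binocular(self.pose, EyeDirection(), self.arr, self.scene(),
                               self.light, baseline=0.0)
        assert res.retinal_left.min() >= 0
        raw = blur_image(res.shaded_left, default_blur_sigma(self.arr))
        assert raw.min() >= -1e-6 * max(raw.max(), 1e-12)

    def test_lesion_validation(self):
        with pytest.raises(ValueError):
            Lesion("monocular")
        with pytest.raises(ValueError):
            Lesion("none", "left")
        with pytest.raises(ValueError):
            Lesion("squint")


def test_remove_scene_side_keeps_midline(rng):
    mesh = small_sphere(0.5, (2.0, 0.9, 0))
    pose = HeadPose(place=(0, 0, 0), head_dir=(0, 0))
    left_removed = remove_scene_side(mesh, pose, "left")
    right_removed = remove_scene_side(mesh, pose, "right")
    assert left_removed.n_faces == 0            # sphere is fully on the left
    assert right_removed.n_faces == mesh.n_faces


def test_pgm_output_is_deterministic_text(tmp_path, rng):
    img = rng.random((6, 8))
    p1, p2 = tmp_path / "a.pgm", tmp_path / "b.pgm"
    write_pgm(img, p1)
    write_pgm(img, p2)
    assert p1.read_bytes() == p2.read_bytes()
    header = p1.read_text().splitlines()
    assert header[0] == "P2" and header[1] == "8 6" and header[2] == "65535"
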