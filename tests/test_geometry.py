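"""Affine algebra, rasterization oracles, boundary meshes, placement."""

import math
import warnings

import numpy as np
import pytest

from segff import geometry as G
from segff.errors import SegffError, TransformError
from segff.model import AffineTransform, Contour, ShapePrimitive


def random_invertible(rng, rigid=False):
    A = rng.normal(size=(3, 3))
    Q, R = np.linalg.qr(A)
    if rigid:
        Q = Q * np.sign(np.diag(R))  # proper-ish orthonormal
        M = Q
    else:
        M = A + 3 * np.eye(3)  # comfortably non-singular
    t = rng.normal(scale=5, size=3)
    return AffineTransform.from_rotation_translation(M, t)


# ---------------------------------------------------------------- affine --

def test_apply_affine_examples():
    I = AffineTransform.identity()
    assert np.allclose(G.apply_affine(I, [(1, 2, 3)]), [(1, 2, 3)])
    rot = AffineTransform.from_rotation_translation(
        [[0, -1, 0], [1, 0, 0], [0, 0, 1]], (0, 0, 0))
    assert np.allclose(G.apply_affine(rot, [(1, 0, 0)]), [(0, 1, 0)])
    tr = AffineTransform.from_rotation_translation(np.eye(3), (2, 3, 4))
    assert np.allclose(G.apply_affine(tr, [(0, 0, 0)]), [(2, 3, 4)])


def test_compose_is_A_after_B_and_translations_add():
    ta = AffineTransform.from_rotation_translation(np.eye(3), (1, 0, 0))
    tb = AffineTransform.from_rotation_translation(np.eye(3), (0, 2, 0))
    assert np.allclose(G.compose(ta, tb).translation, (1, 2, 0))


def test_group_laws_on_random_transforms():
    rng = np.random.default_rng(0)
    I = AffineTransform.identity()
    pts = rng.normal(scale=10, size=(20, 3))
    for _ in range(100):
        T = random_invertible(rng)
        U = random_invertible(rng)
        V = random_invertible(rng)
        # identity law
        assert np.allclose(G.compose(I, T).matrix, T.matrix, atol=1e-9)
        assert np.allclose(G.compose(T, I).matrix, T.matrix, atol=1e-9)
        # inverse law
        assert np.allclose(G.compose(T, G.invert(T)).matrix,
                           I.matrix, atol=1e-9)
        assert np.allclose(
            G.apply_affine(G.invert(T), G.apply_affine(T, pts)), pts,
            atol=1e-9)
        # associativity and A-after-B semantics
        left = G.compose(G.compose(T, U), V)
        right = G.compose(T, G.compose(U, V))
        assert np.allclose(left.matrix, right.matrix, atol=1e-9)
        assert np.allclose(
            G.apply_affine(G.compose(T, U), pts),
            G.apply_affine(T, G.apply_affine(U, pts)), atol=1e-9)


def test_rigid_transforms_preserve_distances():
    rng = np.random.default_rng(1)
    pts = rng.normal(scale=8, size=(15, 3))
    d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    for _ in range(20):
        T = random_invertible(rng, rigid=True)
        q = G.apply_affine(T, pts)
        d1 = np.linalg.norm(q[:, None] - q[None, :], axis=-1)
        assert np.allclose(d0, d1, atol=1e-9)


def test_invert_singular_raises():
    T = AffineTransform(id=0, matrix=np.zeros(12))
    with pytest.raises(TransformError, match="non-invertible"):
        G.invert(T)
    tr = AffineTransform.from_rotation_translation(np.eye(3), (5, -1, 2))
    assert np.allclose(G.invert(tr).translation, (-5, 1, -2))


# ---------------------------------------------------------- rasterization --

def brute_force_sphere_count(center, radius, size):
    n = 0
    for x in range(size[0]):
        for y in range(size[1]):
            for z in range(size[2]):
                if ((x - center[0]) ** 2 + (y - center[1]) ** 2
                        + (z - center[2]) ** 2) <= radius ** 2:
                    n += 1
    return n


@pytest.mark.parametrize("radius,size", [
    (0.5, (9, 9, 9)), (1, (9, 9, 9)), (2, (9, 9, 9)),
    (3, (9, 9, 9)), (5, (13, 13, 13)),
])
def test_sphere_raster_matches_enumeration(radius, size):
    c = tuple(s // 2 for s in size)
    lat = G.rasterize_primitive(ShapePrimitive("sphere", (*c, radius)), size)
    assert int(lat.sum()) == brute_force_sphere_count(c, radius, size)


def test_sphere_r3_is_123_voxels():
    lat = G.rasterize_primitive(ShapePrimitive("sphere", (4, 4, 4, 3)),
                                (9, 9, 9))
    assert int(lat.sum()) == 123


def test_cuboid_covering_whole_lattice():
    size = (5, 6, 7)
    c = tuple((s - 1) / 2 for s in size)
    lat = G.rasterize_primitive(ShapePrimitive("cuboid", (*c, *size)), size)
    assert lat.all()


def test_primitive_with_transform_shifts_voxels():
    T = {1: AffineTransform.from_rotation_translation(np.eye(3), (3, 0, 0),
                                                      id=1)}
    base = G.rasterize_primitive(ShapePrimitive("sphere", (4, 4, 4, 2)),
                                 (12, 9, 9))
    moved = G.rasterize_primitive(
        ShapePrimitive("sphere", (4, 4, 4, 2), transform_id=1), (12, 9, 9),
        transforms=T)
    assert np.array_equal(np.roll(base, 3, axis=0), moved)


def test_contour_square_fill():
    sq = Contour(points=np.array(
        [[1, 1, 2], [5, 1, 2], [5, 5, 2], [1, 5, 2]], float))
    lat = G.rasterize_contours([sq], (8, 8, 4))
    assert int(lat.sum()) == 25
    assert int(lat[:, :, 2].sum()) == 25


def test_nested_squares_even_odd_ring():
    outer = Contour(points=np.array(
        [[0, 0, 1], [8, 0, 1], [8, 8, 1], [0, 8, 1]], float))
    inner = Contour(points=np.array(
        [[2, 2, 1], [6, 2, 1], [6, 6, 1], [2, 6, 1]], float))
    lat = G.rasterize_contours([outer, inner], (10, 10, 3))
    # oracle: per-polygon boundary-inclusive membership (shapely covers),
    # voxel filled iff it lies in an odd number of polygons
    from shapely.geometry import Point, Polygon
    polys = [Polygon([(0, 0), (8, 0), (8, 8), (0, 8)]),
             Polygon([(2, 2), (6, 2), (6, 6), (2, 6)])]
    for ix in range(10):
        for iy in range(10):
            want = sum(p.covers(Point(ix, iy)) for p in polys) % 2 == 1
            assert bool(lat[ix, iy, 1]) == want, (ix, iy)
    # interior of the inner square stays empty, ring is filled
    assert lat[4, 4, 1] == 0 and lat[1, 1, 1] == 1


def test_open_contour_warns_and_contributes_nothing():
    open_c = Contour(points=np.array(
        [[1, 1, 0], [4, 1, 0], [4, 4, 0]], float), closed=False)
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        lat = G.rasterize_contours([open_c], (6, 6, 2))
    assert not lat.any()
    assert any("open contour" in str(w.message) for w in rec)


def test_degenerate_closed_contour_raises():
    bad = Contour(points=np.array([[1, 1, 0], [2, 2, 0]], float),
                  closed=True)
    with pytest.raises(SegffError, match=">= 3 points"):
        G.rasterize_contours([bad], (4, 4, 2))


# --------------------------------------------------------- boundary mesh --

def mesh_euler(mesh):
    edges = set()
    for t in mesh.triangles:
        for a, b in ((0, 1), (1, 2), (2, 0)):
            edges.add(tuple(sorted((int(t[a]), int(t[b])))))
    return len(mesh.vertices) - len(edges) + len(mesh.triangles)


def test_single_voxel_cube_surface():
    lat = np.zeros((3, 3, 3), int)
    lat[1, 1, 1] = 1
    mesh = G.mask_to_boundary_mesh(lat, 1)
    assert len(mesh.triangles) == 12
    assert len(mesh.vertices) == 8
    assert mesh_euler(mesh) == 2


def test_two_voxel_bar_exposed_faces():
    lat = np.zeros((4, 3, 3), int)
    lat[1, 1, 1] = lat[2, 1, 1] = 5
    mesh = G.mask_to_boundary_mesh(lat, 5)
    assert len(mesh.triangles) == 20  # 10 exposed faces
    assert mesh_euler(mesh) == 2


def grow_manifold_blob(rng, n_voxels, extent=12):
    """Random genus-0 blob: add face-adjacent voxels only when they touch
    exactly one existing voxel and share no edge/corner with any other."""
    vox = {(extent // 2,) * 3}
    tries = 0
    while len(vox) < n_voxels and tries < 500:
        tries += 1
        base = list(vox)[int(rng.integers(len(vox)))]
        axis = int(rng.integers(3))
        step = int(rng.choice((-1, 1)))
        cand = list(base)
        cand[axis] += step
        cand = tuple(cand)
        if cand in vox or not all(0 < c < extent - 1 for c in cand):
            continue
        nbr26 = [v for v in vox
                 if max(abs(a - b) for a, b in zip(v, cand)) == 1]
        face_adj = [v for v in nbr26
                    if sum(abs(a - b) for a, b in zip(v, cand)) == 1]
        if len(nbr26) == 1 and len(face_adj) == 1:
            vox.add(cand)
    lat = np.zeros((extent, extent, extent), int)
    for v in vox:
        lat[v] = 1
    return lat


@pytest.mark.parametrize("seed", range(8))
def test_euler_characteristic_of_random_blobs(seed):
    rng = np.random.default_rng(seed)
    lat = grow_manifold_blob(rng, int(rng.integers(2, 20)))
    assert mesh_euler(G.mask_to_boundary_mesh(lat, 1)) == 2


def test_boundary_mesh_value_absent():
    with pytest.raises(SegffError, match="absent"):
        G.mask_to_boundary_mesh(np.zeros((2, 2, 2), int), 3)


# -------------------------------------------------------------- placement --

def translation(t, id=0):
    return AffineTransform.from_rotation_translation(np.eye(3), t, id=id)


def test_single_unit_placement():
    spec = G.CompositeSpec((6, 7, 8), np.full((1, 1, 1), 9.0),
                           [translation((2, 3, 4))])
    out = G.place_subvolumes(spec)
    assert np.count_nonzero(out) == 1
    assert out[2, 3, 4] == 9.0


def test_disjoint_placements_max_mode():
    spec = G.CompositeSpec((8, 8, 8), np.ones((1, 1, 1)),
                           [translation((1, 1, 1)), translation((5, 5, 5))],
                           combine="max")
    assert np.count_nonzero(G.place_subvolumes(spec)) == 2


def test_duplicate_transform_sum_doubles():
    T = translation((2, 2, 2))
    single = G.place_subvolumes(
        G.CompositeSpec((6, 6, 6), np.full((2, 2, 2), 3.0), [T],
                        combine="sum"))
    double = G.place_subvolumes(
        G.CompositeSpec((6, 6, 6), np.full((2, 2, 2), 3.0), [T, T],
                        combine="sum"))
    assert np.allclose(double, 2 * single)


def test_nonoverlapping_counts_scale_with_placements():
    sub = np.zeros((2, 2, 2))
    sub[0, 0, 0] = sub[1, 1, 1] = 1.0
    per = int(np.count_nonzero(sub))
    transforms = [translation((1, 1, 1)), translation((5, 1, 1)),
                  translation((1, 5, 1)), translation((5, 5, 5))]
    out = G.place_subvolumes(G.CompositeSpec((9, 9, 9), sub, transforms))
    assert np.count_nonzero(out) == per * len(transforms)


def test_placement_requires_transforms():
    spec = G.CompositeSpec((4, 4, 4), np.ones((1, 1, 1)), [translation((0, 0, 0))])
    spec.transforms = []
    with pytest.raises(SegffError, match="at least one transform"):
        G.place_subvolumes(spec)
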