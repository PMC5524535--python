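"""Affine algebra, rasterization, boundary meshes and subvolume placement.

Conventions (fixed once, documented in docs/format.md):

* Column vectors: a transform maps ``p' = R @ p + t``.
* Direction: source -> target (subvolume coordinates into tomogram
  coordinates).
* Composition is left-composition: ``compose(A, B)`` applies B first.
* Transforms act in voxel units of the target lattice; physical units enter
  only through lattice ``voxel_size`` metadata.
* Voxel ``(ix, iy, iz)`` has its center at coordinate ``(ix, iy, iz)``,
  0-based.
* Implicit-shape inequalities are closed (boundary voxels included).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import SegffError, TransformError
from .model import AffineTransform, Contour, Mesh, ShapePrimitive


# ---------------------------------------------------------------------------
# affine algebra
# ---------------------------------------------------------------------------

def apply_affine(T: AffineTransform, points) -> np.ndarray:
    """Map points (n, 3) through ``p' = R @ p + t``."""
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    return pts @ T.rotation.T + T.translation


def compose(A: AffineTransform, B: AffineTransform,
            id: int = 0) -> AffineTransform:
    """A after B: ``apply(compose(A, B), p) == apply(A, apply(B, p))``."""
    R = A.rotation @ B.rotation
    t = A.rotation @ B.translation + A.translation
    return AffineTransform.from_rotation_translation(R, t, id=id)


def invert(T: AffineTransform, id: int = 0) -> AffineTransform:
    """Inverse transform; raises on a singular rotation block."""
    R = T.rotation
    if abs(np.linalg.det(R)) < 1e-12:
        raise TransformError("non-invertible transform (singular matrix)")
    Rinv = np.linalg.inv(R)
    return AffineTransform.from_rotation_translation(Rinv, -Rinv @ T.translation,
                                                     id=id)


def _voxel_centers(size):
    nx, ny, nz = size
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    return np.stack([ix, iy, iz], axis=-1).reshape(-1, 3).astype(float)


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def rasterize_primitive(p: ShapePrimitive, size,
                        transforms=None) -> np.ndarray:
    """Binary lattice of voxel centers satisfying the primitive's implicit
    inequality (closed / boundary-inclusive).

    If the primitive carries a ``transform_id``, the transform (looked up in
    ``transforms``, a mapping id -> AffineTransform) maps primitive-local
    coordinates into lattice coordinates; voxel centers are pulled back
    through its inverse before evaluation.
    """
    size = tuple(int(s) for s in size)
    if any(s <= 0 for s in size):
        raise SegffError(f"lattice size must be positive, got {size}")
    pts = _voxel_centers(size)
    if p.transform_id is not None:
        if transforms is None or p.transform_id not in transforms:
            raise SegffError(f"primitive references unknown transform "
                             f"{p.transform_id}")
        pts = apply_affine(invert(transforms[p.transform_id]), pts)

    par = p.parameters
    c = np.asarray(par[:3])
    d = pts - c
    if p.kind == "sphere":
        inside = (d ** 2).sum(axis=1) <= par[3] ** 2
    elif p.kind == "ellipsoid":
        ax = np.asarray(par[3:6])
        inside = ((d / ax) ** 2).sum(axis=1) <= 1.0
    elif p.kind == "cuboid":
        half = np.asarray(par[3:6]) / 2.0
        inside = np.all(np.abs(d) <= half, axis=1)
    elif p.kind == "cylinder":
        r, h = par[3], par[4]
        inside = ((d[:, 0] ** 2 + d[:, 1] ** 2) <= r ** 2) \
            & (np.abs(d[:, 2]) <= h / 2.0)
    else:
        raise SegffError(f"unknown primitive kind {p.kind!r}")
    return inside.reshape(size).astype(np.uint8)


def _point_in_polygon(x, y, poly, eps=1e-9):
    """Even-odd crossing test, boundary-inclusive (a point on an edge is in)."""
    n = len(poly)
    inside = False
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        # on-segment check
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if abs(cross) <= eps * max(1.0, abs(x2 - x1) + abs(y2 - y1)):
            if min(x1, x2) - eps <= x <= max(x1, x2) + eps \
                    and min(y1, y2) - eps <= y <= max(y1, y2) + eps:
                return True
        # even-odd ray cast to +x
        if (y1 > y) != (y2 > y):
            xin = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < xin:
                inside = not inside
    return inside


def rasterize_contours(contours, size) -> np.ndarray:
    """Per-z-slice even-odd polygon fill of voxel centers.

    Open contours contribute nothing (a warning is emitted); closed contours
    with fewer than 3 points are an error. A voxel center lying on a contour
    edge counts as inside.
    """
    size = tuple(int(s) for s in size)
    nx, ny, nz = size
    out = np.zeros(size, dtype=np.uint8)
    by_slice: dict[int, list] = {}
    for c in contours:
        if not c.closed:
            warnings.warn("open contour ignored during rasterization")
            continue
        if len(c.points) < 3:
            raise SegffError(
                f"closed contour needs >= 3 points, got {len(c.points)}")
        z = float(c.points[0, 2])
        iz = int(round(z))
        if 0 <= iz < nz:
            by_slice.setdefault(iz, []).append(c.points[:, :2].tolist())
    for iz, polys in by_slice.items():
        for ix in range(nx):
            for iy in range(ny):
                crossings = sum(
                    _point_in_polygon(float(ix), float(iy), poly)
                    for poly in polys)
                if crossings % 2 == 1:
                    out[ix, iy, iz] = 1
    return out


# ---------------------------------------------------------------------------
# boundary mesh
# ---------------------------------------------------------------------------

# For each face direction, the 4 corner offsets (from the voxel center, in
# half-units doubled to stay integral) in counter-clockwise order as seen
# from outside (right-hand rule -> outward normal).
_FACE_CORNERS = {
    (1, 0, 0): [(1, -1, -1), (1, 1, -1), (1, 1, 1), (1, -1, 1)],
    (-1, 0, 0): [(-1, -1, -1), (-1, -1, 1), (-1, 1, 1), (-1, 1, -1)],
    (0, 1, 0): [(-1, 1, -1), (-1, 1, 1), (1, 1, 1), (1, 1, -1)],
    (0, -1, 0): [(-1, -1, -1), (1, -1, -1), (1, -1, 1), (-1, -1, 1)],
    (0, 0, 1): [(-1, -1, 1), (1, -1, 1), (1, 1, 1), (-1, 1, 1)],
    (0, 0, -1): [(-1, -1, -1), (-1, 1, -1), (1, 1, -1), (1, -1, -1)],
}


def mask_to_boundary_mesh(lattice, value: int) -> Mesh:
    """Watertight boundary surface of the voxel set ``lattice == value``.

    Emits one unit quad (two triangles) per 6-connected exposed face, with
    outward winding. Vertices sit on voxel corners (voxel centers are at
    integer coordinates, so corners are at half-integers).
    """
    arr = np.asarray(lattice)
    mask = arr == value
    if not mask.any():
        raise SegffError(f"value {value} absent from lattice")
    nx, ny, nz = mask.shape
    vert_index: dict[tuple, int] = {}
    vertices: list[tuple] = []
    triangles: list[tuple] = []

    def vid(corner):
        if corner not in vert_index:
            vert_index[corner] = len(vertices)
            vertices.append(corner)
        return vert_index[corner]

    vox = np.argwhere(mask)
    for ix, iy, iz in vox:
        for (dx, dy, dz), corners in _FACE_CORNERS.items():
            jx, jy, jz = ix + dx, iy + dy, iz + dz
            exposed = not (0 <= jx < nx and 0 <= jy < ny and 0 <= jz < nz) \
                or not mask[jx, jy, jz]
            if not exposed:
                continue
            ids = [vid((2 * ix + cx, 2 * iy + cy, 2 * iz + cz))
                   for cx, cy, cz in corners]
            triangles.append((ids[0], ids[1], ids[2]))
            triangles.append((ids[0], ids[2], ids[3]))
    verts = np.asarray(vertices, dtype=float) / 2.0
    return Mesh(vertices=verts, triangles=np.asarray(triangles, dtype=np.int64))


# ---------------------------------------------------------------------------
# subvolume placement
# ---------------------------------------------------------------------------

@dataclass
class CompositeSpec:
    """Recipe for compositing one subvolume (e.g. a sub-tomogram average)
    back into a target volume at many positions/orientations."""

    target_size: tuple
    subvolume: np.ndarray
    transforms: list = field(default_factory=list)
    combine: str = "max"          # {max, sum}
    interpolation: str = "nearest"  # {nearest, trilinear}

    def __post_init__(self):
        self.target_size = tuple(int(s) for s in self.target_size)
        self.subvolume = np.asarray(self.subvolume, dtype=float)
        if self.combine not in ("max", "sum"):
            raise SegffError(f"unknown combine mode {self.combine!r}")
        if self.interpolation not in ("nearest", "trilinear"):
            raise SegffError(
                f"unknown interpolation {self.interpolation!r}")


def place_subvolumes(spec: CompositeSpec) -> np.ndarray:
    """Composite the subvolume into the target through each transform.

    Resampling is pull-based: every target voxel center is mapped through the
    inverse transform and the subvolume is interpolated there (0 outside),
    so rotations leave no holes. Contributions across transforms combine by
    ``max`` (overlay, the default) or ``sum`` (accumulation).
    """
    if not spec.transforms:
        raise SegffError("CompositeSpec needs at least one transform")
    order = 0 if spec.interpolation == "nearest" else 1
    out = np.zeros(spec.target_size, dtype=float)
    centers = _voxel_centers(spec.target_size)
    for T in spec.transforms:
        src = apply_affine(invert(T), centers)  # (N, 3) subvolume coords
        vals = ndimage.map_coordinates(
            spec.subvolume, src.T, order=order, mode="constant", cval=0.0,
            prefilter=False)
        contrib = vals.reshape(spec.target_size)
        if spec.combine == "max":
            out = np.maximum(out, contrib)
        else:
            out += contrib
    return out
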