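"""Segmentation data model.

A :class:`Segmentation` is the root container for one segmentation of a 3D
volume: a forest of :class:`Segment` regions (``parent_id == 0`` marks a
child of the implicit root), a registry of shared label lattices, and a
registry of affine transforms used to place sub-tomogram averages or other
repeated primitives back into a tomogram.

Each segment may carry any combination of representations — surface mesh,
a reference into a shared run-length-encoded voxel lattice (or an external
mask file), geometric shape primitives, and planar slice contours — and at
most one structured biological annotation (a name plus external database
references such as GO or UniProt accessions).

Colours are RGBA floats in [0, 1]; alpha defaults to 1 and a missing colour
canonicalises to opaque mid-grey. Transforms are 3x4 row-major ``[R|t]``
matrices mapping source (segment/subvolume) coordinates to target (tomogram)
coordinates with the column-vector convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError

#: Current interchange format version written by this library.
SCHEMA_VERSION = "0.1.0"

#: Bit-depth modes a lattice may declare. ``u1`` is a logical binary mode
#: (values restricted to {0, 1}); it is stored like u8 on disk.
LATTICE_MODES = {"u1": 1, "u8": 255, "u16": 65535, "u32": 4294967295}

SHAPE_KINDS = ("sphere", "ellipsoid", "cuboid", "cylinder")

DEFAULT_COLOUR = (0.5, 0.5, 0.5, 1.0)


def round9(x: float) -> float:
    """Round to 9 significant digits — the canonical float precision of the
    interchange format (decimal text in XML/JSON, canonical equality)."""
    return float("%.9g" % float(x))


@dataclass
class Colour:
    r: float = 0.5
    g: float = 0.5
    b: float = 0.5
    a: float = 1.0

    def as_tuple(self):
        return (self.r, self.g, self.b, self.a)


@dataclass
class ExternalReference:
    resource: str
    accession: str
    label: str = ""
    description: str = ""
    url: Optional[str] = None


@dataclass
class BiologicalAnnotation:
    name: str = ""
    description: str = ""
    number_of_instances: int = 1
    external_references: list[ExternalReference] = field(default_factory=list)


@dataclass
class SoftwareInfo:
    name: str = ""
    version: str = ""
    processing_details: str = ""


@dataclass
class AffineTransform:
    """3x4 row-major ``[R|t]``: maps p -> R @ p + t (source -> target)."""

    id: int
    matrix: np.ndarray  # shape (3, 4), float64

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.size != 12:
            raise ValueError("affine matrix must have 12 entries (3x4 [R|t])")
        self.matrix = m.reshape(3, 4)

    @classmethod
    def identity(cls, id: int = 0) -> "AffineTransform":
        return cls(id=id, matrix=np.hstack([np.eye(3), np.zeros((3, 1))]))

    @classmethod
    def from_rotation_translation(cls, R, t, id: int = 0) -> "AffineTransform":
        R = np.asarray(R, dtype=float).reshape(3, 3)
        t = np.asarray(t, dtype=float).reshape(3, 1)
        return cls(id=id, matrix=np.hstack([R, t]))

    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:, 3]


@dataclass
class Mesh:
    vertices: np.ndarray  # (n, 3) float
    triangles: np.ndarray  # (m, 3) int, indices into vertices
    normals: Optional[np.ndarray] = None  # (n, 3) float, parallel to vertices
    transform_id: Optional[int] = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)


@dataclass
class ShapePrimitive:
    """One of sphere / ellipsoid / cuboid / cylinder.

    ``parameters`` by kind:
      sphere:    (cx, cy, cz, radius)
      ellipsoid: (cx, cy, cz, ax, ay, az)        semi-axes
      cuboid:    (cx, cy, cz, ex, ey, ez)        full edge lengths
      cylinder:  (cx, cy, cz, radius, height)    axis along z
    """

    kind: str
    parameters: tuple
    transform_id: Optional[int] = None

    def __post_init__(self):
        self.parameters = tuple(float(p) for p in self.parameters)


@dataclass
class Contour:
    points: np.ndarray  # (n, 3) float; all z equal (planar slice contour)
    closed: bool = True

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)


@dataclass
class VolumeRef:
    """Selects a segment's voxels: ``voxel_value`` inside lattice
    ``lattice_id``, or inside an external MRC mask at ``external_path``."""

    lattice_id: Optional[int] = None
    voxel_value: int = 1
    external_path: Optional[str] = None


@dataclass
class Lattice:
    id: int
    size: tuple  # (nx, ny, nz)
    mode: str = "u8"
    origin_voxel: tuple = (0, 0, 0)
    voxel_size: Optional[tuple] = None  # Angstrom / voxel
    runs: list = field(default_factory=list)  # [(value, length), ...]

    def __post_init__(self):
        self.size = tuple(int(s) for s in self.size)
        self.origin_voxel = tuple(int(o) for o in self.origin_voxel)
        if self.voxel_size is not None:
            self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.runs = [(int(v), int(l)) for v, l in self.runs]

    @property
    def voxel_count(self) -> int:
        nx, ny, nz = self.size
        return nx * ny * nz


@dataclass
class Segment:
    id: int
    parent_id: int = 0
    name: str = ""
    colour: Optional[Colour] = None
    biological_annotation: Optional[BiologicalAnnotation] = None
    mesh_list: list[Mesh] = field(default_factory=list)
    volume_ref: Optional[VolumeRef] = None
    shape_primitive_list: list[ShapePrimitive] = field(default_factory=list)
    contour_list: list[Contour] = field(default_factory=list)
    transform_ids: list[int] = field(default_factory=list)

    def has_representation(self) -> bool:
        return bool(
            self.mesh_list
            or self.volume_ref is not None
            or self.shape_primitive_list
            or self.contour_list
        )


@dataclass
class Segmentation:
    name: str = ""
    schema_version: str = SCHEMA_VERSION
    software_list: list[SoftwareInfo] = field(default_factory=list)
    transform_list: list[AffineTransform] = field(default_factory=list)
    bounding_box: Optional[tuple] = None  # (xmin,xmax,ymin,ymax,zmin,zmax) Angstrom
    global_external_references: list[ExternalReference] = field(default_factory=list)
    lattice_list: list[Lattice] = field(default_factory=list)
    segments: list[Segment] = field(default_factory=list)
    details: str = ""

    # -- lookups ---------------------------------------------------------
    def segment(self, id: int) -> Segment:
        for s in self.segments:
            if s.id == id:
                return s
        raise ValidationError(f"unknown segment id {id}")

    def lattice(self, id: int) -> Lattice:
        for l in self.lattice_list:
            if l.id == id:
                return l
        raise ValidationError(f"unknown lattice id {id}")

    def transform(self, id: int) -> AffineTransform:
        for t in self.transform_list:
            if t.id == id:
                return t
        raise ValidationError(f"unknown transform id {id}")

    def children(self, id: int) -> list[Segment]:
        return sorted((s for s in self.segments if s.parent_id == id),
                      key=lambda s: s.id)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def new_segmentation(name: str = "") -> Segmentation:
    """Create an empty, valid segmentation stamped with the current format
    version."""
    return Segmentation(name=name, schema_version=SCHEMA_VERSION)


def add_segment(seg: Segmentation, parent_id: int = 0, name: str = "",
                colour: Optional[Colour] = None) -> int:
    """Append a segment under ``parent_id`` (0 = root) and return its id.

    Ids are assigned smallest-unused so repeated builds give identical files.
    """
    parent_id = int(parent_id)
    if parent_id != 0 and all(s.id != parent_id for s in seg.segments):
        raise ValidationError(f"unknown parent {parent_id}")
    used = {s.id for s in seg.segments}
    new_id = 1
    while new_id in used:
        new_id += 1
    seg.segments.append(Segment(id=new_id, parent_id=parent_id, name=name,
                                colour=colour))
    return new_id


@dataclass(frozen=True)
class Violation:
    code: str
    message: str
    offending_id: Optional[int] = None


def _finite(*vals) -> bool:
    return all(math.isfinite(float(v)) for v in vals)


def validate(seg: Segmentation) -> list[Violation]:
    """Check every model invariant; return violations ordered by (code, id).

    Violations are data, not exceptions: an empty list means the
    segmentation is valid for interchange.
    """
    out: list[Violation] = []

    def v(code, message, oid=None):
        out.append(Violation(code, message, oid))

    if not str(seg.schema_version).strip():
        v("schema_version", "schema_version must be non-empty")

    # --- transform registry
    tids = [t.id for t in seg.transform_list]
    known_tids = set(tids)
    for t in seg.transform_list:
        if t.id < 0:
            v("transform_id", f"transform id {t.id} is negative", t.id)
        if tids.count(t.id) > 1:
            v("transform_id", f"duplicate transform id {t.id}", t.id)
        if not np.all(np.isfinite(t.matrix)):
            v("transform_matrix", f"transform {t.id} has non-finite entries", t.id)

    # --- lattice registry
    lids = [l.id for l in seg.lattice_list]
    known_lids = set(lids)
    for lat in seg.lattice_list:
        if lids.count(lat.id) > 1:
            v("lattice_id", f"duplicate lattice id {lat.id}", lat.id)
        if lat.mode not in LATTICE_MODES:
            v("lattice_mode", f"lattice {lat.id}: unknown mode {lat.mode!r}", lat.id)
            continue
        if any(s <= 0 for s in lat.size):
            v("lattice_size", f"lattice {lat.id}: non-positive size {lat.size}", lat.id)
            continue
        total = sum(l for _, l in lat.runs)
        if total != lat.voxel_count:
            v("lattice_runs",
              f"lattice {lat.id}: run lengths sum to {total}, "
              f"expected {lat.voxel_count} voxels", lat.id)
        vmax = LATTICE_MODES[lat.mode]
        prev = None
        for value, length in lat.runs:
            if length < 1:
                v("lattice_runs", f"lattice {lat.id}: run length {length} < 1", lat.id)
                break
            if value < 0 or value > vmax:
                v("lattice_mode",
                  f"lattice {lat.id}: run value {value} outside mode {lat.mode}",
                  lat.id)
                break
            if prev is not None and value == prev:
                v("lattice_runs",
                  f"lattice {lat.id}: adjacent runs share value {value} "
                  "(not maximally merged)", lat.id)
                break
            prev = value

    # --- segment forest
    sids = [s.id for s in seg.segments]
    known_sids = set(sids)
    for s in seg.segments:
        if s.id <= 0:
            v("segment_id", f"segment id {s.id} is not a positive integer", s.id)
        if sids.count(s.id) > 1:
            v("segment_id", f"duplicate segment id {s.id}", s.id)
    parent = {s.id: s.parent_id for s in seg.segments}
    for s in seg.segments:
        if s.parent_id != 0 and s.parent_id not in known_sids:
            v("parent", f"segment {s.id}: unknown parent {s.parent_id}", s.id)
    # cycle detection by walking each ancestor chain
    for s in seg.segments:
        seen = {s.id}
        p = s.parent_id
        while p != 0 and p in parent:
            if p in seen:
                v("parent_cycle", f"cycle/self-parent at {s.id}", s.id)
                break
            seen.add(p)
            p = parent[p]

    # --- per-segment contents
    for s in sorted(seg.segments, key=lambda s: s.id):
        if s.colour is not None:
            if not all(0.0 <= c <= 1.0 for c in s.colour.as_tuple()):
                v("colour", f"segment {s.id}: colour out of range "
                  f"{s.colour.as_tuple()}", s.id)
        ann = s.biological_annotation
        if ann is not None:
            if ann.number_of_instances < 1:
                v("annotation",
                  f"segment {s.id}: number_of_instances must be >= 1", s.id)
            for ref in ann.external_references:
                if not ref.resource or not ref.accession:
                    v("external_reference",
                      f"segment {s.id}: external reference needs non-empty "
                      "resource and accession", s.id)
        for tid in s.transform_ids:
            if tid not in known_tids:
                v("transform_ref",
                  f"segment {s.id}: unknown transform id {tid}", s.id)
        for k, m in enumerate(s.mesh_list):
            if m.triangles.size and m.triangles.max() >= len(m.vertices):
                v("mesh", f"segment {s.id} mesh {k}: triangle index "
                  f"{int(m.triangles.max())} >= vertex count {len(m.vertices)}",
                  s.id)
            if m.triangles.size and m.triangles.min() < 0:
                v("mesh", f"segment {s.id} mesh {k}: negative triangle index", s.id)
            if m.normals is not None and len(m.normals) != len(m.vertices):
                v("mesh", f"segment {s.id} mesh {k}: normals length "
                  f"{len(m.normals)} != vertex count {len(m.vertices)}", s.id)
            if m.transform_id is not None and m.transform_id not in known_tids:
                v("transform_ref",
                  f"segment {s.id} mesh {k}: unknown transform id "
                  f"{m.transform_id}", s.id)
        vr = s.volume_ref
        if vr is not None:
            if vr.external_path is None:
                if vr.lattice_id not in known_lids:
                    v("lattice_ref",
                      f"segment {s.id}: unknown lattice id {vr.lattice_id}", s.id)
            if vr.voxel_value < 0:
                v("lattice_ref",
                  f"segment {s.id}: negative voxel_value {vr.voxel_value}", s.id)
        for k, p in enumerate(s.shape_primitive_list):
            if p.kind not in SHAPE_KINDS:
                v("shape", f"segment {s.id} shape {k}: unknown kind {p.kind!r}",
                  s.id)
                continue
            sizes = p.parameters[3:]
            if any(x <= 0 for x in sizes):
                v("shape", f"segment {s.id} shape {k}: non-positive size "
                  f"parameter in {p.parameters}", s.id)
            if not _finite(*p.parameters):
                v("shape", f"segment {s.id} shape {k}: non-finite parameter", s.id)
            if p.transform_id is not None and p.transform_id not in known_tids:
                v("transform_ref",
                  f"segment {s.id} shape {k}: unknown transform id "
                  f"{p.transform_id}", s.id)
        for k, c in enumerate(s.contour_list):
            if c.closed and len(c.points) < 3:
                v("contour", f"segment {s.id} contour {k}: closed contour "
                  f"needs >= 3 points, got {len(c.points)}", s.id)
            if len(c.points) and not np.allclose(c.points[:, 2],
                                                 c.points[0, 2]):
                v("contour", f"segment {s.id} contour {k}: points not planar "
                  "in z", s.id)

    if seg.bounding_box is not None and len(tuple(seg.bounding_box)) != 6:
        v("bounding_box", "bounding_box must have 6 entries")
    for ref in seg.global_external_references:
        if not ref.resource or not ref.accession:
            v("external_reference",
              "global external reference needs non-empty resource and accession")

    out.sort(key=lambda viol: (viol.code,
                               viol.offending_id if viol.offending_id is not None
                               else -1))
    return out


def subtree(seg: Segmentation, id: int) -> list[int]:
    """Pre-order list of segment ids under ``id`` (children visited in
    ascending id order); first element is ``id`` itself."""
    if all(s.id != id for s in seg.segments):
        raise ValidationError(f"unknown segment id {id}")
    order: list[int] = []

    def visit(i):
        order.append(i)
        for child in seg.children(i):
            visit(child.id)

    visit(id)
    return order


# ---------------------------------------------------------------------------
# canonical form
# ---------------------------------------------------------------------------

def _cf_colour(c: Optional[Colour]):
    t = DEFAULT_COLOUR if c is None else c.as_tuple()
    return tuple(round9(x) for x in t)


def _cf_ref(r: ExternalReference):
    return ("external_reference", r.resource, r.accession, r.label,
            r.description, r.url or "")


def _cf_annotation(a: Optional[BiologicalAnnotation]):
    if a is None:
        return None
    return (a.name, a.description, int(a.number_of_instances),
            tuple(_cf_ref(r) for r in a.external_references))


def _cf_floats(arr) -> tuple:
    return tuple(round9(x) for x in np.asarray(arr, dtype=float).ravel())


def _cf_mesh(m: Mesh):
    return (_cf_floats(m.vertices),
            tuple(int(i) for i in m.triangles.ravel()),
            None if m.normals is None else _cf_floats(m.normals),
            m.transform_id)


def _cf_segment(s: Segment):
    vr = s.volume_ref
    return {
        "id": s.id,
        "parent_id": s.parent_id,
        "name": s.name,
        "colour": _cf_colour(s.colour),
        "annotation": _cf_annotation(s.biological_annotation),
        "meshes": tuple(_cf_mesh(m) for m in s.mesh_list),
        "volume_ref": None if vr is None else
            (vr.lattice_id, int(vr.voxel_value), vr.external_path),
        "shapes": tuple((p.kind, _cf_floats(p.parameters), p.transform_id)
                        for p in s.shape_primitive_list),
        "contours": tuple((_cf_floats(c.points), bool(c.closed))
                          for c in s.contour_list),
        "transform_ids": tuple(int(t) for t in s.transform_ids),
    }


def canonical_form(seg: Segmentation):
    """Deterministic nested value for interchange equality.

    Segments/transforms/lattices sorted by id, floats rounded to 9
    significant digits, defaults materialised. Two segmentations are
    interchange-equivalent iff their canonical forms compare equal; this is
    the contract the codec round-trip tests assert.
    """
    violations = validate(seg)
    if violations:
        raise ValidationError(
            "cannot canonicalise an invalid segmentation: "
            + "; ".join(viol.message for viol in violations),
            violations)
    return {
        "name": seg.name,
        "schema_version": seg.schema_version,
        "details": seg.details,
        "software": tuple((sw.name, sw.version, sw.processing_details)
                          for sw in seg.software_list),
        "bounding_box": None if seg.bounding_box is None
                        else _cf_floats(seg.bounding_box),
        "global_refs": tuple(_cf_ref(r)
                             for r in seg.global_external_references),
        "transforms": tuple((t.id, _cf_floats(t.matrix))
                            for t in sorted(seg.transform_list,
                                            key=lambda t: t.id)),
        "lattices": tuple((l.id, l.size, l.mode, l.origin_voxel,
                           None if l.voxel_size is None
                           else _cf_floats(l.voxel_size),
                           tuple(l.runs))
                          for l in sorted(seg.lattice_list,
                                          key=lambda l: l.id)),
        "segments": tuple(
            tuple(sorted(_cf_segment(s).items()))
            for s in sorted(seg.segments, key=lambda s: s.id)),
    }
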