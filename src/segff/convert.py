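"""Bridges between common structural-biology carriers and the model.

Rather than parsing each segmentation package's native files, the lingua
franca carriers are supported: MRC2014 volumes for label masks and
densities, and ASCII STL / Wavefront OBJ for surface meshes. Label masks
become shared-lattice segmentations (one segment per nonzero label);
meshes become flat mesh segmentations; volume-backed segments can be
externalised to per-segment MRC mask files with a manifest, separating
annotation metadata from bulk voxel data.
"""

from __future__ import annotations

import colorsys
import copy
import os
import struct
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, SegffError
from . import rle
from .model import (Colour, Lattice, Mesh, Segmentation, Segment, VolumeRef,
                    add_segment, new_segmentation, validate)

# MRC2014 mode -> numpy dtype (little-endian on disk)
_MRC_DTYPES = {0: np.dtype("<i1"), 1: np.dtype("<i2"),
               2: np.dtype("<f4"), 6: np.dtype("<u2")}


@dataclass
class MrcVolume:
    """An MRC2014 volume normalised to x-fastest axis order: ``data`` has
    shape (nx, ny, nz) and is indexed ``[ix, iy, iz]``."""

    data: np.ndarray
    voxel_size: tuple = (1.0, 1.0, 1.0)  # Angstrom
    origin: tuple = (0.0, 0.0, 0.0)      # Angstrom (MRC ORIGIN record)
    mode: int = 2

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise SegffError("MRC volume data must be 3D")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def size(self):
        return self.data.shape


def read_mrc(path) -> MrcVolume:
    """Read an MRC2014 file (modes 0, 1, 2, 6; machine stamp honoured)."""
    with open(path, "rb") as fh:
        header = fh.read(1024)
        if len(header) < 1024:
            raise FormatError(
                f"{path}: not an MRC file (header truncated, "
                f"{len(header)} bytes)")
        if header[208:212] not in (b"MAP ", b"MAP\x00"):
            raise FormatError(f"{path}: bad MRC magic {header[208:212]!r}")
        stamp = header[212]
        if stamp == 0x44:
            endian = "<"
        elif stamp == 0x11:
            endian = ">"
        else:
            raise FormatError(f"{path}: unrecognised machine stamp "
                              f"0x{stamp:02x}")
        ints = struct.unpack(endian + "10i", header[:40])
        nx, ny, nz, mode, _, _, _, mx, my, mz = ints
        cella = struct.unpack(endian + "3f", header[40:52])
        nsymbt = struct.unpack(endian + "i", header[92:96])[0]
        origin = struct.unpack(endian + "3f", header[196:208])
        if mode not in _MRC_DTYPES:
            raise FormatError(f"{path}: unsupported MRC mode {mode}")
        dtype = _MRC_DTYPES[mode].newbyteorder(endian)
        fh.seek(1024 + nsymbt)
        raw = fh.read(nx * ny * nz * dtype.itemsize)
        if len(raw) < nx * ny * nz * dtype.itemsize:
            raise FormatError(f"{path}: data block truncated")
        data = np.frombuffer(raw, dtype=dtype).reshape(nz, ny, nx)
    # x-fastest on disk -> (nx, ny, nz) in memory
    data = np.ascontiguousarray(data.transpose(2, 1, 0))
    vs = tuple(c / m if m else 1.0 for c, m in zip(cella, (mx, my, mz)))
    return MrcVolume(data=data, voxel_size=vs, origin=tuple(origin),
                     mode=mode)


def write_mrc(vol: MrcVolume, path) -> None:
    """Write MRC2014. Integer label lattices go out as mode 0 when the
    maximum label fits a signed byte, else mode 6 (uint16); float data as
    mode 2."""
    data = vol.data
    if np.issubdtype(data.dtype, np.floating):
        mode = 2
    elif np.issubdtype(data.dtype, np.integer):
        if data.size and data.min() < 0:
            raise SegffError("negative labels cannot be written as MRC masks")
        mode = 0 if (data.size == 0 or data.max() <= 127) else 6
        if data.size and data.max() > 65535:
            raise SegffError(f"label {int(data.max())} exceeds uint16 range")
    else:
        raise SegffError(f"unsupported dtype {data.dtype}")
    nx, ny, nz = data.shape
    dtype = _MRC_DTYPES[mode]
    arr = np.ascontiguousarray(data.transpose(2, 1, 0)).astype(dtype)
    fdata = data.astype(float)
    dmin, dmax, dmean = float(fdata.min()), float(fdata.max()), float(fdata.mean())
    rms = float(fdata.std())
    header = bytearray(1024)
    struct.pack_into("<10i", header, 0, nx, ny, nz, mode, 0, 0, 0, nx, ny, nz)
    struct.pack_into("<3f", header, 40,
                     *(n * v for n, v in zip((nx, ny, nz), vol.voxel_size)))
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # MAPC MAPR MAPS
    struct.pack_into("<3f", header, 76, dmin, dmax, dmean)
    struct.pack_into("<2i", header, 88, 1, 0)  # ISPG, NSYMBT
    header[104:108] = b"MRCO"  # EXTTYP
    struct.pack_into("<i", header, 108, 20140)  # NVERSION
    struct.pack_into("<3f", header, 196, *vol.origin)
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0x00, 0x00))
    struct.pack_into("<f", header, 216, rms)
    struct.pack_into("<i", header, 220, 1)  # NLABL
    header[224:224 + 80] = b"segff".ljust(80)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(arr.tobytes())


# ---------------------------------------------------------------------------
# label masks <-> segmentation
# ---------------------------------------------------------------------------

def label_colour(index: int) -> Colour:
    """Deterministic distinguishable palette: golden-ratio hue walk in HSV
    (s=0.75, v=0.9) converted to RGB."""
    hue = (index * 0.6180339887498949) % 1.0
    r, g, b = colorsys.hsv_to_rgb(hue, 0.75, 0.9)
    return Colour(r, g, b, 1.0)


def _mode_for_max(vmax: int) -> str:
    if vmax <= 1:
        return "u1"
    if vmax <= 255:
        return "u8"
    if vmax <= 65535:
        return "u16"
    return "u32"


def from_label_mask(vol: MrcVolume, name: str = "") -> Segmentation:
    """Turn a multi-label integer volume into a flat segmentation: one
    shared RLE lattice, one segment per distinct nonzero label."""
    if not np.issubdtype(vol.data.dtype, np.integer):
        raise SegffError("not a label mask (float data)")
    if vol.data.size and vol.data.min() < 0:
        raise SegffError("not a label mask (negative values)")
    labels = sorted(int(v) for v in np.unique(vol.data) if v != 0)
    vmax = int(vol.data.max()) if vol.data.size else 0
    mode = _mode_for_max(vmax)
    seg = new_segmentation(name)
    seg.lattice_list.append(Lattice(
        id=0, size=vol.data.shape, mode=mode, voxel_size=vol.voxel_size,
        runs=rle.encode(vol.data, mode=mode)))
    for i, label in enumerate(labels):
        sid = add_segment(seg, 0, name=f"segment_{label}",
                          colour=label_colour(i))
        seg.segment(sid).volume_ref = VolumeRef(lattice_id=0,
                                                voxel_value=label)
    return seg


def export_external_masks(seg: Segmentation, directory):
    """Write each volume-backed segment as a binary MRC mask under
    ``directory`` plus a 2-column manifest TSV; return the segmentation
    rewritten with external-path volume refs.

    Shared lattices stay in the returned segmentation so only the
    volume-ref storage location changes; the mask files let tools that only
    need metadata skip the voxel payload.
    """
    os.makedirs(directory, exist_ok=True)
    out = copy.deepcopy(seg)
    rows = []
    for s in out.segments:
        vr = s.volume_ref
        if vr is None or vr.external_path is not None:
            continue
        lat = out.lattice(vr.lattice_id)
        grid = rle.decode(lat.runs, lat.size)
        mask = (grid == vr.voxel_value).astype(np.uint8)
        fname = f"segment_{s.id}.mrc"
        write_mrc(MrcVolume(data=mask,
                            voxel_size=lat.voxel_size or (1.0, 1.0, 1.0)),
                  os.path.join(directory, fname))
        s.volume_ref = VolumeRef(lattice_id=None, voxel_value=1,
                                 external_path=fname)
        rows.append((s.id, fname))
    if not rows:
        warnings.warn("segmentation has no volume-backed segments; "
                      "manifest is empty")
    manifest = os.path.join(directory, "manifest.tsv")
    with open(manifest, "w", encoding="utf-8") as fh:
        fh.write("segment_id\trelative_path\n")
        for sid, fname in rows:
            fh.write(f"{sid}\t{fname}\n")
    return out


def import_external_masks(seg: Segmentation, directory) -> Segmentation:
    """Inverse of :func:`export_external_masks`: load each external mask
    back into an in-file lattice."""
    out = copy.deepcopy(seg)
    next_lid = max((l.id for l in out.lattice_list), default=-1) + 1
    for s in out.segments:
        vr = s.volume_ref
        if vr is None or vr.external_path is None:
            continue
        vol = read_mrc(os.path.join(directory, vr.external_path))
        mask = (vol.data != 0).astype(np.uint8)
        out.lattice_list.append(Lattice(
            id=next_lid, size=mask.shape, mode="u1",
            voxel_size=vol.voxel_size, runs=rle.encode(mask, mode="u1")))
        s.volume_ref = VolumeRef(lattice_id=next_lid, voxel_value=1)
        next_lid += 1
    return out


# ---------------------------------------------------------------------------
# surface meshes
# ---------------------------------------------------------------------------

def _dedup_key(x, y, z):
    return (round(float(x), 6), round(float(y), 6), round(float(z), 6))


def read_stl_ascii(path) -> Mesh:
    """Parse an ASCII STL solid.

    Vertices are deduplicated by exact match after rounding coordinates to
    1e-6. Facet normals are kept by averaging them onto the shared vertices
    (the model stores vertex-parallel normals); the average is renormalised.
    """
    with open(path, "rb") as fh:
        head = fh.read(512)
    if b"\x00" in head or not head.lstrip().lower().startswith(b"solid"):
        raise FormatError("binary STL unsupported (ASCII STL only)")
    verts: list[tuple] = []
    index: dict[tuple, int] = {}
    normals_acc: list[np.ndarray] = []
    triangles: list[tuple] = []
    facet_normal = None
    facet_vertices: list[int] = []
    in_solid = False
    with open(path, "r", encoding="utf-8", errors="strict") as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            kw = tok[0].lower()
            try:
                if kw == "solid":
                    in_solid = True
                elif kw == "facet":
                    facet_normal = np.asarray([float(x) for x in tok[2:5]])
                    facet_vertices = []
                elif kw == "vertex":
                    x, y, z = (float(v) for v in tok[1:4])
                    key = _dedup_key(x, y, z)
                    if key not in index:
                        index[key] = len(verts)
                        verts.append(key)
                        normals_acc.append(np.zeros(3))
                    facet_vertices.append(index[key])
                elif kw == "endfacet":
                    if len(facet_vertices) != 3:
                        raise ValueError(
                            f"facet has {len(facet_vertices)} vertices")
                    triangles.append(tuple(facet_vertices))
                    if facet_normal is not None:
                        for vi in facet_vertices:
                            normals_acc[vi] = normals_acc[vi] + facet_normal
                elif kw in ("outer", "endloop", "endsolid"):
                    pass
                else:
                    raise ValueError(f"unexpected token {tok[0]!r}")
            except (ValueError, IndexError) as exc:
                raise FormatError(
                    f"{path}: malformed STL at line {lineno}: {exc}") from exc
    if not in_solid:
        raise FormatError(f"{path}: no 'solid' record found")
    if not triangles:
        warnings.warn(f"{path}: empty STL solid")
        return Mesh(vertices=np.zeros((0, 3)),
                    triangles=np.zeros((0, 3), dtype=np.int64))
    normals = np.asarray(normals_acc)
    norms = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = np.divide(normals, norms, out=np.zeros_like(normals),
                        where=norms > 0)
    return Mesh(vertices=np.asarray(verts, dtype=float),
                triangles=np.asarray(triangles, dtype=np.int64),
                normals=normals)


def read_obj(path) -> Mesh:
    """Parse a Wavefront OBJ (v/f records only).

    1-based indices become 0-based; negative indices resolve relative to the
    vertices defined so far; faces with more than three vertices are
    fan-triangulated.
    """
    verts: list[tuple] = []
    triangles: list[tuple] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok or tok[0].startswith("#"):
                continue
            if tok[0] == "v":
                try:
                    verts.append(tuple(float(x) for x in tok[1:4]))
                except (ValueError, IndexError) as exc:
                    raise FormatError(
                        f"{path}: malformed vertex at line {lineno}") from exc
            elif tok[0] == "f":
                idx = []
                for ref in tok[1:]:
                    try:
                        i = int(ref.split("/")[0])
                    except ValueError as exc:
                        raise FormatError(
                            f"{path}: malformed face at line "
                            f"{lineno}") from exc
                    if i < 0:
                        i = len(verts) + i
                    else:
                        i = i - 1
                    if not (0 <= i < len(verts)):
                        raise FormatError(
                            f"{path}: face index out of range at line "
                            f"{lineno} (index {ref}, {len(verts)} vertices)")
                    idx.append(i)
                if len(idx) < 3:
                    raise FormatError(
                        f"{path}: face with fewer than 3 vertices at line "
                        f"{lineno}")
                for k in range(1, len(idx) - 1):
                    triangles.append((idx[0], idx[k], idx[k + 1]))
    return Mesh(vertices=np.asarray(verts, dtype=float).reshape(-1, 3),
                triangles=np.asarray(triangles, dtype=np.int64)
                .reshape(-1, 3))


def from_meshes(meshes, name: str = "") -> Segmentation:
    """One flat segment per (name, Mesh) pair."""
    meshes = list(meshes)
    if not meshes:
        raise SegffError("from_meshes needs at least one mesh")
    seg = new_segmentation(name)
    for i, (mesh_name, mesh) in enumerate(meshes):
        sid = add_segment(seg, 0, name=mesh_name, colour=label_colour(i))
        seg.segment(sid).mesh_list.append(mesh)
    return seg
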