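"""Read/write the segmentation model in three interchangeable encodings.

One documented element tree, three encodings:

* **XML** (``.sff``/``.xml``) — the reference text encoding.
* **JSON** (``.json``) — mirrors the XML element tree 1:1, attributes folded
  into keys.
* **HDF5** (``.h5``/``.hff``/``.hdf5``) — hierarchical binary container for
  large lattices and meshes.

Every float written to a text encoding uses shortest round-trip decimal
capped at 9 significant digits, matching ``canonical_form`` rounding, so
``read(write(seg))`` is canonical-equal to ``seg`` in every encoding and
writing the same segmentation twice yields byte-identical XML/JSON.
Unknown fields encountered on read are dropped with a logged warning
(forward compatibility); files declaring a schema version newer than
:data:`segff.model.SCHEMA_VERSION` are rejected.
"""

from __future__ import annotations

import json
import logging
import os
import xml.etree.ElementTree as ET

import h5py
import numpy as np

from .errors import FormatError, ValidationError, VersionError
from . import model as M
from .model import (AffineTransform, BiologicalAnnotation, Colour, Contour,
                    ExternalReference, Lattice, Mesh, Segment, Segmentation,
                    ShapePrimitive, SoftwareInfo, VolumeRef, round9, validate)

log = logging.getLogger(__name__)

_EXT_FORMAT = {".sff": "xml", ".xml": "xml", ".json": "json",
               ".h5": "hdf5", ".hff": "hdf5", ".hdf5": "hdf5"}

FORMATS = ("xml", "json", "hdf5")


def infer_format(path) -> str:
    ext = os.path.splitext(str(path))[1].lower()
    if ext not in _EXT_FORMAT:
        raise FormatError(
            f"cannot infer format from extension {ext!r} "
            f"(known: {', '.join(sorted(_EXT_FORMAT))})")
    return _EXT_FORMAT[ext]


def _check_version(version: str):
    try:
        parts = tuple(int(p) for p in str(version).strip().split("."))
    except ValueError:
        raise FormatError(f"unparseable schema_version {version!r}")
    current = tuple(int(p) for p in M.SCHEMA_VERSION.split("."))
    if parts > current:
        raise VersionError(
            f"file schema_version {version} is newer than supported "
            f"{M.SCHEMA_VERSION}")


def _f(x) -> str:
    return "%.9g" % float(x)


def _floats(seq) -> str:
    return " ".join(_f(x) for x in np.asarray(seq, dtype=float).ravel())


def _ints(seq) -> str:
    return " ".join(str(int(x)) for x in np.asarray(seq).ravel())


# ---------------------------------------------------------------------------
# XML
# ---------------------------------------------------------------------------

def _xml_external_reference(parent, ref: ExternalReference):
    e = ET.SubElement(parent, "externalReference",
                      resource=ref.resource, accession=ref.accession,
                      label=ref.label, description=ref.description)
    if ref.url:
        e.set("url", ref.url)


def _to_xml(seg: Segmentation) -> ET.Element:
    root = ET.Element("segmentation", schemaVersion=seg.schema_version,
                      name=seg.name)
    if seg.details:
        ET.SubElement(root, "details").text = seg.details
    if seg.software_list:
        sl = ET.SubElement(root, "softwareList")
        for sw in seg.software_list:
            ET.SubElement(sl, "software", name=sw.name, version=sw.version,
                          processingDetails=sw.processing_details)
    if seg.bounding_box is not None:
        bb = seg.bounding_box
        ET.SubElement(root, "boundingBox",
                      **{k: _f(v) for k, v in
                         zip(("xmin", "xmax", "ymin", "ymax", "zmin", "zmax"),
                             bb)})
    if seg.global_external_references:
        gl = ET.SubElement(root, "globalExternalReferences")
        for ref in seg.global_external_references:
            _xml_external_reference(gl, ref)
    tl = ET.SubElement(root, "transformList")
    for t in sorted(seg.transform_list, key=lambda t: t.id):
        e = ET.SubElement(tl, "transform", id=str(t.id))
        e.text = _floats(t.matrix)
    ll = ET.SubElement(root, "latticeList")
    for lat in sorted(seg.lattice_list, key=lambda l: l.id):
        e = ET.SubElement(ll, "lattice", id=str(lat.id), mode=lat.mode,
                          size=_ints(lat.size), origin=_ints(lat.origin_voxel))
        if lat.voxel_size is not None:
            e.set("voxelSize", _floats(lat.voxel_size))
        runs = ET.SubElement(e, "runs")
        runs.text = " ".join(f"{v} {l}" for v, l in lat.runs)
    sl = ET.SubElement(root, "segmentList")
    for s in sorted(seg.segments, key=lambda s: s.id):
        e = ET.SubElement(sl, "segment", id=str(s.id),
                          parentId=str(s.parent_id), name=s.name)
        if s.colour is not None:
            ET.SubElement(e, "colour", r=_f(s.colour.r), g=_f(s.colour.g),
                          b=_f(s.colour.b), a=_f(s.colour.a))
        ann = s.biological_annotation
        if ann is not None:
            ae = ET.SubElement(e, "biologicalAnnotation", name=ann.name,
                               description=ann.description,
                               numberOfInstances=str(ann.number_of_instances))
            for ref in ann.external_references:
                _xml_external_reference(ae, ref)
        if s.mesh_list:
            ml = ET.SubElement(e, "meshList")
            for m in s.mesh_list:
                me = ET.SubElement(ml, "mesh")
                if m.transform_id is not None:
                    me.set("transformId", str(m.transform_id))
                ET.SubElement(me, "vertices").text = _floats(m.vertices)
                if m.normals is not None:
                    ET.SubElement(me, "normals").text = _floats(m.normals)
                ET.SubElement(me, "triangles").text = _ints(m.triangles)
        if s.volume_ref is not None:
            vr = s.volume_ref
            ve = ET.SubElement(e, "volumeRef",
                               voxelValue=str(vr.voxel_value))
            if vr.lattice_id is not None:
                ve.set("latticeId", str(vr.lattice_id))
            if vr.external_path is not None:
                ve.set("externalPath", vr.external_path)
        if s.shape_primitive_list:
            pl = ET.SubElement(e, "shapePrimitiveList")
            for p in s.shape_primitive_list:
                pe = ET.SubElement(pl, "shape", kind=p.kind)
                if p.transform_id is not None:
                    pe.set("transformId", str(p.transform_id))
                pe.text = _floats(p.parameters)
        if s.contour_list:
            cl = ET.SubElement(e, "contourList")
            for c in s.contour_list:
                ce = ET.SubElement(cl, "contour",
                                   closed="true" if c.closed else "false")
                ce.text = _floats(c.points)
        if s.transform_ids:
            ET.SubElement(e, "transformIds").text = _ints(s.transform_ids)
    return root


def _req(elem, attr, ctx):
    val = elem.get(attr)
    if val is None:
        raise FormatError(f"{ctx}: missing required attribute {attr!r}")
    return val


def _parse_floats(text, ctx, per_row=None):
    vals = [float(x) for x in (text or "").split()]
    if per_row is not None:
        if len(vals) % per_row:
            raise FormatError(
                f"{ctx}: expected a multiple of {per_row} numbers, "
                f"got {len(vals)}")
        return np.asarray(vals, dtype=float).reshape(-1, per_row)
    return vals


def _parse_runs(text, ctx):
    vals = [int(x) for x in (text or "").split()]
    if len(vals) % 2:
        raise FormatError(f"{ctx}: run list must have an even number of "
                          f"integers, got {len(vals)}")
    return [(vals[i], vals[i + 1]) for i in range(0, len(vals), 2)]


def _warn_unknown(elem, known, ctx):
    for child in elem:
        if child.tag not in known:
            log.warning("%s: ignoring unknown element <%s>", ctx, child.tag)


def _xml_read_reference(e) -> ExternalReference:
    return ExternalReference(resource=_req(e, "resource", "externalReference"),
                             accession=_req(e, "accession", "externalReference"),
                             label=e.get("label", ""),
                             description=e.get("description", ""),
                             url=e.get("url"))


def _from_xml(root: ET.Element) -> Segmentation:
    if root.tag != "segmentation":
        raise FormatError(f"root element is <{root.tag}>, "
                          "expected <segmentation>")
    version = _req(root, "schemaVersion", "segmentation")
    _check_version(version)
    seg = Segmentation(name=root.get("name", ""), schema_version=version)
    known = {"details", "softwareList", "boundingBox",
             "globalExternalReferences", "transformList", "latticeList",
             "segmentList"}
    _warn_unknown(root, known, "segmentation")
    det = root.find("details")
    if det is not None:
        seg.details = det.text or ""
    sl = root.find("softwareList")
    if sl is not None:
        for e in sl.findall("software"):
            seg.software_list.append(SoftwareInfo(
                name=e.get("name", ""), version=e.get("version", ""),
                processing_details=e.get("processingDetails", "")))
    bb = root.find("boundingBox")
    if bb is not None:
        seg.bounding_box = tuple(
            float(_req(bb, k, "boundingBox"))
            for k in ("xmin", "xmax", "ymin", "ymax", "zmin", "zmax"))
    gl = root.find("globalExternalReferences")
    if gl is not None:
        seg.global_external_references = [
            _xml_read_reference(e) for e in gl.findall("externalReference")]
    tl = root.find("transformList")
    if tl is not None:
        for e in tl.findall("transform"):
            vals = _parse_floats(e.text, "transform")
            if len(vals) != 12:
                raise FormatError(
                    f"transform {e.get('id')}: expected 12 floats, "
                    f"got {len(vals)}")
            seg.transform_list.append(AffineTransform(
                id=int(_req(e, "id", "transform")),
                matrix=np.asarray(vals)))
    ll = root.find("latticeList")
    if ll is not None:
        for e in ll.findall("lattice"):
            ctx = f"lattice {e.get('id')}"
            size = tuple(int(x) for x in _req(e, "size", ctx).split())
            origin = tuple(int(x) for x in e.get("origin", "0 0 0").split())
            vs = e.get("voxelSize")
            runs_e = e.find("runs")
            if runs_e is None:
                raise FormatError(f"{ctx}: missing <runs>")
            seg.lattice_list.append(Lattice(
                id=int(_req(e, "id", ctx)), size=size,
                mode=e.get("mode", "u8"), origin_voxel=origin,
                voxel_size=None if vs is None
                else tuple(float(x) for x in vs.split()),
                runs=_parse_runs(runs_e.text, ctx)))
    segl = root.find("segmentList")
    if segl is not None:
        seg_known = {"colour", "biologicalAnnotation", "meshList",
                     "volumeRef", "shapePrimitiveList", "contourList",
                     "transformIds"}
        for e in segl.findall("segment"):
            sid = int(_req(e, "id", "segment"))
            ctx = f"segment {sid}"
            _warn_unknown(e, seg_known, ctx)
            s = Segment(id=sid, parent_id=int(e.get("parentId", "0")),
                        name=e.get("name", ""))
            ce = e.find("colour")
            if ce is not None:
                s.colour = Colour(*(float(_req(ce, k, ctx))
                                    for k in "rgb"),
                                  a=float(ce.get("a", "1")))
            ae = e.find("biologicalAnnotation")
            if ae is not None:
                s.biological_annotation = BiologicalAnnotation(
                    name=ae.get("name", ""),
                    description=ae.get("description", ""),
                    number_of_instances=int(ae.get("numberOfInstances", "1")),
                    external_references=[
                        _xml_read_reference(r)
                        for r in ae.findall("externalReference")])
            ml = e.find("meshList")
            if ml is not None:
                for me in ml.findall("mesh"):
                    ve = me.find("vertices")
                    te = me.find("triangles")
                    if ve is None or te is None:
                        raise FormatError(
                            f"{ctx}: mesh needs <vertices> and <triangles>")
                    ne = me.find("normals")
                    tid = me.get("transformId")
                    s.mesh_list.append(Mesh(
                        vertices=_parse_floats(ve.text, ctx, per_row=3),
                        triangles=np.asarray(
                            [int(x) for x in (te.text or "").split()],
                            dtype=np.int64).reshape(-1, 3),
                        normals=None if ne is None
                        else _parse_floats(ne.text, ctx, per_row=3),
                        transform_id=None if tid is None else int(tid)))
            vre = e.find("volumeRef")
            if vre is not None:
                lid = vre.get("latticeId")
                s.volume_ref = VolumeRef(
                    lattice_id=None if lid is None else int(lid),
                    voxel_value=int(vre.get("voxelValue", "1")),
                    external_path=vre.get("externalPath"))
            pl = e.find("shapePrimitiveList")
            if pl is not None:
                for pe in pl.findall("shape"):
                    tid = pe.get("transformId")
                    s.shape_primitive_list.append(ShapePrimitive(
                        kind=_req(pe, "kind", ctx),
                        parameters=tuple(_parse_floats(pe.text, ctx)),
                        transform_id=None if tid is None else int(tid)))
            cl = e.find("contourList")
            if cl is not None:
                for cte in cl.findall("contour"):
                    s.contour_list.append(Contour(
                        points=_parse_floats(cte.text, ctx, per_row=3),
                        closed=cte.get("closed", "true") == "true"))
            tie = e.find("transformIds")
            if tie is not None:
                s.transform_ids = [int(x) for x in (tie.text or "").split()]
            seg.segments.append(s)
    return seg


# ---------------------------------------------------------------------------
# JSON (mirrors the XML element tree, attributes folded into keys)
# ---------------------------------------------------------------------------

def _json_reference(ref: ExternalReference) -> dict:
    d = {"resource": ref.resource, "accession": ref.accession,
         "label": ref.label, "description": ref.description}
    if ref.url:
        d["url"] = ref.url
    return d


def _to_json_obj(seg: Segmentation) -> dict:
    d: dict = {"schemaVersion": seg.schema_version, "name": seg.name}
    if seg.details:
        d["details"] = seg.details
    if seg.software_list:
        d["softwareList"] = [
            {"name": sw.name, "version": sw.version,
             "processingDetails": sw.processing_details}
            for sw in seg.software_list]
    if seg.bounding_box is not None:
        d["boundingBox"] = dict(zip(
            ("xmin", "xmax", "ymin", "ymax", "zmin", "zmax"),
            (round9(v) for v in seg.bounding_box)))
    if seg.global_external_references:
        d["globalExternalReferences"] = [
            _json_reference(r) for r in seg.global_external_references]
    d["transformList"] = [
        {"id": t.id, "matrix": [round9(x) for x in t.matrix.ravel()]}
        for t in sorted(seg.transform_list, key=lambda t: t.id)]
    d["latticeList"] = []
    for lat in sorted(seg.lattice_list, key=lambda l: l.id):
        le = {"id": lat.id, "mode": lat.mode, "size": list(lat.size),
              "origin": list(lat.origin_voxel),
              "runs": [x for run in lat.runs for x in run]}
        if lat.voxel_size is not None:
            le["voxelSize"] = [round9(v) for v in lat.voxel_size]
        d["latticeList"].append(le)
    d["segmentList"] = []
    for s in sorted(seg.segments, key=lambda s: s.id):
        se: dict = {"id": s.id, "parentId": s.parent_id, "name": s.name}
        if s.colour is not None:
            se["colour"] = {k: round9(v) for k, v in
                            zip("rgba", s.colour.as_tuple())}
        ann = s.biological_annotation
        if ann is not None:
            se["biologicalAnnotation"] = {
                "name": ann.name, "description": ann.description,
                "numberOfInstances": ann.number_of_instances,
                "externalReferences": [
                    _json_reference(r) for r in ann.external_references]}
        if s.mesh_list:
            se["meshList"] = []
            for m in s.mesh_list:
                me = {"vertices": [round9(x) for x in m.vertices.ravel()],
                      "triangles": [int(x) for x in m.triangles.ravel()]}
                if m.normals is not None:
                    me["normals"] = [round9(x) for x in m.normals.ravel()]
                if m.transform_id is not None:
                    me["transformId"] = m.transform_id
                se["meshList"].append(me)
        if s.volume_ref is not None:
            vr = s.volume_ref
            ve: dict = {"voxelValue": vr.voxel_value}
            if vr.lattice_id is not None:
                ve["latticeId"] = vr.lattice_id
            if vr.external_path is not None:
                ve["externalPath"] = vr.external_path
            se["volumeRef"] = ve
        if s.shape_primitive_list:
            se["shapePrimitiveList"] = []
            for p in s.shape_primitive_list:
                pe = {"kind": p.kind,
                      "parameters": [round9(x) for x in p.parameters]}
                if p.transform_id is not None:
                    pe["transformId"] = p.transform_id
                se["shapePrimitiveList"].append(pe)
        if s.contour_list:
            se["contourList"] = [
                {"points": [round9(x) for x in c.points.ravel()],
                 "closed": bool(c.closed)} for c in s.contour_list]
        if s.transform_ids:
            se["transformIds"] = [int(t) for t in s.transform_ids]
        d["segmentList"].append(se)
    return d


def _ref_from_json(d: dict) -> ExternalReference:
    return ExternalReference(resource=d["resource"], accession=d["accession"],
                             label=d.get("label", ""),
                             description=d.get("description", ""),
                             url=d.get("url"))


_JSON_KNOWN = {"schemaVersion", "name", "details", "softwareList",
               "boundingBox", "globalExternalReferences", "transformList",
               "latticeList", "segmentList"}
_JSON_SEG_KNOWN = {"id", "parentId", "name", "colour", "biologicalAnnotation",
                   "meshList", "volumeRef", "shapePrimitiveList",
                   "contourList", "transformIds"}


def _from_json_obj(d: dict) -> Segmentation:
    try:
        version = d["schemaVersion"]
    except KeyError:
        raise FormatError("JSON document lacks schemaVersion")
    _check_version(version)
    for k in d:
        if k not in _JSON_KNOWN:
            log.warning("segmentation: ignoring unknown key %r", k)
    seg = Segmentation(name=d.get("name", ""), schema_version=version)
    seg.details = d.get("details", "")
    for sw in d.get("softwareList", []):
        seg.software_list.append(SoftwareInfo(
            name=sw.get("name", ""), version=sw.get("version", ""),
            processing_details=sw.get("processingDetails", "")))
    if "boundingBox" in d:
        bb = d["boundingBox"]
        seg.bounding_box = tuple(bb[k] for k in
                                 ("xmin", "xmax", "ymin", "ymax",
                                  "zmin", "zmax"))
    seg.global_external_references = [
        _ref_from_json(r) for r in d.get("globalExternalReferences", [])]
    for t in d.get("transformList", []):
        if len(t["matrix"]) != 12:
            raise FormatError(f"transform {t.get('id')}: expected 12 floats")
        seg.transform_list.append(
            AffineTransform(id=int(t["id"]), matrix=np.asarray(t["matrix"])))
    for le in d.get("latticeList", []):
        runs = le.get("runs", [])
        if len(runs) % 2:
            raise FormatError(f"lattice {le.get('id')}: odd run list")
        seg.lattice_list.append(Lattice(
            id=int(le["id"]), size=tuple(le["size"]),
            mode=le.get("mode", "u8"),
            origin_voxel=tuple(le.get("origin", (0, 0, 0))),
            voxel_size=tuple(le["voxelSize"]) if "voxelSize" in le else None,
            runs=[(runs[i], runs[i + 1]) for i in range(0, len(runs), 2)]))
    for se in d.get("segmentList", []):
        sid = int(se["id"])
        for k in se:
            if k not in _JSON_SEG_KNOWN:
                log.warning("segment %d: ignoring unknown key %r", sid, k)
        s = Segment(id=sid, parent_id=int(se.get("parentId", 0)),
                    name=se.get("name", ""))
        if "colour" in se:
            c = se["colour"]
            s.colour = Colour(c["r"], c["g"], c["b"], c.get("a", 1.0))
        if "biologicalAnnotation" in se:
            a = se["biologicalAnnotation"]
            s.biological_annotation = BiologicalAnnotation(
                name=a.get("name", ""), description=a.get("description", ""),
                number_of_instances=int(a.get("numberOfInstances", 1)),
                external_references=[
                    _ref_from_json(r)
                    for r in a.get("externalReferences", [])])
        for me in se.get("meshList", []):
            s.mesh_list.append(Mesh(
                vertices=np.asarray(me["vertices"]).reshape(-1, 3),
                triangles=np.asarray(me["triangles"],
                                     dtype=np.int64).reshape(-1, 3),
                normals=(np.asarray(me["normals"]).reshape(-1, 3)
                         if "normals" in me else None),
                transform_id=me.get("transformId")))
        if "volumeRef" in se:
            ve = se["volumeRef"]
            s.volume_ref = VolumeRef(
                lattice_id=ve.get("latticeId"),
                voxel_value=int(ve.get("voxelValue", 1)),
                external_path=ve.get("externalPath"))
        for pe in se.get("shapePrimitiveList", []):
            s.shape_primitive_list.append(ShapePrimitive(
                kind=pe["kind"], parameters=tuple(pe["parameters"]),
                transform_id=pe.get("transformId")))
        for ce in se.get("contourList", []):
            s.contour_list.append(Contour(
                points=np.asarray(ce["points"]).reshape(-1, 3),
                closed=bool(ce.get("closed", True))))
        s.transform_ids = [int(t) for t in se.get("transformIds", [])]
        seg.segments.append(s)
    return seg


# ---------------------------------------------------------------------------
# HDF5
# ---------------------------------------------------------------------------

_STR = h5py.string_dtype(encoding="utf-8")


def _h5_write_refs(group, refs):
    for k, ref in enumerate(refs):
        g = group.create_group(f"ref_{k}")
        g.attrs["resource"] = ref.resource
        g.attrs["accession"] = ref.accession
        g.attrs["label"] = ref.label
        g.attrs["description"] = ref.description
        if ref.url:
            g.attrs["url"] = ref.url


def _h5_read_refs(group):
    out = []
    for k in sorted(group, key=lambda n: int(n.split("_")[1])):
        g = group[k]
        out.append(ExternalReference(
            resource=g.attrs["resource"], accession=g.attrs["accession"],
            label=g.attrs.get("label", ""),
            description=g.attrs.get("description", ""),
            url=g.attrs.get("url")))
    return out


def _to_hdf5(seg: Segmentation, f: h5py.File):
    meta = f.create_group("metadata")
    meta.attrs["schema_version"] = seg.schema_version
    meta.attrs["name"] = seg.name
    meta.attrs["details"] = seg.details
    if seg.bounding_box is not None:
        meta.create_dataset("bounding_box",
                            data=np.asarray(seg.bounding_box, dtype=float))
    if seg.software_list:
        swg = meta.create_group("software")
        for k, sw in enumerate(seg.software_list):
            g = swg.create_group(f"software_{k}")
            g.attrs["name"] = sw.name
            g.attrs["version"] = sw.version
            g.attrs["processing_details"] = sw.processing_details
    if seg.global_external_references:
        _h5_write_refs(meta.create_group("external_references"),
                       seg.global_external_references)
    tg = f.create_group("transforms")
    ts = sorted(seg.transform_list, key=lambda t: t.id)
    tg.create_dataset("ids", data=np.asarray([t.id for t in ts],
                                             dtype=np.int64))
    tg.create_dataset("matrices",
                      data=np.asarray([t.matrix.ravel() for t in ts],
                                      dtype=float).reshape(len(ts), 12))
    lg = f.create_group("lattices")
    for lat in seg.lattice_list:
        g = lg.create_group(str(lat.id))
        g.attrs["mode"] = lat.mode
        g.create_dataset("size", data=np.asarray(lat.size, dtype=np.int64))
        g.create_dataset("origin",
                         data=np.asarray(lat.origin_voxel, dtype=np.int64))
        if lat.voxel_size is not None:
            g.create_dataset("voxel_size",
                             data=np.asarray(lat.voxel_size, dtype=float))
        run_arr = np.asarray(lat.runs, dtype=np.int64).reshape(-1, 2)
        if run_arr.size and run_arr.max() < 2**31:
            run_arr = run_arr.astype(np.int32)
        g.create_dataset("runs", data=run_arr, compression="gzip",
                         compression_opts=9, shuffle=True)
    sg = f.create_group("segments")
    for s in seg.segments:
        g = sg.create_group(str(s.id))
        g.attrs["parent_id"] = s.parent_id
        g.attrs["name"] = s.name
        if s.colour is not None:
            g.create_dataset("colour",
                             data=np.asarray(s.colour.as_tuple(), dtype=float))
        ann = s.biological_annotation
        if ann is not None:
            ag = g.create_group("annotation")
            ag.attrs["name"] = ann.name
            ag.attrs["description"] = ann.description
            ag.attrs["number_of_instances"] = ann.number_of_instances
            _h5_write_refs(ag.create_group("external_references"),
                           ann.external_references)
        for k, m in enumerate(s.mesh_list):
            mg = g.create_group(f"mesh_{k}")
            mg.create_dataset("vertices", data=m.vertices)
            mg.create_dataset("triangles", data=m.triangles)
            if m.normals is not None:
                mg.create_dataset("normals", data=m.normals)
            if m.transform_id is not None:
                mg.attrs["transform_id"] = m.transform_id
        if s.volume_ref is not None:
            vg = g.create_group("volume_ref")
            vg.attrs["voxel_value"] = s.volume_ref.voxel_value
            if s.volume_ref.lattice_id is not None:
                vg.attrs["lattice_id"] = s.volume_ref.lattice_id
            if s.volume_ref.external_path is not None:
                vg.attrs["external_path"] = s.volume_ref.external_path
        for k, p in enumerate(s.shape_primitive_list):
            pg = g.create_group(f"shape_{k}")
            pg.attrs["kind"] = p.kind
            if p.transform_id is not None:
                pg.attrs["transform_id"] = p.transform_id
            pg.create_dataset("parameters",
                              data=np.asarray(p.parameters, dtype=float))
        for k, c in enumerate(s.contour_list):
            cg = g.create_group(f"contour_{k}")
            cg.attrs["closed"] = bool(c.closed)
            cg.create_dataset("points", data=c.points)
        if s.transform_ids:
            g.create_dataset("transform_ids",
                             data=np.asarray(s.transform_ids, dtype=np.int64))


def _from_hdf5(f: h5py.File) -> Segmentation:
    if "metadata" not in f:
        raise FormatError("HDF5 file lacks /metadata group")
    meta = f["metadata"]
    version = str(meta.attrs.get("schema_version", ""))
    _check_version(version)
    seg = Segmentation(name=str(meta.attrs.get("name", "")),
                       schema_version=version,
                       details=str(meta.attrs.get("details", "")))
    if "bounding_box" in meta:
        seg.bounding_box = tuple(float(x) for x in meta["bounding_box"][()])
    if "software" in meta:
        swg = meta["software"]
        for k in sorted(swg, key=lambda n: int(n.split("_")[1])):
            g = swg[k]
            seg.software_list.append(SoftwareInfo(
                name=str(g.attrs.get("name", "")),
                version=str(g.attrs.get("version", "")),
                processing_details=str(g.attrs.get("processing_details", ""))))
    if "external_references" in meta:
        seg.global_external_references = _h5_read_refs(
            meta["external_references"])
    if "transforms" in f:
        tg = f["transforms"]
        ids = tg["ids"][()]
        mats = tg["matrices"][()]
        for i, mat in zip(ids, mats):
            seg.transform_list.append(AffineTransform(id=int(i), matrix=mat))
    if "lattices" in f:
        for name in sorted(f["lattices"], key=int):
            g = f["lattices"][name]
            seg.lattice_list.append(Lattice(
                id=int(name), size=tuple(g["size"][()]),
                mode=str(g.attrs["mode"]),
                origin_voxel=tuple(g["origin"][()]),
                voxel_size=(tuple(g["voxel_size"][()])
                            if "voxel_size" in g else None),
                runs=[tuple(row) for row in g["runs"][()]]))
    if "segments" in f:
        for name in sorted(f["segments"], key=int):
            g = f["segments"][name]
            s = Segment(id=int(name),
                        parent_id=int(g.attrs.get("parent_id", 0)),
                        name=str(g.attrs.get("name", "")))
            if "colour" in g:
                s.colour = Colour(*(float(x) for x in g["colour"][()]))
            if "annotation" in g:
                ag = g["annotation"]
                s.biological_annotation = BiologicalAnnotation(
                    name=str(ag.attrs.get("name", "")),
                    description=str(ag.attrs.get("description", "")),
                    number_of_instances=int(
                        ag.attrs.get("number_of_instances", 1)),
                    external_references=_h5_read_refs(
                        ag["external_references"])
                    if "external_references" in ag else [])
            for key in sorted((k for k in g if k.startswith("mesh_")),
                              key=lambda n: int(n.split("_")[1])):
                mg = g[key]
                tid = mg.attrs.get("transform_id")
                s.mesh_list.append(Mesh(
                    vertices=mg["vertices"][()],
                    triangles=mg["triangles"][()],
                    normals=mg["normals"][()] if "normals" in mg else None,
                    transform_id=None if tid is None else int(tid)))
            if "volume_ref" in g:
                vg = g["volume_ref"]
                lid = vg.attrs.get("lattice_id")
                s.volume_ref = VolumeRef(
                    lattice_id=None if lid is None else int(lid),
                    voxel_value=int(vg.attrs.get("voxel_value", 1)),
                    external_path=(str(vg.attrs["external_path"])
                                   if "external_path" in vg.attrs else None))
            for key in sorted((k for k in g if k.startswith("shape_")),
                              key=lambda n: int(n.split("_")[1])):
                pg = g[key]
                tid = pg.attrs.get("transform_id")
                s.shape_primitive_list.append(ShapePrimitive(
                    kind=str(pg.attrs["kind"]),
                    parameters=tuple(pg["parameters"][()]),
                    transform_id=None if tid is None else int(tid)))
            for key in sorted((k for k in g if k.startswith("contour_")),
                              key=lambda n: int(n.split("_")[1])):
                cg = g[key]
                s.contour_list.append(Contour(
                    points=cg["points"][()],
                    closed=bool(cg.attrs.get("closed", True))))
            if "transform_ids" in g:
                s.transform_ids = [int(t) for t in g["transform_ids"][()]]
            seg.segments.append(s)
    return seg


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def write(seg: Segmentation, path, format: str | None = None) -> None:
    """Write ``seg`` to ``path``; the encoding is taken from the extension
    unless ``format`` is given. Refuses to write an invalid segmentation."""
    fmt = format or infer_format(path)
    if fmt not in FORMATS:
        raise FormatError(f"unknown format {fmt!r}")
    violations = validate(seg)
    if violations:
        raise ValidationError(
            "refusing to write invalid segmentation: "
            + "; ".join(v.message for v in violations), violations)
    if fmt == "xml":
        root = _to_xml(seg)
        ET.indent(root)
        data = ET.tostring(root, encoding="unicode", xml_declaration=True)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(data)
            fh.write("\n")
    elif fmt == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(_to_json_obj(seg), fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        # libver="latest": compact object headers, keeps containers with a
        # dominant bulk payload smaller than their text encodings
        with h5py.File(path, "w", libver="latest") as fh:
            _to_hdf5(seg, fh)


def read(path, format: str | None = None) -> Segmentation:
    """Read a segmentation file; the result always validates."""
    if not os.path.exists(path):
        raise FormatError(f"no such file: {path}")
    fmt = format or infer_format(path)
    if fmt == "xml":
        try:
            root = ET.parse(path).getroot()
        except ET.ParseError as exc:
            raise FormatError(f"malformed XML in {path}: {exc}") from exc
        seg = _from_xml(root)
    elif fmt == "json":
        try:
            with open(path, "r", encoding="utf-8") as fh:
                obj = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(
                f"malformed JSON in {path}: line {exc.lineno} col "
                f"{exc.colno}: {exc.msg}") from exc
        seg = _from_json_obj(obj)
    elif fmt == "hdf5":
        try:
            with h5py.File(path, "r") as fh:
                seg = _from_hdf5(fh)
        except OSError as exc:
            raise FormatError(f"unreadable HDF5 file {path}: {exc}") from exc
    else:
        raise FormatError(f"unknown format {fmt!r}")
    violations = validate(seg)
    if violations:
        raise FormatError(
            f"{path} parsed but the segmentation is invalid: "
            + "; ".join(v.message for v in violations))
    return seg


def convert_file(in_path, out_path) -> None:
    """Convert between encodings (same-format conversion = normalisation);
    refuses in-place conversion."""
    if os.path.abspath(str(in_path)) == os.path.abspath(str(out_path)):
        raise FormatError("refusing in-place conversion")
    infer_format(in_path)
    infer_format(out_path)
    write(read(in_path), out_path)
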