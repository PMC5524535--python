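# The segff interchange dialect

One segmentation document, three encodings. The element tree below is the
normative description; XML is the reference text rendering, JSON mirrors it
1:1 with attributes folded into keys, and HDF5 stores the same content as
groups/datasets. Extensions select the encoding: `.sff`/`.xml`, `.json`,
`.h5`/`.hff`/`.hdf5`.

## Conventions (fixed once, everywhere)

* **Transforms** are 3×4 row-major `[R|t]` matrices. Column-vector
  convention: `p' = R·p + t`. Direction is **source → target** (subvolume
  coordinates into tomogram coordinates). Composition is left-composition:
  `compose(A, B)` applies B first. A segment's `transformIds` list one
  transform per placed instance.
* **Lattices** flatten x fastest, then y, then z:
  `flat = ix + nx·(iy + ny·iz)` (MRC section order). Runs are maximally
  merged `(value, length)` pairs covering the whole lattice; in XML/JSON
  they serialise as the flat integer list `v1 l1 v2 l2 …`, in HDF5 as an
  N×2 integer dataset.
* **Voxel (ix,iy,iz)** has its center at coordinate `(ix,iy,iz)`, 0-based.
  Physical units (Å) enter only through lattice `voxelSize`.
* **Floats** in text encodings use shortest round-trip decimal capped at 9
  significant digits (`%.9g`); interchange equality (`canonical_form`)
  rounds identically, so all six ordered conversions among the encodings
  preserve canonical equality.
* **Colours** are RGBA floats in [0,1]; a missing colour canonicalises to
  opaque mid-grey `(0.5, 0.5, 0.5, 1)`.
* **Bounding box** units are Å (the format does not inherit them from any
  lattice; stated here because common practice varies).
* Unknown elements/keys are **dropped with a logged warning** on read.
  A `schemaVersion` newer than the library's is a hard version error.

## Element tree (XML names; JSON uses identical keys)

```
<segmentation schemaVersion name>
  <details>                         free text
  <softwareList>/<software name version processingDetails>
  <boundingBox xmin xmax ymin ymax zmin zmax>
  <globalExternalReferences>/<externalReference resource accession label
                                                description url?>
  <transformList>/<transform id>   text: 12 floats, row-major [R|t]
  <latticeList>/<lattice id mode size origin voxelSize?>
      <runs>                       text: v1 l1 v2 l2 …
  <segmentList>/<segment id parentId name>
      <colour r g b a>
      <biologicalAnnotation name description numberOfInstances>
          <externalReference …>    at most ONE biologicalAnnotation
      <meshList>/<mesh transformId?>
          <vertices> <normals?> <triangles>
      <volumeRef latticeId? voxelValue externalPath?>
      <shapePrimitiveList>/<shape kind transformId?>   text: parameters
      <contourList>/<contour closed>   text: x y z …  (planar in z)
      <transformIds>               text: ids, one per placed instance
```

`parentId` 0 means child of the implicit root; the parent graph must be a
forest. Segment ids are unique positive integers. `mode` is one of
`u1 u8 u16 u32` (`u1` is logical binary, stored like `u8`).

Shape parameters by kind: `sphere cx cy cz r`; `ellipsoid cx cy cz ax ay az`
(semi-axes); `cuboid cx cy cz ex ey ez` (full edges);
`cylinder cx cy cz r h` (axis along z). All implicit inequalities are
closed (boundary voxels included).

`volumeRef` selects the segment's voxels: `latticeId` + `voxelValue` for a
shared in-file lattice, or `externalPath` (+ implicit value 1) for an
external binary MRC mask. Whole-file external masks only; sub-file
addressing is an extension point.

## HDF5 layout

```
/metadata            attrs: schema_version, name, details
    bounding_box     (6,) float dataset, optional
    software/software_<k>          attrs: name, version, processing_details
    external_references/ref_<k>    attrs: resource, accession, label, …
/transforms          ids (T,) int; matrices (T,12) float
/lattices/<id>       attrs: mode; size (3,), origin (3,), voxel_size? (3,)
                     runs (N,2) int, gzip+shuffle
/segments/<id>       attrs: parent_id, name
    colour (4,)  annotation/…  mesh_<k>/{vertices,triangles,normals?}
    volume_ref   shape_<k>/{parameters}  contour_<k>/{points}
    transform_ids (M,)
```

Files are written with `libver="latest"`; byte identity is not guaranteed
for HDF5 (content equality is), whereas XML and JSON writes are
byte-deterministic.

A JSON-Schema description of the JSON rendering ships as
`docs/segmentation.schema.json`.
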