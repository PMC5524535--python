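# segff

**Hierarchical segmentation interchange for 3D electron microscopy.**

Segmentation — decomposing a 3D reconstruction into regions associated with
defined biological objects — is produced by many tools (watershed-based
hierarchical segmenters, manual contouring, template matching) in many
mutually unreadable formats, usually without machine-readable biological
annotation. `segff` implements one segmentation data model that covers the
common cases and makes it portable and annotatable:

* a **hierarchical segment forest**, each segment carrying any combination
  of surface meshes, run-length-encoded voxel-mask references (in-file or
  external), geometric shape primitives and planar slice contours, an RGBA
  colour, and at most one structured biological annotation (ontology terms
  and database accessions, e.g. GO or UniProt);
* **three interchangeable encodings** — XML (`.sff`), JSON, HDF5 — with a
  canonical-equality contract guaranteeing lossless conversion among them;
* **affine transforms** (3×4 `[R|t]`, source → target, column vectors) with
  per-segment transform lists, so a sub-tomogram average can be placed back
  at every position and orientation it occupies in a tomogram, and a
  compositor that renders those placements into a volume;
* **converters** from the lingua-franca carriers: MRC2014 label masks,
  ASCII STL and Wavefront OBJ meshes; plus mask externalisation
  (per-segment MRC files + manifest) to separate metadata from bulk voxels;
* an **offline annotation workflow**: OBO ontology loading, ranked term
  search, preset term lists for common assemblies, single-annotation
  editing — as a library and a CLI;
* a **synthetic generator** (Gaussian-blob densities, steepest-ascent
  watershed, saliency-based hierarchical grouping) so the whole machinery
  is exercised without downloading data.

It is aimed at structural biologists and tool developers who need to move
segmentations between packages, attach searchable biology to them, or
archive them alongside maps.

## Worked example

```sh
$ segff demo --seed 0 demo.h5
wrote demo.h5 (16 segments)
$ segff validate demo.h5
0 violations
$ segff convert demo.h5 demo.sff      # HDF5 -> XML, losslessly
wrote demo.sff
$ segff summary demo.sff
segmentation: demo segmentation (seed 0) (schema 0.1.0)
transforms: 3  lattices: 1  segments: 16
1: level2_group1 (group)
  2: level1_group1 (group)
    4: level0_group1 (group)
      8: region_1 (volume)
      ...
13: membrane mesh (mesh x1) [mitochondrion]
14: sphere primitive (shapes x1)
15: slice contour (contours x1)
16: placed sub-tomogram average (shapes x1) [mitochondrial ribosome]
$ segff annotate demo.sff --segment 14 --term GO:0005840 --label ribosome
annotated segment 14 with GO:0005840
$ segff search-terms mitochond
GO:0005739	2	mitochondrion
GO:0005761	2	mitochondrial ribosome
...
```

The summary shows the three-level hierarchy built from the synthetic
density's watershed regions (grouping nodes have no geometry of their own;
leaves reference the shared label lattice), the four representation kinds,
and bracketed annotation labels. The ranked search scores are tier values
(4 = exact name … 1 = substring; here 2 = name prefix).

Placing a subvolume back into a tomogram-sized grid:

```sh
$ segff place --sub avg.mrc --transforms spikes.tsv --size 200,200,100 \
      composite.mrc --mode max --interp trilinear
```

where `spikes.tsv` holds one 12-float row-major `[R|t]` transform per row.

From Python, the same model is a plain object tree:

```python
import segff
seg = segff.synthetic.demo_fixture(0)
segff.write(seg, "demo.json")
assert segff.validate(seg) == []
```

Format conventions (flattening order, transform direction, voxel centers,
float precision) are documented in `docs/format.md`; the science and the
algorithmic choices in `docs/methods.md`.

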