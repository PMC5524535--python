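# Methods

This note documents the models, algorithms and numerical conventions behind
`segff`, and the design decisions that were genuinely open.

## The data model

A segmentation decomposes a 3D reconstruction (tomogram, EM map, 3D-SEM
stack) into regions associated with defined objects. The model is a forest
of segments over an implicit root (`parent_id == 0`), so hierarchical
segmenters — which iteratively group an initial watershed partition — map
onto it directly, while flat segmentations are simply forests of depth 1.

Design decisions worth recording:

* **Multiple representations per segment.** A segment may simultaneously
  carry meshes, a voxel-mask reference, shape primitives and slice
  contours. Forcing one canonical representation (e.g. meshing every
  sphere) would inflate storage and lose precision, so none is enforced.
* **Representation-less segments are grouping nodes.** Internal nodes of a
  hierarchy usually carry no geometry of their own. Validation therefore
  accepts any segment without representations as a grouping node — also
  immediately after `add_segment`, before geometry is attached. The cost is
  that a forgotten representation is not flagged; `summary` renders such
  segments as `(group)` to keep them visible.
* **One annotation per segment.** Alternative/weighted annotations,
  certainty scores and logical combinations are deliberately out of scope;
  an annotation may still carry several external references (one biological
  identity, many identifiers).
* **RGBA colours** in [0,1]. Alpha is retained (defaulting to 1) so imports
  from tools that carry opacity are lossless; only RGB is semantically
  required. A missing colour canonicalises to opaque mid-grey.
* **Ids** are assigned smallest-unused and never reused, so repeated
  builds produce identical files.
* **Interchange equality** is defined by `canonical_form`: entities sorted
  by id, defaults materialised, floats rounded to 9 significant digits.
  The rounding matches the text encodings' `%.9g` float rendering, which is
  what makes XML (decimal) vs HDF5 (binary) round trips exactly testable.

## Run-length lattice codec

Label lattices flatten x-fastest (`flat = ix + nx·(iy + ny·iz)`, the MRC
section order, so masks convert to and from MRC volumes without
reindexing) into maximally merged `(value, length)` runs covering the whole
lattice. Whole-lattice runs (rather than sparse foreground spans) let one
codec serve both binary per-segment masks and shared multi-label lattices;
a segment selects its voxels as `(lattice_id, voxel_value)`. Bit-depth
modes are `u1/u8/u16/u32`; `u1` is a logical binary mode validated as
{0,1} and stored like `u8`. General-purpose compression is left to the
container (the HDF5 encoding gzips run datasets); the codec itself stays
exact and simple.

## Transform algebra and placement

Transforms are 3×4 `[R|t]` matrices, column-vector convention,
source → target, left-composition. These conventions are arbitrary but must
be fixed for interchange to work; they are stated prominently in
`docs/format.md`. Transforms act in voxel units of the target lattice —
placement is lattice resampling, so keeping the math unit-free avoids a
second unit system; physical units enter only through lattice `voxel_size`.

`place_subvolumes` composites a subvolume (e.g. a sub-tomogram average)
into a target grid through each transform by **pull resampling**: every
target voxel center is inverse-mapped and the subvolume interpolated there
(nearest or trilinear via `scipy.ndimage.map_coordinates`, zero outside).
Forward splatting would leave holes under rotation. Contributions combine
by `max` (overlay, the default — appropriate when instances should not
accumulate) or `sum` (accumulation); both are exposed because there is no
single right answer for visual compositing versus quantitative density.

## Rasterization and boundary meshes

Voxel `(ix,iy,iz)` has its center at `(ix,iy,iz)`, 0-based. Primitive
inequalities are closed (≤), so rasterized voxel counts are deterministic
integers an enumeration oracle can reproduce exactly (e.g. a radius-3
sphere centered in a 9³ grid covers exactly 123 voxel centers). Contours
are filled per z-slice by an even–odd crossing test on voxel centers,
boundary-inclusive (a center on a contour edge counts as covered by that
polygon); open contours contribute nothing and warn.

`mask_to_boundary_mesh` emits one unit quad (two triangles) per 6-connected
exposed face with outward winding. The result is watertight by
construction; for any simply connected, pinch-free voxel blob the Euler
characteristic V − E + F is 2, which the tests verify on randomly grown
blobs constrained to stay manifold (each added voxel face-touches exactly
one existing voxel and corner-touches none).

## Synthetic densities, watershed, hierarchy

`make_density` emulates a map as a sum of isotropic Gaussian bumps:
centers uniform with a minimum-separation rejection loop (one quarter of
the smallest dimension — separated enough that each bump contributes its
own peak, as distinct macromolecular densities would), widths
σ ~ U(1.5, 2.5) voxels, amplitudes ~ U(0.8, 1.2). It deliberately omits
tomographic artefacts (missing wedge, CTF, noise); passing tests
demonstrate the interchange machinery, not segmentation robustness on
experimental data.

`watershed` is the steepest-ascent (hill-climbing) formulation: each voxel
above threshold follows its best 26-neighbour uphill to a local maximum and
takes that peak's label. This formulation is per-voxel checkable by an
independent brute-force oracle, unlike immersion/priority-flood variants
whose plateau handling is implementation-defined. Ties break toward the
lowest flattened index; labels are numbered by descending peak value.
Ascent uses the 26-neighbourhood, region adjacency the 6-neighbourhood —
standard practice.

`build_hierarchy` agglomerates watershed regions level by level to the
targets in `HierarchySpec` (strictly decreasing, e.g. `(4, 2, 1)`). The
merge criterion is boundary saliency
`min(peak_a, peak_b) − saddle(a, b)`, with the saddle computed as the
maximum over 6-adjacent cross-boundary voxel pairs of the smaller of the
two densities — the classic dip height between catchments. The **least
salient** boundary merges first (a shallow dip separates near-identical
regions); ties break toward the lowest region label, making the hierarchy
fully deterministic. If remaining clusters share no boundary, the nearest
centroids merge with a warning. Each level's groups become grouping-node
segments; leaves are the watershed regions referencing one shared label
lattice.

## Annotation backend

Entirely offline: a hand-rolled OBO 1.2 subset reader (id, name,
namespace, quoted synonyms, `is_a`, obsolete-skip) with line-numbered
errors, a 12-term GO cellular-component slice packaged for tests and demos,
and preset CSV term lists (`category,term_id,resource,label`) for
frequently studied assemblies (ribosome, proteasome, chaperonin). Search
ranking is tiered — exact name > exact synonym > name prefix > substring —
with shorter names first and the term id as final tiebreak; the scheme is
this package's own (any fixed, documented, deterministic ranking serves
interchange testing). Live lookup services (OLS-style) would slot in
behind the same `TermStore` interface.

Who annotates (depositor vs curator) and at which hierarchy level is a
policy question the library does not decide: `attach_annotation` and the
CLI accept any segment at any level.

## Problem sizes and determinism

Everything is desk-scale by design: demo fixtures use 20³ volumes with
5 blobs, codec properties use lattices up to 32³, oracle comparisons run
at ≤ 10³ where the brute-force oracle is cubic. All randomness flows
through `numpy.random.default_rng` seeds; fixtures, hierarchies and files
are bit-deterministic per seed (XML/JSON byte-identical across repeat
writes; HDF5 content-equal).

## Known limitations

* No native readers for Amira/IMOD/Segger files; MRC masks and STL/OBJ
  meshes are the interchange carriers.
* External masks are whole-file only; sub-file addressing is noted as an
  extension point.
* Non-affine warps (slice distortions/deformations) are out of scope.
* The OBO reader covers the subset above, not full OBO semantics
  (relationship types beyond `is_a`, axioms).
* `u1` lattices are validated as binary but not bit-packed.
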