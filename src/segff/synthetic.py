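"""Synthetic densities and hierarchical segmentations.

Real tomograms are large and download-bound; this module generates the
inputs every other module needs, at desk scale. ``make_density`` emulates a
macromolecular density map as a sum of isotropic Gaussian bumps (well
separated, as sub-tomogram averaging targets tend to be); ``watershed``
performs the steepest-ascent watershed that hierarchical segmenters start
from; ``build_hierarchy`` groups the watershed regions bottom-up into the
multi-level segment forest those tools emit; ``demo_fixture`` assembles a
full segmentation exercising every representation kind.

The generator does not model tomographic artefacts (missing wedge, CTF,
shot noise); what passes here demonstrates the interchange machinery, not
robustness to experimental noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import SegffError
from . import rle
from .convert import label_colour, _mode_for_max
from .model import (BiologicalAnnotation, AffineTransform, Contour,
                    ExternalReference, Lattice, Mesh, Segmentation,
                    ShapePrimitive, SoftwareInfo, VolumeRef, add_segment,
                    new_segmentation)

_OFFSETS_26 = [(dx, dy, dz)
               for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
               if (dx, dy, dz) != (0, 0, 0)]


@dataclass
class DensityVolume:
    data: np.ndarray
    seed: int
    centers: np.ndarray  # (n_blobs, 3) blob centers actually drawn

    @property
    def size(self):
        return self.data.shape


def make_density(size, n_blobs: int, seed: int) -> DensityVolume:
    """Sum of ``n_blobs`` isotropic Gaussian bumps, deterministic per seed.

    Centers are drawn uniformly inside the volume with a minimum-separation
    rejection loop (quarter of the smallest dimension) so distinct blobs
    yield distinct density peaks; widths sigma ~ U(1.5, 2.5) voxels,
    amplitudes ~ U(0.8, 1.2).
    """
    if n_blobs < 1:
        raise SegffError("n_blobs must be >= 1")
    size = tuple(int(s) for s in size)
    rng = np.random.default_rng(seed)
    min_sep = 0.25 * min(size)
    centers = []
    for _ in range(n_blobs):
        for _attempt in range(200):
            c = np.array([rng.uniform(2.0, s - 3.0) for s in size])
            if all(np.linalg.norm(c - p) >= min_sep for p in centers):
                break
        centers.append(c)
    centers = np.asarray(centers)
    sigmas = rng.uniform(1.5, 2.5, size=n_blobs)
    amps = rng.uniform(0.8, 1.2, size=n_blobs)
    ix, iy, iz = np.meshgrid(*(np.arange(s, dtype=float) for s in size),
                             indexing="ij")
    data = np.zeros(size, dtype=float)
    for c, s, a in zip(centers, sigmas, amps):
        r2 = (ix - c[0]) ** 2 + (iy - c[1]) ** 2 + (iz - c[2]) ** 2
        data += a * np.exp(-r2 / (2.0 * s * s))
    return DensityVolume(data=data, seed=int(seed), centers=centers)


def watershed(vol, threshold: float) -> np.ndarray:
    """Steepest-ascent watershed of a density volume.

    Every voxel with value > ``threshold`` follows its steepest 26-neighbour
    uphill (ties broken toward the lowest flattened index,
    ``ix + nx*(iy + ny*iz)``) until it reaches a local maximum; it takes that
    peak's label. Labels are numbered 1..K by descending peak value (ties by
    ascending flat index); voxels at or below the threshold are 0.

    Accepts a :class:`DensityVolume` or a bare ndarray.
    """
    data = vol.data if isinstance(vol, DensityVolume) else np.asarray(vol,
                                                                      dtype=float)
    nx, ny, nz = data.shape
    n = data.size
    # flat index with x fastest
    fx, fy, fz = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                             indexing="ij")
    flat = fx + nx * (fy + ny * fz)

    pad = np.full((nx + 2, ny + 2, nz + 2), -np.inf)
    pad[1:-1, 1:-1, 1:-1] = data
    pflat = np.full((nx + 2, ny + 2, nz + 2), n, dtype=np.int64)
    pflat[1:-1, 1:-1, 1:-1] = flat

    best_val = np.full(data.shape, -np.inf)
    best_flat = np.full(data.shape, n, dtype=np.int64)
    for dx, dy, dz in _OFFSETS_26:
        nv = pad[1 + dx:nx + 1 + dx, 1 + dy:ny + 1 + dy, 1 + dz:nz + 1 + dz]
        nf = pflat[1 + dx:nx + 1 + dx, 1 + dy:ny + 1 + dy, 1 + dz:nz + 1 + dz]
        take = (nv > best_val) | ((nv == best_val) & (nf < best_flat))
        best_val = np.where(take, nv, best_val)
        best_flat = np.where(take, nf, best_flat)

    ascend = best_val > data
    pointer = np.where(ascend, best_flat, flat).ravel(order="F")
    # pointer doubling until every chain reaches its peak
    for _ in range(64):
        nxt = pointer[pointer]
        if np.array_equal(nxt, pointer):
            break
        pointer = nxt

    mask = (data > threshold).ravel(order="F")
    roots = np.unique(pointer[mask]) if mask.any() else np.array([], dtype=np.int64)
    dflat = data.ravel(order="F")
    # label peaks by descending peak value, then ascending flat index
    order = sorted(roots, key=lambda r: (-dflat[r], r))
    label_of = np.zeros(n, dtype=np.int64)
    for k, r in enumerate(order, start=1):
        label_of[r] = k
    labels = np.zeros(n, dtype=np.int64)
    labels[mask] = label_of[pointer[mask]]
    return labels.reshape((nx, ny, nz), order="F")


# ---------------------------------------------------------------------------
# hierarchy
# ---------------------------------------------------------------------------

@dataclass
class HierarchySpec:
    """Target region counts per level, finest first: strictly decreasing,
    e.g. (8, 3, 1) groups the watershed regions into 8 clusters, those into
    3, and those into a single top-level group."""

    level_counts: tuple

    def __post_init__(self):
        lc = tuple(int(c) for c in self.level_counts)
        if not lc or lc[-1] < 1:
            raise SegffError("level_counts must end with a count >= 1")
        if any(a <= b for a, b in zip(lc, lc[1:])):
            raise SegffError("level_counts must be strictly decreasing")
        self.level_counts = lc


def _region_edges(labels, density):
    """6-connectivity adjacency between watershed regions with saddle
    heights: saddle(a, b) = max over boundary voxel pairs of
    min(density_a, density_b)."""
    edges: dict[tuple, float] = {}
    for axis in range(3):
        sl1 = [slice(None)] * 3
        sl2 = [slice(None)] * 3
        sl1[axis] = slice(None, -1)
        sl2[axis] = slice(1, None)
        a = labels[tuple(sl1)].ravel()
        b = labels[tuple(sl2)].ravel()
        da = density[tuple(sl1)].ravel()
        db = density[tuple(sl2)].ravel()
        sel = (a != b) & (a > 0) & (b > 0)
        for ra, rb, saddle in zip(a[sel], b[sel],
                                  np.minimum(da[sel], db[sel])):
            key = (int(min(ra, rb)), int(max(ra, rb)))
            if saddle > edges.get(key, -np.inf):
                edges[key] = float(saddle)
    return edges


def _merge_to(clusters, cluster_peak, cluster_label, edges, centroids, target):
    """Greedy agglomeration down to ``target`` clusters.

    At each step the adjacent pair with the *smallest* saliency
    min(peak_a, peak_b) - saddle(a, b) merges (the shallowest dip separates
    the most similar regions); ties break toward the lowest cluster label
    pair. Disconnected clusters fall back to nearest-centroid merging with a
    warning.
    """
    while len(clusters) > target:
        best = None
        names = sorted(clusters, key=lambda c: cluster_label[c])
        for i, ca in enumerate(names):
            for cb in names[i + 1:]:
                saddle = -np.inf
                for ra in clusters[ca]:
                    for rb in clusters[cb]:
                        key = (min(ra, rb), max(ra, rb))
                        if key in edges and edges[key] > saddle:
                            saddle = edges[key]
                if saddle == -np.inf:
                    continue
                sal = min(cluster_peak[ca], cluster_peak[cb]) - saddle
                cand = (sal, cluster_label[ca], cluster_label[cb], ca, cb)
                if best is None or cand[:3] < best[:3]:
                    best = cand
        if best is None:
            warnings.warn("disconnected regions: merging across nearest "
                          "centroids")
            bd = None
            for i, ca in enumerate(names):
                for cb in names[i + 1:]:
                    d = float(np.linalg.norm(centroids[ca] - centroids[cb]))
                    cand = (d, cluster_label[ca], cluster_label[cb], ca, cb)
                    if bd is None or cand[:3] < bd[:3]:
                        bd = cand
            best = bd
        _, _, _, ca, cb = best
        na, nb = len(clusters[ca]), len(clusters[cb])
        centroids[ca] = (centroids[ca] * na + centroids[cb] * nb) / (na + nb)
        clusters[ca] = clusters[ca] | clusters[cb]
        cluster_peak[ca] = max(cluster_peak[ca], cluster_peak[cb])
        cluster_label[ca] = min(cluster_label[ca], cluster_label[cb])
        for d in (clusters, cluster_peak, cluster_label, centroids):
            del d[cb]
    return clusters


def build_hierarchy(labels, vol, spec: HierarchySpec,
                    name: str = "hierarchical segmentation") -> Segmentation:
    """Group watershed regions into a multi-level segment forest.

    Leaves are the watershed regions (volume refs into one shared label
    lattice); each coarser level is produced by greedy saliency merging
    (see :func:`_merge_to`). Grouping nodes carry no representation.
    """
    if isinstance(spec, (list, tuple)):
        spec = HierarchySpec(tuple(spec))
    density = vol.data if isinstance(vol, DensityVolume) else np.asarray(vol,
                                                                         dtype=float)
    labels = np.asarray(labels)
    regions = sorted(int(r) for r in np.unique(labels) if r > 0)
    if not regions:
        raise SegffError("no watershed regions to organise")
    if spec.level_counts[0] > len(regions):
        raise SegffError(
            f"level target {spec.level_counts[0]} exceeds region count "
            f"{len(regions)}")
    edges = _region_edges(labels, density)
    clusters = {r: {r} for r in regions}
    cluster_peak = {r: float(density[labels == r].max()) for r in regions}
    cluster_label = {r: r for r in regions}
    centroids = {r: np.argwhere(labels == r).mean(axis=0) for r in regions}

    partitions = []  # one frozen partition per level, finest first
    for target in spec.level_counts:
        clusters = _merge_to(clusters, cluster_peak, cluster_label, edges,
                             centroids, target)
        partitions.append({cluster_label[c]: frozenset(clusters[c])
                           for c in clusters})

    seg = new_segmentation(name)
    vmax = max(regions)
    mode = _mode_for_max(vmax)
    seg.lattice_list.append(Lattice(id=0, size=labels.shape, mode=mode,
                                    runs=rle.encode(labels, mode=mode)))
    # add coarsest level first so parents exist before their children
    node_ids: dict[tuple, int] = {}  # (level_index, cluster_key) -> segment id
    n_levels = len(partitions)
    colour_i = 0
    for li in range(n_levels - 1, -1, -1):
        part = partitions[li]
        for ckey in sorted(part):
            if li == n_levels - 1:
                parent = 0
            else:
                coarser = partitions[li + 1]
                parent_key = next(k for k, members in coarser.items()
                                  if part[ckey] <= members)
                parent = node_ids[(li + 1, parent_key)]
            sid = add_segment(seg, parent,
                              name=f"level{li}_group{ckey}",
                              colour=label_colour(colour_i))
            colour_i += 1
            node_ids[(li, ckey)] = sid
    for r in regions:
        finest = partitions[0]
        parent_key = next(k for k, members in finest.items() if r in members)
        sid = add_segment(seg, node_ids[(0, parent_key)],
                          name=f"region_{r}", colour=label_colour(colour_i))
        colour_i += 1
        seg.segment(sid).volume_ref = VolumeRef(lattice_id=0, voxel_value=r)
    return seg


# ---------------------------------------------------------------------------
# demo fixture
# ---------------------------------------------------------------------------

def demo_density(seed: int = 0):
    """The 5-blob density behind :func:`demo_fixture` and its watershed
    labels; retries deterministically until at least 4 regions emerge."""
    size = (20, 20, 20)
    vol, labels = None, None
    for attempt in range(10):
        vol = make_density(size, n_blobs=5, seed=int(seed) * 131 + attempt)
        threshold = 0.05 * float(vol.data.max())
        labels = watershed(vol, threshold)
        if labels.max() >= 4:
            break
    return vol, labels


def demo_fixture(seed: int = 0) -> Segmentation:
    """A valid segmentation exercising every representation kind.

    Contains a 3-level watershed hierarchy over a 5-blob density, a mesh
    segment, a sphere-primitive segment, a planar-contour segment, a segment
    with three placement transforms, and ontology annotations on two
    segments. Deterministic per seed.
    """
    rng = np.random.default_rng(int(seed) + 1)
    vol, labels = demo_density(seed)
    seg = build_hierarchy(labels, vol, HierarchySpec((4, 2, 1)),
                          name=f"demo segmentation (seed {seed})")
    seg.details = "synthetic demonstration fixture"
    seg.software_list.append(SoftwareInfo(name="segff", version="0.1.0",
                                          processing_details="demo_fixture"))
    seg.bounding_box = (0.0, 20.0, 0.0, 20.0, 0.0, 20.0)
    seg.global_external_references.append(ExternalReference(
        resource="NCBITaxon", accession="NCBITaxon:9606",
        label="Homo sapiens"))
    seg.lattice_list[0].voxel_size = (1.0 + rng.uniform(0, 4),) * 3

    # placement transforms: identity plus two rigid placements
    seg.transform_list.append(AffineTransform.identity(0))
    for tid in (1, 2):
        theta = rng.uniform(0, 2 * np.pi)
        c, s = np.cos(theta), np.sin(theta)
        R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        t = rng.uniform(2, 15, size=3)
        seg.transform_list.append(
            AffineTransform.from_rotation_translation(R, t, id=tid))

    mesh_id = add_segment(seg, 0, name="membrane mesh",
                          colour=label_colour(90))
    base = rng.uniform(2, 10, size=3)
    cube = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                     [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]],
                    dtype=float) * rng.uniform(1, 4) + base
    tris = np.array([[0, 2, 1], [0, 3, 2], [4, 5, 6], [4, 6, 7],
                     [0, 1, 5], [0, 5, 4], [2, 3, 7], [2, 7, 6],
                     [1, 2, 6], [1, 6, 5], [3, 0, 4], [3, 4, 7]])
    seg.segment(mesh_id).mesh_list.append(Mesh(vertices=cube, triangles=tris))

    sphere_id = add_segment(seg, 0, name="sphere primitive",
                            colour=label_colour(91))
    seg.segment(sphere_id).shape_primitive_list.append(ShapePrimitive(
        kind="sphere",
        parameters=(*rng.uniform(5, 15, size=3), rng.uniform(1, 3))))

    contour_id = add_segment(seg, 0, name="slice contour",
                             colour=label_colour(92))
    z = float(rng.integers(2, 18))
    square = np.array([[3, 3, z], [12, 3, z], [12, 12, z], [3, 12, z]],
                      dtype=float)
    seg.segment(contour_id).contour_list.append(Contour(points=square,
                                                        closed=True))

    placed_id = add_segment(seg, 0, name="placed sub-tomogram average",
                            colour=label_colour(93))
    seg.segment(placed_id).transform_ids = [0, 1, 2]
    seg.segment(placed_id).shape_primitive_list.append(ShapePrimitive(
        kind="cylinder", parameters=(0.0, 0.0, 0.0, 1.5, 4.0),
        transform_id=1))

    seg.segment(mesh_id).biological_annotation = BiologicalAnnotation(
        name="mitochondrion", description="outer membrane rendering",
        number_of_instances=1,
        external_references=[ExternalReference(
            resource="GO", accession="GO:0005739", label="mitochondrion")])
    seg.segment(placed_id).biological_annotation = BiologicalAnnotation(
        name="mitochondrial ribosome", number_of_instances=3,
        external_references=[
            ExternalReference(resource="GO", accession="GO:0005761",
                              label="mitochondrial ribosome"),
            ExternalReference(resource="UniProt", accession="P12345",
                              label="example subunit",
                              url="https://www.uniprot.org/P12345")])
    return seg
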