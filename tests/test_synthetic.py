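"""Density generator, steepest-ascent watershed, hierarchy construction."""

import numpy as np
import pytest

from segff import rle, synthetic
from segff.errors import SegffError
from segff.model import canonical_form, subtree, validate
from segff.synthetic import HierarchySpec


# ---------------------------------------------------------------- density --

def test_make_density_deterministic():
    a = synthetic.make_density((12, 12, 12), 3, seed=5)
    b = synthetic.make_density((12, 12, 12), 3, seed=5)
    assert np.array_equal(a.data, b.data)
    c = synthetic.make_density((12, 12, 12), 3, seed=6)
    assert not np.array_equal(a.data, c.data)


def test_single_blob_peaks_at_drawn_center():
    vol = synthetic.make_density((15, 15, 15), 1, seed=2)
    peak = np.unravel_index(np.argmax(vol.data), vol.data.shape)
    assert np.array_equal(peak, np.round(vol.centers[0]))


# -------------------------------------------------------------- watershed --

def test_watershed_printed_example():
    vals = np.array([1, 3, 2, 4, 1], dtype=float).reshape(5, 1, 1)
    labels = synthetic.watershed(vals, 0).ravel(order="F")
    # two regions; middle voxel ascends to the steeper peak (value 4)
    assert labels[0] == labels[1]
    assert labels[2] == labels[3] == labels[4]
    assert labels[0] != labels[2]
    # labels numbered by descending peak value: peak 4 -> 1, peak 3 -> 2
    assert labels[3] == 1 and labels[1] == 2


def test_watershed_constant_above_threshold_all_zero():
    flat = np.full((4, 4, 4), 2.0)
    assert not synthetic.watershed(flat, 2.0).any()
    assert not synthetic.watershed(flat, 5.0).any()


def test_watershed_single_blob_single_label():
    vol = synthetic.make_density((12, 12, 12), 1, seed=9)
    labels = synthetic.watershed(vol, 0.05 * vol.data.max())
    assert set(np.unique(labels)) <= {0, 1}
    assert 1 in labels


def brute_force_ascend(data, threshold):
    """Independent per-voxel steepest-ascent oracle (pure python)."""
    nx, ny, nz = data.shape

    def flat(p):
        return p[0] + nx * (p[1] + ny * p[2])

    def climb(p):
        while True:
            best_v, best_f, best_p = data[p], flat(p), None
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        if (dx, dy, dz) == (0, 0, 0):
                            continue
                        q = (p[0] + dx, p[1] + dy, p[2] + dz)
                        if not (0 <= q[0] < nx and 0 <= q[1] < ny
                                and 0 <= q[2] < nz):
                            continue
                        if data[q] > best_v or (data[q] == best_v
                                                and flat(q) < best_f
                                                and data[q] > data[p]):
                            best_v, best_f, best_p = data[q], flat(q), q
            if best_p is None or data[best_p] <= data[p]:
                return p
            p = best_p

    peaks = {}
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                if data[ix, iy, iz] > threshold:
                    peaks[(ix, iy, iz)] = climb((ix, iy, iz))
    return peaks


@pytest.mark.parametrize("seed", range(3))
def test_watershed_matches_per_voxel_oracle(seed):
    vol = synthetic.make_density((10, 10, 10), 3, seed=seed)
    threshold = 0.1 * float(vol.data.max())
    labels = synthetic.watershed(vol, threshold)
    oracle = brute_force_ascend(vol.data, threshold)
    # above-threshold voxels labelled, others zero
    assert set(map(tuple, np.argwhere(labels > 0))) == set(oracle)
    # two voxels share a label iff they ascend to the same peak
    for p, peak in oracle.items():
        assert labels[p] == labels[peak]
    peak_labels = {labels[peak] for peak in set(oracle.values())}
    assert len(peak_labels) == len(set(oracle.values()))


# -------------------------------------------------------------- hierarchy --

def region_voxels(seg, sid, labels):
    """All lattice voxels under a segment (its leaves' label values)."""
    out = set()
    for i in subtree(seg, sid):
        s = seg.segment(i)
        if s.volume_ref is not None:
            out |= set(map(tuple, np.argwhere(
                labels == s.volume_ref.voxel_value)))
    return out


def test_hierarchy_counts_for_four_regions():
    vol, labels = synthetic.demo_density(1)
    labels4 = np.where(labels <= 4, labels, 0)  # keep exactly 4 regions
    n_regions = int(len(np.unique(labels4)) - 1)
    assert n_regions == 4
    seg = synthetic.build_hierarchy(labels4, vol, HierarchySpec((2, 1)))
    # 4 leaves + 2 mid nodes + 1 top node
    assert len(seg.segments) == 7
    assert validate(seg) == []
    top = [s.id for s in seg.segments if s.parent_id == 0]
    assert len(top) == 1
    assert sorted(subtree(seg, top[0])) == sorted(s.id for s in seg.segments)


def test_hierarchy_children_partition_parent():
    vol, labels = synthetic.demo_density(2)
    spec = HierarchySpec((4, 2, 1))
    seg = synthetic.build_hierarchy(labels, vol, spec)
    assert validate(seg) == []
    # leaves partition the above-threshold voxel set
    leaves = [s for s in seg.segments if s.volume_ref is not None]
    all_voxels = set(map(tuple, np.argwhere(labels > 0)))
    union, total = set(), 0
    for leaf in leaves:
        vox = set(map(tuple, np.argwhere(
            labels == leaf.volume_ref.voxel_value)))
        total += len(vox)
        union |= vox
    assert union == all_voxels and total == len(all_voxels)
    # each internal node's voxel set equals the union of its children's
    for s in seg.segments:
        kids = seg.children(s.id)
        if not kids:
            continue
        kid_union = set()
        for k in kids:
            vox = region_voxels(seg, k.id, labels)
            assert not (kid_union & vox)  # disjoint
            kid_union |= vox
        assert kid_union == region_voxels(seg, s.id, labels)


def test_hierarchy_deterministic():
    vol, labels = synthetic.demo_density(3)
    a = synthetic.build_hierarchy(labels, vol, HierarchySpec((4, 2, 1)))
    b = synthetic.build_hierarchy(labels, vol, HierarchySpec((4, 2, 1)))
    assert canonical_form(a) == canonical_form(b)


def test_hierarchy_spec_validation():
    with pytest.raises(SegffError):
        HierarchySpec((2, 4, 1))
    with pytest.raises(SegffError):
        HierarchySpec((3, 1, 0))
    vol, labels = synthetic.demo_density(0)
    with pytest.raises(SegffError, match="exceeds region count"):
        synthetic.build_hierarchy(labels, vol,
                                  HierarchySpec((int(labels.max()) + 5, 1)))


# ----------------------------------------------------------- demo fixture --

def test_demo_fixture_valid_and_complete(demo_seg):
    assert validate(demo_seg) == []
    has = {"mesh": False, "volume": False, "shape": False, "contour": False}
    for s in demo_seg.segments:
        has["mesh"] |= bool(s.mesh_list)
        has["volume"] |= s.volume_ref is not None
        has["shape"] |= bool(s.shape_primitive_list)
        has["contour"] |= bool(s.contour_list)
    assert all(has.values())
    assert any(len(s.transform_ids) == 3 for s in demo_seg.segments)
    annotated = [s for s in demo_seg.segments
                 if s.biological_annotation is not None]
    assert len(annotated) >= 2


def test_demo_fixture_deterministic(demo_seg):
    assert canonical_form(synthetic.demo_fixture(0)) == \
        canonical_form(demo_seg)
    assert canonical_form(synthetic.demo_fixture(1)) != \
        canonical_form(demo_seg)
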