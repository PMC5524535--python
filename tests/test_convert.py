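"""MRC / STL / OBJ carriers and label-mask conversions."""

import warnings

import numpy as np
import pytest

from segff import codecs, convert, rle
from segff.errors import FormatError, SegffError
from segff.model import canonical_form

from conftest import write_cube_obj, write_cube_stl


# ------------------------------------------------------------------- MRC --

@pytest.mark.parametrize("dtype,expected_mode", [
    (np.int8, 0), (np.uint16, 6), (np.float32, 2),
])
def test_mrc_round_trip_modes(dtype, expected_mode, tmp_path, rng):
    if np.issubdtype(dtype, np.floating):
        data = rng.normal(size=(6, 5, 4)).astype(dtype)
    else:
        data = rng.integers(0, 100, size=(6, 5, 4)).astype(dtype)
        if expected_mode == 6:
            data[0, 0, 0] = 300  # force beyond int8
    path = tmp_path / "v.mrc"
    convert.write_mrc(convert.MrcVolume(data=data, voxel_size=(2.1, 2.1, 2.1),
                                        origin=(1.0, -2.0, 3.5)), path)
    back = convert.read_mrc(path)
    assert back.mode == expected_mode
    assert np.allclose(back.data.astype(float), data.astype(float))
    assert np.allclose(back.voxel_size, (2.1, 2.1, 2.1), atol=1e-5)
    assert np.allclose(back.origin, (1.0, -2.0, 3.5), atol=1e-6)


def test_mrc_matches_gemmi_oracle(tmp_path, rng):
    gemmi = pytest.importorskip("gemmi")
    data = rng.normal(size=(8, 6, 5)).astype(np.float32)
    path = tmp_path / "v.mrc"
    convert.write_mrc(convert.MrcVolume(data=data), path)
    grid = np.array(gemmi.read_ccp4_map(str(path)).grid, copy=False)
    assert grid.shape == (8, 6, 5)
    assert np.allclose(grid, data)


def test_small_label_written_as_mode0_large_as_mode6(tmp_path):
    small = np.full((4, 4, 4), 7, dtype=np.int32)
    big = np.full((4, 4, 4), 300, dtype=np.int32)
    p1, p2 = tmp_path / "a.mrc", tmp_path / "b.mrc"
    convert.write_mrc(convert.MrcVolume(data=small), p1)
    convert.write_mrc(convert.MrcVolume(data=big), p2)
    assert convert.read_mrc(p1).mode == 0
    assert convert.read_mrc(p2).mode == 6


def test_all_zero_mask_round_trips(tmp_path):
    data = np.zeros((4, 4, 4), dtype=np.int8)
    path = tmp_path / "z.mrc"
    convert.write_mrc(convert.MrcVolume(data=data), path)
    assert np.array_equal(convert.read_mrc(path).data, data)


def test_negative_labels_rejected():
    with pytest.raises(SegffError, match="negative"):
        convert.write_mrc(
            convert.MrcVolume(data=np.full((2, 2, 2), -1, dtype=np.int32)),
            "/dev/null")


def test_zero_size_file_is_format_error(tmp_path):
    path = tmp_path / "empty.mrc"
    path.write_bytes(b"")
    with pytest.raises(FormatError, match="truncated"):
        convert.read_mrc(path)


def test_bad_magic_is_format_error(tmp_path):
    path = tmp_path / "bad.mrc"
    path.write_bytes(b"\x00" * 1024)
    with pytest.raises(FormatError, match="magic"):
        convert.read_mrc(path)


# ------------------------------------------------------------ label mask --

def test_from_label_mask_counts():
    lab = np.zeros((5, 5, 5), dtype=np.int32)
    lab[:2] = 1
    lab[3:] = 2
    seg = convert.from_label_mask(convert.MrcVolume(data=lab))
    assert len(seg.segments) == 2
    assert [s.name for s in seg.segments] == ["segment_1", "segment_2"]
    assert len(seg.lattice_list) == 1


def test_from_label_mask_all_zero():
    seg = convert.from_label_mask(
        convert.MrcVolume(data=np.zeros((4, 4, 4), dtype=np.int32)))
    assert len(seg.segments) == 0
    assert len(seg.lattice_list) == 1


def test_from_label_mask_rejects_float():
    with pytest.raises(SegffError, match="not a label mask"):
        convert.from_label_mask(
            convert.MrcVolume(data=np.zeros((2, 2, 2), dtype=np.float32)))


@pytest.mark.parametrize("seed", range(10))
def test_per_segment_counts_match_histogram(seed):
    rng = np.random.default_rng(seed)
    size = tuple(int(s) for s in rng.integers(4, 33, size=3))
    n_labels = int(rng.integers(1, 10))
    lab = rng.integers(0, n_labels + 1, size=size).astype(np.int32)
    seg = convert.from_label_mask(convert.MrcVolume(data=lab))
    hist = {int(v): int(c) for v, c in
            zip(*np.unique(lab, return_counts=True)) if v != 0}
    assert len(seg.segments) == len(hist)
    lat = seg.lattice_list[0]
    for s in seg.segments:
        assert rle.count_value(lat.runs, s.volume_ref.voxel_value) \
            == hist[s.volume_ref.voxel_value]


def test_palette_is_distinct_and_deterministic():
    cols = [convert.label_colour(i).as_tuple() for i in range(12)]
    assert len(set(cols)) == 12
    assert cols == [convert.label_colour(i).as_tuple() for i in range(12)]


# ---------------------------------------------------------------- meshes --

def test_stl_cube_dedup(tmp_path):
    mesh = convert.read_stl_ascii(write_cube_stl(tmp_path / "cube.stl"))
    assert len(mesh.vertices) == 8
    assert len(mesh.triangles) == 12
    tm = pytest.importorskip("trimesh").load(str(tmp_path / "cube.stl"))
    assert (len(tm.vertices), len(tm.faces)) == (8, 12)


def test_stl_single_facet(tmp_path):
    path = tmp_path / "tri.stl"
    path.write_text(
        "solid t\nfacet normal 0 0 1\n outer loop\n"
        "  vertex 0 0 0\n  vertex 1 0 0\n  vertex 0 1 0\n"
        " endloop\nendfacet\nendsolid t\n")
    mesh = convert.read_stl_ascii(path)
    assert (len(mesh.vertices), len(mesh.triangles)) == (3, 1)


def test_stl_empty_solid_warns(tmp_path):
    path = tmp_path / "empty.stl"
    path.write_text("solid nothing\nendsolid nothing\n")
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        mesh = convert.read_stl_ascii(path)
    assert len(mesh.triangles) == 0
    assert any("empty" in str(w.message) for w in rec)


def test_binary_stl_rejected(tmp_path):
    path = tmp_path / "bin.stl"
    path.write_bytes(b"\x00" * 84 + b"\x01" * 50)
    with pytest.raises(FormatError, match="binary STL unsupported"):
        convert.read_stl_ascii(path)


def test_malformed_facet_reports_line(tmp_path):
    path = tmp_path / "bad.stl"
    path.write_text(
        "solid t\nfacet normal 0 0 1\n outer loop\n"
        "  vertex 0 0 0\n  vertex 1 0 0\n"
        " endloop\nendfacet\nendsolid t\n")
    with pytest.raises(FormatError, match="line 7"):
        convert.read_stl_ascii(path)


def test_obj_cube_fan_split(tmp_path):
    mesh = convert.read_obj(write_cube_obj(tmp_path / "cube.obj"))
    assert (len(mesh.vertices), len(mesh.triangles)) == (8, 12)
    tm = pytest.importorskip("trimesh").load(str(tmp_path / "cube.obj"))
    assert len(tm.faces) == 12


def test_obj_negative_indices(tmp_path):
    path = tmp_path / "neg.obj"
    path.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf -3 -2 -1\n")
    mesh = convert.read_obj(path)
    assert mesh.triangles.tolist() == [[0, 1, 2]]


def test_obj_out_of_range_index(tmp_path):
    path = tmp_path / "oob.obj"
    path.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 99\n")
    with pytest.raises(FormatError, match="out of range"):
        convert.read_obj(path)


def test_from_meshes(tmp_path):
    m = convert.read_stl_ascii(write_cube_stl(tmp_path / "c.stl"))
    seg = convert.from_meshes([("a", m), ("b", m), ("c", m)])
    assert [s.id for s in seg.segments] == [1, 2, 3]
    assert all(s.parent_id == 0 for s in seg.segments)
    with pytest.raises(SegffError):
        convert.from_meshes([])
    # codec round trip preserves coordinates to canonical rounding
    path = tmp_path / "m.json"
    codecs.write(seg, path)
    assert canonical_form(codecs.read(path)) == canonical_form(seg)


# --------------------------------------------------------- externalisation --

def _mask_voxels(seg, segment):
    lat = seg.lattice(segment.volume_ref.lattice_id)
    grid = rle.decode(lat.runs, lat.size)
    return set(map(tuple, np.argwhere(
        grid == segment.volume_ref.voxel_value)))


def test_export_external_masks_round_trip(tmp_path, rng):
    lab = rng.integers(0, 3, size=(10, 9, 8)).astype(np.int32)
    seg = convert.from_label_mask(convert.MrcVolume(data=lab))
    out_dir = tmp_path / "masks"
    ext = convert.export_external_masks(seg, out_dir)
    manifest = (out_dir / "manifest.tsv").read_text().splitlines()
    assert manifest[0] == "segment_id\trelative_path"
    assert len(manifest) == 1 + 2
    assert sorted(p.name for p in out_dir.glob("*.mrc")) == \
        ["segment_1.mrc", "segment_2.mrc"]
    # canonical form preserved except volume_ref storage location
    cf_orig = canonical_form(seg)
    cf_ext = canonical_form(ext)
    for a, b in zip(cf_orig["segments"], cf_ext["segments"]):
        da, db = dict(a), dict(b)
        da.pop("volume_ref"), db.pop("volume_ref")
        assert da == db
    assert {k: v for k, v in cf_orig.items() if k != "segments"} == \
        {k: v for k, v in cf_ext.items() if k != "segments"}
    # re-import reproduces the original voxel sets
    back = convert.import_external_masks(ext, out_dir)
    for s_orig, s_back in zip(seg.segments, back.segments):
        assert _mask_voxels(seg, s_orig) == _mask_voxels(back, s_back)


def test_export_no_volume_segments_warns(tmp_path, demo_seg):
    import copy
    seg = copy.deepcopy(demo_seg)
    for s in seg.segments:
        s.volume_ref = None
    with warnings.catch_warnings(record=True) as rec:
        warnings.simplefilter("always")
        convert.export_external_masks(seg, tmp_path / "m")
    assert (tmp_path / "m" / "manifest.tsv").read_text().splitlines() == \
        ["segment_id\trelative_path"]
    assert any("no volume-backed" in str(w.message) for w in rec)
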