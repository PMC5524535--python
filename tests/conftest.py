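import numpy as np
import pytest

from segff import synthetic


@pytest.fixture(scope="session")
def demo_seg():
    """One shared demo fixture (seed 0) for read-only tests."""
    return synthetic.demo_fixture(0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def write_cube_stl(path):
    """ASCII STL unit cube: 12 facets referencing 8 distinct corners."""
    verts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                      [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], float)
    tris = [[0, 2, 1], [0, 3, 2], [4, 5, 6], [4, 6, 7],
            [0, 1, 5], [0, 5, 4], [2, 3, 7], [2, 7, 6],
            [1, 2, 6], [1, 6, 5], [3, 0, 4], [3, 4, 7]]
    with open(path, "w") as fh:
        fh.write("solid cube\n")
        for t in tris:
            a, b, c = (verts[i] for i in t)
            n = np.cross(b - a, c - a)
            n = n / np.linalg.norm(n)
            fh.write(f"facet normal {n[0]} {n[1]} {n[2]}\n  outer loop\n")
            for v in (a, b, c):
                fh.write(f"    vertex {v[0]} {v[1]} {v[2]}\n")
            fh.write("  endloop\nendfacet\n")
        fh.write("endsolid cube\n")
    return path


def write_cube_obj(path):
    """OBJ unit cube: 8 vertices, 6 quad faces (fan-split expected)."""
    verts = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                      [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]], float)
    faces = ([1, 2, 3, 4], [8, 7, 6, 5], [1, 5, 6, 2],
             [3, 7, 8, 4], [2, 6, 7, 3], [1, 4, 8, 5])
    with open(path, "w") as fh:
        for v in verts:
            fh.write(f"v {v[0]} {v[1]} {v[2]}\n")
        for f in faces:
            fh.write("f " + " ".join(map(str, f)) + "\n")
    return path
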