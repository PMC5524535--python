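"""Run-length codec for 3D label lattices.

Voxel masks dominate the storage cost of a segmentation file; run-length
encoding of the flattened label grid together with a limited bit depth keeps
files small while staying trivially seekable. Runs cover the whole lattice
as (value, length) pairs — one codec therefore serves both binary
per-segment masks and shared multi-label lattices.

Flattening order is x fastest, then y, then z:
``flat_index = ix + nx * (iy + ny * iz)`` — the section order of MRC
volumes, so masks convert to and from MRC without reindexing. In-memory
lattices are numpy arrays of shape (nx, ny, nz) indexed ``[ix, iy, iz]``;
this flattening is ``ravel(order="F")``.
"""

from __future__ import annotations

import numpy as np

from .errors import SegffError
from .model import LATTICE_MODES

RunList = list  # list[(value, length)]


def encode(lattice, size=None, mode: str = "u32") -> RunList:
    """Run-length encode a 3D grid of non-negative ints.

    Runs are maximally merged: adjacent runs always differ in value.
    ``decode(encode(V), V.shape) == V`` exactly.
    """
    arr = np.asarray(lattice)
    if size is not None and tuple(arr.shape) != tuple(size):
        raise SegffError(f"lattice shape {arr.shape} != declared size {tuple(size)}")
    if arr.ndim != 3:
        raise SegffError(f"expected a 3D lattice, got {arr.ndim} dimensions")
    flat = arr.ravel(order="F")
    if flat.size == 0:
        raise SegffError("cannot encode an empty lattice")
    vmax = LATTICE_MODES[mode]
    bad = np.nonzero((flat < 0) | (flat > vmax))[0]
    if bad.size:
        i = int(bad[0])
        raise SegffError(
            f"value {int(flat[i])} at flat voxel index {i} does not fit "
            f"mode {mode} (0..{vmax})")
    # boundaries where the value changes
    change = np.nonzero(flat[1:] != flat[:-1])[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [flat.size]])
    return [(int(flat[s]), int(e - s)) for s, e in zip(starts, ends)]


def decode(runs: RunList, size) -> np.ndarray:
    """Expand a run list back into a (nx, ny, nz) grid."""
    nx, ny, nz = (int(s) for s in size)
    expected = nx * ny * nz
    total = sum(int(l) for _, l in runs)
    if total != expected:
        raise SegffError(f"expected {expected} voxels, got {total}")
    if any(int(l) < 1 for _, l in runs):
        raise SegffError("run lengths must be >= 1")
    values = np.fromiter((int(v) for v, _ in runs), dtype=np.int64,
                         count=len(runs))
    lengths = np.fromiter((int(l) for _, l in runs), dtype=np.int64,
                          count=len(runs))
    flat = np.repeat(values, lengths)
    return flat.reshape((nx, ny, nz), order="F")


def count_value(runs: RunList, value: int) -> int:
    """Number of voxels equal to ``value`` — per-segment voxel statistics
    without decoding."""
    value = int(value)
    return int(sum(int(l) for v, l in runs if int(v) == value))
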