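"""Shared fixtures: small seeded phantoms generated at test time."""

import numpy as np
import pytest

from chromaxial import PhantomSpec, generate_phantom

# A reduced grid (48 x 48 x 600 um) keeps per-test generation below a second
# while preserving the depth-dependence the regressions need.
SMALL_GRID = dict(shape=(300, 96, 96))


@pytest.fixture(scope="session")
def small_phantom():
    """12-bead two-channel phantom with depth-linear shift and mild jitter."""
    spec = PhantomSpec(seed=21, n_beads=12, shift_jitter_um=0.2, **SMALL_GRID)
    stack, truth, rois = generate_phantom(spec)
    return spec, stack, truth, rois


@pytest.fixture(scope="session")
def clean_phantom():
    """Jitter-free 12-bead phantom for exact round-trip checks."""
    spec = PhantomSpec(seed=13, n_beads=12, shift_jitter_um=0.0, **SMALL_GRID)
    stack, truth, rois = generate_phantom(spec)
    return spec, stack, truth, rois


@pytest.fixture(scope="session")
def detection_phantom():
    """Single-channel, shift-free bead slab for detector tests."""
    spec = PhantomSpec(
        seed=33,
        shape=(120, 96, 96),
        channels=("473",),
        reference_channel="473",
        slopes={},
        intercepts={},
        lateral_offsets={},
        n_beads=10,
        shift_jitter_um=0.0,
    )
    stack, truth, rois = generate_phantom(spec)
    return spec, stack, truth, rois


def brute_force_centroid(vox, dx, dy, dz, z0, x0, y0, zlo, k_start=10.0):
    """Independent reference implementation of the thresholded centre of mass.

    Plain loops: per-column length-3 z median with nearest-edge padding,
    mean/SD of the filtered block, threshold ladder, weighted sum.
    ``x0, y0, zlo`` are the ROI's offsets in the parent grid.
    """
    vox = np.asarray(vox, dtype=float)
    nz, ny, nx = vox.shape
    filt = np.empty_like(vox)
    for y in range(ny):
        for x in range(nx):
            col = vox[:, y, x]
            for z in range(nz):
                if z == 0:
                    vals = [col[0], col[0], col[1]]
                elif z == nz - 1:
                    vals = [col[nz - 2], col[nz - 1], col[nz - 1]]
                else:
                    vals = [col[z - 1], col[z], col[z + 1]]
                filt[z, y, x] = sorted(vals)[1]
    flat = [filt[z, y, x] for z in range(nz) for y in range(ny) for x in range(nx)]
    m = sum(flat) / len(flat)
    s = (sum((v - m) ** 2 for v in flat) / len(flat)) ** 0.5
    k = k_start
    while True:
        kept = [
            (filt[z, y, x], z, y, x)
            for z in range(nz)
            for y in range(ny)
            for x in range(nx)
            if filt[z, y, x] > m + k * s
        ]
        if kept:
            break
        k /= 2.0
        if k < 1.0:
            return None
    tot = sum(w for w, *_ in kept)
    cz = sum(w * z for w, z, _, _ in kept) / tot
    cy = sum(w * y for w, _, y, _ in kept) / tot
    cx = sum(w * x for w, _, _, x in kept) / tot
    return (
        (x0 + cx) * dx,
        (y0 + cy) * dy,
        z0 + (zlo + cz) * dz,
    )
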