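"""Synthetic bead-slab and guide-star phantoms with known aberration.

The generator emulates a calibration acquisition: fluorescent beads embedded
in a cleared gel, imaged in several channels whose axial positions are
shifted relative to the reference channel by a depth-linear law

    Δz(d) = a·d + b + ε,      ε ~ N(0, σ_ε²)  per bead,

plus constant per-channel lateral offsets.  Beads are rendered as anisotropic
3D Gaussians (axial σ elongated by a configurable factor, mimicking the
confocal PSF) so that sub-voxel ground-truth positions are exact and centroid
maths is analytic.  Only the measured *effect* of chromatic aberration is
modelled — no diffraction or refractive-index physics.

Default parameters emulate a deep bead-slab acquisition: a 48 × 48 × 2000 μm
column (0.5 × 0.5 × 2 μm voxels) of 4 μm multi-fluorophore beads imaged at 473
and 559 nm, the 559 nm channel shifted by Δz(d) = 0.004·d − 18 μm — axial
shifts of 10–18 μm over a 2 mm depth range with sub-micrometre lateral
offsets, the regime where depth-dependent correction matters.

Every draw comes from one seeded generator: the same spec and seed reproduce
the stack, truth table and ROIs bit-identically.  The truth table records
each bead's per-channel ε realisation so downstream tests can separate fit
error from model error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError
from .stacks import BeadROI, ChannelStack, MultiChannelStack

__all__ = ["PhantomSpec", "generate_phantom", "generate_guide_star_phantom"]

logger = logging.getLogger(__name__)

_RENDER_NSIGMA = 5.0  # Gaussian support radius used for rendering windows
_ROI_NSIGMA = 4.0  # margin between an object's centre(s) and its ROI faces


@dataclass
class PhantomSpec:
    """Parameters of a synthetic multi-channel acquisition.

    Truth maps (``slopes``, ``intercepts``, ``lateral_offsets``) give each
    non-reference channel's axial-shift law and lateral offset; the reference
    channel is implicitly (and must stay) zero.  ``seed`` is mandatory.
    """

    seed: int
    shape: tuple[int, int, int] = (1000, 96, 96)  # (nz, ny, nx)
    dz: float = 2.0
    dy: float = 0.5
    dx: float = 0.5
    z0: float = 0.0
    channels: tuple[str, ...] = ("473", "559")
    reference_channel: str = "473"
    slopes: dict[str, float] = field(default_factory=lambda: {"559": 0.004})
    intercepts: dict[str, float] = field(default_factory=lambda: {"559": -18.0})
    lateral_offsets: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"559": (0.3, -0.2)}
    )
    n_beads: int = 50
    bead_sigma_um: float = 1.7
    axial_sigma_factor: float = 3.0
    peak: float = 10_000.0
    background: float = 100.0
    read_noise_sigma: float = 50.0
    poisson: bool = False
    shift_jitter_um: float = 0.5

    def __post_init__(self) -> None:
        if self.reference_channel not in self.channels:
            raise DataError(
                f"reference {self.reference_channel!r} not in channels {self.channels}"
            )
        for m in (self.slopes, self.intercepts):
            if m.get(self.reference_channel):
                raise DataError("reference-channel truth must be identically zero")
        off = self.lateral_offsets.get(self.reference_channel)
        if off is not None and tuple(off) != (0.0, 0.0):
            raise DataError("reference-channel truth must be identically zero")
        if min(self.shape) < 1 or min(self.dx, self.dy, self.dz) <= 0:
            raise DataError(f"invalid grid: shape={self.shape}")
        if self.n_beads < 1:
            raise DataError("n_beads must be >= 1")

    @property
    def sigma_z_um(self) -> float:
        return self.bead_sigma_um * self.axial_sigma_factor

    def truth_for(self, channel: str) -> tuple[float, float, float, float]:
        """(slope, intercept, δx, δy) for a channel (zeros for the reference)."""
        a = self.slopes.get(channel, 0.0)
        b = self.intercepts.get(channel, 0.0)
        ox, oy = self.lateral_offsets.get(channel, (0.0, 0.0))
        return a, b, ox, oy


# ---------------------------------------------------------------------------
# placement helpers
# ---------------------------------------------------------------------------

def _boxes_overlap(b1, b2) -> bool:
    return all(lo1 < hi2 and lo2 < hi1 for (lo1, hi1), (lo2, hi2) in zip(b1, b2))


def _place_objects(spec: PhantomSpec, rng, half_extents_fn, depth_sampler, n_objects):
    """Rejection-sample object centres with disjoint, in-bounds ROI boxes.

    ``half_extents_fn(centers)`` maps the dict of per-channel (x, y, z)
    centres to half-extents (hx, hy, hz_lo, hz_hi ranges) in μm;
    ``depth_sampler(rng, n_placed)`` draws a candidate reference depth.
    Returns a list of (centers, box) where ``box`` is ((x0,x1),(y0,y1),(z0,z1))
    in physical μm.
    """
    nz, ny, nx = spec.shape
    x_hi = (nx - 1) * spec.dx
    y_hi = (ny - 1) * spec.dy
    z_lo_phys = spec.z0
    z_hi_phys = spec.z0 + (nz - 1) * spec.dz
    placed = []
    attempts = 0
    max_attempts = 2000 * n_objects
    while len(placed) < n_objects:
        attempts += 1
        if attempts > max_attempts:
            raise DataError(
                f"could not place {n_objects} objects after {max_attempts} attempts; "
                "the spec is infeasible (grid too small for the requested count/shifts)"
            )
        d = depth_sampler(rng, len(placed))
        x = rng.uniform(0.0, x_hi)
        y = rng.uniform(0.0, y_hi)
        centers, box = half_extents_fn(d, x, y, rng)
        if centers is None:
            continue
        (bx0, bx1), (by0, by1), (bz0, bz1) = box
        if bx0 < 0 or by0 < 0 or bz0 < z_lo_phys or bx1 > x_hi or by1 > y_hi or bz1 > z_hi_phys:
            continue
        if any(_boxes_overlap(box, other_box) for _, other_box in placed):
            continue
        placed.append((centers, box))
    return placed


def _box_to_roi(box, spec: PhantomSpec, label: str) -> BeadROI:
    (bx0, bx1), (by0, by1), (bz0, bz1) = box
    return BeadROI(
        x_min=int(np.floor(bx0 / spec.dx)),
        x_max=int(np.ceil(bx1 / spec.dx)) + 1,
        y_min=int(np.floor(by0 / spec.dy)),
        y_max=int(np.ceil(by1 / spec.dy)) + 1,
        z_min=int(np.floor((bz0 - spec.z0) / spec.dz)),
        z_max=int(np.ceil((bz1 - spec.z0) / spec.dz)) + 1,
        label=label,
    )


def _finalize_stack(spec: PhantomSpec, arrays: dict[str, np.ndarray], rng) -> MultiChannelStack:
    channels = []
    for cid in spec.channels:
        arr = arrays[cid]
        arr += spec.background
        if spec.poisson:
            arr = rng.poisson(np.clip(arr, 0, None)).astype(np.float64)
        if spec.read_noise_sigma > 0:
            noise = rng.standard_normal(size=arr.shape, dtype=np.float32)
            noise *= spec.read_noise_sigma
            arr += noise
        np.rint(arr, out=arr)
        np.clip(arr, 0, 65535, out=arr)
        q = arr.astype(np.uint16)
        channels.append(
            ChannelStack(voxels=q, dx=spec.dx, dy=spec.dy, dz=spec.dz, z0=spec.z0, channel_id=cid)
        )
    return MultiChannelStack(
        channels=tuple(channels), reference_channel=spec.reference_channel
    )


def _render_gaussian(arr, spec: PhantomSpec, cx, cy, cz):
    """Add one anisotropic Gaussian bead (physical-μm centre) in place."""
    nz, ny, nx = arr.shape
    sx = sy = spec.bead_sigma_um
    sz = spec.sigma_z_um
    ix, iy = cx / spec.dx, cy / spec.dy
    iz = (cz - spec.z0) / spec.dz
    wx = int(np.ceil(_RENDER_NSIGMA * sx / spec.dx))
    wy = int(np.ceil(_RENDER_NSIGMA * sy / spec.dy))
    wz = int(np.ceil(_RENDER_NSIGMA * sz / spec.dz))
    x0, x1 = max(0, int(ix) - wx), min(nx, int(ix) + wx + 2)
    y0, y1 = max(0, int(iy) - wy), min(ny, int(iy) + wy + 2)
    z0_, z1 = max(0, int(iz) - wz), min(nz, int(iz) + wz + 2)
    gx = np.exp(-((np.arange(x0, x1) * spec.dx - cx) ** 2) / (2 * sx**2))
    gy = np.exp(-((np.arange(y0, y1) * spec.dy - cy) ** 2) / (2 * sy**2))
    gz = np.exp(-((spec.z0 + np.arange(z0_, z1) * spec.dz - cz) ** 2) / (2 * sz**2))
    arr[z0_:z1, y0:y1, x0:x1] += spec.peak * (
        gz[:, None, None] * gy[None, :, None] * gx[None, None, :]
    )


# ---------------------------------------------------------------------------
# bead phantom
# ---------------------------------------------------------------------------

def generate_phantom(
    spec: PhantomSpec,
) -> tuple[MultiChannelStack, pd.DataFrame, list[BeadROI]]:
    """Render a bead-slab acquisition with known per-channel shifts.

    Returns ``(stack, truth, rois)``: the multi-channel stack, a tidy
    ground-truth table (one row per bead per channel, with the exact shift
    including the per-bead jitter realisation ε), and one ROI per bead
    spanning the bead's content in every channel.
    """
    rng = np.random.default_rng(spec.seed)
    nz = spec.shape[0]
    z_lo = spec.z0
    z_hi = spec.z0 + (nz - 1) * spec.dz
    hx = _ROI_NSIGMA * spec.bead_sigma_um + spec.dx
    hy = _ROI_NSIGMA * spec.bead_sigma_um + spec.dy
    hz = _ROI_NSIGMA * spec.sigma_z_um + spec.dz

    def depth_sampler(rng, _index):
        # jitter and shifts are validated per candidate, so sample the full range
        return rng.uniform(z_lo, z_hi)

    def make_centers(d, x, y, rng):
        eps = {
            c: (rng.normal(0.0, spec.shift_jitter_um) if spec.shift_jitter_um > 0 else 0.0)
            for c in spec.channels
            if c != spec.reference_channel
        }
        centers = {}
        for c in spec.channels:
            if c == spec.reference_channel:
                centers[c] = (x, y, d, 0.0)
            else:
                a, b, ox, oy = spec.truth_for(c)
                centers[c] = (x + ox, y + oy, d + a * d + b + eps[c], eps[c])
        xs = [v[0] for v in centers.values()]
        ys = [v[1] for v in centers.values()]
        zs = [v[2] for v in centers.values()]
        box = (
            (min(xs) - hx, max(xs) + hx),
            (min(ys) - hy, max(ys) + hy),
            (min(zs) - hz, max(zs) + hz),
        )
        return centers, box

    placed = _place_objects(spec, rng, make_centers, depth_sampler, spec.n_beads)

    arrays = {c: np.zeros(spec.shape, dtype=np.float64) for c in spec.channels}
    truth_rows = []
    rois = []
    for k, (centers, box) in enumerate(placed, start=1):
        label = f"bead_{k:03d}"
        xr, yr, dr, _ = centers[spec.reference_channel]
        for c in spec.channels:
            cx, cy, cz, eps = centers[c]
            _render_gaussian(arrays[c], spec, cx, cy, cz)
            truth_rows.append(
                {
                    "label": label,
                    "channel": c,
                    "x_um": xr,
                    "y_um": yr,
                    "depth_um": dr,
                    "dx_um": cx - xr,
                    "dy_um": cy - yr,
                    "dz_um": cz - dr,
                    "eps_um": eps,
                }
            )
        rois.append(_box_to_roi(box, spec, label))

    stack = _finalize_stack(spec, arrays, rng)
    truth = pd.DataFrame(truth_rows)
    logger.info("generate_phantom: %d beads on grid %s (seed=%d)", spec.n_beads, spec.shape, spec.seed)
    return stack, truth, rois


# ---------------------------------------------------------------------------
# guide-star phantom
# ---------------------------------------------------------------------------

def _render_capsule(arr, spec: PhantomSpec, p0, p1):
    """Add a tube of Gaussian cross-section between physical points p0, p1."""
    nz, ny, nx = arr.shape
    sx = sy = spec.bead_sigma_um
    sz = spec.sigma_z_um
    lo = np.minimum(p0, p1)
    hi = np.maximum(p0, p1)
    pad = _RENDER_NSIGMA * np.array([sx, sy, sz])
    x0 = max(0, int((lo[0] - pad[0]) / spec.dx))
    x1 = min(nx, int(np.ceil((hi[0] + pad[0]) / spec.dx)) + 1)
    y0 = max(0, int((lo[1] - pad[1]) / spec.dy))
    y1 = min(ny, int(np.ceil((hi[1] + pad[1]) / spec.dy)) + 1)
    z0_ = max(0, int((lo[2] - pad[2] - spec.z0) / spec.dz))
    z1 = min(nz, int(np.ceil((hi[2] + pad[2] - spec.z0) / spec.dz)) + 1)
    zz, yy, xx = np.meshgrid(
        spec.z0 + np.arange(z0_, z1) * spec.dz,
        np.arange(y0, y1) * spec.dy,
        np.arange(x0, x1) * spec.dx,
        indexing="ij",
    )
    # anisotropic normalisation: distances in units of the local sigma
    scale = np.array([sx, sy, sz])
    a = (np.asarray(p0) / scale)
    v = (np.asarray(p1) / scale) - a
    px = xx / scale[0] - a[0]
    py = yy / scale[1] - a[1]
    pz = zz / scale[2] - a[2]
    vv = float(np.dot(v, v))
    t = np.clip((px * v[0] + py * v[1] + pz * v[2]) / vv, 0.0, 1.0) if vv > 0 else 0.0
    d2 = (px - t * v[0]) ** 2 + (py - t * v[1]) ** 2 + (pz - t * v[2]) ** 2
    arr[z0_:z1, y0:y1, x0:x1] += spec.peak * np.exp(-d2 / 2.0)


def generate_guide_star_phantom(
    spec: PhantomSpec,
    neurite_length_um: float = 10.0,
    max_axial_tilt: float = 0.3,
) -> tuple[MultiChannelStack, pd.DataFrame, list[BeadROI]]:
    """Render guide stars: short neurite-like tubes labeled in all channels.

    Objects are capsules (segments with Gaussian cross-section, axially
    elongated like the beads) whose reference depths are drawn only from the
    top and bottom thirds of the feasible depth range — the sampling scheme
    that anchors a linear depth regression at both ends.  ``spec.n_beads``
    sets the number of guide stars; ROIs span each object's full z extent in
    every channel.  Truth rows refer to the capsule midpoint (its centroid).
    """
    rng = np.random.default_rng(spec.seed)
    nz = spec.shape[0]
    z_lo = spec.z0
    z_hi = spec.z0 + (nz - 1) * spec.dz
    span = z_hi - z_lo
    half_len = neurite_length_um / 2.0
    hx = _ROI_NSIGMA * spec.bead_sigma_um + spec.dx
    hy = _ROI_NSIGMA * spec.bead_sigma_um + spec.dy
    hz = _ROI_NSIGMA * spec.sigma_z_um + spec.dz
    n_stars = spec.n_beads

    def depth_sampler(rng, index):
        # alternate top-third / bottom-third cluster membership per placed star
        if index % 2 == 0:
            return rng.uniform(z_lo, z_lo + span / 3.0)
        return rng.uniform(z_hi - span / 3.0, z_hi)

    def make_centers(d, x, y, rng):
        phi = rng.uniform(0.0, 2.0 * np.pi)
        uz = rng.uniform(-max_axial_tilt, max_axial_tilt)
        ur = np.sqrt(1.0 - uz**2)
        direction = np.array([ur * np.cos(phi), ur * np.sin(phi), uz])
        eps = {
            c: (rng.normal(0.0, spec.shift_jitter_um) if spec.shift_jitter_um > 0 else 0.0)
            for c in spec.channels
            if c != spec.reference_channel
        }
        centers = {}
        ends_x, ends_y, ends_z = [], [], []
        for c in spec.channels:
            if c == spec.reference_channel:
                mid = np.array([x, y, d])
                e = 0.0
            else:
                a, b, ox, oy = spec.truth_for(c)
                e = eps[c]
                mid = np.array([x + ox, y + oy, d + a * d + b + e])
            p0 = mid - half_len * direction
            p1 = mid + half_len * direction
            centers[c] = (mid, p0, p1, e)
            ends_x += [p0[0], p1[0]]
            ends_y += [p0[1], p1[1]]
            ends_z += [p0[2], p1[2]]
        box = (
            (min(ends_x) - hx, max(ends_x) + hx),
            (min(ends_y) - hy, max(ends_y) + hy),
            (min(ends_z) - hz, max(ends_z) + hz),
        )
        return centers, box

    placed = _place_objects(spec, rng, make_centers, depth_sampler, n_stars)

    arrays = {c: np.zeros(spec.shape, dtype=np.float64) for c in spec.channels}
    truth_rows = []
    rois = []
    for k, (centers, box) in enumerate(placed, start=1):
        label = f"gs_{k:03d}"
        mid_ref = centers[spec.reference_channel][0]
        for c in spec.channels:
            mid, p0, p1, eps = centers[c]
            _render_capsule(arrays[c], spec, p0, p1)
            truth_rows.append(
                {
                    "label": label,
                    "channel": c,
                    "x_um": mid_ref[0],
                    "y_um": mid_ref[1],
                    "depth_um": mid_ref[2],
                    "dx_um": mid[0] - mid_ref[0],
                    "dy_um": mid[1] - mid_ref[1],
                    "dz_um": mid[2] - mid_ref[2],
                    "eps_um": eps,
                }
            )
        rois.append(_box_to_roi(box, spec, label))

    stack = _finalize_stack(spec, arrays, rng)
    truth = pd.DataFrame(truth_rows)
    logger.info("generate_guide_star_phantom: %d guide stars (seed=%d)", n_stars, spec.seed)
    return stack, truth, rois
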