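"""Intensity-weighted centroids and inter-channel aberration shifts.

For each ROI and channel the object position is estimated as the centre of
mass of the bright voxels:

1. extract the ROI subvolume;
2. median-filter each (y, x) column along z with a length-3 window
   (nearest-neighbour padding at the edge frames) to suppress shot noise;
3. compute mean ``m`` and SD ``s`` of the filtered ROI voxels and keep voxels
   with intensity ``> m + k*s`` (``k`` = 10 by default);
4. centroid = Σ I·pos / Σ I over the kept voxels, in physical micrometres.

Filtering precedes the statistics by default so that shot noise cannot
inflate ``s``; set ``threshold_before_filter=True`` to compute the statistics
and the mask on the raw voxels instead (the weights are always the filtered
intensities).

If no voxel clears ``m + 10 s`` (dim guide stars), ``k`` is halved repeatedly
until at least one voxel passes; if ``k`` drops below 1 the ROI is declared
empty.  Every fallback is recorded in the centroid's flags and logged.

Aberration shifts are differences of per-channel centroids relative to the
reference channel; the sample's depth covariate is the *reference-channel*
centroid z, never the ROI's geometric middle.  Guide stars use the same code
path; a sample with more than 1% of its above-threshold mass in the first or
last ROI frame is flagged ``possibly_truncated`` (the ROI probably does not
span the object's full z extent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DataError
from .stacks import BeadROI, ChannelStack, MultiChannelStack

__all__ = [
    "Centroid",
    "AberrationSample",
    "compute_centroid",
    "measure_sample",
    "measure_batch",
    "samples_to_frame",
    "samples_from_frame",
]

logger = logging.getLogger(__name__)

TRUNCATION_MASS_FRACTION = 0.01


@dataclass(frozen=True)
class Centroid:
    """Centre of mass of one object in one channel, in stage μm."""

    x: float
    y: float
    z: float
    channel_id: str
    total_weight: float
    flags: tuple[str, ...] = ()


@dataclass
class AberrationSample:
    """One object's depth and per-channel centroid shifts vs the reference.

    ``shifts`` maps channel_id -> (Δx, Δy, Δz) in μm; the reference channel
    maps to exactly (0, 0, 0).  ``depth`` is the reference-channel centroid z.
    """

    label: str
    depth: float
    shifts: dict[str, tuple[float, float, float]]
    source: str = "bead"
    flags: tuple[str, ...] = ()
    total_weights: dict[str, float] = field(default_factory=dict)


def compute_centroid(
    stack: ChannelStack,
    roi: BeadROI,
    k_sigma: float = 10.0,
    threshold_before_filter: bool = False,
) -> Centroid:
    """Thresholded centre of mass of the ROI contents, in physical μm."""
    roi.check_within(stack.shape)
    zsl, ysl, xsl = roi.slices(stack.nz)
    if zsl.stop - zsl.start < 3:
        raise DataError(
            f"ROI {roi.label!r}: needs >= 3 frames along z for the median filter, "
            f"got {zsl.stop - zsl.start}"
        )
    sub = stack.voxels[zsl, ysl, xsl].astype(np.float64)
    filtered = ndimage.median_filter(sub, size=(3, 1, 1), mode="nearest")
    stats_src = sub if threshold_before_filter else filtered
    m = float(stats_src.mean())
    s = float(stats_src.std())

    flags: list[str] = []
    k = float(k_sigma)
    while True:
        mask = stats_src > m + k * s
        if mask.any():
            break
        k /= 2.0
        if k < 1.0:
            raise DataError(f"ROI {roi.label!r}: no object found (threshold fallback exhausted)")
    if k != k_sigma:
        flags.append(f"threshold_fallback:k={k:g}")
        logger.warning(
            "ROI %r channel %s: threshold lowered to mean + %g*SD",
            roi.label, stack.channel_id, k,
        )

    weights = filtered[mask]
    zz, yy, xx = np.nonzero(mask)
    total = float(weights.sum())
    if total <= 0:
        raise DataError(f"ROI {roi.label!r}: non-positive total weight")
    # voxel-centre convention: physical position = index * pitch (+ z0 axially)
    z = stack.z0 + (zsl.start + float(np.dot(weights, zz)) / total) * stack.dz
    y = (ysl.start + float(np.dot(weights, yy)) / total) * stack.dy
    x = (xsl.start + float(np.dot(weights, xx)) / total) * stack.dx

    # truncation check: above-threshold mass in the first/last ROI frame
    nz_roi = zsl.stop - zsl.start
    edge_mass = float(weights[(zz == 0) | (zz == nz_roi - 1)].sum())
    if edge_mass > TRUNCATION_MASS_FRACTION * total:
        flags.append("possibly_truncated")

    return Centroid(
        x=x, y=y, z=z, channel_id=stack.channel_id, total_weight=total, flags=tuple(flags)
    )


def measure_sample(
    stack: MultiChannelStack,
    roi: BeadROI,
    source: str = "bead",
    k_sigma: float = 10.0,
    threshold_before_filter: bool = False,
) -> AberrationSample:
    """Per-channel centroid shifts of one object relative to the reference."""
    ref = compute_centroid(
        stack.reference, roi, k_sigma=k_sigma, threshold_before_filter=threshold_before_filter
    )
    shifts: dict[str, tuple[float, float, float]] = {}
    weights: dict[str, float] = {}
    flags: list[str] = [f"{stack.reference_channel}:{f}" for f in ref.flags]
    for chan in stack.channels:
        if chan.channel_id == stack.reference_channel:
            shifts[chan.channel_id] = (0.0, 0.0, 0.0)
            weights[chan.channel_id] = ref.total_weight
            continue
        c = compute_centroid(
            chan, roi, k_sigma=k_sigma, threshold_before_filter=threshold_before_filter
        )
        shifts[chan.channel_id] = (c.x - ref.x, c.y - ref.y, c.z - ref.z)
        weights[chan.channel_id] = c.total_weight
        flags.extend(f"{chan.channel_id}:{f}" for f in c.flags)
    return AberrationSample(
        label=roi.label,
        depth=ref.z,
        shifts=shifts,
        source=source,
        flags=tuple(flags),
        total_weights=weights,
    )


def measure_batch(
    stack: MultiChannelStack,
    rois: list[BeadROI],
    source: str = "bead",
    k_sigma: float = 10.0,
    threshold_before_filter: bool = False,
) -> tuple[list[AberrationSample], list[tuple[str, str]]]:
    """Map :func:`measure_sample` over ROIs, collecting per-ROI failures.

    Returns ``(samples, failures)`` where failures are ``(label, reason)``
    pairs; a failing ROI never aborts the batch.
    """
    samples: list[AberrationSample] = []
    failures: list[tuple[str, str]] = []
    for roi in rois:
        try:
            samples.append(
                measure_sample(
                    stack, roi, source=source, k_sigma=k_sigma,
                    threshold_before_filter=threshold_before_filter,
                )
            )
        except DataError as exc:
            failures.append((roi.label, str(exc)))
            logger.warning("sample %r rejected: %s", roi.label, exc)
    if not samples:
        logger.warning("measure_batch: no sample succeeded (%d failures)", len(failures))
    return samples, failures


def samples_to_frame(samples: list[AberrationSample]) -> pd.DataFrame:
    """Tidy table: one row per sample x channel pair (reference rows included)."""
    rows = []
    for s in samples:
        for chan, (dx, dy, dz) in s.shifts.items():
            rows.append(
                {
                    "label": s.label,
                    "source": s.source,
                    "depth_um": s.depth,
                    "channel": chan,
                    "dx_um": dx,
                    "dy_um": dy,
                    "dz_um": dz,
                    "total_weight": s.total_weights.get(chan, np.nan),
                    "flags": ";".join(f for f in s.flags if f.startswith(f"{chan}:")),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "label", "source", "depth_um", "channel",
            "dx_um", "dy_um", "dz_um", "total_weight", "flags",
        ],
    )


def samples_from_frame(df: pd.DataFrame, reference_channel: str) -> list[AberrationSample]:
    """Inverse of :func:`samples_to_frame` (flags and weights are best-effort)."""
    required = {"label", "depth_um", "channel", "dx_um", "dy_um", "dz_um"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"samples table missing columns {sorted(missing)}")
    samples = []
    for label, grp in df.groupby("label", sort=False):
        depth = float(grp["depth_um"].iloc[0])
        shifts = {
            str(r["channel"]): (float(r["dx_um"]), float(r["dy_um"]), float(r["dz_um"]))
            for _, r in grp.iterrows()
        }
        shifts.setdefault(reference_channel, (0.0, 0.0, 0.0))
        source = str(grp["source"].iloc[0]) if "source" in grp.columns else "bead"
        samples.append(
            AberrationSample(label=str(label), depth=depth, shifts=shifts, source=source)
        )
    return samples
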