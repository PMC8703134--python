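"""Axial correction by z-frame reassignment.

The measured relation between depth d and the axial shift of a target
channel is Δz = a·d + b, i.e. an object at true depth d appears in the
target channel at stage position z = d + a·d + b.  Inverting exactly,

    z_c = (z − b) / (1 + a)

is the true depth whose image content the target frame acquired at stage
position z actually holds.  Correction then rebuilds each non-reference
channel frame-by-frame: reference frame n (at stage position z_ref[n]) takes
the target frame m whose corrected position z_c[m] is nearest z_ref[n].  As
the aberration varies with depth, some target frames are duplicated and
others deleted; content is never interpolated along z by default (nearest
frame only), and x–y content is untouched.

Reference frames whose nearest corrected position is farther than one frame
spacing are flagged "extrapolated" and clamped to the nearest existing frame
(duplication at the stack edge), never blanked.  Ties break toward the
smaller frame index, deterministically.

A first-order variant z_c = z − (a·z + b) is available for comparison; it
differs from the exact inverse by O(a²·z), negligible at realistic slopes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .errors import DataError, ModelInsufficientError
from .model import AxialRegression, CalibrationModel
from .stacks import MultiChannelStack

__all__ = ["FrameMap", "corrected_z", "assign_frames", "apply_correction"]

logger = logging.getLogger(__name__)

_DEGENERATE_SLOPE_TOL = 1e-6


@dataclass(frozen=True)
class FrameMap:
    """For each reference frame index n, the source frame m(n) replacing it."""

    target_channel: str
    assignment: np.ndarray  # int array, len == reference frame count
    duplicated: int  # source frames used more than once
    deleted: int  # source frames never used
    extrapolated: tuple[int, ...] = ()  # reference frames beyond the corrected range


def corrected_z(z, reg: AxialRegression | tuple[float, float], first_order: bool = False):
    """Corrected z position(s): the reference depth a target frame's content holds.

    ``reg`` may be an :class:`AxialRegression` or a plain ``(slope,
    intercept)`` pair.  Exact inverse by default; ``first_order=True`` uses
    z − (a·z + b) instead.
    """
    if isinstance(reg, AxialRegression):
        a, b = reg.slope, reg.intercept
    else:
        a, b = reg
    if abs(1.0 + a) < _DEGENERATE_SLOPE_TOL:
        raise DataError(f"degenerate model: |1 + slope| = {abs(1.0 + a):g} < {_DEGENERATE_SLOPE_TOL}")
    z = np.asarray(z, dtype=float)
    out = z - (a * z + b) if first_order else (z - b) / (1.0 + a)
    return float(out) if out.ndim == 0 else out


def assign_frames(
    ref_positions,
    corrected_positions,
    target_channel: str = "",
) -> FrameMap:
    """Nearest-corrected-position frame assignment.

    ``m(n) = argmin_m |corrected_positions[m] − ref_positions[n]|`` with ties
    broken toward the smaller index.  Both position lists must be non-empty
    and strictly monotone in frame index.
    """
    ref = np.asarray(ref_positions, dtype=float)
    cor = np.asarray(corrected_positions, dtype=float)
    if ref.size == 0 or cor.size == 0:
        raise DataError("assign_frames: empty position list")
    for name, arr in (("reference", ref), ("corrected", cor)):
        if arr.size > 1:
            d = np.diff(arr)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise DataError(f"assign_frames: {name} positions are not strictly monotone")
    dist = np.abs(cor[np.newaxis, :] - ref[:, np.newaxis])
    assignment = np.argmin(dist, axis=1)  # argmin returns the first (smallest) index on ties
    min_dist = dist[np.arange(ref.size), assignment]
    spacing = float(np.median(np.abs(np.diff(ref)))) if ref.size > 1 else np.inf
    extrapolated = tuple(int(i) for i in np.nonzero(min_dist > spacing)[0])
    used, counts = np.unique(assignment, return_counts=True)
    duplicated = int((counts > 1).sum())
    deleted = int(cor.size - used.size)
    if extrapolated:
        logger.warning(
            "assign_frames%s: %d reference frame(s) beyond the corrected range, clamped",
            f" [{target_channel}]" if target_channel else "", len(extrapolated),
        )
    return FrameMap(
        target_channel=target_channel,
        assignment=assignment,
        duplicated=duplicated,
        deleted=deleted,
        extrapolated=extrapolated,
    )


def apply_correction(
    stack: MultiChannelStack,
    model: CalibrationModel,
    force: bool = False,
    first_order: bool = False,
) -> tuple[MultiChannelStack, dict]:
    """Rebuild every non-reference channel by nearest-frame reassignment.

    The reference channel is copied unchanged; each target channel's frames
    are reordered (with duplication/deletion) according to its
    :class:`FrameMap`.  Output dimensions always equal input dimensions.
    Raises :class:`ModelInsufficientError` if any needed regression failed
    the power gate and ``force`` is False.

    Returns the corrected stack and a per-channel report.
    """
    if stack.reference_channel != model.reference_channel:
        raise DataError(
            f"stack reference {stack.reference_channel!r} != model reference "
            f"{model.reference_channel!r}"
        )
    targets = [c for c in stack.channel_ids if c != stack.reference_channel]
    missing = [c for c in targets if c not in model.regressions]
    if missing:
        raise DataError(f"model has no regression for channel(s) {missing}")
    weak = [c for c in targets if model.regressions[c].power < model.power_threshold]
    if weak and not force:
        raise ModelInsufficientError(
            f"regression(s) for channel(s) {weak} fall below the power gate "
            f"({model.power_threshold}); pass force=True / --force to apply anyway"
        )
    if weak:
        logger.warning("applying insufficient-power model to channel(s) %s (forced)", weak)

    ref_positions = stack.reference.frame_positions()
    new_channels = []
    report: dict = {"reference_channel": stack.reference_channel, "channels": {}}
    for chan in stack.channels:
        if chan.channel_id == stack.reference_channel:
            new_channels.append(chan)
            continue
        reg = model.regressions[chan.channel_id]
        zc = corrected_z(chan.frame_positions(), reg, first_order=first_order)
        fmap = assign_frames(ref_positions, zc, target_channel=chan.channel_id)
        new_voxels = chan.voxels[fmap.assignment]
        new_channels.append(replace(chan, voxels=new_voxels))
        report["channels"][chan.channel_id] = {
            "slope": reg.slope,
            "intercept": reg.intercept,
            "power": reg.power,
            "n_frames": int(chan.nz),
            "frames_duplicated": fmap.duplicated,
            "frames_deleted": fmap.deleted,
            "frames_extrapolated": list(fmap.extrapolated),
            "first_order": first_order,
        }
    corrected = replace(stack, channels=tuple(new_channels))
    return corrected, report
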