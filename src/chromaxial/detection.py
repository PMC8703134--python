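"""Automatic bead detection in calibration stacks.

Bead slabs for chromatic-aberration calibration are sparse bright blobs on a
dark background, so a global intensity threshold followed by 3D connected-
component labeling is sufficient.  The stack is binarized at
``mean + k_sigma * SD`` of all voxel intensities (whole-stack statistics:
bead slabs are statistically homogeneous in depth), components are labeled
with 26-connectivity, filtered by voxel count, and each survivor's padded
bounding box becomes a candidate ROI.

Two rejection rules keep the "one bead per ROI" contract that the centroid
measurement depends on, at the cost of discarding some detections:

* a padded box that overlaps any *other* component is dropped (the second
  object would bias the centre of mass);
* a padded box that would extend past the volume border is dropped (a
  truncated bead has a biased centroid).

Both rejection counts are logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .errors import DataError
from .stacks import BeadROI, ChannelStack

__all__ = ["DetectionParams", "detect_beads"]

logger = logging.getLogger(__name__)

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class DetectionParams:
    """Tunable parameters for :func:`detect_beads`.

    ``k_sigma`` is the threshold multiplier over the whole-stack intensity SD;
    ``min_voxels``/``max_voxels`` bound the accepted component size;
    ``margin_xy``/``margin_z`` pad each component's bounding box (voxels).
    The padding should exceed the largest inter-channel shift expected within
    one ROI, since detection runs on the reference channel only and the same
    boxes are reused for every channel.
    """

    k_sigma: float = 10.0
    min_voxels: int = 5
    max_voxels: int = 100_000
    margin_xy: int = 2
    margin_z: int = 2

    def __post_init__(self) -> None:
        if not self.k_sigma > 0:
            raise DataError(f"k_sigma must be > 0, got {self.k_sigma}")
        if not (0 < self.min_voxels <= self.max_voxels):
            raise DataError(
                f"need 0 < min_voxels <= max_voxels, got {self.min_voxels}, {self.max_voxels}"
            )
        if self.margin_xy < 0 or self.margin_z < 0:
            raise DataError("margins must be >= 0")


def detect_beads(stack: ChannelStack, params: DetectionParams | None = None) -> list[BeadROI]:
    """Propose single-bead ROIs from a bead calibration stack.

    Returns a (possibly empty) list of pairwise-disjoint :class:`BeadROI`,
    each containing exactly one above-threshold component of size within
    ``[min_voxels, max_voxels]``.  Raises :class:`DataError` on an
    all-constant stack (SD = 0, no threshold exists).
    """
    params = params or DetectionParams()
    v = stack.voxels
    mean = float(v.mean())
    sd = float(v.std())
    if sd == 0:
        raise DataError("constant stack: intensity SD is zero, cannot threshold")
    mask = v > mean + params.k_sigma * sd
    labels, n_components = ndimage.label(mask, structure=_STRUCT_26)
    if n_components == 0:
        logger.info("detect_beads: no above-threshold components")
        return []
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n_components + 1))
    objects = ndimage.find_objects(labels)

    nz, ny, nx = v.shape
    candidates: list[tuple[int, BeadROI]] = []
    n_size_rejected = n_border = n_overlap = 0
    for lab, (size, slc) in enumerate(zip(sizes, objects), start=1):
        if not (params.min_voxels <= size <= params.max_voxels):
            n_size_rejected += 1
            continue
        zsl, ysl, xsl = slc
        z0, z1 = zsl.start - params.margin_z, zsl.stop + params.margin_z
        y0, y1 = ysl.start - params.margin_xy, ysl.stop + params.margin_xy
        x0, x1 = xsl.start - params.margin_xy, xsl.stop + params.margin_xy
        if z0 < 0 or y0 < 0 or x0 < 0 or z1 > nz or y1 > ny or x1 > nx:
            n_border += 1
            continue
        box = labels[z0:z1, y0:y1, x0:x1]
        if np.any((box != 0) & (box != lab)):
            n_overlap += 1
            continue
        candidates.append(
            (lab, BeadROI(x_min=x0, x_max=x1, y_min=y0, y_max=y1, z_min=z0, z_max=z1))
        )

    # enforce pairwise-disjoint boxes: drop every ROI involved in a box overlap
    def boxes_overlap(a: BeadROI, b: BeadROI) -> bool:
        return (
            a.x_min < b.x_max and b.x_min < a.x_max
            and a.y_min < b.y_max and b.y_min < a.y_max
            and a.z_min < b.z_max and b.z_min < a.z_max  # type: ignore[operator]
        )

    clashing: set[int] = set()
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            if boxes_overlap(candidates[i][1], candidates[j][1]):
                clashing.update((i, j))
    n_overlap += len(clashing)

    kept = [roi for i, (_, roi) in enumerate(candidates) if i not in clashing]
    rois = [replace(roi, label=f"bead_{k:03d}") for k, roi in enumerate(kept, start=1)]
    logger.info(
        "detect_beads: %d components, %d accepted (%d size-rejected, "
        "%d border-rejected, %d overlap-rejected)",
        n_components, len(rois), n_size_rejected, n_border, n_overlap,
    )
    if not rois:
        logger.warning("detect_beads: no ROIs survived filtering")
    return rois
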