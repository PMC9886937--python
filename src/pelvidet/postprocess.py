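"""Rule-based false-positive filters applied to raw detections.

Two FP families survive a regional detector trained inside the expanded
clinical target volume (CTV):

* boxes near the outer boundary of the 10-pixel expansion zone — dealt
  with by the spatial filter: a box is kept only if it overlaps the CTV
  dilated by tau4 pixels (tau4 tuned over 1..10);
* bright vascular/bowel structures — dealt with by the HU filter: the
  tau6 nearest-rank quantile of all HU values inside the box is
  computed, and the box is removed when that quantile exceeds tau5 HU
  (tau5 tuned over {80, 100, 120, 140, 160}; contrast-enhanced vessels
  sit well above soft-tissue nodes).

Both filters are contractions (output is a subset of the input, order
preserved) and idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .detector import DetectionBox
from .imaging import CTVolume, LabelVolume
from .regions import disc_footprint
from .windowing import nearest_rank_quantile

__all__ = [
    "PostprocessParams",
    "filter_expansion_zone",
    "filter_hu_quantile",
    "postprocess",
    "TAU4_RANGE",
    "TAU5_RANGE",
    "TAU6_RANGE",
]

# default tuning ranges
TAU4_RANGE = tuple(range(1, 11))
TAU5_RANGE = (80, 100, 120, 140, 160)
TAU6_RANGE = tuple(round(0.1 * k, 1) for k in range(1, 11))


@dataclass(frozen=True)
class PostprocessParams:
    """tau4: expansion-zone pixel allowance; tau5: HU cutoff; tau6: box HU quantile."""

    tau4: int = 2
    tau5: float = 160.0
    tau6: float = 0.8

    def __post_init__(self) -> None:
        if not (0 <= self.tau4 <= 10):
            raise ValueError(f"tau4 must be in [0, 10], got {self.tau4}")
        if not (0 < self.tau6 <= 1):
            raise ValueError(f"tau6 must be in (0, 1], got {self.tau6}")


def _box_pixel_slices(box: tuple, shape: tuple[int, int]) -> tuple[slice, slice]:
    """Integer pixel extent of a half-open box, clipped to the slice frame."""
    x0, y0, x1, y1 = box
    h, w = shape
    c0 = max(int(np.floor(x0)), 0)
    c1 = min(int(np.ceil(x1)), w)
    r0 = max(int(np.floor(y0)), 0)
    r1 = min(int(np.ceil(y1)), h)
    return slice(r0, r1), slice(c0, c1)


def filter_expansion_zone(
    boxes: Sequence[DetectionBox], ctv: LabelVolume, tau4: int
) -> list[DetectionBox]:
    """Drop boxes living entirely in the outer expansion ring beyond tau4.

    A box is kept iff it overlaps (by at least one pixel) the
    un-expanded CTV dilated in-plane by tau4 pixels on its slice.
    Overlap — not box-center containment — is the permissive reading and
    makes the filter monotone in tau4.
    """
    if not (0 <= tau4 <= 10):
        raise ValueError(f"tau4 must be in [0, 10], got {tau4}")
    if ctv.role != "ctv":
        raise ValueError(f"expected the un-expanded CTV contour, got role {ctv.role!r}")
    foot = disc_footprint(tau4) if tau4 > 0 else None
    dilated: dict[int, np.ndarray] = {}
    shape = ctv.mask.shape[1:]
    kept = []
    for b in boxes:
        if b.z not in dilated:
            plane = ctv.mask[b.z]
            dilated[b.z] = (
                ndimage.binary_dilation(plane, structure=foot)
                if (foot is not None and plane.any())
                else plane
            )
        rs, cs = _box_pixel_slices(b.box, shape)
        if dilated[b.z][rs, cs].any():
            kept.append(b)
    return kept


def filter_hu_quantile(
    boxes: Sequence[DetectionBox], vol: CTVolume, tau5: float, tau6: float
) -> list[DetectionBox]:
    """Drop boxes whose tau6 HU quantile exceeds tau5 (bright vessel/bowel).

    For each box, the nearest-rank tau6 quantile of the HU values of all
    pixels inside the box on its slice is compared against tau5; strict
    inequality (q > tau5) removes the box, equality keeps it.
    """
    if not (0 < tau6 <= 1):
        raise ValueError(f"tau6 must be in (0, 1], got {tau6}")
    shape = vol.shape[1:]
    kept = []
    for b in boxes:
        rs, cs = _box_pixel_slices(b.box, shape)
        pixels = vol.voxels[b.z][rs, cs]
        if pixels.size == 0:
            raise ValueError(f"box {b.box} has no pixels inside the volume frame")
        q = nearest_rank_quantile(pixels, tau6)
        if not q > tau5:
            kept.append(b)
    return kept


def postprocess(
    boxes: Sequence[DetectionBox],
    ctv: LabelVolume,
    vol: CTVolume,
    params: PostprocessParams,
) -> list[DetectionBox]:
    """Both FP filters in sequence: spatial (tau4) then HU (tau5, tau6).

    The spatial test is the cheaper one so it runs first; on detections
    whose FP causes are disjoint the two orders give identical survivor
    sets anyway.
    """
    survivors = filter_expansion_zone(boxes, ctv, params.tau4)
    return filter_hu_quantile(survivors, vol, params.tau5, params.tau6)
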