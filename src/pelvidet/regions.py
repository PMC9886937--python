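"""Region preparation: the two preprocessing paths feeding the detector.

Whole-slice images keep the full field of view and only drop the black
(air) border; regional images zero everything outside the expanded
clinical target volume (CTV) and crop to its bounding box, so the
detector only ever sees the at-risk nodal region.  The CTV is expanded
isotropically in-plane by a pixel radius (default 10 px = 6.48 mm at the
default 0.648 mm pixels) because boundary nodes can fall a pixel or two
outside the RTOG contour.

Augmentation is seeded and applies geometric transforms identically to
image and ground-truth boxes; it is a training-time step only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .imaging import CTVolume, LabelVolume, Slice25D

__all__ = [
    "AugmentParams",
    "EmptyRegionError",
    "expand_mask",
    "mask_and_crop",
    "crop_black_border",
    "augment",
    "disc_footprint",
]

#: HU at or below which a pixel counts as air/black border.
AIR_THRESHOLD_HU = -1000.0


class EmptyRegionError(ValueError):
    """The expanded CTV has no pixels on the requested slice; skip it."""


def disc_footprint(radius: int) -> np.ndarray:
    """Binary Euclidean disc {(dy,dx): dy^2+dx^2 <= radius^2}."""
    if radius < 0:
        raise ValueError(f"radius must be >= 0, got {radius}")
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= r * r


def expand_mask(ctv: LabelVolume, k_px: int) -> LabelVolume:
    """Isotropically expand a CTV mask in-plane by ``k_px`` pixels.

    Each axial slice is dilated with a Euclidean disc of radius k_px
    (the expansion is pixel-unit and in-plane: the quoted physical
    length, 10 px = 6.48 mm, is an in-plane distance).  k_px=0 is the
    identity.
    """
    if k_px < 0:
        raise ValueError(f"expansion radius must be >= 0, got {k_px}")
    if k_px == 0:
        out = ctv.mask.copy()
    else:
        foot = disc_footprint(k_px)
        out = np.zeros_like(ctv.mask)
        for z in range(ctv.mask.shape[0]):
            if ctv.mask[z].any():
                out[z] = ndimage.binary_dilation(ctv.mask[z], structure=foot)
    return LabelVolume(mask=out.astype(np.uint8), role="ctv_expanded", frame=ctv.frame)


def mask_and_crop(slice25d: Slice25D, expanded: LabelVolume) -> Slice25D:
    """Zero pixels outside the expanded CTV and crop to its bounding box.

    The central slice's expanded-CTV mask is applied to all three
    channels, the image is cropped to the mask's tight bounding box, and
    ``crop_offset`` records the crop origin so detection boxes can be
    mapped back to volume coordinates.

    Raises :class:`EmptyRegionError` when the mask is empty on the
    central slice — the caller is expected to skip that slice.
    """
    z = slice25d.center_index
    plane = expanded.mask[z]
    if not plane.any():
        raise EmptyRegionError(f"expanded CTV empty on slice {z}")
    r0, c0 = slice25d.crop_offset
    h, w = slice25d.channels.shape[1:]
    sub = plane[r0 : r0 + h, c0 : c0 + w]
    rows = np.flatnonzero(sub.any(axis=1))
    cols = np.flatnonzero(sub.any(axis=0))
    if rows.size == 0:
        raise EmptyRegionError(f"expanded CTV does not intersect the image on slice {z}")
    rlo, rhi = rows[0], rows[-1] + 1
    clo, chi = cols[0], cols[-1] + 1
    channels = slice25d.channels[:, rlo:rhi, clo:chi] * sub[rlo:rhi, clo:chi]
    return Slice25D(
        channels=channels,
        center_index=z,
        crop_offset=(r0 + int(rlo), c0 + int(clo)),
    )


def crop_black_border(slice25d: Slice25D) -> Slice25D:
    """Strip the maximal all-air margin shared by the three channels.

    Rows/columns where every channel is at or below the air threshold
    (-1000 HU) on all pixels are removed from the outside in; the crop
    offset is updated accordingly.  Idempotent.  A fully black image is
    returned unchanged with a ``"all_black"`` flag.
    """
    body = (slice25d.channels > AIR_THRESHOLD_HU).any(axis=0)
    rows = np.flatnonzero(body.any(axis=1))
    cols = np.flatnonzero(body.any(axis=0))
    if rows.size == 0:
        out = Slice25D(
            channels=slice25d.channels.copy(),
            center_index=slice25d.center_index,
            crop_offset=slice25d.crop_offset,
        )
        out.flags.add("all_black")
        return out
    rlo, rhi = rows[0], rows[-1] + 1
    clo, chi = cols[0], cols[-1] + 1
    r0, c0 = slice25d.crop_offset
    return Slice25D(
        channels=slice25d.channels[:, rlo:rhi, clo:chi],
        center_index=slice25d.center_index,
        crop_offset=(r0 + int(rlo), c0 + int(clo)),
    )


@dataclass(frozen=True)
class AugmentParams:
    """Training-time augmentation settings.

    Geometry: the longest side is resized to a random target in
    [resize_min, resize_max] pixels, the image is horizontally flipped
    with probability hflip_p, and rotated by a random angle in
    [0, rotate_max_deg].  Texture: correlated Gaussian noise (smoothed
    with a noise_kernel-wide Gaussian of sigma noise_sigma) and a
    multiplicative brightness factor in [1-brightness_delta_max,
    1+brightness_delta_max] are applied to the image only.  Everything
    is driven by ``seed``.
    """

    resize_min: int = 640
    resize_max: int = 800
    hflip_p: float = 0.5
    rotate_max_deg: float = 180.0
    noise_kernel: int = 5
    noise_sigma: float = 1.0
    noise_amp: float = 0.02
    brightness_delta_max: float = 0.1
    fill_value: float = 0.0  # outside-frame fill; 0 for post-window images, -1024 pre-window
    seed: int = 0

    def __post_init__(self) -> None:
        if self.resize_min > self.resize_max:
            raise ValueError("resize_min must be <= resize_max")
        if not (0 <= self.hflip_p <= 1):
            raise ValueError("hflip_p must be a probability")


def _rotate_point(x: float, y: float, cx: float, cy: float, rad: float) -> tuple[float, float]:
    # forward map of skimage.transform.rotate: output = c + R(-rad) (p - c)
    dx, dy = x - cx, y - cy
    c, s = np.cos(rad), np.sin(rad)
    return cx + c * dx + s * dy, cy - s * dx + c * dy


def _transform_boxes_rotate(boxes: np.ndarray, shape: tuple[int, int], angle_deg: float) -> np.ndarray:
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    rad = np.deg2rad(angle_deg)
    out = np.empty_like(boxes, dtype=float)
    for i, (x0, y0, x1, y1) in enumerate(boxes):
        corners = [(x0, y0), (x1, y0), (x0, y1), (x1, y1)]
        pts = [_rotate_point(x, y, cx, cy, rad) for x, y in corners]
        xs = [p[0] for p in pts]
        ys = [p[1] for p in pts]
        out[i] = (min(xs), min(ys), max(xs), max(ys))
    return out


def augment(
    slice25d: Slice25D,
    boxes: np.ndarray,
    params: AugmentParams,
) -> tuple[Slice25D, np.ndarray]:
    """Apply seeded augmentation to an image and its ground-truth boxes.

    Geometric transforms (resize, horizontal flip, rotation) are applied
    identically to the image and the boxes; texture transforms (noise,
    brightness) touch the image only.  Deterministic for a given seed.
    """
    from skimage.transform import resize as sk_resize, rotate as sk_rotate

    rng = np.random.default_rng(params.seed)
    channels = slice25d.channels.astype(float)
    boxes = np.asarray(boxes, dtype=float).reshape(-1, 4).copy()
    h, w = channels.shape[1:]

    # random resize of the longest side
    target = int(rng.integers(params.resize_min, params.resize_max + 1))
    scale = target / max(h, w)
    nh, nw = max(1, round(h * scale)), max(1, round(w * scale))
    channels = np.stack(
        [
            sk_resize(ch, (nh, nw), order=1, preserve_range=True, anti_aliasing=False)
            for ch in channels
        ]
    )
    boxes *= scale
    h, w = nh, nw

    # horizontal flip
    if rng.random() < params.hflip_p:
        channels = channels[:, :, ::-1].copy()
        boxes = np.column_stack([w - boxes[:, 2], boxes[:, 1], w - boxes[:, 0], boxes[:, 3]])

    # rotation about the image center, bilinear, constant fill
    angle = float(rng.uniform(0.0, params.rotate_max_deg))
    channels = np.stack(
        [
            sk_rotate(ch, angle, resize=False, order=1, preserve_range=True,
                      cval=params.fill_value, mode="constant")
            for ch in channels
        ]
    )
    if boxes.size:
        boxes = _transform_boxes_rotate(boxes, (h, w), angle)

    # correlated gaussian noise: white noise smoothed by a small kernel
    noise = rng.normal(0.0, 1.0, size=channels.shape[1:])
    truncate = ((params.noise_kernel - 1) / 2.0) / params.noise_sigma
    noise = ndimage.gaussian_filter(noise, sigma=params.noise_sigma, truncate=truncate)
    channels = channels + params.noise_amp * noise

    # multiplicative brightness jitter
    factor = float(rng.uniform(1 - params.brightness_delta_max, 1 + params.brightness_delta_max))
    channels = channels * factor

    out = Slice25D(
        channels=channels,
        center_index=slice25d.center_index,
        crop_offset=slice25d.crop_offset,
    )
    return out, boxes
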