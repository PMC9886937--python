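"""Volumes, masks, 2.5D slice stacks and ground-truth node instances.

Everything downstream shares one voxel frame: arrays are indexed
``(z, y, x)`` (axial slice, row, column) and in-plane boxes are
``(x0, y0, x1, y1)``, 0-based and half-open, so a box covers the pixel
rectangle ``[x0, x1) x [y0, y1)`` on its slice.

CT intensities are Hounsfield units (HU): air is -1024, water 0,
contrast-enhanced vessels are bright (a few hundred HU).  DICOM series
are converted on load via the standard rescale transform
``HU = slope * stored + intercept``; NIfTI volumes are assumed to be in
HU already.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy import ndimage

__all__ = [
    "CTVolume",
    "LabelVolume",
    "Slice25D",
    "NodeInstance",
    "hu_transform",
    "load_volume",
    "load_mask",
    "save_mask",
    "stack_25d",
    "nodes_from_mask",
]

MASK_ROLES = ("ctv", "ctv_expanded", "node_gt", "vessel")


@dataclass(frozen=True)
class CTVolume:
    """A 3D grid of Hounsfield units with per-axis spacing in mm."""

    voxels: np.ndarray  # (z, y, x), float HU
    spacing: tuple[float, float, float]  # (z, y, x) mm

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        if vox.ndim != 3 or min(vox.shape) < 1:
            raise ValueError(f"voxels must be a 3D array, got shape {vox.shape}")
        if not np.all(np.isfinite(vox)):
            raise ValueError("HU values must be finite")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def n_rows(self) -> int:
        return self.voxels.shape[1]

    @property
    def n_cols(self) -> int:
        return self.voxels.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class LabelVolume:
    """A binary mask sharing a CTVolume's voxel frame.

    ``role`` says what the mask delineates: the clinical target volume
    (``ctv``), its expanded search region (``ctv_expanded``), the
    ground-truth metastatic nodes (``node_gt``), or vessel/bowel
    confounders (``vessel``).
    """

    mask: np.ndarray
    role: str
    frame: CTVolume

    def __post_init__(self) -> None:
        if self.role not in MASK_ROLES:
            raise ValueError(f"role must be one of {MASK_ROLES}, got {self.role!r}")
        mask = np.asarray(self.mask)
        if mask.shape != self.frame.shape:
            raise ValueError(
                f"mask shape {mask.shape} does not match volume shape {self.frame.shape}"
            )
        uniq = np.unique(mask)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be binary (0/1)")
        object.__setattr__(self, "mask", mask.astype(bool))


@dataclass
class Slice25D:
    """Three stacked axial slices (z-1, z, z+1) around a center slice.

    ``crop_offset`` records the (row, col) origin of this image within
    the full slice so detections can be mapped back to volume
    coordinates; it is (0, 0) while uncropped.
    """

    channels: np.ndarray  # (3, H, W)
    center_index: int
    crop_offset: tuple[int, int] = (0, 0)
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        ch = np.asarray(self.channels, dtype=float)
        if ch.ndim != 3 or ch.shape[0] != 3:
            raise ValueError(f"channels must be (3, H, W), got {ch.shape}")
        self.channels = ch
        self.crop_offset = (int(self.crop_offset[0]), int(self.crop_offset[1]))


@dataclass(frozen=True)
class NodeInstance:
    """One 3D connected component of the ground-truth node mask.

    A node is the unit of sensitivity: detecting any single slice of it
    counts the whole metastasis as a hit.  ``slice_boxes`` maps each
    slice index to the tight in-plane bounding box of the node's voxels
    on that slice.
    """

    node_id: int
    voxel_set: frozenset  # of (z, y, x)
    slice_boxes: dict  # z -> (x0, y0, x1, y1), half-open

    def slices(self) -> list[int]:
        return sorted(self.slice_boxes)


def hu_transform(stored: np.ndarray, slope: float, intercept: float) -> np.ndarray:
    """Apply the DICOM rescale transform ``HU = slope * stored + intercept``."""
    if not (np.isfinite(slope) and np.isfinite(intercept)):
        raise ValueError("rescale slope and intercept must be finite")
    if slope == 0:
        raise ValueError("rescale slope must be nonzero")
    return np.asarray(stored, dtype=float) * float(slope) + float(intercept)


def stack_25d(vol: CTVolume, z: int, crop_offset: tuple[int, int] = (0, 0)) -> Slice25D:
    """Build the 2.5D channel stack (z-1, z, z+1) around slice ``z``.

    At the volume ends the missing neighbour is replaced by a copy of
    the edge slice, so every slice of the volume yields a valid stack.
    """
    if not (0 <= z < vol.n_slices):
        raise IndexError(f"slice index {z} out of range [0, {vol.n_slices})")
    lo = max(z - 1, 0)
    hi = min(z + 1, vol.n_slices - 1)
    channels = np.stack([vol.voxels[lo], vol.voxels[z], vol.voxels[hi]])
    return Slice25D(channels=channels, center_index=z, crop_offset=crop_offset)


_CONN26 = np.ones((3, 3, 3), dtype=bool)


def nodes_from_mask(gt: LabelVolume) -> list[NodeInstance]:
    """Decompose a ground-truth node mask into NodeInstances.

    Components are 26-connected (diagonal lesion voxels belong
    together).  Instance ids are assigned by the lexicographically first
    voxel of each component in (z, y, x) order, so they are stable
    across runs.  An empty mask yields an empty list.
    """
    if gt.role != "node_gt":
        raise ValueError(f"expected a node_gt mask, got role {gt.role!r}")
    labels, n = ndimage.label(gt.mask, structure=_CONN26)
    if n == 0:
        return []
    # scipy labels in raster order, so label k's first voxel precedes
    # label k+1's; that is exactly the (z,y,x) ordering we want.
    instances = []
    objects = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        sl = objects[lab - 1]
        sub = labels[sl] == lab
        zs0 = sl[0].start
        ys0 = sl[1].start
        xs0 = sl[2].start
        voxels = frozenset(
            (int(z + zs0), int(y + ys0), int(x + xs0)) for z, y, x in np.argwhere(sub)
        )
        slice_boxes = {}
        for dz in range(sub.shape[0]):
            plane = sub[dz]
            if not plane.any():
                continue
            rows = np.flatnonzero(plane.any(axis=1))
            cols = np.flatnonzero(plane.any(axis=0))
            slice_boxes[int(dz + zs0)] = (
                int(cols[0] + xs0),
                int(rows[0] + ys0),
                int(cols[-1] + 1 + xs0),
                int(rows[-1] + 1 + ys0),
            )
        instances.append(
            NodeInstance(node_id=lab - 1, voxel_set=voxels, slice_boxes=slice_boxes)
        )
    return instances


# ---------------------------------------------------------------------------
# File I/O


def _load_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got {data.ndim}D in {path}")
    zooms = img.header.get_zooms()[:3]
    # NIfTI stores (x, y, z); our frame is (z, y, x).
    return data.transpose(2, 1, 0), (float(zooms[2]), float(zooms[1]), float(zooms[0]))


def _load_dicom_series(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ".ima", ""))
    datasets = []
    for p in files:
        if p.is_dir():
            continue
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except Exception:
            continue
    if not datasets:
        raise IOError(f"no readable DICOM files in {path}")
    orientations = {tuple(np.round(ds.ImageOrientationPatient, 4)) for ds in datasets}
    if len(orientations) > 1:
        raise ValueError(f"mixed slice orientations in DICOM series {path}")
    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zpos = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    if len(zpos) > 1:
        gaps = np.diff(zpos)
        if np.any(gaps <= 0):
            raise ValueError(f"duplicate slice positions in DICOM series {path}")
        if np.max(gaps) - np.min(gaps) > 0.01 * np.median(gaps) + 1e-6:
            raise ValueError(
                f"non-uniform slice spacing in DICOM series {path}: "
                f"gaps range {np.min(gaps):.3f}-{np.max(gaps):.3f} mm (missing slice?)"
            )
        dz = float(np.median(gaps))
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0))
    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(hu_transform(ds.pixel_array, slope, intercept))
    dy, dx = (float(v) for v in datasets[0].PixelSpacing)
    return np.stack(slices), (dz, dy, dx)


def load_volume(path: str | os.PathLike) -> CTVolume:
    """Read a CT volume from a DICOM series directory or a NIfTI file.

    DICOM pixels get the rescale slope/intercept applied so voxels come
    out in HU; NIfTI volumes are assumed to be stored in HU already.
    Series with missing slices or mixed orientations are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file or directory: {path}")
    if path.is_dir():
        voxels, spacing = _load_dicom_series(path)
    else:
        voxels, spacing = _load_nifti(path)
    return CTVolume(voxels=voxels, spacing=spacing)


def load_mask(path: str | os.PathLike, role: str, frame: CTVolume) -> LabelVolume:
    """Read a binary NIfTI mask into ``frame``'s voxel grid."""
    data, _spacing = _load_nifti(Path(path))
    return LabelVolume(mask=(data > 0.5).astype(np.uint8), role=role, frame=frame)


def save_mask(mask: LabelVolume, path: str | os.PathLike) -> None:
    """Write a binary mask as NIfTI, with spacing taken from its frame."""
    import nibabel as nib

    sz, sy, sx = mask.frame.spacing
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(mask.mask.astype(np.uint8).transpose(2, 1, 0), affine)
    nib.save(img, str(path))


def save_volume(vol: CTVolume, path: str | os.PathLike) -> None:
    """Write a CT volume as NIfTI.

    HU values are stored as float64 so a save/load round trip is
    lossless — re-running a stage from disk must reproduce the in-memory
    pipeline bit for bit.
    """
    import nibabel as nib

    sz, sy, sx = vol.spacing
    affine = np.diag([sx, sy, sz, 1.0])
    img = nib.Nifti1Image(vol.voxels.astype(np.float64).transpose(2, 1, 0), affine)
    nib.save(img, str(path))
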