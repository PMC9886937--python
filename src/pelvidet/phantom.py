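"""Synthetic pelvic CT phantoms with ground-truth masks and scripted voters.

Clinical data of this kind (contrast-enhanced pelvic CT with PSMA-PET
confirmed nodal metastases) is generally not distributable, so this module
emulates its geometry and contrast so that every pipeline stage — and
the end-to-end run — is testable:

* soft-tissue background around 20 HU with mild texture;
* ellipsoidal node lesions whose HU is Gaussian (default mean 45,
  sd 35), the soft-tissue range the quantile windows target;
* bright tubular vessel/bowel confounders (default 250 +- 40 HU, above
  every tau5 cutoff) crossing the nodal region, since contrast-enhanced
  vessels are the dominant false-positive source;
* a clinical-target-volume (CTV) envelope containing all nodes, built
  as the dilated convex hull of the node footprint;
* an air frame at -1024 HU so black-border cropping has work to do.

The default in-plane pixel spacing is 0.648 mm, so the 10 px = 6.48 mm CTV expansion
holds on fixtures.  Everything is fully
determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .detector import DetectionBox, OracleDetector, PlantedFP, FP_KINDS
from .imaging import CTVolume, LabelVolume, NodeInstance, nodes_from_mask, stack_25d

__all__ = [
    "PhantomSpec",
    "PhantomResult",
    "gen_phantom",
    "plant_false_positives",
    "gen_voter_outputs",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and contrast of a synthetic pelvic volume.

    HU defaults are chosen so the four quantile windows and the
    soft-tissue window clip the image differently (windowing matters)
    and so vessels always violate the strictest HU cutoff (tau5 = 160).
    """

    shape: tuple[int, int, int] = (20, 160, 160)
    spacing: tuple[float, float, float] = (3.0, 0.648, 0.648)
    n_nodes: int = 12
    node_radius_px: tuple[int, int] = (3, 6)  # in-plane semi-axis range
    node_radius_z: tuple[int, int] = (1, 2)  # through-plane semi-axis range (slices)
    node_hu_mean: float = 45.0
    node_hu_sd: float = 35.0
    n_vessels: int = 8
    vessel_radius_px: int = 2
    vessel_hu_mean: float = 250.0
    vessel_hu_sd: float = 40.0
    ctv_margin_px: int = 12
    background_hu_mean: float = 20.0
    background_hu_sd: float = 15.0
    noise_sd: float = 0.0
    air_margin_px: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 0 or self.n_vessels < 0:
            raise ValueError("counts must be >= 0")
        if self.node_hu_sd <= 0:
            raise ValueError("node HU sd must be > 0")
        if self.vessel_hu_mean <= 160:
            raise ValueError(
                "vessel HU mean must exceed the strictest tau5 cutoff (160) "
                "so the HU filter is exercisable"
            )

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PhantomResult:
    """A generated phantom: the CT volume plus all ground-truth masks."""

    volume: CTVolume
    ctv: LabelVolume
    node_gt: LabelVolume
    vessel: LabelVolume
    spec: PhantomSpec

    def __iter__(self):
        return iter((self.volume, self.ctv, self.node_gt, self.vessel))

    def nodes(self) -> list[NodeInstance]:
        return nodes_from_mask(self.node_gt)

    def region_slices(self) -> list[int]:
        """Slices on which the CTV exists — what the regional detector sees."""
        return [int(z) for z in np.flatnonzero(self.ctv.mask.any(axis=(1, 2)))]


def _ellipsoid_voxels(center, semi, shape) -> np.ndarray:
    cz, cy, cx = center
    rz, ry, rx = semi
    z0, z1 = max(cz - rz, 0), min(cz + rz, shape[0] - 1)
    zz, yy, xx = np.mgrid[z0 : z1 + 1, cy - ry : cy + ry + 1, cx - rx : cx + rx + 1]
    inside = ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    pts = np.column_stack([zz[inside], yy[inside], xx[inside]])
    ok = (
        (pts[:, 1] >= 0) & (pts[:, 1] < shape[1]) & (pts[:, 2] >= 0) & (pts[:, 2] < shape[2])
    )
    return pts[ok]


def gen_phantom(spec: PhantomSpec) -> PhantomResult:
    """Generate a phantom volume with CTV, node and vessel masks.

    Nodes are placed without overlap (with a 2-pixel guard band so
    distinct lesions stay distinct under 26-connectivity); vessels are
    drawn as drifting tubes through the nodal region but never closer
    than 2 pixels to a node.  The CTV is the convex envelope of the node
    footprint dilated by ``ctv_margin_px``, so nodes are inside it by
    construction; with no nodes a central fallback region is used.
    Raises if a node cannot be placed after bounded retries.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    node_mask = np.zeros(spec.shape, dtype=bool)
    guard = np.zeros(spec.shape, dtype=bool)  # nodes + 2px halo

    # --- nodes: non-overlapping ellipsoids in a central placement band
    margin = spec.air_margin_px + spec.ctv_margin_px + max(spec.node_radius_px) + 12
    lo_y, hi_y = margin, ny - margin
    lo_x, hi_x = margin, nx - margin
    if spec.n_nodes > 0 and (lo_y >= hi_y or lo_x >= hi_x):
        raise ValueError(f"phantom shape {spec.shape} too small for node placement")
    halo = np.ones((5, 5, 5), dtype=bool)
    for i in range(spec.n_nodes):
        placed = False
        for _attempt in range(200):
            rz = int(rng.integers(spec.node_radius_z[0], spec.node_radius_z[1] + 1))
            ry = int(rng.integers(spec.node_radius_px[0], spec.node_radius_px[1] + 1))
            rx = int(rng.integers(spec.node_radius_px[0], spec.node_radius_px[1] + 1))
            cz = int(rng.integers(rz + 1, nz - rz - 1))
            cy = int(rng.integers(lo_y, hi_y))
            cx = int(rng.integers(lo_x, hi_x))
            pts = _ellipsoid_voxels((cz, cy, cx), (rz, ry, rx), spec.shape)
            idx = tuple(pts.T)
            if guard[idx].any():
                continue
            node_mask[idx] = True
            new_guard = np.zeros(spec.shape, dtype=bool)
            new_guard[idx] = True
            guard |= ndimage.binary_dilation(new_guard, structure=halo)
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place node {i + 1}/{spec.n_nodes} without overlap; "
                "reduce n_nodes or enlarge the phantom"
            )

    # --- CTV: dilated convex envelope of the node footprint
    ctv_mask = np.zeros(spec.shape, dtype=bool)
    if node_mask.any():
        from skimage.morphology import convex_hull_image

        footprint = convex_hull_image(node_mask.any(axis=0))
        from .regions import disc_footprint

        base = ndimage.binary_dilation(footprint, structure=disc_footprint(spec.ctv_margin_px))
        zs = np.flatnonzero(node_mask.any(axis=(1, 2)))
        z_lo = max(int(zs[0]) - 1, 0)
        z_hi = min(int(zs[-1]) + 1, nz - 1)
        ctv_mask[z_lo : z_hi + 1] = base
    else:
        # fallback region so the pipeline has something to look at
        yy, xx = np.mgrid[0:ny, 0:nx]
        disc = (yy - ny / 2) ** 2 + (xx - nx / 2) ** 2 <= (min(ny, nx) / 5) ** 2
        ctv_mask[nz // 4 : 3 * nz // 4] = disc

    # --- vessels: drifting bright tubes crossing the CTV, clear of nodes
    vessel_mask = np.zeros(spec.shape, dtype=bool)
    if spec.n_vessels > 0:
        base2d = ctv_mask.any(axis=0)
        cand = np.argwhere(ndimage.binary_erosion(base2d, iterations=4)) if base2d.any() else None
        yy, xx = np.mgrid[-spec.vessel_radius_px : spec.vessel_radius_px + 1,
                          -spec.vessel_radius_px : spec.vessel_radius_px + 1]
        disc = (yy * yy + xx * xx) <= spec.vessel_radius_px**2
        dyy, dxx = np.nonzero(disc)
        dyy = dyy - spec.vessel_radius_px
        dxx = dxx - spec.vessel_radius_px
        for _v in range(spec.n_vessels):
            if cand is None or len(cand) == 0:
                break
            y, x = cand[int(rng.integers(len(cand)))]
            for z in range(nz):
                ys = np.clip(y + dyy, 0, ny - 1)
                xs = np.clip(x + dxx, 0, nx - 1)
                keep = ~guard[z, ys, xs]  # never within 2px of a node
                vessel_mask[z, ys[keep], xs[keep]] = True
                y = int(np.clip(y + rng.integers(-1, 2), spec.air_margin_px + 4,
                                ny - spec.air_margin_px - 5))
                x = int(np.clip(x + rng.integers(-1, 2), spec.air_margin_px + 4,
                                nx - spec.air_margin_px - 5))

    # --- assemble HU
    voxels = rng.normal(spec.background_hu_mean, spec.background_hu_sd, size=spec.shape)
    voxels[vessel_mask] = rng.normal(spec.vessel_hu_mean, spec.vessel_hu_sd,
                                     size=int(vessel_mask.sum()))
    voxels[node_mask] = rng.normal(spec.node_hu_mean, spec.node_hu_sd,
                                   size=int(node_mask.sum()))
    if spec.noise_sd > 0:
        voxels += rng.normal(0.0, spec.noise_sd, size=spec.shape)
    m = spec.air_margin_px
    if m > 0:
        voxels[:, :m, :] = -1024.0
        voxels[:, -m:, :] = -1024.0
        voxels[:, :, :m] = -1024.0
        voxels[:, :, -m:] = -1024.0

    vol = CTVolume(voxels=voxels, spacing=spec.spacing)
    return PhantomResult(
        volume=vol,
        ctv=LabelVolume(mask=ctv_mask.astype(np.uint8), role="ctv", frame=vol),
        node_gt=LabelVolume(mask=node_mask.astype(np.uint8), role="node_gt", frame=vol),
        vessel=LabelVolume(mask=vessel_mask.astype(np.uint8), role="vessel", frame=vol),
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Planted false positives, one family per post-processing rule


_FP_HALF = 3  # planted FP boxes are 6x6 pixels


def plant_false_positives(
    phantom: PhantomResult,
    counts: Mapping[str, int],
    seed: int = 0,
) -> list[PlantedFP]:
    """Plant cause-labelled false-positive boxes on the phantom.

    * ``expansion_ring`` — 6x6 boxes centered 7-9 px outside the CTV:
      inside the 10-px search expansion but clear of the CTV dilated by
      any tau4 <= 2, so the spatial filter removes them.
    * ``vessel`` — 6x6 boxes over vessel cross-sections inside the CTV
      (>= 30% bright pixels), so the HU-quantile filter removes them at
      (tau5=160, tau6=0.8) while the spatial filter keeps them.
    * ``random_tissue`` — 6x6 soft-tissue boxes inside the CTV away
      from nodes and vessels; both rule filters keep them, only ensemble
      voting can reject them.

    Raises when a requested kind has no valid placement sites.
    """
    for kind in counts:
        if kind not in FP_KINDS:
            raise ValueError(f"unknown FP kind {kind!r}; known: {FP_KINDS}")
    rng = np.random.default_rng(seed)
    nz, ny, nx = phantom.volume.shape
    zs = phantom.region_slices()
    if not zs:
        raise ValueError("phantom has no CTV slices to plant FPs on")
    ctv = phantom.ctv.mask
    node_halo = ndimage.binary_dilation(phantom.node_gt.mask, structure=np.ones((3, 3, 3)))
    h = _FP_HALF
    out: list[PlantedFP] = []

    def box_at(y: int, x: int) -> tuple:
        return (float(x - h), float(y - h), float(x + h), float(y + h))

    def in_frame(y: int, x: int) -> bool:
        return h <= y < ny - h and h <= x < nx - h

    for kind in ("expansion_ring", "vessel", "random_tissue"):
        need = int(counts.get(kind, 0))
        if need == 0:
            continue
        placed = 0
        attempts = 0
        while placed < need:
            attempts += 1
            if attempts > 200 * need:
                raise RuntimeError(f"could not place {need} {kind!r} FPs on this phantom")
            z = int(zs[rng.integers(len(zs))])
            plane = ctv[z]
            if kind == "expansion_ring":
                dist = ndimage.distance_transform_edt(~plane)
                sites = np.argwhere((dist >= 7) & (dist <= 9))
            elif kind == "vessel":
                sites = np.argwhere(phantom.vessel.mask[z] & plane)
            else:
                interior = ndimage.binary_erosion(plane, iterations=h + 1) if plane.any() else plane
                sites = np.argwhere(interior)
            if len(sites) == 0:
                continue
            y, x = (int(v) for v in sites[rng.integers(len(sites))])
            if not in_frame(y, x):
                continue
            rs, cs = slice(y - h, y + h), slice(x - h, x + h)
            if node_halo[z, rs, cs].any():
                continue
            if kind == "vessel":
                bright = phantom.vessel.mask[z, rs, cs].mean()
                if bright < 0.30:
                    continue
            if kind == "random_tissue" and phantom.vessel.mask[z, rs, cs].any():
                continue
            out.append(PlantedFP(z=z, box=box_at(y, x), kind=kind))
            placed += 1
    return out


def gen_voter_outputs(
    phantom: PhantomResult,
    windows: Sequence[str],
    hit_prob: float = 1.0,
    shared_fp_counts: Mapping[str, int] | None = None,
    unique_fp_counts: Mapping[str, int] | None = None,
    shared_groups: Sequence[tuple[str, int, Sequence[str]]] = (),
    jitter_px: int = 0,
    seed: int = 0,
    return_planted: bool = False,
):
    """Scripted per-window voter detections for bagging and pipeline tests.

    All voters see the same slice set (the windows, not the data, are
    what differ between voters — no bootstrap).  ``shared_fp_counts``
    plants one FP set emitted by *every* voter (survives any voting rule
    — the dedicated target of the rule-based filters);
    ``unique_fp_counts`` plants an independent set per voter (removed by
    the minimum-voter rule); ``shared_groups`` entries
    ``(kind, count, voter_ids)`` plant FPs shared by a chosen subset of
    voters.  Warns when the voter count falls outside the
    tau2 tuning range 1-5.
    """
    if not windows:
        raise ValueError("at least one window voter is required")
    if not (1 <= len(windows) <= 5):
        import warnings

        warnings.warn(
            f"{len(windows)} voters is outside the tau2 tuning range 1-5",
            stacklevel=2,
        )
    gt_nodes = phantom.nodes()
    shared = plant_false_positives(phantom, shared_fp_counts or {}, seed=seed * 1000 + 9001)
    group_fps: dict[str, list[PlantedFP]] = {w: [] for w in windows}
    for gi, (kind, count, voter_ids) in enumerate(shared_groups):
        fps = plant_false_positives(phantom, {kind: count}, seed=seed * 1000 + 7 * gi + 3)
        for vid in voter_ids:
            group_fps[vid].extend(fps)

    samples = [stack_25d(phantom.volume, z) for z in phantom.region_slices()]
    out: dict[str, list[DetectionBox]] = {}
    planted: dict[str, list[PlantedFP]] = {w: [] for w in windows}
    for i, window in enumerate(windows):
        unique = plant_false_positives(
            phantom, unique_fp_counts or {}, seed=seed * 1000 + 31 * (i + 1)
        )
        fps = list(shared) + list(unique) + group_fps[window]
        planted[window] = fps
        det = OracleDetector(
            gt_nodes=gt_nodes,
            hit_prob=hit_prob,
            planted_fps=fps,
            jitter_px=jitter_px,
            seed=seed * 100 + i,
            voter_id=window,
            frame_shape=phantom.volume.shape,
        )
        out[window] = det.detect(samples)
    if return_planted:
        return out, planted
    return out
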