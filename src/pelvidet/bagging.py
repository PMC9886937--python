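"""Window bagging: ensemble voting over detectors trained on different HU windows.

Each voter is the same detector trained on a differently windowed view
of the same slices (no bootstrap of the data — the windows themselves
diversify the ensemble).  Per slice, boxes from all voters are clustered
by greedy single-linkage on IoU: the highest-score unassigned box seeds
a cluster and absorbs every unassigned box whose IoU with the seed is at
least tau1.  A cluster survives when at least tau2 distinct voters
support it; its geometry is the score-weighted mean of member
coordinates (a union-box alternative is available), its score the mean
member score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .detector import DetectionBox

__all__ = ["BagParams", "BaggedBox", "iou", "bag", "TAU1_RANGE", "TAU2_RANGE"]

TAU1_RANGE = tuple(round(0.1 * k, 1) for k in range(1, 11))
TAU2_RANGE = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class BagParams:
    """tau1: cross-voter IoU for clustering; tau2: minimum supporting voters.

    tau3 (the IoU for matching bagged predictions to ground truth) is
    carried here for convenience but consumed by the evaluation stage.
    """

    tau1: float = 0.5
    tau2: int = 3
    tau3: float = 0.3
    merge: str = "weighted_mean"  # or "union"

    def __post_init__(self) -> None:
        if not (0 < self.tau1 <= 1):
            raise ValueError(f"tau1 must be in (0, 1], got {self.tau1}")
        if self.tau2 < 1:
            raise ValueError(f"tau2 must be >= 1, got {self.tau2}")
        if self.merge not in ("weighted_mean", "union"):
            raise ValueError(f"merge must be 'weighted_mean' or 'union', got {self.merge!r}")


@dataclass(frozen=True)
class BaggedBox:
    """A surviving cluster of cross-voter detections on one slice."""

    z: int
    box: tuple[float, float, float, float]
    score: float
    voters: frozenset
    members: tuple  # member DetectionBoxes

    def as_detection(self) -> DetectionBox:
        return DetectionBox(z=self.z, box=self.box, score=self.score,
                            voter_id="+".join(sorted(self.voters)))


def iou(a: tuple, b: tuple) -> float:
    """Intersection over union of two half-open boxes (x0, y0, x1, y1)."""
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return float(inter / union)


def _greedy_clusters(boxes: list[DetectionBox], tau1: float) -> list[list[DetectionBox]]:
    """Greedy single-linkage to the seed, seeds in descending-score order.

    Ties in score are broken by (z, x0, y0) so clustering is independent
    of input ordering.
    """
    order = sorted(boxes, key=lambda b: (-b.score, b.z, b.box[0], b.box[1]))
    assigned = set()
    clusters = []
    for seed in order:
        if id(seed) in assigned:
            continue
        cluster = [seed]
        assigned.add(id(seed))
        for cand in order:
            if id(cand) in assigned:
                continue
            if iou(seed.box, cand.box) >= tau1:
                cluster.append(cand)
                assigned.add(id(cand))
        clusters.append(cluster)
    return clusters


def _merge_cluster(cluster: list[DetectionBox], z: int, mode: str) -> tuple[tuple, float]:
    coords = np.array([b.box for b in cluster], dtype=float)
    scores = np.array([b.score for b in cluster], dtype=float)
    if mode == "union":
        box = (coords[:, 0].min(), coords[:, 1].min(), coords[:, 2].max(), coords[:, 3].max())
    else:
        weights = scores / scores.sum()
        box = tuple(float(v) for v in (weights[:, None] * coords).sum(axis=0))
    return box, float(scores.mean())


def bag(
    voters: Mapping[str, Sequence[DetectionBox]],
    params: BagParams,
) -> list[BaggedBox]:
    """Combine per-voter detections into bagged predictions.

    ``voters`` maps voter id (typically the window label) to that
    voter's post-processed boxes.  Duplicate boxes from one voter inside
    a cluster count as a single vote.  Output is sorted by (z, then
    descending score, then coordinates) for reproducibility.
    """
    if not voters:
        raise ValueError("at least one voter is required")
    if params.tau2 > len(voters):
        raise ValueError(
            f"tau2={params.tau2} exceeds the number of voters ({len(voters)})"
        )
    by_slice: dict[int, list[DetectionBox]] = {}
    for voter_id, boxes in voters.items():
        for b in boxes:
            if b.voter_id != voter_id:
                b = DetectionBox(z=b.z, box=b.box, score=b.score, voter_id=voter_id)
            by_slice.setdefault(b.z, []).append(b)

    out: list[BaggedBox] = []
    for z in sorted(by_slice):
        for cluster in _greedy_clusters(by_slice[z], params.tau1):
            support = frozenset(b.voter_id for b in cluster)
            if len(support) < params.tau2:
                continue
            box, score = _merge_cluster(cluster, z, params.merge)
            out.append(BaggedBox(z=z, box=box, score=score, voters=support,
                                 members=tuple(cluster)))
    out.sort(key=lambda b: (b.z, -b.score, b.box))
    return out
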