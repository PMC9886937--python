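"""Independent brute-force reference implementations used to cross-check
the package: pixel-set IoU, sort-index quantiles, BFS connected
components, naive greedy clustering, and all-pairs AUC.  Deliberately
slow and simple — these never share code with the paths they verify.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def pixel_iou(a, b):
    """IoU by enumerating integer pixels of half-open boxes."""
    ax = set((x, y) for x in range(int(a[0]), int(a[2])) for y in range(int(a[1]), int(a[3])))
    bx = set((x, y) for x in range(int(b[0]), int(b[2])) for y in range(int(b[1]), int(b[3])))
    union = len(ax | bx)
    return len(ax & bx) / union if union else 0.0


def sort_index_quantile(pool, q):
    """Nearest-rank quantile via explicit sort: the ceil(q*n)-th value."""
    s = sorted(pool)
    rank = max(1, min(len(s), math.ceil(q * len(s))))
    return s[rank - 1]


def bfs_components_26(mask):
    """3D 26-connected components via flood fill; returns a list of voxel frozensets."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    comps = []
    nbrs = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
            if (dz, dy, dx) != (0, 0, 0)]
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        comp = set()
        queue = deque([start])
        seen[start] = True
        while queue:
            z, y, x = queue.popleft()
            comp.add((z, y, x))
            for dz, dy, dx in nbrs:
                p = (z + dz, y + dy, x + dx)
                if all(0 <= p[i] < mask.shape[i] for i in range(3)) and mask[p] and not seen[p]:
                    seen[p] = True
                    queue.append(p)
        comps.append(frozenset(comp))
    return comps


def tight_slice_boxes(voxels):
    """Per-slice tight (x0, y0, x1, y1) boxes of a voxel set."""
    boxes = {}
    for z in sorted({v[0] for v in voxels}):
        pts = [(y, x) for (zz, y, x) in voxels if zz == z]
        ys = [p[0] for p in pts]
        xs = [p[1] for p in pts]
        boxes[z] = (min(xs), min(ys), max(xs) + 1, max(ys) + 1)
    return boxes


def naive_greedy_clusters(boxes, tau1, iou_fn):
    """Greedy single-linkage clustering re-derived from the stated rule.

    Repeatedly pick the highest-score unassigned box (ties by (z, x0,
    y0)), then absorb every unassigned box whose IoU with that seed
    reaches tau1.  Returns clusters as lists of the original objects.
    """
    remaining = list(boxes)
    clusters = []
    while remaining:
        seed = min(remaining, key=lambda b: (-b.score, b.z, b.box[0], b.box[1]))
        members = [seed]
        for b in list(remaining):
            if b is seed:
                continue
            if iou_fn(seed.box, b.box) >= tau1:
                members.append(b)
        for b in members:
            remaining.remove(b)
        clusters.append(members)
    return clusters


def all_pairs_auc(labels, scores):
    """AUC as the fraction of positive/negative pairs correctly ordered (ties = 1/2)."""
    pos = [s for l, s in zip(labels, scores) if l]
    neg = [s for l, s in zip(labels, scores) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))
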