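"""Node/slice-level evaluation of detections against ground-truth nodes.

The unit conventions mirror how radiation oncologists read the result:

* **Sensitivity** is node-level — if any single slice of a 3D
  metastasis is detected, the whole metastasis counts as a hit.
* **Precision** is slice-level — the fraction of predicted slice boxes
  that match a ground-truth node slice (IoU >= tau3, greedy one-to-one
  by descending score).
* **F-1** is the harmonic mean of those two percentages, mixed levels
  and all, because that is how the operating point is tuned.
* **AUC** is image-based: each axial slice gets the maximum prediction
  score on it (0 if none) and is labelled by whether it contains
  ground-truth node pixels; the AUC is the normalized Mann-Whitney rank
  statistic with ties counted one half.

Grid search exhaustively scans the tau1..tau6 tuning ranges and returns
the best cell under a chosen criterion, ties broken by the
lexicographically smallest tau vector.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bagging import BagParams, BaggedBox, bag, iou, TAU1_RANGE, TAU2_RANGE
from .detector import DetectionBox
from .imaging import CTVolume, LabelVolume, NodeInstance
from .postprocess import PostprocessParams, postprocess, TAU4_RANGE, TAU5_RANGE, TAU6_RANGE

__all__ = [
    "MatchResult",
    "Metrics",
    "match",
    "node_sensitivity",
    "slice_precision",
    "image_auc",
    "evaluate",
    "grid_search",
    "DEFAULT_GRID",
]


def _pred_box(p) -> tuple:
    return p.box


def _pred_score(p) -> float:
    return p.score


def _pred_z(p) -> int:
    return p.z


@dataclass
class MatchResult:
    """Partition of predictions into TP/FP and the claimed GT slices."""

    tp_boxes: list
    fp_boxes: list
    matched_gt_slices: set  # of (node_id, z)
    node_hits: dict  # node_id -> bool

    @property
    def tp(self) -> int:
        return len(self.tp_boxes)

    @property
    def fp(self) -> int:
        return len(self.fp_boxes)


@dataclass
class Metrics:
    """The four headline percentages plus the counts behind them."""

    sensitivity: float
    precision: float
    f1: float
    auc: float
    n_nodes: int = 0
    nodes_hit: int = 0
    tp: int = 0
    fp: int = 0
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "f1": self.f1,
            "auc": self.auc,
            "n_nodes": self.n_nodes,
            "nodes_hit": self.nodes_hit,
            "tp": self.tp,
            "fp": self.fp,
            "flags": list(self.flags),
        }


def match(
    preds: Sequence["DetectionBox | BaggedBox"],
    gt_nodes: Sequence[NodeInstance],
    tau3: float,
) -> MatchResult:
    """Greedy one-to-one matching of predictions to GT slice boxes.

    Predictions claim, in descending score order (ties broken by slice
    and coordinates, so the result is independent of input ordering),
    the unmatched same-slice GT box of maximal IoU provided that IoU is
    at least tau3.  Claimed predictions are TP, the rest FP; each GT
    slice box is claimed at most once.
    """
    if not (0 < tau3 <= 1):
        raise ValueError(f"tau3 must be in (0, 1], got {tau3}")
    gt_by_z: dict[int, list[tuple[int, tuple]]] = {}
    for node in gt_nodes:
        for z, box in node.slice_boxes.items():
            gt_by_z.setdefault(z, []).append((node.node_id, box))

    order = sorted(preds, key=lambda p: (-_pred_score(p), _pred_z(p), _pred_box(p)))
    claimed: set[tuple[int, int]] = set()
    tp_boxes, fp_boxes = [], []
    node_hits = {node.node_id: False for node in gt_nodes}
    for p in order:
        best = None
        best_iou = 0.0
        for node_id, gbox in gt_by_z.get(_pred_z(p), []):
            if (node_id, _pred_z(p)) in claimed:
                continue
            v = iou(_pred_box(p), gbox)
            if v > best_iou or (v == best_iou and best is not None and node_id < best):
                best, best_iou = node_id, v
        if best is not None and best_iou >= tau3:
            claimed.add((best, _pred_z(p)))
            node_hits[best] = True
            tp_boxes.append(p)
        else:
            fp_boxes.append(p)
    return MatchResult(tp_boxes=tp_boxes, fp_boxes=fp_boxes,
                       matched_gt_slices=claimed, node_hits=node_hits)


def node_sensitivity(result: MatchResult, gt_nodes: Sequence[NodeInstance]) -> float:
    """Percent of 3D nodes with at least one detected slice."""
    if not gt_nodes:
        raise ValueError("node sensitivity is undefined without ground-truth nodes")
    hit = sum(bool(result.node_hits.get(n.node_id, False)) for n in gt_nodes)
    return 100.0 * hit / len(gt_nodes)


def slice_precision(result: MatchResult) -> tuple[float, bool]:
    """Percent of predicted slice boxes that are TP.

    With zero predictions the value is defined as 0 and the degenerate
    flag is set (keeps grid search total).
    """
    total = result.tp + result.fp
    if total == 0:
        return 0.0, True
    return 100.0 * result.tp / total, False


def image_auc(per_slice: Sequence[tuple[bool, float]]) -> float:
    """Image-based AUC over (slice-has-node, slice-score) pairs, in percent.

    The slice score is the maximum prediction score on that slice (0
    when there is no prediction).  AUC is the normalized Mann-Whitney
    statistic: ranks of positive-slice scores among all slices, ties
    counted one half.
    """
    labels = np.array([bool(l) for l, _ in per_slice])
    scores = np.array([float(s) for _, s in per_slice])
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0:
        raise ValueError("image AUC undefined: no positive slices")
    if n_neg == 0:
        raise ValueError("image AUC undefined: no negative slices")
    from scipy.stats import rankdata

    ranks = rankdata(scores)  # average ranks on ties == half-credit pairs
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return 100.0 * float(auc)


def slice_scores(
    preds: Sequence["DetectionBox | BaggedBox"],
    gt_nodes: Sequence[NodeInstance],
    eval_slices: Sequence[int],
) -> list[tuple[bool, float]]:
    """Per-slice (label, score) pairs for the image-based AUC.

    ``eval_slices`` is the set of axial slices the detector actually
    saw (the region slices); a slice is positive when any ground-truth
    node has voxels on it.
    """
    positive = set()
    for node in gt_nodes:
        positive.update(node.slice_boxes)
    best: dict[int, float] = {z: 0.0 for z in eval_slices}
    for p in preds:
        z = _pred_z(p)
        if z in best:
            best[z] = max(best[z], _pred_score(p))
    return [(z in positive, best[z]) for z in sorted(best)]


def evaluate(
    preds: Sequence["DetectionBox | BaggedBox"],
    gt_nodes: Sequence[NodeInstance],
    tau3: float,
    eval_slices: Sequence[int] | None = None,
) -> Metrics:
    """Match predictions to ground truth and compute all four metrics.

    ``eval_slices`` defaults to every slice any ground-truth node
    touches plus every slice with a prediction — callers that know the
    true evaluated region (e.g. the CTV extent) should pass it
    explicitly so negative slices are counted correctly.
    """
    result = match(preds, gt_nodes, tau3)
    sens = node_sensitivity(result, gt_nodes)
    prec, degenerate = slice_precision(result)
    f1 = 0.0 if sens + prec == 0 else 2.0 * sens * prec / (sens + prec)
    if eval_slices is None:
        zs = {z for n in gt_nodes for z in n.slice_boxes}
        zs.update(_pred_z(p) for p in preds)
        eval_slices = sorted(zs)
    try:
        auc = image_auc(slice_scores(preds, gt_nodes, eval_slices))
        flags = []
    except ValueError as exc:
        auc = float("nan")
        flags = [f"auc_undefined: {exc}"]
    if degenerate:
        flags.append("no_predictions")
    return Metrics(
        sensitivity=sens,
        precision=prec,
        f1=f1,
        auc=auc,
        n_nodes=len(gt_nodes),
        nodes_hit=sum(result.node_hits.values()),
        tp=result.tp,
        fp=result.fp,
        flags=flags,
    )


#: The full default tuning ranges for all six thresholds.
DEFAULT_GRID: dict[str, tuple] = {
    "tau1": TAU1_RANGE,
    "tau2": TAU2_RANGE,
    "tau3": (0.3,),
    "tau4": TAU4_RANGE,
    "tau5": TAU5_RANGE,
    "tau6": TAU6_RANGE,
}

_TAU_ORDER = ("tau1", "tau2", "tau3", "tau4", "tau5", "tau6")


def grid_search(
    voters: Mapping[str, Sequence[DetectionBox]],
    gt_nodes: Sequence[NodeInstance],
    vol: CTVolume,
    ctv: LabelVolume,
    grid: Mapping[str, Sequence] | None = None,
    criterion: str = "f1",
    eval_slices: Sequence[int] | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive threshold tuning over the tau1..tau6 cross-product.

    For every grid cell the raw per-voter detections are post-processed
    (tau4, tau5, tau6), bagged (tau1, tau2) and evaluated (tau3); the
    cell maximizing ``criterion`` wins, ties broken by the
    lexicographically smallest (tau1..tau6) vector.  Returns the best
    parameter dict and the full per-cell metrics table.
    """
    if criterion not in ("sensitivity", "precision", "f1", "auc"):
        raise ValueError(f"unknown criterion {criterion!r}")
    grid = dict(DEFAULT_GRID if grid is None else grid)
    for key in _TAU_ORDER:
        values = list(grid.get(key, ()))
        if not values:
            raise ValueError(f"empty grid for {key}")
        grid[key] = values

    pp_cache: dict[tuple, dict[str, list[DetectionBox]]] = {}
    rows = []
    best_key = None
    best_params = None
    for tau4, tau5, tau6 in itertools.product(grid["tau4"], grid["tau5"], grid["tau6"]):
        pp_key = (tau4, tau5, tau6)
        if pp_key not in pp_cache:
            params = PostprocessParams(tau4=tau4, tau5=tau5, tau6=tau6)
            pp_cache[pp_key] = {
                vid: postprocess(boxes, ctv, vol, params) for vid, boxes in voters.items()
            }
        processed = pp_cache[pp_key]
        for tau1, tau2, tau3 in itertools.product(grid["tau1"], grid["tau2"], grid["tau3"]):
            bagged = bag(processed, BagParams(tau1=tau1, tau2=tau2, tau3=tau3))
            metrics = evaluate(bagged, gt_nodes, tau3, eval_slices=eval_slices)
            cell = {"tau1": tau1, "tau2": tau2, "tau3": tau3,
                    "tau4": tau4, "tau5": tau5, "tau6": tau6}
            rows.append({**cell, **{k: getattr(metrics, k)
                                    for k in ("sensitivity", "precision", "f1", "auc",
                                              "tp", "fp", "nodes_hit")}})
            value = getattr(metrics, criterion)
            if np.isnan(value):
                continue
            tau_vec = tuple(cell[k] for k in _TAU_ORDER)
            key = (-value, tau_vec)
            if best_key is None or key < best_key:
                best_key = key
                best_params = cell
    if best_params is None:
        raise ValueError("grid search found no cell with a defined criterion value")
    table = pd.DataFrame(rows)
    return best_params, table
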