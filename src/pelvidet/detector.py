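"""Detector contract, the deterministic oracle detector, and backbone config.

The pipeline is detector-agnostic: anything exposing
``detect(samples) -> list[DetectionBox]`` with boxes in volume
coordinates can be plugged in through the registry.  Two
implementations exist:

* :class:`OracleDetector` — a scripted stand-in driven by the known
  ground truth.  It emits each ground-truth slice box with a chosen hit
  probability (with bounded coordinate jitter) plus planted false
  positives of known cause, so filtering, bagging and evaluation can be
  tested against exact expectations.
* a fine-tunable two-stage detection backbone (Mask R-CNN family with
  the mask branch disabled) — an optional extra requiring torch and
  detectron2; :func:`finetune_backbone` raises
  :class:`TrainingUnavailableError` when the extra is absent, and the
  rest of the pipeline does not depend on it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Iterable, Sequence

import numpy as np

from .imaging import NodeInstance, Slice25D

__all__ = [
    "DetectionBox",
    "PlantedFP",
    "DetectorConfig",
    "OracleDetector",
    "TrainingUnavailableError",
    "register_detector",
    "get_detector",
    "detect",
    "finetune_backbone",
    "boxes_to_json",
    "boxes_from_json",
    "save_boxes",
    "load_boxes",
]

FP_KINDS = ("expansion_ring", "vessel", "random_tissue")


@dataclass(frozen=True)
class DetectionBox:
    """One 2D detection on an axial slice, in volume coordinates."""

    z: int
    box: tuple[float, float, float, float]  # (x0, y0, x1, y1), half-open
    score: float
    voter_id: str = ""

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate box {self.box}")
        if not (np.isfinite(self.score) and 0 <= self.score <= 1):
            raise ValueError(f"score must be finite in [0, 1], got {self.score}")
        object.__setattr__(self, "box", tuple(float(v) for v in self.box))
        object.__setattr__(self, "score", float(self.score))
        object.__setattr__(self, "z", int(self.z))


@dataclass(frozen=True)
class PlantedFP:
    """A false positive planted by the phantom, with its known cause."""

    z: int
    box: tuple[float, float, float, float]
    kind: str  # one of FP_KINDS

    def __post_init__(self) -> None:
        if self.kind not in FP_KINDS:
            raise ValueError(f"unknown FP kind {self.kind!r}; known: {FP_KINDS}")


@dataclass
class DetectorConfig:
    """Training schedule for the two-stage backbone.

    Default SGD schedules: whole-slice pretraining
    for 3000 iterations at LR 0.01 (tenfold drop at 2000), then regional
    fine-tuning for 6000 iterations at LR 0.005 (drops at 4000 and
    5000); batch 64, momentum 0.9, weight decay 1e-4 in both stages.
    The mask branch is disabled — the task is pure box detection.
    """

    stage: str = "wsi_pretrain"  # or "regional_finetune"
    iterations: int = 3000
    base_lr: float = 0.01
    lr_drop_iters: list = field(default_factory=lambda: [2000])
    batch_size: int = 64
    momentum: float = 0.9
    weight_decay: float = 1e-4
    mask_branch_enabled: bool = False

    @classmethod
    def wsi_pretrain(cls) -> "DetectorConfig":
        return cls()

    @classmethod
    def regional_finetune(cls) -> "DetectorConfig":
        return cls(stage="regional_finetune", iterations=6000, base_lr=0.005,
                   lr_drop_iters=[4000, 5000])

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        return cls(**d)


class TrainingUnavailableError(RuntimeError):
    """Backbone training requested but the deep-learning extra is absent."""


# ---------------------------------------------------------------------------
# Registry

_REGISTRY: dict[str, Callable[..., object]] = {}


def register_detector(name: str, factory: Callable[..., object]) -> None:
    _REGISTRY[name] = factory


def get_detector(name: str, **kwargs):
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise LookupError(
            f"no detector registered under {name!r}; known: {sorted(_REGISTRY)}"
        ) from None
    return factory(**kwargs)


def detect(detector, samples: Sequence[Slice25D]) -> list[DetectionBox]:
    """Run a detector on 2.5D samples; boxes come back in volume coords."""
    if not hasattr(detector, "detect"):
        raise TypeError(f"{detector!r} does not honour the detector contract")
    boxes = detector.detect(samples)
    for b in boxes:
        if not isinstance(b, DetectionBox):
            raise TypeError(f"detector returned a non-DetectionBox: {b!r}")
    return boxes


class OracleDetector:
    """Scripted detector driven by ground truth — the pipeline test double.

    For each sample's central slice, every ground-truth slice box is
    emitted independently with probability ``hit_prob``, its edges
    jittered by at most ``jitter_px`` pixels, and a confidence drawn
    from U(0.6, 1).  Planted false positives on that slice are emitted
    with confidence U(0.05, 0.7) — below typical true-hit scores but
    overlapping, so score-rank logic is genuinely exercised.

    Per-slice random substreams make the output independent of sample
    order and bit-reproducible for a given seed.
    """

    def __init__(
        self,
        gt_nodes: Sequence[NodeInstance],
        hit_prob: float = 1.0,
        planted_fps: Sequence[PlantedFP] = (),
        jitter_px: int = 0,
        seed: int = 0,
        voter_id: str = "oracle",
        frame_shape: tuple[int, int, int] | None = None,
    ) -> None:
        if not (0 <= hit_prob <= 1):
            raise ValueError(f"hit_prob must be in [0, 1], got {hit_prob}")
        if jitter_px < 0:
            raise ValueError("jitter_px must be >= 0")
        for fp in planted_fps:
            if fp.kind not in FP_KINDS:
                raise ValueError(f"unknown FP kind {fp.kind!r}")
        self.gt_nodes = list(gt_nodes)
        self.hit_prob = float(hit_prob)
        self.planted_fps = list(planted_fps)
        self.jitter_px = int(jitter_px)
        self.seed = int(seed)
        self.voter_id = voter_id
        self.frame_shape = frame_shape
        # index ground truth by slice, in stable (node_id, z) order
        self._gt_by_z: dict[int, list[tuple[int, tuple]]] = {}
        for node in sorted(self.gt_nodes, key=lambda n: n.node_id):
            for z, box in sorted(node.slice_boxes.items()):
                self._gt_by_z.setdefault(z, []).append((node.node_id, box))
        self._fp_by_z: dict[int, list[PlantedFP]] = {}
        for fp in self.planted_fps:
            self._fp_by_z.setdefault(fp.z, []).append(fp)

    def _jitter(self, rng: np.random.Generator, box: tuple) -> tuple:
        if self.jitter_px == 0:
            return tuple(float(v) for v in box)
        j = self.jitter_px
        x0, y0, x1, y1 = (float(v) + int(d) for v, d in zip(box, rng.integers(-j, j + 1, 4)))
        if x1 <= x0:
            x1 = x0 + 1
        if y1 <= y0:
            y1 = y0 + 1
        if self.frame_shape is not None:
            _, h, w = self.frame_shape
            x0 = min(max(x0, 0), w - 1)
            y0 = min(max(y0, 0), h - 1)
            x1 = min(max(x1, x0 + 1), w)
            y1 = min(max(y1, y0 + 1), h)
        return (x0, y0, x1, y1)

    def detect(self, samples: Sequence[Slice25D]) -> list[DetectionBox]:
        out: list[DetectionBox] = []
        for sample in samples:
            z = sample.center_index
            rng = np.random.default_rng([self.seed, z])
            for _node_id, box in self._gt_by_z.get(z, []):
                hit = rng.random() < self.hit_prob
                jittered = self._jitter(rng, box)
                score = float(rng.uniform(0.6, 1.0))
                if hit:
                    out.append(DetectionBox(z=z, box=jittered, score=score,
                                            voter_id=self.voter_id))
            for fp in self._fp_by_z.get(z, []):
                score = float(rng.uniform(0.05, 0.7))
                out.append(DetectionBox(z=z, box=fp.box, score=score,
                                        voter_id=self.voter_id))
        return out


register_detector("oracle", OracleDetector)


def finetune_backbone(config: DetectorConfig, train_data=None):
    """Fine-tune the two-stage detection backbone (optional deep-learning extra).

    Requires torch and detectron2 and a GPU; the detection-box loss is
    the backbone's own (classification + box regression, mask branch
    off).  Without the extra this raises
    :class:`TrainingUnavailableError` and the pipeline remains fully
    usable with the oracle detector.
    """
    try:
        import torch  # noqa: F401
        import detectron2  # noqa: F401
    except ImportError as exc:
        raise TrainingUnavailableError(
            "backbone training unavailable: install the deep-learning extra "
            "(torch + detectron2); the pipeline runs with the oracle detector"
        ) from exc
    raise NotImplementedError("backbone adapter wiring is delegated to detectron2 configs")


# ---------------------------------------------------------------------------
# JSON interchange: the currency between detect / postprocess / bag / evaluate


def boxes_to_json(boxes: Iterable[DetectionBox], voter_id: str | None = None) -> dict:
    items = []
    for b in boxes:
        # floats are written exactly (repr round-trips), so re-reading a
        # stage's output feeds the next stage bit-identical inputs
        items.append({
            "z": b.z,
            "box": [float(v) for v in b.box],
            "score": float(b.score),
            "voter": b.voter_id,
        })
    doc = {"boxes": items}
    if voter_id is not None:
        doc["voter_id"] = voter_id
    return doc


def boxes_from_json(doc: dict) -> list[DetectionBox]:
    default_voter = doc.get("voter_id", "")
    return [
        DetectionBox(z=item["z"], box=tuple(item["box"]), score=item["score"],
                     voter_id=item.get("voter", default_voter))
        for item in doc["boxes"]
    ]


def save_boxes(boxes: Iterable[DetectionBox], path, voter_id: str | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(boxes_to_json(boxes, voter_id), fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_boxes(path) -> list[DetectionBox]:
    with open(path) as fh:
        return boxes_from_json(json.load(fh))
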