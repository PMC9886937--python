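"""End-to-end orchestration: phantom -> preprocess -> detect -> filter -> bag -> evaluate.

A single global seed fans out to per-stage seeds via a stable hash of
the stage name, so each stage is independently re-runnable and chaining
the stage commands reproduces the orchestrated run byte for byte.
Every intermediate is written to disk (NIfTI volumes/masks, JSON box
lists, a JSON report).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .bagging import BagParams, bag
from .detector import DetectionBox, load_boxes, save_boxes
from .evaluation import Metrics, evaluate
from .imaging import CTVolume, LabelVolume, load_mask, load_volume, save_mask, save_volume
from .phantom import PhantomResult, PhantomSpec, gen_phantom, gen_voter_outputs
from .postprocess import PostprocessParams, postprocess
from .regions import EmptyRegionError, crop_black_border, expand_mask, mask_and_crop
from .windowing import WINDOW_PRESETS, apply_window, resolve_window
from .imaging import stack_25d

__all__ = [
    "PipelineConfig",
    "derive_seed",
    "run",
    "save_phantom",
    "load_phantom_dir",
    "preprocess_samples",
]


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed."""
    return zlib.crc32(f"{stage}:{seed}".encode()) & 0x7FFFFFFF


_CONFIG_FIELDS = {
    "path", "windows", "k_px", "tau1", "tau2", "tau3", "tau4", "tau5", "tau6",
    "merge", "detector", "hit_prob", "jitter_px", "shared_fp", "unique_fp",
    "phantom", "seed",
}


@dataclass
class PipelineConfig:
    """Flat, validated configuration for the orchestrated run.

    ``windows`` name the voter ensemble (presets or {"low","high"}
    dicts); ``k_px`` is the CTV expansion; tau1..tau6 are the six
    tunable thresholds; the oracle detector is parameterized by
    ``hit_prob``, ``jitter_px`` and the planted-FP counts.  Unknown
    keys are rejected, not ignored.
    """

    path: str = "regional"
    windows: list = field(default_factory=lambda: list(WINDOW_PRESETS))
    k_px: int = 10
    tau1: float = 0.5
    tau2: int = 3
    tau3: float = 0.3
    tau4: int = 2
    tau5: float = 160.0
    tau6: float = 0.8
    merge: str = "weighted_mean"
    detector: str = "oracle"
    hit_prob: float = 0.95
    jitter_px: int = 1
    shared_fp: dict = field(default_factory=lambda: {"expansion_ring": 5, "vessel": 5})
    unique_fp: dict = field(default_factory=lambda: {"random_tissue": 3})
    phantom: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.path not in ("wsi", "regional"):
            raise ValueError(f"path must be 'wsi' or 'regional', got {self.path!r}")
        if self.tau2 > len(self.windows):
            raise ValueError(
                f"tau2={self.tau2} exceeds the number of windows ({len(self.windows)})"
            )
        for w in self.windows:
            resolve_window(w)

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        unknown = set(d) - _CONFIG_FIELDS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


def save_phantom(phantom: PhantomResult, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_volume(phantom.volume, out_dir / "ct.nii.gz")
    save_mask(phantom.ctv, out_dir / "ctv.nii.gz")
    save_mask(phantom.node_gt, out_dir / "nodes.nii.gz")
    save_mask(phantom.vessel, out_dir / "vessels.nii.gz")
    if phantom.spec is not None:
        with open(out_dir / "provenance.json", "w") as fh:
            json.dump(phantom.spec.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")


def load_phantom_dir(path: Path) -> PhantomResult:
    """Reassemble a PhantomResult from a directory written by save_phantom."""
    path = Path(path)
    vol = load_volume(path / "ct.nii.gz")
    spec = None
    prov = path / "provenance.json"
    if prov.exists():
        with open(prov) as fh:
            d = json.load(fh)
        d["shape"] = tuple(d["shape"])
        d["spacing"] = tuple(d["spacing"])
        d["node_radius_px"] = tuple(d["node_radius_px"])
        d["node_radius_z"] = tuple(d["node_radius_z"])
        spec = PhantomSpec(**d)
    return PhantomResult(
        volume=vol,
        ctv=load_mask(path / "ctv.nii.gz", "ctv", vol),
        node_gt=load_mask(path / "nodes.nii.gz", "node_gt", vol),
        vessel=load_mask(path / "vessels.nii.gz", "vessel", vol),
        spec=spec,
    )


def preprocess_samples(
    vol: CTVolume,
    window,
    path: str = "regional",
    expanded: LabelVolume | None = None,
    slices: Sequence[int] | None = None,
):
    """Produce windowed 2.5D samples for one voter.

    The regional path masks and crops each stack to the expanded CTV
    before windowing; the whole-slice path crops the black border and
    applies the window to the full field of view.  Slices with an empty
    region are skipped (and reported).
    """
    spec = resolve_window(window)
    if path == "regional" and expanded is None:
        raise ValueError("the regional path needs the expanded CTV mask")
    if slices is None:
        slices = range(vol.n_slices)
    samples, skipped = [], []
    for z in slices:
        s = stack_25d(vol, z)
        if path == "regional":
            try:
                s = mask_and_crop(s, expanded)
            except EmptyRegionError:
                skipped.append(z)
                continue
        else:
            s = crop_black_border(s)
        s.channels = apply_window(s.channels, spec)
        samples.append(s)
    return samples, skipped


def metrics_doc(metrics: Metrics, params: Mapping) -> dict:
    """Serializable report with floats rounded for byte-stable reruns."""
    doc = metrics.to_dict()
    for k in ("sensitivity", "precision", "f1", "auc"):
        doc[k] = round(float(doc[k]), 9) if np.isfinite(doc[k]) else None
    return {"metrics": doc, "params": dict(params)}


def run(config: PipelineConfig, out_dir) -> Metrics:
    """Execute the full pipeline on a phantom and write every intermediate.

    Stages: generate phantom -> expand CTV -> per-window regional
    preprocessing + detection -> per-voter rule-based FP filtering ->
    window bagging -> node/slice-level evaluation.  Any stage failure
    aborts with the stage named.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    window_labels = [resolve_window(w).label or str(w) for w in config.windows]

    stage = "phantom"
    try:
        spec = PhantomSpec(**{"seed": derive_seed(config.seed, "phantom"), **config.phantom})
        phantom = gen_phantom(spec)
        save_phantom(phantom, out_dir / "phantom")

        stage = "preprocess"
        expanded = expand_mask(phantom.ctv, config.k_px)
        save_mask(expanded, out_dir / "ctv_expanded.nii.gz")
        region_slices = phantom.region_slices()
        for w in config.windows:
            preprocess_samples(phantom.volume, w, path=config.path,
                               expanded=expanded, slices=region_slices)

        stage = "detect"
        if config.detector != "oracle":
            raise ValueError(f"no detector registered for pipeline use: {config.detector!r}")
        voters = gen_voter_outputs(
            phantom,
            windows=window_labels,
            hit_prob=config.hit_prob,
            shared_fp_counts=config.shared_fp,
            unique_fp_counts=config.unique_fp,
            jitter_px=config.jitter_px,
            seed=derive_seed(config.seed, "detect"),
        )
        for vid, boxes in voters.items():
            save_boxes(boxes, out_dir / f"voter_{vid}.json", voter_id=vid)

        stage = "postprocess"
        pp = PostprocessParams(tau4=config.tau4, tau5=config.tau5, tau6=config.tau6)
        processed = {
            vid: postprocess(boxes, phantom.ctv, phantom.volume, pp)
            for vid, boxes in voters.items()
        }
        for vid, boxes in processed.items():
            save_boxes(boxes, out_dir / f"voter_{vid}_filtered.json", voter_id=vid)

        stage = "bag"
        bagged = bag(processed, BagParams(tau1=config.tau1, tau2=config.tau2,
                                          tau3=config.tau3, merge=config.merge))
        save_boxes([b.as_detection() for b in bagged], out_dir / "bagged.json")

        stage = "evaluate"
        metrics = evaluate(bagged, phantom.nodes(), config.tau3, eval_slices=region_slices)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(metrics_doc(metrics, config.to_dict()), fh, indent=1, sort_keys=True)
            fh.write("\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return metrics
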