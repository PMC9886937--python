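"""Hounsfield-unit windows derived from node-pixel quantiles.

A window is a (low, high) HU range: pixels are clipped to it and
linearly rescaled to [0, 1], which emphasises the soft-tissue contrast
that metastatic lymph nodes live in.  Besides the standard soft-tissue
window (-125, 225), windows are derived empirically by pooling the HU
values of all ground-truth node pixels and symmetrically trimming the
distribution tails at a quantile pair such as (1%, 99%).

Quantiles use the nearest-rank estimator (the ceil(q*n)-th order
statistic), which returns actual sample values — integer HU pools give
integer window edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "QuantileRange",
    "WindowSpec",
    "nearest_rank_quantile",
    "derive_quantile_window",
    "apply_window",
    "unapply_window",
    "WINDOW_PRESETS",
    "QUANTILE_PRESETS",
]


@dataclass(frozen=True)
class QuantileRange:
    """A symmetric tail-trimming pair: lower/upper percentiles of the pool."""

    lower_pct: float
    upper_pct: float

    def __post_init__(self) -> None:
        if not (0 < self.lower_pct < 50):
            raise ValueError(f"lower_pct must be in (0, 50), got {self.lower_pct}")
        if not (50 < self.upper_pct < 100):
            raise ValueError(f"upper_pct must be in (50, 100), got {self.upper_pct}")


@dataclass(frozen=True)
class WindowSpec:
    """An HU clipping/normalization range with a provenance label."""

    low_hu: float
    high_hu: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (np.isfinite(self.low_hu) and np.isfinite(self.high_hu)):
            raise ValueError("window bounds must be finite")
        if self.low_hu > self.high_hu:
            raise ValueError(f"low_hu {self.low_hu} > high_hu {self.high_hu}")

    @property
    def width(self) -> float:
        return self.high_hu - self.low_hu


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """The nearest-rank q-quantile: the ceil(q*n)-th order statistic.

    ``q`` is a fraction in (0, 1].  Always returns an element of
    ``values``.
    """
    values = np.asarray(values).ravel()
    n = values.size
    if n == 0:
        raise ValueError("cannot take a quantile of an empty sample")
    if not (0 < q <= 1):
        raise ValueError(f"quantile fraction must be in (0, 1], got {q}")
    rank = int(np.ceil(q * n))  # 1-based
    rank = min(max(rank, 1), n)
    return float(np.partition(values, rank - 1)[rank - 1])


def derive_quantile_window(hu_samples: np.ndarray, qr: QuantileRange) -> WindowSpec:
    """Derive an HU window from a pool of node-pixel HU samples.

    The window edges are the nearest-rank quantiles of the pool at the
    given percentile pair, i.e. the pool with its extreme tails
    symmetrically excluded.
    """
    hu_samples = np.asarray(hu_samples, dtype=float).ravel()
    if hu_samples.size == 0:
        raise ValueError("no node pixels to derive a window from: empty HU sample pool")
    low = nearest_rank_quantile(hu_samples, qr.lower_pct / 100.0)
    high = nearest_rank_quantile(hu_samples, qr.upper_pct / 100.0)
    label = f"q{qr.lower_pct:g}_{qr.upper_pct:g}"
    return WindowSpec(low_hu=low, high_hu=high, label=label)


def apply_window(image: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """Clip an HU image to the window and map it linearly onto [0, 1].

    A degenerate window (low == high) maps every pixel to 0.5.
    """
    image = np.asarray(image, dtype=float)
    if spec.width == 0:
        return np.full_like(image, 0.5)
    clipped = np.clip(image, spec.low_hu, spec.high_hu)
    return (clipped - spec.low_hu) / spec.width


def unapply_window(normalized: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """Invert apply_window for values that were strictly inside the window."""
    normalized = np.asarray(normalized, dtype=float)
    return spec.low_hu + normalized * spec.width


#: The four quantile windows used for window bagging plus the standard
#: soft-tissue window.  The quantile windows are HU ranges
#: derived from a pooled clinical node-pixel distribution; on other data they
#: should be re-derived with :func:`derive_quantile_window`.
WINDOW_PRESETS: dict[str, WindowSpec] = {
    "q0.5_99.5": WindowSpec(-97, 310, "q0.5_99.5"),
    "q1_99": WindowSpec(-90, 169, "q1_99"),
    "q1.5_98.5": WindowSpec(-84, 151, "q1.5_98.5"),
    "q2_98": WindowSpec(-79, 141, "q2_98"),
    "soft_tissue": WindowSpec(-125, 225, "soft_tissue"),
}

QUANTILE_PRESETS: dict[str, QuantileRange] = {
    "q0.5_99.5": QuantileRange(0.5, 99.5),
    "q1_99": QuantileRange(1, 99),
    "q1.5_98.5": QuantileRange(1.5, 98.5),
    "q2_98": QuantileRange(2, 98),
}


def resolve_window(spec: "WindowSpec | str | dict") -> WindowSpec:
    """Resolve a preset name, {"preset": name} or {"low":, "high":} to a WindowSpec."""
    if isinstance(spec, WindowSpec):
        return spec
    if isinstance(spec, str):
        try:
            return WINDOW_PRESETS[spec]
        except KeyError:
            raise KeyError(
                f"unknown window preset {spec!r}; known: {sorted(WINDOW_PRESETS)}"
            ) from None
    if isinstance(spec, dict):
        if "preset" in spec:
            return resolve_window(spec["preset"])
        if "low" in spec and "high" in spec:
            return WindowSpec(spec["low"], spec["high"], spec.get("label", "custom"))
    raise TypeError(f"cannot interpret window spec {spec!r}")
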