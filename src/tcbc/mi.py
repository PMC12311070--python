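"""Normalized-mutual-information rigid registration baseline.

A standard intensity-based comparator: NMI = (H(A) + H(B)) / H(A, B) from
the joint histogram of paired voxel intensities, maximized with the same
multi-start Nelder-Mead harness used by the ROI-uptake method.  This
reproduces the NMI method family, not any particular external tool
bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import (
    RegistrationResult,
    TcbcConfig,
    _maybe_subsample,
    multistart_nelder_mead,
)
from .errors import InvalidArgumentError, UndefinedEntropyError
from .geometry import ImageVolume, RigidParams, apply_transform, build_transform

__all__ = ["HistogramConfig", "normalized_mutual_information", "mi_register"]


@dataclass
class HistogramConfig:
    bins: int = 32
    clip_percentiles: tuple[float, float] = (0.5, 99.5)
    smooth: bool = False

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise InvalidArgumentError("bins must be >= 2")
        lo, hi = self.clip_percentiles
        if not 0 <= lo < hi <= 100:
            raise InvalidArgumentError("clip percentiles must satisfy low < high")


def _edges(values: np.ndarray, cfg: HistogramConfig) -> np.ndarray:
    lo, hi = np.percentile(values, cfg.clip_percentiles)
    if hi <= lo:
        hi = lo + 1.0  # degenerate range; entropy check happens downstream
    return np.linspace(lo, hi, cfg.bins + 1)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def nmi_from_samples(a: np.ndarray, b: np.ndarray, cfg: HistogramConfig,
                     edges_a: np.ndarray | None = None,
                     edges_b: np.ndarray | None = None) -> float:
    """NMI of two paired intensity sample vectors."""
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidArgumentError("paired samples must be equal-length 1-D")
    if edges_a is None:
        edges_a = _edges(a, cfg)
    if edges_b is None:
        edges_b = _edges(b, cfg)
    # clip into the (possibly percentile-trimmed) range so every pair counts
    a = np.clip(a, edges_a[0], edges_a[-1])
    b = np.clip(b, edges_b[0], edges_b[-1])
    joint, _, _ = np.histogram2d(a, b, bins=[edges_a, edges_b])
    if cfg.smooth:
        joint = ndimage.gaussian_filter(joint, sigma=1.0)
    joint /= joint.sum()
    h_a = _entropy(joint.sum(axis=1))
    h_b = _entropy(joint.sum(axis=0))
    if h_a == 0.0 or h_b == 0.0:
        raise UndefinedEntropyError(
            "constant image: marginal entropy is zero, NMI undefined"
        )
    return (h_a + h_b) / _entropy(joint.ravel())


def normalized_mutual_information(a: ImageVolume, b: ImageVolume,
                                  cfg: HistogramConfig | None = None) -> float:
    """NMI between two volumes already on the same grid; range (1, 2]."""
    cfg = cfg or HistogramConfig()
    if a.shape != b.shape:
        raise InvalidArgumentError("volumes must share a grid")
    return nmi_from_samples(a.data.ravel(), b.data.ravel(), cfg)


def mi_register(fixed: ImageVolume, moving: ImageVolume,
                config: TcbcConfig | None = None,
                hist: HistogramConfig | None = None,
                center: Sequence[float] | None = None) -> RegistrationResult:
    """Rigid registration of ``moving`` onto ``fixed`` by NMI maximization.

    Candidate transforms map moving-space structures onto fixed space: a
    fixed-grid voxel at world w is paired with the moving intensity at
    M^-1 . w.  Only pairs whose moving sample lies inside the moving field
    enter the histogram (overlap-domain convention).
    """
    config = config or TcbcConfig()
    hist = hist or HistogramConfig()
    if center is None:
        center = fixed.world_center()
    center = np.asarray(center, dtype=float)

    idx = np.indices(fixed.shape).reshape(3, -1).T.astype(float)
    world = apply_transform(fixed.affine, idx)
    world = _maybe_subsample(world, config)
    fixed_vals = ndimage.map_coordinates(
        np.ascontiguousarray(fixed.data),
        apply_transform(np.linalg.inv(fixed.affine), world).T,
        order=1, prefilter=False,
    )
    edges_fixed = _edges(fixed_vals, hist)
    edges_moving = _edges(moving.data.ravel(), hist)
    inv_moving_affine = np.linalg.inv(moving.affine)
    moving_data = np.ascontiguousarray(moving.data, dtype=float)
    upper = np.asarray(moving.shape, dtype=float) - 1.0
    min_pairs = max(100, hist.bins ** 2 // 4)

    def objective(x: np.ndarray) -> float:
        m = build_transform(RigidParams.from_array(x), center)
        voxel = apply_transform(inv_moving_affine @ np.linalg.inv(m), world)
        inside = np.all((voxel >= 0.0) & (voxel <= upper), axis=1)
        if inside.sum() < min_pairs:
            return np.inf
        moving_vals = ndimage.map_coordinates(
            moving_data, voxel[inside].T, order=1, prefilter=False,
        )
        try:
            nmi = nmi_from_samples(fixed_vals[inside], moving_vals, hist,
                                   edges_fixed, edges_moving)
        except UndefinedEntropyError:
            return np.inf
        return -nmi

    return multistart_nelder_mead(objective, config, center)
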