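"""SUVR quantification with an eroded white-matter reference region."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import (
    EmptyReferenceError,
    InvalidArgumentError,
    QuantificationError,
)
from .geometry import ImageVolume, ROIMask, is_rigid, resample_mask

__all__ = ["SuvrConfig", "erode_mask", "sum_frames", "compute_suvr",
           "suvr_table"]

_CONNECTIVITY = {6: 1, 18: 2, 26: 3}


def default_targets() -> dict[str, set[int]]:
    # stand-in cortical sector labels assigned by the phantom generator
    return {
        "precuneus": {1001},
        "anterior_cingulate": {1002},
        "posterior_cingulate": {1003},
        "medial_orbitofrontal": {1004},
    }


@dataclass
class SuvrConfig:
    """Target/reference label sets and reference-erosion settings.

    The composite target is always the union of the four named cortical
    ROIs.  Label IDs are configurable because real segmentations (e.g.
    FreeSurfer aparc+aseg) and the synthetic phantom use different IDs;
    cerebral white matter defaults to {2, 41}.
    """

    targets: dict[str, set[int]] = field(default_factory=default_targets)
    reference_labels: set[int] = field(default_factory=lambda: {2, 41})
    erosion_iterations: int = 1
    connectivity: int = 6

    def __post_init__(self) -> None:
        if self.erosion_iterations < 0:
            raise InvalidArgumentError("erosion_iterations must be >= 0")
        if self.connectivity not in _CONNECTIVITY:
            raise InvalidArgumentError(
                f"connectivity must be one of {sorted(_CONNECTIVITY)}"
            )
        if not self.targets:
            raise InvalidArgumentError("at least one target ROI is required")
        all_target = set().union(*self.targets.values())
        if all_target & set(self.reference_labels):
            raise InvalidArgumentError(
                "target and reference label sets must be disjoint"
            )

    @property
    def composite_labels(self) -> set[int]:
        return set().union(*self.targets.values())


def erode_mask(mask: ROIMask, iterations: int = 1,
               connectivity: int = 6) -> ROIMask:
    """Morphological erosion of a binary mask.

    A voxel survives one iteration iff all its structuring-element
    neighbours are inside the mask; 6/18/26-connectivity map to the three
    3-D structuring elements.  Raises if the result is empty.
    """
    if connectivity not in _CONNECTIVITY:
        raise InvalidArgumentError(
            f"connectivity must be one of {sorted(_CONNECTIVITY)}"
        )
    if mask.num_voxels == 0:
        raise InvalidArgumentError("mask is empty")
    data = mask.data != 0
    if iterations > 0:
        structure = ndimage.generate_binary_structure(
            3, _CONNECTIVITY[connectivity])
        data = ndimage.binary_erosion(data, structure=structure,
                                      iterations=iterations)
    if not data.any():
        raise EmptyReferenceError(
            f"erosion with {iterations} iteration(s) emptied the mask"
        )
    return ROIMask(data=data, affine=mask.affine.copy())


def sum_frames(frames: list[ImageVolume],
               window_s: tuple[float, float]) -> ImageVolume:
    """Voxelwise sum of the frames strictly contained in the time window.

    A frame with times [start, end] is included iff
    window_start <= start and end <= window_end; partially overlapping
    frames are excluded.
    """
    if not frames:
        raise InvalidArgumentError("frame list is empty")
    lo, hi = window_s
    selected = []
    for f in frames:
        if f.frame_time is None:
            raise InvalidArgumentError("every frame needs frame_time metadata")
        start, end = f.frame_time
        if lo <= start and end <= hi:
            selected.append(f)
    if not selected:
        raise InvalidArgumentError(
            f"no frame is contained in window [{lo}, {hi}] s"
        )
    shape = selected[0].shape
    for f in selected:
        if f.shape != shape or not np.allclose(f.affine, selected[0].affine):
            raise InvalidArgumentError("frames must share a grid")
    total = np.sum([f.data for f in selected], axis=0)
    times = ([f.frame_time[0] for f in selected],
             [f.frame_time[1] for f in selected])
    return ImageVolume(total, selected[0].affine.copy(),
                       frame_time=(min(times[0]), max(times[1])))


def _roi_mean(pet: ImageVolume, mask: np.ndarray, name: str) -> float:
    if not mask.any():
        raise QuantificationError(f"ROI {name!r} is empty after transformation")
    return float(pet.data[mask].mean())


def compute_suvr(pet: ImageVolume, seg: ROIMask, transform: np.ndarray,
                 cfg: SuvrConfig | None = None) -> dict[str, float]:
    """SUVR per target ROI (and their composite) with an eroded reference.

    ``transform`` is the rigid matrix aligning the MR-space segmentation
    with the PET (e.g. the output of the registration); the segmentation is
    resampled onto the PET grid with nearest-neighbour interpolation, the
    reference is eroded, and each SUVR is the target mean divided by the
    eroded-reference mean.  The composite is the mean over the union of the
    four target ROIs' voxels (not the mean of the four SUVRs).
    """
    cfg = cfg or SuvrConfig()
    if not is_rigid(transform):
        raise InvalidArgumentError("transform must be rigid")
    moved = resample_mask(seg, transform, like=pet)
    ref = ROIMask(np.isin(moved.data, list(cfg.reference_labels)).astype(np.int8),
                  moved.affine)
    if ref.num_voxels == 0:
        raise QuantificationError("reference ROI is empty after transformation")
    ref = erode_mask(ref, cfg.erosion_iterations, cfg.connectivity)
    ref_mean = _roi_mean(pet, ref.data != 0, "reference")
    if ref_mean == 0:
        raise QuantificationError("reference mean is zero")
    out: dict[str, float] = {}
    for name, labels in cfg.targets.items():
        mask = np.isin(moved.data, list(labels))
        out[name] = _roi_mean(pet, mask, name) / ref_mean
    comp = np.isin(moved.data, list(cfg.composite_labels))
    out["composite"] = _roi_mean(pet, comp, "composite") / ref_mean
    return out


def suvr_table(pet: ImageVolume, seg: ROIMask, transform: np.ndarray,
               cfg: SuvrConfig | None = None) -> pd.DataFrame:
    """Detailed SUVR table: ROI name, voxel counts, reference stats, SUVR."""
    cfg = cfg or SuvrConfig()
    moved = resample_mask(seg, transform, like=pet)
    ref0 = ROIMask(np.isin(moved.data, list(cfg.reference_labels)).astype(np.int8),
                   moved.affine)
    ref = erode_mask(ref0, cfg.erosion_iterations, cfg.connectivity)
    ref_mean = _roi_mean(pet, ref.data != 0, "reference")
    suvrs = compute_suvr(pet, seg, transform, cfg)
    rows = []
    label_sets = dict(cfg.targets)
    label_sets["composite"] = cfg.composite_labels
    for name, labels in label_sets.items():
        pre = int(np.isin(seg.data, list(labels)).sum())
        post = int(np.isin(moved.data, list(labels)).sum())
        rows.append({
            "roi": name,
            "labels": ",".join(str(v) for v in sorted(labels)),
            "n_voxels_pre": pre,
            "n_voxels_post": post,
            "reference_n_voxels": ref.num_voxels,
            "reference_mean": ref_mean,
            "suvr": suvrs[name],
        })
    return pd.DataFrame(rows)
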