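"""Seeded, file-based test fixtures built from the simulation pieces.

Every scenario is fully determined by its spec (name, seed, grid, motion),
so rebuilding a fixture yields byte-identical volumes — tests never need
stored binary data or network access.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import InvalidArgumentError
from .geometry import (
    RigidParams,
    build_transform,
    decompose_transform,
    resample_mask,
    resample_volume,
    save_mask,
    save_volume,
)
from .petsim import (
    CountModel,
    PhantomConfig,
    add_poisson_noise,
    default_angles,
    fbp_reconstruct,
    make_phantom,
    project_to_sinograms,
    random_motion,
    scale_counts,
)

__all__ = ["FixtureSpec", "build_fixture", "SCENARIOS"]

SCENARIOS = (
    "noise-free-aligned",
    "noise-free-moved",
    "20min-moved",
    "5min-moved",
    "suvr-phantom",
)

_DURATIONS = {"20min-moved": 1200.0, "5min-moved": 300.0}


@dataclass(frozen=True)
class FixtureSpec:
    scenario: str
    seed: int = 0
    grid: int = 64
    motion: RigidParams | str = "random"

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise InvalidArgumentError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if self.grid < 16:
            raise InvalidArgumentError("grid must be >= 16")


def _motion_for(spec: FixtureSpec) -> RigidParams:
    if spec.scenario == "noise-free-aligned":
        return RigidParams()
    if isinstance(spec.motion, RigidParams):
        return spec.motion
    return random_motion(1, seed=spec.seed + 1)[0]


def build_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate the fixture file set; returns a name -> path map.

    Writes pet.nii, mr.nii, seg.nii and truth.json (applied matrix, its
    inverse's parameters, rotation center, count model and phantom config).
    The suvr-phantom scenario additionally writes four 5-minute dynamic
    frames covering 50-70 min post-injection.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = PhantomConfig(shape=(spec.grid,) * 3,
                        voxel_size_mm=192.0 / spec.grid,
                        seed=spec.seed)
    pet, mr, seg = make_phantom(cfg)
    center = pet.world_center()
    motion = _motion_for(spec)
    applied = build_transform(motion, center)
    truth = decompose_transform(np.linalg.inv(applied), center)

    moved_mr = resample_volume(mr, applied, "trilinear")
    moved_seg = resample_mask(seg, applied)

    truth_record = {
        "scenario": spec.scenario,
        "seed": spec.seed,
        "grid": spec.grid,
        "applied_params": motion.as_dict(),
        "applied_matrix": applied.tolist(),
        "truth_params": truth.as_dict(),
        "rotation_center_mm": center.tolist(),
        "phantom": {
            "shape": list(cfg.shape),
            "voxel_size_mm": cfg.voxel_size_mm,
            "uptake": [cfg.uptake_wm, cfg.uptake_gm, cfg.uptake_ventricle],
        },
    }

    paths: dict[str, Path] = {}
    if spec.scenario in _DURATIONS:
        duration = _DURATIONS[spec.scenario]
        cm = CountModel(duration_s=duration)
        sino = project_to_sinograms(pet, default_angles(min(spec.grid * 2, 180)))
        noisy = add_poisson_noise(scale_counts(sino, cm), seed=spec.seed + 2)
        pet_out = fbp_reconstruct(noisy, "hamming",
                                  output_size=pet.shape[0], affine=pet.affine)
        truth_record["count_model"] = {
            "dose_mbq": cm.dose_mbq,
            "uptake_fraction": cm.uptake_fraction,
            "sensitivity_kcps_per_mbq": cm.sensitivity_kcps_per_mbq,
            "duration_s": cm.duration_s,
            "expected_counts": cm.expected_counts,
            "noisy_counts": noisy.total_counts,
        }
    else:
        pet_out = pet

    paths["pet"] = out_dir / "pet.nii"
    save_volume(pet_out, paths["pet"])
    paths["mr"] = out_dir / "mr.nii"
    save_volume(moved_mr, paths["mr"])
    paths["seg"] = out_dir / "seg.nii"
    save_mask(moved_seg, paths["seg"])

    if spec.scenario == "suvr-phantom":
        # four equal 5-min frames spanning 50-70 min post-injection
        for k in range(4):
            frame = pet.copy_with(pet.data.copy())
            frame.frame_time = (3000.0 + 300.0 * k, 3000.0 + 300.0 * (k + 1))
            p = out_dir / f"frame{k}.nii"
            save_volume(frame, p)
            paths[f"frame{k}"] = p
        truth_record["frame_times_s"] = [
            [3000.0 + 300.0 * k, 3000.0 + 300.0 * (k + 1)] for k in range(4)
        ]

    paths["truth"] = out_dir / "truth.json"
    paths["truth"].write_text(json.dumps(truth_record, indent=2))
    return paths
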