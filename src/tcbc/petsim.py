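"""PET noise/motion simulation benchmark.

Builds a paired digital phantom (PET uptake, T1w-like MR, label
segmentation), forward-projects the PET volume slice-by-slice to 2-D
sinograms, scales them to a realistic count level, adds Poisson noise,
reconstructs by filtered back-projection, and drives repeated
random-motion registration trials for both registration methods.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.transform import iradon, radon

from .core import TcbcConfig, select_target_roi, tcbc_register
from .errors import InvalidArgumentError
from .geometry import (
    ImageVolume,
    PARAM_NAMES,
    ROIMask,
    RigidParams,
    build_transform,
    decompose_transform,
    refine_grid,
    resample_mask,
    resample_volume,
)
from .mi import HistogramConfig, mi_register

__all__ = [
    "PhantomConfig",
    "CountModel",
    "SinogramStack",
    "make_phantom",
    "project_to_sinograms",
    "scale_counts",
    "add_poisson_noise",
    "fbp_reconstruct",
    "random_motion",
    "run_benchmark",
    "default_angles",
    "WM_LEFT",
    "WM_RIGHT",
    "VENTRICLE",
    "GM_SECTORS",
]

# FreeSurfer-style white-matter IDs; stand-in IDs for the other tissues.
WM_LEFT = 2
WM_RIGHT = 41
VENTRICLE = 4
GM_SECTORS = (1001, 1002, 1003, 1004)


@dataclass
class PhantomConfig:
    """Geometry and contrast of the synthetic brain phantom.

    Uptake values emulate an amyloid tracer in a low-amyloid subject: high
    uniform white matter, lower gray matter, near-zero ventricles.  The
    gray-matter shell is split into four sector labels so quantification
    tests have disjoint cortical target ROIs.
    """

    shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_mm: float = 2.0
    uptake_wm: float = 1.0
    uptake_gm: float = 0.5
    uptake_ventricle: float = 0.05
    uptake_background: float = 0.0
    uptake_scalp: float = 0.12
    mr_wm: float = 1.0
    mr_gm: float = 0.55
    mr_ventricle: float = 0.12
    mr_background: float = 0.0
    mr_skull: float = 0.05
    mr_scalp: float = 0.85
    pet_smooth_fwhm_mm: float = 4.0
    mr_smooth_fwhm_mm: float = 2.0
    # smooth multiplicative T1w inhomogeneity (fractional amplitude) and
    # spatially varying gray-matter tracer uptake: MR-only and PET-only
    # confounds that real scans always carry
    mr_bias_amplitude: float = 0.25
    gm_uptake_heterogeneity: float = 0.25
    # semi-axes of the outer (brain) ellipsoid as fractions of the FOV
    brain_fraction: tuple[float, float, float] = (0.33, 0.40, 0.29)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.uptake_wm > self.uptake_gm > self.uptake_ventricle >= 0):
            raise InvalidArgumentError(
                "uptake must satisfy WM > GM > ventricle >= 0"
            )
        if min(self.shape) < 16:
            raise InvalidArgumentError(
                "grid too small to contain the phantom shells (need >= 16)"
            )
        if self.voxel_size_mm <= 0:
            raise InvalidArgumentError("voxel size must be positive")
        if max(self.brain_fraction) * 1.16 >= 0.5:
            raise InvalidArgumentError(
                "brain plus skull/scalp shells must fit inside the field "
                "of view"
            )

    @property
    def affine(self) -> np.ndarray:
        """World-centered scaling affine (world origin at volume center)."""
        s = self.voxel_size_mm
        a = np.diag([s, s, s, 1.0])
        a[:3, 3] = -0.5 * (np.asarray(self.shape) - 1) * s
        return a


def _ellipsoid(x, y, z, center, semi) -> np.ndarray:
    return (((x - center[0]) / semi[0]) ** 2
            + ((y - center[1]) / semi[1]) ** 2
            + ((z - center[2]) / semi[2]) ** 2) <= 1.0


def make_phantom(cfg: PhantomConfig | None = None
                 ) -> tuple[ImageVolume, ImageVolume, ROIMask]:
    """Build the (PET, MR, segmentation) phantom triple.

    The white matter is a central ellipsoid plus four jittered lobes, so it
    is deliberately non-convex and rotationally asymmetric; two off-center
    ventricles are carved out of it.
    """
    cfg = cfg or PhantomConfig()
    rng = np.random.default_rng(cfg.seed)
    affine = cfg.affine
    s = cfg.voxel_size_mm
    nx, ny, nz = cfg.shape
    # world coordinates of voxel centers
    x = (np.arange(nx) - (nx - 1) / 2) * s
    y = (np.arange(ny) - (ny - 1) / 2) * s
    z = (np.arange(nz) - (nz - 1) / 2) * s
    x, y, z = np.meshgrid(x, y, z, indexing="ij")
    fov = np.asarray(cfg.shape) * s
    a, b, c = np.asarray(cfg.brain_fraction) * fov

    brain = _ellipsoid(x, y, z, (0, 0, 0), (a, b, c))
    # gyrus-like angular undulation of the white-matter boundary: many
    # small lobes give the registration objective rotational leverage the
    # way real cortical folding does
    u = x / (0.56 * a)
    v = (y - 0.05 * b) / (0.60 * b)
    w = (z + 0.05 * c) / (0.56 * c)
    rho = np.sqrt(u**2 + v**2 + w**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.arctan2(v, u)
        theta = np.arccos(np.clip(np.where(rho > 0, w / np.maximum(rho, 1e-12),
                                           1.0), -1, 1))
    wave = (0.10 * np.sin(4 * phi + 0.7) * np.sin(2 * theta)
            + 0.08 * np.cos(3 * phi - 1.3) * np.cos(3 * theta)
            + 0.06 * np.sin(5 * phi) * np.sin(4 * theta + 0.5))
    wm = rho <= 1.0 + wave
    # asymmetric lobes make the white matter non-convex and give the
    # objective leverage against all three rotations
    lobe_centers = np.array([
        [+0.46, +0.28, +0.20],
        [-0.38, +0.40, -0.18],
        [+0.34, -0.48, -0.08],
        [-0.26, -0.38, +0.30],
        [+0.06, +0.10, -0.40],
    ])
    lobe_semis = np.array([
        [0.34, 0.26, 0.30],
        [0.28, 0.32, 0.26],
        [0.32, 0.24, 0.34],
        [0.26, 0.34, 0.28],
        [0.30, 0.28, 0.24],
    ])
    lobe_centers = lobe_centers + rng.uniform(-0.04, 0.04, size=(5, 3))
    for (cx, cy, cz), (sx, sy, sz) in zip(lobe_centers, lobe_semis):
        wm |= _ellipsoid(x, y, z, (cx * a, cy * b, cz * c),
                         (sx * a, sy * b, sz * c))
    wm &= _ellipsoid(x, y, z, (0, 0, 0), (0.86 * a, 0.88 * b, 0.86 * c))
    vent = _ellipsoid(x, y, z, (-0.14 * a, -0.04 * b, 0.10 * c),
                      (0.12 * a, 0.28 * b, 0.15 * c))
    vent |= _ellipsoid(x, y, z, (+0.14 * a, -0.04 * b, 0.10 * c),
                       (0.12 * a, 0.28 * b, 0.15 * c))
    vent &= wm
    wm &= ~vent
    gm = brain & ~wm & ~vent
    skull = _ellipsoid(x, y, z, (0, 0, 0),
                       (1.07 * a, 1.07 * b, 1.07 * c)) & ~brain
    scalp = _ellipsoid(x, y, z, (0, 0, 0),
                       (1.15 * a, 1.15 * b, 1.15 * c)) & ~brain & ~skull

    seg = np.zeros(cfg.shape, dtype=np.int32)
    seg[wm & (x < 0)] = WM_LEFT
    seg[wm & (x >= 0)] = WM_RIGHT
    seg[vent] = VENTRICLE
    quadrant = (y >= 0).astype(int) * 2 + (z >= 0).astype(int)
    for q, label in enumerate(GM_SECTORS):
        seg[gm & (quadrant == q)] = label

    pet = np.full(cfg.shape, cfg.uptake_background, dtype=float)
    pet[gm] = cfg.uptake_gm
    if cfg.gm_uptake_heterogeneity > 0:
        # smooth random modulation of GM uptake: tracer binding is patchy
        # in a way T1w intensity is not
        noise = rng.standard_normal(cfg.shape)
        fieldg = ndimage.gaussian_filter(noise, 30.0 / s)
        fieldg /= max(np.abs(fieldg).max(), 1e-12)
        pet[gm] *= 1.0 + cfg.gm_uptake_heterogeneity * fieldg[gm]
    pet[wm] = cfg.uptake_wm
    pet[vent] = cfg.uptake_ventricle
    pet[scalp] = cfg.uptake_scalp
    mr = np.full(cfg.shape, cfg.mr_background, dtype=float)
    mr[gm] = cfg.mr_gm
    mr[wm] = cfg.mr_wm
    mr[vent] = cfg.mr_ventricle
    mr[skull] = cfg.mr_skull
    mr[scalp] = cfg.mr_scalp
    if cfg.mr_bias_amplitude > 0:
        # low-order multiplicative inhomogeneity, the classic T1w artifact
        noise = rng.standard_normal(cfg.shape)
        fieldb = ndimage.gaussian_filter(noise, 60.0 / s)
        fieldb /= max(np.abs(fieldb).max(), 1e-12)
        mr *= 1.0 + cfg.mr_bias_amplitude * fieldb

    if cfg.pet_smooth_fwhm_mm > 0:
        pet = ndimage.gaussian_filter(
            pet, cfg.pet_smooth_fwhm_mm / 2.355 / s)
    if cfg.mr_smooth_fwhm_mm > 0:
        mr = ndimage.gaussian_filter(mr, cfg.mr_smooth_fwhm_mm / 2.355 / s)

    return (ImageVolume(pet, affine.copy()),
            ImageVolume(mr, affine.copy()),
            ROIMask(seg, affine.copy()))


@dataclass
class CountModel:
    """Global count scaling for a static frame of given duration."""

    duration_s: float
    dose_mbq: float = 370.0
    uptake_fraction: float = 0.05
    sensitivity_kcps_per_mbq: float = 15.0

    def __post_init__(self) -> None:
        for v in (self.duration_s, self.dose_mbq, self.uptake_fraction,
                  self.sensitivity_kcps_per_mbq):
            if v <= 0:
                raise InvalidArgumentError("count-model fields must be > 0")

    @property
    def expected_counts(self) -> float:
        # kcps/MBq -> cps/MBq
        return (self.dose_mbq * self.uptake_fraction
                * self.sensitivity_kcps_per_mbq * 1e3 * self.duration_s)


@dataclass
class SinogramStack:
    """Per-slice projection data, shape (n_angles, n_bins, n_slices)."""

    data: np.ndarray
    angles_deg: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.data.ndim != 3:
            raise InvalidArgumentError("sinogram stack must be 3-D")
        if self.data.shape[0] != self.angles_deg.size:
            raise InvalidArgumentError("first axis must match the angle list")

    @property
    def total_counts(self) -> float:
        return float(self.data.sum())


def default_angles(n: int = 180) -> np.ndarray:
    return np.linspace(0.0, 180.0, n, endpoint=False)


def project_to_sinograms(vol: ImageVolume,
                         angles_deg: np.ndarray | None = None) -> SinogramStack:
    """Slice-by-slice discrete Radon transform along the third axis."""
    if angles_deg is None:
        angles_deg = default_angles()
    angles_deg = np.asarray(angles_deg, dtype=float)
    if angles_deg.size == 0:
        raise InvalidArgumentError("angle list must be non-empty")
    if np.any(vol.data < -1e-9):
        raise InvalidArgumentError("volume must be non-negative")
    slices = []
    for k in range(vol.shape[2]):
        # skimage returns (bins, angles); store (angles, bins)
        slices.append(radon(vol.data[:, :, k], theta=angles_deg,
                            circle=False).T)
    return SinogramStack(np.stack(slices, axis=-1), angles_deg)


def scale_counts(s: SinogramStack, cm: CountModel) -> SinogramStack:
    """Globally scale the stack so its total equals the expected counts."""
    total = s.total_counts
    if total <= 0:
        raise InvalidArgumentError("cannot scale a zero-total sinogram")
    factor = cm.expected_counts / total
    return SinogramStack(s.data * factor, s.angles_deg.copy())


def add_poisson_noise(s: SinogramStack, seed: int | None = None
                      ) -> SinogramStack:
    """Replace every bin by an independent Poisson draw with that mean."""
    if np.any(s.data < 0):
        raise InvalidArgumentError("sinogram bins must be non-negative")
    rng = np.random.default_rng(seed)
    return SinogramStack(rng.poisson(s.data).astype(float),
                         s.angles_deg.copy())


_FILTERS = {"hamming": "hamming", "ramp": "ramp"}


def fbp_reconstruct(s: SinogramStack, filter_name: str = "hamming",
                    output_size: int | None = None,
                    affine: np.ndarray | None = None) -> ImageVolume:
    """Per-slice filtered back-projection; negatives clipped to zero.

    ``output_size``/``affine`` restore the original image grid so the
    reconstruction stays in registration with the phantom.
    """
    if filter_name not in _FILTERS:
        raise InvalidArgumentError(
            f"unknown filter {filter_name!r}; expected one of {sorted(_FILTERS)}"
        )
    angles = s.angles_deg
    step = np.median(np.diff(np.sort(angles))) if angles.size > 1 else 180.0
    if np.ptp(angles) + step < 180.0 - 1e-9:
        raise InvalidArgumentError("angles must cover at least a 180 deg span")
    n_slices = s.data.shape[2]
    if output_size is None:
        # invert the circle=False padding used during projection
        output_size = int(np.floor(s.data.shape[1] / np.sqrt(2)))
    out = np.empty((output_size, output_size, n_slices), dtype=float)
    for k in range(n_slices):
        out[:, :, k] = iradon(s.data[:, :, k].T, theta=angles,
                              filter_name=_FILTERS[filter_name],
                              circle=False, output_size=output_size)
    np.clip(out, 0.0, None, out=out)
    if affine is None:
        affine = np.eye(4)
    return ImageVolume(out, np.asarray(affine, dtype=float).copy())


def random_motion(n: int, t_range: tuple[float, float] = (-10.0, 10.0),
                  r_range: tuple[float, float] = (-10.0, 10.0),
                  seed: int | None = None) -> list[RigidParams]:
    """Draw ``n`` independent uniform rigid motions."""
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    if not (t_range[0] < t_range[1] and r_range[0] < r_range[1]):
        raise InvalidArgumentError("ranges must satisfy low < high")
    rng = np.random.default_rng(seed)
    draws = rng.uniform(size=(n, 6))
    draws[:, :3] = t_range[0] + draws[:, :3] * (t_range[1] - t_range[0])
    draws[:, 3:] = r_range[0] + draws[:, 3:] * (r_range[1] - r_range[0])
    return [RigidParams.from_array(row) for row in draws]


def run_benchmark(trials: int,
                  noise_durations_s: list[float | None],
                  methods: list[str],
                  phantom_cfg: PhantomConfig | None = None,
                  reg_config: TcbcConfig | None = None,
                  hist_config: HistogramConfig | None = None,
                  wm_labels: tuple[int, ...] = (WM_LEFT, WM_RIGHT),
                  n_angles: int = 180,
                  seg_upsample: int = 2,
                  seed: int = 0,
                  progress: bool = False) -> pd.DataFrame:
    """Random-motion recovery benchmark.

    Per trial: draw a rigid motion, apply it to the MR image and
    segmentation (the PET stays fixed), then for each noise duration build
    a fresh noisy FBP reconstruction and run each requested method.  The
    ground truth is the decomposition of the inverse applied matrix about
    the shared rotation center, since registration recovers the
    mask-to-PET alignment.  ``None`` in ``noise_durations_s`` means
    noise-free (the phantom PET itself).  The moved segmentation is
    quantized on a ``seg_upsample``-times finer grid, mimicking the
    higher-resolution MR grid real segmentations live on.

    Returns a tidy table, one row per trial x duration x method.
    """
    if trials < 1:
        raise InvalidArgumentError("trials must be >= 1")
    unknown = set(methods) - {"tcbc", "nmi"}
    if unknown:
        raise InvalidArgumentError(f"unknown methods: {sorted(unknown)}")
    phantom_cfg = phantom_cfg or PhantomConfig()
    reg_config = reg_config or TcbcConfig(n_starts=10)
    hist_config = hist_config or HistogramConfig()

    pet, mr, seg = make_phantom(phantom_cfg)
    center = pet.world_center()
    fine_target = refine_grid(seg, seg_upsample) if seg_upsample > 1 else None
    angles = default_angles(n_angles)
    sino = project_to_sinograms(pet, angles)
    scaled = {
        d: scale_counts(sino, CountModel(duration_s=d))
        for d in noise_durations_s if d is not None
    }
    motions = random_motion(trials, seed=np.random.default_rng([seed, 0])
                            .integers(2**31))

    iterator = range(trials)
    if progress:
        from tqdm import tqdm
        iterator = tqdm(iterator, desc="trials")

    rows = []
    for i in iterator:
        applied = build_transform(motions[i], center)
        truth = decompose_transform(np.linalg.inv(applied), center)
        moved_mr = resample_volume(mr, applied, "trilinear")
        moved_seg = resample_mask(seg, applied, like=fine_target)
        moved_wm = select_target_roi(moved_seg, list(wm_labels))
        for d in noise_durations_s:
            if d is None:
                noisy_pet = pet
            else:
                noise_seed = int(np.random.default_rng(
                    [seed, 1, i, int(d)]).integers(2**31))
                noisy = add_poisson_noise(scaled[d], seed=noise_seed)
                noisy_pet = fbp_reconstruct(
                    noisy, "hamming", output_size=pet.shape[0],
                    affine=pet.affine)
            for method in methods:
                trial_cfg = replace(
                    reg_config,
                    seed=int(np.random.default_rng(
                        [seed, 2, i]).integers(2**31)),
                )
                t0 = time.perf_counter()
                row = {
                    "trial": i,
                    "method": method,
                    "duration_s": np.nan if d is None else float(d),
                    "failed": False,
                }
                try:
                    if method == "tcbc":
                        res = tcbc_register(noisy_pet, moved_wm, trial_cfg,
                                            center=center)
                    else:
                        res = mi_register(noisy_pet, moved_mr, trial_cfg,
                                          hist_config, center=center)
                except Exception as exc:  # failed trials recorded, not fatal
                    row.update({"failed": True, "error": str(exc)})
                    rows.append(row)
                    continue
                est = res.params.as_array()
                tru = truth.as_array()
                residual = decompose_transform(res.matrix @ applied, center)
                row.update({
                    "objective": res.objective,
                    "converged": all(
                        c for c, f in zip(res.converged, res.start_objectives)
                        if np.isfinite(f)) and any(res.converged),
                    "best_start": res.best_start,
                    "n_evaluations": res.n_evaluations,
                    "wall_s": time.perf_counter() - t0,
                })
                for j, name in enumerate(PARAM_NAMES):
                    row[f"true_{name}"] = tru[j]
                    row[f"est_{name}"] = est[j]
                    row[f"err_{name}"] = est[j] - tru[j]
                for name, value in residual.as_dict().items():
                    row[f"resid_{name}"] = value
                rows.append(row)
    return pd.DataFrame(rows)
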