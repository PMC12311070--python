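"""ROI-uptake objective and multi-start simplex registration.

The registration objective is the mean PET intensity sampled (trilinearly)
at the transformed world positions of the target-ROI voxel centers.  For a
tracer with high, uniform uptake in the target structure the objective
peaks when the ROI lands on that structure, so rigid alignment is obtained
by maximizing it with a derivative-free simplex search restarted from many
random initial parameter sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import ndimage, optimize

from .errors import InvalidArgumentError, RegistrationFailureError
from .geometry import (
    ImageVolume,
    ROIMask,
    RigidParams,
    apply_transform,
    build_transform,
)

__all__ = [
    "TcbcConfig",
    "RegistrationResult",
    "masked_mean_intensity",
    "tcbc_register",
    "select_target_roi",
]


@dataclass
class TcbcConfig:
    """Multi-start Nelder-Mead settings shared by both registration methods.

    Initial guesses are drawn uniformly from the configured ranges; the
    search itself is unconstrained.  ``sense`` selects whether mean ROI
    uptake is maximized (high-uptake target, e.g. amyloid WM) or minimized
    (low-uptake target).  ``max_eval_points`` optionally caps the number of
    sample points used per objective evaluation (deterministic seeded
    subsample) to bound runtime on large volumes; ``None`` uses every voxel.
    """

    n_starts: int = 100
    init_translation_range: tuple[float, float] = (-10.0, 10.0)
    init_rotation_range: tuple[float, float] = (-10.0, 10.0)
    sense: str = "maximize"
    xatol: float = 1e-4
    fatol: float = 1e-4
    max_iter: int = 1200  # 200 x 6 parameters
    seed: int | None = None
    max_eval_points: int | None = None
    # per-coordinate edge length of the initial simplex (mm / degrees);
    # scipy's default (5% of the start point) is far too local here
    init_simplex_step: float = 2.0

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise InvalidArgumentError("n_starts must be >= 1")
        for lo, hi in (self.init_translation_range, self.init_rotation_range):
            if not lo < hi:
                raise InvalidArgumentError("init range must satisfy low < high")
        if self.sense not in ("maximize", "minimize"):
            raise InvalidArgumentError("sense must be 'maximize' or 'minimize'")
        if self.xatol <= 0 or self.fatol <= 0 or self.max_iter <= 0:
            raise InvalidArgumentError("tolerances and max_iter must be > 0")
        if self.max_eval_points is not None and self.max_eval_points < 1:
            raise InvalidArgumentError("max_eval_points must be >= 1 or None")
        if self.init_simplex_step <= 0:
            raise InvalidArgumentError("init_simplex_step must be > 0")

    def draw_starts(self) -> np.ndarray:
        """(n_starts, 6) initial parameter sets; a prefix-stable stream so
        increasing n_starts keeps earlier starts identical."""
        rng = np.random.default_rng(
            None if self.seed is None else [int(self.seed), 0]
        )
        t_lo, t_hi = self.init_translation_range
        r_lo, r_hi = self.init_rotation_range
        starts = rng.uniform(size=(self.n_starts, 6))
        starts[:, :3] = t_lo + starts[:, :3] * (t_hi - t_lo)
        starts[:, 3:] = r_lo + starts[:, 3:] * (r_hi - r_lo)
        return starts

    def subsample_rng(self) -> np.random.Generator:
        return np.random.default_rng(
            None if self.seed is None else [int(self.seed), 1]
        )


@dataclass
class RegistrationResult:
    """Outcome of one multi-start registration."""

    params: RigidParams
    matrix: np.ndarray
    objective: float
    start_objectives: list[float]
    converged: list[bool]
    best_start: int
    center: np.ndarray
    n_evaluations: int = 0

    def __post_init__(self) -> None:
        finite = [v for v in self.start_objectives if np.isfinite(v)]
        if finite and not np.isclose(self.objective, min(finite)):
            raise InvalidArgumentError(
                "best objective must equal the extremum over starts"
            )


def _roi_world_points(roi: ROIMask) -> np.ndarray:
    idx = np.argwhere(np.asarray(roi.data) != 0)
    if idx.shape[0] == 0:
        raise InvalidArgumentError("ROI mask is empty")
    return apply_transform(roi.affine, idx.astype(float))


class _PointSampler:
    """Samples a volume trilinearly at transformed world points.

    Precomputes the world positions once; each evaluation is a single
    matrix product plus one interpolation call.
    """

    def __init__(self, vol: ImageVolume, world_points: np.ndarray):
        self.data = np.ascontiguousarray(vol.data, dtype=float)
        self.inv_affine = np.linalg.inv(vol.affine)
        self.points = world_points

    def sample(self, m: np.ndarray) -> np.ndarray:
        world = apply_transform(m, self.points)
        voxel = apply_transform(self.inv_affine, world)
        return ndimage.map_coordinates(
            self.data, voxel.T, order=1, mode="constant", cval=0.0,
            prefilter=False,
        )

    def mean(self, m: np.ndarray) -> float:
        # out-of-field samples contribute 0 but stay in the denominator
        return float(self.sample(m).mean())


def masked_mean_intensity(pet: ImageVolume, roi: ROIMask, params: RigidParams,
                          center: Sequence[float] = (0.0, 0.0, 0.0)) -> float:
    """Mean PET intensity over the transformed target ROI.

    Returns (1/N) * sum over ROI voxels v of PET(M . world(v)), PET sampled
    trilinearly; samples falling outside the PET field contribute 0 and
    still count in N (the fixed ROI voxel count).
    """
    pts = _roi_world_points(roi)
    sampler = _PointSampler(pet, pts)
    return sampler.mean(build_transform(params, center))


def multistart_nelder_mead(objective: Callable[[np.ndarray], float],
                           config: TcbcConfig,
                           center: np.ndarray) -> RegistrationResult:
    """Run Nelder-Mead from each configured start; keep the lowest minimum.

    ``objective`` maps a 6-vector (tx,ty,tz,rx,ry,rz) to the value being
    *minimized*.  Ties are broken by lowest start index.
    """
    starts = config.draw_starts()
    finals: list[float] = []
    converged: list[bool] = []
    best: optimize.OptimizeResult | None = None
    best_idx = -1
    n_eval = 0
    for i, x0 in enumerate(starts):
        simplex = np.vstack([x0, x0 + np.eye(6) * config.init_simplex_step])
        try:
            res = optimize.minimize(
                objective, x0, method="Nelder-Mead",
                options={
                    "xatol": config.xatol,
                    "fatol": config.fatol,
                    "maxiter": config.max_iter,
                    "initial_simplex": simplex,
                },
            )
        except (FloatingPointError, ValueError):
            finals.append(np.nan)
            converged.append(False)
            continue
        n_eval += int(res.nfev)
        if not np.isfinite(res.fun):
            finals.append(np.nan)
            converged.append(False)
            continue
        finals.append(float(res.fun))
        converged.append(bool(res.success))
        if best is None or res.fun < best.fun:
            best = res
            best_idx = i
    if best is None:
        raise RegistrationFailureError("no start produced a finite objective")
    params = RigidParams.from_array(best.x)
    return RegistrationResult(
        params=params,
        matrix=build_transform(params, center),
        objective=float(best.fun),
        start_objectives=finals,
        converged=converged,
        best_start=best_idx,
        center=np.asarray(center, dtype=float),
        n_evaluations=n_eval,
    )


def _maybe_subsample(points: np.ndarray, config: TcbcConfig) -> np.ndarray:
    if config.max_eval_points is None or len(points) <= config.max_eval_points:
        return points
    idx = config.subsample_rng().choice(
        len(points), size=config.max_eval_points, replace=False
    )
    return points[np.sort(idx)]


def tcbc_register(pet: ImageVolume, roi: ROIMask,
                  config: TcbcConfig | None = None,
                  center: Sequence[float] | None = None) -> RegistrationResult:
    """Estimate the rigid transform aligning an MR-space ROI with PET.

    Runs ``config.n_starts`` independent Nelder-Mead minimizations of the
    negated (or, for ``sense='minimize'``, plain) masked mean intensity and
    returns the start with the lowest final objective.  The returned matrix
    is the one to apply to the MR image and all MR-derived masks.
    """
    config = config or TcbcConfig()
    if center is None:
        center = pet.world_center()
    center = np.asarray(center, dtype=float)
    pts = _maybe_subsample(_roi_world_points(roi), config)
    sampler = _PointSampler(pet, pts)
    sign = -1.0 if config.sense == "maximize" else 1.0
    # optimize on a normalized intensity scale so fatol is meaningful for
    # arbitrarily scaled inputs (e.g. count-scaled reconstructions)
    scale = float(np.abs(pet.data).max())
    if scale == 0.0:
        scale = 1.0

    def objective(x: np.ndarray) -> float:
        return sign * sampler.mean(
            build_transform(RigidParams.from_array(x), center)
        ) / scale

    result = multistart_nelder_mead(objective, config, center)
    result.objective *= scale
    result.start_objectives = [v * scale for v in result.start_objectives]
    return result


def select_target_roi(segmentation: ROIMask,
                      label_ids: Iterable[int]) -> ROIMask:
    """Binary union of the requested integer labels of a segmentation."""
    label_ids = list(label_ids)
    if not label_ids:
        raise InvalidArgumentError("label_ids must be non-empty")
    mask = np.isin(np.asarray(segmentation.data), label_ids)
    if not mask.any():
        raise InvalidArgumentError(
            f"labels {sorted(label_ids)} select no voxels"
        )
    return ROIMask(data=mask, affine=segmentation.affine.copy())
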