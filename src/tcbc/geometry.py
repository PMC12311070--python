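"""Rigid-body transforms and volume resampling in world (mm) space.

All transforms are 4x4 homogeneous matrices acting on world coordinates
obtained through each volume's voxel-to-world affine, so anisotropic voxel
grids are handled uniformly.  The six-parameter rigid transform is factored
as ``T(tx,ty,tz) . Rz(rz) . Ry(ry) . Rx(rx)`` about an explicit rotation
center; rotations are right-handed and expressed in degrees at the
interface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import DegenerateDecompositionError, InvalidArgumentError

__all__ = [
    "RigidParams",
    "ImageVolume",
    "ROIMask",
    "build_transform",
    "decompose_transform",
    "is_rigid",
    "resample_volume",
    "resample_mask",
    "refine_grid",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_transform",
    "load_transform",
]

PARAM_NAMES = ("tx", "ty", "tz", "rx", "ry", "rz")


@dataclass(frozen=True)
class RigidParams:
    """Six rigid-body degrees of freedom.

    Translations ``tx, ty, tz`` are in millimetres; rotations ``rx, ry, rz``
    are in degrees about the world x, y and z axes (right-handed,
    counterclockwise positive looking down the axis toward the origin).
    """

    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0
    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise InvalidArgumentError("rigid parameters must all be finite")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.tx, self.ty, self.tz, self.rx, self.ry, self.rz], dtype=float
        )

    @classmethod
    def from_array(cls, values: Sequence[float]) -> "RigidParams":
        values = np.asarray(values, dtype=float)
        if values.shape != (6,):
            raise InvalidArgumentError("expected exactly six parameters")
        return cls(*values.tolist())

    def as_dict(self) -> dict:
        return dict(zip(PARAM_NAMES, self.as_array().tolist()))


@dataclass
class ImageVolume:
    """A 3-D scalar volume with a voxel-to-world affine.

    ``frame_time`` optionally holds (start, end) acquisition times in
    seconds post-injection for dynamic PET frames.
    """

    data: np.ndarray
    affine: np.ndarray
    frame_time: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 2:
            raise InvalidArgumentError("volume must be 3-D with >= 2 voxels per axis")
        if self.affine.shape != (4, 4):
            raise InvalidArgumentError("affine must be a 4x4 matrix")
        if np.any(self.spacing <= 0):
            raise InvalidArgumentError("voxel spacing must be strictly positive")

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing in mm per axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def world_center(self) -> np.ndarray:
        """Geometric center of the volume's world-space bounding box."""
        corners = np.array(
            [[i, j, k] for i in (0, self.shape[0] - 1)
             for j in (0, self.shape[1] - 1)
             for k in (0, self.shape[2] - 1)],
            dtype=float,
        )
        world = apply_transform(self.affine, corners)
        return 0.5 * (world.min(axis=0) + world.max(axis=0))

    def copy_with(self, data: np.ndarray) -> "ImageVolume":
        return ImageVolume(data=data, affine=self.affine.copy(),
                           frame_time=self.frame_time)


@dataclass
class ROIMask:
    """Binary or integer-label volume sharing a grid with an ImageVolume."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer) and \
                self.data.dtype != bool:
            raise InvalidArgumentError("mask data must be integer or boolean")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise InvalidArgumentError("mask must be 3-D")
        if self.affine.shape != (4, 4):
            raise InvalidArgumentError("affine must be a 4x4 matrix")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def num_voxels(self) -> int:
        """Number of nonzero voxels."""
        return int(np.count_nonzero(self.data))

    def labels(self) -> np.ndarray:
        values = np.unique(self.data)
        return values[values != 0]

    def binarized(self) -> "ROIMask":
        return ROIMask(data=(self.data != 0), affine=self.affine.copy())


def _rotation_matrix(rx_deg: float, ry_deg: float, rz_deg: float) -> np.ndarray:
    """3x3 rotation Rz(rz) @ Ry(ry) @ Rx(rx), angles in degrees."""
    rx, ry, rz = np.deg2rad([rx_deg, ry_deg, rz_deg])
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    r_x = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    r_y = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    r_z = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return r_z @ r_y @ r_x


def build_transform(params: RigidParams,
                    center: Sequence[float] = (0.0, 0.0, 0.0)) -> np.ndarray:
    """Compose the 4x4 rigid transform T . Rz . Ry . Rx about ``center``.

    A world point p maps to ``R (p - c) + c + t`` where R is the composed
    rotation, c the rotation center and t the translation vector.
    """
    center = np.asarray(center, dtype=float)
    if center.shape != (3,) or not np.all(np.isfinite(center)):
        raise InvalidArgumentError("center must be a finite 3-vector")
    rot = _rotation_matrix(params.rx, params.ry, params.rz)
    m = np.eye(4)
    m[:3, :3] = rot
    m[:3, 3] = np.array([params.tx, params.ty, params.tz]) + center - rot @ center
    return m


def is_rigid(m: np.ndarray, tol: float = 1e-6) -> bool:
    """True if ``m`` is a proper rigid transform (orthonormal, det +1)."""
    m = np.asarray(m, dtype=float)
    if m.shape != (4, 4):
        return False
    if not np.allclose(m[3], [0, 0, 0, 1], atol=tol):
        return False
    rot = m[:3, :3]
    if not np.allclose(rot @ rot.T, np.eye(3), atol=tol):
        return False
    return bool(np.isclose(np.linalg.det(rot), 1.0, atol=tol))


def decompose_transform(m: np.ndarray,
                        center: Sequence[float] = (0.0, 0.0, 0.0)
                        ) -> RigidParams:
    """Recover the six rigid parameters from a transform about ``center``.

    Uses the same Rz.Ry.Rx factorization as :func:`build_transform`; ry is
    constrained to (-90, 90) degrees.  Raises
    :class:`DegenerateDecompositionError` within 1e-6 degrees of gimbal lock.
    """
    m = np.asarray(m, dtype=float)
    if not is_rigid(m):
        raise InvalidArgumentError("matrix is not a proper rigid transform")
    center = np.asarray(center, dtype=float)
    rot = m[:3, :3]
    sy = -rot[2, 0]
    ry = np.rad2deg(np.arcsin(np.clip(sy, -1.0, 1.0)))
    if abs(abs(ry) - 90.0) < 1e-6:
        raise DegenerateDecompositionError(
            "ry at gimbal lock; rx/rz are not separable"
        )
    rx = np.rad2deg(np.arctan2(rot[2, 1], rot[2, 2]))
    rz = np.rad2deg(np.arctan2(rot[1, 0], rot[0, 0]))
    t = m[:3, 3] - center + rot @ center
    return RigidParams(t[0], t[1], t[2], rx, ry, rz)


def apply_transform(m: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a 4x4 homogeneous transform to an (N, 3) point array."""
    points = np.asarray(points, dtype=float)
    return points @ m[:3, :3].T + m[:3, 3]


_INTERP_ORDERS = {"trilinear": 1, "nearest": 0}


def _voxel_map(source_affine: np.ndarray, m: np.ndarray,
               target_affine: np.ndarray) -> np.ndarray:
    """Voxel-to-voxel pull-back map: target voxel -> source voxel."""
    return np.linalg.inv(source_affine) @ np.linalg.inv(m) @ target_affine


def resample_volume(vol: ImageVolume, m: np.ndarray,
                    interpolation: str = "trilinear",
                    like: ImageVolume | ROIMask | None = None) -> ImageVolume:
    """Resample ``vol`` under the rigid transform ``m`` (pull-back).

    The output lives on the grid of ``like`` (default: the input grid); its
    value at voxel v is the input sampled at world position m^-1 . world(v),
    so the structure in the image moves *by* ``m``.  Samples outside the
    input field are filled with 0.
    """
    if interpolation not in _INTERP_ORDERS:
        raise InvalidArgumentError(
            f"unknown interpolation {interpolation!r}; "
            f"expected one of {sorted(_INTERP_ORDERS)}"
        )
    if not is_rigid(m):
        raise InvalidArgumentError("transform must be rigid")
    target = vol if like is None else like
    k = _voxel_map(vol.affine, m, target.affine)
    out = ndimage.affine_transform(
        vol.data, k[:3, :3], offset=k[:3, 3], output_shape=target.shape,
        order=_INTERP_ORDERS[interpolation], cval=0.0, prefilter=False,
    )
    return ImageVolume(data=out, affine=np.asarray(target.affine, float).copy(),
                       frame_time=vol.frame_time)


def resample_mask(mask: ROIMask, m: np.ndarray,
                  like: ImageVolume | ROIMask | None = None) -> ROIMask:
    """Nearest-neighbour resampling for label/mask volumes."""
    if not is_rigid(m):
        raise InvalidArgumentError("transform must be rigid")
    target = mask if like is None else like
    k = _voxel_map(mask.affine, m, target.affine)
    out = ndimage.affine_transform(
        mask.data.astype(np.int32), k[:3, :3], offset=k[:3, 3],
        output_shape=target.shape, order=0, cval=0, prefilter=False,
    )
    return ROIMask(data=out, affine=np.asarray(target.affine, float).copy())


# ---------------------------------------------------------------------------
# I/O


def refine_grid(ref: ImageVolume | ROIMask, factor: int = 2) -> ROIMask:
    """An empty mask on a ``factor``-times finer grid covering ``ref``.

    Useful as the ``like`` target when resampling label volumes under a
    motion: quantizing the moved boundary at sub-voxel resolution (as a
    higher-resolution MR grid would) strongly reduces aliasing bias.
    """
    if factor < 1:
        raise InvalidArgumentError("factor must be >= 1")
    affine = np.asarray(ref.affine, dtype=float).copy()
    affine[:3, :3] /= factor
    # place fine-voxel centers symmetrically inside each coarse voxel
    affine[:3, 3] -= np.asarray(ref.affine, float)[:3, :3] @ np.full(
        3, (factor - 1) / (2.0 * factor))
    shape = tuple(int(s) * factor for s in ref.shape)
    return ROIMask(np.zeros(shape, dtype=np.int8), affine)


def load_volume(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    return ImageVolume(data=np.asarray(img.dataobj, dtype=float),
                       affine=img.affine)


def save_volume(vol: ImageVolume, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(vol.data.astype(np.float32), vol.affine),
             str(path))


def load_mask(path: str | Path) -> ROIMask:
    img = nib.load(str(path))
    return ROIMask(data=np.asarray(img.dataobj).astype(np.int32),
                   affine=img.affine)


def save_mask(mask: ROIMask, path: str | Path) -> None:
    nib.save(nib.Nifti1Image(mask.data.astype(np.int16), mask.affine),
             str(path))


def save_transform(m: np.ndarray, path: str | Path,
                   params: RigidParams | None = None,
                   center: Sequence[float] | None = None) -> None:
    """Write a 4x4 matrix as 4 rows of 4 floats, plus a JSON sidecar."""
    path = Path(path)
    np.savetxt(path, np.asarray(m, dtype=float), fmt="%.12g")
    sidecar = {"matrix_file": path.name}
    if params is not None:
        sidecar["params"] = params.as_dict()
    if center is not None:
        sidecar["rotation_center_mm"] = list(np.asarray(center, float))
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2)
    )


def load_transform(path: str | Path) -> np.ndarray:
    m = np.loadtxt(path)
    if m.shape != (4, 4):
        raise InvalidArgumentError("transform file must contain a 4x4 matrix")
    return m
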