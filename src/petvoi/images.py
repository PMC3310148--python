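"""In-memory containers for PET volumes, label maps and deformation fields.

All volumes live on a regular RAS grid; world coordinates are
``index * voxel_size`` (mm).  NIfTI-1 is the on-disk form throughout, via
nibabel; dynamic images carry their frame schedule as a sidecar TSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .frames import FrameSchedule

__all__ = ["DynamicImage", "LabelVolume", "DeformationField"]


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def _as_voxel_size(voxel_size) -> tuple:
    v = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,))
    if np.any(v <= 0):
        raise ValueError("voxel size must be positive")
    return tuple(float(x) for x in v)


@dataclass
class DynamicImage:
    """A 4D dynamic PET image: spatial grid x frames, with its schedule."""

    data: np.ndarray  # (nx, ny, nz, n_frames)
    voxel_size: tuple
    schedule: FrameSchedule

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("dynamic image must be 4D (x, y, z, frame)")
        if self.data.shape[3] != self.schedule.n_frames:
            raise ValueError(
                f"image has {self.data.shape[3]} frames but schedule has "
                f"{self.schedule.n_frames}"
            )
        self.voxel_size = _as_voxel_size(self.voxel_size)

    @property
    def shape(self) -> tuple:
        return self.data.shape[:3]

    def to_nifti(self, path, schedule_path=None) -> None:
        path = Path(path)
        nib.save(nib.Nifti1Image(self.data, _affine(self.voxel_size)), path)
        if schedule_path is None:
            stem = path.name.removesuffix(".gz").removesuffix(".nii")
            schedule_path = path.parent / f"{stem}_frames.tsv"
        self.schedule.to_tsv(schedule_path)

    @classmethod
    def from_nifti(cls, path, schedule_path=None) -> "DynamicImage":
        path = Path(path)
        img = nib.load(path)
        if schedule_path is None:
            stem = path.name.removesuffix(".gz").removesuffix(".nii")
            schedule_path = path.parent / f"{stem}_frames.tsv"
        schedule = FrameSchedule.from_tsv(schedule_path)
        vox = tuple(float(v) for v in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj, dtype=float), vox, schedule)


@dataclass
class LabelVolume:
    """Integer label map: 0 is background, positive labels are regions."""

    data: np.ndarray
    voxel_size: tuple
    region_names: dict = field(default_factory=dict)  # label -> name

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label volume must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            self.data = np.rint(self.data).astype(np.int32)
        self.voxel_size = _as_voxel_size(self.voxel_size)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def labels(self) -> np.ndarray:
        """Sorted nonzero labels present in the volume."""
        u = np.unique(self.data)
        return u[u > 0]

    def mask(self, label) -> np.ndarray:
        if np.isscalar(label):
            return self.data == label
        return np.isin(self.data, np.asarray(label))

    def brain_mask(self) -> np.ndarray:
        """Union of all nonzero labels."""
        return self.data > 0

    def to_nifti(self, path) -> None:
        nib.save(
            nib.Nifti1Image(self.data.astype(np.int16), _affine(self.voxel_size)),
            path,
        )

    @classmethod
    def from_nifti(cls, path, region_names=None) -> "LabelVolume":
        img = nib.load(path)
        vox = tuple(float(v) for v in img.header.get_zooms()[:3])
        return cls(
            np.asarray(img.dataobj).astype(np.int32), vox, region_names or {}
        )


@dataclass
class DeformationField:
    """Dense displacement field u(x), in mm, on the image grid.

    The field maps grid points to displaced world positions
    ``x_world + u(x)`` and is applied to images by pull-back resampling.
    """

    displacement: np.ndarray  # (nx, ny, nz, 3), mm
    voxel_size: tuple

    def __post_init__(self):
        self.displacement = np.asarray(self.displacement, dtype=float)
        if self.displacement.ndim != 4 or self.displacement.shape[3] != 3:
            raise ValueError("displacement must have shape (nx, ny, nz, 3)")
        self.voxel_size = _as_voxel_size(self.voxel_size)

    @property
    def shape(self) -> tuple:
        return self.displacement.shape[:3]

    def jacobian_determinant(self) -> np.ndarray:
        """Finite-difference Jacobian determinant of x + u(x), per voxel."""
        jac = np.zeros(self.shape + (3, 3))
        for comp in range(3):
            for axis in range(3):
                du = np.gradient(
                    self.displacement[..., comp], self.voxel_size[axis], axis=axis
                )
                jac[..., comp, axis] = du + (1.0 if comp == axis else 0.0)
        return np.linalg.det(jac)

    def invert(self, n_iter: int = 30, tol: float = 1e-3) -> "DeformationField":
        """Approximate inverse by fixed-point iteration.

        Solves ``v(x) = -u(x + v(x))`` so that composing the two fields is
        close to the identity; accurate for the smooth, small-amplitude
        fields this package generates.
        """
        from scipy.ndimage import map_coordinates

        vox = np.asarray(self.voxel_size)
        v = np.zeros_like(self.displacement)
        idx = np.stack(
            np.meshgrid(*[np.arange(s) for s in self.shape], indexing="ij"), axis=-1
        ).astype(float)
        for _ in range(n_iter):
            coords = idx + v / vox  # sample u at x + v, in voxel units
            u_at = np.stack(
                [
                    map_coordinates(
                        self.displacement[..., c],
                        [coords[..., 0], coords[..., 1], coords[..., 2]],
                        order=1,
                        mode="nearest",
                    )
                    for c in range(3)
                ],
                axis=-1,
            )
            v_new = -u_at
            step = np.max(np.abs(v_new - v))
            v = v_new
            if step < tol:
                break
        return DeformationField(v, self.voxel_size)

    def to_nifti(self, path) -> None:
        # 5D NIfTI displacement convention: (nx, ny, nz, 1, 3), mm
        data = self.displacement[:, :, :, np.newaxis, :]
        nib.save(nib.Nifti1Image(data, _affine(self.voxel_size)), path)

    @classmethod
    def from_nifti(cls, path) -> "DeformationField":
        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=float)
        if data.ndim == 5:
            data = data[:, :, :, 0, :]
        vox = tuple(float(v) for v in img.header.get_zooms()[:3])
        return cls(data, vox)

    @classmethod
    def identity(cls, shape, voxel_size) -> "DeformationField":
        return cls(np.zeros(tuple(shape) + (3,)), voxel_size)
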