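"""Core spatial containers: scalar volumes, tissue segmentations, displacement fields.

All images in one analysis live on a common regular 3D grid. Coordinates are
0-based voxel indices; the voxel-to-world mapping is a 4x4 homogeneous matrix
(NIfTI affine semantics). Displacement fields are stored in millimetres and
applied in the pull (backward-sampling) convention: the output voxel at index
``v`` takes the input value sampled at ``v + d(v)/spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = [
    "Volume",
    "TissueSegmentation",
    "DisplacementField",
    "GridMismatchError",
]


class GridMismatchError(ValueError):
    """Raised when two objects that must share a grid do not."""


def _default_affine(shape, voxel_size_mm):
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


@dataclass(frozen=True, eq=False)
class Volume:
    """A 3D scalar image with voxel spacing and a voxel-to-world affine.

    Parameters
    ----------
    data
        3D array of intensities (FA, structural signal, or a binary mask).
    voxel_size_mm
        Per-axis voxel spacing in mm; must be positive and finite.
    affine
        4x4 voxel-to-world matrix. Defaults to a diagonal scaling by the
        voxel size (origin at the first voxel's centre).
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {data.shape}")
        vs = tuple(float(s) for s in np.broadcast_to(self.voxel_size_mm, (3,)))
        if not all(np.isfinite(s) and s > 0 for s in vs):
            raise ValueError(f"voxel size must be positive and finite, got {vs}")
        aff = self.affine
        if aff is None:
            aff = _default_affine(data.shape, vs)
        aff = np.asarray(aff, dtype=float)
        if aff.shape != (4, 4) or abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "voxel_size_mm", vs)
        object.__setattr__(self, "affine", aff)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def same_grid_as(self, other: "Volume") -> bool:
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine
        )

    def require_same_grid(self, other: "Volume", what: str = "volumes") -> None:
        if not self.same_grid_as(other):
            raise GridMismatchError(
                f"{what} must share one grid: {self.shape} vs {other.shape}"
            )

    def with_data(self, data: np.ndarray) -> "Volume":
        return replace(self, data=np.asarray(data))

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (continuous) voxel indices, shape (..., 3), to world mm."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    # NIfTI round trip -------------------------------------------------
    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "Volume":
        img = nib.load(str(path))
        vs = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj), voxel_size_mm=vs, affine=img.affine)


@dataclass(frozen=True, eq=False)
class TissueSegmentation:
    """Disjoint binary WM / GM / CSF masks on one grid."""

    wm: Volume
    gm: Volume
    csf: Volume

    def __post_init__(self):
        self.wm.require_same_grid(self.gm, "tissue masks")
        self.wm.require_same_grid(self.csf, "tissue masks")
        for name, vol in (("wm", self.wm), ("gm", self.gm), ("csf", self.csf)):
            vals = np.unique(vol.data)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError(f"{name} mask must be binary, found values {vals}")
        w, g, c = (v.data.astype(bool) for v in (self.wm, self.gm, self.csf))
        if (w & g).any() or (w & c).any() or (g & c).any():
            raise ValueError("tissue masks must be pairwise disjoint")

    @property
    def brain(self) -> Volume:
        """Union of the three tissue classes."""
        data = (
            self.wm.data.astype(bool)
            | self.gm.data.astype(bool)
            | self.csf.data.astype(bool)
        )
        return self.wm.with_data(data.astype(np.uint8))

    @property
    def non_wm(self) -> Volume:
        """GM ∪ CSF — the "non-white-matter" mask used for misregistration."""
        data = self.gm.data.astype(bool) | self.csf.data.astype(bool)
        return self.gm.with_data(data.astype(np.uint8))

    def save(self, wm_path, gm_path, csf_path) -> None:
        self.wm.save(wm_path)
        self.gm.save(gm_path)
        self.csf.save(csf_path)

    @classmethod
    def load(cls, wm_path, gm_path, csf_path) -> "TissueSegmentation":
        def as_mask(v: Volume) -> Volume:
            return v.with_data((np.asarray(v.data) > 0.5).astype(np.uint8))

        return cls(
            as_mask(Volume.load(wm_path)),
            as_mask(Volume.load(gm_path)),
            as_mask(Volume.load(csf_path)),
        )


@dataclass(frozen=True, eq=False)
class DisplacementField:
    """Per-voxel 3-vector displacements in mm on a regular grid.

    ``vectors`` has shape ``grid_shape + (3,)``. The field acts on images in
    the pull convention (see module docstring); the grid metadata (spacing,
    affine) is carried by ``grid``, a reference Volume on the same lattice.
    """

    vectors: np.ndarray
    grid: Volume

    def __post_init__(self):
        vec = np.asarray(self.vectors, dtype=np.float32)
        if vec.ndim != 4 or vec.shape[-1] != 3:
            raise ValueError(f"vectors must have shape (nx,ny,nz,3), got {vec.shape}")
        if vec.shape[:3] != self.grid.shape:
            raise GridMismatchError(
                f"field grid {vec.shape[:3]} does not match metadata grid "
                f"{self.grid.shape}"
            )
        if not np.isfinite(vec).all():
            raise ValueError("displacement field contains non-finite values")
        object.__setattr__(self, "vectors", vec)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]

    @classmethod
    def zero(cls, like: Volume) -> "DisplacementField":
        return cls(np.zeros(like.shape + (3,), dtype=np.float32), like)

    @classmethod
    def constant(cls, like: Volume, shift_mm) -> "DisplacementField":
        vec = np.empty(like.shape + (3,), dtype=np.float32)
        vec[...] = np.broadcast_to(np.asarray(shift_mm, dtype=np.float32), (3,))
        return cls(vec, like)

    def magnitude_mm(self) -> np.ndarray:
        return np.sqrt((self.vectors**2).sum(axis=-1))

    def rms_mm(self, mask: np.ndarray | None = None) -> float:
        """Root-mean-square displacement magnitude, optionally inside a mask."""
        mag2 = (self.vectors**2).sum(axis=-1)
        if mask is not None:
            mag2 = mag2[np.asarray(mask, dtype=bool)]
        return float(np.sqrt(mag2.mean()))

    def max_mm(self) -> float:
        return float(self.magnitude_mm().max())

    def is_zero(self) -> bool:
        return not self.vectors.any()

    def save(self, path) -> None:
        img = nib.Nifti1Image(
            np.asarray(self.vectors, dtype=np.float32), self.grid.affine
        )
        nib.save(img, str(path))

    @classmethod
    def load(cls, path) -> "DisplacementField":
        img = nib.load(str(path))
        vec = np.asanyarray(img.dataobj)
        vs = tuple(float(z) for z in img.header.get_zooms()[:3])
        grid = Volume(np.zeros(vec.shape[:3]), voxel_size_mm=vs, affine=img.affine)
        return cls(vec, grid)
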