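"""Voxel volumes on a common grid: NIfTI I/O, binary mask stacks, overlap maps.

All volumes taking part in one analysis must share shape and affine. Voxel
indices are 0-based internally; reported coordinates are world (mm) positions
obtained through the affine, matching the MNI-style convention used for
stereotaxic reporting.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "MaskStack",
    "read_mask_stack",
    "overlap_map",
]

#: tolerance for deciding that an on-disk "binary" volume really is binary
BINARY_TOL = 1e-4
#: tolerance for affine agreement across a stack
AFFINE_TOL = 1e-4


@dataclass
class VolumeGrid:
    """A 3D voxel array together with its voxel-to-world affine."""

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge length in mm along each axis (column norms of the affine)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def world_coords(self, ijk: Sequence[float]) -> np.ndarray:
        """Map a voxel index to world (mm) coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return self.affine[:3, :3] @ ijk + self.affine[:3, 3]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        data = self.data
        if data.dtype == bool:
            data = data.astype(np.uint8)
        nib.save(nib.Nifti1Image(data, self.affine), str(path))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "VolumeGrid":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj), np.asarray(img.affine))


def _binarise(values: np.ndarray, name: str) -> np.ndarray:
    near0 = np.abs(values) <= BINARY_TOL
    near1 = np.abs(values - 1.0) <= BINARY_TOL
    if not np.all(near0 | near1):
        bad = values[~(near0 | near1)]
        raise ValueError(
            f"{name}: mask is not binary within tolerance {BINARY_TOL} "
            f"(offending values e.g. {bad.flat[:3]})"
        )
    return near1


@dataclass
class MaskStack:
    """n binary lesion masks sharing one grid, stored as an (n, x, y, z) array."""

    masks: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    ids: list | None = None

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks)
        if self.masks.ndim != 4:
            raise ValueError("mask stack must have shape (n, x, y, z)")
        if self.masks.dtype != bool:
            self.masks = _binarise(self.masks.astype(float), "mask stack")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.ids is None:
            self.ids = list(range(len(self.masks)))

    def __len__(self) -> int:
        return len(self.masks)

    def __getitem__(self, i: int) -> VolumeGrid:
        return VolumeGrid(self.masks[i], self.affine)

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.masks.shape[1:]

    def flat(self) -> np.ndarray:
        """(n, n_voxels) boolean view used by the voxelwise machinery."""
        return self.masks.reshape(len(self.masks), -1)

    def subset(self, indices) -> "MaskStack":
        idx = np.asarray(indices)
        return MaskStack(
            self.masks[idx], self.affine, [self.ids[i] for i in np.atleast_1d(idx)]
        )

    def volumes(self) -> np.ndarray:
        """Lesion volume of each mask in voxels."""
        return self.masks.sum(axis=(1, 2, 3))

    def save(self, directory: str | Path, prefix: str = "lesion") -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = []
        for pid, mask in zip(self.ids, self.masks):
            p = directory / f"{prefix}_{pid}.nii.gz"
            VolumeGrid(mask, self.affine).save(p)
            paths.append(p)
        return paths


def read_mask_stack(paths: Iterable[str | Path]) -> MaskStack:
    """Read binary lesion masks, enforcing grid consistency across the stack.

    Values must be within ``BINARY_TOL`` of 0 or 1; shape or affine mismatches
    raise an error naming the offending file.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no mask paths supplied")
    masks = []
    shape = affine = None
    for p in paths:
        vol = VolumeGrid.load(p)
        if shape is None:
            shape, affine = vol.shape, vol.affine
        else:
            if vol.shape != shape:
                raise ValueError(
                    f"{p}: shape {vol.shape} does not match stack shape {shape}"
                )
            if not np.allclose(vol.affine, affine, atol=AFFINE_TOL):
                raise ValueError(f"{p}: affine does not match the rest of the stack")
        masks.append(_binarise(np.asarray(vol.data, dtype=float), str(p)))
    return MaskStack(np.stack(masks), affine, ids=[p.stem.replace(".nii", "") for p in paths])


def overlap_map(masks: MaskStack | Sequence[VolumeGrid]) -> VolumeGrid:
    """Voxelwise count of patients lesioned at each location."""
    if isinstance(masks, MaskStack):
        if len(masks) == 0:
            raise ValueError("empty mask stack")
        counts = masks.masks.sum(axis=0).astype(np.int32)
        return VolumeGrid(counts, masks.affine)
    masks = list(masks)
    if not masks:
        raise ValueError("empty mask stack")
    shape = masks[0].shape
    counts = np.zeros(shape, dtype=np.int32)
    for m in masks:
        if m.shape != shape:
            raise ValueError("masks do not share a grid")
        counts += _binarise(np.asarray(m.data, dtype=float), "mask").astype(np.int32)
    return VolumeGrid(counts, masks[0].affine)
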