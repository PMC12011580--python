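"""Labelmap container and NIfTI I/O.

Internal orientation convention
-------------------------------
All in-memory labelmaps are canonicalized to RAS+:

* array axis 0 increases toward the patient's **right** (+x, mm),
* array axis 1 increases toward **anterior** (+y, mm),
* array axis 2 increases toward **superior** (+z, mm).

Axial slices are therefore planes of constant axis-2 index, and "anterior"
is unambiguously +y for every downstream geometric operation.  Voxel indices
are 0-based; world coordinates are continuous mm at voxel centers:
``world = origin + index * spacing``.

Files whose affine is axis-aligned up to permutation/flip are reoriented
losslessly; genuinely oblique acquisitions are resampled to the canonical
axes by nearest neighbour with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .schema import LabelSchema

AXIS_CODES = ("R", "A", "S")


class LabelMapError(ValueError):
    """Invalid labelmap or labelmap file."""


@dataclass(frozen=True)
class Mask:
    """A binary 3D mask with physical geometry (canonical RAS axes)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.data.ndim != 3 or self.data.dtype != bool:
            raise LabelMapError("mask must be a 3D boolean array")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def world_points(self, indices: np.ndarray) -> np.ndarray:
        """Voxel-center world coordinates (mm) of an (n, 3) index array."""
        return np.asarray(self.origin) + np.asarray(indices) * np.asarray(self.spacing)


@dataclass(frozen=True)
class LabelMap:
    """Integer labelmap on a regular grid, bound to a :class:`LabelSchema`.

    ``data[i, j, k]`` is the label of the voxel whose center sits at world
    point ``origin + (i, j, k) * spacing`` (mm, RAS axes).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    schema: LabelSchema
    axcodes: tuple[str, str, str] = field(default=AXIS_CODES)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise LabelMapError("labelmap array must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise LabelMapError("labelmap voxels must be integers")
        sp = np.asarray(self.spacing, dtype=float)
        if sp.shape != (3,) or not np.all(np.isfinite(sp)) or np.any(sp <= 0):
            raise LabelMapError("spacing must be three strictly positive finite mm")
        if np.any(self.data < 0):
            raise LabelMapError("labelmap voxels must be non-negative")
        _validate_labels(self.data, self.schema)

    # -- geometry ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def anterior_axis(self) -> int:
        """Array axis pointing anterior (+y in the canonical frame)."""
        return 1

    @property
    def superior_axis(self) -> int:
        """Array axis pointing superior (+z in the canonical frame)."""
        return 2

    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    def voxel_to_world(self, index) -> np.ndarray:
        """World mm coordinates of a voxel center; raises if out of bounds."""
        idx = np.asarray(index)
        if idx.shape != (3,):
            raise LabelMapError("index must be a triple")
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.shape)):
            raise LabelMapError(f"index {tuple(idx)} outside grid {self.shape}")
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_voxel(self, point) -> tuple[int, int, int]:
        """Nearest voxel index of a world point; raises if out of bounds."""
        p = np.asarray(point, dtype=float)
        idx = np.round((p - np.asarray(self.origin)) / np.asarray(self.spacing))
        if np.any(idx < 0) or np.any(idx >= np.asarray(self.shape)):
            raise LabelMapError(f"world point {tuple(p)} maps outside the grid")
        return tuple(int(i) for i in idx)

    # -- masks ---------------------------------------------------------

    def organ_mask(self, role: str) -> Mask:
        """Binary mask of one anatomical role (true where label matches)."""
        lab = self.schema.label(role)
        return Mask(self.data == lab, self.spacing, self.origin)

    def union_mask(self, roles) -> Mask:
        labels = [self.schema.label(r) for r in roles]
        return Mask(np.isin(self.data, labels), self.spacing, self.origin)

    def with_data(self, data: np.ndarray) -> "LabelMap":
        return replace(self, data=data)


def _validate_labels(data: np.ndarray, schema: LabelSchema) -> None:
    present = np.unique(data)
    present = present[present != 0]
    known = schema.known_labels()
    for lab in present:
        if int(lab) not in known:
            count = int(np.sum(data == lab))
            raise LabelMapError(
                f"voxel label {int(lab)} ({count} voxels) absent from schema"
            )


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def read_labelmap(path: str | Path, schema: LabelSchema) -> LabelMap:
    """Read a NIfTI labelmap and canonicalize it to the RAS+ convention.

    Raises :class:`LabelMapError` for non-integer voxel data or labels not
    covered by *schema* (the offending label and its voxel count are
    reported).  Oblique volumes are resampled to axis-aligned RAS by
    nearest neighbour with a warning.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise LabelMapError(f"cannot read NIfTI file {path}: {exc}") from exc

    img = nib.as_closest_canonical(img)
    arr = np.asanyarray(img.dataobj)
    if np.issubdtype(arr.dtype, np.floating):
        rounded = np.round(arr)
        if not np.allclose(arr, rounded, atol=1e-6):
            raise LabelMapError(f"{path}: voxel data are not integer-valued")
        arr = rounded
    arr = arr.astype(np.int16)

    aff = img.affine
    rot = aff[:3, :3]
    if not _is_diagonal(rot):
        warnings.warn(
            f"{path.name}: oblique orientation; resampling to canonical axes "
            "by nearest neighbour",
            stacklevel=2,
        )
        arr, aff = _resample_to_axes(arr, aff)
        rot = aff[:3, :3]

    spacing = tuple(float(s) for s in np.diag(rot))
    origin = tuple(float(t) for t in aff[:3, 3])
    return LabelMap(arr, spacing, origin, schema)


def write_labelmap(labelmap: LabelMap, path: str | Path) -> None:
    """Write a labelmap as NIfTI (.nii or .nii.gz); round-trips voxel-exactly."""
    img = nib.Nifti1Image(labelmap.data.astype(np.int16), labelmap.affine())
    img.header.set_zooms(labelmap.spacing)
    nib.save(img, str(path))


def _is_diagonal(rot: np.ndarray, tol: float = 1e-4) -> bool:
    off = rot - np.diag(np.diag(rot))
    return bool(np.all(np.abs(off) <= tol * np.max(np.abs(rot)))) and bool(
        np.all(np.diag(rot) > 0)
    )


def _resample_to_axes(arr: np.ndarray, aff: np.ndarray):
    """Nearest-neighbour resample of an oblique volume onto RAS-aligned axes."""
    rot = aff[:3, :3]
    spacing = np.linalg.norm(rot, axis=0)
    # world bounding box of the input grid corners
    corners = np.array(
        [[i, j, k] for i in (0, arr.shape[0] - 1) for j in (0, arr.shape[1] - 1)
         for k in (0, arr.shape[2] - 1)],
        dtype=float,
    )
    world = corners @ rot.T + aff[:3, 3]
    lo, hi = world.min(axis=0), world.max(axis=0)
    shape = np.maximum(np.round((hi - lo) / spacing).astype(int) + 1, 1)
    out_aff = np.eye(4)
    out_aff[:3, :3] = np.diag(spacing)
    out_aff[:3, 3] = lo
    # map output voxel -> world -> input voxel
    inv = np.linalg.inv(rot)
    matrix = inv @ np.diag(spacing)
    offset = inv @ (lo - aff[:3, 3])
    out = ndimage.affine_transform(
        arr, matrix=matrix, offset=offset, output_shape=tuple(shape), order=0,
        mode="constant", cval=0,
    )
    return out.astype(arr.dtype), out_aff


def organ_mask(labelmap: LabelMap, role: str) -> Mask:
    """Functional alias for :meth:`LabelMap.organ_mask`."""
    return labelmap.organ_mask(role)


def voxel_to_world(labelmap: LabelMap, index) -> np.ndarray:
    return labelmap.voxel_to_world(index)


def world_to_voxel(labelmap: LabelMap, point) -> tuple[int, int, int]:
    return labelmap.world_to_voxel(point)
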