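"""NIfTI volume I/O, reorientation and resampling.

Every downstream stage works in one canonical geometry: orientation ``PIR``
(axis 0 toward posterior, axis 1 toward inferior, axis 2 toward the
patient's right), matching the cutout convention of the instance stage.
"Superior" therefore means decreasing axis-1 index.  Label maps are always
resampled with nearest-neighbor interpolation so labels stay categorical;
images use trilinear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "AnatomicalVolume",
    "UnsupportedGeometryError",
    "CANONICAL_ORIENTATION",
    "read_volume",
    "write_volume",
    "reorient",
    "resample",
    "canonical_affine",
]

#: Canonical working orientation for all pipeline stages.
CANONICAL_ORIENTATION = "PIR"

#: Maximum deviation from an orthogonal direction matrix before an affine is
#: rejected as unsupported (shear beyond this is never silently resampled).
ORTHOGONALITY_TOL = 1e-4

_VALID_LETTERS = set("RLAPIS")
_AXIS_OF = {"R": 0, "L": 0, "A": 1, "P": 1, "S": 2, "I": 2}


class UnsupportedGeometryError(ValueError):
    """Raised for non-3D images or affines with shear beyond tolerance."""


def _check_orientation_code(code: str) -> tuple[str, str, str]:
    code = str(code).upper()
    if len(code) != 3 or any(c not in _VALID_LETTERS for c in code):
        raise ValueError(f"invalid orientation code {code!r}")
    axes = [_AXIS_OF[c] for c in code]
    if len(set(axes)) != 3:
        raise ValueError(
            f"orientation code {code!r} does not name three distinct anatomical axes"
        )
    return tuple(code)  # type: ignore[return-value]


@dataclass(frozen=True)
class AnatomicalVolume:
    """A 3D voxel grid plus its voxel-to-world (RAS, mm) affine.

    Carrier for both images and label maps.  ``spacing`` and ``orientation``
    are derived from the affine; the direction matrix must be orthogonal
    within :data:`ORTHOGONALITY_TOL`.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        affine = np.asarray(self.affine, dtype=float)
        if data.ndim != 3:
            raise UnsupportedGeometryError(
                f"expected a 3D volume, got {data.ndim} dimensions"
            )
        if affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)
        rot = affine[:3, :3]
        norms = np.linalg.norm(rot, axis=0)
        if np.any(norms <= 0):
            raise UnsupportedGeometryError("affine has a zero-length axis")
        unit = rot / norms
        if np.max(np.abs(unit.T @ unit - np.eye(3))) > ORTHOGONALITY_TOL:
            raise UnsupportedGeometryError(
                "affine direction matrix is not orthogonal within tolerance; "
                "sheared geometries are unsupported"
            )

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Per-axis voxel size in mm (always strictly positive)."""
        return tuple(np.linalg.norm(self.affine[:3, :3], axis=0))

    @property
    def orientation(self) -> str:
        """3-letter axis code, each letter the world direction of increasing index."""
        return "".join(nib.orientations.aff2axcodes(self.affine, _NIB_LABELS))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "AnatomicalVolume":
        """Same geometry, new voxel grid (shape must match)."""
        data = np.asarray(data)
        if data.shape != self.data.shape:
            raise ValueError("replacement data must keep the grid shape")
        return AnatomicalVolume(data, self.affine.copy())

    def same_grid(self, other: "AnatomicalVolume", atol: float = 1e-5) -> bool:
        return self.data.shape == other.data.shape and np.allclose(
            self.affine, other.affine, atol=atol
        )


# nibabel labels axes by the direction of *increasing* index; these labels
# make aff2axcodes emit P/A, I/S, R/L letters directly.
_NIB_LABELS = (("L", "R"), ("P", "A"), ("I", "S"))


def canonical_affine(
    spacing: tuple[float, float, float], origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
) -> np.ndarray:
    """Affine of a PIR-oriented grid with the given spacing (mm)."""
    sp = np.asarray(spacing, dtype=float)
    if np.any(sp <= 0):
        raise ValueError("spacing must be strictly positive")
    aff = np.zeros((4, 4))
    # axis0 -> posterior (-y), axis1 -> inferior (-z), axis2 -> right (+x)
    aff[1, 0] = -sp[0]
    aff[2, 1] = -sp[1]
    aff[0, 2] = sp[2]
    aff[:3, 3] = origin
    aff[3, 3] = 1.0
    return aff


def read_volume(path: str | Path) -> AnatomicalVolume:
    """Read a NIfTI-1 volume, preserving integer label data losslessly.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    UnsupportedGeometryError
        For non-3D images or sheared affines.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    img = nib.load(str(path))
    shape = img.shape
    if len(shape) == 4 and shape[3] == 1:
        img = nib.funcs.squeeze_image(img)
        shape = img.shape
    if len(shape) != 3:
        raise UnsupportedGeometryError(
            f"expected a 3D image, file has shape {shape}"
        )
    on_disk = img.get_data_dtype()
    data = np.asanyarray(img.dataobj)
    if np.issubdtype(on_disk, np.integer):
        # bypass scl_slope/inter float promotion for label maps
        data = np.asanyarray(img.dataobj, dtype=on_disk)
    return AnatomicalVolume(data, img.affine)


def _storage_dtype(data: np.ndarray) -> np.dtype:
    if np.issubdtype(data.dtype, np.integer):
        lo, hi = (int(data.min()), int(data.max())) if data.size else (0, 0)
        if lo >= 0 and hi <= np.iinfo(np.uint8).max:
            return np.dtype(np.uint8)
        if lo >= 0 and hi <= np.iinfo(np.uint16).max:
            return np.dtype(np.uint16)
        return np.dtype(np.int32)
    return np.dtype(np.float32)


def write_volume(vol: AnatomicalVolume, path: str | Path) -> Path:
    """Write a NIfTI-1 file; integer labels stored as unsigned 8/16-bit as range requires."""
    path = Path(path)
    dtype = _storage_dtype(vol.data)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=dtype), vol.affine)
    img.set_qform(vol.affine, code=1)
    img.set_sform(vol.affine, code=1)
    nib.save(img, str(path))
    return path


def reorient(vol: AnatomicalVolume, target: str) -> AnatomicalVolume:
    """Permute/flip axes so the volume's orientation code equals ``target``.

    The voxel multiset is unchanged and world coordinates are preserved via
    the updated affine; reorienting back is the identity.
    """
    _check_orientation_code(target)
    current = nib.orientations.io_orientation(vol.affine)
    wanted = nib.orientations.axcodes2ornt(tuple(target.upper()), _NIB_LABELS)
    xform = nib.orientations.ornt_transform(current, wanted)
    data = nib.orientations.apply_orientation(vol.data, xform)
    affine = vol.affine @ nib.orientations.inv_ornt_aff(xform, vol.data.shape)
    return AnatomicalVolume(np.ascontiguousarray(data), affine)


def to_canonical(vol: AnatomicalVolume) -> AnatomicalVolume:
    """Reorient to the canonical PIR working orientation."""
    if vol.orientation == CANONICAL_ORIENTATION:
        return vol
    return reorient(vol, CANONICAL_ORIENTATION)


def resample(
    vol: AnatomicalVolume,
    target_spacing: tuple[float, float, float],
    mode: str = "nearest",
) -> AnatomicalVolume:
    """Resample onto a grid with ``target_spacing`` (mm).

    ``mode`` is ``"nearest"`` (required for label maps — never invents new
    label values) or ``"linear"`` for images.  Resampling to the volume's
    own spacing returns the data unchanged.
    """
    if mode not in ("nearest", "linear"):
        raise ValueError(f"unknown interpolation mode {mode!r}")
    target = np.asarray(target_spacing, dtype=float)
    if target.shape != (3,) or np.any(target <= 0):
        raise ValueError("target spacing must be three strictly positive values")
    src = np.asarray(vol.spacing)
    if np.allclose(src, target, rtol=0, atol=1e-9):
        return AnatomicalVolume(vol.data.copy(), vol.affine.copy())

    old_shape = np.asarray(vol.data.shape)
    new_shape = np.maximum(1, np.rint(old_shape * src / target).astype(int))
    # new voxel centers in old continuous index coordinates (field of view aligned)
    coords = [
        (np.arange(n) + 0.5) * target[a] / src[a] - 0.5
        for a, n in enumerate(new_shape)
    ]
    if mode == "nearest":
        idx = [np.clip(np.rint(c).astype(int), 0, old_shape[a] - 1) for a, c in enumerate(coords)]
        data = vol.data[np.ix_(*idx)]
    else:
        grid = np.meshgrid(*coords, indexing="ij")
        data = ndimage.map_coordinates(
            vol.data.astype(np.float32), np.stack(grid), order=1, mode="nearest"
        )
    unit = vol.affine[:3, :3] / src
    new_rot = unit * target
    origin0 = vol.affine[:3, :3] @ np.array([c[0] for c in coords]) + vol.affine[:3, 3]
    affine = np.eye(4)
    affine[:3, :3] = new_rot
    affine[:3, 3] = origin0
    return AnatomicalVolume(data, affine)
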