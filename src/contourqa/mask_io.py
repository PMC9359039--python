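"""Binary 3D label masks and paired-contour datasets.

Conventions used throughout the package:

* voxel arrays are indexed ``(z, y, x)``; ``spacing`` and ``origin`` are
  stored in the same axis order, in millimetres;
* the world position of the centre of voxel ``i`` is ``origin + i * spacing``
  (voxel-centre convention);
* float mask volumes are binarised at ``value > 0.5``;
* pairs on different grids are rejected, never resampled — the metrics are
  only meaningful for contours rasterised on a common CT grid.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Literal

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "LabelMask",
    "ContourPair",
    "GridMismatchError",
    "read_mask",
    "write_mask",
    "validate_pair",
    "read_manifest",
    "GRID_TOL_MM",
]

#: tolerance (mm) within which spacings/origins of a pair are considered equal
GRID_TOL_MM = 1e-4

Label = Literal["acceptable", "unacceptable", "unknown"]
SourceSet = Literal[
    "ref_vs_verif_internal",
    "ref_vs_verif_external",
    "acceptable_manual",
    "unacceptable_manual",
    "synthetic",
]

VALID_LABELS = ("acceptable", "unacceptable", "unknown")
VALID_SOURCE_SETS = (
    "ref_vs_verif_internal",
    "ref_vs_verif_external",
    "acceptable_manual",
    "unacceptable_manual",
    "synthetic",
)


class GridMismatchError(ValueError):
    """Raised when two masks do not live on the same voxel grid."""


@dataclass
class LabelMask:
    """A binary segmentation on a 3D anisotropic voxel grid.

    Parameters
    ----------
    voxels : ndarray of bool, shape (nz, ny, nx)
        True inside the structure.
    spacing : 3-tuple of float
        Voxel size in mm, ``(z, y, x)`` order. All components must be > 0.
    origin : 3-tuple of float
        World position (mm) of the centre of voxel ``(0, 0, 0)``.
    structure_name : str
        Free-text anatomical label.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    structure_name: str = ""

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels)
        if vox.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {vox.shape}")
        if vox.dtype != bool:
            vox = vox.astype(float) > 0.5
        self.voxels = vox
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("spacing and origin must be 3-vectors")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def volume_mm3(self) -> float:
        """Occupied volume in cubic millimetres (voxel count x voxel volume)."""
        return float(self.voxels.sum()) * float(np.prod(self.spacing))

    @property
    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    def world_coordinates(self, indices: np.ndarray) -> np.ndarray:
        """Map integer voxel indices (n, 3) to world mm coordinates (n, 3)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def same_grid(self, other: "LabelMask", tol: float = GRID_TOL_MM) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, rtol=0.0, atol=tol)
            and np.allclose(self.origin, other.origin, rtol=0.0, atol=tol)
        )

    def copy(self, **changes) -> "LabelMask":
        out = replace(self, **changes)
        out.voxels = out.voxels.copy()
        return out


@dataclass
class ContourPair:
    """A reference contour and its independent verification contour."""

    reference: LabelMask
    verification: LabelMask
    structure_name: str = ""
    label: Label = "unknown"
    source_set: SourceSet = "synthetic"
    pair_id: str = ""

    def __post_init__(self) -> None:
        if self.label not in VALID_LABELS:
            raise ValueError(f"label must be one of {VALID_LABELS}, got {self.label!r}")
        if self.source_set not in VALID_SOURCE_SETS:
            raise ValueError(
                f"source_set must be one of {VALID_SOURCE_SETS}, got {self.source_set!r}"
            )
        if not self.reference.same_grid(self.verification):
            raise GridMismatchError(
                "reference and verification masks are on different grids "
                f"(shapes {self.reference.shape} vs {self.verification.shape})"
            )


def _check_3d(data: np.ndarray, path: str | os.PathLike) -> np.ndarray:
    # tolerate trailing singleton dims (common in NIfTI exports of 3D masks)
    data = np.squeeze(data)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return data


def read_mask(path: str | os.PathLike, structure_name: str = "") -> LabelMask:
    """Read a NIfTI volume as a binary mask.

    The on-disk NIfTI data order is ``(x, y, z)``; it is transposed to the
    package's ``(z, y, x)`` convention. Voxel values are binarised at 0.5.
    """
    img = nib.load(os.fspath(path))
    data = _check_3d(np.asanyarray(img.dataobj), path)
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError(f"{path}: non-positive voxel spacing {zooms}")
    translation = img.affine[:3, 3]
    voxels = (data.astype(float) > 0.5).transpose(2, 1, 0)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = (float(translation[2]), float(translation[1]), float(translation[0]))
    return LabelMask(voxels, spacing, origin, structure_name=structure_name)


def write_mask(mask: LabelMask, path: str | os.PathLike) -> None:
    """Write a mask as uint8 NIfTI, inverse of :func:`read_mask`."""
    data = mask.voxels.astype(np.uint8).transpose(2, 1, 0)
    affine = np.diag([mask.spacing[2], mask.spacing[1], mask.spacing[0], 1.0])
    affine[:3, 3] = (mask.origin[2], mask.origin[1], mask.origin[0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((mask.spacing[2], mask.spacing[1], mask.spacing[0]))
    nib.save(img, os.fspath(path))


def validate_pair(
    reference: LabelMask,
    verification: LabelMask,
    structure_name: str = "",
    pair_id: str = "",
) -> ContourPair:
    """Pair two masks after checking they share shape, spacing and origin.

    Spacing and origin may differ by at most ``GRID_TOL_MM`` (0.0001 mm);
    any larger mismatch raises :class:`GridMismatchError` because comparing
    contours across grids would require resampling, which changes the metrics.
    """
    if reference.shape != verification.shape:
        raise GridMismatchError(
            f"shape mismatch: {reference.shape} vs {verification.shape}"
        )
    if not np.allclose(reference.spacing, verification.spacing, rtol=0.0, atol=GRID_TOL_MM):
        raise GridMismatchError(
            f"spacing mismatch: {reference.spacing} vs {verification.spacing}"
        )
    if not np.allclose(reference.origin, verification.origin, rtol=0.0, atol=GRID_TOL_MM):
        raise GridMismatchError(
            f"origin mismatch: {reference.origin} vs {verification.origin}"
        )
    name = structure_name or reference.structure_name or verification.structure_name
    return ContourPair(reference, verification, structure_name=name,
                       label="unknown", source_set="synthetic", pair_id=pair_id)


MANIFEST_COLUMNS = ["pair_id", "structure", "reference_path", "verification_path",
                    "label", "source_set"]


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read a dataset manifest CSV and check its schema."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} missing columns: {missing}")
    bad = set(df["label"]) - set(VALID_LABELS)
    if bad:
        raise ValueError(f"manifest {path} has invalid labels: {sorted(bad)}")
    return df


def load_pair(row: pd.Series, base_dir: str | os.PathLike = ".") -> ContourPair:
    """Load one manifest row into a :class:`ContourPair`."""
    ref = read_mask(os.path.join(base_dir, row["reference_path"]), row["structure"])
    ver = read_mask(os.path.join(base_dir, row["verification_path"]), row["structure"])
    pair = validate_pair(ref, ver, structure_name=row["structure"],
                         pair_id=str(row["pair_id"]))
    pair.label = row["label"]
    pair.source_set = row["source_set"]
    return pair
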