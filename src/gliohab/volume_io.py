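"""Reading, writing, validation, and resampling of parametric volumes and tumor masks.

All volumes live on an :class:`ImageGrid`: an axis-aligned RAS+ grid described
by shape, spacing (mm/voxel), and origin (world position, in mm, of the center
of voxel ``(0, 0, 0)``). Voxel indices are 0-based and a voxel is identified
with its center. Inputs are assumed already coregistered; only grid resampling
is provided here, no registration.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "MODALITIES",
    "DEFAULT_UNITS",
    "ImageGrid",
    "ParametricVolume",
    "TumorMask",
    "AlignmentReport",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "write_labels",
    "read_labels",
    "resample_to_grid",
    "resample_mask",
    "check_cohort_alignment",
    "analysis_grid_for_masks",
]

Modality = Literal["Vp", "FAZA", "MD"]
MODALITIES: tuple[str, ...] = ("Vp", "FAZA", "MD")

#: conventional units per modality: Vp in mL/100 mL, FAZA in arbitrary
#: (SUV-like) units, MD in mm^2/s (reported x10^3 in tables).
DEFAULT_UNITS = {"Vp": "mL/100 mL", "FAZA": "arbitrary", "MD": "mm^2/s"}

MaskFlavor = Literal["CE", "FLAIR"]


@dataclass(frozen=True)
class ImageGrid:
    """Axis-aligned RAS+ sampling grid.

    Parameters
    ----------
    shape
        Voxels per axis, all >= 1.
    spacing
        mm per voxel along each axis, all > 0.
    origin
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("ImageGrid is three-dimensional")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if any(s < 1 for s in self.shape):
            raise ValueError(f"grid shape must be >= 1 on all axes, got {self.shape}")
        if any(not np.isfinite(s) or s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be positive and finite, got {self.spacing}")
        if any(not np.isfinite(o) for o in self.origin):
            raise ValueError(f"grid origin must be finite, got {self.origin}")

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm transform (RAS+, axis aligned)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = self.origin
        return aff

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.asarray(idx, dtype=float)
        return idx * np.asarray(self.spacing) + np.asarray(self.origin)

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(low, high) world coordinates of the outer voxel-center envelope."""
        lo = self.voxel_to_world(np.zeros(3))
        hi = self.voxel_to_world(np.asarray(self.shape, dtype=float) - 1.0)
        return np.minimum(lo, hi), np.maximum(lo, hi)

    def contains_world_point(self, xyz: Sequence[float]) -> bool:
        v = self.world_to_voxel(np.asarray(xyz, dtype=float))
        return bool(np.all(v >= -0.5) and np.all(v <= np.asarray(self.shape) - 0.5))

    @classmethod
    def from_affine(cls, shape: Sequence[int], affine: np.ndarray) -> "ImageGrid":
        """Build a grid from a NIfTI affine; requires an axis-aligned RAS+ affine."""
        rot = np.asarray(affine)[:3, :3]
        spacing = np.sqrt((rot**2).sum(axis=0))
        if not np.allclose(rot, np.diag(spacing), atol=1e-4):
            raise ValueError(
                "affine is not axis-aligned RAS+; reorient the image "
                "(e.g. nibabel.as_closest_canonical) before loading"
            )
        return cls(tuple(shape), tuple(spacing), tuple(np.asarray(affine)[:3, 3]))


@dataclass
class ParametricVolume:
    """One 3-D scalar parametric map (Vp, FAZA, or MD) on an :class:`ImageGrid`."""

    grid: ImageGrid
    values: np.ndarray
    modality: str
    units: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}; expected one of {MODALITIES}")
        if not self.units:
            self.units = DEFAULT_UNITS[self.modality]
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if np.isinf(self.values).any():
            raise ValueError(f"volume {self.subject_id}/{self.modality} contains infinities")
        if self.modality == "MD":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and finite.min() < 0:
                raise ValueError("MD values must be non-negative")

    @property
    def has_nan(self) -> bool:
        """NaN is legal only outside masks (e.g. at resampling borders); flagged here."""
        return bool(np.isnan(self.values).any())

    def replace(self, **kw) -> "ParametricVolume":
        return dataclasses.replace(self, **kw)


@dataclass
class TumorMask:
    """Binary tumor region (CE core or the wider FLAIR-hyperintense volume)."""

    grid: ImageGrid
    member: np.ndarray
    flavor: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.member = np.asarray(self.member).astype(bool)
        if self.flavor not in ("CE", "FLAIR"):
            raise ValueError(f"mask flavor must be CE or FLAIR, got {self.flavor!r}")
        if self.member.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.member.shape} != grid shape {self.grid.shape}"
            )

    @property
    def n_voxels(self) -> int:
        return int(self.member.sum())

    @property
    def volume_cm3(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_mm3 / 1000.0


@dataclass
class AlignmentReport:
    """Result of :func:`check_cohort_alignment` (report-only, never raises on mismatch)."""

    reference: ImageGrid
    aligned: bool
    mismatches: list[str] = field(default_factory=list)


def _load_nifti(path: str | Path) -> tuple[np.ndarray, ImageGrid]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    img = nib.load(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected 3-D volume, got {img.ndim}-D")
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    grid = ImageGrid.from_affine(data.shape, img.affine)
    return data, grid


def read_volume(path: str | Path, modality: str, subject_id: str = "") -> ParametricVolume:
    """Load a 3-D NIfTI parametric map; grid taken from the header, values in native units."""
    data, grid = _load_nifti(path)
    return ParametricVolume(grid=grid, values=data, modality=modality, subject_id=subject_id)


def read_mask(path: str | Path, flavor: str, subject_id: str = "") -> TumorMask:
    """Load a NIfTI mask; any nonzero value is a member voxel. Empty masks are an error."""
    data, grid = _load_nifti(path)
    mask = TumorMask(grid=grid, member=data != 0, flavor=flavor, subject_id=subject_id)
    if mask.n_voxels == 0:
        raise ValueError(f"empty {flavor} tumor mask for subject {subject_id!r} ({path})")
    return mask


def write_volume(volume: ParametricVolume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.values.astype(np.float64), volume.grid.affine)
    nib.save(img, str(path))


def write_mask(mask: TumorMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.member.astype(np.uint8), mask.grid.affine)
    nib.save(img, str(path))


def write_labels(labels: np.ndarray, grid: ImageGrid, path: str | Path) -> None:
    """Write an integer label volume (e.g. a habitat map, 0..8) as NIfTI."""
    img = nib.Nifti1Image(np.asarray(labels).astype(np.int16), grid.affine)
    nib.save(img, str(path))


def read_labels(path: str | Path) -> tuple[np.ndarray, ImageGrid]:
    data, grid = _load_nifti(path)
    return data.astype(np.int16), grid


def _grids_equal(a: ImageGrid, b: ImageGrid, tol: float = 1e-6) -> bool:
    return (
        a.shape == b.shape
        and np.allclose(a.spacing, b.spacing, atol=tol)
        and np.allclose(a.origin, b.origin, atol=tol)
    )


def resample_to_grid(
    volume: ParametricVolume,
    target: ImageGrid,
    method: Literal["trilinear", "nearest"] = "trilinear",
) -> ParametricVolume:
    """Resample a parametric map onto ``target``.

    Trilinear interpolation for parametric maps (never overshoots the source
    range), nearest-neighbour for label-like content. Target voxels whose
    centers fall outside the source voxel-center envelope become NaN and are
    treated as "outside mask" downstream.
    """
    if _grids_equal(volume.grid, target):
        return volume.replace(grid=target, values=volume.values.copy())
    src_lo, src_hi = volume.grid.world_bounds()
    tgt_lo, tgt_hi = target.world_bounds()
    if np.any(tgt_hi < src_lo) or np.any(tgt_lo > src_hi):
        raise ValueError("source and target grids are disjoint in world space")

    coords = _target_in_source_voxel_coords(volume.grid, target)
    order = {"trilinear": 1, "nearest": 0}[method]
    out = ndimage.map_coordinates(
        volume.values, coords, order=order, mode="constant", cval=np.nan
    ).reshape(target.shape)
    # map_coordinates pads half a voxel beyond the last center; mask those out
    outside = _outside_source(volume.grid, coords).reshape(target.shape)
    out[outside] = np.nan
    return volume.replace(grid=target, values=out)


def resample_mask(mask: TumorMask, target: ImageGrid) -> TumorMask:
    """Nearest-neighbour resampling of a binary mask; outside-source voxels are non-member."""
    if _grids_equal(mask.grid, target):
        return TumorMask(target, mask.member.copy(), mask.flavor, mask.subject_id)
    coords = _target_in_source_voxel_coords(mask.grid, target)
    out = ndimage.map_coordinates(
        mask.member.astype(np.float64), coords, order=0, mode="constant", cval=0.0
    ).reshape(target.shape)
    out[_outside_source(mask.grid, coords).reshape(target.shape)] = 0.0
    return TumorMask(target, out > 0.5, mask.flavor, mask.subject_id)


def _target_in_source_voxel_coords(source: ImageGrid, target: ImageGrid) -> np.ndarray:
    idx = np.indices(target.shape, dtype=np.float64).reshape(3, -1)
    world = idx * np.asarray(target.spacing)[:, None] + np.asarray(target.origin)[:, None]
    return (world - np.asarray(source.origin)[:, None]) / np.asarray(source.spacing)[:, None]


def _outside_source(source: ImageGrid, coords: np.ndarray) -> np.ndarray:
    hi = np.asarray(source.shape, dtype=float)[:, None] - 1.0
    return np.any((coords < 0.0) | (coords > hi), axis=0)


def check_cohort_alignment(
    volumes: Iterable[ParametricVolume], masks: Iterable[TumorMask] = ()
) -> AlignmentReport:
    """Verify that all of a subject's volumes and masks share one grid.

    Report-only: mismatches are listed by name, nothing is raised for them.
    """
    volumes = list(volumes)
    masks = list(masks)
    if not volumes:
        raise ValueError("no volumes to check")
    ref = volumes[0].grid
    mismatches: list[str] = []
    for v in volumes[1:]:
        if not _grids_equal(v.grid, ref):
            mismatches.append(f"volume {v.subject_id}/{v.modality}: grid differs from reference")
    for m in masks:
        if not _grids_equal(m.grid, ref):
            mismatches.append(f"mask {m.subject_id}/{m.flavor}: grid differs from reference")
    return AlignmentReport(reference=ref, aligned=not mismatches, mismatches=mismatches)


def analysis_grid_for_masks(masks: Sequence[TumorMask], margin_voxels: int = 5) -> ImageGrid:
    """1 mm isotropic grid bounding the union of the masks plus a margin."""
    if not masks:
        raise ValueError("no masks provided")
    los, his = [], []
    for m in masks:
        if m.n_voxels == 0:
            continue
        idx = np.argwhere(m.member)
        los.append(m.grid.voxel_to_world(idx.min(axis=0)))
        his.append(m.grid.voxel_to_world(idx.max(axis=0)))
    if not los:
        raise ValueError("all masks are empty")
    lo = np.min(los, axis=0) - margin_voxels
    hi = np.max(his, axis=0) + margin_voxels
    shape = tuple(int(np.floor(h - l)) + 1 for l, h in zip(lo, hi))
    return ImageGrid(shape=shape, spacing=(1.0, 1.0, 1.0), origin=tuple(lo))
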