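"""Spherical biopsy-VOI sampling of habitat maps.

Stereotactic biopsy targets are world-space points; each is sampled with a
5-mm-diameter spherical volume of interest (membership by voxel-center
Euclidean distance, no partial-volume weighting) and the habitats inside are
reported ordered by prevalence. Histology grades (cellularity 1-5, necrosis
class 0-5 where 0 = 0%, 1 = <=10%, 2 = 11-25%, 3 = 26-50%, 4 = 51-75%,
5 = 76-100%) refer to the central 5 mm segment of the physical specimen and
are joined to the VOI profiles descriptively; no inferential test is attached.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .habitat_core import HabitatMap
from .volume_io import ImageGrid

__all__ = [
    "StereotacticTarget",
    "SphericalVOI",
    "HistologySample",
    "VOIHabitatProfile",
    "sphere_voxels",
    "voi_habitat_profile",
    "histology_correlation_table",
]


@dataclass(frozen=True)
class StereotacticTarget:
    subject_id: str
    sample_label: str
    center: tuple[float, float, float]  # world mm


@dataclass
class SphericalVOI:
    center: tuple[float, float, float]
    diameter: float
    member_voxels: np.ndarray  # (n, 3) voxel indices on ``grid``
    grid: ImageGrid

    @property
    def n_voxels(self) -> int:
        return int(self.member_voxels.shape[0])


@dataclass(frozen=True)
class HistologySample:
    sample_label: str
    cellularity: int | None  # 1 (normal) .. 5 (extremely dense); None if ungradable
    necrosis_class: int | None  # 0..5
    hyperplastic_vessels: int | None = None

    def __post_init__(self) -> None:
        if self.cellularity is not None and not 1 <= self.cellularity <= 5:
            raise ValueError("cellularity must be in 1..5")
        if self.necrosis_class is not None and not 0 <= self.necrosis_class <= 5:
            raise ValueError("necrosis class must be in 0..5")


@dataclass
class VOIHabitatProfile:
    sample_label: str
    habitat_counts: dict[int, int]  # labels 1..8 with count > 0 only
    unassigned_voxels: int  # label 0 or outside the ROI
    ordered_habitats: list[int] = field(default_factory=list)
    dominant_fraction: float = float("nan")


def sphere_voxels(
    grid: ImageGrid,
    center: Sequence[float],
    diameter: float = 5.0,
) -> SphericalVOI:
    """Voxels whose centers lie within ``diameter/2`` mm of ``center`` (world mm)."""
    center = np.asarray(center, dtype=float)
    if not grid.contains_world_point(center):
        raise ValueError(f"VOI center {tuple(center)} lies outside the image grid")
    r = diameter / 2.0
    spacing = np.asarray(grid.spacing)
    cvox = grid.world_to_voxel(center)
    lo = np.maximum(np.ceil(cvox - r / spacing).astype(int), 0)
    hi = np.minimum(np.floor(cvox + r / spacing).astype(int), np.asarray(grid.shape) - 1)
    if np.any(hi < lo):
        raise ValueError(f"empty VOI: diameter {diameter} mm too small for spacing {grid.spacing}")
    axes = [np.arange(l, h + 1) for l, h in zip(lo, hi)]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    world = idx * spacing + np.asarray(grid.origin)
    dist = np.linalg.norm(world - center, axis=1)
    members = idx[dist <= r]
    if members.shape[0] == 0:
        raise ValueError(f"empty VOI at {tuple(center)}: no voxel center within {r} mm")
    return SphericalVOI(center=tuple(center), diameter=float(diameter), member_voxels=members, grid=grid)


def voi_habitat_profile(hmap: HabitatMap, voi: SphericalVOI) -> VOIHabitatProfile:
    """Habitat counts inside a VOI, ordered by descending count (ties: ascending label).

    Voxels with label 0 or outside the tumor ROI are tallied as unassigned.
    ``dominant_fraction`` is the top habitat's share of the assigned VOI voxels.
    """
    if voi.grid.shape != hmap.grid.shape:
        raise ValueError("VOI and habitat map must share a grid")
    i, j, k = voi.member_voxels.T
    labels = hmap.label[i, j, k]
    in_roi = hmap.roi[i, j, k]
    counts = {
        int(h): int(((labels == h) & in_roi).sum())
        for h in range(1, 9)
        if ((labels == h) & in_roi).sum() > 0
    }
    unassigned = int(voi.n_voxels - sum(counts.values()))
    ordered = sorted(counts, key=lambda h: (-counts[h], h))
    assigned = sum(counts.values())
    dominant = counts[ordered[0]] / assigned if ordered else float("nan")
    return VOIHabitatProfile(
        sample_label="",
        habitat_counts=counts,
        unassigned_voxels=unassigned,
        ordered_habitats=ordered,
        dominant_fraction=dominant,
    )


def histology_correlation_table(
    profiles: Iterable[VOIHabitatProfile],
    samples: Iterable[HistologySample] | pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join VOI habitat profiles with semi-quantitative histology grades.

    Returns ``(rows, summary)``: one row per sample (dominant habitat, ordered
    habitat list, grades) and a per-dominant-habitat descriptive summary
    (median cellularity / necrosis class, sample count). Unmatched sample
    labels on either side are reported in an ``unmatched`` column note.
    """
    profiles = {p.sample_label: p for p in profiles}
    if isinstance(samples, pd.DataFrame):
        sample_list = [
            HistologySample(
                sample_label=str(r["sample_label"]),
                cellularity=None if pd.isna(r["cellularity"]) else int(r["cellularity"]),
                necrosis_class=None if pd.isna(r["necrosis_class"]) else int(r["necrosis_class"]),
                hyperplastic_vessels=None if pd.isna(r.get("vessels")) else int(r["vessels"]),
            )
            for _, r in samples.iterrows()
        ]
    else:
        sample_list = list(samples)
    samples_by_label = {s.sample_label: s for s in sample_list}

    rows = []
    for label in sorted(set(profiles) | set(samples_by_label)):
        p = profiles.get(label)
        s = samples_by_label.get(label)
        rows.append(
            {
                "sample_label": label,
                "matched": p is not None and s is not None,
                "dominant_habitat": p.ordered_habitats[0] if p and p.ordered_habitats else None,
                "ordered_habitats": ",".join(map(str, p.ordered_habitats)) if p else None,
                "dominant_fraction": p.dominant_fraction if p else None,
                "cellularity": s.cellularity if s else None,
                "necrosis_class": s.necrosis_class if s else None,
                "vessels": s.hyperplastic_vessels if s else None,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table, pd.DataFrame()
    matched = table[table["matched"] & table["dominant_habitat"].notna()]
    summary = (
        matched.groupby("dominant_habitat")
        .agg(
            n_samples=("sample_label", "count"),
            median_cellularity=("cellularity", "median"),
            median_necrosis_class=("necrosis_class", "median"),
            median_vessels=("vessels", "median"),
        )
        .reset_index()
        if not matched.empty
        else pd.DataFrame()
    )
    return table, summary
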