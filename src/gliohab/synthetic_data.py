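"""Synthetic multi-parametric phantoms with known habitat ground truth.

The phantom emulates the data model of the patient imaging: a tumor built
from concentric ellipsoidal shells, each shell carrying one habitat label,
surrounded by an outer FLAIR halo of pure edema (habitat 7). The habitat
label fixes the high/low level of each map (perfusion, hypoxia, diffusivity)
and voxel values are drawn Normal(mu_level, sigma) per map — the simplest
bimodal structure matching the two-class assumption of Otsu binarization.
The class separation (mu_H - mu_L)/sigma is the single knob controlling
recovery difficulty.

The fixtures of the printed clinical/cohort tables are loaded from here as
well (checksum-verified CSVs packaged with the library).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .habitat_core import HabitatDefinition
from .volume_io import ImageGrid, ParametricVolume, TumorMask

__all__ = [
    "DEFAULT_LEVELS",
    "PhantomSpec",
    "PhantomTruth",
    "generate_phantom",
    "generate_cohort",
    "load_fixture",
]

#: per-map (mu_low, mu_high) defaults in native units (MD in mm^2/s),
#: informed by typical low/high cluster medians in high-grade glioma
DEFAULT_LEVELS: dict[str, tuple[float, float]] = {
    "Vp": (1.0, 4.9),
    "FAZA": (0.3, 1.4),
    "MD": (0.98e-3, 1.32e-3),
}


@dataclass
class PhantomSpec:
    """Geometry and intensity model of one synthetic subject.

    zone_radii are the outer radii (mm) of five concentric ellipsoidal shells
    around ``tumor_center``; each shell carries ``zone_habitats[i]``. Beyond
    the last shell, a FLAIR halo out to ``halo_radius`` carries habitat 7.
    The default radii give the five shells near-equal volumes (the halo gets
    a double share): per-habitat recovery metrics (Dice) are only stable when
    no habitat is a sliver of the tumor, so the default geometry balances the
    zones rather than copying any particular cohort's volume fractions.
    ``axes_scale`` stretches the ellipsoid axes (1,1,1 = spheres).
    ``speckle_fraction`` of the voxels in the two outermost shells is
    re-labeled to habitats 3/4 as small scattered clusters (these habitats are
    fragmented and poorly represented in real tumors).
    """

    grid: ImageGrid = field(default_factory=lambda: ImageGrid((96, 96, 96)))
    tumor_center: tuple[float, float, float] | None = None  # defaults to grid center
    zone_radii: tuple[float, ...] = (19.0, 23.8, 27.2, 29.9, 32.2)
    zone_habitats: tuple[int, ...] = (5, 2, 1, 6, 8)
    halo_radius: float = 36.0
    halo_habitat: int = 7
    axes_scale: tuple[float, float, float] = (1.0, 1.0, 1.0)
    speckle_fraction: float = 0.05
    level_means: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LEVELS)
    )
    separation: float = 4.0  # (mu_H - mu_L) / sigma per map; 0 disables noise
    subject_id: str = "phantom"

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.zone_radii)
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("zone_radii must be strictly increasing")
        if len(self.zone_habitats) != len(radii):
            raise ValueError("one habitat per shell required")
        if self.halo_radius <= radii[-1]:
            raise ValueError("halo_radius must exceed the outermost shell")
        for mod, (lo, hi) in self.level_means.items():
            if hi <= lo:
                raise ValueError(f"{mod}: mu_high must exceed mu_low")
        if self.tumor_center is None:
            c = self.grid.voxel_to_world((np.asarray(self.grid.shape) - 1) / 2.0)
            self.tumor_center = tuple(c)
        extent = np.asarray(self.grid.shape) * np.asarray(self.grid.spacing)
        if np.any(self.halo_radius * np.asarray(self.axes_scale) > extent / 2.0):
            raise ValueError("phantom radii exceed the grid extent")

    def noise_sd(self, modality: str) -> float:
        lo, hi = self.level_means[modality]
        return 0.0 if self.separation == 0 else (hi - lo) / self.separation


@dataclass
class PhantomTruth:
    """Ground-truth channel: true habitat labels, masks, analytic shell volumes."""

    habitat_label: np.ndarray  # 0 outside FLAIR, 1..8 inside
    ce_mask: TumorMask
    flair_mask: TumorMask
    zone_volumes_mm3: dict[int, float]  # habitat -> analytic volume (pre-speckle)

    def fractions(self) -> np.ndarray:
        """True habitat volume fractions (percent), habitats 1..8."""
        inside = self.habitat_label[self.flair_mask.member]
        counts = np.array([(inside == h).sum() for h in range(1, 9)], dtype=float)
        return 100.0 * counts / counts.sum()


def _ellipsoid_volume(r: float, axes: tuple[float, float, float]) -> float:
    return 4.0 / 3.0 * np.pi * (r**3) * float(np.prod(axes))


def generate_phantom(
    spec: PhantomSpec, seed: int
) -> tuple[ParametricVolume, ParametricVolume, ParametricVolume, PhantomTruth]:
    """Draw one phantom subject: (vp, faza, md, truth), deterministic given seed.

    The CE mask covers the shells carrying the contrast-enhancing habitats
    (necrotic core, vital tumor, and the faint-enhancement rim: labels 5, 2,
    1, 6 by default); the FLAIR mask covers all shells plus the halo, so
    CE is a strict subset of FLAIR.
    """
    rng = np.random.default_rng(seed)
    grid = spec.grid
    idx = np.indices(grid.shape, dtype=np.float64)
    world = [idx[a] * grid.spacing[a] + grid.origin[a] for a in range(3)]
    # scaled radial distance: points with d <= r lie in the ellipsoid of radius r
    d = np.sqrt(
        sum(
            ((world[a] - spec.tumor_center[a]) / spec.axes_scale[a]) ** 2
            for a in range(3)
        )
    )

    label = np.zeros(grid.shape, dtype=np.int16)
    inner = 0.0
    zone_volumes: dict[int, float] = {h: 0.0 for h in range(1, 9)}
    ce_outer = 0.0
    for r, hab in zip(spec.zone_radii, spec.zone_habitats):
        label[(d > inner) & (d <= r)] = hab
        zone_volumes[hab] += _ellipsoid_volume(r, spec.axes_scale) - _ellipsoid_volume(
            inner, spec.axes_scale
        )
        if hab in (1, 2, 5, 6):
            ce_outer = r
        inner = r
    halo_sel = (d > inner) & (d <= spec.halo_radius)
    label[halo_sel] = spec.halo_habitat
    zone_volumes[spec.halo_habitat] += _ellipsoid_volume(
        spec.halo_radius, spec.axes_scale
    ) - _ellipsoid_volume(inner, spec.axes_scale)

    flair = d <= spec.halo_radius
    ce = d <= ce_outer

    # scattered speckles of the fragmented habitats 3/4 in the outer shells
    if spec.speckle_fraction > 0:
        outer_zone = (d > spec.zone_radii[-3]) & (d <= spec.halo_radius)
        cand = np.flatnonzero(outer_zone.ravel())
        n_spk = int(round(spec.speckle_fraction * cand.size))
        if n_spk:
            chosen = rng.choice(cand, size=n_spk, replace=False)
            half = n_spk // 2
            flat = label.ravel()
            flat[chosen[:half]] = 3
            flat[chosen[half:]] = 4

    definition = HabitatDefinition()
    vols: list[ParametricVolume] = []
    for mi, mod in enumerate(definition.map_order):
        lo, hi = spec.level_means[mod]
        sd = spec.noise_sd(mod)
        high = np.zeros(grid.shape, dtype=bool)
        for h in range(1, 9):
            if definition.triple_for(h)[mi] == "H":
                high |= label == h
        values = np.where(high, hi, lo).astype(np.float64)
        if sd > 0:
            values = values + rng.normal(0.0, sd, size=grid.shape)
        if mod == "MD":
            values = np.clip(values, 0.0, None)
        vols.append(
            ParametricVolume(grid=grid, values=values, modality=mod, subject_id=spec.subject_id)
        )

    truth = PhantomTruth(
        habitat_label=label,
        ce_mask=TumorMask(grid, ce, "CE", spec.subject_id),
        flair_mask=TumorMask(grid, flair, "FLAIR", spec.subject_id),
        zone_volumes_mm3={h: v for h, v in zone_volumes.items() if v > 0},
    )
    return vols[0], vols[1], vols[2], truth


def generate_cohort(
    n_subjects: int,
    seed: int,
    out_dir: str | Path | None = None,
    radius_jitter: float = 0.1,
    level_jitter: float = 0.1,
    base_spec: PhantomSpec | None = None,
) -> tuple[list[tuple[PhantomSpec, tuple]], pd.DataFrame]:
    """Generate a cohort of jittered phantoms plus a batch-input manifest.

    Per subject, shell radii and level means are jittered uniformly within
    +/- the stated relative ranges, reproducibly from ``seed``. If ``out_dir``
    is given, NIfTI maps/masks/truth labels are written there and the manifest
    paths point at them; otherwise paths are empty and the in-memory phantoms
    are the product.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    subjects, rows = [], []
    for i in range(1, n_subjects + 1):
        sid = f"sub-{i:02d}"
        # jitter shell thicknesses (not radii) so the radii stay increasing
        thick = np.diff((0.0, *base.zone_radii, base.halo_radius))
        thick = thick * (1.0 + rng.uniform(-radius_jitter, radius_jitter, size=thick.size))
        cum = np.cumsum(thick)
        radii = tuple(float(r) for r in cum[:-1])
        halo = float(cum[-1])
        levels = {}
        for mod, (lo, hi) in base.level_means.items():
            lo2 = lo * (1.0 + rng.uniform(-level_jitter, level_jitter))
            hi2 = hi * (1.0 + rng.uniform(-level_jitter, level_jitter))
            levels[mod] = (min(lo2, hi2 * 0.99), max(hi2, lo2 * 1.01))
        spec = PhantomSpec(
            grid=base.grid,
            zone_radii=radii,
            zone_habitats=base.zone_habitats,
            halo_radius=max(halo, radii[-1] * 1.1),
            axes_scale=base.axes_scale,
            speckle_fraction=base.speckle_fraction,
            level_means=levels,
            separation=base.separation,
            subject_id=sid,
        )
        sub_seed = int(rng.integers(0, 2**31 - 1))
        phantom = generate_phantom(spec, sub_seed)
        subjects.append((spec, phantom))
        row = {"subject_id": sid, "seed": sub_seed}
        if out_dir is not None:
            from . import volume_io as vio

            out = Path(out_dir) / sid
            out.mkdir(parents=True, exist_ok=True)
            vp, faza, md, truth = phantom
            paths = {
                "vp_path": out / "vp.nii.gz",
                "faza_path": out / "faza.nii.gz",
                "md_path": out / "md.nii.gz",
                "mask_ce_path": out / "mask_ce.nii.gz",
                "mask_flair_path": out / "mask_flair.nii.gz",
                "truth_path": out / "truth_labels.nii.gz",
            }
            vio.write_volume(vp, paths["vp_path"])
            vio.write_volume(faza, paths["faza_path"])
            vio.write_volume(md, paths["md_path"])
            vio.write_mask(truth.ce_mask, paths["mask_ce_path"])
            vio.write_mask(truth.flair_mask, paths["mask_flair_path"])
            vio.write_labels(truth.habitat_label, spec.grid, paths["truth_path"])
            row.update({k: str(v) for k, v in paths.items()})
        rows.append(row)
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.csv", index=False)
    return subjects, manifest


# ---------------------------------------------------------------------------
# packaged table fixtures


def _fixture_bytes(name: str) -> bytes:
    pkg = resources.files("gliohab") / "fixtures"
    path = pkg / name
    data = path.read_bytes()
    sums = json.loads((pkg / "checksums.json").read_text())
    digest = hashlib.sha256(data).hexdigest()
    if sums.get(name) != digest:
        raise ValueError(f"fixture {name}: checksum mismatch ({digest})")
    return data


def load_fixture(name: str) -> pd.DataFrame:
    """Load one of the packaged cohort tables (checksum-verified).

    table1: clinical records, one row per patient. table2: habitat volume
    fractions (% of tumor volume), habitats x patients. table3: per-habitat
    median map values (MD x 10^3), with a ``whole`` row per map. table4:
    biopsy histology grades with prevalence-ordered habitat lists.
    """
    import io

    if name not in ("table1", "table2", "table3", "table4"):
        raise KeyError(f"unknown fixture {name!r}")
    raw = io.BytesIO(_fixture_bytes(f"{name}.csv"))
    if name == "table1":
        df = pd.read_csv(raw, index_col="patient")
        df["os_weeks"] = df["os_weeks"].astype(float)
        return df
    if name == "table2":
        return pd.read_csv(raw, index_col="habitat")
    if name == "table3":
        return pd.read_csv(raw)
    df = pd.read_csv(raw, dtype={"sample": str})
    df["habitats"] = df["habitats"].apply(
        lambda s: [int(x) for x in str(s).split(",")]
    )
    return df


def fraction_frame_from_table2() -> pd.DataFrame:
    """The table2 fixture as a (subject x habitat) fraction frame."""
    t2 = load_fixture("table2")
    pcols = [c for c in t2.columns if c.startswith("p")]
    frame = t2[pcols].T
    frame.index = pd.Index([int(c[1:]) for c in pcols], name="subject_id")
    frame.columns = [int(h) for h in frame.columns]
    return frame
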