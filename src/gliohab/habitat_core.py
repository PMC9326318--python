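"""Voxel-wise habitat clustering.

Each of the three parametric maps (perfusion Vp, hypoxia FAZA, diffusivity MD)
is binarized inside the tumor ROI with an Otsu threshold — after excluding
voxels beyond mean +/- k*SD of the in-ROI distribution — and the three
high/low cluster volumes are intersected into eight spatial habitats:

    (Vp, FAZA, MD) = HHH -> 1, HHL -> 2, HLH -> 3, HLL -> 4,
                     LHH -> 5, LHL -> 6, LLH -> 7, LLL -> 8

Label 0 marks in-ROI voxels left unassigned (excluded by the inclusion rule
on at least one map). Everything is deterministic: same inputs and config give
bit-identical label maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .volume_io import (
    ImageGrid,
    ParametricVolume,
    TumorMask,
    resample_mask,
    resample_to_grid,
)

__all__ = [
    "CLUSTER_OUTSIDE",
    "CLUSTER_LOW",
    "CLUSTER_HIGH",
    "CLUSTER_EXCLUDED",
    "DegenerateMapError",
    "OtsuResult",
    "BinaryClusterVolume",
    "HabitatDefinition",
    "HabitatMap",
    "RunConfig",
    "inclusion_mask",
    "otsu_threshold",
    "binarize",
    "combine",
    "compute_habitats",
]

# per-voxel codes in a BinaryClusterVolume
CLUSTER_OUTSIDE = 0
CLUSTER_LOW = 1
CLUSTER_HIGH = 2
CLUSTER_EXCLUDED = 3


class DegenerateMapError(ValueError):
    """Raised when a map is constant (or near-constant) inside the ROI."""


@dataclass(frozen=True)
class OtsuResult:
    """Threshold maximizing between-class variance over an intensity histogram."""

    threshold: float
    between_class_variance: float
    n_bins: int
    value_range: tuple[float, float]
    n_values: int

    def __post_init__(self) -> None:
        lo, hi = self.value_range
        if not (lo <= self.threshold <= hi):
            raise ValueError("threshold outside value range")
        if self.between_class_variance < 0:
            raise ValueError("between-class variance must be >= 0")
        if self.n_values < 2:
            raise ValueError("need at least two values")


@dataclass
class BinaryClusterVolume:
    """One map's high/low cluster volume (codes: outside / L / H / excluded)."""

    grid: ImageGrid
    label: np.ndarray
    modality: str
    otsu: OtsuResult

    def __post_init__(self) -> None:
        self.label = np.asarray(self.label, dtype=np.int8)
        if self.label.shape != self.grid.shape:
            raise ValueError("label shape does not match grid")


@dataclass(frozen=True)
class HabitatDefinition:
    """Bijection between (Vp, FAZA, MD) high/low triples and habitat labels 1..8.

    The fixed convention: H=high, L=low, column order perfusion, hypoxia,
    diffusivity; HHH is habitat 1 and LLL habitat 8.
    """

    map_order: tuple[str, str, str] = ("Vp", "FAZA", "MD")
    label_table: Mapping[tuple[str, str, str], int] = field(
        default_factory=lambda: {
            ("H", "H", "H"): 1,
            ("H", "H", "L"): 2,
            ("H", "L", "H"): 3,
            ("H", "L", "L"): 4,
            ("L", "H", "H"): 5,
            ("L", "H", "L"): 6,
            ("L", "L", "H"): 7,
            ("L", "L", "L"): 8,
        }
    )

    def __post_init__(self) -> None:
        labels = sorted(self.label_table.values())
        if labels != list(range(1, 9)) or len(self.label_table) != 8:
            raise ValueError("label table must be a bijection {H,L}^3 <-> 1..8")

    def label_for(self, triple: tuple[str, str, str]) -> int:
        return self.label_table[triple]

    def triple_for(self, label: int) -> tuple[str, str, str]:
        for t, l in self.label_table.items():
            if l == label:
                return t
        raise KeyError(label)


@dataclass
class HabitatMap:
    """Per-voxel habitat labels 0..8 (0 = in-ROI but unassigned) plus provenance."""

    grid: ImageGrid
    label: np.ndarray
    roi: np.ndarray  # boolean ROI the labels live in
    subject_id: str = ""
    definition: HabitatDefinition = field(default_factory=HabitatDefinition)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.label = np.asarray(self.label, dtype=np.int16)
        self.roi = np.asarray(self.roi, dtype=bool)
        if self.label.shape != self.grid.shape or self.roi.shape != self.grid.shape:
            raise ValueError("label/roi shape does not match grid")
        if ((self.label != 0) & ~self.roi).any():
            raise ValueError("habitat labels found outside the ROI")


@dataclass
class RunConfig:
    """Pipeline parameters.

    mask_flavor
        Which tumor mask defines the clustering ROI ("FLAIR" by default; the
        CE-only ROI yields clusters too small and fragmented for biopsy
        correlation).
    n_bins
        Otsu histogram bins over [min, max] of the included values.
    outlier_k
        Voxels with |v - mean| > k*SD of the in-ROI distribution are excluded.
    excluded_policy
        "drop": excluded voxels get habitat label 0. "nearest-cluster":
        they are still assigned H/L against the threshold estimated from the
        included values.
    allow_degenerate
        A constant map is an error by default (it indicates an upstream
        fault); if True, all its ROI voxels are labeled L instead.
    """

    mask_flavor: str = "FLAIR"
    n_bins: int = 256
    outlier_k: float = 3.0
    excluded_policy: str = "drop"
    allow_degenerate: bool = False

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.outlier_k <= 0:
            raise ValueError("outlier_k must be > 0")
        if self.excluded_policy not in ("drop", "nearest-cluster"):
            raise ValueError("excluded_policy must be 'drop' or 'nearest-cluster'")
        if self.mask_flavor not in ("CE", "FLAIR"):
            raise ValueError("mask_flavor must be 'CE' or 'FLAIR'")

    def to_dict(self) -> dict:
        return {
            "mask_flavor": self.mask_flavor,
            "n_bins": self.n_bins,
            "outlier_k": self.outlier_k,
            "excluded_policy": self.excluded_policy,
            "allow_degenerate": self.allow_degenerate,
        }


def inclusion_mask(volume: ParametricVolume, roi: TumorMask, k: float = 3.0) -> np.ndarray:
    """Boolean volume of ROI voxels within mean +/- k*SD of the in-ROI distribution.

    Mean and SD are computed over finite in-ROI values only; non-finite voxels
    are never included. A constant map (SD = 0) includes every finite ROI voxel.
    """
    if roi.n_voxels == 0:
        raise ValueError("empty ROI")
    if volume.values.shape != roi.member.shape:
        raise ValueError("volume and ROI must share a grid")
    vals = volume.values
    finite = np.isfinite(vals) & roi.member
    if not finite.any():
        raise ValueError(
            f"all in-ROI values are non-finite for {volume.subject_id}/{volume.modality}"
        )
    inroi = vals[finite]
    mean = float(inroi.mean())
    sd = float(inroi.std())  # population SD over the ROI
    out = np.zeros_like(finite)
    out[finite] = np.abs(vals[finite] - mean) <= k * sd
    return out


def otsu_threshold(values, n_bins: int = 256) -> OtsuResult:
    """Otsu's global threshold over an ``n_bins`` histogram of ``values``.

    For each candidate threshold t at a histogram bin edge, the between-class
    variance sigma_b^2(t) = w0(t) * w1(t) * (mu0(t) - mu1(t))^2 is evaluated
    and the maximizing t returned (ties broken toward the smallest t). The
    threshold is reported as the upper edge of the selected bin, so the low
    class is {v <= T} and the high class {v > T}.
    """
    vals = np.asarray(values, dtype=np.float64).ravel()
    vals = vals[np.isfinite(vals)]
    if vals.size < 2:
        raise ValueError(f"need >= 2 finite values to threshold, got {vals.size}")
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        raise DegenerateMapError("degenerate map: all values identical")

    hist, edges = np.histogram(vals, bins=n_bins, range=(lo, hi))
    hist = hist.astype(np.float64)
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = hist.sum()

    w0 = np.cumsum(hist)[:-1]  # class 0 = bins 0..k, threshold at edges[k+1]
    w1 = total - w0
    csum = np.cumsum(hist * centers)[:-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = csum / w0
        mu1 = (hist * centers).sum() - csum
        mu1 = mu1 / w1
        sigma_b = (w0 / total) * (w1 / total) * (mu0 - mu1) ** 2
    sigma_b = np.where((w0 == 0) | (w1 == 0), -np.inf, sigma_b)
    k = int(np.argmax(sigma_b))  # argmax takes the first maximum -> smallest t
    return OtsuResult(
        threshold=float(edges[k + 1]),
        between_class_variance=float(max(sigma_b[k], 0.0)),
        n_bins=n_bins,
        value_range=(lo, hi),
        n_values=int(vals.size),
    )


def binarize(
    volume: ParametricVolume,
    roi: TumorMask,
    included: np.ndarray,
    otsu: OtsuResult,
    excluded_policy: str = "drop",
) -> BinaryClusterVolume:
    """Split a map into low/high clusters at the Otsu threshold.

    Included voxels: H if v > T else L (v == T is L). In-ROI voxels failing
    inclusion are coded excluded under the "drop" policy, or binarized like
    the rest under "nearest-cluster". Everything else is outside.
    """
    if volume.values.shape != roi.member.shape or included.shape != roi.member.shape:
        raise ValueError("volume, ROI, and inclusion mask must share a grid")
    label = np.full(volume.values.shape, CLUSTER_OUTSIDE, dtype=np.int8)
    t = otsu.threshold
    inc = included & roi.member
    label[inc] = np.where(volume.values[inc] > t, CLUSTER_HIGH, CLUSTER_LOW)
    exc = roi.member & ~inc
    if excluded_policy == "nearest-cluster":
        finite_exc = exc & np.isfinite(volume.values)
        label[finite_exc] = np.where(
            volume.values[finite_exc] > t, CLUSTER_HIGH, CLUSTER_LOW
        )
        label[exc & ~np.isfinite(volume.values)] = CLUSTER_EXCLUDED
    else:
        label[exc] = CLUSTER_EXCLUDED
    return BinaryClusterVolume(grid=volume.grid, label=label, modality=volume.modality, otsu=otsu)


def combine(
    clusters: list[BinaryClusterVolume],
    roi: TumorMask,
    definition: HabitatDefinition | None = None,
    subject_id: str = "",
) -> HabitatMap:
    """Intersect three binary cluster volumes into the 8-habitat label map.

    Volumes are matched to the (Vp, FAZA, MD) column order by modality tag.
    Voxels excluded on any map get label 0.
    """
    definition = definition or HabitatDefinition()
    by_mod = {c.modality: c for c in clusters}
    if sorted(by_mod) != sorted(definition.map_order) or len(clusters) != 3:
        raise ValueError(
            f"need exactly one cluster volume per modality {definition.map_order}, "
            f"got {[c.modality for c in clusters]}"
        )
    ordered = [by_mod[m] for m in definition.map_order]
    for c in ordered:
        if c.label.shape != roi.member.shape:
            raise ValueError("cluster volumes and ROI must share a grid")

    # label = 1 + 4*LSB(vp) + 2*LSB(faza) + 1*LSB(md) with L->1, H->0 reproduces
    # the fixed table; keep the explicit table lookup as the source of truth.
    label = np.zeros(roi.member.shape, dtype=np.int16)
    assigned = roi.member.copy()
    for c in ordered:
        assigned &= (c.label == CLUSTER_LOW) | (c.label == CLUSTER_HIGH)
    levels = [np.where(c.label == CLUSTER_HIGH, "H", "L") for c in ordered]
    for triple, lab in definition.label_table.items():
        sel = assigned
        for lv, want in zip(levels, triple):
            sel = sel & (lv == want)
        label[sel] = lab
    return HabitatMap(
        grid=roi.grid,
        label=label,
        roi=roi.member.copy(),
        subject_id=subject_id,
        definition=definition,
        provenance={c.modality: c.otsu for c in ordered},
    )


def compute_habitats(
    vp: ParametricVolume,
    faza: ParametricVolume,
    md: ParametricVolume,
    roi: TumorMask,
    config: RunConfig | None = None,
) -> HabitatMap:
    """Full per-subject pipeline: resample -> include -> Otsu -> binarize -> combine.

    All maps are resampled (trilinear) onto the ROI grid if needed. The Otsu
    threshold for each map is global over the subject's whole ROI (multifocal
    tumors are one voxel set). The returned map carries a provenance record
    with thresholds, counts, and the config.
    """
    config = config or RunConfig()
    subject = roi.subject_id or vp.subject_id
    if roi.n_voxels < 2:
        raise ValueError(f"subject {subject!r}: ROI of {roi.n_voxels} voxel(s) cannot be thresholded")

    clusters: list[BinaryClusterVolume] = []
    prov: dict = {"subject_id": subject, "config": config.to_dict(), "maps": {}}
    for vol in (vp, faza, md):
        v = resample_to_grid(vol, roi.grid, method="trilinear")
        try:
            included = inclusion_mask(v, roi, k=config.outlier_k)
            values = v.values[included]
            try:
                otsu = otsu_threshold(values, n_bins=config.n_bins)
            except DegenerateMapError:
                if not config.allow_degenerate:
                    raise
                lo = float(values.min())
                otsu = OtsuResult(lo, 0.0, config.n_bins, (lo, lo + 1.0), int(values.size))
            cluster = binarize(v, roi, included, otsu, config.excluded_policy)
        except Exception as err:
            raise type(err)(f"subject {subject!r}, map {vol.modality}: {err}") from err
        clusters.append(cluster)
        prov["maps"][vol.modality] = {
            "threshold": otsu.threshold,
            "between_class_variance": otsu.between_class_variance,
            "n_bins": otsu.n_bins,
            "value_range": list(otsu.value_range),
            "n_included": int(included.sum()),
            "n_excluded": int((roi.member & ~included).sum()),
        }

    hmap = combine(clusters, roi, subject_id=subject)
    labels = hmap.label[hmap.roi]
    prov["n_roi_voxels"] = int(roi.n_voxels)
    prov["n_assigned"] = int((labels >= 1).sum())
    prov["n_unassigned"] = int((labels == 0).sum())
    prov["habitat_counts"] = {int(h): int((labels == h).sum()) for h in range(1, 9)}
    hmap.provenance = prov
    return hmap
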