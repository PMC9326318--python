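"""Per-subject habitat quantification and cohort-level nonparametric statistics.

Volumetric fractions (percent of assigned tumor volume per habitat), per-habitat
median map values, cohort fraction tables with row averages, summaries grouped
by molecular/histological status, and the Mann-Whitney / Kruskal-Wallis / Dunn
machinery used to compare them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .habitat_core import HabitatMap
from .volume_io import MODALITIES, ParametricVolume

__all__ = [
    "HabitatFractionRow",
    "GroupComparisonResult",
    "habitat_fractions",
    "fraction_frame",
    "habitat_medians",
    "cohort_table",
    "grouped_summary",
    "mann_whitney_u",
    "kruskal_wallis",
    "dunn_bonferroni",
    "descriptive_cohort",
]

HABITATS = tuple(range(1, 9))


@dataclass
class HabitatFractionRow:
    """One subject's habitat volume fractions (percent of assigned tumor volume)."""

    subject_id: str
    fractions: np.ndarray  # 8 values, habitats 1..8, sum to 100
    assigned_voxels: int
    label0_voxels: int

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=np.float64)
        if self.fractions.shape != (8,):
            raise ValueError("expected 8 habitat fractions")
        if (self.fractions < 0).any():
            raise ValueError("fractions must be >= 0")
        if self.assigned_voxels > 0 and abs(self.fractions.sum() - 100.0) > 1e-6:
            raise ValueError("fractions must sum to 100")


@dataclass
class GroupComparisonResult:
    method: str
    groups: dict[str, int]  # label -> sample size
    statistic: float
    p_value: float
    adjusted: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def habitat_fractions(hmap: HabitatMap) -> HabitatFractionRow:
    """Volumetric fraction per habitat: 100 * |label == h| / |label in 1..8|.

    The denominator is the assigned voxels (labels 1..8) inside the ROI;
    label-0 (excluded) voxels are counted but do not enter the denominator.
    """
    labels = hmap.label[hmap.roi]
    counts = np.array([(labels == h).sum() for h in HABITATS], dtype=np.int64)
    assigned = int(counts.sum())
    if assigned == 0:
        raise ValueError(f"subject {hmap.subject_id!r}: no assigned habitat voxels")
    return HabitatFractionRow(
        subject_id=hmap.subject_id,
        fractions=100.0 * counts / assigned,
        assigned_voxels=assigned,
        label0_voxels=int((labels == 0).sum()),
    )


def fraction_frame(rows: Iterable[HabitatFractionRow]) -> pd.DataFrame:
    """Fraction rows as a (subject x habitat) DataFrame, columns 1..8."""
    rows = list(rows)
    return pd.DataFrame(
        [r.fractions for r in rows],
        index=pd.Index([r.subject_id for r in rows], name="subject_id"),
        columns=list(HABITATS),
    )


def habitat_medians(
    hmap: HabitatMap,
    volumes: Sequence[ParametricVolume],
    md_scale: float = 1e3,
) -> pd.DataFrame:
    """Median map value per habitat plus the whole-ROI median.

    Returns a (modality x habitat) DataFrame with columns 1..8 and
    ``whole_mask``. Empty habitats are NaN, never 0. MD medians are scaled by
    ``md_scale`` (tables conventionally print MD x 10^3).
    """
    by_mod = {v.modality: v for v in volumes}
    if sorted(by_mod) != sorted(MODALITIES):
        raise ValueError(f"need one volume per modality {MODALITIES}")
    out = pd.DataFrame(
        index=pd.Index(MODALITIES, name="map"),
        columns=[*HABITATS, "whole_mask"],
        dtype=float,
    )
    for mod in MODALITIES:
        vol = by_mod[mod]
        if vol.values.shape != hmap.label.shape:
            raise ValueError(f"{mod}: volume grid does not match habitat map")
        scale = md_scale if mod == "MD" else 1.0
        vals = vol.values
        for h in HABITATS:
            sel = vals[(hmap.label == h) & np.isfinite(vals)]
            out.loc[mod, h] = scale * float(np.median(sel)) if sel.size else np.nan
        whole = vals[hmap.roi & np.isfinite(vals)]
        out.loc[mod, "whole_mask"] = scale * float(np.median(whole)) if whole.size else np.nan
    return out


def cohort_table(rows: Iterable[HabitatFractionRow] | pd.DataFrame) -> pd.DataFrame:
    """Cohort fraction matrix: habitats as rows, subjects as columns, plus
    an unweighted across-subject ``row_average`` column."""
    frame = rows if isinstance(rows, pd.DataFrame) else fraction_frame(rows)
    if frame.empty:
        raise ValueError("no fraction rows")
    table = frame.T
    table.index.name = "habitat"
    table["row_average"] = table.mean(axis=1)
    return table


def grouped_summary(
    fractions: pd.DataFrame,
    records: pd.DataFrame,
    key: str,
) -> pd.DataFrame:
    """Per-group unweighted mean and median habitat fractions.

    ``fractions`` is a (subject x habitat) frame; ``records`` a clinical table
    indexed by subject with a categorical column ``key`` (e.g. ``idh1``,
    ``who_grade``, ``mgmt``). Subjects with unknown/missing key values are
    dropped with a warning; empty groups are omitted.
    """
    if key not in records.columns:
        raise KeyError(f"no column {key!r} in clinical records")
    merged = fractions.join(records[key], how="inner")
    missing = set(fractions.index) - set(merged.index)
    if missing:
        import warnings

        warnings.warn(f"subjects without clinical record dropped: {sorted(missing)}")
    known = merged[~merged[key].isin(["unknown", "", None]) & merged[key].notna()]
    dropped = set(merged.index) - set(known.index)
    if dropped:
        import warnings

        warnings.warn(f"subjects with unknown {key} dropped: {sorted(dropped)}")
    out = {}
    for group, sub in known.groupby(key, observed=True):
        vals = sub[list(HABITATS)]
        out[(group, "mean")] = vals.mean(axis=0)
        out[(group, "median")] = vals.median(axis=0)
        out[(group, "n")] = pd.Series(len(sub), index=list(HABITATS))
    frame = pd.DataFrame(out)
    frame.index.name = "habitat"
    frame.columns = pd.MultiIndex.from_tuples(frame.columns, names=[key, "stat"])
    return frame


def mann_whitney_u(
    a: Sequence[float],
    b: Sequence[float],
    exact_max_n: int = 20,
    alternative: str = "two-sided",
) -> GroupComparisonResult:
    """Mann-Whitney U test.

    Exact p by full enumeration of the null when max(n_a, n_b) <= exact_max_n
    and there are no ties across the pooled sample; otherwise the normal
    approximation with tie correction. Identical constant samples give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    if np.unique(pooled).size == 1:
        # no rank information at all: U at its null mean, p = 1
        return GroupComparisonResult(
            "mann_whitney_u", {"a": a.size, "b": b.size}, a.size * b.size / 2.0, 1.0
        )
    exact = not ties and max(a.size, b.size) <= exact_max_n
    res = stats.mannwhitneyu(
        a, b, alternative=alternative, method="exact" if exact else "asymptotic"
    )
    return GroupComparisonResult(
        method="mann_whitney_u",
        groups={"a": int(a.size), "b": int(b.size)},
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
    )


def kruskal_wallis(samples: Sequence[Sequence[float]]) -> GroupComparisonResult:
    """Kruskal-Wallis H test (tie-corrected) across >= 2 groups."""
    samples = [np.asarray(s, dtype=float) for s in samples]
    if len(samples) < 2 or any(s.size == 0 for s in samples):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(samples)
    if np.unique(pooled).size == 1:
        return GroupComparisonResult(
            "kruskal_wallis", {str(i): int(s.size) for i, s in enumerate(samples)}, 0.0, 1.0
        )
    h, p = stats.kruskal(*samples)
    return GroupComparisonResult(
        method="kruskal_wallis",
        groups={str(i): int(s.size) for i, s in enumerate(samples)},
        statistic=float(h),
        p_value=float(p),
    )


def dunn_bonferroni(
    samples: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
) -> list[GroupComparisonResult]:
    """Dunn's pairwise post-hoc test on pooled ranks, Bonferroni-adjusted.

    For groups i, j with pooled-sample mean ranks Rbar_i, Rbar_j:

        z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - C_ties) * (1/n_i + 1/n_j))

    with the tie correction C = sum(t^3 - t) / (12 (N - 1)). Two-sided normal
    p-values are multiplied by the number of pairs k(k-1)/2 and capped at 1.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    k = len(samples)
    if k < 3 or any(s.size == 0 for s in samples):
        raise ValueError("need >= 3 non-empty groups")
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    pooled = np.concatenate(samples)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    sizes = [s.size for s in samples]
    splits = np.cumsum(sizes)[:-1]
    group_ranks = np.split(ranks, splits)
    mean_ranks = [r.mean() for r in group_ranks]

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    m = k * (k - 1) // 2
    out: list[GroupComparisonResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p_raw = 2.0 * stats.norm.sf(abs(z))
            out.append(
                GroupComparisonResult(
                    method="dunn_bonferroni",
                    groups={labels[i]: sizes[i], labels[j]: sizes[j]},
                    statistic=float(z),
                    p_value=float(min(1.0, m * p_raw)),
                    adjusted=True,
                )
            )
    return out


def descriptive_cohort(records: pd.DataFrame) -> pd.DataFrame:
    """Mean, SD, median, and range for the main clinical quantities.

    Covers age, CE and FLAIR tumor volumes, the per-patient CE/FLAIR ratio
    (computed per patient, then averaged), and overall survival.
    """
    if records.empty:
        raise ValueError("no patient records")
    cols = {
        "age_years": records["age_years"],
        "ce_volume_cm3": records["ce_volume_cm3"],
        "flair_volume_cm3": records["flair_volume_cm3"],
        "ce_flair_ratio": records["ce_volume_cm3"] / records["flair_volume_cm3"],
        "os_weeks": records["os_weeks"],
    }
    out = {}
    for name, s in cols.items():
        s = pd.to_numeric(s, errors="coerce").dropna()
        sd = float(s.std(ddof=1)) if len(s) > 1 else 0.0
        out[name] = {
            "mean": float(s.mean()),
            "sd": sd,
            "median": float(s.median()),
            "min": float(s.min()),
            "max": float(s.max()),
            "n": int(len(s)),
        }
    frame = pd.DataFrame(out).T
    frame.index.name = "quantity"
    return frame
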