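"""Background masking, per-core disorder feature, and grade comparisons.

The per-core feature is mean(ρ)/std(ρ) over foreground pixels — a
dimensionless inverse coefficient of variation of the local correlation
length.  Background is whatever the length map resolves as very short
range (by default anything below 1.3 μm, where featureless mounting
medium lands), removed by a strict-< threshold.  Groups of cores are
compared with the two-sided Wilcoxon rank-sum (Mann–Whitney) test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .images import CorrelationLengthMap, ForegroundMask

__all__ = [
    "CoreFeature",
    "GroupComparison",
    "apply_background_mask",
    "core_feature",
    "ranksum_test",
    "grade_comparison_table",
    "features_to_csv",
    "features_from_csv",
    "comparisons_to_csv",
]

#: Combined sample size up to which the exact rank-sum null is enumerated
#: (ties force the asymptotic path regardless).
EXACT_RANKSUM_MAX_N = 12

FEATURE_COLUMNS = ["core_id", "group", "n_foreground", "mean_rho_um", "std_rho_um", "feature"]
COMPARISON_COLUMNS = ["group_a", "group_b", "n_a", "n_b", "statistic", "p_value"]


@dataclass(frozen=True)
class CoreFeature:
    """One core's foreground summary: feature = mean(ρ)/std(ρ)."""

    core_id: str
    group: str
    n_foreground: int
    mean_rho: float  # μm
    std_rho: float  # μm, sample (n−1) standard deviation
    feature: float  # dimensionless


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided rank-sum comparison between two (possibly pooled) groups."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float  # rank sum of group a in the pooled ranking
    p_value: float


def apply_background_mask(
    m: CorrelationLengthMap, threshold: float = 1.3
) -> ForegroundMask:
    """Keep valid pixels whose length is at least ``threshold`` μm.

    Lengths strictly below the threshold are background; equality
    survives.  Invalid pixels are never kept.
    """
    if not (threshold > 0):
        raise ValueError(f"threshold must be > 0 μm, got {threshold}")
    with np.errstate(invalid="ignore"):
        keep = m.valid & (m.lengths >= threshold)
    return ForegroundMask(keep=keep, threshold=threshold)


def core_feature(
    m: CorrelationLengthMap,
    mask: ForegroundMask,
    core_id: str = "",
    group: str = "",
) -> CoreFeature:
    """Mean/std feature over foreground pixels of one core's length map.

    Uses the sample (n−1) standard deviation; requires at least two
    foreground pixels and nonzero dispersion.
    """
    if mask.keep.shape != m.shape:
        raise ValueError("mask and map shapes differ")
    kept = m.lengths[mask.keep]
    n = int(kept.size)
    if n < 2:
        raise ValueError(
            f"core {core_id!r}: feature undefined with {n} foreground pixel(s) "
            "(need ≥ 2)"
        )
    mean = float(kept.mean())
    std = float(kept.std(ddof=1))
    if std == 0.0:
        raise ValueError(f"core {core_id!r}: zero dispersion over foreground pixels")
    return CoreFeature(
        core_id=core_id,
        group=group,
        n_foreground=n,
        mean_rho=mean,
        std_rho=std,
        feature=mean / std,
    )


def ranksum_test(
    values_a,
    values_b,
    group_a: str = "A",
    group_b: str = "B",
    method: str | None = None,
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney) comparison.

    Exact null enumeration when the combined sample is small (≤ 12) and
    tie-free; otherwise the normal approximation with tie and continuity
    corrections.  ``method`` ("exact" / "asymptotic") overrides the
    automatic switch.  The reported statistic is the rank sum of
    ``values_a`` in the pooled ranking.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one value")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("group values must be finite")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if method is None:
        method = "exact" if (pooled.size <= EXACT_RANKSUM_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    # rank-sum statistic W = U_a + n_a(n_a+1)/2
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        n_a=int(a.size),
        n_b=int(b.size),
        statistic=w,
        p_value=float(min(res.pvalue, 1.0)),
    )


#: The four canonical diagnostic groups, in grading order.
CANONICAL_GROUPS = ("benign", "grade1", "grade2", "grade3")

#: Pairings emitted when all four canonical groups are present: the two
#: pooled low-vs-high-risk rows first, then all pairwise rows.
CANONICAL_PAIRINGS: list[tuple[tuple[str, ...], tuple[str, ...]]] = [
    (("benign",), ("grade1", "grade2", "grade3")),
    (("benign", "grade1"), ("grade2", "grade3")),
    (("benign",), ("grade1",)),
    (("benign",), ("grade2",)),
    (("benign",), ("grade3",)),
    (("grade1",), ("grade2",)),
    (("grade1",), ("grade3",)),
    (("grade2",), ("grade3",)),
]


def _pool(by_group: dict[str, list[float]], members: tuple[str, ...]) -> list[float]:
    missing = [g for g in members if g not in by_group]
    if missing:
        raise ValueError(f"pooling references absent group(s): {missing}")
    out: list[float] = []
    for g in members:
        out.extend(by_group[g])
    return out


def grade_comparison_table(features: list[CoreFeature]) -> list[GroupComparison]:
    """Pairwise (and, for the canonical 4-group design, pooled) comparisons.

    With the four canonical groups present this emits eight rows:
    benign vs pooled malignant, benign+grade1 vs grade2+grade3, and all
    six pairwise rows, in that fixed order.  Otherwise all pairwise
    comparisons of the groups present, in sorted group order.
    """
    by_group: dict[str, list[float]] = {}
    for f in features:
        by_group.setdefault(f.group, []).append(f.feature)
    groups = sorted(by_group)
    if len(groups) < 2:
        raise ValueError(f"need ≥ 2 groups for comparisons, got {groups}")

    if set(CANONICAL_GROUPS).issubset(by_group):
        rows = []
        for mem_a, mem_b in CANONICAL_PAIRINGS:
            rows.append(
                ranksum_test(
                    _pool(by_group, mem_a),
                    _pool(by_group, mem_b),
                    group_a="+".join(mem_a),
                    group_b="+".join(mem_b),
                )
            )
        return rows
    return [
        ranksum_test(by_group[ga], by_group[gb], group_a=ga, group_b=gb)
        for i, ga in enumerate(groups)
        for gb in groups[i + 1 :]
    ]


# ---------------------------------------------------------------------------
# CSV round-trips
# ---------------------------------------------------------------------------


def features_to_csv(features: list[CoreFeature], path: str | Path) -> None:
    pd.DataFrame(
        [
            (f.core_id, f.group, f.n_foreground, f.mean_rho, f.std_rho, f.feature)
            for f in features
        ],
        columns=FEATURE_COLUMNS,
    ).to_csv(path, index=False)


def features_from_csv(path: str | Path) -> list[CoreFeature]:
    df = pd.read_csv(path)
    missing = set(FEATURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing feature columns {sorted(missing)}")
    return [
        CoreFeature(
            core_id=str(r.core_id),
            group=str(r.group),
            n_foreground=int(r.n_foreground),
            mean_rho=float(r.mean_rho_um),
            std_rho=float(r.std_rho_um),
            feature=float(r.feature),
        )
        for r in df.itertuples()
    ]


def comparisons_to_csv(comparisons: list[GroupComparison], path: str | Path) -> None:
    pd.DataFrame(
        [
            (c.group_a, c.group_b, c.n_a, c.n_b, c.statistic, c.p_value)
            for c in comparisons
        ],
        columns=COMPARISON_COLUMNS,
    ).to_csv(path, index=False)
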