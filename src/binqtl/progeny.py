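"""Recombinant-derived progeny testing for QTL interval refinement.

An introgression line heterozygous for a donor segment, crossed back to
the recurrent parent, yields progeny segregating 1:1 between
heterozygous and homozygous-recurrent genotypes across that segment.
If the two classes differ in phenotype (two-sample t-test, p < alpha)
the QTL lies inside the heterozygous segment; otherwise it lies in the
homozygous remainder.  Combining several recombinant families whose
heterozygous segments tile a prior interval refines the QTL position by
set algebra: intersect the segments of significant families, subtract
the segments of well-powered non-significant families, clip to the
prior interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProgenyPanel",
    "SegmentVerdict",
    "test_family",
    "refine_interval",
]

Interval = tuple[float, float]


@dataclass
class ProgenyPanel:
    """One recombinant family's progeny genotypes and phenotypes.

    ``genotypes`` has one row per progeny, marker columns coded
    ``H`` (heterozygous) / ``A`` (homozygous recurrent parent) ordered
    by position; ``het_segment`` is the parental recombinant's
    heterozygous interval in bp.
    """

    family: str
    genotypes: pd.DataFrame  # marker columns only
    phenotypes: np.ndarray
    het_segment: Interval
    marker_positions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = set(np.unique(self.genotypes.to_numpy()))
        if not vals <= {"H", "A"}:
            raise ValueError(f"family {self.family}: genotypes must be H/A, got {vals}")
        if len(self.genotypes) != len(self.phenotypes):
            raise ValueError("genotype and phenotype row counts differ")

    def segment_markers(self) -> list[str]:
        lo, hi = self.het_segment
        inside = [
            m
            for m in self.genotypes.columns
            if self.marker_positions and lo <= self.marker_positions.get(m, -1) <= hi
        ]
        return inside or list(self.genotypes.columns)

    def classes(self) -> np.ndarray:
        """Progeny class by the segregating segment: True = heterozygous."""
        markers = self.segment_markers()
        sub = self.genotypes[markers].to_numpy()
        return (sub == "H").any(axis=1)


@dataclass
class SegmentVerdict:
    family: str
    het_segment: Interval
    t_statistic: float
    p_value: float
    verdict: str  # "QTL-in-het-region" | "QTL-in-hom-region" | "undefined"
    n_het: int
    n_hom: int

    @property
    def significant(self) -> bool:
        return self.verdict == "QTL-in-het-region"


def test_family(panel: ProgenyPanel, alpha: float = 0.05) -> SegmentVerdict:
    """Two-sample t-test between heterozygous and homozygous progeny.

    The verdict places the QTL inside the family's heterozygous segment
    when the classes differ at p < ``alpha``, in the homozygous
    remainder otherwise.  Fewer than two progeny in either class leaves
    the verdict undefined (with a warning).
    """
    carrier = panel.classes()
    y = np.asarray(panel.phenotypes, dtype=float)
    y_het, y_hom = y[carrier], y[~carrier]
    if y_het.size < 2 or y_hom.size < 2:
        warnings.warn(
            f"family {panel.family}: a genotype class has < 2 progeny; "
            "verdict undefined",
            stacklevel=2,
        )
        return SegmentVerdict(
            panel.family, panel.het_segment, np.nan, np.nan, "undefined",
            int(y_het.size), int(y_hom.size),
        )
    t, p = stats.ttest_ind(y_het, y_hom)
    verdict = "QTL-in-het-region" if p < alpha else "QTL-in-hom-region"
    return SegmentVerdict(
        panel.family, panel.het_segment, float(t), float(p), verdict,
        int(y_het.size), int(y_hom.size),
    )


test_family.__test__ = False  # not a pytest test


# -- interval algebra -------------------------------------------------------


def _intersect(a: list[Interval], b: list[Interval]) -> list[Interval]:
    out = []
    for lo1, hi1 in a:
        for lo2, hi2 in b:
            lo, hi = max(lo1, lo2), min(hi1, hi2)
            if hi > lo:
                out.append((lo, hi))
    return sorted(out)


def _subtract(a: list[Interval], seg: Interval) -> list[Interval]:
    lo2, hi2 = seg
    out = []
    for lo1, hi1 in a:
        if hi2 <= lo1 or lo2 >= hi1:
            out.append((lo1, hi1))
            continue
        if lo1 < lo2:
            out.append((lo1, lo2))
        if hi2 < hi1:
            out.append((hi2, hi1))
    return sorted(out)


def refine_interval(
    verdicts: list[SegmentVerdict],
    prior: Interval,
    min_class_n: int = 20,
) -> dict:
    """Combine family verdicts into a refined QTL interval.

    The QTL must lie inside every significant family's heterozygous
    segment and outside every non-significant family's segment; the
    result is clipped to the prior interval.  Exclusions from families
    whose smaller genotype class has fewer than ``min_class_n`` progeny
    are recorded as weak evidence but not applied (an underpowered
    non-significant test excludes nothing).  An empty intersection
    raises the contradiction flag and returns no interval.
    """
    if not verdicts:
        raise ValueError("need at least one family verdict")
    region: list[Interval] = [prior]
    weak: list[str] = []
    for v in verdicts:
        if v.verdict == "undefined":
            continue
        if v.significant:
            region = _intersect(region, [v.het_segment])
        else:
            if min(v.n_het, v.n_hom) < min_class_n:
                weak.append(v.family)
                continue
            region = _subtract(region, v.het_segment)
    contradiction = not region
    return {
        "intervals": region,
        "contradiction": contradiction,
        "weak_exclusions": weak,
        "prior": prior,
    }
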