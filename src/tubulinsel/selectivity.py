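"""Selectivity ratios, worst-case Kd interval bounds and relative-SD reporting.

The question whether a ligand prefers one binding site or target over
another is answered here with plain arithmetic, the way affinity tables are
usually argued over: |ΔG| ratios between sites, Kd ratios between targets,
mean ± 1 SD interval bounds, and the interval-overlap verdict. No
distributional assumption is made — an "overlapping" verdict means only
that the 1-SD worst cases of the two measurements meet.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from .errors import DomainError


class IntervalBounds(NamedTuple):
    low: float
    high: float
    degenerate: bool  # low clamped at 0 because sd >= mean


@dataclass
class SelectivityReport:
    """Selectivity arithmetic for one ligand between two measurements A and B."""

    ligand: str
    ratio: float
    ratio_kind: str               # "dg_site_ratio" or "kd_target_ratio"
    kd_low_a: float               # µM, lower 1-SD bound of measurement A
    kd_high_b: float              # µM, upper 1-SD bound of measurement B
    overlap: bool
    rel_sd_a: int                 # percent
    rel_sd_b: int                 # percent


def dg_site_ratio(dg_a: float, dg_b: float) -> float:
    """|ΔG_a| / |ΔG_b| — how much stronger site A binds than site B."""
    if dg_b == 0:
        raise DomainError("dg_b must be nonzero")
    return abs(dg_a) / abs(dg_b)


def kd_target_ratio(kd_a: float, kd_b: float) -> float:
    """Kd_a / Kd_b (both µM) — fold difference in dissociation constants."""
    if kd_a <= 0 or kd_b <= 0:
        raise DomainError("Kd values must be strictly positive")
    return kd_a / kd_b


def kd_interval_bounds(kd_mean: float, kd_sd: float) -> IntervalBounds:
    """(mean − SD, mean + SD) in µM; the low bound is clamped at 0 when SD ≥ mean."""
    if kd_mean <= 0:
        raise DomainError("kd_mean must be strictly positive")
    if kd_sd < 0:
        raise DomainError("kd_sd must be non-negative")
    low = kd_mean - kd_sd
    degenerate = low < 0
    return IntervalBounds(max(low, 0.0), kd_mean + kd_sd, degenerate)


def relative_sd(mean: float, sd: float) -> int:
    """100·SD/|mean|, rounded to integer percent."""
    if mean == 0:
        raise DomainError("mean must be nonzero")
    if sd < 0:
        raise DomainError("sd must be non-negative")
    return int(round(100.0 * sd / abs(mean)))


def build_report(
    ligand: str,
    kd_a: tuple[float, float],
    kd_b: tuple[float, float],
    ratio: float | None = None,
    ratio_kind: str = "kd_target_ratio",
) -> SelectivityReport:
    """Assemble the interval comparison of two (mean, SD) Kd measurements in µM.

    A is the weaker-binding measurement (larger Kd), B the claimed-stronger
    one; ``overlap`` is True when A's lower 1-SD bound does not exceed B's
    upper bound, i.e. the two worst cases meet.
    """
    mean_a, sd_a = kd_a
    mean_b, sd_b = kd_b
    low_a = kd_interval_bounds(mean_a, sd_a).low
    high_b = kd_interval_bounds(mean_b, sd_b).high
    if ratio is None:
        ratio = kd_target_ratio(mean_a, mean_b)
    return SelectivityReport(
        ligand=ligand, ratio=ratio, ratio_kind=ratio_kind,
        kd_low_a=low_a, kd_high_b=high_b, overlap=low_a <= high_b,
        rel_sd_a=relative_sd(mean_a, sd_a), rel_sd_b=relative_sd(mean_b, sd_b),
    )


def preference_verdict(report: SelectivityReport) -> str:
    """Literal interval-overlap rule on the 1-SD worst-case bounds.

    ``"overlapping"`` — the claimed preference may be insignificant;
    ``"separated"`` — the 1-SD intervals are disjoint. Bounds that barely
    miss each other still read "separated"; callers should inspect
    ``kd_low_a`` and ``kd_high_b`` before leaning on the verdict.
    """
    return "overlapping" if report.overlap else "separated"
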