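"""Limits of quantification (LOQ) and confirmation (LOC).

Two LOQ strategies are used depending on whether the analyte shows a
substantial signal in the procedural blanks:

* no substantial blank → the LOQ is the lowest non-zero fortification
  level of the MFS calibration ladder whose quantifier peak reaches
  S/N ≥ 6;
* substantial blank → the LOQ is 3.3 × the blank-equivalent
  concentration, snapped up to the calibration grid.

The LOC is the lowest MFS level at which the identity-confirmation
criteria are met, never below the LOQ. The EURL rule that procedural-blank
levels must not exceed 30% of sample levels is provided as a per-sample
check, and the determined LOQ can be raised against the spiked validation
results when the level just above it fails the performance criteria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BLANK_LOQ_FACTOR",
    "SNR_MIN_DEFAULT",
    "BLANK_CONTRIBUTION_MAX",
    "LimitFlag",
    "LimitSet",
    "loq_snr_strategy",
    "loq_blank_strategy",
    "snap_to_level",
    "determine_loc",
    "blank_contribution_check",
    "assess_loq_against_validation",
    "blank_is_substantial",
    "determine_limits",
]

BLANK_LOQ_FACTOR = 3.3
SNR_MIN_DEFAULT = 6.0
#: Maximum tolerated blank contribution relative to the sample level (inclusive).
BLANK_CONTRIBUTION_MAX = 0.30
#: A blank is "substantial" above this fraction of the lowest non-zero MFS level.
SUBSTANTIAL_BLANK_FRACTION = 0.30


class LimitFlag:
    LOQ_UNDETERMINABLE = "loq-undeterminable"
    LOC_UNDETERMINABLE = "loc-undeterminable"
    ABOVE_TOP_LEVEL = "above-top-level"
    BLANK_CONTRIBUTION = "blank-contribution"
    RAISED_BY_VALIDATION = "raised-by-validation"
    UNASSESSED = "unassessed"


@dataclass(frozen=True)
class LimitSet:
    """Determined limits for one analyte in one matrix category."""

    analyte_id: str
    category: str
    loq: float | None            # ng/kg, on the MFS grid when determinable
    loq_strategy: str            # "snr_based" | "blank_based"
    loq_raw: float | None        # pre-snap value (blank strategy) or same as loq
    loc: float | None            # ng/kg
    blank_level: float           # blank-equivalent concentration, ng/kg
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.loq is not None and self.loc is not None and self.loc < self.loq:
            raise ValueError("LOC cannot lie below the LOQ")
        if self.loq_strategy == "blank_based" and self.blank_level <= 0:
            raise ValueError("blank-based LOQ requires a positive blank level")


def loq_snr_strategy(snr_by_level: dict[float, float], mfs_levels,
                     snr_min: float = SNR_MIN_DEFAULT) -> tuple[float | None, list[str]]:
    """Lowest non-zero MFS level whose quantifier S/N meets the threshold."""
    for level in sorted(l for l in mfs_levels if l > 0):
        if snr_by_level.get(level, 0.0) >= snr_min:
            return level, []
    return None, [LimitFlag.LOQ_UNDETERMINABLE]


def loq_blank_strategy(blank_conc: float) -> float:
    """Raw blank-based LOQ: 3.3 × the procedural-blank concentration."""
    if blank_conc <= 0:
        raise ValueError("blank concentration must be positive for the blank strategy")
    return BLANK_LOQ_FACTOR * blank_conc


def snap_to_level(raw_loq: float, mfs_levels) -> tuple[float, list[str]]:
    """Smallest MFS level at or above the raw LOQ; flagged above the top level."""
    if raw_loq <= 0:
        raise ValueError("raw LOQ must be positive")
    eligible = sorted(l for l in mfs_levels if l >= raw_loq)
    if eligible:
        return eligible[0], []
    return max(mfs_levels), [LimitFlag.ABOVE_TOP_LEVEL]


def determine_loc(confirmed_by_level: dict[float, bool], loq: float | None
                  ) -> tuple[float | None, list[str]]:
    """Lowest MFS level meeting the confirmatory criteria, floored at the LOQ."""
    confirmed_levels = sorted(l for l, ok in confirmed_by_level.items() if ok and l > 0)
    if not confirmed_levels:
        return None, [LimitFlag.LOC_UNDETERMINABLE]
    loc = confirmed_levels[0]
    if loq is not None and loc < loq:
        loc = loq
    return loc, []


def blank_contribution_check(blank_level: float, sample_conc: float) -> bool:
    """True (pass) when the blank contributes at most 30% of the sample level."""
    if blank_level < 0 or sample_conc < 0:
        raise ValueError("levels must be non-negative")
    if blank_level == 0:
        return True
    if sample_conc == 0:
        return False
    return blank_level <= BLANK_CONTRIBUTION_MAX * sample_conc


def assess_loq_against_validation(
    loq: float | None,
    level_passes: dict[float, bool] | None,
) -> tuple[float | None, list[str]]:
    """Cross-check the determined LOQ against the spiked validation results.

    ``level_passes`` maps spike level → whether recovery/precision criteria
    were met. If the lowest spike level at or above the LOQ fails, the LOQ
    is raised to the next spike level that passes (flagged); with no spiked
    data the LOQ is returned unchanged with an ``unassessed`` flag.
    """
    if loq is None:
        return None, []
    if not level_passes:
        return loq, [LimitFlag.UNASSESSED]
    relevant = sorted(l for l in level_passes if l >= loq)
    if not relevant:
        return loq, [LimitFlag.UNASSESSED]
    if level_passes[relevant[0]]:
        return loq, []
    for level in relevant[1:]:
        if level_passes[level]:
            return level, [LimitFlag.RAISED_BY_VALIDATION]
    return relevant[-1], [LimitFlag.RAISED_BY_VALIDATION, LimitFlag.LOQ_UNDETERMINABLE]


def blank_is_substantial(blank_conc: float, mfs_levels,
                         fraction: float = SUBSTANTIAL_BLANK_FRACTION) -> bool:
    """Branch selector between the S/N and blank LOQ strategies."""
    lowest = min(l for l in mfs_levels if l > 0)
    return blank_conc > fraction * lowest


def determine_limits(
    analyte_id: str,
    category: str,
    snr_by_level: dict[float, float],
    confirmed_by_level: dict[float, bool],
    blank_conc: float,
    mfs_levels,
    snr_min: float = SNR_MIN_DEFAULT,
    validation_level_passes: dict[float, bool] | None = None,
) -> LimitSet:
    """Full limit determination for one analyte × category."""
    flags: list[str] = []
    if blank_is_substantial(blank_conc, mfs_levels):
        strategy = "blank_based"
        raw = loq_blank_strategy(blank_conc)
        loq, f = snap_to_level(raw, mfs_levels)
        flags += f
    else:
        strategy = "snr_based"
        loq, f = loq_snr_strategy(snr_by_level, mfs_levels, snr_min)
        raw = loq
        flags += f
    if validation_level_passes is not None:
        loq, f = assess_loq_against_validation(loq, validation_level_passes)
        flags += f
    loc, f = determine_loc(confirmed_by_level, loq)
    flags += f
    return LimitSet(
        analyte_id=analyte_id, category=category, loq=loq, loq_strategy=strategy,
        loq_raw=raw, loc=loc, blank_level=max(blank_conc, 0.0), flags=tuple(flags),
    )
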