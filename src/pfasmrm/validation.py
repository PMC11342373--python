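"""Method-validation statistics: apparent recovery, repeatability (RSD_r),
within-laboratory reproducibility (RSD_RL), quantitative/qualitative
classification, internal-standard stability ANOVA, and the absolute-
recovery / matrix-effect diagnostics based on the injection standards.

Performance criteria for monitoring purposes: apparent recovery within
65–135% and RSD_RL ≤ 25% at every evaluated spike level (boundaries
inclusive). An analyte meeting both at all levels is classified ``quan``
(usable quantitatively); otherwise ``qual`` (identification only). Note
the repeatability estimate pools the different matrices within a category,
so it overestimates true same-matrix repeatability; this is deliberate —
it probes the method across a wide range of produce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RECOVERY_BOUNDS",
    "RSD_RL_MAX",
    "ValidationSummary",
    "StabilityResult",
    "apparent_recovery",
    "rsd",
    "aggregate_validation",
    "classify",
    "anova_stability",
    "matrix_effect",
    "absolute_recovery",
]

#: Apparent-recovery acceptance band, percent (inclusive).
RECOVERY_BOUNDS = (65.0, 135.0)
#: Maximum within-laboratory reproducibility RSD, percent (inclusive).
RSD_RL_MAX = 25.0


@dataclass(frozen=True)
class ValidationSummary:
    """Per analyte × spike level roll-up of the validation campaign."""

    analyte_id: str
    spike_level: float           # ng/kg
    n_samples: int
    n_confirmed: int
    recovery_mean: float         # percent
    rsd_r: dict[str, float]      # percent, per matrix category
    rsd_rl: float                # percent, across all matrices
    flags: tuple[str, ...] = ()

    def passes_criteria(
        self,
        recovery_bounds: tuple[float, float] = RECOVERY_BOUNDS,
        rsd_rl_max: float = RSD_RL_MAX,
    ) -> bool:
        lo, hi = recovery_bounds
        return lo <= self.recovery_mean <= hi and self.rsd_rl <= rsd_rl_max


@dataclass(frozen=True)
class StabilityResult:
    """One-way ANOVA on internal-standard signal RSDs across compounds."""

    f_statistic: float
    p_value: float
    group_labels: tuple[str, ...]
    group_rsds: tuple[tuple[float, ...], ...]


def apparent_recovery(calculated_conc: float, spike_conc: float,
                      baseline_conc: float = 0.0) -> float:
    """Trueness: calculated over spiked concentration, percent.

    ``baseline_conc`` subtracts a signal already present in the unfortified
    sample or the procedural blank before the ratio is taken.
    """
    if spike_conc <= 0:
        raise ValueError("spike concentration must be positive")
    return (calculated_conc - baseline_conc) / spike_conc * 100.0


def rsd(values) -> float:
    """Relative standard deviation, percent, with the n−1 sample sd."""
    arr = np.asarray(list(values), float)
    if arr.size < 2:
        raise ValueError("RSD needs at least two values")
    mean = arr.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(arr.std(ddof=1) / abs(mean) * 100.0)


def aggregate_validation(per_sample: pd.DataFrame) -> list[ValidationSummary]:
    """Roll per-sample results up to analyte × spike level summaries.

    ``per_sample`` columns: analyte_id, matrix_category, spike_level,
    recovery (percent), confirmed (bool). Recovery mean and RSD_RL pool all
    matrices at a level; RSD_r is computed within each matrix category.
    Missing categories/levels yield partial summaries flagged ``partial``.
    """
    required = {"analyte_id", "matrix_category", "spike_level", "recovery", "confirmed"}
    missing = required - set(per_sample.columns)
    if missing:
        raise ValueError(f"per-sample results missing columns {sorted(missing)}")

    out: list[ValidationSummary] = []
    for (analyte, level), grp in per_sample.groupby(["analyte_id", "spike_level"], sort=True):
        flags: list[str] = []
        rec = grp["recovery"].to_numpy(float)
        rsd_r: dict[str, float] = {}
        for cat, sub in grp.groupby("matrix_category"):
            vals = sub["recovery"].to_numpy(float)
            if vals.size >= 2 and vals.mean() != 0:
                rsd_r[cat] = rsd(vals)
            else:
                flags.append(f"rsd_r-undefined:{cat}")
        if rec.size >= 2 and rec.mean() != 0:
            rsd_rl = rsd(rec)
        else:
            rsd_rl = float("nan")
            flags.append("rsd_rl-undefined")
        if grp["matrix_category"].nunique() < per_sample["matrix_category"].nunique():
            flags.append("partial")
        out.append(ValidationSummary(
            analyte_id=analyte,
            spike_level=float(level),
            n_samples=int(len(grp)),
            n_confirmed=int(grp["confirmed"].sum()),
            recovery_mean=float(rec.mean()),
            rsd_r=rsd_r,
            rsd_rl=rsd_rl,
            flags=tuple(flags),
        ))
    return out


def classify(
    summaries: list[ValidationSummary],
    recovery_bounds: tuple[float, float] = RECOVERY_BOUNDS,
    rsd_rl_max: float = RSD_RL_MAX,
) -> str:
    """``quan`` iff every evaluated spike level meets both criteria, else ``qual``."""
    if not summaries:
        raise ValueError("no summaries to classify")
    ok = all(s.passes_criteria(recovery_bounds, rsd_rl_max) for s in summaries)
    return "quan" if ok else "qual"


def anova_stability(group_rsds: dict[str, list[float]]) -> StabilityResult:
    """Single-factor ANOVA across groups of internal-standard signal RSDs.

    Used to probe compound stability: a degradation-prone internal standard
    would show a systematically different signal variability than stable
    ones, surfacing as a significant between-group effect.
    """
    labels = tuple(group_rsds)
    groups = [np.asarray(v, float) for v in group_rsds.values()]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("ANOVA needs ≥2 groups with ≥2 values each")
    f_stat, p = stats.f_oneway(*groups)
    return StabilityResult(
        f_statistic=float(f_stat),
        p_value=float(p),
        group_labels=labels,
        group_rsds=tuple(tuple(g) for g in groups),
    )


def matrix_effect(injstd_area_matrix: float, injstd_area_blank: float) -> float:
    """Ionization suppression/enhancement, percent.

    Compares the injection standard added to a matrix extract after
    cleanup with the same standard added to the procedural blank; 100%
    means no matrix effect, below 100% suppression, above enhancement.
    """
    if injstd_area_blank <= 0:
        raise ValueError("blank injection-standard area must be positive")
    return injstd_area_matrix / injstd_area_blank * 100.0


def absolute_recovery(is_over_injstd_sample: float, is_over_injstd_reference: float) -> float:
    """Preparation recovery, percent, from IS/injection-standard abundance ratios.

    The internal standard is added before preparation, the injection
    standard after cleanup; their ratio in the sample over the same ratio
    in a lossless reference isolates preparation losses from ionization
    effects.
    """
    if is_over_injstd_reference <= 0:
        raise ValueError("reference ratio must be positive")
    return is_over_injstd_sample / is_over_injstd_reference * 100.0
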