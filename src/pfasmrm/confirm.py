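"""Identity confirmation from ion ratios and relative retention times.

A detection is confirmed when both diagnostic checks agree with the
reference values derived from the matrix-fortified calibration set: the
qualifier/quantifier area ratio may deviate at most 30% (relative) from
the reference ion ratio, and the relative retention time at most 1%. "Not
deviate more than" is read inclusively: a deviation of exactly 30% (or 1%)
still passes. Single-product analytes assessed on a precursor (pseudo)
transition are confirmable but flagged, since that channel does not meet
the usual two-product-ion requirement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "DEFAULT_THRESHOLDS",
    "FailureReason",
    "ConfirmationVerdict",
    "ion_ratio",
    "relative_deviation",
    "check_confirmation",
]

#: Maximum allowed relative deviations, percent.
DEFAULT_THRESHOLDS = {"ion_ratio": 30.0, "rrt": 1.0}


class FailureReason:
    ION_RATIO = "ion-ratio"
    RRT = "rrt"
    NO_QUANTIFIER = "no-quantifier"
    NOT_ASSESSABLE = "not-assessable"


@dataclass(frozen=True)
class ConfirmationVerdict:
    sample_id: str
    analyte_id: str
    ion_ratio_obs: float | None
    ion_ratio_dev: float | None   # percent
    rrt_obs: float | None
    rrt_dev: float | None         # percent
    confirmed: bool
    reasons: tuple[str, ...]
    pseudo_ratio: bool = False    # second channel is a precursor transition

    def __post_init__(self) -> None:
        if self.confirmed and self.reasons:
            raise ValueError("a confirmed verdict carries no failure reasons")
        if not self.confirmed and not self.reasons:
            raise ValueError("an unconfirmed verdict must state its reasons")


def ion_ratio(qualifier_area: float, quantifier_area: float) -> float:
    """Relative abundance of the two diagnostic ions."""
    if quantifier_area <= 0:
        raise ValueError("quantifier area must be positive for an ion ratio")
    return qualifier_area / quantifier_area


def relative_deviation(observed: float, reference: float) -> float:
    """Absolute relative deviation from the reference, percent."""
    if reference <= 0:
        raise ValueError("reference must be positive")
    return abs(observed - reference) / reference * 100.0


def check_confirmation(
    sample_id: str,
    analyte_id: str,
    quantifier_area: float,
    qualifier_area: float | None,
    rt_analyte: float | None,
    rt_is: float | None,
    ref_ion_ratio: float | None,
    ref_rrt: float | None,
    thresholds: dict[str, float] | None = None,
    pseudo_ratio: bool = False,
) -> ConfirmationVerdict:
    """Full identity check for one sample × analyte.

    Both references come from the batch's own MFS calibration. Missing
    references yield a not-assessable (unconfirmed) verdict; a missing or
    zero quantifier fails with ``no-quantifier``.
    """
    th = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    reasons: list[str] = []

    if quantifier_area is None or quantifier_area <= 0:
        return ConfirmationVerdict(sample_id, analyte_id, None, None, None, None,
                                   False, (FailureReason.NO_QUANTIFIER,), pseudo_ratio)
    if ref_ion_ratio is None or ref_ion_ratio <= 0 or ref_rrt is None or ref_rrt <= 0:
        return ConfirmationVerdict(sample_id, analyte_id, None, None, None, None,
                                   False, (FailureReason.NOT_ASSESSABLE,), pseudo_ratio)

    ir_obs = ion_ratio(0.0 if qualifier_area is None else qualifier_area, quantifier_area)
    ir_dev = relative_deviation(ir_obs, ref_ion_ratio)
    if ir_dev > th["ion_ratio"]:
        reasons.append(FailureReason.ION_RATIO)

    rrt_obs = rrt_dev = None
    if rt_analyte is not None and rt_is is not None and rt_is > 0:
        from .peaks import compute_rrt

        rrt_obs = compute_rrt(rt_analyte, rt_is)
        rrt_dev = relative_deviation(rrt_obs, ref_rrt)
        if rrt_dev > th["rrt"]:
            reasons.append(FailureReason.RRT)
    else:
        reasons.append(FailureReason.NOT_ASSESSABLE)

    return ConfirmationVerdict(
        sample_id, analyte_id, ir_obs, ir_dev, rrt_obs, rrt_dev,
        confirmed=not reasons, reasons=tuple(reasons), pseudo_ratio=pseudo_ratio,
    )
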