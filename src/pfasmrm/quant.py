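"""Isotope-dilution quantitation: response ratios, procedural-blank
correction, and segmented matrix-fortified-standard (MFS) calibration.

The quantity calibrated is the response ratio — analyte quantifier peak
area divided by the quantifier area of its internal standard — which
cancels preparation losses and ionization matrix effects to the extent the
analyte and its IS co-vary. All samples in a batch, calibrants included,
are first corrected by the mean response of the duplicate procedural
blanks; the blank-corrected response is then regressed on the nominal
fortification level with 1/x weighting (the calibration spans four
decades, so unweighted least squares would be dominated by the top
levels). Because the calibration range is wide, two overlapping segments
are kept (0–100 and 50–2000 ng/kg) and a provisional full-range fit picks
the segment per sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QuantFlag",
    "CalibrationModel",
    "LOW_SEGMENT",
    "HIGH_SEGMENT",
    "SEGMENT_SPLIT",
    "response_ratio",
    "average_blank_response",
    "blank_correct",
    "fit_mfs_calibration",
    "select_segment",
    "quantify",
]

LOW_SEGMENT = (0.0, 100.0)
HIGH_SEGMENT = (50.0, 2000.0)
SEGMENT_SPLIT = 100.0  # preliminary concentrations at or below stay on the low segment


class QuantFlag:
    BELOW_BLANK = "below-blank"
    NEGATIVE_CONC = "negative-concentration"
    EXTRAPOLATION = "extrapolation"
    NO_IS = "quantification-impossible"
    SINGLE_BLANK = "single-blank"


@dataclass(frozen=True)
class CalibrationModel:
    """Per-analyte fitted response line plus confirmation references.

    ``ref_ion_ratio`` and ``ref_rrt`` are the mean qualifier/quantifier area
    ratio and mean relative retention time over the MFS calibrants whose
    qualifier channel was usable (S/N ≥ 3): they are the reference values
    identity confirmation compares against.
    """

    analyte_id: str
    slope: float
    intercept: float
    segment: tuple[float, float]
    weighting: str
    ref_ion_ratio: float | None
    ref_rrt: float | None
    n_points: int

    @property
    def usable(self) -> bool:
        return self.slope > 0


def response_ratio(analyte_area: float, is_area: float) -> float:
    """Analyte quantifier area over internal-standard quantifier area."""
    if is_area <= 0:
        raise ValueError(QuantFlag.NO_IS + ": internal-standard area must be positive")
    return analyte_area / is_area


def average_blank_response(blank_responses) -> float:
    """Mean response ratio of the procedural blanks for one analyte.

    Blanks are prepared in duplicate; a single blank still yields a usable
    correction but is flagged with a warning.
    """
    values = np.asarray(list(blank_responses), float)
    if values.size == 0:
        warnings.warn("no procedural blanks: blank correction skipped", stacklevel=2)
        return 0.0
    if values.size < 2:
        warnings.warn("only one procedural blank available; duplicate preparation "
                      "is the intended design", stacklevel=2)
    return float(values.mean())


def blank_correct(response: float, blank_response: float) -> tuple[float, list[str]]:
    """Subtract the mean procedural-blank response.

    Negative corrected responses are retained (clipping would bias the
    validation statistics upward at the lowest spike level) and flagged.
    """
    corrected = response - blank_response
    flags = [QuantFlag.BELOW_BLANK] if corrected < 0 else []
    return corrected, flags


def fit_mfs_calibration(
    levels,
    responses,
    analyte_id: str = "",
    segment: tuple[float, float] | None = None,
    ref_ion_ratio: float | None = None,
    ref_rrt: float | None = None,
) -> CalibrationModel:
    """Weighted linear fit of blank-corrected response vs fortification level.

    Weights are 1/x for x > 0; the 0 ng/kg calibrant enters with unit
    weight and anchors the intercept. When ``segment`` is given, only
    levels inside it are used. Requires at least five usable levels.
    """
    levels = np.asarray(list(levels), float)
    responses = np.asarray(list(responses), float)
    if levels.shape != responses.shape:
        raise ValueError("levels and responses must align")
    if segment is not None:
        lo, hi = segment
        keep = (levels >= lo) & (levels <= hi)
        levels, responses = levels[keep], responses[keep]
    else:
        lo, hi = (float(levels.min()), float(levels.max())) if levels.size else (0.0, 0.0)
    if np.unique(levels).size < 5:
        raise ValueError(
            f"{analyte_id or 'calibration'}: need ≥5 distinct levels in the segment, "
            f"got {np.unique(levels).size}"
        )
    if np.allclose(responses, responses[0]):
        raise ValueError(f"{analyte_id or 'calibration'}: degenerate (constant) responses")

    w = np.where(levels > 0, 1.0 / np.where(levels > 0, levels, 1.0), 1.0)
    sw = np.sqrt(w)
    design = np.column_stack([levels * sw, sw])
    coef, *_ = np.linalg.lstsq(design, responses * sw, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])

    return CalibrationModel(
        analyte_id=analyte_id,
        slope=slope,
        intercept=intercept,
        segment=(lo, hi),
        weighting="1/x",
        ref_ion_ratio=ref_ion_ratio,
        ref_rrt=ref_rrt,
        n_points=int(levels.size),
    )


def select_segment(preliminary_conc: float, mfs_levels) -> tuple[tuple[float, float], list[str]]:
    """Choose the calibration segment bracketing a provisional concentration.

    The low segment (0–100 ng/kg) serves concentrations up to 100 ng/kg;
    anything higher uses the high segment (50–2000 ng/kg). The overlap
    guarantees every concentration is bracketed. Concentrations above the
    top calibrant are quantified on the high segment with an extrapolation
    flag.
    """
    if preliminary_conc < 0:
        # a negative provisional estimate is a low-end case by construction
        return LOW_SEGMENT, []
    top = max(mfs_levels)
    flags = [QuantFlag.EXTRAPOLATION] if preliminary_conc > top else []
    if preliminary_conc <= SEGMENT_SPLIT:
        return LOW_SEGMENT, flags
    return HIGH_SEGMENT, flags


def quantify(corrected_response: float, model: CalibrationModel) -> tuple[float, list[str]]:
    """Invert the calibration line; negative concentrations are kept, flagged."""
    if model.slope <= 0:
        raise ValueError(f"{model.analyte_id}: non-positive calibration slope")
    conc = (corrected_response - model.intercept) / model.slope
    flags = [QuantFlag.NEGATIVE_CONC] if conc < 0 else []
    return conc, flags
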