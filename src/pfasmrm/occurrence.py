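"""Occurrence summaries: detection decisions, per-category detection
frequencies, and lower-/upper-bound sums for exposure assessment.

A concentration at or below the LOQ reports the *absence* of a substance
(detection requires strictly exceeding the LOQ); a detection additionally
confirmed by the identity criteria counts toward occurrence. For exposure
sums over an analyte subset (by default the EFSA-4: PFOA, PFNA, PFHxS,
PFOS), the lower bound replaces non-detects by zero and the upper bound by
the LOQ — lower LOQs therefore directly shrink upper-bound exposure.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .panel import EFSA4

__all__ = [
    "OccurrenceRecord",
    "detect_decision",
    "frequency_by_category",
    "bound_sums",
]


@dataclass(frozen=True)
class OccurrenceRecord:
    sample_id: str
    category: str
    analyte_id: str
    conc: float          # ng/kg
    loq: float           # ng/kg
    loc: float | None    # ng/kg
    detected: bool
    confirmed: bool

    def __post_init__(self) -> None:
        if self.detected and not self.conc > self.loq:
            raise ValueError("detected requires conc > LOQ")
        if self.confirmed and not self.detected:
            raise ValueError("confirmed requires detected")


def detect_decision(conc: float, loq: float | None, verdict_confirmed: bool
                    ) -> tuple[bool, bool]:
    """(detected, confirmed) for one result; ``conc ≤ LOQ`` reports absence."""
    if loq is None:
        raise ValueError("not assessable: LOQ unknown")
    detected = conc > loq
    return detected, detected and verdict_confirmed


def frequency_by_category(records: list[OccurrenceRecord]) -> pd.DataFrame:
    """Per-category sample counts and the fraction with ≥1 confirmed analyte.

    A sample counts once no matter how many of its analytes confirm.
    """
    if not records:
        raise ValueError("no records")
    df = pd.DataFrame([r.__dict__ for r in records])
    per_sample = df.groupby(["category", "sample_id"])["confirmed"].any().reset_index()
    out = per_sample.groupby("category").agg(
        n_samples=("sample_id", "nunique"),
        n_with_confirmed=("confirmed", "sum"),
    ).reset_index()
    out["fraction"] = out["n_with_confirmed"] / out["n_samples"]
    return out


def bound_sums(
    records: list[OccurrenceRecord],
    subset: tuple[str, ...] = EFSA4,
    loqs: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-sample lower- and upper-bound sums over an analyte subset, ng/kg.

    Lower bound: non-detects contribute zero. Upper bound: non-detects
    contribute their LOQ (taken from ``loqs`` when given, else from the
    record). Every subset analyte needs a known LOQ.
    """
    if not records:
        raise ValueError("no records")
    rows = []
    df = pd.DataFrame([r.__dict__ for r in records])
    df = df[df["analyte_id"].isin(subset)]
    for sid, grp in df.groupby("sample_id", sort=True):
        present = set(grp["analyte_id"])
        missing = [a for a in subset if a not in present]
        lb = ub = 0.0
        for row in grp.itertuples(index=False):
            loq = loqs.get(row.analyte_id, row.loq) if loqs else row.loq
            if loq is None:
                raise ValueError(f"missing LOQ for {row.analyte_id} in sample {sid}")
            if row.detected:
                lb += row.conc
                ub += row.conc
            else:
                ub += loq
        for analyte in missing:
            if loqs is None or analyte not in loqs:
                raise ValueError(f"missing LOQ for {analyte} in sample {sid}")
            ub += loqs[analyte]
        rows.append({"sample_id": sid, "lower_bound": lb, "upper_bound": ub})
    return pd.DataFrame(rows)
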