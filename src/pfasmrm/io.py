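"""Delimited-text schemas and run configuration.

All interchange is comma-separated UTF-8 text with a header row, "."
decimal, concentrations in ng/kg and retention times in minutes:

* peak table: ``sample_id, transition_id, area, rt[, snr]``
* sample sheet: ``sample_id, role, matrix_category, matrix_name,
  spike_level_ng_kg, batch_id``
* traces (long format): ``sample_id, transition_id, time_min, intensity``

Readers validate eagerly and report offending row numbers; writers produce
canonical files that round-trip byte-stably.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .simulate import (
    CATEGORIES,
    ROLE_MFS,
    ROLE_PROCEDURAL_BLANK,
    ROLE_SPIKED,
    ROLE_UNKNOWN,
    SampleRecord,
)

__all__ = [
    "SchemaError",
    "Thresholds",
    "RunConfig",
    "read_peak_table",
    "write_peak_table",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_traces",
    "write_traces",
]

_ROLES = (ROLE_PROCEDURAL_BLANK, ROLE_MFS, ROLE_SPIKED, ROLE_UNKNOWN)
_ROLE_SUGGESTIONS = {
    "blank": ROLE_PROCEDURAL_BLANK,
    "procedural blank": ROLE_PROCEDURAL_BLANK,
    "calibrant": ROLE_MFS,
    "mfs": ROLE_MFS,
    "standard": ROLE_MFS,
    "spike": ROLE_SPIKED,
    "sample": ROLE_UNKNOWN,
}


class SchemaError(ValueError):
    """A file violated one of the interchange schemas."""


@dataclass(frozen=True)
class Thresholds:
    """Decision thresholds of the pipeline; defaults are the method's values."""

    ion_ratio_pct: float = 30.0
    rrt_pct: float = 1.0
    snr_min: float = 6.0
    blank_loq_factor: float = 3.3
    recovery_bounds: tuple[float, float] = (65.0, 135.0)
    rsd_rl_max: float = 25.0

    def __post_init__(self) -> None:
        vals = (self.ion_ratio_pct, self.rrt_pct, self.snr_min,
                self.blank_loq_factor, *self.recovery_bounds, self.rsd_rl_max)
        if any(v <= 0 for v in vals):
            raise ValueError("all thresholds must be positive")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 1
    out_dir: str = "pfasmrm-out"
    categories: tuple[str, ...] = CATEGORIES
    noise_cv: float = 0.10
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        th = Thresholds(**{k: (tuple(v) if isinstance(v, list) else v)
                           for k, v in raw.pop("thresholds", {}).items()})
        if "categories" in raw:
            raw["categories"] = tuple(raw["categories"])
        return cls(thresholds=th, **raw)


# ---------------------------------------------------------------------------
# Peak tables
# ---------------------------------------------------------------------------

def read_peak_table(path: str | Path, known_transitions: set[str] | None = None
                    ) -> pd.DataFrame:
    """Read and validate a peak table; optional snr column defaults to NaN."""
    df = pd.read_csv(path)
    required = ["sample_id", "transition_id", "area", "rt"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if "snr" not in df.columns:
        df["snr"] = float("nan")
    for col in ("area", "rt", "snr"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # header + 1-based
            raise SchemaError(f"{path}: non-numeric {col!r} at row {row}")
        df[col] = pd.to_numeric(df[col], errors="coerce")
    dup = df.duplicated(["sample_id", "transition_id"])
    if dup.any():
        row = int(dup.idxmax()) + 2
        raise SchemaError(f"{path}: duplicate (sample_id, transition_id) at row {row}")
    if known_transitions is not None:
        unknown = ~df["transition_id"].isin(known_transitions)
        if unknown.any():
            rows = [int(i) + 2 for i in df.index[unknown][:5]]
            ids = sorted(df.loc[unknown, "transition_id"].unique()[:5])
            raise SchemaError(f"{path}: unknown transition ids {ids} at rows {rows}")
    return df[["sample_id", "transition_id", "area", "rt", "snr"]]


def write_peak_table(df: pd.DataFrame, path: str | Path) -> None:
    cols = ["sample_id", "transition_id", "area", "rt"]
    if "snr" in df.columns:
        cols.append("snr")
    df[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Sample sheets
# ---------------------------------------------------------------------------

def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    df = pd.read_csv(path)
    required = ["sample_id", "role", "matrix_category", "matrix_name",
                "spike_level_ng_kg", "batch_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    records: list[SampleRecord] = []
    for i, row in df.iterrows():
        rownum = int(i) + 2
        role = str(row["role"])
        if role not in _ROLES:
            hint = _ROLE_SUGGESTIONS.get(role.strip().lower())
            suggestion = f"; did you mean {hint!r}?" if hint else ""
            raise SchemaError(f"{path}: unknown role {role!r} at row {rownum}{suggestion}")
        cat = str(row["matrix_category"])
        if role != ROLE_PROCEDURAL_BLANK and cat not in CATEGORIES:
            raise SchemaError(f"{path}: unknown matrix category {cat!r} at row {rownum}")
        level = row["spike_level_ng_kg"]
        if pd.isna(level):
            if role in (ROLE_MFS, ROLE_SPIKED):
                raise SchemaError(
                    f"{path}: role {role!r} requires spike_level_ng_kg at row {rownum}"
                )
            level = 0.0
        records.append(SampleRecord(
            sample_id=str(row["sample_id"]), role=role, matrix_category=cat,
            matrix_name=str(row["matrix_name"]), spike_level_ng_kg=float(level),
            batch_id=str(row["batch_id"]),
        ))
    return records


def write_sample_sheet(records: list[SampleRecord], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Traces
# ---------------------------------------------------------------------------

def read_traces(path: str | Path):
    from .simulate import frame_to_traces

    df = pd.read_csv(path)
    required = ["sample_id", "transition_id", "time_min", "intensity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    return frame_to_traces(df)


def write_traces(traces, path: str | Path) -> None:
    from .simulate import traces_to_frame

    traces_to_frame(traces).to_csv(path, index=False)
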