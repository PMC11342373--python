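"""End-to-end batch processing: peak table → concentrations, identity
verdicts, limits, validation statistics and occurrence summaries.

The unit of processing is one batch (one matrix category, one day): its
peak table and sample sheet go in; a results table with blank-corrected,
calibrated concentrations and confirmation verdicts comes out. Campaign-
level helpers combine the five category batches into the validation
report and the limits report.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import confirm as _confirm
from . import quant as _quant
from .io import RunConfig, Thresholds, write_peak_table, write_sample_sheet
from .limits import LimitSet, determine_limits
from .panel import AnalytePanel, build_default_panel
from .simulate import (
    ROLE_MFS,
    ROLE_PROCEDURAL_BLANK,
    ROLE_SPIKED,
    ROLE_UNKNOWN,
    GenerationParams,
    SampleRecord,
    design_validation_batch,
    default_generation_params,
    simulate_peak_table,
)
from .validation import ValidationSummary, aggregate_validation, classify

__all__ = ["BatchResult", "quantify_batch", "batch_limits", "campaign_validation",
           "run_pipeline"]

#: Qualifier S/N below which a calibrant's ion ratio / RRT is excluded from
#: the reference means (low levels would otherwise corrupt the reference).
QUALIFIER_USABILITY_SNR = 3.0


@dataclass
class BatchResult:
    """Everything computed from one batch."""

    category: str
    results: pd.DataFrame
    models: dict[str, _quant.CalibrationModel]          # full-range, per analyte
    segment_models: dict[tuple[str, tuple[float, float]], _quant.CalibrationModel]
    blank_responses: dict[str, float]
    mfs_levels: tuple[float, ...]
    log: list[str] = field(default_factory=list)


def _index_peaks(peak_table: pd.DataFrame) -> dict[tuple[str, str], tuple[float, float, float]]:
    out = {}
    for row in peak_table.itertuples(index=False):
        snr = getattr(row, "snr", math.nan)
        out[(row.sample_id, row.transition_id)] = (row.area, row.rt, snr)
    return out


def quantify_batch(
    peak_table: pd.DataFrame,
    samples: list[SampleRecord],
    panel: AnalytePanel,
    thresholds: Thresholds | None = None,
    mfs_levels: tuple[float, ...] | None = None,
) -> BatchResult:
    """Quantify and confirm every sample × analyte of one batch.

    Steps: response ratios against each analyte's internal standard; blank
    correction by the mean procedural-blank response; full-range 1/x-weighted
    calibration per analyte (also yielding the reference ion ratio and RRT
    from calibrants with usable qualifier signal); per-sample segment
    selection and segment-model quantification; identity confirmation.
    """
    th = thresholds or Thresholds()
    peaks = _index_peaks(peak_table)
    by_role: dict[str, list[SampleRecord]] = {}
    for s in samples:
        by_role.setdefault(s.role, []).append(s)
    calibrants = by_role.get(ROLE_MFS, [])
    blanks = by_role.get(ROLE_PROCEDURAL_BLANK, [])
    levels = mfs_levels or tuple(sorted({s.spike_level_ng_kg for s in calibrants}))
    log: list[str] = []
    pseudo_analytes = set(panel.single_product_analytes())

    def lookup(sample_id: str, compound: str, which: str = "quantifier"):
        tr = panel.quantifier(compound) if which == "quantifier" else panel.qualifier(compound)
        if tr is None:
            return None
        return peaks.get((sample_id, tr.transition_id))

    def response_of(sample_id: str, analyte: str) -> tuple[float | None, list[str]]:
        q = lookup(sample_id, analyte)
        isd = lookup(sample_id, panel.is_map[analyte])
        if q is None or isd is None or isd[0] <= 0:
            return None, [_quant.QuantFlag.NO_IS]
        return _quant.response_ratio(q[0], isd[0]), []

    # -- blank correction ----------------------------------------------------
    blank_responses: dict[str, float] = {}
    for analyte in panel.analytes:
        vals = []
        for b in blanks:
            r, _ = response_of(b.sample_id, analyte)
            if r is not None:
                vals.append(r)
        if vals:
            blank_responses[analyte] = _quant.average_blank_response(vals)
        else:
            blank_responses[analyte] = 0.0
            log.append(f"{analyte}: no procedural blank response; correction skipped")
        log.append(f"blank-correction {analyte}: subtracted mean response "
                   f"{blank_responses[analyte]:.6g} from all samples")

    # -- calibration ---------------------------------------------------------
    models: dict[str, _quant.CalibrationModel] = {}
    seg_models: dict[tuple[str, tuple[float, float]], _quant.CalibrationModel] = {}
    cal_points: dict[str, tuple[list[float], list[float]]] = {}
    for analyte in panel.analytes:
        xs, ys, ratios, rrts = [], [], [], []
        for c in calibrants:
            r, fl = response_of(c.sample_id, analyte)
            if r is None:
                continue
            corrected, _ = _quant.blank_correct(r, blank_responses[analyte])
            xs.append(c.spike_level_ng_kg)
            ys.append(corrected)
            q = lookup(c.sample_id, analyte)
            ql = lookup(c.sample_id, analyte, "qualifier")
            # same usability rule for both references: qualifier S/N ≥ 3
            usable = (q and ql and q[0] > 0
                      and not (math.isnan(ql[2]) or ql[2] < QUALIFIER_USABILITY_SNR))
            if usable:
                ratios.append(ql[0] / q[0])
                isd = lookup(c.sample_id, panel.is_map[analyte])
                if isd and isd[1] > 0:
                    rrts.append(q[1] / isd[1])
        ref_ir = float(np.mean(ratios)) if ratios else None
        ref_rrt = float(np.mean(rrts)) if rrts else None
        try:
            models[analyte] = _quant.fit_mfs_calibration(
                xs, ys, analyte_id=analyte, ref_ion_ratio=ref_ir, ref_rrt=ref_rrt
            )
            cal_points[analyte] = (xs, ys)
        except ValueError as exc:
            log.append(f"{analyte}: calibration failed ({exc})")

    def segment_model(analyte: str, segment: tuple[float, float]):
        key = (analyte, segment)
        if key not in seg_models:
            xs, ys = cal_points[analyte]
            full = models[analyte]
            seg_models[key] = _quant.fit_mfs_calibration(
                xs, ys, analyte_id=analyte, segment=segment,
                ref_ion_ratio=full.ref_ion_ratio, ref_rrt=full.ref_rrt,
            )
        return seg_models[key]

    # -- quantify + confirm every sample -------------------------------------
    rows = []
    for s in samples:
        for analyte in panel.analytes:
            r, flags = response_of(s.sample_id, analyte)
            conc = corrected = None
            confirmed = False
            verdict = None
            if r is not None and analyte in models:
                corrected, f2 = _quant.blank_correct(r, blank_responses[analyte])
                flags += f2
                prelim, _ = _quant.quantify(corrected, models[analyte])
                segment, f3 = _quant.select_segment(prelim, levels)
                flags += f3
                try:
                    model = segment_model(analyte, segment)
                except ValueError:
                    model = models[analyte]
                conc, f4 = _quant.quantify(corrected, model)
                flags += f4
            q = lookup(s.sample_id, analyte)
            ql = lookup(s.sample_id, analyte, "qualifier")
            isd = lookup(s.sample_id, panel.is_map[analyte])
            ref = models.get(analyte)
            verdict = _confirm.check_confirmation(
                s.sample_id, analyte,
                quantifier_area=q[0] if q else None,
                qualifier_area=ql[0] if ql else None,
                rt_analyte=q[1] if q else None,
                rt_is=isd[1] if isd else None,
                ref_ion_ratio=ref.ref_ion_ratio if ref else None,
                ref_rrt=ref.ref_rrt if ref else None,
                thresholds={"ion_ratio": th.ion_ratio_pct, "rrt": th.rrt_pct},
                pseudo_ratio=analyte in pseudo_analytes,
            )
            confirmed = verdict.confirmed
            rows.append({
                "sample_id": s.sample_id, "role": s.role,
                "matrix_category": s.matrix_category, "matrix_name": s.matrix_name,
                "spike_level": s.spike_level_ng_kg, "analyte_id": analyte,
                "response": r, "corrected_response": corrected, "conc": conc,
                "ion_ratio": verdict.ion_ratio_obs, "ion_ratio_dev": verdict.ion_ratio_dev,
                "rrt": verdict.rrt_obs, "rrt_dev": verdict.rrt_dev,
                "confirmed": confirmed, "reasons": ";".join(verdict.reasons),
                "pseudo_ratio": verdict.pseudo_ratio, "flags": ";".join(flags),
            })

    return BatchResult(
        category=samples[0].matrix_category if samples else "",
        results=pd.DataFrame(rows),
        models=models,
        segment_models=seg_models,
        blank_responses=blank_responses,
        mfs_levels=levels,
        log=log,
    )


def batch_limits(batch: BatchResult, peak_table: pd.DataFrame, panel: AnalytePanel,
                 thresholds: Thresholds | None = None,
                 validation_passes: dict[str, dict[float, bool]] | None = None
                 ) -> list[LimitSet]:
    """Determine the LOQ/LOC of every analyte from the batch's MFS ladder.

    The blank-equivalent concentration is the mean blank response divided by
    the low-segment (or full-range) calibration slope.
    """
    th = thresholds or Thresholds()
    peaks = _index_peaks(peak_table)
    res = batch.results
    mfs = res[res["role"] == ROLE_MFS]
    out: list[LimitSet] = []
    for analyte in panel.analytes:
        model = batch.segment_models.get((analyte, _quant.LOW_SEGMENT)) \
            or batch.models.get(analyte)
        if model is None or model.slope <= 0:
            continue
        blank_conc = batch.blank_responses.get(analyte, 0.0) / model.slope
        tr = panel.quantifier(analyte)
        snr_by_level: dict[float, float] = {}
        confirmed_by_level: dict[float, bool] = {}
        for row in mfs[mfs["analyte_id"] == analyte].itertuples(index=False):
            pk = peaks.get((row.sample_id, tr.transition_id))
            snr = pk[2] if pk is not None else math.nan
            snr_by_level[row.spike_level] = 0.0 if math.isnan(snr) else snr
            confirmed_by_level[row.spike_level] = bool(row.confirmed)
        out.append(determine_limits(
            analyte, batch.category, snr_by_level, confirmed_by_level,
            blank_conc, batch.mfs_levels, snr_min=th.snr_min,
            validation_level_passes=(validation_passes or {}).get(analyte),
        ))
    return out


def campaign_validation(batches: list[BatchResult], limits_by_cat=None
                        ) -> tuple[list[ValidationSummary], dict[str, str]]:
    """Validation summaries and quan/qual verdicts across all category batches.

    Apparent recovery per spiked sample uses the unfortified result of the
    same matrix as baseline when that result is itself quantifiable (above
    the category LOQ); otherwise no baseline is subtracted — the procedural-
    blank contribution has already been removed in response space.

    When limits are supplied, spike levels below an analyte's LOQ in a
    category are excluded from that analyte's evaluation: below the LOQ the
    addition is not quantifiable by definition (e.g. a 2.5 ng/kg spike on
    top of a 5 ng/kg blank background), so no recovery row is produced
    there, mirroring how validation tables omit sub-LOQ levels.
    """
    frames = []
    for batch in batches:
        res = batch.results
        spiked = res[res["role"] == ROLE_SPIKED].copy()
        unspiked = res[res["role"] == ROLE_UNKNOWN]
        base = {(r.matrix_name, r.analyte_id): r.conc
                for r in unspiked.itertuples(index=False) if r.conc is not None}
        loqs = {}
        if limits_by_cat and batch.category in limits_by_cat:
            loqs = {ls.analyte_id: ls.loq for ls in limits_by_cat[batch.category]}
        recov, keep = [], []
        for r in spiked.itertuples(index=False):
            baseline = 0.0
            b = base.get((r.matrix_name, r.analyte_id))
            loq = loqs.get(r.analyte_id)
            if b is not None and loq is not None and b > loq:
                baseline = b
            recov.append(
                (r.conc - baseline) / r.spike_level * 100.0 if r.conc is not None
                else math.nan
            )
            keep.append(loq is None or r.spike_level >= loq)
        spiked["recovery"] = recov
        frames.append(spiked[pd.Series(keep, index=spiked.index)])
    all_spiked = pd.concat(frames, ignore_index=True).dropna(subset=["recovery"])
    summaries = aggregate_validation(all_spiked)
    verdicts: dict[str, str] = {}
    for analyte in sorted({s.analyte_id for s in summaries}):
        verdicts[analyte] = classify([s for s in summaries if s.analyte_id == analyte])
    return summaries, verdicts


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, params: GenerationParams | None = None,
                 panel: AnalytePanel | None = None) -> dict:
    """Simulate, quantify, confirm, determine limits, validate and summarize.

    Deterministic for a fixed config seed. Writes the report bundle (results
    table, limits report, validation report, occurrence summary, log and a
    machine-readable summary.json) into ``config.out_dir`` and returns the
    bundle as a dict of DataFrames / objects.
    """
    panel = panel or build_default_panel()
    params = params or default_generation_params(noise_cv=config.noise_cv)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    batches: list[BatchResult] = []
    limits_by_cat: dict[str, list[LimitSet]] = {}
    log: list[str] = []
    for i, category in enumerate(config.categories):
        design = design_validation_batch(category, seed=config.seed * 1000 + i)
        table = simulate_peak_table(design, params, panel)
        samples = design.samples()
        batch = quantify_batch(table, samples, panel, config.thresholds,
                               mfs_levels=design.mfs_levels)
        limits_by_cat[category] = batch_limits(batch, table, panel, config.thresholds)
        batches.append(batch)
        log.extend(f"[{category}] {line}" for line in batch.log)
        write_peak_table(table, out / f"peaks_{category}.csv")
        write_sample_sheet(samples, out / f"samples_{category}.csv")

    summaries, verdicts = campaign_validation(batches, limits_by_cat)

    results = pd.concat([b.results for b in batches], ignore_index=True)
    limits_rows = [ls.__dict__ | {"flags": ";".join(ls.flags)}
                   for lst in limits_by_cat.values() for ls in lst]
    limits_df = pd.DataFrame(limits_rows)
    val_df = pd.DataFrame([{
        "analyte_id": s.analyte_id, "spike_level": s.spike_level,
        "n_samples": s.n_samples, "n_confirmed": s.n_confirmed,
        "recovery_pct": round(s.recovery_mean, 1),
        "rsd_rl_pct": round(s.rsd_rl, 1),
        "conclusion": verdicts[s.analyte_id],
    } for s in summaries])

    # occurrence over the unfortified validation matrices
    from .occurrence import OccurrenceRecord, detect_decision, frequency_by_category

    occ_records = []
    for batch in batches:
        loqs = {ls.analyte_id: ls for ls in limits_by_cat[batch.category]}
        unk = batch.results[batch.results["role"] == ROLE_UNKNOWN]
        for r in unk.itertuples(index=False):
            ls = loqs.get(r.analyte_id)
            if ls is None or ls.loq is None or r.conc is None:
                continue
            detected, confirmed = detect_decision(r.conc, ls.loq, bool(r.confirmed))
            occ_records.append(OccurrenceRecord(
                r.sample_id, batch.category, r.analyte_id, r.conc,
                ls.loq, ls.loc, detected, confirmed,
            ))
    occ_df = frequency_by_category(occ_records) if occ_records else pd.DataFrame()

    results.to_csv(out / "results.csv", index=False)
    limits_df.to_csv(out / "limits.csv", index=False)
    val_df.to_csv(out / "validation.csv", index=False)
    if not occ_df.empty:
        occ_df.to_csv(out / "occurrence.csv", index=False)
    (out / "run.log").write_text("\n".join(log) + "\n")
    summary = {
        "seed": config.seed,
        "categories": list(config.categories),
        "verdicts": verdicts,
        "n_quan": sum(v == "quan" for v in verdicts.values()),
        "n_qual": sum(v == "qual" for v in verdicts.values()),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    return {
        "batches": batches,
        "results": results,
        "limits": limits_df,
        "limit_sets": limits_by_cat,
        "validation": val_df,
        "summaries": summaries,
        "verdicts": verdicts,
        "occurrence": occ_df,
        "summary": summary,
    }
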