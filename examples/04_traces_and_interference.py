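"""From chromatograms to an identity verdict - and how interference breaks it.

Synthesizes the MRM traces of a spiked sample, integrates them, and runs
the two-channel identity check (ion ratio within 30%, relative retention
time within 1% of the calibration references). A co-eluting interferent
injected on the sensitive PFOS qualifier channel (the bile-acid failure
mode that motivates monitoring the less sensitive 499>99 transition as
quantifier) distorts the ion ratio and the verdict flips.
"""

from pfasmrm import (
    build_default_panel,
    default_generation_params,
    design_validation_batch,
    simulate_peak_table,
)
from pfasmrm.confirm import check_confirmation
from pfasmrm.peaks import process_trace
from pfasmrm.simulate import (
    InterferenceSpec,
    TraceParams,
    synthesize_traces,
    synthesize_traces_with_interference,
)

panel = build_default_panel()
design = design_validation_batch("root", seed=3)
params = default_generation_params(noise_cv=0.0)
params.rt_jitter_sd = 0.0
table = simulate_peak_table(design, params, panel)

sid = "root-day-P2-s50"
tp = TraceParams(baseline_noise_sd=1e-4)
quant_id = panel.quantifier("PFOS").transition_id
qual_id = panel.qualifier("PFOS").transition_id
is_id = panel.quantifier(panel.is_map["PFOS"]).transition_id
sub = table[(table.sample_id == sid)
            & table.transition_id.isin([quant_id, qual_id, is_id])]
ref_ir = panel.qualifier("PFOS").true_ion_fraction / panel.quantifier("PFOS").true_ion_fraction

for label, traces in [
    ("clean", synthesize_traces(sub, panel, tp, seed=4)),
    ("with co-eluting interferent on the qualifier channel",
     synthesize_traces_with_interference(
         sub, panel, tp,
         InterferenceSpec(transition_id=qual_id, rt_offset_min=0.02, area=1.5),
         seed=4)),
]:
    peaks = {tid: process_trace(traces[(sid, tid)], panel.expected_rt["PFOS"], 0.45)
             for tid in (quant_id, qual_id, is_id)}
    verdict = check_confirmation(
        sid, "PFOS",
        quantifier_area=peaks[quant_id].area,
        qualifier_area=peaks[qual_id].area,
        rt_analyte=peaks[quant_id].rt_apex,
        rt_is=peaks[is_id].rt_apex,
        ref_ion_ratio=ref_ir, ref_rrt=1.0,
    )
    print(f"{label}:")
    print(f"  ion ratio {verdict.ion_ratio_obs:.3f} "
          f"(deviation {verdict.ion_ratio_dev:.1f}%), "
          f"RRT deviation {verdict.rrt_dev:.3f}%")
    print(f"  confirmed: {verdict.confirmed}"
          + (f"  reasons: {', '.join(verdict.reasons)}" if verdict.reasons else ""))
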