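import math

import numpy as np
import pandas as pd
import pytest

from pfasmrm.panel import build_default_panel
from pfasmrm.simulate import (
    MFS_LEVELS,
    BatchDesign,
    GenerationParams,
    InterferenceSpec,
    TraceParams,
    design_validation_batch,
    frame_to_traces,
    simulate_peak_table,
    synthesize_traces,
    synthesize_traces_with_interference,
    traces_to_frame,
)


def single_matrix_params(noise_cv=0.0, **overrides) -> GenerationParams:
    base = dict(
        response_slope=0.02,
        abs_recovery={c: 0.5 for c in ("leafy", "bulb_leek", "root", "fruit", "other")},
        matrix_effect={c: 1.0 for c in ("leafy", "bulb_leek", "root", "fruit", "other")},
        noise_cv=noise_cv,
        rt_jitter_sd=0.0,
    )
    base.update(overrides)
    return GenerationParams(**base)


class TestBatchDesign:
    def test_validation_batch_layout(self):
        design = design_validation_batch("leafy", 1)
        samples = design.samples()
        assert design.mfs_levels == MFS_LEVELS
        roles = pd.Series([s.role for s in samples]).value_counts()
        assert roles["mfs_calibrant"] == 12
        assert roles["procedural_blank"] == 2
        # 6 matrices x (1 unspiked + 3 spike levels)
        assert roles["spiked"] == 18
        assert roles["unknown"] == 6

    def test_unknown_category_rejected(self):
        with pytest.raises(ValueError, match="category"):
            design_validation_batch("seaweed", 1)

    def test_levels_must_increase(self):
        with pytest.raises(ValueError):
            BatchDesign(category="root", mfs_levels=(0.0, 5.0, 5.0))


class TestPeakTable:
    def test_noise_free_quantifier_area_is_product_of_factors(self, panel):
        design = BatchDesign(category="root", seed=0)
        params = single_matrix_params()
        table = simulate_peak_table(design, params, panel)
        tr = panel.quantifier("PFOS")
        row = table[(table.sample_id == "root-day-P2-s50") &
                    (table.transition_id == tr.transition_id)]
        # 50 ng/kg * 0.02 * 0.5 recovery * 1.0 matrix effect
        assert row.area.iloc[0] == pytest.approx(0.5, abs=1e-12)

    def test_seeded_determinism(self, panel):
        design = BatchDesign(category="fruit", seed=42)
        params = single_matrix_params(noise_cv=0.15, rt_jitter_sd=0.01)
        t1 = simulate_peak_table(design, params, panel)
        t2 = simulate_peak_table(design, params, panel)
        pd.testing.assert_frame_equal(t1, t2)
        assert t1.to_csv() == t2.to_csv()

    def test_lognormal_noise_has_unit_mean(self, panel):
        # oracle: E[LN] = 1 by construction; the sample mean over many
        # replicates must sit within 1% of the noise-free area
        design = BatchDesign(category="other", seed=5)
        params0 = single_matrix_params()
        noise_free = simulate_peak_table(design, params0, panel)
        tr = panel.quantifier("PFNA").transition_id
        ref = noise_free[(noise_free.sample_id == "other-day-P2-s500") &
                         (noise_free.transition_id == tr)].area.iloc[0]
        rng = np.random.default_rng(123)
        n = 10_000
        cv = 0.1
        sigma2 = math.log(1 + cv * cv)
        draws = ref * rng.lognormal(-sigma2 / 2, math.sqrt(sigma2), n)
        assert draws.mean() == pytest.approx(ref, rel=0.01)
        # and the simulator's own noisy areas average near the clean value
        areas = []
        for seed in range(60):
            t = simulate_peak_table(
                BatchDesign(category="other", seed=seed),
                single_matrix_params(noise_cv=cv), panel)
            areas.append(t[(t.sample_id == "other-day-P2-s500") &
                           (t.transition_id == tr)].area.iloc[0])
        assert np.mean(areas) == pytest.approx(ref, rel=0.06)

    def test_conservation_of_ion_fractions(self, panel):
        # noise-free: per-analyte channel areas split the total signal
        # exactly by true ion fraction
        design = BatchDesign(category="leafy", seed=0)
        params = single_matrix_params()
        table = simulate_peak_table(design, params, panel)
        for analyte in ("PFOA", "PFOS", "PFPeA"):
            trs = panel.transitions_of(analyte)
            quant = panel.quantifier(analyte)
            sub = table[table.sample_id == "leafy-day-P2-s500"]
            areas = {t.transition_id: sub[sub.transition_id == t.transition_id].area.iloc[0]
                     for t in trs}
            total = areas[quant.transition_id] / quant.true_ion_fraction
            assert sum(areas.values()) == pytest.approx(
                total * sum(t.true_ion_fraction for t in trs), rel=1e-12)

    def test_area_strictly_increasing_in_spike_level(self, panel):
        design = BatchDesign(category="fruit", seed=0)
        table = simulate_peak_table(design, single_matrix_params(), panel)
        tr = panel.quantifier("PFHxS").transition_id
        mfs = table[table.sample_id.str.contains("mfs") & (table.transition_id == tr)]
        levels = [float(s.rsplit("-", 1)[1]) for s in mfs.sample_id]
        areas = mfs.area.to_numpy()
        order = np.argsort(levels)
        assert np.all(np.diff(areas[order]) > 0)

    def test_injection_standard_bypasses_recovery(self, panel):
        design = BatchDesign(category="root", seed=0)
        params = single_matrix_params()  # recovery 0.5
        table = simulate_peak_table(design, params, panel)
        sub = table[table.sample_id == "root-day-P2-u"]
        is_area = sub[sub.transition_id == panel.quantifier("13C4-PFOA").transition_id].area.iloc[0]
        inj_area = sub[sub.transition_id == panel.quantifier("13C8-PFOA").transition_id].area.iloc[0]
        assert inj_area == pytest.approx(2 * is_area, rel=1e-9)


class TestTraces:
    def test_gaussian_integral_matches_tabulated_area(self, panel):
        design = BatchDesign(category="root", seed=0)
        table = simulate_peak_table(design, single_matrix_params(), panel)
        sub = table[table.sample_id == "root-day-P2-s500"].head(6)
        tp = TraceParams(baseline_noise_sd=0.0)
        traces = synthesize_traces(sub, panel, tp, seed=0)
        for row in sub.itertuples(index=False):
            t, y = traces[(row.sample_id, row.transition_id)]
            if row.area == 0:
                continue
            assert np.trapezoid(y, t) == pytest.approx(row.area, rel=0.001)

    def test_undersampled_peak_rejected(self, panel):
        design = BatchDesign(category="root", seed=0)
        table = simulate_peak_table(design, single_matrix_params(), panel).head(2)
        with pytest.raises(ValueError, match="undersampled"):
            synthesize_traces(table, panel, TraceParams(sampling_interval_min=0.1), seed=0)

    def test_interference_hits_only_target_transition(self, panel):
        # a TDCA-like interferent on the sensitive PFOS channel appears on
        # that transition only
        design = BatchDesign(category="root", seed=0)
        table = simulate_peak_table(design, single_matrix_params(), panel)
        sub = table[(table.sample_id == "root-day-P2-s50") &
                    (table.transition_id.str.startswith("PFOS_"))]
        target = panel.qualifier("PFOS").transition_id  # the 499>80 channel
        other = panel.quantifier("PFOS").transition_id
        spec = InterferenceSpec(transition_id=target, rt_offset_min=0.3, area=1.0)
        tp = TraceParams(baseline_noise_sd=0.0)
        clean = synthesize_traces(sub, panel, tp, seed=0)
        dirty = synthesize_traces_with_interference(sub, panel, tp, spec, seed=0)
        sid = "root-day-P2-s50"
        extra = np.trapezoid(dirty[(sid, target)][1], dirty[(sid, target)][0]) - \
            np.trapezoid(clean[(sid, target)][1], clean[(sid, target)][0])
        assert extra == pytest.approx(1.0, rel=0.01)
        np.testing.assert_allclose(dirty[(sid, other)][1], clean[(sid, other)][1])

    def test_baseline_noise_moments(self, panel):
        # empty channel: trace mean ~ 0 and sd ~ the requested noise floor
        design = BatchDesign(category="root", seed=0)
        params = single_matrix_params()
        table = simulate_peak_table(design, params, panel)
        tr = panel.quantifier("PFOS").transition_id
        blank = table[(table.sample_id == "root-day-blk1") & (table.transition_id == tr)]
        tp = TraceParams(baseline_noise_sd=0.02, sampling_interval_min=0.0004)
        traces = synthesize_traces(blank, panel, tp, seed=9)
        t, y = traces[("root-day-blk1", tr)]
        assert t.size >= 2000
        assert abs(y.mean()) < 0.002
        assert y.std(ddof=1) == pytest.approx(0.02, rel=0.10)

    def test_trace_frame_round_trip(self, panel):
        design = BatchDesign(category="root", seed=0)
        table = simulate_peak_table(design, single_matrix_params(), panel).head(3)
        traces = synthesize_traces(table, panel, TraceParams(), seed=1)
        back = frame_to_traces(traces_to_frame(traces))
        assert set(back) == set(traces)
        for key in traces:
            np.testing.assert_array_equal(back[key][1], traces[key][1])
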