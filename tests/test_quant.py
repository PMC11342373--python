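import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pfasmrm.quant import (
    HIGH_SEGMENT,
    LOW_SEGMENT,
    CalibrationModel,
    QuantFlag,
    average_blank_response,
    blank_correct,
    fit_mfs_calibration,
    quantify,
    response_ratio,
    select_segment,
)
from pfasmrm.simulate import MFS_LEVELS


def weighted_normal_equations(levels, responses):
    """Independent oracle: solve the 1/x-weighted normal equations by hand."""
    x = np.asarray(levels, float)
    y = np.asarray(responses, float)
    w = np.where(x > 0, 1.0 / np.where(x > 0, x, 1.0), 1.0)
    sw, swx, swx2 = w.sum(), (w * x).sum(), (w * x * x).sum()
    swy, swxy = (w * y).sum(), (w * x * y).sum()
    det = swx2 * sw - swx * swx
    slope = (swxy * sw - swx * swy) / det
    intercept = (swx2 * swy - swx * swxy) / det
    return slope, intercept


class TestResponseRatio:
    def test_basic_division(self):
        assert response_ratio(0.5, 0.05) == pytest.approx(10.0)

    def test_zero_is_area_rejected(self):
        with pytest.raises(ValueError, match="internal-standard"):
            response_ratio(1.0, 0.0)

    @given(k=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=25, deadline=None)
    def test_common_factor_cancels(self, k):
        # an ionization or injection-volume factor hitting both channels
        # leaves the response ratio unchanged
        base = response_ratio(2.0, 0.4)
        assert response_ratio(2.0 * k, 0.4 * k) == pytest.approx(base, rel=1e-12)


class TestBlankCorrection:
    def test_mean_of_duplicates(self):
        assert average_blank_response([0.10, 0.14]) == pytest.approx(0.12)

    def test_single_blank_warns(self):
        with pytest.warns(UserWarning, match="one procedural blank"):
            assert average_blank_response([0.10]) == pytest.approx(0.10)

    def test_no_blanks_warn_and_skip(self):
        with pytest.warns(UserWarning, match="no procedural blanks"):
            assert average_blank_response([]) == 0.0

    def test_subtraction_and_flag(self):
        corrected, flags = blank_correct(0.5, 0.12)
        assert corrected == pytest.approx(0.38)
        assert flags == []
        corrected, flags = blank_correct(0.05, 0.12)
        assert corrected == pytest.approx(-0.07)
        assert flags == [QuantFlag.BELOW_BLANK]


class TestCalibrationFit:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        levels = np.array(MFS_LEVELS)
        responses = 0.017 * levels + 0.003 + rng.normal(0, 0.002, levels.size)
        model = fit_mfs_calibration(levels, responses, analyte_id="PFOA")
        slope, intercept = weighted_normal_equations(levels, responses)
        assert model.slope == pytest.approx(slope, rel=1e-10)
        assert model.intercept == pytest.approx(intercept, rel=1e-10)
        assert model.weighting == "1/x"
        assert model.n_points == levels.size

    def test_exact_line_recovered_exactly(self):
        levels = np.array(MFS_LEVELS)
        model = fit_mfs_calibration(levels, 0.02 * levels, analyte_id="X")
        assert model.slope == pytest.approx(0.02, abs=1e-14)
        assert model.intercept == pytest.approx(0.0, abs=1e-14)

    def test_segment_restriction(self):
        levels = np.array(MFS_LEVELS)
        responses = 0.02 * levels
        low = fit_mfs_calibration(levels, responses, segment=LOW_SEGMENT)
        assert low.segment == LOW_SEGMENT
        assert low.n_points == sum(1 for l in MFS_LEVELS if l <= 100)
        high = fit_mfs_calibration(levels, responses, segment=HIGH_SEGMENT)
        assert high.n_points == sum(1 for l in MFS_LEVELS if 50 <= l <= 2000)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError, match="5 distinct levels"):
            fit_mfs_calibration([0, 1, 2, 5], [0, 0.02, 0.04, 0.1])

    def test_constant_responses_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_mfs_calibration(MFS_LEVELS, [0.5] * len(MFS_LEVELS))

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=20, deadline=None)
    def test_quantify_round_trips_the_fit(self, seed):
        rng = np.random.default_rng(seed)
        levels = np.array(MFS_LEVELS)
        responses = 0.02 * levels + rng.normal(0, 0.001, levels.size)
        model = fit_mfs_calibration(levels, responses)
        # inverting the line at a fitted point returns the corresponding x
        x = 50.0
        y = model.slope * x + model.intercept
        conc, flags = quantify(y, model)
        assert conc == pytest.approx(x, rel=1e-9)
        assert flags == []

    def test_parameter_recovery_under_noise(self):
        # n = 30 noisy calibrations at CV 5%: mean fitted slope within 3%
        true_slope = 0.02
        levels = np.array(MFS_LEVELS)
        cv = 0.05
        sigma2 = np.log(1 + cv * cv)
        slopes = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            noise = rng.lognormal(-sigma2 / 2, np.sqrt(sigma2), levels.size)
            model = fit_mfs_calibration(levels, true_slope * levels * noise)
            slopes.append(model.slope)
        assert 0.97 <= np.mean(slopes) / true_slope <= 1.03


class TestSegmentSelection:
    @pytest.mark.parametrize("conc,expected", [
        (0.0, LOW_SEGMENT),
        (50.0, LOW_SEGMENT),
        (100.0, LOW_SEGMENT),      # split level stays low
        (100.1, HIGH_SEGMENT),
        (1999.0, HIGH_SEGMENT),
        (-3.0, LOW_SEGMENT),       # negative provisional is a low-end case
    ])
    def test_bracketing(self, conc, expected):
        segment, flags = select_segment(conc, MFS_LEVELS)
        assert segment == expected
        assert flags == []

    def test_above_top_flags_extrapolation(self):
        segment, flags = select_segment(2500.0, MFS_LEVELS)
        assert segment == HIGH_SEGMENT
        assert flags == [QuantFlag.EXTRAPOLATION]


class TestQuantify:
    def test_inversion_arithmetic(self):
        model = CalibrationModel("X", 0.02, 0.001, LOW_SEGMENT, "1/x", None, None, 8)
        conc, flags = quantify(0.5, model)
        assert conc == pytest.approx((0.5 - 0.001) / 0.02)
        assert flags == []

    def test_negative_conc_kept_and_flagged(self):
        model = CalibrationModel("X", 0.02, 0.01, LOW_SEGMENT, "1/x", None, None, 8)
        conc, flags = quantify(0.0, model)
        assert conc < 0
        assert flags == [QuantFlag.NEGATIVE_CONC]

    def test_nonpositive_slope_rejected(self):
        model = CalibrationModel("X", 0.0, 0.0, LOW_SEGMENT, "1/x", None, None, 8)
        with pytest.raises(ValueError, match="slope"):
            quantify(0.5, model)


class TestBlankShiftInvariance:
    @given(shift=st.floats(min_value=0.0, max_value=0.5))
    @settings(max_examples=20, deadline=None)
    def test_constant_blank_cancels_through_correction(self, shift):
        # adding the same background response to calibrants and samples,
        # and to the blanks used for correction, leaves concentrations fixed
        levels = np.array(MFS_LEVELS)
        clean = 0.02 * levels
        blank = average_blank_response([shift, shift])
        corrected = [blank_correct(r + shift, blank)[0] for r in clean]
        model = fit_mfs_calibration(levels, corrected)
        sample_response = 0.02 * 50.0 + shift
        conc, _ = quantify(blank_correct(sample_response, blank)[0], model)
        assert conc == pytest.approx(50.0, abs=1e-8)
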