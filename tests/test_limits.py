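import pytest
from hypothesis import given, settings, strategies as st

from pfasmrm.limits import (
    BLANK_LOQ_FACTOR,
    LimitFlag,
    LimitSet,
    assess_loq_against_validation,
    blank_contribution_check,
    blank_is_substantial,
    determine_limits,
    determine_loc,
    loq_blank_strategy,
    loq_snr_strategy,
    snap_to_level,
)
from pfasmrm.simulate import MFS_LEVELS


class TestBlankStrategy:
    def test_factor_is_3_3(self):
        assert loq_blank_strategy(5.0) == pytest.approx(16.5)
        assert BLANK_LOQ_FACTOR == 3.3

    def test_requires_positive_blank(self):
        with pytest.raises(ValueError):
            loq_blank_strategy(0.0)

    @pytest.mark.parametrize("raw,expected", [
        (16.5, 25.0),   # 3.3 x 5 ng/kg blank snaps up to the 25 level
        (1.65, 2.5),
        (0.5, 0.5),     # already on the grid: stays
        (0.2, 0.5),
        (1500.0, 2000.0),
    ])
    def test_snap_to_grid(self, raw, expected):
        level, flags = snap_to_level(raw, MFS_LEVELS)
        assert level == expected
        assert flags == []

    def test_snap_above_top_flags(self):
        level, flags = snap_to_level(5000.0, MFS_LEVELS)
        assert level == max(MFS_LEVELS)
        assert flags == [LimitFlag.ABOVE_TOP_LEVEL]


class TestSnrStrategy:
    def test_lowest_level_meeting_snr(self):
        snr = {0.5: 8.0, 1.0: 20.0, 2.5: 60.0}
        loq, flags = loq_snr_strategy(snr, MFS_LEVELS)
        assert loq == 0.5
        assert flags == []

    def test_skips_levels_below_threshold(self):
        snr = {0.5: 4.0, 1.0: 5.9, 2.5: 6.0}
        loq, _ = loq_snr_strategy(snr, MFS_LEVELS)
        assert loq == 2.5   # threshold inclusive at exactly 6

    def test_no_level_passes(self):
        loq, flags = loq_snr_strategy({0.5: 1.0}, MFS_LEVELS)
        assert loq is None
        assert flags == [LimitFlag.LOQ_UNDETERMINABLE]


class TestStrategyDichotomy:
    def test_substantial_blank_boundary(self):
        # lowest nonzero level is 0.5; substantial means > 0.3 x 0.5 = 0.15
        assert not blank_is_substantial(0.15, MFS_LEVELS)
        assert blank_is_substantial(0.151, MFS_LEVELS)
        assert not blank_is_substantial(0.0, MFS_LEVELS)

    @given(blank=st.floats(min_value=0.0, max_value=100.0))
    @settings(max_examples=50, deadline=None)
    def test_determine_limits_picks_exactly_one_strategy(self, blank):
        snr = {l: 100.0 for l in MFS_LEVELS if l > 0}
        confirmed = {l: True for l in MFS_LEVELS if l > 0}
        ls = determine_limits("A", "root", snr, confirmed, blank, MFS_LEVELS)
        if blank > 0.15:
            assert ls.loq_strategy == "blank_based"
            assert ls.loq_raw == pytest.approx(3.3 * blank)
        else:
            assert ls.loq_strategy == "snr_based"
            assert ls.loq == 0.5


class TestLoc:
    def test_lowest_confirmed_level(self):
        confirmed = {0.5: False, 1.0: True, 2.5: True}
        loc, flags = determine_loc(confirmed, loq=0.5)
        assert loc == 1.0
        assert flags == []

    def test_floored_at_loq(self):
        confirmed = {0.5: True, 1.0: True}
        loc, _ = determine_loc(confirmed, loq=2.5)
        assert loc == 2.5

    def test_nothing_confirmed(self):
        loc, flags = determine_loc({0.5: False}, loq=0.5)
        assert loc is None
        assert flags == [LimitFlag.LOC_UNDETERMINABLE]

    @given(loq=st.sampled_from([l for l in MFS_LEVELS if l > 0]))
    @settings(max_examples=12, deadline=None)
    def test_loc_never_below_loq(self, loq):
        confirmed = {l: True for l in MFS_LEVELS if l > 0}
        loc, _ = determine_loc(confirmed, loq)
        assert loc >= loq

    def test_limit_set_enforces_order(self):
        with pytest.raises(ValueError, match="LOC"):
            LimitSet("A", "root", loq=25.0, loq_strategy="snr_based",
                     loq_raw=25.0, loc=10.0, blank_level=0.0)


class TestBlankContribution:
    def test_at_30_percent_passes(self):
        assert blank_contribution_check(3.0, 10.0)

    def test_strictly_above_fails(self):
        assert not blank_contribution_check(4.0, 10.0)
        assert not blank_contribution_check(3.0 + 1e-9, 10.0)

    def test_zero_blank_always_passes(self):
        assert blank_contribution_check(0.0, 0.0)

    def test_zero_sample_with_blank_fails(self):
        assert not blank_contribution_check(1.0, 0.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            blank_contribution_check(-1.0, 10.0)


class TestValidationCrossCheck:
    def test_passing_level_keeps_loq(self):
        loq, flags = assess_loq_against_validation(2.5, {2.5: True, 50.0: True})
        assert loq == 2.5
        assert flags == []

    def test_failing_level_raises_loq(self):
        loq, flags = assess_loq_against_validation(2.5, {2.5: False, 50.0: True})
        assert loq == 50.0
        assert flags == [LimitFlag.RAISED_BY_VALIDATION]

    def test_no_data_flags_unassessed(self):
        loq, flags = assess_loq_against_validation(2.5, {})
        assert loq == 2.5
        assert flags == [LimitFlag.UNASSESSED]

    def test_all_levels_fail(self):
        loq, flags = assess_loq_against_validation(2.5, {2.5: False, 50.0: False})
        assert loq == 50.0
        assert LimitFlag.LOQ_UNDETERMINABLE in flags
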