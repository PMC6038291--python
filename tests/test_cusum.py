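import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peercusum.cusum import (
    CusumParams,
    cusum_update,
    detect,
    detection_delay_closed_form,
    reference_stats,
)

from conftest import random_series


class TestParams:
    def test_defaults_and_derived_min_observations(self):
        p = CusumParams()
        assert (p.window_months, p.k_multiplier, p.h_multiplier) == (12, 0.5, 5.0)
        assert p.min_observations == 13

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(window_months=0),
            dict(k_multiplier=-0.1),
            dict(h_multiplier=0.4, k_multiplier=0.5),
            dict(mode="bogus"),
            dict(min_observations=10),
            dict(sigma_floor=-1),
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CusumParams(**kwargs)


class TestReferenceStats:
    def test_constant_window(self):
        assert reference_stats([10.0] * 12) == (10.0, 0.0)

    def test_population_sd(self, alternating_window):
        assert reference_stats(alternating_window) == (10.0, 4.0)

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="exactly 12"):
            reference_stats([10.0] * 11)

    def test_sigma_floor_applied(self):
        _, sigma = reference_stats([10.0] * 12, sigma_floor=2.5)
        assert sigma == 2.5


class TestUpdate:
    @pytest.mark.parametrize(
        "cp, cn, x, mu0, k, expected",
        [
            (0, 0, 15, 10, 2, (3, 0)),
            (3, 0, 9, 10, 2, (0, 0)),
            (0, -3, 5, 10, 2, (0, -6)),
        ],
    )
    def test_hand_computed_triples(self, cp, cn, x, mu0, k, expected):
        assert cusum_update(cp, cn, x, mu0, k) == expected

    @settings(max_examples=300, derandomize=True)
    @given(
        cp=st.floats(0, 500),
        cn=st.floats(-500, 0),
        x=st.floats(0, 100),
        mu0=st.floats(0, 100),
        k=st.floats(0, 50),
    )
    def test_sign_constraints_always_hold(self, cp, cn, x, mu0, k):
        new_pos, new_neg = cusum_update(cp, cn, x, mu0, k)
        assert new_pos >= 0.0
        assert new_neg <= 0.0


class TestClosedFormDelay:
    @pytest.mark.parametrize(
        "delta, k, h, expected", [(12, 2, 20, 2), (22, 2, 20, 1), (3, 2, 20, 20)]
    )
    def test_known_delays(self, delta, k, h, expected):
        assert detection_delay_closed_form(delta, k, h) == expected

    def test_step_at_or_below_allowance_rejected(self):
        with pytest.raises(ValueError):
            detection_delay_closed_form(2, 2, 20)


class TestDetect:
    def test_deviations_inside_allowance_never_alert(self, alternating_window):
        series = alternating_window + [10.0] * 24
        assert detect(series) == []

    def test_clean_step_alerts_on_second_post_window_month(self, alternating_window):
        # mu0=10, sigma=4 -> K=2, H=20; x=22 adds 10/month to C+
        series = alternating_window + [22.0] * 6
        alerts = detect(series)
        assert alerts[0].month == 13  # 2nd post-window observation
        assert alerts[0].direction == "increase"
        assert alerts[0].cusum_magnitude == pytest.approx(20.0)
        assert alerts[0].reference_mean == 10.0 and alerts[0].reference_sd == 4.0

    def test_decrease_mirrors_increase(self):
        window = [46.0, 54.0] * 6  # mean 50, sd 4; maps onto itself under x -> 100 - x
        up = detect(window + [62.0] * 6)
        down = detect([100 - v for v in window] + [100 - 62.0] * 6)
        assert [a.month for a in down] == [a.month for a in up]
        assert all(a.direction == "decrease" for a in down)
        assert all(a.direction == "increase" for a in up)

    def test_no_alert_inside_reference_window(self):
        # huge jump in month 11 is still part of the window: no alert there
        series = [10.0] * 11 + [90.0] + [10.0] * 5
        alerts = detect(series)
        assert all(a.month >= 12 for a in alerts)

    def test_insufficient_data_logs_and_returns_empty(self, caplog):
        with caplog.at_level(logging.INFO, logger="peercusum.cusum"):
            out = detect([50.0] * 12, entity_id="E42")
        assert out == []
        assert "insufficient data" in caplog.text and "E42" in caplog.text

    def test_out_of_range_percentile_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            detect([50.0] * 12 + [104.0])

    def test_flat_window_alerts_on_any_nonzero_deviation_only(self):
        flat = [10.0] * 12
        assert detect(flat + [10.0] * 6) == []  # zero deviation: silence
        alerts = detect(flat + [10.5])
        assert len(alerts) == 1 and alerts[0].direction == "increase"

    def test_sigma_floor_damps_flat_window(self):
        flat = [10.0] * 12
        params = CusumParams(sigma_floor=2.0)  # K=1, H=10
        assert detect(flat + [10.5] * 3, params) == []

    def test_standard_mode_resets_reference_to_recent_window(self, alternating_window):
        series = alternating_window + [22.0] * 20
        alerts = detect(series, CusumParams(mode="standard"))
        # after the first alert the refreshed reference absorbs the shift, so
        # a constant plateau produces at most a couple more alerts, not one
        # every other month forever
        assert 1 <= len(alerts) <= 3
        second_refs = [a.reference_mean for a in alerts[1:]]
        assert all(r > 10.0 for r in second_refs)

    def test_continuing_mode_marks_retriggers(self, alternating_window):
        ramp = [10 + 6 * i for i in range(10)]
        series = alternating_window + ramp
        alerts = detect(series, CusumParams(mode="continuing"))
        assert alerts[0].is_retrigger is False
        assert all(a.is_retrigger for a in alerts[1:])
        assert len(alerts) >= 3

    def test_missing_months_are_dropped_not_scored(self, alternating_window):
        base = pd.Series(
            alternating_window + [22.0] * 6,
            index=pd.period_range("2010-01", periods=18, freq="M"),
        )
        gappy = base.copy()
        gappy = pd.concat(
            [
                gappy[:6],
                pd.Series([np.nan], index=pd.period_range("2020-01", periods=1, freq="M")),
                gappy[6:],
            ]
        )
        assert [(a.direction,) for a in detect(gappy)] == [
            (a.direction,) for a in detect(base)
        ]


class TestStreamingAgainstNaiveOracle:
    @pytest.mark.parametrize("mode", ["standard", "continuing"])
    def test_seeded_series_agree_exactly(self, mode):
        from _oracle import naive_detect

        params = CusumParams(mode=mode)
        for seed in range(250):
            x = random_series(seed)
            ours = [(a.month, a.direction, a.is_retrigger) for a in detect(x, params)]
            assert ours == naive_detect(x, mode=mode), f"seed {seed}"
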