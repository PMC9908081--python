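"""Freeze-timing arithmetic, valve-dip detection and curve alignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ribbonquant.errors import (
    InsufficientShots,
    InvalidConstants,
    MissingChannel,
    NegativeMechanicsDelay,
    NoValveEvent,
)
from ribbonquant.hpf_timing import (
    SensorShot,
    TimingConstants,
    align_internal_curves,
    chamber_cooling_from_shots,
    detect_valve_opening,
    shot_timing,
    specimen_freeze_offset,
)
from ribbonquant.synthetic import gen_sensor_shot


class TestSpecimenFreezeOffset:
    @pytest.mark.parametrize(
        "chamber,sapphire,center,expected",
        [
            (5.41, 0.01, 1.1, 6.52),  # instrument defaults
            (0.0, 0.0, 0.0, 0.0),
            (5.0, 0.5, 1.5, 7.0),
        ],
    )
    def test_sum_of_components(self, chamber, sapphire, center, expected):
        c = TimingConstants(
            T_chamber_at_0=chamber, T_sapphire_at_0=sapphire, T_sample_center_at_0=center
        )
        assert specimen_freeze_offset(c) == pytest.approx(expected, abs=1e-12)

    def test_negative_component_rejected(self):
        with pytest.raises(InvalidConstants):
            TimingConstants(T_chamber_at_0=-1.0)


class TestChamberCooling:
    def test_constant_sample(self):
        mean, sd = chamber_cooling_from_shots([(4.0, 1.41)] * 10)
        assert mean == pytest.approx(5.41)
        assert sd == pytest.approx(0.0)

    def test_two_shots_sample_sd(self):
        mean, sd = chamber_cooling_from_shots([(4, 1), (5, 2)])
        assert mean == pytest.approx(6.0)
        assert sd == pytest.approx(np.sqrt(2.0))  # n-1 denominator

    @pytest.mark.parametrize("shots", [[], [(3, 0)]])
    def test_too_few_shots(self, shots):
        with pytest.raises(InsufficientShots):
            chamber_cooling_from_shots(shots)


class TestValveDetection:
    def test_noiseless_dip_recovered_within_one_sample(self):
        shot, truth = gen_sensor_shot(7, T_mechanics_ms=32.0, noise_rel=0.0)
        dt = np.median(np.diff(shot.pneumatic[:, 0]))
        assert detect_valve_opening(shot.pneumatic) == pytest.approx(
            truth["t_dip_ms"], abs=dt
        )

    def test_flat_trace_has_no_event(self):
        t = np.arange(0, 500.0, 0.1)
        with pytest.raises(NoValveEvent):
            detect_valve_opening(np.column_stack([t, np.full(t.size, 3.0)]))

    def test_monotone_rise_without_drop_has_no_event(self):
        t = np.arange(0, 500.0, 0.1)
        with pytest.raises(NoValveEvent):
            detect_valve_opening(np.column_stack([t, t * 0.01]))

    def test_noisy_dip_within_half_ms(self):
        # noise SD = 1% of the dip depth, 10 kHz sampling
        for seed in range(30):
            shot, truth = gen_sensor_shot(
                seed, T_mechanics_ms=25.4, noise_rel=0.01 * 0.3 / 6.5
            )
            assert detect_valve_opening(shot.pneumatic) == pytest.approx(
                truth["t_dip_ms"], abs=0.5
            )


class TestAlignment:
    def _shot(self):
        t = np.arange(0, 500.0, 0.1)
        rel = np.arange(0, 30.0, 0.1)
        return SensorShot(
            shot_id="s",
            pneumatic=np.column_stack([t, t * 0.01]),
            internal_pressure=np.column_stack([rel, rel * 70.0]),
            internal_temperature=np.column_stack([rel, 20 - rel]),
        )

    @pytest.mark.parametrize("delta,first", [(0.0, 430.0), (2.5, 432.5)])
    def test_anchor_shift(self, delta, first):
        out = align_internal_curves(self._shot(), 430.0, delta_ms=delta)
        assert out["internal_pressure"][0, 0] == pytest.approx(first)
        assert out["internal_temperature"][0, 0] == pytest.approx(first)

    def test_round_trip_recovers_relative_times(self):
        shot = self._shot()
        out = align_internal_curves(shot, 430.0, delta_ms=1.5)
        shift = out["internal_pressure"][0, 0] - shot.internal_pressure[0, 0]
        np.testing.assert_allclose(
            out["internal_pressure"][:, 0] - shift, shot.internal_pressure[:, 0]
        )

    def test_missing_channel(self):
        shot = SensorShot(
            shot_id="s", pneumatic=np.column_stack([np.arange(5.0), np.arange(5.0)])
        )
        with pytest.raises(MissingChannel):
            align_internal_curves(shot, 100.0)


class TestShotTiming:
    def _shot(self, stim_start):
        t = np.arange(0, 10.0, 1.0)
        return SensorShot(
            shot_id="s",
            pneumatic=np.column_stack([t, t]),
            stim_start_ms=stim_start,
        )

    @pytest.mark.parametrize(
        "t_mech,expected_delay", [(25.4, 431.92), (41.6, 448.12)]
    )
    def test_printed_delay_range(self, t_mech, expected_delay):
        st_ = shot_timing(self._shot(390.0), t_valve_open_ms=400.0 + t_mech)
        assert st_.T_HPM_delay_ms == pytest.approx(expected_delay, abs=1e-9)

    def test_long_stim_duration(self):
        # T_HPM_delay 438.0 with stim from 390 ms -> 48 ms of light
        st_ = shot_timing(self._shot(390.0), t_valve_open_ms=431.48)
        assert st_.T_HPM_delay_ms == pytest.approx(438.0)
        assert st_.stim_duration_ms == pytest.approx(48.0)
        assert st_.condition_label == "LongStim"

    def test_short_stim_label(self):
        st_ = shot_timing(self._shot(425.0), t_valve_open_ms=430.0)
        assert st_.condition_label == "ShortStim"

    def test_not_stimulated_when_light_after_freeze(self):
        st_ = shot_timing(self._shot(500.0), t_valve_open_ms=430.0)
        assert st_.stim_duration_ms == 0.0
        assert st_.condition_label == "NotStimulated"

    def test_custom_label(self):
        st_ = shot_timing(self._shot(100.0), t_valve_open_ms=430.0)
        assert st_.condition_label == "Custom"

    def test_negative_mechanics_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            st_ = shot_timing(self._shot(390.0), t_valve_open_ms=395.0)
        assert st_.T_mechanics_ms == 0.0

    def test_negative_mechanics_raise_mode(self):
        with pytest.raises(NegativeMechanicsDelay):
            shot_timing(
                self._shot(390.0), t_valve_open_ms=395.0, on_negative_mechanics="raise"
            )


class TestTimingProperties:
    @given(
        t_mech=st.floats(0.1, 100),
        chamber=st.floats(0, 20),
        stim=st.floats(0, 500),
    )
    @settings(max_examples=50, deadline=None)
    def test_delay_additive_and_stim_identity(self, t_mech, chamber, stim):
        c = TimingConstants(T_chamber_at_0=chamber)
        t = np.arange(0, 5.0)
        shot = SensorShot(
            "s", np.column_stack([t, t]), stim_start_ms=stim
        )
        st_ = shot_timing(shot, constants=c, t_valve_open_ms=400.0 + t_mech)
        expected = 400.0 + t_mech + specimen_freeze_offset(c)
        assert st_.T_HPM_delay_ms == pytest.approx(expected)
        # enlarging any component strictly increases the delay
        bigger = shot_timing(
            shot,
            constants=TimingConstants(T_chamber_at_0=chamber + 1),
            t_valve_open_ms=400.0 + t_mech,
        )
        assert bigger.T_HPM_delay_ms > st_.T_HPM_delay_ms
        # stim_duration + stim_start == delay whenever the light started early enough
        if stim <= st_.T_HPM_delay_ms:
            assert st_.stim_duration_ms + stim == pytest.approx(st_.T_HPM_delay_ms)
        else:
            assert st_.stim_duration_ms == 0.0

    def test_end_to_end_recovery_from_generated_shots(self):
        rng = np.random.default_rng(0)
        for seed in range(20):
            t_mech = float(rng.uniform(25.4, 41.6))
            shot, truth = gen_sensor_shot(
                seed, T_mechanics_ms=t_mech, noise_rel=0.001, stim_start_ms=390.0
            )
            st_ = shot_timing(shot)
            assert st_.T_HPM_delay_ms == pytest.approx(truth["T_HPM_delay_ms"], abs=0.5)
            assert st_.stim_duration_ms == pytest.approx(
                truth["stim_duration_ms"], abs=0.5
            )
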