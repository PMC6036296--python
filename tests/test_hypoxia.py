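"""Sulfite zero calibration, level-to-rate estimation, suppression stats."""

import numpy as np
import pytest

import granuflux as gf
from granuflux import (
    CalibrationError,
    MicrochamberModel,
    NoiseModel,
    OxygenCalibration,
    ValidationError,
)
from granuflux.flux_core import InjectionEvent, InjectionSchedule
from granuflux.hypoxia import LevelCycle, LevelTrace
from granuflux.synthetic_flux import (
    ChannelKinetics,
    RatePreset,
    simulate_level_plate,
)


def _const_preset(rate: float, ambient_kpa: float, n_cycles: int = 6) -> RatePreset:
    sched = InjectionSchedule((InjectionEvent("MEDIA", 2),))
    return RatePreset(
        name=f"const{rate:g}",
        schedule=sched,
        n_cycles=n_cycles,
        ocr=ChannelKinetics(baseline=rate, responses=(None,)),
        ambient_o2_kpa=ambient_kpa,
    )


def _estimate_means(plate, cal, chamber):
    out = []
    for lt in plate.samples.values():
        tr = gf.estimate_rates_from_levels(lt, cal, chamber)
        out.append(float(np.mean(tr.values("ocr"))))
    return np.array(out)


class TestPercentSuppression:
    def test_published_pair_rounds_to_95(self):
        assert round(gf.percent_suppression(389.7, 17.8)) == 95

    def test_equal_rates_zero(self):
        assert gf.percent_suppression(42.0, 42.0) == 0.0

    def test_full_suppression_is_100(self):
        assert gf.percent_suppression(42.0, 0.0) == 100.0

    def test_nonpositive_normoxic_rejected(self):
        with pytest.raises(ValidationError):
            gf.percent_suppression(0.0, 5.0)


class TestCalibrateZero:
    def test_simulated_sulfite_wells_hit_sensor_floor(self):
        chamber = MicrochamberModel(ambient_o2_kpa=19.1)
        plate = simulate_level_plate(
            _const_preset(50.0, 19.1), n_wells=2, noise=NoiseModel(seed=3)
        )
        cal = gf.calibrate_zero(
            list(plate.sulfite.values()), plate.sulfite_schedule, 19.1
        )
        assert cal.zero_signal == pytest.approx(chamber.signal_zero, abs=0.5)
        assert cal.ambient_signal == pytest.approx(
            chamber.signal_zero + chamber.signal_gain * 19.1, abs=0.5
        )

    def test_two_wells_pool_their_medians(self):
        plate = simulate_level_plate(
            _const_preset(50.0, 19.1), n_wells=2, noise=NoiseModel(seed=3)
        )
        both = gf.calibrate_zero(
            list(plate.sulfite.values()), plate.sulfite_schedule, 19.1
        )
        single = gf.calibrate_zero(
            [next(iter(plate.sulfite.values()))], plate.sulfite_schedule, 19.1
        )
        assert both.zero_signal == pytest.approx(single.zero_signal, abs=0.5)

    def test_flat_sulfite_signal_is_calibration_error(self):
        cycles = [
            LevelCycle(index=k, times_min=np.arange(5) + 10.0 * k,
                       signal=np.full(5, 500.0))
            for k in range(1, 6)
        ]
        tr = LevelTrace("S1", "sulfite", cycles)
        sched = InjectionSchedule((InjectionEvent("SULFITE", 1),))
        with pytest.raises(CalibrationError, match="not below"):
            gf.calibrate_zero([tr], sched, 19.1)

    def test_too_few_post_sulfite_cycles_rejected(self):
        cycles = [
            LevelCycle(index=k, times_min=np.arange(5) + 10.0 * k,
                       signal=np.full(5, 500.0 - 100.0 * k))
            for k in range(1, 4)
        ]
        tr = LevelTrace("S1", "sulfite", cycles)
        sched = InjectionSchedule((InjectionEvent("SULFITE", 1),))
        with pytest.raises(CalibrationError, match="post-sulfite"):
            gf.calibrate_zero([tr], sched, 19.1)

    def test_identity_calibration_is_identity_mapping(self):
        cal = OxygenCalibration.identity(19.1)
        x = np.linspace(0, 19.1, 7)
        np.testing.assert_allclose(cal.signal_to_kpa(x), x)

    def test_equal_anchors_rejected(self):
        with pytest.raises(CalibrationError):
            OxygenCalibration(19.1, zero_signal=200.0, ambient_signal=200.0)


class TestRateEstimation:
    def test_normoxic_recovery_within_10_percent(self):
        preset = _const_preset(50.0, 19.1)
        plate = simulate_level_plate(preset, n_wells=4, noise=NoiseModel(seed=1))
        cal = gf.calibrate_zero(
            list(plate.sulfite.values()), plate.sulfite_schedule, 19.1
        )
        chamber = MicrochamberModel(ambient_o2_kpa=19.1)
        est = _estimate_means(plate, cal, chamber)
        assert np.mean(est) == pytest.approx(50.0, rel=0.10)

    def test_zero_consumption_estimates_zero(self):
        preset = _const_preset(0.0, 19.1)
        plate = simulate_level_plate(preset, n_wells=2, noise=NoiseModel.off())
        cal = OxygenCalibration(
            19.1, zero_signal=200.0, ambient_signal=200.0 + 40.0 * 19.1
        )
        est = _estimate_means(plate, cal, MicrochamberModel(ambient_o2_kpa=19.1))
        assert np.allclose(est, 0.0, atol=1e-6)

    def test_hypoxic_run_needs_hypoxic_calibration(self):
        """Analyzing a hypoxic plate against a normoxic ambient anchor biases
        the estimate; the sulfite-anchored hypoxic calibration does not."""
        kpa = 0.81
        preset = _const_preset(8.0, kpa)
        plate = simulate_level_plate(preset, n_wells=4, noise=NoiseModel(seed=2))
        cal_good = gf.calibrate_zero(
            list(plate.sulfite.values()), plate.sulfite_schedule, kpa
        )
        cal_bad = OxygenCalibration(
            ambient_o2_kpa=19.1,
            zero_signal=cal_good.zero_signal,
            ambient_signal=cal_good.ambient_signal,
        )
        chamber = MicrochamberModel(ambient_o2_kpa=kpa)
        good = np.mean(_estimate_means(plate, cal_good, chamber))
        bad = np.mean(_estimate_means(plate, cal_bad, chamber))
        assert good == pytest.approx(8.0, rel=0.10)
        assert abs(bad - 8.0) / 8.0 > 0.5  # grossly biased

    def test_estimator_linear_in_true_rate(self):
        """Noiseless estimates across a simulated dilution series lie on a
        straight line through the origin with unit slope (to a few %)."""
        rates = [10.0, 20.0, 40.0]
        est = []
        for r in rates:
            plate = simulate_level_plate(
                _const_preset(r, 19.1), n_wells=1, noise=NoiseModel.off()
            )
            cal = gf.calibrate_zero(
                list(plate.sulfite.values()), plate.sulfite_schedule, 19.1
            )
            est.append(
                float(np.mean(_estimate_means(plate, cal,
                                              MicrochamberModel(ambient_o2_kpa=19.1))))
            )
        slope, intercept = np.polyfit(rates, est, 1)
        assert slope == pytest.approx(1.0, rel=0.05)
        assert abs(intercept) < 0.5
        # exact proportionality of the estimator itself
        assert est[2] / est[0] == pytest.approx(4.0, rel=0.02)

    def test_sparse_fit_window_warns_and_skips(self):
        cal = OxygenCalibration.identity(19.1)
        cycles = [
            LevelCycle(index=k, times_min=np.linspace(0, 3, 4) + 6.0 * k,
                       signal=np.linspace(19.1, 18.0, 4))
            for k in range(1, 4)
        ]
        tr = LevelTrace("A1", "g", cycles)
        with pytest.warns(UserWarning, match="fit"):
            with pytest.raises(ValidationError):
                gf.estimate_rates_from_levels(
                    tr, cal, MicrochamberModel(ambient_o2_kpa=19.1)
                )
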