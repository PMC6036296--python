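"""Simulator determinism, kinetics, microchamber physics, preset library."""

import numpy as np
import pytest

import granuflux as gf
from granuflux import ConfigurationError, MicrochamberModel, NoiseModel
from granuflux.flux_core import InjectionEvent, InjectionSchedule
from granuflux.synthetic_flux import (
    ChannelKinetics,
    RatePreset,
    StepResponse,
    TransientComponent,
    TransientResponse,
    get_preset,
    preset_from_json,
    preset_library,
    preset_to_json,
    rate_function,
    simulate_level_plate,
    simulate_rate_plate,
)


class TestRateFunction:
    def test_step_relaxation_closed_form(self):
        kin = ChannelKinetics(baseline=10.0, responses=(StepResponse(40.0, 5.0),))
        r = rate_function(kin, [30.0])
        assert r(29.9) == 10.0
        t = np.array([35.0, 40.0])
        np.testing.assert_allclose(
            r(t), 40.0 + (10.0 - 40.0) * np.exp(-(t - 30.0) / 5.0)
        )

    def test_instant_step(self):
        kin = ChannelKinetics(baseline=10.0, responses=(StepResponse(40.0, 0.0),))
        r = rate_function(kin, [30.0])
        assert r(30.01) == 40.0

    def test_transient_rides_on_pre_injection_rate(self):
        comp = TransientComponent(100.0, tau_rise=5.0, tau_decay=50.0)
        kin = ChannelKinetics(
            baseline=20.0, responses=(TransientResponse((comp,)),)
        )
        r = rate_function(kin, [10.0])
        dt = 12.0
        expected = 20.0 + 100.0 * (1 - np.exp(-dt / 5.0)) * np.exp(-dt / 50.0)
        assert r(10.0 + dt) == pytest.approx(expected)

    def test_null_response_continues_previous_segment(self):
        kin = ChannelKinetics(
            baseline=15.0, responses=(None, StepResponse(30.0, 0.0))
        )
        r = rate_function(kin, [10.0, 20.0])
        assert r(15.0) == 15.0  # primer with no effect
        assert r(25.0) == 30.0


class TestRateMode:
    def test_same_seed_identical_plate(self):
        p = get_preset("eos_glyco_10mM")
        a = simulate_rate_plate(p, n_wells=4, noise=NoiseModel(seed=11))
        b = simulate_rate_plate(p, n_wells=4, noise=NoiseModel(seed=11))
        for w in a.traces:
            np.testing.assert_array_equal(
                a.traces[w].values("ecar"), b.traces[w].values("ecar")
            )

    def test_different_seed_differs(self):
        p = get_preset("eos_glyco_10mM")
        a = simulate_rate_plate(p, n_wells=1, noise=NoiseModel(seed=11))
        b = simulate_rate_plate(p, n_wells=1, noise=NoiseModel(seed=12))
        assert not np.array_equal(
            a.traces["A1"].values("ecar"), b.traces["A1"].values("ecar")
        )

    def test_wells_independent_of_plate_size(self):
        p = get_preset("eos_glyco_10mM")
        small = simulate_rate_plate(p, n_wells=2, noise=NoiseModel(seed=5))
        large = simulate_rate_plate(p, n_wells=6, noise=NoiseModel(seed=5))
        for w in small.traces:
            np.testing.assert_array_equal(
                small.traces[w].values("ecar"), large.traces[w].values("ecar")
            )

    def test_doubling_cells_doubles_noiseless_rates(self):
        p = get_preset("eos_glyco_10mM")
        a1 = simulate_rate_plate(p, n_wells=1, noise=NoiseModel.off())
        a2 = simulate_rate_plate(
            p, n_wells=1, noise=NoiseModel.off(), cells_per_well=2 * p.reference_cells
        )
        np.testing.assert_allclose(
            a2.traces["A1"].values("ecar"), 2.0 * a1.traces["A1"].values("ecar")
        )

    def test_monte_carlo_peak_recovery_unbiased(self):
        """Mean post-glucose peak over 200 noisy wells within 2 SEM of truth
        (plus the small positive max-of-noise offset bounded by 5%)."""
        p = get_preset("eos_glyco_10mM")
        assay = simulate_rate_plate(p, n_wells=96, noise=NoiseModel(seed=42))
        peaks = [
            gf.post_glucose_peak(tr, assay.schedule) for tr in assay.traces.values()
        ]
        assay2 = simulate_rate_plate(p, n_wells=96, noise=NoiseModel(seed=43))
        peaks += [
            gf.post_glucose_peak(tr, assay2.schedule) for tr in assay2.traces.values()
        ]
        truth = p.truth["post_glucose_peak_ecar"][0]
        mean, sem = np.mean(peaks), np.std(peaks, ddof=1) / np.sqrt(len(peaks))
        assert abs(mean - truth) < max(2 * sem, 0.05 * truth)

    def test_schedule_preset_mismatch_rejected(self):
        p = get_preset("eos_glyco_10mM")
        bad = InjectionSchedule((InjectionEvent("GLUC", 3),))
        with pytest.raises(ConfigurationError):
            simulate_rate_plate(p, n_wells=1, schedule=bad)


class TestLevelMode:
    def test_zero_rate_stays_at_ambient(self):
        sched = InjectionSchedule((InjectionEvent("MEDIA", 2),))
        p = RatePreset(
            name="null", schedule=sched, n_cycles=4,
            ocr=ChannelKinetics(0.0, (None,)), ambient_o2_kpa=19.1,
        )
        plate = simulate_level_plate(p, n_wells=1, noise=NoiseModel.off())
        chamber = MicrochamberModel(ambient_o2_kpa=19.1)
        for cyc in plate.samples["A1"].cycles:
            kpa = (cyc.signal - chamber.signal_zero) / chamber.signal_gain
            np.testing.assert_allclose(kpa, 19.1, rtol=1e-9)

    def test_constant_rate_no_backdiffusion_is_linear(self):
        """With kd = 0 the chamber level declines linearly at -r/(V alpha);
        the fixed-step integrator must match the closed form to 1e-6."""
        sched = InjectionSchedule((InjectionEvent("MEDIA", 2),))
        p = RatePreset(
            name="lin", schedule=sched, n_cycles=3,
            ocr=ChannelKinetics(50.0, (None,)), ambient_o2_kpa=19.1,
        )
        chamber = MicrochamberModel(ambient_o2_kpa=19.1, kd_per_min=0.0)
        plate = simulate_level_plate(
            p, n_wells=1, noise=NoiseModel.off(), chamber=chamber
        )
        v_alpha = chamber.volume_ul * chamber.solubility_pmol_per_ul_kpa
        for cyc in plate.samples["A1"].cycles:
            kpa = (cyc.signal - chamber.signal_zero) / chamber.signal_gain
            t_rel = cyc.times_min - cyc.times_min[0]
            expected = 19.1 - 50.0 / v_alpha * t_rel
            np.testing.assert_allclose(kpa, expected, rtol=1e-6)

    def test_cross_module_recovery_within_10_percent(self):
        """estimate_rates_from_levels on a simulated mito plate recovers the
        preset's post-FCCP rate within 10%."""
        p = get_preset("eos_fccp_hypoxia")
        plate = simulate_level_plate(p, n_wells=3, noise=NoiseModel(seed=9))
        cal = gf.calibrate_zero(
            list(plate.sulfite.values()), plate.sulfite_schedule, p.ambient_o2_kpa
        )
        chamber = MicrochamberModel(ambient_o2_kpa=p.ambient_o2_kpa)
        peaks = []
        for lt in plate.samples.values():
            tr = gf.estimate_rates_from_levels(lt, cal, chamber)
            m = gf.mito_params(tr, plate.schedule)
            peaks.append(m.max_cap + m.non_mito)
        truth = p.truth["post_fccp_peak_ocr"][0]
        assert np.mean(peaks) == pytest.approx(truth, rel=0.10)


class TestPresetLibrary:
    def test_eos_pma_is_biphasic_two_component(self):
        p = get_preset("eos_pma")
        (resp,) = p.ocr.responses
        assert isinstance(resp, TransientResponse)
        assert len(resp.components) == 2

    def test_unknown_name_errors(self):
        with pytest.raises(KeyError, match="unknown preset"):
            get_preset("eos_warp_drive")

    def test_all_presets_serialize_losslessly(self):
        for name, p in preset_library().items():
            back = preset_from_json(preset_to_json(p))
            assert back == p, name

    def test_truths_match_published_group_means(self):
        lib = preset_library()
        assert lib["eos_glyco_1mM"].truth["post_glucose_peak_ecar"] == (31.2, 6.4)
        assert lib["neut_glyco_10mM"].truth["post_glucose_peak_ecar"] == (73.1, 0.4)
        assert lib["eos_pma"].truth["peak_ocr"] == (572.8, 15.8)
        assert lib["neut_pma_hypoxia"].truth["peak_ocr"] == (17.8, 0.8)
        assert lib["eos_fccp_normoxia"].truth["post_fccp_peak_ocr"] == (63.8, 0.7)
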