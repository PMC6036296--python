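"""Data model, I/O round-trips, window segmentation and aggregation."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import granuflux as gf
from granuflux import (
    FormatError,
    InjectionEvent,
    InjectionSchedule,
    NoiseModel,
    OutlierRule,
    RateMeasurement,
    ValidationError,
)
from granuflux.synthetic_flux import get_preset, simulate_rate_plate

from conftest import make_trace, schedule


def _assert_assays_equal(a, b):
    assert set(a.traces) == set(b.traces)
    assert a.schedule == b.schedule
    assert a.cells_per_well == pytest.approx(b.cells_per_well)
    for well in a.traces:
        ma, mb = a.traces[well].measurements, b.traces[well].measurements
        assert len(ma) == len(mb)
        for x, y in zip(ma, mb):
            assert (x.index, x.group) == (y.index, y.group)
            assert x.time_min == pytest.approx(y.time_min)
            for ch in ("ecar", "ocr"):
                vx, vy = getattr(x, ch), getattr(y, ch)
                assert (vx is None) == (vy is None)
                if vx is not None:
                    assert vx == pytest.approx(vy)


class TestMeasurementInvariants:
    def test_rejects_zero_index(self):
        with pytest.raises(ValidationError):
            RateMeasurement("A1", "g", 0, 1.0, ecar=1.0)

    def test_rejects_both_rates_absent(self):
        with pytest.raises(ValidationError):
            RateMeasurement("A1", "g", 1, 1.0)

    def test_trace_rejects_duplicate_index(self):
        ms = [
            RateMeasurement("A1", "g", 1, 1.0, ecar=1.0),
            RateMeasurement("A1", "g", 1, 2.0, ecar=2.0),
        ]
        with pytest.raises(ValidationError, match="duplicate"):
            gf.KineticTrace("A1", "g", ms)

    def test_trace_rejects_nonmonotone_time(self):
        ms = [
            RateMeasurement("A1", "g", 1, 5.0, ecar=1.0),
            RateMeasurement("A1", "g", 2, 5.0, ecar=2.0),
        ]
        with pytest.raises(ValidationError, match="time"):
            gf.KineticTrace("A1", "g", ms)


class TestRateTableIO:
    def test_round_trip_simulated_plate(self):
        assay = simulate_rate_plate(
            get_preset("eos_glyco_10mM"), n_wells=4, noise=NoiseModel(seed=7)
        )
        rates, sched = io.StringIO(), io.StringIO()
        gf.write_rate_table(assay, rates, sched)
        rates.seek(0), sched.seek(0)
        back = gf.read_rate_table(rates, sched)
        _assert_assays_equal(assay, back)

    def test_row_count_matches_plate(self):
        assay = simulate_rate_plate(
            get_preset("mito_reference"), n_wells=96, noise=NoiseModel.off()
        )
        sink = io.StringIO()
        gf.write_rate_table(assay, sink)
        n_rows = len(sink.getvalue().strip().splitlines())
        # 96 wells x 12 cycles + header + 1 metadata comment line per field
        assert n_rows >= 96 * 12 + 1

    def test_missing_column_is_format_error(self):
        with pytest.raises(FormatError):
            gf.read_rate_table(io.StringIO("well,group,index\nA1,g,1\n"))

    def test_no_rate_column_is_format_error(self):
        with pytest.raises(FormatError):
            gf.read_rate_table(io.StringIO("well,group,index,time_min\nA1,g,1,1.0\n"))

    def test_duplicate_well_index_rejected(self):
        csv = (
            "well,group,index,time_min,ecar\n"
            "A1,g,4,1.0,5\nA1,g,4,2.0,6\nA1,g,5,3.0,7\n"
        )
        with pytest.raises(ValidationError, match="duplicate"):
            gf.read_rate_table(io.StringIO(csv))

    def test_schedule_beyond_trace_rejected(self):
        csv = "well,group,index,time_min,ecar\nA1,g,1,1.0,5\nA1,g,2,2.0,6\n"
        sched = "name,after_index\nGLUC,2\n"
        with pytest.raises(ValidationError):
            gf.read_rate_table(io.StringIO(csv), io.StringIO(sched))


class TestSegmentWindows:
    def test_three_events_partition(self):
        tr = make_trace(ecar=range(12))
        ws = gf.segment_windows(tr, schedule(("A", 3), ("B", 6), ("C", 9)))
        assert [(w.start, w.end) for w in ws] == [(1, 3), (4, 6), (7, 9), (10, 12)]
        assert [w.label for w in ws] == ["baseline", "A", "B", "C"]

    def test_single_event(self):
        tr = make_trace(ecar=range(6))
        ws = gf.segment_windows(tr, schedule(("GLUC", 3)))
        assert [(w.start, w.end) for w in ws] == [(1, 3), (4, 6)]

    def test_equal_after_index_rejected(self):
        with pytest.raises(ValidationError):
            schedule(("A", 3), ("B", 3))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_windows_partition_cycle_range(self, data):
        n = data.draw(st.integers(6, 30))
        k = data.draw(st.integers(0, min(4, n - 2)))
        cuts = data.draw(
            st.lists(st.integers(1, n - 1), min_size=k, max_size=k, unique=True)
        )
        sched = schedule(*[(f"E{i}", a) for i, a in enumerate(sorted(cuts))])
        tr = make_trace(ecar=range(n))
        ws = gf.segment_windows(tr, sched)
        covered = sorted(i for w in ws for i in w.indices())
        assert covered == list(range(1, n + 1))  # union = all, no overlap


class TestAggregateGroup:
    def test_mean_sem_hand_computed(self):
        traces = {
            w: make_trace(ocr=[v, v + 1], well_id=w, group="g")
            for w, v in zip(["A1", "A2", "A3"], [10, 12, 14])
        }
        assay = gf.PlateAssay(traces, InjectionSchedule(()))
        gt = gf.aggregate_group(assay, "g")
        assert gt.ocr_mean[0] == pytest.approx(12.0)
        assert gt.ocr_sem[0] == pytest.approx(2.0 / np.sqrt(3))  # 1.1547
        assert gt.ocr_n[0] == 3

    def test_single_well_sem_absent(self):
        assay = gf.PlateAssay(
            {"A1": make_trace(ocr=[5, 6], group="g")}, InjectionSchedule(())
        )
        gt = gf.aggregate_group(assay, "g")
        assert gt.ocr_mean[0] == 5.0
        assert np.isnan(gt.ocr_sem[0])

    def test_unknown_group_errors(self):
        assay = gf.PlateAssay(
            {"A1": make_trace(ocr=[5, 6], group="g")}, InjectionSchedule(())
        )
        with pytest.raises(ValidationError):
            gf.aggregate_group(assay, "nope")

    def test_outlier_flagged_but_included_by_default(self):
        traces = {}
        for w, v in zip(["A1", "A2", "A3", "A4", "A5"], [10, 10.5, 9.5, 10.2, 300]):
            traces[w] = make_trace(ocr=[v, v], well_id=w, group="g",
                                   times=[1.0, 2.0])
        assay = gf.PlateAssay(traces, InjectionSchedule(()))
        gt = gf.aggregate_group(assay, "g")
        assert "A5" in gt.flagged_wells
        assert gt.excluded_wells == ()
        assert gt.ocr_n[0] == 5  # still included
        gt_on = gf.aggregate_group(assay, "g", OutlierRule(enabled=True))
        assert "A5" in gt_on.excluded_wells
        assert gt_on.ocr_n[0] == 4

    def test_matches_brute_force_on_random_plate(self, rng):
        traces = {}
        for w in range(8):
            vals = rng.normal(50, 10, size=6)
            traces[f"A{w+1}"] = make_trace(
                ocr=vals, well_id=f"A{w+1}", group="g"
            )
        assay = gf.PlateAssay(traces, InjectionSchedule(()))
        gt = gf.aggregate_group(assay, "g")
        stack = np.array([traces[f"A{w+1}"].values("ocr") for w in range(8)])
        np.testing.assert_allclose(gt.ocr_mean, stack.mean(axis=0))
        np.testing.assert_allclose(
            gt.ocr_sem, stack.std(axis=0, ddof=1) / np.sqrt(8)
        )


class TestDensityScaling:
    def test_identity_and_linearity(self):
        assert gf.scale_to_reference_density(40.0, 150e3, 150e3) == 40.0
        assert gf.scale_to_reference_density(40.0, 300e3, 150e3) == 20.0

    def test_nonpositive_counts_rejected(self):
        with pytest.raises(ValidationError):
            gf.scale_to_reference_density(40.0, 0, 150e3)

    def test_normalized_double_density_matches_reference(self):
        preset = get_preset("eos_glyco_10mM")
        a1 = simulate_rate_plate(preset, n_wells=1, noise=NoiseModel.off())
        a2 = simulate_rate_plate(
            preset, n_wells=1, noise=NoiseModel.off(), cells_per_well=300e3
        )
        v1 = a1.traces["A1"].values("ecar")
        v2 = gf.scale_to_reference_density(
            a2.traces["A1"].values("ecar"), 300e3, preset.reference_cells
        )
        np.testing.assert_allclose(v2, v1)
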