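import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tspopet import (
    DynamicImage,
    FrameSchedule,
    TimeActivityCurve,
    build_frame_schedule,
    decay_correct,
    decay_uncorrect,
    extract_roi_tac,
    read_dynamic,
    to_percent_id,
    window_mean,
    write_dynamic,
)
from tspopet.core import HALF_LIFE_MIN, InvalidScheduleError, UnitsError


def make_tac(values, **kw):
    sched = FrameSchedule.from_durations([1.0] * len(values))
    return TimeActivityCurve(schedule=sched, values=values, **kw)


class TestFrameSchedule:
    def test_default_acquisition(self):
        sched = build_frame_schedule([1.0] * 5 + [2.0] * 5 + [5.0] * 3 + [10.0] * 3)
        assert sched.n_frames == 16
        assert sched.total_duration == 60.0
        assert sched.midpoints[-1] == 55.0

    def test_single_frame(self):
        sched = build_frame_schedule([1.0])
        assert sched.n_frames == 1
        assert sched.starts[0] == 0.0
        assert sched.midpoints[0] == 0.5

    @pytest.mark.parametrize("durations", [[], [1.0, -1.0], [0.0]])
    def test_invalid_durations_rejected(self, durations):
        with pytest.raises(InvalidScheduleError):
            build_frame_schedule(durations)

    @given(st.lists(st.floats(0.1, 30.0), min_size=1, max_size=40))
    @settings(deadline=None, max_examples=50)
    def test_contiguity_and_midpoints(self, durations):
        sched = build_frame_schedule(durations)
        np.testing.assert_allclose(sched.starts[1:],
                                   sched.starts[:-1] + sched.durations[:-1])
        np.testing.assert_allclose(sched.midpoints,
                                   sched.starts + sched.durations / 2)
        assert sched.starts[0] == 0.0


class TestDecayCorrection:
    def test_zero_tac_stays_zero(self):
        tac = make_tac(np.zeros(4), decay_corrected=False, isotope="C11")
        assert np.all(decay_correct(tac).values == 0.0)

    def test_one_half_life_doubles(self):
        half_life = HALF_LIFE_MIN["C11"]
        sched = FrameSchedule.from_durations([2 * half_life])  # midpoint = T1/2
        tac = TimeActivityCurve(schedule=sched, values=[1.0],
                                decay_corrected=False, isotope="C11")
        assert decay_correct(tac).values[0] == pytest.approx(2.0, rel=1e-12)

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        tac = make_tac(rng.uniform(1, 10, 8), decay_corrected=False, isotope="F18")
        back = decay_uncorrect(decay_correct(tac))
        np.testing.assert_allclose(back.values, tac.values, rtol=1e-12)

    def test_unknown_isotope_and_double_correction(self):
        tac = make_tac(np.ones(3), decay_corrected=False, isotope="none")
        with pytest.raises(ValueError):
            decay_correct(tac)
        corrected = make_tac(np.ones(3), decay_corrected=True, isotope="C11")
        with pytest.raises(UnitsError):
            decay_correct(corrected)


class TestPercentID:
    def test_conversion_value(self):
        tac = make_tac([100.0])
        out = to_percent_id(tac, injected_dose_MBq=100.0)
        assert out.values[0] == pytest.approx(0.1)
        assert out.units == "%ID/cm3"

    def test_zero_maps_to_zero_and_linearity(self):
        tac = make_tac([0.0, 50.0, 100.0])
        out1 = to_percent_id(tac, injected_dose_MBq=10.0)
        out2 = to_percent_id(tac, injected_dose_MBq=20.0)
        assert out1.values[0] == 0.0
        np.testing.assert_allclose(out1.values, 2 * out2.values)
        assert np.all(np.diff(out1.values) > 0)  # order preserved

    def test_errors(self):
        tac = make_tac([1.0])
        with pytest.raises(ValueError):
            to_percent_id(tac, injected_dose_MBq=0.0)
        pct = to_percent_id(tac, injected_dose_MBq=1.0)
        with pytest.raises(UnitsError):
            to_percent_id(pct, injected_dose_MBq=1.0)


class TestWindowMean:
    def test_constant_tac(self, schedule):
        tac = TimeActivityCurve(schedule=schedule, values=np.full(16, 3.25))
        assert window_mean(tac, 40, 60) == pytest.approx(3.25)

    def test_equal_duration_frames_average(self, schedule):
        values = np.zeros(16)
        values[-2:] = [2.0, 4.0]  # 40-50 and 50-60 min frames
        tac = TimeActivityCurve(schedule=schedule, values=values)
        assert window_mean(tac, 40, 60) == pytest.approx(3.0)

    def test_partial_overlap_pro_rata(self):
        tac = make_tac([1.0, 3.0])
        # window [0.5, 1.5): half of each 1-min frame
        assert window_mean(tac, 0.5, 1.5) == pytest.approx(2.0)

    def test_whole_schedule_equals_weighted_mean(self, schedule):
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 5, 16)
        tac = TimeActivityCurve(schedule=schedule, values=values)
        expected = np.average(values, weights=schedule.durations)
        assert window_mean(tac, 0, 60) == pytest.approx(expected)

    def test_errors(self, schedule):
        tac = TimeActivityCurve(schedule=schedule, values=np.ones(16))
        with pytest.raises(ValueError):
            window_mean(tac, 70, 80)
        with pytest.raises(ValueError):
            window_mean(tac, 50, 40)


class TestRoiExtraction:
    def _image(self, data):
        return DynamicImage(data=data, voxel_size_mm=[1, 1, 1],
                            schedule=FrameSchedule.from_durations([1.0] * data.shape[3]))

    def test_uniform_image(self):
        data = np.tile(np.array([1.0, 2.0, 3.0]), (4, 4, 4, 1))
        img = self._image(data)
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1:3, 1:3, 1:3] = True
        np.testing.assert_allclose(extract_roi_tac(img, mask).values, [1, 2, 3])

    def test_two_voxel_mean(self):
        data = np.zeros((2, 1, 1, 1))
        data[0, 0, 0, 0] = 1.0
        data[1, 0, 0, 0] = 3.0
        img = self._image(data)
        mask = np.ones((2, 1, 1), dtype=bool)
        assert extract_roi_tac(img, mask).values[0] == pytest.approx(2.0)

    def test_bad_masks(self):
        img = self._image(np.zeros((2, 2, 2, 1)))
        with pytest.raises(ValueError):
            extract_roi_tac(img, np.zeros((2, 2, 2), dtype=bool))  # empty
        with pytest.raises(ValueError):
            extract_roi_tac(img, np.ones((3, 3, 3), dtype=bool))  # wrong grid


class TestNiftiRoundTrip:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        img = DynamicImage(
            data=rng.uniform(0, 100, (8, 8, 8, 16)),
            voxel_size_mm=[0.776, 0.776, 0.796],
            schedule=FrameSchedule.default(),
            isotope="F18",
            injected_dose_MBq=21.5,
        )
        path = tmp_path / "scan.nii"
        write_dynamic(img, path)
        back = read_dynamic(path)
        assert np.abs(back.data - img.data).max() < 1e-4  # float32 storage
        np.testing.assert_allclose(back.voxel_size_mm, img.voxel_size_mm, rtol=1e-6)
        assert back.schedule == img.schedule
        assert back.isotope == "F18"
        assert back.injected_dose_MBq == pytest.approx(21.5)

    def test_sidecar_frame_mismatch(self, tmp_path):
        import json

        img = DynamicImage(data=np.zeros((4, 4, 4, 16)), voxel_size_mm=[1, 1, 1],
                           schedule=FrameSchedule.default())
        path = tmp_path / "scan.nii"
        write_dynamic(img, path)
        sidecar = tmp_path / "scan.json"
        payload = json.loads(sidecar.read_text())
        payload["frame_durations_min"] = payload["frame_durations_min"][:15]
        sidecar.write_text(json.dumps(payload))
        with pytest.raises(ValueError):
            read_dynamic(path)

    def test_missing_sidecar(self, tmp_path):
        img = DynamicImage(data=np.zeros((4, 4, 4, 1)), voxel_size_mm=[1, 1, 1],
                           schedule=FrameSchedule.from_durations([1.0]))
        path = tmp_path / "scan.nii"
        write_dynamic(img, path)
        (tmp_path / "scan.json").unlink()
        with pytest.raises(FileNotFoundError):
            read_dynamic(path)
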