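"""Excision, tiling, gating, normalization, STFT and diurnal tagging."""

from datetime import datetime, time

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import holterpaf as hp
from holterpaf.io import BeatAnnotation, BeatClass, HolterRecording, PatientRecord
from holterpaf.preprocess import (
    Diurnal,
    EcgSegment,
    SEGMENT_SAMPLES,
    Setting,
    build_excision_mask,
    diurnal_tag,
    extract_segments,
    label_segments,
    noise_gate,
    stft_transform,
    znormalize,
)

FS = 128.0


def _rec(duration_s=70.0, start=datetime(2020, 6, 1, 9, 0, 0), seed=0):
    n = int(duration_s * FS)
    rng = np.random.default_rng(seed)
    return HolterRecording("PX", rng.normal(0, 0.3, (3, n)), FS,
                           ["a", "b", "c"], start)


def _seg(samples, **kw):
    return EcgSegment("PX", datetime(2020, 6, 1, 12, 0), samples, **kw)


class TestExcisionMask:
    def test_no_ectopy_keeps_everything(self):
        rec = _rec(70.0)
        mask = build_excision_mask(rec, [], Setting.WITH_SVE)
        assert mask.kept_intervals == [(0, 8960)]

    def test_single_ve_at_35s(self):
        rec = _rec(70.0)
        anns = [BeatAnnotation(int(35 * FS), BeatClass.VE)]
        mask = build_excision_mask(rec, anns, Setting.WITH_SVE)
        assert mask.kept_intervals == [(0, 4032), (4928, 8960)]
        assert mask.removal_log["VE_window"] == 1

    def test_sve_kept_in_setting1_excised_in_setting2(self):
        rec = _rec(70.0)
        anns = [BeatAnnotation(int(35 * FS), BeatClass.SVE)]
        m1 = build_excision_mask(rec, anns, Setting.WITH_SVE)
        assert m1.kept_intervals == [(0, 8960)]
        m2 = build_excision_mask(rec, anns, Setting.WITHOUT_SVE)
        assert m2.kept_intervals == [(0, 4032), (4928, 8960)]
        segs = extract_segments(rec, m1, anns)
        covering = [s for s in segs if s.contains_sve]
        assert len(covering) == 1  # the window containing t=35 s

    def test_overlapping_windows_merge(self):
        rec = _rec(70.0)
        anns = [BeatAnnotation(int(30 * FS), BeatClass.VE),
                BeatAnnotation(int(33 * FS), BeatClass.VE)]
        mask = build_excision_mask(rec, anns, Setting.WITH_SVE)
        assert mask.kept_intervals == [
            (0, int(26.5 * FS)), (int(36.5 * FS), 8960)]

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 8959),
                              st.sampled_from(["N", "S", "V"])),
                    max_size=12),
           st.sampled_from([Setting.WITH_SVE, Setting.WITHOUT_SVE]))
    def test_mask_equals_brute_force_sample_mask(self, beats, setting):
        rec = _rec(70.0, seed=1)
        cls = {"N": BeatClass.NORMAL, "S": BeatClass.SVE, "V": BeatClass.VE}
        anns = sorted((BeatAnnotation(i, cls[s]) for i, s in beats),
                      key=lambda a: a.sample_index)
        mask = build_excision_mask(rec, anns, setting)
        # oracle: per-sample boolean removal
        removed = np.zeros(8960, dtype=bool)
        half = int(3.5 * FS)
        for a in anns:
            if a.beat_class == BeatClass.VE or (
                    a.beat_class == BeatClass.SVE
                    and setting == Setting.WITHOUT_SVE):
                removed[max(0, a.sample_index - half):
                        a.sample_index + half] = True
        kept = np.zeros(8960, dtype=bool)
        for lo, hi in mask.kept_intervals:
            kept[lo:hi] = True
        assert np.array_equal(kept, ~removed)


class TestSegmentExtraction:
    def test_exact_70s_gives_10(self):
        rec = _rec(70.0)
        mask = build_excision_mask(rec, [], Setting.WITH_SVE)
        assert len(extract_segments(rec, mask)) == 10

    def test_ve_excision_leaves_8(self):
        rec = _rec(70.0)
        anns = [BeatAnnotation(int(35 * FS), BeatClass.VE)]
        mask = build_excision_mask(rec, anns, Setting.WITH_SVE)
        assert len(extract_segments(rec, mask, anns)) == 8

    def test_below_window_gives_0(self):
        rec = _rec(6.9)
        mask = build_excision_mask(rec, [], Setting.WITH_SVE)
        assert extract_segments(rec, mask) == []

    @settings(max_examples=40, deadline=None)
    @given(st.lists(st.integers(0, 8959), max_size=8))
    def test_count_matches_brute_force_tiling(self, ve_samples):
        rec = _rec(70.0, seed=2)
        anns = sorted((BeatAnnotation(i, BeatClass.VE) for i in ve_samples),
                      key=lambda a: a.sample_index)
        mask = build_excision_mask(rec, anns, Setting.WITH_SVE)
        segs = extract_segments(rec, mask, anns)
        expected = sum((b - a) // SEGMENT_SAMPLES
                       for a, b in mask.kept_intervals)
        assert len(segs) == expected
        # no segment may overlap an excised region
        kept = np.zeros(8960, dtype=bool)
        for lo, hi in mask.kept_intervals:
            kept[lo:hi] = True
        for s in segs:
            k = rec.sample_of_time(s.start_time)
            assert kept[k:k + SEGMENT_SAMPLES].all()
        assert SEGMENT_SAMPLES * len(segs) <= rec.n_samples

    def test_segments_partition_day_night(self, tiny_cohort):
        _, manifest, data = tiny_cohort
        rec, anns = data["P0000"]
        mask = build_excision_mask(rec, anns, Setting.WITH_SVE)
        segs = extract_segments(rec, mask, anns)
        assert all(s.diurnal in (Diurnal.DAY, Diurnal.NIGHT) for s in segs)

    def test_setting2_has_no_sve_segments(self, tiny_cohort):
        _, manifest, data = tiny_cohort
        for p in manifest:
            rec, anns = data[p.patient_id]
            segs = hp.preprocess_patient(rec, anns, p, Setting.WITHOUT_SVE)
            assert not any(s.contains_sve for s in segs)


class TestNoiseGate:
    def test_all_zero_dropped(self):
        assert not noise_gate(_seg(np.zeros((3, SEGMENT_SAMPLES))))

    def test_clean_beat_train_kept(self, quiet_recording):
        rec, anns = quiet_recording
        mask = build_excision_mask(rec, anns, Setting.WITH_SVE)
        segs = extract_segments(rec, mask, anns)
        assert segs and all(noise_gate(s) for s in segs)

    def test_ten_percent_clipped_dropped(self, rng):
        x = rng.normal(0, 0.3, (3, SEGMENT_SAMPLES))
        n_clip = int(0.10 * SEGMENT_SAMPLES)
        x[0, :n_clip] = 5.0
        assert not noise_gate(_seg(x))

    def test_normalized_input_rejected(self, rng):
        seg = znormalize(_seg(rng.normal(0, 1, (3, SEGMENT_SAMPLES))))
        with pytest.raises(ValueError):
            noise_gate(seg)


class TestZNormalize:
    def test_zero_mean_unit_sd(self, rng):
        seg = znormalize(_seg(rng.normal(2.0, 3.0, (3, SEGMENT_SAMPLES))))
        assert np.allclose(seg.samples.mean(axis=1), 0, atol=1e-6)
        assert np.allclose(seg.samples.std(axis=1), 1, atol=1e-6)

    def test_constant_channel_maps_to_zeros(self, rng):
        x = rng.normal(0, 1, (3, SEGMENT_SAMPLES))
        x[1] = 4.2
        seg = znormalize(_seg(x))
        assert np.all(seg.samples[1] == 0)
        assert np.allclose(seg.samples[0].std(), 1, atol=1e-6)

    def test_idempotent(self, rng):
        seg = znormalize(_seg(rng.normal(1, 2, (3, SEGMENT_SAMPLES))))
        again = znormalize(seg)
        assert np.allclose(seg.samples, again.samples, atol=1e-9)


class TestStft:
    def test_zero_input_zero_spectrogram(self):
        seg = _seg(np.zeros((3, SEGMENT_SAMPLES)))
        seg.normalized = True
        assert np.all(stft_transform(seg).values == 0)

    def test_shape_formula(self, rng):
        seg = znormalize(_seg(rng.normal(0, 1, (3, SEGMENT_SAMPLES))))
        spec = stft_transform(seg, window_size=50, hop=25)
        assert spec.values.shape == (3, 26, 34)
        spec2 = stft_transform(seg, window_size=64, hop=16)
        assert spec2.values.shape == (3, 33, (896 - 64) // 16 + 1)

    def test_window_larger_than_segment_rejected(self, rng):
        seg = znormalize(_seg(rng.normal(0, 1, (3, SEGMENT_SAMPLES))))
        with pytest.raises(ValueError):
            stft_transform(seg, window_size=1000)

    def test_pure_tone_concentrates_in_its_bin(self):
        # bin k of a 50-sample window at 128 Hz sits at k * 128 / 50 Hz
        k = 5
        f = k * FS / 50
        t = np.arange(SEGMENT_SAMPLES) / FS
        x = np.tile(np.sin(2 * np.pi * f * t), (3, 1))
        seg = _seg(x)
        seg.normalized = True
        spec = stft_transform(seg, window_size=50, hop=25)
        energy = np.expm1(spec.values[0]) ** 2  # undo log1p -> |X|^2
        frame_energy = energy.sum(axis=0)
        # Hann leakage spreads into adjacent bins; require >= 90% in k-1..k+1
        in_bin = energy[k - 1:k + 2].sum(axis=0)
        assert np.all(in_bin >= 0.9 * frame_energy)


class TestDiurnalTag:
    @pytest.mark.parametrize("clock,expected", [
        (time(22, 0, 0), Diurnal.NIGHT),
        (time(7, 0, 0), Diurnal.DAY),
        (time(12, 0, 0), Diurnal.DAY),
        (time(6, 59, 59), Diurnal.NIGHT),
        (time(21, 59, 59), Diurnal.DAY),
        (time(0, 30, 0), Diurnal.NIGHT),
    ])
    def test_boundaries_half_open(self, clock, expected):
        assert diurnal_tag(clock) == expected
        assert diurnal_tag(datetime(2020, 6, 1, clock.hour, clock.minute,
                                    clock.second)) == expected


class TestLabeling:
    def test_labels_propagate(self, rng):
        segs = [_seg(rng.normal(0, 1, (3, SEGMENT_SAMPLES)))
                for _ in range(5)]
        paf = PatientRecord("P1", True, datetime(2020, 6, 1),
                            index_date=datetime(2019, 6, 1))
        ctrl = PatientRecord("P2", False, datetime(2020, 6, 1))
        assert all(s.label for s in label_segments(segs, paf))
        assert not any(s.label for s in label_segments(segs, ctrl))

    def test_mixed_cohort_counts(self, tiny_cohort):
        _, manifest, data = tiny_cohort
        total_true = total = 0
        per_patient = {}
        for p in manifest:
            rec, anns = data[p.patient_id]
            segs = hp.preprocess_patient(rec, anns, p, Setting.WITH_SVE)
            per_patient[p.patient_id] = len(segs)
            total += len(segs)
            total_true += sum(bool(s.label) for s in segs)
        expected_true = sum(per_patient[p.patient_id]
                            for p in manifest if p.paf_label)
        assert total_true == expected_true
        assert total == sum(per_patient.values())
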