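"""R-peak detection, isoelectric estimation and small-wave delineation."""
import dataclasses

import numpy as np
import pytest

from ecgparafit import (
    DetectorConfig,
    EcgSignal,
    default_template,
    detect_pqrst,
    detect_r_peaks,
    error_profile,
    estimate_isoelectric_level,
    find_error_minima,
    generate_ecg,
    pqrst_window_halfwidth,
    r_window_halfwidth,
)
from ecgparafit.core import FitProfile


def _profile_from(eps, a=None, w=1):
    eps = np.asarray(eps, float)
    n = eps.size
    if a is None:
        a = np.full(n, -1.0)
    return FitProfile(
        centers=np.arange(w, w + n, dtype=np.int64),
        a=np.asarray(a, float),
        v=np.zeros(n),
        epsilon=eps,
        w=w,
    )


class TestFindErrorMinima:
    def test_monotone_error_has_no_candidates(self):
        assert find_error_minima(_profile_from([5, 4, 3, 2, 1]), 1e-6).size == 0

    def test_single_interior_minimum(self):
        got = find_error_minima(_profile_from([3, 1, 2, 4]), 1e-6)
        assert list(got) == [2]  # centers start at w=1

    def test_plateau_reports_leftmost_index(self):
        got = find_error_minima(_profile_from([5, 2, 2, 2, 6]), 1e-6)
        assert list(got) == [2]

    def test_sign_filter(self):
        prof = _profile_from([3, 1, 3, 1, 3], a=[-1, -1, 1, 1, 1])
        assert list(find_error_minima(prof, 1e-6, "max")) == [2]
        assert list(find_error_minima(prof, 1e-6, "min")) == [4]
        assert list(find_error_minima(prof, 1e-6, "either")) == [2, 4]

    def test_magnitude_threshold(self):
        prof = _profile_from([3, 1, 3], a=[-1, -1e-9, -1])
        assert find_error_minima(prof, 1e-6).size == 0

    def test_gaussian_peak_yields_one_candidate_at_apex(self, gaussian_peak):
        sig, apex = gaussian_peak
        prof = error_profile(sig, w=6)
        got = find_error_minima(prof, 1e-4, "max")
        assert got.size == 1
        assert abs(got[0] - apex) <= 1


class TestDetectRPeaks:
    def test_clean_ten_beats_at_60_bpm(self, config):
        sig, truth = generate_ecg(fs=500.0, n_beats=10, rr_mean=1.0, seed=5)
        r_truth = [a.index for a in truth if a.label == "R"]
        anns = detect_r_peaks(sig, config)
        assert len(anns) == 10
        for ann, ref in zip(anns, r_truth):
            assert abs(ann.index - ref) <= 5  # 10 ms at 500 Hz
            assert ann.label == "R"

    def test_inverted_signal_yields_nothing(self, config):
        sig, _ = generate_ecg(fs=500.0, n_beats=5, rr_mean=0.8, seed=5)
        flipped = sig.replace_samples(-sig.samples)
        assert detect_r_peaks(flipped, config) == []

    def test_robust_to_small_25hz_interference(self, config):
        sig, _ = generate_ecg(fs=500.0, n_beats=10, rr_mean=0.8, seed=9)
        t = sig.times
        noisy = sig.replace_samples(sig.samples + 0.05 * np.sin(2 * np.pi * 25.0 * t))
        base = [a.index for a in detect_r_peaks(sig, config)]
        pert = [a.index for a in detect_r_peaks(noisy, config)]
        assert len(base) == len(pert) == 10
        assert max(abs(b - p) for b, p in zip(base, pert)) <= 1

    def test_refractory_collapses_close_candidates(self):
        # two R-like bumps 50 ms apart must yield a single detection
        fs = 500.0
        t = np.arange(1000) / fs
        y = np.exp(-((t - 1.0) ** 2) / (2 * 0.012**2))
        y += 0.8 * np.exp(-((t - 1.05) ** 2) / (2 * 0.012**2))
        anns = detect_r_peaks(EcgSignal(samples=y, fs=fs), DetectorConfig())
        assert len(anns) == 1
        assert abs(anns[0].index - 500) <= 2  # the taller bump wins

    def test_deterministic(self, clean_record, config):
        sig, _ = clean_record
        a1 = detect_r_peaks(sig, config)
        a2 = detect_r_peaks(sig, config)
        assert a1 == a2 and [x.label for x in a1] == [y.label for y in a2]


class TestIsoelectricLevel:
    def test_zero_signal(self, config):
        level = estimate_isoelectric_level(EcgSignal(samples=np.zeros(500), fs=500.0), config)
        assert level == pytest.approx(0.0, abs=1e-12)

    def test_recovers_synthetic_baseline_level(self, config):
        tpl = dataclasses.replace(default_template(), baseline_level=0.1)
        sig, _ = generate_ecg(template=tpl, fs=500.0, n_beats=10, rr_mean=0.8, seed=13)
        level = estimate_isoelectric_level(sig, config)
        assert level == pytest.approx(0.1, abs=0.02)

    def test_steep_parabola_triggers_median_fallback(self, config):
        d = np.arange(-400, 401).astype(float)
        sig = EcgSignal(samples=0.01 * d**2, fs=500.0)
        with pytest.warns(UserWarning, match="no flat region"):
            level = estimate_isoelectric_level(sig, config)
        assert level == pytest.approx(np.median(sig.samples))


class TestDetectPqrst:
    def _one_beat(self, template=None, seed=21):
        tpl = template or default_template()
        sig, truth = generate_ecg(template=tpl, fs=500.0, n_beats=3, rr_mean=0.8, seed=seed)
        r_truth = [a.index for a in truth if a.label == "R"]
        r = r_truth[1]
        half = 192
        beat = EcgSignal(samples=sig.samples[r - half : r + half + 1], fs=500.0)
        local_truth = {
            a.label: a.index - (r - half)
            for a in truth
            if r - half <= a.index <= r + half
        }
        return beat, half, local_truth

    def test_all_five_waves_within_10ms(self, config):
        beat, r_local, truth = self._one_beat()
        anns = detect_pqrst(beat, r_local, 0.0, config)
        got = {a.label: a.index for a in anns}
        assert set(got) == {"P", "Q", "R", "S", "T"}
        for label, ref in truth.items():
            assert abs(got[label] - ref) <= 5, label

    def test_shallow_q_absent_not_mislabeled(self, config):
        tpl = default_template()
        tpl = dataclasses.replace(tpl, q=dataclasses.replace(tpl.q, amplitude=-0.02))
        beat, r_local, _ = self._one_beat(template=tpl)
        anns = detect_pqrst(beat, r_local, 0.0, config)
        labels = {a.label for a in anns}
        assert "Q" not in labels
        assert {"P", "R", "S", "T"} <= labels

    def test_flat_beat_yields_only_r(self, config):
        beat = EcgSignal(samples=np.zeros(385), fs=500.0)
        anns = detect_pqrst(beat, 192, 0.0, config)
        assert [a.label for a in anns] == ["R"]

    def test_label_ordering_invariant(self, config):
        for seed in range(5):
            beat, r_local, _ = self._one_beat(seed=100 + seed)
            anns = detect_pqrst(beat, r_local, 0.0, config)
            idx = {a.label: a.index for a in anns}
            order = [idx[l] for l in "PQRST" if l in idx]
            assert order == sorted(order)
            assert [a.index for a in anns] == sorted(a.index for a in anns)

    def test_detections_sit_on_local_extrema_of_the_beat(self, config):
        # the error minimum can land one sample off the rendered apex
        beat, r_local, _ = self._one_beat()
        w = pqrst_window_halfwidth(beat.fs)
        for a in detect_pqrst(beat, r_local, 0.0, config):
            lo = max(0, a.index - w)
            hi = min(len(beat), a.index + w + 1)
            seg = beat.samples[lo:hi]
            ext = {lo + int(np.argmax(seg)), lo + int(np.argmin(seg))}
            assert min(abs(a.index - e) for e in ext) <= 1

    def test_r_out_of_beat_rejected(self, config):
        beat = EcgSignal(samples=np.zeros(100), fs=500.0)
        with pytest.raises(ValueError):
            detect_pqrst(beat, 100, 0.0, config)


class TestDetectorConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            DetectorConfig(a_min_r=0.0)
        with pytest.raises(ValueError):
            DetectorConfig(min_peak_distance_ms=300.0, r_refractory_ms=200.0)
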