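"""Synthetic phonocardiogram generator: timing, rhythm, murmurs, noise."""

import numpy as np
import pytest

import heartsound as hs
from heartsound.simulate import NoiseProfile


class TestGenerateRecording:
    def test_regular_rhythm_rr_spacing(self, normal_recording):
        cfg = hs.SimulationConfig(heart_rate_bpm=60.0, duration_s=10.0, seed=1)
        rec = hs.generate_recording(cfg)
        s1 = np.asarray(rec.annotation.s1_times_s)
        assert len(s1) in (9, 10)
        rr = np.diff(s1)
        assert np.allclose(rr, 1.0, atol=1e-9)
        assert rr.std() < 1e-3  # regular rhythm: RR jitter < 1 ms

    def test_annotation_interleaves_and_counts_match(self, normal_recording):
        ann = normal_recording.annotation
        s1, s2 = np.asarray(ann.s1_times_s), np.asarray(ann.s2_times_s)
        assert len(s1) == ann.n_cycles
        assert np.all(s1[: len(s2)] < s2)
        assert np.all(s2[:-1] < s1[1 : len(s2) + 1])

    def test_af_rr_cv_recovered_at_scale(self):
        cfg = hs.SimulationConfig(heart_rate_bpm=70.0, af_mode=True, rr_cv=0.2,
                                  duration_s=220.0, seed=1)
        rec = hs.generate_recording(cfg)
        rr = np.diff([b[0] for b in rec.annotation.cycle_bounds_s])
        assert len(rr) >= 200
        assert rr.std() / rr.mean() == pytest.approx(0.2, abs=0.05)

    def test_extra_sound_timing(self):
        """S3 sits 120-180 ms after S2; S4 sits 70-100 ms before the next S1."""
        for cls, lo, hi, anchor in [(hs.SoundClass.S3, 0.12, 0.18, "s2"),
                                    (hs.SoundClass.S4, -0.10, -0.07, "next_s1")]:
            rec = hs.generate_recording(hs.SimulationConfig(
                sound_class=cls, heart_rate_bpm=60.0, seed=4))
            ann = rec.annotation
            env = np.abs(rec.samples)
            fs = rec.sample_rate_hz
            # search a mid-recording diastole, clear of the S2 tail and of
            # the next S1's rising flank
            s2 = ann.s2_times_s[3]
            nxt = ann.s1_times_s[4]
            if anchor == "s2":
                a, b = int((s2 + 0.08) * fs), int((nxt - 0.15) * fs)
            else:
                a, b = int((s2 + 0.25) * fs), int((nxt - 0.05) * fs)
            t_extra = (a + np.argmax(env[a:b])) / fs
            ref = s2 if anchor == "s2" else nxt
            assert lo - 0.02 <= t_extra - ref <= hi + 0.02

    @pytest.mark.parametrize("cls", [hs.SoundClass.SYSTOLIC_MURMUR,
                                     hs.SoundClass.DIASTOLIC_MURMUR])
    def test_murmur_energy_in_right_phase(self, cls):
        rec = hs.generate_recording(hs.SimulationConfig(
            sound_class=cls, murmur_intensity=0.5, heart_rate_bpm=60.0, seed=7))
        ann = rec.annotation
        fs = rec.sample_rate_hz

        def band_energy(t0, t1):
            seg = rec.samples[int(t0 * fs): int(t1 * fs)]
            return np.mean(seg**2) + 1e-12

        sys_e, dia_e = [], []
        for (s1, s2), (_, end) in zip(
                zip(ann.s1_times_s, ann.s2_times_s), ann.cycle_bounds_s):
            mid_sys = 0.5 * (s1 + s2)
            mid_dia = 0.5 * (s2 + end)
            sys_e.append(band_energy(mid_sys - 0.03, mid_sys + 0.03))
            dia_e.append(band_energy(mid_dia - 0.03, mid_dia + 0.03))
        ratio_db = 10 * np.log10(np.mean(sys_e) / np.mean(dia_e))
        if cls is hs.SoundClass.SYSTOLIC_MURMUR:
            assert ratio_db >= 6.0
        else:
            assert ratio_db <= -6.0

    def test_signal_energy_concentrated_below_150_hz(self):
        for cls in hs.SoundClass:
            rec = hs.generate_recording(hs.SimulationConfig(sound_class=cls, seed=3))
            spec = np.abs(np.fft.rfft(rec.samples)) ** 2
            f = np.fft.rfftfreq(rec.samples.size, 1 / rec.sample_rate_hz)
            frac = spec[f < 150].sum() / spec.sum()
            assert frac >= 0.90, f"{cls}: only {frac:.2f} of energy below 150 Hz"

    def test_deterministic_given_seed(self):
        cfg = hs.SimulationConfig(sound_class=hs.SoundClass.S3, snr_db=15.0, seed=42)
        a, b = hs.generate_recording(cfg), hs.generate_recording(cfg)
        assert np.array_equal(a.samples, b.samples)
        assert a.annotation == b.annotation

    def test_peak_normalization_and_length(self):
        rec = hs.generate_recording(hs.SimulationConfig(duration_s=7.3, seed=2))
        assert rec.samples.size == round(7.3 * rec.sample_rate_hz)
        assert np.max(np.abs(rec.samples)) == pytest.approx(0.9, abs=1e-6)

    @pytest.mark.parametrize("bad", [
        dict(heart_rate_bpm=20.0), dict(heart_rate_bpm=250.0),
        dict(sample_rate_hz=800.0), dict(duration_s=0.0),
        dict(murmur_intensity=-0.1),
        dict(sound_class=hs.SoundClass.S4, af_mode=True),
    ])
    def test_invalid_configs_rejected(self, bad):
        with pytest.raises(hs.ConfigurationError):
            hs.SimulationConfig(**bad)


class TestAddNoise:
    def test_high_snr_is_nearly_identity(self, normal_recording):
        noisy = hs.add_noise(normal_recording, 60.0, seed=1)
        rms = np.sqrt(np.mean(normal_recording.samples**2))
        err = np.sqrt(np.mean((noisy.samples - normal_recording.samples) ** 2))
        assert err / rms < 0.011  # 60 dB SNR: noise RMS ~0.1% of signal power

    def test_requested_snr_achieved(self, normal_recording):
        for snr in (0.0, 6.0, 20.0):
            noisy = hs.add_noise(normal_recording, snr, seed=2)
            scale = noisy.meta["noise_scale"]
            noise = noisy.samples - scale * normal_recording.samples
            got = 10 * np.log10(np.mean((scale * normal_recording.samples) ** 2)
                                / np.mean(noise**2))
            assert got == pytest.approx(snr, abs=0.5)
            assert noisy.annotation == normal_recording.annotation

    def test_pink_noise_spectrum_slope(self):
        """Pink PSD falls ~3 dB/octave across 20-500 Hz."""
        from heartsound.simulate import _make_noise
        rng = np.random.default_rng(0)
        x = _make_noise(rng, 2**19, 4000.0, NoiseProfile(white=0, pink=1))
        f, psd = __import__("scipy.signal", fromlist=["welch"]).welch(
            x, fs=4000.0, nperseg=4096)
        sel = (f >= 20) & (f <= 500)
        slope = np.polyfit(np.log2(f[sel]), 10 * np.log10(psd[sel]), 1)[0]
        assert slope == pytest.approx(-3.0, abs=0.7)

    def test_non_finite_snr_rejected(self, normal_recording):
        with pytest.raises(hs.ConfigurationError):
            hs.add_noise(normal_recording, float("nan"))


class TestGenerateDataset:
    def test_balanced_counts_and_determinism(self):
        recs = hs.generate_dataset(4, seed=9)
        assert len(recs) == 20
        labels = [r.annotation.label for r in recs]
        for cls in hs.SoundClass:
            assert labels.count(cls) == 4
        again = hs.generate_dataset(4, seed=9)
        assert all(np.array_equal(a.samples, b.samples) for a, b in zip(recs, again))

    def test_different_seeds_differ_but_stay_balanced(self):
        a = hs.generate_dataset(2, seed=1)
        b = hs.generate_dataset(2, seed=2)
        assert not np.array_equal(a[0].samples, b[0].samples)
        assert ([r.annotation.label for r in a] == [r.annotation.label for r in b])

    def test_bad_count_rejected(self):
        with pytest.raises(hs.ConfigurationError):
            hs.generate_dataset(0)
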