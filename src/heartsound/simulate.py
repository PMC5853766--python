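"""Synthetic phonocardiogram generator.

Emulates ~10 s chest-wall recordings of the five diagnostic classes
(normal, S3, S4, systolic murmur, diastolic murmur) with ground-truth
S1/S2 timing, so that every downstream stage — denoising, segmentation,
feature extraction, the CNN — can be exercised and scored without any
clinical audio.

Timbre model
------------
S1 and S2 are Gaussian-windowed tone bursts inside the 20–100 Hz band where
heart sounds concentrate (S1: 35 Hz / 110 ms; S2: 60 Hz / 90 ms at 0.8x the
S1 amplitude). S3 and S4 are shorter, fainter low-frequency bursts placed
120–180 ms after S2 and 70–100 ms before S1 respectively. Murmurs are
band-limited (40–100 Hz) Gaussian noise with a diamond (crescendo–
decrescendo) envelope filling systole, or a decrescendo envelope filling
early diastole. Systole occupies a fixed 35% of each RR interval. Atrial
fibrillation draws RR intervals i.i.d. from a gamma distribution with the
configured coefficient of variation; S4 is physiologically incompatible
with AF (no atrial kick) and is rejected.

The waveform is peak-normalized to 0.9 before optional noise addition
(white / pink / 50 Hz mains-hum mix at a requested SNR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import Annotation, PCGRecording, SoundClass
from .errors import ConfigurationError

__all__ = [
    "SimulationConfig",
    "NoiseProfile",
    "ConfigRanges",
    "generate_recording",
    "generate_dataset",
    "add_noise",
]

# burst parameters: (center frequency Hz, duration s, amplitude rel. S1)
_S1_BURST = (35.0, 0.110, 1.0)
_S2_BURST = (60.0, 0.090, 0.8)
_S3_BURST = (28.0, 0.070, 0.15)
_S4_BURST = (30.0, 0.070, 0.15)
_MURMUR_BAND = (40.0, 100.0)
_MURMUR_SCALE = 0.35  # noise std at envelope peak, per unit murmur_intensity
_SYSTOLE_FRACTION = 0.35
_PEAK_NORM = 0.9


@dataclass(frozen=True)
class NoiseProfile:
    """Mix weights of the additive-noise components (need not sum to 1)."""

    white: float = 1.0
    pink: float = 0.0
    hum: float = 0.0  # 50 Hz mains + first harmonic

    def __post_init__(self) -> None:
        if min(self.white, self.pink, self.hum) < 0 or self.white + self.pink + self.hum <= 0:
            raise ConfigurationError("noise_profile weights must be >= 0 with a positive sum")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic recording."""

    sound_class: SoundClass = SoundClass.NORMAL
    heart_rate_bpm: float = 70.0
    duration_s: float = 10.0
    sample_rate_hz: float = 4000.0
    af_mode: bool = False
    rr_cv: float = 0.2
    murmur_intensity: float = 0.5
    snr_db: float | None = None  # None -> no added noise
    noise_profile: NoiseProfile = field(default_factory=NoiseProfile)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 30 <= self.heart_rate_bpm <= 200:
            raise ConfigurationError("heart_rate_bpm must lie in [30, 200]")
        if self.sample_rate_hz < 2000:
            raise ConfigurationError("sample_rate_hz must be >= 2000")
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        if self.murmur_intensity < 0:
            raise ConfigurationError("murmur_intensity must be >= 0")
        if self.af_mode and self.sound_class is SoundClass.S4:
            raise ConfigurationError("af_mode excludes sound_class S4 (AF abolishes the atrial kick)")
        if self.af_mode and not 0 < self.rr_cv < 1:
            raise ConfigurationError("rr_cv must lie in (0, 1) when af_mode is set")
        if self.snr_db is not None and not np.isfinite(self.snr_db):
            raise ConfigurationError("snr_db must be finite")


def _tone_burst(t: np.ndarray, center_s: float, freq_hz: float, dur_s: float,
                amp: float, phase: float) -> np.ndarray:
    """Gaussian-windowed sinusoid centered at ``center_s`` (sigma = dur/6)."""
    sigma = dur_s / 6.0
    env = np.exp(-0.5 * ((t - center_s) / sigma) ** 2)
    # negligible outside +-3 sigma; envelope peak = amp at the center
    return amp * env * np.sin(2 * np.pi * freq_hz * (t - center_s) + phase)


def _murmur_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to the murmur band."""
    raw = rng.standard_normal(n + 1024)
    sos = sps.butter(4, _MURMUR_BAND, btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfilt(sos, raw)[1024:]
    sd = filt.std()
    return filt / sd if sd > 0 else filt


def _draw_rr_intervals(rng: np.random.Generator, cfg: SimulationConfig) -> np.ndarray:
    mean_rr = 60.0 / cfg.heart_rate_bpm
    n_max = int(np.ceil(cfg.duration_s / mean_rr * 3)) + 4
    if cfg.af_mode:
        shape = 1.0 / cfg.rr_cv**2
        rr = rng.gamma(shape, mean_rr / shape, size=n_max)
        rr = np.clip(rr, 0.25, 2.5)  # physiologic guard rails
    else:
        rr = np.full(n_max, mean_rr)
    return rr


def generate_recording(config: SimulationConfig) -> PCGRecording:
    """Synthesize one annotated phonocardiogram.

    Deterministic given ``config`` (including its seed). The returned
    recording is peak-normalized to 0.9 and carries a complete
    :class:`~heartsound.core.Annotation`; noise is added afterwards when
    ``config.snr_db`` is set.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sample_rate_hz
    n = int(round(cfg.duration_s * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)

    rr = _draw_rr_intervals(rng, cfg)
    # per-recording extra-sound offsets, drawn once from physiologic windows
    s3_delay = rng.uniform(0.12, 0.18)
    s4_lead = rng.uniform(0.07, 0.10)

    s1_times: list[float] = []
    s2_times: list[float] = []
    bounds: list[tuple[float, float]] = []
    murmur_env = np.zeros(n)

    start = 0.1  # lead-in silence
    for rr_i in rr:
        end = start + rr_i
        s1_c = start
        s2_c = start + _SYSTOLE_FRACTION * rr_i
        # require the whole cycle (plus the S1 burst tail) to fit
        if end + _S1_BURST[1] / 2 > cfg.duration_s:
            break
        s1_times.append(s1_c)
        s2_times.append(s2_c)
        bounds.append((s1_c, end))

        x += _tone_burst(t, s1_c, *_S1_BURST, phase=rng.uniform(0, 2 * np.pi))
        x += _tone_burst(t, s2_c, *_S2_BURST, phase=rng.uniform(0, 2 * np.pi))

        if cfg.sound_class is SoundClass.S3:
            x += _tone_burst(t, s2_c + s3_delay, *_S3_BURST, phase=rng.uniform(0, 2 * np.pi))
        elif cfg.sound_class is SoundClass.S4:
            x += _tone_burst(t, end - s4_lead, *_S4_BURST, phase=rng.uniform(0, 2 * np.pi))
        elif cfg.sound_class is SoundClass.SYSTOLIC_MURMUR:
            # diamond envelope between the S1 tail and the S2 onset
            a = s1_c + _S1_BURST[1] / 2
            b = s2_c - _S2_BURST[1] / 2
            if b > a:
                seg = (t >= a) & (t <= b)
                mid = 0.5 * (a + b)
                murmur_env[seg] = 1.0 - np.abs(t[seg] - mid) / ((b - a) / 2)
        elif cfg.sound_class is SoundClass.DIASTOLIC_MURMUR:
            # decrescendo from just after S2 across early diastole
            a = s2_c + _S2_BURST[1] / 2
            b = s2_c + 0.7 * (end - s2_c)
            if b > a:
                seg = (t >= a) & (t <= b)
                murmur_env[seg] = 1.0 - (t[seg] - a) / (b - a)
        start = end

    if cfg.sound_class in (SoundClass.SYSTOLIC_MURMUR, SoundClass.DIASTOLIC_MURMUR):
        x += cfg.murmur_intensity * _MURMUR_SCALE * murmur_env * _murmur_noise(rng, n, fs)

    peak = np.max(np.abs(x)) if n else 0.0
    if peak > 0:
        x *= _PEAK_NORM / peak

    ann = Annotation(
        s1_times_s=tuple(s1_times),
        s2_times_s=tuple(s2_times),
        cycle_bounds_s=tuple(bounds),
        label=cfg.sound_class,
    )
    rec = PCGRecording(
        samples=x,
        sample_rate_hz=fs,
        annotation=ann,
        source_id=f"synth-{cfg.sound_class.value}-seed{cfg.seed}",
        meta={"config": cfg},
    )
    if cfg.snr_db is not None:
        rec = add_noise(rec, cfg.snr_db, cfg.noise_profile, seed=rng.integers(2**31))
    return rec


def _make_noise(rng: np.random.Generator, n: int, fs: float, profile: NoiseProfile) -> np.ndarray:
    total = profile.white + profile.pink + profile.hum
    parts = np.zeros(n)
    if profile.white > 0:
        parts += (profile.white / total) * rng.standard_normal(n)
    if profile.pink > 0:
        # shape a white spectrum by 1/sqrt(f): -3 dB per octave in PSD
        w = rng.standard_normal(n)
        spec = np.fft.rfft(w)
        f = np.fft.rfftfreq(n, 1 / fs)
        scale = np.ones_like(f)
        scale[1:] = 1.0 / np.sqrt(f[1:])
        pink = np.fft.irfft(spec * scale, n)
        sd = pink.std()
        if sd > 0:
            pink /= sd
        parts += (profile.pink / total) * pink
    if profile.hum > 0:
        t = np.arange(n) / fs
        hum = np.sin(2 * np.pi * 50.0 * t + rng.uniform(0, 2 * np.pi))
        hum += 0.3 * np.sin(2 * np.pi * 100.0 * t + rng.uniform(0, 2 * np.pi))
        parts += (profile.hum / total) * hum / hum.std()
    return parts


def add_noise(rec: PCGRecording, snr_db: float, noise_profile: NoiseProfile | None = None,
              seed: int = 0) -> PCGRecording:
    """Add environmental noise at a requested global SNR (dB, re the input).

    The annotation is unchanged. If the noisy waveform would exceed full
    scale it is rescaled (which leaves the SNR untouched).
    """
    if rec.samples.size == 0:
        raise ConfigurationError("recording is empty")
    if not np.isfinite(snr_db):
        raise ConfigurationError("snr_db must be finite")
    profile = noise_profile or NoiseProfile()
    rng = np.random.default_rng(seed)
    noise = _make_noise(rng, rec.samples.size, rec.sample_rate_hz, profile)
    p_sig = np.mean(rec.samples**2)
    p_noise = np.mean(noise**2)
    if p_noise > 0 and p_sig > 0:
        noise *= np.sqrt(p_sig / p_noise) * 10 ** (-snr_db / 20)
    noisy = rec.samples + noise
    peak = np.max(np.abs(noisy))
    scale = 1.0 / peak if peak > 1.0 else 1.0
    # rescaling leaves the signal-to-noise power ratio untouched; the scale
    # is recorded so callers can align a clean reference exactly
    return rec.with_samples(noisy * scale, snr_db=snr_db, noise_scale=scale)


@dataclass(frozen=True)
class ConfigRanges:
    """Sampling ranges for :func:`generate_dataset` (uniform draws)."""

    heart_rate_bpm: tuple[float, float] = (50.0, 110.0)
    murmur_intensity: tuple[float, float] = (0.3, 0.6)
    snr_db: tuple[float, float] | None = (10.0, 30.0)
    duration_s: float = 10.0
    sample_rate_hz: float = 4000.0
    af_fraction: float = 0.0
    rr_cv: float = 0.2
    noise_profile: NoiseProfile = field(default_factory=NoiseProfile)

    def __post_init__(self) -> None:
        for name in ("heart_rate_bpm", "murmur_intensity"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ConfigurationError(f"{name} range must satisfy low <= high")
        if self.snr_db is not None and not self.snr_db[0] <= self.snr_db[1]:
            raise ConfigurationError("snr_db range must satisfy low <= high")
        if not 0 <= self.af_fraction <= 1:
            raise ConfigurationError("af_fraction must lie in [0, 1]")


def generate_dataset(per_class_count: int, config_ranges: ConfigRanges | None = None,
                     seed: int = 0) -> list[PCGRecording]:
    """Generate a class-balanced labeled collection of recordings.

    Heart rates, murmur intensities and SNRs are drawn uniformly from
    ``config_ranges``; the result is reproducible given ``seed`` and ordered
    class-by-class.
    """
    if per_class_count < 1:
        raise ConfigurationError("per_class_count must be >= 1")
    ranges = config_ranges or ConfigRanges()
    rng = np.random.default_rng(seed)
    recordings: list[PCGRecording] = []
    for cls in SoundClass:
        for _ in range(per_class_count):
            af = bool(cls is not SoundClass.S4 and rng.random() < ranges.af_fraction)
            cfg = SimulationConfig(
                sound_class=cls,
                heart_rate_bpm=float(rng.uniform(*ranges.heart_rate_bpm)),
                duration_s=ranges.duration_s,
                sample_rate_hz=ranges.sample_rate_hz,
                af_mode=af,
                rr_cv=ranges.rr_cv,
                murmur_intensity=float(rng.uniform(*ranges.murmur_intensity)),
                snr_db=float(rng.uniform(*ranges.snr_db)) if ranges.snr_db else None,
                noise_profile=ranges.noise_profile,
                seed=int(rng.integers(2**31)),
            )
            recordings.append(generate_recording(cfg))
    return recordings
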