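"""Per-cycle 40x40 spectrogram features for the CNN.

Each cardiac cycle (S1 onset to the next S1 onset) is resampled to a
canonical 800 ms at a 1 kHz working rate, short-time-Fourier-transformed
(64 ms Hann window, 75% overlap, zero-padded FFT), log-compressed with
log(1 + |X|), cropped to 10–200 Hz (the 20–100 Hz heart-sound band with
margin), bilinearly resized to exactly 40 (time) x 40 (frequency), and
min–max normalized per matrix. The cycle waveform is peak-normalized
before the STFT, so features are invariant to recording gain — important
when recordings come from phones with different microphone gains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.interpolate import RegularGridInterpolator
from sklearn.base import BaseEstimator

from .core import PCGRecording
from .errors import FeatureExtractionError
from .segmentation import CycleSegmentation

__all__ = ["SpectrogramConfig", "SpectrogramFeature", "CycleSpectrogramExtractor",
           "extract_cycle_spectrogram", "featurize_recording"]

logger = logging.getLogger(__name__)

N_BINS = 40


@dataclass(frozen=True)
class SpectrogramConfig:
    canonical_cycle_s: float = 0.8
    working_rate_hz: float = 1000.0
    window_s: float = 0.064
    overlap: float = 0.75
    nfft: int = 256
    freq_range_hz: tuple[float, float] = (10.0, 200.0)
    min_cycle_s: float = 0.2


@dataclass(frozen=True)
class SpectrogramFeature:
    """One normalized 40x40 time-frequency matrix for one cardiac cycle."""

    matrix: np.ndarray  # shape (40 time, 40 frequency), values in [0, 1]
    cycle_index: int
    time_span_s: tuple[float, float]
    freq_range_hz: tuple[float, float]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.shape != (N_BINS, N_BINS):
            raise FeatureExtractionError(f"feature matrix must be 40x40, got {m.shape}")
        if not np.all(np.isfinite(m)) or m.min() < 0 or m.max() > 1:
            raise FeatureExtractionError("feature values must be finite and in [0, 1]")


def _bilinear_resize(a: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Resize a 2-D array with bilinear interpolation to an exact shape."""
    src_r = np.arange(a.shape[0], dtype=float)
    src_c = np.arange(a.shape[1], dtype=float)
    interp = RegularGridInterpolator((src_r, src_c), a, method="linear",
                                     bounds_error=False, fill_value=None)
    rr = np.linspace(0, a.shape[0] - 1, shape[0])
    cc = np.linspace(0, a.shape[1] - 1, shape[1])
    grid = np.stack(np.meshgrid(rr, cc, indexing="ij"), axis=-1)
    return interp(grid)


class CycleSpectrogramExtractor(BaseEstimator):
    """Transformer from (recording, segmentation) to SpectrogramFeature lists."""

    def __init__(self, canonical_cycle_s: float = 0.8, working_rate_hz: float = 1000.0,
                 window_s: float = 0.064, overlap: float = 0.75, nfft: int = 256,
                 freq_low_hz: float = 10.0, freq_high_hz: float = 200.0,
                 min_cycle_s: float = 0.2):
        self.canonical_cycle_s = canonical_cycle_s
        self.working_rate_hz = working_rate_hz
        self.window_s = window_s
        self.overlap = overlap
        self.nfft = nfft
        self.freq_low_hz = freq_low_hz
        self.freq_high_hz = freq_high_hz
        self.min_cycle_s = min_cycle_s

    def fit(self, X=None, y=None):
        return self

    def extract_cycle(self, rec: PCGRecording, cycle: tuple[float, float],
                      cycle_index: int = 0) -> SpectrogramFeature:
        start, end = float(cycle[0]), float(cycle[-1])
        if end - start < self.min_cycle_s:
            raise FeatureExtractionError(
                f"cycle [{start:.3f}, {end:.3f}] s shorter than {self.min_cycle_s} s"
            )
        if start < 0 or end > rec.duration_s + 1e-9:
            raise FeatureExtractionError(
                f"cycle [{start:.3f}, {end:.3f}] s outside the recording "
                f"(0-{rec.duration_s:.3f} s)"
            )
        fs = rec.sample_rate_hz
        i0, i1 = int(round(start * fs)), int(round(end * fs))
        x = rec.samples[i0:i1]
        if x.size < 2:
            raise FeatureExtractionError("degenerate cycle: too few samples")
        peak = np.max(np.abs(x))
        if peak > 0:  # gain invariance
            x = x / peak
        n_target = int(round(self.canonical_cycle_s * self.working_rate_hz))
        x = sps.resample(x, n_target)

        nperseg = int(round(self.window_s * self.working_rate_hz))
        hop = max(1, int(round(nperseg * (1 - self.overlap))))
        win = sps.windows.hann(nperseg, sym=False)
        stft = sps.ShortTimeFFT(win, hop=hop, fs=self.working_rate_hz, mfft=self.nfft)
        S = stft.stft(x)
        mag = np.log1p(np.abs(S))
        freqs = stft.f
        keep = (freqs >= self.freq_low_hz) & (freqs <= self.freq_high_hz)
        mag = mag[keep, :]  # (freq, time)
        m = _bilinear_resize(mag.T, (N_BINS, N_BINS))  # -> (time, freq)
        rng_ = m.max() - m.min()
        m = (m - m.min()) / rng_ if rng_ > 0 else np.zeros_like(m)
        return SpectrogramFeature(
            matrix=np.clip(m, 0.0, 1.0),
            cycle_index=cycle_index,
            time_span_s=(start, end),
            freq_range_hz=(self.freq_low_hz, self.freq_high_hz),
        )

    def transform_one(self, rec: PCGRecording,
                      seg: CycleSegmentation) -> list[SpectrogramFeature]:
        if seg.n_cycles == 0:
            raise FeatureExtractionError("segmentation contains no complete cycle")
        feats: list[SpectrogramFeature] = []
        for i, (s1, _s2, nxt) in enumerate(seg.cycles):
            try:
                feats.append(self.extract_cycle(rec, (s1, nxt), cycle_index=i))
            except FeatureExtractionError as exc:
                logger.warning("skipping cycle %d of %s: %s", i, rec.source_id or "?", exc)
        if not feats:
            raise FeatureExtractionError("every cycle failed feature extraction")
        return feats

    def transform(self, X):
        return [self.transform_one(rec, seg) for rec, seg in X]


def extract_cycle_spectrogram(rec: PCGRecording, cycle: tuple[float, float],
                              config: SpectrogramConfig | None = None,
                              cycle_index: int = 0) -> SpectrogramFeature:
    """Extract one cycle's 40x40 feature (wrapper over the transformer)."""
    c = config or SpectrogramConfig()
    ext = CycleSpectrogramExtractor(c.canonical_cycle_s, c.working_rate_hz, c.window_s,
                                    c.overlap, c.nfft, c.freq_range_hz[0],
                                    c.freq_range_hz[1], c.min_cycle_s)
    return ext.extract_cycle(rec, cycle, cycle_index=cycle_index)


def featurize_recording(rec: PCGRecording, seg: CycleSegmentation,
                        config: SpectrogramConfig | None = None) -> list[SpectrogramFeature]:
    """One 40x40 feature per complete cycle; failed cycles are skipped."""
    c = config or SpectrogramConfig()
    ext = CycleSpectrogramExtractor(c.canonical_cycle_s, c.working_rate_hz, c.window_s,
                                    c.overlap, c.nfft, c.freq_range_hz[0],
                                    c.freq_range_hz[1], c.min_cycle_s)
    return ext.transform_one(rec, seg)
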