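"""Denoising front end: band-pass filtering and spectral subtraction.

Heart sounds concentrate in 20–100 Hz while lung sounds live far higher
(100–2500 Hz), so a simple zero-phase Butterworth band-pass removes most
respiratory and high-frequency interference without disturbing S1/S2
timing. Residual broadband noise is reduced by classical magnitude
spectral subtraction: the noise magnitude spectrum is estimated from the
lowest-energy analysis frames (heart sounds are temporally sparse, so the
quietest frames of an auscultation are a good noise sample), subtracted
from every short-time FFT frame, and the signal resynthesized by
overlap-add with the original phase.

An advisory interpretability gate mirrors the two dominant failure modes
of phone auscultation — too-small amplitude and too-much background
noise — as threshold checks on peak amplitude and an envelope-based SNR
estimate.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator

from .core import PCGRecording
from .errors import ConfigurationError

__all__ = [
    "FilterSpec",
    "DenoiseParams",
    "FailureReason",
    "InterpretabilityReport",
    "BandpassFilter",
    "SpectralSubtractor",
    "bandpass",
    "spectral_subtract",
    "assess_interpretability",
    "estimate_snr_db",
]


@dataclass(frozen=True)
class FilterSpec:
    low_cut_hz: float = 20.0
    high_cut_hz: float = 100.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, sample_rate_hz: float) -> None:
        if not 0 < self.low_cut_hz < self.high_cut_hz:
            raise ConfigurationError("low_cut_hz must satisfy 0 < low_cut_hz < high_cut_hz")
        if self.high_cut_hz >= sample_rate_hz / 2:
            raise ConfigurationError(
                f"high_cut_hz={self.high_cut_hz} must be below the Nyquist "
                f"frequency {sample_rate_hz / 2}"
            )
        if self.order < 1:
            raise ConfigurationError("order must be >= 1")


class BandpassFilter(BaseEstimator):
    """Zero-phase Butterworth band-pass over the heart-sound band.

    Stateless transformer: ``transform`` maps recordings to filtered
    recordings of identical length, rate and annotation.
    """

    def __init__(self, low_cut_hz: float = 20.0, high_cut_hz: float = 100.0,
                 order: int = 4, zero_phase: bool = True):
        self.low_cut_hz = low_cut_hz
        self.high_cut_hz = high_cut_hz
        self.order = order
        self.zero_phase = zero_phase

    def _spec(self) -> FilterSpec:
        return FilterSpec(self.low_cut_hz, self.high_cut_hz, self.order, self.zero_phase)

    def fit(self, X=None, y=None):  # stateless; sklearn API compliance
        return self

    def transform_one(self, rec: PCGRecording) -> PCGRecording:
        spec = self._spec()
        spec.validate(rec.sample_rate_hz)
        sos = sps.butter(spec.order, [spec.low_cut_hz, spec.high_cut_hz],
                         btype="bandpass", fs=rec.sample_rate_hz, output="sos")
        if spec.zero_phase:
            y = sps.sosfiltfilt(sos, rec.samples)
        else:
            y = sps.sosfilt(sos, rec.samples)
        peak = np.max(np.abs(y)) if y.size else 0.0
        if peak > 1.0:  # filter overshoot guard; rescaling keeps relative shape
            y = y / peak
        return rec.with_samples(y, bandpass=(spec.low_cut_hz, spec.high_cut_hz))

    def transform(self, X):
        return [self.transform_one(rec) for rec in X]


@dataclass(frozen=True)
class DenoiseParams:
    """Spectral-subtraction settings (conventional defaults).

    ``frame_s`` is the analysis frame length in seconds (Hann window,
    50% hop); the noise spectrum is the mean magnitude of the
    ``noise_percentile`` lowest-energy frames; each bin keeps at least
    ``spectral_floor`` of its original magnitude.
    """

    frame_s: float = 0.256
    hop_fraction: float = 0.5
    noise_percentile: float = 0.25
    over_subtraction: float = 1.0
    spectral_floor: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.hop_fraction <= 1:
            raise ConfigurationError("hop_fraction must lie in (0, 1]")
        if not 0 < self.noise_percentile <= 0.5:
            raise ConfigurationError("noise_percentile must lie in (0, 0.5]")
        if not 0 <= self.spectral_floor <= 0.5:
            raise ConfigurationError("spectral_floor must lie in [0, 0.5]")
        if self.frame_s <= 0 or self.over_subtraction < 0:
            raise ConfigurationError("frame_s must be > 0 and over_subtraction >= 0")


class SpectralSubtractor(BaseEstimator):
    """FFT-domain noise subtraction with overlap-add resynthesis."""

    def __init__(self, frame_s: float = 0.256, hop_fraction: float = 0.5,
                 noise_percentile: float = 0.25, over_subtraction: float = 1.0,
                 spectral_floor: float = 0.05):
        self.frame_s = frame_s
        self.hop_fraction = hop_fraction
        self.noise_percentile = noise_percentile
        self.over_subtraction = over_subtraction
        self.spectral_floor = spectral_floor

    def _params(self) -> DenoiseParams:
        return DenoiseParams(self.frame_s, self.hop_fraction, self.noise_percentile,
                             self.over_subtraction, self.spectral_floor)

    def fit(self, X=None, y=None):
        return self

    def transform_one(self, rec: PCGRecording) -> PCGRecording:
        p = self._params()
        fs = rec.sample_rate_hz
        nperseg = int(round(p.frame_s * fs))
        if rec.samples.size < nperseg:
            raise ConfigurationError(
                f"recording ({rec.samples.size} samples) shorter than one "
                f"analysis frame ({nperseg} samples)"
            )
        hop = max(1, int(round(nperseg * p.hop_fraction)))
        win = sps.windows.hann(nperseg, sym=False)
        stft = sps.ShortTimeFFT(win, hop=hop, fs=fs)
        X = stft.stft(rec.samples)
        mag = np.abs(X)
        # noise template: mean magnitude of the quietest frames
        frame_energy = np.sum(mag**2, axis=0)
        k = max(1, int(np.ceil(p.noise_percentile * mag.shape[1])))
        quiet = np.argsort(frame_energy)[:k]
        noise_mag = mag[:, quiet].mean(axis=1, keepdims=True)
        cleaned = np.maximum(mag - p.over_subtraction * noise_mag,
                             p.spectral_floor * mag)
        phase = np.exp(1j * np.angle(X))
        y = stft.istft(cleaned * phase, k1=rec.samples.size)
        y = np.asarray(y)[: rec.samples.size]
        if y.size < rec.samples.size:  # pragma: no cover - defensive pad
            y = np.pad(y, (0, rec.samples.size - y.size))
        peak = np.max(np.abs(y)) if y.size else 0.0
        if peak > 1.0:
            y = y / peak
        return rec.with_samples(y, denoised=True)

    def transform(self, X):
        return [self.transform_one(rec) for rec in X]


def bandpass(rec: PCGRecording, spec: FilterSpec | None = None) -> PCGRecording:
    """Band-pass one recording (thin wrapper over :class:`BandpassFilter`)."""
    spec = spec or FilterSpec()
    return BandpassFilter(spec.low_cut_hz, spec.high_cut_hz, spec.order,
                          spec.zero_phase).transform_one(rec)


def spectral_subtract(rec: PCGRecording, params: DenoiseParams | None = None) -> PCGRecording:
    """Denoise one recording (thin wrapper over :class:`SpectralSubtractor`)."""
    p = params or DenoiseParams()
    return SpectralSubtractor(p.frame_s, p.hop_fraction, p.noise_percentile,
                              p.over_subtraction, p.spectral_floor).transform_one(rec)


class FailureReason(str, enum.Enum):
    LOW_AMPLITUDE = "low_amplitude"
    HIGH_NOISE = "high_noise"


@dataclass(frozen=True)
class InterpretabilityReport:
    interpretable: bool
    estimated_snr_db: float
    peak_amplitude: float
    reasons: tuple[FailureReason, ...]

    def to_dict(self) -> dict:
        return {
            "interpretable": self.interpretable,
            "estimated_snr_db": round(float(self.estimated_snr_db), 2),
            "peak_amplitude": round(float(self.peak_amplitude), 6),
            "reasons": [r.value for r in self.reasons],
        }


def estimate_snr_db(rec: PCGRecording, smooth_s: float = 0.05) -> float:
    """Blind SNR estimate: envelope-peak power over envelope-trough power.

    Heart sounds are impulsive, so the upper envelope percentiles track
    S1/S2 bursts and the lower percentiles track the noise floor between
    them; their power ratio approximates the SNR without a clean reference.
    """
    x = rec.samples
    if x.size == 0:
        return -np.inf
    win = max(1, int(round(smooth_s * rec.sample_rate_hz)))
    power = np.convolve(x**2, np.ones(win) / win, mode="same")
    hi = np.percentile(power, 98)
    lo = np.percentile(power, 20)
    if hi <= 0:
        return -np.inf
    lo = max(lo, 1e-12 * hi)
    return float(10 * np.log10(hi / lo))


def assess_interpretability(rec: PCGRecording, min_snr_db: float = 5.0,
                            min_peak: float = 0.01) -> InterpretabilityReport:
    """Flag recordings too faint or too noisy to interpret (advisory)."""
    if rec.samples.size == 0:
        raise ConfigurationError("recording is empty")
    peak = float(np.max(np.abs(rec.samples)))
    snr = estimate_snr_db(rec)
    reasons: list[FailureReason] = []
    if peak < min_peak:
        reasons.append(FailureReason.LOW_AMPLITUDE)
    if snr < min_snr_db:
        reasons.append(FailureReason.HIGH_NOISE)
    return InterpretabilityReport(
        interpretable=not reasons,
        estimated_snr_db=snr,
        peak_amplitude=peak,
        reasons=tuple(reasons),
    )
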