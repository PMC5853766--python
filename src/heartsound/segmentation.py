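"""ECG-free S1/S2 detection via the Shannon-energy envelogram.

The classic envelogram pipeline: the recording is downsampled to a 1 kHz
working rate and peak-normalized; the average Shannon energy
``E = -(1/N) * sum(x^2 ln x^2)`` is computed over short sliding windows
(20 ms window, 10 ms hop) and standardized to zero mean / unit variance.
Shannon energy accentuates mid-amplitude transients such as S1/S2 against
both the noise floor and sharp spikes. Candidate events are local envelope
maxima above a threshold with a refractory minimum gap, with an optional
lowered-threshold re-scan of suspiciously long gaps.

Labeling candidates as S1 vs S2 uses two complementary strategies and
keeps whichever yields more physiologically plausible cycles:

* *phase clustering* — with the beat period estimated from the envelope
  autocorrelation, event times are clustered by their phase within the
  cycle; the two most populated clusters are the S1 and S2 trains and any
  extra-sound clusters (S3, S4, murmur peaks) are discarded. The cluster
  pair is oriented by the interval rule: the shorter of the two
  alternating intervals is systole, so it runs S1 -> S2.
* *strict alternation* — events are assumed to alternate S1/S2 and the
  phase is chosen so that systole < diastole. This handles irregular
  rhythm (atrial fibrillation), where phase clustering smears out.

Event times mark the center of each detected transient, matching the
simulator's annotation convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator

from .core import PCGRecording
from .errors import ConfigurationError, SegmentationFailure

__all__ = [
    "EnvelopeParams",
    "CycleSegmentation",
    "shannon_energy",
    "shannon_envelope",
    "detect_events",
    "assign_s1_s2",
    "segment",
    "ShannonSegmenter",
]

_WORKING_RATE = 1000.0  # Hz; envelope analysis rate before hopping


@dataclass(frozen=True)
class EnvelopeParams:
    window_ms: float = 20.0
    hop_ms: float = 10.0
    peak_threshold: float = 0.5  # in standardized envelope units
    min_gap_ms: float = 120.0   # refractory spacing < any physiologic systole
    recovery: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.hop_ms <= self.window_ms:
            raise ConfigurationError("hop_ms must satisfy 0 < hop_ms <= window_ms")
        if self.min_gap_ms <= 0:
            raise ConfigurationError("min_gap_ms must be positive")
        if not np.isfinite(self.peak_threshold):
            raise ConfigurationError("peak_threshold must be finite")


@dataclass(frozen=True)
class CycleSegmentation:
    """Detected S1/S2 events partitioning a recording into cardiac cycles.

    ``cycles`` holds (s1, s2, next_s1) onset triples for every plausible
    cycle; ``quality`` is the fraction of candidate S1–S1 intervals that
    produced a plausible cycle (exactly one S2, systole shorter than
    diastole-compatible bounds).
    """

    s1_times_s: tuple[float, ...]
    s2_times_s: tuple[float, ...]
    cycles: tuple[tuple[float, float, float], ...]
    mean_rr_s: float
    quality: float

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)

    def to_dict(self) -> dict:
        return {
            "s1_times_s": list(self.s1_times_s),
            "s2_times_s": list(self.s2_times_s),
            "cycles": [list(c) for c in self.cycles],
            "mean_rr_s": float(self.mean_rr_s),
            "quality": float(self.quality),
        }


def shannon_energy(x: np.ndarray) -> np.ndarray:
    """Per-sample Shannon energy ``-x^2 ln(x^2)`` with ``0 ln 0 := 0``.

    Maximal (= 1/e) at ``|x| = e**-0.5``; zero at 0 and at |x| = 1, which
    is what de-emphasizes both the noise floor and full-scale spikes.
    """
    x2 = np.square(np.asarray(x, dtype=float))
    out = np.zeros_like(x2)
    nz = x2 > 0
    out[nz] = -x2[nz] * np.log(x2[nz])
    return out


def shannon_envelope(rec: PCGRecording, params: EnvelopeParams | None = None,
                     standardize: bool = True) -> tuple[np.ndarray, float]:
    """Windowed average Shannon energy of a peak-normalized recording.

    Returns ``(envelope, envelope_rate_hz)`` with one value per hop. The
    input is downsampled to the 1 kHz working rate and peak-normalized, so
    the envelope is invariant to overall gain. When ``standardize`` the
    envelope is z-scored (an all-zero input stays all-zero).
    """
    p = params or EnvelopeParams()
    if rec.samples.size == 0:
        raise ConfigurationError("recording is empty")
    x = rec.samples
    fs = rec.sample_rate_hz
    if fs != _WORKING_RATE:
        q = fs / _WORKING_RATE
        up, down = 1000, int(round(1000 * q))
        x = sps.resample_poly(x, up, down)
        fs = _WORKING_RATE
    peak = np.max(np.abs(x))
    if peak > 0:
        x = x / peak
    e = shannon_energy(x)
    win = max(1, int(round(p.window_ms * fs / 1000)))
    hop = max(1, int(round(p.hop_ms * fs / 1000)))
    kernel = np.ones(win) / win
    smooth = np.convolve(e, kernel, mode="same")
    env = smooth[::hop].copy()
    if standardize:
        sd = env.std()
        if sd > 0:
            env = (env - env.mean()) / sd
    return env, fs / hop


def detect_events(envelope: np.ndarray, params: EnvelopeParams | None = None,
                  envelope_rate_hz: float | None = None) -> np.ndarray:
    """Candidate heart-sound event times from a standardized envelope.

    Local maxima above ``peak_threshold`` separated by at least
    ``min_gap_ms``; with ``recovery``, gaps longer than 1.5x the median
    inter-event interval are re-scanned at half threshold.
    """
    p = params or EnvelopeParams()
    rate = envelope_rate_hz if envelope_rate_hz is not None else 1000.0 / p.hop_ms
    env = np.asarray(envelope, dtype=float)
    dist = max(1, int(round(p.min_gap_ms * rate / 1000)))
    peaks, _ = sps.find_peaks(env, height=p.peak_threshold, distance=dist)
    if p.recovery and len(peaks) >= 3:
        gaps = np.diff(peaks)
        med = np.median(gaps)
        extra: list[int] = []
        for i, g in enumerate(gaps):
            if g > 1.5 * med:
                lo, hi = peaks[i] + dist, peaks[i + 1] - dist
                if hi > lo:
                    sub, _ = sps.find_peaks(env[lo:hi], height=p.peak_threshold / 2,
                                            distance=dist)
                    extra.extend(sub + lo)
        if extra:
            peaks = np.sort(np.concatenate([peaks, np.array(extra, dtype=int)]))
    return peaks / rate


def _estimate_period(envelope: np.ndarray, rate: float,
                     lo_s: float = 60.0 / 200, hi_s: float = 60.0 / 30) -> float | None:
    """Beat period from the autocorrelation of the positive envelope."""
    e = np.clip(np.asarray(envelope, dtype=float), 0, None)
    if e.size < int(lo_s * rate) * 2:
        return None
    e = e - e.mean()
    ac = np.correlate(e, e, mode="full")[e.size - 1:]
    lo = int(round(lo_s * rate))
    hi = min(int(round(hi_s * rate)), e.size - 1)
    if hi <= lo:
        return None
    lag = lo + int(np.argmax(ac[lo:hi]))
    if ac[lag] <= 0:
        return None
    return lag / rate


def _build_cycles(s1: np.ndarray, s2: np.ndarray) -> tuple[list, float]:
    """Pair S1/S2 trains into plausible cycles; returns (cycles, quality)."""
    cycles: list[tuple[float, float, float]] = []
    n_candidates = max(1, len(s1) - 1)
    for a, b in zip(s1[:-1], s1[1:]):
        between = s2[(s2 > a) & (s2 < b)]
        if len(between) != 1:
            continue
        t2 = float(between[0])
        frac = (t2 - a) / (b - a)
        if 0.15 <= frac <= 0.60:  # systole shorter than diastole, physiologic
            cycles.append((float(a), t2, float(b)))
    quality = len(cycles) / n_candidates
    return cycles, quality


def _phase_cluster_pairs(events: np.ndarray, amplitudes: np.ndarray | None,
                         period: float) -> list[tuple[np.ndarray, np.ndarray]]:
    """Candidate S1/S2 train pairs from phase clustering at the beat period.

    All events sharing a phase within the cycle form one cluster (the S1
    train, the S2 train, and possibly extra-sound trains such as a
    mid-systolic murmur peak). Every pair of sufficiently populated
    clusters is returned as a hypothesis, oriented by the interval rule
    (the shorter alternating interval is systole, so it runs S1 -> S2);
    the caller scores hypotheses by cycle plausibility and amplitude.
    """
    if period <= 0 or len(events) < 4:
        return []
    phases = np.mod(events, period)
    amps = amplitudes if amplitudes is not None else np.ones_like(events)
    clusters: list[dict] = []
    # tight tolerance: regular-rhythm trains jitter by far less, while the
    # closest distinct trains (S2 vs an early-diastolic murmur peak) sit
    # only ~0.1 period apart and must not merge
    tol = 0.07 * period
    for t, ph, a in sorted(zip(events, phases, amps), key=lambda z: -z[2]):
        best = None
        for c in clusters:
            d = abs(ph - c["phase"])
            d = min(d, period - d)
            if d < tol and (best is None or d < best[0]):
                best = (d, c)
        if best is None:
            clusters.append({"phase": ph, "members": [t], "amp": a})
        else:
            c = best[1]
            c["members"].append(t)
            # running circular-ish mean; phases cluster tightly so linear ok
            d = ph - c["phase"]
            if d > period / 2:
                d -= period
            elif d < -period / 2:
                d += period
            c["phase"] = (c["phase"] + d / len(c["members"])) % period
            c["amp"] += a
    clusters.sort(key=lambda c: (-len(c["members"]), -c["amp"]))
    top = [c for c in clusters[:4] if len(c["members"]) >= 2]
    pairs: list[tuple[np.ndarray, np.ndarray]] = []
    for i in range(len(top)):
        for j in range(i + 1, len(top)):
            a_c, b_c = top[i], top[j]
            d_ab = (b_c["phase"] - a_c["phase"]) % period
            if d_ab < period - d_ab:  # A -> B is the short (systolic) interval
                s1_c, s2_c = a_c, b_c
            else:
                s1_c, s2_c = b_c, a_c
            pairs.append((np.sort(s1_c["members"]), np.sort(s2_c["members"])))
    return pairs


def _alternation(events: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Assume strict S1/S2 alternation; phase chosen so systole < diastole."""
    gaps = np.diff(events)
    even = gaps[0::2].mean() if len(gaps[0::2]) else np.inf
    odd = gaps[1::2].mean() if len(gaps[1::2]) else np.inf
    if even <= odd:  # first gap is systole -> first event is S1
        s1, s2 = events[0::2], events[1::2]
    else:
        s1, s2 = events[1::2], events[2::2]
    return s1, s2


def assign_s1_s2(events: np.ndarray, mean_rr_s: float | None = None,
                 amplitudes: np.ndarray | None = None) -> CycleSegmentation:
    """Label candidate events as S1/S2 and build cardiac cycles.

    Tries phase clustering at ``mean_rr_s`` (when known) and strict
    alternation, and keeps whichever explains more plausible cycles.
    """
    events = np.sort(np.asarray(events, dtype=float))
    if len(events) < 4:
        raise SegmentationFailure(
            f"only {len(events)} events detected; at least 4 are needed"
        )
    hypotheses: list[tuple[np.ndarray, np.ndarray]] = []
    period = mean_rr_s
    if period is None and len(events) >= 6:
        # every-other-event spacing approximates RR when events alternate
        period = float(np.median(events[2:] - events[:-2]))
    if period:
        hypotheses.extend(_phase_cluster_pairs(events, amplitudes, period))
    hypotheses.append(_alternation(events))

    amp_of = dict(zip(events, amplitudes)) if amplitudes is not None else {}
    best = None
    for s1, s2 in hypotheses:
        if len(s1) < 2:
            continue
        cycles, quality = _build_cycles(np.asarray(s1), np.asarray(s2))
        # plausible-cycle yield (count weighted by quality) ranks hypotheses;
        # the amplitude sum breaks ties between equally plausible train
        # pairs: S1 and S2 are the strongest periodic trains in the envelope
        amp = sum(amp_of.get(t, 0.0) for t in list(s1) + list(s2))
        score = (round(len(cycles) * quality, 3), amp)
        if best is None or score > best[0]:
            best = (score, cycles, quality, np.asarray(s2))
    if best is None or not best[1]:
        raise SegmentationFailure("no plausible cardiac cycle could be formed")
    _, cycles, quality, s2_train = best
    s1_final = np.array([c[0] for c in cycles] + [cycles[-1][2]])
    s1_final = np.unique(s1_final)
    s2_final = sorted({c[1] for c in cycles})
    # recover the trailing S2 of the final (incomplete) cycle, if detected
    last_s1 = s1_final[-1]
    rr_est = float(np.mean(np.diff(s1_final))) if len(s1_final) > 1 else None
    if rr_est:
        trailing = s2_train[(s2_train > last_s1) & (s2_train < last_s1 + 0.8 * rr_est)]
        if len(trailing):
            s2_final.append(float(trailing[0]))
    s2_final = np.array(s2_final)
    rr = np.diff([c[0] for c in cycles] + [cycles[-1][2]])
    return CycleSegmentation(
        s1_times_s=tuple(s1_final),
        s2_times_s=tuple(s2_final),
        cycles=tuple((a, b, c) for a, b, c in cycles),
        mean_rr_s=float(np.mean(rr)) if len(rr) else float("nan"),
        quality=float(quality),
    )


class ShannonSegmenter(BaseEstimator):
    """End-to-end envelogram segmenter (envelope -> events -> cycles)."""

    def __init__(self, window_ms: float = 20.0, hop_ms: float = 10.0,
                 peak_threshold: float = 0.5, min_gap_ms: float = 120.0,
                 recovery: bool = True):
        self.window_ms = window_ms
        self.hop_ms = hop_ms
        self.peak_threshold = peak_threshold
        self.min_gap_ms = min_gap_ms
        self.recovery = recovery

    def _params(self) -> EnvelopeParams:
        return EnvelopeParams(self.window_ms, self.hop_ms, self.peak_threshold,
                              self.min_gap_ms, self.recovery)

    def fit(self, X=None, y=None):
        return self

    def segment(self, rec: PCGRecording) -> CycleSegmentation:
        p = self._params()
        env, rate = shannon_envelope(rec, p)
        events = detect_events(env, p, envelope_rate_hz=rate)
        if len(events) < 4:
            raise SegmentationFailure(
                f"only {len(events)} envelope peaks found in "
                f"{rec.duration_s:.1f} s of audio"
            )
        idx = np.clip(np.round(events * rate).astype(int), 0, len(env) - 1)
        amplitudes = env[idx]
        period = _estimate_period(env, rate)
        return assign_s1_s2(events, mean_rr_s=period, amplitudes=amplitudes)

    def transform(self, X):
        return [self.segment(rec) for rec in X]


def segment(rec: PCGRecording, params: EnvelopeParams | None = None) -> CycleSegmentation:
    """Segment one recording into cardiac cycles (wrapper over the class)."""
    p = params or EnvelopeParams()
    return ShannonSegmenter(p.window_ms, p.hop_ms, p.peak_threshold,
                            p.min_gap_ms, p.recovery).segment(rec)
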