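"""Core domain objects: sound classes, annotations, recordings.

A :class:`PCGRecording` is the unit every pipeline stage consumes and
produces: a mono waveform in [-1, 1] with its sample rate, an optional
ground-truth :class:`Annotation` (S1/S2 event times and cycle bounds), and a
free-text provenance id.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

__all__ = ["SoundClass", "Annotation", "PCGRecording", "POSITIVE_CLASSES"]


class SoundClass(str, enum.Enum):
    """The five diagnostic categories of a heart-sound recording."""

    NORMAL = "normal"
    S3 = "s3"
    S4 = "s4"
    SYSTOLIC_MURMUR = "systolic_murmur"
    DIASTOLIC_MURMUR = "diastolic_murmur"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: every class other than NORMAL counts as a positive (abnormal) finding
POSITIVE_CLASSES = frozenset(
    {SoundClass.S3, SoundClass.S4, SoundClass.SYSTOLIC_MURMUR, SoundClass.DIASTOLIC_MURMUR}
)


@dataclass(frozen=True)
class Annotation:
    """Ground-truth timing of heart-sound events within one recording.

    Times mark the acoustic *center* of each transient, in seconds from the
    start of the recording. S1 and S2 events strictly interleave; every
    cardiac cycle contains exactly one S1 followed by one S2.
    """

    s1_times_s: tuple[float, ...]
    s2_times_s: tuple[float, ...]
    cycle_bounds_s: tuple[tuple[float, float], ...]
    label: SoundClass

    def __post_init__(self) -> None:
        s1 = np.asarray(self.s1_times_s, dtype=float)
        s2 = np.asarray(self.s2_times_s, dtype=float)
        if np.any(np.diff(s1) <= 0) or np.any(np.diff(s2) <= 0):
            raise ConfigurationError("annotation event times must be strictly increasing")
        if len(s1) not in (len(s2), len(s2) + 1) or len(s1) != len(self.cycle_bounds_s):
            raise ConfigurationError(
                "annotation must hold one S1 per cycle and S1/S2 counts may differ by at most 1"
            )
        merged = np.sort(np.concatenate([s1, s2]))
        interleaved = np.sort(np.ravel(
            np.column_stack([s1[: len(s2)], s2]) if len(s2) else s1
        ))
        if len(s2) and not np.array_equal(merged[: 2 * len(s2)], interleaved):
            raise ConfigurationError("S1 and S2 events must strictly interleave")

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_bounds_s)

    def to_dict(self) -> dict:
        return {
            "s1_times_s": list(self.s1_times_s),
            "s2_times_s": list(self.s2_times_s),
            "cycle_bounds_s": [list(b) for b in self.cycle_bounds_s],
            "label": self.label.value,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Annotation":
        return cls(
            s1_times_s=tuple(float(t) for t in d["s1_times_s"]),
            s2_times_s=tuple(float(t) for t in d["s2_times_s"]),
            cycle_bounds_s=tuple((float(a), float(b)) for a, b in d["cycle_bounds_s"]),
            label=SoundClass(d["label"]),
        )


@dataclass
class PCGRecording:
    """A sampled phonocardiogram waveform.

    ``samples`` is a 1-D float array with values in [-1, 1]; ``annotation``
    carries ground truth when the recording came from the simulator or from
    an annotation sidecar file.
    """

    samples: np.ndarray
    sample_rate_hz: float
    annotation: Annotation | None = None
    source_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if self.sample_rate_hz <= 0:
            raise ConfigurationError("sample_rate_hz must be positive")
        if self.samples.size and np.max(np.abs(self.samples)) > 1.0 + 1e-9:
            raise ConfigurationError("samples must lie in [-1, 1]")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate_hz

    def with_samples(self, samples: np.ndarray, **meta) -> "PCGRecording":
        """Return a copy carrying new samples but the same rate/annotation."""
        out = replace(self, samples=np.asarray(samples, dtype=np.float64))
        out.meta = {**self.meta, **meta}
        return out
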