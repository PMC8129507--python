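"""Shared containers and exceptions.

The atomic objects passed between the synthesis, feature-extraction and
statistics layers: a sampled waveform, a cycle-by-cycle pitch-period track,
and the seven-feature vector of one utterance.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Recording format of the study protocol: mono, 44.1 kHz, 16 bit.
STUDY_SAMPLE_RATE = 44_100


class PadvoiceError(Exception):
    """Base class for all package errors."""


class AudioFormatError(PadvoiceError):
    """Unsupported or malformed audio input (stereo, bad codec, truncated)."""


class ClippingError(PadvoiceError):
    """A rendered sample would exceed full scale [-1, 1]."""


class NoVoicedContentError(PadvoiceError):
    """No analysis frame passed the voicing decision."""


class SilentInputError(PadvoiceError):
    """Every frame fell below the silence floor."""


class ConfigurationError(PadvoiceError):
    """Infeasible analysis configuration (e.g. F0 band vs sample rate)."""


@dataclass(frozen=True)
class VoiceRecording:
    """A mono waveform with its sample rate.

    Samples are float values in [-1, 1]; integer PCM is normalized on read.
    """

    samples: np.ndarray
    sample_rate: float = STUDY_SAMPLE_RATE
    source_id: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", samples)
        if samples.ndim != 1:
            raise AudioFormatError(
                f"expected a mono 1-D sample array, got shape {samples.shape}"
            )
        if self.sample_rate <= 0:
            raise AudioFormatError("sample_rate must be positive")
        if len(samples) < 0.1 * self.sample_rate:
            raise AudioFormatError("recording shorter than 0.1 s")
        if not np.all(np.isfinite(samples)):
            raise AudioFormatError("non-finite samples")
        if np.max(np.abs(samples)) > 1.0 + 1e-12:
            raise AudioFormatError("samples outside [-1, 1]")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass(frozen=True)
class PitchPeriodSequence:
    """Ordered voiced pitch periods T_i (ms) with per-period amplitudes A_k.

    ``onset_times`` (s) give the start of each period within the recording.
    """

    periods_ms: np.ndarray
    amplitudes: np.ndarray
    onset_times: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.periods_ms, dtype=float)
        a = np.asarray(self.amplitudes, dtype=float)
        t = np.asarray(self.onset_times, dtype=float)
        object.__setattr__(self, "periods_ms", p)
        object.__setattr__(self, "amplitudes", a)
        object.__setattr__(self, "onset_times", t)
        if len(p) != len(a) or len(p) != len(t):
            raise ValueError("periods, amplitudes and onsets must align")
        if len(p) and (np.any(p <= 0) or np.any(a <= 0)):
            raise ValueError("periods and amplitudes must be positive")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("onset_times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.periods_ms)


@dataclass(frozen=True)
class AcousticFeatureVector:
    """The seven features of one utterance plus QC fields.

    Perturbation fields are NaN (undefined), never zero, when fewer than two
    pitch periods were found.
    """

    velocity: float  # s per word
    mean_f0: float  # Hz
    f0_sd: float  # Hz
    intensity: float  # dB
    jitter_pct: float  # %
    shimmer_pct: float  # %
    hnr: float  # dB
    n_periods: int
    voiced_fraction: float

    FEATURE_NAMES = (
        "velocity",
        "mean_f0",
        "f0_sd",
        "intensity",
        "jitter_pct",
        "shimmer_pct",
        "hnr",
    )

    def as_dict(self) -> dict[str, float]:
        d = {name: getattr(self, name) for name in self.FEATURE_NAMES}
        d["n_periods"] = self.n_periods
        d["voiced_fraction"] = self.voiced_fraction
        return d


@dataclass(frozen=True)
class AnnotatedUtterance:
    """A synthetic utterance with its ground truth attached.

    ``word_boundaries`` are (start_s, end_s) pairs, non-overlapping and
    increasing; ``true_spec`` is the VoiceSynthesisSpec that generated it.
    """

    recording: VoiceRecording
    word_count: int
    word_boundaries: tuple[tuple[float, float], ...]
    true_spec: "object" = None  # VoiceSynthesisSpec; kept loose to avoid cycle

    def __post_init__(self) -> None:
        if self.word_count != len(self.word_boundaries):
            raise ValueError("word_count must equal number of boundaries")
        prev_end = -math.inf
        for start, end in self.word_boundaries:
            if not (0.0 <= start < end <= self.recording.duration + 1e-9):
                raise ValueError("word boundary outside the recording")
            if start < prev_end:
                raise ValueError("word boundaries overlap")
            prev_end = end


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero, the tabulation convention (0.275 -> 0.28)."""
    if isinstance(x, float) and math.isnan(x):
        return x
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5) / scale, x)
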