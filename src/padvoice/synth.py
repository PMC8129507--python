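"""Seeded synthesis of voiced utterances with controllable perturbation.

The source model is a harmonic pulse train: cosine-phase harmonics with 1/h
amplitude roll-off give one dominant glottal-like peak per cycle.  The seven
generator dials map one-to-one onto the features the extractor estimates:

* mean_f0 / f0_sd   - slow F0 contour (anchor points every 0.3 s, linearly
                      interpolated, anchor SD calibrated so the per-period
                      F0 SD equals f0_sd)
* jitter_target     - iid Gaussian perturbation of each period,
                      sigma = (target/100) * sqrt(pi)/2, so the expected
                      two-point jitter statistic equals the target
* shimmer_target    - same calibration on per-pulse amplitudes
* hnr_target        - additive white Gaussian noise with power =
                      harmonic power / 10^(target/10); +inf disables noise
* intensity_target  - waveform scaled so the extractor's energy-mean dB
                      convention returns the target
* n_words, seconds_per_word, pause_fraction - word/pause timing
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    AnnotatedUtterance,
    ClippingError,
    PitchPeriodSequence,
    STUDY_SAMPLE_RATE,
    VoiceRecording,
)

#: Hard limit on injected perturbation; larger targets can produce
#: non-positive periods or amplitudes.
MAX_PERTURBATION_PCT = 30.0

#: Calibration: E|e_i - e_{i-1}| = 2 sigma / sqrt(pi) for iid N(0, sigma).
SIGMA_PER_UNIT_TARGET = math.sqrt(math.pi) / 2.0

#: F0 contour anchor spacing (s) and the variance-compensation factor for
#: linear interpolation between iid anchors (E[(1-u)^2 + u^2] = 2/3).
F0_ANCHOR_SPACING = 0.3
F0_ANCHOR_SD_FACTOR = math.sqrt(1.5)

#: Harmonic source: first H harmonics with 1/h roll-off, capped by Nyquist.
MAX_HARMONICS = 30

_DETECTOR_BAND = (75.0, 600.0)


@dataclass(frozen=True)
class VoiceSynthesisSpec:
    """Ground-truth parameters of one synthetic utterance."""

    mean_f0: float  # Hz
    f0_sd: float = 0.0  # Hz, slow-contour SD
    jitter_target: float = 0.0  # %, two-point period perturbation
    shimmer_target: float = 0.0  # %, two-point amplitude perturbation
    hnr_target: float = math.inf  # dB; +inf = no noise
    intensity_target: float = 70.0  # dB (70 dB = the fixed input level)
    n_words: int = 9
    seconds_per_word: float = 0.3
    pause_fraction: float = 0.2
    sample_rate: float = STUDY_SAMPLE_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = _DETECTOR_BAND
        if not (lo < self.mean_f0 < hi):
            raise ValueError(
                f"mean_f0 {self.mean_f0} Hz outside the detector band ({lo}, {hi})"
            )
        if self.f0_sd < 0:
            raise ValueError("f0_sd must be >= 0")
        for name in ("jitter_target", "shimmer_target"):
            v = getattr(self, name)
            if not (0 <= v <= MAX_PERTURBATION_PCT):
                raise ValueError(
                    f"{name}={v}% outside [0, {MAX_PERTURBATION_PCT}]%"
                )
        if self.n_words < 1 or self.seconds_per_word <= 0:
            raise ValueError("need n_words >= 1 and seconds_per_word > 0")
        if not (0 <= self.pause_fraction < 1):
            raise ValueError("pause_fraction must be in [0, 1)")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def total_duration(self) -> float:
        return self.n_words * self.seconds_per_word * (1 + self.pause_fraction)


def _f0_contour(
    spec: VoiceSynthesisSpec, duration: float, rng: np.random.Generator
):
    """Piecewise-linear F0 contour sampled at arbitrary times."""
    n_anchor = max(2, int(duration / F0_ANCHOR_SPACING) + 2)
    sd = spec.f0_sd * F0_ANCHOR_SD_FACTOR
    anchors = spec.mean_f0 + np.clip(
        rng.normal(0.0, sd, n_anchor) if sd > 0 else np.zeros(n_anchor),
        -3.0 * sd,
        3.0 * sd,
    )
    times = np.arange(n_anchor) * F0_ANCHOR_SPACING
    return lambda t: float(np.interp(t, times, anchors))


def synthesize_period_sequence(
    spec: VoiceSynthesisSpec,
    rng: np.random.Generator | None = None,
    duration: float | None = None,
    n_periods: int | None = None,
) -> PitchPeriodSequence:
    """Draw the period/amplitude track T_i = (1/f0_i)(1 + e_i), A_k = 1 + n_k.

    ``duration`` defaults to one word (seconds_per_word); alternatively a
    fixed ``n_periods`` can be requested for calibration work.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    if duration is None:
        duration = spec.seconds_per_word
    sigma_j = spec.jitter_target / 100.0 * SIGMA_PER_UNIT_TARGET
    sigma_s = spec.shimmer_target / 100.0 * SIGMA_PER_UNIT_TARGET
    horizon = duration if n_periods is None else 1.5 * n_periods / spec.mean_f0
    contour = _f0_contour(spec, horizon, rng)

    cap = n_periods if n_periods is not None else int(duration * spec.mean_f0 * 2) + 20
    periods = np.empty(cap)
    t = 0.0
    count = 0
    while count < cap:
        f0 = contour(t)
        eps = rng.normal(0.0, sigma_j) if sigma_j > 0 else 0.0
        period = (1.0 / f0) * (1.0 + eps)
        if period <= 0:
            raise ValueError("perturbation produced a non-positive period")
        periods[count] = period
        t += period
        count += 1
        if n_periods is None and t >= duration:
            break
    periods = periods[:count]
    amps = 1.0 + (rng.normal(0.0, sigma_s, count) if sigma_s > 0 else np.zeros(count))
    if np.any(amps <= 0):
        raise ValueError("perturbation produced a non-positive amplitude")
    onsets = np.concatenate([[0.0], np.cumsum(periods)[:-1]])
    return PitchPeriodSequence(periods * 1000.0, amps, onsets)


def _harmonic_count(spec: VoiceSynthesisSpec, max_f0: float) -> int:
    by_nyquist = int(0.45 * spec.sample_rate / max_f0)
    return max(1, min(MAX_HARMONICS, by_nyquist))


def render_waveform(
    periods: PitchPeriodSequence,
    spec: VoiceSynthesisSpec,
    rng: np.random.Generator | None = None,
    intensity_reference: float = 2e-5,
) -> VoiceRecording:
    """Render a period track to a waveform in [-1, 1].

    The harmonic part is a cosine-phase pulse train following the period
    track, with the k-th pulse scaled by A_k (amplitude switches mid-cycle,
    away from the pulse).  White noise is added at the requested
    harmonics-to-noise ratio and the result is scaled to the intensity
    target; a sample that would clip raises ClippingError.
    """
    if len(periods) == 0:
        raise ValueError("empty period sequence")
    rng = rng if rng is not None else np.random.default_rng(spec.seed + 1)
    sr = spec.sample_rate
    t_s = periods.periods_ms / 1000.0
    starts = np.concatenate([[0.0], np.cumsum(t_s)])
    n = int(starts[-1] * sr)
    if n < 2:
        raise ValueError("period sequence too short to render")
    tt = np.arange(n) / sr
    idx = np.clip(np.searchsorted(starts, tt, "right") - 1, 0, len(t_s) - 1)
    phase = idx + (tt - starts[idx]) / t_s[idx]

    h_count = _harmonic_count(spec, 1.0 / t_s.min())
    wave = np.zeros(n)
    two_pi_phase = 2.0 * math.pi * phase
    for h in range(1, h_count + 1):
        wave += (1.0 / h) * np.cos(h * two_pi_phase)
    # pulse k peaks at integer phase k (the start of cycle k, so successive
    # peak spacings equal the periods); its amplitude applies half a cycle
    # to each side, so the switch happens in the quiet part of the waveform
    pulse_idx = np.clip(np.round(phase).astype(int), 0, len(t_s) - 1)
    wave *= periods.amplitudes[pulse_idx]

    harmonic_power = float(np.mean(wave**2))
    if np.isfinite(spec.hnr_target):
        noise_power = harmonic_power / 10.0 ** (spec.hnr_target / 10.0)
        wave = wave + rng.normal(0.0, math.sqrt(noise_power), n)

    target_rms = intensity_reference * 10.0 ** (spec.intensity_target / 20.0)
    wave *= target_rms / math.sqrt(np.mean(wave**2))
    peak = float(np.max(np.abs(wave)))
    if peak > 1.0:
        raise ClippingError(
            f"rendering would clip (peak {peak:.3f} > 1); lower intensity_target"
        )
    return VoiceRecording(wave, sr)


def synthesize_utterance(
    spec: VoiceSynthesisSpec, intensity_reference: float = 2e-5
) -> AnnotatedUtterance:
    """n_words voiced segments separated by silence, with known boundaries.

    Total duration is n_words * seconds_per_word * (1 + pause_fraction) to
    within one sample; the pause after each word is seconds_per_word *
    pause_fraction of silence.
    """
    rng = np.random.default_rng(spec.seed)
    sr = spec.sample_rate
    slot = spec.seconds_per_word * (1.0 + spec.pause_fraction)
    total = int(round(spec.n_words * slot * sr))
    buf = np.zeros(total)
    boundaries = []
    word_samples = int(round(spec.seconds_per_word * sr))
    for w in range(spec.n_words):
        start = int(round(w * slot * sr))
        p = synthesize_period_sequence(spec, rng, duration=spec.seconds_per_word)
        rec = render_waveform(p, spec, rng, intensity_reference)
        seg = rec.samples[:word_samples]
        buf[start : start + len(seg)] = seg
        boundaries.append((start / sr, (start + len(seg)) / sr))
    return AnnotatedUtterance(
        recording=VoiceRecording(buf, sr),
        word_count=spec.n_words,
        word_boundaries=tuple(boundaries),
        true_spec=spec,
    )
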