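"""Extraction of the seven acoustic features from a mono waveform.

The pipeline is: frame-wise normalized autocorrelation for voicing, F0
candidates and harmonicity; adaptive cycle-by-cycle pitch marking inside
voiced regions; then the classical two-point perturbation statistics on the
period/amplitude track:

* jitter%   = mean |T_i - T_{i-1}| / mean T        (cycle-to-cycle F0 perturbation)
* shimmer%  = mean |A_k - A_{k-1}| / mean A        (cycle-to-cycle amplitude perturbation)
* HNR (dB)  = 10 log10( r' / (1 - r') )            (periodic vs noise energy, from the
                                                    normalized autocorrelation peak r')

plus mean F0 and F0 SD over per-period instantaneous F0, an energy-mean
intensity in dB, and speech velocity in seconds per word.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .core import (
    AcousticFeatureVector,
    AnnotatedUtterance,
    ConfigurationError,
    NoVoicedContentError,
    PitchPeriodSequence,
    SilentInputError,
    VoiceRecording,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExtractionConfig:
    """Analysis settings; defaults cover the 75-600 Hz speaking range."""

    f0_min: float = 75.0  # Hz, lower edge of the period search band
    f0_max: float = 600.0  # Hz, upper edge
    voicing_threshold: float = 0.45  # normalized autocorrelation minimum
    frame_length: float | None = None  # s; default 4.5 / f0_min
    hop: float = 0.01  # s
    silence_floor_db: float = -25.0  # dB relative to the loudest frame
    min_pause: float = 0.10  # s; shorter silent gaps count as speech
    intensity_reference: float = 2e-5  # pressure-equivalent dB reference
    hnr_cap_db: float = 60.0  # reporting cap for near-noiseless signals
    octave_cost: float = 0.01  # candidate penalty per octave of lag

    def __post_init__(self) -> None:
        if not (0 < self.f0_min < self.f0_max):
            raise ConfigurationError("need 0 < f0_min < f0_max")
        if not (0 < self.voicing_threshold < 1):
            raise ConfigurationError("voicing_threshold must be in (0, 1)")
        if self.frame_length is None:
            object.__setattr__(self, "frame_length", 4.5 / self.f0_min)

    def lag_band(self, sample_rate: float) -> tuple[int, int]:
        lag_lo = int(sample_rate / self.f0_max)
        lag_hi = int(math.ceil(sample_rate / self.f0_min))
        n = int(self.frame_length * sample_rate)
        if lag_lo < 2 or lag_hi + 2 >= n // 2:
            raise ConfigurationError(
                f"F0 band [{self.f0_min}, {self.f0_max}] Hz infeasible at "
                f"{sample_rate} Hz with {self.frame_length:.3f} s frames"
            )
        return lag_lo, lag_hi


@dataclass(frozen=True)
class FrameTrack:
    """Per-frame analysis: voicing decisions, F0 and harmonicity candidates."""

    times: np.ndarray  # frame start, s
    f0: np.ndarray  # Hz, NaN where unvoiced
    r_prime: np.ndarray  # normalized autocorrelation peak, NaN where unvoiced
    rms: np.ndarray
    voiced: np.ndarray  # bool
    silent: np.ndarray  # bool

    @property
    def voiced_fraction(self) -> float:
        return float(self.voiced.mean()) if len(self.voiced) else 0.0


def _parabolic(ym: np.ndarray, y0: np.ndarray, yp: np.ndarray):
    """Vertex offset and value of the parabola through three equi-spaced points."""
    den = ym - 2.0 * y0 + yp
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(den < 0, 0.5 * (ym - yp) / den, 0.0)
    d = np.clip(d, -0.5, 0.5)
    return d, y0 - 0.25 * (ym - yp) * d


_SINC_TAPS = 24
_SINC_UPSAMPLE = 8
_SINC_BETA = 6.0


def _sinc_kernel() -> tuple[np.ndarray, np.ndarray]:
    from scipy.special import i0

    offsets = np.arange(-_SINC_UPSAMPLE, _SINC_UPSAMPLE + 1) / _SINC_UPSAMPLE
    j = np.arange(-_SINC_TAPS, _SINC_TAPS + 1)
    arg = j[None, :] - offsets[:, None]
    # Kaiser taper evaluated on the (shifted) sinc argument so the window
    # tracks the interpolation point; a fixed window droops by ~1e-3
    window = i0(
        _SINC_BETA * np.sqrt(np.clip(1.0 - (arg / (_SINC_TAPS + 1)) ** 2, 0.0, 1.0))
    ) / i0(_SINC_BETA)
    kernel = np.sinc(arg) * window
    return offsets, kernel


_SINC_OFFSETS, _SINC_KERNEL = _sinc_kernel()


def _refine_peak(
    cc: np.ndarray, e0: np.ndarray, e_lag: np.ndarray, k: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Sub-sample lag and peak value of the normalized correlation.

    The raw correlation is sinc-interpolated around the integer peak on a
    1/8-sample grid (valid because the signal, hence the correlation, is
    band-limited); the energy normalization varies slowly and is linearly
    interpolated.
    """
    n_lags = cc.shape[1]
    taps = np.clip(
        k[:, None] + np.arange(-_SINC_TAPS, _SINC_TAPS + 1)[None, :], 0, n_lags - 1
    )
    rows = np.arange(len(k))[:, None]
    cc_fine = cc[rows, taps] @ _SINC_KERNEL.T  # (frames, offsets)
    tau_fine = k[:, None] + _SINC_OFFSETS[None, :]
    lo = np.clip(np.floor(tau_fine).astype(int), 0, n_lags - 1)
    hi = np.clip(lo + 1, 0, n_lags - 1)
    frac = tau_fine - lo
    e_fine = e_lag[rows, lo] * (1 - frac) + e_lag[rows, hi] * frac
    with np.errstate(divide="ignore", invalid="ignore"):
        rho_fine = cc_fine / np.sqrt(np.maximum(e0[:, None] * e_fine, 1e-300))
    best = np.argmax(rho_fine, axis=1)
    r = rho_fine[np.arange(len(k)), best]
    tau = tau_fine[np.arange(len(k)), best]
    return tau, r


def analyze_frames(rec: VoiceRecording, cfg: ExtractionConfig) -> FrameTrack:
    """Frame-wise normalized cross-correlation analysis.

    Each frame's first half is correlated against the full frame over the
    period lag band; candidate lags are the local correlation maxima, scored
    with a small octave cost so the true period beats its subharmonics on
    clean signals.
    """
    x = rec.samples
    sr = rec.sample_rate
    lag_lo, lag_hi = cfg.lag_band(sr)
    n = int(cfg.frame_length * sr)
    head = n // 2
    step = max(1, int(cfg.hop * sr))
    if len(x) < n + 1:
        raise ConfigurationError("recording shorter than one analysis frame")

    starts = np.arange(0, len(x) - n, step)
    frames = np.lib.stride_tricks.sliding_window_view(x, n)[starts]
    frames = frames - frames.mean(axis=1, keepdims=True)
    rms = np.sqrt((frames**2).mean(axis=1))

    nfft = 1
    while nfft < n + lag_hi + 2:
        nfft *= 2
    heads = frames[:, :head]
    f_full = np.fft.rfft(frames, nfft, axis=1)
    f_head = np.fft.rfft(heads, nfft, axis=1)
    cc = np.fft.irfft(np.conj(f_head) * f_full, nfft, axis=1)[:, : lag_hi + 2]
    e0 = (heads**2).sum(axis=1)
    csum = np.concatenate(
        [np.zeros((len(frames), 1)), np.cumsum(frames**2, axis=1)], axis=1
    )
    lags = np.arange(lag_hi + 2)
    e_lag = csum[:, lags + head] - csum[:, lags]
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = cc / np.sqrt(np.maximum(e0[:, None] * e_lag, 1e-300))

    band = rho[:, lag_lo : lag_hi + 1]
    interior = band[:, 1:-1]
    is_peak = (interior >= band[:, :-2]) & (interior >= band[:, 2:])
    cand_lags = np.arange(lag_lo + 1, lag_hi)
    score = interior - cfg.octave_cost * np.log2(cand_lags / lag_lo)[None, :]
    score = np.where(is_peak, score, -np.inf)
    best = np.argmax(score, axis=1)
    k = cand_lags[best]
    has_peak = np.isfinite(score[np.arange(len(frames)), best])

    rows = np.arange(len(frames))
    # the correlation peak is sharp (band-limited but wideband); refine it on
    # a sinc-interpolated fine grid, which recovers the peak height a 3-point
    # parabola misses
    tau, r_peak = _refine_peak(cc, e0, e_lag, k)
    f0 = sr / tau
    r_peak = np.minimum(r_peak, 1.0 - 1e-6)

    peak_rms = rms.max() if len(rms) else 0.0
    if peak_rms <= 0:
        raise SilentInputError("all-zero input")
    silent = rms < peak_rms * 10 ** (cfg.silence_floor_db / 20.0)
    # frames whose correlation span overlaps a silent stretch (voicing
    # onset/offset) have unreliable normalized correlations: require every
    # hop-sized slice under the span to be above the silence floor
    span_hops = int(np.ceil((head + lag_hi) / step))
    n_hops = len(x) // step
    hop_sq = np.add.reduceat(x[: n_hops * step] ** 2, np.arange(0, n_hops * step, step))
    hop_rms = np.sqrt(hop_sq / step)
    hop_ok = hop_rms >= hop_rms.max() * 10 ** (cfg.silence_floor_db / 20.0)
    cum = np.concatenate([[0], np.cumsum(hop_ok.astype(int))])
    frame_hop = np.minimum(starts // step, n_hops - 1)
    span_end = np.minimum(frame_hop + span_hops, n_hops)
    fully_voiced_span = (cum[span_end] - cum[frame_hop]) == (span_end - frame_hop)
    voiced = has_peak & ~silent & fully_voiced_span & (r_peak >= cfg.voicing_threshold)
    # reject octave-jump outliers: frames straddling a pause can correlate
    # one word's tail with the next word's head at a spurious long lag
    if voiced.sum() >= 5:
        med = float(np.median(f0[voiced]))
        voiced &= (f0 > 0.45 * med) & (f0 < 2.2 * med)
    logger.debug(
        "frames=%d voiced=%d silent=%d", len(frames), voiced.sum(), silent.sum()
    )

    f0 = np.where(voiced, f0, np.nan)
    r_peak = np.where(voiced, r_peak, np.nan)
    return FrameTrack(starts / sr, f0, r_peak, rms, voiced, silent)


def _mark_cycles(
    x: np.ndarray, start: int, stop: int, t0: float, first_search: int | None = None
) -> np.ndarray:
    """Cycle peaks in x[start:stop] by adaptive cross-correlation stepping.

    ``t0`` is the initial period guess in samples.  Each step correlates one
    period around the last mark against the signal over lags 0.7-1.4 times
    the running (median of last three) period estimate, with parabolic
    sub-sample refinement.  Stepping stops when the best correlation drops
    below 0.3 (end of coherent voicing).
    """
    seg_len = stop - start
    if seg_len < 3 * t0:
        return np.empty(0)
    # the voiced region may begin with up to a frame of silence; search wide
    # enough for the first genuine pulse
    if first_search is None:
        first_search = int(3.5 * t0)
    half0 = int(t0 / 2)
    a0 = start + half0
    span = min(seg_len - half0 - 1, first_search + int(2.2 * t0))
    m0 = a0 + int(np.argmax(np.abs(x[a0 : start + span])))
    marks = [float(m0)]
    recent = [t0]
    while True:
        t_loc = float(np.median(recent[-3:]))
        c = int(round(marks[-1]))
        half = int(t_loc / 2)
        lo, hi = int(0.7 * t_loc), int(1.4 * t_loc)
        if c - half < start or c + hi + half >= stop:
            break
        ref = x[c - half : c + half]
        e_ref = float(ref @ ref)
        if e_ref <= 0:
            break
        window = x[c - half + lo : c + half + hi]
        cc = np.correlate(window[:-1], ref, mode="valid")
        csum = np.concatenate([[0.0], np.cumsum(window**2)])
        en = csum[np.arange(len(cc)) + 2 * half] - csum[: len(cc)]
        rr = cc / np.sqrt(e_ref * np.maximum(en, 1e-300))
        k = int(np.argmax(rr))
        if rr[k] < 0.4:
            break
        if 0 < k < len(rr) - 1:
            d, _ = _parabolic(rr[k - 1], rr[k], rr[k + 1])
            d = float(d)
        else:
            d = 0.0
        step = lo + k + d
        marks.append(c + step)
        recent.append(step)
    return np.asarray(marks)


def detect_pitch_periods(
    rec: VoiceRecording, cfg: ExtractionConfig | None = None
) -> PitchPeriodSequence:
    """Cycle-by-cycle pitch periods and per-period amplitudes.

    Voiced regions (runs of voiced frames) are marked independently; the
    per-period amplitude is the RMS over one period centred on each cycle
    peak, which is robust to additive noise.
    """
    cfg = cfg or ExtractionConfig()
    track = analyze_frames(rec, cfg)
    if not track.voiced.any():
        raise NoVoicedContentError("no frame passed the voicing decision")
    return _periods_from_track(rec, cfg, track)


def _periods_from_track(
    rec: VoiceRecording, cfg: ExtractionConfig, track: FrameTrack
) -> PitchPeriodSequence:
    x = rec.samples
    sr = rec.sample_rate
    n = int(cfg.frame_length * sr)
    step = max(1, int(cfg.hop * sr))

    periods, amps, onsets = [], [], []
    idx = np.flatnonzero(track.voiced)
    # split voiced frames into contiguous runs
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    runs = [run for run in np.split(idx, splits) if len(run)]
    for ri, run in enumerate(runs):
        start = int(run[0]) * step
        stop = min(int(run[-1]) * step + n, len(x))
        if ri + 1 < len(runs):  # regions must not overlap the next one
            stop = min(stop, int(runs[ri + 1][0]) * step)
        t0 = sr / float(np.median(track.f0[run]))
        marks = _mark_cycles(x, start, stop, t0, first_search=n)
        if len(marks) < 4:
            continue
        # the first and last cycle of a region sit on voicing onset/offset
        # edges and carry unreliable marks
        marks = marks[1:-1]
        t = np.diff(marks)
        run_amps = np.empty(len(t))
        for i, m in enumerate(marks[:-1]):
            half = t[i] / 2.0
            lo = int(max(start, m - half))
            hi = int(min(stop, m + half))
            seg = x[lo:hi]
            run_amps[i] = np.sqrt((seg**2).mean()) if len(seg) else 0.0
        keep = run_amps > 0
        if onsets:  # keep the global onset track strictly increasing
            keep &= (marks[:-1] / sr) > onsets[-1]
        periods.extend((t[keep] / sr * 1000.0).tolist())
        onsets.extend((marks[:-1][keep] / sr).tolist())
        amps.extend(run_amps[keep].tolist())
    if len(periods) < 1:
        raise NoVoicedContentError("voiced regions too short for cycle marking")
    return PitchPeriodSequence(
        np.asarray(periods), np.asarray(amps), np.asarray(onsets)
    )


# ---------------------------------------------------------------------------
# period-track statistics


def mean_period(p: PitchPeriodSequence) -> float:
    """Arithmetic mean of the pitch periods, ms."""
    if len(p) < 1:
        raise ValueError("empty period sequence")
    return float(np.mean(p.periods_ms))


def jitter_absolute(p: PitchPeriodSequence) -> float:
    """Mean absolute difference of consecutive periods, ms."""
    if len(p) < 2:
        raise ValueError("need at least two periods")
    return float(np.mean(np.abs(np.diff(p.periods_ms))))


def jitter_percent(p: PitchPeriodSequence) -> float:
    """100 x jitter_absolute / mean period."""
    return 100.0 * jitter_absolute(p) / mean_period(p)


def shimmer_percent(p: PitchPeriodSequence) -> float:
    """100 x mean |A_k - A_{k-1}| / mean amplitude."""
    if len(p) < 2:
        raise ValueError("need at least two periods")
    a = p.amplitudes
    return 100.0 * float(np.mean(np.abs(np.diff(a))) / np.mean(a))


def mean_pitch(p: PitchPeriodSequence) -> float:
    """Mean of per-period instantaneous F0 = 1000 / T_i(ms), Hz."""
    if len(p) < 1:
        raise ValueError("empty period sequence")
    return float(np.mean(1000.0 / p.periods_ms))


def pitch_sd(p: PitchPeriodSequence) -> float:
    """Sample SD (N-1) of per-period instantaneous F0, Hz."""
    if len(p) < 2:
        raise ValueError("need at least two periods")
    return float(np.std(1000.0 / p.periods_ms, ddof=1))


def hnr_from_r_prime(r_prime: float, cap_db: float = 60.0) -> float:
    """10 log10(r' / (1 - r')), clamped and capped."""
    r = min(max(r_prime, 0.0), 1.0 - 1e-6)
    if r <= 0.0:
        return -cap_db
    return min(10.0 * math.log10(r / (1.0 - r)), cap_db)


def harmonicity_hnr(
    rec: VoiceRecording,
    p: PitchPeriodSequence | None = None,
    cfg: ExtractionConfig | None = None,
    *,
    _track: FrameTrack | None = None,
) -> float:
    """Utterance HNR: mean over voiced frames of the frame HNR in dB."""
    cfg = cfg or ExtractionConfig()
    track = _track if _track is not None else analyze_frames(rec, cfg)
    r = track.r_prime[track.voiced]
    if len(r) == 0:
        raise NoVoicedContentError("no voiced frames for harmonicity")
    vals = [hnr_from_r_prime(float(v), cfg.hnr_cap_db) for v in r]
    return float(np.mean(vals))


def intensity_db(
    rec: VoiceRecording,
    cfg: ExtractionConfig | None = None,
    *,
    _track: FrameTrack | None = None,
) -> float:
    """Energy-mean voiced-frame level: 10 log10(mean RMS^2 / ref^2), dB."""
    cfg = cfg or ExtractionConfig()
    track = _track if _track is not None else analyze_frames(rec, cfg)
    use = track.voiced if track.voiced.any() else ~track.silent
    if not use.any():
        raise SilentInputError("all frames below the silence floor")
    mean_power = float((track.rms[use] ** 2).mean())
    return 10.0 * math.log10(mean_power / cfg.intensity_reference**2)


def speech_velocity(
    rec_or_utt: VoiceRecording | AnnotatedUtterance,
    word_count: int | None = None,
    cfg: ExtractionConfig | None = None,
) -> float:
    """Average seconds per word; internal pauses >= min_pause are excluded.

    Uses annotation boundaries when present, otherwise silence-threshold
    segmentation on the frame RMS track.
    """
    cfg = cfg or ExtractionConfig()
    if isinstance(rec_or_utt, AnnotatedUtterance):
        utt = rec_or_utt
        n_words = word_count if word_count is not None else utt.word_count
        if n_words < 1:
            raise ValueError("word_count must be >= 1")
        speech = sum(end - start for start, end in utt.word_boundaries)
        return speech / n_words
    rec = rec_or_utt
    if word_count is None or word_count < 1:
        raise ValueError("word_count must be >= 1")
    # hop-resolution silence segmentation (finer than the analysis frames)
    x = rec.samples
    step = max(1, int(cfg.hop * rec.sample_rate))
    n_hops = len(x) // step
    hop_sq = np.add.reduceat(x[: n_hops * step] ** 2, np.arange(0, n_hops * step, step))
    hop_rms = np.sqrt(hop_sq / step)
    floor = hop_rms.max() * 10 ** (cfg.silence_floor_db / 20.0)
    speaking = hop_rms >= floor
    if not speaking.any():
        raise SilentInputError("fully silent input")
    # close silent gaps shorter than min_pause
    gap_hops = max(1, int(round(cfg.min_pause / cfg.hop)))
    first, last = np.flatnonzero(speaking)[[0, -1]]
    filled = speaking.copy()
    run_start = None
    for i in range(first, last + 1):
        if not speaking[i]:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and i - run_start < gap_hops:
                filled[run_start:i] = True
            run_start = None
    speech_time = float(filled.sum()) * cfg.hop
    return speech_time / word_count


def extract_features(
    utt: AnnotatedUtterance | VoiceRecording,
    word_count: int | None = None,
    cfg: ExtractionConfig | None = None,
) -> AcousticFeatureVector:
    """All seven features of one utterance, with QC fields.

    Perturbation statistics are reported as NaN rather than zero when fewer
    than two pitch periods were detected.
    """
    cfg = cfg or ExtractionConfig()
    rec = utt.recording if isinstance(utt, AnnotatedUtterance) else utt
    track = analyze_frames(rec, cfg)

    nan = float("nan")
    if track.voiced.any():
        try:
            p = _periods_from_track(rec, cfg, track)
        except NoVoicedContentError:
            p = None
    else:
        p = None

    n_periods = len(p) if p is not None else 0
    if p is not None and n_periods >= 2:
        f0 = mean_pitch(p)
        f0sd = pitch_sd(p)
        jit = jitter_percent(p)
        shi = shimmer_percent(p)
    else:
        f0 = f0sd = jit = shi = nan

    hnr = harmonicity_hnr(rec, p, cfg, _track=track) if track.voiced.any() else nan
    try:
        level = intensity_db(rec, cfg, _track=track)
    except SilentInputError:
        level = nan

    if isinstance(utt, AnnotatedUtterance):
        vel = speech_velocity(utt, word_count, cfg)
    elif word_count is not None:
        vel = speech_velocity(rec, word_count, cfg)
    else:
        vel = nan

    return AcousticFeatureVector(
        velocity=vel,
        mean_f0=f0,
        f0_sd=f0sd,
        intensity=level,
        jitter_pct=jit,
        shimmer_pct=shi,
        hnr=hnr,
        n_periods=n_periods,
        voiced_fraction=track.voiced_fraction,
    )
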