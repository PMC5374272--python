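"""Frame-based acoustic analysis of audio diaries.

Recordings are short "voicemail"-style diary entries, PCM mono at 8 kHz
with 16-bit precision.  Analysis is classical short-term processing:
25 ms frames with 10 ms hop; per-frame F0 by normalized autocorrelation
with parabolic peak interpolation; vocal effort as the high-band/low-band
spectral balance; harmonics-to-noise ratio (HNR) from the autocorrelation
value at the pitch period; speaking rate from peaks of the smoothed energy
envelope.  Frame features are aggregated per recording as means and SDs,
and per participant as means across the recordings in the assessment
window.

PitchVar is the within-recording SD of voiced-frame F0 in Hz;
MeanPitchVar / MeanVocalEffort are the across-recording means that enter
the symptom models.  The lexical content of recordings is never analyzed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.io import wavfile
from scipy.signal import find_peaks

AUDIO_RATE = 8000
"""Required sampling rate (Hz)."""

FRAME_LEN = 200
"""Analysis frame length in samples (25 ms at 8 kHz)."""

HOP = 80
"""Frame hop in samples (10 ms at 8 kHz)."""

# The 25 ms frame supports normalized autocorrelation lags up to 100
# samples (frame_len / 2), so the F0 search floor is 80 Hz rather than the
# 60 Hz a longer frame would allow; the ceiling is 400 Hz.
F0_MIN_HZ = 80.0
F0_MAX_HZ = 400.0

VOICING_THRESHOLD = 0.45
"""Minimum normalized autocorrelation peak for a frame to count as voiced."""

_HNR_CLAMP_DB = (-20.0, 40.0)
_EFFORT_SPLIT_HZ = 1000.0
_EFFORT_TOP_HZ = 4000.0

#: Participant-level acoustic feature registry (the LASSO screening input).
AUDIO_FEATURE_NAMES: tuple[str, ...] = (
    "MeanPitchVar",
    "MeanVocalEffort",
    "MeanSpeakingRate",
    "MeanHNR",
    "SdPitchVar",
)


class AudioFormatError(ValueError):
    """A recording violates the required PCM mono 8 kHz 16-bit format."""


@dataclass
class AudioDiary:
    """One diary recording: 16-bit PCM mono samples at 8 kHz."""

    participant_id: str
    t: int
    samples: np.ndarray
    rate: int = AUDIO_RATE

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.rate != AUDIO_RATE:
            raise AudioFormatError(f"rate must be {AUDIO_RATE} Hz, got {self.rate}")
        if self.samples.size == 0:
            raise AudioFormatError("recording is empty")
        if self.samples.ndim != 1:
            raise AudioFormatError("recording must be mono")
        if self.samples.min() < -32768 or self.samples.max() > 32767:
            raise AudioFormatError("samples exceed 16-bit range")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate

    def as_float(self) -> np.ndarray:
        return self.samples.astype(np.float64) / 32768.0

    @classmethod
    def read_wav(cls, path, participant_id: str = "", t: int = 0) -> "AudioDiary":
        rate, data = wavfile.read(path)
        if data.ndim != 1:
            raise AudioFormatError(f"{path}: expected mono audio")
        if data.dtype != np.int16:
            raise AudioFormatError(f"{path}: expected 16-bit PCM, got {data.dtype}")
        return cls(participant_id=participant_id, t=t, samples=data, rate=int(rate))


@dataclass
class RecordingFeatures:
    """Per-recording aggregates of the frame-level analysis."""

    f0_mean: float
    f0_sd: float
    vocal_effort: float
    speaking_rate: float
    hnr: float
    voiced_fraction: float
    n_frames: int


@dataclass
class ParticipantAudioFeatures:
    """Across-recording means entering the symptom models."""

    MeanPitchVar: float
    MeanVocalEffort: float
    MeanSpeakingRate: float
    MeanHNR: float
    SdPitchVar: float
    n_recordings: int


def frame_signal(
    samples: np.ndarray, frame_len: int = FRAME_LEN, hop: int = HOP
) -> np.ndarray:
    """Slice a signal into overlapping frames (final partial frame dropped).

    Returns an array of shape ``(n_frames, frame_len)``; an input shorter
    than one frame yields zero frames.
    """
    if not (frame_len >= hop > 0):
        raise ValueError(f"require frame_len >= hop > 0, got {frame_len}, {hop}")
    x = np.asarray(samples, dtype=np.float64)
    if x.size < frame_len:
        return np.empty((0, frame_len))
    n_frames = (x.size - frame_len) // hop + 1
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n_frames)[:, None]
    return x[idx]


def _normalized_autocorr(frame: np.ndarray, max_lag: int) -> np.ndarray:
    """r(tau) = sum x_t x_{t+tau} / sqrt(sum x_t^2 * sum x_{t+tau}^2), tau=0..max_lag."""
    x = frame - frame.mean()
    n = x.size
    cum = np.cumsum(x**2)
    total = cum[-1]
    if total <= 0:
        return np.zeros(max_lag + 1)
    num = np.correlate(x, x, mode="full")[n - 1 : n + max_lag]
    lags = np.arange(max_lag + 1)
    e_head = cum[n - 1 - lags]  # energy of x[:n-lag]
    e_tail = total - np.concatenate(([0.0], cum[:max_lag]))  # energy of x[lag:]
    denom = np.sqrt(e_head * e_tail)
    r = np.divide(num, denom, out=np.zeros_like(num), where=denom > 0)
    r[0] = 1.0
    return r


def estimate_f0(
    frame: np.ndarray,
    rate: int = AUDIO_RATE,
    f0_min: float = F0_MIN_HZ,
    f0_max: float = F0_MAX_HZ,
    threshold: float = VOICING_THRESHOLD,
) -> float | None:
    """Per-frame F0 in Hz, or ``None`` for an unvoiced frame.

    Normalized-autocorrelation peak search over the lag range for
    ``[f0_min, f0_max]``; voiced iff the peak value reaches ``threshold``.
    Among local maxima within 10% of the best, the shortest lag wins
    (suppresses octave-down errors); the winning lag is refined by
    parabolic interpolation.
    """
    frame = np.asarray(frame, dtype=np.float64)
    lag_min = max(2, int(math.floor(rate / f0_max)))
    lag_max = int(math.ceil(rate / f0_min))
    if frame.size < 2 * lag_max:
        raise ValueError(
            f"frame of {frame.size} samples cannot support lags up to {lag_max}"
        )
    r = _normalized_autocorr(frame, lag_max)
    seg = r[lag_min : lag_max + 1]
    if seg.size < 3:
        return None
    peaks, _ = find_peaks(seg)
    if peaks.size == 0:
        best = int(np.argmax(seg))
        cand = [best]
    else:
        r_best = float(seg[peaks].max())
        if r_best < threshold:
            return None
        cand = [int(p) for p in peaks if seg[p] >= 0.9 * r_best]
    lag_rel = min(cand)
    if seg[lag_rel] < threshold:
        return None
    lag = lag_rel + lag_min
    # Parabolic interpolation of the autocorrelation peak.
    if 1 <= lag < lag_max:
        y0, y1, y2 = r[lag - 1], r[lag], r[lag + 1]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    return rate / (lag + delta)


def _peak_autocorr_value(frame: np.ndarray, f0: float, rate: int = AUDIO_RATE) -> float:
    lag = int(round(rate / f0))
    r = _normalized_autocorr(np.asarray(frame, dtype=np.float64), lag)
    return float(r[lag])


def vocal_effort(frame: np.ndarray, rate: int = AUDIO_RATE) -> float | None:
    """High/low spectral balance in dB: 10*log10(E[1-4 kHz) / E[0-1 kHz)).

    Computed from the Hann-windowed frame's power spectrum.  Returns
    ``None`` for a zero-energy frame (excluded upstream, not an error).
    A flat power spectrum gives 10*log10(3) ~= 4.77 dB (3 kHz vs 1 kHz of
    bandwidth).
    """
    frame = np.asarray(frame, dtype=np.float64)
    if frame.size == 0 or not np.any(frame):
        return None
    w = np.hanning(frame.size)
    spec = np.abs(np.fft.rfft(frame * w)) ** 2
    freqs = np.fft.rfftfreq(frame.size, 1.0 / rate)
    low = spec[freqs < _EFFORT_SPLIT_HZ].sum()
    high = spec[(freqs >= _EFFORT_SPLIT_HZ) & (freqs < _EFFORT_TOP_HZ)].sum()
    if low <= 0 or high <= 0:
        return None
    return 10.0 * math.log10(high / low)


def hnr_from_r(r: float) -> float:
    """Map a normalized autocorrelation value to HNR in dB.

    ``10*log10(r/(1-r))`` clamped to [-20, 40] dB; ``r=0.5`` gives 0 dB and
    ``r -> 1`` (noiseless periodicity) hits the 40 dB ceiling.
    """
    lo, hi = _HNR_CLAMP_DB
    if r >= 1.0:
        return hi
    if r <= 0.0:
        return lo
    return float(np.clip(10.0 * math.log10(r / (1.0 - r)), lo, hi))


def hnr(frame: np.ndarray, f0: float, rate: int = AUDIO_RATE) -> float:
    """Harmonics-to-noise ratio at the pitch lag of a voiced frame, in dB."""
    return hnr_from_r(_peak_autocorr_value(frame, f0, rate))


def speaking_rate(samples: np.ndarray, rate: int = AUDIO_RATE) -> float:
    """Syllable-like bursts per second from the smoothed energy envelope.

    The envelope is 50 ms RMS at 10 ms hop; bursts are envelope peaks above
    median + 2*MAD, separated by at least 100 ms and prominent relative to
    the envelope's dynamic range (a steady tone has no bursts).  Silent
    input gives 0.
    """
    x = np.asarray(samples, dtype=np.float64)
    duration = x.size / rate
    if duration <= 0 or not np.any(x):
        return 0.0
    win = int(0.050 * rate)
    hop = int(0.010 * rate)
    frames = frame_signal(x, frame_len=win, hop=hop) if x.size >= win else x[None, :]
    env = np.sqrt((frames**2).mean(axis=1))
    med = float(np.median(env))
    mad = float(np.median(np.abs(env - med)))
    thresh = med + 2.0 * mad
    min_sep = max(1, int(0.100 * rate / hop))
    prominence = 0.2 * float(env.max())
    peaks, _ = find_peaks(env, height=thresh, distance=min_sep, prominence=prominence)
    return float(peaks.size) / duration


def analyze_recording(diary: AudioDiary) -> RecordingFeatures:
    """Run the full frame-based analysis for one recording."""
    x = diary.as_float()
    frames = frame_signal(x)
    f0s: list[float] = []
    efforts: list[float] = []
    hnrs: list[float] = []
    for frame in frames:
        f0 = estimate_f0(frame)
        if f0 is not None:
            f0s.append(f0)
            hnrs.append(hnr(frame, f0))
        eff = vocal_effort(frame)
        if eff is not None:
            efforts.append(eff)
    n_frames = len(frames)
    voiced_fraction = len(f0s) / n_frames if n_frames else 0.0
    return RecordingFeatures(
        f0_mean=float(np.mean(f0s)) if f0s else math.nan,
        f0_sd=float(np.std(f0s, ddof=1)) if len(f0s) >= 2 else (0.0 if f0s else math.nan),
        vocal_effort=float(np.mean(efforts)) if efforts else math.nan,
        speaking_rate=speaking_rate(x),
        hnr=float(np.mean(hnrs)) if hnrs else math.nan,
        voiced_fraction=voiced_fraction,
        n_frames=n_frames,
    )


aggregate_recording = analyze_recording


def participant_audio_features(
    recordings: Sequence[tuple[int, RecordingFeatures]],
    assessment_time: float,
    window_days: float = 7,
) -> ParticipantAudioFeatures:
    """Average per-recording features over the assessment window.

    ``recordings`` are ``(timestamp, features)`` pairs; only those with
    timestamp in ``[assessment_time - window_days*86400, assessment_time)``
    contribute.  With no in-window recording every field is missing.
    """
    start = assessment_time - window_days * 86400.0
    in_window = [rf for t, rf in recordings if start <= t < assessment_time]
    if not in_window:
        return ParticipantAudioFeatures(
            MeanPitchVar=math.nan,
            MeanVocalEffort=math.nan,
            MeanSpeakingRate=math.nan,
            MeanHNR=math.nan,
            SdPitchVar=math.nan,
            n_recordings=0,
        )

    def _mean(vals: list[float]) -> float:
        vals = [v for v in vals if not math.isnan(v)]
        return float(np.mean(vals)) if vals else math.nan

    pitch_vars = [rf.f0_sd for rf in in_window if not math.isnan(rf.f0_sd)]
    return ParticipantAudioFeatures(
        MeanPitchVar=_mean([rf.f0_sd for rf in in_window]),
        MeanVocalEffort=_mean([rf.vocal_effort for rf in in_window]),
        MeanSpeakingRate=_mean([rf.speaking_rate for rf in in_window]),
        MeanHNR=_mean([rf.hnr for rf in in_window]),
        SdPitchVar=float(np.std(pitch_vars, ddof=1)) if len(pitch_vars) >= 2 else math.nan,
        n_recordings=len(in_window),
    )
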