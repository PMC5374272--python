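"""Seeded synthetic cohorts: symptom labels, phone trace streams, audio diaries.

Participant-level data from mobile-sensing field studies is never released,
so this module generates cohorts with the statistical structure the
downstream analysis assumes: binary symptom labels at configurable
prevalence, event streams (calls, SMS, GPS, screen) whose weekly summary
features are shifted by a configurable standardized effect size *d* when a
symptom is present, and synthetic voiced audio with controlled fundamental
frequency (F0) variability, spectral tilt, syllable rate and
signal-to-noise ratio.

Calibration contract: for each plantable trace feature the generator knows
the analytic mean and SD of the weekly feature under the baseline model
(homogeneous compound-Poisson event processes), and a planted effect of
size ``d`` shifts the generating rate so the feature's group mean moves by
``d`` of those SDs.  :func:`nominal_feature_moments` exposes the moments so
tests can check recovery against the generator's own parameters.

Reproducibility: one RNG stream per (participant, modality), spawned from
the master seed and the participant's index, so enlarging a cohort never
perturbs previously generated participants.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.ndimage import gaussian_filter1d

from .audio_features import AUDIO_RATE, AudioDiary
from .trace_features import TraceEvent, write_trace_log

SYMPTOMS: tuple[str, ...] = (
    "depressed_mood",
    "diminished_interest",
    "fatigue",
    "avoidance",
)

#: Trace features that support planted standardized effects.
PLANTABLE_FEATURES: tuple[str, ...] = (
    "call.out.sum",
    "sms.address.count",
    "travel.distance.sum",
)

WEEK_S = 7 * 86400

# Internal generative constants (not part of the public rate surface).
_CALL_DUR_MEDIAN_MIN = 2.0     # lognormal median outbound/inbound call length
_CALL_DUR_SIGMA = 0.9          # lognormal sigma (log scale)
_EXCURSIONS_PER_DAY = 2.0      # home-anchored trips per day
_EXCURSION_GAMMA_SHAPE = 4.0   # shape of the trip-radius Gamma distribution
_WALK_SPEED_MPS = 1.4          # excursion travel speed
_DWELL_S = 600.0               # pause at the excursion endpoint
_SCREEN_PER_DAY = 40.0         # screen-on events per day (unused downstream)
_CONTACT_POOL = 30             # per-participant contact pool size
_GPS_JITTER_M = 15.0           # positioning noise SD per coordinate
_M_PER_DEG_LAT = 111195.0      # metres per degree latitude (spherical)
_TRAIT_SIGMA = 0.4             # log-SD of per-person trait multipliers
                               # (calling, texting, mobility), mean 1

_MODALITY_CODES = {"labels": 0, "trace": 1, "audio": 2}


class ConfigurationError(ValueError):
    """A synthetic-cohort configuration field is invalid."""


def _default_prevalence() -> dict[str, float]:
    return {s: 0.4 for s in SYMPTOMS}


def _default_effects() -> dict[tuple[str, str], float]:
    # Behavioral withdrawal: symptom presence reduces outbound calling,
    # texting breadth and travel.  Directions are assumptions (documented),
    # magnitudes moderate-to-large.
    return {
        ("fatigue", "call.out.sum"): -0.8,
        ("fatigue", "sms.address.count"): -0.8,
        ("diminished_interest", "sms.address.count"): -0.8,
        ("diminished_interest", "travel.distance.sum"): -0.8,
        ("avoidance", "call.out.sum"): -0.8,
        ("avoidance", "sms.address.count"): -0.8,
    }


def _default_base_rates() -> dict[str, float]:
    return {
        "calls_out_per_day": 2.0,
        "calls_in_per_day": 2.0,
        "sms_out_per_day": 6.0,
        "sms_in_per_day": 5.0,
        "unique_contacts_per_week": 8.0,
        "km_per_day": 12.0,
        "gps_interval_s": 300.0,
    }


def _default_audio_params() -> dict[str, float]:
    # Flattened prosody and reduced vocal effort (shallower high-frequency
    # energy) when depressed mood is present.
    return {
        "f0_mean": 140.0,
        "f0_sd_present": 15.0,
        "f0_sd_absent": 30.0,
        "tilt_present": -14.0,
        "tilt_absent": -9.0,
        "snr": 30.0,
        "duration_s": 10.0,
        "diaries_per_week": 2.0,
        "syllable_rate": 4.0,
        # between-participant trait variation (SDs of stable per-person offsets)
        "f0_mean_between_sd": 10.0,
        "f0_sd_between_sd": 8.0,
        "tilt_between_sd": 3.5,
    }


@dataclass
class SyntheticConfig:
    """Generative settings for one synthetic cohort.

    ``effect_sizes`` maps ``(symptom, feature)`` to a standardized mean
    shift *d* of the weekly feature for symptom-positive participants;
    supported features are :data:`PLANTABLE_FEATURES`.  Audio contrast is
    expressed through the ``*_present`` / ``*_absent`` audio parameters and
    is keyed on the ``depressed_mood`` label.
    """

    n_participants: int = 73
    weeks: int = 12
    symptom_prevalence: dict[str, float] = field(default_factory=_default_prevalence)
    effect_sizes: dict[tuple[str, str], float] = field(default_factory=_default_effects)
    base_rates: dict[str, float] = field(default_factory=_default_base_rates)
    audio_params: dict[str, float] = field(default_factory=_default_audio_params)
    event_drop_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        base = _default_base_rates()
        base.update(self.base_rates)
        self.base_rates = base
        audio = _default_audio_params()
        audio.update(self.audio_params)
        self.audio_params = audio
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ConfigurationError(f"n_participants must be >= 2, got {self.n_participants}")
        if self.weeks < 1:
            raise ConfigurationError(f"weeks must be >= 1, got {self.weeks}")
        for sym, p in self.symptom_prevalence.items():
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"symptom_prevalence[{sym!r}] must be in [0,1], got {p}")
        for key, rate in self.base_rates.items():
            if rate <= 0:
                raise ConfigurationError(f"base_rates[{key!r}] must be > 0, got {rate}")
        for sym, feat in self.effect_sizes:
            if feat not in PLANTABLE_FEATURES:
                raise ConfigurationError(
                    f"effect_sizes feature {feat!r} not plantable; choose from {PLANTABLE_FEATURES}"
                )
        f0 = self.audio_params["f0_mean"]
        if not (60.0 < f0 < 400.0):
            raise ConfigurationError(f"audio_params['f0_mean'] must be in (60, 400) Hz, got {f0}")
        for key in ("f0_sd_present", "f0_sd_absent"):
            if self.audio_params[key] < 0:
                raise ConfigurationError(f"audio_params[{key!r}] must be >= 0")
        if self.audio_params["duration_s"] <= 0:
            raise ConfigurationError("audio_params['duration_s'] must be > 0")
        if not (0.0 <= self.event_drop_rate < 1.0):
            raise ConfigurationError(f"event_drop_rate must be in [0,1), got {self.event_drop_rate}")

    @property
    def assessment_time(self) -> int:
        """End of the simulated period (epoch seconds; origin at 0)."""
        return self.weeks * WEEK_S


@dataclass(frozen=True)
class Participant:
    participant_id: str
    index: int
    labels: dict[str, int]
    assessment_time: int


@dataclass
class Cohort:
    participants: list[Participant]

    def __post_init__(self) -> None:
        ids = [p.participant_id for p in self.participants]
        if len(set(ids)) != len(ids):
            raise ValueError("participant ids must be unique")

    def labels_frame(self) -> pd.DataFrame:
        rows = [
            {
                "participant_id": p.participant_id,
                "assessment_time": p.assessment_time,
                "symptom": sym,
                "present": lab,
            }
            for p in self.participants
            for sym, lab in sorted(p.labels.items())
        ]
        return pd.DataFrame(rows, columns=["participant_id", "assessment_time", "symptom", "present"])


def _rng(config_seed: int, participant_index: int, modality: str) -> np.random.Generator:
    ss = np.random.SeedSequence([config_seed, participant_index, _MODALITY_CODES[modality]])
    return np.random.Generator(np.random.PCG64(ss))


def _peer_hash(contact_index: int, salt: str) -> str:
    """Opaque salted counterpart descriptor — no raw numbers in the stream."""
    return hashlib.sha1(f"{salt}:{contact_index}".encode()).hexdigest()[:16]


def nominal_feature_moments(config: SyntheticConfig) -> dict[str, tuple[float, float]]:
    """Analytic (mean, SD) of each plantable weekly feature under baseline.

    Each data source is driven by a stable per-person lognormal trait
    multiplier ``T`` (mean 1, log-SD 0.4) — sociability on the phone,
    texting habit, mobility — so features of the same source correlate
    across participants.  Conditional on the trait:
    call.out.sum — compound Poisson of lognormal call minutes;
    sms.address.count — Poisson weekly unique counterparties;
    travel.distance.sum — compound Poisson of out-and-back trip lengths
    ``2R`` with ``R ~ Gamma(shape k, mean T*Rbar)``.
    Total variance adds the between-person trait component
    (``v = exp(sigma_t^2) - 1``).
    """
    br = config.base_rates
    v = math.exp(_TRAIT_SIGMA**2) - 1.0

    lam_calls = 7.0 * br["calls_out_per_day"]
    e_dur = _CALL_DUR_MEDIAN_MIN * math.exp(_CALL_DUR_SIGMA**2 / 2)
    e_dur2 = _CALL_DUR_MEDIAN_MIN**2 * math.exp(2 * _CALL_DUR_SIGMA**2)
    call_mean = lam_calls * e_dur
    call_sd = math.sqrt(lam_calls * e_dur2 + v * call_mean**2)

    kappa = br["unique_contacts_per_week"]
    sms_mean, sms_sd = kappa, math.sqrt(kappa + v * kappa**2)

    mu_exc = 7.0 * _EXCURSIONS_PER_DAY
    r_bar = br["km_per_day"] / (2.0 * _EXCURSIONS_PER_DAY)
    e_r2 = r_bar**2 * (1.0 + 1.0 / _EXCURSION_GAMMA_SHAPE)
    dist_mean = mu_exc * 2.0 * r_bar
    dist_sd = math.sqrt((1.0 + v) * mu_exc * 4.0 * e_r2 + v * dist_mean**2)

    return {
        "call.out.sum": (call_mean, call_sd),
        "sms.address.count": (sms_mean, sms_sd),
        "travel.distance.sum": (dist_mean, dist_sd),
    }


def _draw_traits(rng: np.random.Generator) -> dict[str, float]:
    """Per-person lognormal (mean-1) source traits: calls, texts, mobility."""
    mu = -_TRAIT_SIGMA**2 / 2.0
    return {
        "calls": float(rng.lognormal(mu, _TRAIT_SIGMA)),
        "texts": float(rng.lognormal(mu, _TRAIT_SIGMA)),
        "mobility": float(rng.lognormal(mu, _TRAIT_SIGMA)),
    }


def _planted_shift(config: SyntheticConfig, labels: Mapping[str, int], feature: str) -> float:
    """Total feature-unit mean shift for this participant (sums over symptoms)."""
    _, sd = nominal_feature_moments(config)[feature]
    d = sum(
        eff
        for (sym, feat), eff in config.effect_sizes.items()
        if feat == feature and labels.get(sym, 0) == 1
    )
    return d * sd


def draw_weekly_features(
    rng: np.random.Generator, config: SyntheticConfig, n: int
) -> pd.DataFrame:
    """Sample the plantable weekly features directly from their generative laws.

    Bypasses event-stream synthesis (and hence GPS measurement noise):
    weekly outbound-call minutes are a compound Poisson of lognormal call
    lengths, weekly unique texting counterparties are Poisson, and weekly
    travel is a compound Poisson of out-and-back trip lengths.  Useful for
    fast simulation studies of the modeling stack under the generator's own
    feature distributions.
    """
    br = config.base_rates
    mu_t = -_TRAIT_SIGMA**2 / 2.0
    t_calls = rng.lognormal(mu_t, _TRAIT_SIGMA, n)
    t_texts = rng.lognormal(mu_t, _TRAIT_SIGMA, n)
    t_mob = rng.lognormal(mu_t, _TRAIT_SIGMA, n)

    lam_calls = 7.0 * br["calls_out_per_day"]
    counts = rng.poisson(t_calls * lam_calls)
    call_sum = np.array(
        [
            _CALL_DUR_MEDIAN_MIN * np.exp(rng.normal(0, _CALL_DUR_SIGMA, c)).sum()
            for c in counts
        ]
    )
    sms_addr = rng.poisson(t_texts * br["unique_contacts_per_week"]).astype(float)
    mu_exc = 7.0 * _EXCURSIONS_PER_DAY
    r_bar = br["km_per_day"] / (2.0 * _EXCURSIONS_PER_DAY)
    trips = rng.poisson(mu_exc, n)
    travel = np.array(
        [
            2.0 * t * rng.gamma(_EXCURSION_GAMMA_SHAPE, r_bar / _EXCURSION_GAMMA_SHAPE, m).sum()
            for t, m in zip(t_mob, trips)
        ]
    )
    return pd.DataFrame(
        {
            "call.out.sum": call_sum,
            "sms.address.count": sms_addr,
            "travel.distance.sum": travel,
        },
        index=[f"P{i:04d}" for i in range(n)],
    )


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Draw labels independently per symptom at the configured prevalence."""
    config.validate()
    participants = []
    for i in range(config.n_participants):
        rng = _rng(config.seed, i, "labels")
        labels = {
            sym: int(rng.random() < p) for sym, p in sorted(config.symptom_prevalence.items())
        }
        participants.append(
            Participant(
                participant_id=f"P{i:04d}",
                index=i,
                labels=labels,
                assessment_time=config.assessment_time,
            )
        )
    return Cohort(participants=participants)


# ---------------------------------------------------------------------------
# Trace stream synthesis
# ---------------------------------------------------------------------------

def _weekly_uniform_times(rng: np.random.Generator, week_start: float, count: int) -> np.ndarray:
    return np.sort(week_start + rng.random(count) * WEEK_S)


def generate_trace_stream(
    participant: Participant, labels: Mapping[str, int], config: SyntheticConfig, seed: int
) -> list[TraceEvent]:
    """Synthesize the participant's full-period event stream.

    Outbound calls are Poisson with lognormal durations; SMS counterparties
    are drawn weekly from a per-participant contact pool whose unique count
    carries the planted shift; GPS follows a home-anchored out-and-back
    mobility walk with Gaussian positioning jitter; screen on/off events are
    emitted but unused downstream.
    """
    rng = _rng(seed, participant.index, "trace")
    br = config.base_rates
    salt = f"{seed}:{participant.index}"
    events: list[TraceEvent] = []
    traits = _draw_traits(rng)

    # --- calls -------------------------------------------------------------
    # The planted effect scales the whole calling source: behavioral
    # withdrawal suppresses outgoing and incoming alike.  The scale factor
    # is calibrated so call.out.sum shifts by exactly d nominal SDs.
    e_dur_min = _CALL_DUR_MEDIAN_MIN * math.exp(_CALL_DUR_SIGMA**2 / 2)
    shift_min = _planted_shift(config, labels, "call.out.sum")
    lam_base = 7.0 * br["calls_out_per_day"]
    g_calls = max(0.02, lam_base + shift_min / e_dur_min) / lam_base
    lam_out = traits["calls"] * g_calls * lam_base
    lam_in = traits["calls"] * g_calls * 7.0 * br["calls_in_per_day"]

    def _calls(kind: str, lam: float) -> None:
        for w in range(config.weeks):
            n = rng.poisson(lam)
            times = _weekly_uniform_times(rng, w * WEEK_S, n)
            durs = _CALL_DUR_MEDIAN_MIN * np.exp(rng.normal(0, _CALL_DUR_SIGMA, n)) * 60.0
            peers = rng.integers(0, _CONTACT_POOL, n)
            for t, dur, peer in zip(times, durs, peers):
                events.append(
                    TraceEvent(t=int(t), kind=kind, peer=_peer_hash(int(peer), salt), dur_s=float(dur))
                )

    _calls("call_out", lam_out)
    _calls("call_in", lam_in)

    # --- SMS (texting source scaled coherently, calibrated on the unique
    # weekly counterparty count) ---------------------------------------------
    kappa_base = br["unique_contacts_per_week"]
    g_texts = (
        max(0.2, kappa_base + _planted_shift(config, labels, "sms.address.count")) / kappa_base
    )
    kappa = traits["texts"] * g_texts * kappa_base
    for w in range(config.weeks):
        k = int(min(_CONTACT_POOL, rng.poisson(kappa)))
        chosen = rng.choice(_CONTACT_POOL, size=k, replace=False) if k else np.array([], dtype=int)
        total = max(k, rng.poisson(traits["texts"] * g_texts * 7.0 * br["sms_out_per_day"]))
        extra = total - k
        counts = np.ones(k, dtype=int)
        if k and extra > 0:
            counts += rng.multinomial(extra, np.full(k, 1.0 / k))
        msgs = np.repeat(chosen, counts)
        times = _weekly_uniform_times(rng, w * WEEK_S, len(msgs))
        for t, peer in zip(times, rng.permutation(msgs)):
            events.append(TraceEvent(t=int(t), kind="sms_out", peer=_peer_hash(int(peer), salt)))
        n_in = rng.poisson(traits["texts"] * g_texts * 7.0 * br["sms_in_per_day"])
        times = _weekly_uniform_times(rng, w * WEEK_S, n_in)
        peers = rng.integers(0, _CONTACT_POOL, n_in)
        for t, peer in zip(times, peers):
            events.append(TraceEvent(t=int(t), kind="sms_in", peer=_peer_hash(int(peer), salt)))

    # --- GPS: home-anchored two-state mobility walk -------------------------
    home_lat = float(rng.uniform(35.0, 45.0))
    home_lon = float(rng.uniform(-120.0, -70.0))
    m_per_deg_lon = _M_PER_DEG_LAT * math.cos(math.radians(home_lat))
    r_bar = br["km_per_day"] / (2.0 * _EXCURSIONS_PER_DAY)
    mu_exc = 7.0 * _EXCURSIONS_PER_DAY
    shift_km = _planted_shift(config, labels, "travel.distance.sum")
    r_eff = traits["mobility"] * max(0.0, r_bar + shift_km / (2.0 * mu_exc))
    interval = br["gps_interval_s"]

    for w in range(config.weeks):
        week_start = w * WEEK_S
        n_exc = rng.poisson(mu_exc)
        radii_km = (
            rng.gamma(_EXCURSION_GAMMA_SHAPE, r_eff / _EXCURSION_GAMMA_SHAPE, n_exc)
            if r_eff > 0
            else np.zeros(n_exc)
        )
        bearings = rng.uniform(0, 2 * math.pi, n_exc)
        starts = np.sort(rng.uniform(0, WEEK_S, n_exc))
        trips = []  # (start, out_end, dwell_end, ret_end, radius_m, bearing)
        cursor = 0.0
        for s, r_km, b in zip(starts, radii_km, bearings):
            s = max(s, cursor)
            r_m = r_km * 1000.0
            leg = r_m / _WALK_SPEED_MPS
            trips.append((s, s + leg, s + leg + _DWELL_S, s + 2 * leg + _DWELL_S, r_m, b))
            cursor = s + 2 * leg + _DWELL_S
        fix_times = np.arange(0.0, WEEK_S, interval)
        dist_m = np.zeros_like(fix_times)
        bear = np.zeros_like(fix_times)
        for s, out_end, dwell_end, ret_end, r_m, b in trips:
            m = (fix_times >= s) & (fix_times < ret_end)
            if not m.any():
                continue
            tt = fix_times[m]
            d = np.where(
                tt < out_end,
                (tt - s) * _WALK_SPEED_MPS,
                np.where(tt < dwell_end, r_m, r_m - (tt - dwell_end) * _WALK_SPEED_MPS),
            )
            dist_m[m] = np.clip(d, 0.0, r_m)
            bear[m] = b
        jitter = rng.normal(0.0, _GPS_JITTER_M, (len(fix_times), 2))
        north = dist_m * np.cos(bear) + jitter[:, 0]
        east = dist_m * np.sin(bear) + jitter[:, 1]
        lats = home_lat + north / _M_PER_DEG_LAT
        lons = home_lon + east / m_per_deg_lon
        for t, la, lo in zip(fix_times, lats, lons):
            events.append(
                TraceEvent(t=int(week_start + t), kind="gps", lat=float(la), lon=float(lo))
            )

    # --- screen toggles (collected, unused downstream) ----------------------
    for w in range(config.weeks):
        n = rng.poisson(7.0 * _SCREEN_PER_DAY)
        times = _weekly_uniform_times(rng, w * WEEK_S, n)
        dwell = rng.exponential(120.0, n)
        for t, dw in zip(times, dwell):
            events.append(TraceEvent(t=int(t), kind="screen_on"))
            events.append(TraceEvent(t=int(t + dw) + 1, kind="screen_off"))

    if config.event_drop_rate > 0:
        keep = rng.random(len(events)) >= config.event_drop_rate
        events = [e for e, k in zip(events, keep) if k]
    events.sort(key=lambda e: e.t)
    return events


# ---------------------------------------------------------------------------
# Audio synthesis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AudioGroundTruth:
    """Sidecar truth for one synthesized diary (statistics of the actual contour)."""

    f0_mean: float
    f0_sd: float
    tilt_db_per_octave: float
    syllable_rate: float
    snr_db: float
    voiced_fraction: float


def synthesize_voice(
    rng: np.random.Generator,
    f0_mean: float,
    f0_sd: float,
    tilt_db_per_octave: float,
    snr_db: float,
    duration_s: float,
    syllable_rate: float = 4.0,
    rate: int = AUDIO_RATE,
) -> tuple[np.ndarray, AudioGroundTruth]:
    """Render a synthetic voiced signal and its ground truth.

    A glottal-style impulse train follows a slowly varying F0 contour
    (Gaussian process smoothed to ~0.3 s, standardized to the requested
    mean/SD), is spectrally shaped by a constant dB/octave tilt filter
    (reference 1 kHz), amplitude-gated into syllable-like bursts, and mixed
    with white noise at the requested SNR (measured over speech-active
    samples).  Returns float samples in [-1, 1] and the realized truth.
    """
    if not (60.0 < f0_mean < 400.0):
        raise ConfigurationError(f"f0_mean must be in (60, 400) Hz, got {f0_mean}")
    n = int(round(duration_s * rate))
    t = np.arange(n) / rate

    # F0 contour: smoothed Gaussian noise standardized to (f0_mean, f0_sd).
    coarse_rate = 100.0
    g = rng.normal(size=max(8, int(math.ceil(duration_s * coarse_rate)) + 1))
    g = gaussian_filter1d(g, sigma=0.3 * coarse_rate, mode="reflect")
    sd = g.std()
    g = (g - g.mean()) / (sd if sd > 0 else 1.0)
    contour = np.interp(t, np.arange(len(g)) / coarse_rate, g)
    f0 = np.clip(f0_mean + f0_sd * contour, 65.0, 395.0)

    # Impulse train by phase accumulation.
    phase = np.cumsum(2.0 * math.pi * f0 / rate)
    pulses = np.zeros(n)
    wraps = np.nonzero(np.diff(np.floor(phase / (2.0 * math.pi))) > 0)[0]
    pulses[wraps] = 1.0

    # Spectral tilt: gain 10^(tilt*log2(f/1kHz)/20), flattened below 50 Hz.
    spec = np.fft.rfft(pulses)
    freqs = np.fft.rfftfreq(n, 1.0 / rate)
    f_ref = np.maximum(freqs, 50.0)
    gain = 10.0 ** (tilt_db_per_octave * np.log2(f_ref / 1000.0) / 20.0)
    gain[0] = 0.0
    voiced = np.fft.irfft(spec * gain, n)

    # Syllable gate: Hann-shaped bursts at the requested rate, ~45% duty, so
    # the energy envelope shows one clean peak per syllable.
    gate = np.zeros(n)
    period = 1.0 / syllable_rate
    burst = 0.45 * period
    k = 0
    while True:
        onset = k * period + float(rng.uniform(-0.08, 0.08)) * period
        if onset >= duration_s:
            break
        i0, i1 = int(max(0.0, onset) * rate), int(min(duration_s, onset + burst) * rate)
        if i1 > i0:
            seg = 0.5 * (1.0 - np.cos(2.0 * math.pi * np.arange(i1 - i0) / max(1, i1 - i0)))
            gate[i0:i1] = np.maximum(gate[i0:i1], seg)
        k += 1
    voiced *= gate

    active = gate > 0.5
    p_sig = float(np.mean(voiced[active] ** 2)) if active.any() else 0.0
    noise = rng.normal(size=n)
    if p_sig > 0:
        noise *= math.sqrt(p_sig / 10.0 ** (snr_db / 10.0))
    else:
        noise *= 1e-4
    signal = voiced + noise

    peak = np.abs(signal).max()
    if peak > 0:
        signal = signal * (0.5 / peak)

    vf = float(active.mean())
    truth = AudioGroundTruth(
        f0_mean=float(f0[active].mean()) if active.any() else float("nan"),
        f0_sd=float(f0[active].std()) if active.any() else float("nan"),
        tilt_db_per_octave=float(tilt_db_per_octave),
        syllable_rate=float(syllable_rate),
        snr_db=float(snr_db),
        voiced_fraction=vf,
    )
    return signal, truth


def generate_audio_diary(
    participant: Participant,
    labels: Mapping[str, int],
    config: SyntheticConfig,
    seed: int,
    diary_index: int = 0,
    t: int | None = None,
) -> tuple[AudioDiary, AudioGroundTruth]:
    """Synthesize one diary recording as 8 kHz 16-bit PCM plus ground truth.

    Prosodic parameters switch on the ``depressed_mood`` label: the
    ``*_present`` F0-variability and tilt values apply when the symptom is
    present, the ``*_absent`` values otherwise.
    """
    ap = config.audio_params
    depressed = labels.get("depressed_mood", 0) == 1
    # Stable per-participant voice traits (drawn once per participant).
    trait_rng = np.random.Generator(
        np.random.PCG64(
            np.random.SeedSequence([seed, participant.index, _MODALITY_CODES["audio"], 999_999])
        )
    )
    f0_mean = float(
        np.clip(ap["f0_mean"] + trait_rng.normal(0.0, ap["f0_mean_between_sd"]), 70.0, 390.0)
    )
    f0_sd_base = ap["f0_sd_present"] if depressed else ap["f0_sd_absent"]
    f0_sd = max(0.5, f0_sd_base + float(trait_rng.normal(0.0, ap["f0_sd_between_sd"])))
    tilt_base = ap["tilt_present"] if depressed else ap["tilt_absent"]
    tilt = tilt_base + float(trait_rng.normal(0.0, ap["tilt_between_sd"]))
    # Per-diary child stream: independent recordings, stable under cohort growth.
    child = np.random.Generator(
        np.random.PCG64(
            np.random.SeedSequence([seed, participant.index, _MODALITY_CODES["audio"], diary_index])
        )
    )
    # Natural between-recording variation in articulation tempo.
    rate_jitter = float(child.normal(0.0, 0.1 * ap["syllable_rate"]))
    signal, truth = synthesize_voice(
        child,
        f0_mean=f0_mean,
        f0_sd=f0_sd,
        tilt_db_per_octave=tilt,
        snr_db=ap["snr"],
        duration_s=ap["duration_s"],
        syllable_rate=max(1.0, ap["syllable_rate"] + rate_jitter),
    )
    samples = np.clip(np.round(signal * 32767.0), -32768, 32767).astype(np.int16)
    if t is None:
        t = diary_index * 86400
    diary = AudioDiary(participant_id=participant.participant_id, t=int(t), samples=samples)
    return diary, truth


def diary_schedule(config: SyntheticConfig) -> list[int]:
    """Evenly spaced diary timestamps over the study period (epoch seconds)."""
    dpw = max(1, int(round(config.audio_params["diaries_per_week"])))
    times = []
    for w in range(config.weeks):
        for j in range(dpw):
            times.append(int(w * WEEK_S + (j + 0.5) / dpw * WEEK_S))
    return times


def generate_dataset(
    config: SyntheticConfig, last_weeks_only: int | None = None
) -> tuple[Cohort, dict[str, list[TraceEvent]], dict[str, list[tuple[AudioDiary, AudioGroundTruth]]]]:
    """Generate the whole cohort: labels, trace streams, diary recordings.

    ``last_weeks_only`` restricts *retention* of events/diaries to the final
    N weeks (generation is unchanged, so results are identical to filtering
    a full dataset) — useful when only the assessment-adjacent window will
    be analyzed.
    """
    cohort = generate_cohort(config)
    streams: dict[str, list[TraceEvent]] = {}
    diaries: dict[str, list[tuple[AudioDiary, AudioGroundTruth]]] = {}
    cutoff = (
        config.assessment_time - last_weeks_only * WEEK_S
        if last_weeks_only is not None
        else None
    )
    schedule = diary_schedule(config)
    for p in cohort.participants:
        ev = generate_trace_stream(p, p.labels, config, config.seed)
        if cutoff is not None:
            ev = [e for e in ev if e.t >= cutoff]
        streams[p.participant_id] = ev
        recs = []
        for j, t in enumerate(schedule):
            if cutoff is not None and t < cutoff:
                continue
            recs.append(generate_audio_diary(p, p.labels, config, config.seed, j, t))
        diaries[p.participant_id] = recs
    return cohort, streams, diaries


# ---------------------------------------------------------------------------
# Fixture serialization
# ---------------------------------------------------------------------------

MANIFEST_SCHEMA_VERSION = 1


def write_fixture_dataset(
    cohort: Cohort,
    streams: Mapping[str, Sequence[TraceEvent]],
    diaries: Mapping[str, Sequence[tuple[AudioDiary, AudioGroundTruth]]],
    out_dir,
) -> dict:
    """Write a re-readable fixture directory and return its manifest.

    Layout: ``traces/<pid>.jsonl``, ``audio/<pid>_<k>.wav`` (PCM mono 8 kHz
    16-bit), ``labels.csv``, ``manifest.json`` (paths, timestamps, audio
    ground truth).
    """
    out = Path(out_dir)
    try:
        (out / "traces").mkdir(parents=True, exist_ok=True)
        (out / "audio").mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out}: {exc}") from exc

    manifest: dict = {"schema_version": MANIFEST_SCHEMA_VERSION, "participants": []}
    for p in cohort.participants:
        entry: dict = {
            "participant_id": p.participant_id,
            "assessment_time": p.assessment_time,
            "labels": dict(sorted(p.labels.items())),
            "trace_path": None,
            "recordings": [],
        }
        if p.participant_id in streams:
            rel = f"traces/{p.participant_id}.jsonl"
            write_trace_log(streams[p.participant_id], out / rel)
            entry["trace_path"] = rel
        for k, (diary, truth) in enumerate(diaries.get(p.participant_id, [])):
            rel = f"audio/{p.participant_id}_{k:03d}.wav"
            wavfile.write(out / rel, diary.rate, diary.samples)
            entry["recordings"].append(
                {
                    "path": rel,
                    "t": diary.t,
                    "ground_truth": {
                        "f0_mean": truth.f0_mean,
                        "f0_sd": truth.f0_sd,
                        "tilt_db_per_octave": truth.tilt_db_per_octave,
                        "syllable_rate": truth.syllable_rate,
                        "snr_db": truth.snr_db,
                        "voiced_fraction": truth.voiced_fraction,
                    },
                }
            )
        manifest["participants"].append(entry)

    cohort.labels_frame().to_csv(out / "labels.csv", index=False)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
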