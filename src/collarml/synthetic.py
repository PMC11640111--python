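"""Synthetic multi-rate collar sessions with labeled behavioral states.

Emulates a scripted canine evaluation session recorded by a smart collar:
a dog proceeds through a fixed protocol of 50 labeled states (exam steps,
noise distractions, exploration, ...) while six sensor modalities record
at their native rates — 3-axis IMU, audio level and ambient light at
100 Hz; temperature, humidity and pressure at 1 Hz.

Each state has a motion *motif*: a base level, a dominant oscillation
frequency/amplitude, a jerkiness multiplier feeding high-frequency
content, Gaussian sensor noise, and a probability per second of a loud
audio burst (dropped bowls, vacuum cleaners).  Environmental channels
drift slowly and carry almost no state information, mirroring an indoor
test room.

Generation is a pure function of ``(config, dog_id, seed)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

HIGH_RATE_HZ = 100.0
LOW_RATE_HZ = 1.0

#: modality -> (n_channels, rate_hz)
MODALITIES: dict[str, tuple[int, float]] = {
    "imu": (3, HIGH_RATE_HZ),
    "audio": (1, HIGH_RATE_HZ),
    "light": (1, HIGH_RATE_HZ),
    "temperature": (1, LOW_RATE_HZ),
    "humidity": (1, LOW_RATE_HZ),
    "pressure": (1, LOW_RATE_HZ),
}

AUDIO_BASELINE_DB = 45.0
AUDIO_BURST_DB = 30.0        # peak height of a loud-event spike
AUDIO_BURST_DECAY_S = 0.2    # exponential decay constant of a burst
ENV_NOISE_SD = 0.01

#: session-start levels for the slowly drifting channels (sensor units)
ENV_BASE = {"light": 300.0, "temperature": 21.0, "humidity": 45.0, "pressure": 1013.0}


class ConfigurationError(ValueError):
    """Raised for invalid catalogue or generation settings."""


class SessionFormatError(ValueError):
    """Raised when an on-disk session layout is malformed."""


@dataclass(frozen=True)
class StateMotif:
    """Per-state signal recipe for one labeled behavioral state."""

    state_name: str
    base: tuple[float, float, float] = (0.0, 0.0, 1.0)  # IMU rest levels (g)
    amplitude: float = 0.5          # oscillation amplitude (g)
    frequency: float = 2.0          # dominant oscillation frequency (Hz)
    noise_sd: float = 0.1           # Gaussian sensor noise SD (g)
    jerk_factor: float = 0.0        # multiplier on 7x-frequency content
    audio_burst_prob: float = 0.0   # P(loud event) per second
    env_drift_rate: float = 0.001   # units/s drift of environmental channels

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError(f"{self.state_name}: noise_sd must be >= 0")
        if self.frequency < 0:
            raise ConfigurationError(f"{self.state_name}: frequency must be >= 0")
        if not 0.0 <= self.audio_burst_prob <= 1.0:
            raise ConfigurationError(
                f"{self.state_name}: audio_burst_prob must be in [0, 1]")


@dataclass(frozen=True)
class StateEvent:
    state_name: str
    start_s: float
    end_s: float

    def __post_init__(self) -> None:
        if not self.start_s < self.end_s:
            raise ConfigurationError(
                f"event {self.state_name}: start {self.start_s} !< end {self.end_s}")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SensorStream:
    modality: str
    rate_hz: float
    timestamps: np.ndarray      # (n,) seconds, strictly increasing
    values: np.ndarray          # (n, n_channels)

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def validate(self) -> None:
        if self.modality not in MODALITIES:
            raise ConfigurationError(f"unknown modality {self.modality!r}")
        n_ch, rate = MODALITIES[self.modality]
        if self.values.shape != (len(self.timestamps), n_ch):
            raise SessionFormatError(
                f"{self.modality}: values shape {self.values.shape} does not match "
                f"{len(self.timestamps)} timestamps x {n_ch} channels")
        if self.rate_hz != rate:
            raise SessionFormatError(f"{self.modality}: rate must be {rate} Hz")
        if np.any(np.diff(self.timestamps) <= 0):
            raise SessionFormatError(f"{self.modality}: timestamps not strictly increasing")


@dataclass
class Session:
    """One dog's full labeled recording."""

    dog_id: str
    seed: int
    streams: dict[str, SensorStream]
    events: list[StateEvent]
    duration_s: float

    def validate(self) -> None:
        missing = set(MODALITIES) - set(self.streams)
        if missing:
            raise SessionFormatError(f"missing modalities: {sorted(missing)}")
        for s in self.streams.values():
            s.validate()
        prev_end = 0.0
        for ev in self.events:
            if ev.start_s < prev_end - 1e-9:
                raise SessionFormatError(f"events overlap or out of order at {ev.state_name}")
            if ev.end_s > self.duration_s + 1e-9:
                raise SessionFormatError(f"event {ev.state_name} past session end")
            prev_end = ev.end_s


# ---------------------------------------------------------------------------
# Default 50-state catalogue.
#
# The protocol mixes exam handling, noise distractions, dog/stranger
# distractions and free exploration.  Frequencies span 0.4-8 Hz so that
# states are separable by their dominant spectral peak; excitable states
# get high jerk factors, noise-distraction states get high audio burst
# probabilities.  Two deliberately confusable pairs share an IMU motif and
# differ only in audio ("Noise can shake" vs "Noise can seen", "Vacuum
# on-On leash" vs "Vacuum off-On leash"), so audio fusion carries real
# information.
# ---------------------------------------------------------------------------

_STATE_NAMES = [
    "Idle", "Leash on", "Walk to arena", "Explore-Enters Space", "Explore-Free roam",
    "Ignore dog", "Handler returns", "Sit command", "Down command", "Stay command",
    "Recall", "Heel walking", "Trot on leash", "Pace change", "Stairs up",
    "Stairs down", "Umbrella opens", "Noise can shake", "Noise can seen", "Food bowl drop",
    "Vacuum on-On leash", "Vacuum off-On leash", "Fan passes", "Fan stationary", "Cart passes",
    "Sees distraction dog", "Dog dist-Approach", "Dog dist-Dog returns to handler",
    "Sees Unusual Person", "Stranger greets", "Stranger pets", "Sees bat", "Rolly toy seen",
    "Rolly toy chase", "Tug play", "Fetch", "Jump on table", "Exam-load on table",
    "Dog on table", "Vet arrives", "Ear check", "Paw check", "Exam complete",
    "Unload from table", "Treat reward", "Water break", "Rest period", "Crate enter",
    "Crate rest", "Leash off",
]

# per-state (frequency Hz, amplitude g, noise_sd g, jerk, burst prob)
_MOTIF_PARAMS: dict[str, tuple[float, float, float, float, float]] = {}


def _build_default_params() -> None:
    # deterministic spread of frequencies over the catalogue, then
    # hand-tuned overrides for the behaviorally meaningful states
    for idx, name in enumerate(_STATE_NAMES):
        freq = 0.4 + 0.152 * idx          # 0.4 .. 7.85 Hz
        amp = 0.3 + 0.02 * (idx % 8)
        _MOTIF_PARAMS[name] = (freq, amp, 0.12, 0.0, 0.0)
    overrides = {
        # calm states: slow, small
        "Idle": (0.5, 0.05, 0.03, 0.0, 0.0),
        "Rest period": (0.45, 0.04, 0.03, 0.0, 0.0),
        "Crate rest": (0.4, 0.04, 0.03, 0.0, 0.0),
        "Ignore dog": (0.6, 0.08, 0.04, 0.0, 0.0),
        # locomotion: gait-band frequencies
        "Heel walking": (2.0, 0.6, 0.08, 0.2, 0.0),
        "Trot on leash": (3.2, 0.9, 0.08, 0.3, 0.0),
        "Explore-Enters Space": (1.4, 0.7, 0.10, 0.4, 0.0),
        "Explore-Free roam": (1.8, 0.8, 0.10, 0.4, 0.0),
        # excitable states: erratic, high jerkiness
        "Rolly toy chase": (5.5, 1.4, 0.25, 2.0, 0.0),
        "Tug play": (6.0, 1.5, 0.30, 2.5, 0.0),
        "Fetch": (5.0, 1.3, 0.25, 2.0, 0.0),
        "Jump on table": (4.5, 1.6, 0.20, 1.8, 0.0),
        # noise distractions: audio bursts; two pairs share IMU motifs and
        # differ only in burst probability (audio disambiguates them)
        "Noise can shake": (2.6, 0.5, 0.10, 0.5, 0.95),
        "Noise can seen": (2.6, 0.5, 0.10, 0.5, 0.0),
        "Vacuum on-On leash": (3.8, 0.6, 0.12, 0.6, 0.9),
        "Vacuum off-On leash": (3.8, 0.6, 0.12, 0.6, 0.0),
        "Food bowl drop": (2.2, 0.6, 0.12, 0.8, 0.9),
        "Umbrella opens": (3.0, 0.7, 0.12, 0.9, 0.6),
        "Fan passes": (7.5, 0.4, 0.08, 0.1, 0.3),
        # exam handling: slow, constrained
        "Exam-load on table": (1.0, 0.4, 0.10, 0.3, 0.0),
        "Dog on table": (0.8, 0.15, 0.06, 0.1, 0.0),
        "Vet arrives": (0.9, 0.2, 0.08, 0.1, 0.0),
        "Exam complete": (1.1, 0.3, 0.10, 0.2, 0.0),
    }
    _MOTIF_PARAMS.update(overrides)


_build_default_params()


def default_catalogue() -> list[StateMotif]:
    """The default 50-state motif catalogue, in protocol order."""
    cat = []
    for name in _STATE_NAMES:
        freq, amp, noise, jerk, burst = _MOTIF_PARAMS[name]
        cat.append(StateMotif(
            state_name=name,
            base=(0.0, 0.0, 1.0),
            amplitude=amp,
            frequency=freq,
            noise_sd=noise,
            jerk_factor=jerk,
            audio_burst_prob=burst,
            env_drift_rate=0.001,
        ))
    return cat


@dataclass
class CohortConfig:
    """Conditions for a cohort of synthetic evaluation sessions."""

    n_dogs: int = 20
    state_catalogue: list[StateMotif] = field(default_factory=default_catalogue)
    duration_range_s: tuple[float, float] = (8.0, 16.0)  # ~50 x 12 s = ten minutes
    noise_scale: float = 1.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dogs < 1:
            raise ConfigurationError("n_dogs must be >= 1")
        names = [m.state_name for m in self.state_catalogue]
        if len(names) != len(set(names)):
            raise ConfigurationError("state names must be unique within a catalogue")
        lo, hi = self.duration_range_s
        if lo <= 0 or hi < lo:
            raise ConfigurationError("duration range must be positive and ordered")


def _dog_seed(master_seed: int, dog_index: int) -> int:
    """Stable per-dog seed: a splittable counter scheme over the master seed."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(dog_index,))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def _imu_motif_signal(motif: StateMotif, t_rel: np.ndarray, noise_scale: float,
                      rng: np.random.Generator) -> np.ndarray:
    """IMU channel model: base + amplitude*sin(2*pi*f*t + phase_c)
    + jerk-scaled 7x-harmonic + Gaussian noise; per-channel phases fixed."""
    out = np.empty((len(t_rel), 3))
    for c in range(3):
        phase = 2.0 * np.pi * c / 3.0
        sig = motif.base[c] + motif.amplitude * np.sin(
            2.0 * np.pi * motif.frequency * t_rel + phase)
        if motif.jerk_factor > 0:
            sig = sig + motif.jerk_factor * 0.3 * motif.amplitude * np.sin(
                2.0 * np.pi * 7.0 * motif.frequency * t_rel + phase + 0.7)
        if motif.noise_sd > 0:
            sig = sig + rng.normal(0.0, motif.noise_sd * noise_scale, size=len(t_rel))
        out[:, c] = sig
    return out


def _audio_signal(motif: StateMotif, t_rel: np.ndarray, noise_scale: float,
                  rng: np.random.Generator) -> np.ndarray:
    sig = AUDIO_BASELINE_DB + rng.normal(0.0, 1.5 * noise_scale, size=len(t_rel))
    if motif.audio_burst_prob > 0 and len(t_rel):
        dur = t_rel[-1] - t_rel[0]
        n_sec = max(int(np.ceil(dur)), 1)
        burst_mask = rng.random(n_sec) < motif.audio_burst_prob
        for sec in np.flatnonzero(burst_mask):
            onset = t_rel[0] + sec + rng.uniform(0.0, 1.0)
            dt = t_rel - onset
            sig = sig + np.where(dt >= 0, AUDIO_BURST_DB * np.exp(-dt / AUDIO_BURST_DECAY_S), 0.0)
    return sig[:, None]


def generate_session(config: CohortConfig, dog_id: str, seed: int) -> Session:
    """Generate one labeled session; bit-identical for identical inputs."""
    if seed < 0:
        raise ConfigurationError("seed must be a nonnegative integer")
    if not config.state_catalogue:
        raise ConfigurationError("state catalogue is empty")
    rng = np.random.default_rng(seed)

    # protocol order: events enumerate the catalogue states sequentially
    durations = rng.uniform(*config.duration_range_s, size=len(config.state_catalogue))
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    events = [StateEvent(m.state_name, float(s), float(s + d))
              for m, s, d in zip(config.state_catalogue, starts, durations)]
    duration_s = float(starts[-1] + durations[-1])

    n_hi = int(np.floor(duration_s * HIGH_RATE_HZ)) + 1
    t_hi = np.arange(n_hi) / HIGH_RATE_HZ
    n_lo = int(np.floor(duration_s * LOW_RATE_HZ)) + 1
    t_lo = np.arange(n_lo) / LOW_RATE_HZ

    event_idx_hi = np.minimum(np.searchsorted(starts, t_hi, side="right") - 1,
                              len(events) - 1)
    imu = np.empty((n_hi, 3))
    audio = np.empty((n_hi, 1))
    for k, motif in enumerate(config.state_catalogue):
        mask = event_idx_hi == k
        t_rel = t_hi[mask] - starts[k]
        imu[mask] = _imu_motif_signal(motif, t_rel, config.noise_scale, rng)
        audio[mask] = _audio_signal(motif, t_rel, config.noise_scale, rng)

    # environmental channels: slow per-state drift integrated over the
    # session plus tiny measurement noise; near-constant indoors
    drift_rates = np.array([m.env_drift_rate for m in config.state_catalogue])

    def env_channel(t: np.ndarray, base: float, sign: float, scale: float) -> np.ndarray:
        idx = np.minimum(np.searchsorted(starts, t, side="right") - 1, len(events) - 1)
        cum_at_start = np.concatenate([[0.0], np.cumsum(drift_rates * durations)[:-1]])
        drift = cum_at_start[idx] + drift_rates[idx] * (t - starts[idx])
        noise = rng.normal(0.0, ENV_NOISE_SD * scale * config.noise_scale, size=len(t))
        return (base + sign * scale * drift + noise)[:, None]

    light = env_channel(t_hi, ENV_BASE["light"], +1.0, 50.0)
    temperature = env_channel(t_lo, ENV_BASE["temperature"], +1.0, 1.0)
    humidity = env_channel(t_lo, ENV_BASE["humidity"], -1.0, 2.0)
    pressure = env_channel(t_lo, ENV_BASE["pressure"], -1.0, 0.5)

    streams = {
        "imu": SensorStream("imu", HIGH_RATE_HZ, t_hi, imu),
        "audio": SensorStream("audio", HIGH_RATE_HZ, t_hi, audio),
        "light": SensorStream("light", HIGH_RATE_HZ, t_hi, light),
        "temperature": SensorStream("temperature", LOW_RATE_HZ, t_lo, temperature),
        "humidity": SensorStream("humidity", LOW_RATE_HZ, t_lo, humidity),
        "pressure": SensorStream("pressure", LOW_RATE_HZ, t_lo, pressure),
    }
    session = Session(dog_id=dog_id, seed=seed, streams=streams,
                      events=events, duration_s=duration_s)
    session.validate()
    return session


def generate_cohort(config: CohortConfig) -> list[Session]:
    """n_dogs sessions with per-dog seeds split off the master seed."""
    return [
        generate_session(config, dog_id=f"dog{idx:03d}", seed=_dog_seed(config.master_seed, idx))
        for idx in range(config.n_dogs)
    ]


# ---------------------------------------------------------------------------
# CSV session layout: one file per modality (time_s, ch1..chC) + events.csv
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.12g"


def export_session(session: Session, directory: str | Path) -> list[Path]:
    """Write one CSV per modality plus an events CSV; returns paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for name, stream in session.streams.items():
        df = pd.DataFrame(stream.values,
                          columns=[f"ch{i + 1}" for i in range(stream.n_channels)])
        df.insert(0, "time_s", stream.timestamps)
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False, float_format=_FLOAT_FMT)
        written.append(path)
    ev = pd.DataFrame([(e.state_name, e.start_s, e.end_s) for e in session.events],
                      columns=["state", "start_s", "end_s"])
    path = directory / "events.csv"
    ev.to_csv(path, index=False, float_format=_FLOAT_FMT)
    written.append(path)
    return written


def import_session(directory: str | Path, dog_id: str | None = None,
                   strict: bool = True) -> Session:
    """Read the CSV layout back into a Session.

    With ``strict=True`` out-of-order events are rejected; otherwise they
    are re-sorted by start time.
    """
    directory = Path(directory)
    streams = {}
    for name, (n_ch, rate) in MODALITIES.items():
        path = directory / f"{name}.csv"
        if not path.exists():
            raise SessionFormatError(f"missing modality file: {name} ({path})")
        df = pd.read_csv(path)
        expected = ["time_s"] + [f"ch{i + 1}" for i in range(n_ch)]
        if list(df.columns) != expected:
            raise SessionFormatError(
                f"{name}: expected columns {expected}, found {list(df.columns)}")
        t = df["time_s"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise SessionFormatError(f"{name}: non-monotone timestamps")
        streams[name] = SensorStream(name, rate, t, df[expected[1:]].to_numpy(float))
    ev_path = directory / "events.csv"
    if not ev_path.exists():
        raise SessionFormatError(f"missing events file ({ev_path})")
    ev = pd.read_csv(ev_path)
    starts = ev["start_s"].to_numpy(float)
    if np.any(np.diff(starts) < 0):
        if strict:
            raise SessionFormatError("events out of order on disk (strict mode)")
        ev = ev.sort_values("start_s")
    events = [StateEvent(str(r.state), float(r.start_s), float(r.end_s))
              for r in ev.itertuples(index=False)]
    duration = max(s.timestamps[-1] for s in streams.values())
    duration = max(duration, max(e.end_s for e in events))
    session = Session(dog_id=dog_id or directory.name, seed=-1,
                      streams=streams, events=events, duration_s=duration)
    session.validate()
    return session


def catalogue_to_dict(catalogue: list[StateMotif]) -> list[dict]:
    return [dataclasses.asdict(m) for m in catalogue]


def catalogue_from_dict(entries: list[dict]) -> list[StateMotif]:
    return [StateMotif(**{**e, "base": tuple(e["base"])}) for e in entries]
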