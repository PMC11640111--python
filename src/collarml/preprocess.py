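"""Turn labeled sessions into fixed-shape dataset variants.

Each labeled event is time-warped onto a common 500-sample grid by
piecewise-linear interpolation of every selected channel ("interpolate"
sampling); optionally each 500-row sequence is split into twenty
contiguous 25-row windows ("subsample" sampling).  Channels are selected
by fusion group: IMU (3 channels), IMU-Audio (4) or IMU-Audio-Env (8).
Streams are Z-normalized per modality over the whole session before
gridding.  Variants are the cross of sampling x state-space size (10 or
50) x fusion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .synthetic import Session, SensorStream, StateEvent

logger = logging.getLogger(__name__)

GRID_LENGTH = 500
WINDOW_LENGTH = 25
N_WINDOWS = GRID_LENGTH // WINDOW_LENGTH  # 20

#: fusion name -> ordered (modality, channel) selection.
#: Channel order is fixed: imu x,y,z; audio; light; temperature; humidity;
#: pressure.  Light samples at 100 Hz but belongs to the environmental group.
FUSIONS: dict[str, list[tuple[str, int]]] = {
    "imu": [("imu", 0), ("imu", 1), ("imu", 2)],
    "imu-audio": [("imu", 0), ("imu", 1), ("imu", 2), ("audio", 0)],
    "imu-audio-env": [("imu", 0), ("imu", 1), ("imu", 2), ("audio", 0),
                      ("light", 0), ("temperature", 0), ("humidity", 0),
                      ("pressure", 0)],
}

SAMPLINGS = ("interpolate", "subsample")
STATE_COUNTS = (10, 50)


class DataError(ValueError):
    """Raised when session data cannot satisfy an operation's contract."""


@dataclass(frozen=True)
class NormalizationStats:
    """Per-modality session mean and population SD used for Z-scores."""

    mean: dict[str, float]
    sd: dict[str, float]


@dataclass
class AlignedSequence:
    label: str
    values: np.ndarray            # (500, C)
    channel_names: list[str]
    provenance: tuple[str, int]   # (dog_id, event index)


@dataclass
class WindowSample:
    label: str
    values: np.ndarray            # (25, C)
    provenance: tuple[str, int]
    window_index: int             # 0..19


@dataclass
class DatasetVariant:
    sampling: str
    n_states: int
    fusion: str
    samples: list                 # AlignedSequence | WindowSample
    vocabulary: list[str]

    @property
    def n_channels(self) -> int:
        return len(FUSIONS[self.fusion])

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack into (X, y) with y as integer label indices."""
        X = np.stack([s.values for s in self.samples])
        index = {name: i for i, name in enumerate(self.vocabulary)}
        y = np.array([index[s.label] for s in self.samples])
        return X, y


@dataclass
class SplitDataset:
    train: list
    test: list
    ratio: float
    seed: int
    level: str                    # "event" | "window"
    vocabulary: list[str] = field(default_factory=list)

    def arrays(self, which: str = "train") -> tuple[np.ndarray, np.ndarray]:
        samples = self.train if which == "train" else self.test
        X = np.stack([s.values for s in samples])
        index = {name: i for i, name in enumerate(self.vocabulary)}
        y = np.array([index[s.label] for s in samples])
        return X, y


def _in_event(stream: SensorStream, event: StateEvent) -> np.ndarray:
    mask = (stream.timestamps >= event.start_s - 1e-12) & \
           (stream.timestamps <= event.end_s + 1e-12)
    return np.flatnonzero(mask)


def interpolate_event(session: Session, event: StateEvent, fusion: str,
                      event_index: int = 0) -> AlignedSequence:
    """Resample one event onto 500 equally spaced times spanning it.

    Piecewise-linear interpolation through the in-event samples of each
    selected channel; grid endpoints coincide with the event boundaries.
    A low-rate stream contributing a single in-event sample yields a
    constant channel at that value.
    """
    if fusion not in FUSIONS:
        raise ValueError(f"unknown fusion {fusion!r}; choose from {sorted(FUSIONS)}")
    grid = np.linspace(event.start_s, event.end_s, GRID_LENGTH)
    cols, names = [], []
    for modality, ch in FUSIONS[fusion]:
        stream = session.streams[modality]
        idx = _in_event(stream, event)
        if len(idx) == 0:
            raise DataError(
                f"no {modality} samples inside event {event.state_name!r} "
                f"[{event.start_s}, {event.end_s}]")
        t = stream.timestamps[idx]
        v = stream.values[idx, ch]
        if len(idx) == 1:
            if stream.rate_hz >= 100.0:
                raise DataError(
                    f"{modality}: fewer than 2 samples in event {event.state_name!r}")
            col = np.full(GRID_LENGTH, v[0])
        else:
            col = np.interp(grid, t, v)
        cols.append(col)
        names.append(f"{modality}_{'xyz'[ch] if modality == 'imu' else 'ch1'}")
    return AlignedSequence(label=event.state_name,
                           values=np.column_stack(cols),
                           channel_names=names,
                           provenance=(session.dog_id, event_index))


def znormalize_session(session: Session) -> tuple[Session, NormalizationStats]:
    """Z-score each modality over the entire session (population SD).

    All channels of a modality share one (mean, SD) pair, since they share
    units.  A constant modality (SD = 0) is set identically to zero and a
    warning is logged.
    """
    means, sds = {}, {}
    new_streams = {}
    for name, stream in session.streams.items():
        if stream.values.size == 0:
            raise DataError(f"{name}: empty stream")
        mu = float(stream.values.mean())
        sigma = float(stream.values.std())  # population SD
        means[name], sds[name] = mu, sigma
        if sigma == 0.0:
            logger.warning("modality %s is constant; Z-scores set to 0", name)
            vals = np.zeros_like(stream.values)
        else:
            vals = (stream.values - mu) / sigma
        new_streams[name] = SensorStream(name, stream.rate_hz,
                                         stream.timestamps.copy(), vals)
    normalized = Session(dog_id=session.dog_id, seed=session.seed,
                         streams=new_streams, events=list(session.events),
                         duration_s=session.duration_s)
    return normalized, NormalizationStats(mean=means, sd=sds)


def window_sequence(aligned: AlignedSequence) -> list[WindowSample]:
    """Split a 500-row sequence into 20 contiguous 25-row windows."""
    n = aligned.values.shape[0]
    if n % WINDOW_LENGTH:
        raise ValueError(f"row count {n} not divisible by {WINDOW_LENGTH}")
    return [
        WindowSample(label=aligned.label,
                     values=aligned.values[k * WINDOW_LENGTH:(k + 1) * WINDOW_LENGTH],
                     provenance=aligned.provenance,
                     window_index=k)
        for k in range(n // WINDOW_LENGTH)
    ]


def select_top_states(confusion, k: int) -> list[str]:
    """The k states with the highest per-class recall.

    Recall is the diagonal count over the row sum (0 for an empty row);
    ties break lexicographically by state name.
    """
    labels = list(confusion.labels)
    counts = np.asarray(confusion.counts, dtype=float)
    if k > len(labels):
        raise ValueError(f"k={k} exceeds {len(labels)} states")
    row_sums = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        recall = np.where(row_sums > 0, np.diag(counts) / row_sums, 0.0)
    order = sorted(range(len(labels)), key=lambda i: (-recall[i], labels[i]))
    return sorted(labels[i] for i in order[:k])


def build_dataset_variant(sessions: list[Session], sampling: str, n_states: int,
                          fusion: str, state_subset: list[str] | None = None,
                          min_per_state: int = 1) -> DatasetVariant:
    """Assemble one (sampling x state-count x fusion) variant.

    Sessions must already be Z-normalized.  Emits one aligned sequence per
    event ("interpolate") or its 20 windows ("subsample"), restricted to
    the requested state subset.
    """
    if sampling not in SAMPLINGS:
        raise ValueError(f"sampling must be one of {SAMPLINGS}")
    if n_states not in STATE_COUNTS:
        raise ValueError(f"n_states must be one of {STATE_COUNTS}")
    if n_states == 10:
        if state_subset is None or len(state_subset) != 10:
            raise ValueError("a 10-state subset is required when n_states=10")
        subset = sorted(state_subset)
    else:
        names = sorted({e.state_name for s in sessions for e in s.events})
        subset = names if state_subset is None else sorted(state_subset)
        if len(subset) != n_states:
            raise ValueError(f"found {len(subset)} states, expected {n_states}")
    subset_set = set(subset)

    samples: list = []
    per_state: dict[str, int] = {name: 0 for name in subset}
    for session in sessions:
        for idx, event in enumerate(session.events):
            if event.state_name not in subset_set:
                continue
            aligned = interpolate_event(session, event, fusion, event_index=idx)
            per_state[event.state_name] += 1
            if sampling == "interpolate":
                samples.append(aligned)
            else:
                samples.extend(window_sequence(aligned))
    short = {k: v for k, v in per_state.items() if v < min_per_state}
    if short:
        raise DataError(
            f"insufficient data for {sampling}/{n_states}/{fusion}: "
            f"states below {min_per_state} events: {sorted(short)}")
    return DatasetVariant(sampling=sampling, n_states=n_states, fusion=fusion,
                          samples=samples, vocabulary=subset)


def split_train_test(variant: DatasetVariant, ratio: float = 0.7,
                     seed: int = 0, level: str = "event") -> SplitDataset:
    """Stratified train/test split, default 70/30.

    At level="event" every window of one event lands on the same side (no
    leakage between train and test); level="window" splits windows
    independently.  Reproducible given the seed.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    if level not in ("event", "window"):
        raise ValueError("level must be 'event' or 'window'")
    rng = np.random.default_rng(seed)
    # group key: provenance for event-level, unique id for window-level
    groups: dict = {}
    for i, s in enumerate(variant.samples):
        key = s.provenance if level == "event" else (s.provenance, getattr(s, "window_index", i))
        groups.setdefault((s.label, key), []).append(i)

    by_label: dict[str, list] = {}
    for (label, key), idxs in groups.items():
        by_label.setdefault(label, []).append(idxs)

    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in sorted(by_label):
        grps = by_label[label]
        if len(grps) < 2:
            warnings.warn(f"label {label!r} has < 2 groups; assigned to train")
            for idxs in grps:
                train_idx.extend(idxs)
            continue
        order = rng.permutation(len(grps))
        n_train = int(round(len(grps) * ratio))
        n_train = min(max(n_train, 1), len(grps) - 1)
        for j, gi in enumerate(order):
            (train_idx if j < n_train else test_idx).extend(grps[gi])
    train_idx.sort()
    test_idx.sort()
    return SplitDataset(train=[variant.samples[i] for i in train_idx],
                        test=[variant.samples[i] for i in test_idx],
                        ratio=ratio, seed=seed, level=level,
                        vocabulary=list(variant.vocabulary))
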