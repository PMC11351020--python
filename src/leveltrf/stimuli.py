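"""Click trains and level-scheduled speech sessions.

Builds the two stimulus conditions of the experiment: pseudo-Poisson click
trains with alternating polarity, and sessions of 1-min speech trials whose
presentation level follows a randomized schedule over a fixed set of dB steps
(either constant within a trial, or changing every 5 s), with raised-cosine
crossfades at every level change.

Levels are stored as dB relative to the loudest step (absolute dBA
calibration is a hardware concern and is not represented here).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "AudioSignal",
    "ClickTrain",
    "Segment",
    "Trial",
    "TrialSchedule",
    "generate_click_train",
    "build_trial_schedule",
    "apply_level_gains",
    "gain_envelope",
    "render_clicks",
    "read_wav",
    "write_wav",
    "save_schedule",
    "load_schedule",
]

SPEECH_LEVELS = (36.0, 48.0, 60.0, 72.0)
CLICK_LEVELS = (36.0, 48.0, 60.0, 66.0)

#: rectangular click width in seconds (four samples at 44.1 kHz)
CLICK_DURATION = 91e-6


@dataclass
class AudioSignal:
    """A pressure waveform in arbitrary units."""

    samples: np.ndarray
    sample_rate: float = 44100.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("AudioSignal must be single channel")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("AudioSignal contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sample_rate


@dataclass
class ClickTrain:
    """Onsets and polarities of an alternating-polarity click train.

    Polarity convention: rarefaction = -1, condensation = +1; trains start
    with a rarefaction click.
    """

    onset_times: np.ndarray
    polarities: np.ndarray
    click_duration: float = CLICK_DURATION
    sample_rate: float = 44100.0

    def __post_init__(self) -> None:
        self.onset_times = np.asarray(self.onset_times, dtype=float)
        self.polarities = np.asarray(self.polarities, dtype=int)

    def __len__(self) -> int:
        return len(self.onset_times)

    def validate(self, min_ici: float | None = None) -> None:
        if len(self.onset_times) != len(self.polarities):
            raise ValueError("onsets and polarities differ in length")
        if len(self) == 0:
            return
        ici = np.diff(self.onset_times)
        if np.any(ici <= 0):
            raise ValueError("onsets must be strictly increasing")
        if min_ici is not None and np.any(ici < min_ici):
            raise ValueError(f"inter-click interval below {min_ici} s")
        if not np.all(np.abs(self.polarities) == 1):
            raise ValueError("polarities must be +/-1")
        if np.any(self.polarities[1:] == self.polarities[:-1]):
            raise ValueError("polarities must strictly alternate")


@dataclass(frozen=True)
class Segment:
    start: float
    end: float
    level: float


@dataclass(frozen=True)
class Trial:
    index: int
    kind: str  # "long" | "short"
    segments: tuple[Segment, ...]


@dataclass
class TrialSchedule:
    """Ordered trials with per-segment presentation levels (dB)."""

    trials: tuple[Trial, ...]
    levels: tuple[float, ...]

    @property
    def duration(self) -> float:
        return self.trials[-1].segments[-1].end if self.trials else 0.0

    def segments(self) -> list[Segment]:
        return [s for t in self.trials for s in t.segments]

    def per_level_duration(self) -> dict[float, float]:
        out = {lvl: 0.0 for lvl in self.levels}
        for seg in self.segments():
            out[seg.level] += seg.end - seg.start
        return out

    def level_at_samples(self, n_samples: int, rate: float) -> np.ndarray:
        """Per-sample level; NaN for samples beyond the schedule."""
        segs = self.segments()
        starts = np.array([s.start for s in segs])
        ends = np.array([s.end for s in segs])
        lvls = np.array([s.level for s in segs])
        t = np.arange(n_samples) / rate
        idx = np.searchsorted(starts, t, side="right") - 1
        idx = np.clip(idx, 0, len(segs) - 1)
        out = lvls[idx]
        out[(t < starts[0]) | (t >= ends[-1])] = np.nan
        return out

    def validate(self) -> None:
        prev_end = 0.0
        for trial in self.trials:
            for seg in trial.segments:
                if not np.isclose(seg.start, prev_end):
                    raise ValueError("segments must be contiguous")
                if seg.end <= seg.start:
                    raise ValueError("segment must have positive duration")
                prev_end = seg.end
        durs = self.per_level_duration().values()
        if len(self.levels) > 1 and not np.allclose(list(durs), np.mean(list(durs))):
            raise ValueError("per-level durations are unequal")


def generate_click_train(
    duration: float,
    rate: float = 44.0,
    min_ici: float = 0.015,
    sample_rate: float = 44100.0,
    seed: int = 0,
    click_duration: float = CLICK_DURATION,
) -> ClickTrain:
    """Pseudo-Poisson click train with a hard minimum inter-click interval.

    Inter-onset gaps are ``min_ici`` plus exponential jitter; the jitter parts
    are then rescaled so that exactly ``round(duration * rate)`` clicks fit in
    ``duration``. Rescaling acts on the jitter only, so the minimum interval
    is honored exactly.
    """
    if duration < 0:
        raise ValueError("duration must be non-negative")
    if rate * min_ici >= 1:
        raise ValueError(
            f"infeasible parameters: rate*min_ici = {rate * min_ici:.3f} >= 1"
        )
    n = int(round(duration * rate))
    if n == 0:
        return ClickTrain(np.array([]), np.array([], dtype=int), click_duration, sample_rate)
    onset_max = duration - click_duration
    base = (n - 1) * min_ici
    if base > onset_max:
        raise ValueError("duration too short for the requested click count")
    rng = np.random.default_rng(seed)
    jitter = rng.exponential(1.0, size=n)
    gaps = jitter * (onset_max - base) / jitter.sum()
    gaps[1:] += min_ici
    onsets = np.cumsum(gaps)
    polarities = np.where(np.arange(n) % 2 == 0, -1, 1)
    train = ClickTrain(onsets, polarities, click_duration, sample_rate)
    train.validate(min_ici=min_ici)
    return train


def build_trial_schedule(
    n_long: int,
    n_short: int,
    levels: tuple[float, ...] = SPEECH_LEVELS,
    seed: int = 0,
    trial_duration: float = 60.0,
    short_segment: float = 5.0,
) -> TrialSchedule:
    """Randomized session of long (constant-level) and short (level-hopping)
    trials, balanced so every level is presented for the same total time.

    Long trials hold one level for the full trial; the level multiset across
    long trials is balanced. Short trials split into ``trial_duration /
    short_segment`` segments, within which each level appears equally often
    (a shuffled balanced multiset per trial).
    """
    levels = tuple(float(v) for v in levels)
    if not levels:
        raise ValueError("levels must be non-empty")
    L = len(levels)
    n_seg = trial_duration / short_segment
    if abs(n_seg - round(n_seg)) > 1e-9:
        raise ValueError("trial_duration must be a multiple of short_segment")
    n_seg = int(round(n_seg))
    if n_short > 0 and n_seg % L:
        raise ValueError(
            f"short-trial segment count {n_seg} not divisible by {L} levels"
        )
    if n_long > 0 and n_long % L:
        raise ValueError(f"n_long = {n_long} not divisible by {L} levels")

    rng = np.random.default_rng(seed)
    kinds = ["long"] * n_long + ["short"] * n_short
    kinds = [kinds[i] for i in rng.permutation(len(kinds))]
    long_pool = list(np.repeat(levels, n_long // L if n_long else 0))
    long_pool = [long_pool[i] for i in rng.permutation(len(long_pool))]

    trials = []
    t = 0.0
    for idx, kind in enumerate(kinds):
        if kind == "long":
            segs = (Segment(t, t + trial_duration, long_pool.pop()),)
            t += trial_duration
        else:
            pool = np.repeat(levels, n_seg // L)
            pool = pool[rng.permutation(n_seg)]
            segs = []
            for lvl in pool:
                segs.append(Segment(t, t + short_segment, float(lvl)))
                t += short_segment
            segs = tuple(segs)
        trials.append(Trial(idx, kind, segs))
    schedule = TrialSchedule(tuple(trials), levels)
    schedule.validate()
    return schedule


def gain_envelope(
    schedule: TrialSchedule,
    n_samples: int,
    rate: float,
    reference_level: float | None = None,
    ramp: float = 0.5,
) -> np.ndarray:
    """Per-sample amplitude gain implied by a schedule.

    Steady-state gain within a segment is ``10**((level - reference)/20)``;
    at every change of level a raised-cosine crossfade of width ``ramp``,
    centered on the boundary, interpolates between the two gains.
    """
    if reference_level is None:
        reference_level = max(schedule.levels)
    segs = schedule.segments()
    min_seg = min(s.end - s.start for s in segs)
    if ramp >= min_seg:
        raise ValueError("ramp must be shorter than the shortest segment")
    lvl = schedule.level_at_samples(n_samples, rate)
    lvl_filled = lvl.copy()
    if np.any(np.isnan(lvl)):
        # samples beyond the schedule keep the last scheduled gain
        valid = ~np.isnan(lvl)
        if not valid.any():
            raise ValueError("schedule does not cover any audio samples")
        lvl_filled[~valid] = lvl[valid][-1]
    env = 10.0 ** ((lvl_filled - reference_level) / 20.0)

    half = ramp / 2.0
    for prev, nxt in zip(segs[:-1], segs[1:]):
        if prev.level == nxt.level:
            continue
        g1 = 10.0 ** ((prev.level - reference_level) / 20.0)
        g2 = 10.0 ** ((nxt.level - reference_level) / 20.0)
        i0 = int(np.ceil((prev.end - half) * rate))
        i1 = int(np.ceil((prev.end + half) * rate))
        i0c, i1c = max(i0, 0), min(i1, n_samples)
        if i0c >= i1c:
            continue
        tau = (np.arange(i0c, i1c) / rate - (prev.end - half)) / ramp
        env[i0c:i1c] = g1 + (g2 - g1) * (1 - np.cos(np.pi * tau)) / 2.0
    return env


def apply_level_gains(
    audio: AudioSignal,
    schedule: TrialSchedule,
    reference_level: float | None = None,
    ramp: float = 0.5,
) -> AudioSignal:
    """Scale audio according to the schedule's level steps (see
    :func:`gain_envelope`)."""
    n = len(audio.samples)
    if schedule.duration > audio.duration + 0.5 / audio.sample_rate:
        raise ValueError(
            f"schedule ({schedule.duration:.2f} s) longer than audio "
            f"({audio.duration:.2f} s)"
        )
    env = gain_envelope(schedule, n, audio.sample_rate, reference_level, ramp)
    return AudioSignal(audio.samples * env, audio.sample_rate)


def render_clicks(train: ClickTrain, total_duration: float | None = None) -> AudioSignal:
    """Render a click train as signed rectangular pulses."""
    fs = train.sample_rate
    width = max(int(round(train.click_duration * fs)), 1)
    if len(train) == 0:
        n = int(round((total_duration or 0.0) * fs))
        return AudioSignal(np.zeros(n), fs)
    train.validate()
    starts = np.round(train.onset_times * fs).astype(int)
    if np.any(np.diff(starts) < width):
        raise ValueError("clicks overlap at this sample rate")
    dur = total_duration if total_duration is not None else train.onset_times[-1] + train.click_duration
    n = max(int(np.ceil(dur * fs)), starts[-1] + width)
    sig = np.zeros(n)
    for start, pol in zip(starts, train.polarities):
        sig[start : start + width] = pol
    return AudioSignal(sig, fs)


# ---------------------------------------------------------------------------
# serialization

def write_wav(path, audio: AudioSignal) -> None:
    wavfile.write(path, int(audio.sample_rate), audio.samples.astype(np.float32))


def read_wav(path) -> AudioSignal:
    rate, data = wavfile.read(path)
    if data.dtype.kind == "i":
        data = data / float(np.iinfo(data.dtype).max)
    return AudioSignal(np.asarray(data, dtype=float), float(rate))


def schedule_to_frame(schedule: TrialSchedule) -> pd.DataFrame:
    rows = [
        {"trial": t.index, "kind": t.kind, "start": s.start, "end": s.end, "level": s.level}
        for t in schedule.trials
        for s in t.segments
    ]
    return pd.DataFrame(rows)


def schedule_from_frame(df: pd.DataFrame) -> TrialSchedule:
    trials = []
    for idx, grp in df.groupby("trial", sort=True):
        segs = tuple(
            Segment(r.start, r.end, r.level) for r in grp.sort_values("start").itertuples()
        )
        trials.append(Trial(int(idx), str(grp["kind"].iloc[0]), segs))
    levels = tuple(sorted(df["level"].unique()))
    return TrialSchedule(tuple(trials), levels)


def save_schedule(path, schedule: TrialSchedule) -> None:
    schedule_to_frame(schedule).to_csv(path, index=False)


def load_schedule(path) -> TrialSchedule:
    return schedule_from_frame(pd.read_csv(path))
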