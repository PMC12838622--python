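"""Core data types and file I/O for force/EMG time series, cue schedules and task logs.

All streams share a session-relative clock with ``t0 = 0`` at stream start.
Time series are stored as CSV (``time_s,value``) with a JSON sidecar holding
the sampling rate, units and channel label; task logs are JSON-lines event
files; session manifests are plain JSON.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeries",
    "CueSchedule",
    "SessionManifest",
    "Release",
    "Hit",
    "TaskLog",
    "FormatError",
    "DataError",
    "read_timeseries",
    "write_timeseries",
    "read_task_log",
    "write_task_log",
    "read_manifest",
    "write_manifest",
    "build_cue_schedule",
]

N_BINS = 16  #: release bins of the object-hit task

CONDITIONS = ("pct5", "pct50", "pct75")


class FormatError(ValueError):
    """A file does not conform to the expected on-disk layout."""


class DataError(ValueError):
    """A file parses but its contents violate a data invariant."""


@dataclass
class TimeSeries:
    """A uniformly sampled signal.

    Sample ``k`` is taken at ``t0 + k / rate`` seconds; timestamps are
    therefore strictly increasing by construction.  Missing samples are
    encoded as NaN and rejected by analysis operations.

    Parameters
    ----------
    t0 : float
        Session-relative start time in seconds.
    rate : float
        Sampling rate in Hz, strictly positive.
    values : ndarray
        Ordered real samples, length >= 1.
    units : str
        Unit label, e.g. ``"force-au"`` or ``"volts"``.
    channel : str
        Channel label, e.g. ``"grip-force"`` or ``"emg-fcr-right"``.
    """

    t0: float
    rate: float
    values: np.ndarray
    units: str = "au"
    channel: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise ValueError(f"rate must be > 0, got {self.rate}")
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D array")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Span between first and last sample, in seconds."""
        return (self.n - 1) / self.rate

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.rate

    def slice_time(self, t_start: float, t_end: float) -> "TimeSeries":
        """Samples with ``t_start <= t <= t_end`` (half-sample tolerance at the edges)."""
        eps = 0.5 / self.rate
        i0 = int(math.ceil((t_start - self.t0) * self.rate - eps))
        i1 = int(math.floor((t_end - self.t0) * self.rate + eps))
        i0 = max(i0, 0)
        i1 = min(i1, self.n - 1)
        if i1 < i0:
            raise ValueError(f"empty window [{t_start}, {t_end}]")
        return replace(self, t0=self.t0 + i0 / self.rate, values=self.values[i0 : i1 + 1])

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass(frozen=True)
class CueSchedule:
    """Ordered, non-overlapping contraction windows on the session clock."""

    cycles: tuple[tuple[float, float], ...]
    task_duration: float

    def __post_init__(self) -> None:
        prev_end = -math.inf
        for start, end in self.cycles:
            if end <= start:
                raise ValueError(f"window ({start}, {end}) has non-positive duration")
            if start < prev_end:
                raise ValueError("cue windows must be sorted and non-overlapping")
            prev_end = end

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)


def build_cue_schedule(n_cycles: int, on_s: float, off_s: float) -> CueSchedule:
    """Build the cued contraction/rest schedule.

    Window ``k`` occupies ``[k*(on_s+off_s), k*(on_s+off_s)+on_s]``; the task
    lasts ``n_cycles*(on_s+off_s)`` seconds.  The fatiguing-task protocol is
    ``build_cue_schedule(270, 1.0, 1.0)``: 270 one-second contractions with
    one-second rests, nine minutes in total.
    """
    if n_cycles < 0:
        raise ValueError("n_cycles must be >= 0")
    if on_s <= 0 or off_s <= 0:
        raise ValueError("on_s and off_s must be > 0")
    period = on_s + off_s
    cycles = tuple((k * period, k * period + on_s) for k in range(n_cycles))
    return CueSchedule(cycles=cycles, task_duration=n_cycles * period)


@dataclass(frozen=True)
class SessionManifest:
    """Pointers to one subject-condition session's data streams.

    ``condition`` is the fatiguing-task force level as a fraction of baseline
    MVC: ``pct5``, ``pct50`` or ``pct75``.  ``files`` maps stream names
    (``force``, ``mvc_post``, ``emg_fcr``, ``emg_ecr``, ``task_log``) to paths;
    streams may be absent.
    """

    subject_id: str
    condition: str
    round_index: int
    baseline_mvc: float
    files: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if not 1 <= self.round_index <= 3:
            raise ValueError("round_index must be in 1..3")
        if self.baseline_mvc <= 0:
            raise ValueError("baseline_mvc must be > 0")


@dataclass(frozen=True)
class Release:
    time: float
    bin: int
    speed: float

    def __post_init__(self) -> None:
        if not 0 <= self.bin < N_BINS:
            raise ValueError(f"bin must be in [0, {N_BINS - 1}], got {self.bin}")


@dataclass(frozen=True)
class Hit:
    time: float
    hand: str
    bin: int

    def __post_init__(self) -> None:
        if self.hand not in ("left", "right"):
            raise ValueError(f"hand must be 'left' or 'right', got {self.hand!r}")
        if not 0 <= self.bin < N_BINS:
            raise ValueError(f"bin must be in [0, {N_BINS - 1}], got {self.bin}")


@dataclass
class TaskLog:
    """Timestamped events of one object-hit assessment run.

    ``trajectories`` maps hand to an ``(x, y)`` pair of equally sampled
    TimeSeries in workspace centimetres.
    """

    releases: list[Release] = field(default_factory=list)
    hits: list[Hit] = field(default_factory=list)
    trajectories: dict[str, tuple[TimeSeries, TimeSeries]] = field(default_factory=dict)
    duration: float = 0.0

    def __post_init__(self) -> None:
        self.releases = sorted(self.releases, key=lambda r: r.time)
        self.hits = sorted(self.hits, key=lambda h: h.time)
        if self.duration:
            for h in self.hits:
                if h.time > self.duration + 1e-9:
                    raise DataError(f"hit at t={h.time} beyond task duration {self.duration}")


# ---------------------------------------------------------------------------
# time-series files


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def write_timeseries(ts: TimeSeries, path: str | Path) -> None:
    """Write ``time_s,value`` CSV plus a ``<name>.meta.json`` sidecar.

    Values round-trip bit-identically through :func:`read_timeseries`.
    """
    path = Path(path)
    df = pd.DataFrame({"time_s": ts.times(), "value": ts.values})
    # %.17g round-trips float64 exactly
    df.to_csv(path, index=False, float_format="%.17g")
    meta = {"rate": ts.rate, "units": ts.units, "channel": ts.channel, "t0": ts.t0}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_timeseries(path: str | Path) -> TimeSeries:
    """Read a CSV time series written by :func:`write_timeseries`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    for col in ("time_s", "value"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise DataError(f"{path}: time column is not strictly increasing")
    side = _sidecar(path)
    if not side.exists():
        raise FormatError(f"missing sidecar {side}")
    meta = json.loads(side.read_text())
    return TimeSeries(
        t0=float(meta.get("t0", t[0] if t.size else 0.0)),
        rate=float(meta["rate"]),
        values=df["value"].to_numpy(dtype=float),
        units=meta.get("units", "au"),
        channel=meta.get("channel", ""),
    )


# ---------------------------------------------------------------------------
# task-log files (JSON lines)


def write_task_log(log: TaskLog, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(json.dumps({"ev": "meta", "duration": log.duration}) + "\n")
        for r in log.releases:
            fh.write(json.dumps({"ev": "release", "t": r.time, "bin": r.bin, "speed": r.speed}) + "\n")
        for h in log.hits:
            fh.write(json.dumps({"ev": "hit", "t": h.time, "hand": h.hand, "bin": h.bin}) + "\n")
        for hand, (tx, ty) in sorted(log.trajectories.items()):
            times = tx.times()
            for t, x, y in zip(times, tx.values, ty.values):
                fh.write(json.dumps({"ev": "pos", "t": t, "hand": hand, "x": x, "y": y}) + "\n")


def read_task_log(path: str | Path) -> TaskLog:
    """Parse a JSON-lines event file into a :class:`TaskLog`.

    Events are sorted by time; position events are reassembled into per-hand
    trajectory TimeSeries (rate inferred from the median inter-sample step).
    An empty file yields an empty log.
    """
    path = Path(path)
    releases: list[Release] = []
    hits: list[Hit] = []
    pos: dict[str, list[tuple[float, float, float]]] = {}
    duration = 0.0
    with path.open() as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            try:
                ev = json.loads(line)
            except json.JSONDecodeError as exc:
                raise FormatError(f"{path}:{lineno}: invalid JSON") from exc
            kind = ev.get("ev")
            if kind == "meta":
                duration = float(ev.get("duration", 0.0))
            elif kind == "release":
                releases.append(Release(float(ev["t"]), int(ev["bin"]), float(ev["speed"])))
            elif kind == "hit":
                hits.append(Hit(float(ev["t"]), str(ev["hand"]), int(ev["bin"])))
            elif kind == "pos":
                pos.setdefault(str(ev["hand"]), []).append(
                    (float(ev["t"]), float(ev["x"]), float(ev["y"]))
                )
            else:
                raise FormatError(f"{path}:{lineno}: unknown event type {kind!r}")
    trajectories = {}
    for hand, samples in pos.items():
        samples.sort(key=lambda s: s[0])
        t = np.array([s[0] for s in samples])
        if t.size < 2:
            raise DataError(f"{path}: trajectory for {hand} has fewer than 2 samples")
        dt = np.median(np.diff(t))
        if dt <= 0:
            raise DataError(f"{path}: non-monotone trajectory timestamps for {hand}")
        rate = 1.0 / dt
        x = np.array([s[1] for s in samples])
        y = np.array([s[2] for s in samples])
        trajectories[hand] = (
            TimeSeries(t0=t[0], rate=rate, values=x, units="cm", channel=f"{hand}-x"),
            TimeSeries(t0=t[0], rate=rate, values=y, units="cm", channel=f"{hand}-y"),
        )
    return TaskLog(releases=releases, hits=hits, trajectories=trajectories, duration=duration)


# ---------------------------------------------------------------------------
# session manifests


def write_manifest(manifest: SessionManifest, path: str | Path) -> None:
    doc = {
        "subject_id": manifest.subject_id,
        "condition": manifest.condition,
        "round_index": manifest.round_index,
        "baseline_mvc": manifest.baseline_mvc,
        "files": dict(manifest.files),
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_manifest(path: str | Path) -> SessionManifest:
    doc = json.loads(Path(path).read_text())
    try:
        return SessionManifest(
            subject_id=str(doc["subject_id"]),
            condition=str(doc["condition"]),
            round_index=int(doc["round_index"]),
            baseline_mvc=float(doc["baseline_mvc"]),
            files={str(k): str(v) for k, v in doc.get("files", {}).items()},
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing manifest field {exc}") from exc
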