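"""Session container, domain types and bundle I/O.

All times are seconds on a single session clock starting at 0; bins are
half-open ``[t, t + dt)``.  A session bundle is an HDF5 file of arrays plus a
JSON manifest of events and metadata, with CSV mirrors of the spike and laser
tables for inspectability.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Atlas-style region labels accepted by default (Allen CCF groupings).
DEFAULT_REGIONS = (
    "PVZ", "BMA", "ACA", "AI", "BLA", "BST", "DORpm", "DORsm", "HPC", "ILA",
    "LA", "LS", "LZ", "MBmot", "MEZ", "OLF", "PALd", "PALm", "PIR", "PL",
    "SSp", "SSs", "STRd", "STRv", "VISC", "PTLp",
)


class FormatError(ValueError):
    """A session bundle is malformed."""


@dataclass
class TimeSeries:
    """A uniformly sampled continuous channel.

    Sample ``i`` occurs at ``t0 + i / sample_rate`` on the session clock.
    """

    values: np.ndarray
    sample_rate: float
    t0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be > 0")
        if self.t0 < 0:
            raise ValueError(f"stream {self.label!r}: t0 < 0 breaks the session clock")

    @property
    def duration(self) -> float:
        return self.values.size / self.sample_rate

    @property
    def end(self) -> float:
        return self.t0 + self.duration

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.sample_rate

    def index_at(self, t: float) -> int:
        """Index of the sample bin containing time ``t`` (half-open bins)."""
        return int(np.floor((t - self.t0) * self.sample_rate + 1e-9))

    def slice(self, start: float, end: float) -> np.ndarray:
        """Samples in ``[start, end)``, clipped to the series extent."""
        i0 = max(self.index_at(start), 0)
        i1 = min(self.index_at(end), self.values.size)
        return self.values[i0:i1]


@dataclass
class LaserEvent:
    """One optogenetic stimulation train."""

    onset: float
    duration: float
    pulse_frequency: float  # Hz; 5, 10 or 20 typical
    pulse_width: float = 0.02
    pattern: str = "continuous"  # or "5s_on_off"

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("laser duration must be > 0")
        if self.onset < 0:
            raise ValueError("laser onset must be >= 0")

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass
class SpikeTrain:
    """Curated spike times of one unit with its region label.

    ``baseline_rate`` is the mean rate lambda excluding the encoding-model
    test segments; it is filled by the curation stage and consumed by the
    Poisson inactivity and latency statistics.
    """

    unit_id: str
    region: str
    spike_times: np.ndarray
    baseline_rate: float | None = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size > 1 and np.any(np.diff(self.spike_times) <= 0):
            raise ValueError(f"unit {self.unit_id}: spike_times must be strictly increasing")
        if not self.region:
            raise ValueError("region must be non-empty")
        if self.baseline_rate is not None and self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass
class AnalysisWindow:
    """A labelled half-open time window ``[start, end)``."""

    start: float
    end: float
    role: str = "baseline"  # pre_laser | laser_onset | syncope_onset | stim | post_stim | baseline | control

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("window end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass
class SyncopeEvent:
    """Detected syncope bout: 50% band-power onset, 80% recovery offset."""

    onset: float
    offset: float | None = None
    band: tuple[float, float] = (8.0, 100.0)
    source: str = ""
    laser_onset: float | None = None

    def __post_init__(self) -> None:
        if self.offset is not None and self.offset <= self.onset:
            raise ValueError("syncope offset must exceed onset")


@dataclass
class BehaviorStreams:
    """Face-video feature streams on a common 30-Hz clock.

    ``movie_svd`` and ``motion_svd`` are component x time matrices (250
    components by default); ``keypoints`` holds the four pupil points
    (top, bottom, left, right) as a (4, 2, T) array with per-point
    confidences (4, T).
    """

    movie_svd: np.ndarray | None = None        # (C, T)
    motion_svd: np.ndarray | None = None       # (C, T)
    whisker_motion_svd: np.ndarray | None = None  # (>=10, T)
    keypoints: np.ndarray | None = None        # (4, 2, T)
    confidence: np.ndarray | None = None       # (4, T)
    eye_dark_pixel_count: np.ndarray | None = None  # (T,)
    sample_rate: float = 30.0
    t0: float = 0.0

    def n_frames(self) -> int:
        for a in (self.movie_svd, self.motion_svd, self.whisker_motion_svd):
            if a is not None:
                return a.shape[-1]
        if self.keypoints is not None:
            return self.keypoints.shape[-1]
        return 0

    def frame_times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames()) / self.sample_rate


@dataclass
class Session:
    """All per-recording streams bound to one session clock (0 = start)."""

    id: str
    streams: dict[str, TimeSeries] = field(default_factory=dict)
    units: list[SpikeTrain] = field(default_factory=list)
    behavior: BehaviorStreams = field(default_factory=BehaviorStreams)
    lasers: list[LaserEvent] = field(default_factory=list)
    syncope: list[SyncopeEvent] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def validate_regions(self, allowed=DEFAULT_REGIONS) -> None:
        bad = {u.region for u in self.units} - set(allowed)
        if bad:
            raise ValueError(f"unknown region labels: {sorted(bad)}")

    def duration(self) -> float:
        ends = [ts.end for ts in self.streams.values()]
        if self.units:
            ends += [u.spike_times[-1] if u.n_spikes else 0.0 for u in self.units]
        ends += [ev.end for ev in self.lasers]
        return max(ends, default=0.0)

    def lasers_at(self, pulse_frequency: float) -> list[LaserEvent]:
        return [ev for ev in self.lasers if ev.pulse_frequency == pulse_frequency]


# ---------------------------------------------------------------------------
# Bundle I/O
# ---------------------------------------------------------------------------

_BEHAVIOR_FIELDS = ("movie_svd", "motion_svd", "whisker_motion_svd",
                    "keypoints", "confidence", "eye_dark_pixel_count")


def save_session(session: Session, path: str | Path) -> None:
    """Write a session bundle: ``<id>.h5`` + ``<id>.manifest.json`` + CSVs.

    ``path`` is the HDF5 file path; sibling manifest and CSV files are
    derived from it.  Writes are deterministic: fixed field ordering and no
    HDF5 timestamps, so identical sessions produce byte-identical files.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w", track_order=False) as f:
        g = f.create_group("streams")
        for name in sorted(session.streams):
            ts = session.streams[name]
            sg = g.create_group(name)
            sg.create_dataset("values", data=ts.values, track_times=False)
            sg.attrs["sample_rate"] = ts.sample_rate
            sg.attrs["t0"] = ts.t0
            sg.attrs["label"] = ts.label
        g = f.create_group("units")
        for u in session.units:
            ug = g.create_group(u.unit_id)
            ug.create_dataset("spike_times", data=u.spike_times, track_times=False)
            ug.attrs["region"] = u.region
            if u.baseline_rate is not None:
                ug.attrs["baseline_rate"] = u.baseline_rate
        g = f.create_group("behavior")
        g.attrs["sample_rate"] = session.behavior.sample_rate
        g.attrs["t0"] = session.behavior.t0
        for name in _BEHAVIOR_FIELDS:
            arr = getattr(session.behavior, name)
            if arr is not None:
                g.create_dataset(name, data=np.asarray(arr, dtype=float),
                                 track_times=False)

    manifest = {
        "id": session.id,
        "lasers": [dataclasses.asdict(ev) for ev in session.lasers],
        "syncope": [
            {"onset": ev.onset, "offset": ev.offset, "band": list(ev.band),
             "source": ev.source, "laser_onset": ev.laser_onset}
            for ev in session.syncope
        ],
        "regions": sorted({u.region for u in session.units}),
        "metadata": session.metadata,
    }
    manifest_path = path.with_suffix("").with_suffix(".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    spike_rows = [
        {"unit_id": u.unit_id, "region": u.region, "spike_time_s": t}
        for u in session.units for t in u.spike_times
    ]
    pd.DataFrame(spike_rows, columns=["unit_id", "region", "spike_time_s"]).to_csv(
        path.with_suffix("").with_suffix(".spikes.csv"), index=False)
    laser_rows = [
        {"onset_s": ev.onset, "duration_s": ev.duration, "pulse_hz": ev.pulse_frequency,
         "pulse_width_s": ev.pulse_width, "pattern": ev.pattern}
        for ev in session.lasers
    ]
    pd.DataFrame(laser_rows, columns=["onset_s", "duration_s", "pulse_hz",
                                      "pulse_width_s", "pattern"]).to_csv(
        path.with_suffix("").with_suffix(".lasers.csv"), index=False)


def load_session(path: str | Path) -> Session:
    """Load a session bundle written by :func:`save_session`.

    Missing optional groups yield empty fields rather than errors; a
    malformed manifest raises :class:`FormatError` naming the offending key.
    """
    path = Path(path)
    manifest_path = path.with_suffix("").with_suffix(".manifest.json")
    if not manifest_path.exists():
        raise FormatError(f"missing manifest {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    for key in ("id", "lasers"):
        if key not in manifest:
            raise FormatError(f"manifest missing required key {key!r}")
    try:
        lasers = [LaserEvent(**ev) for ev in manifest["lasers"]]
    except TypeError as e:
        raise FormatError(f"malformed laser event in manifest: {e}") from e
    syncope = [
        SyncopeEvent(onset=ev["onset"], offset=ev.get("offset"),
                     band=tuple(ev.get("band", (8.0, 100.0))),
                     source=ev.get("source", ""), laser_onset=ev.get("laser_onset"))
        for ev in manifest.get("syncope", [])
    ]

    streams: dict[str, TimeSeries] = {}
    units: list[SpikeTrain] = []
    behavior = BehaviorStreams()
    with h5py.File(path, "r") as f:
        for name, sg in f.get("streams", {}).items():
            t0 = float(sg.attrs["t0"])
            if t0 < 0:
                raise FormatError(f"stream {name!r}: t0 < 0")
            streams[name] = TimeSeries(values=sg["values"][()],
                                       sample_rate=float(sg.attrs["sample_rate"]),
                                       t0=t0, label=str(sg.attrs.get("label", name)))
        for uid, ug in f.get("units", {}).items():
            units.append(SpikeTrain(
                unit_id=uid, region=str(ug.attrs["region"]),
                spike_times=ug["spike_times"][()],
                baseline_rate=(float(ug.attrs["baseline_rate"])
                               if "baseline_rate" in ug.attrs else None)))
        if "behavior" in f:
            bg = f["behavior"]
            kwargs = {name: bg[name][()] for name in _BEHAVIOR_FIELDS if name in bg}
            behavior = BehaviorStreams(sample_rate=float(bg.attrs.get("sample_rate", 30.0)),
                                       t0=float(bg.attrs.get("t0", 0.0)), **kwargs)
    units.sort(key=lambda u: u.unit_id)
    return Session(id=manifest["id"], streams=streams, units=units,
                   behavior=behavior, lasers=lasers, syncope=syncope,
                   metadata=manifest.get("metadata", {}))


# ---------------------------------------------------------------------------
# Event-aligned extraction
# ---------------------------------------------------------------------------

def cut_windows(series: TimeSeries, events: list[LaserEvent] | list[float],
                pre: float, post: float) -> list[np.ndarray]:
    """Extract one ``[-pre, +post)`` segment per event onset.

    Segments have exactly ``round((pre + post) * sample_rate)`` samples with
    the time axis relative to the event onset.  Events whose window falls
    outside the series extent are dropped with a warning.  Shifting both the
    series ``t0`` and all event onsets by the same amount leaves the output
    unchanged.
    """
    if pre < 0 or post < 0:
        raise ValueError("pre and post must be >= 0")
    n = int(round((pre + post) * series.sample_rate))
    out: list[np.ndarray] = []
    for ev in events:
        onset = ev.onset if hasattr(ev, "onset") else float(ev)
        i0 = int(round((onset - pre - series.t0) * series.sample_rate))
        if i0 < 0 or i0 + n > series.values.size:
            warnings.warn(f"event at {onset:.3f} s too close to series edge; dropped")
            continue
        out.append(series.values[i0:i0 + n].copy())
    return out


def window_times(pre: float, post: float, sample_rate: float) -> np.ndarray:
    """Relative time axis matching :func:`cut_windows` segments."""
    n = int(round((pre + post) * sample_rate))
    return -pre + np.arange(n) / sample_rate
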