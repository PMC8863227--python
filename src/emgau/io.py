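"""Readers and writers for the pipeline's on-disk formats.

Formats are deliberately plain text so sessions can be inspected and diffed:

* signal matrices   -- delimited text, one row per channel (or per sample;
                       orientation is auto-detected, the longer axis is time);
* electrode layouts -- CSV with columns ``channel,x,y,region``;
* AU tables         -- the OpenFace output CSV dialect (``frame``,
                       ``timestamp``, ``AUxx_r`` intensity columns, optional
                       ``success``/``confidence`` flags);
* trigger lists     -- CSV with columns ``label,onset,offset`` (seconds).

An optional EDF reader is provided through MNE when that package is
available; it is not required for any core functionality.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "LayoutError",
    "TimingError",
    "ElectrodeLayout",
    "Recording",
    "AUTrackSet",
    "TriggerEvent",
    "TriggerList",
    "STANDARD_AU_IDS",
    "default_layout",
    "read_signal_matrix",
    "write_signal_matrix",
    "read_electrode_layout",
    "write_electrode_layout",
    "read_openface_aus",
    "write_openface_aus",
    "read_triggers",
    "write_triggers",
    "read_edf",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class LayoutError(ValueError):
    """An electrode layout is inconsistent or does not match a recording."""


class TimingError(ValueError):
    """Timestamps or trigger times are inconsistent."""


#: The 17 action units whose intensities OpenFace reports (0-5 scale).
STANDARD_AU_IDS: tuple[int, ...] = (1, 2, 4, 5, 6, 7, 9, 10, 12, 14, 15, 17, 20, 23, 25, 26, 45)

_REGIONS = ("jaw", "cheek", "eye", "eyebrow")


@dataclass
class ElectrodeLayout:
    """2D positions of the electrodes in a normalized face frame.

    Coordinates live in the unit square: ``x`` runs laterally, ``y``
    vertically with larger values higher on the face.  Each channel carries
    a coarse anatomical region tag (jaw, cheek, eye or eyebrow).
    """

    channel_ids: np.ndarray  # (C,) int
    coords: np.ndarray  # (C, 2) float, in [0, 1]^2
    regions: tuple[str, ...]

    def __post_init__(self) -> None:
        self.channel_ids = np.asarray(self.channel_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        c = len(self.channel_ids)
        if self.coords.shape != (c, 2):
            raise LayoutError(f"coords shape {self.coords.shape} does not match {c} channels")
        if len(self.regions) != c:
            raise LayoutError("one region tag per channel required")
        if len(set(self.channel_ids.tolist())) != c:
            raise LayoutError("duplicate channel ids in layout")
        if np.any(self.coords < 0) or np.any(self.coords > 1):
            raise LayoutError("electrode coordinates must lie in [0, 1]^2")
        for r in self.regions:
            if r not in _REGIONS:
                raise LayoutError(f"unknown region tag {r!r}")

    def __len__(self) -> int:
        return len(self.channel_ids)

    def channels_in_region(self, region: str) -> np.ndarray:
        return self.channel_ids[np.array([r == region for r in self.regions])]


def default_layout() -> ElectrodeLayout:
    """The built-in 16-channel facial layout.

    Channels 0-2 sit over the upper jaw, 3-8 cover the cheek, 9-11 surround
    the eye and 12-15 sit above the eyebrow; the y coordinate increases in
    that order (jaw < cheek < eye < eyebrow).  The exact coordinates are
    fixed package constants chosen to spread the array over the right side
    of the face.
    """
    coords = np.array(
        [
            # jaw (0-2)
            (0.30, 0.10), (0.45, 0.08), (0.60, 0.12),
            # cheek (3-8)
            (0.30, 0.30), (0.45, 0.27), (0.62, 0.30),
            (0.35, 0.42), (0.52, 0.40), (0.70, 0.44),
            # eye (9-11)
            (0.45, 0.58), (0.60, 0.62), (0.75, 0.60),
            # eyebrow (12-15)
            (0.35, 0.80), (0.50, 0.84), (0.65, 0.82), (0.80, 0.78),
        ]
    )
    regions = ("jaw",) * 3 + ("cheek",) * 6 + ("eye",) * 3 + ("eyebrow",) * 4
    return ElectrodeLayout(np.arange(16), coords, regions)


@dataclass
class Recording:
    """A multichannel sEMG recording (microvolts, channels x time)."""

    samples: np.ndarray  # (C, T)
    fs: float
    channel_ids: np.ndarray
    layout: ElectrodeLayout
    stage: str = "raw"  # "raw" | "filtered"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.channel_ids = np.asarray(self.channel_ids, dtype=int)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2D channels x time matrix")
        if self.samples.shape[0] != len(self.channel_ids):
            raise LayoutError("row count does not match channel ids")
        if len(self.layout) != self.samples.shape[0]:
            raise LayoutError(
                f"{self.samples.shape[0]} channels but layout has {len(self.layout)} electrodes"
            )
        if self.stage not in ("raw", "filtered"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def copy_with(self, samples: np.ndarray, stage: str | None = None) -> "Recording":
        return Recording(samples, self.fs, self.channel_ids.copy(), self.layout, stage or self.stage)


@dataclass
class AUTrackSet:
    """Per-frame action-unit intensity tracks on the FACS 0-5 scale.

    Frames where the video tracker failed may hold NaN; downstream
    alignment drops those frames pairwise.
    """

    frame_rate: float
    tracks: dict[int, np.ndarray]
    timestamps: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tracks = {int(k): np.asarray(v, dtype=float) for k, v in self.tracks.items()}
        lengths = {len(v) for v in self.tracks.values()}
        if len(lengths) > 1:
            raise FormatError("AU tracks have unequal lengths")
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")
        n = self.n_frames
        if self.timestamps is None:
            self.timestamps = np.arange(n) / self.frame_rate
        else:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if len(self.timestamps) != n:
                raise TimingError("timestamps do not match track length")
        for v in self.tracks.values():
            finite = np.isfinite(v)
            np.clip(v, 0.0, 5.0, out=v, where=finite)

    @property
    def au_ids(self) -> tuple[int, ...]:
        return tuple(sorted(self.tracks))

    @property
    def n_frames(self) -> int:
        if not self.tracks:
            return 0
        return len(next(iter(self.tracks.values())))

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


@dataclass(frozen=True)
class TriggerEvent:
    label: str
    onset: float
    offset: float


@dataclass
class TriggerList:
    """Instruction events: (label, onset, offset) with strictly increasing onsets."""

    events: list[TriggerEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise TimingError("trigger onsets must be strictly increasing")
        for e in self.events:
            if e.offset <= e.onset:
                raise TimingError(f"event {e.label!r}: offset must exceed onset")

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def span(self) -> float:
        """End time of the last event (s); 0 for an empty list."""
        return self.events[-1].offset if self.events else 0.0


# ---------------------------------------------------------------------------
# signal matrices

def _load_delimited(path: str | Path) -> np.ndarray:
    text = Path(path).read_text()
    delim = "," if "," in text.splitlines()[0] else None
    try:
        return np.loadtxt(_io.StringIO(text), delimiter=delim, ndmin=2)
    except ValueError as exc:
        # recover the offending row for the error message
        for i, line in enumerate(text.splitlines()):
            fields = line.split(delim) if delim else line.split()
            for f in fields:
                try:
                    float(f)
                except ValueError:
                    raise FormatError(f"non-numeric cell at row {i}: {f!r}") from exc
        raise FormatError(str(exc)) from exc


def read_signal_matrix(path: str | Path, fs: float, layout: ElectrodeLayout) -> Recording:
    """Load a delimited-text signal matrix as a raw :class:`Recording`.

    Orientation is auto-detected: the longer axis is taken as time.
    """
    mat = _load_delimited(path)
    if mat.shape[0] > mat.shape[1]:
        mat = mat.T
    if mat.shape[0] != len(layout):
        raise LayoutError(
            f"file has {mat.shape[0]} channels but layout has {len(layout)} electrodes"
        )
    return Recording(mat, fs, layout.channel_ids.copy(), layout, stage="raw")


def write_signal_matrix(path: str | Path, rec: Recording) -> None:
    np.savetxt(path, rec.samples, delimiter=",", fmt="%.17g")


# ---------------------------------------------------------------------------
# electrode layouts

def read_electrode_layout(path: str | Path | None = None) -> ElectrodeLayout:
    """Read a ``channel,x,y,region`` CSV; with no path, return the default 16-channel layout."""
    if path is None:
        return default_layout()
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    required = {"channel", "x", "y", "region"}
    if not required.issubset(df.columns):
        raise FormatError(f"layout file must have columns {sorted(required)}")
    order = np.argsort(df["channel"].to_numpy())
    df = df.iloc[order]
    return ElectrodeLayout(
        df["channel"].to_numpy(int),
        df[["x", "y"]].to_numpy(float),
        tuple(s.strip() for s in df["region"]),
    )


def write_electrode_layout(path: str | Path, layout: ElectrodeLayout) -> None:
    df = pd.DataFrame(
        {
            "channel": layout.channel_ids,
            "x": layout.coords[:, 0],
            "y": layout.coords[:, 1],
            "region": list(layout.regions),
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# OpenFace AU tables

_AU_COL = re.compile(r"^AU(\d+)_r$")


def read_openface_aus(path: str | Path, max_gap: float = 0.5) -> AUTrackSet:
    """Parse an OpenFace output table into an :class:`AUTrackSet`.

    Rows flagged as tracking failures (``success == 0``) are removed; the
    resulting gaps are linearly interpolated when at most ``max_gap``
    seconds long, otherwise left as NaN runs that alignment later drops.
    """
    df = pd.read_csv(path)
    df.columns = [c.strip() for c in df.columns]
    au_cols = {c: int(_AU_COL.match(c).group(1)) for c in df.columns if _AU_COL.match(c)}
    if not au_cols:
        raise FormatError("no AU intensity columns (AUxx_r) found")

    if "timestamp" in df.columns and len(df) > 1:
        ts = df["timestamp"].to_numpy(float)
        if np.any(np.diff(ts) <= 0):
            raise TimingError("timestamps are not strictly increasing")
        frame_rate = 1.0 / float(np.median(np.diff(ts)))
    else:
        ts = None
        frame_rate = 30.0

    bad = np.zeros(len(df), dtype=bool)
    if "success" in df.columns and len(df):
        bad = df["success"].to_numpy(float) == 0

    tracks: dict[int, np.ndarray] = {}
    for col, au in au_cols.items():
        v = df[col].to_numpy(float).copy()
        v[bad] = np.nan
        tracks[au] = _interpolate_short_gaps(v, frame_rate, max_gap)
    return AUTrackSet(frame_rate=frame_rate, tracks=tracks, timestamps=ts)


def _interpolate_short_gaps(v: np.ndarray, frame_rate: float, max_gap: float) -> np.ndarray:
    """Linearly fill NaN runs no longer than ``max_gap`` seconds."""
    isnan = ~np.isfinite(v)
    if not isnan.any() or isnan.all():
        return v
    max_frames = int(round(max_gap * frame_rate))
    out = v.copy()
    idx = np.arange(len(v))
    # locate NaN runs
    starts = np.flatnonzero(isnan & ~np.roll(isnan, 1))
    if isnan[0]:
        starts = np.unique(np.concatenate([[0], starts]))
    for s in starts:
        e = s
        while e < len(v) and isnan[e]:
            e += 1
        if e - s <= max_frames and s > 0 and e < len(v):
            out[s:e] = np.interp(idx[s:e], [s - 1, e], [v[s - 1], v[e]])
    return out


def write_openface_aus(path: str | Path, aus: AUTrackSet) -> None:
    data = {"frame": np.arange(aus.n_frames) + 1, "timestamp": aus.timestamps}
    for au in aus.au_ids:
        data[f"AU{au:02d}_r"] = aus.tracks[au]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# triggers

def read_triggers(path: str | Path) -> TriggerList:
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"label", "onset", "offset"}.issubset(df.columns):
        raise FormatError("trigger file must have columns label,onset,offset")
    events = [
        TriggerEvent(str(r.label), float(r.onset), float(r.offset)) for r in df.itertuples()
    ]
    return TriggerList(events)


def write_triggers(path: str | Path, triggers: TriggerList) -> None:
    df = pd.DataFrame(
        {
            "label": [e.label for e in triggers],
            "onset": [e.onset for e in triggers],
            "offset": [e.offset for e in triggers],
        }
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# EDF (optional)

def read_edf(path: str | Path, layout: ElectrodeLayout | None = None,
             channel_map: dict[str, int] | None = None) -> Recording:
    """Read a multichannel EDF file via MNE (optional dependency).

    ``channel_map`` maps EDF channel labels to layout channel ids; with no
    map, EDF channel order is taken as layout order.
    """
    try:
        import mne  # noqa: PLC0415
    except ImportError as exc:  # pragma: no cover - depends on environment
        raise ImportError("EDF support requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE returns volts; recordings are in microvolts
    if layout is None:
        layout = default_layout()
    if channel_map is not None:
        order = [raw.ch_names.index(name) for name, _ in sorted(channel_map.items(), key=lambda kv: kv[1])]
        data = data[order]
    return Recording(data, float(raw.info["sfreq"]), layout.channel_ids.copy(), layout, "raw")
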