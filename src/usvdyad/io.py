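"""Readers, writers, configuration, and logging for the dyadic USV pipeline.

All on-disk formats are plain text or standard WAV:

* multichannel float32 WAV for array audio (one channel per microphone),
* CSV trajectory tables with columns ``frame, mouse_id, x_m, y_m,
  major_axis_m, minor_axis_m, heading_rad`` (the ellipse-per-frame output
  convention of video trackers such as Motr),
* CSV/XLSX per-vocalization feature tables compatible with the published
  supplementary layout (emitter, bandwidth, duration, ... , context),
* YAML session configuration, JSON run reports.

Conventions used throughout the package: positions in metres, arena origin
at the lower-left corner, 0-based frame indexing, times in seconds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

log = logging.getLogger("usvdyad")

DEFAULT_FRAME_RATE = 30.0  # camera trigger rate, frames/s
DEFAULT_SAMPLE_RATE = 250_000  # audio sampling rate, samples/s
DEFAULT_ARENA = (0.762, 0.762)  # cage width x length, metres

#: Canonical feature-table schema, in writing order.
FEATURE_COLUMNS = [
    "date",
    "voc_id",
    "emitter",
    "bandwidth_hz",
    "duration_ms",
    "high_freq_hz",
    "low_freq_hz",
    "mean_freq_hz",
    "slope_hz_per_s",
    "amplitude_mv",
    "context",
]

#: Mandatory columns for a readable feature table.
MANDATORY_FEATURE_COLUMNS = [
    "emitter",
    "bandwidth_hz",
    "duration_ms",
    "high_freq_hz",
    "low_freq_hz",
    "mean_freq_hz",
    "slope_hz_per_s",
]

# Case-insensitive aliases mapping supplementary-table style headers onto the
# canonical schema.  Matching strips whitespace, parenthesised units and
# punctuation, so "High frequency (Hz)" -> high_freq_hz.
_COLUMN_ALIASES = {
    "date": "date",
    "dateoftherecording": "date",
    "session": "date",
    "sessionid": "date",
    "vocid": "voc_id",
    "vocalizationnumber": "voc_id",
    "vocalisationnumber": "voc_id",
    "signalid": "voc_id",
    "emitter": "emitter",
    "bandwidth": "bandwidth_hz",
    "bandwidthhz": "bandwidth_hz",
    "duration": "duration_ms",
    "durationms": "duration_ms",
    "highfrequency": "high_freq_hz",
    "highfrequencyhz": "high_freq_hz",
    "highfreqhz": "high_freq_hz",
    "lowfrequency": "low_freq_hz",
    "lowfrequencyhz": "low_freq_hz",
    "lowfreqhz": "low_freq_hz",
    "meanfundamentalfrequency": "mean_freq_hz",
    "meanfundamentalfrequencyhz": "mean_freq_hz",
    "meanfrequency": "mean_freq_hz",
    "meanfreqhz": "mean_freq_hz",
    "slope": "slope_hz_per_s",
    "slopehzs": "slope_hz_per_s",
    "slopehzpers": "slope_hz_per_s",
    "amplitude": "amplitude_mv",
    "amplitudemv": "amplitude_mv",
    "context": "context",
}

TRACK_COLUMNS = [
    "frame",
    "mouse_id",
    "x_m",
    "y_m",
    "major_axis_m",
    "minor_axis_m",
    "heading_rad",
]


class SchemaError(ValueError):
    """A configuration or table does not match the documented schema."""


class FormatError(ValueError):
    """On-disk data is internally inconsistent (e.g. channel counts)."""


class DependencyError(FileNotFoundError):
    """A pipeline stage is missing an upstream artifact."""


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


# ---------------------------------------------------------------------------
# Geometry and session bundle
# ---------------------------------------------------------------------------


@dataclass
class MicArrayGeometry:
    """Positions of the microphones and the arena bounds.

    ``mic_positions`` is an (M, 2) array of (x, y) in metres; ``arena`` is
    (width, height) in metres with the origin at the lower-left corner.
    """

    mic_positions: np.ndarray
    arena: tuple[float, float] = DEFAULT_ARENA

    def __post_init__(self) -> None:
        self.mic_positions = np.asarray(self.mic_positions, dtype=float)
        if self.mic_positions.ndim != 2 or self.mic_positions.shape[1] != 2:
            raise SchemaError("mic_positions must be an (M, 2) array")
        if len(self.mic_positions) < 4:
            raise SchemaError("at least 4 microphones are required")
        if not np.all(np.isfinite(self.mic_positions)):
            raise SchemaError("microphone positions must be finite")
        if not (self.arena[0] > 0 and self.arena[1] > 0):
            raise SchemaError("arena dimensions must be positive")

    @property
    def n_mics(self) -> int:
        return len(self.mic_positions)


def default_geometry(n_mics: int = 8, arena: tuple[float, float] = DEFAULT_ARENA) -> MicArrayGeometry:
    """Eight microphones spaced around the arena perimeter (corners and
    edge midpoints), mirroring an array mounted on the cage walls."""
    w, h = arena
    corners = [(0.0, 0.0), (w, 0.0), (w, h), (0.0, h)]
    mids = [(w / 2, 0.0), (w, h / 2), (w / 2, h), (0.0, h / 2)]
    pts = []
    for c, m in zip(corners, mids):
        pts.append(c)
        pts.append(m)
    return MicArrayGeometry(np.array(pts[:n_mics]), arena)


@dataclass
class SessionBundle:
    """One recording session: array audio, trajectories, and geometry."""

    session_id: str
    audio: Path
    tracks: Path
    geometry: MicArrayGeometry
    frame_rate: float = DEFAULT_FRAME_RATE
    sample_rate: int = DEFAULT_SAMPLE_RATE


def read_wav(path: Path) -> tuple[int, np.ndarray]:
    """Read a (possibly multichannel) WAV file as (sample_rate, float array
    of shape (n_samples, n_channels))."""
    rate, data = wavfile.read(str(path))
    if data.ndim == 1:
        data = data[:, None]
    if data.dtype.kind == "i":  # integer PCM -> [-1, 1) floats
        data = data.astype(np.float64) / float(np.iinfo(data.dtype).max + 1)
    else:
        data = data.astype(np.float64)
    return rate, data


def write_wav(path: Path, sample_rate: int, data: np.ndarray) -> Path:
    data = np.asarray(data, dtype=np.float32)
    if data.ndim == 1:
        data = data[:, None]
    wavfile.write(str(path), int(sample_rate), data)
    return Path(path)


def read_tracks(path: Path):
    """Read a trajectory CSV into per-mouse tracks.

    Returns a dict mouse_id -> :class:`usvdyad.behavior.MouseTrack`.
    """
    from .behavior import MouseTrack  # local import to avoid a cycle

    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"trajectory table is missing columns: {missing}")
    tracks = {}
    for mouse_id, grp in df.groupby("mouse_id", sort=True):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy()
        if not np.array_equal(frames, np.arange(frames[0], frames[0] + len(frames))):
            raise FormatError(f"track for {mouse_id!r} has missing frames")
        tracks[str(mouse_id)] = MouseTrack(
            mouse_id=str(mouse_id),
            xy=grp[["x_m", "y_m"]].to_numpy(),
            major_axis=grp["major_axis_m"].to_numpy(),
            minor_axis=grp["minor_axis_m"].to_numpy(),
            heading=grp["heading_rad"].to_numpy(),
            frame_rate=DEFAULT_FRAME_RATE,
        )
    return tracks


def write_tracks(path: Path, tracks: dict) -> Path:
    rows = []
    for mouse_id, tr in tracks.items():
        for i in range(len(tr.xy)):
            rows.append(
                (i, mouse_id, tr.xy[i, 0], tr.xy[i, 1], tr.major_axis[i], tr.minor_axis[i], tr.heading[i])
            )
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False)
    return Path(path)


# ---------------------------------------------------------------------------
# Session configuration
# ---------------------------------------------------------------------------


def _normalise_header(name: str) -> str:
    out = []
    depth = 0
    for ch in str(name):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth = max(0, depth - 1)
        elif depth == 0 and ch.isalnum():
            out.append(ch.lower())
    return "".join(out)


def read_session(config_path: Path) -> SessionBundle:
    """Read and validate a YAML session configuration.

    Schema::

        session_id: <str>
        audio: <path to multichannel WAV>       # relative to the config file
        tracks: <path to trajectory CSV>
        sample_rate: 250000                     # optional
        frame_rate: 30                          # optional
        geometry:                               # optional, defaults to the
          arena: [0.762, 0.762]                 # 8-mic perimeter array
          mic_positions: [[x, y], ...]
    """
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError("config must be a YAML mapping")
    for key in ("session_id", "audio", "tracks"):
        if key not in cfg:
            raise SchemaError(f"config is missing required key {key!r}")
    base = config_path.parent
    audio = base / cfg["audio"]
    tracks = base / cfg["tracks"]
    frame_rate = float(cfg.get("frame_rate", DEFAULT_FRAME_RATE))
    sample_rate = int(cfg.get("sample_rate", DEFAULT_SAMPLE_RATE))
    geo_cfg = cfg.get("geometry", {})
    if geo_cfg and "mic_positions" in geo_cfg:
        geometry = MicArrayGeometry(
            np.asarray(geo_cfg["mic_positions"], dtype=float),
            tuple(geo_cfg.get("arena", DEFAULT_ARENA)),
        )
    else:
        geometry = default_geometry(arena=tuple(geo_cfg.get("arena", DEFAULT_ARENA)) if geo_cfg else DEFAULT_ARENA)

    if not audio.exists():
        raise SchemaError(f"audio file {audio} does not exist")
    if not tracks.exists():
        raise SchemaError(f"tracks file {tracks} does not exist")

    rate, data = read_wav(audio)
    if data.shape[1] != geometry.n_mics:
        raise FormatError(
            f"audio has {data.shape[1]} channels but geometry has {geometry.n_mics} microphones"
        )
    if rate != sample_rate:
        raise FormatError(f"audio sample rate {rate} != configured {sample_rate}")

    trk = pd.read_csv(tracks)
    missing = [c for c in TRACK_COLUMNS if c not in trk.columns]
    if missing:
        raise SchemaError(f"trajectory table is missing columns: {missing}")
    n_frames = int(trk.groupby("mouse_id")["frame"].count().max())
    # one frame of slack between the video clock and the audio clock
    if (n_frames - 1) * sample_rate / frame_rate > data.shape[0] + sample_rate / frame_rate:
        raise FormatError("trajectory is longer than the audio recording")

    return SessionBundle(
        session_id=str(cfg["session_id"]),
        audio=audio,
        tracks=tracks,
        geometry=geometry,
        frame_rate=frame_rate,
        sample_rate=sample_rate,
    )


def write_session_config(path: Path, session: SessionBundle) -> Path:
    cfg = {
        "session_id": session.session_id,
        "audio": str(Path(session.audio).name),
        "tracks": str(Path(session.tracks).name),
        "sample_rate": int(session.sample_rate),
        "frame_rate": float(session.frame_rate),
        "geometry": {
            "arena": [float(a) for a in session.geometry.arena],
            "mic_positions": [[float(x), float(y)] for x, y in session.geometry.mic_positions],
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return Path(path)


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


def read_feature_table(path: Path) -> pd.DataFrame:
    """Read a per-vocalization feature table (CSV or XLSX).

    Headers are matched case-insensitively, ignoring units in parentheses,
    onto the canonical schema (:data:`FEATURE_COLUMNS`).  Units are taken
    as-is (Hz, ms, Hz/s, mV).  Rows with an empty emitter are labelled
    ``"unassigned"``.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    rename = {}
    for col in df.columns:
        key = _normalise_header(col)
        if key in _COLUMN_ALIASES:
            rename[col] = _COLUMN_ALIASES[key]
    df = df.rename(columns=rename)
    missing = [c for c in MANDATORY_FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table is missing columns: {missing}")
    for col in FEATURE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[FEATURE_COLUMNS]
    df["emitter"] = df["emitter"].fillna("unassigned").astype(str)
    df.loc[df["emitter"].str.strip() == "", "emitter"] = "unassigned"
    return df


def write_feature_table(table: pd.DataFrame, path: Path) -> Path:
    """Write a feature table as CSV in canonical column order.

    Numeric values are written at full precision (repr round-trip), so the
    output is byte-identical for identical input.
    """
    df = table.copy()
    for col in FEATURE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    bad = df["bandwidth_hz"].notna() & (
        np.abs(df["bandwidth_hz"] - (df["high_freq_hz"] - df["low_freq_hz"])) > 1e-6
    )
    if bad.any():
        raise FormatError("bandwidth_hz must equal high_freq_hz - low_freq_hz")
    df[FEATURE_COLUMNS].to_csv(path, index=False)
    return Path(path)
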