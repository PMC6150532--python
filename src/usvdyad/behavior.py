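"""Trajectory-based social-behavior classification.

Each frame of a dyadic recording is screened for three behavioral contexts:

* ``following`` — the mouse is pursuing its partner,
* ``followed`` — the mouse is being pursued,
* ``not_close`` — the two body centers are >= 15 cm apart.

Pursuit requires four simultaneous criteria: the pursuer is behind the
leader, movement directions are aligned within 25 degrees, centroid
distance is under 5 cm, and both animals move faster than 20 cm/s.  Any
context must hold for at least 10 consecutive frames (at 30 frames/s) to
count as a bout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

# Classification thresholds (defaults from the study design; all exposed).
ANGLE_DEG = 25.0  # max angle between movement directions
FOLLOW_DIST_M = 0.05  # max centroid distance during pursuit
SPEED_CMS = 20.0  # min speed of both animals during pursuit
NOT_CLOSE_M = 0.15  # min centroid distance for "not close"
MIN_FRAMES = 10  # min consecutive frames for any bout
SMOOTH_FRAMES = 5  # moving-average window for velocity
MIN_SPEED_FOR_DIRECTION = 1.0  # cm/s; below this, direction is undefined

CONTEXTS = ("following", "followed", "not_close")


@dataclass
class MouseTrack:
    """Per-frame tracking ellipse for one mouse at a fixed frame rate."""

    mouse_id: str
    xy: np.ndarray  # (T, 2) centroid, metres
    major_axis: np.ndarray  # (T,) metres
    minor_axis: np.ndarray  # (T,) metres
    heading: np.ndarray  # (T,) radians in (-pi, pi]
    frame_rate: float = 30.0

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.major_axis = np.asarray(self.major_axis, dtype=float)
        self.minor_axis = np.asarray(self.minor_axis, dtype=float)
        self.heading = np.asarray(self.heading, dtype=float)
        if np.any(self.major_axis <= 0) or np.any(self.minor_axis <= 0):
            raise ValueError("ellipse axes must be positive")
        if np.any(self.heading <= -np.pi) or np.any(self.heading > np.pi):
            raise ValueError("headings must lie in (-pi, pi]")

    def __len__(self) -> int:
        return len(self.xy)


@dataclass
class BehaviorInterval:
    """A bout of one context for one mouse, frames inclusive."""

    mouse_id: str
    kind: str
    start_frame: int
    end_frame: int
    partner_id: str | None = None

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


def nose_position(track: MouseTrack, frame: int | np.ndarray) -> np.ndarray:
    """Nose = centroid displaced half the major axis along the heading."""
    half = 0.5 * track.major_axis[frame]
    h = track.heading[frame]
    return track.xy[frame] + np.stack([half * np.cos(h), half * np.sin(h)], axis=-1)


def kinematics(track: MouseTrack) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame speed (cm/s) and movement direction (radians).

    Velocity is the central difference of the centroid (one-sided at the
    ends), smoothed with a 5-frame moving average.  Direction is the angle
    of the smoothed velocity and is NaN wherever speed < 1 cm/s.
    """
    if len(track) < 2:
        raise ValueError("kinematics needs at least 2 frames")
    v = np.gradient(track.xy, axis=0) * track.frame_rate  # m/s
    v = uniform_filter1d(v, SMOOTH_FRAMES, axis=0, mode="nearest")
    speed = np.hypot(v[:, 0], v[:, 1]) * 100.0  # cm/s
    direction = np.arctan2(v[:, 1], v[:, 0])
    direction[speed < MIN_SPEED_FOR_DIRECTION] = np.nan
    return speed, direction


def _angle_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d = np.abs(a - b) % (2 * np.pi)
    return np.minimum(d, 2 * np.pi - d)


def classify_frames(
    track_a: MouseTrack,
    track_b: MouseTrack,
    angle_deg: float = ANGLE_DEG,
    follow_dist_m: float = FOLLOW_DIST_M,
    speed_cms: float = SPEED_CMS,
    not_close_m: float = NOT_CLOSE_M,
) -> dict[str, np.ndarray]:
    """Per-frame candidate flags for the three contexts.

    Returns a dict with boolean arrays ``a_follows_b``, ``b_follows_a``
    and ``not_close``.  "X follows Y" requires X behind Y (the vector from
    X's centroid to Y's centroid projects positively onto Y's movement
    direction and the reverse projection test fails), aligned directions,
    close centroids and both animals fast.
    """
    if len(track_a) != len(track_b):
        raise ValueError("tracks must have equal length")
    if track_a.frame_rate != track_b.frame_rate:
        raise ValueError("tracks must share a frame rate")

    speed_a, dir_a = kinematics(track_a)
    speed_b, dir_b = kinematics(track_b)
    delta = track_b.xy - track_a.xy  # a -> b
    dist = np.hypot(delta[:, 0], delta[:, 1])

    with np.errstate(invalid="ignore"):
        aligned = _angle_diff(dir_a, dir_b) < np.deg2rad(angle_deg)
        aligned &= np.isfinite(dir_a) & np.isfinite(dir_b)
        close = dist < follow_dist_m
        fast = (speed_a > speed_cms) & (speed_b > speed_cms)
        # projection of (follower -> leader) onto leader's movement direction
        proj_on_a = -(delta[:, 0] * np.cos(dir_a) + delta[:, 1] * np.sin(dir_a))
        proj_on_b = delta[:, 0] * np.cos(dir_b) + delta[:, 1] * np.sin(dir_b)
        b_behind_a = (proj_on_a > 0) & (proj_on_b <= 0)
        a_behind_b = (proj_on_b > 0) & (proj_on_a <= 0)

    common = aligned & close & fast
    return {
        "b_follows_a": common & b_behind_a,
        "a_follows_b": common & a_behind_b,
        "not_close": dist >= not_close_m,
    }


def extract_bouts(flags: np.ndarray, min_frames: int = MIN_FRAMES) -> list[tuple[int, int]]:
    """Maximal runs of True of length >= min_frames, as (start, end) inclusive."""
    flags = np.asarray(flags, dtype=bool)
    if flags.size == 0:
        return []
    padded = np.concatenate([[False], flags, [False]]).astype(np.int8)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return [(int(s), int(e)) for s, e in zip(starts, ends) if e - s + 1 >= min_frames]


def classify_session(
    track_a: MouseTrack,
    track_b: MouseTrack,
    min_frames: int = MIN_FRAMES,
    **kwargs,
) -> list[BehaviorInterval]:
    """All behavior intervals for both mice in one session.

    Every "B follows A" run yields a ``following`` interval for B and an
    identically-framed ``followed`` interval for A (and symmetrically).
    ``not_close`` intervals are emitted for both mice.
    """
    flags = classify_frames(track_a, track_b, **kwargs)
    ida, idb = track_a.mouse_id, track_b.mouse_id
    intervals: list[BehaviorInterval] = []
    for s, e in extract_bouts(flags["b_follows_a"], min_frames):
        intervals.append(BehaviorInterval(idb, "following", s, e, ida))
        intervals.append(BehaviorInterval(ida, "followed", s, e, idb))
    for s, e in extract_bouts(flags["a_follows_b"], min_frames):
        intervals.append(BehaviorInterval(ida, "following", s, e, idb))
        intervals.append(BehaviorInterval(idb, "followed", s, e, ida))
    for s, e in extract_bouts(flags["not_close"], min_frames):
        intervals.append(BehaviorInterval(ida, "not_close", s, e, idb))
        intervals.append(BehaviorInterval(idb, "not_close", s, e, ida))

    # a frame under 5 cm apart cannot simultaneously be >= 15 cm apart
    follow_frames: dict[str, set[int]] = {}
    for iv in intervals:
        if iv.kind in ("following", "followed"):
            follow_frames.setdefault(iv.mouse_id, set()).update(range(iv.start_frame, iv.end_frame + 1))
    for iv in intervals:
        if iv.kind == "not_close":
            overlap = follow_frames.get(iv.mouse_id, set()) & set(range(iv.start_frame, iv.end_frame + 1))
            assert not overlap, "frame classified both as pursuit and not-close"
    return intervals


def label_vocalizations(
    features: pd.DataFrame,
    intervals: list[BehaviorInterval],
    onset_frames: np.ndarray,
    emitters: np.ndarray | None = None,
) -> pd.DataFrame:
    """Attach a behavioral context to each assigned vocalization.

    A record's context is the kind of the emitter's interval containing the
    signal onset frame (precedence following > followed > not_close should
    overlaps ever occur); records outside every interval get ``"other"``;
    unassigned records get no context.
    """
    out = features.copy()
    emit = out["emitter"].to_numpy() if emitters is None else np.asarray(emitters)
    contexts = np.array(["other"] * len(out), dtype=object)
    priority = {"following": 0, "followed": 1, "not_close": 2}
    best = np.full(len(out), 99)
    for iv in sorted(intervals, key=lambda iv: priority[iv.kind]):
        hit = (
            (emit == iv.mouse_id)
            & (onset_frames >= iv.start_frame)
            & (onset_frames <= iv.end_frame)
            & (priority[iv.kind] < best)
        )
        contexts[hit] = iv.kind
        best[hit] = np.minimum(best[hit], priority[iv.kind])
    contexts[emit == "unassigned"] = ""
    out["context"] = contexts
    return out


def context_table(
    features: pd.DataFrame,
    intervals: list[BehaviorInterval] | None = None,
    onset_frames: np.ndarray | None = None,
    sex_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-sex, per-context tallies of bouts-with-vocalization and signals.

    Returns a table indexed by (sex, context) with columns ``n_instances``
    (bouts during which the mouse emitted >= 1 signal; only available when
    ``intervals`` and ``onset_frames`` are given) and ``n_signals``.
    """
    assigned = (features["emitter"] != "unassigned").to_numpy()
    df = features[assigned]
    if sex_of is None:
        sex_of = {e: e for e in df["emitter"].unique()}
    onsets = None
    if onset_frames is not None:
        onsets = np.asarray(onset_frames)
        if len(onsets) == len(features):
            onsets = onsets[assigned]
    rows = []
    for sex in sorted(set(sex_of.values())):
        mice = {m for m, s in sex_of.items() if s == sex}
        sub = df[df["emitter"].isin(mice)]
        for ctx in CONTEXTS:
            n_signals = int((sub["context"] == ctx).sum())
            n_instances = np.nan
            if intervals is not None and onsets is not None:
                n_instances = 0
                for iv in intervals:
                    if iv.kind != ctx or iv.mouse_id not in mice:
                        continue
                    ons = onsets[(df["emitter"] == iv.mouse_id).to_numpy()]
                    if np.any((ons >= iv.start_frame) & (ons <= iv.end_frame)):
                        n_instances += 1
            rows.append((sex, ctx, n_instances, n_signals))
    return pd.DataFrame(rows, columns=["sex", "context", "n_instances", "n_signals"]).set_index(
        ["sex", "context"]
    )
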