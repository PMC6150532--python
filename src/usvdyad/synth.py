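"""Ground-truth-labelled synthetic data for the dyadic USV pipeline.

The raw recordings behind this kind of study are multichannel ultrasound
plus overhead video of two freely moving mice.  This module generates the
analysis-ready equivalents with known ground truth:

* two-mouse trajectories containing scripted following / followed /
  not-close bouts that the behavior classifier recovers exactly,
* linear-FM ultrasonic chirps (10-30 ms, 30-110 kHz) as emitted waveforms,
* 8-channel array audio rendered with free-field propagation (straight-line
  delay at 343 m/s, 1/r amplitude, optional white noise) from point sources
  at the emitting mouse's nose,
* per-vocalization feature tables with the sex structure reported for real
  dyads (males vocalize ~7x more; male bandwidths larger, male slopes more
  negative), used as the test bed for the Monte-Carlo statistics.

Scripted bouts work by running both mice on a circle at constant speed and
switching the angular gap between them instantaneously at bout boundaries
(the trailing edge always jumps *forward*, so movement direction is never
reversed).  Distance is then the only criterion that changes state, and it
is computed from raw positions without smoothing, so candidate frames match
the script exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import MouseTrack
from .io import DEFAULT_ARENA, DEFAULT_FRAME_RATE, DEFAULT_SAMPLE_RATE, MicArrayGeometry

SPEED_OF_SOUND = 343.0  # m/s

# Circle-running geometry for scripted trajectories.  Chord distances (m)
# between the two mice for each segment kind; the circle radius is chosen so
# the "other" gap (7.5 cm) sits between the 5 cm pursuit and 15 cm not-close
# thresholds and tangent directions stay aligned within 25 degrees.
_CIRCLE_RADIUS = 0.25
_RUN_SPEED = 0.25  # m/s along the circle
_CHORD = {"following": 0.04, "not_close": 0.16, "other": 0.075}


class ValidationError(ValueError):
    pass


@dataclass
class EmissionEvent:
    """One ultrasonic chirp emitted by one mouse."""

    emitter_id: str
    onset_s: float
    duration_s: float
    f_start_hz: float
    f_end_hz: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValidationError("onset must be >= 0")
        if self.duration_s <= 0:
            raise ValidationError("duration must be > 0")
        for f in (self.f_start_hz, self.f_end_hz):
            if not (30_000 <= f <= 110_000):
                raise ValidationError("chirp frequencies must lie in [30, 110] kHz")


@dataclass
class BoutSpec:
    kind: str  # following | not_close | other
    start_frame: int
    n_frames: int
    leader_id: str | None = None  # for "following": the mouse being followed

    def __post_init__(self) -> None:
        if self.kind not in ("following", "not_close", "other"):
            raise ValidationError(f"unknown bout kind {self.kind!r}")
        if self.n_frames < 1:
            raise ValidationError("bouts need n_frames >= 1")


@dataclass
class BehaviorScript:
    """Ordered, non-overlapping bout specs over a session of n_frames."""

    bouts: list[BoutSpec]
    n_frames: int

    def __post_init__(self) -> None:
        prev_end = -1
        for b in sorted(self.bouts, key=lambda b: b.start_frame):
            if b.start_frame <= prev_end:
                raise ValidationError("bouts overlap")
            if b.start_frame + b.n_frames > self.n_frames:
                raise ValidationError("bout extends past the session")
            prev_end = b.start_frame + b.n_frames - 1


def _chord_to_angle(chord: float, r: float = _CIRCLE_RADIUS) -> float:
    return 2.0 * np.arcsin(chord / (2.0 * r))


def simulate_trajectories(
    script: BehaviorScript,
    frame_rate: float = DEFAULT_FRAME_RATE,
    arena: tuple[float, float] = DEFAULT_ARENA,
    seed: int = 0,
    mouse_ids: tuple[str, str] = ("male", "female"),
) -> tuple[dict[str, MouseTrack], pd.DataFrame]:
    """Generate two tracks realising a behavior script, plus frame labels.

    Returns ``(tracks, labels)`` where labels has one row per (frame, mouse)
    with the scripted context (``following``/``followed``/``not_close``/
    ``other``).
    """
    rng = np.random.default_rng(seed)
    n = script.n_frames
    if n < 2:
        raise ValidationError("need at least 2 frames")
    r = _CIRCLE_RADIUS
    if 2 * r + 0.10 > min(arena):
        raise ValidationError("arena too small for the scripted circle")
    cx, cy = arena[0] / 2.0, arena[1] / 2.0
    omega = _RUN_SPEED / r / frame_rate  # radians per frame
    theta0 = rng.uniform(0, 2 * np.pi)

    id_a, id_b = mouse_ids
    # per-frame signed angular gap phi = theta_a - theta_b (>0: b trails a)
    phi = np.full(n, _chord_to_angle(_CHORD["other"]))
    labels_a = np.array(["other"] * n, dtype=object)
    labels_b = np.array(["other"] * n, dtype=object)
    for b in script.bouts:
        sl = slice(b.start_frame, b.start_frame + b.n_frames)
        if b.kind == "following":
            leader = b.leader_id or id_a
            if leader not in mouse_ids:
                raise ValidationError(f"unknown leader {leader!r}")
            gap = _chord_to_angle(_CHORD["following"])
            if leader == id_a:
                phi[sl] = gap
                labels_a[sl], labels_b[sl] = "followed", "following"
            else:
                phi[sl] = -gap
                labels_a[sl], labels_b[sl] = "following", "followed"
        elif b.kind == "not_close":
            phi[sl] = _chord_to_angle(_CHORD["not_close"])
            labels_a[sl] = labels_b[sl] = "not_close"
        # "other" keeps defaults

    # cumulative forward-only leaps: when phi increases, mouse a jumps
    # forward; when it decreases, mouse b jumps forward
    dphi = np.diff(phi, prepend=phi[0])
    lead_a = np.cumsum(np.where(dphi > 0, dphi, 0.0))
    lead_b = np.cumsum(np.where(dphi < 0, -dphi, 0.0))
    base = theta0 + omega * np.arange(n)
    th_a = base + lead_a
    th_b = th_a - phi  # == base + lead_b + const; all steps forward

    tracks = {}
    for mid, th in ((id_a, th_a), (id_b, th_b)):
        xy = np.stack([cx + r * np.cos(th), cy + r * np.sin(th)], axis=1)
        heading = np.mod(th + np.pi / 2 + np.pi, 2 * np.pi) - np.pi  # tangent, CCW
        heading[heading <= -np.pi] += 2 * np.pi
        tracks[mid] = MouseTrack(
            mouse_id=mid,
            xy=xy,
            major_axis=np.full(n, 0.07),
            minor_axis=np.full(n, 0.03),
            heading=heading,
            frame_rate=frame_rate,
        )
    labels = pd.DataFrame(
        {
            "frame": np.tile(np.arange(n), 2),
            "mouse_id": np.repeat([id_a, id_b], n),
            "context": np.concatenate([labels_a, labels_b]),
        }
    )
    return tracks, labels


# ---------------------------------------------------------------------------
# Waveforms
# ---------------------------------------------------------------------------


def _chirp_eval(t: np.ndarray, event: EmissionEvent) -> np.ndarray:
    """Evaluate the enveloped linear-FM chirp at arbitrary times t (seconds,
    relative to onset).  Zero outside [0, duration]."""
    T = event.duration_s
    inside = (t >= 0) & (t <= T)
    tt = np.where(inside, t, 0.0)
    sweep = (event.f_end_hz - event.f_start_hz) / T
    phase = 2 * np.pi * (event.f_start_hz * tt + 0.5 * sweep * tt**2)
    ramp = min(0.0005, 0.2 * T)  # raised-cosine onset/offset ramps
    env = np.ones_like(tt)
    head = tt < ramp
    tail = tt > T - ramp
    env[head] = 0.5 * (1 - np.cos(np.pi * tt[head] / ramp))
    env[tail] = 0.5 * (1 - np.cos(np.pi * (T - tt[tail]) / ramp))
    return np.where(inside, event.amplitude * env * np.sin(phase), 0.0)


def synth_usv(event: EmissionEvent, sample_rate: int = DEFAULT_SAMPLE_RATE) -> np.ndarray:
    """Render one chirp at the given sample rate (instantaneous frequency
    linear from f_start to f_end over the duration)."""
    fmax = max(event.f_start_hz, event.f_end_hz)
    if sample_rate < 2.2 * fmax:
        raise ValidationError(f"sample rate {sample_rate} < 2.2 x {fmax:.0f} Hz")
    n = int(round(event.duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    return _chirp_eval(t, event)


def simulate_array_audio(
    tracks: dict[str, MouseTrack],
    events: list[EmissionEvent],
    geometry: MicArrayGeometry,
    sample_rate: int = DEFAULT_SAMPLE_RATE,
    noise_sd: float = 0.0,
    seed: int = 0,
    duration_s: float | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render array audio for a set of emission events.

    Each event is a point source fixed at the emitter's nose position at
    onset.  Per channel, the wave arrives delayed by distance/343 m/s with
    amplitude scaled by 1/distance (free-field, no echoes), evaluated with
    exact fractional delays.  Independent Gaussian noise of sd ``noise_sd``
    is added per channel.  Returns ``(audio (N, M), truth table)`` where the
    truth table records the true source coordinates per event.
    """
    from .behavior import nose_position

    rng = np.random.default_rng(seed)
    any_track = next(iter(tracks.values()))
    frame_rate = any_track.frame_rate
    if duration_s is None:
        duration_s = len(any_track) / frame_rate
    n_samples = int(round(duration_s * sample_rate))
    audio = np.zeros((n_samples, geometry.n_mics), dtype=np.float64)

    truth_rows = []
    for k, ev in enumerate(events):
        if ev.emitter_id not in tracks:
            raise ValidationError(f"event emitter {ev.emitter_id!r} has no track")
        if ev.onset_s + ev.duration_s > duration_s:
            raise ValidationError("event extends past the track duration")
        frame = min(int(round(ev.onset_s * frame_rate)), len(tracks[ev.emitter_id]) - 1)
        src = nose_position(tracks[ev.emitter_id], frame)
        if not (0 <= src[0] <= geometry.arena[0] and 0 <= src[1] <= geometry.arena[1]):
            raise ValidationError(f"event {k} source {src} outside the arena")
        for m, mic in enumerate(geometry.mic_positions):
            d = float(np.hypot(*(src - mic)))
            delay = d / SPEED_OF_SOUND
            i0 = int(np.floor((ev.onset_s + delay) * sample_rate))
            i1 = int(np.ceil((ev.onset_s + delay + ev.duration_s) * sample_rate)) + 1
            i0, i1 = max(i0, 0), min(i1, n_samples)
            t = np.arange(i0, i1) / sample_rate - ev.onset_s - delay
            audio[i0:i1, m] += _chirp_eval(t, ev) / max(d, 1e-3)
        truth_rows.append(
            (k, ev.emitter_id, ev.onset_s, ev.duration_s, ev.f_start_hz, ev.f_end_hz, src[0], src[1])
        )
    if noise_sd > 0:
        audio += rng.normal(0.0, noise_sd, audio.shape)
    truth = pd.DataFrame(
        truth_rows,
        columns=["event", "emitter", "onset_s", "duration_s", "f_start_hz", "f_end_hz", "x_m", "y_m"],
    )
    return audio, truth


def make_dyad_events(
    tracks: dict[str, MouseTrack],
    n_events: int,
    seed: int = 0,
    male_fraction: float = 0.845,
    duration_range: tuple[float, float] = (0.015, 0.030),
    f_low_range: tuple[float, float] = (55_000.0, 70_000.0),
    bandwidth_range: tuple[float, float] = (8_000.0, 25_000.0),
    amplitude: float = 1.0,
) -> list[EmissionEvent]:
    """Draw a set of chirp events for a simulated dyad.

    Emitters are drawn with the male producing ``male_fraction`` of signals
    (84.5% in real dyads); onsets are spaced evenly with jitter so chirps
    never overlap; up- and down-sweeps are equally likely.
    """
    rng = np.random.default_rng(seed)
    ids = list(tracks.keys())
    any_track = next(iter(tracks.values()))
    total_s = len(any_track) / any_track.frame_rate
    slot = (total_s - 0.2) / n_events
    if slot < max(duration_range) + 0.01:
        raise ValidationError("session too short for the requested event count")
    events = []
    for k in range(n_events):
        onset = 0.1 + k * slot + rng.uniform(0, slot - max(duration_range) - 0.005)
        dur = rng.uniform(*duration_range)
        f_lo = rng.uniform(*f_low_range)
        bw = rng.uniform(*bandwidth_range)
        f0, f1 = (f_lo, f_lo + bw) if rng.random() < 0.5 else (f_lo + bw, f_lo)
        emitter = ids[0] if rng.random() < male_fraction else ids[1]
        events.append(EmissionEvent(emitter, onset, dur, f0, f1, amplitude))
    return events


# ---------------------------------------------------------------------------
# Feature tables with sex structure
# ---------------------------------------------------------------------------


@dataclass
class SexEffectSpec:
    """Per-sex generative parameters for the seven acoustic features.

    Positive features are log-normal, parameterised by (median, log-sd);
    slope is plain normal (median, sd) since it is signed.  Defaults
    reproduce the pooled medians reported for real dyads (male bandwidth
    7.9 kHz vs female 6.1 kHz, male duration 17.2 ms vs female 17.9 ms,
    male slope negative vs female positive, ...); log-sds are matched to
    the reported IQRs where those are unambiguous.
    """

    bandwidth_hz: dict = field(
        default_factory=lambda: {"male": (7_900.0, 0.634), "female": (6_100.0, 0.615)}
    )
    duration_ms: dict = field(
        default_factory=lambda: {"male": (17.2, 0.528), "female": (17.9, 0.561)}
    )
    low_freq_hz: dict = field(
        default_factory=lambda: {"male": (66_400.0, 0.131), "female": (66_600.0, 0.138)}
    )
    slope_hz_per_s: dict = field(
        default_factory=lambda: {"male": (-4_000.0, 15_000.0), "female": (6_400.0, 10_000.0)}
    )
    amplitude_mv: dict = field(
        default_factory=lambda: {"male": (48.6, 0.59), "female": (45.0, 0.61)}
    )
    # per-session signal counts: log-normal (median, log-sd), log-correlated
    counts: dict = field(
        default_factory=lambda: {"male": (3_318.0, 0.721), "female": (477.0, 0.834), "log_corr": 0.9}
    )

    def __post_init__(self) -> None:
        for name in ("bandwidth_hz", "duration_ms", "low_freq_hz", "amplitude_mv"):
            for med, sd in getattr(self, name).values():
                if sd <= 0:
                    raise ValidationError(f"{name} scale must be positive")
                if med <= 0:
                    raise ValidationError(f"{name} median must be positive")
        for med, sd in self.slope_hz_per_s.values():
            if sd <= 0:
                raise ValidationError("slope scale must be positive")


# Per-sex context proportions among assigned signals, matching the tallies
# observed in real dyads (the large remainder is unscripted "other").
_CONTEXT_RATES = {
    "male": {"not_close": 5013 / 32290, "followed": 137 / 32290, "following": 3386 / 32290},
    "female": {"not_close": 51 / 5904, "followed": 859 / 5904, "following": 16 / 5904},
}


def simulate_feature_table(
    n_sessions: int = 13,
    effects: SexEffectSpec | None = None,
    seed: int = 0,
    counts_per_sex: dict | None = None,
) -> pd.DataFrame:
    """Generate an assigned-signal feature table for ``n_sessions`` dyads.

    Each session draws correlated per-sex signal counts, then per-signal
    features from the per-sex families in ``effects``.  High frequency is
    derived as low + bandwidth and mean frequency as a Beta(2, 2) position
    inside the band, so the per-row feature invariants hold exactly.
    ``counts_per_sex`` may pin exact counts, e.g. ``{"male": 600,
    "female": 600}`` for balanced sampling tests.
    """
    rng = np.random.default_rng(seed)
    eff = effects or SexEffectSpec()
    rows = []
    for s in range(n_sessions):
        date = f"session{s:02d}"
        if counts_per_sex is not None:
            n_m, n_f = int(counts_per_sex["male"]), int(counts_per_sex["female"])
        else:
            mu = np.log([eff.counts["male"][0], eff.counts["female"][0]])
            sd = np.array([eff.counts["male"][1], eff.counts["female"][1]])
            rho = eff.counts["log_corr"]
            cov = np.array([[sd[0] ** 2, rho * sd[0] * sd[1]], [rho * sd[0] * sd[1], sd[1] ** 2]])
            draw = rng.multivariate_normal(mu, cov)
            n_m, n_f = int(max(50, round(np.exp(draw[0])))), int(max(50, round(np.exp(draw[1]))))
        for sex, n in (("male", n_m), ("female", n_f)):
            bw = np.exp(rng.normal(np.log(eff.bandwidth_hz[sex][0]), eff.bandwidth_hz[sex][1], n))
            dur = np.exp(rng.normal(np.log(eff.duration_ms[sex][0]), eff.duration_ms[sex][1], n))
            low = np.exp(rng.normal(np.log(eff.low_freq_hz[sex][0]), eff.low_freq_hz[sex][1], n))
            low = np.clip(low, 30_000.0, None)
            bw = np.minimum(bw, 110_000.0 - low)  # keep high inside the band
            high = low + bw
            mean = low + rng.beta(2.0, 2.0, n) * bw
            slope = rng.normal(eff.slope_hz_per_s[sex][0], eff.slope_hz_per_s[sex][1], n)
            amp = np.exp(rng.normal(np.log(eff.amplitude_mv[sex][0]), eff.amplitude_mv[sex][1], n))
            rates = _CONTEXT_RATES[sex]
            p = [rates["following"], rates["followed"], rates["not_close"]]
            ctx = rng.choice(
                ["following", "followed", "not_close", "other"],
                size=n,
                p=p + [1.0 - sum(p)],
            )
            for i in range(n):
                rows.append(
                    (date, i, sex, bw[i], dur[i], high[i], low[i], mean[i], slope[i], amp[i], ctx[i])
                )
    from .io import FEATURE_COLUMNS

    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
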