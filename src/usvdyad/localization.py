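"""Sound-source localization and per-mouse assignment of vocal signals.

For each vocal signal the array is jackknifed: every microphone is omitted
once and a planar source estimate is computed from the remaining seven
channels, giving eight leave-one-out point estimates.  Their mean is the
overall source estimate, and their scatter (inflated by the jackknife
variance factor (m-1)/m * sum of squared deviations) parameterises a
bivariate normal density over the cage.  Each mouse is then assigned the
density value D_n at its nose, and the mouse probability index

    MPI_n = D_n / sum_i D_i

quantifies the probability that mouse n emitted the signal.  A signal is
assigned only when one mouse's MPI strictly exceeds 0.95.

The single-subset point estimator here is GCC-PHAT cross-correlation
time-differences-of-arrival followed by planar nonlinear least squares.
It stands in for the original array-specific estimator, which is not fully
specified by the analysis being reproduced; the jackknife/MPI layer is
estimator-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .io import DEFAULT_SAMPLE_RATE, MicArrayGeometry
from .segmentation import VocalSignal

SPEED_OF_SOUND = 343.0  # m/s
MPI_THRESHOLD = 0.95
DENSITY_FLOOR_SD_M = 0.01  # minimum per-axis sd of the density, metres
MAX_INVALID_POINTS = 2


@dataclass
class LocalizationResult:
    """Jackknife localization and assignment for one vocal signal."""

    signal_id: int
    jackknife_points: np.ndarray  # (m, 2) leave-one-out estimates
    overall_estimate: np.ndarray  # (2,) mean of the points
    cov: np.ndarray  # (2, 2) density covariance
    d_values: dict[str, float] = field(default_factory=dict)
    mpi: dict[str, float] = field(default_factory=dict)
    assigned_to: str | None = None
    valid: bool = True
    underflow: bool = False


def _gcc_phat_tdoa(
    x: np.ndarray, y: np.ndarray, sample_rate: float, max_delay_s: float
) -> float:
    """Time delay of y relative to x via phase-transform cross-correlation,
    with parabolic sub-sample interpolation."""
    n = len(x) + len(y)
    nfft = 1 << (n - 1).bit_length()
    X = np.fft.rfft(x, nfft)
    Y = np.fft.rfft(y, nfft)
    r = X * np.conj(Y)
    mag = np.abs(r)
    r = np.where(mag > 0, r / np.maximum(mag, 1e-300), 0)
    cc = np.fft.irfft(r, nfft)
    max_shift = min(int(max_delay_s * sample_rate) + 1, nfft // 2 - 1)
    cc = np.concatenate((cc[-max_shift:], cc[: max_shift + 1]))
    i = int(np.argmax(cc))
    # parabolic refinement
    if 0 < i < len(cc) - 1:
        y0, y1, y2 = cc[i - 1], cc[i], cc[i + 1]
        denom = y0 - 2 * y1 + y2
        frac = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-12 else 0.0
        frac = float(np.clip(frac, -0.5, 0.5))
    else:
        frac = 0.0
    return (i + frac - max_shift) / sample_rate


def _extract_traces(
    signal: VocalSignal, audio: np.ndarray, sample_rate: float, pad_s: float
) -> np.ndarray:
    i0 = max(0, int((signal.start_s - pad_s) * sample_rate))
    i1 = min(audio.shape[0], int((signal.stop_s + pad_s) * sample_rate) + 1)
    return audio[i0:i1]


def _pairwise_tdoas(
    traces: np.ndarray, sample_rate: float, max_delay_s: float
) -> np.ndarray:
    """TDOA matrix tau[i, j] = arrival time at i minus arrival time at j."""
    m = traces.shape[1]
    tau = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            # positive when channel i hears the signal later than channel j
            t = _gcc_phat_tdoa(traces[:, i], traces[:, j], sample_rate, max_delay_s)
            tau[i, j] = t
            tau[j, i] = -t
    return tau


def _solve_tdoa(
    tau: np.ndarray,
    mic_positions: np.ndarray,
    geometry: MicArrayGeometry,
    subset: np.ndarray,
) -> np.ndarray:
    """Planar least-squares source position from pairwise TDOAs."""
    pairs = [(i, j) for k, i in enumerate(subset) for j in subset[k + 1 :]]
    meas = np.array([tau[i, j] for i, j in pairs])
    pi = mic_positions[[i for i, _ in pairs]]
    pj = mic_positions[[j for _, j in pairs]]

    def residuals(p):
        di = np.hypot(p[0] - pi[:, 0], p[1] - pi[:, 1])
        dj = np.hypot(p[0] - pj[:, 0], p[1] - pj[:, 1])
        return (di - dj) / SPEED_OF_SOUND - meas

    x0 = np.array([geometry.arena[0] / 2.0, geometry.arena[1] / 2.0])
    sol = optimize.least_squares(residuals, x0, method="lm", max_nfev=200)
    p = sol.x
    # clamp estimates to the arena
    return np.clip(p, [0.0, 0.0], list(geometry.arena))


def point_estimate(
    signal: VocalSignal,
    audio: np.ndarray,
    geometry: MicArrayGeometry,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    channels: np.ndarray | None = None,
) -> tuple[np.ndarray, bool]:
    """Single planar source estimate from a channel subset (>= 4 mics).

    Returns ``(xy, valid)``; invalid when the traces carry no energy.
    """
    subset = np.arange(audio.shape[1]) if channels is None else np.asarray(channels)
    if len(subset) < 4:
        raise ValueError("need at least 4 microphones")
    max_delay = float(np.hypot(*geometry.arena)) / SPEED_OF_SOUND
    traces = _extract_traces(signal, audio, sample_rate, pad_s=1.5 * max_delay)
    if traces.shape[0] < 16 or np.max(np.abs(traces[:, subset])) <= 0:
        return np.array([np.nan, np.nan]), False
    tau = np.full((audio.shape[1], audio.shape[1]), np.nan)
    sub_traces = traces
    m = len(subset)
    for a in range(m):
        for b in range(a + 1, m):
            i, j = subset[a], subset[b]
            t = _gcc_phat_tdoa(sub_traces[:, i], sub_traces[:, j], sample_rate, max_delay)
            tau[i, j] = t
            tau[j, i] = -t
    xy = _solve_tdoa(tau, geometry.mic_positions, geometry, subset)
    return xy, True


def jackknife_localize(
    signal: VocalSignal,
    audio: np.ndarray,
    geometry: MicArrayGeometry,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    floor_sd_m: float = DENSITY_FLOOR_SD_M,
) -> LocalizationResult:
    """Leave-one-microphone-out localization of one signal.

    Each of the m microphones is omitted once; the m point estimates are
    averaged into the overall estimate and their scatter sets the density
    covariance (jackknife variance (m-1)/m * sum d d', eigenvalue-floored
    at ``floor_sd_m``^2).
    """
    m = audio.shape[1]
    if m != geometry.n_mics:
        raise ValueError("audio channel count does not match the geometry")
    max_delay = float(np.hypot(*geometry.arena)) / SPEED_OF_SOUND
    traces = _extract_traces(signal, audio, sample_rate, pad_s=1.5 * max_delay)
    if traces.shape[0] < 16 or np.max(np.abs(traces)) <= 0:
        return LocalizationResult(
            signal_id=signal.id,
            jackknife_points=np.full((m, 2), np.nan),
            overall_estimate=np.array([np.nan, np.nan]),
            cov=np.eye(2),
            valid=False,
        )
    tau = _pairwise_tdoas(traces, sample_rate, max_delay)

    points = np.empty((m, 2))
    n_invalid = 0
    for omit in range(m):
        subset = np.array([i for i in range(m) if i != omit])
        if np.max(np.abs(traces[:, subset])) <= 0:
            points[omit] = np.nan
            n_invalid += 1
            continue
        points[omit] = _solve_tdoa(tau, geometry.mic_positions, geometry, subset)
    if n_invalid > MAX_INVALID_POINTS:
        return LocalizationResult(
            signal_id=signal.id,
            jackknife_points=points,
            overall_estimate=np.array([np.nan, np.nan]),
            cov=np.eye(2),
            valid=False,
        )
    good = points[~np.isnan(points[:, 0])]
    overall = good.mean(axis=0)
    dev = good - overall
    k = len(good)
    cov = (k - 1) / k * (dev.T @ dev)
    # floor the covariance so coincident estimates still define a density
    w, v = np.linalg.eigh(cov)
    w = np.maximum(w, floor_sd_m**2)
    cov = (v * w) @ v.T
    return LocalizationResult(
        signal_id=signal.id,
        jackknife_points=points,
        overall_estimate=overall,
        cov=cov,
    )


def assign_mpi(
    result: LocalizationResult,
    nose_positions: dict[str, np.ndarray],
    threshold: float = MPI_THRESHOLD,
) -> LocalizationResult:
    """Evaluate the density at each mouse's nose and assign by MPI.

    MPI_n = D_n / sum_i D_i; a signal is assigned iff max MPI strictly
    exceeds ``threshold``.  Ties and sub-threshold maxima stay unassigned.
    Computed in log space so distant noses underflow gracefully.
    """
    if not result.valid:
        return result
    if not nose_positions:
        raise ValueError("need at least one mouse")
    inv = np.linalg.inv(result.cov)
    _, logdet = np.linalg.slogdet(result.cov)
    names = list(nose_positions)
    logd = np.empty(len(names))
    for i, name in enumerate(names):
        d = np.asarray(nose_positions[name], dtype=float) - result.overall_estimate
        logd[i] = -0.5 * (d @ inv @ d) - 0.5 * logdet - np.log(2 * np.pi)
    result.d_values = {n: float(np.exp(ld)) for n, ld in zip(names, logd)}
    if not np.any(np.isfinite(logd)):
        result.underflow = True
        result.mpi = {n: np.nan for n in names}
        result.assigned_to = None
        return result
    rel = np.exp(logd - np.max(logd))
    mpi = rel / rel.sum()
    result.mpi = {n: float(p) for n, p in zip(names, mpi)}
    best = int(np.argmax(mpi))
    top = mpi[best]
    if top > threshold and np.sum(mpi == top) == 1:
        result.assigned_to = names[best]
    else:
        result.assigned_to = None
    return result


def localize_session(
    signals: list[VocalSignal],
    audio: np.ndarray,
    tracks: dict,
    geometry: MicArrayGeometry,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    frame_rate: float = 30.0,
    threshold: float = MPI_THRESHOLD,
) -> list[LocalizationResult]:
    """Jackknife-localize and assign every signal in a session."""
    from .behavior import nose_position

    results = []
    for sig in signals:
        res = jackknife_localize(sig, audio, geometry, sample_rate)
        if res.valid:
            frame = int(round(sig.start_s * frame_rate))
            noses = {
                mid: nose_position(tr, min(frame, len(tr) - 1)) for mid, tr in tracks.items()
            }
            res = assign_mpi(res, noses, threshold)
        results.append(res)
    return results
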