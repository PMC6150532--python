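"""Per-signal acoustic features.

Seven features are measured for every vocal signal: bandwidth, duration,
high frequency, low frequency, mean fundamental frequency, slope (change
in frequency over time, from a robust linear regression of the frequency
contour), and amplitude (from a sine fit to the raw voltage trace on each
microphone, taking the largest fitted amplitude across channels).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .io import DEFAULT_SAMPLE_RATE
from .segmentation import VocalSignal

IRLS_MAX_ITER = 50
BISQUARE_C = 4.685


@dataclass
class FeatureRecord:
    signal_id: int
    emitter: str  # mouse id or "unassigned"
    bandwidth_hz: float
    duration_ms: float
    high_freq_hz: float
    low_freq_hz: float
    mean_freq_hz: float
    slope_hz_per_s: float
    amplitude_mv: float
    session_id: str = ""
    context: str | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate:
            assert abs(self.bandwidth_hz - (self.high_freq_hz - self.low_freq_hz)) < 1e-6
            assert self.low_freq_hz - 1e-9 <= self.mean_freq_hz <= self.high_freq_hz + 1e-9


def contour_features(contour: np.ndarray) -> dict[str, float]:
    """Bandwidth, duration, high/low and mean fundamental frequency.

    ``contour`` has columns (time_s, freq_hz, power).  Mean fundamental
    frequency is the power-weighted average of the contour frequencies.
    Single-point contours are flagged degenerate (zero bandwidth and
    duration).
    """
    c = np.asarray(contour, dtype=float)
    if c.ndim != 2 or c.shape[0] < 1 or c.shape[1] < 2:
        raise ValueError("contour must have at least one (time, freq) point")
    f = c[:, 1]
    w = c[:, 2] if c.shape[1] > 2 else np.ones_like(f)
    high = float(f.max())
    low = float(f.min())
    tot = w.sum()
    mean = float(np.average(f, weights=w)) if tot > 0 else float(f.mean())
    return {
        "bandwidth_hz": high - low,
        "duration_ms": float((c[-1, 0] - c[0, 0]) * 1000.0),
        "high_freq_hz": high,
        "low_freq_hz": low,
        "mean_freq_hz": mean,
        "degenerate": bool(len(c) < 2),
    }


def contour_slope(contour: np.ndarray) -> float:
    """Slope (Hz/s) of a robust linear fit of frequency on time.

    Iteratively reweighted least squares with Tukey bisquare weights
    (tuning constant 4.685, <= 50 iterations).  Needs >= 3 contour points;
    returns NaN otherwise.
    """
    c = np.asarray(contour, dtype=float)
    if len(c) < 3:
        return np.nan
    t = c[:, 0] - c[0, 0]
    f = c[:, 1]
    if np.ptp(t) == 0:
        return np.nan
    X = sm.add_constant(t)
    model = sm.RLM(f, X, M=sm.robust.norms.TukeyBiweight(c=BISQUARE_C))
    with warnings.catch_warnings():
        # a perfect fit (noise-free synthetic contour) is fine, not a problem
        warnings.simplefilter("ignore", category=ConvergenceWarning)
        fit = model.fit(maxiter=IRLS_MAX_ITER)
    return float(fit.params[1])


def _fit_sine(trace: np.ndarray, sample_rate: float, f0: float) -> float | None:
    """Least-squares sine fit; returns the fitted amplitude (peak minus
    midpoint) or None on failure."""
    t = np.arange(len(trace)) / sample_rate
    ptp = np.ptp(trace)
    if ptp <= 0:
        return None
    # linear solve for (a, b, c) at fixed f gives amplitude and a phase init
    def linfit(f):
        A = np.column_stack([np.sin(2 * np.pi * f * t), np.cos(2 * np.pi * f * t), np.ones_like(t)])
        coef, *_ = np.linalg.lstsq(A, trace, rcond=None)
        resid = trace - A @ coef
        return coef, float(resid @ resid)

    coef, _ = linfit(f0)
    amp0 = float(np.hypot(coef[0], coef[1]))
    phase0 = float(np.arctan2(coef[1], coef[0]))
    x0 = np.array([max(amp0, 0.5 * ptp / 2), f0, phase0, float(coef[2])])

    def residuals(p):
        return p[0] * np.sin(2 * np.pi * p[1] * t + p[2]) + p[3] - trace

    try:
        sol = optimize.least_squares(residuals, x0, max_nfev=400)
    except Exception:
        return None
    if not np.isfinite(sol.x).all():
        return None
    return abs(float(sol.x[0]))


def signal_amplitude(
    signal: VocalSignal,
    audio: np.ndarray,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    f0_hz: float | None = None,
) -> float:
    """Amplitude of a signal: per channel, fit a sine to the voltage trace
    over [start, stop] and take the largest fitted amplitude.

    Units follow the audio file's voltage scale; calibration to mV is the
    caller's concern.  Channels where the fit fails are skipped; NaN when
    every channel fails.
    """
    i0 = max(0, int(signal.start_s * sample_rate))
    i1 = min(audio.shape[0], int(signal.stop_s * sample_rate) + 1)
    if i1 <= i0:
        return np.nan
    f0 = f0_hz
    if f0 is None:
        feats = contour_features(signal.contour)
        f0 = feats["mean_freq_hz"]
    best = np.nan
    for ch in range(audio.shape[1]):
        amp = _fit_sine(audio[i0:i1, ch], sample_rate, f0)
        if amp is not None and (np.isnan(best) or amp > best):
            best = amp
    return best


def extract_features(
    signals: list[VocalSignal],
    audio: np.ndarray | None = None,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    emitters: dict[int, str] | None = None,
    session_id: str = "",
) -> list[FeatureRecord]:
    """Feature records for a list of signals.

    ``emitters`` maps signal id -> mouse id (from localization); signals
    without an entry are recorded as unassigned.  Harmonic stacks already
    carry the fundamental's contour, so no special-casing is needed here.
    """
    records = []
    for sig in signals:
        base = contour_features(sig.contour)
        slope = contour_slope(sig.contour)
        amp = signal_amplitude(sig, audio, sample_rate) if audio is not None else np.nan
        records.append(
            FeatureRecord(
                signal_id=sig.id,
                emitter=(emitters or {}).get(sig.id, "unassigned"),
                bandwidth_hz=base["bandwidth_hz"],
                duration_ms=base["duration_ms"],
                high_freq_hz=base["high_freq_hz"],
                low_freq_hz=base["low_freq_hz"],
                mean_freq_hz=base["mean_freq_hz"],
                slope_hz_per_s=slope,
                amplitude_mv=amp,
                session_id=session_id,
                degenerate=base["degenerate"],
            )
        )
    return records


def records_to_table(records: list[FeatureRecord]):
    import pandas as pd

    from .io import FEATURE_COLUMNS

    rows = [
        (
            r.session_id,
            r.signal_id,
            r.emitter,
            r.bandwidth_hz,
            r.duration_ms,
            r.high_freq_hz,
            r.low_freq_hz,
            r.mean_freq_hz,
            r.slope_hz_per_s,
            r.amplitude_mv,
            r.context if r.context is not None else "",
        )
        for r in records
    ]
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)
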