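"""Sex-difference statistics for per-vocalization feature tables.

The feature distributions of mouse USVs are heavily skewed, so the whole
battery is nonparametric: Mann-Whitney U tests (two-tailed, alpha 0.05),
medians with 25th-75th percentile IQRs, per-animal medians to control for
individual contribution, Pearson correlations where a linear association
is asked of paired counts, and a Monte-Carlo median-difference index that
controls for the large male/female sample-size imbalance:

    index = (male_median - female_median) / (male_median + female_median)

computed on 1000 independent random samples of 500 signals per sex.  For
slope — the one signed feature — all slopes are first shifted by the
absolute value of the most negative slope so the index operates on
nonnegative values while preserving differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_MAX_N = 8  # exact U distribution when min(n1, n2) <= this
N_SAMPLES = 1000
SAMPLE_SIZE = 500
VOCALIZER_SPLIT = 2200  # signals/session separating high from low vocalizers


class ValidationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------


@dataclass
class TestResult:
    u: float
    z: float
    p: float
    n1: int
    n2: int
    median1: float
    median2: float
    iqr1: tuple[float, float]
    iqr2: tuple[float, float]
    method: str = "asymptotic"
    degenerate: bool = False


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x via the rank-sum formula (midranks for ties)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def mann_whitney(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact permutation distribution of U (ties handled by enumeration) when
    min(n1, n2) <= 8; otherwise the tie-corrected, continuity-corrected
    normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValidationError("both samples must be non-empty")
    med1, q1l, q1h = median_iqr(x)
    med2, q2l, q2h = median_iqr(y)
    u = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return TestResult(u, 0.0, 1.0, n1, n2, med1, med2, (q1l, q1h), (q2l, q2h), "degenerate", True)

    if min(n1, n2) <= EXACT_MAX_N:
        # enumerate all C(n1+n2, n1) group assignments of the pooled values
        n = n1 + n2
        ranks = sps.rankdata(pooled)
        offset = n1 * (n1 + 1) / 2.0
        count_le = 0
        count_ge = 0
        total = comb(n, n1)
        for idx in combinations(range(n), n1):
            u_perm = ranks[list(idx)].sum() - offset
            if u_perm <= u + 1e-9:
                count_le += 1
            if u_perm >= u - 1e-9:
                count_ge += 1
        p_one = min(count_le, count_ge) / total
        p = min(1.0, 2.0 * p_one)
        # report a z value from the (tie-corrected) normal approx for reference
        z = _mw_z(u, n1, n2, pooled)
        return TestResult(u, z, p, n1, n2, med1, med2, (q1l, q1h), (q2l, q2h), "exact")

    z = _mw_z(u, n1, n2, pooled)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult(u, z, p, n1, n2, med1, med2, (q1l, q1h), (q2l, q2h), "asymptotic")


def _mw_z(u: float, n1: int, n2: int, pooled: np.ndarray) -> float:
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var_u <= 0:
        return 0.0
    mean_u = n1 * n2 / 2.0
    cc = 0.5 if u != mean_u else 0.0  # continuity correction toward the mean
    return float((u - mean_u - np.sign(u - mean_u) * cc) / np.sqrt(var_u))


def median_iqr(values) -> tuple[float, float, float]:
    """Median and 25th/75th percentiles (linear interpolation)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValidationError("empty sample")
    return (
        float(np.median(v)),
        float(np.percentile(v, 25)),
        float(np.percentile(v, 75)),
    )


# ---------------------------------------------------------------------------
# Per-animal medians and correlations
# ---------------------------------------------------------------------------


def per_animal_medians(table: pd.DataFrame, feature: str) -> pd.DataFrame:
    """One median per animal per session.

    Animals are identified by (session, emitter); for dyadic recordings
    this yields one male and one female point per session.  Sessions with
    no assigned signals for a sex contribute no point for that sex.
    """
    df = table[table["emitter"] != "unassigned"]
    if df.empty:
        raise ValidationError("no assigned signals")
    out = (
        df.groupby(["date", "emitter"], sort=True)[feature]
        .median()
        .reset_index()
        .rename(columns={feature: "median"})
    )
    return out


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with the t-transform p-value (n-2 d.f.)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValidationError("pearson needs >= 3 paired values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def ks_nongaussian(values) -> float:
    """One-sample KS p-value against a normal with the sample mean/sd.

    Used to justify the nonparametric battery; small p = non-Gaussian.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 10:
        raise ValidationError("need n >= 10")
    sd = v.std(ddof=1)
    if sd == 0:
        return np.nan  # degenerate: constant sample
    return float(sps.kstest(v, "norm", args=(v.mean(), sd)).pvalue)


# ---------------------------------------------------------------------------
# Monte-Carlo sex-difference index
# ---------------------------------------------------------------------------


@dataclass
class IndexDistribution:
    feature: str
    indices: np.ndarray
    n_samples: int
    sample_size: int
    n_positive: int
    n_negative: int
    slope_shift_constant: float | None
    seed: int

    @property
    def n_zero(self) -> int:
        return self.n_samples - self.n_positive - self.n_negative


def sex_index(male_median: float, female_median: float) -> float:
    """(m - f) / (m + f); positive = male-driven, negative = female-driven."""
    denom = male_median + female_median
    if denom == 0:
        raise ValidationError("zero denominator in sex index")
    return (male_median - female_median) / denom


def monte_carlo_index(
    table: pd.DataFrame,
    feature: str,
    n_samples: int = N_SAMPLES,
    sample_size: int = SAMPLE_SIZE,
    seed: int = 0,
    male_label: str = "male",
    female_label: str = "female",
) -> IndexDistribution:
    """Distribution of the sex-difference index over random subsamples.

    Each of ``n_samples`` iterations draws ``sample_size`` male and
    ``sample_size`` female signals without replacement (independently
    across iterations) and computes the index of the two sample medians.
    For ``feature == "slope_hz_per_s"`` all slopes are first shifted by
    |min slope| over every assigned signal, making values nonnegative
    while preserving differences.
    """
    males = table.loc[table["emitter"] == male_label, feature].to_numpy(dtype=float)
    females = table.loc[table["emitter"] == female_label, feature].to_numpy(dtype=float)
    if len(males) < sample_size or len(females) < sample_size:
        raise ValidationError(
            f"need >= {sample_size} signals per sex, have male={len(males)} female={len(females)}"
        )
    shift = None
    if feature == "slope_hz_per_s":
        shift = float(abs(min(np.min(males), np.min(females))))
        males = males + shift
        females = females + shift
    rng = np.random.default_rng(seed)
    idx = np.empty(n_samples)
    for i in range(n_samples):
        m = np.median(rng.choice(males, sample_size, replace=False))
        f = np.median(rng.choice(females, sample_size, replace=False))
        idx[i] = sex_index(m, f)
    return IndexDistribution(
        feature=feature,
        indices=idx,
        n_samples=n_samples,
        sample_size=sample_size,
        n_positive=int(np.sum(idx > 0)),
        n_negative=int(np.sum(idx < 0)),
        slope_shift_constant=shift,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# High/low vocalizer split
# ---------------------------------------------------------------------------


def vocalizer_split(
    male_session_counts: dict[str, int], threshold: int = VOCALIZER_SPLIT
) -> dict[str, str]:
    """Label each session high/low by the male's signal count.

    A male is a high vocalizer when he emitted strictly more than
    ``threshold`` signals; his partner female inherits the label.
    """
    return {s: ("high" if c > threshold else "low") for s, c in male_session_counts.items()}


def session_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Assigned-signal counts per (session, emitter)."""
    df = table[table["emitter"] != "unassigned"]
    return df.groupby(["date", "emitter"]).size().rename("count").reset_index()
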