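"""Stage-wise pipeline: simulate -> segment -> localize -> features ->
behavior -> stats.

Each stage reads the previous stage's artifact from the output directory,
writes its own, and records per-stage tallies in a JSON run report.  With
a fixed seed the whole chain is reproducible.
"""

from __future__ import annotations

import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as uio
from .behavior import classify_session, context_table, label_vocalizations
from .features import extract_features, records_to_table
from .localization import localize_session
from .segmentation import segment_audio
from .stats import (
    ks_nongaussian,
    mann_whitney,
    monte_carlo_index,
    pearson,
    per_animal_medians,
    session_counts,
    vocalizer_split,
)
from .synth import BehaviorScript, BoutSpec, make_dyad_events, simulate_array_audio, simulate_trajectories

log = logging.getLogger("usvdyad.pipeline")

STAGES = ("simulate", "segment", "localize", "features", "behavior", "stats")

NUMERIC_FEATURES = [
    "bandwidth_hz",
    "duration_ms",
    "high_freq_hz",
    "low_freq_hz",
    "mean_freq_hz",
    "slope_hz_per_s",
    "amplitude_mv",
]


def _default_script(n_frames: int) -> BehaviorScript:
    """A session with one bout of each scripted kind, spaced apart."""
    third = n_frames // 4
    return BehaviorScript(
        bouts=[
            BoutSpec("following", third // 2, 30, leader_id="male"),
            BoutSpec("not_close", 2 * third, 30),
            BoutSpec("following", 3 * third, 30, leader_id="female"),
        ],
        n_frames=n_frames,
    )


def run_pipeline(
    config: Path | None,
    stages: list[str],
    seed: int,
    out_dir: Path,
    n_events: int = 50,
    duration_s: float = 20.0,
    noise_sd: float = 0.0,
    feature_table: Path | None = None,
) -> dict:
    """Run an ordered subset of pipeline stages.

    ``config`` points at a YAML session (required for segment/localize
    unless a simulate stage precedes them and writes one).  ``stats`` can
    run standalone on ``feature_table``.  Returns the run report dict
    (also written to ``out_dir/report.json``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    stages = [s for s in STAGES if s in stages]

    report: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": int(seed),
        "stages": {},
    }
    session = None
    signals = mask = audio = None
    loc_results = None
    table = None

    for stage in stages:
        log.info("stage %s", stage)
        if stage == "simulate":
            n_frames = int(round(duration_s * uio.DEFAULT_FRAME_RATE))
            script = _default_script(n_frames)
            tracks, labels = simulate_trajectories(script, seed=seed)
            events = make_dyad_events(tracks, n_events, seed=seed + 1)
            geometry = uio.default_geometry()
            sim_audio, truth = simulate_array_audio(
                tracks, events, geometry, noise_sd=noise_sd, seed=seed + 2
            )
            uio.write_wav(out_dir / "audio.wav", uio.DEFAULT_SAMPLE_RATE, sim_audio)
            uio.write_tracks(out_dir / "tracks.csv", tracks)
            labels.to_csv(out_dir / "frame_labels.csv", index=False)
            truth.to_csv(out_dir / "ground_truth.csv", index=False)
            session = uio.SessionBundle(
                session_id=f"sim-{seed}",
                audio=out_dir / "audio.wav",
                tracks=out_dir / "tracks.csv",
                geometry=geometry,
            )
            config = uio.write_session_config(out_dir / "session.yaml", session)
            report["stages"]["simulate"] = {
                "n_events": len(events),
                "n_frames": n_frames,
                "noise_sd": noise_sd,
            }
        elif stage == "segment":
            session = session or uio.read_session(_require(config, "segment", "config"))
            _, audio = uio.read_wav(session.audio)
            signals, mask = segment_audio(audio, session.sample_rate)
            rows = [
                (s.id, s.start_s, s.stop_s, s.n_pixels, s.harmonic_flag) for s in signals
            ]
            pd.DataFrame(rows, columns=["signal_id", "start_s", "stop_s", "n_pixels", "harmonic_flag"]).to_csv(
                out_dir / "signals.csv", index=False
            )
            pd.concat(
                [
                    pd.DataFrame(s.contour, columns=["time_s", "freq_hz", "power"]).assign(signal_id=s.id)
                    for s in signals
                ]
                or [pd.DataFrame(columns=["time_s", "freq_hz", "power", "signal_id"])]
            ).to_csv(out_dir / "contours.csv", index=False)
            report["stages"]["segment"] = {"n_signals": len(signals)}
        elif stage == "localize":
            session = session or uio.read_session(_require(config, "localize", "config"))
            if signals is None:
                raise uio.DependencyError("localize needs the segment stage's signals")
            tracks = uio.read_tracks(session.tracks)
            loc_results = localize_session(
                signals, audio, tracks, session.geometry, session.sample_rate, session.frame_rate
            )
            rows = []
            for r in loc_results:
                row = {
                    "signal_id": r.signal_id,
                    "x_m": r.overall_estimate[0],
                    "y_m": r.overall_estimate[1],
                    "assigned_to": r.assigned_to or "unassigned",
                }
                for mid, p in r.mpi.items():
                    row[f"mpi_{mid}"] = p
                rows.append(row)
            pd.DataFrame(rows).to_csv(out_dir / "localization.csv", index=False)
            n_assigned = sum(1 for r in loc_results if r.assigned_to)
            report["stages"]["localize"] = {
                "n_signals": len(loc_results),
                "n_assigned": n_assigned,
            }
        elif stage == "features":
            if signals is None or loc_results is None:
                raise uio.DependencyError("features needs segment and localize artifacts")
            emitters = {r.signal_id: r.assigned_to for r in loc_results if r.assigned_to}
            records = extract_features(
                signals, audio, session.sample_rate, emitters, session.session_id
            )
            table = records_to_table(records)
            uio.write_feature_table(table, out_dir / "features.csv")
            report["stages"]["features"] = {
                "n_records": len(table),
                "n_assigned": int((table["emitter"] != "unassigned").sum()),
            }
        elif stage == "behavior":
            session = session or uio.read_session(_require(config, "behavior", "config"))
            if table is None:
                raise uio.DependencyError("behavior needs the features artifact")
            tracks = uio.read_tracks(session.tracks)
            ids = list(tracks)
            intervals = classify_session(tracks[ids[0]], tracks[ids[1]])
            onset_frames = np.array(
                [
                    int(round(s * session.frame_rate))
                    for s in _onsets_for_table(table, signals)
                ]
            )
            table = label_vocalizations(table, intervals, onset_frames)
            pd.DataFrame(
                [(iv.mouse_id, iv.kind, iv.start_frame, iv.end_frame, iv.partner_id) for iv in intervals],
                columns=["mouse_id", "kind", "start_frame", "end_frame", "partner_id"],
            ).to_csv(out_dir / "bouts.csv", index=False)
            uio.write_feature_table(table, out_dir / "features.csv")
            ctx = context_table(table, intervals, onset_frames)
            ctx.to_csv(out_dir / "context_table.csv")
            per_ctx = table[table["emitter"] != "unassigned"]["context"].value_counts().to_dict()
            report["stages"]["behavior"] = {
                "n_bouts": len(intervals),
                "signals_per_context": {k: int(v) for k, v in per_ctx.items()},
            }
        elif stage == "stats":
            if table is None:
                src = feature_table or (out_dir / "features.csv")
                if not Path(src).exists():
                    raise uio.DependencyError(f"stats needs a feature table; {src} is absent")
                table = uio.read_feature_table(src)
            report["stages"]["stats"] = run_stats(table, out_dir, seed=seed)

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report


def _require(value, stage: str, what: str):
    if value is None:
        raise uio.DependencyError(f"stage {stage!r} needs a {what}")
    return value


def _onsets_for_table(table: pd.DataFrame, signals) -> list[float]:
    if signals is not None:
        by_id = {s.id: s.start_s for s in signals}
        return [by_id.get(v, 0.0) for v in table["voc_id"]]
    return [0.0] * len(table)


def run_stats(
    table: pd.DataFrame,
    out_dir: Path | None = None,
    seed: int = 0,
    n_samples: int = 1000,
    sample_size: int = 500,
    male_label: str = "male",
    female_label: str = "female",
) -> dict:
    """The full statistical battery on an assigned feature table.

    Pooled and per-animal Mann-Whitney contrasts per feature, KS
    non-Gaussianity checks, the Monte-Carlo index distributions (with the
    slope shift), per-session counts with the male-female count
    correlation, and the high/low vocalizer split.
    """
    df = table[table["emitter"] != "unassigned"]
    males = df[df["emitter"] == male_label]
    females = df[df["emitter"] == female_label]
    summary: dict = {
        "n_assigned": int(len(df)),
        "n_male": int(len(males)),
        "n_female": int(len(females)),
    }
    if len(df):
        summary["female_fraction"] = len(females) / len(df)

    pooled_rows = []
    mc_rows = []
    for feat in NUMERIC_FEATURES:
        xm = males[feat].dropna().to_numpy()
        xf = females[feat].dropna().to_numpy()
        if len(xm) == 0 or len(xf) == 0:
            continue
        tr = mann_whitney(xm, xf)
        pooled_rows.append(
            (
                feat, tr.u, tr.z, tr.p, tr.n1, tr.n2,
                tr.median1, tr.iqr1[0], tr.iqr1[1],
                tr.median2, tr.iqr2[0], tr.iqr2[1],
                ks_nongaussian(np.concatenate([xm, xf])) if len(xm) + len(xf) >= 10 else np.nan,
            )
        )
        if len(xm) >= sample_size and len(xf) >= sample_size:
            dist = monte_carlo_index(
                df, feat, n_samples=n_samples, sample_size=sample_size, seed=seed,
                male_label=male_label, female_label=female_label,
            )
            mc_rows.append(
                (feat, dist.n_positive, dist.n_negative, float(np.median(dist.indices)),
                 dist.slope_shift_constant)
            )
    pooled = pd.DataFrame(
        pooled_rows,
        columns=[
            "feature", "U", "z", "p", "n_male", "n_female",
            "male_median", "male_q25", "male_q75",
            "female_median", "female_q25", "female_q75", "ks_p",
        ],
    )
    mc = pd.DataFrame(
        mc_rows,
        columns=["feature", "n_positive", "n_negative", "median_index", "slope_shift"],
    )

    # per-animal medians (one point per animal per session)
    animal_rows = []
    for feat in NUMERIC_FEATURES:
        if df[feat].dropna().empty:
            continue
        med = per_animal_medians(df, feat)
        xm = med.loc[med["emitter"] == male_label, "median"].to_numpy()
        xf = med.loc[med["emitter"] == female_label, "median"].to_numpy()
        if len(xm) and len(xf):
            tr = mann_whitney(xm, xf)
            animal_rows.append(
                (feat, tr.u, tr.z, tr.p, len(xm), len(xf), tr.median1, tr.median2, tr.method)
            )
    per_animal = pd.DataFrame(
        animal_rows,
        columns=["feature", "U", "z", "p", "n_male", "n_female", "male_median", "female_median", "method"],
    )

    counts = session_counts(df)
    cm = counts[counts["emitter"] == male_label].set_index("date")["count"]
    cf = counts[counts["emitter"] == female_label].set_index("date")["count"]
    joint = pd.concat([cm, cf], axis=1, keys=["male", "female"]).dropna()
    if len(joint) >= 3 and joint["male"].std() > 0 and joint["female"].std() > 0:
        r, p = pearson(joint["male"], joint["female"])
        summary["count_correlation_r"] = r
        summary["count_correlation_p"] = p
    split = vocalizer_split(joint["male"].to_dict()) if len(joint) else {}
    summary["n_high_vocalizer_sessions"] = sum(1 for v in split.values() if v == "high")
    summary["median_male_count"] = float(cm.median()) if len(cm) else np.nan
    summary["median_female_count"] = float(cf.median()) if len(cf) else np.nan

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        pooled.to_csv(out_dir / "stats_pooled.csv", index=False)
        per_animal.to_csv(out_dir / "stats_per_animal.csv", index=False)
        mc.to_csv(out_dir / "stats_mc_index.csv", index=False)
        counts.to_csv(out_dir / "stats_session_counts.csv", index=False)
    summary["features_tested"] = pooled["feature"].tolist()
    summary["mc_features"] = mc["feature"].tolist()
    return summary
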