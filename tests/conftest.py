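"""Shared fixtures: one small noise-free simulated dyad reused across the
segmentation/localization/feature tests (segmentation of array audio is the
expensive step, so it runs once per session)."""

from __future__ import annotations

import numpy as np
import pytest

from usvdyad.io import default_geometry
from usvdyad.segmentation import segment_audio
from usvdyad.synth import (
    BehaviorScript,
    BoutSpec,
    make_dyad_events,
    simulate_array_audio,
    simulate_trajectories,
)


@pytest.fixture(scope="session")
def geometry():
    return default_geometry()


@pytest.fixture(scope="session")
def dyad(geometry):
    """A 5 s noise-free dyad with 8 planted chirps, segmented once.

    Returns a dict with tracks, events truth table, audio, and the
    extracted signals (in onset order, one per planted chirp).
    """
    script = BehaviorScript(
        bouts=[BoutSpec("following", 30, 20, leader_id="male"), BoutSpec("not_close", 90, 25)],
        n_frames=150,
    )
    tracks, labels = simulate_trajectories(script, seed=11)
    events = make_dyad_events(tracks, 8, seed=12)
    audio, truth = simulate_array_audio(tracks, events, geometry, noise_sd=0.0, seed=13)
    signals, mask = segment_audio(audio)
    return {
        "tracks": tracks,
        "labels": labels,
        "events": events,
        "truth": truth,
        "audio": audio,
        "signals": signals,
        "mask": mask,
        "geometry": geometry,
    }


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)
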