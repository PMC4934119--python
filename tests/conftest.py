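"""Shared fixtures: small hand-built songs and seeded synthetic chunks."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from songpulse.io import NoteEvent, SongChunk
from songpulse import synth


def make_chunk(onsets, durations=0.05, labels=None, bird_id="bird", index=0):
    """Build a chunk from explicit onset times (uniform duration by default)."""
    onsets = list(onsets)
    if np.isscalar(durations):
        durations = [durations] * len(onsets)
    if labels is None:
        labels = [chr(ord("a") + i % 4) for i in range(len(onsets))]
    events = [
        NoteEvent(onset=t, offset=t + d, label=lab)
        for t, d, lab in zip(onsets, durations, labels)
    ]
    return SongChunk(bird_id=bird_id, chunk_index=index, events=events)


def random_chunk(rng, n_notes=6, ioi_range=(0.06, 0.20), duration_frac=0.6):
    """A chunk with uniformly random IOIs — no underlying pulse."""
    iois = rng.uniform(*ioi_range, size=n_notes - 1)
    onsets = np.concatenate(([0.0], np.cumsum(iois)))
    durations = duration_frac * np.concatenate((iois, [iois[-1]]))
    return make_chunk(onsets, durations)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def jittered_chunk():
    """A pulse-aligned 25 Hz chunk with 2 ms timing jitter."""
    spec = synth.default_spec(25.0, seed=7, jitter_sd=0.002, n_motifs=3)
    chunk, transitions, truth = synth.generate_pulse_aligned_chunk(spec)
    return chunk, transitions, truth


@pytest.fixture
def synthetic_bird():
    """Ten chunks of one simulated bird (shared motif, 25 Hz, 2 ms jitter)."""
    return synth.bird_chunks(25.0, 10, seed=42, jitter_sd=0.002, bird_id="b1")
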