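"""Synthetic zebra-finch-like songs with known rhythmic ground truth.

Real zebra finch song consists of motifs of 4-7 distinct notes repeated up
to ~10 times per chunk; note durations lie roughly between 26 and 256 ms
(134 +/- 60 ms) and within-chunk silent gaps mostly between 6 and 88 ms.
The generator emulates exactly this structure on an explicit isochronous
grid: note onsets sit on integer multiples of a pulse period (10-60 Hz),
note durations span whole periods minus a sub-period gap residue, and
within-note gesture transitions sit on interior pulse times. Gaussian
timing jitter (truncated at +/- 2 sd to preserve event order) then blurs
every onset, offset and transition independently. Because the generating
frequency, phase and transition times are known, pulse-recovery and
coincidence statistics can be validated without any recordings.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import NoteEvent, SongChunk, write_label_file
from .gestures import GestureTransitionSet
from .nullmodels import MomentSpec, sample_durations

__all__ = [
    "SynthSpec",
    "default_spec",
    "bird_chunks",
    "generate_pulse_aligned_chunk",
    "generate_arrhythmic_chunk",
    "write_fixture",
]

_NOTE_RANGE = (0.026, 0.256)  # realistic note duration bounds (s)
_GAP_RESIDUE_RANGE = (0.008, 0.030)  # sub-period gap residues (s)


@dataclass(frozen=True)
class SynthSpec:
    """Blueprint of one pulse-aligned synthetic chunk.

    ``note_lengths[label]`` is the note's span in whole pulse periods; the
    gap after a note is ``gap_periods[label]`` whole periods plus
    ``gap_residue[label]`` seconds, carved out of the note's final period so
    consecutive onsets stay on the pulse grid. ``gesture_layout[label]``
    lists interior pulse indices (1 .. periods-1) that carry a gesture
    transition.
    """

    f0: float
    pattern: tuple[str, ...]
    note_lengths: dict[str, int]
    gap_residue: dict[str, float]
    gap_periods: dict[str, int] = field(default_factory=dict)
    gesture_layout: dict[str, tuple[int, ...]] = field(default_factory=dict)
    jitter_sd: float = 0.0
    n_motifs: int = 3
    start: float = 0.5
    seed: int = 0
    bird_id: str = "synthetic"
    chunk_index: int = 0
    #: emulated measurement resolution (s); annotation timestamps are read
    #: off at 1 ms, so generated times are quantized the same way
    time_resolution: float = 0.001

    def __post_init__(self) -> None:
        if not (10.0 <= self.f0 <= 60.0):
            raise ValueError("f0 must lie in the 10-60 Hz range of plausible pulses")
        if not (1 <= self.n_motifs <= 10):
            raise ValueError("n_motifs must be between 1 and 10")
        if len(set(self.pattern)) < 3:
            raise ValueError("pattern needs at least 3 distinct labels")
        period = 1.0 / self.f0
        for lab in self.pattern:
            k = self.note_lengths[lab]
            if k < 1:
                raise ValueError(f"note {lab!r} must span >= 1 period")
            res = self.gap_residue[lab]
            if not (0 < res < period):
                raise ValueError(
                    f"gap residue for {lab!r} must lie strictly inside one period"
                )
            if self.gap_periods.get(lab, 0) < 0:
                raise ValueError("gap_periods must be >= 0")
            for g in self.gesture_layout.get(lab, ()):
                if not (1 <= g <= k - 1):
                    raise ValueError(
                        f"gesture index {g} of note {lab!r} must be interior (1..{k - 1})"
                    )


def default_spec(
    f0: float,
    seed: int = 0,
    jitter_sd: float = 0.0,
    n_motifs: int = 3,
    bird_id: str = "synthetic",
    chunk_index: int = 0,
) -> SynthSpec:
    """A realistic random spec at the given pulse frequency.

    Samples a motif of 4-7 distinct notes whose durations respect the
    26-256 ms range at this tempo. The first two notes get consecutive
    period counts, which makes the set of inter-onset period counts coprime
    and the generating pulse the unique slowest zero-deviation pulse. Every
    inter-onset interval spans at least two periods, matching real song,
    where the shortest measured IOI sits well below the pulse period count
    of one (derived scan floors of 5.5-14.9 Hz against 18-45 Hz pulses);
    this keeps the per-chunk scan floor below f0 even under jitter.
    """
    rng = np.random.default_rng(seed)
    period = 1.0 / f0
    res_lo, res_hi = _GAP_RESIDUE_RANGE
    res_hi = min(res_hi, 0.8 * period)
    if res_hi <= res_lo:
        res_lo, res_hi = 0.5 * res_hi, res_hi
    n_labels = int(rng.integers(4, 8))
    labels = tuple("abcdefg"[:n_labels])
    note_lengths: dict[str, int] = {}
    gap_residue: dict[str, float] = {}
    gesture_layout: dict[str, tuple[int, ...]] = {}
    lo, hi = _NOTE_RANGE
    gap_periods: dict[str, int] = {}
    for j, lab in enumerate(labels):
        res = float(rng.uniform(res_lo, res_hi))
        k_min = max(2, math.ceil((lo + res) / period))
        k_max = max(k_min, math.floor((hi + res) / period))
        if j == 0:
            k = k_min
        elif j == 1:
            # force a period count coprime with the first note's: via the
            # note itself, or via a whole-period gap when durations cap out
            if k_max > k_min:
                k = k_min + 1
            else:
                k = k_min
                gap_periods[lab] = 1
        else:
            k = int(rng.integers(k_min, k_max + 1))
        note_lengths[lab] = k
        gap_residue[lab] = res
        gesture_layout[lab] = tuple(range(1, k))  # every interior pulse
    return SynthSpec(
        f0=f0,
        pattern=labels,
        note_lengths=note_lengths,
        gap_residue=gap_residue,
        gap_periods=gap_periods,
        gesture_layout=gesture_layout,
        jitter_sd=jitter_sd,
        n_motifs=n_motifs,
        seed=seed,
        bird_id=bird_id,
        chunk_index=chunk_index,
    )


def bird_chunks(
    f0: float,
    n_chunks: int,
    seed: int = 0,
    jitter_sd: float = 0.002,
    motif_range: tuple[int, int] = (2, 5),
    bird_id: str = "synthetic",
) -> list[tuple[SongChunk, GestureTransitionSet, dict]]:
    """A bird's worth of chunks: one shared motif blueprint, varying renditions.

    Real birds sing one stereotyped motif, so all chunks of a simulated bird
    share the blueprint drawn from ``seed``; chunks differ in motif count
    (uniform over ``motif_range``) and in their independent timing jitter.
    This keeps within-type duration spread at jitter scale, as in real song.
    """
    base = default_spec(f0, seed=seed, jitter_sd=jitter_sd, bird_id=bird_id)
    rng = np.random.default_rng(seed)
    out = []
    lo, hi = motif_range
    for ci in range(n_chunks):
        spec = replace(
            base,
            seed=seed + 1 + ci,
            chunk_index=ci,
            n_motifs=int(rng.integers(lo, hi + 1)),
        )
        out.append(generate_pulse_aligned_chunk(spec))
    return out


def _truncated_jitter(rng: np.random.Generator, sd: float, n: int) -> np.ndarray:
    """Gaussian jitter truncated at +/- 2 sd (redrawn, not clipped)."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    out = rng.normal(0.0, sd, n)
    for _ in range(100):
        bad = np.abs(out) > 2 * sd
        if not bad.any():
            break
        out[bad] = rng.normal(0.0, sd, int(bad.sum()))
    return np.clip(out, -2 * sd, 2 * sd)


def generate_pulse_aligned_chunk(
    spec: SynthSpec,
) -> tuple[SongChunk, GestureTransitionSet, dict]:
    """Realize a spec: grid-aligned events, then independent timing jitter.

    Returns ``(chunk, transitions, ground_truth)`` where ``ground_truth``
    records the generating frequency ``f0``, the grid phase, and the
    unjittered onset/transition times.

    Raises if the jittered events overlap (possible only for specs whose
    gaps are shorter than four jitter standard deviations).
    """
    rng = np.random.default_rng(spec.seed)
    period = 1.0 / spec.f0
    onsets, offsets, labels, transitions = [], [], [], []
    t = spec.start
    seq = list(spec.pattern) * spec.n_motifs
    for lab in seq:
        k = spec.note_lengths[lab]
        res = spec.gap_residue[lab]
        onsets.append(t)
        offsets.append(t + k * period - res)
        labels.append(lab)
        for g in spec.gesture_layout.get(lab, ()):
            transitions.append(t + g * period)
        t += (k + spec.gap_periods.get(lab, 0)) * period
    onsets = np.asarray(onsets)
    offsets = np.asarray(offsets)
    transitions = np.asarray(transitions)

    truth = {
        "f0": spec.f0,
        "phase": spec.start % period,
        "onsets": onsets.tolist(),
        "transitions": transitions.tolist(),
        "seed": spec.seed,
    }

    j_on = _truncated_jitter(rng, spec.jitter_sd, onsets.size)
    j_off = _truncated_jitter(rng, spec.jitter_sd, offsets.size)
    j_tr = _truncated_jitter(rng, spec.jitter_sd, transitions.size)
    onsets = onsets + j_on
    offsets = offsets + j_off
    transitions = transitions + j_tr
    if spec.time_resolution > 0:
        # annotated timestamps carry finite measurement resolution
        q = spec.time_resolution
        onsets = np.round(onsets / q) * q
        offsets = np.round(offsets / q) * q
        transitions = np.round(transitions / q) * q

    events = []
    for i, lab in enumerate(labels):
        if onsets[i] >= offsets[i] or (i > 0 and onsets[i] < offsets[i - 1]):
            raise ValueError(
                "jittered events overlap; reduce jitter_sd or widen the gaps"
            )
        events.append(NoteEvent(onset=float(onsets[i]), offset=float(offsets[i]), label=lab))
    chunk = SongChunk(
        bird_id=spec.bird_id,
        chunk_index=spec.chunk_index,
        events=events,
        context="synthetic",
    )
    tset = GestureTransitionSet(
        chunk_ref=chunk.ref,
        times=tuple(float(x) for x in transitions),
        source="curated",
    )
    return chunk, tset, truth


def generate_arrhythmic_chunk(
    note_moments: MomentSpec,
    gap_moments: MomentSpec,
    n_notes: int,
    seed: int,
    bird_id: str = "arrhythmic",
    chunk_index: int = 0,
    start: float = 0.5,
) -> SongChunk:
    """Negative control: independent finch-like durations, no underlying pulse.

    Note and gap durations are independent Pearson draws from the given
    moment specs; with zero-variance (degenerate) specs the output collapses
    to an isochronous grid. Labels cycle a, b, c, ... so the chunk passes
    the complexity filter.
    """
    if n_notes < 1:
        raise ValueError("n_notes must be >= 1")
    rng = np.random.default_rng(seed)
    note_durs = sample_durations(note_moments, n_notes, rng)
    gap_durs = sample_durations(gap_moments, max(n_notes - 1, 0), rng)
    labels = [chr(ord("a") + i % 5) for i in range(n_notes)]
    events = []
    t = start
    for i in range(n_notes):
        events.append(NoteEvent(onset=t, offset=t + note_durs[i], label=labels[i]))
        t += note_durs[i]
        if i < n_notes - 1:
            t += gap_durs[i]
    return SongChunk(
        bird_id=bird_id, chunk_index=chunk_index, events=events, context="synthetic"
    )


def write_fixture(
    spec: SynthSpec, out_dir: str | Path, dialect: str = "audacity_tsv"
) -> dict[str, Path]:
    """Write a spec's label file and ground-truth JSON to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chunk, tset, truth = generate_pulse_aligned_chunk(spec)
    ext = "txt" if dialect == "audacity_tsv" else "csv"
    label_path = out_dir / f"{spec.bird_id}_{spec.chunk_index:03d}.{ext}"
    write_label_file(chunk.events, label_path, dialect=dialect)
    truth_path = out_dir / f"{spec.bird_id}_{spec.chunk_index:03d}.truth.json"
    truth_payload = dict(truth)
    truth_payload["transition_times"] = list(tset.times)
    with open(truth_path, "w") as fh:
        json.dump(truth_payload, fh, indent=1)
    return {"labels": label_path, "truth": truth_path}
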