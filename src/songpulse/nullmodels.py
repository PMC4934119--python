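"""Randomized null songs and the restricted-range pulse comparison.

Two surrogate models ask whether a well-fitting isochronous pulse is a
property of the recorded song or of any sequence of finch-like durations:

* **Model R** ("random sequence") redraws every note and gap duration
  independently from a Pearson-family distribution matched to the first
  four moments of the observed duration pools, destroying both sequence
  and repetition structure.
* **Model C** ("consistent sequence") keeps the note sequence: each note
  or gap type gets a fixed set of 100 candidate durations (standard-normal
  draws retargeted to a random mean within the observed range of type
  means, with spread equal to the mean of the type spreads), and every
  instance of a type draws from its set — so repetitions of a type stay
  similar, as in real song.

Real and surrogate chunks are then refitted within a restricted frequency
band one octave wide (upper bound = 2 x lower) centered on the bird's
dominant cluster frequency, and their FRMSDs compared over repeated
surrogate draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._pearson import pearson_rvs
from .io import DurationTable, NoteEvent, SongChunk, build_duration_table
from .pulse import PulseFit, ScanConfig, gat_best_pulse, restrict

__all__ = [
    "MomentSpec",
    "TypeDurationSets",
    "ModelConfig",
    "fit_moments",
    "filter_gap_durations",
    "sample_durations",
    "model_r_chunk",
    "model_c_sets",
    "model_c_chunk",
    "restricted_range",
    "run_comparison",
    "DEFAULT_MIN_DURATION",
]

#: Durations below this (s) are rejected and redrawn.
DEFAULT_MIN_DURATION = 0.005

_MAX_REJECTION_ROUNDS = 1000


@dataclass(frozen=True)
class MomentSpec:
    """First four moments of a duration pool (kurtosis conventional: normal = 3)."""

    mean: float
    std: float
    skewness: float
    kurtosis: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.std < 0:
            raise ValueError("std must be non-negative")
        if not self.degenerate and self.kurtosis < self.skewness**2 + 1:
            raise ValueError(
                f"infeasible moments: kurtosis {self.kurtosis} below the bound "
                f"skewness^2 + 1 = {self.skewness**2 + 1}"
            )


@dataclass(frozen=True)
class TypeDurationSets:
    """Fixed per-type candidate duration sets for Model C (100 values each)."""

    note_sets: dict[str, np.ndarray]
    gap_sets: dict[str, np.ndarray]
    bird_seed: int


@dataclass(frozen=True)
class ModelConfig:
    """Configuration of one null-model comparison run."""

    model: str  # "R" or "C"
    freq_range: tuple[float, float]
    reps: int = 50
    bird_seed: int = 1
    chunk_seed_base: int = 10_000
    min_duration: float = DEFAULT_MIN_DURATION

    def __post_init__(self) -> None:
        if self.model not in ("R", "C"):
            raise ValueError(f"model must be 'R' or 'C', got {self.model!r}")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        lower, upper = self.freq_range
        if not np.isclose(upper, 2 * lower):
            raise ValueError(
                f"restricted range must span one octave (upper = 2 x lower), "
                f"got {self.freq_range}"
            )


def fit_moments(samples: Sequence[float]) -> MomentSpec:
    """Sample mean, std, skewness and conventional kurtosis of a duration pool.

    Constant pools are flagged degenerate (skewness/kurtosis undefined;
    reported as 0 and 3). Requires at least 4 samples.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 4:
        raise ValueError(f"need >= 4 samples to fit four moments, got {x.size}")
    std = float(np.std(x, ddof=1))
    if np.all(x == x[0]):
        return MomentSpec(mean=float(x[0]), std=0.0, skewness=0.0, kurtosis=3.0,
                          degenerate=True)
    return MomentSpec(
        mean=float(np.mean(x)),
        std=std,
        skewness=float(sps.skew(x)),
        kurtosis=float(sps.kurtosis(x, fisher=False)),
    )


def filter_gap_durations(
    gap_table: DurationTable,
    iqr_factor: float = 1.5,
    type_mean_max: float = 0.09,
    type_std_max: float = 0.03,
) -> tuple[np.ndarray, dict[str, int]]:
    """Exclude unusual gaps before fitting the Model R gap distribution.

    Two-stage exclusion: (a) within each type, values outside the Tukey
    fences Q1/Q3 -/+ ``iqr_factor`` x IQR are dropped; (b) whole gap
    *types* whose remaining values still have mean > ``type_mean_max`` or
    std > ``type_std_max`` are dropped entirely (the long, variable
    between-motif silences carry no within-motif rhythm information).
    Returns the pooled surviving durations and removal counts.
    """
    if not gap_table.gap_durations:
        raise ValueError("empty gap table")
    removed = {"types_removed": 0, "values_in_removed_types": 0, "outliers": 0}
    survivors: list[np.ndarray] = []
    for label in sorted(gap_table.gap_durations):
        vals = np.asarray(gap_table.gap_durations[label], dtype=float)
        q1, q3 = np.percentile(vals, [25, 75])
        iqr = q3 - q1
        lo, hi = q1 - iqr_factor * iqr, q3 + iqr_factor * iqr
        keep = (vals >= lo) & (vals <= hi)
        kept = vals[keep]
        mean = float(np.mean(kept)) if kept.size else np.inf
        std = float(np.std(kept, ddof=1)) if kept.size > 1 else 0.0
        if mean > type_mean_max or std > type_std_max:
            removed["types_removed"] += 1
            removed["values_in_removed_types"] += vals.size
            continue
        removed["outliers"] += int((~keep).sum())
        survivors.append(kept)
    pooled = np.concatenate(survivors) if survivors else np.empty(0)
    return pooled, removed


def sample_durations(
    spec: MomentSpec,
    size: int,
    rng: np.random.Generator,
    min_duration: float = DEFAULT_MIN_DURATION,
) -> np.ndarray:
    """Pearson-family draws with rejection below ``min_duration``.

    Rejection (rather than truncation-by-clipping) keeps the realized
    moments close to the spec when the sub-threshold mass is small.
    """
    out = np.empty(size)
    filled = 0
    for _ in range(_MAX_REJECTION_ROUNDS):
        if filled == size:
            return out
        draws = pearson_rvs(
            spec.mean, spec.std, spec.skewness, spec.kurtosis, size - filled, rng
        )
        good = draws[draws >= min_duration]
        take = min(good.size, size - filled)
        out[filled : filled + take] = good[:take]
        filled += take
    raise RuntimeError(
        f"rejection sampling failed: moment spec {spec} places almost all mass "
        f"below min_duration={min_duration}"
    )


def _chunk_from_durations(
    template: SongChunk,
    note_durs: np.ndarray,
    gap_durs: np.ndarray,
    suffix: str,
) -> SongChunk:
    events = []
    t = template.start
    for i, ev in enumerate(template.events):
        events.append(NoteEvent(onset=t, offset=t + note_durs[i], label=ev.label))
        t += note_durs[i]
        if i < len(template.events) - 1:
            t += gap_durs[i]
    return SongChunk(
        bird_id=template.bird_id,
        chunk_index=template.chunk_index,
        events=events,
        context=suffix,
    )


def model_r_chunk(
    template: SongChunk,
    note_moments: MomentSpec,
    gap_moments: MomentSpec,
    seed: int,
    min_duration: float = DEFAULT_MIN_DURATION,
) -> SongChunk:
    """Random-sequence surrogate: every duration drawn independently.

    The surrogate has the template's note count and labels but all note and
    gap durations are fresh Pearson draws from the pooled-moment specs, so
    neither the sequence nor the repetition structure of the original
    survives.
    """
    rng = np.random.default_rng(seed)
    n = template.n_notes
    note_durs = sample_durations(note_moments, n, rng, min_duration)
    gap_durs = sample_durations(gap_moments, n - 1, rng, min_duration) if n > 1 else np.empty(0)
    return _chunk_from_durations(template, note_durs, gap_durs, "model_R")


def model_c_sets(
    table: DurationTable,
    bird_seed: int,
    set_size: int = 100,
    min_duration: float = DEFAULT_MIN_DURATION,
) -> TypeDurationSets:
    """Build the fixed per-type duration sets for Model C.

    For every note type, ``set_size`` standard-normal draws are affinely
    retargeted: the set mean is a uniform draw between the smallest and
    largest observed note-type means, the set std is the mean of the
    observed note-type stds. Gap types are treated the same way using the
    gap-type statistics. Values below ``min_duration`` are redrawn. The
    same ``bird_seed`` reproduces identical sets, so all chunks of one bird
    share one realization.
    """
    if not table.note_durations or not table.gap_durations:
        raise ValueError("need at least one note type and one gap type")
    rng = np.random.default_rng(bird_seed)

    def build(per_type: dict[str, list[float]]) -> dict[str, np.ndarray]:
        labels = sorted(per_type)
        means = {
            lab: float(np.mean(per_type[lab])) for lab in labels
        }
        stds = {
            lab: float(np.std(per_type[lab], ddof=1)) if len(per_type[lab]) > 1 else 0.0
            for lab in labels
        }
        lo, hi = min(means.values()), max(means.values())
        target_std = float(np.mean(list(stds.values())))
        sets = {}
        for lab in labels:
            target_mean = float(rng.uniform(lo, hi)) if hi > lo else lo
            vals = target_mean + target_std * rng.standard_normal(set_size)
            for _ in range(_MAX_REJECTION_ROUNDS):
                bad = vals < min_duration
                if not bad.any():
                    break
                vals[bad] = target_mean + target_std * rng.standard_normal(
                    int(bad.sum())
                )
            else:
                raise RuntimeError(
                    f"cannot keep type {lab!r} durations above {min_duration}s"
                )
            sets[lab] = vals
        return sets

    return TypeDurationSets(
        note_sets=build(table.note_durations),
        gap_sets=build(table.gap_durations),
        bird_seed=bird_seed,
    )


def model_c_chunk(
    template: SongChunk,
    sets: TypeDurationSets,
    chunk_seed: int,
) -> SongChunk:
    """Consistent-sequence surrogate: each instance draws from its type's set.

    Two instances of the same type may receive different values, but always
    from the same fixed 100-element set, which keeps repetitions of a type
    similar across the chunk (and, via ``bird_seed``, across all chunks of
    the bird). Gaps use the set of their preceding note's type.
    """
    rng = np.random.default_rng(chunk_seed)
    n = template.n_notes
    note_durs = np.empty(n)
    gap_durs = np.empty(max(n - 1, 0))
    for i, ev in enumerate(template.events):
        if ev.label not in sets.note_sets:
            raise ValueError(f"no Model C set for note type {ev.label!r}")
        note_durs[i] = sets.note_sets[ev.label][rng.integers(0, len(sets.note_sets[ev.label]))]
        if i < n - 1:
            if ev.label not in sets.gap_sets:
                raise ValueError(f"no Model C set for gap type {ev.label!r}'")
            gap_durs[i] = sets.gap_sets[ev.label][rng.integers(0, len(sets.gap_sets[ev.label]))]
    return _chunk_from_durations(template, note_durs, gap_durs, "model_C")


def restricted_range(center: float) -> tuple[float, float]:
    """Octave-wide scan band geometrically centered on ``center``.

    ``lower = center / sqrt(2)``, ``upper = center * sqrt(2)``, so
    ``upper = 2 * lower`` exactly: any frequency outside the band has
    exactly one power-of-two multiple or fraction inside it.
    """
    if center <= 0:
        raise ValueError("center frequency must be positive")
    lower = center / np.sqrt(2)
    return (float(lower), float(2 * lower))


def run_comparison(
    chunks: Sequence[SongChunk],
    config: ModelConfig,
    scan: ScanConfig = ScanConfig(),
    duration_table: DurationTable | None = None,
) -> pd.DataFrame:
    """Paired FRMSD comparison of real chunks against surrogate counterparts.

    Every real chunk is refitted inside ``config.freq_range``; for each of
    ``config.reps`` repetitions a surrogate counterpart is generated
    (Model R or C, seeded deterministically from ``chunk_seed_base``, chunk
    index and repetition) and fitted in the same band. Returns a table with
    one row per (chunk, rep):
    ``bird_id, chunk_index, rep, model, frmsd_real, frmsd_model, n_notes``.
    """
    if not chunks:
        raise ValueError("no chunks to compare")
    lower, upper = config.freq_range
    band = restrict(scan, lower, upper)
    if duration_table is None:
        duration_table = build_duration_table(chunks)

    if config.model == "R":
        note_moments = fit_moments(duration_table.pooled_notes())
        gaps, _ = filter_gap_durations(duration_table)
        gap_moments = fit_moments(gaps)
    else:
        sets = model_c_sets(
            duration_table, config.bird_seed, min_duration=config.min_duration
        )

    rows = []
    for ci, chunk in enumerate(chunks):
        real_fit: PulseFit = gat_best_pulse(chunk, band)
        for rep in range(config.reps):
            seed = config.chunk_seed_base + ci * config.reps + rep
            if config.model == "R":
                surrogate = model_r_chunk(
                    chunk, note_moments, gap_moments, seed, config.min_duration
                )
            else:
                surrogate = model_c_chunk(chunk, sets, seed)
            model_fit = gat_best_pulse(surrogate, band)
            rows.append(
                {
                    "bird_id": chunk.bird_id,
                    "chunk_index": chunk.chunk_index,
                    "rep": rep,
                    "model": config.model,
                    "frmsd_real": real_fit.frmsd,
                    "frmsd_model": model_fit.frmsd,
                    "n_notes": chunk.n_notes,
                }
            )
    return pd.DataFrame(rows)
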