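"""Gesture transitions and their coincidence with the fitted pulse.

Notes concatenate one or more neuromuscular gestures; the boundary between
successive gestures shows up as a local minimum of the amplitude envelope
together with a discontinuity in the frequency trace. This module detects
candidate transitions from a sampled envelope, measures how often curated
transitions fall within a window around the nearest pulse time (windows of
1/10, 1/6 and 1/4 of the pulse period), and tests the per-bird coincidence
fractions against the analytic chance level of 2 x window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.signal import find_peaks

from .pulse import PulseFit

__all__ = [
    "GestureTransitionSet",
    "CoincidenceResult",
    "DEFAULT_WINDOWS",
    "envelope_minima_candidates",
    "coincidence_fractions",
    "chance_level",
    "coincidence_ttest",
]

#: Coincidence windows as fractions of the pulse period.
DEFAULT_WINDOWS = (1 / 10, 1 / 6, 1 / 4)


@dataclass(frozen=True)
class GestureTransitionSet:
    """Within-note transition times for one chunk."""

    chunk_ref: tuple[str, int]
    times: tuple[float, ...]
    source: str = "curated"  # or "envelope_detected"

    def __post_init__(self) -> None:
        if self.source not in ("curated", "envelope_detected"):
            raise ValueError(f"unknown source {self.source!r}")


@dataclass(frozen=True)
class CoincidenceResult:
    """Observed vs chance coincidence fractions per window."""

    windows: tuple[float, ...]
    observed_fraction: tuple[float, ...]
    chance: tuple[float, ...]
    n_transitions: int


def envelope_minima_candidates(
    times: Sequence[float],
    amplitude: Sequence[float],
    min_depth: float,
    min_separation: float,
    note_spans: Sequence[tuple[float, float]],
) -> np.ndarray:
    """Candidate gesture transitions: prominent envelope minima inside notes.

    A simplified local-minima detector: minima of the uniformly sampled
    amplitude envelope with prominence >= ``min_depth`` and pairwise
    separation >= ``min_separation`` are returned, restricted to the given
    note spans. Candidates still require curation against the spectrogram
    (minima also occur inside gestures); this stage only proposes times.
    """
    times = np.asarray(times, dtype=float)
    amplitude = np.asarray(amplitude, dtype=float)
    if times.size != amplitude.size or times.size < 3:
        raise ValueError("envelope needs matched time/amplitude arrays, length >= 3")
    if min_depth <= 0 or min_separation <= 0:
        raise ValueError("min_depth and min_separation must be positive")
    dt = np.diff(times)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("envelope must be uniformly sampled")
    step = float(dt[0])
    distance = max(1, int(round(min_separation / step)))
    minima, _ = find_peaks(-amplitude, prominence=min_depth, distance=distance)
    candidate_times = times[minima]
    keep = np.zeros(candidate_times.size, dtype=bool)
    for onset, offset in note_spans:
        keep |= (candidate_times >= onset) & (candidate_times <= offset)
    return candidate_times[keep]


def coincidence_fractions(
    transitions: GestureTransitionSet,
    fit: PulseFit,
    windows: Sequence[float] = DEFAULT_WINDOWS,
) -> CoincidenceResult:
    """Fraction of transitions within each window around the nearest pulse.

    A transition counts for window ``w`` when its distance to the nearest
    pulse time is strictly less than ``w`` periods. Fractions are therefore
    non-decreasing in ``w``.
    """
    t = np.asarray(transitions.times, dtype=float)
    if t.size == 0:
        raise ValueError("empty transition set")
    period = fit.period
    rel = (t - fit.anchor - fit.offset) % period
    dist = np.minimum(rel, period - rel)
    observed = tuple(float(np.mean(dist < w * period)) for w in windows)
    chance = tuple(chance_level(w) for w in windows)
    return CoincidenceResult(
        windows=tuple(windows),
        observed_fraction=observed,
        chance=chance,
        n_transitions=int(t.size),
    )


def chance_level(window: float) -> float:
    """Probability that a uniformly random time lands within ``window`` periods
    of the nearest pulse: the window extends to both sides of every pulse, so
    the covered fraction of total time is exactly ``2 * window``."""
    if not (0 < window <= 0.5):
        raise ValueError("window must be in (0, 1/2]; larger windows overlap")
    return 2.0 * window


def coincidence_ttest(
    per_bird_fractions: Sequence[float], chance: float
) -> tuple[float, int, float]:
    """Two-sided one-sample t-test of per-bird coincidence fractions vs chance.

    Returns ``(t, df, p)`` with ``df = n - 1``.
    """
    x = np.asarray(per_bird_fractions, dtype=float)
    if x.size < 2:
        raise ValueError("need fractions from at least 2 birds")
    if np.all(x == x[0]):
        # zero variance: no evidence either way (t would be 0/0)
        return (0.0, int(x.size - 1), 1.0) if x[0] == chance else (
            float(np.inf) * np.sign(x[0] - chance),
            int(x.size - 1),
            0.0,
        )
    res = sps.ttest_1samp(x, popmean=chance)
    return float(res.statistic), int(x.size - 1), float(res.pvalue)
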