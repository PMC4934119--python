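"""Isochronous pulse estimation from note-onset times.

The signal-derived pulse of a song chunk is found by generate-and-test
(GAT): candidate isochronous pulses are laid out on a frequency grid, each
is phase-shifted over a full period in 1 ms steps, and the goodness of fit
of each (frequency, offset) pair is the root-mean-square deviation (RMSD)
of all note onsets from their nearest pulse time. Because faster pulses
trivially achieve smaller RMSDs, the selection statistic is the
frequency-normalized RMSD (FRMSD = RMSD x frequency), i.e. deviation as a
fraction of the pulse period; the best pulse is the one with minimal FRMSD,
ties going to the slowest pulse. An independent point-process Fourier
estimate corroborates the GAT frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io import SongChunk

__all__ = [
    "ScanConfig",
    "PulseFit",
    "ScanCurve",
    "min_scan_frequency",
    "frequency_grid",
    "offset_grid",
    "rmsd_at",
    "best_offset",
    "gat_best_pulse",
    "scan_curve",
    "fft_peak_frequency",
    "method_agreement",
    "restrict",
]


@dataclass(frozen=True)
class ScanConfig:
    """Grid-search parameters for pulse matching.

    ``f_min`` is normally left ``None`` and derived per chunk from the
    shortest inter-onset interval plus a 10% margin; set it explicitly
    (together with ``f_max``) to restrict the scan to a fixed band, as in
    the null-model comparisons.
    """

    f_min: float | None = None
    f_max: float = 100.0
    f_step: float = 0.01
    offset_step: float = 0.001
    ioi_margin: float = 0.10
    agreement_tol: float = 0.25
    fft_resolution: float = 0.01

    def __post_init__(self) -> None:
        if self.f_step <= 0 or self.offset_step <= 0:
            raise ValueError("f_step and offset_step must be positive")
        if self.f_min is not None and not (0 < self.f_min):
            raise ValueError("f_min must be positive")

    def resolve_f_min(self, chunk: SongChunk) -> float:
        if self.f_min is not None:
            return self.f_min
        return min_scan_frequency(chunk, self.ioi_margin)


@dataclass(frozen=True)
class PulseFit:
    """A fitted isochronous pulse for one chunk.

    Pulse times are ``anchor + offset + k / frequency`` for integer ``k``;
    the anchor is the chunk's first note onset, so fits are invariant to
    translating the whole chunk in time.
    """

    frequency: float
    offset: float
    rmsd: float
    frmsd: float
    chunk_ref: tuple[str, int]
    anchor: float

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    def pulse_times(self, t_start: float, t_end: float) -> np.ndarray:
        """All pulse timestamps covering [t_start, t_end]."""
        p = self.period
        k0 = int(np.floor((t_start - self.anchor - self.offset) / p))
        k1 = int(np.ceil((t_end - self.anchor - self.offset) / p))
        return self.anchor + self.offset + np.arange(k0, k1 + 1) * p


@dataclass(frozen=True)
class ScanCurve:
    """Offset-optimized RMSD and FRMSD over the whole frequency grid."""

    frequencies: np.ndarray
    min_rmsd: np.ndarray
    min_frmsd: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.frequencies) == len(self.min_rmsd) == len(self.min_frmsd)):
            raise ValueError("scan-curve arrays must have equal length")


def min_scan_frequency(chunk: SongChunk, ioi_margin: float = 0.10) -> float:
    """Lower frequency limit for the scan: 1 / ((1 + margin) * shortest IOI).

    Pulses slower than this cannot place a distinct pulse time on every
    onset; the margin absorbs onset-measurement variability.
    """
    if chunk.n_notes < 2:
        raise ValueError("need at least 2 onsets to bound the scan frequency")
    min_ioi = float(np.min(chunk.iois))
    if min_ioi <= 0:
        raise ValueError("non-positive inter-onset interval")
    return 1.0 / ((1.0 + ioi_margin) * min_ioi)


def frequency_grid(f_min: float, f_max: float, f_step: float) -> np.ndarray:
    """Frequencies f_min, f_min + step, ... up to and including f_max."""
    if f_min > f_max:
        raise ValueError(f"empty frequency grid: f_min={f_min} > f_max={f_max}")
    n = int(np.floor((f_max - f_min) / f_step + 1e-9)) + 1
    return f_min + f_step * np.arange(n)


def offset_grid(frequency: float, offset_step: float = 0.001) -> np.ndarray:
    """Offsets 0, step, 2*step, ... covering the half-open [0, period)."""
    period = 1.0 / frequency
    m = int(np.floor(period / offset_step - 1e-9)) + 1
    return offset_step * np.arange(m)


def _nearest_pulse_dev(rel: np.ndarray, period: float) -> np.ndarray:
    """Distance of each value of ``rel`` to the nearest integer multiple of period."""
    r = rel % period
    return np.minimum(r, period - r)


def rmsd_at(onsets: Sequence[float], frequency: float, offset: float) -> float:
    """RMS deviation of onsets from the pulse grid anchored at the first onset."""
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("onsets must be non-empty")
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    period = 1.0 / frequency
    dev = _nearest_pulse_dev(onsets - (onsets[0] + offset), period)
    return float(np.sqrt(np.mean(dev**2)))


def best_offset(
    onsets: Sequence[float], frequency: float, offset_step: float = 0.001
) -> tuple[float, float]:
    """Grid-optimal phase offset for one frequency.

    Returns ``(offset, rmsd)`` minimizing the RMSD over the 1 ms offset
    grid; exact ties go to the smallest offset.
    """
    onsets = np.asarray(onsets, dtype=float)
    phis = offset_grid(frequency, offset_step)
    rms = _rms_per_offset(onsets, frequency, phis)
    i = int(np.argmin(rms))
    return float(phis[i]), float(rms[i])


def _rms_per_offset(
    onsets: np.ndarray, frequency: float, phis: np.ndarray
) -> np.ndarray:
    period = 1.0 / frequency
    rel = (onsets - onsets[0])[np.newaxis, :] - phis[:, np.newaxis]
    dev = _nearest_pulse_dev(rel, period)
    return np.sqrt(np.mean(dev**2, axis=1))


#: FRMSD ties are detected at this relative tolerance. Onset sequences that
#: fit several harmonics equally well in real arithmetic (e.g. noise-free
#: times commensurate with the grid) produce FRMSDs differing only by float
#: summation noise; without the tolerance the "slowest pulse" tie rule would
#: be decided by rounding luck.
_FRMSD_TIE_RTOL = 1e-9


def gat_best_pulse(chunk: SongChunk, config: ScanConfig = ScanConfig()) -> PulseFit:
    """Best-fitting pulse by exhaustive generate-and-test.

    Scans the full (frequency x offset) grid and returns the fit with the
    lowest FRMSD. FRMSD ties (equality up to float noise, see
    ``_FRMSD_TIE_RTOL``) are broken toward the lowest frequency — the
    slowest pulse consistent with the onsets — then the lowest offset.
    """
    onsets = chunk.onsets
    f_min = config.resolve_f_min(chunk)
    freqs = frequency_grid(f_min, config.f_max, config.f_step)
    best: tuple[float, float, float, float] | None = None  # (frmsd, f, phi, rmsd)
    for f in freqs:
        phis = offset_grid(f, config.offset_step)
        rms = _rms_per_offset(onsets, f, phis)
        i = int(np.argmin(rms))
        frmsd = rms[i] * f
        if best is None or frmsd < best[0] * (1.0 - _FRMSD_TIE_RTOL):
            best = (float(frmsd), float(f), float(phis[i]), float(rms[i]))
    assert best is not None
    frmsd, f, phi, rmsd = best
    return PulseFit(
        frequency=f,
        offset=phi,
        rmsd=rmsd,
        frmsd=frmsd,
        chunk_ref=chunk.ref,
        anchor=float(onsets[0]),
    )


def scan_curve(chunk: SongChunk, config: ScanConfig = ScanConfig()) -> ScanCurve:
    """Offset-optimized RMSD/FRMSD at every frequency of the scan grid."""
    onsets = chunk.onsets
    f_min = config.resolve_f_min(chunk)
    freqs = frequency_grid(f_min, config.f_max, config.f_step)
    min_rmsd = np.empty_like(freqs)
    for j, f in enumerate(freqs):
        phis = offset_grid(f, config.offset_step)
        min_rmsd[j] = np.min(_rms_per_offset(onsets, f, phis))
    return ScanCurve(frequencies=freqs, min_rmsd=min_rmsd, min_frmsd=min_rmsd * freqs)


#: Bins whose power is within this relative factor of the maximum count as
#: tied; the lowest tied frequency is returned. Guards against floating-point
#: asymmetry between analytically equal harmonic peaks.
_FFT_TIE_RTOL = 1e-9


def fft_peak_frequency(chunk: SongChunk, config: ScanConfig = ScanConfig()) -> float:
    """Dominant frequency of the onset point process.

    Onsets are binned into a 0/1 string at 1 ms resolution starting at the
    first onset, zero-padded so the spectral resolution is at most
    ``config.fft_resolution``, and the frequency of maximum power within
    the same [f_min, f_max] band as the GAT scan is returned. Near-exact
    power ties are broken toward the lowest frequency.
    """
    if chunk.n_notes < 2:
        raise ValueError("need at least 2 onsets for a spectrum")
    fs = 1000.0  # 1 ms resolution
    onsets = chunk.onsets
    idx = np.round((onsets - onsets[0]) * fs).astype(int)
    n_signal = int(idx[-1]) + 1
    n_fft = max(n_signal, int(np.ceil(fs / config.fft_resolution)))
    signal = np.zeros(n_signal)
    signal[idx] = 1.0
    spectrum = np.fft.rfft(signal, n=n_fft)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    power = np.abs(spectrum) ** 2
    f_min = config.resolve_f_min(chunk)
    band = (freqs >= f_min) & (freqs <= config.f_max)
    if not band.any():
        raise ValueError("no FFT bins inside the scan band")
    band_freqs = freqs[band]
    band_power = power[band]
    peak = band_power.max()
    tied = np.flatnonzero(band_power >= peak * (1.0 - _FFT_TIE_RTOL))
    return float(band_freqs[tied[0]])


def method_agreement(
    gat_freqs: Sequence[float], fft_freqs: Sequence[float], tol: float = 0.25
) -> float:
    """Fraction of chunks where GAT and FFT frequencies differ by < tol Hz."""
    gat = np.asarray(gat_freqs, dtype=float)
    fft = np.asarray(fft_freqs, dtype=float)
    if gat.shape != fft.shape:
        raise ValueError("paired frequency lists must have equal length")
    if gat.size == 0:
        raise ValueError("empty frequency lists")
    return float(np.mean(np.abs(gat - fft) < tol))


def restrict(config: ScanConfig, f_min: float, f_max: float) -> ScanConfig:
    """Copy of ``config`` locked to a fixed frequency band."""
    return replace(config, f_min=f_min, f_max=f_max)
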