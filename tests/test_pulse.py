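"""Pulse matching: RMSD/FRMSD grid search, FFT estimator, agreement."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from songpulse import synth
from songpulse.pulse import (
    PulseFit,
    ScanConfig,
    best_offset,
    fft_peak_frequency,
    frequency_grid,
    gat_best_pulse,
    method_agreement,
    min_scan_frequency,
    offset_grid,
    rmsd_at,
    scan_curve,
)

from conftest import make_chunk, random_chunk


# ---------------------------------------------------------------------------
# independent brute-force oracle: plain-Python double loop over the same grids
# ---------------------------------------------------------------------------

def oracle_rmsd(onsets, frequency, offset):
    period = 1.0 / frequency
    total = 0.0
    anchor = onsets[0]
    for t in onsets:
        r = (t - anchor - offset) % period
        d = min(r, period - r)
        total += d * d
    return math.sqrt(total / len(onsets))


def oracle_best_pulse(chunk, config):
    onsets = list(chunk.onsets)
    f_min = config.resolve_f_min(chunk)
    n_f = int(math.floor((config.f_max - f_min) / config.f_step + 1e-9)) + 1
    best = None  # (frmsd, f, phi, rmsd)
    for j in range(n_f):
        f = f_min + config.f_step * j
        period = 1.0 / f
        m = int(math.floor(period / config.offset_step - 1e-9)) + 1
        for k in range(m):
            phi = config.offset_step * k
            r = oracle_rmsd(onsets, f, phi)
            frmsd = r * f
            # same near-tie rule as the implementation: improvements below
            # float-noise level keep the earlier (slower) pulse
            if best is None or frmsd < best[0] * (1.0 - 1e-9):
                best = (frmsd, f, phi, r)
    return best


class TestMinScanFrequency:
    def test_hand_value(self):
        chunk = make_chunk([0.0, 0.100, 0.250])
        assert min_scan_frequency(chunk) == pytest.approx(1 / (1.1 * 0.100))
        assert min_scan_frequency(chunk) == pytest.approx(9.0909, abs=1e-4)

    def test_formula_inversion(self):
        # a 5.5 Hz lower limit implies a shortest IOI of ~165 ms
        min_ioi = 1 / (1.1 * 5.5)
        chunk = make_chunk([0.0, min_ioi, 2 * min_ioi], durations=0.05)
        assert min_scan_frequency(chunk) == pytest.approx(5.5)
        assert min_ioi == pytest.approx(0.1653, abs=2e-4)

    def test_single_onset_errors(self):
        with pytest.raises(ValueError):
            min_scan_frequency(make_chunk([0.0]))


class TestRmsd:
    def test_on_grid_zero(self):
        onsets = [0.0, 0.04, 0.08, 0.16]
        assert rmsd_at(onsets, 25.0, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_single_onset_midway(self):
        # one onset exactly between pulses: deviation is half a period
        assert rmsd_at([0.02], 25.0, 0.0) == pytest.approx(0.0, abs=1e-12)
        assert rmsd_at([0.0], 25.0, 0.02) == pytest.approx(0.02)

    def test_hand_rms(self):
        r = rmsd_at([0.0, 0.105, 0.200], 10.0, 0.0)
        assert r == pytest.approx(0.005 / math.sqrt(3), rel=1e-9)
        assert r * 10.0 == pytest.approx(0.028868, abs=1e-6)


class TestBestOffset:
    def test_shifted_grid(self):
        onsets = np.array([0.003, 0.053, 0.103, 0.153]) + 1.0
        # anchored at the first onset, a plain 20 Hz grid fits at offset 0
        phi, r = best_offset(onsets, 20.0)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_minimum_over_grid(self, rng):
        onsets = np.sort(rng.uniform(0, 0.5, 6))
        phi, r = best_offset(onsets, 30.0)
        for k in range(len(offset_grid(30.0))):
            assert r <= rmsd_at(onsets, 30.0, 0.001 * k) + 1e-15

    def test_matches_exhaustive_oracle(self, rng):
        onsets = np.sort(rng.uniform(0, 0.4, 6))
        phi, r = best_offset(onsets, 30.0)
        cands = [(oracle_rmsd(list(onsets), 30.0, 0.001 * k), 0.001 * k)
                 for k in range(len(offset_grid(30.0)))]
        best_r, best_phi = min(cands)
        assert (phi, r) == (best_phi, best_r)


class TestGatBestPulse:
    def test_tie_break_selects_slowest(self):
        # exact binary arithmetic: onsets on a 1/32 s grid with coprime
        # period counts, so 32 Hz and 64 Hz both fit with exactly zero
        # deviation; the tie must resolve to the slower pulse
        onsets = [0.0, 0.03125, 0.0625, 0.125, 0.15625]
        chunk = make_chunk(onsets, durations=0.02)
        fit = gat_best_pulse(chunk, ScanConfig(f_min=8.0, f_max=64.0, f_step=8.0))
        assert fit.frequency == 32.0 and fit.frmsd == 0.0 and fit.offset == 0.0

    def test_perfect_25hz_grid(self):
        chunk = make_chunk([0.0, 0.04, 0.08, 0.12, 0.16], durations=0.02)
        fit = gat_best_pulse(chunk)
        assert abs(fit.frequency - 25.0) <= 0.01  # grid resolution
        assert fit.frmsd < 0.02

    def test_matches_oracle_small_band(self, rng):
        chunk = random_chunk(rng, n_notes=5, ioi_range=(0.08, 0.18))
        config = ScanConfig(f_min=10.0, f_max=14.0)
        got = gat_best_pulse(chunk, config)
        frmsd, f, phi, r = oracle_best_pulse(chunk, config)
        assert (got.frmsd, got.frequency, got.offset, got.rmsd) == (frmsd, f, phi, r)

    def test_normalization_penalizes_double_tempo(self):
        # with jitter, the 25 Hz pulse must beat its 50 Hz harmonic on FRMSD
        wins = 0
        for seed in range(40):
            g = np.random.default_rng(seed)
            onsets = np.arange(8) * 0.04 + g.normal(0, 0.002, 8)
            onsets.sort()
            f25 = best_offset(onsets, 25.0)[1] * 25.0
            f50 = best_offset(onsets, 50.0)[1] * 50.0
            wins += f25 < f50
        assert wins >= 38

    def test_empty_grid_errors(self):
        chunk = make_chunk([0.0, 0.1, 0.2])
        with pytest.raises(ValueError, match="empty frequency grid"):
            gat_best_pulse(chunk, ScanConfig(f_min=50.0, f_max=40.0))


class TestScanCurve:
    def test_minimum_equals_best_pulse(self, jittered_chunk):
        chunk, _, _ = jittered_chunk
        config = ScanConfig(f_max=60.0)
        curve = scan_curve(chunk, config)
        fit = gat_best_pulse(chunk, config)
        j = int(np.argmin(curve.min_frmsd))
        assert curve.frequencies[j] == fit.frequency
        assert curve.min_frmsd[j] == fit.frmsd

    def test_frmsd_bound(self, rng):
        chunk = random_chunk(rng, n_notes=8)
        curve = scan_curve(chunk, ScanConfig(f_max=60.0, f_step=0.05))
        assert np.all(curve.min_frmsd >= 0)
        assert np.all(curve.min_frmsd <= 0.5)
        assert np.allclose(curve.min_frmsd, curve.min_rmsd * curve.frequencies)


class TestFft:
    def test_exact_comb_returns_fundamental(self):
        onsets = np.arange(25) * 0.040
        chunk = make_chunk(onsets, durations=0.02)
        f = fft_peak_frequency(chunk)
        # harmonics at 50/75/100 Hz tie analytically; lowest wins
        assert f == pytest.approx(25.0, abs=0.011)

    def test_jittered_comb_unique_max(self):
        # same band limits as the clean comb (jitter on a one-period IOI
        # would otherwise push the per-chunk floor above the fundamental)
        config = ScanConfig(f_min=1 / (1.1 * 0.040))
        hits = 0
        for seed in range(20):
            g = np.random.default_rng(seed)
            onsets = np.sort(np.arange(25) * 0.040 + g.normal(0, 0.002, 25))
            chunk = make_chunk(onsets, durations=0.02)
            hits += abs(fft_peak_frequency(chunk, config) - 25.0) < 0.25
        assert hits >= 19

    def test_single_onset_errors(self):
        with pytest.raises(ValueError):
            fft_peak_frequency(make_chunk([0.0]))

    def test_resolution_bound(self, jittered_chunk):
        chunk, _, _ = jittered_chunk
        config = ScanConfig(fft_resolution=0.01)
        f1 = fft_peak_frequency(chunk, config)
        # returned frequency must sit on a grid at least as fine as 0.01 Hz
        assert f1 == pytest.approx(round(f1, 2), abs=0.01)


class TestAgreement:
    def test_identical(self):
        assert method_agreement([25.0, 30.0], [25.0, 30.0]) == 1.0

    def test_direct_count(self):
        assert method_agreement([10.0, 10.0], [10.10, 10.30]) == 0.5

    def test_boundary_strict(self):
        assert method_agreement([10.0], [10.25]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            method_agreement([1.0], [1.0, 2.0])


@given(
    st.lists(st.floats(0.0, 2.0), min_size=2, max_size=8, unique=True),
    st.floats(5.0, 60.0),
)
@settings(max_examples=60, deadline=None)
def test_frmsd_bound_property(onsets, frequency):
    """Nearest-pulse deviation can never exceed half a period."""
    onsets = sorted(onsets)
    phi, r = best_offset(onsets, frequency)
    assert 0 <= r * frequency <= 0.5 + 1e-12


def test_pulse_times_cover_span(jittered_chunk):
    chunk, _, _ = jittered_chunk
    fit = gat_best_pulse(chunk, ScanConfig(f_max=60.0))
    times = fit.pulse_times(chunk.start, chunk.end)
    assert times[0] <= chunk.start and times[-1] >= chunk.end
    assert np.allclose(np.diff(times), fit.period)
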