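"""Moment fitting, Pearson sampling, Model R / Model C, restricted range."""

import numpy as np
import pytest
from scipy import stats as sps

from songpulse.io import DurationTable, build_duration_table
from songpulse.nullmodels import (
    ModelConfig,
    MomentSpec,
    filter_gap_durations,
    fit_moments,
    model_c_chunk,
    model_c_sets,
    model_r_chunk,
    restricted_range,
    run_comparison,
    sample_durations,
)
from songpulse import synth

from conftest import make_chunk


class TestFitMoments:
    def test_constant_degenerate(self):
        spec = fit_moments([0.1] * 6)
        assert spec.degenerate and spec.std == 0.0
        assert (spec.skewness, spec.kurtosis) == (0.0, 3.0)

    def test_normal_recovery(self):
        g = np.random.default_rng(3)
        spec = fit_moments(g.normal(0.134, 0.060, 10_000))
        assert spec.mean == pytest.approx(0.134, abs=0.002)
        assert spec.std == pytest.approx(0.060, abs=0.002)
        assert abs(spec.skewness) < 0.1
        assert abs(spec.kurtosis - 3) < 0.2

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            fit_moments([0.1, 0.2, 0.3])

    def test_infeasible_moments_rejected(self):
        with pytest.raises(ValueError, match="bound"):
            MomentSpec(mean=0.1, std=0.05, skewness=2.0, kurtosis=2.0)


class TestFilterGaps:
    def test_all_clean_unchanged(self):
        table = DurationTable(gap_durations={"a": [0.03, 0.04, 0.05], "b": [0.04, 0.045]})
        pooled, removed = filter_gap_durations(table)
        assert pooled.size == 5
        assert removed == {"types_removed": 0, "values_in_removed_types": 0, "outliers": 0}

    def test_tukey_fences(self):
        # Q1=0.04, Q3=0.05, IQR=0.01 -> upper fence 0.065 removes 0.30
        table = DurationTable(gap_durations={"a": [0.03, 0.04, 0.04, 0.05, 0.30]})
        pooled, removed = filter_gap_durations(table)
        assert 0.30 not in pooled
        assert removed["outliers"] == 1 and pooled.size == 4

    def test_high_mean_type_removed(self):
        table = DurationTable(
            gap_durations={"a": [0.14, 0.15, 0.16], "b": [0.03, 0.04, 0.05]}
        )
        pooled, removed = filter_gap_durations(table, type_mean_max=0.09)
        assert removed["types_removed"] == 1
        assert pooled.max() < 0.09

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            filter_gap_durations(DurationTable())


class TestModelR:
    def _template(self):
        return make_chunk([0.0, 0.15, 0.30, 0.45, 0.60], durations=0.08,
                          labels=list("abcab"))

    def test_zero_variance_yields_means(self):
        notes = MomentSpec(0.08, 0.0, 0.0, 3.0, degenerate=True)
        gaps = MomentSpec(0.04, 0.0, 0.0, 3.0, degenerate=True)
        c = model_r_chunk(self._template(), notes, gaps, seed=1)
        assert np.allclose([e.duration for e in c.events], 0.08)
        assert np.allclose(c.gaps, 0.04)

    def test_moment_recovery(self):
        notes = MomentSpec(0.134, 0.060, 0.5, 3.2)
        gaps = MomentSpec(0.038, 0.012, 0.3, 3.0)
        template = make_chunk(np.arange(100) * 0.2, durations=0.1,
                              labels=[chr(97 + i % 5) for i in range(100)])
        durs = []
        for seed in range(100):
            c = model_r_chunk(template, notes, gaps, seed=seed)
            durs.extend(e.duration for e in c.events)
        durs = np.asarray(durs)
        assert durs.mean() == pytest.approx(0.134, rel=0.02)
        assert durs.std(ddof=1) == pytest.approx(0.060, rel=0.02)
        assert sps.skew(durs) == pytest.approx(0.5, abs=0.1)
        assert sps.kurtosis(durs, fisher=False) == pytest.approx(3.2, abs=0.3)

    def test_determinism(self):
        notes = MomentSpec(0.134, 0.060, 0.5, 3.2)
        gaps = MomentSpec(0.038, 0.012, 0.0, 3.0)
        a = model_r_chunk(self._template(), notes, gaps, seed=7)
        b = model_r_chunk(self._template(), notes, gaps, seed=7)
        assert [e.onset for e in a.events] == [e.onset for e in b.events]

    def test_min_duration_rejection(self):
        spec = MomentSpec(0.006, 0.002, 0.0, 3.0)
        g = np.random.default_rng(0)
        draws = sample_durations(spec, 2000, g, min_duration=0.005)
        assert draws.min() >= 0.005


class TestModelC:
    def _table(self):
        chunks = [t[0] for t in synth.bird_chunks(25.0, 6, seed=9, jitter_sd=0.002)]
        return build_duration_table(chunks)

    def test_sets_are_deterministic(self):
        table = self._table()
        s1 = model_c_sets(table, bird_seed=11)
        s2 = model_c_sets(table, bird_seed=11)
        for lab in s1.note_sets:
            assert np.array_equal(s1.note_sets[lab], s2.note_sets[lab])
        for lab in s1.gap_sets:
            assert np.array_equal(s1.gap_sets[lab], s2.gap_sets[lab])

    def test_set_size_and_std(self):
        table = self._table()
        sets = model_c_sets(table, bird_seed=3)
        note_stds = [
            np.std(v, ddof=1) if len(v) > 1 else 0.0
            for v in table.note_durations.values()
        ]
        target = np.mean(note_stds)
        for vals in sets.note_sets.values():
            assert vals.size == 100
            assert np.std(vals, ddof=1) == pytest.approx(target, rel=0.15)

    def test_set_means_within_observed_range(self):
        table = self._table()
        sets = model_c_sets(table, bird_seed=3)
        type_means = [np.mean(v) for v in table.note_durations.values()]
        lo, hi = min(type_means), max(type_means)
        spread = np.mean([np.std(v, ddof=1) for v in table.note_durations.values()])
        for vals in sets.note_sets.values():
            assert lo - 4 * spread <= np.mean(vals) <= hi + 4 * spread

    def test_chunk_draws_from_sets(self):
        table = self._table()
        sets = model_c_sets(table, bird_seed=3)
        template = make_chunk([0.0, 0.15, 0.30, 0.45], durations=0.08,
                              labels=list("abab"))
        c = model_c_chunk(template, sets, chunk_seed=5)
        for e in c.events:
            # onset accumulation costs ~1 ulp, so match up to float noise
            assert np.min(np.abs(sets.note_sets[e.label] - e.duration)) < 1e-12

    def test_chunk_determinism(self):
        table = self._table()
        sets = model_c_sets(table, bird_seed=3)
        template = make_chunk([0.0, 0.15, 0.30, 0.45], durations=0.08,
                              labels=list("abca"))
        c1 = model_c_chunk(template, sets, chunk_seed=5)
        c2 = model_c_chunk(template, sets, chunk_seed=5)
        assert [e.onset for e in c1.events] == [e.onset for e in c2.events]

    def test_degenerate_single_value_sets(self):
        from songpulse.nullmodels import TypeDurationSets

        sets = TypeDurationSets(
            note_sets={"a": np.full(100, 0.08), "b": np.full(100, 0.1)},
            gap_sets={"a": np.full(100, 0.04), "b": np.full(100, 0.04)},
            bird_seed=0,
        )
        template = make_chunk([0.0, 0.15, 0.30, 0.45], durations=0.08,
                              labels=list("abab"))
        c = model_c_chunk(template, sets, chunk_seed=1)
        assert {round(e.duration, 3) for e in c.events} == {0.08, 0.1}

    def test_missing_type_errors(self):
        from songpulse.nullmodels import TypeDurationSets

        sets = TypeDurationSets(note_sets={"a": np.full(100, 0.08)},
                                gap_sets={"a": np.full(100, 0.04)}, bird_seed=0)
        template = make_chunk([0.0, 0.2], durations=0.08, labels=list("az"))
        with pytest.raises(ValueError, match="no Model C set"):
            model_c_chunk(template, sets, chunk_seed=1)


class TestRestrictedRange:
    def test_hand_value(self):
        lower, upper = restricted_range(30.0)
        assert lower == pytest.approx(21.213, abs=1e-3)
        assert upper == pytest.approx(42.426, abs=1e-3)

    def test_octave_exact(self, rng):
        for center in rng.uniform(5, 80, 20):
            lower, upper = restricted_range(center)
            assert upper / lower == pytest.approx(2.0, rel=1e-12)

    def test_octave_covering(self, rng):
        lower, upper = restricted_range(30.0)
        for f in rng.uniform(1.0, 200.0, 50):
            mapped = [f * 2.0**k for k in range(-8, 9)]
            inside = [m for m in mapped if lower <= m < upper]
            assert len(inside) == 1


class TestRunComparison:
    def test_single_rep_single_chunk(self, synthetic_bird):
        chunk = synthetic_bird[0][0]
        cfg = ModelConfig(model="R", freq_range=restricted_range(25.0), reps=1)
        pairs = run_comparison([chunk], cfg)
        assert len(pairs) == 1
        assert set(pairs.columns) == {
            "bird_id", "chunk_index", "rep", "model",
            "frmsd_real", "frmsd_model", "n_notes",
        }

    def test_determinism(self, synthetic_bird):
        chunks = [t[0] for t in synthetic_bird[:2]]
        cfg = ModelConfig(model="C", freq_range=restricted_range(25.0), reps=2,
                          bird_seed=5, chunk_seed_base=100)
        p1 = run_comparison(chunks, cfg)
        p2 = run_comparison(chunks, cfg)
        assert p1.equals(p2)

    def test_range_must_be_octave(self):
        with pytest.raises(ValueError, match="octave"):
            ModelConfig(model="R", freq_range=(20.0, 50.0))
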