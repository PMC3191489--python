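"""Interval extraction: slicing quantization, count filtering, censoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from initsteps.extraction import (
    IntervalDataset,
    extract_dataset,
    extract_intervals,
    quantize_spots,
    rna_count_series,
    summarize,
)
from initsteps.synthetic import CellTrace, counts_at_frames, simulate_spot_intensities


def make_trace(counts, t0=60.0, dt=60.0, divisions=()):
    counts = np.asarray(counts)
    return CellTrace(
        "c0", t0 + dt * np.arange(counts.size), counts, np.asarray(divisions, float)
    )


class TestQuantization:
    def test_small_sample_by_hand(self):
        res = quantize_spots(np.array([1.0, 1.05, 0.95, 2.0, 3.1]))
        assert res.unit_intensity == pytest.approx(1.0, rel=0.2)
        np.testing.assert_array_equal(res.counts, [1, 1, 1, 2, 3])

    def test_identical_intensities(self):
        res = quantize_spots(np.full(10, 7.5))
        assert res.unit_intensity == 7.5
        assert np.all(res.counts == 1)

    def test_noiseless_two_state_mixture(self, rng):
        u = 40.0
        intensity = np.where(rng.random(1000) < 0.6, u, 2 * u)
        res = quantize_spots(intensity)
        assert res.unit_intensity == pytest.approx(u, rel=0.02)

    def test_noisy_mixture_first_mode(self):
        counts = np.where(np.random.default_rng(3).random(5000) < 0.7, 1, 2)
        tab = simulate_spot_intensities(counts, 100.0, 0.1, seed=4)
        res = quantize_spots(tab)
        assert res.unit_intensity == pytest.approx(100.0, rel=0.05)

    def test_too_few_spots(self):
        with pytest.raises(ValueError, match="at least 5"):
            quantize_spots(np.array([1.0, 2.0]))


class TestCountFilter:
    def test_running_max(self):
        tr = make_trace([0, 1, 0, 1, 2])
        np.testing.assert_array_equal(rna_count_series(tr).rna_counts, [0, 1, 1, 1, 2])

    def test_segments_filtered_independently(self):
        # division between frames 2 and 3 resets the count
        tr = make_trace([0, 2, 2, 0, 1], divisions=[215.0])
        out = rna_count_series(tr).rna_counts
        np.testing.assert_array_equal(out, [0, 2, 2, 0, 1])

    def test_idempotent(self):
        tr = make_trace([0, 1, 1, 3, 3, 4])
        once = rna_count_series(tr)
        twice = rna_count_series(once)
        np.testing.assert_array_equal(once.rna_counts, twice.rna_counts)


class TestExtractIntervals:
    def test_by_hand(self):
        tr = make_trace([0, 0, 1, 1, 2, 2, 2, 3])
        np.testing.assert_allclose(extract_intervals(tr), [120.0, 180.0])

    def test_all_zero(self):
        assert extract_intervals(make_trace([0, 0, 0, 0])).size == 0

    def test_division_censors_spanning_interval(self):
        # appearance at 300 s, division at 400 s, next appearance at 540 s:
        # the spanning interval is discarded
        counts = counts_at_frames([290.0], 60.0 * np.arange(1, 10))
        counts2 = counts_at_frames([530.0], 60.0 * np.arange(1, 10))
        merged = np.where(60.0 * np.arange(1, 10) < 400.0, counts, counts2)
        tr = make_trace(merged, divisions=[400.0])
        assert extract_intervals(tr).size == 0

    def test_multi_rna_jump_censored(self):
        # a jump of 2 at one frame: two appearances share the frame time and
        # the sub-resolution interval between them is discarded
        tr = make_trace([0, 2, 2, 3])
        np.testing.assert_allclose(extract_intervals(tr), [120.0])

    def test_first_frame_count_not_an_appearance(self):
        tr = make_trace([3, 3, 4])
        np.testing.assert_allclose(extract_intervals(tr), [])

    def test_non_monotone_rejected(self):
        with pytest.raises(ValueError, match="decreases"):
            extract_intervals(make_trace([0, 2, 1]))

    def test_intervals_at_least_frame_interval(self, weak_traces):
        for tr in weak_traces:
            iv = extract_intervals(rna_count_series(tr))
            assert np.all(iv >= tr.frame_interval - 1e-9)

    @given(st.lists(st.integers(min_value=0, max_value=5), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_interval_count_identity(self, increments):
        """#intervals == #appearance-frames - #segments with >= 1 appearance."""
        counts = np.cumsum(increments)
        tr = make_trace(counts)
        iv = extract_intervals(tr)
        n_appearance_frames = int(np.sum(np.diff(counts) > 0))
        expected = n_appearance_frames - (1 if n_appearance_frames else 0)
        assert iv.size == expected

    def test_round_trip_recovers_simulated_intervals(self, rng):
        """Well-separated productions are recovered to within one frame."""
        prod = np.cumsum(rng.uniform(400, 1500, size=8))
        frames = 60.0 + 60.0 * np.arange(200)
        visible = prod[prod < frames[-1]]
        tr = make_trace(counts_at_frames(prod, frames))
        iv = extract_intervals(tr)
        true_iv = np.diff(visible)
        assert iv.size == true_iv.size
        np.testing.assert_allclose(iv, true_iv, atol=60.0)


class TestDatasetAndSummary:
    def test_extract_dataset_pools_cells(self, weak_traces):
        ds = extract_dataset(weak_traces, condition="weak-like")
        assert ds.n > 0
        assert ds.frame_interval == 60.0
        assert ds.n_cells_source == len(weak_traces)
        assert np.all(ds.intervals > 0)

    def test_summarize_by_hand(self):
        s = summarize(IntervalDataset(np.array([1000.0, 2000.0])))
        assert s.mean == 1500.0
        assert s.n == 2
        assert s.sd == pytest.approx(np.sqrt(2) * 500.0)

    def test_rate_interval_conversion(self):
        # a 900-s mean interval corresponds to 4 RNA per hour
        s = summarize(np.array([800.0, 1000.0, 900.0, 900.0]))
        assert s.mean == 900.0
        assert s.rate_per_hour == pytest.approx(4.0)

    def test_simulation_consistency(self, weak_sample):
        s = summarize(IntervalDataset(weak_sample))
        se = s.sd / np.sqrt(s.n)
        assert abs(s.mean - 2232.0) < 3 * se

    def test_needs_two_intervals(self):
        with pytest.raises(ValueError):
            summarize(np.array([1000.0]))

    def test_invalid_dataset(self):
        with pytest.raises(ValueError):
            IntervalDataset(np.array([100.0, -5.0]))
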