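"""From fluorescent spots and per-cell count traces to production intervals.

The likelihood consumes the sample of intervals Δt_k between consecutive
RNA productions within single cells.  This module provides the steps that
produce it:

* ``quantize_spots`` — the "slicing" quantization: the single-RNA unit
  intensity is the first peak of the spot-intensity histogram (located on
  a kernel-density estimate) and each spot's RNA count is its intensity
  divided by that unit, rounded;
* ``rna_count_series`` — a running-maximum filter that makes counts
  monotone between divisions (tagged RNA is not degraded on the movie's
  timescale, so an apparent decrease is detection noise);
* ``extract_intervals`` — appearance times and their successive
  differences, counting only same-cell intervals and discarding any
  interval that spans a cell division;
* ``summarize`` — sample mean/SD/N and the implied production rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import CellTrace

__all__ = [
    "IntervalDataset",
    "QuantizationResult",
    "IntervalSummary",
    "quantize_spots",
    "rna_count_series",
    "extract_intervals",
    "extract_dataset",
    "summarize",
]


@dataclass(frozen=True)
class IntervalDataset:
    """The interval sample Δt_k a step model is fitted to."""

    intervals: np.ndarray
    condition: str = ""
    frame_interval: float | None = None
    n_cells_source: int | None = None

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float)
        if iv.ndim != 1:
            raise ValueError("intervals must be a 1-d array")
        if iv.size and (np.any(iv <= 0) or not np.all(np.isfinite(iv))):
            raise ValueError("all intervals must be finite and positive")
        object.__setattr__(self, "intervals", iv)

    @property
    def n(self) -> int:
        return int(self.intervals.size)


@dataclass(frozen=True)
class QuantizationResult:
    """Unit (single-RNA) intensity and the integer RNA count of each spot."""

    unit_intensity: float
    counts: np.ndarray


@dataclass(frozen=True)
class IntervalSummary:
    mean: float
    sd: float
    n: int
    rate_per_hour: float


def _silverman_bandwidth(x: np.ndarray) -> float:
    sd = float(np.std(x, ddof=1))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        spread = 0.05 * float(np.mean(x))
    return 0.9 * spread * x.size ** (-0.2)


def quantize_spots(spots, bandwidth: float | None = None) -> QuantizationResult:
    """Estimate integer RNA counts per spot from fluorescence intensities.

    The unit (single-RNA) intensity is located as the first local maximum
    of a Gaussian kernel-density estimate of the intensity sample; each
    spot's count is ``round(intensity / unit)``, floored at one (a detected
    spot contains at least one RNA).

    Parameters
    ----------
    spots
        A SpotTable (DataFrame with an ``intensity`` column) or a plain
        array of intensities; at least 5 spots.
    bandwidth
        KDE bandwidth in intensity units; default is Silverman's plug-in
        rule on the sample.
    """
    if isinstance(spots, pd.DataFrame):
        intensity = spots["intensity"].to_numpy(dtype=float)
    else:
        intensity = np.asarray(spots, dtype=float)
    if intensity.size < 5:
        raise ValueError("need at least 5 spots to locate the unit-intensity peak")
    if np.any(intensity <= 0):
        raise ValueError("intensities must be strictly positive")

    if np.ptp(intensity) == 0:
        unit = float(intensity[0])
        return QuantizationResult(unit, np.ones(intensity.size, dtype=int))

    h = bandwidth if bandwidth is not None else _silverman_bandwidth(intensity)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    kde = stats.gaussian_kde(intensity, bw_method=h / np.std(intensity, ddof=1))
    lo = max(1e-12, intensity.min() - 3 * h)
    hi = intensity.max() + 3 * h
    grid = np.linspace(lo, hi, 2048)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.flatnonzero(interior) + 1
    peaks = peaks[dens[peaks] >= 0.01 * dens.max()]
    if peaks.size == 0:
        if dens[0] >= dens[1]:  # monotone decreasing from the left edge
            peaks = np.array([0])
        else:
            raise ValueError("no detectable peak in the intensity distribution")
    unit = float(grid[peaks[0]])
    counts = np.maximum(1, np.rint(intensity / unit).astype(int))
    return QuantizationResult(unit, counts)


def _segment_slices(trace: CellTrace) -> list[slice]:
    """Frame-index slices of the inter-division segments of a trace."""
    ft = trace.frame_times
    cuts = [0]
    for dt in trace.division_times:
        idx = int(np.searchsorted(ft, dt, side="left"))
        if 0 < idx < ft.size:
            cuts.append(idx)
    cuts.append(ft.size)
    cuts = sorted(set(cuts))
    return [slice(a, b) for a, b in zip(cuts[:-1], cuts[1:]) if b > a]


def rna_count_series(trace: CellTrace) -> CellTrace:
    """Running-maximum filter applied independently within each
    inter-division segment, so counts never decrease between divisions.
    Idempotent; already-monotone traces are returned unchanged in value."""
    counts = trace.rna_counts.copy()
    for seg in _segment_slices(trace):
        counts[seg] = np.maximum.accumulate(counts[seg])
    return CellTrace(
        cell_id=trace.cell_id,
        frame_times=trace.frame_times,
        rna_counts=counts,
        division_times=trace.division_times,
    )


def extract_intervals(trace: CellTrace) -> np.ndarray:
    """Intervals (s) between consecutive RNA appearances within one cell.

    An appearance is the frame time at which the count first increases.  A
    jump of k >= 2 at a single frame stands for k productions less than one
    frame interval apart; the k-1 sub-resolution intervals are discarded
    rather than assigned a fabricated duration.  Intervals never span a
    division (mother-to-daughter intervals are censored), and the wait from
    movie start or division to the first appearance is not an interval.

    The trace must already be monotone within segments (apply
    :func:`rna_count_series` first).
    """
    intervals: list[float] = []
    for seg in _segment_slices(trace):
        counts = trace.rna_counts[seg]
        times = trace.frame_times[seg]
        if np.any(np.diff(counts) < 0):
            raise ValueError(
                "count series decreases within a segment; apply rna_count_series first"
            )
        rises = np.flatnonzero(np.diff(counts) > 0) + 1
        appearance_times = times[rises]  # distinct frames: zero-gaps already excluded
        if appearance_times.size >= 2:
            intervals.extend(np.diff(appearance_times))
    return np.asarray(intervals, dtype=float)


def extract_dataset(
    traces, condition: str = "", *, filter_counts: bool = True
) -> IntervalDataset:
    """Pool the same-cell intervals of many traces into one dataset."""
    traces = list(traces)
    if not traces:
        raise ValueError("no traces given")
    all_iv = []
    for tr in traces:
        if filter_counts:
            tr = rna_count_series(tr)
        all_iv.append(extract_intervals(tr))
    fi = traces[0].frame_interval if traces[0].frame_times.size >= 2 else None
    return IntervalDataset(
        intervals=np.concatenate(all_iv) if all_iv else np.empty(0),
        condition=condition,
        frame_interval=fi,
        n_cells_source=len(traces),
    )


def summarize(dataset: IntervalDataset | np.ndarray) -> IntervalSummary:
    """Sample mean and SD (denominator N-1), N, and the implied mean
    production rate 3600/mean in RNA per hour."""
    iv = getattr(dataset, "intervals", dataset)
    iv = np.asarray(iv, dtype=float)
    if iv.size < 2:
        raise ValueError("need at least 2 intervals to summarize")
    mean = float(np.mean(iv))
    return IntervalSummary(
        mean=mean,
        sd=float(np.std(iv, ddof=1)),
        n=int(iv.size),
        rate_per_hour=3600.0 / mean,
    )
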