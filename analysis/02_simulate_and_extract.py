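#!/usr/bin/env python
"""Simulate weak-induction-like movies and extract production intervals.

Generates 283 cells of 2-h, one-frame-per-minute RNA-count traces from
the 2-step model (1116 s + 1116 s), with 60% of cells silent, plus a
spot-intensity table, then runs slicing quantization and interval
extraction.

Typical output at the default seed: ~240 same-cell intervals whose sample
mean (~1600-1700 s) sits below the 2232-s model mean because intervals
must fit inside the 2-h observation window (right truncation).
"""

import argparse
from pathlib import Path

import numpy as np

from initsteps import io
from initsteps.extraction import extract_dataset, quantize_spots, summarize
from initsteps.synthetic import (
    SimulationConfig,
    simulate_cell_traces,
    simulate_spot_intensities,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(seed=args.seed)
    traces = simulate_cell_traces(cfg)
    io.write_traces(traces, args.outdir / "traces.tsv", seed=args.seed, config=cfg)

    # one spot observation per frame with visible RNA, 10% intensity CV;
    # single-RNA spots dominate early frames, giving the unit-intensity peak
    frame_counts, cell_ids, frame_times = [], [], []
    for tr in traces:
        vis = tr.rna_counts > 0
        frame_counts.extend(tr.rna_counts[vis])
        cell_ids.extend([tr.cell_id] * int(vis.sum()))
        frame_times.extend(tr.frame_times[vis])
    spots = simulate_spot_intensities(
        frame_counts, 150.0, 0.10, seed=args.seed,
        cell_ids=cell_ids, frame_times=frame_times,
    )
    io.write_spots(spots, args.outdir / "spots.tsv", seed=args.seed)
    q = quantize_spots(spots)
    match = np.mean(q.counts == np.asarray(frame_counts))
    print(
        f"slicing quantization over {len(frame_counts)} spot observations: "
        f"unit {q.unit_intensity:.1f} a.u. (true 150.0), "
        f"{100 * match:.0f}% of per-frame counts recovered exactly"
    )

    ds = extract_dataset(traces, condition="weak-like")
    io.write_intervals(ds, args.outdir / "intervals.tsv", seed=args.seed, config=cfg)
    s = summarize(ds)
    print(
        f"{len(traces)} cells -> {s.n} same-cell intervals; "
        f"mean {s.mean:.0f} s, sd {s.sd:.0f} s, {s.rate_per_hour:.1f} RNA/h per producer"
    )
    print(f"wrote {args.outdir}/traces.tsv, spots.tsv, intervals.tsv")


if __name__ == "__main__":
    main()
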