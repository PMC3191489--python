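"""Plain-text (tab-separated) readers and writers for every artifact.

All files are TSV with a one-line column header, preceded by ``#`` comment
lines carrying provenance (package version, seed, config hash), so every
artifact is diff-able and parses back into its domain type.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .extraction import IntervalDataset
from .hypoexp import ModelSelectionTable
from .synthetic import CellTrace, frame_to_traces, traces_to_frame

__all__ = [
    "read_intervals",
    "write_intervals",
    "read_traces",
    "write_traces",
    "read_spots",
    "write_spots",
    "write_selection_report",
    "config_hash",
    "provenance_lines",
]


#: configuration fields that affect where results go, not what is computed
_NON_SCIENTIFIC_FIELDS = ("outdir", "make_figure")


def config_hash(config) -> str:
    """Short stable hash of a configuration mapping or dataclass.

    Output-location fields are excluded so that identical analyses written
    to different directories carry the same hash.
    """
    if hasattr(config, "__dataclass_fields__"):
        config = {k: getattr(config, k) for k in config.__dataclass_fields__}
    if isinstance(config, dict):
        config = {k: v for k, v in config.items() if k not in _NON_SCIENTIFIC_FIELDS}
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def provenance_lines(seed=None, config=None, extra: dict | None = None) -> list[str]:
    lines = [f"# initsteps {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    if config is not None:
        lines.append(f"# config_hash: {config_hash(config)}")
    for k, v in (extra or {}).items():
        lines.append(f"# {k}: {v}")
    return lines


def _write_tsv(df: pd.DataFrame, path, header_lines: list[str] | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_intervals(
    dataset: IntervalDataset, path, *, seed=None, config=None
) -> None:
    extra = {}
    if dataset.condition:
        extra["condition"] = dataset.condition
    if dataset.frame_interval is not None:
        extra["frame_interval_s"] = dataset.frame_interval
    if dataset.n_cells_source is not None:
        extra["n_cells_source"] = dataset.n_cells_source
    df = pd.DataFrame({"interval_s": dataset.intervals})
    _write_tsv(df, path, provenance_lines(seed, config, extra))


def read_intervals(path) -> IntervalDataset:
    """Read a single-column interval file (header ``interval_s``).

    Malformed rows are rejected with their line number.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    values: list[float] = []
    header_seen = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" in line:
                    k, _, v = line.lstrip("# ").partition(":")
                    meta[k.strip()] = v.strip()
                continue
            if not header_seen:
                if line.split("\t")[0] != "interval_s":
                    raise ValueError(
                        f"{path}:{lineno}: expected header 'interval_s', got {line!r}"
                    )
                header_seen = True
                continue
            try:
                v = float(line.split("\t")[0])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric interval {line!r}") from exc
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{path}:{lineno}: intervals must be positive, got {v}")
            values.append(v)
    if not header_seen:
        raise ValueError(f"{path}: missing 'interval_s' header")
    fi = meta.get("frame_interval_s")
    ncells = meta.get("n_cells_source")
    return IntervalDataset(
        intervals=np.asarray(values),
        condition=meta.get("condition", ""),
        frame_interval=float(fi) if fi is not None else None,
        n_cells_source=int(ncells) if ncells is not None else None,
    )


def write_traces(traces: list[CellTrace], path, *, seed=None, config=None) -> None:
    _write_tsv(traces_to_frame(traces), path, provenance_lines(seed, config))


def read_traces(path) -> list[CellTrace]:
    return frame_to_traces(_read_tsv(path))


def write_spots(spots: pd.DataFrame, path, *, seed=None, config=None) -> None:
    _write_tsv(spots, path, provenance_lines(seed, config))


def read_spots(path) -> pd.DataFrame:
    df = _read_tsv(path)
    missing = {"cell_id", "frame_time_s", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"spot table is missing columns: {sorted(missing)}")
    if (df["intensity"] <= 0).any():
        raise ValueError("spot intensities must be strictly positive")
    return df


def selection_to_frames(table: ModelSelectionTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Model-fit and likelihood-ratio summaries as two tables.

    The first has one row per step count: d, log-likelihood, and the fitted
    step durations mu_1..mu_d (sorted descending, below-resolution steps
    flagged).  The second has one row per (d, d+1) test.
    """
    d_max = max(f.d for f in table.fits)
    fit_rows = []
    for f, flags in zip(table.fits, table.below_resolution):
        row = {"d": f.d, "loglik": f.loglik}
        for i in range(d_max):
            row[f"mu_{i + 1}_s"] = f.model.mu[i] if i < f.d else np.nan
        row["below_resolution"] = ",".join(str(i + 1) for i in flags)
        row["selected"] = int(f.d == table.selected_d)
        fit_rows.append(row)
    test_rows = [
        {
            "d0": t.d0,
            "d1": t.d1,
            "statistic": t.statistic,
            "df": t.df,
            "p_value": t.p_value,
            "rejected": int(t.p_value < table.alpha),
        }
        for t in table.tests
    ]
    return pd.DataFrame(fit_rows), pd.DataFrame(test_rows)


def write_selection_report(
    table: ModelSelectionTable, fits_path, tests_path, *, seed=None, config=None
) -> None:
    fits_df, tests_df = selection_to_frames(table)
    extra = {"selected_d": table.selected_d, "alpha": table.alpha}
    _write_tsv(fits_df, fits_path, provenance_lines(seed, config, extra))
    _write_tsv(tests_df, tests_path, provenance_lines(seed, config, extra))
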