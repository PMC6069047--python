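"""Plain-text I/O: record CSVs, peak lists, traces, and run manifests."""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import MultichannelRecord

RECORD_COLUMNS = ["time_s", "sigL", "sigR", "sigaL", "sigaR"]


def write_record_csv(path, record: MultichannelRecord, clean_ecg=None) -> None:
    """Write a record as CSV with one row per sample.

    Columns: ``time_s, sigL, sigR, sigaL, sigaR`` plus ``clean_ecg`` when a
    clean reference waveform is supplied (synthetic records).
    """
    n = record.n_samples
    data = {
        "time_s": np.arange(n) / record.fs,
        "sigL": record.sigL,
        "sigR": record.sigR,
        "sigaL": record.sigaL,
        "sigaR": record.sigaR,
    }
    if clean_ecg is None and record.ecg_contact is not None:
        clean_ecg = record.ecg_contact
    if clean_ecg is not None:
        data["clean_ecg"] = np.asarray(clean_ecg, dtype=float)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.8g")


def read_record_csv(path) -> MultichannelRecord:
    """Read a record CSV written by :func:`write_record_csv`.

    The sampling rate is recovered from the ``time_s`` column.
    """
    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record CSV missing columns: {missing}")
    t = df["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("record CSV must contain at least two samples")
    fs = 1.0 / float(np.median(np.diff(t)))
    return MultichannelRecord(
        fs=fs,
        sigL=df["sigL"].to_numpy(),
        sigR=df["sigR"].to_numpy(),
        sigaL=df["sigaL"].to_numpy(),
        sigaR=df["sigaR"].to_numpy(),
        ecg_contact=df["clean_ecg"].to_numpy() if "clean_ecg" in df.columns else None,
        meta={"source": str(path)},
    )


def write_peaks(path, indices) -> None:
    """One sample index per line."""
    with open(path, "w") as fh:
        for idx in np.asarray(indices, dtype=int):
            fh.write(f"{idx}\n")


def read_peaks(path) -> np.ndarray:
    text = Path(path).read_text().split()
    return np.asarray([int(x) for x in text], dtype=int)


def write_signal_csv(path, signal, fs: float, column: str = "value") -> None:
    n = len(signal)
    pd.DataFrame(
        {"time_s": np.arange(n) / fs, column: np.asarray(signal, dtype=float)}
    ).to_csv(path, index=False, float_format="%.8g")


def read_signal_csv(path, column: str | None = None) -> tuple[np.ndarray, float]:
    """Return ``(signal, fs)`` from a two-column time/value CSV."""
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    if column is None:
        candidates = [c for c in df.columns if c != "time_s"]
        if not candidates:
            raise ValueError("no signal column found")
        column = candidates[0]
    return df[column].to_numpy(), fs


def write_trace_csv(path, traces) -> None:
    """Per-iteration trace: iteration, branch, APA update norm, delta, error."""
    rows = {
        "iteration": np.arange(len(traces)),
        "branch": [t.branch.value for t in traces],
        "apa_update_norm": [t.apa_update_norm for t in traces],
        "delta": [t.delta_after for t in traces],
        "error": [t.error for t in traces],
        "step_norm": [t.step_norm for t in traces],
    }
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.8g")


def write_manifest(path, *, command: str, config: dict, seeds: dict, paths: dict) -> None:
    """Reproducibility manifest accompanying every CLI run."""
    from . import __version__

    manifest = {
        "command": command,
        "config": config,
        "seeds": seeds,
        "paths": {k: str(v) for k, v in paths.items()},
        "version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
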