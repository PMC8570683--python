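"""Plain-text I/O: trial tables, waveforms, spike ensembles and result JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .observer import SpikeEnsemble

__all__ = [
    "read_trial_table",
    "write_trial_table",
    "export_waveform",
    "write_spike_ensemble",
    "read_spike_ensemble",
    "write_json",
    "read_json",
]

TRIAL_COLUMNS = ("participant", "condition", "line", "level_ms", "is_change", "response")


class TrialTableError(ValueError):
    """Malformed trial table, reported with the offending line number."""


def read_trial_table(path) -> pd.DataFrame:
    """Read a delimited trial table (CSV with header).

    Required columns: participant, condition, line, level_ms, is_change,
    response.  Malformed rows raise TrialTableError with the 1-based data line.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # includes empty files
        raise TrialTableError(f"{path}: cannot parse trial table ({exc})") from exc
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialTableError(f"{path}: missing columns {missing}")
    if df.empty:
        raise TrialTableError(f"{path}: table has no trials")
    for col, kind in (("level_ms", float), ("is_change", int), ("response", int)):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna()
        if bad.any():
            line = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # +header, 1-based
            raise TrialTableError(f"{path}: bad value in column {col!r} at line {line}")
        df[col] = coerced.astype(kind)
    if not df["response"].isin([0, 1]).all():
        line = int(np.nonzero(~df["response"].isin([0, 1]).to_numpy())[0][0]) + 2
        raise TrialTableError(f"{path}: response must be 0/1 (line {line})")
    return df


def write_trial_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def export_waveform(waveform: np.ndarray, sample_rate: float, path) -> None:
    """Two-column delimited export: time_ms, position_um."""
    t = np.arange(waveform.size) * (1000.0 / sample_rate)
    np.savetxt(
        path,
        np.column_stack([t, waveform]),
        fmt="%.6f",
        delimiter="\t",
        header="time_ms\tposition_um",
        comments="",
    )


def write_spike_ensemble(ens: SpikeEnsemble, path, *, rate: float, n_units: int, seed: int) -> None:
    """Delimited (pulses × trials) count matrix with a one-line # header."""
    with open(path, "w") as fh:
        fh.write(f"# label={ens.label} rate={rate} n_units={n_units} seed={seed}\n")
        np.savetxt(fh, ens.per_pulse, fmt="%d", delimiter="\t")


def read_spike_ensemble(path) -> SpikeEnsemble:
    with open(path) as fh:
        header = fh.readline().strip()
        label = ""
        for tok in header.lstrip("# ").split():
            if tok.startswith("label="):
                label = tok[6:]
        counts = np.loadtxt(fh, delimiter="\t", dtype=int, ndmin=2)
    return SpikeEnsemble(per_pulse=counts, label=label)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
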