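"""Readers and writers for the package's plain-text interchange formats.

Formats (all delimited text, lossless numeric round-trip at full precision):

* pressure CSV — ``unit_id, t_seconds, pressure_hPa, temperature_C``; one
  file may hold many units;
* peak-list CSV — ``mz, intensity``; one file per sample;
* ASV TSV — ``asv_id, taxonomy, <sample1>, <sample2>, ...``; taxonomy is a
  semicolon-delimited rank string whose 6th field is the genus;
* results TSV/JSON — per-cycle metrics, distance matrices, test results.

Malformed files raise :class:`cesdyn.errors.FormatError` naming the file,
the offending column/id and, for bad cells, the 1-based line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .community import ASVTable
from .dom import Peak
from .errors import FormatError
from .pressure import PressureTrace

__all__ = [
    "read_pressure_csv",
    "write_pressure_csv",
    "read_peaklist_csv",
    "write_peaklist_csv",
    "read_asv_table",
    "write_asv_table",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_json",
    "read_json",
]

def _read_table(path, sep: str, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep=sep, dtype=str)
    except Exception as exc:  # parser errors carry their own line info
        raise FormatError(f"cannot parse: {exc}", path=path) from exc
    for col in required:
        if col not in frame.columns:
            raise FormatError(f"missing required column {col!r}", path=path)
    return frame


def _numeric(frame: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(frame[col], errors="coerce")
    bad = vals.isna() & frame[col].notna()
    if bad.any():
        row = int(bad.idxmax())
        raise FormatError(
            f"non-numeric value {frame[col][row]!r} in column {col!r}",
            path=path, line=row + 2)  # +1 header, +1 one-based
    if vals.isna().any():
        row = int(vals.isna().idxmax())
        raise FormatError(f"empty value in column {col!r}", path=path, line=row + 2)
    # numpy's string conversion is correctly rounded (exact round trip);
    # pandas' fast csv float parser is not
    return frame[col].astype(np.float64).to_numpy()


# ---------------------------------------------------------------------------
# Pressure traces
# ---------------------------------------------------------------------------

def read_pressure_csv(
    path, schedule: tuple[float, float] = (0.0, 12.0)
) -> dict[str, PressureTrace]:
    """Read all units from a pressure CSV; returns {unit_id: PressureTrace}."""
    frame = _read_table(path, ",", ["unit_id", "t_seconds", "pressure_hPa",
                                    "temperature_C"])
    t = _numeric(frame, "t_seconds", path)
    P = _numeric(frame, "pressure_hPa", path)
    T = _numeric(frame, "temperature_C", path)
    out: dict[str, PressureTrace] = {}
    units = frame["unit_id"].to_numpy()
    for unit in pd.unique(units):
        sel = units == unit
        order = np.argsort(t[sel], kind="stable")
        try:
            out[str(unit)] = PressureTrace(
                unit_id=str(unit), t=t[sel][order], P=P[sel][order],
                T=T[sel][order], schedule=schedule)
        except ValueError as exc:
            raise FormatError(f"unit {unit!r}: {exc}", path=path) from exc
    return out


def write_pressure_csv(traces: Sequence[PressureTrace], path) -> None:
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "unit_id": tr.unit_id, "t_seconds": tr.t,
            "pressure_hPa": tr.P, "temperature_C": tr.T}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Peak lists
# ---------------------------------------------------------------------------

def read_peaklist_csv(path) -> list[Peak]:
    frame = _read_table(path, ",", ["mz", "intensity"])
    mz = _numeric(frame, "mz", path)
    inten = _numeric(frame, "intensity", path)
    return [Peak(float(m), float(i)) for m, i in zip(mz, inten)]


def write_peaklist_csv(peaks: Sequence[Peak], path) -> None:
    pd.DataFrame({"mz": [p.mz for p in peaks],
                  "intensity": [p.intensity for p in peaks]}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ASV tables
# ---------------------------------------------------------------------------

def read_asv_table(path, sample_metadata: pd.DataFrame | None = None) -> ASVTable:
    frame = _read_table(path, "\t", ["asv_id", "taxonomy"])
    dup = frame["asv_id"][frame["asv_id"].duplicated()]
    if len(dup):
        raise FormatError(f"duplicate asv_id {dup.iloc[0]!r}", path=path)
    sample_cols = [c for c in frame.columns if c not in ("asv_id", "taxonomy")]
    if not sample_cols:
        raise FormatError("no sample columns after asv_id/taxonomy", path=path)
    counts = {}
    for col in sample_cols:
        vals = _numeric(frame, col, path)
        if not np.allclose(vals, np.round(vals)):
            row = int(np.flatnonzero(vals != np.round(vals))[0])
            raise FormatError(
                f"non-integral count {vals[row]} in sample column {col!r}",
                path=path, line=row + 2)
        counts[col] = vals.astype(np.int64)
    counts_frame = pd.DataFrame(counts, index=frame["asv_id"].to_list())
    taxonomy = pd.Series(frame["taxonomy"].to_list(), index=counts_frame.index)
    return ASVTable(counts=counts_frame, taxonomy=taxonomy,
                    sample_metadata=sample_metadata)


def write_asv_table(table: ASVTable, path) -> None:
    out = table.counts.copy()
    out.insert(0, "taxonomy", table.taxonomy)
    out.insert(0, "asv_id", out.index)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

def write_distance_matrix(dm, path) -> None:
    data, ids = np.asarray(dm.data, dtype=float), list(dm.ids)
    pd.DataFrame(data, index=ids, columns=ids).to_csv(path, sep="\t")


def read_distance_matrix(path):
    from skbio import DistanceMatrix

    frame = pd.read_csv(path, sep="\t", index_col=0,
                        float_precision="round_trip")
    return DistanceMatrix(frame.to_numpy(dtype=float),
                          ids=[str(i) for i in frame.index])


class _NumpyJSONEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(payload, path) -> None:
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, cls=_NumpyJSONEncoder)
        + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
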