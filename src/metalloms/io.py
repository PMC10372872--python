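"""Readers and writers for the formats the pipeline touches.

Spectra come in as mzML (via pyteomics) or two-column text; sequences as
FASTA (via Biopython); arrival-time distributions as two-column text/CSV.
Results go out as CSV with a deterministic column order and fixed float
precision (6 d.p. for m/z, 1 d.p. for CCS) or as JSON with sorted keys.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from Bio import SeqIO

from .chem import ProteinSequence
from .isotopes import Spectrum
from .mobility import ArrivalTimeDistribution

__all__ = [
    "read_spectrum",
    "read_fasta",
    "read_atd",
    "read_peaks",
    "write_results",
]

_PRECISION_BY_STEM = {
    "mz": 6,
    "ppm": 2,
    "ccs": 1,
    "fwhm": 1,
    "score": 6,
    "scale": 4,
    "residual": 6,
    "intensity": 4,
}


def _parse_two_columns(path: Path) -> tuple[np.ndarray, np.ndarray]:
    xs: list[float] = []
    ys: list[float] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.replace(",", " ").split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two columns, got {raw!r}")
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as err:
            raise ValueError(f"{path}:{lineno}: {err}") from err
    if not xs:
        raise ValueError(f"{path}: no data rows")
    return np.asarray(xs), np.asarray(ys)


def _sort_if_needed(x: np.ndarray, y: np.ndarray, what: str):
    if np.any(np.diff(x) < 0):
        warnings.warn(f"{what} axis was not sorted; sorting on read", stacklevel=3)
        order = np.argsort(x, kind="stable")
        x, y = x[order], y[order]
    # collapse exact duplicates (strictly increasing axis required downstream)
    keep = np.concatenate(([True], np.diff(x) > 0))
    return x[keep], y[keep]


def read_spectrum(path: str | Path, kind: str | None = None, scan: int = 0) -> Spectrum:
    """Read a spectrum from mzML or two-column text (``#`` comments allowed).

    ``kind`` defaults by extension; for mzML, ``scan`` selects the spectrum
    index. The m/z axis is sorted on read (with a warning) if needed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if kind is None:
        kind = "mzml" if path.suffix.lower() == ".mzml" else "text"
    if kind == "mzml":
        from pyteomics import mzml as _mzml

        with _mzml.MzML(str(path)) as reader:
            for index, entry in enumerate(reader):
                if index == scan:
                    mz = np.asarray(entry["m/z array"], float)
                    inten = np.asarray(entry["intensity array"], float)
                    mz, inten = _sort_if_needed(mz, inten, "m/z")
                    centroided = entry.get("centroid spectrum") is not None
                    return Spectrum(
                        mz,
                        inten,
                        label=entry.get("id", path.stem),
                        metadata={"centroided": centroided, "source": str(path)},
                    )
        raise ValueError(f"{path}: no spectrum at scan index {scan}")
    if kind != "text":
        raise ValueError(f"unknown spectrum kind {kind!r}")
    mz, inten = _parse_two_columns(path)
    mz, inten = _sort_if_needed(mz, inten, "m/z")
    return Spectrum(mz, inten, label=path.stem, metadata={"source": str(path)})


def read_peaks(path: str | Path) -> list[tuple[float, float]]:
    """Centroided peak list from two-column text: (m/z, intensity) tuples."""
    mz, inten = _parse_two_columns(Path(path))
    return list(zip(mz.tolist(), inten.tolist()))


def read_fasta(path: str | Path, record_id: str | None = None) -> ProteinSequence:
    """Single-record FASTA (or pick a record by id from a multi-record file)."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    if record_id is None:
        if len(records) > 1:
            ids = ", ".join(r.id for r in records[:5])
            raise ValueError(
                f"{path} holds {len(records)} records ({ids}...); pass record_id"
            )
        record = records[0]
    else:
        try:
            record = next(r for r in records if r.id == record_id)
        except StopIteration:
            raise ValueError(f"{path}: no record with id {record_id!r}") from None
    return ProteinSequence(str(record.seq).upper(), name=record.id)


def read_atd(
    path: str | Path,
    label: str = "",
    charge: int = 0,
    mass: float = 0.0,
    tw_set: str | None = None,
) -> ArrivalTimeDistribution:
    """Arrival-time distribution from two-column text/CSV (time ms, intensity)."""
    t, inten = _parse_two_columns(Path(path))
    t, inten = _sort_if_needed(t, inten, "time")
    return ArrivalTimeDistribution(
        times=t,
        intensity=np.clip(inten, 0.0, None),
        label=label or Path(path).stem,
        charge=charge,
        mass=mass,
        tw_set=tw_set,
    )


def _as_records(results: Any) -> list[dict]:
    if isinstance(results, pd.DataFrame):
        return results.to_dict("records")
    records = []
    for item in results:
        if dataclasses.is_dataclass(item):
            records.append(dataclasses.asdict(item))
        elif isinstance(item, dict):
            records.append(dict(item))
        else:
            raise TypeError(f"cannot serialize result of type {type(item)!r}")
    return records


def _round_value(key: str, value: Any) -> Any:
    if isinstance(value, float):
        for stem, ndigits in _PRECISION_BY_STEM.items():
            if stem in key.lower():
                return round(value, ndigits)
        return round(value, 6)
    return value


def write_results(results: Any, path: str | Path, format: str | None = None) -> None:
    """Write a list of records (dataclasses or dicts) as CSV or JSON.

    Column order follows the first record's field order; floats are rounded
    at a fixed, column-dependent precision so outputs are byte-stable.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower() or "csv"
    records = _as_records(results)
    rounded = [
        {k: _round_value(k, v) for k, v in record.items()} for record in records
    ]
    if format == "csv":
        if rounded:
            frame = pd.DataFrame(rounded, columns=list(rounded[0].keys()))
        else:
            frame = pd.DataFrame()
        frame.to_csv(path, index=False)
    elif format == "json":
        path.write_text(json.dumps(rounded, indent=2, sort_keys=True, default=str) + "\n")
    else:
        raise ValueError(f"unknown output format {format!r}")
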