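"""Reading and writing pressure records and analysis tables.

A pressure record is stored as two plain-text files sharing a base name:

``<base>.meta.json``
    Plate geometry (:class:`PlateSpec`), start time, frame count and optional
    trial metadata (:class:`TrialMeta`).

``<base>.frames.csv``
    Sparse frame data, header ``t,row,col,p_kpa``, one row per non-zero cell.
    Elephant footprints occupy well under 10% of the plate, so the sparse
    layout is compact and diff-able.

Coordinate convention: 0-based ``(row, col)`` grid indices; physical
coordinates are cell centres, ``x = (col + 0.5) * pitch_x_m`` across the plate
width (mediolateral axis) and ``y = (row + 0.5) * pitch_y_m`` along the
direction of travel (cranio-caudal axis).  Pressures are kPa throughout.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd

from elefoot.errors import FormatError, SchemaError

__all__ = [
    "PlateSpec",
    "PressureRecord",
    "TrialMeta",
    "read_pressure_record",
    "write_pressure_record",
    "read_table",
    "write_cop_table",
]


@dataclass(frozen=True)
class PlateSpec:
    """Geometry and timing of a pressure platform.

    Defaults reproduce a 44 x 160 sensor plate of 0.605 m x 2.122 m sampled
    at 100 Hz (7040 sensors, about 0.55 sensors per cm^2), the configuration
    used for adult elephants walking over ground-level platforms.
    """

    n_cols: int = 44
    n_rows: int = 160
    width_m: float = 0.605
    length_m: float = 2.122
    freq_hz: int = 100

    def __post_init__(self) -> None:
        for name in ("n_cols", "n_rows", "freq_hz"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.width_m <= 0 or self.length_m <= 0:
            raise ValueError("plate dimensions must be positive")

    @property
    def pitch_x_m(self) -> float:
        """Sensor spacing across the plate width (mediolateral)."""
        return self.width_m / self.n_cols

    @property
    def pitch_y_m(self) -> float:
        """Sensor spacing along the plate length (direction of travel)."""
        return self.length_m / self.n_rows

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_centre(self, row: float, col: float) -> tuple[float, float]:
        """Physical (x_m, y_m) of a (possibly fractional) grid position."""
        return ((col + 0.5) * self.pitch_x_m, (row + 0.5) * self.pitch_y_m)

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)


@dataclass(frozen=True)
class TrialMeta:
    """Per-trial subject metadata."""

    subject_id: str = ""
    body_mass_kg: float | None = None
    shoulder_height_m: float | None = None
    hip_height_m: float | None = None
    velocity_ms: float | None = None
    side_hint: str | None = None  # walking direction: "+y" or "-y"

    def __post_init__(self) -> None:
        for name in ("body_mass_kg", "shoulder_height_m", "hip_height_m", "velocity_ms"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")

    def to_dict(self) -> dict[str, Any]:
        return {k: v for k, v in asdict(self).items() if v is not None and v != ""}


@dataclass
class PressureRecord:
    """A time-ordered stack of pressure frames on a fixed sensor grid.

    ``frames`` has shape ``(n_frames, n_rows, n_cols)`` in kPa.
    """

    spec: PlateSpec
    frames: np.ndarray
    t0: float = 0.0
    meta: TrialMeta = field(default_factory=TrialMeta)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D array (t, row, col)")
        if self.frames.shape[0] < 1:
            raise ValueError("record must hold at least one frame")
        if self.frames.shape[1:] != self.spec.shape:
            raise ValueError(
                f"frame shape {self.frames.shape[1:]} does not match plate {self.spec.shape}"
            )
        if np.any(self.frames < 0):
            bad = int(np.argwhere(self.frames < 0)[0, 0])
            raise FormatError(f"negative pressure in frame {bad}")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.spec.freq_hz

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PressureRecord):
            return NotImplemented
        return (
            self.spec == other.spec
            and self.t0 == other.t0
            and self.meta == other.meta
            and self.frames.shape == other.frames.shape
            and bool(np.all(self.frames == other.frames))
        )


_FORMAT_VERSION = 1


def _base_path(path: str | Path) -> Path:
    p = Path(path)
    name = p.name
    for suffix in (".meta.json", ".frames.csv"):
        if name.endswith(suffix):
            return p.with_name(name[: -len(suffix)])
    return p


def write_pressure_record(record: PressureRecord, path: str | Path) -> None:
    """Write ``record`` to ``<path>.meta.json`` + ``<path>.frames.csv``.

    Float values are written with shortest round-tripping ``repr``, so a
    read-back record compares equal bit-for-bit.
    """
    base = _base_path(path)
    header = {
        "format_version": _FORMAT_VERSION,
        "plate": record.spec.to_dict(),
        "t0": record.t0,
        "n_frames": record.n_frames,
        "meta": record.meta.to_dict(),
    }
    base.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{base}.meta.json", "w") as fh:
        json.dump(header, fh, indent=2, sort_keys=True)
        fh.write("\n")
    t, r, c = np.nonzero(record.frames)
    p = record.frames[t, r, c]
    buf = io.StringIO()
    buf.write("t,row,col,p_kpa\n")
    for ti, ri, ci, pi in zip(t.tolist(), r.tolist(), c.tolist(), p.tolist()):
        buf.write(f"{ti},{ri},{ci},{pi!r}\n")
    with open(f"{base}.frames.csv", "w") as fh:
        fh.write(buf.getvalue())


def read_pressure_record(path: str | Path) -> PressureRecord:
    """Read a record written by :func:`write_pressure_record`.

    ``path`` may be the base name or either component file.
    """
    base = _base_path(path)
    meta_path = Path(f"{base}.meta.json")
    frames_path = Path(f"{base}.frames.csv")
    if not meta_path.exists():
        raise FormatError(f"missing header file {meta_path}")
    if not frames_path.exists():
        raise FormatError(f"missing frames file {frames_path}")
    try:
        header = json.loads(meta_path.read_text())
        spec = PlateSpec(**header["plate"])
        n_frames = int(header["n_frames"])
        t0 = float(header["t0"])
        meta = TrialMeta(**header.get("meta", {}))
    except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
        raise FormatError(f"malformed header {meta_path}: {exc}") from exc
    if n_frames < 1:
        raise FormatError("header declares no frames")
    frames = np.zeros((n_frames, spec.n_rows, spec.n_cols), dtype=float)
    with open(frames_path) as fh:
        reader = csv.reader(fh)
        head = next(reader, None)
        if head != ["t", "row", "col", "p_kpa"]:
            raise FormatError(f"unexpected frames header {head!r}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                ti, ri, ci = int(row[0]), int(row[1]), int(row[2])
                pi = float(row[3])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"bad frame row at line {lineno}: {row!r}") from exc
            if not (0 <= ti < n_frames):
                raise FormatError(f"frame index {ti} out of declared range at line {lineno}")
            if not (0 <= ri < spec.n_rows and 0 <= ci < spec.n_cols):
                raise FormatError(
                    f"cell ({ri}, {ci}) outside the declared grid in frame {ti}"
                )
            if pi < 0:
                raise FormatError(f"negative pressure in frame {ti}")
            frames[ti, ri, ci] = pi
    return PressureRecord(spec=spec, frames=frames, t0=t0, meta=meta)


def _convert(value: str, typ: type) -> Any:
    value = value.strip()
    if typ is str:
        return value
    if typ is int:
        return int(value)
    if typ is float:
        try:
            return float(value)
        except ValueError:
            # tolerate decimal commas from continental exports
            return float(value.replace(",", "."))
    raise TypeError(f"unsupported schema type {typ!r}")


def read_table(path: str | Path, schema: Mapping[str, type]) -> pd.DataFrame:
    """Tolerant reader for supplementary-style delimited exports.

    Sniffs the delimiter among ``, ; \\t``, accepts both decimal point and
    decimal comma, types the columns named in ``schema`` and preserves unknown
    columns as text.

    Parameters
    ----------
    path:
        Delimited text file with a header row.
    schema:
        Mapping of required column name to ``str``/``int``/``float``.

    Raises
    ------
    SchemaError
        If any required column is missing.
    """
    text = Path(path).read_text()
    first_line = text.splitlines()[0] if text else ""
    try:
        dialect = csv.Sniffer().sniff(first_line, delimiters=",;\t")
        delim = dialect.delimiter
    except csv.Error:
        delim = ","
    rows = list(csv.reader(io.StringIO(text), delimiter=delim))
    if not rows:
        raise SchemaError("empty table")
    header = [h.strip() for h in rows[0]]
    missing = [name for name in schema if name not in header]
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    data: dict[str, list[Any]] = {name: [] for name in header}
    for row in rows[1:]:
        if not any(cell.strip() for cell in row):
            continue
        for name, cell in zip(header, row):
            typ = schema.get(name, str)
            data[name].append(_convert(cell, typ))
    return pd.DataFrame(data)


def write_cop_table(rows: Iterable[Mapping[str, Any]], path: str | Path) -> None:
    """Write a COP table CSV with columns step_id,frame,x_m,y_m,p_total_kpa."""
    cols = ["step_id", "frame", "x_m", "y_m", "p_total_kpa"]
    df = pd.DataFrame(list(rows), columns=cols)
    df.to_csv(path, index=False)
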