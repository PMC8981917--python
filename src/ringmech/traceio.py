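"""Reading and writing raw tensile traces, protocols, geometry and result tables.

Canonical internal units are N, mm, s and MPa (N mm^-2), so stress computed
from loads in N and areas in mm^2 is unit-free.  Force may be declared in mN
on input and is converted on read.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "TensileTrace",
    "TestProtocol",
    "TraceFormatError",
    "TraceValidationError",
    "read_trace",
    "write_trace",
    "read_protocol",
    "write_protocol",
    "write_summary",
    "read_summary",
    "read_table",
    "write_table",
]

#: mandatory header of a measurement table (long format)
TABLE_COLUMNS = ["specimen_id", "group", "day", "endpoint", "value"]

#: header of a per-specimen mechanical summary file
SUMMARY_COLUMNS = [
    "specimen_id",
    "uts_mpa",
    "mtm_mpa",
    "failure_strain",
    "strain_at_uts",
    "failure_detected",
    "a0_mm2",
    "area_convention",
    "gauge_length_mm",
    "stress_convention",
]


class TraceFormatError(ValueError):
    """A trace file is structurally malformed (missing/unknown columns)."""


class TraceValidationError(ValueError):
    """A trace violates its invariants; the message names the offending index."""


@dataclass(frozen=True)
class TestProtocol:
    """Uniaxial pull-to-failure protocol.

    Defaults reproduce the reference protocol: rings brought to a 5 mm
    grip-to-grip distance, pulled at 0.1% of initial length per second
    (5 um/s crosshead speed) with load/extension sampled at 20 Hz, and the
    test terminated at the first drop in load greater than 40% of the
    running maximum.
    """

    initial_grip_distance: float = 5.0  # mm
    strain_rate: float = 0.001  # fraction of initial length per second
    sampling_rate: float = 20.0  # Hz
    termination_drop_fraction: float = 0.40

    def __post_init__(self) -> None:
        for name in ("initial_grip_distance", "strain_rate", "sampling_rate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0.0 < self.termination_drop_fraction < 1.0:
            raise ValueError(
                f"termination_drop_fraction must lie in (0, 1), got "
                f"{self.termination_drop_fraction}"
            )

    @property
    def crosshead_speed(self) -> float:
        """Commanded crosshead speed in mm/s (strain rate x initial length)."""
        return self.strain_rate * self.initial_grip_distance

    @property
    def sampling_interval(self) -> float:
        """Nominal time between samples, s."""
        return 1.0 / self.sampling_rate


@dataclass
class TensileTrace:
    """One pull-to-failure record (or a specimen-free drag baseline).

    ``load`` is stored in N; ``extension`` is crosshead displacement in mm
    relative to the start of the test (grips at the initial grip-to-grip
    distance); ``time`` in s.
    """

    time: np.ndarray
    extension: np.ndarray
    load: np.ndarray
    specimen_id: str = ""
    is_baseline: bool = False

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.extension = np.asarray(self.extension, dtype=float)
        self.load = np.asarray(self.load, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.time)
        if not (len(self.extension) == len(self.load) == n):
            raise TraceValidationError(
                f"array length mismatch: time={n}, extension={len(self.extension)}, "
                f"load={len(self.load)}"
            )
        if n < 2:
            raise TraceValidationError(f"trace needs >= 2 samples, got {n}")
        dt = np.diff(self.time)
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            raise TraceValidationError(
                f"time must be strictly increasing; first violation at index {bad[0] + 1}"
            )
        de = np.diff(self.extension)
        bad = np.flatnonzero(de < 0)
        if bad.size:
            raise TraceValidationError(
                f"extension must be non-decreasing; first violation at index {bad[0] + 1}"
            )

    def __len__(self) -> int:
        return len(self.time)

    def replace(self, **kwargs) -> "TensileTrace":
        return dataclasses.replace(self, **kwargs)


def read_trace(
    path,
    units_declaration: str | None = None,
    specimen_id: str | None = None,
    is_baseline: bool = False,
) -> TensileTrace:
    """Read a trace CSV with header ``time_s,extension_mm,load_N`` (or ``load_mN``).

    ``units_declaration`` ("N" or "mN") overrides the unit implied by the
    header.  Rows containing NaN/Inf are dropped (their count is recorded on
    the returned object as ``n_dropped_rows``).
    """
    path = Path(path)
    df = pd.read_csv(path)
    cols = {c.strip(): c for c in df.columns}
    if "time_s" not in cols or "extension_mm" not in cols:
        raise TraceFormatError(
            f"{path.name}: header must contain time_s and extension_mm, got {list(df.columns)}"
        )
    if "load_N" in cols:
        load_col, file_units = cols["load_N"], "N"
    elif "load_mN" in cols:
        load_col, file_units = cols["load_mN"], "mN"
    else:
        raise TraceFormatError(f"{path.name}: missing load_N or load_mN column")
    units = units_declaration or file_units
    if units not in ("N", "mN"):
        raise TraceFormatError(f"unknown load units {units!r}; expected 'N' or 'mN'")

    arr = df[[cols["time_s"], cols["extension_mm"], load_col]].to_numpy(dtype=float)
    finite = np.isfinite(arr).all(axis=1)
    n_dropped = int((~finite).sum())
    arr = arr[finite]
    load = arr[:, 2] / 1000.0 if units == "mN" else arr[:, 2]
    trace = TensileTrace(
        time=arr[:, 0],
        extension=arr[:, 1],
        load=load,
        specimen_id=specimen_id if specimen_id is not None else path.stem,
        is_baseline=is_baseline,
    )
    trace.n_dropped_rows = n_dropped
    return trace


def write_trace(trace: TensileTrace, path, units: str = "N") -> None:
    """Write a trace as CSV; loads are written in ``units`` ("N" or "mN")."""
    if units == "N":
        load, col = trace.load, "load_N"
    elif units == "mN":
        load, col = trace.load * 1000.0, "load_mN"
    else:
        raise ValueError(f"unknown units {units!r}")
    df = pd.DataFrame(
        {"time_s": trace.time, "extension_mm": trace.extension, col: load}
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_protocol(path) -> TestProtocol:
    """Read a YAML protocol file mirroring :class:`TestProtocol` field names."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(TestProtocol)}
    unknown = set(data) - known
    if unknown:
        raise TraceFormatError(f"unknown protocol keys: {sorted(unknown)}")
    return TestProtocol(**data)


def write_protocol(protocol: TestProtocol, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(protocol), fh, sort_keys=False)


def write_summary(records, path) -> None:
    """Write mechanical summaries as a tidy CSV, one row per specimen.

    ``records`` is a non-empty iterable of dicts or objects exposing the
    :data:`SUMMARY_COLUMNS` fields (e.g. rows produced by the pipeline).
    """
    rows = []
    for rec in records:
        if isinstance(rec, dict):
            rows.append({c: rec.get(c) for c in SUMMARY_COLUMNS})
        else:
            rows.append({c: getattr(rec, c) for c in SUMMARY_COLUMNS})
    if not rows:
        raise ValueError("write_summary requires at least one record")
    pd.DataFrame(rows, columns=SUMMARY_COLUMNS).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"summary file missing columns: {missing}")
    return df


def read_table(path) -> pd.DataFrame:
    """Read a long-format measurement table (specimen x group x day x endpoint)."""
    df = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"measurement table missing columns: {missing}")
    return df[TABLE_COLUMNS]


def write_table(df: pd.DataFrame, path) -> None:
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement table missing columns: {missing}")
    df[TABLE_COLUMNS].to_csv(path, index=False)
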