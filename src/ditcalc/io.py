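"""Reading and writing calorimetry traces, feeding protocols and DIT reports.

Everything is plain text: a trace is a CSV file whose first line is a
``#``-prefixed JSON metadata header, and reports are versioned JSON
documents.  The CSV layout is this package's own — metabolic-cage vendors
(MK-5000RQ/Supermex and friends) export proprietary formats that are not
parsed here; export your monitor's data to the columns below first.

Trace CSV layout::

    # ditcalc-trace v1 {"animal_id": "m1", "condition": "fasted", ...}
    time_min,vo2,vco2,activity
    0,1.7234,1.4122,35
    3,1.6988,1.3901,12
    ...

``time_min`` counts minutes since the first sample; the wall-clock time of
that first sample lives in the header as ``clock_offset`` ("HHMM"), which is
all the method needs (photoperiod and measurement windows are clock-of-day
windows, never calendar dates).  Gas rates are stored in the declared
``gas_unit`` (mL/min by default — typical mouse-scale magnitudes) and are
converted to L/min internally before the energy-expenditure equation is
applied; the unit is always declared, never guessed, because a silent
mismatch is a 1000-fold error in every downstream number.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CalorimetryError",
    "TraceFormatError",
    "TraceStructureError",
    "TraceValidationError",
    "CalorimetrySample",
    "CalorimetryTrace",
    "FeedingProtocol",
    "GAS_UNITS",
    "CONDITIONS",
    "RESTRICTION_LABELS",
    "parse_clock",
    "format_clock",
    "read_trace",
    "write_trace",
    "read_protocol",
    "write_protocol",
    "write_dit_report",
    "read_dit_report",
]

TRACE_MAGIC = "ditcalc-trace v1"
REPORT_SCHEMA_VERSION = "1"

GAS_UNITS = ("mL_per_min", "L_per_min")
CONDITIONS = ("fasted", "fed")
RESTRICTION_LABELS = ("ad_libitum", "restricted_33", "restricted_66", "custom")

_TRACE_COLUMNS = ("time_min", "vo2", "vco2", "activity")


class CalorimetryError(ValueError):
    """Base class for trace/protocol/report errors."""


class TraceFormatError(CalorimetryError):
    """The file is not a well-formed trace (missing header, columns, ...)."""


class TraceStructureError(CalorimetryError):
    """The samples violate the time grid (non-monotone or gapped)."""


class TraceValidationError(CalorimetryError):
    """A sample value violates a physical invariant (negative rate, ...)."""


def parse_clock(clock: str) -> int:
    """Parse an ``HHMM`` wall-clock string to minutes after midnight."""
    if not (isinstance(clock, str) and len(clock) == 4 and clock.isdigit()):
        raise CalorimetryError(f"clock time must be 'HHMM', got {clock!r}")
    hh, mm = int(clock[:2]), int(clock[2:])
    if hh > 23 or mm > 59:
        raise CalorimetryError(f"clock time out of range: {clock!r}")
    return 60 * hh + mm


def format_clock(minutes: float) -> str:
    m = int(round(minutes)) % (24 * 60)
    return f"{m // 60:02d}{m % 60:02d}"


@dataclass(frozen=True)
class CalorimetrySample:
    """One 3-min monitor reading: gas rates plus infrared beam-break count."""

    time: float  # minutes since trace start
    vo2: float  # in the trace's declared gas unit
    vco2: float
    activity: float  # beam crossings per minute, >= 0


@dataclass
class CalorimetryTrace:
    """An ordered, evenly sampled calorimetry recording for one animal.

    Invariants (enforced on construction): non-negative gas rates and
    activity, strictly increasing times on a constant grid equal to
    ``sampling_interval``.
    """

    time: np.ndarray
    vo2: np.ndarray
    vco2: np.ndarray
    activity: np.ndarray
    condition: str
    animal_id: str = "unknown"
    clock_offset: str = "0000"
    gas_unit: str = "mL_per_min"
    sampling_interval: float = 3.0

    def __post_init__(self) -> None:
        for name in ("time", "vo2", "vco2", "activity"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.validate()

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        if self.condition not in CONDITIONS:
            raise TraceValidationError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.gas_unit not in GAS_UNITS:
            raise TraceValidationError(
                f"gas_unit must be one of {GAS_UNITS}, got {self.gas_unit!r}"
            )
        parse_clock(self.clock_offset)
        if self.sampling_interval <= 0:
            raise TraceValidationError("sampling_interval must be positive")
        n = len(self.time)
        for name in ("vo2", "vco2", "activity"):
            arr = getattr(self, name)
            if len(arr) != n:
                raise TraceFormatError(
                    f"column {name} has {len(arr)} values, expected {n}"
                )
            if not np.all(np.isfinite(arr)):
                row = int(np.flatnonzero(~np.isfinite(arr))[0])
                raise TraceValidationError(f"non-finite {name} at row {row}")
            if np.any(arr < 0):
                row = int(np.flatnonzero(arr < 0)[0])
                raise TraceValidationError(
                    f"negative {name} ({arr[row]:g}) at row {row}"
                )
        if n and self.time[0] < 0:
            raise TraceValidationError("time must be non-negative")
        if n > 1:
            steps = np.diff(self.time)
            bad = np.flatnonzero(~np.isclose(steps, self.sampling_interval, atol=1e-9))
            if bad.size:
                row = int(bad[0]) + 1
                raise TraceStructureError(
                    f"time step of {steps[bad[0]]:g} min at row {row} "
                    f"(expected constant {self.sampling_interval:g}-min grid)"
                )

    # -- convenience -----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.time)

    @property
    def samples(self) -> Iterator[CalorimetrySample]:
        for t, o, c, a in zip(self.time, self.vo2, self.vco2, self.activity):
            yield CalorimetrySample(float(t), float(o), float(c), float(a))

    def gas_rates_l_per_min(self) -> tuple[np.ndarray, np.ndarray]:
        """VO2/VCO2 converted to L/min regardless of the stored unit."""
        scale = 1e-3 if self.gas_unit == "mL_per_min" else 1.0
        return self.vo2 * scale, self.vco2 * scale

    def clock_minutes(self) -> np.ndarray:
        """Wall-clock minutes after midnight of each sample (mod 24 h)."""
        return (parse_clock(self.clock_offset) + self.time) % (24 * 60)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CalorimetryTrace):
            return NotImplemented
        meta = ("condition", "animal_id", "clock_offset", "gas_unit")
        return (
            all(getattr(self, k) == getattr(other, k) for k in meta)
            and math.isclose(self.sampling_interval, other.sampling_interval)
            and all(
                np.array_equal(getattr(self, k), getattr(other, k))
                for k in ("time", "vo2", "vco2", "activity")
            )
        )


@dataclass(frozen=True)
class FeedingProtocol:
    """Meal timing and measured energy provision for one feeding regimen.

    ``intake_kcal`` is the measured daily intake (weighed food), never an
    estimate: for ad libitum runs it must be supplied by the experimenter.
    """

    intake_kcal: float
    meal_onset: str = "1700"
    restriction_label: str = "ad_libitum"

    def __post_init__(self) -> None:
        if self.intake_kcal <= 0:
            raise CalorimetryError("intake_kcal must be positive")
        if self.restriction_label not in RESTRICTION_LABELS:
            raise CalorimetryError(
                f"restriction_label must be one of {RESTRICTION_LABELS}, "
                f"got {self.restriction_label!r}"
            )
        parse_clock(self.meal_onset)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FeedingProtocol":
        return cls(
            intake_kcal=float(d["intake_kcal"]),
            meal_onset=str(d.get("meal_onset", "1700")),
            restriction_label=str(d.get("restriction_label", "custom")),
        )


# ---------------------------------------------------------------------------
# trace CSV


def write_trace(trace: CalorimetryTrace, path: str | Path) -> None:
    """Write a trace as header-line CSV, re-readable by :func:`read_trace`.

    Numbers are serialized with 17 significant digits, so a round trip is
    bit-faithful for float64 values.
    """
    if trace.n_samples == 0:
        raise CalorimetryError("refusing to write a trace with no samples")
    meta = {
        "animal_id": trace.animal_id,
        "condition": trace.condition,
        "clock_offset": trace.clock_offset,
        "gas_unit": trace.gas_unit,
        "sampling_interval": trace.sampling_interval,
    }
    lines = [f"# {TRACE_MAGIC} {json.dumps(meta)}", ",".join(_TRACE_COLUMNS)]
    for t, o, c, a in zip(trace.time, trace.vo2, trace.vco2, trace.activity):
        lines.append(f"{t:.17g},{o:.17g},{c:.17g},{a:.17g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_trace(path: str | Path, gas_unit: str | None = None) -> CalorimetryTrace:
    """Read and validate a trace CSV.

    Parameters
    ----------
    path:
        CSV file written by :func:`write_trace` (or hand-assembled in the
        same layout).
    gas_unit:
        Overrides the unit declared in the file header.  Required if the
        header lacks one; the unit is never inferred from magnitudes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open("r", encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        meta: dict = {}
        skip = 0
        if first.startswith("#"):
            skip = 1
            body = first.lstrip("# ").strip()
            if not body.startswith(TRACE_MAGIC):
                raise TraceFormatError(
                    f"unrecognized trace header in {path.name}: {first[:60]!r}"
                )
            payload = body[len(TRACE_MAGIC):].strip()
            if payload:
                try:
                    meta = json.loads(payload)
                except json.JSONDecodeError as exc:
                    raise TraceFormatError(
                        f"malformed metadata JSON in {path.name}: {exc}"
                    ) from exc
    try:
        df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise TraceFormatError(f"cannot parse {path.name}: {exc}") from exc
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path.name} is missing column(s) {missing}")
    if len(df) == 0:
        raise TraceFormatError(f"{path.name} contains no samples")

    unit = gas_unit or meta.get("gas_unit")
    if unit is None:
        raise TraceFormatError(
            f"{path.name} declares no gas_unit and none was supplied"
        )
    if "condition" not in meta:
        raise TraceFormatError(f"{path.name} metadata lacks 'condition'")
    return CalorimetryTrace(
        time=df["time_min"].to_numpy(float),
        vo2=df["vo2"].to_numpy(float),
        vco2=df["vco2"].to_numpy(float),
        activity=df["activity"].to_numpy(float),
        condition=str(meta["condition"]),
        animal_id=str(meta.get("animal_id", "unknown")),
        clock_offset=str(meta.get("clock_offset", "0000")),
        gas_unit=str(unit),
        sampling_interval=float(meta.get("sampling_interval", 3.0)),
    )


# ---------------------------------------------------------------------------
# protocol JSON


def write_protocol(protocol: FeedingProtocol, path: str | Path) -> None:
    Path(path).write_text(json.dumps(protocol.to_dict(), indent=2) + "\n")


def read_protocol(path: str | Path) -> FeedingProtocol:
    try:
        data = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise CalorimetryError(f"malformed protocol JSON: {exc}") from exc
    return FeedingProtocol.from_dict(data)


# ---------------------------------------------------------------------------
# DIT report JSON


def write_dit_report(result, path: str | Path) -> None:
    """Serialize a :class:`~ditcalc.dit.DITResult` as versioned JSON."""
    doc = result.to_dict()
    doc["schema_version"] = REPORT_SCHEMA_VERSION
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_dit_report(path: str | Path) -> dict:
    """Load a report written by :func:`write_dit_report` as a dict."""
    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != REPORT_SCHEMA_VERSION:
        raise CalorimetryError(
            f"unsupported report schema_version {version!r} "
            f"(expected {REPORT_SCHEMA_VERSION!r})"
        )
    return doc
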