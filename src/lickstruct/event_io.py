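"""Reading and writing on-disk lickometry artifacts.

The module owns four kinds of file:

* raw event logs — one timestamped touch/release transition per row, as a
  capacitive lickometer writes them ("events" dialect), or raw sensor
  readings at a fixed sample rate ("samples" dialect, consumed by
  :mod:`lickstruct.lick_processing`);
* session manifests — one row of animal/condition metadata per drinking
  session, including bottle and body masses for intake conversion;
* processed lick and bout tables;
* JSON analysis summaries.

All timestamps are stored in memory as seconds from the session start at
millisecond resolution, regardless of the on-disk datetime format.  The
session epoch, when timestamps are ISO datetimes, comes from the dialect —
never from the first event, so an initial quiet period does not shift the
clock.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

_log = logging.getLogger(__name__)

TOUCH = "touch"
RELEASE = "release"
POLARITIES = (TOUCH, RELEASE)

GENOTYPES = ("wild_type", "adh1_ko")
SEXES = ("F", "M")
FLUIDS = ("ethanol20", "ethanol20_saccharin03", "saccharin01", "water")

#: Sentinel written in the lick table's bout_id column for licks outside any
#: bout.  A literal string rather than an empty field: robust to readers that
#: trim delimiters.
NONBOUT = "none"

LICK_COLUMNS = ("session_id", "channel", "onset_s", "duration_s", "bout_id")
BOUT_COLUMNS = (
    "session_id",
    "bout_id",
    "start_s",
    "end_s",
    "n_licks",
    "total_lick_duration_s",
)
MANIFEST_REQUIRED = (
    "session_id",
    "animal_id",
    "genotype",
    "sex",
    "fluid",
    "session_length",
    "bottle_mass_pre",
    "bottle_mass_post",
    "body_mass",
    "day_index",
)


@dataclass(frozen=True)
class RawEvent:
    """One sensor transition: a touch or release on a channel.

    ``t`` is seconds from session start; ``sensor_value`` is the raw filtered
    capacitance reading when the log carries one (pre-digested logs do not).
    """

    t: float
    channel: int
    polarity: str
    sensor_value: int | None = None

    def __post_init__(self):
        if self.t < 0:
            raise ValidationError(f"event time must be >= 0, got {self.t}")
        if self.polarity not in POLARITIES:
            raise ValidationError(
                f"polarity must be one of {POLARITIES}, got {self.polarity!r}"
            )


@dataclass
class SessionRecord:
    """Metadata for one drinking session.

    Bottle masses are grams before/after the session; ``bec`` is the blood
    ethanol concentration measured at session end, in whatever unit the
    experiment used (the package treats it opaquely — only slopes and slope
    ratios are reported, which are unit-consistent).
    """

    session_id: str
    animal_id: str
    genotype: str
    sex: str
    fluid: str
    session_length: float
    bottle_mass_pre: float
    bottle_mass_post: float
    body_mass: float
    day_index: int = 1
    bec: float | None = None

    def __post_init__(self):
        if self.genotype not in GENOTYPES:
            raise ValidationError(
                f"session {self.session_id}: genotype {self.genotype!r} "
                f"not in {GENOTYPES}"
            )
        if self.sex not in SEXES:
            raise ValidationError(
                f"session {self.session_id}: sex {self.sex!r} not in {SEXES}"
            )
        if self.fluid not in FLUIDS:
            raise ValidationError(
                f"session {self.session_id}: fluid {self.fluid!r} not in {FLUIDS}"
            )
        if self.session_length <= 0:
            raise ValidationError(
                f"session {self.session_id}: session_length must be > 0"
            )
        if self.body_mass <= 0:
            raise ValidationError(f"session {self.session_id}: body_mass must be > 0")
        if self.bottle_mass_post > self.bottle_mass_pre:
            raise ValidationError(
                f"session {self.session_id}: bottle_mass_post "
                f"({self.bottle_mass_post}) exceeds bottle_mass_pre "
                f"({self.bottle_mass_pre})"
            )


@dataclass(frozen=True)
class LogDialect:
    """Shape of a raw log file.

    ``kind`` is ``"events"`` (touch/release rows: t, channel, polarity,
    sensor_value) or ``"samples"`` (fixed-rate readings: t, channel, value).
    ``timestamp`` is ``"seconds"`` (numeric seconds from session start) or
    ``"iso"`` (ISO-8601 datetimes converted against ``epoch``).
    """

    kind: str = "events"
    delimiter: str = ","
    timestamp: str = "seconds"
    epoch: datetime | None = None
    has_header: bool = True

    def __post_init__(self):
        if self.kind not in ("events", "samples"):
            raise ValidationError(f"unknown log kind {self.kind!r}")
        if self.timestamp not in ("seconds", "iso"):
            raise ValidationError(f"unknown timestamp format {self.timestamp!r}")
        if self.timestamp == "iso" and self.epoch is None:
            raise ValidationError("iso timestamps require a session epoch")


EVENTS_DIALECT = LogDialect(kind="events")
SAMPLES_DIALECT = LogDialect(kind="samples")


def _parse_time(raw: str, dialect: LogDialect) -> float:
    if dialect.timestamp == "seconds":
        return float(raw)
    dt = datetime.fromisoformat(raw)
    return (dt - dialect.epoch).total_seconds()


def read_event_log(
    path: str | Path,
    dialect: LogDialect = EVENTS_DIALECT,
    strict: bool = True,
) -> list[RawEvent]:
    """Read a pre-digested touch/release log.

    Events are returned in file order with timestamps converted to seconds
    from session start.  In strict mode a malformed row raises
    :class:`ParseError` naming the 1-based file line; in lenient mode it is
    skipped with a logged warning.
    """
    if dialect.kind != "events":
        raise ValidationError("read_event_log requires an 'events' dialect")
    path = Path(path)
    events: list[RawEvent] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter=dialect.delimiter)
        for lineno, row in enumerate(reader, start=1):
            if lineno == 1 and dialect.has_header:
                continue
            if not row or all(not c.strip() for c in row):
                continue
            try:
                if len(row) < 3:
                    raise ValueError(f"expected >= 3 fields, got {len(row)}")
                t = _parse_time(row[0].strip(), dialect)
                channel = int(row[1])
                polarity = row[2].strip()
                if polarity not in POLARITIES:
                    raise ValueError(f"bad polarity {polarity!r}")
                sensor_value = (
                    int(row[3]) if len(row) > 3 and row[3].strip() != "" else None
                )
                events.append(RawEvent(t, channel, polarity, sensor_value))
            except (ValueError, ValidationError) as exc:
                if strict:
                    raise ParseError(str(exc), line=lineno) from exc
                _log.warning("%s: skipping malformed row at line %d: %s",
                             path, lineno, exc)
    return events


def read_sample_log(
    path: str | Path, dialect: LogDialect = SAMPLES_DIALECT
) -> pd.DataFrame:
    """Read a raw sensor-sample log into a frame with columns t, channel, value.

    Sample logs can run to millions of rows, so parsing goes through pandas;
    timestamps are converted to seconds from session start.
    """
    if dialect.kind != "samples":
        raise ValidationError("read_sample_log requires a 'samples' dialect")
    df = pd.read_csv(
        path,
        delimiter=dialect.delimiter,
        header=0 if dialect.has_header else None,
        names=("t", "channel", "value") if not dialect.has_header else None,
    )
    missing = {"t", "channel", "value"} - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: sample log missing columns {sorted(missing)}")
    if dialect.timestamp == "iso":
        epoch = pd.Timestamp(dialect.epoch)
        df["t"] = (pd.to_datetime(df["t"]) - epoch).dt.total_seconds()
    return df[["t", "channel", "value"]]


def read_session_manifest(path: str | Path) -> list[SessionRecord]:
    """Read a session manifest CSV into validated records.

    The header must name every required field; ``bec`` is optional and may be
    blank.  A row violating a record invariant raises a
    :class:`ValidationError` naming the offending session_id.
    """
    df = pd.read_csv(path)
    missing = set(MANIFEST_REQUIRED) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: manifest missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        bec = None
        if "bec" in df.columns and pd.notna(row["bec"]):
            bec = float(row["bec"])
        records.append(
            SessionRecord(
                session_id=str(row["session_id"]),
                animal_id=str(row["animal_id"]),
                genotype=str(row["genotype"]),
                sex=str(row["sex"]),
                fluid=str(row["fluid"]),
                session_length=float(row["session_length"]),
                bottle_mass_pre=float(row["bottle_mass_pre"]),
                bottle_mass_post=float(row["bottle_mass_post"]),
                body_mass=float(row["body_mass"]),
                day_index=int(row["day_index"]),
                bec=bec,
            )
        )
    return records


def write_session_manifest(records: Sequence[SessionRecord], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for r in records:
        d = {k: getattr(r, k) for k in MANIFEST_REQUIRED}
        d["bec"] = r.bec
        rows.append(d)
    pd.DataFrame(rows, columns=list(MANIFEST_REQUIRED) + ["bec"]).to_csv(
        path, index=False, float_format="%.6f"
    )
    return path


def write_event_log(
    events: Iterable[RawEvent], path: str | Path, dialect: LogDialect = EVENTS_DIALECT
) -> Path:
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        if dialect.has_header:
            writer.writerow(("t", "channel", "polarity", "sensor_value"))
        for ev in events:
            writer.writerow(
                (
                    f"{ev.t:.6f}",
                    ev.channel,
                    ev.polarity,
                    "" if ev.sensor_value is None else ev.sensor_value,
                )
            )
    return path


def write_sample_log(
    times, values, channel: int, path: str | Path
) -> Path:
    df = pd.DataFrame({"t": times, "channel": channel, "value": values})
    df.to_csv(path, index=False, float_format="%.6f")
    return Path(path)


def write_tables(
    lick_table: pd.DataFrame,
    bout_table: pd.DataFrame,
    summaries: Sequence[dict] | dict,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the processed lick table, bout table and JSON summary.

    Frames must carry the documented columns (:data:`LICK_COLUMNS`,
    :data:`BOUT_COLUMNS`).  Reals are written with 6 decimal places; a
    read-back reproduces integers bit-exactly and reals to that precision.
    Empty frames produce header-only files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for frame, cols, name in (
        (lick_table, LICK_COLUMNS, "lick table"),
        (bout_table, BOUT_COLUMNS, "bout table"),
    ):
        missing = set(cols) - set(frame.columns)
        if missing:
            raise SchemaError(f"{name} missing columns {sorted(missing)}")
    lick_sessions = set(lick_table["session_id"].unique())
    bout_sessions = set(bout_table["session_id"].unique())
    if not bout_sessions <= lick_sessions and len(lick_table):
        raise ValidationError(
            f"bout table references sessions absent from lick table: "
            f"{sorted(bout_sessions - lick_sessions)}"
        )
    paths = {
        "licks": out_dir / "licks.csv",
        "bouts": out_dir / "bouts.csv",
        "summary": out_dir / "summary.json",
    }
    lick_table[list(LICK_COLUMNS)].to_csv(
        paths["licks"], index=False, float_format="%.6f"
    )
    bout_table[list(BOUT_COLUMNS)].to_csv(
        paths["bouts"], index=False, float_format="%.6f"
    )
    with open(paths["summary"], "w", encoding="utf-8") as fh:
        json.dump(summaries, fh, indent=2, default=float)
        fh.write("\n")
    return paths


def read_lick_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"bout_id": str})
    missing = set(LICK_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: lick table missing columns {sorted(missing)}")
    if len(df):
        df["channel"] = df["channel"].astype(int)
    return df


def read_bout_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(BOUT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: bout table missing columns {sorted(missing)}")
    if len(df):
        df["bout_id"] = df["bout_id"].astype(int)
        df["n_licks"] = df["n_licks"].astype(int)
    return df


def read_summary(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
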