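"""Tagged longitudinal record store and the script-facing history queries.

Every saved value carries the six study identifiers — project, study,
protocol, case, observation, timestamp — so exports can be merged and
filtered without joins.  *Placement* is the 1-based ordinal of a save
within one variable's history; range queries over placement and over
calendar dates are both inclusive at both ends.

The backend is a single-file embedded SQLite database (":memory:" by
default).  Read-only stores (lookup tables) reject writes.  Encryption
at rest is a pluggable codec hook: the default identity codec does
nothing; configuring any other codec makes opening require a password.
"""
from __future__ import annotations

import csv
import sqlite3
from dataclasses import dataclass
from datetime import date, datetime
from pathlib import Path
from typing import Callable, Optional

from .errors import QueryError, StorageError

ENVIRONMENTS = ("development", "test", "production")

CSV_HEADER = ["project_id", "study_id", "protocol_id", "case_id",
              "observation_id", "timestamp", "instrument", "entity",
              "code", "value"]


@dataclass(frozen=True)
class RecordTag:
    project_id: str
    study_id: str
    protocol_id: str
    case_id: str
    observation_id: str
    timestamp: datetime

    def __post_init__(self):
        for name in ("project_id", "study_id", "protocol_id",
                     "case_id", "observation_id"):
            if not getattr(self, name):
                raise StorageError(f"record tag field {name} is empty")


@dataclass(frozen=True)
class DataRecord:
    tag: RecordTag
    instrument: str
    entity: str
    code: str
    value: str

    @property
    def variable(self) -> str:
        return f"{self.instrument}_{self.entity}"


class IdentityCodec:
    """Default pass-through 'encryption': no password required."""
    requires_password = False

    def encode(self, data: bytes) -> bytes:
        return data

    def decode(self, data: bytes) -> bytes:
        return data


class DataStore:
    """One record database.  ``read_only=True`` models a lookup store."""

    _SCHEMA = """
    CREATE TABLE IF NOT EXISTS records (
        rowid_seq   INTEGER PRIMARY KEY AUTOINCREMENT,
        project_id  TEXT NOT NULL, study_id TEXT NOT NULL,
        protocol_id TEXT NOT NULL, case_id  TEXT NOT NULL,
        observation_id TEXT NOT NULL, timestamp TEXT NOT NULL,
        instrument  TEXT NOT NULL, entity TEXT NOT NULL,
        code TEXT NOT NULL, value TEXT NOT NULL,
        variable TEXT NOT NULL, placement INTEGER NOT NULL
    );
    CREATE INDEX IF NOT EXISTS idx_variable ON records (variable, placement);
    """

    def __init__(self, path: str = ":memory:", read_only: bool = False,
                 codec: Optional[object] = None,
                 password: Optional[str] = None):
        self.path = path
        self.read_only = read_only
        self.codec = codec or IdentityCodec()
        if getattr(self.codec, "requires_password", True) and \
                not isinstance(self.codec, IdentityCodec) and not password:
            raise StorageError(
                "an encrypted store requires a password to open")
        try:
            self._conn = sqlite3.connect(path)
        except sqlite3.OperationalError as exc:
            raise StorageError(f"cannot open {path!r}: {exc}") from exc
        if not read_only:
            try:
                self._conn.executescript(self._SCHEMA)
                self._conn.commit()
            except sqlite3.OperationalError as exc:
                raise StorageError(
                    f"cannot open {path!r} for writing: {exc}") from exc

    def close(self) -> None:
        self._conn.close()

    # --- writes ----------------------------------------------------------

    def save_record(self, tag: RecordTag, instrument: str, entity: str,
                    code: str, value: str) -> int:
        """Append one record; increments the variable's placement counter.
        Raises :class:`StorageError` on a read-only store."""
        if self.read_only:
            raise StorageError(f"store {self.path!r} is read-only")
        variable = f"{instrument}_{entity}"
        try:
            return self._insert(tag, instrument, entity, code, value,
                                variable)
        except sqlite3.OperationalError as exc:
            raise StorageError(f"cannot write to {self.path!r}: {exc}") \
                from exc

    def _insert(self, tag, instrument, entity, code, value, variable) -> int:
        cur = self._conn.execute(
            "SELECT COALESCE(MAX(placement), 0) FROM records "
            "WHERE variable = ?", (variable,))
        placement = cur.fetchone()[0] + 1
        cur = self._conn.execute(
            "INSERT INTO records (project_id, study_id, protocol_id, "
            "case_id, observation_id, timestamp, instrument, entity, "
            "code, value, variable, placement) "
            "VALUES (?,?,?,?,?,?,?,?,?,?,?,?)",
            (tag.project_id, tag.study_id, tag.protocol_id, tag.case_id,
             tag.observation_id, tag.timestamp.isoformat(), instrument,
             entity, code, value, variable, placement))
        self._conn.commit()
        return cur.lastrowid

    # --- script-facing queries -------------------------------------------

    def _values(self, where: str, params: tuple) -> list[str]:
        cur = self._conn.execute(
            f"SELECT value FROM records WHERE {where} ORDER BY rowid_seq",
            params)
        return [row[0] for row in cur.fetchall()]

    def find_latest(self, variable: str) -> Optional[str]:
        """Most recent saved value of ``variable`` (save order), or None."""
        cur = self._conn.execute(
            "SELECT value FROM records WHERE variable = ? "
            "ORDER BY rowid_seq DESC LIMIT 1", (variable,))
        row = cur.fetchone()
        return row[0] if row else None

    def find_latest_n(self, variable: str, n: int) -> list[str]:
        """Up to ``n`` most recent values, newest first."""
        if n < 1:
            raise QueryError(f"findLatestN needs n >= 1, got {n}")
        cur = self._conn.execute(
            "SELECT value FROM records WHERE variable = ? "
            "ORDER BY rowid_seq DESC LIMIT ?", (variable, n))
        return [row[0] for row in cur.fetchall()]

    def find_by_date(self, variable: str, date_from: date,
                     date_to: date) -> list[str]:
        """Values whose timestamp date lies in [date_from, date_to]."""
        if date_from > date_to:
            raise QueryError("findByDate: range is inverted")
        return self._values(
            "variable = ? AND date(timestamp) BETWEEN ? AND ?",
            (variable, date_from.isoformat(), date_to.isoformat()))

    def find_by_placement(self, variable: str, placement_from: int,
                          placement_to: int) -> list[str]:
        """Values whose 1-based save ordinal lies in the inclusive range."""
        if placement_from < 1 or placement_from > placement_to:
            raise QueryError(
                f"findByPlacement: invalid bounds "
                f"({placement_from}, {placement_to})")
        return self._values(
            "variable = ? AND placement BETWEEN ? AND ?",
            (variable, placement_from, placement_to))

    def variables(self) -> list[str]:
        cur = self._conn.execute(
            "SELECT DISTINCT variable FROM records ORDER BY variable")
        return [row[0] for row in cur.fetchall()]

    def placement_count(self, variable: str) -> int:
        cur = self._conn.execute(
            "SELECT COALESCE(MAX(placement), 0) FROM records "
            "WHERE variable = ?", (variable,))
        return cur.fetchone()[0]

    def all_records(self) -> list[DataRecord]:
        cur = self._conn.execute(
            "SELECT project_id, study_id, protocol_id, case_id, "
            "observation_id, timestamp, instrument, entity, code, value "
            "FROM records ORDER BY rowid_seq")
        return [DataRecord(
            tag=RecordTag(r[0], r[1], r[2], r[3], r[4],
                          datetime.fromisoformat(r[5])),
            instrument=r[6], entity=r[7], code=r[8], value=r[9])
            for r in cur.fetchall()]

    # --- export ----------------------------------------------------------

    def export_csv(self, out_dir: str, environment: str = "development",
                   study_id: Optional[str] = None,
                   protocol_id: Optional[str] = None,
                   case_id: Optional[str] = None,
                   filename: str = "export.csv") -> Path:
        """Write the (optionally filtered) records as CSV.

        The environment label only routes the output directory
        (``<out_dir>/<environment>/``), keeping test exports out of the
        production tree; content is identical across environments.
        """
        if environment not in ENVIRONMENTS:
            raise StorageError(f"unknown environment {environment!r}")
        clauses, params = ["1=1"], []
        for column, value in (("study_id", study_id),
                              ("protocol_id", protocol_id),
                              ("case_id", case_id)):
            if value is not None:
                clauses.append(f"{column} = ?")
                params.append(value)
        cur = self._conn.execute(
            "SELECT project_id, study_id, protocol_id, case_id, "
            "observation_id, timestamp, instrument, entity, code, value "
            f"FROM records WHERE {' AND '.join(clauses)} "
            "ORDER BY rowid_seq", params)
        target_dir = Path(out_dir) / environment
        target_dir.mkdir(parents=True, exist_ok=True)
        target = target_dir / filename
        with open(target, "w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(CSV_HEADER)
            writer.writerows(cur.fetchall())
        return target

    def import_csv(self, path: str) -> int:
        """Reload an export (round-trip support); returns rows imported."""
        count = 0
        with open(path, newline="") as handle:
            reader = csv.reader(handle)
            header = next(reader)
            if header != CSV_HEADER:
                raise StorageError(f"unexpected CSV header in {path!r}")
            for row in reader:
                tag = RecordTag(row[0], row[1], row[2], row[3], row[4],
                                datetime.fromisoformat(row[5]))
                self.save_record(tag, row[6], row[7], row[8], row[9])
                count += 1
        return count


def flush_pending(ctx, store: DataStore, tag: RecordTag) -> int:
    """Persist a context's pending (instrument, entity, code, value)
    tuples under one tag; clears the pending list."""
    count = 0
    for instrument, entity, code, value in ctx.pending_records:
        store.save_record(tag, instrument, entity, code, value)
        count += 1
    ctx.pending_records.clear()
    return count
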