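"""Planning-record persistence in a single-file SQLite store.

Each planning run is archived as an immutable record: volume metadata
(shape, spacing, per-role voxel counts and volumes), the planning
configuration, the weighted ranking, the Pareto screening result and any
interactive evaluations.  Payloads are stored as JSON text whose floats
round-trip bit-exactly (shortest-repr serialization); the creation
timestamp lives in its own column so payload checksums are reproducible.
"""

from __future__ import annotations

import csv
import json
import sqlite3
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

from .constraints import FeasibleSet, PlanningConfig
from .errors import ConfigurationError, RecordNotFoundError, StoreError
from .planner_pareto import ParetoResult
from .planner_weighted import RankedPlan
from .volume_io import LabelVolume

_SCHEMA = """
CREATE TABLE IF NOT EXISTS records (
    id INTEGER PRIMARY KEY AUTOINCREMENT,
    created_at TEXT NOT NULL,
    payload TEXT NOT NULL
);
"""

_CSV_COLUMNS = (
    "rank",
    "entry_x_mm", "entry_y_mm", "entry_z_mm",
    "target_x_mm", "target_y_mm", "target_z_mm",
    "clearance_mm", "path_length_mm", "capsule_angle_deg",
    "clearance_score", "length_score", "angle_score", "score",
)


def volume_metadata(volume: LabelVolume) -> dict:
    """Shape/spacing/origin plus per-role voxel counts and volumes in mL."""
    voxel_ml = float(
        volume.grid.spacing[0] * volume.grid.spacing[1] * volume.grid.spacing[2]
    ) / 1000.0
    counts = volume.role_voxel_counts()
    return {
        "shape": list(volume.grid.shape),
        "spacing_mm": list(volume.grid.spacing),
        "origin_mm": list(volume.grid.origin),
        "role_labels": {r: list(v) for r, v in volume.role_map.items()},
        "role_voxel_counts": counts,
        "role_volumes_ml": {r: n * voxel_ml for r, n in counts.items()},
    }


@dataclass
class PlanningRecord:
    """One archived planning run; immutable once saved."""

    volume_meta: dict
    config: dict
    ranking: list[dict]
    top_k: int
    pareto: dict | None = None
    interactive: list[dict] = field(default_factory=list)
    rejections: dict = field(default_factory=dict)
    notes: str = ""
    record_id: int | None = None
    created_at: str | None = None

    @classmethod
    def from_plan(
        cls,
        volume: LabelVolume,
        config: PlanningConfig,
        plan: RankedPlan,
        feasible: FeasibleSet,
        pareto: ParetoResult | None = None,
        interactive: list[dict] | None = None,
        notes: str = "",
    ) -> "PlanningRecord":
        return cls(
            volume_meta=volume_metadata(volume),
            config=config.to_dict(),
            ranking=[c.to_dict() for c in plan.ranking],
            top_k=plan.k,
            pareto=pareto.to_dict() if pareto is not None else None,
            interactive=list(interactive or []),
            rejections=dict(feasible.rejections),
            notes=notes,
        )

    def payload(self) -> str:
        """Deterministic JSON body (excludes id and timestamp)."""
        body = {
            "volume_meta": self.volume_meta,
            "config": self.config,
            "ranking": self.ranking,
            "top_k": self.top_k,
            "pareto": self.pareto,
            "interactive": self.interactive,
            "rejections": self.rejections,
            "notes": self.notes,
        }
        return json.dumps(body, sort_keys=True)

    @classmethod
    def from_row(cls, record_id: int, created_at: str, payload: str) -> "PlanningRecord":
        body = json.loads(payload)
        return cls(record_id=record_id, created_at=created_at, **body)


class PlanningStore:
    """Single-file embedded relational store of planning records."""

    def __init__(self, path):
        self.path = Path(path)
        try:
            self._conn = sqlite3.connect(self.path)
            self._conn.execute(_SCHEMA)
            self._conn.commit()
        except sqlite3.Error as exc:
            raise StoreError(f"cannot open store {self.path}: {exc}") from exc

    def close(self) -> None:
        self._conn.close()

    def __enter__(self) -> "PlanningStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def save_record(self, record: PlanningRecord) -> int:
        """Insert the record; ids are unique and monotonically assigned."""
        created = record.created_at or datetime.now(timezone.utc).isoformat()
        try:
            cur = self._conn.execute(
                "INSERT INTO records (created_at, payload) VALUES (?, ?)",
                (created, record.payload()),
            )
            self._conn.commit()
        except sqlite3.Error as exc:
            raise StoreError(f"cannot save record: {exc}") from exc
        record.record_id = int(cur.lastrowid)
        record.created_at = created
        return record.record_id

    def load_record(self, record_id: int) -> PlanningRecord:
        row = self._conn.execute(
            "SELECT id, created_at, payload FROM records WHERE id = ?", (record_id,)
        ).fetchone()
        if row is None:
            raise RecordNotFoundError(f"no record with id {record_id}")
        return PlanningRecord.from_row(*row)

    def record_ids(self) -> list[int]:
        return [r[0] for r in self._conn.execute("SELECT id FROM records ORDER BY id")]

    def export_report(self, record_id: int, path, format: str = "json") -> None:
        """Write a human-readable report (JSON: full record; CSV: top-k paths)."""
        record = self.load_record(record_id)
        export_report(record, path, format=format)


def export_report(record: PlanningRecord, path, format: str = "json") -> None:
    path = Path(path)
    if format == "json":
        body = json.loads(record.payload())
        body["record_id"] = record.record_id
        body["created_at"] = record.created_at
        path.write_text(json.dumps(body, indent=2, sort_keys=True))
    elif format == "csv":
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_CSV_COLUMNS)
            for rank, cand in enumerate(record.ranking[: record.top_k], start=1):
                writer.writerow(
                    [
                        rank,
                        *[repr(float(v)) for v in cand["entry"]],
                        *[repr(float(v)) for v in cand["target"]],
                        repr(float(cand["clearance_mm"])),
                        repr(float(cand["path_length_mm"])),
                        repr(float(cand["capsule_angle_deg"])),
                        repr(float(cand["clearance_score"])),
                        repr(float(cand["length_score"])),
                        repr(float(cand["angle_score"])),
                        repr(float(cand["score"])),
                    ]
                )
    else:
        raise ConfigurationError(f"unknown report format {format!r}; use json or csv")
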