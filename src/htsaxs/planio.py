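"""Spreadsheet, filename and run-log I/O for screening experiments.

Plans travel as XLSX or CSV with fixed lower-case headers (well, selected,
buffer, wash, notes); exports append per-well result columns (images,
bubble_label, bubble_variance) which import recognises and ignores, so
export -> import round-trips.  The run log is a plain-text, append-safe
mirror of the Log tab: date, time, every data-collection and robot step,
all file names, and the bubble-detection result for each exposure.
"""
from __future__ import annotations

import csv
import datetime
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import openpyxl

from .errors import PlanError, ValidationError
from .plans import MAX_PLAN_ROWS, PlanRow, ScreeningPlan
from .wells import WellAddress, parse_well  # noqa: F401  (re-exported surface)

PLAN_COLUMNS = ("well", "selected", "buffer", "wash", "notes")
RESULT_COLUMNS = ("images", "bubble_label", "bubble_variance")

#: run epoch used to render the simulated clock as ISO-8601 timestamps
RUN_EPOCH = datetime.datetime(2000, 1, 1, 0, 0, 0)

_TRUE = {"1", "true", "yes", "y", "x"}
_FALSE = {"", "0", "false", "no", "n", "none"}


def _parse_flag(value, row_no: int, column: str, problems: list) -> bool:
    token = "" if value is None else str(value).strip().lower()
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    problems.append(f"row {row_no}: {column}={value!r} is not a boolean flag")
    return False


def _read_table(path: Path) -> list[list]:
    if path.suffix.lower() == ".csv":
        with open(path, newline="") as fh:
            return [list(row) for row in csv.reader(fh)]
    if path.suffix.lower() == ".xlsx":
        wb = openpyxl.load_workbook(path, read_only=True)
        ws = wb.active
        rows = [["" if c is None else c for c in row] for row in ws.iter_rows(values_only=True)]
        wb.close()
        return rows
    raise ValidationError(f"unrecognised plan dialect {path.suffix!r} (use .xlsx or .csv)")


def import_plan(path) -> ScreeningPlan:
    """Read a screening plan spreadsheet (XLSX or CSV).

    All validation problems are collected and raised together with their
    row numbers (header = row 1).
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"plan file not found: {path}")
    table = _read_table(path)
    if not table:
        raise PlanError(["empty spreadsheet"])
    header = [str(c).strip().lower() for c in table[0]]
    problems = []
    unknown = [c for c in header if c and c not in PLAN_COLUMNS + RESULT_COLUMNS]
    if unknown:
        problems.append(f"unknown columns: {', '.join(unknown)}")
    missing = [c for c in PLAN_COLUMNS if c not in header]
    if missing:
        problems.append(f"missing required columns: {', '.join(missing)}")
    if problems:
        raise PlanError(problems)
    idx = {c: header.index(c) for c in PLAN_COLUMNS}

    rows: list[PlanRow] = []
    seen: dict[str, int] = {}
    body = [r for r in table[1:] if any(str(c).strip() for c in r)]
    if len(body) > MAX_PLAN_ROWS:
        problems.append(f"{len(body)} data rows exceed the {MAX_PLAN_ROWS}-well plate")
    for offset, raw in enumerate(body):
        row_no = offset + 2

        def cell(col):
            i = idx[col]
            return raw[i] if i < len(raw) else ""

        try:
            well = parse_well(str(cell("well")))
        except ValidationError as exc:
            problems.append(f"row {row_no}: {exc}")
            continue
        key = str(well)
        if key in seen:
            problems.append(f"row {row_no}: duplicate well {key} (first at row {seen[key]})")
        else:
            seen[key] = row_no
        rows.append(
            PlanRow(
                well=well,
                selected=_parse_flag(cell("selected"), row_no, "selected", problems),
                is_buffer=_parse_flag(cell("buffer"), row_no, "buffer", problems),
                wash_after=_parse_flag(cell("wash"), row_no, "wash", problems),
                notes="" if cell("notes") is None else str(cell("notes")),
            )
        )
    if problems:
        raise PlanError(problems)
    return ScreeningPlan(rows=rows)


def export_plan(plan: ScreeningPlan, records: Sequence = (), path="plan_out.xlsx") -> Path:
    """Write plan columns plus per-well result columns; importable again.

    ``records`` are ExposureRecords; each contributes its image file name
    and bubble result to its well's row.
    """
    path = Path(path)
    by_well: dict[str, list] = {}
    for rec in records:
        if rec.well is not None:
            by_well.setdefault(str(rec.well), []).append(rec)
    header = list(PLAN_COLUMNS) + list(RESULT_COLUMNS)
    out_rows = [header]
    for row in plan.rows:
        recs = by_well.get(str(row.well), [])
        images = ";".join(Path(r.image_path).name for r in recs)
        labels = ";".join(r.bubble.label.value for r in recs if r.bubble is not None)
        variances = ";".join(
            f"{r.bubble.variance:.1f}" for r in recs if r.bubble is not None
        )
        out_rows.append(
            [
                str(row.well),
                "1" if row.selected else "0",
                "1" if row.is_buffer else "0",
                "1" if row.wash_after else "0",
                row.notes,
                images,
                labels,
                variances,
            ]
        )
    try:
        if path.suffix.lower() == ".csv":
            with open(path, "w", newline="") as fh:
                csv.writer(fh).writerows(out_rows)
        else:
            wb = openpyxl.Workbook()
            ws = wb.active
            ws.title = "screening"
            for r in out_rows:
                ws.append(r)
            wb.save(path)
    except OSError as exc:
        raise ValidationError(f"cannot write plan to {path}: {exc}") from exc
    return path


def write_template(path, n_rows: int = 96) -> Path:
    """Write a blank plan covering the first ``n_rows`` wells of the plate."""
    from .wells import all_wells

    plan = ScreeningPlan(rows=[PlanRow(w, selected=False) for w in all_wells()[:n_rows]])
    return export_plan(plan, (), path)


_PREFIX_RE = re.compile(r"^[A-Za-z0-9._-]+$")
_KIND_SUFFIX = {"image": ".png", "trace": ".tsv", "snapshot": ".snap.png"}


def make_filename(prefix: str, well: Optional[WellAddress], exposure_index: int,
                  kind: str) -> str:
    """Deterministic data file name: ``prefix_WELL_eN.<suffix>``.

    Wells are part of the name so that the 96 x 5 x 3 files of a full plan
    are distinct; a well-less snapshot run uses ``X0`` as placeholder.
    """
    if not prefix or not _PREFIX_RE.match(prefix):
        raise ValidationError(
            f"illegal prefix {prefix!r}: use letters, digits, '.', '_' or '-'"
        )
    if kind not in _KIND_SUFFIX:
        raise ValidationError(f"unknown file kind {kind!r}")
    well_part = str(well) if well is not None else "X0"
    return f"{prefix}_{well_part}_e{exposure_index}{_KIND_SUFFIX[kind]}"


@dataclass
class LogEntry:
    """One Log-tab line: a robot step or an exposure with its artefacts."""

    time: float  # simulated seconds since the run epoch
    step: str
    files: list = field(default_factory=list)
    bubble_label: Optional[str] = None
    bubble_variance: Optional[float] = None
    trace_file: Optional[str] = None

    def render(self) -> str:
        stamp = (RUN_EPOCH + datetime.timedelta(seconds=self.time)).isoformat()
        parts = [stamp, self.step]
        if self.files:
            parts.append(",".join(self.files))
        if self.bubble_label is not None:
            parts.append(f"bubble={self.bubble_label}:{self.bubble_variance:.1f}")
        return "\t".join(parts)


def write_log(entries: Sequence[LogEntry], path, append: bool = False) -> Path:
    """Write (or append) the plain-text run log, one line per entry."""
    path = Path(path)
    times = [e.time for e in entries]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValidationError("log entries must be time-ordered")
    try:
        with open(path, "a" if append else "w") as fh:
            for entry in entries:
                fh.write(entry.render() + "\n")
    except OSError as exc:
        raise ValidationError(f"cannot write log to {path}: {exc}") from exc
    return path
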