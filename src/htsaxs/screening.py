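"""The screening scripted operation: plan -> task queue -> executed run.

A plan of up to 96 wells is compiled into a flat task queue (row order x
action-template order, with a water wash appended after each row flagged
``wash_after``).  The queue then runs entirely hub-side: a beam dump
pauses collection until light is restored and resumes automatically; a
robot fault pauses and fires a SERIOUS notification; a disconnected client
changes nothing.  Each exposure is preceded by a cell snapshot and bubble
check, and sample exposures are paired with their nearest preceding
buffer for subtraction.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

from .devices import Beamline, RobotMethod
from .errors import DeviceFault, PlanError, ValidationError
from .expose import ExposureRecord, RunDefinition, run_expose
from .hub import ControlHub, Message, MessageKind, OperationStatus, Severity
from .planio import LogEntry, export_plan, write_log
from .plans import MAX_TEMPLATE_STEPS, PlanRow, ScreeningPlan  # noqa: F401 (surface)
from .wells import WellAddress


@dataclass
class Task:
    well: WellAddress
    method: RobotMethod
    rate: float = 10.0
    volume: float = 15.0


@dataclass
class TaskQueue:
    tasks: list[Task]
    cursor: int = 0
    status: OperationStatus = field(default_factory=lambda: OperationStatus("local"))


def compile_plan(plan: ScreeningPlan) -> TaskQueue:
    """Expand a plan into its deterministic task list.

    For each *selected* row, in plan order: the template steps bound to
    that row's well, then one WASH_WATER iff the row's wash flag is set.
    """
    plan.validate()
    selected = plan.selected_rows()
    if not selected:
        raise PlanError(["no wells selected"])
    tasks = []
    for row in selected:
        for method in plan.action_template:
            tasks.append(Task(row.well, method, plan.aspiration_rate, plan.volume))
        if row.wash_after:
            tasks.append(Task(row.well, RobotMethod.WASH_WATER, plan.aspiration_rate,
                              plan.volume))
    return TaskQueue(tasks=tasks)


@dataclass
class ScreeningResult:
    records: list[ExposureRecord]
    status: OperationStatus
    log_entries: list[LogEntry]

    def record_keys(self) -> list[tuple]:
        return [r.key() for r in self.records]


def execute_queue(
    queue: TaskQueue,
    beamline: Beamline,
    plan: ScreeningPlan,
    notify: Optional[Callable] = None,
    out_dir: Optional[str] = None,
) -> ScreeningResult:
    """Run every compiled task in order on the simulated bench.

    Beam dumps are absorbed inside the expose step (status PAUSED while
    waiting, automatic resume).  A robot fault leaves the operation PAUSED
    after exactly one SERIOUS notification; re-calling execute_queue
    resumes from the cursor once the fault is cleared.
    """
    status = queue.status
    if status.state.value == "PENDING":
        status.transition("RUNNING")
    elif status.state.value == "PAUSED":
        status.transition("RUNNING", "resumed after intervention")
    out_dir = out_dir or plan.directory
    records: list[ExposureRecord] = []
    log: list[LogEntry] = []
    exposure_counts: dict[str, int] = {}
    while queue.cursor < len(queue.tasks):
        task = queue.tasks[queue.cursor]
        if task.method is RobotMethod.EXPOSE:
            offset = exposure_counts.get(str(task.well), 0)
            run = RunDefinition(
                prefix=plan.prefix,
                directory=out_dir,
                binning=plan.binning,
                well=task.well,
                aspiration_rate=task.rate,
                volume=task.volume,
            )
            recs = run_expose(
                plan.exposure_times,
                run,
                beamline,
                status=status,
                log=log,
                exposure_index_offset=offset,
            )
            exposure_counts[str(task.well)] = offset + len(recs)
            records.extend(recs)
        else:
            try:
                beamline.robot.execute(task.method, well=task.well, rate=task.rate,
                                       volume=task.volume)
            except DeviceFault as exc:
                status.transition("PAUSED", f"robot fault at task {queue.cursor}: {exc}")
                if notify is not None:
                    notify(f"robot fault during {task.method.value} at {task.well}: {exc}",
                           Severity.SERIOUS)
                return ScreeningResult(records, status, log)
            log.append(
                LogEntry(
                    time=beamline.clock.now,
                    step=f"{task.method.value} well={task.well}",
                )
            )
        queue.cursor += 1
    status.transition("COMPLETED", f"{len(records)} exposures recorded")
    return ScreeningResult(records, status, log)


def estimate_duration(
    plan: ScreeningPlan,
    durations: Optional[dict] = None,
    exposure_overhead: float = 0.0,
) -> float:
    """Predicted run time: sum of method durations over the compiled tasks.

    Each EXPOSE contributes the sum of the exposure times plus
    ``exposure_overhead`` per exposure.  Actual wall time on hardware
    depends heavily on the commanded steps; this is the same bookkeeping.
    """
    if durations is None:
        from .config import RobotConfig

        durations = RobotConfig().durations
    queue = compile_plan(plan)
    total = 0.0
    for task in queue.tasks:
        if task.method is RobotMethod.EXPOSE:
            total += sum(plan.exposure_times)
            total += exposure_overhead * len(list(plan.exposure_times))
        else:
            if task.method.value not in durations:
                raise ValidationError(f"no duration entry for {task.method.value}")
            total += durations[task.method.value]
    return total


def buffer_pairing(
    records: Sequence[ExposureRecord],
    plan: ScreeningPlan,
    pair_mode: str = "before",
) -> list[tuple[ExposureRecord, ExposureRecord]]:
    """Match each sample exposure with its buffer exposure for subtraction.

    Plan rows are scanned in order; a buffer row opens a group and every
    following sample row (until the next buffer) pairs with it, exposure
    index by exposure index.  ``pair_mode="before_and_after"`` additionally
    pairs each sample with the next group's buffer, the
    bracketing-blank protocol used to verify there is no carry-over.
    """
    if pair_mode not in ("before", "before_and_after"):
        raise ValidationError(f"unknown pair_mode {pair_mode!r}")
    by_well: dict[str, list[ExposureRecord]] = {}
    for rec in records:
        if rec.well is not None:
            by_well.setdefault(str(rec.well), []).append(rec)
    selected = plan.selected_rows()
    orphans = []
    pairs: list[tuple[ExposureRecord, ExposureRecord]] = []
    current_buffer: Optional[PlanRow] = None
    # sample row index -> (sample row, preceding buffer row)
    assignments: list[tuple[PlanRow, Optional[PlanRow], int]] = []
    for i, row in enumerate(selected):
        if row.is_buffer:
            current_buffer = row
        else:
            if current_buffer is None:
                orphans.append(str(row.well))
            assignments.append((row, current_buffer, i))
    if orphans:
        raise PlanError(
            [f"sample well {w} has no preceding buffer in its group" for w in orphans]
        )
    next_buffer_after: dict[int, Optional[PlanRow]] = {}
    if pair_mode == "before_and_after":
        nxt = None
        for i in range(len(selected) - 1, -1, -1):
            next_buffer_after[i] = nxt
            if selected[i].is_buffer:
                nxt = selected[i]
    for row, buf, i in assignments:
        sample_recs = by_well.get(str(row.well), [])
        partners = [buf]
        if pair_mode == "before_and_after" and next_buffer_after.get(i) is not None:
            partners.append(next_buffer_after[i])
        for partner in partners:
            buf_recs = by_well.get(str(partner.well), [])
            for k, sample_rec in enumerate(sample_recs):
                if k < len(buf_recs):
                    pairs.append((sample_rec, buf_recs[k]))
    return pairs


# -- hub wiring -------------------------------------------------------------

def screening_handler(plan: ScreeningPlan, beamline: Beamline,
                      out_dir: Optional[str] = None) -> Callable:
    """Build a hub operation handler executing ``plan`` on ``beamline``.

    The result is stashed on the hub as ``hub.last_screening_result``.
    """

    def handler(hub: ControlHub, status: OperationStatus, payload: dict):
        queue = compile_plan(plan)
        queue.status = status
        result = execute_queue(queue, beamline, plan, notify=hub.notify,
                               out_dir=out_dir)
        hub.last_screening_result = result

    return handler


def run_screening_session(
    plan: ScreeningPlan,
    config=None,
    seed: int = 0,
    out_dir: Optional[str] = None,
    user: str = "user",
    disconnect_after_submit: bool = False,
    notification_hook: Optional[Callable] = None,
    write_outputs: bool = True,
) -> ScreeningResult:
    """End-to-end convenience: hub + bench + one screening operation.

    Registers a session, grants it the active role, submits the screening
    command, optionally disconnects the client (the run is hub-resident
    and continues regardless), executes, and writes the run log and the
    results spreadsheet next to the data.
    """
    beamline = Beamline(config=config, seed=seed)
    out = Path(out_dir or plan.directory)
    hub = ControlHub()
    hub.register_beamline(beamline)
    hub.register_operation("screen", screening_handler(plan, beamline, str(out)))
    if notification_hook is not None:
        hub.add_notification_hook(notification_hook)
    session = hub.register_session(user)
    hub.request_active(session.session_id)
    hub.submit_operation(
        session.session_id,
        Message(kind=MessageKind.COMMAND, source=session.session_id,
                payload={"operation": "screen"}),
    )
    if disconnect_after_submit:
        hub.disconnect(session.session_id)
    hub.run_pending()
    result: ScreeningResult = hub.last_screening_result
    if write_outputs:
        out.mkdir(parents=True, exist_ok=True)
        write_log(result.log_entries, out / f"{plan.prefix}.log")
        export_plan(plan, result.records, out / f"{plan.prefix}_results.xlsx")
        (out / "hub_state.json").write_text(hub.state_json())
    return result
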