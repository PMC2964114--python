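"""Screening-plan domain types: one 96-well experiment description."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .devices import RobotMethod
from .errors import PlanError, ValidationError
from .wells import WellAddress

MAX_PLAN_ROWS = 96
MAX_TEMPLATE_STEPS = 8
MAX_EXPOSURE_TIMES = 5


@dataclass
class PlanRow:
    """One well's entry: selection, buffer/wash flags and free-text notes."""

    well: WellAddress
    selected: bool = True
    is_buffer: bool = False
    wash_after: bool = False
    notes: str = ""


@dataclass
class ScreeningPlan:
    """A high-throughput screening experiment over at most 96 wells.

    Every selected row receives the same ``action_template`` (1-8 robot
    steps, at least one of which must be EXPOSE for a data-collection
    plan); ``exposure_times`` (1-5 values, seconds) apply to each EXPOSE
    step.  ``wash_after`` on a row appends a water wash once that row's
    template has finished — the per-row checkbox model that lets dilution
    series skip the ~3 min wash bottleneck between related samples.
    """

    rows: list[PlanRow]
    action_template: Sequence[RobotMethod] = (
        RobotMethod.LOAD_SAMPLE,
        RobotMethod.BUBBLE,
        RobotMethod.EXPOSE,
        RobotMethod.EMPTY_TO_WELL,
    )
    exposure_times: Sequence[float] = (0.5, 5.0, 0.5)
    prefix: str = "run"
    directory: str = "."
    binning: int = 8
    aspiration_rate: float = 10.0
    volume: float = 15.0
    notes: dict = field(default_factory=dict)

    def validate(self, require_expose: bool = True) -> None:
        """Raise PlanError listing every violation at once."""
        problems = []
        if len(self.rows) > MAX_PLAN_ROWS:
            problems.append(f"{len(self.rows)} rows exceed the {MAX_PLAN_ROWS}-well plate")
        seen: dict[WellAddress, int] = {}
        for i, row in enumerate(self.rows):
            if row.well in seen:
                problems.append(f"duplicate well {row.well} (rows {seen[row.well]} and {i})")
            else:
                seen[row.well] = i
        n_steps = len(list(self.action_template))
        if not (1 <= n_steps <= MAX_TEMPLATE_STEPS):
            problems.append(
                f"action template has {n_steps} steps; must be 1-{MAX_TEMPLATE_STEPS}"
            )
        if require_expose and RobotMethod.EXPOSE not in list(self.action_template):
            problems.append("data-collection template must contain an EXPOSE step")
        n_times = len(list(self.exposure_times))
        if not (1 <= n_times <= MAX_EXPOSURE_TIMES):
            problems.append(
                f"{n_times} exposure times; must be 1-{MAX_EXPOSURE_TIMES}"
            )
        if any(t <= 0 for t in self.exposure_times):
            problems.append("exposure times must be positive")
        if self.binning not in (2, 4, 8):
            problems.append(f"binning {self.binning} not in (2, 4, 8)")
        if problems:
            raise PlanError(problems)

    def selected_rows(self) -> list[PlanRow]:
        return [r for r in self.rows if r.selected]
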