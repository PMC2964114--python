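"""Central control hub: session arbitration, message routing, operations.

The hub plays the server role of a distributed beamline control system:
many client sessions may watch, but at most one is ACTIVE and allowed to
command.  Submitted operations are stored hub-side, so the client that
launched a screening run can disconnect (purposely or accidentally) and
the run continues untouched.  Serious faults fan out to registered
notification hooks (email/SMS in the field; any callable here); simple
interruptions like a beam dump only flip the operation to PAUSED.
"""
from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Callable, Optional

from .errors import ArbitrationError, BeamlineError, IllegalTransition, ValidationError


class Role(enum.Enum):
    ACTIVE = "ACTIVE"
    PASSIVE = "PASSIVE"


class Severity(enum.Enum):
    PAUSE = "PAUSE"
    SERIOUS = "SERIOUS"


@dataclass
class ClientSession:
    session_id: str
    user_name: str
    role: Role = Role.PASSIVE
    connected: bool = True


class MessageKind(enum.Enum):
    COMMAND = "COMMAND"
    STATUS = "STATUS"
    UPDATE = "UPDATE"
    ERROR = "ERROR"


@dataclass
class Message:
    """Line-delimited-JSON-serializable unit of the in-process bus."""

    kind: MessageKind
    source: str
    operation_id: str = ""
    payload: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "kind": self.kind.value,
                "source": self.source,
                "operation_id": self.operation_id,
                "payload": self.payload,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, line: str) -> "Message":
        raw = json.loads(line)
        return cls(
            kind=MessageKind(raw["kind"]),
            source=raw["source"],
            operation_id=raw.get("operation_id", ""),
            payload=raw.get("payload", {}),
        )


class OpState(enum.Enum):
    PENDING = "PENDING"
    RUNNING = "RUNNING"
    PAUSED = "PAUSED"
    COMPLETED = "COMPLETED"
    FAILED = "FAILED"
    ABORTED = "ABORTED"


#: legal transitions; terminal states are absorbing.  PENDING -> ABORTED is
#: included so an operation can be cancelled before the hub starts it.
LEGAL_TRANSITIONS: dict[OpState, frozenset] = {
    OpState.PENDING: frozenset({OpState.RUNNING, OpState.ABORTED}),
    OpState.RUNNING: frozenset(
        {OpState.PAUSED, OpState.COMPLETED, OpState.FAILED, OpState.ABORTED}
    ),
    OpState.PAUSED: frozenset({OpState.RUNNING, OpState.ABORTED}),
    OpState.COMPLETED: frozenset(),
    OpState.FAILED: frozenset(),
    OpState.ABORTED: frozenset(),
}

TERMINAL_STATES = frozenset({OpState.COMPLETED, OpState.FAILED, OpState.ABORTED})


class OperationStatus:
    """State machine for one hub-resident operation, with full history."""

    def __init__(self, operation_id: str, detail: str = ""):
        self.operation_id = operation_id
        self.state = OpState.PENDING
        self.detail = detail
        self.history: list[tuple[OpState, str]] = [(OpState.PENDING, detail)]

    def transition(self, new_state, detail: str = "") -> "OperationStatus":
        new_state = OpState(new_state) if not isinstance(new_state, OpState) else new_state
        if new_state not in LEGAL_TRANSITIONS[self.state]:
            raise IllegalTransition(
                f"operation {self.operation_id}: {self.state.value} -> {new_state.value}"
            )
        self.state = new_state
        self.detail = detail
        self.history.append((new_state, detail))
        return self

    @property
    def terminal(self) -> bool:
        return self.state in TERMINAL_STATES

    def paused_intervals(self) -> int:
        return sum(1 for s, _ in self.history if s is OpState.PAUSED)

    def as_dict(self) -> dict:
        return {
            "operation_id": self.operation_id,
            "state": self.state.value,
            "detail": self.detail,
            "history": [(s.value, d) for s, d in self.history],
        }


@dataclass
class _StoredOperation:
    status: OperationStatus
    command: Message
    handler: Optional[Callable] = None


class ControlHub:
    """Device/operation registry with single-active-client arbitration."""

    def __init__(self):
        self.sessions: dict[str, ClientSession] = {}
        self.devices: dict[str, object] = {}
        self.operation_handlers: dict[str, Callable] = {}
        self.operations: dict[str, _StoredOperation] = {}
        self.notification_hooks: list[Callable] = []
        self.notifications: list[tuple[str, Severity]] = []
        self.bus_log: list[Message] = []
        self._next_session = 1
        self._next_operation = 1

    # -- sessions ----------------------------------------------------------
    def register_session(self, user_name: str) -> ClientSession:
        """New sessions always start PASSIVE (monitoring only)."""
        sid = f"s{self._next_session}"
        self._next_session += 1
        session = ClientSession(session_id=sid, user_name=user_name)
        self.sessions[sid] = session
        return session

    def enumerate_sessions(self) -> list[ClientSession]:
        return list(self.sessions.values())

    @property
    def active_session(self) -> Optional[ClientSession]:
        for s in self.sessions.values():
            if s.role is Role.ACTIVE:
                return s
        return None

    def request_active(self, session_id: str) -> ClientSession:
        """Grant the active role, demoting any current holder (takeover)."""
        session = self.sessions.get(session_id)
        if session is None:
            raise ArbitrationError(f"unknown session {session_id!r}")
        if not session.connected:
            raise ArbitrationError(f"session {session_id} is disconnected")
        current = self.active_session
        if current is not None and current.session_id != session_id:
            current.role = Role.PASSIVE
            self.bus_log.append(
                Message(
                    kind=MessageKind.UPDATE,
                    source="hub",
                    payload={"event": "demoted", "session": current.session_id},
                )
            )
        session.role = Role.ACTIVE
        return session

    def disconnect(self, session_id: str) -> None:
        session = self.sessions.get(session_id)
        if session is None:
            raise ArbitrationError(f"unknown session {session_id!r}")
        session.connected = False
        session.role = Role.PASSIVE  # a disconnected session is never ACTIVE

    # -- devices and operations --------------------------------------------
    def register_device(self, name: str, device) -> None:
        self.devices[name] = device

    def register_beamline(self, beamline) -> None:
        """Register the standard device adapters under their fixed names."""
        self.register_device("shutter", beamline.shutter)
        self.register_device("detector", beamline.detector)
        self.register_device("robot", beamline.robot)
        self.register_device("ionchambers", beamline.ion_chambers)
        self.register_device("beam", beamline.beam)
        self.register_device("_beamline", beamline)

    def register_operation(self, name: str, handler: Callable) -> None:
        """``handler(hub, status, payload)`` runs the named scripted operation."""
        self.operation_handlers[name] = handler

    def submit_operation(self, session_id: str, command: Message) -> OperationStatus:
        """Accept a COMMAND from the ACTIVE session and store it hub-side."""
        session = self.sessions.get(session_id)
        if session is None:
            raise ArbitrationError(f"unknown session {session_id!r}")
        if session.role is not Role.ACTIVE:
            raise ArbitrationError(
                f"session {session_id} is PASSIVE (monitoring only) and cannot command"
            )
        op_id = str(self._next_operation)
        self._next_operation += 1
        command.operation_id = op_id
        status = OperationStatus(op_id, detail=command.payload.get("operation", ""))
        name = command.payload.get("operation", "")
        device = command.payload.get("device")
        stored = _StoredOperation(status=status, command=command)
        self.operations[op_id] = stored
        if device is not None and device not in self.devices:
            status.transition(OpState.RUNNING)
            status.transition(OpState.FAILED, f"unknown device {device!r}")
        elif name not in self.operation_handlers:
            status.transition(OpState.RUNNING)
            status.transition(OpState.FAILED, f"unknown operation {name!r}")
        else:
            stored.handler = self.operation_handlers[name]
        self.bus_log.append(command)
        return status

    def abort(self, operation_id: str) -> OperationStatus:
        stored = self.operations.get(operation_id)
        if stored is None:
            raise ValidationError(f"unknown operation {operation_id!r}")
        stored.status.transition(OpState.ABORTED, "aborted by client")
        stored.handler = None
        return stored.status

    def run_pending(self) -> list[OperationStatus]:
        """Execute stored operations in submission order.

        Execution happens hub-side: whether the submitting session is still
        connected is irrelevant.  Every accepted command ends in a terminal
        STATUS message on the bus.
        """
        done = []
        for op_id in sorted(self.operations, key=int):
            stored = self.operations[op_id]
            status = stored.status
            if status.state is not OpState.PENDING or stored.handler is None:
                continue
            status.transition(OpState.RUNNING)
            try:
                stored.handler(self, status, stored.command.payload)
                if not status.terminal:
                    status.transition(OpState.COMPLETED)
            except BeamlineError as exc:
                if status.state is OpState.PAUSED:
                    pass  # left paused for intervention (e.g. robot fault)
                elif not status.terminal:
                    status.transition(OpState.FAILED, str(exc))
            self.bus_log.append(
                Message(
                    kind=MessageKind.STATUS,
                    source="hub",
                    operation_id=op_id,
                    payload={"state": status.state.value, "detail": status.detail},
                )
            )
            done.append(status)
        return done

    # -- notifications -----------------------------------------------------
    def add_notification_hook(self, hook: Callable) -> None:
        self.notification_hooks.append(hook)

    def notify(self, event: str, severity: Severity = Severity.SERIOUS) -> int:
        """Deliver SERIOUS events to every hook exactly once; PAUSE events to none.

        A failing hook never affects the operation.  Returns the number of
        hook invocations attempted.
        """
        severity = Severity(severity) if not isinstance(severity, Severity) else severity
        self.notifications.append((event, severity))
        if severity is not Severity.SERIOUS:
            return 0
        count = 0
        for hook in self.notification_hooks:
            count += 1
            try:
                hook(event)
            except Exception:
                pass
        return count

    # -- introspection ------------------------------------------------------
    def state_dump(self) -> dict:
        return {
            "sessions": [
                {
                    "session_id": s.session_id,
                    "user_name": s.user_name,
                    "role": s.role.value,
                    "connected": s.connected,
                }
                for s in self.sessions.values()
            ],
            "devices": sorted(k for k in self.devices if not k.startswith("_")),
            "operations": [
                self.operations[k].status.as_dict()
                for k in sorted(self.operations, key=int)
            ],
        }

    def state_json(self) -> str:
        return json.dumps(self.state_dump(), indent=2, sort_keys=True)
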