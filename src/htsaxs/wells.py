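"""96-well plate addressing (rows A-H, columns 1-12)."""
from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

ROWS = "ABCDEFGH"
N_COLUMNS = 12


@dataclass(frozen=True, order=True)
class WellAddress:
    """One well of a standard 96-well plate.

    ``row`` and ``column`` are 0-based internally; ``A1`` is (0, 0) and
    ``H12`` is (7, 11).  The canonical text form is row letter + 1-based
    column number.
    """

    row: int
    column: int

    def __post_init__(self):
        if not (0 <= self.row < len(ROWS)):
            raise ValidationError(f"well row index {self.row} outside A-H")
        if not (0 <= self.column < N_COLUMNS):
            raise ValidationError(f"well column index {self.column} outside 1-12")

    def __str__(self) -> str:
        return f"{ROWS[self.row]}{self.column + 1}"


def parse_well(text: str) -> WellAddress:
    """Parse a well label such as ``"A1"`` or ``"h12"`` (case-insensitive)."""
    token = str(text).strip()
    if len(token) < 2:
        raise ValidationError(f"malformed well address {token!r}")
    letter, digits = token[0].upper(), token[1:]
    if letter not in ROWS:
        raise ValidationError(f"well row {token!r} out of range A-H")
    if not digits.isdigit():
        raise ValidationError(f"malformed well address {token!r}")
    column = int(digits)
    if not (1 <= column <= N_COLUMNS):
        raise ValidationError(f"well column {token!r} out of range 1-12")
    return WellAddress(ROWS.index(letter), column - 1)


def all_wells() -> list[WellAddress]:
    """All 96 addresses in row-major (A1..A12, B1..) order."""
    return [WellAddress(r, c) for r in range(len(ROWS)) for c in range(N_COLUMNS)]
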