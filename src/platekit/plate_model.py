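"""Plate geometry, well naming and well selection.

Supports the seven standard rectangular formats (6 to 1536 wells, 2:3
aspect).  Wells are addressed internally by 0-based ``(row, col)`` pairs;
all user-facing text uses the conventional letter + 1-based column form
("A1", "H12", "AF48").  Row letters beyond ``Z`` continue ``AA, AB, ...``
(bijective base-26, Excel style), the only convention that yields 32
distinct labels for a 1536-well plate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from .errors import GeometryError, WellNameError

#: (rows, cols) of every supported format, keyed by well count.
STANDARD_SHAPES: dict[int, tuple[int, int]] = {
    6: (2, 3),
    12: (3, 4),
    24: (4, 6),
    48: (6, 8),
    96: (8, 12),
    384: (16, 24),
    1536: (32, 48),
}

#: Canonical well-name grammar: 1-2 row letters, optional zero padding,
#: then a 1-based column number.
WELL_NAME_RE = re.compile(r"^([A-Za-z]{1,2})0*([1-9][0-9]*)$")


def row_label(row: int) -> str:
    """0-based row index -> letters: 0->A ... 25->Z, 26->AA ... 31->AF."""
    if row < 0:
        raise GeometryError(f"negative row index {row}")
    if row < 26:
        return chr(ord("A") + row)
    if row < 26 * 27:
        first, second = divmod(row - 26, 26)
        return chr(ord("A") + first) + chr(ord("A") + second)
    raise GeometryError(f"row index {row} has no supported label")


def row_from_label(label: str) -> int:
    """Inverse of :func:`row_label` (case-insensitive)."""
    label = label.upper()
    if not (1 <= len(label) <= 2 and label.isalpha()):
        raise GeometryError(f"invalid row label {label!r}")
    value = 0
    for ch in label:
        value = value * 26 + (ord(ch) - ord("A") + 1)
    return value - 1


@dataclass(frozen=True, order=True)
class WellRef:
    """A single well, 0-based row/column."""

    row: int
    col: int


@dataclass(frozen=True)
class PlateGeometry:
    """Dimensions of a standard multi-well plate."""

    n_rows: int
    n_cols: int
    format_name: str = ""

    def __post_init__(self):
        shape = STANDARD_SHAPES.get(self.n_rows * self.n_cols)
        if shape != (self.n_rows, self.n_cols):
            raise GeometryError(
                f"({self.n_rows} x {self.n_cols}) is not a standard plate "
                f"format; supported: {sorted(STANDARD_SHAPES)}"
            )
        if not self.format_name:
            object.__setattr__(self, "format_name", str(self.n_wells))

    @classmethod
    def from_format(cls, fmt: int | str) -> "PlateGeometry":
        """Build from a well count such as 96, 384 or "1536"."""
        try:
            n = int(fmt)
            rows, cols = STANDARD_SHAPES[n]
        except (KeyError, ValueError):
            raise GeometryError(f"unknown plate format {fmt!r}") from None
        return cls(rows, cols, str(n))

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols

    def contains(self, well: WellRef) -> bool:
        return 0 <= well.row < self.n_rows and 0 <= well.col < self.n_cols

    def check(self, well: WellRef) -> WellRef:
        if not self.contains(well):
            raise GeometryError(
                f"well ({well.row},{well.col}) outside {self.format_name}-well plate"
            )
        return well

    def well_index(self, well: WellRef) -> int:
        """Row-major index; defines the "first well" (lowest index) order."""
        self.check(well)
        return well.row * self.n_cols + well.col

    def iter_wells(self) -> Iterator[WellRef]:
        """All wells in row-major order."""
        for r in range(self.n_rows):
            for c in range(self.n_cols):
                yield WellRef(r, c)


def well_name(geometry: PlateGeometry, well: WellRef) -> str:
    """Canonical name: uppercase row letters + unpadded 1-based column."""
    geometry.check(well)
    return f"{row_label(well.row)}{well.col + 1}"


def parse_well_name(geometry: PlateGeometry, name: str) -> WellRef:
    """Parse a well name, case-insensitively, tolerating zero-padded columns.

    Raises :class:`WellNameError` carrying the offending text when the name
    does not match the grammar or addresses a well outside the plate.
    """
    m = WELL_NAME_RE.match(name.strip())
    if not m:
        raise WellNameError(name, "does not match row-letters + column-number")
    try:
        row = row_from_label(m.group(1))
    except GeometryError as e:
        raise WellNameError(name, str(e)) from None
    well = WellRef(row, int(m.group(2)) - 1)
    if not geometry.contains(well):
        raise WellNameError(
            name, f"outside the {geometry.format_name}-well plate"
        )
    return well


@dataclass(frozen=True)
class WellSelection:
    """An ordered, duplicate-free set of wells on one geometry."""

    geometry: PlateGeometry
    wells: tuple[WellRef, ...] = field(default_factory=tuple)

    def __post_init__(self):
        seen: dict[WellRef, None] = {}
        for w in self.wells:
            self.geometry.check(w)
            seen.setdefault(w, None)
        object.__setattr__(self, "wells", tuple(seen))

    def __len__(self) -> int:
        return len(self.wells)

    def __iter__(self) -> Iterator[WellRef]:
        return iter(self.wells)

    def __contains__(self, well: WellRef) -> bool:
        return well in set(self.wells)

    def names(self) -> list[str]:
        return [well_name(self.geometry, w) for w in self.wells]


def select_block(
    geometry: PlateGeometry, top_left: WellRef, bottom_right: WellRef
) -> WellSelection:
    """Inclusive rectangle between the two corners, row-major order."""
    geometry.check(top_left)
    geometry.check(bottom_right)
    if top_left.row > bottom_right.row or top_left.col > bottom_right.col:
        raise GeometryError("top_left must be <= bottom_right componentwise")
    wells = tuple(
        WellRef(r, c)
        for r in range(top_left.row, bottom_right.row + 1)
        for c in range(top_left.col, bottom_right.col + 1)
    )
    return WellSelection(geometry, wells)


def select_rows(geometry: PlateGeometry, indices: Sequence[int]) -> WellSelection:
    """Union of entire rows, each row swept left to right."""
    for i in indices:
        if not 0 <= i < geometry.n_rows:
            raise GeometryError(f"row index {i} outside plate")
    wells = tuple(
        WellRef(r, c) for r in indices for c in range(geometry.n_cols)
    )
    return WellSelection(geometry, wells)


def select_cols(geometry: PlateGeometry, indices: Sequence[int]) -> WellSelection:
    """Union of entire columns, each column swept top to bottom."""
    for i in indices:
        if not 0 <= i < geometry.n_cols:
            raise GeometryError(f"column index {i} outside plate")
    wells = tuple(
        WellRef(r, c) for c in indices for r in range(geometry.n_rows)
    )
    return WellSelection(geometry, wells)


def select_names(geometry: PlateGeometry, names: Iterable[str]) -> WellSelection:
    """Selection from well names (convenience for layouts built in code)."""
    return WellSelection(
        geometry, tuple(parse_well_name(geometry, n) for n in names)
    )


def union(sel1: WellSelection, sel2: WellSelection) -> WellSelection:
    """Union preserving first-seen order, deduplicated (Ctrl-click add)."""
    if sel1.geometry != sel2.geometry:
        raise GeometryError("cannot union selections on different geometries")
    return WellSelection(sel1.geometry, sel1.wells + sel2.wells)
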