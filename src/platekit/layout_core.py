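"""Layered plate layouts: areas, tagging, range numbering, concentrations.

A :class:`Layout` holds an area registry and an ordered list of layers.
Each layer maps wells to at most one :class:`WellTag` (an area, plus an
item index for ranges and an optional concentration).  Overlapping layers
encode factorial combinations: a well tagged "CellA" on layer 1 and
"VirusA" on layer 2 belongs to the CellA x VirusA condition.

Tagging rules
-------------
In the default *strict* mode a well may never end up carrying both a
control tag and a sample/range tag, on any combination of layers; the
*permissive* mode lifts that check.  Re-tagging a well on the same layer
overwrites its previous tag.

Range numbering
---------------
Ranges are self-incrementing sample areas.  Automatic numbering visits the
selected wells in a scan order set by ``(direction, priority)``:
*direction* fixes how the ``replicates`` wells of one item sit contiguously
(horizontal = consecutive columns, vertical = consecutive rows) and
*priority* fixes how successive items advance (row = sweep rows first,
column = sweep columns first).  Every consecutive group of ``replicates``
wells in that order receives the same 1-based index; a trailing short
group still gets the next index.  A *custom* mode bypasses numbering and
lets the caller stamp an explicit index on an arbitrary block of wells.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

from .errors import GeometryError, LayoutError, OverlapError
from .plate_model import PlateGeometry, WellRef, WellSelection, well_name


class AreaKind(str, enum.Enum):
    SAMPLE = "sample"
    RANGE = "range"
    POSITIVE_CONTROL = "positive_control"
    NEGATIVE_CONTROL = "negative_control"

    @property
    def is_control(self) -> bool:
        return self in (AreaKind.POSITIVE_CONTROL, AreaKind.NEGATIVE_CONTROL)


class Direction(str, enum.Enum):
    HORIZONTAL = "horizontal"
    VERTICAL = "vertical"


class Priority(str, enum.Enum):
    ROW = "row"
    COLUMN = "column"


@dataclass(frozen=True)
class RangeSpec:
    """Numbering options of a range area.

    Defaults follow the editor convention: one replicate, Horizontal /
    Row.  ``custom=True`` disables automatic numbering entirely.
    """

    replicates: int = 1
    direction: Direction = Direction.HORIZONTAL
    priority: Priority = Priority.ROW
    custom: bool = False

    def __post_init__(self):
        if self.replicates < 1:
            raise LayoutError("replicates must be a positive integer")


@dataclass(frozen=True)
class Area:
    name: str
    kind: AreaKind
    color: str = ""
    range_spec: Optional[RangeSpec] = None

    def __post_init__(self):
        if self.kind is AreaKind.RANGE and self.range_spec is None:
            object.__setattr__(self, "range_spec", RangeSpec())
        if self.kind is not AreaKind.RANGE and self.range_spec is not None:
            raise LayoutError(f"area {self.name!r}: only ranges carry a RangeSpec")


@dataclass(frozen=True)
class Concentration:
    value: float
    unit: str

    def __post_init__(self):
        if not self.value > 0:
            raise LayoutError(f"concentration must be positive, got {self.value}")


@dataclass(frozen=True)
class WellTag:
    area: str  # area name; resolved through the layout registry
    range_index: Optional[int] = None
    concentration: Optional[Concentration] = None


@dataclass
class Layer:
    id: int
    tags: dict[WellRef, WellTag] = field(default_factory=dict)


@dataclass
class Layout:
    geometry: PlateGeometry
    layers: list[Layer] = field(default_factory=list)
    areas: dict[str, Area] = field(default_factory=dict)

    def __post_init__(self):
        if not self.layers:
            self.layers = [Layer(id=1)]

    # -- registry ---------------------------------------------------------
    def area(self, name: str) -> Area:
        try:
            return self.areas[name]
        except KeyError:
            raise LayoutError(f"unknown area {name!r}") from None

    def layer(self, layer_id: int) -> Layer:
        for layer in self.layers:
            if layer.id == layer_id:
                return layer
        raise LayoutError(f"unknown layer {layer_id}")

    def add_layer(self) -> Layer:
        new = Layer(id=max(l.id for l in self.layers) + 1)
        self.layers.append(new)
        return new

    def tags_at(self, well: WellRef) -> list[tuple[int, WellTag]]:
        """(layer id, tag) pairs carried by a well, in layer order."""
        return [
            (layer.id, layer.tags[well])
            for layer in self.layers
            if well in layer.tags
        ]

    def wells_of_area(self, name: str) -> list[WellRef]:
        """Wells tagged with the area on any layer, row-major order."""
        found = {
            well
            for layer in self.layers
            for well, tag in layer.tags.items()
            if tag.area == name
        }
        return sorted(found, key=self.geometry.well_index)


def create_area(
    layout: Layout,
    name: str,
    kind: AreaKind | str,
    color: str = "",
    range_spec: Optional[RangeSpec] = None,
) -> Area:
    """Register a new area; range areas default to 1 replicate, Horizontal/Row."""
    if not name:
        raise LayoutError("area name must be non-empty")
    if name in layout.areas:
        raise LayoutError(f"area name {name!r} already registered")
    kind = AreaKind(kind)
    area = Area(
        name,
        kind,
        color,
        range_spec if kind is AreaKind.RANGE else None,
    )
    layout.areas[name] = area
    return area


# -- range numbering -------------------------------------------------------


def _scan_order(selection: WellSelection, spec: RangeSpec) -> list[WellRef]:
    """Wells of the selection in the (direction, priority) scan order.

    Bands are computed relative to the selection's bounding box so a block
    tagged anywhere on the plate numbers exactly like one at the origin.
    """
    wells = list(selection)
    min_row = min(w.row for w in wells)
    min_col = min(w.col for w in wells)
    r = spec.replicates
    d, p = spec.direction, spec.priority

    def key(w: WellRef):
        rr, cc = w.row - min_row, w.col - min_col
        if d is Direction.HORIZONTAL and p is Priority.ROW:
            return (rr, cc)  # plain row-major
        if d is Direction.VERTICAL and p is Priority.COLUMN:
            return (cc, rr)  # plain column-major
        if d is Direction.HORIZONTAL and p is Priority.COLUMN:
            # items stack downward within a band of `replicates` columns
            return (cc // r, rr, cc)
        # vertical / row: items advance rightward within a band of rows
        return (rr // r, cc, rr)

    return sorted(wells, key=key)


def assign_range_indices(
    selection: WellSelection, spec: RangeSpec
) -> dict[WellRef, int]:
    """Automatic numbering: consecutive groups of ``replicates`` wells in
    scan order share an index, starting at 1.  A trailing group smaller
    than ``replicates`` still receives the next index."""
    if len(selection) == 0:
        raise LayoutError("cannot number an empty selection")
    if spec.custom:
        raise LayoutError("custom ranges are numbered with assign_custom_index")
    ordered = _scan_order(selection, spec)
    return {w: i // spec.replicates + 1 for i, w in enumerate(ordered)}


def assign_custom_index(selection: WellSelection, index: int) -> dict[WellRef, int]:
    """Custom numbering: every selected well gets the given index.

    Repeated calls may reuse an index to build replicate blocks spanning
    multiple rows and/or columns."""
    if index < 1:
        raise LayoutError("range index must be >= 1")
    return {w: index for w in selection}


# -- tagging ---------------------------------------------------------------


def _strict_check(
    layout: Layout, layer_id: int, area: Area, selection: WellSelection
) -> None:
    """Fail if any selected well would carry both a control tag and a
    sample/range tag across all layers.  The well's current tag on the
    written layer also counts: replacing a sample tag with a control tag
    is a permissive-mode operation."""
    offending: list[WellRef] = []
    for well in selection:
        kinds = {
            layout.area(tag.area).kind.is_control
            for _, tag in layout.tags_at(well)
        }
        kinds.add(area.kind.is_control)
        if len(kinds) == 2:
            offending.append(well)
    if offending:
        names = ", ".join(well_name(layout.geometry, w) for w in offending)
        raise OverlapError(
            offending,
            f"strict mode: control and sample/range tags would overlap on: {names}",
        )


def tag_area(
    layout: Layout,
    layer_id: int,
    area: Area | str,
    selection: WellSelection,
    mode: str = "strict",
) -> Layout:
    """Tag every selected well with the area on one layer.

    Overwrites any prior tag on the same layer.  Non-custom range areas
    are auto-numbered, continuing after the highest index the area already
    carries on that layer (self-incrementing across calls).
    """
    if mode not in ("strict", "permissive"):
        raise LayoutError(f"unknown tagging mode {mode!r}")
    if selection.geometry != layout.geometry:
        raise GeometryError("selection geometry differs from layout geometry")
    area = layout.area(area if isinstance(area, str) else area.name)
    layer = layout.layer(layer_id)
    if mode == "strict":
        _strict_check(layout, layer_id, area, selection)

    indices: Mapping[WellRef, int] = {}
    if area.kind is AreaKind.RANGE and not area.range_spec.custom:
        base = max(
            (t.range_index or 0 for t in layer.tags.values() if t.area == area.name),
            default=0,
        )
        indices = {
            w: i + base
            for w, i in assign_range_indices(selection, area.range_spec).items()
        }
    for well in selection:
        layer.tags[well] = WellTag(area.name, indices.get(well))
    return layout


def tag_custom_range(
    layout: Layout,
    layer_id: int,
    area: Area | str,
    selection: WellSelection,
    index: int,
    mode: str = "strict",
) -> Layout:
    """Tag a custom range block, stamping the user-chosen item index."""
    area = layout.area(area if isinstance(area, str) else area.name)
    if area.kind is not AreaKind.RANGE or not area.range_spec.custom:
        raise LayoutError(f"area {area.name!r} is not a custom range")
    if mode == "strict":
        _strict_check(layout, layer_id, area, selection)
    layer = layout.layer(layer_id)
    for well, idx in assign_custom_index(selection, index).items():
        layer.tags[well] = WellTag(area.name, idx)
    return layout


def tag_concentration(
    layout: Layout,
    layer_id: int,
    selection: WellSelection,
    value: float,
    unit: str,
) -> Layout:
    """Attach a single concentration to already-tagged wells on a layer.

    Last write wins: re-tagging replaces the previous value."""
    conc = Concentration(value, unit)
    layer = layout.layer(layer_id)
    untagged = [w for w in selection if w not in layer.tags]
    if untagged:
        names = ", ".join(well_name(layout.geometry, w) for w in untagged)
        raise LayoutError(
            f"concentration annotates an area tag; untagged wells on layer "
            f"{layer_id}: {names}"
        )
    for well in selection:
        layer.tags[well] = replace(layer.tags[well], concentration=conc)
    return layout


def dose_series(top: float, n_doses: int, fold: float) -> list[float]:
    """Serial-dilution concentrations top, top/fold, ..., top/fold^(n-1)."""
    if not top > 0:
        raise LayoutError("top concentration must be positive")
    if n_doses < 2:
        raise LayoutError("a dose-response needs at least 2 doses")
    if not fold > 1:
        raise LayoutError("dilution fold must be > 1")
    return [top / fold**k for k in range(n_doses)]


def tag_dose_response(
    layout: Layout,
    layer_id: int,
    selection: WellSelection,
    top: float,
    n_doses: int,
    fold: float,
    unit: str,
    ordering: RangeSpec | None = None,
) -> Layout:
    """Lay a serial-dilution series across the selection.

    Dose ``k`` has value ``top / fold**k``.  Doses are assigned in the scan
    order of ``ordering`` (direction/priority; defaults Horizontal/Row)
    with ``len(selection) // n_doses`` replicate wells per dose.
    """
    series = dose_series(top, n_doses, fold)
    if len(selection) % n_doses != 0:
        raise LayoutError(
            f"selection of {len(selection)} wells is not divisible into "
            f"{n_doses} doses"
        )
    reps = len(selection) // n_doses
    base = ordering or RangeSpec()
    order_spec = RangeSpec(reps, base.direction, base.priority)
    groups = assign_range_indices(selection, order_spec)
    layer = layout.layer(layer_id)
    untagged = [w for w in selection if w not in layer.tags]
    if untagged:
        names = ", ".join(well_name(layout.geometry, w) for w in untagged)
        raise LayoutError(
            f"dose-response annotates an area tag; untagged wells on layer "
            f"{layer_id}: {names}"
        )
    for well, group in groups.items():
        conc = Concentration(series[group - 1], unit)
        layer.tags[well] = replace(layer.tags[well], concentration=conc)
    return layout


# -- validation ------------------------------------------------------------


def validate_layout(layout: Layout, strict: bool = True) -> list[str]:
    """Return a list of problems (empty when the layout is valid).

    Checks the registry/tag consistency invariants and, when ``strict``,
    the control vs sample/range overlap rule across layers.
    """
    problems: list[str] = []
    for layer in layout.layers:
        for well, tag in layer.tags.items():
            wn = well_name(layout.geometry, well)
            if tag.area not in layout.areas:
                problems.append(
                    f"layer {layer.id} well {wn}: unregistered area {tag.area!r}"
                )
                continue
            kind = layout.areas[tag.area].kind
            if (tag.range_index is not None) != (kind is AreaKind.RANGE):
                problems.append(
                    f"layer {layer.id} well {wn}: range_index must be present "
                    f"iff the area is a range (area kind {kind.value})"
                )
    if strict:
        for well in layout.geometry.iter_wells():
            kinds = {
                layout.areas[tag.area].kind.is_control
                for _, tag in layout.tags_at(well)
                if tag.area in layout.areas
            }
            if len(kinds) == 2:
                problems.append(
                    f"well {well_name(layout.geometry, well)}: control and "
                    f"sample/range tags overlap across layers"
                )
    return problems
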