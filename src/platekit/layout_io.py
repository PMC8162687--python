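"""Layout serialization, streaming file parsing, mapping and pairing.

Result and definition files are read row by row (constant memory in the
number of rows) from delimited text (comma/semicolon/tab, sniffed) or
xlsx workbooks.  Legacy binary ``.xls`` is not supported.  Layouts are
persisted as a versioned UTF-8 JSON document whose schema is defined by
this package.

Name resolution for range items follows four rules depending on which of
the Well ID / Plate ID columns are mapped on the definition file:

===================  ====================================================
Columns mapped       Rule (item index ``i`` is 1-based, plate position
                     ``j`` is 0-based)
===================  ====================================================
none                 name at data row ``i + n*j`` for a range of ``n``
                     items, rows counted 1-based excluding the header
Well ID              name at the ``(j+1)``-th occurrence of the item's
                     first-well ID
Plate ID             name at the ``i``-th occurrence of the plate ID
both                 name where well ID and plate ID both match
===================  ====================================================

Whenever a rule misses, the generic name ``"RangeName (#i)"`` is used.
"""

from __future__ import annotations

import csv
import datetime as _dt
import io
import json
import os
import warnings
import zipfile
from dataclasses import dataclass, field
from typing import Any, Iterable, Iterator, Optional, Sequence

from .errors import (
    MappingError,
    PairingError,
    PlateKitError,
    ValidationError,
)
from .layout_core import (
    Area,
    AreaKind,
    Concentration,
    Direction,
    Layer,
    Layout,
    Priority,
    RangeSpec,
    WellTag,
)
from .plate_model import (
    WELL_NAME_RE,
    PlateGeometry,
    WellRef,
    parse_well_name,
    well_name,
)

SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# Layout JSON
# ---------------------------------------------------------------------------


def save_layout(layout: Layout) -> dict:
    """Serialize a layout to a plain JSON-compatible document."""
    def tag_doc(tag: WellTag) -> dict:
        doc: dict[str, Any] = {"area": tag.area}
        if tag.range_index is not None:
            doc["range_index"] = tag.range_index
        if tag.concentration is not None:
            doc["concentration"] = {
                "value": tag.concentration.value,
                "unit": tag.concentration.unit,
            }
        return doc

    return {
        "schema_version": SCHEMA_VERSION,
        "geometry": {
            "format": layout.geometry.format_name,
            "n_rows": layout.geometry.n_rows,
            "n_cols": layout.geometry.n_cols,
        },
        "areas": [
            {
                "name": a.name,
                "kind": a.kind.value,
                "color": a.color,
                "range_spec": None
                if a.range_spec is None
                else {
                    "replicates": a.range_spec.replicates,
                    "direction": a.range_spec.direction.value,
                    "priority": a.range_spec.priority.value,
                    "custom": a.range_spec.custom,
                },
            }
            for a in layout.areas.values()
        ],
        "layers": [
            {
                "id": layer.id,
                "tags": {
                    well_name(layout.geometry, w): tag_doc(t)
                    for w, t in sorted(
                        layer.tags.items(),
                        key=lambda kv: layout.geometry.well_index(kv[0]),
                    )
                },
            }
            for layer in layout.layers
        ],
    }


def _require(doc: Any, key: str, types, path: str) -> Any:
    if not isinstance(doc, dict) or key not in doc:
        raise ValidationError(path, f"missing required key {key!r}")
    value = doc[key]
    if types is not None and not isinstance(value, types):
        raise ValidationError(f"{path}.{key}", f"expected {types}, got {type(value).__name__}")
    return value


def load_layout(doc: dict) -> Layout:
    """Rebuild a layout from its JSON document, validating the schema.

    Raises :class:`ValidationError` carrying a JSON path on any violation.
    """
    version = _require(doc, "schema_version", int, "$")
    if version != SCHEMA_VERSION:
        raise ValidationError("$.schema_version", f"unsupported version {version}")
    geo_doc = _require(doc, "geometry", dict, "$")
    try:
        geometry = PlateGeometry(
            _require(geo_doc, "n_rows", int, "$.geometry"),
            _require(geo_doc, "n_cols", int, "$.geometry"),
            str(geo_doc.get("format", "")),
        )
    except PlateKitError as e:
        if isinstance(e, ValidationError):
            raise
        raise ValidationError("$.geometry", str(e)) from None

    areas: dict[str, Area] = {}
    for k, a_doc in enumerate(_require(doc, "areas", list, "$")):
        path = f"$.areas[{k}]"
        name = _require(a_doc, "name", str, path)
        kind_text = _require(a_doc, "kind", str, path)
        try:
            kind = AreaKind(kind_text)
        except ValueError:
            raise ValidationError(f"{path}.kind", f"unknown kind {kind_text!r}") from None
        spec_doc = a_doc.get("range_spec")
        spec = None
        if spec_doc is not None:
            spath = f"{path}.range_spec"
            try:
                spec = RangeSpec(
                    _require(spec_doc, "replicates", int, spath),
                    Direction(_require(spec_doc, "direction", str, spath)),
                    Priority(_require(spec_doc, "priority", str, spath)),
                    bool(spec_doc.get("custom", False)),
                )
            except ValueError as e:
                raise ValidationError(spath, str(e)) from None
        if name in areas:
            raise ValidationError(f"{path}.name", f"duplicate area name {name!r}")
        try:
            areas[name] = Area(name, kind, str(a_doc.get("color", "")), spec)
        except PlateKitError as e:
            raise ValidationError(path, str(e)) from None

    layers: list[Layer] = []
    for k, l_doc in enumerate(_require(doc, "layers", list, "$")):
        path = f"$.layers[{k}]"
        layer = Layer(id=_require(l_doc, "id", int, path))
        for wname, t_doc in _require(l_doc, "tags", dict, path).items():
            tpath = f"{path}.tags[{wname!r}]"
            try:
                well = parse_well_name(geometry, wname)
            except PlateKitError as e:
                raise ValidationError(tpath, str(e)) from None
            area_name = _require(t_doc, "area", str, tpath)
            if area_name not in areas:
                raise ValidationError(f"{tpath}.area", f"unregistered area {area_name!r}")
            conc = None
            if t_doc.get("concentration") is not None:
                c_doc = t_doc["concentration"]
                cpath = f"{tpath}.concentration"
                try:
                    conc = Concentration(
                        float(_require(c_doc, "value", (int, float), cpath)),
                        _require(c_doc, "unit", str, cpath),
                    )
                except PlateKitError as e:
                    raise ValidationError(cpath, str(e)) from None
            idx = t_doc.get("range_index")
            if idx is not None and (not isinstance(idx, int) or idx < 1):
                raise ValidationError(f"{tpath}.range_index", "must be a positive integer")
            if (idx is not None) != (areas[area_name].kind is AreaKind.RANGE):
                raise ValidationError(
                    f"{tpath}.range_index",
                    "present iff the tagged area is a range",
                )
            layer.tags[well] = WellTag(area_name, idx, conc)
        layers.append(layer)
    if not layers:
        raise ValidationError("$.layers", "at least one layer is required")
    return Layout(geometry, layers, areas)


def write_layout(layout: Layout, path: str | os.PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(save_layout(layout), fh, indent=1)
        fh.write("\n")


def read_layout(path: str | os.PathLike) -> Layout:
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as e:
            raise ValidationError("$", f"not valid JSON: {e}") from None
    return load_layout(doc)


# ---------------------------------------------------------------------------
# Row streaming
# ---------------------------------------------------------------------------

_EXCEL_EPOCH = _dt.datetime(1899, 12, 30)


def _cell_to_text(value: Any) -> str:
    """Normalize a spreadsheet cell to the text its CSV export would hold.

    Dates are returned as numbers (spreadsheet serial values), not
    interpreted; integral floats print without a decimal point.
    """
    if value is None:
        return ""
    if isinstance(value, _dt.datetime):
        delta = value - _EXCEL_EPOCH
        value = delta.days + delta.seconds / 86400.0
    elif isinstance(value, _dt.date):
        value = (_dt.datetime(value.year, value.month, value.day) - _EXCEL_EPOCH).days
    if isinstance(value, bool):
        return "TRUE" if value else "FALSE"
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return str(value)


def _sniff_delimiter(sample_line: str, path: str) -> str:
    counts = {d: sample_line.count(d) for d in (",", ";", "\t")}
    best = max(counts, key=counts.get)
    if counts[best] > 0:
        return best
    return "\t" if str(path).lower().endswith((".tsv", ".txt")) else ","


def _iter_raw_rows(source, sheet: Optional[str] = None) -> Iterator[list[str]]:
    path = str(source)
    if path.lower().endswith(".xlsx"):
        import openpyxl

        wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
        try:
            ws = wb[sheet] if sheet else wb.worksheets[0]
            for row in ws.iter_rows(values_only=True):
                yield [_cell_to_text(c) for c in row]
        finally:
            wb.close()
        return
    if path.lower().endswith(".xls"):
        raise MappingError(
            "legacy binary .xls is not supported; convert to .xlsx or CSV"
        )
    with open(path, newline="", encoding="utf-8-sig") as fh:
        first = fh.readline()
        if not first:
            return
        fh.seek(0)
        reader = csv.reader(fh, delimiter=_sniff_delimiter(first, path))
        for row in reader:
            yield [c for c in row]


def read_header(source, sheet: Optional[str] = None) -> list[str]:
    """Column names from the first row; error on an empty file."""
    for row in _iter_raw_rows(source, sheet):
        return [c.strip() for c in row]
    raise MappingError(f"{source}: empty file, no header row")


def stream_rows(source, sheet: Optional[str] = None) -> Iterator[dict[str, str]]:
    """Yield one ``{column: text}`` record per data row, in file order.

    The header row is consumed for column names.  Ragged short rows are
    padded with empty values (with a warning); extra cells are dropped.
    The file is never materialized in memory.
    """
    raw = _iter_raw_rows(source, sheet)
    header = None
    for row in raw:
        header = [c.strip() for c in row]
        break
    if header is None:
        raise MappingError(f"{source}: empty file, no header row")
    n = len(header)
    for row in raw:
        if len(row) != n:
            if len(row) < n:
                warnings.warn(
                    f"{source}: ragged row padded from {len(row)} to {n} cells",
                    stacklevel=2,
                )
            row = (list(row) + [""] * n)[:n]
        yield dict(zip(header, row))


def peek_first_data_row(source, sheet: Optional[str] = None) -> Optional[dict[str, str]]:
    for record in stream_rows(source, sheet):
        return record
    return None


# ---------------------------------------------------------------------------
# Column mapping
# ---------------------------------------------------------------------------


@dataclass
class ColumnMapping:
    """Which columns hold the well name, plate name and measured parameters."""

    well_col: Optional[str] = None
    plate_col: Optional[str] = None
    param_cols: list[tuple[str, bool]] = field(default_factory=list)

    @property
    def param_names(self) -> list[str]:
        return [name for name, _ in self.param_cols]

    def is_numeric(self, param: str) -> bool:
        for name, numeric in self.param_cols:
            if name == param:
                return numeric
        raise MappingError(f"parameter {param!r} is not mapped")


def _parses_numeric(text: str) -> bool:
    try:
        float(text)
        return True
    except (TypeError, ValueError):
        return False


def auto_map_columns(
    header: Sequence[str], first_data_row: Optional[dict | Sequence] = None
) -> ColumnMapping:
    """Automatic mapping: the first header containing the keyword "well"
    (case-insensitive substring) becomes the Well ID column; every other
    column becomes a candidate parameter, numeric when its first data cell
    parses as a number.  Callers may override any part of the result."""
    if not header:
        raise MappingError("empty header")
    if isinstance(first_data_row, dict):
        first_cells = [first_data_row.get(h, "") for h in header]
    elif first_data_row is not None:
        first_cells = list(first_data_row) + [""] * (len(header) - len(first_data_row))
    else:
        first_cells = [""] * len(header)
    well_col = next((h for h in header if "well" in h.lower()), None)
    params = [
        (h, _parses_numeric(cell))
        for h, cell in zip(header, first_cells)
        if h != well_col
    ]
    return ColumnMapping(well_col=well_col, param_cols=params)


def auto_map_file(source, sheet: Optional[str] = None) -> ColumnMapping:
    """Convenience: auto-map straight from a file's header + first row."""
    header = read_header(source, sheet)
    return auto_map_columns(header, peek_first_data_row(source, sheet))


def _canon_well(text: str) -> str:
    """Canonical comparison form of a well cell ("a01" -> "A1")."""
    text = text.strip()
    m = WELL_NAME_RE.match(text)
    if m:
        return f"{m.group(1).upper()}{int(m.group(2))}"
    return text.upper()


# ---------------------------------------------------------------------------
# Result sets
# ---------------------------------------------------------------------------


@dataclass
class ResultSet:
    """A result file bound through a column mapping.

    ``plate_keys`` are the distinct plate names in order of first
    appearance when a Plate ID column is mapped; otherwise synthetic
    integer keys ``1..K`` where ``K`` is the maximum number of times any
    single well name occurs in the file.
    """

    source: str
    mapping: ColumnMapping
    sheet: Optional[str] = None
    _plate_keys: Optional[list] = field(default=None, repr=False)

    def __post_init__(self):
        if not self.mapping.well_col:
            raise MappingError("a result file requires a mapped Well ID column")
        if not self.mapping.param_cols:
            raise MappingError("at least one column must be mapped as a parameter")

    @property
    def plate_keys(self) -> list:
        if self._plate_keys is None:
            self._plate_keys = index_plates(self)
        return self._plate_keys


def attach_results(
    source, mapping: Optional[ColumnMapping] = None, sheet: Optional[str] = None
) -> ResultSet:
    """Bind a result file, auto-mapping columns when no mapping is given."""
    if mapping is None:
        mapping = auto_map_file(source, sheet)
        plate = next(
            (h for h, _ in mapping.param_cols if "plate" in h.lower()), None
        )
        if plate is not None:
            mapping.plate_col = plate
            mapping.param_cols = [p for p in mapping.param_cols if p[0] != plate]
    return ResultSet(str(source), mapping, sheet)


def index_plates(resultset: ResultSet) -> list:
    """Plate keys of a result file (see :class:`ResultSet`)."""
    mapping = resultset.mapping
    if mapping.plate_col:
        keys: dict[str, None] = {}
        for record in stream_rows(resultset.source, resultset.sheet):
            keys.setdefault(record.get(mapping.plate_col, "").strip(), None)
        keys.pop("", None)
        return list(keys)
    counts: dict[str, int] = {}
    for record in stream_rows(resultset.source, resultset.sheet):
        wname = _canon_well(record.get(mapping.well_col, ""))
        if wname:
            counts[wname] = counts.get(wname, 0) + 1
    k = max(counts.values(), default=0)
    return list(range(1, k + 1))


def fetch_plate_values(
    resultset: ResultSet,
    plate_key,
    param: str,
    geometry: PlateGeometry,
) -> dict[WellRef, Any]:
    """Values of one parameter on one plate, keyed by well.

    With a Plate ID column, rows whose plate cell equals the key are used;
    without, synthetic key ``j`` selects the j-th occurrence of each well
    name.  Unparseable numeric cells become missing; a duplicated
    (plate, well) pair keeps the last value with a warning.
    """
    mapping = resultset.mapping
    if plate_key not in resultset.plate_keys:
        raise MappingError(f"unknown plate key {plate_key!r}")
    numeric = mapping.is_numeric(param)
    values: dict[WellRef, Any] = {}
    occurrence: dict[str, int] = {}
    for record in stream_rows(resultset.source, resultset.sheet):
        wtext = record.get(mapping.well_col, "").strip()
        if not wtext:
            continue
        if mapping.plate_col:
            if record.get(mapping.plate_col, "").strip() != str(plate_key):
                continue
        else:
            canon = _canon_well(wtext)
            occurrence[canon] = occurrence.get(canon, 0) + 1
            if occurrence[canon] != plate_key:
                continue
        try:
            well = parse_well_name(geometry, wtext)
        except PlateKitError:
            warnings.warn(
                f"{resultset.source}: skipping unrecognized well name {wtext!r}",
                stacklevel=2,
            )
            continue
        cell = record.get(param, "")
        if numeric:
            try:
                value: Any = float(cell)
            except (TypeError, ValueError):
                continue  # unparseable numeric cell -> missing
        else:
            value = cell
        if well in values:
            warnings.warn(
                f"{resultset.source}: duplicate value for plate {plate_key!r} well "
                f"{wtext!r}; last value wins",
                stacklevel=2,
            )
        values[well] = value
    return values


# ---------------------------------------------------------------------------
# Definitions and name resolution
# ---------------------------------------------------------------------------


@dataclass
class DefinitionSource:
    """A definition file mapping range item indices to names.

    ``n_items`` is the range size on one plate, needed by the row-counting
    rule when neither Well ID nor Plate ID is mapped.
    """

    source: str
    name_col: str
    well_col: Optional[str] = None
    plate_col: Optional[str] = None
    n_items: int = 0
    sheet: Optional[str] = None

    def plate_keys(self) -> list[str]:
        if not self.plate_col:
            return []
        keys: dict[str, None] = {}
        for record in stream_rows(self.source, self.sheet):
            keys.setdefault(record.get(self.plate_col, "").strip(), None)
        keys.pop("", None)
        return list(keys)


def resolve_range_name(
    defn: Optional[DefinitionSource],
    range_name: str,
    i: int,
    j: int = 0,
    n: Optional[int] = None,
    well_id: Optional[str] = None,
    plate_id: Optional[str] = None,
) -> str:
    """Resolve the display name of range item ``i`` on plate position ``j``.

    ``well_id`` is the item's first-well name (needed when the definition
    maps a Well ID column) and ``plate_id`` the paired definition plate
    (needed when it maps a Plate ID column).  Resolution is total: every
    miss falls back to the generic ``"RangeName (#i)"``.
    """
    fallback = f"{range_name} (#{i})"
    if defn is None or i < 1 or j < 0:
        return fallback
    has_well = bool(defn.well_col)
    has_plate = bool(defn.plate_col)
    try:
        if not has_well and not has_plate:
            size = n if n is not None else defn.n_items
            if size < 1:
                return fallback
            target = i + size * j
            for rownum, record in enumerate(stream_rows(defn.source, defn.sheet), 1):
                if rownum == target:
                    name = record.get(defn.name_col, "").strip()
                    return name or fallback
            return fallback
        if has_well and not has_plate:
            if well_id is None:
                return fallback
            want = _canon_well(well_id)
            seen = 0
            for record in stream_rows(defn.source, defn.sheet):
                if _canon_well(record.get(defn.well_col, "")) == want:
                    seen += 1
                    if seen == j + 1:
                        name = record.get(defn.name_col, "").strip()
                        return name or fallback
            return fallback
        if has_plate and not has_well:
            if plate_id is None:
                return fallback
            seen = 0
            for record in stream_rows(defn.source, defn.sheet):
                if record.get(defn.plate_col, "").strip() == str(plate_id):
                    seen += 1
                    if seen == i:
                        name = record.get(defn.name_col, "").strip()
                        return name or fallback
            return fallback
        # both columns mapped
        if well_id is None or plate_id is None:
            return fallback
        want = _canon_well(well_id)
        for record in stream_rows(defn.source, defn.sheet):
            if (
                _canon_well(record.get(defn.well_col, "")) == want
                and record.get(defn.plate_col, "").strip() == str(plate_id)
            ):
                name = record.get(defn.name_col, "").strip()
                return name or fallback
        return fallback
    except PlateKitError:
        return fallback


# ---------------------------------------------------------------------------
# Pairing
# ---------------------------------------------------------------------------


@dataclass
class PairingMap:
    """Association of result plates with definition plates."""

    pairs: dict[Any, list]
    mode: str

    def definition_plates(self, result_key) -> list:
        return self.pairs.get(result_key, [])


def pair_plates(
    result_keys: Sequence,
    definition_keys: Sequence,
    mode: str = "auto_by_name",
    manual: Optional[dict] = None,
) -> PairingMap:
    """Pair result plates with definition plates.

    ``auto_by_name`` matches exact key strings (unmatched result plates
    stay unpaired, with a warning — their range names then resolve through
    the generic fallback); ``by_index`` matches positionally; ``manual``
    validates caller-supplied pairs.
    """
    pairs: dict[Any, list] = {}
    if mode == "auto_by_name":
        defs = {str(k): k for k in definition_keys}
        for rk in result_keys:
            if str(rk) in defs:
                pairs[rk] = [defs[str(rk)]]
            else:
                warnings.warn(f"result plate {rk!r} has no matching definition plate",
                              stacklevel=2)
    elif mode == "by_index":
        for rk, dk in zip(result_keys, definition_keys):
            pairs[rk] = [dk]
    elif mode == "manual":
        manual = manual or {}
        for rk, dks in manual.items():
            if rk not in result_keys:
                raise PairingError(f"unknown result plate key {rk!r}")
            dks = [dks] if not isinstance(dks, (list, tuple)) else list(dks)
            for dk in dks:
                if dk not in definition_keys:
                    raise PairingError(f"unknown definition plate key {dk!r}")
            pairs[rk] = dks
    else:
        raise PairingError(f"unknown pairing mode {mode!r}")
    return PairingMap(pairs, mode)


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------


def render_cell(value: Any) -> str:
    """Cell text for TSV export; undefined/missing renders blank."""
    from .analysis import Undefined

    if value is None or isinstance(value, Undefined):
        return ""
    if isinstance(value, float):
        return format(value, ".6g")
    return str(value)


def table_to_tsv(header: Sequence[str], rows: Iterable[Sequence]) -> str:
    """Tab-separated text with a header row, UTF-8, LF line ends."""
    out = io.StringIO()
    out.write("\t".join(str(h) for h in header) + "\n")
    for row in rows:
        out.write("\t".join(render_cell(c) for c in row) + "\n")
    return out.getvalue()


def export_zip(tables: dict[str, str], path: str | os.PathLike) -> None:
    """Write an organized zip archive: one file per table, keys are
    archive paths like ``"controls/plate_P1.tsv"`` (directory per tool)."""
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name, text in tables.items():
            zf.writestr(name, text)
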