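"""Aggregation and QC analyses: controls, per-combination columns, grouped tables.

Statistics
----------
For n numeric values with average ``Avg``:

.. math::

    SD = \\sqrt{\\tfrac{1}{n}\\sum_i (x_i - Avg)^2}
    \\qquad CV = 100 \\times SD / Avg

i.e. the *population* standard deviation (divisor n) and the coefficient
of variation in percent.  Assay quality for a positive/negative control
pair uses the Z-factor and window:

.. math::

    Z' = 1 - \\frac{3 (SD_{pos} + SD_{neg})}{|Avg_{pos} - Avg_{neg}|}
    \\qquad W = \\frac{\\max(Avg_{pos}, Avg_{neg})}{\\min(Avg_{pos}, Avg_{neg})}

Z' is 1 for a noiseless assay and conventionally excellent above 0.5.
Degenerate cases (equal control means, a zero control mean) yield a typed
:class:`Undefined` value carrying the reason — rendered blank in exports,
never raised mid-report.

Missing or non-numeric well values are excluded from every aggregation;
``n`` counts included values only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Callable, Optional, Sequence, Union

from .errors import LayoutError, MappingError, PlateKitError
from .layout_core import AreaKind, Layout
from .layout_io import ResultSet, fetch_plate_values, table_to_tsv
from .plate_model import WellRef, WellSelection


class Undefined:
    """A value that could not be computed, with the reason why.

    Falsy; renders blank in tabular exports."""

    __slots__ = ("reason",)

    def __init__(self, reason: str):
        self.reason = reason

    def __bool__(self) -> bool:
        return False

    def __repr__(self) -> str:
        return f"Undefined({self.reason!r})"


MaybeFloat = Union[float, Undefined]


@dataclass(frozen=True)
class StatSummary:
    """Average, population SD (divisor n), count and CV (%) of a sample."""

    avg: float
    sd: float
    n: int
    cv: Optional[float]


def stat_summary(values: Sequence[float]) -> StatSummary:
    """Summary statistics of at least one numeric value."""
    values = [float(v) for v in values]
    if not values:
        raise PlateKitError("stat_summary requires at least one numeric value")
    n = len(values)
    avg = sum(values) / n
    sd = math.sqrt(sum((x - avg) ** 2 for x in values) / n)
    cv = 100.0 * sd / avg if avg != 0 else None
    return StatSummary(avg, sd, n, cv)


def z_prime(pos: StatSummary, neg: StatSummary) -> MaybeFloat:
    """Z-factor of a positive/negative control pair."""
    sep = abs(pos.avg - neg.avg)
    if sep == 0:
        return Undefined("positive and negative control means are equal")
    return 1.0 - 3.0 * (pos.sd + neg.sd) / sep


def window(pos: StatSummary, neg: StatSummary) -> MaybeFloat:
    """Signal window: larger control mean over the smaller (symmetric)."""
    lo, hi = sorted((pos.avg, neg.avg))
    if lo == 0:
        return Undefined("smaller control mean is zero")
    return hi / lo


# ---------------------------------------------------------------------------
# Combinations
# ---------------------------------------------------------------------------

#: Resolves the display label of range item ``i`` of an area; signature
#: ``(area_name, item_index, first_well) -> str``.
NameResolver = Callable[[str, int, WellRef], str]


@dataclass(frozen=True)
class ComboComponent:
    """One layer's contribution to a combination key."""

    layer_id: int
    area: str
    item_index: Optional[int] = None
    item_label: Optional[str] = None
    concentration: Optional[tuple[float, str]] = None

    def label(self) -> str:
        text = self.item_label if self.item_label is not None else self.area
        if self.concentration is not None:
            value, unit = self.concentration
            text += f" @ {value:g} {unit}".rstrip()
        return text

    def _sort_key(self):
        conc = -self.concentration[0] if self.concentration else 0.0
        unit = self.concentration[1] if self.concentration else ""
        return (self.layer_id, self.area, self.item_index or 0, conc, unit)


ComboKey = tuple[ComboComponent, ...]


def combo_label(key: ComboKey) -> str:
    return " / ".join(c.label() for c in key)


def _combo_sort_key(key: ComboKey):
    return tuple(c._sort_key() for c in key)


def enumerate_combinations(
    layout: Layout, name_resolver: Optional[NameResolver] = None
) -> list[tuple[ComboKey, WellSelection]]:
    """Group tagged wells by their unique cross-layer tag tuple.

    Every well sharing the same (area, range item, concentration) tuple
    over all layers forms one combination; untagged wells contribute
    nothing and empty combinations never appear.  Output is canonically
    ordered: layers by id, areas lexically, range items by index,
    concentrations descending.
    """
    groups: dict[ComboKey, list[WellRef]] = {}
    first_well: dict[tuple[str, int], WellRef] = {}
    # pass 1: remember each range item's first well (lowest row-major index)
    for well in layout.geometry.iter_wells():
        for _, tag in layout.tags_at(well):
            if tag.range_index is not None:
                first_well.setdefault((tag.area, tag.range_index), well)

    def resolve(area: str, idx: int) -> str:
        well = first_well[(area, idx)]
        if name_resolver is not None:
            return name_resolver(area, idx, well)
        return f"{area} (#{idx})"

    for well in layout.geometry.iter_wells():
        comps = []
        for layer_id, tag in layout.tags_at(well):
            label = (
                resolve(tag.area, tag.range_index)
                if tag.range_index is not None
                else None
            )
            conc = (
                (tag.concentration.value, tag.concentration.unit)
                if tag.concentration is not None
                else None
            )
            comps.append(
                ComboComponent(layer_id, tag.area, tag.range_index, label, conc)
            )
        if comps:
            groups.setdefault(tuple(comps), []).append(well)
    return [
        (key, WellSelection(layout.geometry, tuple(wells)))
        for key, wells in sorted(groups.items(), key=lambda kv: _combo_sort_key(kv[0]))
    ]


# ---------------------------------------------------------------------------
# Controls analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ControlPairQC:
    pos: str
    neg: str
    z_prime: MaybeFloat
    window: MaybeFloat


@dataclass
class ControlsReport:
    """Per-plate control statistics, pairwise Z'/Window, cross-plate summary."""

    param: str
    plates: list
    positives: list[str]
    negatives: list[str]
    per_plate_stats: dict  # plate -> control name -> StatSummary | None
    pair_qc: dict  # plate -> (pos, neg) -> ControlPairQC
    summary: dict  # (pos, neg) -> {"z_prime": StatSummary|Undefined, "window": ...}

    def to_tables(self) -> dict[str, str]:
        """TSV tables keyed by archive path (one directory per tool)."""
        tables: dict[str, str] = {}
        controls = self.positives + self.negatives
        for plate in self.plates:
            stats = self.per_plate_stats[plate]
            rows = [
                [name]
                + [
                    getattr(stats[name], f) if stats[name] else None
                    for f in ("avg", "sd", "n")
                ]
                for name in controls
            ]
            tables[f"controls/plate_{plate}.tsv"] = table_to_tsv(
                ["Control", "Avg", "SD", "N"], rows
            )
            qc_rows = [
                [pos, neg, qc.z_prime, qc.window]
                for (pos, neg), qc in self.pair_qc[plate].items()
            ]
            tables[f"controls/plate_{plate}_zprime.tsv"] = table_to_tsv(
                ["Positive", "Negative", "Z'", "Window"], qc_rows
            )
        sum_rows = []
        for (pos, neg), stats in self.summary.items():
            for metric in ("z_prime", "window"):
                s = stats[metric]
                if isinstance(s, Undefined):
                    sum_rows.append([pos, neg, metric, None, None, 0])
                else:
                    sum_rows.append([pos, neg, metric, s.avg, s.sd, s.n])
        tables["controls/summary.tsv"] = table_to_tsv(
            ["Positive", "Negative", "Metric", "Avg", "SD", "N"], sum_rows
        )
        return tables


def _numeric(values: dict[WellRef, Any], wells) -> list[float]:
    out = []
    for w in wells:
        v = values.get(w)
        if isinstance(v, (int, float)) and not isinstance(v, bool):
            out.append(float(v))
    return out


def controls_report(
    layout: Layout,
    resultset: ResultSet,
    param: str,
    visited_plates: Optional[Sequence] = None,
) -> ControlsReport:
    """Aggregate control wells, compute Z'/Window for every positive x
    negative pair on each visited plate, and summarize across plates.

    Only wells tagged with a control contribute.  The cross-plate summary
    is the average/SD/N of the per-plate Z' and window values (defined
    values only)."""
    positives = sorted(
        a.name for a in layout.areas.values() if a.kind is AreaKind.POSITIVE_CONTROL
    )
    negatives = sorted(
        a.name for a in layout.areas.values() if a.kind is AreaKind.NEGATIVE_CONTROL
    )
    if not positives or not negatives:
        raise LayoutError(
            "controls analysis needs at least one positive and one negative control"
        )
    control_wells = {name: layout.wells_of_area(name) for name in positives + negatives}
    if any(not wells for wells in control_wells.values()):
        empty = [n for n, w in control_wells.items() if not w]
        raise LayoutError(f"control areas with no tagged wells: {', '.join(empty)}")

    plates = list(visited_plates) if visited_plates is not None else list(
        resultset.plate_keys
    )
    per_plate_stats: dict = {}
    pair_qc: dict = {}
    for plate in plates:
        values = fetch_plate_values(resultset, plate, param, layout.geometry)
        stats = {}
        for name, wells in control_wells.items():
            nums = _numeric(values, wells)
            stats[name] = stat_summary(nums) if nums else None
        per_plate_stats[plate] = stats
        pair_qc[plate] = {}
        for pos in positives:
            for neg in negatives:
                if stats[pos] is None or stats[neg] is None:
                    qc = ControlPairQC(
                        pos, neg,
                        Undefined("no numeric control values"),
                        Undefined("no numeric control values"),
                    )
                else:
                    qc = ControlPairQC(
                        pos, neg,
                        z_prime(stats[pos], stats[neg]),
                        window(stats[pos], stats[neg]),
                    )
                pair_qc[plate][(pos, neg)] = qc

    summary: dict = {}
    for pos in positives:
        for neg in negatives:
            entry = {}
            for metric in ("z_prime", "window"):
                vals = [
                    getattr(pair_qc[p][(pos, neg)], metric)
                    for p in plates
                ]
                defined = [v for v in vals if not isinstance(v, Undefined)]
                entry[metric] = (
                    stat_summary(defined)
                    if defined
                    else Undefined("undefined on every visited plate")
                )
            summary[(pos, neg)] = entry
    return ControlsReport(
        param, plates, positives, negatives, per_plate_stats, pair_qc, summary
    )


# ---------------------------------------------------------------------------
# Column analysis
# ---------------------------------------------------------------------------


def column_analysis(
    layout: Layout,
    resultset: ResultSet,
    param: str,
    plate_key=None,
    name_resolver: Optional[NameResolver] = None,
) -> list[tuple[ComboKey, StatSummary]]:
    """One statistics column per unique tag combination on one plate.

    Combinations without any numeric value are dropped.  Ordering is the
    canonical combination order."""
    if plate_key is None:
        if not resultset.plate_keys:
            raise MappingError("result file contains no plates")
        plate_key = resultset.plate_keys[0]
    values = fetch_plate_values(resultset, plate_key, param, layout.geometry)
    out = []
    for key, selection in enumerate_combinations(layout, name_resolver):
        nums = _numeric(values, selection)
        if nums:
            out.append((key, stat_summary(nums)))
    return out


def column_table(
    results: list[tuple[ComboKey, StatSummary]], show_cv: bool = False
) -> str:
    """TSV rendering of a column analysis (CV column only on request)."""
    header = ["Combination", "Avg", "SD", "N"] + (["CV"] if show_cv else [])
    rows = []
    for key, s in results:
        row = [combo_label(key), s.avg, s.sd, s.n]
        if show_cv:
            row.append(s.cv)
        rows.append(row)
    return table_to_tsv(header, rows)


# ---------------------------------------------------------------------------
# Grouped (two-entry) analysis
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dimension:
    """An axis of the two-entry table: a concentration series, the items
    of one range, or the set of areas on a layer (or any layer)."""

    kind: str  # "concentration" | "range" | "areas"
    area: Optional[str] = None
    layer_id: Optional[int] = None

    @classmethod
    def concentration(cls, layer_id: Optional[int] = None) -> "Dimension":
        return cls("concentration", layer_id=layer_id)

    @classmethod
    def range_items(cls, area: str) -> "Dimension":
        return cls("range", area=area)

    @classmethod
    def areas(cls, layer_id: Optional[int] = None) -> "Dimension":
        return cls("areas", layer_id=layer_id)

    def key_for(self, layout: Layout, well: WellRef):
        """Axis key of a well, or None when it has none."""
        tags = [
            (lid, tag)
            for lid, tag in layout.tags_at(well)
            if self.layer_id is None or lid == self.layer_id
        ]
        if self.kind == "concentration":
            for _, tag in tags:
                if tag.concentration is not None:
                    return (tag.concentration.value, tag.concentration.unit)
            return None
        if self.kind == "range":
            for _, tag in tags:
                if tag.area == self.area and tag.range_index is not None:
                    return tag.range_index
            return None
        if self.kind == "areas":
            for _, tag in tags:
                return tag.area
            return None
        raise LayoutError(f"unknown dimension kind {self.kind!r}")

    def sort_keys(self, keys):
        """Canonical axis order: concentrations descending (top dose
        first), range items by index, area names lexically."""
        if self.kind == "concentration":
            return sorted(keys, key=lambda k: (-k[0], k[1]))
        return sorted(keys)

    def label_key(self, key, layout: Layout,
                  name_resolver: Optional[NameResolver] = None) -> str:
        if self.kind == "concentration":
            return f"{key[0]:g} {key[1]}".rstrip()
        if self.kind == "range":
            if name_resolver is not None:
                wells = [
                    w
                    for layer in layout.layers
                    for w, t in layer.tags.items()
                    if t.area == self.area and t.range_index == key
                ]
                first = min(wells, key=layout.geometry.well_index)
                return name_resolver(self.area, key, first)
            return f"{self.area} (#{key})"
        return str(key)


@dataclass
class GroupedTable:
    """Double-entry aggregation; cells are StatSummary or None (empty)."""

    row_dim: Dimension
    col_dim: Dimension
    row_keys: list
    col_keys: list
    row_labels: list[str]
    col_labels: list[str]
    cells: dict  # (row_key, col_key) -> StatSummary | None
    agg_mode: str  # "average" | "full"

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.row_keys), len(self.col_keys))

    def cell(self, row_key, col_key) -> Optional[StatSummary]:
        return self.cells.get((row_key, col_key))

    def to_tsv(self) -> str:
        def fmt(s: Optional[StatSummary]):
            if s is None:
                return None
            if self.agg_mode == "average":
                return s.avg
            return f"{s.avg:.6g} ± {s.sd:.6g} (n={s.n})"

        rows = [
            [rl] + [fmt(self.cells.get((rk, ck))) for ck in self.col_keys]
            for rk, rl in zip(self.row_keys, self.row_labels)
        ]
        return table_to_tsv([""] + list(self.col_labels), rows)


def grouped_analysis(
    layout: Layout,
    resultset: ResultSet,
    param: str,
    row_dim: Dimension,
    col_dim: Dimension,
    agg_mode: str = "full",
    plate_key=None,
    name_resolver: Optional[NameResolver] = None,
) -> GroupedTable:
    """Aggregate one plate's values into a two-entry table.

    Cell (r, c) summarizes every numeric value whose well matches both
    axis keys; empty intersections stay empty.  ``agg_mode`` "average"
    renders only the mean, "full" the whole summary."""
    if row_dim == col_dim:
        raise LayoutError("row and column dimensions must differ")
    if agg_mode not in ("average", "full"):
        raise LayoutError(f"unknown aggregation mode {agg_mode!r}")
    if plate_key is None:
        if not resultset.plate_keys:
            raise MappingError("result file contains no plates")
        plate_key = resultset.plate_keys[0]
    values = fetch_plate_values(resultset, plate_key, param, layout.geometry)

    buckets: dict[tuple, list[float]] = {}
    row_seen, col_seen = set(), set()
    for well in layout.geometry.iter_wells():
        rk = row_dim.key_for(layout, well)
        ck = col_dim.key_for(layout, well)
        if rk is None or ck is None:
            continue
        row_seen.add(rk)
        col_seen.add(ck)
        v = values.get(well)
        if isinstance(v, (int, float)) and not isinstance(v, bool):
            buckets.setdefault((rk, ck), []).append(float(v))

    row_keys = row_dim.sort_keys(row_seen)
    col_keys = col_dim.sort_keys(col_seen)
    cells = {
        key: stat_summary(vals) if vals else None for key, vals in buckets.items()
    }
    return GroupedTable(
        row_dim,
        col_dim,
        row_keys,
        col_keys,
        [row_dim.label_key(k, layout, name_resolver) for k in row_keys],
        [col_dim.label_key(k, layout, name_resolver) for k in col_keys],
        cells,
        agg_mode,
    )
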