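"""Seeded synthetic fixtures for three canonical plate experiments.

Each generator writes a complete, analyzable file set (layout JSON,
result CSV and, where meaningful, a definition CSV) for one worked
example:

``screening``
    96-well primary screen on one layer: an 80-well single-replicate
    compound range (columns 2-11), a negative control column (solvent,
    column 1) and a positive control column (inhibitor, column 12).
    Multi-plate result file with a plate-name column; definition file
    pairable by plate name.  Control wells draw from normal
    distributions (negative mean 100, positive mean 10, SD 5 by
    default — a typical normalized viability scale); compound wells draw
    from the negative distribution except a seeded 5% hit fraction that
    behaves like the positive control.

``drc``
    96-well dose-response: one 10-replicate Horizontal/Row range holding
    6 compounds (rows A-F, columns 1-10), overlaid with a 10-dose
    2-fold serial dilution from a 20 uM top concentration (one dose per
    plate column).  Signals follow a saturation-binding response
    ``5 + 100*c/(c + EC50)`` with per-compound log-uniform EC50, plus
    normal noise — strictly decreasing along the dilution at zero noise.

``infection``
    96-well combination experiment on two layers: two cell types (rows
    A-D / E-H, layer 1) crossed with two virus strains (columns 1-6 /
    7-12, layer 2) at two multiplicities of infection (MOI 5 and 20,
    tagged on the virus layer), i.e. 8 unique conditions of 12 wells.
    Generated values have 8 distinct condition means (20..90 step 10).

All output is deterministic under a fixed seed (byte-identical files).
Returned objects carry the generator's ground truth so tests can check
parameter recovery.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ConfigError
from .layout_core import (
    AreaKind,
    Direction,
    Layout,
    Priority,
    RangeSpec,
    create_area,
    dose_series,
    tag_area,
    tag_concentration,
    tag_dose_response,
)
from .layout_io import write_layout
from .plate_model import (
    PlateGeometry,
    WellRef,
    select_block,
    select_cols,
    select_rows,
    union,
    well_name,
)


@dataclass
class FixtureSpec:
    """Parameters of a synthetic worked example."""

    example: str  # screening | drc | infection
    n_plates: int = 3
    seed: int = 1
    noise_sd: Optional[float] = None  # per-example default when None
    neg_mean: float = 100.0
    pos_mean: float = 10.0
    hit_rate: float = 0.05

    def __post_init__(self):
        if self.example not in ("screening", "drc", "infection"):
            raise ConfigError(f"unknown fixture example {self.example!r}")
        if self.n_plates < 1:
            raise ConfigError("n_plates must be >= 1")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


@dataclass
class FixtureFiles:
    """Paths of the generated files plus the generator's ground truth."""

    layout: Path
    results: Path
    definition: Optional[Path] = None
    truth: dict = field(default_factory=dict)


def _fmt(v: float) -> str:
    return f"{v:.4f}"


def _write_csv(path: Path, header: list[str], rows: list[list[str]]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(",".join(header) + "\n")
        for row in rows:
            fh.write(",".join(row) + "\n")


# ---------------------------------------------------------------------------
# Primary screening
# ---------------------------------------------------------------------------


def screening_layout() -> Layout:
    """Single-layer 96-well screening layout (range + neg + pos control)."""
    geometry = PlateGeometry.from_format(96)
    layout = Layout(geometry)
    create_area(layout, "Compounds", AreaKind.RANGE, color="blue")
    create_area(layout, "Solvent", AreaKind.NEGATIVE_CONTROL, color="green")
    create_area(layout, "Inhibitor", AreaKind.POSITIVE_CONTROL, color="red")
    tag_area(layout, 1, "Solvent", select_cols(geometry, [0]))
    tag_area(layout, 1, "Inhibitor", select_cols(geometry, [geometry.n_cols - 1]))
    tag_area(
        layout, 1, "Compounds",
        select_block(geometry, WellRef(0, 1), WellRef(7, 10)),
    )
    return layout


def make_screening_fixture(
    out_dir, spec: Optional[FixtureSpec] = None, **kwargs
) -> FixtureFiles:
    """Write layout + definition + multi-plate result files for a screen."""
    spec = spec or FixtureSpec("screening", **kwargs)
    noise_sd = 5.0 if spec.noise_sd is None else spec.noise_sd
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    layout = screening_layout()
    geometry = layout.geometry
    layout_path = out / "screening_layout.json"
    write_layout(layout, layout_path)

    range_wells = {
        w: tag.range_index
        for w, tag in layout.layers[0].tags.items()
        if tag.area == "Compounds"
    }
    neg_wells = set(layout.wells_of_area("Solvent"))
    pos_wells = set(layout.wells_of_area("Inhibitor"))
    n_items = max(range_wells.values())

    plates = [f"Plate_{p + 1}" for p in range(spec.n_plates)]
    defn_rows = []
    names: dict[tuple[str, int], str] = {}
    for p, plate in enumerate(plates):
        for i in range(1, n_items + 1):
            name = f"CMP-{p + 1:02d}-{i:03d}"
            names[(plate, i)] = name
            defn_rows.append([plate, name])
    defn_path = out / "screening_definitions.csv"
    _write_csv(defn_path, ["Plate", "Compound"], defn_rows)

    hits: dict[str, list[int]] = {}
    result_rows = []
    for plate in plates:
        is_hit = rng.random(n_items) < spec.hit_rate
        hits[plate] = [i + 1 for i in range(n_items) if is_hit[i]]
        for well in geometry.iter_wells():
            if well in neg_wells:
                mean = spec.neg_mean
            elif well in pos_wells:
                mean = spec.pos_mean
            elif well in range_wells:
                mean = (
                    spec.pos_mean
                    if is_hit[range_wells[well] - 1]
                    else spec.neg_mean
                )
            else:  # pragma: no cover - layout covers the whole plate
                continue
            value = rng.normal(mean, noise_sd) if noise_sd > 0 else mean
            result_rows.append([plate, well_name(geometry, well), _fmt(value)])
    results_path = out / "screening_results.csv"
    _write_csv(results_path, ["Plate", "Well", "Signal"], result_rows)
    return FixtureFiles(
        layout_path,
        results_path,
        defn_path,
        truth={
            "plates": plates,
            "neg_mean": spec.neg_mean,
            "pos_mean": spec.pos_mean,
            "noise_sd": noise_sd,
            "hits": hits,
            "names": names,
            "n_items": n_items,
        },
    )


# ---------------------------------------------------------------------------
# Dose-response
# ---------------------------------------------------------------------------

DRC_TOP = 20.0
DRC_N_DOSES = 10
DRC_FOLD = 2.0
DRC_UNIT = "uM"
DRC_N_COMPOUNDS = 6


def drc_layout() -> Layout:
    """96-well dose-response layout: 6 compounds x 10 doses (2-fold from
    20 uM), one compound per row, doses decreasing left to right."""
    geometry = PlateGeometry.from_format(96)
    layout = Layout(geometry)
    create_area(
        layout, "Compounds", AreaKind.RANGE, color="blue",
        range_spec=RangeSpec(replicates=DRC_N_DOSES),
    )
    block = select_block(
        geometry, WellRef(0, 0), WellRef(DRC_N_COMPOUNDS - 1, DRC_N_DOSES - 1)
    )
    tag_area(layout, 1, "Compounds", block)
    tag_dose_response(
        layout, 1, block, DRC_TOP, DRC_N_DOSES, DRC_FOLD, DRC_UNIT,
        ordering=RangeSpec(direction=Direction.VERTICAL, priority=Priority.COLUMN),
    )
    return layout


def make_drc_fixture(
    out_dir, spec: Optional[FixtureSpec] = None, **kwargs
) -> FixtureFiles:
    """Write layout + definition + result files for the dilution series."""
    spec = spec or FixtureSpec("drc", **kwargs)
    noise_sd = 2.0 if spec.noise_sd is None else spec.noise_sd
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    layout = drc_layout()
    geometry = layout.geometry
    layout_path = out / "drc_layout.json"
    write_layout(layout, layout_path)

    names = [f"Compound_{chr(ord('A') + i)}" for i in range(DRC_N_COMPOUNDS)]
    defn_path = out / "drc_definitions.csv"
    _write_csv(defn_path, ["Name"], [[n] for n in names])

    ec50 = 10 ** rng.uniform(np.log10(0.05), np.log10(5.0), DRC_N_COMPOUNDS)
    doses = dose_series(DRC_TOP, DRC_N_DOSES, DRC_FOLD)
    result_rows = []
    for well in geometry.iter_wells():
        tag = layout.layers[0].tags.get(well)
        if tag is None:
            continue
        compound = tag.range_index - 1
        c = tag.concentration.value
        mean = 5.0 + 100.0 * c / (c + ec50[compound])
        value = rng.normal(mean, noise_sd) if noise_sd > 0 else mean
        result_rows.append([well_name(geometry, well), _fmt(value)])
    results_path = out / "drc_results.csv"
    _write_csv(results_path, ["Well", "Signal"], result_rows)
    return FixtureFiles(
        layout_path,
        results_path,
        defn_path,
        truth={
            "names": names,
            "ec50": ec50.tolist(),
            "doses": doses,
            "noise_sd": noise_sd,
        },
    )


# ---------------------------------------------------------------------------
# Infection combinations
# ---------------------------------------------------------------------------


def infection_layout() -> Layout:
    """Two-layer 96-well combination layout: 2 cells x 2 viruses x 2 MOIs."""
    geometry = PlateGeometry.from_format(96)
    layout = Layout(geometry)
    layout.add_layer()
    create_area(layout, "CellA", AreaKind.SAMPLE, color="blue")
    create_area(layout, "CellB", AreaKind.SAMPLE, color="green")
    create_area(layout, "VirusA", AreaKind.SAMPLE, color="pink")
    create_area(layout, "VirusB", AreaKind.SAMPLE, color="purple")
    tag_area(layout, 1, "CellA", select_rows(geometry, [0, 1, 2, 3]))
    tag_area(layout, 1, "CellB", select_rows(geometry, [4, 5, 6, 7]))
    tag_area(layout, 2, "VirusA", select_cols(geometry, [0, 1, 2, 3, 4, 5]))
    tag_area(layout, 2, "VirusB", select_cols(geometry, [6, 7, 8, 9, 10, 11]))
    moi5 = union(select_cols(geometry, [0, 1, 2]), select_cols(geometry, [6, 7, 8]))
    moi20 = union(select_cols(geometry, [3, 4, 5]), select_cols(geometry, [9, 10, 11]))
    tag_concentration(layout, 2, moi5, 5.0, "MOI")
    tag_concentration(layout, 2, moi20, 20.0, "MOI")
    return layout


def make_infection_fixture(
    out_dir, spec: Optional[FixtureSpec] = None, **kwargs
) -> FixtureFiles:
    """Write layout + result files for the 8-condition infection example."""
    spec = spec or FixtureSpec("infection", **kwargs)
    noise_sd = 3.0 if spec.noise_sd is None else spec.noise_sd
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    layout = infection_layout()
    geometry = layout.geometry
    layout_path = out / "infection_layout.json"
    write_layout(layout, layout_path)

    means: dict[tuple[str, str, float], float] = {}
    level = 20.0
    for cell in ("CellA", "CellB"):
        for virus in ("VirusA", "VirusB"):
            for moi in (5.0, 20.0):
                means[(cell, virus, moi)] = level
                level += 10.0

    result_rows = []
    for well in geometry.iter_wells():
        cell_tag = layout.layers[0].tags[well]
        virus_tag = layout.layers[1].tags[well]
        mean = means[(cell_tag.area, virus_tag.area, virus_tag.concentration.value)]
        value = rng.normal(mean, noise_sd) if noise_sd > 0 else mean
        result_rows.append([well_name(geometry, well), _fmt(value)])
    results_path = out / "infection_results.csv"
    _write_csv(results_path, ["Well", "Infection"], result_rows)
    return FixtureFiles(
        layout_path,
        results_path,
        truth={"means": {f"{c}/{v}/{m:g}": mu for (c, v, m), mu in means.items()},
               "noise_sd": noise_sd,
               "wells_per_condition": geometry.n_wells // len(means)},
    )


def make_fixture(spec: FixtureSpec, out_dir) -> FixtureFiles:
    """Dispatch on ``spec.example``."""
    maker = {
        "screening": make_screening_fixture,
        "drc": make_drc_fixture,
        "infection": make_infection_fixture,
    }[spec.example]
    return maker(out_dir, spec)
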