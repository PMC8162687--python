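"""Heatmap normalization, three-color mapping and the named-color palette.

Values are first normalized to ``t in [0, 1]`` against a (min, max)
domain taken across all plates (default), the current plate only, or a
user-fixed custom pair; ``t`` is then mapped through a piecewise-linear
low -> mid -> high color ramp.  The palette of selectable colors is the
CSS3 extended named-color list with spelling aliases collapsed, leaving
138 uniquely-valued entries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any, Mapping, Optional

from .errors import ConfigError, PlateKitError
from .plate_model import PlateGeometry, WellRef

RGB = tuple[int, int, int]


# ---------------------------------------------------------------------------
# Palette
# ---------------------------------------------------------------------------


def _css3_named_colors() -> list[tuple[str, RGB]]:
    from matplotlib import colors as mcolors

    entries: dict[str, RGB] = {}
    for name, hexval in mcolors.CSS4_COLORS.items():
        if name == "rebeccapurple":  # CSS4 addition, not in the CSS3 list
            continue
        r, g, b = mcolors.to_rgb(hexval)
        entries[name] = (round(r * 255), round(g * 255), round(b * 255))
    # collapse alias spellings (gray/grey, aqua/cyan, ...): keep the
    # alphabetically first name per RGB value; stable alphabetical order
    seen: dict[RGB, str] = {}
    out: list[tuple[str, RGB]] = []
    for name in sorted(entries):
        rgb = entries[name]
        if rgb not in seen:
            seen[rgb] = name
            out.append((name, rgb))
    return out


@dataclass(frozen=True)
class NamedColor:
    name: str
    rgb: RGB

    @property
    def hex(self) -> str:
        return "#{:02x}{:02x}{:02x}".format(*self.rgb)


_PALETTE: Optional[list[NamedColor]] = None


def palette() -> list[NamedColor]:
    """The 138 uniquely-valued named colors, in stable alphabetical order."""
    global _PALETTE
    if _PALETTE is None:
        _PALETTE = [NamedColor(n, rgb) for n, rgb in _css3_named_colors()]
    return list(_PALETTE)


def color_by_name(name: str) -> NamedColor:
    for c in palette():
        if c.name == name.lower():
            return c
    raise ConfigError(f"unknown palette color {name!r}")


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NormalizationConfig:
    """How raw values map onto the [0, 1] color scale.

    ``all_plates`` (default) uses the min/max found across every available
    plate, ``current_plate`` only the displayed plate, ``custom`` a fixed
    user-entered pair."""

    mode: str = "all_plates"  # all_plates | current_plate | custom
    min: Optional[float] = None
    max: Optional[float] = None

    def __post_init__(self):
        if self.mode not in ("all_plates", "current_plate", "custom"):
            raise ConfigError(f"unknown normalization mode {self.mode!r}")
        if self.mode == "custom":
            if self.min is None or self.max is None or not self.min < self.max:
                raise ConfigError("custom normalization requires min < max")


def _numeric_values(plate_values: Mapping[WellRef, Any]) -> list[float]:
    return [
        float(v)
        for v in plate_values.values()
        if isinstance(v, (int, float)) and not isinstance(v, bool)
    ]


def normalize(
    values_by_plate: Mapping[Any, Mapping[WellRef, Any]],
    config: NormalizationConfig,
    plate_key,
) -> dict[WellRef, float]:
    """Normalized ``t`` per well of one plate.

    Values outside the domain clamp to 0/1; a constant domain maps every
    well to 0.5 (uniform mid color rather than a division by zero).
    Non-numeric wells are missing from the output."""
    if plate_key not in values_by_plate:
        raise ConfigError(f"unknown plate key {plate_key!r}")
    if config.mode == "custom":
        vmin, vmax = float(config.min), float(config.max)
    else:
        if config.mode == "all_plates":
            pool = [v for pv in values_by_plate.values() for v in _numeric_values(pv)]
        else:
            pool = _numeric_values(values_by_plate[plate_key])
        if not pool:
            raise PlateKitError("no numeric values in the normalization domain")
        vmin, vmax = min(pool), max(pool)
    out: dict[WellRef, float] = {}
    for well, v in values_by_plate[plate_key].items():
        if not isinstance(v, (int, float)) or isinstance(v, bool):
            continue
        if vmax == vmin:
            out[well] = 0.5
        else:
            t = (float(v) - vmin) / (vmax - vmin)
            out[well] = min(1.0, max(0.0, t))
    return out


# ---------------------------------------------------------------------------
# Color mapping
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ColorScale:
    """Three-color ramp low -> mid -> high."""

    low: RGB = (0, 0, 255)  # blue
    mid: RGB = (255, 255, 255)  # white
    high: RGB = (255, 0, 0)  # red

    @classmethod
    def from_names(cls, low: str, mid: str, high: str) -> "ColorScale":
        return cls(
            color_by_name(low).rgb, color_by_name(mid).rgb, color_by_name(high).rgb
        )


def _round_half_up(x: float) -> int:
    import math

    return int(math.floor(x + 0.5))


def map_color(t: float, scale: ColorScale = ColorScale()) -> RGB:
    """Piecewise-linear interpolation: low->mid on [0, 0.5], mid->high on
    [0.5, 1], per channel, round-half-up to 8-bit."""
    if not 0.0 <= t <= 1.0:
        raise ConfigError(f"normalized value {t} outside [0, 1]")
    if t <= 0.5:
        a, b, u = scale.low, scale.mid, t / 0.5
    else:
        a, b, u = scale.mid, scale.high, (t - 0.5) / 0.5
    return tuple(_round_half_up(a[i] + (b[i] - a[i]) * u) for i in range(3))


def rgb_to_hex(rgb: RGB) -> str:
    return "#{:02x}{:02x}{:02x}".format(*rgb)


def heatmap_hex_grid(
    geometry: PlateGeometry,
    tmap: Mapping[WellRef, float],
    scale: ColorScale = ColorScale(),
    missing: str = "",
) -> list[list[str]]:
    """Per-well hex colors as a rows x cols grid (missing wells blank)."""
    return [
        [
            rgb_to_hex(map_color(tmap[WellRef(r, c)], scale))
            if WellRef(r, c) in tmap
            else missing
            for c in range(geometry.n_cols)
        ]
        for r in range(geometry.n_rows)
    ]


def heatmap_to_tsv(
    geometry: PlateGeometry,
    tmap: Mapping[WellRef, float],
    scale: ColorScale = ColorScale(),
) -> str:
    """Bit-exact TSV export of a plate heatmap (hex color per well)."""
    from .layout_io import table_to_tsv
    from .plate_model import row_label

    grid = heatmap_hex_grid(geometry, tmap, scale)
    header = [""] + [str(c + 1) for c in range(geometry.n_cols)]
    rows = [[row_label(r)] + grid[r] for r in range(geometry.n_rows)]
    return table_to_tsv(header, rows)


def render_heatmap_png(
    geometry: PlateGeometry,
    tmap: Mapping[WellRef, float],
    path,
    scale: ColorScale = ColorScale(),
) -> None:
    """Optional raster rendering of a plate heatmap via matplotlib."""
    import numpy as np
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = np.ones((geometry.n_rows, geometry.n_cols, 3))
    for well, t in tmap.items():
        img[well.row, well.col] = [c / 255 for c in map_color(t, scale)]
    fig, ax = plt.subplots(figsize=(geometry.n_cols / 2, geometry.n_rows / 2))
    ax.imshow(img, interpolation="nearest")
    ax.set_xticks(range(geometry.n_cols), [str(c + 1) for c in range(geometry.n_cols)])
    from .plate_model import row_label

    ax.set_yticks(range(geometry.n_rows), [row_label(r) for r in range(geometry.n_rows)])
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
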